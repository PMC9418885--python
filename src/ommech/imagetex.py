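"""Quantification of AFM topographies.

Flattening removes per-scanline polynomial backgrounds and a global plane.
Because supported-bilayer images contain several height plateaus, a naive
per-row fit latches onto whichever phase dominates each row and shears the
image; instead the leveling iterates: rough global leveling, a quick
multi-level height model (histogram peaks), then per-row fits on the
*residual* heights (observed minus modelled plateau), which uses every
pixel of every row without mixing plateaus. The substrate reference is the
lowest significant histogram peak, shifted to 0 nm.

Segmentation assigns level classes by multi-Otsu thresholds (deterministic
default), marks "rough" pixels by local height variance against the smooth-
phase variance, and protruding connected components as bumps. Texture
periodicity uses a Hann-windowed 2D power spectrum; vesicles are sized by
the equal-area disc diameter of each connected component at half its
maximal height — the same convention the synthetic generator uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates, uniform_filter
from scipy.signal import find_peaks
from skimage.filters import threshold_multiotsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk, opening

from .datatypes import CLASS_ORDER, LIPID_CLASSES, HeightMap, SegmentLabelMap

# --------------------------------------------------------------------------
# Histogram level model
# --------------------------------------------------------------------------


def _histogram_levels(h: np.ndarray, bin_nm: float = 0.05,
                      min_frac: float = 0.02, smooth_bins: int = 5):
    """Detect plateau levels as significant peaks of the height histogram.

    Returns an array of level heights (ascending). A featureless map yields
    a single level at its median.
    """
    lo, hi = np.percentile(h, [0.1, 99.9])
    if hi - lo < bin_nm * 4:
        return np.array([float(np.median(h))])
    edges = np.arange(lo, hi + bin_nm, bin_nm)
    counts, _ = np.histogram(h, bins=edges)
    smoothed = gaussian_filter1d(counts.astype(float), smooth_bins, mode="nearest")
    peaks, _ = find_peaks(smoothed, height=max(min_frac * smoothed.max(), 1.0),
                          distance=max(int(0.3 / bin_nm), 1))
    if len(peaks) == 0:
        return np.array([float(np.median(h))])
    centers = (edges[:-1] + edges[1:]) / 2.0
    return np.sort(centers[peaks])


def _assign_levels(h: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Nearest-level assignment (index array)."""
    if len(levels) == 1:
        return np.zeros(h.shape, dtype=np.int16)
    return np.argmin(np.abs(h[..., None] - levels[None, None, :]), axis=-1).astype(np.int16)


# --------------------------------------------------------------------------
# Flattening
# --------------------------------------------------------------------------


def _polyfit_rows(resid: np.ndarray, valid: np.ndarray, order: int):
    """Least-squares per-row polynomial fit of residuals on valid pixels.

    Rows with too few valid pixels are fitted on all their pixels (with a
    warning), matching what an operator would accept for a fully-masked line.
    """
    ny, nx = resid.shape
    x = np.linspace(-1.0, 1.0, nx)
    V = np.vander(x, order + 1, increasing=True)
    fit = np.zeros_like(resid)
    n_fallback = 0
    for i in range(ny):
        m = valid[i]
        if m.sum() < max(order + 2, 8):
            m = np.ones(nx, dtype=bool)
            n_fallback += 1
        coef, *_ = np.linalg.lstsq(V[m], resid[i, m], rcond=None)
        fit[i] = V @ coef
    if n_fallback:
        warnings.warn(f"{n_fallback} scan line(s) had a fully-excluded mask; "
                      "fitted on all pixels", stacklevel=3)
    return fit


def _fit_plane(h: np.ndarray, valid: np.ndarray) -> np.ndarray:
    ny, nx = h.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    A = np.column_stack([np.ones(valid.sum()), xx[valid], yy[valid]])
    coef, *_ = np.linalg.lstsq(A, h[valid], rcond=None)
    return coef[0] + coef[1] * xx + coef[2] * yy


def flatten_map(hm: HeightMap, order: int = 1,
                exclude: Optional[np.ndarray] = None,
                max_iterations: int = 25, tol: float = 1e-9) -> HeightMap:
    """Remove per-scanline polynomial backgrounds and the global plane.

    ``order`` (0, 1 or 2) is the per-row polynomial order; ``exclude`` marks
    pixels (features) to leave out of all fits. The correction is iterated to
    a fixed point: level the map, rebuild the multi-plateau height model,
    refit the rows on the residual heights (observed minus modelled plateau,
    so multi-phase rows use all their pixels without shearing), until the
    increment vanishes. After leveling, the lowest significant histogram
    peak (the substrate, when present) is shifted to 0 nm.
    """
    if order not in (0, 1, 2):
        raise ValueError("flatten order must be 0, 1 or 2")
    h = hm.heights.astype(float)
    include = ~exclude if exclude is not None else np.ones(h.shape, dtype=bool)

    correction = np.zeros_like(h)
    for _ in range(max_iterations):
        w = h - correction
        levels = _histogram_levels(w[include])
        assign = _assign_levels(w, levels)
        # refine levels continuously (medians of the assigned pixels) so the
        # model is independent of histogram binning
        for li in range(len(levels)):
            sel = include & (assign == li)
            if sel.any():
                levels[li] = np.median(w[sel])
        model = levels[assign]
        resid = w - model
        # sigma-clip pixels far from any plateau (rough domains, vesicles)
        sd = max(float(np.median(np.abs(resid[include]))) * 1.4826, 1e-6)
        valid = include & (np.abs(resid) < 3.0 * sd)
        increment = _polyfit_rows(resid, valid, order)
        increment = increment + _fit_plane(resid - increment, valid)
        correction = correction + increment
        if float(np.sqrt(np.mean(increment ** 2))) < tol:
            break

    flat = h - correction
    # substrate reference: median of the pixels belonging to the lowest
    # histogram peak (set selection by the inter-peak midpoint keeps a second
    # application an exact no-op)
    levels = _histogram_levels(flat[include])
    cut = 0.5 * (levels[0] + levels[1]) if len(levels) > 1 else np.inf
    lowest = flat[include & (flat < cut)]
    flat = flat - float(np.median(lowest if lowest.size else flat[include]))

    meta = dict(hm.metadata)
    meta.update(flattened=True, flatten_order=order)
    return HeightMap(heights=flat, pixel_size=hm.pixel_size, metadata=meta)


# --------------------------------------------------------------------------
# Segmentation
# --------------------------------------------------------------------------

#: Height below which the lowest class is interpreted as bare substrate.
SUBSTRATE_MAX_HEIGHT = 1.5  # nm
#: Single-class naming boundary between fluid- and solid-like plateaus.
FLUID_SOLID_BOUNDARY = 4.5  # nm


def segment_heights(
    hm: HeightMap,
    n_classes="auto",
    *,
    rough_detection: bool = True,
    rough_factor: float = 3.0,
    rough_window: int = 5,
    bump_margin: float = 1.5,
) -> SegmentLabelMap:
    """Classify each pixel of a flattened map into phase classes.

    Level classes come from multi-Otsu thresholds (``n_classes='auto'``
    chooses the histogram-peak count, capped at 4). Within lipid regions,
    pixels whose local height variance exceeds ``rough_factor`` times the
    smooth-phase variance are relabelled "rough"; connected components
    protruding more than ``bump_margin`` above the top plateau become
    "bump".
    """
    h = hm.heights
    if n_classes == "auto":
        k = int(min(len(_histogram_levels(h)), 4))
    else:
        k = int(n_classes)
        if k < 1:
            raise ValueError("n_classes must be >= 1")
    if k == 1 or np.ptp(h) < 1e-9:
        if n_classes != "auto" and k > 1:
            warnings.warn("degenerate height histogram: single class", stacklevel=2)
        k = 1
        codes = np.zeros(h.shape, dtype=np.int16)
        thresholds = []
    else:
        thresholds = list(threshold_multiotsu(h, classes=k))
        codes = np.digitize(h, thresholds).astype(np.int16)

    level_heights = [float(np.median(h[codes == c])) for c in range(k)]

    # name the level classes
    names = []
    lipid_levels = [lh for lh in level_heights]
    if k >= 2 and level_heights[0] < SUBSTRATE_MAX_HEIGHT:
        names.append("substrate")
        lipid_levels = level_heights[1:]
    elif k == 1 and level_heights[0] < SUBSTRATE_MAX_HEIGHT:
        names.append("substrate")
        lipid_levels = []
    if len(lipid_levels) == 1:
        names.append("fluid" if lipid_levels[0] <= FLUID_SOLID_BOUNDARY else "solid")
    elif len(lipid_levels) >= 2:
        # lowest lipid level is fluid, the rest merge into solid naming
        names.append("fluid")
        names.extend(["solid"] * (len(lipid_levels) - 1))

    # remap to canonical codes: build final class list
    class_names = []
    final = np.zeros(h.shape, dtype=np.int16)
    name_of_code = {}
    for c in range(k):
        nm = names[c]
        if nm not in class_names:
            class_names.append(nm)
        name_of_code[c] = class_names.index(nm)
    for c in range(k):
        final[codes == c] = name_of_code[c]

    class_heights = {}
    for i, nm in enumerate(class_names):
        sel = final == i
        if sel.any():
            class_heights[nm] = float(np.median(h[sel]))

    lipid_mask = np.isin(final, [i for i, nm in enumerate(class_names)
                                 if nm in LIPID_CLASSES])

    # --- rough domains: local variance against the smooth-phase variance ---
    if rough_detection and lipid_mask.any() and k >= 2:
        local_mean = uniform_filter(h, rough_window)
        local_var = uniform_filter(h * h, rough_window) - local_mean ** 2
        # erode the lipid mask so substrate edges do not masquerade as texture
        interior = uniform_filter(lipid_mask.astype(float), rough_window) > 0.999
        # lower quartile so the estimate stays on the smooth phase even when
        # rough domains cover a large share of the lipid area
        smooth_var = float(np.percentile(local_var[interior], 25)) if interior.any() else 0.0
        rough = interior & (local_var > rough_factor * max(smooth_var, 1e-12))
        # plateau steps leave thin high-variance ribbons (about one window
        # wide); opening removes them while true rough domains survive
        rough = opening(rough, disk(rough_window // 2 + 1))
        if rough.any():
            if "rough" not in class_names:
                class_names.append("rough")
            final[rough] = class_names.index("rough")
            class_heights["rough"] = float(np.median(h[rough]))
            lipid_mask |= rough

    # --- bumps: components protruding above the top plateau ---
    top = max([class_heights[nm] for nm in class_names if nm in ("fluid", "solid")],
              default=0.0)
    protrusion = h > top + bump_margin
    if protrusion.any() and lipid_mask.any():
        comp = cc_label(protrusion)
        if comp.max() > 0:
            if "bump" not in class_names:
                class_names.append("bump")
            final[protrusion] = class_names.index("bump")
            class_heights["bump"] = float(np.median(h[protrusion]))

    return SegmentLabelMap(labels=final, class_names=class_names,
                           class_heights=class_heights)


def coverage_fractions(labels: SegmentLabelMap, denominator: str = "lipid") -> dict:
    """Pixel-count coverage fractions per class.

    ``denominator='lipid'`` reports fractions of the lipid-covered area
    (excluding substrate); ``'total'`` uses all pixels. Raises when the
    lipid denominator is empty.
    """
    if denominator not in ("lipid", "total"):
        raise ValueError("denominator must be 'lipid' or 'total'")
    counts = {nm: int((labels.labels == i).sum())
              for i, nm in enumerate(labels.class_names)}
    if denominator == "total":
        denom = labels.labels.size
        classes = list(labels.class_names)
    else:
        classes = [nm for nm in labels.class_names if nm in LIPID_CLASSES or nm == "vesicle"]
        denom = sum(counts.get(nm, 0) for nm in classes)
        if denom == 0:
            raise ValueError("no lipid-covered pixels: lipid coverage undefined")
    return {nm: counts.get(nm, 0) / denom for nm in classes}


# --------------------------------------------------------------------------
# Roughness and profiles
# --------------------------------------------------------------------------


def roughness_rq(hm: HeightMap, mask: Optional[np.ndarray] = None) -> float:
    """Root-mean-square roughness about the mean over ``mask`` (nm)."""
    h = hm.heights if mask is None else hm.heights[mask]
    if h.size < 100:
        raise ValueError("roughness mask must contain at least 100 pixels")
    return float(np.sqrt(np.mean((h - h.mean()) ** 2)))


def extract_profile(hm: HeightMap, start, end, n_points: Optional[int] = None):
    """Bilinear height profile along a segment.

    ``start``/``end`` are (x, y) positions in nm (x along columns, y along
    rows, origin at the top-left pixel centre). Returns ``(distance_nm,
    height_nm)`` arrays.
    """
    (x0, y0), (x1, y1) = start, end
    px = hm.pixel_size
    length = float(np.hypot(x1 - x0, y1 - y0))
    if length <= 0:
        raise ValueError("profile endpoints must be distinct")
    ny, nx = hm.shape
    for x, y in (start, end):
        if not (0 <= x <= (nx - 1) * px and 0 <= y <= (ny - 1) * px):
            raise ValueError("profile endpoints must lie inside the map")
    if n_points is None:
        n_points = max(int(np.ceil(length / px)) + 1, 2)
    t = np.linspace(0.0, 1.0, n_points)
    cols = (x0 + t * (x1 - x0)) / px
    rows = (y0 + t * (y1 - y0)) / px
    heights = map_coordinates(hm.heights, [rows, cols], order=1, mode="nearest")
    return t * length, heights


# --------------------------------------------------------------------------
# Stripe periodicity
# --------------------------------------------------------------------------


@dataclass
class TextureSpectrum:
    """Radially resolvable 2D texture spectrum summary."""

    wavelength: np.ndarray  # nm, per evaluated bin (peak neighbourhood)
    power: np.ndarray
    dominant_wavelength: Optional[float]  # nm; None when no periodicity
    dominant_amplitude: Optional[float]  # nm
    orientation: Optional[float] = None  # rad
    peak_to_floor: float = 0.0
    periodic: bool = False
    extras: dict = field(default_factory=dict)


def stripe_period(
    hm: HeightMap,
    mask: Optional[np.ndarray] = None,
    *,
    peak_factor: float = 30.0,
    max_wavelength_frac: float = 0.25,
) -> TextureSpectrum:
    """Dominant stripe wavelength and amplitude of a (masked) region.

    The masked region is detrended (plane), Hann-windowed and Fourier
    transformed; the dominant wavelength is the highest-power bin outside
    the low-frequency disc (wavelengths above ``max_wavelength_frac`` of the
    image side are treated as background). When the peak does not exceed
    ``peak_factor`` times the median spectral power, the result reports "no
    periodicity" rather than an error.
    """
    h = hm.heights.astype(float)
    ny, nx = h.shape
    m = np.ones_like(h) if mask is None else mask.astype(float)
    if m.sum() < 16:
        raise ValueError("mask too small for spectral analysis")

    plane = _fit_plane(h, m > 0)
    det = (h - plane) * m * np.outer(np.hanning(ny), np.hanning(nx))

    F = np.fft.rfft2(det)
    P = np.abs(F) ** 2
    fy = np.fft.fftfreq(ny, d=hm.pixel_size)
    fx = np.fft.rfftfreq(nx, d=hm.pixel_size)
    fmag = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)

    side_nm = min(ny, nx) * hm.pixel_size
    valid = fmag > 1.0 / (max_wavelength_frac * side_nm)
    if not valid.any():
        raise ValueError("map too small to resolve any wavelength")
    Pv = np.where(valid, P, 0.0)
    floor = float(np.median(P[valid]))
    peak_idx = np.unravel_index(int(np.argmax(Pv)), P.shape)
    peak_power = float(P[peak_idx])
    ratio = peak_power / max(floor, 1e-300)

    iy, ix = peak_idx
    wavelength = 1.0 / fmag[iy, ix]
    orientation = float(np.arctan2(fy[iy], fx[ix]))

    # Parseval bookkeeping: amplitude of the equivalent full-frame sinusoid.
    ny_lo, ny_hi = max(iy - 1, 0), min(iy + 2, P.shape[0])
    nx_lo, nx_hi = max(ix - 1, 0), min(ix + 2, P.shape[1])
    # the rfft half-spectrum holds one of the two conjugate peaks, whose
    # energy is (A^2/4) * n_pix * sum(w^2)
    neighbourhood = P[ny_lo:ny_hi, nx_lo:nx_hi].sum()
    n_pix = ny * nx
    wsq = float(np.sum(np.outer(np.hanning(ny), np.hanning(nx)) ** 2))
    amplitude = 2.0 * np.sqrt(neighbourhood / (n_pix * wsq))

    periodic = ratio >= peak_factor
    wl_band = 1.0 / np.maximum(fmag[ny_lo:ny_hi, nx_lo:nx_hi].ravel(), 1e-12)
    return TextureSpectrum(
        wavelength=wl_band,
        power=P[ny_lo:ny_hi, nx_lo:nx_hi].ravel(),
        dominant_wavelength=float(wavelength) if periodic else None,
        dominant_amplitude=float(amplitude) if periodic else None,
        orientation=orientation if periodic else None,
        peak_to_floor=float(ratio),
        periodic=bool(periodic),
        extras={"frequency_bin_nm": float(wavelength ** 2 / side_nm)},
    )


# --------------------------------------------------------------------------
# Vesicle detection
# --------------------------------------------------------------------------


def detect_vesicles(
    hm: HeightMap,
    min_height: float = 1.0,
    min_area_px: int = 4,
    exclude_border: bool = True,
) -> list:
    """Detect protruding caps and size them at half-maximal height.

    Each connected component above ``min_height`` yields one detection with
    ``diameter`` = equal-area disc diameter of the pixels at or above half
    the component's maximal height. Returns a (possibly empty) list of
    ``{"center_nm", "diameter", "max_height"}``.
    """
    h = hm.heights
    above = h > min_height
    comp = cc_label(above)
    out = []
    ny, nx = h.shape
    for region in regionprops(comp, intensity_image=h):
        if region.area < min_area_px:
            continue
        if exclude_border:
            minr, minc, maxr, maxc = region.bbox
            if minr == 0 or minc == 0 or maxr == ny or maxc == nx:
                continue
        hmax = float(region.intensity_max)
        sl = region.slice
        in_region = comp[sl] == region.label
        area_half = int(np.sum(in_region & (h[sl] >= hmax / 2.0)))
        if area_half == 0:
            continue
        diameter = 2.0 * np.sqrt(area_half * hm.pixel_size ** 2 / np.pi)
        cy, cx = region.centroid
        out.append({
            "center_nm": (cx * hm.pixel_size, cy * hm.pixel_size),
            "diameter": float(diameter),
            "max_height": hmax,
            "area_px": int(region.area),
        })
    return out


def vesicle_summary(detections: list) -> dict:
    d = np.array([v["diameter"] for v in detections], dtype=float)
    return {
        "count": len(detections),
        "mean_diameter": float(d.mean()) if len(d) else np.nan,
        "sd_diameter": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
    }
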