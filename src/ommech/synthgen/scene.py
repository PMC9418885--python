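"""Synthetic AFM topographies with per-pixel ground-truth labels.

A scene is built from (i) a smoothed Gaussian random field thresholded at
exact pixel quantiles, which yields blobby, nested phase domains with pixel-
exact coverages (substrate outside, fluid rim, solid interior, rough LPS
domains innermost — mirroring how the real patches organise); (ii) flat
plateaus at the declared phase heights plus independent Gaussian texture per
class; (iii) optional sinusoidal stripes and spherical-cap vesicles; and
(iv) instrument artifacts: a global background plane and per-scanline linear
tilt/offset errors.

Vesicle caps share a sizing convention with the detector: the drawn
"diameter" is the equal-area disc diameter of the cap contour at half its
maximal height, with cap height = ``cap_aspect`` times that diameter; the
cap footprint radius realising this is derived in closed form in
``_cap_footprint_radius``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from ..datatypes import HeightMap
from .presets import SceneSpec
from .seeds import TAG_IMAGE, child_rng

#: Class stacking order used for quantile nesting (low field value -> low class).
NESTING_ORDER = ("fluid", "solid", "rough")


@dataclass
class SceneTruth:
    """Ground truth emitted alongside a generated height map."""

    scene: str
    seed: int
    counter: int
    class_names: list
    labels: np.ndarray  # int codes into class_names
    coverages_total: dict  # class -> fraction of all pixels
    coverages_lipid: dict  # class -> fraction of lipid-covered pixels
    clean_heights: np.ndarray  # heights before scan-line / plane artifacts
    vesicles: list = field(default_factory=list)  # dicts: x_nm, y_nm, diameter, height
    stripe: dict | None = None
    scanline_offsets: np.ndarray | None = None
    scanline_tilts: np.ndarray | None = None
    plane: tuple = (0.0, 0.0)


def _cap_footprint_radius(diameter: float, aspect: float) -> float:
    """Footprint radius of a spherical cap whose half-max equal-area
    diameter equals ``diameter`` at cap height = aspect * diameter.

    For a cap of footprint radius a and height h (sphere radius
    R = (a^2+h^2)/(2h)), the half-max contour radius obeys
    r_half^2 = a^2/2 + h^2/4; solving r_half = d/2 with h = aspect*d gives
    a^2 = d^2 * (1/2 - aspect^2/2) ... explicitly a^2/2 = d^2/4 - (aspect*d)^2/4.
    """
    h = aspect * diameter
    a_sq = 2.0 * (diameter ** 2 / 4.0 - h ** 2 / 4.0)
    return float(np.sqrt(a_sq))


def cap_half_max_diameter(footprint_radius: float, height: float) -> float:
    """Inverse convention check: half-max equal-area diameter of a cap."""
    a, h = footprint_radius, height
    r_half_sq = a ** 2 / 2.0 + h ** 2 / 4.0
    return 2.0 * float(np.sqrt(r_half_sq))


def _draw_diameter(rng: np.random.Generator, ves) -> float:
    """Lognormal diameter with the requested mean/sd, floored at min_diameter."""
    mean, sd = ves.diameter_mean, ves.diameter_sd
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    for _ in range(200):
        d = float(rng.lognormal(mu, np.sqrt(sigma2)))
        if d >= ves.min_diameter:
            return d
    return ves.min_diameter


def gen_height_map(scene: SceneSpec, seed: int, *, counter: int = 0):
    """Generate one calibrated height map and its truth record."""
    scene.validate()
    rng = child_rng(seed, TAG_IMAGE, counter)
    n = scene.pixels_per_side
    px = scene.pixel_size
    n_pix = n * n

    # --- phase pattern by exact-quantile thresholding of a smooth field ---
    classes = ["substrate"] + [c for c in NESTING_ORDER if scene.target_coverages.get(c, 0) > 0]
    labels = np.zeros((n, n), dtype=np.int16)
    if len(classes) > 1:
        frac_sub = 1.0 - sum(scene.target_coverages.get(c, 0.0) for c in classes[1:])
        if frac_sub >= 1e-12:
            fld = gaussian_filter(rng.standard_normal((n, n)), scene.correlation_px)
            order = np.argsort(fld, axis=None, kind="stable")
        else:
            # full lipid coverage with a single class needs no field
            fld = None
            order = np.arange(n_pix)
        counts = [int(round(frac_sub * n_pix))]
        for c in classes[1:-1]:
            counts.append(int(round(scene.target_coverages[c] * n_pix)))
        counts.append(n_pix - sum(counts))  # last class absorbs rounding
        flat = np.empty(n_pix, dtype=np.int16)
        start = 0
        for code, cnt in enumerate(counts):
            flat[order[start:start + cnt]] = code
            start += cnt
        labels = flat.reshape(n, n)

    class_names = list(classes)
    heights = np.zeros((n, n))
    for code, cname in enumerate(class_names):
        m = labels == code
        if not m.any():
            continue
        base = 0.0 if cname == "substrate" else scene.phase_heights[cname]
        sd = scene.texture_sd.get(cname, 0.0)
        heights[m] = base
        if sd > 0:
            heights[m] += rng.normal(0.0, sd, size=int(m.sum()))

    # --- stripes ---
    stripe_truth = None
    if scene.stripe is not None:
        st = scene.stripe
        yy, xx = np.mgrid[0:n, 0:n]
        x_nm, y_nm = xx * px, yy * px
        phase = float(rng.uniform(0, 2 * np.pi))
        kx = np.cos(st.orientation) / st.period
        ky = np.sin(st.orientation) / st.period
        wave = st.amplitude * np.sin(2 * np.pi * (kx * x_nm + ky * y_nm) + phase)
        target = (st.classes or tuple(c for c in class_names if c != "substrate"))
        region = np.isin(labels, [class_names.index(c) for c in target if c in class_names])
        heights[region] += wave[region]
        stripe_truth = {
            "period": st.period, "amplitude": st.amplitude,
            "orientation": st.orientation, "phase": phase,
        }

    # --- vesicle caps on the substrate ---
    vesicles = []
    if scene.vesicles is not None and scene.vesicles.count > 0:
        ves = scene.vesicles
        if "vesicle" not in class_names:
            class_names.append("vesicle")
        ves_code = class_names.index("vesicle")
        yy, xx = np.mgrid[0:n, 0:n]
        occupied = labels != 0  # only place on substrate
        placed = 0
        attempts = 0
        while placed < ves.count and attempts < 200 * ves.count:
            attempts += 1
            d = _draw_diameter(rng, ves)
            h = ves.cap_aspect * d
            a = _cap_footprint_radius(d, ves.cap_aspect)
            a_px = a / px
            margin = a_px + 3.0
            cx = rng.uniform(margin, n - margin)
            cy = rng.uniform(margin, n - margin)
            r_px = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
            foot = r_px <= a_px + 2.0
            if occupied[foot].any():
                continue
            r_nm = r_px * px
            sphere_r = (a ** 2 + h ** 2) / (2.0 * h)
            inside = r_nm <= a
            cap = np.zeros((n, n))
            cap[inside] = np.sqrt(np.maximum(sphere_r ** 2 - r_nm[inside] ** 2, 0.0)) - (sphere_r - h)
            heights[inside] += cap[inside]
            labels[inside] = ves_code
            occupied |= foot
            vesicles.append({
                "x_nm": cx * px, "y_nm": cy * px,
                "diameter": d, "height": h, "footprint_radius": a,
            })
            placed += 1

    clean = heights.copy()

    # --- instrument artifacts ---
    plane = (0.0, 0.0)
    offsets = tilts = None
    if scene.plane_tilt_nm > 0:
        theta = rng.uniform(0, 2 * np.pi)
        gx = scene.plane_tilt_nm * np.cos(theta) / n
        gy = scene.plane_tilt_nm * np.sin(theta) / n
        yy, xx = np.mgrid[0:n, 0:n]
        heights = heights + gx * xx + gy * yy
        plane = (gx, gy)
    if scene.scanline is not None:
        sl = scene.scanline
        offsets = rng.normal(0.0, sl.offset_sd, size=n)
        tilts = rng.normal(0.0, sl.tilt_sd, size=n)
        xline = np.linspace(-0.5, 0.5, n)
        heights = heights + offsets[:, None] + tilts[:, None] * xline[None, :]

    total = {c: float((labels == i).sum()) / n_pix for i, c in enumerate(class_names)}
    lipid_px = int((labels != 0).sum())
    lipid = {
        c: (float((labels == i).sum()) / lipid_px if lipid_px else 0.0)
        for i, c in enumerate(class_names) if c != "substrate"
    }

    hm = HeightMap(
        heights=heights,
        pixel_size=px,
        metadata={"sample": scene.name, "seed": int(seed), "counter": int(counter)},
    )
    truth = SceneTruth(
        scene=scene.name, seed=int(seed), counter=int(counter),
        class_names=class_names, labels=labels,
        coverages_total=total, coverages_lipid=lipid,
        clean_heights=clean, vesicles=vesicles, stripe=stripe_truth,
        scanline_offsets=offsets, scanline_tilts=tilts, plane=plane,
    )
    return hm, truth
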