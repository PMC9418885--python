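"""Detection, measurement and classification of membrane-rupture events.

The detector operates on median-filtered, baseline-subtracted approach
curves. Ruptures are found with a running-maximum hysteresis on the filtered
force (a drop must exceed the detection threshold before a new event can
open), then localised to sample precision on the unfiltered force via the
most negative first difference near the candidate edge — the median filter
preserves step edges but rounds the force peak at the yield point, so the
reported rupture force is the raw (baseline-subtracted) force at the last
sample before the drop. Rupture thickness is the separation span from the
yield sample to the sample at which force rises again above the noise floor.

Population labels follow the event-topology convention for these membranes:
within a multi-step curve every event but the last is an initial
low-force step (alpha) and the last is the bilayer rupture (beta); a
single-step curve is beta below the gamma force gate and gamma (a combined,
high-force rupture, characteristic of protein/LPS-reinforced bilayers)
above it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .datatypes import (
    APPROACH,
    RETRACT,
    CurveResult,
    ForceCurve,
    NoContactError,
    RuptureEvent,
)

#: Fixed single-step gamma/beta gate used when a batch cannot support a
#: mixture fit (fewer than 20 single-step events, or unimodal force data).
FALLBACK_GAMMA_GATE = 1.7  # nN

#: Numerical floor for "the force has risen again" on noiseless data.
RISE_EPS = 1e-9


# --------------------------------------------------------------------------
# Preprocessing
# --------------------------------------------------------------------------


def preprocess_curve(curve: ForceCurve, window: int = 5,
                     baseline_fraction: float = 0.2) -> ForceCurve:
    """Median-filter the force and subtract the far-field baseline.

    The baseline is the mean force over the ``baseline_fraction`` of samples
    at the largest separations. Separation is untouched. The returned curve
    carries the baseline-subtracted unfiltered force in ``force_raw`` and
    robust noise estimates in its metadata.
    """
    if window < 1 or window % 2 == 0 or window >= len(curve):
        raise ValueError("window must be odd, >= 1 and smaller than the curve")
    n_base = max(int(round(baseline_fraction * len(curve))), 8)
    if curve.direction == APPROACH:
        base_slice = slice(0, n_base)  # acquisition order: far field first
    else:
        base_slice = slice(len(curve) - n_base, len(curve))
    filtered = median_filter(curve.force, size=window, mode="nearest") if window > 1 \
        else curve.force.copy()
    baseline = float(np.mean(filtered[base_slice]))
    filtered = filtered - baseline
    raw = curve.force - baseline

    def _mad_sd(x):
        return float(np.median(np.abs(x - np.median(x))) * 1.4826)

    meta = dict(curve.metadata)
    meta.update(
        preprocessed=True,
        filter_window=window,
        baseline=baseline,
        noise_sd_raw=_mad_sd(raw[base_slice]),
        noise_sd_filtered=_mad_sd(filtered[base_slice]),
    )
    return ForceCurve(separation=curve.separation.copy(), force=filtered,
                      direction=curve.direction, metadata=meta, force_raw=raw)


def _require_preprocessed(curve: ForceCurve) -> ForceCurve:
    return curve if curve.is_preprocessed else preprocess_curve(curve)


# --------------------------------------------------------------------------
# Contact point
# --------------------------------------------------------------------------


def find_contact_point(curve: ForceCurve, threshold_sd: float = 5.0,
                       sustain: int = 5) -> float:
    """Separation of the first sustained repulsive force onset.

    Returns the largest separation at which the filtered force exceeds
    ``threshold_sd`` times the far-field noise and stays above it for
    ``sustain`` consecutive samples toward contact. Raises
    ``NoContactError`` when no such crossing exists.
    """
    curve = _require_preprocessed(curve)
    if curve.direction != APPROACH:
        raise ValueError("contact point is defined on approach curves")
    sigma = curve.metadata.get("noise_sd_filtered", 0.0)
    thr = max(threshold_sd * sigma, RISE_EPS)
    above = curve.force > thr
    if sustain > 1:
        kernel = np.ones(sustain, dtype=int)
        runs = np.convolve(above.astype(int), kernel, mode="valid") == sustain
        idx = np.nonzero(runs)[0]
    else:
        idx = np.nonzero(above)[0]
    if len(idx) == 0:
        raise NoContactError("no sustained force onset found")
    return float(curve.separation[idx[0]])


def _contact_index(curve: ForceCurve, threshold_sd: float = 5.0) -> int:
    s_c = find_contact_point(curve, threshold_sd=threshold_sd)
    return int(np.argmin(np.abs(curve.separation - s_c)))


# --------------------------------------------------------------------------
# Step detection
# --------------------------------------------------------------------------


def _sustained_rise(f: np.ndarray, k: int, rise_level: float) -> bool:
    """True when the force stays above the noise floor ahead of sample ``k``
    (a real re-contact keeps loading; a lone noise excursion does not)."""
    n = len(f)
    return all(f[j] > rise_level for j in (k + 2, k + 4) if j < n)


def detect_steps(
    curve: ForceCurve,
    min_force: float = 0.1,
    min_thickness: float = 0.1,
    *,
    drop_threshold: Optional[float] = None,
    gate_on: str = "yield",
) -> list:
    """Detect membrane-rupture steps in a preprocessed approach curve.

    Events whose gating force (force at yield by default, drop magnitude
    with ``gate_on='drop'``) exceeds ``min_force`` and whose yield-to-
    force-recovery distance exceeds ``min_thickness`` are returned, ordered
    by decreasing separation.
    """
    if curve.direction != APPROACH:
        raise ValueError("detect_steps operates on approach curves")
    if gate_on not in ("yield", "drop"):
        raise ValueError("gate_on must be 'yield' or 'drop'")
    curve = _require_preprocessed(curve)
    s = curve.separation
    f = curve.force
    fr = curve.force_raw if curve.force_raw is not None else f
    n = len(f)
    sigma_f = curve.metadata.get("noise_sd_filtered", 0.0)
    if drop_threshold is None:
        drop_threshold = max(5.0 * sigma_f, 0.05)
    rise_level = max(4.0 * sigma_f, RISE_EPS)

    try:
        j0 = _contact_index(curve)
    except NoContactError:
        return []

    events = []
    run_max_val = f[j0]
    run_max_idx = j0
    j = j0 + 1
    while j < n:
        if f[j] > run_max_val:  # ties keep the larger-separation sample
            run_max_val = f[j]
            run_max_idx = j
            j += 1
            continue
        if run_max_val - f[j] < drop_threshold:
            j += 1
            continue
        # --- candidate rupture: localise the edge on the raw force ---
        lo = max(run_max_idx - 3, j0)
        diffs = fr[lo + 1:j + 1] - fr[lo:j]
        j_y = lo + int(np.argmin(diffs))
        # --- find the trough and the subsequent force increase ---
        k = j_y + 1
        trough_idx = min(j_y + 1, n - 1)
        entered_gap = False
        recovery = None
        while k < n:
            if f[k] < f[trough_idx]:
                trough_idx = k
            if f[k] <= rise_level:
                entered_gap = True
            elif entered_gap and _sustained_rise(f, k, rise_level):
                recovery = k
                break
            elif f[k] > f[j_y]:
                # partial drop that never reached the noise floor: the
                # force increase resumes from the local minimum
                recovery = trough_idx
                break
            k += 1
        if recovery is None:
            # drop runs to the end of the curve: no recovery, no event
            j = k
            continue
        thickness = float(s[j_y] - s[recovery])
        rupture_force = float(fr[j_y])
        drop = float(fr[j_y] - np.min(fr[j_y + 1:recovery + 1]))
        if thickness > 0:
            events.append(RuptureEvent(
                yield_separation=float(s[j_y]),
                rupture_force=rupture_force,
                thickness=thickness,
                force_drop=drop,
                index_in_curve=len(events),
                yield_index=int(j_y),
                recovery_index=int(recovery),
            ))
        # restart past both the recovery point and the trigger sample so the
        # scan always advances even on noise-triggered candidates
        anchor = max(recovery, j)
        j = anchor + 1
        run_max_val = f[anchor]
        run_max_idx = anchor

    gate_val = (lambda e: e.rupture_force) if gate_on == "yield" else (lambda e: e.force_drop)
    kept = [e for e in events if gate_val(e) > min_force and e.thickness > min_thickness]
    for i, e in enumerate(kept):
        e.index_in_curve = i
    return kept


def analyze_curve(
    curve: ForceCurve,
    min_force: float = 0.1,
    min_thickness: float = 0.1,
    window: int = 5,
    curve_id: Optional[str] = None,
    **detect_kwargs,
) -> CurveResult:
    """Preprocess, locate contact and detect steps in one call."""
    prepped = preprocess_curve(curve, window=window) if not curve.is_preprocessed else curve
    result = CurveResult(events=[], curve_id=curve_id)
    try:
        result.contact_point = find_contact_point(prepped)
    except NoContactError:
        result.warnings.append("no contact found")
        return result
    setpoint = prepped.metadata.get("setpoint_nN")
    if setpoint is not None and np.max(prepped.force) < 0.95 * setpoint:
        result.warnings.append("curve never reached the setpoint; analysed as-is")
        warnings.warn(f"curve {curve_id or ''} never reached the setpoint", stacklevel=2)
    result.events = detect_steps(prepped, min_force=min_force,
                                 min_thickness=min_thickness, **detect_kwargs)
    return result


def analyze_batch(curves: Sequence[ForceCurve], **kwargs) -> list:
    return [analyze_curve(c, curve_id=str(c.metadata.get("counter", i)), **kwargs)
            for i, c in enumerate(curves)]


# --------------------------------------------------------------------------
# Population classification
# --------------------------------------------------------------------------


@dataclass
class PopulationModel:
    """Gating parameters for alpha/beta/gamma event labelling."""

    gamma_gate: float = FALLBACK_GAMMA_GATE  # nN, single-step beta/gamma split
    source: str = "fallback"  # fallback | mixture | config


def fit_population_model(results: Sequence[CurveResult],
                         min_events: int = 20) -> PopulationModel:
    """Fit the single-step gamma/beta force gate.

    With at least ``min_events`` single-step events, a one-dimensional
    two-component Gaussian mixture is compared against a single component by
    BIC; if two modes are supported the gate is the midpoint between their
    means, otherwise (and for small batches) the fixed fallback gate is used.
    """
    singles = np.array([r.final_rupture_force for r in results
                        if r.step_count == 1], dtype=float)
    if len(singles) < min_events:
        return PopulationModel()
    from sklearn.mixture import GaussianMixture

    X = singles.reshape(-1, 1)
    gm1 = GaussianMixture(n_components=1, random_state=0).fit(X)
    gm2 = GaussianMixture(n_components=2, random_state=0, n_init=5).fit(X)
    if gm2.bic(X) + 2.0 < gm1.bic(X):
        means = np.sort(gm2.means_.ravel())
        return PopulationModel(gamma_gate=float(means.mean()), source="mixture")
    return PopulationModel()


def classify_events(results: Sequence[CurveResult],
                    model: Optional[PopulationModel] = None) -> PopulationModel:
    """Label every detected event alpha/beta/gamma in place.

    Multi-step curves: all but the last event are alpha, the last is beta.
    Single-step curves: beta below the gamma gate, gamma at or above it.
    Returns the (possibly fitted) population model used.
    """
    if model is None:
        model = fit_population_model(results)
    n_events = sum(r.step_count for r in results)
    if n_events == 0:
        warnings.warn("no events to classify", stacklevel=2)
        return model
    for r in results:
        if r.step_count == 0:
            continue
        if r.step_count == 1:
            e = r.events[0]
            e.label = "gamma" if e.rupture_force >= model.gamma_gate else "beta"
        else:
            for e in r.events[:-1]:
                e.label = "alpha"
            r.events[-1].label = "beta"
    return model


# --------------------------------------------------------------------------
# Batch summaries
# --------------------------------------------------------------------------


def summarize_curves(results: Sequence[CurveResult],
                     batch: str = "batch") -> dict:
    """Batch summary statistics mirroring the standard force-map readouts."""
    if len(results) == 0:
        raise ValueError("need at least one curve result")
    finals = np.array([r.final_rupture_force for r in results
                       if r.final_rupture_force is not None], dtype=float)
    steps = np.array([r.step_count for r in results], dtype=float)
    all_events = [e for r in results for e in r.events]
    labels = [e.label for e in all_events]

    pop = {}
    for lab in ("alpha", "beta", "gamma"):
        ev = [e for e in all_events if e.label == lab]
        if ev:
            pop[lab] = {
                "count": len(ev),
                "mean_force": float(np.mean([e.rupture_force for e in ev])),
                "mean_thickness": float(np.mean([e.thickness for e in ev])),
            }

    n_beta_curves = sum(
        1 for r in results if any(e.label == "beta" for e in r.events)
    )
    n_beta_without_alpha = sum(
        1 for r in results
        if any(e.label == "beta" for e in r.events)
        and not any(e.label == "alpha" for e in r.events)
    )
    frac = (n_beta_without_alpha / n_beta_curves) if n_beta_curves else np.nan

    return {
        "batch": batch,
        "n_curves": len(results),
        "n_curves_with_events": int(np.sum(steps > 0)),
        "mean_final_rupture_force": float(np.mean(finals)) if len(finals) else np.nan,
        "sd_final_rupture_force": float(np.std(finals, ddof=1)) if len(finals) > 1 else 0.0,
        "mean_step_count": float(np.mean(steps)),
        "populations": pop,
        "frac_beta_without_alpha": float(frac) if frac == frac else np.nan,
        "n_labelled": sum(lab is not None for lab in labels),
    }


def scatter_map(results: Sequence[CurveResult]) -> pd.DataFrame:
    """Force-vs-thickness scatter of every event (the 2D rupture map)."""
    rows = [
        {
            "curve_id": r.curve_id,
            "force_nN": e.rupture_force,
            "thickness_nm": e.thickness,
            "yield_separation_nm": e.yield_separation,
            "label": e.label or "",
        }
        for r in results for e in r.events
    ]
    return pd.DataFrame(rows, columns=["curve_id", "force_nN", "thickness_nm",
                                       "yield_separation_nm", "label"])


# --------------------------------------------------------------------------
# Retraction: unfolding releases
# --------------------------------------------------------------------------


def detect_unfolding(curve: ForceCurve, min_force: float = 0.1) -> list:
    """Detect sawtooth release events in a retract curve.

    A release is a gradual attractive (negative) force build-up terminated
    by an abrupt single-sample rise exceeding ``min_force``. Positions are
    the separations of the last loaded sample before release. No polymer
    model is fitted.
    """
    if curve.direction != RETRACT:
        raise ValueError("detect_unfolding operates on retract curves")
    curve = _require_preprocessed(curve)
    s = curve.separation
    fr = curve.force_raw if curve.force_raw is not None else curve.force
    f = curve.force
    sigma = curve.metadata.get("noise_sd_raw", 0.0)
    jump_min = max(5.0 * sigma, 0.6 * min_force)
    diffs = np.diff(fr)
    candidates = np.nonzero(diffs > jump_min)[0]
    releases = []
    last = -10
    for j in candidates:
        if j - last < 5:  # merge adjacent samples of the same release
            last = j
            continue
        # must release from an attractive (negative) loaded state
        if f[j] < -0.5 * jump_min:
            releases.append({
                "separation": float(s[j]),
                "force_drop": float(diffs[j]),
                "index": int(j),
            })
        last = j
    return releases
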