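"""Synthetic force-distance curves with known breakthrough ground truth.

The approach model: the force is baseline noise at large separation; after
the tip contacts the top of the layer stack it loads piecewise-linearly in
indentation (optionally through a soft elastic-compression prelude); when the
load reaches a layer's sampled rupture force the layer yields instantaneously
at sample resolution, the tip advances through the layer thickness at zero
force, then re-contacts the next layer (or the substrate) and loads again
until the setpoint is reached.

Truth records carry both the drawn (analytic) event parameters and their
grid-realized counterparts measured directly on the emitted noiseless
samples, so that detector output can be compared to truth exactly on
noise-free curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..datatypes import APPROACH, RETRACT, ForceCurve
from .presets import ScenarioPreset
from .seeds import TAG_FORCE, TAG_RETRACT, child_rng

#: Smallest force treated as "the force has risen again" on noiseless data.
RISE_EPS = 1e-9

#: Physical floors applied when sampling event parameters.
MIN_SAMPLED_FORCE = 0.05  # nN
MIN_SAMPLED_THICKNESS = 0.2  # nm


@dataclass
class TruthEvent:
    """Ground truth for one inserted breakthrough."""

    layer: str
    rupture_force: float  # drawn value, nN
    thickness: float  # drawn value, nm
    yield_separation: float  # analytic, nm
    grid_yield_index: int
    grid_yield_separation: float
    grid_rupture_force: float  # noiseless force at the yield sample
    grid_rise_index: int
    grid_thickness: float  # yield sample to first force re-increase sample


@dataclass
class ForceCurveTruth:
    """Truth record for one generated curve."""

    preset: str
    seed: int
    counter: int
    contact_separation: float
    events: list = field(default_factory=list)
    release_positions: list = field(default_factory=list)  # retract sawteeth, nm

    @property
    def n_events(self) -> int:
        return len(self.events)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    """Normal draw re-sampled (then clipped) to respect a physical floor."""
    if sd == 0:
        return max(mean, lo)
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x >= lo:
            return float(x)
    return lo


def _load_profile(stiffness: float, layer, indentation: np.ndarray) -> np.ndarray:
    """Force as a function of indentation depth for one layer's loading ramp."""
    k = stiffness
    d, r = layer.prelude_depth_nm, layer.prelude_stiffness_ratio
    soft = k * r * indentation
    stiff = k * r * d + k * (indentation - d)
    return np.where(indentation < d, soft, stiff)


def _yield_indentation(stiffness: float, layer, force: float) -> float:
    """Indentation at which the loading ramp reaches ``force``."""
    k = stiffness
    d, r = layer.prelude_depth_nm, layer.prelude_stiffness_ratio
    if force <= k * r * d:
        return force / (k * r)
    return d + (force - k * r * d) / k


def gen_force_curve(
    preset: ScenarioPreset,
    seed: int,
    *,
    counter: int = 0,
    noise_sd: float | None = None,
):
    """Generate one approach curve and its truth record.

    ``counter`` indexes the curve within a batch; each (seed, counter) pair
    yields an independent, bit-reproducible curve.
    """
    preset.validate()
    rng = child_rng(seed, TAG_FORCE, counter)
    sigma = preset.noise_sd if noise_sd is None else float(noise_sd)
    k = preset.contact_stiffness
    ds = preset.sample_step

    present = [lyr for lyr in preset.layers if rng.uniform() < lyr.presence_probability]
    forces = [_truncated_normal(rng, l.mean_rupture_force, l.sd_rupture_force,
                                MIN_SAMPLED_FORCE) for l in present]
    thicknesses = [_truncated_normal(rng, l.mean_thickness, l.sd_thickness,
                                     MIN_SAMPLED_THICKNESS) for l in present]
    forces = [min(f, preset.max_force - 0.5) for f in forces]

    if preset.contact_separation is not None:
        contact = preset.contact_separation
    else:
        contact = float(np.sum(thicknesses))

    # Piecewise segments: (contact point, layer-or-None, yield separation).
    segments = []
    c = contact
    for lyr, f_rup, t in zip(present, forces, thicknesses):
        s_yield = c - _yield_indentation(k, lyr, f_rup)
        segments.append((c, lyr, f_rup, t, s_yield))
        c = s_yield - t
    # Final substrate loading up to the setpoint (plain linear, no prelude).
    s_end = c - preset.max_force / k

    start = contact + preset.free_travel
    if any(t > start - s for (_, _, _, t, s) in segments):
        raise ValueError("layer thicknesses exceed the free-travel range")
    n = int(np.ceil((start - s_end) / ds)) + 1
    s = start - ds * np.arange(n)

    force = np.zeros(n)
    for (c_i, lyr, f_rup, t, s_y) in segments:
        on_ramp = (s <= c_i) & (s >= s_y - 1e-12)
        force[on_ramp] = _load_profile(k, lyr, c_i - s[on_ramp])
        gap = (s < s_y - 1e-12) & (s > s_y - t)
        force[gap] = 0.0
    sub = s <= c + 1e-12
    force[sub] = k * (c - s[sub])
    # terminate at the first sample at/above the setpoint
    over = np.nonzero(force >= preset.max_force)[0]
    if len(over):
        n = over[0] + 1
        s, force = s[:n], force[:n]

    truth = ForceCurveTruth(
        preset=preset.name, seed=int(seed), counter=int(counter),
        contact_separation=contact,
    )
    for (c_i, lyr, f_rup, t, s_y) in segments:
        j_y = int(np.max(np.nonzero(s >= s_y - 1e-12)[0]))
        after = np.nonzero((np.arange(n) > j_y) & (force > RISE_EPS))[0]
        j_rise = int(after[0]) if len(after) else n - 1
        truth.events.append(TruthEvent(
            layer=lyr.name,
            rupture_force=f_rup,
            thickness=t,
            yield_separation=s_y,
            grid_yield_index=j_y,
            grid_yield_separation=float(s[j_y]),
            grid_rupture_force=float(force[j_y]),
            grid_rise_index=j_rise,
            grid_thickness=float(s[j_y] - s[j_rise]),
        ))

    if sigma > 0:
        force = force + rng.normal(0.0, sigma, size=n)

    curve = ForceCurve(
        separation=s,
        force=force,
        direction=APPROACH,
        metadata={
            "sample": preset.name,
            "seed": int(seed),
            "counter": int(counter),
            "velocity_um_s": 0.5,
            "setpoint_nN": preset.max_force,
            "noise_sd_true": sigma,
        },
    )
    return curve, truth


def gen_force_batch(preset: ScenarioPreset, n: int, seed: int, *, noise_sd=None):
    """Generate ``n`` curves with independent sub-streams of ``seed``."""
    out = [gen_force_curve(preset, seed, counter=i, noise_sd=noise_sd) for i in range(n)]
    curves = [c for c, _ in out]
    truths = [t for _, t in out]
    return curves, truths


# --------------------------------------------------------------------------
# Retraction
# --------------------------------------------------------------------------


def gen_retract_curve(
    preset: ScenarioPreset,
    seed: int,
    *,
    unfolding: bool = False,
    n_teeth: int = 2,
    counter: int = 0,
    noise_sd: float | None = None,
    max_separation: float = 60.0,
):
    """Generate a retraction trace with an adhesion well and optional
    unfolding sawteeth (gradual attractive rise, abrupt single-sample
    release); truth records the release positions."""
    preset.validate()
    rng = child_rng(seed, TAG_RETRACT, counter)
    sigma = preset.noise_sd if noise_sd is None else float(noise_sd)
    ds = preset.sample_step
    n = int(np.ceil(max_separation / ds)) + 1
    s = ds * np.arange(n)

    # Adhesion well: zero at contact, single minimum, smooth decay.
    a_depth = 0.3  # nN
    a_width = 2.0  # nm
    force = -a_depth * (s / a_width) * np.exp(1.0 - s / a_width)

    truth = ForceCurveTruth(
        preset=preset.name, seed=int(seed), counter=int(counter),
        contact_separation=0.0,
    )
    if unfolding:
        positions = np.sort(rng.uniform(12.0, 45.0, size=n_teeth))
        # enforce a minimal spacing so teeth do not overlap
        for i in range(1, len(positions)):
            positions[i] = max(positions[i], positions[i - 1] + 4.0)
        for p in positions:
            amp = _truncated_normal(rng, 0.25, 0.05, 0.12)
            rise = 3.0  # nm of gradual attractive loading before release
            j_rel = int(np.floor(p / ds))
            seg = (s > p - rise) & (s <= s[j_rel])
            force[seg] += -amp * (s[seg] - (p - rise)) / rise
            truth.release_positions.append(float(s[j_rel]))

    if sigma > 0:
        force = force + rng.normal(0.0, sigma, size=n)

    curve = ForceCurve(
        separation=s,
        force=force,
        direction=RETRACT,
        metadata={
            "sample": preset.name,
            "seed": int(seed),
            "counter": int(counter),
            "unfolding": bool(unfolding),
            "noise_sd_true": sigma,
        },
    )
    return curve, truth
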