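"""Scenario and scene presets emulating the membrane systems under study.

Force-curve presets encode the breakthrough mechanics of each sample class
(gel- and fluid-phase DMPC supported bilayers, LPS-doped DMPC with its extra
penetrable oligosaccharide layer, protein-reinforced OM-DMPC, and intact LPS
vesicles compressed through a three-regime response). Image presets encode
the corresponding topographies. Parameters anchored to measured values are
noted per preset in ``anchored``; everything else is a free default chosen
once to be realistic for this kind of sample, and listed in ``free``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import yaml

# --------------------------------------------------------------------------
# Force-curve scenario presets
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LayerSpec:
    """One penetrable layer of the stack above the substrate.

    ``prelude_depth_nm``/``prelude_stiffness_ratio`` describe an optional
    initial soft elastic-compression regime: the first ``prelude_depth_nm`` of
    indentation load at ``prelude_stiffness_ratio`` times the contact
    stiffness before the full stiffness takes over.
    """

    mean_rupture_force: float  # nN
    sd_rupture_force: float  # nN
    mean_thickness: float  # nm
    sd_thickness: float  # nm
    presence_probability: float = 1.0
    prelude_depth_nm: float = 0.0
    prelude_stiffness_ratio: float = 1.0
    name: str = "layer"

    def validate(self) -> None:
        if not 0.0 <= self.presence_probability <= 1.0:
            raise ValueError("presence_probability must lie in [0, 1]")
        if self.sd_rupture_force < 0 or self.sd_thickness < 0:
            raise ValueError("standard deviations must be non-negative")
        if not self.mean_thickness > 0:
            raise ValueError("mean_thickness must be positive")
        if self.prelude_depth_nm < 0 or not 0 < self.prelude_stiffness_ratio <= 1:
            raise ValueError("invalid elastic-compression prelude")


@dataclass(frozen=True)
class ScenarioPreset:
    """Named parameter bundle for one force-spectroscopy sample scenario."""

    name: str
    layers: tuple
    contact_stiffness: float = 1.0  # nN/nm
    max_force: float = 10.0  # nN setpoint
    noise_sd: float = 0.05  # nN
    contact_separation: Optional[float] = None  # nm; default: sum of thicknesses
    free_travel: float = 15.0  # nm of baseline above first contact
    sample_step: float = 0.02  # nm separation grid step
    anchored: tuple = ()
    free: tuple = ()

    def validate(self) -> None:
        if not self.layers:
            pass  # an empty stack (bare substrate) is legal
        for layer in self.layers:
            layer.validate()
            if self.max_force <= layer.mean_rupture_force + 4 * layer.sd_rupture_force:
                raise ValueError(
                    f"{self.name}: max_force {self.max_force} nN does not exceed "
                    f"layer {layer.name} mean+4sd rupture force"
                )
        if self.contact_stiffness <= 0 or self.noise_sd < 0:
            raise ValueError("contact_stiffness must be > 0 and noise_sd >= 0")
        if self.sample_step <= 0 or self.free_travel <= 0:
            raise ValueError("sample_step and free_travel must be positive")
        if self.contact_separation is not None:
            worst = sum(l.mean_thickness + 4 * l.sd_thickness for l in self.layers)
            if worst > self.contact_separation + self.max_force / self.contact_stiffness:
                raise ValueError(
                    f"{self.name}: layer thicknesses exceed the travel range below "
                    f"the stated contact separation"
                )

    def with_overrides(self, **kwargs) -> "ScenarioPreset":
        preset = replace(self, **kwargs)
        preset.validate()
        return preset


FORCE_PRESETS = {
    # Gel-phase DMPC bilayer: single-step rupture.
    "DMPC-20C": ScenarioPreset(
        name="DMPC-20C",
        layers=(LayerSpec(1.3, 0.3, 5.0, 0.4, 1.0, name="bilayer"),),
        contact_stiffness=1.0,
        anchored=("rupture force 1.3+-0.3 nN", "thickness ~5 nm", "setpoint 10 nN"),
        free=("contact stiffness 1 nN/nm", "thickness sd 0.4 nm"),
    ),
    # Fluid-phase DMPC bilayer: thinner, much softer rupture.
    "DMPC-30C": ScenarioPreset(
        name="DMPC-30C",
        layers=(LayerSpec(0.34, 0.08, 4.0, 0.4, 1.0, name="bilayer"),),
        contact_stiffness=0.5,
        noise_sd=0.02,
        anchored=("rupture force 0.34+-0.08 nN", "thickness ~4 nm"),
        free=("contact stiffness 0.5 nN/nm", "thickness sd 0.4 nm"),
    ),
    # LPS-doped DMPC: a low-force hydrated oligosaccharide layer (alpha)
    # pierced before the bilayer proper (beta); alpha is absent in a small
    # fraction of curves where the tip lands on LPS-free membrane.
    "LPS-DMPC": ScenarioPreset(
        name="LPS-DMPC",
        layers=(
            LayerSpec(0.5, 0.2, 3.0, 0.5, 0.95, name="oligosaccharide"),
            LayerSpec(1.4, 0.5, 5.0, 0.4, 1.0, name="bilayer"),
        ),
        contact_stiffness=1.0,
        anchored=("final rupture force 1.4+-0.5 nN", "alpha presence 0.95"),
        free=("alpha force 0.5+-0.2 nN", "alpha thickness 3+-0.5 nm"),
    ),
    # Protein/LPS-reinforced bilayer: thicker, stiffer, single high-force
    # rupture after an elastic-compression prelude.
    "OM-DMPC": ScenarioPreset(
        name="OM-DMPC",
        layers=(
            LayerSpec(
                2.03, 0.41, 6.0, 0.5, 1.0,
                prelude_depth_nm=2.0, prelude_stiffness_ratio=0.25,
                name="reinforced-bilayer",
            ),
        ),
        contact_stiffness=1.2,
        anchored=("rupture force 2.03+-0.41 nN", "thickness ~6 nm"),
        free=("prelude depth 2 nm at 0.25x stiffness", "contact stiffness 1.2 nN/nm"),
    ),
    # Intact LPS vesicle under compression: gentle force rise from 30 nm
    # (vesicle collapse), stiff loading from 12 nm (double bilayer), rupture
    # near 6 nN.
    "LPS-VESICLE": ScenarioPreset(
        name="LPS-VESICLE",
        layers=(
            LayerSpec(
                6.0, 0.5, 8.0, 1.0, 1.0,
                prelude_depth_nm=18.0, prelude_stiffness_ratio=0.1,
                name="double-bilayer",
            ),
        ),
        contact_stiffness=1.0,
        contact_separation=30.0,
        free_travel=15.0,
        anchored=("soft regime from 30 nm", "stiff regime from 12 nm", "rupture ~6 nN"),
        free=("soft/stiff stiffness ratio 1:10", "rupture sd 0.5 nN", "thickness 8+-1 nm"),
    ),
}


# --------------------------------------------------------------------------
# Height-map scene presets
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StripeSpec:
    period: float  # nm
    amplitude: float  # nm
    orientation: float = 0.0  # rad, direction of the wave vector
    classes: tuple = ()  # empty -> applied to all lipid classes


@dataclass(frozen=True)
class VesicleSpec:
    count: int
    diameter_mean: float = 29.0  # nm, under the half-max equal-area convention
    diameter_sd: float = 22.0  # nm
    min_diameter: float = 8.0  # nm hard floor (below AFM detectability here)
    cap_aspect: float = 0.4  # cap height / measured diameter


@dataclass(frozen=True)
class ScanlineSpec:
    offset_sd: float = 0.15  # nm per-row offset
    tilt_sd: float = 0.3  # nm total tilt across the row width


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of one synthetic topography."""

    name: str
    image_size_um: float = 2.0
    pixels_per_side: int = 512
    phase_heights: dict = field(default_factory=dict)  # class -> nm
    target_coverages: dict = field(default_factory=dict)  # class -> fraction of total
    texture_sd: dict = field(default_factory=dict)  # class -> nm
    stripe: Optional[StripeSpec] = None
    vesicles: Optional[VesicleSpec] = None
    scanline: Optional[ScanlineSpec] = field(default_factory=ScanlineSpec)
    plane_tilt_nm: float = 1.0  # amplitude of the global background plane
    correlation_px: float = 24.0  # smoothing length of the phase pattern

    def validate(self) -> None:
        if self.pixels_per_side < 64:
            raise ValueError("scene must be at least 64 pixels per side")
        total = sum(self.target_coverages.values())
        if any(v < 0 for v in self.target_coverages.values()) or total > 1 + 1e-9:
            raise ValueError("coverages must be >= 0 and sum to <= 1")
        for cls, h in self.phase_heights.items():
            if h <= 0:
                raise ValueError(f"phase height for {cls!r} must be positive")
        for cls in self.target_coverages:
            if cls not in self.phase_heights:
                raise ValueError(f"no phase height declared for class {cls!r}")
        side_nm = self.image_size_um * 1000.0
        if self.stripe is not None and not 0 < self.stripe.period < side_nm:
            raise ValueError("stripe period must be positive and below the image side")
        n_min = self.min_class_pixels()
        if 0 < n_min < 1:
            raise ValueError("requested coverage cannot be tiled into the pixel grid")

    def min_class_pixels(self) -> float:
        n_pix = self.pixels_per_side ** 2
        fracs = [v for v in self.target_coverages.values() if v > 0]
        return min(fracs) * n_pix if fracs else 0.0

    @property
    def pixel_size(self) -> float:
        return self.image_size_um * 1000.0 / self.pixels_per_side


SCENE_PRESETS = {
    # Two-phase gel/fluid DMPC patch: 65% solid / 35% fluid of the lipid
    # area, plateaus at 5 and 4 nm over bare mica.
    "DMPC-20C": SceneSpec(
        name="DMPC-20C",
        phase_heights={"fluid": 4.0, "solid": 5.0},
        target_coverages={"fluid": 0.35 * 0.7, "solid": 0.65 * 0.7},
        texture_sd={"substrate": 0.05, "fluid": 0.08, "solid": 0.08},
    ),
    # Homogeneous fluid-phase DMPC at 30 C: one 4 nm plateau, full coverage.
    "DMPC-30C": SceneSpec(
        name="DMPC-30C",
        phase_heights={"fluid": 4.0},
        target_coverages={"fluid": 1.0},
        texture_sd={"fluid": 0.08},
    ),
    # Single-plateau surface whose texture reproduces the measured RMS
    # roughness of a DMPC SLB image (R_q = 0.77 nm).
    "DMPC-RQ": SceneSpec(
        name="DMPC-RQ",
        phase_heights={"solid": 5.0},
        target_coverages={"solid": 1.0},
        texture_sd={"solid": 0.77},
    ),
    # LPS-doped DMPC: smooth fluid rim, solid patch interior, rough
    # LPS-condensed domains inside the solid phase.
    "LPS-DMPC": SceneSpec(
        name="LPS-DMPC",
        phase_heights={"fluid": 4.0, "solid": 5.0, "rough": 5.5},
        target_coverages={"fluid": 0.28, "solid": 0.17, "rough": 0.27},
        texture_sd={"substrate": 0.05, "fluid": 0.08, "solid": 0.08, "rough": 0.5},
    ),
    # Protein/LPS-reinforced bilayer: full 6 nm plateau carrying the striped
    # nanotexture (15 nm period, 0.4 nm amplitude).
    "OM-DMPC": SceneSpec(
        name="OM-DMPC",
        phase_heights={"solid": 6.0},
        target_coverages={"solid": 1.0},
        texture_sd={"solid": 0.1},
        stripe=StripeSpec(period=15.0, amplitude=0.4, orientation=0.6),
    ),
    # Field of adsorbed LPS vesicles on bare substrate.
    "LPS-VESICLES": SceneSpec(
        name="LPS-VESICLES",
        phase_heights={},
        target_coverages={},
        texture_sd={"substrate": 0.05},
        vesicles=VesicleSpec(count=60),
    ),
}


# --------------------------------------------------------------------------
# YAML config loading
# --------------------------------------------------------------------------


def _layer_from_dict(d: dict) -> LayerSpec:
    return LayerSpec(
        mean_rupture_force=float(d["mean_rupture_force"]),
        sd_rupture_force=float(d["sd_rupture_force"]),
        mean_thickness=float(d["mean_thickness"]),
        sd_thickness=float(d["sd_thickness"]),
        presence_probability=float(d.get("presence_probability", 1.0)),
        prelude_depth_nm=float(d.get("prelude_depth_nm", 0.0)),
        prelude_stiffness_ratio=float(d.get("prelude_stiffness_ratio", 1.0)),
        name=str(d.get("name", "layer")),
    )


def scenario_from_dict(name: str, d: dict) -> ScenarioPreset:
    preset = ScenarioPreset(
        name=name,
        layers=tuple(_layer_from_dict(l) for l in d.get("layers", [])),
        contact_stiffness=float(d.get("contact_stiffness", 1.0)),
        max_force=float(d.get("max_force", 10.0)),
        noise_sd=float(d.get("noise_sd", 0.05)),
        contact_separation=(
            float(d["contact_separation"]) if d.get("contact_separation") is not None else None
        ),
        free_travel=float(d.get("free_travel", 15.0)),
        sample_step=float(d.get("sample_step", 0.02)),
    )
    preset.validate()
    return preset


def scene_from_dict(name: str, d: dict) -> SceneSpec:
    stripe = d.get("stripe")
    vesicles = d.get("vesicles")
    scanline = d.get("scanline", {})
    scene = SceneSpec(
        name=name,
        image_size_um=float(d.get("image_size_um", 2.0)),
        pixels_per_side=int(d.get("pixels_per_side", 512)),
        phase_heights={k: float(v) for k, v in d.get("phase_heights", {}).items()},
        target_coverages={k: float(v) for k, v in d.get("target_coverages", {}).items()},
        texture_sd={k: float(v) for k, v in d.get("texture_sd", {}).items()},
        stripe=StripeSpec(**stripe) if stripe else None,
        vesicles=VesicleSpec(**vesicles) if vesicles else None,
        scanline=ScanlineSpec(**scanline) if scanline is not None else None,
        plane_tilt_nm=float(d.get("plane_tilt_nm", 1.0)),
        correlation_px=float(d.get("correlation_px", 24.0)),
    )
    scene.validate()
    return scene


def load_config(path) -> dict:
    """Load user-declared scenario and scene presets from a YAML file.

    Returns ``{"scenarios": {...}, "scenes": {...}}`` merged over the
    built-in presets (user entries win).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    scenarios = dict(FORCE_PRESETS)
    scenes = dict(SCENE_PRESETS)
    for name, d in (raw.get("scenarios") or {}).items():
        scenarios[name] = scenario_from_dict(name, d)
    for name, d in (raw.get("scenes") or {}).items():
        scenes[name] = scene_from_dict(name, d)
    return {"scenarios": scenarios, "scenes": scenes}


def get_force_preset(name: str) -> ScenarioPreset:
    try:
        return FORCE_PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown force preset {name!r}; have {sorted(FORCE_PRESETS)}")


def get_scene_preset(name: str) -> SceneSpec:
    try:
        return SCENE_PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown scene preset {name!r}; have {sorted(SCENE_PRESETS)}")


for _p in FORCE_PRESETS.values():
    _p.validate()
for _s in SCENE_PRESETS.values():
    _s.validate()
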