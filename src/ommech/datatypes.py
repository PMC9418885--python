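"""Core in-memory containers shared by the generator and the analysis stages.

Conventions
-----------
* Tip-sample separation is in nm and decreases during approach; approach
  curves are stored in acquisition order (separation strictly decreasing),
  retract curves with separation strictly increasing.
* Heights are in nm, images are row-major with the origin at the top-left
  pixel and half-open pixel coordinates.
* DLS lag times are in seconds; size distributions carry intensity weights
  on a strictly increasing diameter grid in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

APPROACH = "approach"
RETRACT = "retract"


class NoContactError(RuntimeError):
    """Raised when an approach curve never shows a sustained force onset."""


@dataclass
class ForceCurve:
    """One approach or retract force-distance trace.

    ``force`` holds the working (possibly median-filtered, baseline-subtracted)
    force; after preprocessing, ``force_raw`` keeps the baseline-subtracted but
    unfiltered samples so detectors can localise single-sample discontinuities
    without filter smearing.
    """

    separation: np.ndarray  # nm
    force: np.ndarray  # nN
    direction: str = APPROACH
    metadata: dict = field(default_factory=dict)
    force_raw: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.separation = np.asarray(self.separation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.direction not in (APPROACH, RETRACT):
            raise ValueError(f"direction must be approach|retract, got {self.direction!r}")
        if self.separation.ndim != 1 or self.separation.shape != self.force.shape:
            raise ValueError("separation and force must be 1D arrays of equal length")
        if len(self.separation) < 16:
            raise ValueError("force curve must hold at least 16 samples")
        if not (np.all(np.isfinite(self.separation)) and np.all(np.isfinite(self.force))):
            raise ValueError("force curve contains non-finite values")
        ds = np.diff(self.separation)
        if self.direction == APPROACH and not np.all(ds < 0):
            raise ValueError("approach curve separation must strictly decrease")
        if self.direction == RETRACT and not np.all(ds > 0):
            raise ValueError("retract curve separation must strictly increase")

    def __len__(self) -> int:
        return len(self.separation)

    @property
    def is_preprocessed(self) -> bool:
        return bool(self.metadata.get("preprocessed", False))


@dataclass
class RuptureEvent:
    """One detected membrane breakthrough.

    ``rupture_force`` is the force at the point of yield (the last sample on
    the loading ramp before the drop); ``thickness`` is the separation span
    from the yield point to the subsequent force increase.
    """

    yield_separation: float  # nm
    rupture_force: float  # nN
    thickness: float  # nm
    force_drop: float  # nN
    index_in_curve: int
    yield_index: int = -1
    recovery_index: int = -1
    label: Optional[str] = None  # alpha | beta | gamma

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ValueError("rupture thickness must be positive")


@dataclass
class CurveResult:
    """Per-curve detection outcome."""

    events: list
    contact_point: Optional[float] = None  # nm
    curve_id: Optional[str] = None
    warnings: list = field(default_factory=list)

    @property
    def step_count(self) -> int:
        return len(self.events)

    @property
    def final_rupture_force(self) -> Optional[float]:
        return self.events[-1].rupture_force if self.events else None


@dataclass
class HeightMap:
    """Calibrated 2D topography in nm."""

    heights: np.ndarray  # nm, shape (ny, nx)
    pixel_size: float  # nm / pixel
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("height map must be 2D")
        if min(self.heights.shape) < 64:
            raise ValueError("height map must be at least 64x64 pixels")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("height map contains non-finite values")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self):
        return self.heights.shape

    @property
    def extent_nm(self):
        ny, nx = self.heights.shape
        return ny * self.pixel_size, nx * self.pixel_size


#: Canonical ordering of segmentation classes from lowest to highest surface.
CLASS_ORDER = ("substrate", "fluid", "solid", "rough", "bump", "vesicle")
LIPID_CLASSES = ("fluid", "solid", "rough", "bump")


@dataclass
class SegmentLabelMap:
    """Per-pixel phase classification of a height map."""

    labels: np.ndarray  # int codes into class_names
    class_names: list  # index -> name
    class_heights: dict  # name -> nm

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2D")
        order = {name: i for i, name in enumerate(CLASS_ORDER)}
        heights = [
            self.class_heights[n]
            for n in sorted(self.class_heights, key=lambda n: order.get(n, 99))
            if n in ("substrate", "fluid", "solid")
        ]
        if heights != sorted(heights):
            raise ValueError("class heights must be ordered substrate < fluid < solid")

    def mask(self, *names: str) -> np.ndarray:
        codes = [i for i, n in enumerate(self.class_names) if n in names]
        return np.isin(self.labels, codes)

    @property
    def present_classes(self) -> list:
        present = np.unique(self.labels)
        return [self.class_names[i] for i in present]


@dataclass
class SizeDistribution:
    """Particle-diameter weights (intensity weighting) on an increasing grid."""

    diameters: np.ndarray  # nm
    weights: np.ndarray  # fractions, sum to 1

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.diameters.shape != self.weights.shape or self.diameters.ndim != 1:
            raise ValueError("diameters and weights must be 1D arrays of equal length")
        if not np.all(np.diff(self.diameters) > 0):
            raise ValueError("diameters must be strictly increasing")
        if np.any(self.diameters <= 0):
            raise ValueError("diameters must be positive")
        if np.any(self.weights < -1e-12):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if not np.isclose(total, 1.0, rtol=0, atol=1e-6):
            raise ValueError(f"weights must sum to 1 (got {total:.6g})")


@dataclass
class Correlogram:
    """Measured or modelled intensity autocorrelation g2(tau)."""

    lags: np.ndarray  # s
    g2: np.ndarray
    noise_sd: Optional[float] = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if self.lags.shape != self.g2.shape or self.lags.ndim != 1:
            raise ValueError("lags and g2 must be 1D arrays of equal length")
        if np.any(self.lags <= 0) or not np.all(np.diff(self.lags) > 0):
            raise ValueError("lags must be positive and strictly increasing")
        if not np.all(np.isfinite(self.g2)):
            raise ValueError("g2 contains non-finite values")
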