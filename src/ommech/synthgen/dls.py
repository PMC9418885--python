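"""Synthetic DLS correlograms from known size distributions.

The noiseless signal comes from the same forward model used by the
inversion (``ommech.dlsinv.g2_model``); this module only adds measurement
noise, so generator and inverter can never drift apart physically.
"""

from __future__ import annotations

import numpy as np

from ..datatypes import Correlogram, SizeDistribution
from ..dlsinv import InstrumentSpec, default_lag_grid, g2_model
from .seeds import TAG_DLS, child_rng


def gen_correlogram(
    dist: SizeDistribution,
    instrument: InstrumentSpec,
    lags=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    counter: int = 0,
) -> Correlogram:
    """Forward-model g2(tau) and add Gaussian noise of sd ``noise_sd``."""
    lags = default_lag_grid() if lags is None else np.asarray(lags, dtype=float)
    clean = g2_model(dist, instrument, lags)
    g2 = clean.g2
    if noise_sd > 0:
        rng = child_rng(seed, TAG_DLS, counter)
        g2 = g2 + rng.normal(0.0, noise_sd, size=len(lags))
    return Correlogram(lags=lags, g2=g2, noise_sd=float(noise_sd))


def monodisperse(diameter_nm: float, grid=None) -> SizeDistribution:
    """Delta distribution at (the grid point nearest to) a diameter."""
    if grid is None:
        d = np.array([diameter_nm], dtype=float)
        w = np.array([1.0])
        return SizeDistribution(diameters=d, weights=w)
    grid = np.asarray(grid, dtype=float)
    w = np.zeros_like(grid)
    w[int(np.argmin(np.abs(np.log(grid) - np.log(diameter_nm))))] = 1.0
    return SizeDistribution(diameters=grid, weights=w)
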