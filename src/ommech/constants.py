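"""Physical constants and tabulated water properties used across the package.

Viscosity and refractive index are tabulated rather than hard-coded at call
sites so that instrument specifications at any experimental temperature pick
up consistent values.
"""

from __future__ import annotations

import numpy as np

#: Boltzmann constant, J/K.
BOLTZMANN_K = 1.380649e-23

#: Dynamic viscosity of water, Pa*s, by temperature in deg C (CRC handbook
#: values; linearly interpolated in between).
WATER_VISCOSITY_TABLE = {
    10.0: 1.3059e-3,
    15.0: 1.1375e-3,
    20.0: 1.0016e-3,
    25.0: 0.8900e-3,
    30.0: 0.7972e-3,
    35.0: 0.7190e-3,
    40.0: 0.6527e-3,
}

#: Refractive index of water near 457 nm (weak dispersion and temperature
#: dependence are ignored at the precision DLS sizing requires).
WATER_REFRACTIVE_INDEX = 1.340


def water_viscosity(temperature_k: float) -> float:
    """Dynamic viscosity of water in Pa*s at the given temperature (K).

    Linear interpolation in the tabulated 10-40 deg C range; temperatures
    outside the table raise ``ValueError`` rather than extrapolating.
    """
    t_c = float(temperature_k) - 273.15
    temps = np.array(sorted(WATER_VISCOSITY_TABLE))
    viscs = np.array([WATER_VISCOSITY_TABLE[t] for t in temps])
    if not (temps[0] <= t_c <= temps[-1]):
        raise ValueError(
            f"temperature {t_c:.1f} C outside tabulated range "
            f"[{temps[0]:.0f}, {temps[-1]:.0f}] C"
        )
    return float(np.interp(t_c, temps, viscs))
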