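"""Environmental sample container: one (station, depth) grid point.

Holds temperature, dissolved nutrient concentrations and the downwelling
spectral irradiance on the 400–700 nm / 5 nm grid used throughout the
package.  PAR is the spectral integral and is validated against the cached
value to 0.5%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WAVELENGTHS", "DELTA_LAMBDA", "EnvironmentSample"]

#: Wavelength grid, nm (inclusive), and its step.
WAVELENGTHS = np.arange(400.0, 701.0, 5.0)
DELTA_LAMBDA = 5.0


@dataclass
class EnvironmentSample:
    """In situ conditions at one (station, depth).

    nutrients: substrate id (extracellular metabolite id, e.g. ``nh4_e``)
    → concentration in mol·m⁻³.  irradiance_spectrum: E(λ) in
    µmol photons·m⁻²·s⁻¹·nm⁻¹ on :data:`WAVELENGTHS`.
    """

    station: str
    latitude: float
    depth: float            # m, positive down
    temperature: float      # K
    nutrients: dict[str, float]
    irradiance_spectrum: np.ndarray
    par: float = None       # µmol photons m-2 s-1; computed if omitted

    def __post_init__(self):
        self.irradiance_spectrum = np.asarray(self.irradiance_spectrum, dtype=float)
        if self.irradiance_spectrum.shape != WAVELENGTHS.shape:
            raise ValueError(
                f"irradiance spectrum must be on the {len(WAVELENGTHS)}-point grid"
            )
        if np.any(self.irradiance_spectrum < 0):
            raise ValueError("negative irradiance")
        if any(v < 0 for v in self.nutrients.values()):
            raise ValueError("negative nutrient concentration")
        integral = float(np.sum(self.irradiance_spectrum) * DELTA_LAMBDA)
        if self.par is None:
            self.par = integral
        elif integral > 0 and abs(self.par - integral) > 5e-3 * max(integral, 1e-12):
            raise ValueError(
                f"cached PAR {self.par} inconsistent with spectral integral {integral}"
            )

    @property
    def key(self) -> tuple:
        return (self.station, self.depth)
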