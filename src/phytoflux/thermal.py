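"""Thermal performance scaling of growth and metabolic rates.

The dimensionless factor γ(T) follows a Sharpe–Schoolfield-type form with
high-temperature inactivation,

    A(T) = exp[−E_a/R (1/T − 1/T_ref)] / (1 + exp[E_h/R (1/T_h − 1/T)])
    γ(T) = A(T) / A(OGT),

which preserves the Arrhenius parameterization on the sub-optimal limb
(ln γ linear in 1/T with slope −E_a/R) while exhibiting a single optimum.
The inactivation half-point T_h is fixed by requiring argmax A = OGT, which
has the closed form 1/T_h = 1/OGT + (R/E_h)·ln[E_a/(E_h − E_a)].

γ multiplies all fluxes uniformly; scaling a feasible steady-state flux
vector by a scalar preserves S·v = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["R_GAS", "ThermalParams", "thermal_factor", "fit_arrhenius",
           "apply_thermal_scaling"]

R_GAS = 8.31446261815324e-3  # kJ mol-1 K-1

T_REF = 293.15  # K; cancels under the γ normalization


@dataclass(frozen=True)
class ThermalParams:
    """Per-strain thermal response: activation energy E_a (kJ/mol), optimal
    growth temperature OGT (K), inactivation energy E_h (kJ/mol)."""

    E_a: float
    OGT: float
    E_h: float = 200.0

    def __post_init__(self):
        if not (self.E_h > self.E_a > 0):
            raise ValueError("require E_h > E_a > 0")
        if not 250 < self.OGT < 330:
            raise ValueError("OGT outside plausible range (250, 330) K")

    @property
    def T_h(self) -> float:
        """Inactivation half-point (K) from the analytic argmax condition."""
        inv = 1.0 / self.OGT + (R_GAS / self.E_h) * math.log(
            self.E_a / (self.E_h - self.E_a)
        )
        return 1.0 / inv


def _raw(T, params: ThermalParams):
    T = np.asarray(T, dtype=float)
    arr = np.exp(-params.E_a / R_GAS * (1.0 / T - 1.0 / T_REF))
    inact = 1.0 + np.exp(params.E_h / R_GAS * (1.0 / params.T_h - 1.0 / T))
    return arr / inact


def thermal_factor(T, params: ThermalParams):
    """γ(T) ∈ (0, 1], normalized so γ(OGT) = 1; T in K (scalar or array)."""
    Ta = np.asarray(T, dtype=float)
    if np.any(Ta <= 250) or np.any(Ta >= 330):
        raise ValueError("temperature outside supported range (250, 330) K")
    out = _raw(Ta, params) / _raw(params.OGT, params)
    return float(out) if np.isscalar(T) or Ta.ndim == 0 else out


def fit_arrhenius(growth_rates, temperatures) -> float:
    """Activation energy E_a (kJ/mol) from the sub-optimal limb.

    Least squares of ln μ on 1/T restricted to observations below the
    empirical optimum temperature; E_a = −slope·R.  Requires ≥3 sub-optimal
    points with μ > 0.
    """
    mu = np.asarray(growth_rates, dtype=float)
    T = np.asarray(temperatures, dtype=float)
    if mu.shape != T.shape:
        raise ValueError("growth_rates and temperatures must align")
    if np.any(mu <= 0):
        raise ValueError("growth rates must be positive")
    t_opt = T[np.argmax(mu)]
    mask = T <= t_opt
    if mask.sum() < 3:
        raise ValueError("insufficient sub-optimal observations (need >= 3)")
    x = 1.0 / T[mask]
    y = np.log(mu[mask])
    slope = np.polyfit(x, y, 1)[0]
    return float(-slope * R_GAS)


def apply_thermal_scaling(result, T: float, params: ThermalParams):
    """Scale an acclimation result's growth rate and fluxes by γ(T).

    Composition, transporter counts and geometry are left untouched; only
    rates change.  Returns a new result object.
    """
    gamma = thermal_factor(T, params)
    return result.scaled(gamma)
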