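"""Transect orchestration, population scaling and ecosystem diagnostics.

One strain in one environment runs the acclimation pipeline: transporter /
cell-size optimization (OptTrans) → composition / pigment optimization
(PhysOpt) → thermal scaling.  Strains are then scaled to ecotypes and
populations: each ecotype is represented by its fittest strain per sample
and population quantities are abundance-weighted means.

Diagnostics derived here: photosynthesis–irradiance (PI) curve fits (Webb
exponential form, whose parameters are the initial slope α, the
assimilation number P^B_max and the saturation irradiance E_k = P^B_max/α),
the quantum yield of carbon fixation, the f-ratio (share of N uptake
supplied by nitrate), gross oxygen production, density-dependent mortality
fits, and strain-pair relative-growth comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import MetabolicNetwork, build_flux_problem
from .environment import EnvironmentSample
from .physiology import (
    AcclimationResult, BiomassComposition, PhysOptOptions, default_composition,
    harvest_photon_flux, optimize_physiology, composition_metrics,
    build_biomass_reaction,
)
from .thermal import ThermalParams, thermal_factor
from .transport import (
    TransporterSpec, TransporterState, CellGeometry, optimize_transporters,
    find_transport_reaction, uptake_rate, per_cell_to_specific,
    specific_to_per_cell, default_radius_grid, AVOGADRO,
)
from . import fba

__all__ = [
    "PICurve",
    "DensityDependenceFit",
    "PopulationField",
    "acclimate_strain",
    "simulate_transect",
    "population_weight",
    "fit_pi_curve",
    "quantum_yield",
    "nitrogen_diagnostics",
    "gross_oxygen_production",
    "fit_density_dependence",
    "compare_strains",
]

MG_C_PER_MMOL = 12.011

_N_TRANSPORTERS = ("TR_NH4", "TR_NO2", "TR_NO3")


# ---------------------------------------------------------------------------
# single-strain acclimation
# ---------------------------------------------------------------------------

def _limiting_resource(model, composition, env, uptake_bounds, opts) -> str:
    """Classify the limiting resource by μ-elasticity of the uptake bounds.

    Elasticity = (marginal μ gain per unit bound relaxation) × flux / μ, a
    dimensionless share that is comparable across substrates with very
    different molar demands.  Energy uses the photon mass-balance shadow
    price × absorbed flux.
    """
    from .physiology import _apply_env_bounds, _model_with_biomass

    net = _model_with_biomass(model, composition)
    prob = build_flux_problem(net)
    phi_h = _apply_env_bounds(net, prob, composition, env, uptake_bounds, opts)
    sol = fba.solve_fba(prob, net.biomass_reaction_id)
    if sol.status != "optimal" or sol.objective_value <= 0:
        return "energy" if phi_h <= 1e-9 else "none"
    mu = sol.objective_value
    rxn_ids = set(prob.col_ids)

    def elasticity(rid):
        if rid not in rxn_ids:
            return 0.0
        s = sol.bound_sensitivities.get(rid, 0.0)
        return abs(s) * abs(sol.fluxes.get(rid, 0.0)) / mu

    scores = {
        "nitrogen": max(elasticity(r) for r in _N_TRANSPORTERS),
        "phosphorus": elasticity("TR_PO4"),
        "carbon": elasticity("TR_CO2"),
        "energy": abs(sol.duals.get("photon_c", 0.0)) * phi_h / mu,
    }
    best = max(scores, key=lambda k: (scores[k], k))
    return best if scores[best] > 1e-6 else "none"


def acclimate_strain(
    strain_model: MetabolicNetwork,
    specs: list[TransporterSpec],
    env: EnvironmentSample,
    thermal_params: ThermalParams = None,
    composition: BiomassComposition = None,
    strain_id: str = None,
    r_grid=None,
    physopt_options: PhysOptOptions = None,
    mode: str = "full",
) -> AcclimationResult:
    """Full acclimation pipeline for one strain at one grid point.

    mode="full": OptTrans → PhysOpt → thermal scaling (the default).
    mode="frozen": the strain keeps its nutrient-replete batch phenotype —
    transporter counts sized for saturating uptake, default composition, no
    compositional or pigment optimization — and only experiences the ambient
    uptake kinetics, light and temperature.  The contrast between the two
    modes measures the fitness gain of acclimation.
    """
    strain_id = strain_id or strain_model.annotations.get("strain_id", "strain")
    comp0 = (composition or default_composition()).copy()
    opts = physopt_options or PhysOptOptions()
    phi0 = harvest_photon_flux(comp0.pigments, env.irradiance_spectrum)

    if mode == "full":
        ot = optimize_transporters(
            strain_model, specs, env, r_grid=r_grid,
            photon_bound=lambda dm: phi0,
        )
        uptake_bounds = {
            find_transport_reaction(strain_model, sid): ub
            for sid, ub in ot.uptake_bounds.items()
        }
        result = optimize_physiology(
            strain_model, uptake_bounds, env, comp0, opts, strain_id=strain_id,
        )
    elif mode == "frozen":
        ot = _frozen_transporters(strain_model, specs, env, r_grid)
        uptake_bounds = {
            find_transport_reaction(strain_model, sid): ub
            for sid, ub in ot.uptake_bounds.items()
        }
        pinched = comp0.copy()
        for p in pinched.pools:
            if p.name != "pigment":
                p.bounds = (p.mass_fraction, p.mass_fraction)
        for p in pinched.pigments:
            p.bounds = (p.quota, p.quota)
        pinched.sync_pigment_pool()
        result = optimize_physiology(
            strain_model, uptake_bounds, env, pinched, opts, strain_id=strain_id,
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    result.radius = ot.geometry.radius
    result.transporters = ot.states
    result.diagnoses = ot.diagnoses
    if result.status == "optimal" and result.mu > 0:
        result.limiting_resource = _limiting_resource(
            strain_model, result.composition, env, uptake_bounds, opts,
        )
    else:
        result.limiting_resource = "energy" if phi0 <= 1e-9 else "none"
    if thermal_params is not None:
        result = result.scaled(thermal_factor(env.temperature, thermal_params))
    return result


def _frozen_transporters(strain_model, specs, env, r_grid):
    """Replete batch phenotype: mid-grid radius, transporters sized for the
    saturating-uptake demand (the porter limit), exposed to ambient S∞."""
    from .transport import OptTransResult, classify_limitation, _exchange_for

    grid = r_grid if r_grid is not None else default_radius_grid()
    radius = float(grid[len(grid) // 2])
    geom = CellGeometry(radius)
    prob = build_flux_problem(strain_model)
    tr = {s.substrate_id: find_transport_reaction(strain_model, s.substrate_id)
          for s in specs}
    for s in specs:
        prob.v_ub[prob.col(tr[s.substrate_id])] = 1000.0
        ex = _exchange_for(strain_model, s.substrate_id)
        if ex is not None:
            prob.v_lb[prob.col(ex)] = -1000.0
    sat = fba.solve_fba(prob, strain_model.biomass_reaction_id)
    states, bounds, diagnoses = {}, {}, {}
    for s in sorted(specs, key=lambda s: s.substrate_id):
        demand = sat.fluxes.get(tr[s.substrate_id], 0.0) if sat.status == "optimal" else 0.0
        demand_cell = specific_to_per_cell(max(demand, 0.0), geom.dry_mass)
        n = demand_cell * AVOGADRO / s.k_cat * 1.05 if demand_cell > 0 else 0.0
        st = TransporterState(s, n, n_star=n)
        sinf = env.nutrients.get(s.substrate_id, 0.0)
        v = uptake_rate(st, geom, sinf)
        states[s.substrate_id] = st
        bounds[s.substrate_id] = per_cell_to_specific(v, geom.dry_mass)
        diagnoses[s.substrate_id] = classify_limitation(
            st, geom, sinf, max(demand_cell, 1e-30), 0.0,
        )
    return OptTransResult(
        mu=float("nan"), geometry=geom, states=states, uptake_bounds=bounds,
        diagnoses=diagnoses, area_budget_used=0.0,
    )


# ---------------------------------------------------------------------------
# transect
# ---------------------------------------------------------------------------

def simulate_transect(
    strain_configs, samples, mode: str = "full", r_grid=None, progress=False,
) -> dict:
    """Acclimate every strain at every sample; (strain_id, sample.key) → result.

    Per-cell failures are recorded as zero-growth results, never fatal.
    Iteration order is deterministic (strains, then samples, as given).
    """
    results = {}
    for cfg in strain_configs:
        for env in samples:
            try:
                res = acclimate_strain(
                    cfg.model, cfg.transporter_specs, env, cfg.thermal,
                    composition=cfg.composition, strain_id=cfg.strain_id,
                    r_grid=r_grid, mode=mode,
                )
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"{cfg.strain_id}@{env.key}: {exc}")
                res = AcclimationResult(
                    strain_id=cfg.strain_id, environment=env, mu=0.0, fluxes={},
                    composition=cfg.composition, metrics=composition_metrics(cfg.composition),
                    absorbed_photons={}, status="failed",
                )
            results[(cfg.strain_id, env.key)] = res
            if progress:
                print(f"{cfg.strain_id} {env.key} mu={res.mu:.4g}")
    return results


# ---------------------------------------------------------------------------
# population scaling
# ---------------------------------------------------------------------------

@dataclass
class PopulationField:
    """Abundance-weighted population quantities over the sample grid.

    ``weighted[quantity][sample_key]`` is the abundance-weighted mean over
    ecotypes (each represented by its fittest strain); samples with zero
    total abundance carry the explicit missing marker ``None``.
    """

    abundances: dict                 # (ecotype, sample_key) -> cells/mL
    representative_strain: dict      # (ecotype, sample_key) -> strain_id
    weighted: dict                   # quantity -> {sample_key: value | None}
    volumetric_gop: dict = field(default_factory=dict)  # mmol O2 m-3 h-1


def population_weight(results: dict, abundances: dict, ecotype_of: dict) -> PopulationField:
    """Scale strain results to populations.

    Each ecotype is represented at each sample by its highest-μ strain (ties
    broken lexicographically); quantities are weighted by ecotype abundance.
    """
    sample_keys = sorted({k[1] for k in results}, key=str)
    strains_by_eco: dict[str, list[str]] = {}
    for sid, eco in ecotype_of.items():
        strains_by_eco.setdefault(eco, []).append(sid)
    rep, weighted = {}, {}
    quantities = ("growth_rate_d", "c_to_n", "enthalpy", "gop", "f_ratio")
    weighted = {q: {} for q in quantities}
    vol_gop = {}
    for sk in sample_keys:
        entries = []  # (abundance, result)
        for eco, strain_ids in sorted(strains_by_eco.items()):
            ab = abundances.get((eco, sk), 0.0)
            cands = [(results[(s, sk)].mu, s) for s in sorted(strain_ids)
                     if (s, sk) in results]
            if not cands:
                continue
            # ties: max mu, then lexicographically smallest strain id
            best_mu = max(m for m, _ in cands)
            best_sid = min(s for m, s in cands if m == best_mu)
            rep[(eco, sk)] = best_sid
            if ab > 0:
                entries.append((ab, results[(best_sid, sk)]))
        total = sum(ab for ab, _ in entries)
        if total <= 0:
            for q in quantities:
                weighted[q][sk] = None
            vol_gop[sk] = None
            continue
        def wmean(fn):
            vals = [(ab, fn(res)) for ab, res in entries]
            vals = [(ab, v) for ab, v in vals if v is not None]
            tot = sum(ab for ab, _ in vals)
            return sum(ab * v for ab, v in vals) / tot if tot > 0 else None
        weighted["growth_rate_d"][sk] = wmean(lambda r: r.mu * 24.0)
        weighted["c_to_n"][sk] = wmean(lambda r: r.metrics.c_to_n)
        weighted["enthalpy"][sk] = wmean(lambda r: r.metrics.enthalpy)
        weighted["gop"][sk] = wmean(gross_oxygen_production)
        weighted["f_ratio"][sk] = wmean(lambda r: nitrogen_diagnostics(r)[0])
        vol = 0.0
        for ab, res in entries:
            dm = CellGeometry(res.radius).dry_mass if res.radius else 0.0
            # cells mL⁻¹ → cells m⁻³ (×1e6); gDW cell⁻¹ × mmol gDW⁻¹ h⁻¹
            vol += ab * 1e6 * dm * gross_oxygen_production(res)
        vol_gop[sk] = vol
    return PopulationField(dict(abundances), rep, weighted, vol_gop)


# ---------------------------------------------------------------------------
# PI curves
# ---------------------------------------------------------------------------

@dataclass
class PICurve:
    """Webb exponential PI fit: P = P_max (1 − exp(−α E / P_max))."""

    alpha: float     # gC gChl⁻¹ h⁻¹ per (µmol photons m⁻² s⁻¹)
    p_max_b: float   # assimilation number, gC gChl⁻¹ h⁻¹
    r_squared: float
    saturating: bool = True

    def __post_init__(self):
        if self.alpha <= 0 or self.p_max_b <= 0:
            raise ValueError("alpha and P_max must be positive")

    @property
    def e_k(self) -> float:
        """Saturation irradiance, µmol photons m⁻² s⁻¹ (= P_max/α)."""
        return self.p_max_b / self.alpha


def fit_pi_curve(P, E) -> PICurve:
    """Least-squares Webb fit of chlorophyll-normalized photosynthesis
    against irradiance; warns (``saturating=False``) if the data do not
    reach the fitted saturation irradiance."""
    P = np.asarray(P, dtype=float)
    E = np.asarray(E, dtype=float)
    if len(P) < 4:
        raise ValueError("need at least 4 points")
    if np.any(np.diff(E) <= 0):
        raise ValueError("irradiances must be strictly increasing")

    def webb(e, pmax, alpha):
        return pmax * (1.0 - np.exp(-alpha * e / pmax))

    nz = np.nonzero(E > 0)[0]
    alpha0 = P[nz[0]] / E[nz[0]] if P[nz[0]] > 0 else 1e-3
    p0 = (max(P.max(), 1e-9), max(alpha0, 1e-9))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(webb, E, P, p0=p0, maxfev=20000)
    pmax, alpha = float(popt[0]), float(popt[1])
    pred = webb(E, pmax, alpha)
    ss_res = float(np.sum((P - pred) ** 2))
    ss_tot = float(np.sum((P - P.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    fit = PICurve(alpha=alpha, p_max_b=pmax, r_squared=r2,
                  saturating=bool(E.max() >= pmax / alpha))
    if not fit.saturating:
        warnings.warn("PI data do not reach the saturation irradiance E_k")
    return fit


def pi_curve_points(results: list[AcclimationResult]):
    """(P^B, E) pairs from acclimation results: carboxylation flux converted
    to gC gChl⁻¹ h⁻¹ against sample PAR."""
    pts = []
    for r in results:
        chl = r.composition.chlorophyll_per_dw
        if chl <= 0:
            continue
        p_b = r.fluxes.get("CBB", 0.0) * MG_C_PER_MMOL / chl
        pts.append((p_b, r.environment.par))
    pts.sort(key=lambda t: t[1])
    P = [p for p, _ in pts]
    E = [e for _, e in pts]
    return P, E


# ---------------------------------------------------------------------------
# per-result diagnostics
# ---------------------------------------------------------------------------

def quantum_yield(result: AcclimationResult):
    """mol C fixed by carboxylation per mol photons absorbed by the
    light-harvesting pigments; None when nothing is absorbed."""
    phi = result.harvest_photon_flux
    if phi <= 0:
        return None
    return result.fluxes.get("CBB", 0.0) / phi


def nitrogen_diagnostics(result: AcclimationResult):
    """(f-ratio, per-source N uptake fluxes); f-ratio None if no N uptake."""
    v = {rid: max(result.fluxes.get(rid, 0.0), 0.0) for rid in _N_TRANSPORTERS}
    total = sum(v.values())
    if total <= 0:
        return None, v
    return v["TR_NO3"] / total, v


def gross_oxygen_production(result: AcclimationResult) -> float:
    """PSII water-splitting O₂ evolution, mmol O₂ gDW⁻¹ h⁻¹ (the linear
    electron flow reaction evolves one O₂ per 8 photons)."""
    return max(result.fluxes.get("PSET", 0.0), 0.0)


# ---------------------------------------------------------------------------
# density dependence
# ---------------------------------------------------------------------------

@dataclass
class DensityDependenceFit:
    """Steady-state density-dependent mortality: dB/dt = μB − mB^x = 0 gives
    μ = m B^(x−1), fit in log–log space; the linear-mortality alternative
    predicts a B-independent μ."""

    m: float
    x: float
    r_squared_power: float
    r_squared_linear: float

    def __post_init__(self):
        if self.x <= 0:
            raise ValueError("density exponent must be positive")

    @property
    def preferred(self) -> str:
        return "power" if self.r_squared_power > self.r_squared_linear + 1e-9 else "linear"


def fit_density_dependence(abundances, growth_rates) -> DensityDependenceFit:
    B = np.asarray(abundances, dtype=float)
    mu = np.asarray(growth_rates, dtype=float)
    mask = (B > 0) & (mu > 0)
    B, mu = B[mask], mu[mask]
    if len(B) < 4:
        raise ValueError("need at least 4 positive (B, mu) pairs")
    lb, lm = np.log(B), np.log(mu)
    slope, intercept = np.polyfit(lb, lm, 1)
    pred = slope * lb + intercept
    ss_tot = float(np.sum((lm - lm.mean()) ** 2))
    # zero growth-rate variance: density dependence explains nothing
    r2_power = 1.0 - float(np.sum((lm - pred) ** 2)) / ss_tot if ss_tot > 0 else 0.0
    # linear-mortality alternative: mu independent of B (OLS mu ~ B)
    b1, b0 = np.polyfit(B, mu, 1)
    pred_lin = b0 + b1 * B
    ss_tot_lin = float(np.sum((mu - mu.mean()) ** 2))
    r2_lin = (1.0 - float(np.sum((mu - pred_lin) ** 2)) / ss_tot_lin
              if ss_tot_lin > 0 else 0.0)
    x = 1.0 + float(slope)
    if x <= 0:
        x = 1e-6
    return DensityDependenceFit(
        m=float(np.exp(intercept)), x=x,
        r_squared_power=max(r2_power, 0.0), r_squared_linear=max(r2_lin, 0.0),
    )


# ---------------------------------------------------------------------------
# strain-pair comparison
# ---------------------------------------------------------------------------

def compare_strains(results_a: dict, results_b: dict) -> pd.DataFrame:
    """Relative growth field 100·(μ_A − μ_B)/μ_B plus limiting resources.

    Inputs map sample_key → AcclimationResult for each strain on the same
    grid; μ_B = 0 cells get a missing marker (NaN).
    """
    keys_a = set(results_a)
    if keys_a != set(results_b):
        raise ValueError("strain results are not on the same grid")
    rows = []
    for sk in sorted(keys_a, key=str):
        ra, rb = results_a[sk], results_b[sk]
        rel = (100.0 * (ra.mu - rb.mu) / rb.mu) if rb.mu > 0 else float("nan")
        rows.append({
            "station": ra.environment.station,
            "depth_m": ra.environment.depth,
            "relative_growth_pct": rel,
            "mu_a": ra.mu, "mu_b": rb.mu,
            "limiting_a": ra.limiting_resource,
            "limiting_b": rb.limiting_resource,
        })
    return pd.DataFrame(rows)
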