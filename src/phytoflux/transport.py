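"""Mechanistic nutrient uptake and transporter optimization (OptTrans).

Uptake by a spherical cell of radius r carrying n copies of a transporter
follows a Michaelis form that interpolates exactly between the two physical
limits:

- the diffusive encounter limit ``4 π D r S∞`` (all molecules reaching the
  cell surface are taken up), and
- the porter limit ``n k_cat`` (every transporter works at full turnover),

via ``v = V_max S∞ / (S∞ + K_eff)`` with ``V_max = n k_cat / N_A`` (mol
cell⁻¹ s⁻¹) and ``K_eff = V_max / (4 π D r)``.  The critical concentration
S* is the ambient level at which uptake just meets the demand of the rest
of metabolism; above it the cell is growth-limited and uptake is clamped to
demand by the flux balance itself.

OptTrans searches a deterministic radius grid and a set of transporter
allocations subject to the membrane area budget ``Σ n_i a_i ≤ f_A 4πr²``,
scoring each candidate by FBA growth rate with transporter synthesis debited
as a growth-associated ATP increment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import MetabolicNetwork, Reaction, build_flux_problem
from .environment import EnvironmentSample
from . import fba

__all__ = [
    "AVOGADRO",
    "TransporterSpec",
    "TransporterState",
    "CellGeometry",
    "UptakeDiagnosis",
    "uptake_rate",
    "critical_concentration",
    "classify_limitation",
    "optimize_transporters",
    "OptTransResult",
    "per_cell_to_specific",
    "specific_to_per_cell",
    "default_radius_grid",
]

AVOGADRO = 6.02214076e23

#: default fraction of the membrane area available to transporters
DEFAULT_AREA_FRACTION = 0.04
#: default dry mass per unit cell volume, g·µm⁻³ (250 fg µm⁻³)
DEFAULT_DW_DENSITY = 250e-15
#: cell-envelope synthesis cost per gDW of new biomass: the membrane/wall
#: mass per unit biomass scales with the surface:volume ratio (∝ 1/r), so
#: small cells pay a higher envelope cost per gram grown.  Debited both as
#: ATP (assembly energy) and as carbohydrate units (wall material), which is
#: what makes large cells optimal when uptake is not limiting.
DEFAULT_ENVELOPE_COST = 0.6     # mmol ATP · µm per gDW
DEFAULT_ENVELOPE_CARBON = 0.6   # mmol CH2O-equivalents · µm per gDW


@dataclass(frozen=True)
class TransporterSpec:
    """Physical parameters of one transporter type.

    k_cat: substrate molecules per transporter per second; footprint: membrane
    area per transporter, nm²; diffusivity: substrate molecular diffusivity,
    m² s⁻¹; synthesis_cost: mmol ATP-equivalents per mmol transporter.
    """

    substrate_id: str
    k_cat: float
    footprint: float = 25.0
    diffusivity: float = 1e-9
    synthesis_cost: float = 5e4

    def __post_init__(self):
        for f in ("k_cat", "footprint", "diffusivity", "synthesis_cost"):
            if getattr(self, f) <= 0:
                raise ValueError(f"TransporterSpec.{f} must be > 0")


@dataclass
class TransporterState:
    spec: TransporterSpec
    n: float            # transporters per cell, continuous
    n_star: float = None  # optimal count once known

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("transporter count must be >= 0")


@dataclass(frozen=True)
class CellGeometry:
    """Spherical cell geometry; derived fields follow from the radius."""

    radius: float                       # µm
    dw_density: float = DEFAULT_DW_DENSITY  # g per µm³

    @property
    def volume(self) -> float:
        """µm³"""
        return 4.0 / 3.0 * math.pi * self.radius ** 3

    @property
    def membrane_area(self) -> float:
        """µm²"""
        return 4.0 * math.pi * self.radius ** 2

    @property
    def membrane_area_nm2(self) -> float:
        return self.membrane_area * 1e6

    @property
    def dry_mass(self) -> float:
        """gDW per cell"""
        return self.dw_density * self.volume


def _vmax(state: TransporterState) -> float:
    """Porter-limited uptake, mol cell⁻¹ s⁻¹."""
    return state.n * state.spec.k_cat / AVOGADRO


def k_eff(state: TransporterState, geometry: CellGeometry) -> float:
    """Effective half-saturation, mol m⁻³: V_max / (4 π D r)."""
    r_m = geometry.radius * 1e-6
    return _vmax(state) / (4.0 * math.pi * state.spec.diffusivity * r_m)


def uptake_rate(state: TransporterState, geometry: CellGeometry, s_infinity: float) -> float:
    """Uptake in mol cell⁻¹ s⁻¹ at ambient concentration S∞ (mol m⁻³)."""
    if s_infinity < 0:
        raise ValueError("S_infinity must be >= 0")
    if state.n == 0 or s_infinity == 0:
        return 0.0
    vmax = _vmax(state)
    keff = k_eff(state, geometry)
    return vmax * s_infinity / (s_infinity + keff)


def critical_concentration(
    state: TransporterState, geometry: CellGeometry, demand: float
) -> float:
    """S* (mol m⁻³): ambient concentration at which uptake equals demand.

    Above S* uptake is held at the demanded level; if demand ≥ V_max no
    concentration suffices and S* = +inf.
    """
    if demand <= 0:
        raise ValueError("demand must be > 0")
    vmax = _vmax(state)
    if demand >= vmax:
        return math.inf
    return demand * k_eff(state, geometry) / (vmax - demand)


@dataclass
class UptakeDiagnosis:
    regime: str  # diffusion_limited | porter_limited | surface_area_limited | growth_limited
    s_infinity: float
    s_star: float
    uptake: float  # mol cell⁻¹ s⁻¹


def classify_limitation(
    state: TransporterState,
    geometry: CellGeometry,
    s_infinity: float,
    demand: float,
    area_budget_used: float,
) -> UptakeDiagnosis:
    """Assign the uptake limitation regime for one substrate.

    Growth limitation (S∞ > S*): supply exceeds demand and uptake is clamped.
    Otherwise the uptake machinery is limiting: by membrane space if the area
    budget is exhausted, by diffusion if S∞ sits below K_eff, else by porter
    turnover.
    """
    if not all(map(math.isfinite, (s_infinity, area_budget_used))):
        raise ValueError("inputs must be finite")
    s_star = critical_concentration(state, geometry, demand) if demand > 0 else 0.0
    v = uptake_rate(state, geometry, s_infinity)
    if s_infinity > s_star:
        return UptakeDiagnosis("growth_limited", s_infinity, s_star, min(v, demand))
    if area_budget_used >= 1.0 - 1e-6:
        return UptakeDiagnosis("surface_area_limited", s_infinity, s_star, v)
    if state.n > 0 and s_infinity < k_eff(state, geometry):
        return UptakeDiagnosis("diffusion_limited", s_infinity, s_star, v)
    return UptakeDiagnosis("porter_limited", s_infinity, s_star, v)


# ---------------------------------------------------------------------------
# unit conversions (centralized)
# ---------------------------------------------------------------------------

def per_cell_to_specific(v_mol_cell_s: float, dry_mass_g: float) -> float:
    """mol cell⁻¹ s⁻¹ → mmol gDW⁻¹ h⁻¹."""
    return v_mol_cell_s * 1000.0 * 3600.0 / dry_mass_g


def specific_to_per_cell(v_mmol_gdw_h: float, dry_mass_g: float) -> float:
    """mmol gDW⁻¹ h⁻¹ → mol cell⁻¹ s⁻¹."""
    return v_mmol_gdw_h * dry_mass_g / (1000.0 * 3600.0)


def transporters_per_cell_to_specific(n: float, dry_mass_g: float) -> float:
    """transporters cell⁻¹ → mmol transporter gDW⁻¹."""
    return n / AVOGADRO * 1000.0 / dry_mass_g


# ---------------------------------------------------------------------------
# OptTrans
# ---------------------------------------------------------------------------

def default_radius_grid(n: int = 16, lo: float = 0.25, hi: float = 1.0) -> np.ndarray:
    """Logarithmic radius grid in µm (deterministic)."""
    return np.geomspace(lo, hi, n)


@dataclass
class OptTransResult:
    mu: float
    geometry: CellGeometry
    states: dict[str, TransporterState]       # substrate_id -> state (n = n*)
    uptake_bounds: dict[str, float]           # substrate_id -> mmol/gDW/h
    diagnoses: dict[str, UptakeDiagnosis]
    area_budget_used: float
    fluxes: dict[str, float] = field(default_factory=dict)


def find_transport_reaction(network: MetabolicNetwork, substrate_id: str) -> str:
    """The (single) non-exchange reaction consuming an extracellular substrate."""
    hits = [
        r.id for r in network.reactions
        if not r.is_exchange and r.stoichiometry.get(substrate_id, 0) < 0
    ]
    if not hits:
        raise KeyError(f"no transport reaction consumes {substrate_id}")
    if len(hits) > 1:
        raise KeyError(f"ambiguous transport for {substrate_id}: {hits}")
    return hits[0]


def _exchange_for(network: MetabolicNetwork, substrate_id: str) -> str | None:
    for r in network.reactions:
        if r.is_exchange and substrate_id in r.stoichiometry:
            return r.id
    return None


def _debit_synthesis_cost(network: MetabolicNetwork, atp_mmol_per_gdw: float,
                          ch2o_mmol_per_gdw: float = 0.0) -> MetabolicNetwork:
    """Add growth-associated ATP and carbon increments to the biomass reaction.

    The debit is proportional to biomass flux (μ), so the inner problem stays
    an LP: cost·n per gDW of new biomass.
    """
    if atp_mmol_per_gdw <= 0 and ch2o_mmol_per_gdw <= 0:
        return network
    bio = network.reaction(network.biomass_reaction_id)
    st = dict(bio.stoichiometry)
    met_ids = {m.id for m in network.metabolites}
    for mid, coef in (("atp_c", -atp_mmol_per_gdw), ("h2o_c", -atp_mmol_per_gdw),
                      ("adp_c", atp_mmol_per_gdw), ("pi_c", atp_mmol_per_gdw),
                      ("ch2o_c", -ch2o_mmol_per_gdw)):
        if mid in met_ids and coef:
            st[mid] = st.get(mid, 0.0) + coef
    new_bio = replace(bio, stoichiometry=st)
    rxns = [new_bio if r.id == bio.id else r for r in network.reactions]
    return MetabolicNetwork(network.metabolites, rxns, network.biomass_reaction_id,
                            network.annotations)


def _n_for_demand(spec: TransporterSpec, geometry: CellGeometry,
                  s_inf: float, demand_cell: float) -> float:
    """Smallest n achieving ``uptake >= demand`` at S∞; inf if unreachable.

    Inverts v(n) = (n k/N_A) S / (S + n k / (N_A 4πDr)): diffusion caps the
    achievable uptake at 4πDrS regardless of n.
    """
    if demand_cell <= 0:
        return 0.0
    if s_inf <= 0:
        return math.inf
    r_m = geometry.radius * 1e-6
    diff_cap = 4.0 * math.pi * spec.diffusivity * r_m * s_inf
    if demand_cell >= diff_cap:
        return math.inf
    a = spec.k_cat / AVOGADRO
    b = spec.k_cat / (AVOGADRO * 4.0 * math.pi * spec.diffusivity * r_m)
    # v = a n S / (S + b n)  =>  n = v S / (a S - b v)
    return demand_cell * s_inf / (a * s_inf - b * demand_cell)


def _simplex_grid(k: int, steps: int = 4):
    """All nonnegative weight vectors on the k-simplex with denominator `steps`."""
    if k == 1:
        return [(1.0,)]
    out = []

    def rec(prefix, remaining, slots):
        if slots == 1:
            out.append(tuple(prefix + [remaining / steps]))
            return
        for i in range(remaining + 1):
            rec(prefix + [i / steps], remaining - i, slots - 1)

    rec([], steps, k)
    return out


def optimize_transporters(
    strain_model: MetabolicNetwork,
    specs: list[TransporterSpec],
    env: EnvironmentSample,
    r_grid: np.ndarray = None,
    f_area: float = DEFAULT_AREA_FRACTION,
    dw_density: float = DEFAULT_DW_DENSITY,
    envelope_cost: float = DEFAULT_ENVELOPE_COST,
    photon_bound: "callable | None" = None,
    objective_id: str = None,
) -> OptTransResult:
    """Joint deterministic optimization of transporter counts and cell radius.

    For each radius in the grid, a demand-seeded set of candidate allocations
    (scalings of the per-substrate demand solution, plus simplex splits of
    the full area budget when demand exceeds it) is scored by FBA with the
    transporter synthesis ATP debit.  Returns the allocation maximizing μ;
    ties break toward smaller radius, then candidate order.

    ``photon_bound`` may be a callable ``dry_mass_g -> mmol photons/gDW/h``
    fixing the photon transport flux for this environment (cell-size
    dependent light capture is per-gDW-invariant here, so it usually is a
    constant function).
    """
    if r_grid is None:
        r_grid = default_radius_grid()
    objective_id = objective_id or strain_model.biomass_reaction_id
    specs = sorted(specs, key=lambda s: s.substrate_id)
    tr_rxn = {s.substrate_id: find_transport_reaction(strain_model, s.substrate_id)
              for s in specs}

    base_prob = build_flux_problem(strain_model)

    best = None
    for radius in r_grid:
        geom = CellGeometry(float(radius), dw_density)
        area = f_area * geom.membrane_area_nm2
        dm = geom.dry_mass
        # demand probe at ambient-achievable capacity: each substrate's
        # uptake is bounded by the flux a full-membrane allocation could
        # sustain at S∞, so scarce substrates surface their co-substrate
        # demands (e.g. nitrate when ammonium cannot cover N)
        probe = base_prob.copy()
        cap = {}
        for s in specs:
            st_full = TransporterState(s, area / s.footprint)
            sinf = env.nutrients.get(s.substrate_id, 0.0)
            cap[s.substrate_id] = per_cell_to_specific(
                uptake_rate(st_full, geom, sinf), dm)
            probe.v_ub[probe.col(tr_rxn[s.substrate_id])] = cap[s.substrate_id]
            ex = _exchange_for(strain_model, s.substrate_id)
            if ex is not None:
                probe.v_lb[probe.col(ex)] = -1000.0
        if photon_bound is not None:
            _apply_photon_bound(strain_model, probe, photon_bound(dm))
        sat = fba.solve_fba(probe, objective_id)
        demand_cell = {
            s.substrate_id: specific_to_per_cell(
                max(sat.fluxes.get(tr_rxn[s.substrate_id], 0.0), 0.0)
                if sat.status == "optimal" else 0.0, dm)
            for s in specs
        }
        n_dem = {}
        for s in specs:
            sinf = env.nutrients.get(s.substrate_id, 0.0)
            nd = _n_for_demand(s, geom, sinf, demand_cell[s.substrate_id])
            # 5% margin: supply strictly exceeds demand at the optimum, so the
            # growth-limited (S∞ > S*) classification is numerically robust
            n_dem[s.substrate_id] = min(nd * 1.05, area / s.footprint)
        candidates = []
        total_fp = sum(n_dem[s.substrate_id] * s.footprint for s in specs)
        if total_fp <= area:
            for scale in (1.0, 0.75, 0.5, 0.25, 1.5, 2.0):
                cand = {
                    s.substrate_id: min(scale * n_dem[s.substrate_id], area / s.footprint)
                    for s in specs
                }
                if sum(cand[s.substrate_id] * s.footprint for s in specs) <= area * (1 + 1e-9):
                    candidates.append(cand)
        else:
            # demand exceeds the budget: split the full budget across substrates
            for w in _simplex_grid(len(specs), steps=4):
                candidates.append({
                    s.substrate_id: w[i] * area / s.footprint
                    for i, s in enumerate(specs)
                })
            # scaled-down demand vector as an extra candidate
            candidates.append({
                sid: n * area / total_fp for sid, n in n_dem.items()
            })
        for cand in candidates:
            res = _score_allocation(
                strain_model, base_prob, specs, tr_rxn, env, geom, cand, area,
                photon_bound, objective_id, envelope_cost,
            )
            if best is None or res.mu > best.mu + 1e-12:
                best = res
    # attach n_star and diagnoses on the winner
    for sid, st in best.states.items():
        st.n_star = st.n
    return best


def _apply_photon_bound(network: MetabolicNetwork, prob, bound: float):
    for r in network.reactions:
        if not r.is_exchange and r.stoichiometry.get("photon_e", 0) < 0:
            j = prob.col(r.id)
            prob.v_ub[j] = bound
            ex = _exchange_for(network, "photon_e")
            if ex is not None:
                prob.v_lb[prob.col(ex)] = -1000.0
            return


def _score_allocation(
    strain_model, base_prob, specs, tr_rxn, env, geom, n_alloc, area,
    photon_bound, objective_id, envelope_cost=DEFAULT_ENVELOPE_COST,
):
    dm = geom.dry_mass
    # ATP debit per gDW biomass: transporter synthesis (cost_i × n_i per gDW)
    # plus the surface:volume-scaled envelope cost (ATP and wall carbon)
    debit = sum(
        s.synthesis_cost * transporters_per_cell_to_specific(n_alloc[s.substrate_id], dm)
        for s in specs
    ) + envelope_cost / geom.radius
    carbon = DEFAULT_ENVELOPE_CARBON * (envelope_cost / DEFAULT_ENVELOPE_COST) / geom.radius
    model = _debit_synthesis_cost(strain_model, debit, carbon)
    prob = build_flux_problem(model)
    states, bounds = {}, {}
    for s in specs:
        st = TransporterState(s, n_alloc[s.substrate_id])
        sinf = env.nutrients.get(s.substrate_id, 0.0)
        v_cell = uptake_rate(st, geom, sinf)
        v_spec = per_cell_to_specific(v_cell, dm)
        j = prob.col(tr_rxn[s.substrate_id])
        prob.v_ub[j] = v_spec
        ex = _exchange_for(model, s.substrate_id)
        if ex is not None:
            prob.v_lb[prob.col(ex)] = -1000.0
        states[s.substrate_id] = st
        bounds[s.substrate_id] = v_spec
    if photon_bound is not None:
        _apply_photon_bound(model, prob, photon_bound(dm))
    sol = fba.solve_fba(prob, objective_id)
    mu = sol.objective_value if sol.status == "optimal" else 0.0
    if sol.status != "optimal":
        sol_fluxes = {}
    else:
        sol_fluxes = sol.fluxes
    used = sum(n_alloc[s.substrate_id] * s.footprint for s in specs) / area if area > 0 else 0.0
    diagnoses = {}
    for s in specs:
        sid = s.substrate_id
        realized = sol_fluxes.get(tr_rxn[sid], 0.0)
        demand_cell = specific_to_per_cell(max(realized, 1e-30), dm)
        diagnoses[sid] = classify_limitation(
            states[sid], geom, env.nutrients.get(sid, 0.0), demand_cell, used
        )
    return OptTransResult(
        mu=max(mu, 0.0), geometry=geom, states=states, uptake_bounds=bounds,
        diagnoses=diagnoses, area_budget_used=used, fluxes=sol_fluxes,
    )
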