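"""Macromolecular composition, pigments and photoacclimation (PhysOpt).

A biomass composition is a set of macromolecular pools (mass fractions
summing to one, ash-free convention) plus pigment quotas (mg per gDW).
:func:`build_biomass_reaction` turns a composition into a biomass drain
reaction whose coefficients are the mmol of each precursor per gram of
biomass plus an ATP polymerization cost.

Light handling: each pigment carries a specific absorption spectrum
a*(λ) (m² mg⁻¹) on the shared 400–700 nm grid; :func:`photon_capture`
integrates it against the downwelling irradiance to give an absorbed photon
flux per pigment (mmol photons gDW⁻¹ h⁻¹).  Photons absorbed by
light-harvesting pigments are forced into the cell (the photon transport
flux is pinned to the absorbed flux) where flux balance routes them to the
photosystems (linear electron flow requires 8 photons per CO₂ fixed, so the
quantum yield of carbon fixation cannot exceed 1/8), to cyclic electron
flow, to heat via non-photochemical quenching (capacity proportional to the
zeaxanthin quota), or — once quenching saturates — to a reductant-consuming
singlet-oxygen detoxification flux, which is the photoinhibition mechanism.

:func:`optimize_physiology` is a deterministic coordinate descent over pool
fractions and pigment quotas (fixed sweep order, step halving, sum-to-one
renormalization against the carbohydrate buffer pool) with an FBA inner
problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import ATOMIC_MASS, MetabolicNetwork, Reaction, build_flux_problem, parse_formula
from .environment import DELTA_LAMBDA, WAVELENGTHS, EnvironmentSample
from . import fba

__all__ = [
    "MacromoleculePool",
    "PigmentSpec",
    "BiomassComposition",
    "CompositionMetrics",
    "AcclimationResult",
    "photon_capture",
    "build_biomass_reaction",
    "optimize_physiology",
    "composition_metrics",
    "default_composition",
    "default_pigments",
    "gaussian_absorption",
    "PhysOptOptions",
]

POOL_NAMES = (
    "protein", "dna", "rna", "lipid", "carbohydrate", "cell_wall",
    "pigment", "osmolyte", "mineral", "metabolite",
)
PIGMENT_NAMES = ("dv_chl_a", "dv_chl_b", "alpha_carotene", "zeaxanthin")

#: precursor metabolite, combustion enthalpy (kJ/g) and ATP polymerization
#: cost (mmol ATP per g pool) for each pool
_POOL_LIBRARY = {
    "protein":      ("aa_c",    "C4H7NO2",  23.9, 40.0),
    "rna":          ("nuc_c",   "C5H15N2O7P", 14.5, 25.0),
    "dna":          ("nuc_c",   "C5H15N2O7P", 14.5, 25.0),
    "lipid":        ("lipid_c", "C4H8O2",   39.5, 10.0),
    "carbohydrate": ("ch2o_c",  "CH2O",     17.5, 5.0),
    "cell_wall":    ("ch2o_c",  "CH2O",     17.5, 8.0),
    "osmolyte":     ("ch2o_c",  "CH2O",     20.0, 5.0),
    "metabolite":   ("ch2o_c",  "CH2O",     20.0, 5.0),
    "mineral":      ("pi_c",    "H3PO4",    0.0,  1.0),
}

PIGMENT_FORMULA = "C10H13NO"
PIGMENT_COST = 50.0  # mmol ATP per g pigment


def _molar_mass(formula: str) -> float:
    return sum(ATOMIC_MASS[el] * n for el, n in parse_formula(formula).items())


@dataclass
class MacromoleculePool:
    """One macromolecular pool of the biomass.

    mass_fraction and bounds are g per g ash-free dry weight;
    elemental_formula_per_gram maps element → mol per g pool.
    """

    name: str
    mass_fraction: float
    bounds: tuple[float, float]
    precursor_id: str
    precursor_formula: str
    synthesis_cost: float       # mmol ATP per g
    combustion_enthalpy: float  # kJ per g

    def __post_init__(self):
        lo, hi = self.bounds
        if not (0 <= lo <= hi <= 1):
            raise ValueError(f"pool {self.name}: bounds must lie within [0, 1]")
        if not (lo - 1e-9 <= self.mass_fraction <= hi + 1e-9):
            raise ValueError(f"pool {self.name}: fraction outside bounds")

    @property
    def molar_mass(self) -> float:
        return _molar_mass(self.precursor_formula)

    @property
    def elemental_formula_per_gram(self) -> dict[str, float]:
        M = self.molar_mass
        return {el: n / M for el, n in parse_formula(self.precursor_formula).items()}


def gaussian_absorption(bands: list[tuple[float, float, float]]) -> np.ndarray:
    """Gaussian-band specific absorption spectrum on the shared grid.

    ``bands`` is a list of (peak nm, width nm, amplitude m² mg⁻¹).
    """
    a = np.zeros_like(WAVELENGTHS)
    for peak, width, amp in bands:
        a += amp * np.exp(-0.5 * ((WAVELENGTHS - peak) / width) ** 2)
    return a


_DEFAULT_BANDS = {
    "dv_chl_a": [(442.0, 20.0, 0.020), (672.0, 15.0, 0.012)],
    "dv_chl_b": [(460.0, 20.0, 0.022), (650.0, 15.0, 0.010)],
    "alpha_carotene": [(450.0, 30.0, 0.012)],
    "zeaxanthin": [(454.0, 30.0, 0.010)],
}


@dataclass
class PigmentSpec:
    """A pigment with its absorption spectrum, role and cellular quota.

    role ``harvest`` feeds absorbed photons to the photosystems; role
    ``protect`` (zeaxanthin) only provides quenching capacity.
    Quota and bounds in mg per gDW.
    """

    name: str
    absorption_spectrum: np.ndarray
    role: str
    quota: float
    bounds: tuple[float, float]

    def __post_init__(self):
        self.absorption_spectrum = np.asarray(self.absorption_spectrum, dtype=float)
        if self.absorption_spectrum.shape != WAVELENGTHS.shape:
            raise ValueError("absorption spectrum must be on the shared wavelength grid")
        if np.any(self.absorption_spectrum < 0):
            raise ValueError("absorption spectrum must be nonnegative")
        if self.name == "zeaxanthin" and self.role != "protect":
            raise ValueError("zeaxanthin is a photoprotective pigment (role='protect')")
        lo, hi = self.bounds
        if not (0 <= lo <= hi):
            raise ValueError("bad quota bounds")
        if not (lo - 1e-9 <= self.quota <= hi + 1e-9):
            raise ValueError(f"pigment {self.name}: quota outside bounds")

    @property
    def metabolite_id(self) -> str:
        return f"{self.name}_c"


def default_pigments(light_adapted: str = "HL") -> list[PigmentSpec]:
    """Default pigment complement for a high-light or low-light strain.

    Low-light strains carry more divinyl-chlorophyll (especially b, which is
    blue-shifted) and less photoprotective capacity.
    """
    if light_adapted == "HL":
        cfg = {"dv_chl_a": (1.5, (0.8, 5.0)), "dv_chl_b": (0.3, (0.1, 2.0)),
               "alpha_carotene": (0.5, (0.1, 2.0)), "zeaxanthin": (0.2, (0.05, 0.4))}
    else:
        cfg = {"dv_chl_a": (2.5, (1.0, 8.0)), "dv_chl_b": (1.5, (0.5, 6.0)),
               "alpha_carotene": (0.4, (0.1, 2.0)), "zeaxanthin": (0.1, (0.02, 0.2))}
    out = []
    for name in PIGMENT_NAMES:
        quota, bounds = cfg[name]
        role = "protect" if name == "zeaxanthin" else "harvest"
        out.append(PigmentSpec(name, gaussian_absorption(_DEFAULT_BANDS[name]),
                               role, quota, bounds))
    return out


@dataclass
class BiomassComposition:
    """Pools plus pigments; pool fractions sum to 1 (ash-free convention).

    The ``pigment`` pool's mass fraction is derived from the pigment quotas
    (Σ quota / 1000) and kept in sync automatically.
    """

    pools: list[MacromoleculePool]
    pigments: list[PigmentSpec]

    def __post_init__(self):
        self.sync_pigment_pool()
        self.validate()

    def pool(self, name: str) -> MacromoleculePool:
        for p in self.pools:
            if p.name == name:
                return p
        raise KeyError(name)

    def pigment(self, name: str) -> PigmentSpec:
        for p in self.pigments:
            if p.name == name:
                return p
        raise KeyError(name)

    def sync_pigment_pool(self):
        total = sum(p.quota for p in self.pigments) / 1000.0
        for p in self.pools:
            if p.name == "pigment":
                p.mass_fraction = total
                p.bounds = (
                    sum(q.bounds[0] for q in self.pigments) / 1000.0,
                    sum(q.bounds[1] for q in self.pigments) / 1000.0,
                )

    def validate(self):
        s = sum(p.mass_fraction for p in self.pools)
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"pool mass fractions sum to {s}, expected 1")

    @property
    def chlorophyll_per_dw(self) -> float:
        """mg (dv-chl a + dv-chl b) per gDW; 0 for pigment-free compositions."""
        return sum(p.quota for p in self.pigments
                   if p.name in ("dv_chl_a", "dv_chl_b"))

    def copy(self) -> "BiomassComposition":
        return BiomassComposition(
            [replace(p) for p in self.pools],
            [replace(p, absorption_spectrum=p.absorption_spectrum.copy())
             for p in self.pigments],
        )


def default_composition(light_adapted: str = "HL") -> BiomassComposition:
    """Nutrient-replete batch-culture composition used as acclimation seed."""
    fractions = {
        "protein": (0.55, (0.30, 0.65)),
        "lipid": (0.12, (0.05, 0.30)),
        "rna": (0.07, (0.03, 0.12)),
        "dna": (0.015, (0.01, 0.03)),
        "cell_wall": (0.04, (0.02, 0.06)),
        "osmolyte": (0.01, (0.005, 0.02)),
        "metabolite": (0.015, (0.01, 0.03)),
        "mineral": (0.005, (0.0, 0.01)),
    }
    pigments = default_pigments(light_adapted)
    pig_total = sum(p.quota for p in pigments) / 1000.0
    carb = 1.0 - sum(v[0] for v in fractions.values()) - pig_total
    pools = []
    for name, (frac, bounds) in fractions.items():
        prec, formula, dh, cost = _POOL_LIBRARY[name]
        pools.append(MacromoleculePool(name, frac, bounds, prec, formula, cost, dh))
    prec, formula, dh, cost = _POOL_LIBRARY["carbohydrate"]
    pools.append(MacromoleculePool("carbohydrate", carb, (0.05, 0.45), prec, formula, cost, dh))
    pools.append(MacromoleculePool(
        "pigment", pig_total, (pig_total, pig_total), "pigment", PIGMENT_FORMULA,
        PIGMENT_COST, 20.0,
    ))
    return BiomassComposition(pools, pigments)


# ---------------------------------------------------------------------------
# photon capture
# ---------------------------------------------------------------------------

def photon_capture(
    pigments: list[PigmentSpec], irradiance_spectrum: np.ndarray,
) -> dict[str, float]:
    """Absorbed photon flux per pigment, mmol photons gDW⁻¹ h⁻¹.

    Φ_p = quota_p · Σ_λ a*_p(λ) E(λ) Δλ with E in
    µmol photons m⁻² s⁻¹ nm⁻¹ and quota in mg gDW⁻¹
    (µmol gDW⁻¹ s⁻¹ × 3.6 → mmol gDW⁻¹ h⁻¹).
    """
    E = np.asarray(irradiance_spectrum, dtype=float)
    if E.shape != WAVELENGTHS.shape:
        raise ValueError("irradiance spectrum not on the shared wavelength grid")
    out = {}
    for p in pigments:
        integral = float(np.sum(p.absorption_spectrum * E) * DELTA_LAMBDA)
        # µmol gDW⁻¹ s⁻¹ → mmol gDW⁻¹ h⁻¹: × 3600 / 1000
        out[p.name] = p.quota * integral * 3.6
    return out


def harvest_photon_flux(pigments, irradiance_spectrum) -> float:
    """Total absorbed flux of the light-harvesting (role='harvest') pigments."""
    phi = photon_capture(pigments, irradiance_spectrum)
    return sum(phi[p.name] for p in pigments if p.role == "harvest")


# ---------------------------------------------------------------------------
# biomass reaction
# ---------------------------------------------------------------------------

def build_biomass_reaction(composition: BiomassComposition, rxn_id: str = "BIOMASS") -> Reaction:
    """Biomass drain: mmol of each precursor per gram of new biomass plus the
    ATP polymerization cost; flux unit is gDW gDW⁻¹ h⁻¹ = μ (h⁻¹)."""
    composition.validate()
    stoich: dict[str, float] = {}
    atp_cost = 0.0
    for p in composition.pools:
        if p.name == "pigment":
            continue  # pigments itemized individually below
        if p.mass_fraction <= 0:
            continue
        mmol = p.mass_fraction * 1000.0 / p.molar_mass
        stoich[p.precursor_id] = stoich.get(p.precursor_id, 0.0) - mmol
        atp_cost += p.mass_fraction * p.synthesis_cost
    M_pig = _molar_mass(PIGMENT_FORMULA)
    for pig in composition.pigments:
        if pig.quota <= 0:
            continue
        stoich[pig.metabolite_id] = stoich.get(pig.metabolite_id, 0.0) - pig.quota / M_pig
        atp_cost += pig.quota / 1000.0 * PIGMENT_COST
    stoich["atp_c"] = stoich.get("atp_c", 0.0) - atp_cost
    stoich["h2o_c"] = stoich.get("h2o_c", 0.0) - atp_cost
    stoich["adp_c"] = stoich.get("adp_c", 0.0) + atp_cost
    stoich["pi_c"] = stoich.get("pi_c", 0.0) + atp_cost
    return Reaction(rxn_id, stoich, 0.0, 1000.0, is_biomass=True,
                    name="biomass synthesis", subsystem="biomass")


# ---------------------------------------------------------------------------
# composition metrics
# ---------------------------------------------------------------------------

@dataclass
class CompositionMetrics:
    c_to_n: float
    c_to_p: float
    enthalpy: float            # kJ per gDW
    chlorophyll_per_dw: float  # mg per gDW


def composition_metrics(composition: BiomassComposition) -> CompositionMetrics:
    """Elemental stoichiometry and combustion enthalpy of the composition."""
    totals: dict[str, float] = {}
    enthalpy = 0.0
    for p in composition.pools:
        for el, mol_per_g in p.elemental_formula_per_gram.items():
            totals[el] = totals.get(el, 0.0) + p.mass_fraction * mol_per_g
        enthalpy += p.mass_fraction * p.combustion_enthalpy
    c = totals.get("C", 0.0)
    n = totals.get("N", 0.0)
    p_ = totals.get("P", 0.0)
    return CompositionMetrics(
        c_to_n=c / n if n > 0 else math.inf,
        c_to_p=c / p_ if p_ > 0 else math.inf,
        enthalpy=enthalpy,
        chlorophyll_per_dw=composition.chlorophyll_per_dw,
    )


# ---------------------------------------------------------------------------
# acclimation result container (shared with ecology / thermal)
# ---------------------------------------------------------------------------

@dataclass
class AcclimationResult:
    """One strain's optimized phenotype in one environment."""

    strain_id: str
    environment: EnvironmentSample
    mu: float                              # h⁻¹
    fluxes: dict[str, float]
    composition: BiomassComposition
    metrics: CompositionMetrics
    absorbed_photons: dict[str, float]     # pigment → mmol photons/gDW/h
    radius: float = None                   # µm
    transporters: dict = field(default_factory=dict)
    diagnoses: dict = field(default_factory=dict)
    limiting_resource: str = "none"
    gamma: float = 1.0
    status: str = "optimal"

    @property
    def harvest_photon_flux(self) -> float:
        return sum(
            self.absorbed_photons.get(p.name, 0.0)
            for p in self.composition.pigments if p.role == "harvest"
        )

    def scaled(self, gamma: float) -> "AcclimationResult":
        """Thermal scaling: rates ×γ, composition and optics unchanged."""
        return replace(
            self,
            mu=self.mu * gamma,
            fluxes={k: v * gamma for k, v in self.fluxes.items()},
            gamma=self.gamma * gamma,
        )


# ---------------------------------------------------------------------------
# PhysOpt
# ---------------------------------------------------------------------------

@dataclass
class PhysOptOptions:
    npq_per_mg_zeaxanthin: float = 50.0  # mmol photons quenched per mg zeax per h
    #: proteome capacity: maximum growth rate supported per unit protein mass
    #: fraction (h⁻¹).  Protein is the catalytic machinery, so μ is capped at
    #: capacity × protein fraction; this is what keeps protein content high
    #: under replete growth while N scarcity favors shedding it.
    protein_growth_capacity: float = 0.09
    sweeps: int = 3
    initial_step_fraction: float = 0.25  # of each coordinate's bound range
    photon_transport_id: str = "TR_PHOT"
    npq_id: str = "NPQ"
    improvement_tol: float = 1e-10


def _model_with_biomass(strain_model: MetabolicNetwork,
                        composition: BiomassComposition) -> MetabolicNetwork:
    """Swap in the biomass reaction for a composition.

    If the network carries the proteome-capacity species ``psu_c``, biomass
    consumes one capacity unit per unit growth, coupling growth (and any
    photodamage flux draining the same pool) to the protein machinery.
    """
    bio = build_biomass_reaction(composition, strain_model.biomass_reaction_id)
    if any(m.id == "psu_c" for m in strain_model.metabolites):
        bio = replace(bio, stoichiometry={**bio.stoichiometry, "psu_c": -1.0})
    rxns = [bio if r.id == strain_model.biomass_reaction_id else r
            for r in strain_model.reactions]
    return MetabolicNetwork(strain_model.metabolites, rxns,
                            strain_model.biomass_reaction_id,
                            strain_model.annotations)


def _apply_env_bounds(model, prob, composition, env, uptake_bounds, opts):
    """Pin photon transport to the absorbed harvest flux, set the NPQ
    capacity from the zeaxanthin quota, cap growth by the proteome capacity,
    and apply transporter uptake bounds."""
    phi_h = harvest_photon_flux(composition.pigments, env.irradiance_spectrum)
    jt = prob.col(opts.photon_transport_id)
    prob.v_lb[jt] = phi_h
    prob.v_ub[jt] = phi_h
    try:
        zeax = composition.pigment("zeaxanthin").quota
    except KeyError:
        zeax = 0.0
    jn = prob.col(opts.npq_id)
    prob.v_ub[jn] = opts.npq_per_mg_zeaxanthin * zeax
    try:
        protein = composition.pool("protein").mass_fraction
    except KeyError:
        protein = None  # protein-free test compositions: no machinery cap
    if protein is not None:
        cap = opts.protein_growth_capacity * protein
        if "PSUPOOL" in prob._col_index:
            # capacity is a pool shared between growth and photodamage
            prob.v_ub[prob.col("PSUPOOL")] = cap
        else:
            jb = prob.col(model.biomass_reaction_id)
            prob.v_ub[jb] = min(prob.v_ub[jb], cap)
    for rid, ub in uptake_bounds.items():
        prob.v_ub[prob.col(rid)] = ub
    return phi_h


def _evaluate(strain_model, composition, env, uptake_bounds, opts, objective_id,
              parsimonious=False):
    model = _model_with_biomass(strain_model, composition)
    prob = build_flux_problem(model)
    _apply_env_bounds(model, prob, composition, env, uptake_bounds, opts)
    if parsimonious:
        sol = fba.solve_pfba(prob, objective_id, fraction=1.0)
    else:
        sol = fba.solve_fba(prob, objective_id)
    if sol.status != "optimal":
        return None, sol
    return sol.objective_value, sol


def _coordinates(composition: BiomassComposition):
    """Adjustable coordinates in fixed declared order: pigments, then pools
    (carbohydrate is the balance pool and is never a coordinate)."""
    coords = [("pigment", p.name) for p in composition.pigments]
    coords += [
        ("pool", p.name) for p in composition.pools
        if p.name not in ("carbohydrate", "pigment") and p.bounds[1] - p.bounds[0] > 1e-12
    ]
    return coords


def _try_move(composition: BiomassComposition, kind: str, name: str, delta: float):
    """A candidate composition with one coordinate moved and the carbohydrate
    buffer renormalized to keep Σ fractions = 1; None if bounds forbid it."""
    cand = composition.copy()
    carb = cand.pool("carbohydrate")
    if kind == "pigment":
        pig = cand.pigment(name)
        new_q = pig.quota + delta
        lo, hi = pig.bounds
        if not (lo - 1e-12 <= new_q <= hi + 1e-12):
            return None
        d_frac = (new_q - pig.quota) / 1000.0
        if not (carb.bounds[0] - 1e-12 <= carb.mass_fraction - d_frac <= carb.bounds[1] + 1e-12):
            return None
        pig.quota = min(max(new_q, lo), hi)
        carb.mass_fraction -= d_frac
        cand.sync_pigment_pool()
    else:
        pool = cand.pool(name)
        new_f = pool.mass_fraction + delta
        lo, hi = pool.bounds
        if not (lo - 1e-12 <= new_f <= hi + 1e-12):
            return None
        d = new_f - pool.mass_fraction
        if not (carb.bounds[0] - 1e-12 <= carb.mass_fraction - d <= carb.bounds[1] + 1e-12):
            return None
        pool.mass_fraction = min(max(new_f, lo), hi)
        carb.mass_fraction -= d
    cand.validate()
    return cand


def optimize_physiology(
    strain_model: MetabolicNetwork,
    uptake_bounds: dict[str, float],
    env: EnvironmentSample,
    composition: BiomassComposition = None,
    options: PhysOptOptions = None,
    strain_id: str = "strain",
) -> AcclimationResult:
    """Optimize macromolecular pools and pigment quotas for growth.

    ``uptake_bounds`` maps transport reaction ids to upper bounds
    (mmol gDW⁻¹ h⁻¹), normally the OptTrans output.  The search is a fixed-
    schedule coordinate descent (deterministic); the returned fluxes are the
    L1-minimal (parsimonious) optimum at the final composition.
    """
    opts = options or PhysOptOptions()
    comp = (composition or default_composition()).copy()
    objective_id = strain_model.biomass_reaction_id

    best_mu, _ = _evaluate(strain_model, comp, env, uptake_bounds, opts, objective_id)
    coords = _coordinates(comp)
    if best_mu is not None:
        for sweep in range(opts.sweeps):
            for kind, name in coords:
                if kind == "pigment":
                    lo, hi = comp.pigment(name).bounds
                else:
                    lo, hi = comp.pool(name).bounds
                step = opts.initial_step_fraction * (hi - lo) / (2 ** sweep)
                if step <= 0:
                    continue
                for delta in (step, -step):
                    cand = _try_move(comp, kind, name, delta)
                    if cand is None:
                        continue
                    mu, _ = _evaluate(strain_model, cand, env, uptake_bounds, opts,
                                      objective_id)
                    if mu is not None and mu > best_mu + opts.improvement_tol:
                        comp, best_mu = cand, mu
                        break

    mu_final, sol = _evaluate(strain_model, comp, env, uptake_bounds, opts,
                              objective_id, parsimonious=True)
    phi = photon_capture(comp.pigments, env.irradiance_spectrum)
    if mu_final is None:
        return AcclimationResult(
            strain_id=strain_id, environment=env, mu=0.0, fluxes={},
            composition=comp, metrics=composition_metrics(comp),
            absorbed_photons=phi, status="infeasible",
        )
    return AcclimationResult(
        strain_id=strain_id, environment=env, mu=float(mu_final),
        fluxes=sol.fluxes, composition=comp, metrics=composition_metrics(comp),
        absorbed_photons=phi, status="optimal",
    )
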