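"""Metabolic network data model, stoichiometric assembly, I/O and quality control.

The central object is :class:`MetabolicNetwork`, a plain in-memory container
for a genome-scale metabolic model (GEM): metabolites with elemental formulas
and compartments, reactions with flux bounds and ortholog-cluster
associations, and a designated biomass reaction.  :func:`build_flux_problem`
assembles the steady-state linear program

    maximize  c^T v   subject to   S v = 0,   v_lb <= v <= v_ub

in a deterministic column order, and :func:`qc_network` runs a compact model
quality battery (stoichiometric consistency, per-reaction mass balance,
biomass producibility, blocked reactions, energy-generating cycles).

Flux units are mmol·gDW⁻¹·h⁻¹ throughout; the biomass flux is the specific
growth rate μ in h⁻¹ (synthesis of 1 g ash-free dry biomass per gDW per h).

SBML (Level 3 + fbc) reading/writing is delegated to cobrapy; the JSON
dialect mirrors the same content one-to-one and is handled natively.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

__all__ = [
    "COMPARTMENTS",
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "FluxProblem",
    "QCReport",
    "load_network",
    "save_network",
    "networks_close",
    "build_flux_problem",
    "qc_network",
]

#: Recognized compartment codes.
COMPARTMENTS = {
    "c": "cytosol",
    "l": "thylakoid_lumen",
    "p": "periplasm",
    "e": "extracellular",
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

#: Tolerance below which an FVA extreme flux counts as blocked.
BLOCKED_TOL = 1e-9


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style elemental formula string into element→count."""
    if not formula:
        return {}
    out: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"malformed formula {formula!r}")
        pos = m.end()
        out[m.group(1)] = out.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r}")
    return out


def format_formula(counts: dict[str, int]) -> str:
    return "".join(
        f"{el}{n if n != 1 else ''}" for el, n in sorted(counts.items()) if n
    )


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in one compartment.

    ``formula`` maps element symbol to a nonnegative integer count; an empty
    map denotes a massless species (photons), which is exempted from mass
    conservation checks.
    """

    id: str
    name: str = ""
    formula: dict[str, int] = field(default_factory=dict)
    charge: int = 0
    compartment: str = "c"

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r} for metabolite {self.id}"
            )
        if any((not isinstance(n, int)) or n < 0 for n in self.formula.values()):
            raise ValueError(f"formula counts must be nonnegative integers ({self.id})")

    @property
    def molar_mass(self) -> float:
        """Molar mass in g·mol⁻¹ from the elemental formula."""
        return sum(ATOMIC_MASS[el] * n for el, n in self.formula.items())


#: Atomic masses (g/mol) for the elements the toy chemistry uses.
ATOMIC_MASS = {
    "C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06,
    "Mg": 24.305, "Fe": 55.845,
}


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite id → coefficient (negative = consumed).
    ``ortholog_ids`` lists the ortholog clusters whose gene products catalyze
    the reaction; an empty set marks spontaneous or gap-filled reactions.
    Bounds are in mmol·gDW⁻¹·h⁻¹.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    ortholog_ids: frozenset[str] = frozenset()
    subsystem: str = ""
    is_exchange: bool = False
    is_biomass: bool = False
    name: str = ""

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        object.__setattr__(self, "ortholog_ids", frozenset(self.ortholog_ids))

    def with_bounds(self, lb: float, ub: float) -> "Reaction":
        return replace(self, lower_bound=lb, upper_bound=ub)


class MetabolicNetwork:
    """A validated collection of metabolites and reactions with a biomass target."""

    def __init__(
        self,
        metabolites: list[Metabolite],
        reactions: list[Reaction],
        biomass_reaction_id: str,
        annotations: dict | None = None,
    ):
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.biomass_reaction_id = biomass_reaction_id
        self.annotations = dict(annotations or {})
        self._validate()
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    def _validate(self):
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ValueError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ValueError("duplicate reaction ids")
        known = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ValueError(f"reaction {r.id} references unknown metabolites {sorted(missing)}")
            if r.is_exchange:
                if len(r.stoichiometry) != 1:
                    raise ValueError(f"exchange reaction {r.id} must touch exactly one metabolite")
        if self.biomass_reaction_id not in set(rxn_ids):
            raise ValueError("biomass_reaction_id unresolved")
        for r in self.reactions:
            if r.is_exchange:
                (mid,) = r.stoichiometry
                met = next(m for m in self.metabolites if m.id == mid)
                if met.compartment != "e":
                    raise ValueError(
                        f"exchange reaction {r.id} touches non-extracellular metabolite {mid}"
                    )

    # -- lookups -----------------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        return self._met_index[mid]

    def reaction(self, rid: str) -> Reaction:
        return self._rxn_index[rid]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            list(self.metabolites),
            list(self.reactions),
            self.biomass_reaction_id,
            dict(self.annotations),
        )

    def with_reactions(self, reactions: list[Reaction]) -> "MetabolicNetwork":
        """A new network with the given reaction list (metabolites pruned to use)."""
        used = set()
        for r in reactions:
            used |= set(r.stoichiometry)
        mets = [m for m in self.metabolites if m.id in used]
        return MetabolicNetwork(mets, reactions, self.biomass_reaction_id, dict(self.annotations))

    def __eq__(self, other):
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return (
            sorted(self.metabolites, key=lambda m: m.id)
            == sorted(other.metabolites, key=lambda m: m.id)
            and {r.id: _rxn_key(r) for r in self.reactions}
            == {r.id: _rxn_key(r) for r in other.reactions}
            and self.biomass_reaction_id == other.biomass_reaction_id
        )

    def __repr__(self):
        return (
            f"<MetabolicNetwork {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, biomass={self.biomass_reaction_id!r}>"
        )


def networks_close(a: MetabolicNetwork, b: MetabolicNetwork, tol: float = 1e-9) -> bool:
    """Equality of ids, stoichiometry, bounds and ortholog sets up to a
    relative float tolerance (SBML serializes doubles at ~15 significant
    digits, so exact equality only holds for the JSON dialect)."""
    if set(a.reaction_ids) != set(b.reaction_ids):
        return False
    if set(a.metabolite_ids) != set(b.metabolite_ids):
        return False
    if a.biomass_reaction_id != b.biomass_reaction_id:
        return False

    def close(x, y):
        return abs(x - y) <= tol * max(1.0, abs(x), abs(y))

    for ra in a.reactions:
        rb = b.reaction(ra.id)
        if set(ra.stoichiometry) != set(rb.stoichiometry):
            return False
        if not all(close(v, rb.stoichiometry[k]) for k, v in ra.stoichiometry.items()):
            return False
        if not (close(ra.lower_bound, rb.lower_bound) and close(ra.upper_bound, rb.upper_bound)):
            return False
        if ra.ortholog_ids != rb.ortholog_ids or ra.is_exchange != rb.is_exchange:
            return False
    return True


def _rxn_key(r: Reaction):
    return (
        tuple(sorted(r.stoichiometry.items())),
        r.lower_bound,
        r.upper_bound,
        tuple(sorted(r.ortholog_ids)),
        r.is_exchange,
        r.is_biomass,
    )


@dataclass
class FluxProblem:
    """The assembled LP data of the steady-state flux balance.

    Rows are internal (non-boundary) metabolites; columns are reactions in
    lexicographic id order, so identical networks give identical problems.
    Boundary metabolites of exchange reactions are dropped (open-system
    convention: boundary pools are unbounded).
    """

    S: sparse.csr_matrix
    c: np.ndarray
    v_lb: np.ndarray
    v_ub: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def col(self, rid: str) -> int:
        return self._col_index[rid]

    def __post_init__(self):
        m, n = self.S.shape
        assert len(self.row_ids) == m and len(self.col_ids) == n
        assert self.c.shape == (n,) and self.v_lb.shape == (n,) and self.v_ub.shape == (n,)
        self._col_index = {rid: j for j, rid in enumerate(self.col_ids)}

    def copy(self) -> "FluxProblem":
        return FluxProblem(
            self.S.copy(), self.c.copy(), self.v_lb.copy(), self.v_ub.copy(),
            list(self.row_ids), list(self.col_ids),
        )


def build_flux_problem(network: MetabolicNetwork) -> FluxProblem:
    """Assemble S, c and bound vectors from a network.

    Exchange reactions already encode the open boundary (their implicit
    partner pool is unbounded), so their extracellular species remain rows;
    a metabolite touched *only* by exchange reactions is a dangling boundary
    pool and is dropped from the rows.
    """
    touched_internally = set()
    for r in network.reactions:
        if not r.is_exchange:
            touched_internally |= set(r.stoichiometry)
    boundary = {
        next(iter(r.stoichiometry))
        for r in network.reactions
        if r.is_exchange
    } - touched_internally
    rows = [m.id for m in sorted(network.metabolites, key=lambda m: m.id) if m.id not in boundary]
    row_index = {mid: i for i, mid in enumerate(rows)}
    cols = sorted(network.reaction_ids)
    data, ri, ci = [], [], []
    lb = np.zeros(len(cols))
    ub = np.zeros(len(cols))
    c = np.zeros(len(cols))
    for j, rid in enumerate(cols):
        r = network.reaction(rid)
        lb[j], ub[j] = r.lower_bound, r.upper_bound
        if r.is_biomass:
            c[j] = 1.0
        for mid, coef in r.stoichiometry.items():
            if mid in row_index:
                ri.append(row_index[mid])
                ci.append(j)
                data.append(float(coef))
    S = sparse.csr_matrix(
        (data, (ri, ci)), shape=(len(rows), len(cols)), dtype=float
    )
    return FluxProblem(S=S, c=c, v_lb=lb, v_ub=ub, row_ids=rows, col_ids=cols)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _to_json_dict(network: MetabolicNetwork) -> dict:
    return {
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": format_formula(m.formula),
                "charge": m.charge,
                "compartment": m.compartment,
            }
            for m in network.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: v for k, v in sorted(r.stoichiometry.items())},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "ortholog_ids": sorted(r.ortholog_ids),
                "subsystem": r.subsystem,
                "is_exchange": r.is_exchange,
                "is_biomass": r.is_biomass,
            }
            for r in network.reactions
        ],
        "biomass_reaction_id": network.biomass_reaction_id,
        "annotations": network.annotations,
    }


def _from_json_dict(doc: dict) -> MetabolicNetwork:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                formula=parse_formula(m.get("formula", "")),
                charge=int(m.get("charge", 0)),
                compartment=m.get("compartment", "c"),
            )
            for m in doc["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                ortholog_ids=frozenset(r.get("ortholog_ids", [])),
                subsystem=r.get("subsystem", ""),
                is_exchange=bool(r.get("is_exchange", False)),
                is_biomass=bool(r.get("is_biomass", False)),
            )
            for r in doc["reactions"]
        ]
    except KeyError as exc:
        raise ValueError(f"malformed model JSON: missing key {exc}") from exc
    return MetabolicNetwork(
        mets, rxns, doc["biomass_reaction_id"], doc.get("annotations", {})
    )


def _to_cobra(network: MetabolicNetwork):
    import cobra

    model = cobra.Model("phytoflux")
    mets = {}
    for m in network.metabolites:
        cm = cobra.Metabolite(
            m.id, formula=format_formula(m.formula), name=m.name or m.id,
            charge=m.charge, compartment=m.compartment,
        )
        mets[m.id] = cm
    model.add_metabolites(list(mets.values()))
    rxns = []
    for r in network.reactions:
        cr = cobra.Reaction(r.id, name=r.name or r.id,
                            lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(cr)
    model.add_reactions(rxns)
    for r in network.reactions:
        cr = model.reactions.get_by_id(r.id)
        cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        if r.ortholog_ids:
            cr.gene_reaction_rule = " or ".join(sorted(r.ortholog_ids))
        if r.subsystem:
            cr.subsystem = r.subsystem
    model.objective = model.reactions.get_by_id(network.biomass_reaction_id)
    return model


def _from_cobra(model) -> MetabolicNetwork:
    mets = [
        Metabolite(
            id=m.id, name=m.name or "", formula=parse_formula(m.formula or ""),
            charge=int(m.charge or 0), compartment=m.compartment or "c",
        )
        for m in model.metabolites
    ]
    biomass = None
    for r in model.reactions:
        if r.objective_coefficient:
            biomass = r.id
    if biomass is None:
        raise ValueError("biomass_reaction_id unresolved")
    rxns = []
    for r in model.reactions:
        stoich = {m.id: float(v) for m, v in r.metabolites.items()}
        is_exchange = r.id.startswith("EX_") and len(stoich) == 1
        orth = frozenset(g.id for g in r.genes)
        rxns.append(
            Reaction(
                id=r.id, name=r.name or "", stoichiometry=stoich,
                lower_bound=float(r.lower_bound), upper_bound=float(r.upper_bound),
                ortholog_ids=orth, subsystem=getattr(r, "subsystem", "") or "",
                is_exchange=is_exchange, is_biomass=(r.id == biomass),
            )
        )
    return MetabolicNetwork(mets, rxns, biomass)


def load_network(path, format: str = None) -> MetabolicNetwork:
    """Load a model from SBML L3+fbc (``.xml``) or the JSON dialect (``.json``)."""
    path = str(path)
    if format is None:
        format = "sbml" if path.endswith((".xml", ".sbml")) else "json"
    if format == "json":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValueError(f"malformed model JSON {path}: {exc}") from exc
        return _from_json_dict(doc)
    if format == "sbml":
        import cobra.io

        model = cobra.io.read_sbml_model(path)
        return _from_cobra(model)
    raise ValueError(f"unknown format {format!r}")


def save_network(network: MetabolicNetwork, path, format: str = None) -> None:
    """Write a model to SBML or the JSON dialect (inferred from the suffix)."""
    path = str(path)
    if format is None:
        format = "sbml" if path.endswith((".xml", ".sbml")) else "json"
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_to_json_dict(network), fh, indent=1, sort_keys=True)
    elif format == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(_to_cobra(network), path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    stoichiometrically_consistent: bool
    unbalanced_reactions: list[str]
    untestable_reactions: list[str]
    biomass_producible: bool
    blocked_fraction: float
    energy_cycle_free: bool

    def passed(self) -> bool:
        return (
            self.stoichiometrically_consistent
            and not self.unbalanced_reactions
            and self.biomass_producible
            and self.blocked_fraction == 0.0
            and self.energy_cycle_free
        )

    def to_dict(self) -> dict:
        return {
            "stoichiometrically_consistent": self.stoichiometrically_consistent,
            "unbalanced_reactions": self.unbalanced_reactions,
            "untestable_reactions": self.untestable_reactions,
            "biomass_producible": self.biomass_producible,
            "blocked_fraction": self.blocked_fraction,
            "energy_cycle_free": self.energy_cycle_free,
        }


def _mass_balance(network: MetabolicNetwork):
    """Per-reaction elemental balance from formulas.

    Exchange and biomass reactions are exempt (open boundaries / mass drain by
    definition).  Reactions involving a metabolite with no formula are marked
    untestable rather than failed.  Massless metabolites (empty formula on a
    species flagged massless, e.g. photons) contribute nothing.
    """
    unbalanced, untestable = [], []
    for r in network.reactions:
        if r.is_exchange or r.is_biomass:
            continue
        totals: dict[str, float] = {}
        testable = True
        for mid, coef in r.stoichiometry.items():
            m = network.metabolite(mid)
            if not m.formula and not m.name.startswith("photon"):
                # a species with genuinely unknown composition
                if m.id.split("_")[0] not in ("photon",):
                    testable = False
                    break
            for el, n in m.formula.items():
                totals[el] = totals.get(el, 0.0) + coef * n
        if not testable:
            untestable.append(r.id)
        elif any(abs(v) > 1e-6 for v in totals.values()):
            unbalanced.append(r.id)
    return unbalanced, untestable


def _stoichiometric_consistency(network: MetabolicNetwork) -> bool:
    """Existence of a strictly positive molecular-mass vector m with S_intᵀ m = 0.

    Only internal (non-exchange, non-biomass) reactions constrain m; massless
    species (photons) are excluded from the requirement m ≥ 1.
    """
    from scipy.optimize import linprog

    prob = build_flux_problem(network)
    internal = [
        j for j, rid in enumerate(prob.col_ids)
        if not network.reaction(rid).is_exchange and not network.reaction(rid).is_biomass
    ]
    if not internal:
        return True
    A = prob.S[:, internal].T.tocsr()  # (n_int × m) — rows: Sᵀ m = 0
    m_rows = len(prob.row_ids)
    massless = [
        i for i, mid in enumerate(prob.row_ids)
        if not network.metabolite(mid).formula
    ]
    lo = np.ones(m_rows)
    hi = np.full(m_rows, np.inf)
    for i in massless:
        lo[i] = 0.0
        hi[i] = 0.0
    res = linprog(
        c=np.zeros(m_rows), A_eq=A, b_eq=np.zeros(A.shape[0]),
        bounds=list(zip(lo, hi)), method="highs",
    )
    return res.status == 0


def qc_network(network: MetabolicNetwork) -> QCReport:
    """Run the five-check quality battery on a network."""
    from . import fba

    unbalanced, untestable = _mass_balance(network)
    consistent = _stoichiometric_consistency(network)

    prob = build_flux_problem(network)
    sol = fba.solve_fba(prob, network.biomass_reaction_id)
    producible = sol.status == "optimal" and sol.objective_value > 1e-6

    # blocked fraction: FVA with all exchanges open, no objective floor
    open_prob = prob.copy()
    for rid in network.exchange_ids:
        j = open_prob.col(rid)
        open_prob.v_lb[j] = -1000.0
        open_prob.v_ub[j] = 1000.0
    blocked = 0
    ranges = fba.flux_variability(open_prob, network.biomass_reaction_id, fraction=0.0)
    for fr in ranges:
        if max(abs(fr.v_min), abs(fr.v_max)) < BLOCKED_TOL:
            blocked += 1
    blocked_fraction = blocked / len(ranges) if ranges else 0.0

    # energy cycle: close all exchanges, maximize ATP-hydrolysis-like flux
    closed = prob.copy()
    for rid in network.exchange_ids:
        j = closed.col(rid)
        closed.v_lb[j] = 0.0
        closed.v_ub[j] = 0.0
    # also release any forced fluxes (e.g. maintenance lower bounds)
    closed.v_lb = np.minimum(closed.v_lb, 0.0)
    energy_free = True
    atp_like = [
        r.id for r in network.reactions
        if _is_atp_hydrolysis(network, r)
    ]
    for rid in atp_like:
        s = fba.solve_fba(closed, rid)
        if s.status == "optimal" and s.objective_value > 1e-6:
            energy_free = False
            break
    return QCReport(
        stoichiometrically_consistent=consistent,
        unbalanced_reactions=unbalanced,
        untestable_reactions=untestable,
        biomass_producible=producible,
        blocked_fraction=blocked_fraction,
        energy_cycle_free=energy_free,
    )


def _is_atp_hydrolysis(network: MetabolicNetwork, r: Reaction) -> bool:
    """Heuristic: reaction consumes atp and produces adp (maintenance-like)."""
    if r.is_exchange or r.is_biomass:
        return False
    consumed = {m for m, v in r.stoichiometry.items() if v < 0}
    produced = {m for m, v in r.stoichiometry.items() if v > 0}
    return any(m.startswith("atp") for m in consumed) and any(
        m.startswith("adp") for m in produced
    )
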