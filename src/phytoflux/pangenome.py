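"""Pangenome assembly, rarefaction analysis and strain-model extraction.

The pangenome-scale model (PanGEM) is the union of all reactions encoded by
any ortholog cluster present in at least one strain, on top of a scaffold of
gene-free reactions (exchanges, biomass, maintenance, spontaneous steps).
Reactions split into

- **core**: encoded by a cluster present in every strain (scaffold
  reactions, present in every strain by construction, count as core),
- **accessory**: encoded only in some strains,
- **gapfilled**: added without gene evidence to make biomass producible.

Rarefaction follows Heaps' law: the mean number of previously unseen
clusters contributed by the k-th strain over random strain orderings decays
as κ·k^(−α); α ≤ 1 marks an *open* pangenome.

Strain models are extracted by a sparsity-driven (compressed-sensing style)
procedure: an iteratively reweighted L1 flux minimization finds a small
reaction support that sustains growth and synthesizes every biomass
component de novo, a deterministic greedy deletion pass enforces
superset-minimality, and strain-specific reactions are appended on top.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog, milp, LinearConstraint, Bounds

from .core import MetabolicNetwork, Reaction, build_flux_problem
from . import fba

__all__ = [
    "ECOTYPES",
    "OrthologMatrix",
    "RarefactionFit",
    "PanGEM",
    "assemble_pangem",
    "rarefaction_curve",
    "fit_heaps",
    "essential_core",
    "extract_strain_gem",
    "gap_fill",
    "GapFillSet",
    "MU_MIN_DEFAULT",
]

ECOTYPES = ("HLI", "HLII", "LLI", "LLII_III", "LLIV")

MU_MIN_DEFAULT = 1e-3  # h⁻¹

SUPPORT_TOL = 1e-9


@dataclass
class OrthologMatrix:
    """Strains × ortholog-cluster presence/absence with ecotype labels."""

    strains: list[str]
    clusters: list[str]
    presence: np.ndarray  # binary, strains × clusters
    ecotype: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.presence = np.asarray(self.presence)
        if self.presence.shape != (len(self.strains), len(self.clusters)):
            raise ValueError("presence matrix shape mismatch")
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence entries must be 0/1")
        if len(self.strains) and (self.presence.sum(axis=1) == 0).any():
            raise ValueError("every strain must carry at least one cluster")
        for s, e in self.ecotype.items():
            if e not in ECOTYPES:
                raise ValueError(f"unknown ecotype {e!r} for strain {s}")

    def clusters_of(self, strain_id: str) -> frozenset[str]:
        i = self.strains.index(strain_id)
        return frozenset(
            c for c, v in zip(self.clusters, self.presence[i]) if v
        )

    @classmethod
    def from_tsv(cls, path) -> "OrthologMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        eco = {}
        if "ecotype" in df.columns:
            eco = df["ecotype"].to_dict()
            df = df.drop(columns=["ecotype"])
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=int), eco)

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.presence, index=self.strains, columns=self.clusters)
        if self.ecotype:
            df["ecotype"] = [self.ecotype.get(s, "") for s in self.strains]
        df.to_csv(path, sep="\t")


@dataclass
class RarefactionFit:
    kappa: float
    alpha: float
    r_squared: float

    def __post_init__(self):
        if self.kappa <= 0 or self.alpha <= 0:
            raise ValueError("kappa and alpha must be positive")

    @property
    def openness(self) -> str:
        """Open when new-gene discovery decays sublinearly (α ≤ 1)."""
        return "open" if self.alpha <= 1.0 else "closed"


@dataclass
class PanGEM:
    """Union metabolic network over a pangenome with reaction provenance."""

    network: MetabolicNetwork
    core_reaction_ids: frozenset[str]
    accessory_reaction_ids: frozenset[str]
    gapfilled_reaction_ids: frozenset[str]
    ortholog_matrix: OrthologMatrix
    catalog: dict[str, list[str]] = field(default_factory=dict)  # cluster -> reaction ids
    _essential_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        non_exchange = {
            r.id for r in self.network.reactions if not r.is_exchange
        }
        union = self.core_reaction_ids | self.accessory_reaction_ids | self.gapfilled_reaction_ids
        if union != non_exchange:
            raise ValueError("core ∪ accessory ∪ gapfilled must equal the non-exchange set")
        if (self.core_reaction_ids & self.accessory_reaction_ids
                or self.core_reaction_ids & self.gapfilled_reaction_ids
                or self.accessory_reaction_ids & self.gapfilled_reaction_ids):
            raise ValueError("core/accessory/gapfilled must be pairwise disjoint")

    def strain_reaction_ids(self, strain_id: str) -> frozenset[str]:
        """Gene-encoded reactions available to one strain."""
        clusters = self.ortholog_matrix.clusters_of(strain_id)
        out = set()
        for c in clusters:
            out.update(self.catalog.get(c, ()))
        return frozenset(out)


def assemble_pangem(
    matrix: OrthologMatrix,
    catalog: dict[str, list[Reaction]],
    scaffold: MetabolicNetwork,
    gapfill_candidates: list[Reaction] = (),
    mu_min: float = MU_MIN_DEFAULT,
) -> PanGEM:
    """Build the pangenome model from presence data and a reaction catalog.

    ``catalog`` maps cluster id → reactions encoded by that cluster (may be
    empty: most genetic novelty is non-metabolic).  ``scaffold`` supplies
    metabolites, exchanges, biomass and gene-free reactions shared by all
    strains.  If the union network cannot produce biomass, a minimum-
    cardinality gap fill from ``gapfill_candidates`` is applied and flagged.
    """
    present_any = matrix.presence.any(axis=0)
    present_all = matrix.presence.all(axis=0)
    cluster_state = {
        c: ("all" if a else "some")
        for c, p, a in zip(matrix.clusters, present_any, present_all)
        if p
    }
    reactions = {r.id: r for r in scaffold.reactions}
    rxn_clusters: dict[str, set[str]] = {}
    for c, state in cluster_state.items():
        for r in catalog.get(c, ()):
            if r.id in reactions and reactions[r.id] != r and r.id not in {
                s.id for s in scaffold.reactions
            }:
                raise ValueError(f"conflicting definitions for reaction {r.id}")
            reactions.setdefault(r.id, r)
            rxn_clusters.setdefault(r.id, set()).add(c)

    core, accessory = set(), set()
    strain_clusters = [
        frozenset(c for c, v in zip(matrix.clusters, row) if v)
        for row in matrix.presence
    ]
    for rid, clusters in rxn_clusters.items():
        if all(clusters & sc for sc in strain_clusters):
            core.add(rid)
        else:
            accessory.add(rid)
    for r in scaffold.reactions:
        if not r.is_exchange and r.id not in rxn_clusters:
            core.add(r.id)

    net = MetabolicNetwork(
        scaffold.metabolites, sorted(reactions.values(), key=lambda r: r.id),
        scaffold.biomass_reaction_id, dict(scaffold.annotations),
    )
    gapfilled: set[str] = set()
    sol = fba.solve_fba(build_flux_problem(net), net.biomass_reaction_id)
    if sol.status != "optimal" or sol.objective_value < mu_min:
        if not gapfill_candidates:
            _raise_orphan(net)
        universe = MetabolicNetwork(
            scaffold.metabolites,
            sorted({**reactions, **{r.id: r for r in gapfill_candidates}}.values(),
                   key=lambda r: r.id),
            scaffold.biomass_reaction_id, dict(scaffold.annotations),
        )
        added = gap_fill(net, universe, mu_min)
        gapfilled = set(added)
        all_rxns = {**reactions, **{rid: universe.reaction(rid) for rid in added}}
        net = MetabolicNetwork(
            scaffold.metabolites, sorted(all_rxns.values(), key=lambda r: r.id),
            scaffold.biomass_reaction_id, dict(scaffold.annotations),
        )
    return PanGEM(
        network=net,
        core_reaction_ids=frozenset(core),
        accessory_reaction_ids=frozenset(accessory),
        gapfilled_reaction_ids=frozenset(gapfilled),
        ortholog_matrix=matrix,
        catalog={c: [r.id for r in catalog.get(c, ())] for c in matrix.clusters},
    )


def pangem_from_network(network: MetabolicNetwork,
                        matrix: OrthologMatrix) -> PanGEM:
    """Rebuild a PanGEM from a serialized union network and its matrix.

    The cluster → reaction catalog is reconstructed from the reactions'
    ortholog associations (which both model dialects preserve); gap-filled
    provenance is not stored in the files, so gene-free reactions are
    classified as core scaffold (they are universal either way).
    """
    catalog: dict[str, list[str]] = {c: [] for c in matrix.clusters}
    core, accessory = set(), set()
    strain_clusters = [
        frozenset(c for c, v in zip(matrix.clusters, row) if v)
        for row in matrix.presence
    ]
    for r in network.reactions:
        if r.is_exchange:
            continue
        if not r.ortholog_ids:
            core.add(r.id)
            continue
        for c in r.ortholog_ids:
            catalog.setdefault(c, []).append(r.id)
        if all(r.ortholog_ids & sc for sc in strain_clusters):
            core.add(r.id)
        else:
            accessory.add(r.id)
    return PanGEM(
        network=network, core_reaction_ids=frozenset(core),
        accessory_reaction_ids=frozenset(accessory),
        gapfilled_reaction_ids=frozenset(), ortholog_matrix=matrix,
        catalog=catalog,
    )


def _raise_orphan(net: MetabolicNetwork):
    """Name the biomass components with no producing reaction."""
    bio = net.reaction(net.biomass_reaction_id)
    producers = {mid for r in net.reactions if not r.is_exchange and r.id != bio.id
                 for mid, v in r.stoichiometry.items() if v > 0}
    orphans = [m for m, v in bio.stoichiometry.items() if v < 0 and m not in producers]
    raise ValueError(
        f"biomass not producible and no gap-fill candidates; orphan components: {orphans}"
    )


# ---------------------------------------------------------------------------
# rarefaction / Heaps
# ---------------------------------------------------------------------------

def rarefaction_curve(
    matrix: OrthologMatrix, n_permutations: int = 100, seed: int = 0
) -> np.ndarray:
    """Mean new clusters contributed by the k-th strain over random orderings.

    Returns an array of length n_strains (k = 1 … n); element 0 is the mean
    cluster count of the first strain drawn.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n = len(matrix.strains)
    if n < 3:
        raise ValueError("need at least 3 strains for rarefaction")
    rng = np.random.default_rng(seed)
    P = matrix.presence.astype(bool)
    acc = np.zeros(n)
    for _ in range(n_permutations):
        order = rng.permutation(n)
        seen = np.zeros(P.shape[1], dtype=bool)
        for k, i in enumerate(order):
            new = P[i] & ~seen
            acc[k] += int(new.sum())
            seen |= P[i]
    return acc / n_permutations


def fit_heaps(curve) -> RarefactionFit:
    """Power-law fit new(k) = κ·k^(−α) by least squares in log–log space.

    k = 1 is excluded (every cluster of the first strain is trivially new);
    zero points are excluded with a warning.  Raises if fewer than 4 usable
    points remain or the curve is all-zero beyond k = 1.
    """
    y = np.asarray(curve, dtype=float)
    k = np.arange(1, len(y) + 1)
    mask = (k >= 2) & (y > 0)
    if not (y[k >= 2] > 0).any():
        raise ValueError("pangenome fully saturated; no fit")
    if mask.sum() < (k >= 2).sum():
        warnings.warn("zero points excluded from Heaps fit")
    if mask.sum() < 4:
        raise ValueError("need at least 4 positive points for the Heaps fit")
    x = np.log(k[mask])
    z = np.log(y[mask])
    slope, intercept = np.polyfit(x, z, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((z - pred) ** 2))
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RarefactionFit(kappa=float(np.exp(intercept)), alpha=float(-slope),
                          r_squared=r2)


# ---------------------------------------------------------------------------
# compressed-sensing style strain extraction
# ---------------------------------------------------------------------------

def _internal_columns(network: MetabolicNetwork, prob) -> list[int]:
    return [
        j for j, rid in enumerate(prob.col_ids)
        if not network.reaction(rid).is_exchange and not network.reaction(rid).is_biomass
    ]


def _biomass_components(network: MetabolicNetwork) -> list[str]:
    bio = network.reaction(network.biomass_reaction_id)
    # currency metabolites regenerated by the ATP debit are not components
    skip = {"atp_c", "adp_c", "pi_c", "h2o_c"}
    return [m for m, v in bio.stoichiometry.items() if v < 0 and m not in skip]


def _feasible_with(network, keep_ids, mu_min, components=True) -> bool:
    """Biomass ≥ mu_min, and each biomass component producible de novo,
    using only ``keep_ids`` among the internal reactions."""
    prob = build_flux_problem(network)
    keep = set(keep_ids)
    for j, rid in enumerate(prob.col_ids):
        r = network.reaction(rid)
        if not r.is_exchange and not r.is_biomass and rid not in keep:
            prob.v_lb[j] = 0.0
            prob.v_ub[j] = 0.0
    sol = fba.solve_fba(prob, network.biomass_reaction_id)
    if sol.status != "optimal" or sol.objective_value < mu_min - 1e-9:
        return False
    if not components:
        return True
    for comp in _biomass_components(network):
        if not _demand_feasible(network, prob, comp):
            return False
    return True


def _demand_feasible(network, prob, metabolite_id, threshold=1e-6) -> bool:
    """Max achievable net production of one metabolite via the biomass drain
    replaced by a pure demand on that component."""
    n = len(prob.col_ids)
    jb = prob.col(network.biomass_reaction_id)
    dprob = prob.copy()
    dprob.v_lb[jb] = 0.0
    dprob.v_ub[jb] = 0.0
    try:
        i = dprob.row_ids.index(metabolite_id)
    except ValueError:
        return True  # boundary species: trivially available
    c = np.zeros(n)
    # maximize production: add a virtual drain by relaxing the row to >=0 is
    # equivalent to maximizing S_row · v
    row = dprob.S.getrow(i).toarray().ravel()
    c[:] = -row
    S2 = sparse.vstack([
        dprob.S[:i], dprob.S[i + 1:]
    ]).tocsr() if dprob.S.shape[0] > 1 else sparse.csr_matrix((0, n))
    res = linprog(
        c=c, A_eq=S2, b_eq=np.zeros(S2.shape[0]),
        bounds=np.column_stack([dprob.v_lb, dprob.v_ub]), method="highs",
    )
    return res.status == 0 and -res.fun > threshold


def essential_core(
    pangem: PanGEM, mu_min: float = MU_MIN_DEFAULT,
) -> frozenset[str]:
    """Sparse reaction support sustaining growth and de-novo synthesis of
    every biomass component.

    Iteratively reweighted L1 (5 iterations, w = 1/(|v|+1e−6)) followed by a
    deterministic greedy deletion pass in lexicographic reaction order.
    Exchange reactions and the biomass reaction are not counted; the
    returned ids are internal reactions only.  The search is restricted to
    universally available reactions (core, spontaneous and gap-filled):
    the essential subset is shared by every strain, so accessory reactions
    are closed during the search and only re-admitted by gap filling if the
    universal subnetwork cannot make some biomass component.
    """
    key = ("essential", mu_min)
    if key in pangem._essential_cache:
        return pangem._essential_cache[key]
    network = pangem.network
    prob = build_flux_problem(network)
    jb = prob.col(network.biomass_reaction_id)
    base = fba.solve_fba(prob, network.biomass_reaction_id)
    if base.status != "optimal" or base.objective_value < mu_min:
        raise ValueError(f"pangenome cannot grow at mu_min={mu_min}")
    n = len(prob.col_ids)
    internal = _internal_columns(network, prob)
    int_mask = np.zeros(n, dtype=bool)
    int_mask[internal] = True

    # reweighted L1 on split variables; accessory columns closed (the
    # essential subset must be available to every strain)
    accessory = pangem.accessory_reaction_ids
    S2 = sparse.hstack([prob.S, -prob.S]).tocsr()
    lb = np.concatenate([np.maximum(prob.v_lb, 0), np.maximum(-prob.v_ub, 0)])
    ub = np.concatenate([np.maximum(prob.v_ub, 0), np.maximum(-prob.v_lb, 0)])
    lb2, ub2 = lb.copy(), ub.copy()
    for j, rid in enumerate(prob.col_ids):
        if rid in accessory:
            lb2[j] = ub2[j] = 0.0
            lb2[n + j] = ub2[n + j] = 0.0
    lb2[jb] = max(lb2[jb], mu_min)  # force growth
    w = np.ones(n)
    v = None
    for it in range(5):
        c = np.concatenate([w * int_mask, w * int_mask])
        res = linprog(c=c, A_eq=S2, b_eq=np.zeros(S2.shape[0]),
                      bounds=np.column_stack([lb2, ub2]), method="highs")
        if res.status != 0:
            if it == 0:
                # the universal subnetwork alone cannot grow: re-open the
                # accessory columns and let gap filling sort out universality
                lb2, ub2 = lb.copy(), ub.copy()
                lb2[jb] = max(lb2[jb], mu_min)
                res = linprog(c=c, A_eq=S2, b_eq=np.zeros(S2.shape[0]),
                              bounds=np.column_stack([lb2, ub2]), method="highs")
            if res.status != 0:
                raise RuntimeError("reweighted-L1 subproblem infeasible")
        v = res.x[:n] - res.x[n:]
        w = 1.0 / (np.abs(v) + 1e-6)
    support = {
        prob.col_ids[j] for j in internal if abs(v[j]) > SUPPORT_TOL
    }

    # re-admit reactions needed for any component not producible de novo
    universe_ids = {prob.col_ids[j] for j in internal}
    if not _feasible_with(network, support, mu_min):
        sub = network.with_reactions([
            r for r in network.reactions
            if r.is_exchange or r.is_biomass or r.id in support
        ])
        added = gap_fill(sub, network, mu_min)
        support |= set(added)

    # deterministic greedy pruning toward superset-minimality
    for rid in sorted(support):
        trial = support - {rid}
        if _feasible_with(network, trial, mu_min):
            support = trial
    support = frozenset(support)
    pangem._essential_cache[key] = support
    return support


def extract_strain_gem(
    pangem: PanGEM, strain_id: str, mu_min: float = MU_MIN_DEFAULT,
) -> MetabolicNetwork:
    """Strain model = essential core ∪ strain-specific gene reactions, plus
    exchanges, biomass and all gene-free reactions (spontaneous scaffold
    steps and gap-filled reactions are universal); gap-filled further if
    needed, error if hopeless."""
    if strain_id not in pangem.ortholog_matrix.strains:
        raise KeyError(f"unknown strain {strain_id}")
    essential = essential_core(pangem, mu_min)
    strain_rxns = pangem.strain_reaction_ids(strain_id)
    keep = set(essential) | set(strain_rxns)
    network = pangem.network
    rxns = [
        r for r in network.reactions
        if r.is_exchange or r.is_biomass or not r.ortholog_ids or r.id in keep
    ]
    # the full metabolite universe is retained so that later knock-ins of
    # pangenome reactions (e.g. nano-niche experiments) remain valid
    def build(reactions):
        return MetabolicNetwork(network.metabolites, reactions,
                                network.biomass_reaction_id,
                                dict(network.annotations))

    model = build(rxns)
    sol = fba.solve_fba(build_flux_problem(model), model.biomass_reaction_id)
    if sol.status != "optimal" or sol.objective_value < mu_min:
        added = gap_fill(model, network, mu_min)
        rxns += [network.reaction(rid) for rid in added]
        model = build(rxns)
        sol = fba.solve_fba(build_flux_problem(model), model.biomass_reaction_id)
        if sol.status != "optimal" or sol.objective_value < mu_min:
            _raise_orphan(model)
    model.annotations["strain_id"] = strain_id
    return model


# ---------------------------------------------------------------------------
# gap filling
# ---------------------------------------------------------------------------

class GapFillSet(frozenset):
    """Set of added reaction ids; ``exact`` records whether the minimum-
    cardinality integer program (rather than the greedy fallback) was used."""

    exact: bool = True

    def __new__(cls, items, exact=True):
        obj = super().__new__(cls, items)
        obj.exact = exact
        return obj


def gap_fill(
    model: MetabolicNetwork,
    universe: MetabolicNetwork,
    mu_min: float = MU_MIN_DEFAULT,
    exact_threshold: int = 64,
) -> GapFillSet:
    """Minimum-cardinality reaction additions restoring growth ≥ mu_min.

    Candidates are universe reactions absent from the model.  Solved exactly
    as a mixed-integer program while the candidate set is small; above
    ``exact_threshold`` a greedy L1-support heuristic is used and flagged on
    the result.  Raises if the universe itself cannot grow.
    """
    usol = fba.solve_fba(build_flux_problem(universe), universe.biomass_reaction_id)
    if usol.status != "optimal" or usol.objective_value < mu_min:
        raise ValueError("gap-fill universe cannot reach mu_min")
    msol = fba.solve_fba(build_flux_problem(model), model.biomass_reaction_id)
    if msol.status == "optimal" and msol.objective_value >= mu_min:
        return GapFillSet(())

    have = set(model.reaction_ids)
    candidates = sorted(r.id for r in universe.reactions if r.id not in have)
    prob = build_flux_problem(universe)
    n = len(prob.col_ids)
    jb = prob.col(universe.biomass_reaction_id)
    lb, ub = prob.v_lb.copy(), prob.v_ub.copy()
    lb[jb] = max(lb[jb], mu_min)

    if len(candidates) <= exact_threshold:
        cand_idx = [prob.col(rid) for rid in candidates]
        ncand = len(cand_idx)
        # variables: v (n) then y (ncand binary)
        c = np.concatenate([np.zeros(n), np.ones(ncand)])
        A_rows, lo_list, hi_list = [], [], []
        A_eq = sparse.hstack([prob.S, sparse.csr_matrix((prob.S.shape[0], ncand))])
        A_rows.append(A_eq)
        lo_list.append(np.zeros(prob.S.shape[0]))
        hi_list.append(np.zeros(prob.S.shape[0]))
        # v_j - ub_j * y_j <= 0 and v_j - lb_j * y_j >= 0
        big = np.maximum(np.abs(lb), np.abs(ub)) + 1.0
        rows_u = sparse.lil_matrix((ncand, n + ncand))
        rows_l = sparse.lil_matrix((ncand, n + ncand))
        for i, j in enumerate(cand_idx):
            rows_u[i, j] = 1.0
            rows_u[i, n + i] = -max(ub[j], 0.0) - (big[j] if ub[j] < 0 else 0)
            rows_l[i, j] = 1.0
            rows_l[i, n + i] = -min(lb[j], 0.0) + (big[j] if lb[j] > 0 else 0)
        A_rows.append(rows_u.tocsr())
        lo_list.append(np.full(ncand, -np.inf))
        hi_list.append(np.zeros(ncand))
        A_rows.append(rows_l.tocsr())
        lo_list.append(np.zeros(ncand))
        hi_list.append(np.full(ncand, np.inf))
        A = sparse.vstack(A_rows)
        constraints = LinearConstraint(A, np.concatenate(lo_list), np.concatenate(hi_list))
        bounds = Bounds(
            np.concatenate([lb, np.zeros(ncand)]),
            np.concatenate([ub, np.ones(ncand)]),
        )
        integrality = np.concatenate([np.zeros(n), np.ones(ncand)])
        res = milp(c=c, constraints=constraints, bounds=bounds, integrality=integrality)
        if res.status != 0:
            raise RuntimeError("gap-fill MILP failed")
        y = res.x[n:]
        added = {candidates[i] for i in range(ncand) if y[i] > 0.5}
        return GapFillSet(added, exact=True)

    # greedy fallback: L1-minimal flux over the universe with candidates
    # penalized, then prune
    c = np.zeros(2 * n)
    S2 = sparse.hstack([prob.S, -prob.S]).tocsr()
    lbs = np.concatenate([np.maximum(lb, 0), np.maximum(-ub, 0)])
    ubs = np.concatenate([np.maximum(ub, 0), np.maximum(-lb, 0)])
    for rid in candidates:
        j = prob.col(rid)
        c[j] = c[n + j] = 1.0
    res = linprog(c=c, A_eq=S2, b_eq=np.zeros(S2.shape[0]),
                  bounds=np.column_stack([lbs, ubs]), method="highs")
    if res.status != 0:
        raise RuntimeError("greedy gap-fill LP failed")
    v = res.x[:n] - res.x[n:]
    added = {rid for rid in candidates if abs(v[prob.col(rid)]) > SUPPORT_TOL}
    for rid in sorted(added):
        trial = added - {rid}
        sub = universe.with_reactions([
            r for r in universe.reactions if r.id in have or r.id in trial
        ])
        s = fba.solve_fba(build_flux_problem(sub), sub.biomass_reaction_id)
        if s.status == "optimal" and s.objective_value >= mu_min:
            added = trial
    return GapFillSet(added, exact=False)
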