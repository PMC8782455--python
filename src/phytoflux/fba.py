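"""Linear-programming core: FBA, parsimonious (L1-minimal) FBA, flux
variability analysis, dual-based sensitivities and network edits.

All solves go through scipy's HiGHS interface.  Maximization of the
objective flux is posed as minimization of its negation; duals are
sign-corrected so that a shadow price is the marginal change of the
*maximized* objective per unit relaxation of the corresponding constraint.

Degenerate optima: when alternate optima exist the reported flux vector of
:func:`solve_pfba` (L1-minimal at fraction 1.0) is the reproducible choice;
duals at a degenerate optimum are one valid subgradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import FluxProblem, MetabolicNetwork, Reaction

__all__ = [
    "FluxSolution",
    "FluxRange",
    "solve_fba",
    "solve_pfba",
    "flux_variability",
    "sensitivity",
    "edit_reactions",
]

FEAS_TOL = 1e-9
OPT_TOL = 1e-9

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class FluxSolution:
    objective_value: float
    fluxes: dict[str, float]
    status: str
    duals: dict[str, float]
    reduced_costs: dict[str, float]
    #: marginal objective gain per unit relaxation of each upper/lower bound
    bound_sensitivities: dict[str, float] = None
    #: dual objective value (maximization convention); equals the primal
    #: objective at an optimum by LP strong duality
    dual_objective: float = float("nan")

    def flux_vector(self, col_ids) -> np.ndarray:
        return np.array([self.fluxes[r] for r in col_ids])


def _solve(problem: FluxProblem, c_min: np.ndarray, extra_A=None, extra_b=None):
    """Minimize c_min·v over the flux polytope (+ optional inequality rows)."""
    kwargs = dict(
        A_eq=problem.S, b_eq=np.zeros(problem.S.shape[0]),
        bounds=np.column_stack([problem.v_lb, problem.v_ub]),
        method="highs",
        options={"primal_feasibility_tolerance": FEAS_TOL,
                 "dual_feasibility_tolerance": OPT_TOL},
    )
    if extra_A is not None:
        kwargs["A_ub"] = extra_A
        kwargs["b_ub"] = extra_b
    return linprog(c=c_min, **kwargs)


def solve_fba(problem: FluxProblem, objective_id: str) -> FluxSolution:
    """Maximize the flux of ``objective_id`` subject to S v = 0 and bounds.

    Returns the LP optimum with duals (shadow prices on the mass-balance
    rows) and reduced costs; infeasible/unbounded status is reported, never
    silently zeroed.
    """
    j = problem.col(objective_id)
    c = np.zeros(len(problem.col_ids))
    c[j] = -1.0
    res = _solve(problem, c)
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxSolution(float("nan"), {}, status, {}, {})
    fluxes = dict(zip(problem.col_ids, res.x))
    # linprog minimizes -v_obj: flip dual signs to the maximization convention
    duals = dict(zip(problem.row_ids, -res.eqlin.marginals))
    red = -(res.lower.marginals + res.upper.marginals)
    reduced_costs = dict(zip(problem.col_ids, red))
    # marginal objective gain per unit relaxation of the active bound in its
    # natural direction (raise an upper bound / lower a lower bound); >= 0 at
    # a maximum for any improving relaxation
    bsens = dict(zip(problem.col_ids, res.lower.marginals - res.upper.marginals))
    # dual objective by homogeneity: Σ ∂obj/∂rhs × rhs over all constraints
    # (b_eq = 0 contributes nothing; inactive infinite bounds carry zero duals)
    lo = np.where(np.isfinite(problem.v_lb), problem.v_lb, 0.0)
    hi = np.where(np.isfinite(problem.v_ub), problem.v_ub, 0.0)
    dual_min = float(res.lower.marginals @ lo + res.upper.marginals @ hi)
    return FluxSolution(float(res.x[j]), fluxes, "optimal", duals, reduced_costs,
                        bsens, dual_objective=-dual_min)


def solve_pfba(problem: FluxProblem, objective_id: str, fraction: float = 1.0) -> FluxSolution:
    """L1-minimal flux vector subject to objective ≥ fraction × optimum.

    Uses the standard split into nonnegative forward/reverse components, so
    futile cycles carry zero flux in the reported solution.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    base = solve_fba(problem, objective_id)
    if base.status != "optimal":
        return base
    n = len(problem.col_ids)
    j = problem.col(objective_id)
    S = problem.S
    # variables: v+ (n), v- (n); v = v+ - v-
    S2 = sparse.hstack([S, -S]).tocsr()
    lb = np.concatenate([np.maximum(problem.v_lb, 0.0), np.maximum(-problem.v_ub, 0.0)])
    ub = np.concatenate([np.maximum(problem.v_ub, 0.0), np.maximum(-problem.v_lb, 0.0)])
    c = np.ones(2 * n)
    # objective floor: v_j >= fraction * opt  ->  -(v+_j - v-_j) <= -floor
    floor = fraction * base.objective_value
    row = np.zeros(2 * n)
    row[j] = -1.0
    row[n + j] = 1.0
    res = linprog(
        c=c, A_eq=S2, b_eq=np.zeros(S2.shape[0]),
        A_ub=row.reshape(1, -1), b_ub=np.array([-floor]),
        bounds=np.column_stack([lb, ub]), method="highs",
        options={"primal_feasibility_tolerance": FEAS_TOL,
                 "dual_feasibility_tolerance": OPT_TOL},
    )
    if res.status != 0:
        return FluxSolution(float("nan"), {}, _STATUS.get(res.status, "numerical"), {}, {})
    v = res.x[:n] - res.x[n:]
    fluxes = dict(zip(problem.col_ids, v))
    return FluxSolution(float(v[j]), fluxes, "optimal", base.duals, base.reduced_costs,
                        base.bound_sensitivities)


@dataclass
class FluxRange:
    reaction_id: str
    v_min: float
    v_max: float

    def __post_init__(self):
        if self.v_min > self.v_max + 1e-9:
            raise ValueError("v_min > v_max")


def flux_variability(
    problem: FluxProblem, objective_id: str, fraction: float = 1.0,
    reaction_ids=None,
) -> list[FluxRange]:
    """Per-reaction flux range with the objective held ≥ fraction × optimum.

    ``fraction=0`` drops the objective floor entirely (used for blocked-
    reaction detection).
    """
    n = len(problem.col_ids)
    extra_A = extra_b = None
    if fraction > 0:
        base = solve_fba(problem, objective_id)
        if base.status != "optimal":
            raise RuntimeError(f"base FBA {base.status}")
        j = problem.col(objective_id)
        row = np.zeros(n)
        row[j] = -1.0
        extra_A = row.reshape(1, -1)
        extra_b = np.array([-fraction * base.objective_value])
    targets = reaction_ids if reaction_ids is not None else problem.col_ids
    out = []
    for rid in targets:
        k = problem.col(rid)
        c = np.zeros(n)
        c[k] = 1.0
        lo = _solve(problem, c, extra_A, extra_b)
        c[k] = -1.0
        hi = _solve(problem, c, extra_A, extra_b)
        if lo.status != 0 or hi.status != 0:
            raise RuntimeError(f"FVA subproblem failed for {rid}")
        vmin, vmax = float(lo.x[k]), float(hi.x[k])
        if vmin > vmax:  # solver noise at degenerate vertices
            vmin = vmax = (vmin + vmax) / 2
        out.append(FluxRange(rid, vmin, vmax))
    return out


def sensitivity(problem: FluxProblem, objective_id: str):
    """Shadow prices on the mass-balance rows and reaction reduced costs.

    The bound sensitivity of an exchange reaction (marginal objective gain
    per unit bound relaxation) is its reduced-cost magnitude at the optimum;
    for a single-bottleneck chain this equals the biomass yield per unit of
    the limiting substrate.
    """
    sol = solve_fba(problem, objective_id)
    if sol.status != "optimal":
        raise RuntimeError(f"FBA {sol.status}")
    return sol.duals, sol.reduced_costs


def edit_reactions(
    network: MetabolicNetwork, remove=(), add: list[Reaction] = ()
) -> MetabolicNetwork:
    """Pure-functional knockout / knock-in: returns a new network."""
    remove = set(remove)
    present = set(network.reaction_ids)
    missing = remove - present
    if missing:
        raise ValueError(f"cannot remove absent reactions {sorted(missing)}")
    if network.biomass_reaction_id in remove:
        raise ValueError("cannot remove the biomass reaction")
    kept = [r for r in network.reactions if r.id not in remove]
    for r in add:
        if r.id in {k.id for k in kept}:
            raise ValueError(f"reaction {r.id} already present")
        kept.append(r)
    # union of metabolites: original plus any new ones referenced by additions
    known = {m.id for m in network.metabolites}
    for r in add:
        unknown = set(r.stoichiometry) - known
        if unknown:
            raise ValueError(f"added reaction {r.id} references unknown metabolites {sorted(unknown)}")
    return MetabolicNetwork(
        list(network.metabolites), kept, network.biomass_reaction_id,
        dict(network.annotations),
    )
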