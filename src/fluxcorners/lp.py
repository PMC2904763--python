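"""Linear programming over the flux polytope.

All solves go through HiGHS dual simplex (scipy ``linprog`` backend
``highs-ds``), which returns a basic feasible solution — a vertex of
``{v : S v = 0, lb <= v <= ub}``.  That vertex property is the contract the
corner sampler depends on; interior-point solutions are never accepted.

Also implements flux variability analysis (FVA), detection of reactions able
to run in stoichiometrically balanced internal loops (they hit the default
+/-1000 bound in FVA), and calibration of the replacement loop bound: the
smallest multiple of a step (default 0.1 mmol h^-1 g-DW^-1) that keeps the
experimentally constrained model feasible once every loop reaction is
clamped to [-B, B] (or [0, B] for irreversible reactions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .model import ConditionConstraints, MetabolicModel, apply_condition

FEAS_TOL = 1e-9          # relative steady-state tolerance
BOUND_TOL = 1e-6         # absolute bound-violation tolerance
SOLVER_METHOD = "highs-ds"


class InfeasibleModelError(RuntimeError):
    """The constraint set S v = 0, lb <= v <= ub admits no solution."""


class SolverError(RuntimeError):
    """The LP backend failed for a reason other than infeasibility."""


@dataclass
class LPSolution:
    status: str                      # optimal | infeasible | unbounded
    flux_vector: np.ndarray | None   # per-reaction values when optimal
    objective_value: float | None
    is_vertex: bool = False


@dataclass
class FVAResult:
    reaction_ids: list[str]
    min_flux: np.ndarray
    max_flux: np.ndarray
    loop_flags: np.ndarray | None = None

    def width(self) -> np.ndarray:
        return self.max_flux - self.min_flux


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded"}


def _run(model: MetabolicModel, c: np.ndarray) -> LPSolution:
    if np.any(model.lower_bounds > model.upper_bounds):
        return LPSolution("infeasible", None, None)
    res = linprog(
        c,
        A_eq=model.S,
        b_eq=np.zeros(model.n_metabolites),
        bounds=np.column_stack([model.lower_bounds, model.upper_bounds]),
        method=SOLVER_METHOD,
    )
    status = _STATUS.get(res.status, "error")
    if status == "optimal":
        v = np.asarray(res.x, dtype=float)
        resid = np.abs(model.S @ v)
        scale = max(1.0, float(np.max(np.abs(v))))
        if resid.size and resid.max() > FEAS_TOL * scale * 1e3:
            raise SolverError(f"steady-state residual {resid.max():.3g} above tolerance")
        return LPSolution("optimal", v, float(-res.fun), is_vertex=True)
    if status in ("infeasible", "unbounded"):
        return LPSolution(status, None, None)
    raise SolverError(f"LP solver failure: {res.message}")


def solve_lp(model: MetabolicModel, objective: dict[str, float],
             sense: str = "max") -> LPSolution:
    """Maximize ``sum w_i v_i`` over the flux polytope; returns a vertex.

    ``objective`` maps reaction ids to weights and must be nonempty.
    """
    if not objective:
        raise ValueError("objective must be nonempty")
    if sense != "max":
        raise ValueError("only sense='max' is supported")
    c = np.zeros(model.n_reactions)
    for rxn, w in objective.items():
        c[model.reaction_index(rxn)] = -float(w)  # linprog minimizes
    return _run(model, c)


def check_feasible(model: MetabolicModel) -> bool:
    """Feasibility probe: zero-objective LP over the current bounds."""
    return _run(model, np.zeros(model.n_reactions)).status == "optimal"


def run_fva(model: MetabolicModel, reactions: list[str] | None = None) -> FVAResult:
    """Per-reaction flux minimum and maximum under steady state and bounds."""
    if not check_feasible(model):
        raise InfeasibleModelError("model infeasible under current bounds; FVA not attempted")
    ids = list(model.reaction_ids) if reactions is None else list(reactions)
    lo = np.empty(len(ids))
    hi = np.empty(len(ids))
    c = np.zeros(model.n_reactions)
    for k, rxn in enumerate(ids):
        j = model.reaction_index(rxn)
        c[:] = 0.0
        c[j] = 1.0           # minimize
        sol = _run(model, c)
        lo[k] = sol.flux_vector[j] if sol.status == "optimal" else -math.inf
        c[j] = -1.0          # maximize
        sol = _run(model, c)
        hi[k] = sol.flux_vector[j] if sol.status == "optimal" else math.inf
    return FVAResult(ids, lo, hi)


def detect_loop_reactions(fva: FVAResult, default_bound: float,
                          tol_frac: float = 1e-6) -> set[str]:
    """Reactions whose FVA range touches +/- the default bound.

    A reaction that can carry flux all the way to the default bound can only
    do so through an internal stoichiometrically balanced cycle (exchange
    fluxes are capped far below it), so these are the loop-capable reactions.
    """
    tol = tol_frac * default_bound
    out = set()
    for rxn, lo, hi in zip(fva.reaction_ids, fva.min_flux, fva.max_flux):
        if lo <= -default_bound + tol or hi >= default_bound - tol:
            out.add(rxn)
    return out


def apply_loop_bound(model: MetabolicModel, loop_set: set[str], bound: float) -> MetabolicModel:
    """Clamp loop reactions to [-B, B], keeping irreversible ones at [0, B]."""
    out = model.copy()
    for rxn in loop_set:
        j = out.reaction_index(rxn)
        out.lower_bounds[j] = max(out.lower_bounds[j], -bound)
        out.upper_bounds[j] = min(out.upper_bounds[j], bound)
    return out


def calibrate_loop_bound(model: MetabolicModel, cond: ConditionConstraints,
                         loop_set: set[str], step: float = 0.1) -> float:
    """Smallest multiple of ``step`` that restores feasibility once loop
    reactions are clamped.

    Feasibility is monotone in the bound (shrinking a polytope can only
    remove solutions), so the smallest feasible multiple is located by
    bisection over the multiples; the result equals a linear scan from
    ``step`` upward.
    """
    if not loop_set:
        raise ValueError("loop_set must be nonempty")
    if step <= 0:
        raise ValueError("step must be positive")
    constrained = apply_condition(model, cond)
    k_max = int(math.ceil(model.default_bound / step))

    def feasible(k: int) -> bool:
        return check_feasible(apply_loop_bound(constrained, loop_set, k * step))

    if not feasible(k_max):
        raise InfeasibleModelError(
            "condition constraints are infeasible even without loop clamping"
        )
    lo, hi = 0, k_max  # invariant: feasible(hi), not feasible(lo) (k=0 clamps loops shut)
    if feasible(1):
        return step
    lo = 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if feasible(mid):
            hi = mid
        else:
            lo = mid
    return hi * step
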