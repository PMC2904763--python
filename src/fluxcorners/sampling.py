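"""Corner (convex-basis) sampling of the feasible flux polytope, plus a
Hit-and-Run baseline.

The corner sampler repeatedly maximizes a random two-term objective
``w_1 v_i + w_2 v_j`` with the simplex method; each optimum is a vertex
("corner") of the experimentally constrained flux polytope.  Weights are
``u / m`` with ``u ~ Uniform(0, 1)`` and ``m`` the FVA flux magnitude of the
reaction, so reactions operating on different scales contribute comparably.
Loop-capable reactions are excluded from objectives and clamped to a
calibrated bound beforehand, so no objective rewards spinning an internal
cycle.

Per-reaction means and population variances over the n samples are the
summary statistics consumed by the flux-change Z-scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from . import lp
from .model import ConditionConstraints, MetabolicModel, apply_condition

ELIGIBILITY_FLOOR = 1e-9


@dataclass(frozen=True)
class ObjectiveSpec:
    """A random paired-reaction objective: list of (reaction id, weight > 0)."""

    terms: tuple[tuple[str, float], ...]
    seed_tag: str = ""

    def __post_init__(self) -> None:
        for rxn, w in self.terms:
            if not (np.isfinite(w) and w > 0):
                raise ValueError(f"weight for {rxn} must be finite and > 0, got {w}")

    def as_dict(self) -> dict[str, float]:
        return dict(self.terms)


@dataclass
class FluxSampleSet:
    """n_samples x n_reactions matrix of sampled flux vectors with summaries."""

    condition_name: str
    reaction_ids: list[str]
    samples: np.ndarray
    sampler: str                     # "CB" or "HR"
    seed: int
    loop_bound: float | None = None
    loop_set: set[str] = field(default_factory=set)
    means: np.ndarray | None = None
    variances: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def summary(self) -> pd.DataFrame:
        if self.means is None or self.variances is None:
            df = summarize(self)
            self.means = df["mean"].to_numpy()
            self.variances = df["variance"].to_numpy()
            return df
        return pd.DataFrame(
            {"mean": self.means, "variance": self.variances}, index=self.reaction_ids
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.reaction_ids)

    def write_tsv(self, path, sidecar_path=None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
        if sidecar_path is not None:
            import json

            meta = {
                "condition": self.condition_name,
                "sampler": self.sampler,
                "seed": int(self.seed),
                "n_samples": int(self.n_samples),
                "loop_bound": self.loop_bound,
                "loop_set": sorted(self.loop_set),
                "solver": lp.SOLVER_METHOD,
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=1)


def summarize(samples: FluxSampleSet) -> pd.DataFrame:
    """Arithmetic mean and population variance per reaction column."""
    if samples.n_samples < 2:
        raise ValueError("variance needs at least 2 samples")
    means = samples.samples.mean(axis=0)
    variances = samples.samples.var(axis=0)  # population (ddof=0)
    return pd.DataFrame({"mean": means, "variance": variances},
                        index=samples.reaction_ids)


def draw_objective(model: MetabolicModel, fva: lp.FVAResult, loop_set: set[str],
                   rng: np.random.Generator, n_terms: int = 2) -> ObjectiveSpec:
    """Pick ``n_terms`` distinct eligible reactions and assign FVA-normalized
    positive random weights.

    Eligible reactions are non-loop with FVA magnitude above a floor; the
    normalizer is ``max(|fva min|, |fva max|)`` so reversible reactions whose
    maximum is 0 still get a finite weight.
    """
    mags = np.maximum(np.abs(fva.min_flux), np.abs(fva.max_flux))
    eligible = [
        (rxn, m)
        for rxn, m in zip(fva.reaction_ids, mags)
        if rxn not in loop_set and m > ELIGIBILITY_FLOOR
    ]
    if len(eligible) < n_terms:
        raise ValueError(
            f"only {len(eligible)} eligible reactions, need {n_terms} "
            "(loop-flagged and zero-range reactions are excluded)"
        )
    idx = rng.choice(len(eligible), size=n_terms, replace=False)
    terms = []
    for i in idx:
        rxn, m = eligible[i]
        terms.append((rxn, float(rng.uniform()) / m))
    return ObjectiveSpec(terms=tuple(terms))


def prepare_polytope(model: MetabolicModel, cond: ConditionConstraints,
                     step: float = 0.1) -> tuple[MetabolicModel, lp.FVAResult, set[str], float | None]:
    """Constrain, detect loops, calibrate and apply the loop bound, re-run FVA.

    Returns the sampling-ready model, its FVA, the loop set, and the
    calibrated bound (None when the model is loop-free).
    """
    constrained = apply_condition(model, cond)
    fva = lp.run_fva(constrained)
    loop_set = lp.detect_loop_reactions(fva, model.default_bound)
    bound = None
    if loop_set:
        bound = lp.calibrate_loop_bound(model, cond, loop_set, step=step)
        constrained = lp.apply_loop_bound(constrained, loop_set, bound)
        fva = lp.run_fva(constrained)
    return constrained, fva, loop_set, bound


def sample_corners(model: MetabolicModel, cond: ConditionConstraints,
                   n: int = 500, seed: int = 0, step: float = 0.1,
                   n_terms: int = 2) -> FluxSampleSet:
    """Draw ``n`` vertices of the constrained flux polytope (duplicates kept).

    Pipeline: fix measured fluxes -> FVA -> flag loop reactions -> calibrate
    and apply the loop bound -> n times {random objective, simplex maximize}.
    """
    constrained, fva, loop_set, bound = prepare_polytope(model, cond, step=step)
    rng = np.random.default_rng(seed)
    samples = np.empty((n, model.n_reactions))
    for k in range(n):
        obj = draw_objective(constrained, fva, loop_set, rng, n_terms=n_terms)
        sol = lp.solve_lp(constrained, obj.as_dict())
        if sol.status == "unbounded":
            raise lp.SolverError(
                f"unbounded LP for objective {obj.terms}; loop bounding failed"
            )
        if sol.status != "optimal":
            raise lp.InfeasibleModelError(
                f"LP infeasible after calibration (objective {obj.terms})"
            )
        samples[k] = sol.flux_vector
    out = FluxSampleSet(
        condition_name=cond.condition_name,
        reaction_ids=list(model.reaction_ids),
        samples=samples,
        sampler="CB",
        seed=seed,
        loop_bound=bound,
        loop_set=loop_set,
    )
    out.summary()
    return out


# ---------------------------------------------------------------------------
# Hit-and-Run baseline


def _null_space_parameterization(model: MetabolicModel):
    """Affine parameterization v = v0 + N y of {S v = 0, fixed bounds}.

    Reactions whose bounds pin them to a point are folded into the equality
    system so HR directions never move them.
    """
    fixed = np.nonzero(model.upper_bounds - model.lower_bounds <= 1e-12)[0]
    A = model.S.toarray()
    b = np.zeros(A.shape[0])
    if fixed.size:
        E = np.zeros((fixed.size, model.n_reactions))
        E[np.arange(fixed.size), fixed] = 1.0
        A = np.vstack([A, E])
        b = np.concatenate([b, model.lower_bounds[fixed]])
    v0, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.max(np.abs(A @ v0 - b), initial=0.0) > 1e-8:
        raise lp.InfeasibleModelError("equality constraints are inconsistent")
    N = scipy.linalg.null_space(A)
    return v0, N


def _chebyshev_center(G: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Center of the largest inscribed ball of {y : G y <= h}."""
    from scipy.optimize import linprog

    norms = np.linalg.norm(G, axis=1)
    d = G.shape[1]
    c = np.zeros(d + 1)
    c[-1] = -1.0  # maximize radius
    A_ub = np.hstack([G, norms[:, None]])
    res = linprog(c, A_ub=A_ub, b_ub=h,
                  bounds=[(None, None)] * d + [(0, None)], method="highs")
    if res.status != 0:
        raise lp.InfeasibleModelError("could not find an interior starting point")
    return res.x[:d]


def sample_hit_and_run(model: MetabolicModel, cond: ConditionConstraints,
                       n: int, seed: int = 0, thinning: int | None = None,
                       warmup: int | None = None, step: float = 0.1) -> FluxSampleSet:
    """Approximately uniform points from the constrained polytope.

    Runs hit-and-run in the null-space parameterization after the same loop
    bounding as the corner sampler.  Defaults: warmup = 10 x degrees of
    freedom, thinning = degrees of freedom.  A zero-dimensional polytope
    yields ``n`` identical samples with a warning.
    """
    constrained, _fva, loop_set, bound = prepare_polytope(model, cond, step=step)
    v0, N = _null_space_parameterization(constrained)
    dof = N.shape[1]
    rng = np.random.default_rng(seed)
    if dof == 0:
        warnings.warn("polytope has 0 degrees of freedom; all samples identical",
                      stacklevel=2)
        samples = np.tile(v0, (n, 1))
    else:
        thinning = dof if thinning is None else max(1, int(thinning))
        warmup = 10 * dof if warmup is None else max(0, int(warmup))
        # rows of G y <= h: +/- each free coordinate's bound
        G = np.vstack([N, -N])
        h = np.concatenate([constrained.upper_bounds - v0, v0 - constrained.lower_bounds])
        keep = np.linalg.norm(G, axis=1) > 1e-12
        G, h = G[keep], h[keep]
        y = _chebyshev_center(G, h)
        samples = np.empty((n, constrained.n_reactions))
        total = warmup + n * thinning
        got = 0
        for it in range(total):
            u = rng.standard_normal(dof)
            u /= np.linalg.norm(u)
            Gu = G @ u
            slack = h - G @ y
            with np.errstate(divide="ignore"):
                t = slack / Gu
            t_hi = np.min(t[Gu > 1e-14], initial=np.inf)
            t_lo = np.max(t[Gu < -1e-14], initial=-np.inf)
            if not np.isfinite(t_hi) or not np.isfinite(t_lo):
                continue  # unbounded chord cannot occur in a bounded polytope
            y = y + rng.uniform(t_lo, t_hi) * u
            k = it - warmup + 1
            if k > 0 and k % thinning == 0 and got < n:
                samples[got] = v0 + N @ y
                got += 1
        if got < n:
            samples[got:] = v0 + N @ y
    out = FluxSampleSet(
        condition_name=cond.condition_name,
        reaction_ids=list(model.reaction_ids),
        samples=samples,
        sampler="HR",
        seed=seed,
        loop_bound=bound,
        loop_set=loop_set,
    )
    if n >= 2:
        out.summary()
    return out
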