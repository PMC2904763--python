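"""Synthetic metabolic networks with analytically known geometry.

Every fixture is a small mass-balanced network whose experimentally
constrained flux polytope has a hand-checkable vertex set, plus
``enumerate_vertices``, a brute-force basic-feasible-solution oracle used to
verify that corner samples really are vertices.  The ``planted_regulation``
fixture builds two conditions and an expression table that realize known
TR / PR / MR / none labels end to end.

Flux magnitudes sit in the 0.1-15 mmol h^-1 g-DW^-1 range typical of
chemostat exchange measurements.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .model import (ConditionConstraints, ExpressionScores, MetabolicModel,
                    DEFAULT_BOUND)

VERTEX_DEDUP_TOL = 1e-8
MAX_DOF = 6


@dataclass
class Fixture:
    """A synthetic model plus its condition(s) and ground truth."""

    kind: str
    model: MetabolicModel
    conditions: list[ConditionConstraints]
    known_vertices: list[np.ndarray] | None = None
    planted_labels: dict[str, str] = field(default_factory=dict)
    expression: ExpressionScores | None = None

    @property
    def condition(self) -> ConditionConstraints:
        return self.conditions[0]


def _model(mets, rxns, entries, bounds, genes=None) -> MetabolicModel:
    """entries: list of (met, rxn, coeff); bounds: dict rxn -> (lb, ub)."""
    mi = {m: i for i, m in enumerate(mets)}
    ri = {r: j for j, r in enumerate(rxns)}
    rows = [mi[m] for m, _, _ in entries]
    cols = [ri[r] for _, r, _ in entries]
    data = [float(c) for _, _, c in entries]
    S = sp.csr_matrix((data, (rows, cols)), shape=(len(mets), len(rxns)))
    lb = np.array([bounds[r][0] for r in rxns], dtype=float)
    ub = np.array([bounds[r][1] for r in rxns], dtype=float)
    return MetabolicModel(list(mets), list(rxns), S, lb, ub,
                          gene_links=dict(genes or {}))


def make_fixture(kind: str, **params) -> Fixture:
    """Build a named fixture; see the individual builders for parameters."""
    builders = {
        "chain": _chain,
        "diamond": _diamond,
        "cycle": _cycle,
        "interval": _interval,
        "simplex": _simplex,
        "planted_regulation": _planted_regulation,
    }
    if kind not in builders:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return builders[kind](**params)


def _chain(length: int = 2, uptake: float = 1.0) -> Fixture:
    """Linear pathway with fixed uptake: zero degrees of freedom."""
    if length < 1:
        raise ValueError("length must be >= 1")
    mets = [f"M{i}" for i in range(length + 1)]
    rxns = ["EX_in"] + [f"R{i}" for i in range(length)] + ["EX_out"]
    entries = [("M0", "EX_in", -1.0), (mets[-1], "EX_out", -1.0)]
    for i in range(length):
        entries += [(mets[i], f"R{i}", -1.0), (mets[i + 1], f"R{i}", 1.0)]
    bounds = {r: (0.0, DEFAULT_BOUND) for r in rxns}
    bounds["EX_in"] = (-DEFAULT_BOUND, 0.0)
    m = _model(mets, rxns, entries, bounds)
    cond = ConditionConstraints("chain", {"EX_in": -uptake})
    v = np.full(len(rxns), uptake)
    v[0] = -uptake
    return Fixture("chain", m, [cond], known_vertices=[v])


def _parallel_branches(n_branches: int, uptake: float,
                       caps: dict[int, float] | None = None) -> Fixture:
    """Fixed uptake split over n parallel A->B branches: an (n-1)-simplex
    scaled by the uptake, optionally with per-branch capacity caps."""
    mets = ["A", "B"]
    branch_ids = [f"b{i + 1}" for i in range(n_branches)]
    rxns = ["EX_A"] + branch_ids + ["EX_B"]
    entries = [("A", "EX_A", -1.0), ("B", "EX_B", -1.0)]
    for b in branch_ids:
        entries += [("A", b, -1.0), ("B", b, 1.0)]
    bounds = {r: (0.0, DEFAULT_BOUND) for r in rxns}
    bounds["EX_A"] = (-DEFAULT_BOUND, 0.0)
    for i, cap in (caps or {}).items():
        bounds[branch_ids[i]] = (0.0, float(cap))
    m = _model(mets, rxns, entries, bounds)
    cond = ConditionConstraints("split", {"EX_A": -uptake})
    return Fixture("split", m, [cond])


def _diamond(uptake: float = 1.0, cap_branch1: float | None = None) -> Fixture:
    """Two parallel routes sharing a fixed uptake: the 1-simplex."""
    caps = {0: cap_branch1} if cap_branch1 is not None else None
    fx = _parallel_branches(2, uptake, caps)
    fx.kind = "diamond"
    if cap_branch1 is None:
        verts = [(uptake, 0.0), (0.0, uptake)]
    else:
        verts = [(cap_branch1, uptake - cap_branch1), (0.0, uptake)]
    fx.known_vertices = [
        np.array([-uptake, v1, v2, uptake]) for v1, v2 in verts
    ]
    return fx


def _interval(width: float = 10.0) -> Fixture:
    """One degree of freedom spanning [0, width] on the first branch.

    Realized as a two-branch split (a literal in/out pipe has its fluxes
    perfectly correlated, which positive-weight maximization could never
    drive to the 0 endpoint)."""
    fx = _diamond(uptake=width)
    fx.kind = "interval"
    return fx


def _simplex(n_branches: int = 3, uptake: float = 1.0) -> Fixture:
    """(n-1)-simplex over n parallel branches with unit total throughput."""
    fx = _parallel_branches(n_branches, uptake)
    fx.kind = "simplex"
    fx.known_vertices = []
    for i in range(n_branches):
        v = np.zeros(n_branches + 2)
        v[0] = -uptake
        v[1 + i] = uptake
        v[-1] = uptake
        fx.known_vertices.append(v)
    return fx


def _cycle(through: float = 0.0, uptake: float = 1.0) -> Fixture:
    """Internal loop fixtures.

    ``through = 0``: a driven chain plus an isolated reversible 3-cycle
    (X->Y->Z->X); FVA flags exactly the three cycle reactions.

    ``through > 0``: a forward/backward 2-cycle (X->Y, Y->X, both
    irreversible) sits on the only route, so the forward member must carry
    the measured throughput and the calibrated loop bound is the smallest
    step multiple >= ``through``.
    """
    if through > 0:
        mets = ["A", "X", "Y", "B"]
        rxns = ["EX_A", "R_in", "C_f", "C_b", "R_out", "EX_B"]
        entries = [
            ("A", "EX_A", -1.0),
            ("A", "R_in", -1.0), ("X", "R_in", 1.0),
            ("X", "C_f", -1.0), ("Y", "C_f", 1.0),
            ("Y", "C_b", -1.0), ("X", "C_b", 1.0),
            ("Y", "R_out", -1.0), ("B", "R_out", 1.0),
            ("B", "EX_B", -1.0),
        ]
        bounds = {r: (0.0, DEFAULT_BOUND) for r in rxns}
        bounds["EX_A"] = (-DEFAULT_BOUND, 0.0)
        m = _model(mets, rxns, entries, bounds)
        cond = ConditionConstraints("through_loop", {"EX_A": -through})
        return Fixture("cycle", m, [cond])
    mets = ["A", "B", "X", "Y", "Z"]
    rxns = ["EX_A", "R_ab", "EX_B", "C1", "C2", "C3"]
    entries = [
        ("A", "EX_A", -1.0),
        ("A", "R_ab", -1.0), ("B", "R_ab", 1.0),
        ("B", "EX_B", -1.0),
        ("X", "C1", -1.0), ("Y", "C1", 1.0),
        ("Y", "C2", -1.0), ("Z", "C2", 1.0),
        ("Z", "C3", -1.0), ("X", "C3", 1.0),
    ]
    bounds = {
        "EX_A": (-DEFAULT_BOUND, 0.0),
        "R_ab": (0.0, DEFAULT_BOUND),
        "EX_B": (0.0, DEFAULT_BOUND),
        "C1": (-DEFAULT_BOUND, DEFAULT_BOUND),
        "C2": (-DEFAULT_BOUND, DEFAULT_BOUND),
        "C3": (-DEFAULT_BOUND, DEFAULT_BOUND),
    }
    m = _model(mets, rxns, entries, bounds)
    cond = ConditionConstraints("cycle", {"EX_A": -uptake})
    return Fixture("cycle", m, [cond])


def _planted_regulation(n_tr: int = 5, n_pr: int = 5, n_mr: int = 5,
                        n_none: int = 2, signal_z: float = 5.0,
                        noise_z: float = 0.3) -> Fixture:
    """Independent linear units with planted regulation labels.

    Each unit is EX_in -> R (gene-linked) -> EX_out.  Units planted TR or MR
    change uptake between conditions (flux change); TR and PR genes get a
    significant expression Z oriented with the flux-magnitude change
    (positive = higher in condition A); MR and none genes get only noise.
    MR noise is oriented against the flux change (a same-direction
    expression change, however small, leaves probability mass on the
    transcriptional explanation and can only dilute the metabolic call).
    """
    labels: list[str] = (["TR"] * n_tr + ["PR"] * n_pr + ["MR"] * n_mr
                         + ["none"] * n_none)
    mets, rxns, entries = [], [], []
    bounds, genes = {}, {}
    fixed_a, fixed_b, z_by_gene, planted = {}, {}, {}, {}
    for i, lab in enumerate(labels):
        a_m, b_m = f"A{i}", f"B{i}"
        ein, r, eout = f"EX_in{i}", f"R{i}", f"EX_out{i}"
        gene = f"g{i}"
        mets += [a_m, b_m]
        rxns += [ein, r, eout]
        entries += [
            (a_m, ein, -1.0),
            (a_m, r, -1.0), (b_m, r, 1.0),
            (b_m, eout, -1.0),
        ]
        bounds[ein] = (-DEFAULT_BOUND, 0.0)
        bounds[r] = (0.0, DEFAULT_BOUND)
        bounds[eout] = (0.0, DEFAULT_BOUND)
        genes[r] = [gene]
        flux_changes = lab in ("TR", "MR")
        fixed_a[ein] = -2.0
        fixed_b[ein] = -1.0 if flux_changes else -2.0
        z_by_gene[gene] = {"TR": signal_z, "PR": signal_z,
                           "MR": -noise_z, "none": noise_z}[lab]
        planted[gene] = lab
    m = _model(mets, rxns, entries, bounds, genes)
    cond_a = ConditionConstraints("condA", fixed_a)
    cond_b = ConditionConstraints("condB", fixed_b)
    expr = ExpressionScores("condA_vs_condB", z_by_gene)
    return Fixture("planted_regulation", m, [cond_a, cond_b],
                   planted_labels=planted, expression=expr)


# ---------------------------------------------------------------------------
# brute-force vertex oracle


def enumerate_vertices(model: MetabolicModel,
                       cond: ConditionConstraints | None = None,
                       max_dof: int = MAX_DOF) -> list[np.ndarray]:
    """Exhaustively enumerate the vertices of {S v = 0, lb <= v <= ub}.

    Works in the null-space parameterization v = v0 + N y and activates
    every size-d subset of bound constraints (d = degrees of freedom);
    refuses models with more than ``max_dof`` free directions.  Independent
    of the LP path: used as the oracle that corner samples are vertices.
    """
    from .model import apply_condition
    from .sampling import _null_space_parameterization

    work = apply_condition(model, cond) if cond is not None else model
    v0, N = _null_space_parameterization(work)
    d = N.shape[1]
    if d > max_dof:
        raise ValueError(f"{d} degrees of freedom exceeds the enumeration guard {max_dof}")
    if d == 0:
        ok = np.all(v0 >= work.lower_bounds - 1e-7) and np.all(v0 <= work.upper_bounds + 1e-7)
        return [v0] if ok else []
    G = np.vstack([N, -N])
    h = np.concatenate([work.upper_bounds - v0, v0 - work.lower_bounds])
    keep = np.linalg.norm(G, axis=1) > 1e-10
    G, h = G[keep], h[keep]
    verts: list[np.ndarray] = []
    for combo in itertools.combinations(range(G.shape[0]), d):
        Gs = G[list(combo)]
        if np.linalg.matrix_rank(Gs, tol=1e-10) < d:
            continue
        y, *_ = np.linalg.lstsq(Gs, h[list(combo)], rcond=None)
        if np.max(np.abs(Gs @ y - h[list(combo)])) > 1e-8:
            continue
        if np.all(G @ y <= h + 1e-7):
            v = v0 + N @ y
            if not any(np.max(np.abs(v - w)) <= VERTEX_DEDUP_TOL for w in verts):
                verts.append(v)
    return verts


def nearest_vertex_distance(v: np.ndarray, vertices: list[np.ndarray]) -> float:
    """Infinity-norm distance from ``v`` to the closest enumerated vertex."""
    return min(float(np.max(np.abs(v - w))) for w in vertices)
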