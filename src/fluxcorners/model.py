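"""Metabolic network representation and per-condition experimental constraints.

The central object is :class:`MetabolicModel`: a stoichiometric matrix ``S``
(metabolites x reactions), per-reaction flux bounds in mmol h^-1 g-DW^-1,
and optional reaction->gene associations.  Steady-state flux vectors satisfy
``S @ v = 0`` with ``lb <= v <= ub``; experimentally measured exchange fluxes
are pinned per condition via :class:`ConditionConstraints`.

Sign convention: exchange reactions are written as ``metabolite -> (boundary)``
so uptake carries negative flux.  Input files are taken at face value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """Raised when a model file violates a structural invariant."""


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed; names the offending record."""


@dataclass
class MetabolicModel:
    """A stoichiometric model with bounds and gene associations.

    Parameters
    ----------
    metabolite_ids, reaction_ids
        Ordered unique identifiers; ``S`` is metabolites x reactions.
    S
        Sparse stoichiometric coefficient matrix.
    lower_bounds, upper_bounds
        Per-reaction flux bounds (mmol h^-1 g-DW^-1).
    default_bound
        Magnitude substituted for missing bounds (1000 by convention).
    gene_links
        Per-reaction list of associated gene ids; isoenzymes appear as
        separate entries (no AND/OR logic is evaluated).
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sp.csr_matrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    default_bound: float = DEFAULT_BOUND
    gene_links: dict[str, list[str]] = field(default_factory=dict)
    exchange_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.S = sp.csr_matrix(self.S, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.validate()
        if self.exchange_flags is None:
            self.exchange_flags = self.detect_exchanges()

    # -- structure ---------------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, rxn_id: str) -> int:
        try:
            return self.reaction_ids.index(rxn_id)
        except ValueError:
            raise KeyError(f"unknown reaction id: {rxn_id}") from None

    def validate(self) -> None:
        m, r = self.S.shape
        if m != self.n_metabolites or r != self.n_reactions:
            raise ModelValidationError(
                f"S is {m}x{r} but model declares "
                f"{self.n_metabolites} metabolites x {self.n_reactions} reactions"
            )
        for name, ids in (("metabolite", self.metabolite_ids),
                          ("reaction", self.reaction_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({i for i in ids if ids.count(i) > 1})
                raise ModelValidationError(f"duplicate {name} ids: {dup}")
        if self.lower_bounds.shape != (r,) or self.upper_bounds.shape != (r,):
            raise ModelValidationError("bound arrays must have one entry per reaction")
        bad = np.nonzero(self.lower_bounds > self.upper_bounds)[0]
        if bad.size:
            raise ModelValidationError(
                f"lower bound exceeds upper bound for {self.reaction_ids[bad[0]]}"
            )
        known = set(self.reaction_ids)
        for rxn in self.gene_links:
            if rxn not in known:
                raise ModelValidationError(f"gene association references unknown reaction {rxn}")

    def detect_exchanges(self) -> np.ndarray:
        """Exchange reactions are columns touching a single metabolite."""
        counts = np.asarray((self.S != 0).sum(axis=0)).ravel()
        return counts == 1

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            default_bound=self.default_bound,
            gene_links={k: list(v) for k, v in self.gene_links.items()},
            exchange_flags=None if self.exchange_flags is None else self.exchange_flags.copy(),
        )

    # -- serialization -----------------------------------------------------

    def to_json_dict(self) -> dict:
        Sc = self.S.tocsc()
        reactions = []
        for j, rid in enumerate(self.reaction_ids):
            col = Sc.getcol(j)
            stoich = {self.metabolite_ids[i]: float(c)
                      for i, c in zip(col.indices, col.data)}
            reactions.append({
                "id": rid,
                "stoich": stoich,
                "lb": float(self.lower_bounds[j]),
                "ub": float(self.upper_bounds[j]),
                "genes": list(self.gene_links.get(rid, [])),
            })
        return {"metabolites": list(self.metabolite_ids), "reactions": reactions}

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)


@dataclass(frozen=True)
class ConditionConstraints:
    """Measured exchange fluxes fixed for one experimental condition.

    ``tolerance_mode`` is ``"exact"`` (bounds pinned to the measured value)
    or ``"band"`` (relative band of half-width ``tolerance * |v_exp|``).
    """

    condition_name: str
    fixed_fluxes: dict[str, float]
    tolerance_mode: str = "exact"
    tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.tolerance_mode not in ("exact", "band"):
            raise ValueError(f"unknown tolerance_mode {self.tolerance_mode!r}")
        if self.tolerance < 0:
            raise ValueError("tolerance fraction must be >= 0")


@dataclass(frozen=True)
class ExpressionScores:
    """Signed gene-expression change Z-scores for one condition comparison."""

    comparison_name: str
    z_by_gene: dict[str, float]

    def __post_init__(self) -> None:
        bad = [g for g, z in self.z_by_gene.items() if not np.isfinite(z)]
        if bad:
            raise ValueError(f"non-finite expression Z for genes: {bad[:5]}")


def apply_condition(model: MetabolicModel, cond: ConditionConstraints) -> MetabolicModel:
    """Pin measured fluxes into a copy of the model's bounds.

    Exact mode sets ``lb = ub = v_exp``; band mode sets
    ``[v(1-eps), v(1+eps)]`` with endpoints ordered.  A measured value
    outside the original bounds triggers an infeasibility warning but is
    still applied (the downstream LP reports the infeasibility).
    """
    out = model.copy()
    for rxn, value in cond.fixed_fluxes.items():
        j = out.reaction_index(rxn)
        if not (model.lower_bounds[j] - 1e-9 <= value <= model.upper_bounds[j] + 1e-9):
            warnings.warn(
                f"measured flux {value} for {rxn} lies outside model bounds "
                f"[{model.lower_bounds[j]}, {model.upper_bounds[j]}]; "
                "constraint applied, LP may be infeasible",
                stacklevel=2,
            )
        if cond.tolerance_mode == "exact":
            lo = hi = value
        else:
            a = value * (1.0 - cond.tolerance)
            b = value * (1.0 + cond.tolerance)
            lo, hi = min(a, b), max(a, b)
        out.lower_bounds[j] = lo
        out.upper_bounds[j] = hi
    return out


# ---------------------------------------------------------------------------
# readers


def load_model(path, format: str) -> MetabolicModel:
    """Read a model from SBML, the JSON dialect, or the sectioned TSV dialect.

    Reactions lacking bounds get ``(-default_bound, default_bound)`` if
    reversible and ``(0, default_bound)`` if flagged irreversible.
    """
    if format == "sbml":
        return _load_sbml(path)
    if format == "json":
        return _load_json(path)
    if format == "tsv":
        return _load_tsv(path)
    raise ValueError(f"unknown model format {format!r}")


def _finish(metabolites, reactions, stoich, bounds, genes, reversible) -> MetabolicModel:
    met_index = {m: i for i, m in enumerate(metabolites)}
    rows, cols, data = [], [], []
    for j, rid in enumerate(reactions):
        for met, coeff in stoich[rid].items():
            if met not in met_index:
                raise ModelParseError(
                    f"reaction {rid} references undeclared metabolite {met}"
                )
            rows.append(met_index[met])
            cols.append(j)
            data.append(float(coeff))
    S = sp.csr_matrix((data, (rows, cols)),
                      shape=(len(metabolites), len(reactions)))
    lb = np.empty(len(reactions))
    ub = np.empty(len(reactions))
    for j, rid in enumerate(reactions):
        if rid in bounds:
            lb[j], ub[j] = bounds[rid]
        else:
            lb[j] = 0.0 if not reversible.get(rid, True) else -DEFAULT_BOUND
            ub[j] = DEFAULT_BOUND
    return MetabolicModel(
        metabolite_ids=list(metabolites),
        reaction_ids=list(reactions),
        S=S,
        lower_bounds=lb,
        upper_bounds=ub,
        gene_links={r: g for r, g in genes.items() if g},
    )


def _load_json(path) -> MetabolicModel:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        metabolites = list(doc["metabolites"])
        rx = doc["reactions"]
    except (KeyError, TypeError) as exc:
        raise ModelParseError(f"missing top-level key: {exc}") from None
    reactions, stoich, bounds, genes, reversible = [], {}, {}, {}, {}
    for rec in rx:
        try:
            rid = rec["id"]
            stoich[rid] = dict(rec["stoich"])
        except (KeyError, TypeError):
            raise ModelParseError(f"malformed reaction record: {rec!r}") from None
        reactions.append(rid)
        if "lb" in rec and "ub" in rec:
            bounds[rid] = (float(rec["lb"]), float(rec["ub"]))
        reversible[rid] = bool(rec.get("reversible", True))
        genes[rid] = list(rec.get("genes", []))
    if len(set(reactions)) != len(reactions):
        raise ModelValidationError("duplicate reaction ids in JSON model")
    return _finish(metabolites, reactions, stoich, bounds, genes, reversible)


def _load_tsv(path) -> MetabolicModel:
    """Sectioned long-format TSV.

    Rows (tab-separated):
      ``stoich  <reaction>  <metabolite>  <coefficient>``
      ``bounds  <reaction>  <lb>  <ub>``
      ``gene    <reaction>  <gene>``
      ``metabolite  <id>`` (optional explicit declaration)
    Metabolites may also be declared implicitly by stoich rows only when no
    explicit declarations are present.
    """
    metabolites: list[str] = []
    declared = False
    reactions: list[str] = []
    stoich: dict[str, dict[str, float]] = {}
    bounds: dict[str, tuple[float, float]] = {}
    genes: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            kind = parts[0]
            try:
                if kind == "metabolite":
                    declared = True
                    metabolites.append(parts[1])
                elif kind == "stoich":
                    rid, met, coeff = parts[1], parts[2], float(parts[3])
                    if rid not in stoich:
                        stoich[rid] = {}
                        reactions.append(rid)
                    stoich[rid][met] = coeff
                    if not declared and met not in metabolites:
                        metabolites.append(met)
                elif kind == "bounds":
                    bounds[parts[1]] = (float(parts[2]), float(parts[3]))
                elif kind == "gene":
                    genes.setdefault(parts[1], []).append(parts[2])
                else:
                    raise ModelParseError(
                        f"{path}:{lineno}: unknown record type {kind!r}"
                    )
            except (IndexError, ValueError) as exc:
                if isinstance(exc, ModelParseError):
                    raise
                raise ModelParseError(f"{path}:{lineno}: malformed record {line!r}") from None
    if declared:
        for rid, st in stoich.items():
            for met in st:
                if met not in metabolites:
                    raise ModelParseError(
                        f"reaction {rid} references undeclared metabolite {met}"
                    )
    return _finish(metabolites, reactions, stoich, bounds, genes, {})


def _load_sbml(path) -> MetabolicModel:
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    metabolites = [m.id for m in cm.metabolites]
    reactions = [r.id for r in cm.reactions]
    met_index = {m: i for i, m in enumerate(metabolites)}
    rows, cols, data = [], [], []
    lb = np.empty(len(reactions))
    ub = np.empty(len(reactions))
    genes: dict[str, list[str]] = {}
    for j, r in enumerate(cm.reactions):
        for met, coeff in r.metabolites.items():
            rows.append(met_index[met.id])
            cols.append(j)
            data.append(float(coeff))
        lb[j], ub[j] = float(r.lower_bound), float(r.upper_bound)
        if r.genes:
            genes[r.id] = sorted(g.id for g in r.genes)
    S = sp.csr_matrix((data, (rows, cols)), shape=(len(metabolites), len(reactions)))
    return MetabolicModel(metabolites, reactions, S, lb, ub, gene_links=genes)


def load_json_dict(doc: dict) -> MetabolicModel:
    """Build a model from an in-memory JSON-dialect dict (round-trip helper)."""
    metabolites = list(doc["metabolites"])
    reactions, stoich, bounds, genes, reversible = [], {}, {}, {}, {}
    for rec in doc["reactions"]:
        rid = rec["id"]
        reactions.append(rid)
        stoich[rid] = dict(rec["stoich"])
        if "lb" in rec and "ub" in rec:
            bounds[rid] = (float(rec["lb"]), float(rec["ub"]))
        reversible[rid] = bool(rec.get("reversible", True))
        genes[rid] = list(rec.get("genes", []))
    return _finish(metabolites, reactions, stoich, bounds, genes, reversible)


def read_measured_fluxes(path) -> dict[str, ConditionConstraints]:
    """Read a measured-flux TSV (columns: condition, reaction_id, value)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    need = {"condition", "reaction_id", "value"}
    if not need.issubset(df.columns):
        raise ModelParseError(f"measured-flux TSV must have columns {sorted(need)}")
    out = {}
    for cond, grp in df.groupby("condition", sort=False):
        out[str(cond)] = ConditionConstraints(
            condition_name=str(cond),
            fixed_fluxes=dict(zip(grp["reaction_id"], grp["value"].astype(float))),
        )
    return out


def read_expression_scores(path) -> dict[str, ExpressionScores]:
    """Read an expression TSV (columns: comparison, gene_id, z)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    need = {"comparison", "gene_id", "z"}
    if not need.issubset(df.columns):
        raise ModelParseError(f"expression TSV must have columns {sorted(need)}")
    out = {}
    for comp, grp in df.groupby("comparison", sort=False):
        out[str(comp)] = ExpressionScores(
            comparison_name=str(comp),
            z_by_gene=dict(zip(grp["gene_id"], grp["z"].astype(float))),
        )
    return out
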