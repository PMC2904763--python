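"""Flux-change Z-scores and the transcriptional / post-transcriptional /
metabolic regulation classifier.

For a reaction sampled under two conditions A and B the flux-change score is

    Z = (mean_A - mean_B) / sqrt(var_A + var_B)

(the variance of a difference of independent estimates is the sum of the
variances).  An expression Z-score for the enzyme's gene, oriented the same
way (positive = higher in A), is combined with Z into probabilities of
change via the two-sided Gaussian tail p(z) = erf(|z| / sqrt(2)):

    p_tr  = p_same * p(Z_flux)          transcriptional regulation
    p_ptr = p(Z_expr) * (1 - p(Z_flux)) post-transcriptional regulation
    p_mr  = p(Z_flux) * (1 - p_same)    metabolic regulation

where p_same = p(Z_expr) when expression and flux magnitude move in the
same direction and the flux does not invert its sign between conditions,
and 0 otherwise: a flux change opposed to (or independent of) the
expression change cannot be transcriptionally driven, so its probability
mass falls to the metabolic class.  A label is assigned when the winning
probability exceeds the cutoff (default 0.95).

The decision grid this yields, at saturating |Z|:

    Exp \\ Flux |  +   |  -   |  =
    -----------+------+------+-----
        +      |  TR  |  MR  |  PR
        -      |  MR  |  TR  |  PR
        =      |  MR  |  MR  | none

"Direction" of a flux change is the change in flux magnitude: a negative
flux becoming more negative counts as an increase, via absolute values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

Z_CAP = 38.0  # erf saturates to 1.0 in double precision well before this


@dataclass
class FluxChangeScore:
    reaction_id: str
    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    z_flux: float
    direction_inverted: bool = False
    capped: bool = False

    @property
    def magnitude_effect(self) -> float:
        """Sign of the flux-magnitude change, oriented A minus B."""
        d = abs(self.mean_a) - abs(self.mean_b)
        return float(np.sign(d))


@dataclass
class RegulationScores:
    gene_id: str
    reaction_id: str
    z_expr: float
    z_flux: float
    p_tr: float
    p_ptr: float
    p_mr: float
    label: str           # TR | PR | MR | none
    threshold: float
    flags: str = ""


def deviation_z(measured: float, mean: float, variance: float) -> float:
    """Number of standard deviations separating a measured flux from the
    sampled mean: |measured - mean| / sqrt(variance)."""
    if variance <= 0:
        raise ValueError("variance must be positive")
    return abs(measured - mean) / math.sqrt(variance)


def prob_change(z: float) -> float:
    """Two-sided probability that a change of |z| standard deviations is
    real: erf(|z|/sqrt(2)) = 2*Phi(|z|) - 1.  p(0) = 0, p(inf) = 1."""
    return math.erf(min(abs(z), Z_CAP) / math.sqrt(2.0))


def required_sample_size(max_error: float = 0.15, confidence: float = 0.999) -> int:
    """Smallest n such that a Z estimate with sd 1/sqrt(n) stays within
    ``max_error`` of the truth with the given probability."""
    from scipy.stats import norm

    if not (0 < confidence < 1):
        raise ValueError("confidence must be in (0, 1)")
    if max_error <= 0:
        raise ValueError("max_error must be positive")
    q = norm.ppf((1.0 + confidence) / 2.0)
    return max(1, math.ceil((q / max_error) ** 2))


def _noise_floor(mean: float, var: float) -> bool:
    """Is the mean distinguishable from zero given the sampling spread?"""
    return abs(mean) > 2.0 * math.sqrt(max(var, 0.0)) + 1e-9


def flux_change_z(summary_a: pd.DataFrame, summary_b: pd.DataFrame) -> list[FluxChangeScore]:
    """Per-reaction flux-change Z-scores between two sampling summaries.

    Summaries are DataFrames indexed by reaction id with columns ``mean``
    and ``variance`` (as produced by ``sampling.summarize``).  Degenerate
    zero-variance reactions get z = 0 when the means agree and a capped
    sentinel (+/-38, flagged) otherwise.
    """
    if set(summary_a.index) != set(summary_b.index):
        raise ValueError("summaries cover different reaction sets")
    scores = []
    for rxn in summary_a.index:
        ma, va = float(summary_a.at[rxn, "mean"]), float(summary_a.at[rxn, "variance"])
        mb, vb = float(summary_b.at[rxn, "mean"]), float(summary_b.at[rxn, "variance"])
        denom = va + vb
        capped = False
        if denom > 0:
            z = (ma - mb) / math.sqrt(denom)
            if abs(z) > Z_CAP:
                z = math.copysign(Z_CAP, z)
                capped = True
        elif math.isclose(ma, mb, rel_tol=0.0, abs_tol=1e-12):
            z = 0.0
        else:
            z = math.copysign(Z_CAP, ma - mb)
            capped = True
        inverted = (
            _noise_floor(ma, va) and _noise_floor(mb, vb)
            and np.sign(ma) != np.sign(mb)
        )
        scores.append(FluxChangeScore(rxn, ma, mb, va, vb, z,
                                      direction_inverted=inverted, capped=capped))
    return scores


def classify_regulation(z_expr: float, flux: FluxChangeScore,
                        threshold: float = 0.95, gene_id: str = "") -> RegulationScores:
    """Assign TR / PR / MR / none to one (gene, reaction) pair.

    The transcriptional probability is zeroed when expression and flux
    magnitude move in opposite directions, or when the flux reverses sign
    between conditions (such changes must be metabolically driven).
    """
    p_e = prob_change(z_expr)
    p_f = prob_change(flux.z_flux)
    same_direction = (
        not flux.direction_inverted
        and np.sign(z_expr) * flux.magnitude_effect > 0
    )
    p_same = p_e if same_direction else 0.0
    p_tr = p_same * p_f
    p_ptr = p_e * (1.0 - p_f)
    p_mr = p_f * (1.0 - p_same)
    probs = {"TR": p_tr, "PR": p_ptr, "MR": p_mr}
    label = max(probs, key=probs.get)
    if probs[label] <= threshold:
        label = "none"
    flags = []
    if flux.direction_inverted:
        flags.append("inverted")
    if flux.capped:
        flags.append("z_capped")
    return RegulationScores(
        gene_id=gene_id,
        reaction_id=flux.reaction_id,
        z_expr=z_expr,
        z_flux=flux.z_flux,
        p_tr=p_tr,
        p_ptr=p_ptr,
        p_mr=p_mr,
        label=label,
        threshold=threshold,
        flags=",".join(flags),
    )


def classify_table(flux_scores: list[FluxChangeScore], z_by_gene: dict[str, float],
                   gene_links: dict[str, list[str]],
                   threshold: float = 0.95) -> pd.DataFrame:
    """Score every (gene, reaction) pair with both a flux and expression Z.

    A reaction with k isoenzymes yields k rows.  Genes in the expression
    table but absent from the model (or vice versa) are silently dropped;
    callers may count them for diagnostics.
    """
    rows = []
    for fc in flux_scores:
        for gene in gene_links.get(fc.reaction_id, []):
            if gene not in z_by_gene:
                continue
            rs = classify_regulation(z_by_gene[gene], fc, threshold=threshold,
                                     gene_id=gene)
            rows.append({
                "gene_id": rs.gene_id,
                "reaction_id": rs.reaction_id,
                "z_expr": rs.z_expr,
                "z_flux": rs.z_flux,
                "p_tr": rs.p_tr,
                "p_ptr": rs.p_ptr,
                "p_mr": rs.p_mr,
                "label": rs.label,
                "flags": rs.flags,
            })
    return pd.DataFrame(
        rows, columns=["gene_id", "reaction_id", "z_expr", "z_flux",
                       "p_tr", "p_ptr", "p_mr", "label", "flags"],
    )
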