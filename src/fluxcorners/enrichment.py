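"""Transcription-factor over-representation among transcriptionally
regulated enzymes.

For each TF a 2x2 table is built over the union of the transcriptionally
(TR) and post-transcriptionally (PR) regulated gene sets:

              target   non-target
    TR genes    a          b
    PR genes    c          d

and a one-sided exact hypergeometric p-value asks whether the TF's targets
are over-represented in the TR group.  The background is deliberately
TR ∪ PR — a direct two-group comparison, not a genome-wide test.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom


@dataclass
class EnrichmentResult:
    tf_id: str
    a: int  # TF targets among TR genes
    b: int  # TR genes not targeted
    c: int  # TF targets among PR genes
    d: int  # PR genes not targeted
    p_value: float


def read_tf_map(path) -> dict[str, set[str]]:
    """Read a TF->target map from TSV (columns: tf_id, gene_id)."""
    df = pd.read_csv(path, sep="\t")
    if not {"tf_id", "gene_id"}.issubset(df.columns):
        raise ValueError("TF map TSV must have columns tf_id, gene_id")
    out: dict[str, set[str]] = {}
    for tf, grp in df.groupby("tf_id", sort=False):
        out[str(tf)] = set(grp["gene_id"].astype(str))
    return out


def tf_enrichment(tr_genes: set[str], pr_genes: set[str],
                  tfmap: dict[str, set[str]],
                  bh_correct: bool = False) -> list[EnrichmentResult]:
    """One-sided over-representation test per TF, sorted by p-value.

    TFs with no target in TR ∪ PR are skipped.  With ``bh_correct`` a
    Benjamini-Hochberg ``q_value`` attribute is attached to each result.
    """
    tr_genes, pr_genes = set(tr_genes), set(pr_genes)
    if not tr_genes or not pr_genes:
        raise ValueError("TR and PR gene sets must both be nonempty")
    if tr_genes & pr_genes:
        raise ValueError("TR and PR gene sets must be disjoint")
    n_tr, n_pr = len(tr_genes), len(pr_genes)
    N = n_tr + n_pr
    results = []
    for tf, targets in tfmap.items():
        a = len(targets & tr_genes)
        c = len(targets & pr_genes)
        if a + c == 0:
            continue  # no signal possible for this TF
        # P(X >= a) with X ~ Hypergeom(N, K = a + c targets, n = n_tr draws)
        p = float(hypergeom.sf(a - 1, N, a + c, n_tr))
        results.append(EnrichmentResult(tf, a, n_tr - a, c, n_pr - c, min(p, 1.0)))
    results.sort(key=lambda r: (r.p_value, r.tf_id))
    if bh_correct and results:
        from statsmodels.stats.multitest import multipletests

        _, q, *_ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, qv in zip(results, q):
            r.q_value = float(qv)  # type: ignore[attr-defined]
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"tf_id": r.tf_id, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
               "p_value": r.p_value}
        if hasattr(r, "q_value"):
            row["q_value"] = r.q_value  # type: ignore[attr-defined]
        rows.append(row)
    return pd.DataFrame(rows)
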