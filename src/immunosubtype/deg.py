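"""Two-group differential expression and Robust Rank Aggregation (RRA).

The DE engine is a Welch t-test on log-normalized expression with
Benjamini-Hochberg adjustment: the pipeline only needs per-cohort gene
rankings, and the cohorts it targets ship normalized rather than raw
counts, so a negative-binomial count model is deliberately not used.

RRA scores how consistently a gene ranks near the top across cohorts.
For a gene with normalized ranks r_(1) <= ... <= r_(k) over k lists, the
j-th beta score is P(Binomial(k, r_(j)) >= j) — the probability that at
least j of k uniform ranks fall at or below r_(j) — rho is the minimum
beta score and the reported score is the Bonferroni correction min(1, k*rho).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

__all__ = [
    "differential_expression",
    "bh_adjust",
    "rra_score",
    "robust_deg_pipeline",
]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(expr: ExpressionMatrix,
                            groups: pd.Series) -> pd.DataFrame:
    """Welch DE between two groups on the lognorm layer.

    ``groups`` maps sample -> group label (exactly two labels, each with at
    least 2 samples).  log2fc is group1 mean minus group2 mean where group1
    is the first label in sorted order; genes with zero variance in both
    groups get log2fc 0 and p 1.  Returns a gene-indexed frame with columns
    ``log2fc``, ``p``, ``padj``.
    """
    if expr.layer != "lognorm":
        raise ValueError("differential_expression expects the lognorm layer")
    groups = groups.reindex(expr.values.columns).dropna()
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    idx1 = groups.index[groups == labels[0]]
    idx2 = groups.index[groups == labels[1]]
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError("each group needs at least 2 samples")
    X1 = expr.values[idx1].to_numpy()
    X2 = expr.values[idx2].to_numpy()
    log2fc = X1.mean(axis=1) - X2.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(X1, X2, axis=1, equal_var=False)
    flat = (X1.var(axis=1) == 0) & (X2.var(axis=1) == 0)
    p = np.where(flat, 1.0, p)
    log2fc = np.where(flat, 0.0, log2fc)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame({
        "log2fc": log2fc,
        "p": p,
        "padj": bh_adjust(p),
    }, index=expr.values.index)


def rra_score(rank_lists: List[pd.Series]) -> pd.DataFrame:
    """Robust Rank Aggregation over per-cohort gene rankings.

    Each element of ``rank_lists`` maps gene -> integer rank (1 = best) in
    a shared universe of size N = the union of all genes.  A gene absent
    from a list gets the worst normalized rank 1.  Returns a gene-indexed
    frame with columns ``rho`` and ``score``.
    """
    if not rank_lists:
        raise ValueError("need at least one rank list")
    universe = sorted(set().union(*[set(s.index) for s in rank_lists]))
    N = len(universe)
    k = len(rank_lists)
    R = np.ones((N, k))
    for j, s in enumerate(rank_lists):
        if (s.to_numpy() > N).any() or (s.to_numpy() < 1).any():
            raise ValueError(f"list {j}: ranks must lie in [1, {N}]")
        r = s.reindex(universe)
        R[:, j] = np.where(np.isnan(r.to_numpy()), 1.0, r.to_numpy() / N)
    R.sort(axis=1)  # ascending normalized ranks per gene
    j_idx = np.arange(1, k + 1)
    # beta score: P(Binomial(k, r_(j)) >= j)
    beta = stats.binom.sf(j_idx - 1, k, R)
    rho = beta.min(axis=1)
    score = np.minimum(1.0, k * rho)
    return pd.DataFrame({"rho": rho, "score": score}, index=universe)


def _signed_rankings(de: pd.DataFrame) -> Dict[str, pd.Series]:
    """Up- and down-regulation rankings from one cohort's DE table.

    Genes are ordered by a signed evidence score, log2fc-signed -log10(p):
    the up list ranks strong up-regulation first, the down list strong
    down-regulation first.  Both rankings cover the full tested universe.
    """
    with np.errstate(divide="ignore"):
        evidence = np.sign(de["log2fc"].to_numpy()) * -np.log10(
            np.clip(de["p"].to_numpy(), 1e-300, None))
    s = pd.Series(evidence, index=de.index)
    up = s.rank(ascending=False, method="first").astype(int)
    down = s.rank(ascending=True, method="first").astype(int)
    return {"up": up, "down": down}


def robust_deg_pipeline(de_results: List[pd.DataFrame],
                        score_cutoff: float = 0.05) -> pd.DataFrame:
    """Aggregate per-cohort DE tables into a robust DEG list.

    Up- and down-regulated rankings are aggregated in two separate RRA
    runs; the result is the union of genes scoring below ``score_cutoff``
    in either direction, annotated with direction and score.
    """
    if not de_results:
        raise ValueError("need at least one DE result")
    universes = [set(de.index) for de in de_results]
    if len(de_results) > 1 and not set.intersection(*universes):
        raise ValueError("cohorts have disjoint gene universes")
    up_lists = [_signed_rankings(de)["up"] for de in de_results]
    down_lists = [_signed_rankings(de)["down"] for de in de_results]
    up = rra_score(up_lists)
    down = rra_score(down_lists)
    rows = []
    for direction, table in (("up", up), ("down", down)):
        hits = table[table["score"] < score_cutoff]
        for gene, row in hits.iterrows():
            rows.append({"gene": gene, "direction": direction,
                         "rho": row["rho"], "score": row["score"]})
    out = pd.DataFrame(rows, columns=["gene", "direction", "rho", "score"])
    return out.sort_values("score", kind="stable").reset_index(drop=True)
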