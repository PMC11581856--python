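"""Per-sample immune/stromal enrichment, cell-type abundances, TIS, quartiles.

Immune and stromal scores are single-sample gene-set enrichment (ssGSEA)
scores: rank-based running sums contrasting the weighted in-set ECDF with
the out-of-set ECDF.  Because they are rank statistics they are invariant
under any strictly increasing per-sample transform and are comparable only
within a cohort (no affine recalibration to other tools' score scales is
attempted).  Cell-type abundances come from nonnegative least squares
against a signature matrix; the T cell infiltration score (TIS) is the sum
of six T-cell subset abundances.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import rankdata

from .io import ExpressionMatrix

__all__ = [
    "ssgsea_score",
    "immune_stromal_scores",
    "nnls_abundances",
    "tis",
    "quartile_groups",
    "TIS_CELLTYPES",
]

#: the six T-cell subsets whose absolute abundances sum to the TIS
TIS_CELLTYPES = (
    "CD8_T",
    "CD4_naive_T",
    "CD4_memory_T",
    "T_follicular_helper",
    "regulatory_T",
    "gamma_delta_T",
)


def ssgsea_score(expr: ExpressionMatrix, gene_set: Sequence[str],
                 alpha: float = 0.25) -> pd.Series:
    """Single-sample enrichment score of ``gene_set`` for every sample.

    Per sample: genes are ranked by expression in decreasing order (average
    ranks on ties, so the statistic depends on the data only through ranks);
    walking down the ranking, the score accumulates the difference between
    the in-set ECDF weighted by ``rank_value**alpha`` and the unweighted
    out-of-set ECDF.
    """
    genes = expr.values.index
    in_mask = genes.isin(set(gene_set))
    n_in = int(in_mask.sum())
    if n_in == 0:
        raise ValueError("gene set shares no genes with the expression matrix")
    if n_in < 2:
        raise ValueError("need at least 2 gene-set genes present in the matrix")
    if n_in == len(genes):
        raise ValueError("gene set covers every gene; out-of-set ECDF is empty")

    vals = expr.values.to_numpy()
    n_genes, n_samples = vals.shape
    scores = np.empty(n_samples)
    for j in range(n_samples):
        # rank value: largest expression gets rank n_genes (ascending ranks)
        r = rankdata(vals[:, j], method="average")
        order = np.argsort(-r, kind="stable")  # decreasing expression
        hit = in_mask[order]
        w = r[order] ** alpha
        hit_w = np.where(hit, w, 0.0)
        p_in = np.cumsum(hit_w) / hit_w.sum()
        p_out = np.cumsum(~hit) / (n_genes - n_in)
        scores[j] = float(np.sum(p_in - p_out))
    return pd.Series(scores, index=expr.values.columns)


def immune_stromal_scores(expr: ExpressionMatrix, immune_set: Sequence[str],
                          stromal_set: Sequence[str],
                          alpha: float = 0.25) -> pd.DataFrame:
    """Immune and stromal ssGSEA scores per sample (columns
    ``immune_score``, ``stromal_score``)."""
    return pd.DataFrame({
        "immune_score": ssgsea_score(expr, immune_set, alpha=alpha),
        "stromal_score": ssgsea_score(expr, stromal_set, alpha=alpha),
    })


def nnls_abundances(expr: ExpressionMatrix, signature_matrix: pd.DataFrame,
                    normalize: bool = False) -> pd.DataFrame:
    """Cell-type abundances per sample by nonnegative least squares.

    ``signature_matrix`` is celltype x gene mean profiles.  Per sample f
    solves min ||expr_sig - W^T f||^2 subject to f >= 0 over the signature
    genes present in the matrix.  With ``normalize=True`` each sample's
    abundances are rescaled to sum to 1 (fractions).
    """
    if signature_matrix.shape[0] < 2:
        raise ValueError("need at least 2 cell types in the signature matrix")
    if (expr.values.to_numpy() < 0).any() or (signature_matrix.to_numpy() < 0).any():
        raise ValueError("negative inputs are not allowed")
    shared = [g for g in signature_matrix.columns if g in expr.values.index]
    if not shared:
        raise ValueError("no signature genes present in the expression matrix")
    W = signature_matrix[shared].to_numpy(dtype=float)  # types x genes
    if np.linalg.matrix_rank(W) < W.shape[0]:
        warnings.warn("signature matrix is rank-deficient; fractions not unique")
    A = W.T  # genes x types
    X = expr.values.loc[shared].to_numpy(dtype=float)
    out = np.empty((expr.n_samples, W.shape[0]))
    for j in range(expr.n_samples):
        out[j], _ = nnls(A, X[:, j])
    if normalize:
        sums = out.sum(axis=1, keepdims=True)
        out = np.divide(out, sums, out=np.zeros_like(out), where=sums > 0)
    return pd.DataFrame(out, index=expr.values.columns,
                        columns=list(signature_matrix.index))


def tis(abundances: pd.DataFrame,
        celltypes: Sequence[str] = TIS_CELLTYPES) -> pd.Series:
    """T cell infiltration score: the sum of the six T-subset abundances."""
    missing = [c for c in celltypes if c not in abundances.columns]
    if missing:
        raise ValueError(f"abundance table is missing columns: {missing}")
    return abundances[list(celltypes)].sum(axis=1).rename("tis")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def quartile_groups(scores: pd.Series, q: float = 0.25) -> pd.Series:
    """Label the top-k samples 'high', bottom-k 'low', rest 'middle'.

    ``k = round_half_up(q * n)``: 43 per group for a 173-sample cohort and
    64 for a 255-sample cohort.  Ties are broken by stable input order.
    """
    if not 0 < q <= 0.5:
        raise ValueError("q must lie in (0, 0.5]")
    n = len(scores)
    if n < 4:
        raise ValueError("need at least 4 samples to form quartile groups")
    k = _round_half_up(q * n)
    order = np.argsort(-scores.to_numpy(), kind="stable")
    labels = np.array(["middle"] * n, dtype=object)
    labels[order[:k]] = "high"
    labels[order[n - k:]] = "low"
    return pd.Series(labels, index=scores.index, name="quartile_group")
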