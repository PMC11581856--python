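"""Single-cell to bulk phenotype association and sample labeling.

Cells are associated with a binary bulk phenotype (the G1/G2 subgroup) by
a sparse logistic regression of the phenotype on the sample x cell
correlation matrix: cells with positive coefficients are Scissor+
(phenotype-1 / G1-associated), negative are Scissor-, and unselected cells
are background (BC).  Samples are then labeled G1- or G2-featured from
their Scissor+/- cell composition using two criteria: labeled cells must
exceed 20% of the sample's cells, and the Scissor+/Scissor- fold change
must exceed 1.5 (|log2 FC| > 0.59).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .io import ExpressionMatrix
from .synthetic import SingleCellCohort

__all__ = [
    "preprocess_sc",
    "cell_bulk_correlation",
    "scissor_select",
    "label_samples",
    "composition_tables",
]


def preprocess_sc(sc: SingleCellCohort, min_cells: int = 3,
                  max_pct_mito: float = 5.0,
                  max_features: int = 3000) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Quality-filter and log-normalize a single-cell cohort.

    Genes detected in fewer than ``min_cells`` cells are dropped; cells
    with ``percent_mito >= max_pct_mito`` (strict < survives) or with a
    detected-gene count ``>= max_features`` are dropped.  Survivors are
    log-normalized to log2(counts per 10k + 1).  Returns (lognorm matrix,
    filtered cell metadata).
    """
    counts = sc.counts
    meta = sc.cell_meta
    keep_cells = meta.index[
        (meta["percent_mito"] < max_pct_mito)
        & ((counts.loc[:, meta.index] > 0).sum(axis=0) < max_features)
    ]
    counts = counts[keep_cells]
    detected_in = (counts > 0).sum(axis=1)
    counts = counts.loc[detected_in >= min_cells]
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("no genes or cells survive single-cell QC")
    libsize = counts.sum(axis=0)
    nonzero = libsize > 0
    counts = counts.loc[:, nonzero]
    lognorm = np.log2(counts.div(counts.sum(axis=0), axis=1) * 1e4 + 1.0)
    return lognorm, meta.loc[lognorm.columns]


def cell_bulk_correlation(sc_expr: pd.DataFrame,
                          bulk_expr: pd.DataFrame,
                          min_shared_genes: int = 100) -> pd.DataFrame:
    """Pearson correlation of every bulk sample with every cell.

    Both inputs are log-normalized genes x columns matrices; correlations
    run over the shared gene namespace.  Constant cells or samples are
    excluded with a warning.  Returns sample x cell correlations.
    """
    shared = sc_expr.index.intersection(bulk_expr.index)
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} shared genes; need >= {min_shared_genes}")
    A = bulk_expr.loc[shared].to_numpy(dtype=float)  # genes x samples
    B = sc_expr.loc[shared].to_numpy(dtype=float)  # genes x cells
    a_sd, b_sd = A.std(axis=0), B.std(axis=0)
    if (a_sd == 0).any():
        bad = list(bulk_expr.columns[a_sd == 0])
        warnings.warn(f"excluding constant bulk samples: {bad}")
    if (b_sd == 0).any():
        bad = list(sc_expr.columns[b_sd == 0])
        warnings.warn(f"excluding constant cells: {bad}")
    samp_keep = a_sd > 0
    cell_keep = b_sd > 0
    A = A[:, samp_keep]
    B = B[:, cell_keep]
    Ac = (A - A.mean(axis=0)) / A.std(axis=0)
    Bc = (B - B.mean(axis=0)) / B.std(axis=0)
    S = Ac.T @ Bc / len(shared)
    return pd.DataFrame(S, index=bulk_expr.columns[samp_keep],
                        columns=sc_expr.columns[cell_keep])


def scissor_select(S: pd.DataFrame, phenotype: pd.Series,
                   l1_ratio: float = 0.5,
                   lambda_grid: Optional[Sequence[float]] = None,
                   max_selected_frac: float = 0.25,
                   seed: int = 0) -> pd.Series:
    """Label cells Scissor+/Scissor-/BC by sparse logistic regression.

    The binary phenotype (one value per bulk sample) is regressed on the
    row-normalized correlation matrix ``S`` (samples x cells) with an
    elastic-net penalty.  Walking the penalty grid from weakest to
    strongest, the weakest penalty whose selected-cell fraction stays
    within ``max_selected_frac`` is used; if none qualifies, the penalty
    with the smallest selection is used with a warning.  Cells with
    positive coefficients are Scissor+ (phenotype-1-associated), negative
    Scissor-, zero BC.
    """
    phenotype = phenotype.reindex(S.index)
    values = set(phenotype.unique())
    if len(values) < 2:
        raise ValueError("phenotype is constant")
    if not values <= {0, 1}:
        raise ValueError(f"phenotype must be binary 0/1, got {sorted(values)}")
    X = S.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    X = X / np.where(norms > 0, norms, 1.0)
    y = phenotype.to_numpy(dtype=int)

    if lambda_grid is None:
        lambda_grid = np.geomspace(1e-3, 10.0, 12)
    lambda_grid = sorted(lambda_grid)  # weakest penalty first

    n_cells = X.shape[1]
    fits = []  # (n_selected, coef) per lambda
    for lam in lambda_grid:
        model = LogisticRegression(
            l1_ratio=l1_ratio, C=1.0 / (lam * len(y)),
            solver="saga", max_iter=5000, random_state=seed)
        model.fit(X, y)
        coef = model.coef_.ravel()
        fits.append((int(np.sum(coef != 0)), coef))
    nonzero = [(n, c) for n, c in fits if n > 0]
    within = [(n, c) for n, c in nonzero if n <= max_selected_frac * n_cells]
    if within:
        chosen = max(within, key=lambda nc: nc[0])[1]
    elif nonzero:
        warnings.warn("no penalty met the selected-cell cap; using the "
                      "smallest nonzero selection")
        chosen = min(nonzero, key=lambda nc: nc[0])[1]
    else:  # full shrinkage everywhere: every cell is background
        chosen = fits[0][1]

    labels = np.where(chosen > 0, "Scissor+",
                      np.where(chosen < 0, "Scissor-", "BC"))
    return pd.Series(labels, index=S.columns, name="scissor_label")


def _round_half_even(x: float, digits: int) -> float:
    from decimal import Decimal, ROUND_HALF_EVEN
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_EVEN))


def label_samples(counts: pd.DataFrame, min_labeled_frac: float = 0.20,
                  min_abs_log2fc: float = math.log2(1.5)) -> pd.DataFrame:
    """Label samples G1-/G2-featured from Scissor cell counts.

    ``counts`` is indexed by sample with columns ``total``, ``n_plus``,
    ``n_minus`` (missing counts may be NaN).  A sample is G1-featured when
    (1) labeled cells exceed ``min_labeled_frac`` of its cells, and (2)
    log2(n_plus / n_minus) exceeds ``min_abs_log2fc`` (both strict); it is
    G2-featured when (1) holds and the log fold change falls below the
    negative threshold; otherwise Neither.  A zero count on one side gives
    an infinite fold change (which passes any finite threshold); a missing
    or doubly-zero count gives a missing fold change and Neither.

    Returns a frame with ``prop_plus``, ``prop_minus``, ``log2fc`` (rounded
    half-even to 2 decimals for display parity with published tables) and
    ``label``.
    """
    rows = {}
    for sample, row in counts.iterrows():
        total = row["total"]
        if not total or total <= 0 or pd.isna(total):
            raise ValueError(f"sample {sample}: total cell count must be > 0")
        n_plus, n_minus = row["n_plus"], row["n_minus"]
        missing = pd.isna(n_plus) or pd.isna(n_minus)
        prop_plus = float(n_plus) / total if not pd.isna(n_plus) else np.nan
        prop_minus = float(n_minus) / total if not pd.isna(n_minus) else np.nan
        if missing or (n_plus == 0 and n_minus == 0):
            log2fc = np.nan
        elif n_minus == 0:
            log2fc = math.inf
        elif n_plus == 0:
            log2fc = -math.inf
        else:
            log2fc = math.log2(float(n_plus) / float(n_minus))

        label = "Neither"
        if not (missing or np.isnan(log2fc)):
            labeled_frac = (float(n_plus) + float(n_minus)) / total
            if labeled_frac > min_labeled_frac and abs(log2fc) > min_abs_log2fc:
                label = "G1-featured" if log2fc > 0 else "G2-featured"

        rows[sample] = {
            "total": int(total),
            "n_plus": np.nan if pd.isna(n_plus) else int(n_plus),
            "n_minus": np.nan if pd.isna(n_minus) else int(n_minus),
            "prop_plus": np.nan if np.isnan(prop_plus) else _round_half_even(prop_plus, 2),
            "prop_minus": np.nan if np.isnan(prop_minus) else _round_half_even(prop_minus, 2),
            "log2fc": (log2fc if not np.isfinite(log2fc)
                       else _round_half_even(log2fc, 2)) if not np.isnan(log2fc) else np.nan,
            "label": label,
        }
    return pd.DataFrame(rows).T


def composition_tables(cell_labels: pd.Series,
                       cell_meta: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Cross-tabulations of Scissor label vs malignancy and cell type.

    Returns counts and within-label proportions for both breakdowns.
    """
    meta = cell_meta.loc[cell_labels.index]
    out = {}
    for key, col in (("malignant", "malignant"), ("celltype", "celltype")):
        tab = pd.crosstab(cell_labels, meta[col])
        prop = tab.div(tab.sum(axis=1).replace(0, 1), axis=0)
        out[f"{key}_counts"] = tab
        out[f"{key}_proportions"] = prop
    return out
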