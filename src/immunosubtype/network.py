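"""Weighted co-expression network modules and key-gene selection.

An unsigned adjacency ``a_ij = |cor(x_i, x_j)|^beta`` is raised to a soft
power chosen for approximate scale-free topology, converted to topological
overlap (TOM), and cut into modules by average-linkage clustering with a
static tree cut.  Genes are then scored by gene significance (GS, the
absolute correlation with a clinical trait such as the immune score) and
module membership (MM, the correlation with their module's eigengene);
key genes are the high-GS/high-MM members of trait-correlated modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "NetworkConfig",
    "ModuleResult",
    "pick_soft_power",
    "adjacency_tom",
    "detect_modules",
    "module_eigengene",
    "gs_mm",
    "module_trait_correlation",
    "select_key_genes",
    "remove_outlier_samples",
    "scale_free_fit",
]

GREY = "grey"


@dataclass
class NetworkConfig:
    """Network construction parameters (unsigned network)."""

    power: int = 4
    min_module_size: int = 10
    cut_height: float = 0.95

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if self.min_module_size < 3:
            raise ValueError("min_module_size must be >= 3")
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must lie in (0, 1]")


@dataclass
class ModuleResult:
    """Module labels plus derived per-module and per-gene statistics."""

    labels: pd.Series  # gene -> module name; 'grey' = unassigned
    eigengenes: Optional[pd.DataFrame] = None  # module x sample
    module_trait_cor: Optional[pd.DataFrame] = None  # module -> cor, p
    gs: Optional[pd.Series] = None  # per-gene |cor(gene, trait)|
    mm: Optional[pd.Series] = None  # per-gene cor(gene, own-module eigengene)

    def modules(self) -> List[str]:
        return [m for m in self.labels.unique() if m != GREY]


def _drop_constant(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.std(axis=1)
    constant = sd[sd == 0]
    if len(constant):
        warnings.warn(f"excluding {len(constant)} constant genes")
        expr = expr.drop(index=constant.index)
    return expr


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log regression of binned degree frequency.

    Connectivities are binned into ``n_bins`` equal-width bins; the
    regression is log10(frequency) on log10(mean connectivity) over
    non-empty bins.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 3:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(k[mask].mean())
        ys.append(mask.mean())
    if len(xs) < 3:
        return 0.0
    lx, ly = np.log10(xs), np.log10(ys)
    r = stats.pearsonr(lx, ly).statistic
    return float(r ** 2)


def pick_soft_power(expr: pd.DataFrame,
                    candidate_powers: Sequence[int] = range(1, 21),
                    target_r2: float = 0.8) -> int:
    """Smallest power giving scale-free fit R^2 >= target (else argmax R^2).

    ``expr`` is genes x samples; constant genes are excluded with a warning.
    """
    expr = _drop_constant(expr)
    C = np.abs(np.corrcoef(expr.to_numpy()))
    np.fill_diagonal(C, 0.0)
    best_power, best_r2 = None, -1.0
    for beta in candidate_powers:
        A = C ** beta
        r2 = scale_free_fit(A.sum(axis=1))
        if r2 >= target_r2:
            return int(beta)
        if r2 > best_r2:
            best_power, best_r2 = int(beta), r2
    warnings.warn(f"no power reached R^2 >= {target_r2}; "
                  f"returning argmax R^2 = {best_r2:.3f} at power {best_power}")
    return best_power


def adjacency_tom(expr: pd.DataFrame, power: int = 4) -> pd.DataFrame:
    """Topological overlap matrix of the unsigned adjacency |cor|^power.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    the sum excluding u in {i, j}; diagonal set to 1.
    """
    X = expr.to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = list(expr.index[np.isnan(X).any(axis=1)])
        raise ValueError(f"NaN expression for genes: {bad[:5]}")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = list(expr.index[sd == 0])
        raise ValueError(f"constant genes produce NaN correlations: {bad[:5]}")
    A = np.abs(np.corrcoef(X)) ** power
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A  # with zero diagonal this excludes u = i and u = j terms
    kmin = np.minimum.outer(k, k)
    tom = (L + A) / (kmin + 1.0 - A)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=expr.index, columns=expr.index)


def detect_modules(tom: pd.DataFrame, config: NetworkConfig) -> ModuleResult:
    """Average-linkage clustering on 1 - TOM with a static cut.

    Clusters smaller than ``min_module_size`` are relabeled grey.  Module
    names M1, M2, ... are assigned by decreasing size (ties broken by the
    lexicographically smallest member gene), so labels do not depend on
    gene input order.
    """
    D = 1.0 - tom.to_numpy()
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=config.cut_height, criterion="distance")
    genes = list(tom.index)
    clusters: Dict[int, List[str]] = {}
    for g, c in zip(genes, raw):
        clusters.setdefault(int(c), []).append(g)
    kept = [members for members in clusters.values()
            if len(members) >= config.min_module_size]
    kept.sort(key=lambda ms: (-len(ms), min(ms)))
    labels = pd.Series(GREY, index=tom.index, name="module", dtype=object)
    for i, members in enumerate(kept):
        labels.loc[members] = f"M{i + 1}"
    if not kept:
        warnings.warn("all genes are grey (no module reached min_module_size)")
    return ModuleResult(labels=labels)


def _standardize(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.std(axis=1, ddof=0)
    return expr.sub(expr.mean(axis=1), axis=0).div(sd.where(sd > 0, 1.0), axis=0)


def module_eigengene(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component per module (module x sample).

    Expression is standardized per gene first; each eigengene's sign is
    aligned so that it correlates positively with the module's mean
    expression profile, making results reproducible across runs.  A
    one-gene module's eigengene is that gene's standardized profile.
    """
    Xs = _standardize(expr)
    out = {}
    for module in sorted(labels.unique()):
        genes = labels.index[labels == module]
        sub = Xs.loc[genes].to_numpy()
        if sub.shape[0] == 1:
            eig = sub[0]
        else:
            # samples x genes SVD: first right-singular vector of genes x samples
            U, S, Vt = np.linalg.svd(sub, full_matrices=False)
            eig = Vt[0]
        mean_profile = sub.mean(axis=0)
        if np.corrcoef(eig, mean_profile)[0, 1] < 0:
            eig = -eig
        out[module] = eig
    return pd.DataFrame(out, index=expr.columns).T


def gs_mm(expr: pd.DataFrame, eigengenes: pd.DataFrame, labels: pd.Series,
          trait: pd.Series) -> Tuple[pd.Series, pd.Series]:
    """Gene significance and module membership per gene.

    GS = |Pearson cor(gene, trait)|, MM = Pearson cor(gene, eigengene of
    the gene's own module).
    """
    trait = trait.reindex(expr.columns)
    t = trait.to_numpy(dtype=float)
    if np.std(t) == 0:
        raise ValueError("trait is constant")
    X = expr.to_numpy(dtype=float)
    tc = (t - t.mean()) / t.std()
    sd = X.std(axis=1)
    Xc = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    gs = np.abs(Xc @ tc / len(t))
    mm = np.empty(len(expr))
    E = eigengenes.to_numpy(dtype=float)
    Ec = (E - E.mean(axis=1, keepdims=True)) / E.std(axis=1, keepdims=True)
    mod_row = {m: i for i, m in enumerate(eigengenes.index)}
    for i, g in enumerate(expr.index):
        e = Ec[mod_row[labels.loc[g]]]
        mm[i] = float(Xc[i] @ e / len(t))
    return (pd.Series(gs, index=expr.index, name="gs"),
            pd.Series(mm, index=expr.index, name="mm"))


def module_trait_correlation(eigengenes: pd.DataFrame,
                             trait: pd.Series) -> pd.DataFrame:
    """Pearson correlation (and p) of each module eigengene with the trait."""
    trait = trait.reindex(eigengenes.columns)
    rows = {}
    for module in eigengenes.index:
        r, p = stats.pearsonr(eigengenes.loc[module], trait)
        rows[module] = {"cor": r, "p": p}
    return pd.DataFrame(rows).T


def select_key_genes(result: ModuleResult, module_cor_min: float = 0.6,
                     module_p_max: float = 0.001, gs_min: float = 0.2,
                     mm_min: float = 0.8) -> List[str]:
    """Key genes: high-GS, high-MM members of trait-specific modules.

    Modules with ``|cor| >= module_cor_min`` and ``p < module_p_max``
    against the trait are trait-specific; within them genes with
    ``GS >= gs_min`` and ``MM >= mm_min`` are selected.
    """
    if result.module_trait_cor is None or result.gs is None or result.mm is None:
        raise ValueError("ModuleResult lacks trait correlations or GS/MM")
    mt = result.module_trait_cor
    specific = [m for m in mt.index
                if m != GREY and abs(mt.loc[m, "cor"]) >= module_cor_min
                and mt.loc[m, "p"] < module_p_max]
    if not specific:
        warnings.warn("no trait-specific module; key-gene set is empty")
        return []
    keep = []
    for gene in result.labels.index:
        if (result.labels.loc[gene] in specific
                and result.gs.loc[gene] >= gs_min
                and result.mm.loc[gene] >= mm_min):
            keep.append(gene)
    return keep


def remove_outlier_samples(expr: pd.DataFrame, z_cut: float = -2.5) -> pd.DataFrame:
    """Drop outlier samples by standardized sample connectivity.

    A sample's connectivity is its summed correlation with all other
    samples; samples with connectivity z-score below ``z_cut`` are dropped.
    """
    C = np.corrcoef(expr.to_numpy().T)
    np.fill_diagonal(C, 0.0)
    k = C.sum(axis=1)
    z = (k - k.mean()) / k.std() if k.std() > 0 else np.zeros_like(k)
    keep = expr.columns[z >= z_cut]
    dropped = [c for c in expr.columns if c not in set(keep)]
    if dropped:
        warnings.warn(f"removed outlier samples: {dropped}")
    return expr[keep]
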