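"""Synthetic AML-like cohorts with planted immune subgroups.

The generator emulates the statistical structure the downstream analyses
assume: two latent subgroups (G1, high-infiltration / monocytic; G2,
low-infiltration / granulocytic) whose bulk expression profiles are
negative-binomial counts around cell-type mixtures, with group-dependent
mutation frequencies, group-dependent survival hazards, and ex vivo drug
AUCs correlated with the immune mixing fraction.  Everything is
deterministic given the config seed; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "SimConfig",
    "BulkCohort",
    "SingleCellCohort",
    "generate_bulk_cohort",
    "generate_sc_cohort",
    "export_gene_sets",
]

DEFAULT_CELLTYPES = ("monocyte", "granulocyte", "T_cell", "B_cell", "stromal")
#: cell types whose mixing fractions constitute the "immune" fraction of a
#: sample (drives immune scores and the drug-AUC correlation target)
DEFAULT_IMMUNE_CELLTYPES = ("monocyte", "T_cell", "B_cell")


def _default_signatures(n_genes: int, celltypes: Tuple[str, ...], seed: int,
                        n_markers: int = 100, marker_fold: float = 12.0) -> pd.DataFrame:
    """Cell-type mean-expression profiles: shared lognormal baseline plus a
    disjoint block of ``n_markers`` up-weighted marker genes per type."""
    rng = np.random.default_rng(seed + 101)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    base = rng.lognormal(mean=1.0, sigma=0.5, size=n_genes)
    profiles = np.tile(base, (len(celltypes), 1)).astype(float)
    block = min(n_markers, n_genes // len(celltypes))
    for t in range(len(celltypes)):
        lo = t * block
        profiles[t, lo:lo + block] *= marker_fold
    return pd.DataFrame(profiles, index=list(celltypes), columns=genes)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    ``nb_dispersion`` is the negative-binomial size parameter theta in the
    mean/dispersion parameterization var = mu + mu^2/theta; ``math.inf``
    gives the Poisson (zero-dispersion) limit.  ``mutation_freqs`` maps gene
    name -> (P(mutated | G1), P(mutated | G2)).  ``survival_hazard_ratio``
    is the G1-vs-G2 hazard ratio (>1 means G1 dies faster).
    ``drug_immune_corr`` maps drug name -> target Pearson correlation
    between that drug's AUC and the sample immune mixing fraction.
    """

    n_samples: int = 200
    n_genes: int = 2000
    n_celltypes: int = 5
    subgroup_fractions: Tuple[float, float] = (0.45, 0.55)
    celltypes: Tuple[str, ...] = DEFAULT_CELLTYPES
    immune_celltypes: Tuple[str, ...] = DEFAULT_IMMUNE_CELLTYPES
    malignant_celltypes: Tuple[str, ...] = ("monocyte", "granulocyte")
    signature_profiles: Optional[pd.DataFrame] = None
    mixing_priors: Dict[str, Tuple[float, ...]] = field(default_factory=lambda: {
        "G1": (12.0, 3.0, 6.0, 4.0, 2.0),
        "G2": (3.0, 14.0, 3.0, 3.0, 4.0),
    })
    nb_dispersion: float = 10.0
    libsize_range: Tuple[float, float] = (2e5, 5e5)
    mutation_freqs: Dict[str, Tuple[float, float]] = field(default_factory=lambda: {
        "FLT3": (0.38, 0.18),
        "DNMT3A": (0.34, 0.18),
        "NPM1": (0.30, 0.06),
    })
    survival_hazard_ratio: float = 2.0
    baseline_hazard: float = 0.02
    censor_max: float = 60.0
    drug_immune_corr: Dict[str, float] = field(default_factory=lambda: {
        "elesclomol": 0.5,
        "panobinostat": 0.5,
        "venetoclax": -0.5,
    })
    n_cells: int = 2000
    cells_per_type: Optional[Dict[str, int]] = None
    sc_libsize_range: Tuple[float, float] = (1000.0, 3000.0)
    n_sc_samples: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.subgroup_fractions) - 1.0) > 1e-9:
            raise ValueError("subgroup_fractions must sum to 1")
        if any(not 0 <= f <= 1 for f in self.subgroup_fractions):
            raise ValueError("subgroup_fractions must lie in [0, 1]")
        if not self.nb_dispersion > 0:
            raise ValueError("nb_dispersion must be positive")
        if len(self.celltypes) != self.n_celltypes:
            raise ValueError("celltypes length must equal n_celltypes")
        for gene, (p1, p2) in self.mutation_freqs.items():
            if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
                raise ValueError(f"mutation frequency for {gene} outside [0, 1]")
        for drug, rho in self.drug_immune_corr.items():
            if not -1 <= rho <= 1:
                raise ValueError(f"drug_immune_corr for {drug} outside [-1, 1]")
        if self.signature_profiles is None:
            self.signature_profiles = _default_signatures(
                self.n_genes, self.celltypes, self.seed)
        sig = self.signature_profiles
        if sig.shape[0] != self.n_celltypes:
            raise ValueError(
                f"signature_profiles has {sig.shape[0]} rows but n_celltypes={self.n_celltypes}")
        if (sig.to_numpy() < 0).any():
            raise ValueError("signature_profiles must be nonnegative")
        if (sig.sum(axis=1) <= 0).any():
            bad = list(sig.index[sig.sum(axis=1) <= 0])
            raise ValueError(f"zero-gene signature for cell types: {bad}")
        if self.libsize_range[0] <= 0 or self.libsize_range[1] < self.libsize_range[0]:
            raise ValueError("libsize_range must be a positive interval")
        for g, prior in self.mixing_priors.items():
            if len(prior) != self.n_celltypes:
                raise ValueError(f"mixing prior for {g} has wrong length")


@dataclass
class BulkCohort:
    """A simulated bulk cohort: counts, clinical table, drug AUCs, truth."""

    expression: ExpressionMatrix
    clinical: pd.DataFrame
    drug_auc: pd.DataFrame
    truth: pd.DataFrame  # per-sample true mixing fractions (sums to 1)

    def __post_init__(self) -> None:
        vals = self.expression.values.to_numpy()
        assert (vals >= 0).all() and np.allclose(vals, np.round(vals))
        assert (self.clinical["survival_time"] > 0).all()
        assert set(self.clinical["event"].unique()) <= {0, 1}
        assert np.allclose(self.truth.sum(axis=1), 1.0)


@dataclass
class SingleCellCohort:
    """A simulated single-cell cohort: counts and per-cell metadata."""

    counts: pd.DataFrame  # genes x cells, nonnegative integers
    cell_meta: pd.DataFrame  # celltype, malignant, sample_of_origin, percent_mito

    def __post_init__(self) -> None:
        assert (self.counts.to_numpy() >= 0).all()
        assert self.cell_meta["percent_mito"].between(0, 100).all()
        assert self.cell_meta["celltype"].notna().all()


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + mu^2/theta; Poisson when theta=inf."""
    mu = np.clip(mu, 0, None)
    if math.isinf(theta):
        return rng.poisson(mu)
    lam = rng.gamma(shape=theta, scale=np.where(mu > 0, mu / theta, 0.0))
    return rng.poisson(lam)


def _subgroup_labels(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n1 = int(round(cfg.subgroup_fractions[0] * cfg.n_samples))
    labels = np.array(["G1"] * n1 + ["G2"] * (cfg.n_samples - n1))
    rng.shuffle(labels)
    return labels


def generate_bulk_cohort(config: SimConfig) -> BulkCohort:
    """Simulate a bulk cohort with planted G1/G2 structure.

    Per-sample expected expression is ``library_size x sum_t fraction_t x
    normalized signature_t``; counts are negative-binomial around it.
    Survival is exponential (Weibull shape 1) with the configured G1-vs-G2
    hazard ratio and independent uniform censoring on (0, censor_max).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    labels = _subgroup_labels(cfg, rng)

    sig = cfg.signature_profiles.to_numpy(dtype=float)
    sig_norm = sig / sig.sum(axis=1, keepdims=True)  # each row sums to 1

    fractions = np.empty((cfg.n_samples, cfg.n_celltypes))
    for i, lab in enumerate(labels):
        fractions[i] = rng.dirichlet(cfg.mixing_priors[lab])

    libsizes = rng.uniform(*cfg.libsize_range, size=cfg.n_samples)
    mu = (fractions @ sig_norm) * libsizes[:, None]  # samples x genes
    counts = _nb_counts(rng, mu, cfg.nb_dispersion).T  # genes x samples
    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=list(cfg.signature_profiles.columns),
                     columns=samples).astype(float),
        layer="counts",
    )

    # survival: exponential with hazard baseline x HR for G1
    is_g1 = labels == "G1"
    hazard = np.where(is_g1, cfg.baseline_hazard * cfg.survival_hazard_ratio,
                      cfg.baseline_hazard)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, cfg.censor_max, size=cfg.n_samples)
    censor_time = np.maximum(censor_time, 1e-6)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    clinical = pd.DataFrame({
        "true_subgroup": labels,
        "survival_time": time,
        "event": event,
        "age": np.round(rng.normal(np.where(is_g1, 61, 54), 10.0)).clip(18, 90),
        "sex": rng.choice(["M", "F"], size=cfg.n_samples),
    }, index=samples)
    for gene, (p1, p2) in cfg.mutation_freqs.items():
        p = np.where(is_g1, p1, p2)
        clinical[f"mut_{gene}"] = (rng.uniform(size=cfg.n_samples) < p).astype(int)

    # drug AUC: affine in the immune mixing fraction, noise tuned to the
    # target correlation (corr = sign / sqrt(1 + sd^2) with sd chosen so
    # that corr = rho)
    immune_idx = [cfg.celltypes.index(t) for t in cfg.immune_celltypes]
    f_imm = fractions[:, immune_idx].sum(axis=1)
    z = (f_imm - f_imm.mean()) / f_imm.std()
    drug_cols = {}
    for drug, rho in cfg.drug_immune_corr.items():
        if rho == 0:
            drug_cols[drug] = 100 + 20 * rng.normal(size=cfg.n_samples)
            continue
        noise_sd = math.sqrt(1.0 / rho ** 2 - 1.0)
        signal = np.sign(rho) * z + noise_sd * rng.normal(size=cfg.n_samples)
        drug_cols[drug] = 100 + 20 * signal  # AUC-like scale, higher = resistant
    drug_auc = pd.DataFrame(drug_cols, index=samples)

    truth = pd.DataFrame(fractions, index=samples, columns=list(cfg.celltypes))
    return BulkCohort(expr, clinical, drug_auc, truth)


def generate_sc_cohort(config: SimConfig) -> SingleCellCohort:
    """Simulate single cells: per type, NB counts around its signature."""
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1)
    per_type = cfg.cells_per_type or {
        t: cfg.n_cells // cfg.n_celltypes +
           (1 if i < cfg.n_cells % cfg.n_celltypes else 0)
        for i, t in enumerate(cfg.celltypes)
    }
    unknown = set(per_type) - set(cfg.celltypes)
    if unknown:
        raise ValueError(f"cells_per_type names unknown cell types: {sorted(unknown)}")

    sig = cfg.signature_profiles
    sig_norm = sig.to_numpy(dtype=float)
    sig_norm = sig_norm / sig_norm.sum(axis=1, keepdims=True)

    blocks, meta_rows, cell_ids = [], [], []
    counter = 0
    for t_idx, ctype in enumerate(cfg.celltypes):
        n_c = per_type.get(ctype, 0)
        if n_c == 0:
            continue
        libs = rng.uniform(*cfg.sc_libsize_range, size=n_c)
        mu = sig_norm[t_idx][None, :] * libs[:, None]
        blocks.append(_nb_counts(rng, mu, cfg.nb_dispersion))
        for j in range(n_c):
            cell_ids.append(f"C{counter:05d}")
            meta_rows.append({
                "celltype": ctype,
                "malignant": ctype in cfg.malignant_celltypes,
                "sample_of_origin": f"SC{rng.integers(cfg.n_sc_samples):02d}",
                "percent_mito": float(rng.uniform(0.0, 8.0)),
            })
            counter += 1
    counts = pd.DataFrame(np.vstack(blocks).T, index=list(sig.columns),
                          columns=cell_ids).astype(float)
    cell_meta = pd.DataFrame(meta_rows, index=cell_ids)
    return SingleCellCohort(counts, cell_meta)


def export_gene_sets(config: SimConfig, k: int = 50) -> GeneSetCollection:
    """Gene sets derived from the generator's signatures.

    One set per cell type (its top-``k`` genes by signature weight), plus an
    ``immune`` set (union of the immune cell types' top genes) and a
    ``stromal`` set (top genes of the stromal type when present).
    """
    cfg = config
    if k > cfg.n_genes:
        raise ValueError(f"k={k} exceeds n_genes={cfg.n_genes}")
    sig = cfg.signature_profiles
    sets: Dict[str, List[str]] = {}
    for ctype in cfg.celltypes:
        top = sig.loc[ctype].sort_values(ascending=False, kind="stable").index[:k]
        sets[ctype] = list(top)
    immune = []
    for ctype in cfg.immune_celltypes:
        immune.extend(g for g in sets[ctype] if g not in immune)
    sets["immune"] = immune
    if "stromal" in cfg.celltypes:
        sets["stromal_set"] = list(sets["stromal"])
    descriptions = {name: "synthetic signature" for name in sets}
    return GeneSetCollection(sets, descriptions)
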