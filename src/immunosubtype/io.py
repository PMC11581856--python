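"""Expression-matrix containers, file formats and normalization.

The pipeline's canonical in-memory container is :class:`ExpressionMatrix`, a
genes x samples table with a layer tag saying how the values are scaled
(``counts``, ``lognorm`` or ``zscore``).  Gene and sample identifiers are
opaque strings; no symbol/Ensembl mapping is attempted.  Gene sets travel as
:class:`GeneSetCollection`, backed by the tab-separated GMT dialect
(``name<TAB>description<TAB>gene1<TAB>gene2...``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_counts",
    "write_counts",
    "parse_gmt",
    "write_gmt",
    "lognormalize",
    "expressed_gene_filter",
]

_LAYERS = ("counts", "lognorm", "zscore")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with named axes and a layer tag.

    Parameters
    ----------
    values
        DataFrame with genes as the index and samples as the columns.
    layer
        One of ``counts`` (nonnegative raw counts), ``lognorm``
        (log2(CPM+1)) or ``zscore`` (per-gene standardized).
    """

    values: pd.DataFrame
    layer: str = "counts"

    def __post_init__(self) -> None:
        if self.layer not in _LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {_LAYERS}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if self.layer == "counts" and (self.values.to_numpy() < 0).any():
            raise ValueError("counts layer contains negative values")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def library_sizes(self) -> pd.Series:
        """Per-sample total counts (counts layer only)."""
        if self.layer != "counts":
            raise ValueError("library sizes are defined for the counts layer")
        return self.values.sum(axis=0)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes], layer=self.layer)


@dataclass
class GeneSetCollection:
    """Named, non-empty gene lists with optional per-set descriptions."""

    sets: Dict[str, List[str]]
    descriptions: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> List[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> List[str]:
        return list(self.sets)


def read_counts(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read a genes x samples count matrix from TSV or MatrixMarket files.

    For ``format='mtx'`` the path is the ``.mtx`` triplet file; row (gene)
    and column (sample) names are read from sibling files with the same stem
    and suffixes ``.rownames.txt`` / ``.colnames.txt``, one id per line.
    """
    path = Path(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0,
                             float_precision="round_trip")
        except Exception as exc:  # surface the offending line from pandas
            raise ValueError(f"malformed counts TSV {path}: {exc}") from exc
        if df.empty and df.columns.empty:
            raise ValueError(f"malformed counts TSV {path}: no sample columns parsed")
    elif format == "mtx":
        mat = scipy.io.mmread(path)
        genes = _read_name_file(path.with_suffix("").with_suffix(".rownames.txt"))
        samples = _read_name_file(path.with_suffix("").with_suffix(".colnames.txt"))
        arr = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
        if arr.shape != (len(genes), len(samples)):
            raise ValueError(
                f"MTX shape {arr.shape} does not match names "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        df = pd.DataFrame(arr, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format {format!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), layer="counts")


def _read_name_file(path: Path) -> List[str]:
    if not path.exists():
        raise FileNotFoundError(f"MTX name file missing: {path}")
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def write_counts(expr: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write an expression matrix as TSV (full float precision) or MTX."""
    path = Path(path)
    if format == "tsv":
        expr.values.to_csv(path, sep="\t", float_format="%.17g")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(expr.values.to_numpy()))
        stem = path.with_suffix("")
        stem.with_suffix(".rownames.txt").write_text("\n".join(expr.gene_ids) + "\n")
        stem.with_suffix(".colnames.txt").write_text("\n".join(expr.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def parse_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name\\tdescription\\tgenes...``."""
    sets: Dict[str, List[str]] = {}
    descriptions: Dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: fewer than 3 tab-separated fields")
        name, desc, *genes = fields
        genes = [g for g in genes if g]  # drop trailing/interior empties
        if name in sets:
            raise ValueError(f"GMT line {lineno}: duplicated set name {name!r}")
        if not genes:
            raise ValueError(f"GMT line {lineno}: set {name!r} has no genes")
        sets[name] = genes
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, genes in collection.sets.items():
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def lognormalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """CPM log transform: ``log2(1e6 * count / library_size + 1)`` per sample."""
    if expr.layer != "counts":
        raise ValueError("lognormalize expects the counts layer")
    libsizes = expr.library_sizes()
    zero = libsizes[libsizes == 0]
    if len(zero):
        raise ValueError(f"zero library size for samples: {list(zero.index)}")
    cpm = expr.values.div(libsizes, axis=1) * 1e6
    return ExpressionMatrix(np.log2(cpm + 1.0), layer="lognorm")


def expressed_gene_filter(expr: ExpressionMatrix, min_fraction: float = 0.20) -> List[str]:
    """Genes with count > 0 in at least ``ceil(min_fraction * n_samples)`` samples.

    With the default 20% threshold a 173-sample cohort requires detection in
    at least 35 samples (ceil(0.2 x 173) = 35).
    """
    if expr.layer != "counts":
        raise ValueError("expressed_gene_filter expects the counts layer")
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    threshold = int(np.ceil(min_fraction * expr.n_samples))
    detected = (expr.values > 0).sum(axis=1)
    keep = list(expr.values.index[detected >= threshold])
    if not keep:
        warnings.warn("expressed_gene_filter removed every gene")
    return keep
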