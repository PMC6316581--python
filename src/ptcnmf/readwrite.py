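"""Expression-matrix and gene-set containers plus the readers/writers and
preprocessing steps used ahead of factorization.

The central container is :class:`ExpressionMatrix`, a genes x samples table of
nonnegative expression values (RSEM/FPKM-like) on linear scale, or real values
after ``log2(x + pseudocount)`` transformation. Gene sets follow the MSigDB
GMT convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LINEAR = "linear"
LOG2P1 = "log2p1"


class ExpressionFormatError(ValueError):
    """Raised when an expression file cannot be parsed."""


class ExpressionValidationError(ValueError):
    """Raised when parsed values violate matrix invariants."""


class GMTFormatError(ValueError):
    """Raised for malformed GMT gene-set files."""


class GeneAlignmentError(ValueError):
    """Raised when two gene universes share no genes."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit scale.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with sample ids as columns. Must be
        complete (no missing values); nonnegative when ``scale='linear'``.
    scale
        ``'linear'`` for raw abundance, ``'log2p1'`` after log transformation.
    """

    data: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2P1):
            raise ExpressionValidationError(f"unknown scale {self.scale!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ExpressionValidationError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            raise ExpressionValidationError("duplicate sample ids")
        if self.data.isna().any().any():
            raise ExpressionValidationError("missing values are not supported")
        if self.scale == LINEAR and (self.data.values < 0).any():
            g, s = np.argwhere(self.data.values < 0)[0]
            raise ExpressionValidationError(
                f"negative value at gene {self.data.index[g]!r}, "
                f"sample {self.data.columns[s]!r} on linear scale"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class GeneSetCollection:
    """Named gene sets (MSigDB-style), order-preserving and deduplicated."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (gene rows, sample columns).

    The first column holds gene ids, the header row sample ids. Duplicate
    gene rows are collapsed by their mean (linear scale), keeping first-seen
    order. Any non-numeric or missing cell is a parse error naming the cell.
    """
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                          keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ExpressionFormatError(f"{path}: empty expression file") from exc
    if raw.shape[1] == 0:
        raise ExpressionFormatError(f"{path}: no sample columns found")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        g, s = np.argwhere(bad.values)[0]
        cell = raw.iloc[g, s]
        raise ExpressionFormatError(
            f"{path}: non-numeric value {cell!r} at gene "
            f"{raw.index[g]!r}, sample {raw.columns[s]!r}"
        )
    if (numeric.values < 0).any():
        g, s = np.argwhere(numeric.values < 0)[0]
        raise ExpressionValidationError(
            f"{path}: negative value at gene {numeric.index[g]!r}, "
            f"sample {numeric.columns[s]!r}"
        )
    n_raw = numeric.shape[0]
    if numeric.index.has_duplicates:
        # mean-collapse duplicates in linear space, first-seen row order
        order = numeric.index.drop_duplicates()
        numeric = numeric.groupby(level=0, sort=False).mean().loc[order]
        logger.info("collapsed %d duplicate gene rows", n_raw - numeric.shape[0])
    numeric.index = numeric.index.astype(str)
    numeric.index.name = "gene_id"
    numeric.columns = numeric.columns.astype(str)
    logger.info("read %d genes x %d samples from %s", *numeric.shape, path)
    return ExpressionMatrix(numeric, scale=LINEAR)


def write_expression_tsv(E: ExpressionMatrix, path) -> None:
    """Write an expression matrix in the same dialect ``read_expression_tsv`` reads."""
    out = E.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def log_transform(E: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return ``log2(x + pseudocount)`` of a linear-scale matrix."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if E.scale != LINEAR:
        raise ExpressionValidationError("matrix is already log-scale")
    return ExpressionMatrix(np.log2(E.data + pseudocount), scale=LOG2P1)


def select_variable_genes(E: ExpressionMatrix, n: int) -> ExpressionMatrix:
    """Keep the ``n`` genes with the largest median absolute deviation.

    MAD is computed per gene across samples; ties break lexicographically on
    gene id so the selection is deterministic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > E.n_genes:
        raise IndexError(f"requested {n} genes but matrix has {E.n_genes}")
    med = E.data.median(axis=1)
    mad = (E.data.sub(med, axis=0)).abs().median(axis=1)
    order = sorted(E.gene_ids, key=lambda g: (-mad[g], g))
    chosen = set(order[:n])
    keep = [g for g in E.gene_ids if g in chosen]  # original row order
    return ExpressionMatrix(E.data.loc[keep], scale=E.scale)


@dataclass
class AlignedExpression:
    matrix: ExpressionMatrix
    dropped: list[str]


def align_genes(E: ExpressionMatrix, reference_gene_ids: list[str]) -> AlignedExpression:
    """Subset/reorder rows to the intersection with a reference gene list.

    Rows come back in reference order; genes of the reference absent from
    ``E`` are reported as dropped.
    """
    present = set(E.gene_ids)
    shared = [g for g in reference_gene_ids if g in present]
    dropped = [g for g in reference_gene_ids if g not in present]
    if not shared:
        raise GeneAlignmentError("no genes shared with the reference")
    if dropped:
        logger.warning("align_genes dropped %d/%d reference genes",
                       len(dropped), len(reference_gene_ids))
    return AlignedExpression(ExpressionMatrix(E.data.loc[shared], scale=E.scale), dropped)


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets from a GMT file (name TAB description TAB gene ...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GMTFormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            name, desc, *genes = parts
            seen: dict[str, None] = {}
            for g in genes:
                if g:
                    seen.setdefault(g)
            sets[name] = list(seen)
            descriptions[name] = desc
    logger.info("read %d gene sets from %s", len(sets), path)
    return GeneSetCollection(sets, descriptions)
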