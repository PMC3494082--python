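"""Tag-count matrices, tags-per-million normalization, and expression statistics.

Digital gene expression (tag-seq) experiments report, per library, the number
of 21-bp tags mapping to each gene.  This module holds the two core
containers — :class:`CountMatrix` (raw integer counts plus library sizes) and
:class:`TpmMatrix` (counts rescaled to tags per million) — together with the
low-expression filter and per-gene mean/SD/CV summaries used throughout the
reference-gene screens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "TpmMatrix",
    "read_counts",
    "write_counts",
    "read_tpm",
    "write_tpm",
    "normalize_tpm",
    "filter_low_expression",
    "gene_stats",
]


class CountMatrixError(ValueError):
    """Raised when a count matrix violates its invariants."""


@dataclass
class CountMatrix:
    """Raw tag counts (genes x conditions) plus per-library total tag counts.

    ``library_sizes`` is the total number of tags in each library; it may
    exceed the column sum of ``counts`` (not every sequenced tag maps to a
    gene model) but never fall below it.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise CountMatrixError(f"duplicate gene id: {dup!r}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()][0]
            raise CountMatrixError(f"duplicate condition label: {dup!r}")
        if counts.shape[1] < 2:
            raise CountMatrixError("need at least 2 conditions")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise CountMatrixError("counts must be numeric")
        if np.any(values < 0):
            g, c = np.argwhere(values < 0)[0]
            raise CountMatrixError(
                f"negative count for gene {counts.index[g]!r}, "
                f"condition {counts.columns[c]!r}"
            )
        if not np.allclose(values, np.round(values)):
            g, c = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise CountMatrixError(
                f"non-integer count for gene {counts.index[g]!r}, "
                f"condition {counts.columns[c]!r}"
            )
        self.counts = counts.astype(np.int64)
        self.counts.index.name = "gene_id"
        sizes = pd.Series(self.library_sizes, dtype=np.int64)
        sizes = sizes.reindex(counts.columns)
        if sizes.isna().any():
            missing = sizes.index[sizes.isna()][0]
            raise CountMatrixError(f"missing library size for condition {missing!r}")
        if (sizes <= 0).any():
            bad = sizes.index[sizes <= 0][0]
            raise CountMatrixError(f"non-positive library size for {bad!r}")
        colsums = self.counts.sum(axis=0)
        if (sizes < colsums).any():
            bad = sizes.index[sizes < colsums][0]
            raise CountMatrixError(
                f"library size for {bad!r} ({sizes[bad]}) is below the mapped "
                f"tag total ({colsums[bad]})"
            )
        self.library_sizes = sizes

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def condition_labels(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    def subset(self, genes: Iterable[str]) -> "CountMatrix":
        """Restrict to ``genes`` (kept in the given order)."""
        genes = list(genes)
        missing = set(genes) - set(self.counts.index)
        if missing:
            raise KeyError(f"genes absent from count matrix: {sorted(missing)[:5]}")
        return CountMatrix(self.counts.loc[genes].copy(), self.library_sizes.copy())


@dataclass
class TpmMatrix:
    """Library-size-normalized expression: tpm = count / library_size * 1e6."""

    tpm: pd.DataFrame
    library_sizes: pd.Series | None = None
    source: CountMatrix | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.tpm.index.has_duplicates or self.tpm.columns.has_duplicates:
            raise CountMatrixError("duplicate gene ids or condition labels")
        if (self.tpm.to_numpy() < 0).any():
            raise CountMatrixError("tpm values must be non-negative")
        self.tpm.index.name = "gene_id"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def condition_labels(self) -> list[str]:
        return list(self.tpm.columns)

    @property
    def n_genes(self) -> int:
        return self.tpm.shape[0]

    def subset(self, genes: Iterable[str]) -> "TpmMatrix":
        genes = list(genes)
        missing = set(genes) - set(self.tpm.index)
        if missing:
            raise KeyError(f"genes absent from tpm matrix: {sorted(missing)[:5]}")
        return TpmMatrix(self.tpm.loc[genes].copy(), self.library_sizes, self.source)


def _coerce_library_sizes(
    library_sizes: Mapping[str, int] | pd.Series | str | Path | None,
) -> pd.Series | None:
    if library_sizes is None:
        return None
    if isinstance(library_sizes, (str, Path)):
        table = pd.read_csv(library_sizes, sep="\t")
        if table.shape[1] != 2:
            raise CountMatrixError(
                "library-sizes file must have two columns (condition, total_tags)"
            )
        return pd.Series(table.iloc[:, 1].values, index=table.iloc[:, 0].values)
    return pd.Series(library_sizes)


def read_counts(
    path: str | Path,
    library_sizes: Mapping[str, int] | pd.Series | str | Path | None = None,
) -> CountMatrix:
    """Read a tab-separated count matrix (first column ``gene_id``).

    When ``library_sizes`` is omitted the per-column sums of mapped tags are
    used; pass explicit totals (mapping, Series, or sidecar TSV path) when the
    true sequenced-library sizes are known.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 3:
        raise CountMatrixError(f"{path}: need a gene_id column and >= 2 conditions")
    df = df.set_index(df.columns[0])
    for col in df.columns:
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any():
            # +2 for the header line and 1-based numbering
            line = int(np.argmax(parsed.isna().to_numpy())) + 2
            raise CountMatrixError(f"{path}: malformed count at line {line}, column {col!r}")
        df[col] = parsed
    sizes = _coerce_library_sizes(library_sizes)
    if sizes is None:
        sizes = df.sum(axis=0)
        logger.info("library sizes not supplied; defaulting to column sums")
    return CountMatrix(df, sizes)


def write_counts(
    cm: CountMatrix,
    path: str | Path,
    library_sizes_path: str | Path | None = None,
) -> None:
    """Write counts as TSV; optionally write the library-size sidecar."""
    cm.counts.to_csv(path, sep="\t")
    if library_sizes_path is not None:
        sizes = cm.library_sizes.rename("total_tags")
        sizes.index.name = "condition"
        sizes.to_csv(library_sizes_path, sep="\t")


def read_tpm(path: str | Path) -> TpmMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str}).set_index("gene_id")
    return TpmMatrix(df.astype(float))


def write_tpm(tm: TpmMatrix, path: str | Path) -> None:
    # repr-precision floats survive a read/write round trip exactly
    tm.tpm.to_csv(path, sep="\t", float_format="%.17g")


def normalize_tpm(cm: CountMatrix) -> TpmMatrix:
    """Scale each library to tags per million: count / library_size * 1e6."""
    tpm = cm.counts / cm.library_sizes * 1.0e6
    return TpmMatrix(tpm, cm.library_sizes.copy(), source=cm)


def filter_low_expression(tm: TpmMatrix, threshold: float = 2.5) -> TpmMatrix:
    """Drop genes whose tpm is below ``threshold`` in *every* condition.

    A gene at or above the threshold in at least one condition is retained,
    so retained genes may still have a mean tpm below the threshold.  Gene
    order is preserved.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = (tm.tpm >= threshold).any(axis=1)
    n_removed = int((~keep).sum())
    logger.info(
        "low-expression filter (< %.3g tpm everywhere): removed %d, retained %d",
        threshold,
        n_removed,
        int(keep.sum()),
    )
    return TpmMatrix(tm.tpm.loc[keep].copy(), tm.library_sizes, tm.source)


def gene_stats(tm: TpmMatrix, genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-gene mean, sample SD (n-1), and CV%% across conditions.

    CV is undefined for genes with zero mean (all-zero expression); those rows
    carry ``cv_percent = NaN`` and ``cv_defined = False`` rather than a silent
    zero.
    """
    df = tm.tpm if genes is None else tm.tpm.loc[list(genes)]
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mean
    cv = cv.where(mean > 0, np.nan)
    return pd.DataFrame(
        {
            "mean_tpm": mean,
            "sd_tpm": sd,
            "cv_percent": cv,
            "cv_defined": mean > 0,
        }
    )
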