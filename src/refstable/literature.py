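"""Screen literature-derived candidate reference genes by expression stability.

Candidate housekeeping genes (actin, GAPDH, tubulins, ubiquitin-conjugating
enzymes, ...) arrive as a homolog table mapping gene ids to reference-gene
families.  The screen joins each candidate with its expression statistics
(mean tpm, CV%) and summarizes each family's spread, exposing how variable
"canonical" reference genes actually are in the data at hand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import TpmMatrix, gene_stats

logger = logging.getLogger(__name__)

__all__ = ["HomologTable", "ScreenResult", "read_homolog_table", "screen_homologs"]


@dataclass
class HomologTable:
    """Rows of (gene_id, family, source); (gene_id, family) pairs unique."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "family"}
        if not required.issubset(self.table.columns):
            raise ValueError("homolog table needs 'gene_id' and 'family' columns")
        if "source" not in self.table.columns:
            self.table = self.table.assign(source="")
        dup = self.table.duplicated(subset=["gene_id", "family"])
        if dup.any():
            row = self.table[dup].iloc[0]
            raise ValueError(
                f"duplicate (gene_id, family) pair: ({row['gene_id']!r}, {row['family']!r})"
            )

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ScreenResult:
    """Per-gene and per-family stability summaries plus unmatched entries."""

    per_gene: pd.DataFrame
    per_family: pd.DataFrame
    unmatched: pd.DataFrame


def read_homolog_table(path: str | Path) -> HomologTable:
    return HomologTable(pd.read_csv(path, sep="\t", dtype=str))


def write_homolog_table(ht: HomologTable, path: str | Path) -> None:
    ht.table.to_csv(path, sep="\t", index=False)


def screen_homologs(tm: TpmMatrix, ht: HomologTable) -> ScreenResult:
    """Join homolog families with gene statistics and summarize per family.

    Genes in the table but absent from the expression matrix are reported in
    ``unmatched``, never silently dropped.  Families are sorted by the median
    member CV%% (most stable family first).
    """
    if len(ht) == 0:
        logger.warning("empty homolog table: nothing to screen")
        empty = pd.DataFrame()
        return ScreenResult(empty, empty, empty)
    present = ht.table["gene_id"].isin(tm.tpm.index)
    matched = ht.table[present].copy()
    unmatched = ht.table[~present].copy()
    if len(matched):
        stats = gene_stats(tm, matched["gene_id"].unique().tolist())
        per_gene = matched.merge(
            stats, left_on="gene_id", right_index=True, how="left"
        ).reset_index(drop=True)
        per_family = (
            per_gene.groupby("family")
            .agg(
                n_members=("gene_id", "size"),
                mean_tpm_min=("mean_tpm", "min"),
                mean_tpm_max=("mean_tpm", "max"),
                cv_min=("cv_percent", "min"),
                cv_max=("cv_percent", "max"),
                cv_median=("cv_percent", "median"),
            )
            .sort_values("cv_median", kind="stable")
            .reset_index()
        )
    else:
        per_gene = matched.assign(
            mean_tpm=np.nan, sd_tpm=np.nan, cv_percent=np.nan, cv_defined=False
        )
        per_family = pd.DataFrame(
            columns=[
                "family",
                "n_members",
                "mean_tpm_min",
                "mean_tpm_max",
                "cv_min",
                "cv_max",
                "cv_median",
            ]
        )
    return ScreenResult(per_gene, per_family, unmatched.reset_index(drop=True))
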