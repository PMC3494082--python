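"""Cross-method comparison reports: deviation profiles and Venn regions.

The three screens (literature homologs, stable k-means clusters, posterior
fold-change selection) each yield a gene set.  Two reports arbitrate among
them: the *deviation profile* — for a set, the average per-condition
departure from each gene's own mean, in tpm (identically 0 for perfectly
constitutive sets) — and the exact Venn decomposition of the sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .counts import TpmMatrix

__all__ = ["DeviationProfile", "VennSummary", "deviation_profile", "venn_compare"]


@dataclass
class DeviationProfile:
    """Mean per-condition deviation from gene means over a gene set."""

    name: str
    per_condition_mean_deviation: pd.Series  # tpm; sums to ~0 across conditions
    mean_sd: float  # mean over genes of the per-gene sample SD, tpm
    size: int

    @property
    def deviation_range(self) -> tuple[float, float]:
        return (
            float(self.per_condition_mean_deviation.min()),
            float(self.per_condition_mean_deviation.max()),
        )


@dataclass
class VennSummary:
    """Exact disjoint region decomposition of named gene sets."""

    set_names: list[str]
    regions: dict[tuple[str, ...], list[str]]  # exclusive membership -> genes

    def counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region": "&".join(names),
                "count": len(genes),
                "genes": ",".join(genes),
            }
            for names, genes in self.regions.items()
        ]
        return pd.DataFrame(rows)


def deviation_profile(tm: TpmMatrix, genes: Iterable[str], name: str) -> DeviationProfile:
    """Average change in tag count from each gene's mean expression, in tpm."""
    genes = list(genes)
    if not genes:
        raise ValueError("deviation profile undefined for an empty gene set")
    missing = set(genes) - set(tm.tpm.index)
    if missing:
        raise KeyError(f"genes absent from tpm matrix: {sorted(missing)[:5]}")
    sub = tm.tpm.loc[genes]
    deviations = sub.sub(sub.mean(axis=1), axis=0)
    return DeviationProfile(
        name=name,
        per_condition_mean_deviation=deviations.mean(axis=0),
        mean_sd=float(sub.std(axis=1, ddof=1).mean()),
        size=len(genes),
    )


def venn_compare(
    sets: Mapping[str, Iterable[str]] | Sequence[tuple[str, Iterable[str]]],
) -> VennSummary:
    """Decompose named gene sets into their 2^m - 1 exclusive Venn regions.

    Region keys are sorted tuples of the set names containing exactly those
    genes.  Empty regions are included (count 0), so counts always sum to the
    size of the union.
    """
    if not isinstance(sets, Mapping):
        names = [n for n, _ in sets]
        if len(names) != len(set(names)):
            raise ValueError("duplicate set names")
        sets = dict(sets)
    named = {name: set(members) for name, members in sets.items()}
    if len(named) < 2:
        raise ValueError("need at least 2 sets")
    names = sorted(named)
    regions: dict[tuple[str, ...], list[str]] = {}
    for r in range(len(names), 0, -1):
        for inside in combinations(names, r):
            members = set.intersection(*(named[n] for n in inside))
            for other in names:
                if other not in inside:
                    members -= named[other]
            regions[inside] = sorted(members)
    return VennSummary(names, regions)
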