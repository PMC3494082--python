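"""Synthetic tag-seq libraries with ground-truth stable/differential genes.

The generator emulates a replicate-free nutrient-limitation experiment: four
libraries (replete reference plus three limited treatments) of uneven depth,
~10^4 genes whose abundances span several orders of magnitude, most genes
stable and a minority differentially expressed at fixed fold changes.  Gene
abundances are log-normal; per-condition expected proportions are
renormalized so each library's expected mapped-tag total is
``mapped_fraction`` of its size; counts are Poisson (or negative binomial
with dispersion ``nb_dispersion``) around those means.  The paired truth
table records each gene's base proportion, per-condition log2 fold change
relative to the reference, and a stability flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .literature import HomologTable, write_homolog_table

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate",
    "simulate_pair_from_prior",
    "make_fixture",
    "PRESETS",
]

DEFAULT_CONDITIONS = ("replete", "P-limited", "Fe-limited", "Co-limited")
DEFAULT_LIBRARY_SIZES = (12_000_000, 13_000_000, 23_000_000, 26_000_000)


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic tag-seq generator."""

    n_genes: int = 10_000
    condition_labels: tuple[str, ...] = DEFAULT_CONDITIONS
    library_sizes: tuple[int, ...] = DEFAULT_LIBRARY_SIZES
    library_scale: float = 1.0  # multiply library sizes (e.g. 0.1 for desk scale)
    abundance_sigma: float = 1.5  # log-normal spread; spans ~0.1-5000 tpm
    stable_fraction: float = 0.9
    de_log2fc_choices: tuple[float, ...] = (
        -2.0,
        -1.0,
        -np.log2(1.5),
        np.log2(1.5),
        1.0,
        2.0,
    )
    noise: str = "poisson"  # or "nb"
    nb_dispersion: float = 0.1
    mapped_fraction: float = 0.95  # mapped tags / sequenced tags
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.stable_fraction <= 1.0:
            raise ValueError("stable_fraction must lie in [0, 1]")
        if len(self.condition_labels) != len(self.library_sizes):
            raise ValueError("one library size per condition required")
        if self.noise not in {"poisson", "nb"}:
            raise ValueError("noise must be 'poisson' or 'nb'")
        if not 0 < self.mapped_fraction <= 1:
            raise ValueError("mapped_fraction must lie in (0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth aligned to the simulated count matrix."""

    table: pd.DataFrame  # base_proportion, log2fc_<condition>..., is_stable
    reference_condition: str

    @property
    def is_stable(self) -> pd.Series:
        return self.table["is_stable"]

    def log2fc(self, condition: str) -> pd.Series:
        return self.table[f"log2fc_{condition}"]


def simulate(
    config: SimulationConfig, counts_seed: int | None = None
) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw one synthetic experiment; bit-reproducible given ``config.seed``.

    ``counts_seed`` reseeds only the count noise, keeping the ground truth
    (abundances and fold changes) fixed — useful for replicated draws around
    one truth.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    conditions = list(config.condition_labels)
    reference = conditions[0]
    sizes = np.round(np.asarray(config.library_sizes, dtype=float) * config.library_scale)
    sizes = sizes.astype(np.int64)
    if (sizes <= 0).any():
        raise ValueError("scaled library sizes must be positive")

    raw = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    base_p = raw / raw.sum()

    lam = np.zeros((n, len(conditions)))
    n_de = int(round(n * (1.0 - config.stable_fraction)))
    de_idx = rng.choice(n, size=n_de, replace=False)
    for c in range(1, len(conditions)):
        lam[de_idx, c] = rng.choice(config.de_log2fc_choices, size=n_de)

    gene_ids = [f"gene{i:05d}" for i in range(n)]
    if counts_seed is not None:
        rng = np.random.default_rng(counts_seed)
    counts = np.empty((n, len(conditions)), dtype=np.int64)
    for c, _label in enumerate(conditions):
        weights = base_p * np.exp2(lam[:, c])
        scale = weights.sum()
        if not np.isfinite(scale) or scale <= 0:
            raise ValueError("degenerate expected proportions")
        if abs(scale - 1.0) > 0.25:
            warnings.warn(
                f"expected proportions sum to {scale:.3f} before renormalization",
                stacklevel=2,
            )
        mu = sizes[c] * config.mapped_fraction * weights / scale
        if config.noise == "poisson":
            counts[:, c] = rng.poisson(mu)
        else:
            r = 1.0 / config.nb_dispersion
            counts[:, c] = rng.negative_binomial(r, r / (r + mu))

    lib_sizes = pd.Series(sizes, index=conditions)
    colsums = counts.sum(axis=0)
    over = colsums > sizes
    if over.any():
        warnings.warn("mapped tags exceeded a library size; sizes raised", stacklevel=2)
        lib_sizes[over] = colsums[over]

    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=conditions), lib_sizes
    )
    truth_cols = {"base_proportion": base_p}
    for c, label in enumerate(conditions):
        if label == reference:
            continue
        truth_cols[f"log2fc_{label}"] = lam[:, c]
    table = pd.DataFrame(truth_cols, index=gene_ids)
    table["is_stable"] = (lam != 0).sum(axis=1) == 0
    return cm, SyntheticTruth(table, reference)


def simulate_pair_from_prior(
    n_genes: int,
    n_ref: float,
    n_alt: float,
    w: float,
    tau1: float,
    tau2: float,
    abundance_sigma: float = 1.5,
    seed: int = 0,
    labels: tuple[str, str] = ("reference", "alternate"),
) -> tuple[CountMatrix, np.ndarray]:
    """Two libraries drawn from the posterior model's own prior.

    Each gene's log2 fold change is drawn from the zero-mean normal mixture
    ``w N(0, tau1^2) + (1-w) N(0, tau2^2)`` and split symmetrically between
    the libraries (2^(-lambda/2) vs 2^(+lambda/2)), matching the sampling
    model of the fold-change test.  Returns the counts and the true lambdas.
    """
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(0.0, abundance_sigma, size=n_genes)
    p = raw / raw.sum()
    comp = rng.random(n_genes) < w
    lam = np.where(
        comp, rng.normal(0.0, tau1, n_genes), rng.normal(0.0, tau2, n_genes)
    )
    mu_ref = n_ref * p * np.exp2(-lam / 2.0)
    mu_alt = n_alt * p * np.exp2(lam / 2.0)
    y_ref = rng.poisson(mu_ref)
    y_alt = rng.poisson(mu_alt)
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    counts = pd.DataFrame(
        {labels[0]: y_ref, labels[1]: y_alt}, index=gene_ids
    )
    sizes = pd.Series(
        [max(int(n_ref), int(y_ref.sum())), max(int(n_alt), int(y_alt.sum()))],
        index=list(labels),
    )
    return CountMatrix(counts, sizes), lam


PRESETS: dict[str, SimulationConfig] = {
    # 200 genes, ~1e5-tag libraries: fast smoke-test scale
    "tiny": SimulationConfig(n_genes=200, library_scale=0.01),
    # 1e4 genes, ~1e6-tag libraries: the study layout at desk scale
    "paper-like": SimulationConfig(n_genes=10_000, library_scale=0.1),
}


def _fixture_homologs(cm: CountMatrix, truth: SyntheticTruth) -> HomologTable:
    """A small homolog table naming simulated 'housekeeping-like' genes.

    Mirrors real literature tables: families mix genuinely stable members
    with differentially expressed paralogs.
    """
    tpm = cm.counts / cm.library_sizes * 1e6
    mean_tpm = tpm.mean(axis=1)
    stable = truth.is_stable
    families = ["actin-like", "tubulin-like", "gapdh-like", "ubiquitin-like", "cyclophilin-like"]
    rows = []
    stable_pool = mean_tpm[stable & (mean_tpm > 20)].sort_values(ascending=False)
    de_pool = mean_tpm[~stable & (mean_tpm > 5)].sort_values(ascending=False)
    s_iter = iter(stable_pool.index)
    d_iter = iter(de_pool.index)
    for fam in families:
        for _ in range(3):
            try:
                rows.append({"gene_id": next(s_iter), "family": fam, "source": "synthetic-stable"})
            except StopIteration:
                break
        try:
            rows.append({"gene_id": next(d_iter), "family": fam, "source": "synthetic-de"})
        except StopIteration:
            pass
    return HomologTable(pd.DataFrame(rows))


def make_fixture(
    preset: str, out_dir: str | Path, seed: int | None = None
) -> dict[str, Path]:
    """Write a named preset (counts, library sizes, truth, homologs) as TSVs."""
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    config = PRESETS[preset]
    if seed is not None:
        config = replace(config, seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cm, truth = simulate(config)
    paths = {
        "counts": out_dir / "counts.tsv",
        "library_sizes": out_dir / "library_sizes.tsv",
        "truth": out_dir / "truth.tsv",
        "homologs": out_dir / "homologs.tsv",
    }
    from .counts import write_counts

    write_counts(cm, paths["counts"], paths["library_sizes"])
    table = truth.table.copy()
    table.index.name = "gene_id"
    table.to_csv(paths["truth"], sep="\t", float_format="%.17g")
    write_homolog_table(_fixture_homologs(cm, truth), paths["homologs"])
    return paths
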