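"""Transcriptome partitioning under Pearson correlation distance.

k-means with the Pearson correlation "distance" (1 - r) is realized by
z-scoring each gene's expression profile and running ordinary Euclidean
Lloyd iterations: for unit-variance, zero-mean rows the squared Euclidean
distance is an affine function of 1 - r, so cluster assignments coincide
while the centroid step stays exact.  The number of clusters is chosen by a
figure of merit (FOM): cluster on all conditions but one, then score how
well cluster membership predicts the held-out condition.  Clusters are
finally ranked by the expression stability of their members (median CV%).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .counts import TpmMatrix, gene_stats

logger = logging.getLogger(__name__)

__all__ = [
    "Clustering",
    "FomCurve",
    "standardize_rows",
    "kmeans_pearson",
    "compute_fom",
    "rank_stable_clusters",
]


@dataclass
class Clustering:
    """A k-means partition of genes; labels 1..k sorted by descending size."""

    k: int
    assignments: pd.Series  # gene id -> cluster label in 1..k
    centroids: np.ndarray  # (k, n_conditions) means of standardized profiles
    objective: float  # total within-cluster squared distance
    seed: int
    n_restarts: int
    zero_variance_genes: list[str] = field(default_factory=list)


@dataclass
class FomCurve:
    """Aggregate figure-of-merit versus cluster count.

    ``fom_raw`` is the plain within-cluster RMS prediction error of the
    held-out condition; ``fom_adjusted`` divides by sqrt((n - k) / n);
    ``fom_loo`` predicts each gene from its cluster mean *excluding that
    gene* (jackknife).  ``argmin_k`` minimizes ``fom_loo``: the global
    adjustment only cancels the mean-absorption bias, leaving the curve flat
    past the true cluster count, whereas the jackknifed error rises again
    when clusters split noise, giving a well-defined minimum.
    """

    k_values: list[int]
    fom_raw: list[float]
    fom_adjusted: list[float]
    fom_loo: list[float]
    argmin_k: int
    seed: int


def standardize_rows(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each row (population SD); zero-variance rows map to 0.

    Returns the standardized array and a boolean mask of zero-variance rows.
    Constant genes are perfectly stable — they must survive clustering, so
    they are kept with an all-zero profile rather than rejected.
    """
    x = df.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (x - mean) / sd
    z[flat] = 0.0
    return z, flat


def _relabel_by_size(labels: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Map raw labels to 1..k in order of descending cluster size."""
    sizes = np.bincount(labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    return remap[labels], order


def kmeans_pearson(
    tm: TpmMatrix,
    k: int,
    seed: int,
    n_restarts: int = 10,
    max_iter: int = 100,
) -> Clustering:
    """Best-of-``n_restarts`` k-means on row-standardized profiles.

    Deterministic given ``seed``.  Raises if ``k`` exceeds the gene count.
    """
    n = tm.n_genes
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    z, flat = standardize_rows(tm.tpm)
    # k-means++ seeding is strong on large instances but nearly deterministic
    # on tiny ones (it keeps proposing the same far-apart centers); mixing in
    # uniform-random restarts escapes that shared basin
    n_pp = max(1, n_restarts - n_restarts // 2)
    n_rand = max(1, n_restarts // 2)
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_pp, max_iter=max_iter,
        random_state=seed,
    ).fit(z)
    if k > 1:
        km_rand = KMeans(
            n_clusters=k, init="random", n_init=n_rand, max_iter=max_iter,
            random_state=seed + 1,
        ).fit(z)
        if km_rand.inertia_ < km.inertia_:
            km = km_rand
    labels, order = _relabel_by_size(km.labels_, k)
    return Clustering(
        k=k,
        assignments=pd.Series(labels, index=tm.tpm.index, name="cluster"),
        centroids=km.cluster_centers_[order],
        objective=float(km.inertia_),
        seed=seed,
        n_restarts=n_restarts,
        zero_variance_genes=list(tm.tpm.index[flat]),
    )


def compute_fom(
    tm: TpmMatrix,
    k_range: Sequence[int] | None = None,
    seed: int = 0,
    n_restarts: int = 3,
) -> FomCurve:
    """Leave-one-condition-out figure of merit over a range of k.

    For each held-out condition e, genes are clustered on the remaining
    conditions (row-standardized over those conditions), and FOM(e, k) is the
    root-mean-square deviation of the held-out values around their cluster
    means.  The held-out value of each gene is standardized by the *retained*
    columns' row mean and SD: including the held-out column in its own
    standardization lets cluster structure predict it through the shared row
    mean, which biases the curve downward as k grows.  The aggregate FOM(k)
    sums over held-out conditions; the adjusted FOM divides by
    sqrt((n - k) / n) to undo the trivial decrease with k, and the reported
    ``argmin_k`` minimizes the adjusted curve.
    """
    conditions = tm.condition_labels
    if len(conditions) < 2:
        raise ValueError("FOM needs at least 2 conditions")
    n = tm.n_genes
    if k_range is None:
        k_range = range(1, 51)
    ks = [k for k in k_range if k < n]
    dropped = [k for k in k_range if k >= n]
    if dropped:
        warnings.warn(
            f"k values {dropped} with k >= n_genes ({n}) excluded from the FOM curve",
            stacklevel=2,
        )
    if not ks:
        raise ValueError("no usable k values below the gene count")

    x = tm.tpm.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    fom_by_k = {k: 0.0 for k in ks}
    fom_loo_by_k = {k: 0.0 for k in ks}
    for e_idx, held_out in enumerate(conditions):
        retained = [c for c in conditions if c != held_out]
        z_sub, flat = standardize_rows(tm.tpm[retained])
        r_idx = [conditions.index(c) for c in retained]
        m = x[:, r_idx].mean(axis=1)
        s = x[:, r_idx].std(axis=1, ddof=0)
        s[flat] = 1.0
        target = (x[:, e_idx] - m) / s
        target[flat] = 0.0
        for k in ks:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            if k == 1:
                labels = np.zeros(n, dtype=int)
            else:
                labels = KMeans(
                    n_clusters=k,
                    init="k-means++",
                    n_init=n_restarts,
                    random_state=sub_seed,
                ).fit_predict(z_sub)
            resid_sq = 0.0
            loo_sq = 0.0
            for c in range(k):
                members = target[labels == c]
                n_c = members.size
                if n_c == 0:
                    continue
                sq = (members - members.mean()) ** 2
                resid_sq += float(sq.sum())
                # leave-one-out identity: x - mean(rest) = (x - mean) * n/(n-1)
                loo_sq += float(sq.sum()) * (n_c / max(n_c - 1, 1)) ** 2
            fom_by_k[k] += float(np.sqrt(resid_sq / n))
            fom_loo_by_k[k] += float(np.sqrt(loo_sq / n))
    fom_raw = [fom_by_k[k] for k in ks]
    fom_adjusted = [f / np.sqrt((n - k) / n) for f, k in zip(fom_raw, ks)]
    fom_loo = [fom_loo_by_k[k] for k in ks]
    argmin_k = ks[int(np.argmin(fom_loo))]
    return FomCurve(list(ks), fom_raw, fom_adjusted, fom_loo, argmin_k, seed)


def rank_stable_clusters(tm: TpmMatrix, cl: Clustering) -> pd.DataFrame:
    """Score clusters by member expression stability, most stable first.

    ``stability_score`` is the median member CV%% (genes with undefined CV —
    all-zero expression — are perfectly stable and ignored by the median);
    ``mean_abs_deviation`` is the mean over members of the gene's mean
    absolute deviation from its own mean, in tpm.  Rank 1 is the most stable.
    """
    missing = set(cl.assignments.index) - set(tm.tpm.index)
    if missing:
        raise KeyError(f"clustering refers to genes absent from tpm: {sorted(missing)[:5]}")
    stats = gene_stats(tm, list(cl.assignments.index))
    tpm = tm.tpm.loc[cl.assignments.index]
    abs_dev = (tpm.sub(tpm.mean(axis=1), axis=0)).abs().mean(axis=1)
    rows = []
    for label in range(1, cl.k + 1):
        members = cl.assignments.index[cl.assignments == label]
        cvs = stats.loc[members, "cv_percent"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            score = float(np.nanmedian(cvs.to_numpy())) if len(members) else float("nan")
        if np.isnan(score) and len(members):
            score = 0.0  # every member constant at zero
        rows.append(
            {
                "cluster": label,
                "size": int(len(members)),
                "stability_score": score,
                "mean_abs_deviation": float(abs_dev.loc[members].mean())
                if len(members)
                else float("nan"),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        "stability_score", kind="stable", ignore_index=True
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out
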