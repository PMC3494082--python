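# Methods

This note documents the statistical machinery in `refstable`: the models,
the numerical choices, what the synthetic data emulates, and where the
boundaries of the approach lie.

## Counts, normalization, filtering

A `CountMatrix` holds non-negative integer tag counts (genes × conditions)
plus per-library total tag counts. Library sizes may exceed the column sums
(not every sequenced tag maps to a gene model) but never fall below them;
when not supplied they default to the column sums. Normalization to tags per
million is exact: tpm = count / library_size × 10⁶, kept at full floating
precision.

The low-expression filter removes a gene only when its tpm is below the
threshold (default 2.5) in **every** condition. A gene above threshold in a
single condition survives, so retained genes can have mean tpm below the
threshold. The filter is idempotent and monotone in the threshold.

Per-gene statistics use the sample standard deviation (n−1 denominator);
CV% = 100·sd/mean. With only a handful of conditions the choice of n vs n−1
denominator shifts CV by a constant factor; the sample version was chosen as
the conventional estimator. CV is undefined (NaN, flagged) for genes with
zero mean rather than silently zero.

## Posterior fold-change screen

### Sampling model

Tag counts for one gene in two libraries are modeled as independent
Poissons whose means split a log₂ fold change λ symmetrically:

    y_ref ~ Poisson(N_ref · p · 2^(−λ/2)),  y_alt ~ Poisson(N_alt · p · 2^(+λ/2)).

Conditioning on n = y_ref + y_alt removes the unknown abundance p exactly,
leaving y_alt | n ~ Binomial(n, q(λ)) with
q(λ) = N_alt·2^λ / (N_ref + N_alt·2^λ). This conditional-likelihood trick is
what makes the screen usable without replicates: the only free quantity per
gene is λ itself, and information about plausible λ values is shared across
the whole transcriptome through the prior. Overdispersion beyond Poisson is
*not* modeled; see Limitations.

### Empirical prior

The prior on λ is a zero-mean two-component normal mixture
w·N(0, τ₁²) + (1−w)·N(0, τ₂²) — a narrow "stable" component plus a wide
"regulated" component — discretized on a symmetric grid spanning [−8, +8]
log₂ units with step 0.05. The three parameters are fitted by EM,
maximizing the marginal likelihood over all genes with at least one tag in
the pair (at least 50 such genes are required). Numerical choices:

- deterministic initialization w = 0.9, τ₁ = 0.1, τ₂ = 1.0;
- convergence when the log-likelihood gain drops below 1e−8 (absolute),
  with a cap of 5000 iterations — each iteration is a handful of
  matrix-vector products, and realistic ensembles need a few hundred to a
  few thousand;
- τ components are floored at 0.01 log₂ units: narrower components are
  unresolvable at the grid step and degenerate toward a point mass on
  perfectly proportional data, stalling EM and producing a spike no
  quadrature can integrate;
- component variances are swapped if needed so τ₁ ≤ τ₂ always holds;
- non-convergence raises an error carrying the last iterate and the full
  log-likelihood trace.

By default each perturbed-vs-reference pair gets its own prior
(`prior_mode="per-comparison"`); a single pooled fit across all pairs is
available (`"shared"`).

### Posterior summaries

Per gene, the posterior over the grid gives the posterior mean of λ (a
point-mass sum — spectrally accurate for full-line integrals of smooth
integrands). Tail probabilities post-p(δ) = P(|λ| ≥ log₂ δ) are integrated
more carefully: a half-line sum cut through the steep flank of a posterior
narrower than the grid step (high-count genes have posterior SD ≪ 0.05)
incurs composite-midpoint errors near 1e−2. post-p is therefore computed by
midpoint quadrature on a 20× sub-grid of every cell, using the exact
binomial likelihood and the continuous prior density, with the sub-cell
containing the bin boundary split linearly. Measured against an adaptive
(scipy `quad`) oracle the error is below 2e−5. All bins share one
quadrature, so post-p is exactly non-increasing in δ; the construction is
symmetric under exchanging the two libraries (the posterior mean negates,
every post-p is preserved).

Genes with n = 0 are legal: their posterior equals the prior.

### Selection rule

A gene enters the stable set for bin δ iff post-p(δ) < cutoff (strict) in
**all** perturbed-vs-reference comparisons. The summary per (δ, cutoff)
reports the count and the min/median/max of the selected genes' mean tpm.
Set sizes are monotone non-decreasing in both δ and the cutoff.

## Cluster screen

### Pearson k-means

Rows are z-scored (population SD); for zero-mean unit-variance rows the
squared Euclidean distance is an affine function of 1 − Pearson r, so
Euclidean Lloyd iterations preserve the Pearson ordering while keeping an
exact centroid step. Zero-variance genes cannot be z-scored; they are
assigned the all-zero profile and flagged (they are perfectly stable and
must not crash the clustering). Fitting uses scikit-learn's `KMeans` with
restarts split between k-means++ and uniform-random point initializations
(best inertia wins): k-means++ is strong on large instances but proposes
nearly the same far-apart centers on tiny ones and can sit in a shared
local basin. Results are deterministic given the seed; cluster labels are
renumbered 1..k by descending size, since raw k-means labels are
seed-dependent and not comparable across runs.

### Figure of merit

For each held-out condition e, genes are clustered on the remaining
conditions (row-standardized over those conditions) and FOM(e, k) is the
RMS deviation of the held-out values around their cluster means. Two
details matter:

- **Leave-one-out standardization.** The held-out value is standardized by
  the *retained* columns' row mean and SD. Including the held-out column in
  its own row standardization lets cluster structure predict it through the
  shared row mean, biasing the curve downward as k grows.
- **Jackknifed argmin.** Three curves are reported: the raw aggregate
  (summed over held-out conditions), the adjusted curve (÷ sqrt((n−k)/n)),
  and a jackknifed curve in which each gene is predicted by its cluster
  mean *excluding that gene*. The adjustment exactly cancels the
  mean-absorption bias, which leaves the adjusted curve statistically flat
  beyond the true cluster count — its argmin over a flat tail is noise. The
  jackknifed error instead rises again once clusters start splitting noise,
  giving a well-defined minimum; `argmin_k` minimizes it.

k values at or above the gene count are excluded (with a warning). With
four conditions the leave-one-out clustering runs on three points per gene;
correlation over three points is degenerate but well-defined after
z-scoring.

### Stability ranking

Clusters are ranked by the median CV% of their members (rank 1 = most
stable); the mean absolute deviation from each gene's own mean (in tpm) is
reported alongside. Genes with undefined CV (all-zero) count as perfectly
stable. The ranking deliberately does *not* automate the exclusion of
clusters with coherent regulation patterns — a cluster can be "stable" by
CV yet clearly treatment-driven, and that judgment is left to the analyst
via the deviation profiles.

## Literature screen

The screen consumes a pre-built homolog table (gene_id, family, source);
sequence-level homolog discovery is out of scope. It joins each candidate
with its gene statistics and summarizes each family (member count, mean-tpm
range, CV range, median CV), sorted most-stable-family first. Genes in the
table but absent from the matrix are listed as unmatched, never dropped
silently.

## Comparison reports

The deviation profile of a gene set is the per-condition mean of
(tpm − gene mean) over the set, in tpm — identically zero for perfectly
constitutive sets — plus the mean per-gene sample SD. Profiles are computed
in tpm, not standardized units, so magnitudes are comparable across sets.
The Venn report decomposes up to m named sets into their 2^m − 1 exclusive
regions with exact gene lists; region counts always sum to the union size.

## Synthetic data

The generator emulates a four-library nutrient-limitation tag-seq
experiment: condition labels replete/P-limited/Fe-limited/Co-limited with
library sizes 12, 13, 23, 26 million tags (scalable by a factor), ~10⁴
genes, 90% stable. Abundances are log-normal (σ = 1.5 on the log scale),
spanning roughly 0.1–5000 tpm so that ~95% of genes survive the 2.5-tpm
filter. Differentially expressed genes draw a log₂ fold change per
non-reference condition independently from ±{log₂ 1.5, 1, 2}. Expected
proportions are renormalized per condition and scaled by a mapped-tag
fraction of 0.95, so expected column sums sit safely below the library
sizes; counts are Poisson by default, or negative binomial
(var = μ + φμ²) to probe overdispersion. Two presets are fixed:
`tiny` (200 genes, ~10⁵-tag libraries) and `paper-like` (10⁴ genes,
~10⁶-tag libraries — the study layout at desk scale, keeping the full
pipeline under a minute per comparison).

What the generator does **not** emulate: tag-level artifacts (restriction
site absence, multi-mapping, polyA selection bias), correlated regulation
across conditions, library-preparation batch effects, or biological
replicate structure. Passing tests on this generator therefore demonstrate
the statistical machinery under its own assumptions — Poisson (or NB)
counting noise around fixed proportions — not robustness to every artifact
of real tag-seq data.

The planted-structure fixtures used in the clustering tests are designed
around a subtlety of per-gene standardization: the row mean and SD leak a
little information about the retained columns' noise into the held-out
target when noise enters with pattern-heterogeneous weights. The fixtures
therefore use row-scale × (pattern + additive noise) so that the scale
cancels exactly in z-scoring, and modest ensemble sizes (90 genes for the
FOM recovery test) where the jackknife penalty has resolving power.

## Known limitations

- The Poisson conditional model understates uncertainty for overdispersed
  data; under NB noise the fitted prior widens and selections shrink
  (tested as a directional property). There is no replicate-aware mode.
- post-p cutoffs are raw posterior probabilities; no multiplicity
  adjustment is applied (none is intended — the screen inverts a
  significance test rather than controlling an error rate).
- The two-component mixture prior is a parametric re-specification of the
  empirical-Bayes idea; a heavier-tailed ensemble would be approximated by
  an inflated τ₂ rather than matched exactly.
- Exact reproduction of gene counts from any particular published dataset
  depends on that dataset's tag-to-gene mapping pipeline, which is out of
  scope; the screens start from a gene-level count matrix.
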