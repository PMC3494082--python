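import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import binom, norm

from refstable.asc import (
    PriorSpec,
    discretize_mixture,
    estimate_prior,
    make_grid,
    posterior_comparison,
    select_stable_genes,
)
from refstable.counts import CountMatrix
from refstable.simulate import simulate_pair_from_prior


def quad_post_p(y_ref, y_alt, n_ref, n_alt, prior, delta):
    """Adaptive-quadrature tail probability, independent of the grid path."""
    n = y_ref + y_alt

    def integrand(lam):
        q = n_alt * 2.0**lam / (n_ref + n_alt * 2.0**lam)
        density = prior.w * norm.pdf(lam, 0, prior.tau1) + (1 - prior.w) * norm.pdf(
            lam, 0, prior.tau2
        )
        return binom.pmf(y_alt, n, q) * density

    b = float(np.log2(delta))
    lo = quad(integrand, -8, -b, limit=200)[0]
    mid = quad(integrand, -b, b, limit=200)[0]
    hi = quad(integrand, b, 8, limit=200)[0]
    return (lo + hi) / (lo + mid + hi)


class TestPosteriorComparison:
    def test_matches_adaptive_quadrature_on_fixed_inputs(self, unit_normal_prior):
        res = posterior_comparison(30, 1e6, 90, 2e6, unit_normal_prior, (1.25,))
        expected = quad_post_p(30, 90, 1e6, 2e6, unit_normal_prior, 1.25)
        assert res.post_p[1.25] == pytest.approx(expected, abs=1e-4)

    def test_equal_proportions_give_near_zero_posterior_mean(self, unit_normal_prior):
        res = posterior_comparison(100, 1e6, 100, 1e6, unit_normal_prior, (1.25,))
        assert abs(res.posterior_mean_lambda) < 0.05

    def test_swapping_libraries_negates_mean_and_preserves_post_p(
        self, unit_normal_prior
    ):
        a = posterior_comparison(37, 1e6, 90, 2.3e6, unit_normal_prior)
        b = posterior_comparison(90, 2.3e6, 37, 1e6, unit_normal_prior)
        assert a.posterior_mean_lambda == pytest.approx(-b.posterior_mean_lambda, abs=1e-12)
        for d in a.post_p:
            assert a.post_p[d] == pytest.approx(b.post_p[d], abs=1e-12)

    def test_no_data_posterior_equals_prior(self, unit_normal_prior):
        res = posterior_comparison(0, 1e6, 0, 2e6, unit_normal_prior, (1.25,))
        assert res.posterior_mean_lambda == pytest.approx(0.0, abs=1e-12)
        expected = quad_post_p(0, 0, 1e6, 2e6, unit_normal_prior, 1.25)
        assert res.post_p[1.25] == pytest.approx(expected, abs=1e-4)

    @given(
        y_ref=st.integers(min_value=0, max_value=2000),
        y_alt=st.integers(min_value=0, max_value=2000),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_post_p_non_increasing_in_delta(self, y_ref, y_alt):
        grid = make_grid(8.0, 0.05)
        prior = PriorSpec(grid, discretize_mixture(grid, 0.8, 0.1, 1.0), 0.8, 0.1, 1.0)
        res = posterior_comparison(y_ref, 1e6, y_alt, 2e6, prior, (1.05, 1.10, 1.25, 1.5, 2.0))
        values = [res.post_p[d] for d in sorted(res.post_p)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))
        assert all(0.0 <= v <= 1.0 for v in values)

    def test_rejects_invalid_inputs(self, unit_normal_prior):
        with pytest.raises(ValueError):
            posterior_comparison(-1, 1e6, 5, 1e6, unit_normal_prior)
        with pytest.raises(ValueError):
            posterior_comparison(1, 0, 5, 1e6, unit_normal_prior)
        with pytest.raises(ValueError):
            posterior_comparison(1, 1e6, 5, 1e6, unit_normal_prior, (0.9,))


class TestEstimatePrior:
    def test_prior_normalized_and_symmetric(self):
        cm, _ = simulate_pair_from_prior(500, 1e5, 2e5, 0.8, 0.1, 1.0, seed=4)
        prior = estimate_prior(cm, "reference", "alternate")
        assert prior.prior_prob.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(prior.prior_prob, prior.prior_prob[::-1])

    def test_identical_proportions_concentrate_prior_near_zero(self):
        rng = np.random.default_rng(9)
        y = rng.integers(500, 5000, size=300)
        counts = pd.DataFrame(
            {"A": y, "B": 2 * y}, index=[f"g{i}" for i in range(300)]
        )
        sizes = pd.Series({"A": int(y.sum()), "B": int(2 * y.sum())})
        prior = estimate_prior(CountMatrix(counts, sizes), "A", "B")
        near_zero = np.abs(prior.grid) <= 0.2
        assert prior.prior_prob[near_zero].sum() > 0.95

    def test_too_few_informative_genes_raises(self):
        counts = pd.DataFrame(
            {"A": [0] * 30 + [5] * 10, "B": [0] * 30 + [5] * 10},
            index=[f"g{i}" for i in range(40)],
        )
        cm = CountMatrix(counts, pd.Series({"A": 1000, "B": 1000}))
        with pytest.raises(ValueError, match="need >= 50"):
            estimate_prior(cm, "A", "B")

    def test_unknown_condition_raises(self):
        counts = pd.DataFrame({"A": [1] * 60, "B": [1] * 60},
                              index=[f"g{i}" for i in range(60)])
        cm = CountMatrix(counts, pd.Series({"A": 100, "B": 100}))
        with pytest.raises(KeyError):
            estimate_prior(cm, "A", "C")


def _stable_gene_matrix(n_extra=200, seed=5):
    """One perfectly proportional high-count gene among noisy background genes."""
    rng = np.random.default_rng(seed)
    mu = rng.uniform(5, 200, size=n_extra)
    data = {
        "replete": np.concatenate([[1000], rng.poisson(mu)]),
        "P-limited": np.concatenate([[2000], rng.poisson(2 * mu)]),
        "Fe-limited": np.concatenate([[500], rng.poisson(0.5 * mu)]),
    }
    idx = ["anchor"] + [f"g{i}" for i in range(n_extra)]
    counts = pd.DataFrame(data, index=idx)
    sizes = pd.Series(
        {"replete": 1_000_000, "P-limited": 2_000_000, "Fe-limited": 500_000}
    )
    return CountMatrix(counts, sizes)


class TestSelectStableGenes:
    def test_perfectly_stable_high_count_gene_selected_at_every_delta(self):
        cm = _stable_gene_matrix()
        sets = select_stable_genes(cm, "replete", cutoff=0.1)
        for s in sets.values():
            assert "anchor" in s.gene_ids

    def test_set_sizes_monotone_in_delta_and_cutoff(self):
        cm = _stable_gene_matrix()
        by_cutoff = {
            c: select_stable_genes(cm, "replete", cutoff=c) for c in (0.05, 0.1, 0.2)
        }
        for sets in by_cutoff.values():
            counts = [sets[d].summary["count"] for d in sorted(sets)]
            assert counts == sorted(counts)
        for d in (1.10, 1.25, 1.50):
            counts = [by_cutoff[c][d].summary["count"] for c in (0.05, 0.1, 0.2)]
            assert counts == sorted(counts)

    def test_summary_ordering(self):
        cm = _stable_gene_matrix()
        sets = select_stable_genes(cm, "replete", cutoff=0.2)
        s = sets[1.5].summary
        assert s["min_mean_tpm"] <= s["median_mean_tpm"] <= s["max_mean_tpm"]

    def test_unknown_reference_raises(self):
        cm = _stable_gene_matrix()
        with pytest.raises(KeyError, match="unknown reference"):
            select_stable_genes(cm, "nope")

    def test_shared_prior_mode_runs(self):
        cm = _stable_gene_matrix()
        sets, priors, _ = select_stable_genes(
            cm, "replete", cutoff=0.1, prior_mode="shared", return_details=True
        )
        fitted = {id(p) for p in priors.values()}
        assert len(fitted) == 1
        assert "anchor" in sets[1.5].gene_ids


def test_nb_noise_shrinks_selection_relative_to_poisson():
    """Overdispersed counts look less stable, so selection stays conservative."""
    from refstable.counts import filter_low_expression, normalize_tpm
    from refstable.simulate import SimulationConfig, simulate

    base = dict(n_genes=1500, library_scale=0.05, seed=21)
    sizes = {}
    for noise in ("poisson", "nb"):
        cm, _ = simulate(SimulationConfig(noise=noise, nb_dispersion=0.05, **base))
        kept = filter_low_expression(normalize_tpm(cm))
        sets = select_stable_genes(cm.subset(kept.gene_ids), "replete", cutoff=0.1)
        sizes[noise] = sets[1.25].summary["count"]
    assert sizes["nb"] < sizes["poisson"]
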