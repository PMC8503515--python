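"""Principal scores, ancestral information and its maximum-likelihood twin."""

import numpy as np
import pytest

from ancspec import (
    AdmixtureDesign,
    PopulationAssignment,
    ancestral_information,
    compute_spectrum,
    make_loadings,
    mle_ancestral_information,
    principal_scores,
    simulate_genotypes,
    simulate_panel,
    summarize_spectra,
    SimConfig,
)

from conftest import make_genotypes, make_panel


@pytest.fixture
def mu_panel():
    # single population with mu = (0.2, 0.4), i.e. f = (0.1, 0.2)
    return make_panel({"K": [0.1, 0.2]})


class TestMakeLoadings:
    def test_direct_evaluation(self, mu_panel):
        lv = make_loadings(mu_panel)
        np.testing.assert_allclose(lv.b[:, 0], [1.0, 2.0])
        np.testing.assert_allclose(lv.d[:, 0], [1 / 0.6, 1 / 0.6])
        assert lv.sum_mu[0] == pytest.approx(0.6)
        assert lv.sum_mu2[0] == pytest.approx(0.2)

    def test_expected_score_of_population_member_is_one(self, mu_panel):
        lv = make_loadings(mu_panel)
        mu = mu_panel.mu
        assert float(mu @ lv.b[:, 0]) == pytest.approx(1.0)
        assert float(mu @ lv.d[:, 0]) == pytest.approx(1.0)

    def test_loadings_zero_outside_own_block(self, two_pop_panel):
        lv = make_loadings(two_pop_panel)
        p1 = two_pop_panel.block("P1")
        p2 = two_pop_panel.block("P2")
        assert not lv.b[p2, 0].any() and not lv.b[p1, 1].any()
        assert not lv.d[p2, 0].any() and not lv.d[p1, 1].any()

    def test_unit_norm_direction(self, mu_panel):
        lv = make_loadings(mu_panel)
        assert np.linalg.norm(lv.v[:, 0]) == pytest.approx(1.0)


class TestPrincipalScores:
    def test_direct_evaluation(self, mu_panel):
        g = make_genotypes(mu_panel, [[1, 0]])
        a = principal_scores(g, make_loadings(mu_panel))
        assert a[0, 0] == pytest.approx(1.0)

    def test_zero_genotypes_zero_scores(self, two_pop_panel):
        g = make_genotypes(two_pop_panel, [[0] * 5])
        assert not principal_scores(g, make_loadings(two_pop_panel)).any()

    def test_misaligned_columns_error(self, mu_panel, two_pop_panel):
        g = make_genotypes(two_pop_panel, [[0] * 5])
        with pytest.raises(ValueError, match="aligned"):
            principal_scores(g, make_loadings(mu_panel))

    def test_reference_simulation_recovers_one(self):
        """Own-population score mean near 1; other-population scores exactly 0."""
        panel = simulate_panel(SimConfig(populations=("P1", "P2"), m_per_pop=5000, seed=3))
        design = AdmixtureDesign.pure("P1", 100, panel.populations)
        g = simulate_genotypes(panel, design, seed=4)
        a = principal_scores(g, make_loadings(panel))
        own = a[:, list(panel.populations).index("P1")]
        other = a[:, list(panel.populations).index("P2")]
        se = own.std(ddof=1) / np.sqrt(len(own))
        assert abs(own.mean() - 1.0) <= 3 * se
        assert (other == 0.0).all()


class TestAncestralInformation:
    def test_direct_evaluation(self, mu_panel):
        g = make_genotypes(mu_panel, [[1, 1]])
        p = ancestral_information(g, make_loadings(mu_panel))
        assert p[0, 0] == pytest.approx(2 / 0.6)

    def test_zero_iff_no_specific_alleles(self, two_pop_panel):
        g = make_genotypes(two_pop_panel, [[0, 0, 1, 0, 0]])
        p = ancestral_information(g, make_loadings(two_pop_panel))
        assert p[0, 0] == 0.0 and p[0, 1] > 0

    def test_matrix_form_equals_rowwise_ratio(self, two_pop_panel):
        rng = np.random.default_rng(8)
        g = make_genotypes(two_pop_panel, rng.integers(0, 3, size=(10, 5)).tolist())
        p = ancestral_information(g, make_loadings(two_pop_panel))
        for k, pop in enumerate(two_pop_panel.populations):
            idx = two_pop_panel.block(pop)
            manual = g.values[:, idx].sum(axis=1) / two_pop_panel.mu[idx].sum()
            np.testing.assert_allclose(p[:, k], manual, atol=1e-12)

    def test_values_above_one_are_not_clipped(self, mu_panel):
        g = make_genotypes(mu_panel, [[2, 2]])
        p = ancestral_information(g, make_loadings(mu_panel))
        assert p[0, 0] == pytest.approx(4 / 0.6)

    def test_missing_calls_count_zero_copies(self, mu_panel):
        g = make_genotypes(mu_panel, [[1, np.nan]])
        p = ancestral_information(g, make_loadings(mu_panel))
        assert p[0, 0] == pytest.approx(1 / 0.6)


class TestMle:
    def test_no_specific_alleles_gives_zero(self, mu_panel):
        p, boundary = mle_ancestral_information(np.zeros(2), mu_panel, "K")
        assert p == 0.0 and not boundary

    def test_two_snp_closed_form_equals_moment_estimate(self):
        panel = make_panel({"K": [0.02, 0.02]})  # mu = 0.04 each
        p, boundary = mle_ancestral_information(np.array([1.0, 0.0]), panel, "K")
        assert not boundary
        assert p == pytest.approx(12.5, abs=1e-8)
        assert p == pytest.approx(1 / 0.08, abs=1e-8)

    def test_homozygous_counts_truncated_with_warning(self, mu_panel):
        with pytest.warns(UserWarning, match="truncated"):
            p, _ = mle_ancestral_information(np.array([2.0, 0.0]), mu_panel, "K")
        p1, _ = mle_ancestral_information(np.array([1.0, 0.0]), mu_panel, "K")
        assert p == pytest.approx(p1)

    def test_boundary_flag_when_all_alleles_carried(self):
        panel = make_panel({"K": [0.02, 0.02]})
        p, boundary = mle_ancestral_information(np.array([1.0, 1.0]), panel, "K")
        assert boundary
        assert p == pytest.approx((1 - 1e-9) / 0.04)

    def test_agrees_with_moment_estimator_at_small_maf(self):
        panel = simulate_panel(
            SimConfig(populations=("K",), m_per_pop=5000, maf_law=(0.01, 0.025), seed=9)
        )
        design = AdmixtureDesign.pure("K", 20, ("K",))
        g = simulate_genotypes(panel, design, seed=10)
        result = compute_spectrum(g, panel, mle=True)
        assert np.mean(np.abs(result.mle - result.info)) < 0.02


class TestBatchInvariance:
    def test_scores_bitwise_identical_alone_or_in_batch(self, two_pop_panel):
        rng = np.random.default_rng(21)
        batch = make_genotypes(two_pop_panel, rng.integers(0, 3, size=(8, 5)).tolist())
        alone = batch.subset_samples([3])
        r_batch = compute_spectrum(batch, two_pop_panel)
        r_alone = compute_spectrum(alone, two_pop_panel)
        assert (r_batch.scores[3] == r_alone.scores[0]).all()
        assert (r_batch.info[3] == r_alone.info[0]).all()


class TestSummarizeSpectra:
    def _result(self, panel, rows, sample_ids):
        g = make_genotypes(panel, rows, sample_ids=sample_ids)
        return compute_spectrum(g, panel)

    def test_singleton_group_sd_missing(self, mu_panel):
        r = self._result(mu_panel, [[1, 0]], ["a"])
        summary, outliers = summarize_spectra(
            r, PopulationAssignment(("a",), ("G1",))
        )
        assert np.isnan(summary.loc[0, "INFO_K_STD"])
        assert len(outliers) == 0

    def test_identical_individuals_sd_zero(self, mu_panel):
        r = self._result(mu_panel, [[1, 0], [1, 0]], ["a", "b"])
        summary, outliers = summarize_spectra(
            r, PopulationAssignment(("a", "b"), ("G1", "G1"))
        )
        assert summary.loc[0, "INFO_K_STD"] == 0.0
        assert len(outliers) == 0

    def test_constructed_outlier_is_flagged(self, mu_panel):
        # forty identical individuals and one far-away spectrum
        rows = [[1, 0]] * 40 + [[2, 2]]
        ids = [f"s{i}" for i in range(41)]
        r = self._result(mu_panel, rows, ids)
        summary, outliers = summarize_spectra(
            r, PopulationAssignment(tuple(ids), ("G1",) * 41)
        )
        assert "s40" in outliers["SAMPLE"].tolist()


def test_total_information_is_row_sum(two_pop_panel):
    g = make_genotypes(two_pop_panel, [[1, 0, 1, 0, 1], [0, 2, 0, 0, 0]])
    r = compute_spectrum(g, two_pop_panel)
    np.testing.assert_allclose(r.total, r.info.sum(axis=1))


def test_blue_has_smaller_variance_than_principal_score():
    """Equal weights beat MAF-proportional weights for non-constant MAFs."""
    panel = simulate_panel(SimConfig(populations=("K",), m_per_pop=2000, seed=30))
    design = AdmixtureDesign.pure("K", 300, ("K",))
    g = simulate_genotypes(panel, design, seed=31)
    r = compute_spectrum(g, panel)
    assert r.info[:, 0].var(ddof=1) < r.scores[:, 0].var(ddof=1)
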