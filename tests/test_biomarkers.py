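"""Bayes factor filter, LOOCV wrapper, coefficient scores, panel discovery."""

import numpy as np
import pytest

import micasel as mcs
from micasel.biomarkers import all_bayes_factors, _loocv_rate
from micasel.exceptions import DegenerateVarianceError


def _labels(n_per_class):
    return np.repeat([-1, 1], n_per_class)


class TestBayesFactor:
    def test_null_data_favours_equal_means(self, rng):
        bfs = [mcs.gene_bayes_factor(rng.normal(size=60), _labels(30))
               for _ in range(20)]
        assert np.median(bfs) > 1.0  # evidence for the null on most draws

    def test_strong_effect_gives_tiny_factor(self, rng):
        expr = np.concatenate([rng.normal(0, 1, 20), rng.normal(10, 1, 20)])
        assert mcs.gene_bayes_factor(expr, _labels(20)) < 0.01

    def test_constant_gene_is_degenerate(self):
        with pytest.raises(DegenerateVarianceError):
            mcs.gene_bayes_factor(np.ones(10), _labels(5))

    def test_vectorized_factors_match_scalar(self, rng):
        prof = mcs.generate_two_class_profile(
            mcs.SyntheticSpec(p_per_class=10, n=30, effect_size=2.0, seed=1))
        vec = all_bayes_factors(prof)
        for j in (0, 7, 29):
            scalar = mcs.gene_bayes_factor(prof.values[:, j], prof.labels)
            assert vec[j] == pytest.approx(scalar, rel=1e-10)


class TestLoocvRate:
    def test_separable_gene_is_perfect(self):
        expr = np.concatenate([np.linspace(-5, -4, 10), np.linspace(4, 5, 10)])
        assert mcs.gene_svm_loocv_rate(expr, _labels(10)) == 1.0

    def test_minimal_balanced_case(self):
        assert mcs.gene_svm_loocv_rate(np.array([-3.0, -2.9, 3.0, 2.9]),
                                       np.array([-1, -1, 1, 1])) == 1.0

    def test_label_independent_gene_near_chance(self, rng):
        rates = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            rates.append(mcs.gene_svm_loocv_rate(r.normal(size=40), _labels(20)))
        assert abs(np.mean(rates) - 0.5) < 0.2

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            mcs.gene_svm_loocv_rate(np.array([1.0, 2.0]), np.array([1, -1]))


class TestMicaCoefficient:
    def test_euclidean_norm_of_column(self, fitted):
        from micasel.mica import model_from_dict, model_to_dict
        model = model_from_dict(model_to_dict(fitted[0]))  # private copy
        model.Z[:, 5] = 0.0
        assert mcs.mica_gene_coefficient(model, 5) == 0.0
        model.Z[:2, 5] = [3.0, 4.0]
        assert mcs.mica_gene_coefficient(model, 5) == pytest.approx(5.0)

    def test_ranking_invariant_to_sign_flips(self, small_profile):
        model, _ = mcs.fit_mica(small_profile, level=4, tau=3, seed=21)
        coeffs = [mcs.mica_gene_coefficient(model, j) for j in range(20)]
        model.Z = -model.Z  # flip every component
        flipped = [mcs.mica_gene_coefficient(model, j) for j in range(20)]
        np.testing.assert_allclose(coeffs, flipped)

    def test_bounds_checked(self, fitted):
        model, _ = fitted
        with pytest.raises(IndexError):
            mcs.mica_gene_coefficient(model, model.Z.shape[1])


@pytest.fixture(scope="module")
def planted():
    return mcs.generate_two_class_profile(mcs.planted_marker_spec(13, n_nulls=200))


class TestDiscovery:
    def test_max_panel_one_returns_best_single_gene(self, planted):
        recs = mcs.discover_biomarkers(planted, filter_size=10, max_panel=1,
                                       level=5, seed=13)
        assert len(recs) == 1
        assert recs[0].selection_order == 1
        # its wrapper rate is the max single-gene rate among the filtered set
        bf = all_bayes_factors(planted)
        top = np.lexsort((np.arange(planted.n_genes), bf))[:10]
        singles = [_loocv_rate(planted.values[:, [g]], planted.labels)
                   for g in top]
        assert recs[0].panel_rate == pytest.approx(max(singles))

    def test_panel_rate_nondecreasing(self, planted):
        recs = mcs.discover_biomarkers(planted, filter_size=10, max_panel=4,
                                       level=5, seed=13)
        rates = [r.panel_rate for r in recs]
        assert rates == sorted(rates)

    def test_records_in_selection_order_with_scores(self, planted):
        recs = mcs.discover_biomarkers(planted, filter_size=10, max_panel=3,
                                       level=5, seed=13)
        assert [r.selection_order for r in recs] == list(range(1, len(recs) + 1))
        for r in recs:
            assert 0.0 <= r.svm_rate <= 1.0
            assert r.bayes_factor > 0
            assert r.mica_coefficient >= 0

    def test_planted_markers_found(self, planted):
        spec = mcs.planted_marker_spec(13, n_nulls=200)
        recs = mcs.discover_biomarkers(planted, filter_size=10, max_panel=4,
                                       level=5, seed=13)
        assert set(spec.block_starts) <= {r.gene_index for r in recs}

    def test_stopping_when_additions_hurt(self):
        """A panel stops growing when every remaining candidate lowers the
        LOOCV rate: one clean separator plus huge-variance noise genes."""
        rng = np.random.default_rng(3)
        n = 40
        good = np.concatenate([rng.normal(-4, 0.2, n // 2),
                               rng.normal(4, 0.2, n // 2)])
        noise = rng.normal(0, 500.0, size=(n, 3))  # wrecks the rbf length-scale
        values = np.column_stack([good, noise])
        prof = mcs.ExpressionProfile(values, [f"s{i}" for i in range(n)],
                                     ["marker", "n1", "n2", "n3"],
                                     _labels(n // 2))
        recs = mcs.discover_biomarkers(prof, filter_size=4, max_panel=4,
                                       level=1, tau=1, wavelet_name="haar",
                                       seed=0)
        assert [r.gene_id for r in recs] == ["marker"]

    def test_filter_size_clipped_with_warning(self, planted, caplog):
        with caplog.at_level("WARNING"):
            recs = mcs.discover_biomarkers(planted, filter_size=10**6,
                                           max_panel=1, level=5, seed=13)
        assert len(recs) == 1
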