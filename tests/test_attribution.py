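"""Integrated gradients: exactness, completeness, axioms, rank agreement."""

import numpy as np
import pytest
from scipy.stats import rankdata

from ubisite.attribution import (AttributionTable, attribute_sites,
                                 completeness_gap, feature_importance_ranking,
                                 integrated_gradients, rank_agreement)
from ubisite.seqsites import SiteRecord


class LinearModel:
    """F(x) = w . x + b — integrated gradients are exact here."""

    def __init__(self, w, b=0.0):
        self.w = np.asarray(w, dtype=np.float64)
        self.b = b

    def predict_logits(self, x):
        return np.atleast_2d(x) @ self.w + self.b

    def input_gradient(self, x):
        return np.broadcast_to(self.w, np.atleast_2d(x).shape).copy()


class QuadraticModel:
    """F(x) = sum a_i x_i^2 — nonlinear but analytically integrable:
    IG_i = a_i x_i^2 for a zero baseline."""

    def __init__(self, a):
        self.a = np.asarray(a, dtype=np.float64)

    def predict_logits(self, x):
        return (np.atleast_2d(x) ** 2 @ self.a)

    def input_gradient(self, x):
        return 2.0 * self.a * np.atleast_2d(x)


class TestIntegratedGradients:
    @pytest.mark.parametrize("n_steps", [1, 8, 64])
    def test_exact_on_linear_model(self, n_steps):
        model = LinearModel([2.0, -1.0])
        attr = integrated_gradients(model, np.array([1.0, 3.0]),
                                    n_steps=n_steps)
        np.testing.assert_allclose(attr, [[2.0, -3.0]], atol=1e-12)

    def test_zero_path_gives_zero(self):
        model = LinearModel([2.0, -1.0])
        x = np.array([0.7, -0.2])
        attr = integrated_gradients(model, x, baseline=x.copy())
        np.testing.assert_allclose(attr, 0.0, atol=1e-15)

    def test_completeness_on_trained_toy_head(self, audit_head, blob_data):
        """|sum IG - (F(x) - F(0))| < 1e-3 at 256 steps on a trained
        residual network (compact and strongly weight-decayed, so its
        piecewise-linear kinks stay mild; larger nets need more steps)."""
        x = blob_data[0][:10]
        attr = integrated_gradients(audit_head, x, n_steps=256)
        gap = completeness_gap(audit_head, x, attributions=attr)
        assert np.all(gap < 1e-3)

    def test_dummy_feature_gets_zero_attribution(self):
        model = LinearModel([1.5, 0.0, -2.0])  # feature 1 is ignored
        attr = integrated_gradients(model, np.array([2.0, 5.0, 1.0]))
        assert attr[0, 1] == 0.0

    def test_symmetric_features_get_equal_attribution(self):
        model = QuadraticModel([1.0, 1.0])
        attr = integrated_gradients(model, np.array([3.0, 3.0]), n_steps=128)
        assert attr[0, 0] == pytest.approx(attr[0, 1], abs=1e-12)

    def test_linearity_in_the_model(self, rng):
        """IG(a*F + b*G) = a*IG(F) + b*IG(G) for shared x and baseline."""
        w1, w2 = rng.standard_normal(4), rng.standard_normal(4)
        x = rng.standard_normal(4)

        class Combo:
            def predict_logits(self, xx):
                return (3.0 * LinearModel(w1).predict_logits(xx)
                        - 2.0 * LinearModel(w2).predict_logits(xx))

            def input_gradient(self, xx):
                return (3.0 * LinearModel(w1).input_gradient(xx)
                        - 2.0 * LinearModel(w2).input_gradient(xx))

        combo = integrated_gradients(Combo(), x, n_steps=32)
        parts = (3.0 * integrated_gradients(LinearModel(w1), x, n_steps=32)
                 - 2.0 * integrated_gradients(LinearModel(w2), x,
                                              n_steps=32))
        np.testing.assert_allclose(combo, parts, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            integrated_gradients(LinearModel([1.0, 2.0]),
                                 np.array([1.0, 2.0]),
                                 baseline=np.zeros(3))


class TestCompletenessGap:
    def test_zero_for_linear_model(self):
        model = LinearModel([1.0, -4.0], b=2.0)
        x = np.array([0.5, 0.25])
        gap = completeness_gap(model, x, n_steps=16)
        assert gap[0] < 1e-12

    def test_shrinks_as_steps_double(self):
        """On a smooth nonlinear model the midpoint-rule gap decreases
        (within jitter) as the discretisation is refined."""
        class Cubic:
            def predict_logits(self, x):
                return (np.atleast_2d(x) ** 3).sum(axis=1)

            def input_gradient(self, x):
                return 3.0 * np.atleast_2d(x) ** 2

        x = np.array([1.3, -0.7, 2.1])
        gaps = []
        for n_steps in (8, 16, 32, 64, 128, 256):
            attr = integrated_gradients(Cubic(), x, n_steps=n_steps)
            gaps.append(completeness_gap(Cubic(), x, attributions=attr)[0])
        for a, b in zip(gaps, gaps[1:]):
            assert b <= a * 1.1

    def test_invariant_under_consistent_permutation(self, rng):
        w = rng.standard_normal(5)
        x = rng.standard_normal(5)
        perm = rng.permutation(5)
        gap = completeness_gap(QuadraticModel(w ** 2), x, n_steps=64)
        gap_p = completeness_gap(QuadraticModel((w ** 2)[perm]), x[perm],
                                 n_steps=64)
        assert gap[0] == pytest.approx(gap_p[0], abs=1e-12)


class TestFeatureRanking:
    def _table(self, mat):
        sites = [SiteRecord(f"p{i}", 1) for i in range(mat.shape[0])]
        return AttributionTable(sites=sites, attributions=mat)

    def test_planted_driver_ranks_first(self, rng):
        mat = 0.01 * rng.standard_normal((20, 6))
        mat[:, 3] += 5.0  # feature 3 drives the model
        ranking = feature_importance_ranking(self._table(mat), top_k=3)
        assert ranking[0].feature_index == 3
        assert ranking[0].sign_consistency == 1.0

    def test_full_ranking_is_permutation(self, rng):
        mat = rng.standard_normal((10, 7))
        ranking = feature_importance_ranking(self._table(mat))
        assert sorted(r.feature_index for r in ranking) == list(range(7))

    def test_invariant_to_site_order(self, rng):
        mat = rng.standard_normal((12, 5))
        a = feature_importance_ranking(self._table(mat))
        b = feature_importance_ranking(self._table(mat[::-1]))
        assert [r.feature_index for r in a] == [r.feature_index for r in b]

    def test_ties_break_to_lower_index(self):
        mat = np.ones((4, 3))
        ranking = feature_importance_ranking(self._table(mat))
        assert [r.feature_index for r in ranking] == [0, 1, 2]

    def test_top_k_beyond_dim_rejected(self, rng):
        with pytest.raises(ValueError):
            feature_importance_ranking(self._table(np.ones((2, 3))), top_k=4)


class TestRankAgreement:
    def test_identical_vectors(self):
        rho, p = rank_agreement([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert rho == pytest.approx(1.0)

    def test_reversed_vectors(self):
        rho, _ = rank_agreement([1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0])
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        for _ in range(20):
            a = rng.standard_normal(50)
            b = rng.standard_normal(50)
            rho, _ = rank_agreement(a, b)
            ra, rb = rankdata(a), rankdata(b)
            pearson = np.corrcoef(ra, rb)[0, 1]
            assert rho == pytest.approx(pearson, abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            rank_agreement([1.0, 2.0], [2.0, 1.0])


class TestAttributeSites:
    def test_table_shape_and_gap(self, trained_toy_head, separable_data):
        x = separable_data.table.features[:8]
        sites = separable_data.table.sites[:8]
        table = attribute_sites(trained_toy_head, x, sites, n_steps=64)
        assert table.attributions.shape == (8, 32)
        assert table.completeness_gap.shape == (8,)
        assert np.all(np.isfinite(table.completeness_gap))

    def test_informative_coordinates_dominate(self, trained_toy_head,
                                              separable_data):
        """The generator plants the class signal on the first four
        coordinates; the trained model's attributions must rank one of
        them first."""
        x = separable_data.table.features[:50]
        sites = separable_data.table.sites[:50]
        table = attribute_sites(trained_toy_head, x, sites, n_steps=64)
        ranking = feature_importance_ranking(table, top_k=1)
        assert ranking[0].feature_index in range(4)
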