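"""Filtering, scaling and standardization rules."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

import omicvae as ov
from omicvae.preprocess import observed_feature_sds


def _view(values, mask=None, name="v", modality="continuous"):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    return ov.OmicMatrix(
        name,
        np.where(mask, values, 0.0),
        mask,
        [f"s{i}" for i in range(values.shape[0])],
        [f"f{j}" for j in range(values.shape[1])],
        modality,
    )


class TestSDMixtureThreshold:
    def test_symmetric_mixture_crosses_at_midpoint(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(0, 1, 10000), rng.normal(4, 1, 10000)])
        fit = ov.fit_sd_mixture_threshold(x, seed=0)
        assert abs(fit.threshold - 2.0) < 0.1

    def test_general_case_matches_bisection_oracle(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 1, 10000), rng.normal(4, 2, 10000)])
        fit = ov.fit_sd_mixture_threshold(x, seed=0)
        m, s, w = fit.means, fit.sds, fit.weights

        def diff(t):
            return w[0] * norm.pdf(t, m[0], s[0]) - w[1] * norm.pdf(t, m[1], s[1])

        grid = np.linspace(m[0], m[1] + 3 * s[1], 4000)
        sign = np.sign(diff(grid))
        crossings = np.where(np.diff(sign) != 0)[0]
        assert crossings.size > 0
        roots = [brentq(diff, grid[i], grid[i + 1]) for i in crossings]
        assert abs(fit.threshold - max(roots)) < 1e-6

    def test_densities_equal_at_threshold(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0.5, 0.3, 5000), rng.normal(3, 1, 5000)])
        fit = ov.fit_sd_mixture_threshold(x, seed=1)
        d0 = fit.component_density(fit.threshold, 0)
        d1 = fit.component_density(fit.threshold, 1)
        assert abs(d0 - d1) < 1e-8 * max(d0, d1, 1e-300)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 1, 2000), rng.normal(3, 1, 2000)])
        t1 = ov.fit_sd_mixture_threshold(x, seed=9).threshold
        t2 = ov.fit_sd_mixture_threshold(x, seed=9).threshold
        assert t1 == t2

    @pytest.mark.parametrize("bad", [np.ones(5), np.full(50, 2.0)])
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            ov.fit_sd_mixture_threshold(bad, seed=0)


class TestVariableFeatureFilter:
    def test_strict_threshold(self):
        from omicvae.preprocess import SDMixtureFit

        fit = SDMixtureFit(np.r_[0.0, 2.0], np.r_[1.0, 1.0], np.r_[0.5, 0.5], 1.0)
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((200, 3)) * np.array([0.1, 0.5, 3.0])
        view = _view(vals)
        kept = ov.filter_variable_features(view, fit)
        assert list(kept) == ["f2"]

    def test_threshold_below_all_keeps_all(self):
        from omicvae.preprocess import SDMixtureFit

        fit = SDMixtureFit(np.r_[0.0, 0.0], np.r_[1.0, 1.0], np.r_[0.5, 0.5], 0.0)
        view = _view(np.random.default_rng(0).standard_normal((50, 4)))
        assert len(ov.filter_variable_features(view, fit)) == 4

    def test_planted_high_sd_recovery(self):
        rng = np.random.default_rng(21)
        n, p, n_high = 300, 1000, 300
        sds = np.r_[np.full(n_high, 3.0), np.full(p - n_high, 0.2)]
        vals = rng.standard_normal((n, p)) * sds
        view = _view(vals)
        fit = ov.fit_sd_mixture_threshold(observed_feature_sds(view), seed=0)
        kept = set(ov.filter_variable_features(view, fit))
        planted = {f"f{j}" for j in range(n_high)}
        recovered = len(kept & planted) / n_high
        assert recovered >= 0.95


class TestMissingRateFilter:
    def test_boundary_is_strict(self):
        mask = np.ones((20, 2), dtype=bool)
        mask[:18, 0] = False  # 90% missing -> dropped
        mask[:17, 1] = False  # 85% missing -> kept ("higher than")
        view = _view(np.ones((20, 2)), mask)
        out = ov.filter_missing_rate(view, 0.85)
        assert list(out.feature_ids) == ["f1"]

    def test_matches_columnwise_enumeration(self):
        rng = np.random.default_rng(8)
        mask = rng.random((40, 60)) > 0.5
        view = _view(rng.standard_normal((40, 60)), mask)
        out = ov.filter_missing_rate(view, 0.4)
        expected = sum(
            1 for j in range(60) if (1 - mask[:, j].mean()) <= 0.4
        )
        assert out.n_features == expected


class TestScaleCrispr:
    def _random_view(self, seed=0, n=10, p=50):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal((n, p)) - 1.0
        return _view(vals, name="crispr")

    def test_reference_medians_exact(self):
        view = self._random_view()
        ess = [f"f{j}" for j in range(10)]
        non = [f"f{j}" for j in range(10, 20)]
        out = ov.scale_crispr(view, ess, non)
        ess_idx = np.isin(out.feature_ids, ess)
        non_idx = np.isin(out.feature_ids, non)
        for i in range(out.n_samples):
            assert np.median(out.values[i, ess_idx]) == pytest.approx(-1.0, abs=1e-12)
            assert np.median(out.values[i, non_idx]) == pytest.approx(0.0, abs=1e-12)

    def test_already_scaled_is_identity(self):
        rng = np.random.default_rng(4)
        vals = rng.standard_normal((3, 21))
        ess = [f"f{j}" for j in range(5)]
        non = [f"f{j}" for j in range(5, 10)]
        # force each sample's reference medians to -1 and 0 exactly
        for i in range(3):
            vals[i, :5] -= np.median(vals[i, :5]) + 1.0
            vals[i, 5:10] -= np.median(vals[i, 5:10])
        view = _view(vals, name="crispr")
        out = ov.scale_crispr(view, ess, non)
        np.testing.assert_allclose(out.values, view.values, atol=1e-12)

    def test_equal_medians_error_names_sample(self):
        vals = np.ones((2, 10))
        view = _view(vals, name="crispr")
        with pytest.raises(ValueError, match="s0"):
            ov.scale_crispr(view, ["f0", "f1"], ["f2", "f3"])

    def test_masks_unchanged(self):
        rng = np.random.default_rng(5)
        mask = rng.random((6, 30)) > 0.2
        vals = rng.standard_normal((6, 30))
        view = _view(vals, mask, name="crispr")
        out = ov.scale_crispr(
            view, [f"f{j}" for j in range(8)], [f"f{j}" for j in range(8, 16)]
        )
        np.testing.assert_array_equal(out.mask, view.mask)


class TestNeverEssentialFilter:
    def test_sign_cases(self):
        vals = np.array([[-0.4, -0.6], [-0.2, 0.3], [0.1, 0.5]])
        out = ov.filter_never_essential(_view(vals))
        # gene 0 min -0.4 > -0.5 -> removed; gene 1 hits -0.6 -> kept
        assert list(out.feature_ids) == ["f1"]

    def test_matches_row_min_enumeration(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(-0.3, 0.4, size=(30, 80))
        mask = rng.random((30, 80)) > 0.1
        view = _view(vals, mask)
        out = ov.filter_never_essential(view)
        expected = {
            f"f{j}"
            for j in range(80)
            if mask[:, j].any() and vals[mask[:, j], j].min() <= -0.5
        }
        assert set(out.feature_ids) == expected


class TestZScore:
    def test_three_point_closed_form(self):
        view = _view(np.array([[1.0], [2.0], [3.0]]))
        out = ov.zscore_standardize(view)
        np.testing.assert_allclose(
            out.values.ravel(), [-1.224744871, 0.0, 1.224744871], atol=1e-8
        )

    def test_ordinal_view_unchanged(self):
        vals = np.array([[0.0, 2.0], [4.0, 1.0]])
        view = _view(vals, name="cn", modality="ordinal")
        out = ov.zscore_standardize(view)
        np.testing.assert_array_equal(out.values, vals)

    def test_partial_observation_uses_observed_subset(self):
        rng = np.random.default_rng(9)
        vals = rng.standard_normal((20, 1)) * 3 + 5
        mask = np.ones((20, 1), dtype=bool)
        mask[::3] = False
        view = _view(vals, mask)
        out = ov.zscore_standardize(view)
        obs = mask[:, 0]
        mu, sd = vals[obs, 0].mean(), vals[obs, 0].std(ddof=0)
        np.testing.assert_allclose(
            out.values[obs, 0], (vals[obs, 0] - mu) / sd, atol=1e-12
        )
        np.testing.assert_array_equal(out.values[~obs, 0], 0.0)

    def test_zero_variance_warns_and_zeroes(self):
        view = _view(np.ones((5, 1)))
        with pytest.warns(UserWarning, match="zero-variance"):
            out = ov.zscore_standardize(view)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_idempotent_to_machine_precision(self):
        rng = np.random.default_rng(2)
        view = _view(rng.standard_normal((50, 8)) * 4 + 1)
        once = ov.zscore_standardize(view)
        twice = ov.zscore_standardize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)
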