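"""Model architecture, stochastic layers and the three loss terms."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

import omicvae as ov
from omicvae.model import _Network


class TestBuild:
    def test_hidden_layer_size_rule(self):
        cfg = ov.ModelConfig(joint_latent_dim=8, hidden_frac=0.7)
        net = _Network([100], [100], 20, cfg, seed=0)
        # encoder input 100 + 20 conditionals -> hidden round(0.7 * 120) = 84
        assert net.encoders[0].body.layers[0].weight.shape == (120, 84)

    def test_same_seed_identical_parameters(self):
        cfg = ov.ModelConfig(joint_latent_dim=4)
        nets = [_Network([30, 20], [40, 25], 5, cfg, seed=7) for _ in range(2)]
        sums = [
            sum(float(np.abs(p.data).sum()) for p in net.parameters())
            for net in nets
        ]
        assert sums[0] == sums[1]

    def test_asymmetry_reduces_parameter_count(self, small_dataset, small_config):
        dataset, _ = small_dataset
        asym = dataset
        # symmetric twin: encoder consumes every feature
        sym = ov.MultiOmicVAE.__new__(ov.MultiOmicVAE)
        cfg = small_config
        full = ov.io.MultiOmicDataset(
            [v.copy() for v in dataset.views],
            dataset.conditionals,
            {v.name: v.feature_ids.copy() for v in dataset.views},
            tissues=dataset.tissues,
        )
        # restrict the asymmetric twin's encoders to half the features
        half = ov.io.MultiOmicDataset(
            [v.copy() for v in dataset.views],
            dataset.conditionals,
            {v.name: v.feature_ids[: v.n_features // 2].copy()
             for v in dataset.views},
            tissues=dataset.tissues,
        )
        n_sym = ov.MultiOmicVAE(full, cfg).parameter_count()
        n_asym = ov.MultiOmicVAE(half, cfg).parameter_count()
        assert n_asym < n_sym

    def test_nonpositive_layer_size_rejected(self):
        with pytest.raises(ValueError):
            _Network([0], [10], 0, ov.ModelConfig(joint_latent_dim=4), seed=0)


class TestViewDropout:
    def test_rate_zero_is_identity(self):
        rng = np.random.default_rng(0)
        xs = [rng.standard_normal((10, 4)) for _ in range(3)]
        out, dropped = ov.view_dropout(xs, 0.0, rng)
        for a, b in zip(out, xs):
            np.testing.assert_array_equal(a, b)
        assert not dropped.any()

    def test_empirical_rate_within_3_binomial_ses(self):
        rng = np.random.default_rng(123)
        n_views, rate, n = 7, 0.5, 10_000
        xs = [np.ones((n, 2)) for _ in range(n_views)]
        _, dropped = ov.view_dropout(xs, rate, rng)
        # redraw-on-all-dropped slightly deflates the marginal rate;
        # correct the expectation for the conditioning
        p_all = rate**n_views
        expected = rate * (1 - rate ** (n_views - 1)) / (1 - p_all)
        se = np.sqrt(expected * (1 - expected) / n)
        freq = dropped.mean(axis=0)
        assert np.all(np.abs(freq - expected) < 3 * se)

    def test_no_sample_loses_every_view(self):
        rng = np.random.default_rng(5)
        xs = [np.ones((2000, 1)) for _ in range(2)]
        out, dropped = ov.view_dropout(xs, 0.9, rng)
        assert not dropped.all(axis=1).any()

    def test_dropped_views_are_exactly_zero_without_rescaling(self):
        rng = np.random.default_rng(6)
        xs = [np.full((500, 3), 2.0) for _ in range(3)]
        out, dropped = ov.view_dropout(xs, 0.4, rng)
        for j in range(3):
            np.testing.assert_array_equal(out[j][dropped[:, j]], 0.0)
            np.testing.assert_array_equal(out[j][~dropped[:, j]], 2.0)

    def test_rate_one_rejected(self):
        with pytest.raises(ValueError):
            ov.view_dropout([np.ones((2, 2))], 1.0, np.random.default_rng(0))


class TestReparameterize:
    def test_sampling_disabled_returns_mu(self):
        mu = np.random.default_rng(0).standard_normal((5, 3))
        np.testing.assert_array_equal(ov.reparameterize(mu, mu * 0, None), mu)

    def test_sigma_to_zero_limit(self):
        mu = np.ones((4, 2))
        z = ov.reparameterize(mu, np.full((4, 2), -700.0), np.random.default_rng(1))
        np.testing.assert_allclose(z, mu, atol=1e-100)

    def test_moments_standard_normal(self):
        rng = np.random.default_rng(2)
        z = ov.reparameterize(np.zeros((50_000, 1)), np.zeros((50_000, 1)), rng)
        se_mean = 1 / np.sqrt(50_000)
        assert abs(z.mean()) < 3 * se_mean
        se_var = np.sqrt(2 / 50_000)
        assert abs(z.var() - 1) < 3 * se_var

    def test_reproducible_under_seed(self):
        mu, lv = np.zeros((3, 3)), np.zeros((3, 3))
        z1 = ov.reparameterize(mu, lv, np.random.default_rng(7))
        z2 = ov.reparameterize(mu, lv, np.random.default_rng(7))
        np.testing.assert_array_equal(z1, z2)


class TestReconstructionLoss:
    def test_perfect_reconstruction_is_zero(self):
        x = np.random.default_rng(0).standard_normal((4, 5))
        total, _ = ov.loss_reconstruction([x], [x], [np.ones_like(x, bool)])
        assert total == 0.0

    def test_masked_entries_excluded_bit_exact(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((6, 4))
        recon = rng.standard_normal((6, 4))
        mask = rng.random((6, 4)) > 0.5
        t1, _ = ov.loss_reconstruction([recon], [x], [mask])
        x_perturbed = x.copy()
        x_perturbed[~mask] += rng.standard_normal((~mask).sum()) * 100
        t2, _ = ov.loss_reconstruction([recon], [x_perturbed], [mask])
        assert t1 == t2

    def test_hand_computed_two_by_two(self):
        target = np.zeros((2, 2))
        recon = np.array([[1.0, 99.0], [99.0, 3.0]])
        mask = np.eye(2, dtype=bool)
        total, per_view = ov.loss_reconstruction([recon], [target], [mask])
        assert total == pytest.approx((1 + 9) / 2)

    def test_sum_over_views(self):
        x = np.ones((2, 2))
        zero = np.zeros((2, 2))
        m = np.ones((2, 2), bool)
        total, per_view = ov.loss_reconstruction([zero, zero], [x, 2 * x], [m, m])
        assert total == pytest.approx(1.0 + 4.0)
        assert per_view == {0: pytest.approx(1.0), 1: pytest.approx(4.0)}

    def test_empty_view_contributes_zero_with_warning(self):
        x = np.ones((2, 2))
        with pytest.warns(UserWarning, match="no observed"):
            total, _ = ov.loss_reconstruction(
                [x], [x * 5], [np.zeros((2, 2), bool)]
            )
        assert total == 0.0


class TestKLLoss:
    def test_standard_normal_is_zero(self):
        assert ov.loss_kl(np.zeros((3, 4)), np.zeros((3, 4))) == 0.0

    def test_unit_mean_one_dim(self):
        assert ov.loss_kl(np.array([[1.0]]), np.array([[0.0]])) == pytest.approx(0.5)

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(3)
        mu = rng.standard_normal((4, 3))
        logvar = rng.standard_normal((4, 3)) * 0.5

        def kl_1d(m, lv):
            s = np.exp(lv / 2)

            def integrand(x):
                q = norm.pdf(x, m, s)
                return q * (norm.logpdf(x, m, s) - norm.logpdf(x, 0, 1))

            return quad(integrand, m - 12 * s, m + 12 * s, limit=200)[0]

        expected = np.mean(
            [
                sum(kl_1d(mu[i, j], logvar[i, j]) for j in range(3))
                for i in range(4)
            ]
        )
        assert ov.loss_kl(mu, logvar) == pytest.approx(expected, abs=1e-6)


class TestContrastiveLoss:
    def test_identical_same_tissue_is_zero(self):
        z = np.tile([1.0, 2.0], (4, 1))
        labels = np.array(["lung"] * 4)
        assert ov.loss_contrastive(z, labels) == 0.0

    def test_orthogonal_different_tissues_is_zero(self):
        z = np.eye(3)
        labels = np.array(["a", "b", "c"])
        assert ov.loss_contrastive(z, labels) == 0.0

    def test_hand_case_three_samples(self):
        z = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        labels = np.array(["A", "A", "B"])
        assert ov.loss_contrastive(z, labels) == pytest.approx(1.275, abs=1e-10)

    def test_zero_norm_embedding_warns(self):
        z = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="zero-norm"):
            val = ov.loss_contrastive(z, np.array(["A", "A"]))
        assert val == pytest.approx(0.85)  # cos treated as 0

    def test_single_class_batches(self):
        z = np.array([[1.0, 0.0], [0.0, 1.0]])
        # all same tissue: only the positive term
        assert ov.loss_contrastive(z, np.array(["A", "A"])) == pytest.approx(0.85)
        # all different: only the negative term, cos=0 < m_neg
        assert ov.loss_contrastive(z, np.array(["A", "B"])) == 0.0


class TestTotalLoss:
    def test_weights_zero(self):
        assert ov.loss_total(1.0, 2.0, 3.0, 0.0, 0.0) == 1.0

    def test_default_weights(self):
        assert ov.loss_total(1.0, 2.0, 3.0) == pytest.approx(1.0152)

    def test_gradient_is_weighted_sum(self):
        # scalar toy model: all three losses quadratic in one parameter
        from omicvae.autodiff import Tensor

        w = Tensor(np.array([[0.7]]), requires_grad=True)
        lam, alpha = 1e-2, 5e-1
        rec = (w**2.0).sum()
        kl = (3.0 * w**2.0).sum()
        con = (5.0 * w**2.0).sum()
        total = rec + lam * kl + alpha * con
        total.backward()
        expected = 2 * 0.7 * (1 + lam * 3 + alpha * 5)
        assert w.grad[0, 0] == pytest.approx(expected, rel=1e-10)


class TestForwardContracts:
    def test_decode_encode_deterministic(self, trained_model):
        model, _ = trained_model
        state1 = model.encode()
        state2 = model.encode()
        np.testing.assert_array_equal(state1.mu, state2.mu)
        r1 = model.decode(state1.mu)
        r2 = model.decode(state2.mu)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a, b)

    def test_all_views_zeroed_still_decodes(self, trained_model):
        model, _ = trained_model
        zeros = [np.zeros_like(x) for x in model._enc_values]
        state = model.encode(view_values=zeros)
        recons = model.decode(state.mu)
        assert all(np.isfinite(r).all() for r in recons)

    def test_conditional_flag_shifts_trained_output(self):
        # planted conditional effect: flipping the flag must move the decoder
        spec = ov.SyntheticSpec(
            n_samples=150, view_features=(12,), latent_dim=2, n_conditionals=1,
            conditional_effect=3.0, conditional_rate=0.5, mcar_rate=0.0,
            view_absence_rate=0.0, noise_sd=0.2, seed=4,
        )
        dataset, truth = ov.generate(spec)
        cfg = ov.ModelConfig(
            joint_latent_dim=4, batch_size=64, view_latent_cap=16, seed=0,
            learning_rate=3e-3, dropout_p=0.0, view_dropout_p=0.0,
        )
        model = ov.MultiOmicVAE(dataset, cfg)
        model.fit(epochs=150)
        state = model.encode()
        cond_on = np.ones((dataset.n_samples, 1))
        cond_off = np.zeros((dataset.n_samples, 1))
        rec_on = model.decode(state.mu, cond_on)[0]
        rec_off = model.decode(state.mu, cond_off)[0]
        B = truth.cond_effects[0][0]
        hit = B != 0
        shift = (rec_on - rec_off).mean(axis=0)
        # the decoder's learned shift agrees in sign with the planted effect
        signs = np.sign(shift[hit]) == np.sign(B[hit])
        assert signs.mean() > 0.8

    def test_masked_target_invariance_of_total_loss(self, small_dataset,
                                                    small_config):
        dataset, _ = small_dataset
        model = ov.MultiOmicVAE(dataset, small_config)
        recons = model.decode(model.encode().mu)
        targets = [v.values for v in dataset.views]
        masks = [v.mask for v in dataset.views]
        t1, _ = ov.loss_reconstruction(recons, targets, masks)
        rng = np.random.default_rng(0)
        perturbed = []
        for t, m in zip(targets, masks):
            t = t.copy()
            t[~m] = rng.standard_normal((~m).sum()) * 1e6
            perturbed.append(t)
        t2, _ = ov.loss_reconstruction(recons, perturbed, masks)
        assert t1 == t2


class TestCheckpoint:
    def test_save_load_roundtrip(self, trained_model, tmp_path, small_dataset,
                                 small_config):
        model, _ = trained_model
        path = tmp_path / "model.ckpt.npz"
        model.save(path)
        dataset, _ = small_dataset
        fresh = ov.MultiOmicVAE(dataset, small_config)
        meta = fresh.load_parameters(path)
        assert meta["format_version"] == 1
        np.testing.assert_array_equal(
            fresh.encode().mu, model.encode().mu
        )
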