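import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

import topicimpute as ti
from topicimpute._nn import MLP, softmax
from topicimpute.topic_model import TopicModelConfig, _Encoder, TopicModelState


def tiny_state(n_genes=6, n_topics=3, seed=0):
    rng = np.random.default_rng(seed)
    enc = _Encoder(n_genes, 8, n_topics, rng)
    beta_logits = rng.normal(size=(n_topics, n_genes))
    return TopicModelState(
        enc, beta_logits, [f"g{j}" for j in range(n_genes)], TopicModelConfig(n_topics=n_topics)
    )


class TestEncode:
    def test_deterministic(self):
        state = tiny_state()
        y = np.random.default_rng(1).random((4, 6))
        mu1, lv1 = ti.encode(y, state)
        mu2, lv2 = ti.encode(y, state)
        np.testing.assert_array_equal(mu1, mu2)
        np.testing.assert_array_equal(lv1, lv2)
        assert mu1.shape == lv1.shape == (4, 3)

    def test_zeroed_heads_give_zero_outputs(self):
        state = tiny_state()
        state.encoder.mu_head.W[:] = 0
        state.encoder.mu_head.b[:] = 0
        mu, _ = ti.encode(np.ones((2, 6)), state)
        np.testing.assert_array_equal(mu, 0.0)

    def test_dimension_mismatch_raises(self):
        state = tiny_state()
        with pytest.raises(ValueError, match="6"):
            ti.encode(np.ones((2, 7)), state)


class TestReparameterize:
    def test_zero_sigma_recovers_softmax_of_mu(self):
        theta = ti.reparameterize_theta(np.zeros(4), np.full(4, -1e10), n_samples=1)
        np.testing.assert_allclose(theta[0], 0.25)
        theta = ti.reparameterize_theta(np.array([np.log(2.0), 0.0]), np.full(2, -1e10))
        np.testing.assert_allclose(theta[0], [2 / 3, 1 / 3], atol=1e-12)

    def test_seeded_reproducibility(self):
        a = ti.reparameterize_theta(np.zeros(3), np.zeros(3), n_samples=3, rng_seed=5)
        b = ti.reparameterize_theta(np.zeros(3), np.zeros(3), n_samples=3, rng_seed=5)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(a.sum(axis=-1), 1.0)


class TestReconstruction:
    def test_closed_form(self):
        beta = np.array([[0.5, 0.5], [0.9, 0.1]])
        val = ti.reconstruction_loglik(np.array([2.0, 0.0]), np.array([1.0, 0.0]), beta)
        assert val == pytest.approx(2 * np.log(0.5))
        assert val == pytest.approx(-1.386294, abs=1e-6)

    def test_zero_profile_gives_zero(self):
        beta = softmax(np.random.default_rng(0).normal(size=(2, 5)), axis=1)
        assert ti.reconstruction_loglik(np.zeros(5), np.array([0.4, 0.6]), beta) == 0.0

    def test_matches_explicit_loop(self):
        rng = np.random.default_rng(2)
        theta = rng.dirichlet(np.ones(3))
        beta = softmax(rng.normal(size=(3, 5)), axis=1)
        y = rng.random(5)
        expected = sum(
            y[j] * np.log(sum(theta[k] * beta[k, j] for k in range(3))) for j in range(5)
        )
        assert ti.reconstruction_loglik(y, theta, beta) == pytest.approx(expected)

    def test_gene_permutation_invariance(self):
        rng = np.random.default_rng(3)
        theta = rng.dirichlet(np.ones(4))
        beta = softmax(rng.normal(size=(4, 6)), axis=1)
        y = rng.random(6)
        perm = rng.permutation(6)
        assert ti.reconstruction_loglik(y, theta, beta) == pytest.approx(
            ti.reconstruction_loglik(y[perm], theta, beta[:, perm])
        )

    def test_non_simplex_theta_rejected(self):
        beta = np.full((2, 2), 0.5)
        with pytest.raises(ValueError, match="probability"):
            ti.reconstruction_loglik(np.ones(2), np.array([0.7, 0.7]), beta)


class TestKL:
    def test_standard_normal_is_zero(self):
        assert ti.kl_to_standard_normal(np.zeros(3), np.zeros(3)) == 0.0

    def test_unit_mean_shift(self):
        assert ti.kl_to_standard_normal(np.array([1.0, 0.0]), np.zeros(2)) == 0.5

    def test_matches_quadrature(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            mu = rng.normal(scale=1.5)
            lv = rng.normal(scale=0.8)
            sd = np.exp(0.5 * lv)

            def integrand(x):
                q = norm.pdf(x, mu, sd)
                return q * (norm.logpdf(x, mu, sd) - norm.logpdf(x, 0, 1))

            num, _ = quad(integrand, mu - 12 * sd, mu + 12 * sd)
            assert ti.kl_to_standard_normal([mu], [lv]) == pytest.approx(num, abs=1e-4)

    def test_nonnegative(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            assert ti.kl_to_standard_normal(rng.normal(size=6), rng.normal(size=6)) >= 0


class TestBackprop:
    def test_mlp_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        mlp = MLP([5, 4, 2], rng)
        x = rng.random((3, 5))

        def loss():
            return 0.5 * float((mlp.forward(x) ** 2).sum())

        loss()
        mlp.backward(mlp.forward(x))
        eps = 1e-6
        for p, g in mlp.params:
            it = np.nditer(p, flags=["multi_index"])
            for _ in range(min(p.size, 6)):
                idx = it.multi_index
                orig = p[idx]
                p[idx] = orig + eps
                up = loss()
                p[idx] = orig - eps
                down = loss()
                p[idx] = orig
                assert g[idx] == pytest.approx((up - down) / (2 * eps), rel=1e-4, abs=1e-7)
                it.iternext()


@pytest.fixture(scope="module")
def trained(topic_sim):
    counts = ti.filter_qc(topic_sim.observed_counts)
    norm = ti.normalize(counts)
    cfg = TopicModelConfig(n_topics=3, epochs=60, seed=0)
    state, post = ti.train(norm, cfg)
    return norm, state, post


class TestTraining:
    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TopicModelConfig(epochs=0)
        with pytest.raises(ValueError):
            TopicModelConfig(n_topics=1)

    def test_theta_rows_are_simplex(self, trained):
        _, _, post = trained
        np.testing.assert_allclose(post.theta.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(post.theta > 0) and np.all(post.theta < 1)

    def test_seeded_training_is_bitwise_reproducible(self, topic_sim):
        counts = ti.filter_qc(topic_sim.observed_counts)
        norm = ti.normalize(counts)
        cfg = TopicModelConfig(n_topics=3, epochs=5, seed=7)
        s1, p1 = ti.train(norm, cfg)
        s2, p2 = ti.train(norm, cfg)
        assert s1.training_log == s2.training_log
        np.testing.assert_array_equal(p1.theta, p2.theta)

    def test_elbo_decomposes_into_recon_minus_kl(self, trained):
        norm, state, post = trained
        from topicimpute.topic_model import _full_elbo

        y = norm.y_cell
        w = y * (norm.library_sizes / np.maximum(y.sum(1), 1e-12))[:, None]
        total = 0.0
        for i in range(y.shape[0]):
            theta = softmax(post.mu[i])
            total += ti.reconstruction_loglik(w[i], theta, state.topic_gene)
            total -= ti.kl_to_standard_normal(post.mu[i], post.log_var[i])
        assert _full_elbo(y, w, state) == pytest.approx(total / y.shape[0])

    def test_reinference_matches_training_posterior(self, trained):
        norm, state, post = trained
        again = ti.infer_theta(norm, state)
        np.testing.assert_array_equal(again.theta, post.theta)

    def test_cell_permutation_permutes_theta(self, trained):
        norm, state, post = trained
        perm = np.random.default_rng(0).permutation(norm.y_cell.shape[0])
        import copy

        norm2 = copy.copy(norm)
        norm2.y_cell = norm.y_cell[perm]
        np.testing.assert_array_equal(ti.infer_theta(norm2, state).theta, post.theta[perm])

    def test_gene_mismatch_refers_to_alignment(self, trained):
        norm, state, _ = trained
        import copy

        norm2 = copy.copy(norm)
        norm2.y_cell = norm.y_cell[:, :-1]
        with pytest.raises(ValueError, match="align"):
            ti.infer_theta(norm2, state)


class TestPersistence:
    def test_save_load_roundtrip(self, topic_sim, tmp_path):
        counts = ti.filter_qc(topic_sim.observed_counts)
        norm = ti.normalize(counts)
        state, post = ti.train(norm, TopicModelConfig(n_topics=3, epochs=5, seed=0))
        ti.save_model(state, str(tmp_path / "model"))
        loaded = ti.load_model(str(tmp_path / "model"))
        np.testing.assert_array_equal(ti.infer_theta(norm, loaded).theta, post.theta)
        # save -> load -> save produces byte-identical metadata
        ti.save_model(loaded, str(tmp_path / "model2"))
        a = (tmp_path / "model" / "meta.json").read_bytes()
        b = (tmp_path / "model2" / "meta.json").read_bytes()
        assert a == b

    def test_corrupt_metadata_names_missing_field(self, tmp_path):
        d = tmp_path / "model"
        d.mkdir()
        (d / "meta.json").write_text('{"gene_ids": []}')
        with pytest.raises(ValueError, match="schema_version"):
            ti.load_model(str(d))
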