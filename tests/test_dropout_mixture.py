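import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist, norm as norm_dist

import topicimpute as ti
from topicimpute.dropout_mixture import (
    MixtureNetConfig,
    dropout_rates,
    fit_mixture_em,
    fit_mixture_em_all,
    fit_mixture_net,
    gene_loglik,
    mixture_pdf,
)
from topicimpute.synthetic import BimodalSimConfig, simulate_bimodal


def draw_mixture(n, lam, shape, rate, mean, sd, seed):
    rng = np.random.default_rng(seed)
    comp = rng.random(n) < lam
    y = np.where(comp, rng.gamma(shape, 1.0 / rate, n), rng.normal(mean, sd, n))
    return np.maximum(y, 1e-6)


class TestMixturePdf:
    def test_lambda_zero_is_pure_normal(self):
        y = np.linspace(0.1, 3, 7)
        np.testing.assert_allclose(
            mixture_pdf(y, 0.0, 2.0, 3.0, 1.0, 0.5), norm_dist.pdf(y, 1.0, 0.5)
        )

    def test_exponential_special_case(self):
        assert mixture_pdf(0.5, 1.0, 1.0, 1.0, 0.0, 1.0) == pytest.approx(
            np.exp(-0.5), abs=1e-6
        )

    def test_even_mixture_hand_value(self):
        val = mixture_pdf(1.0, 0.5, 1.0, 1.0, 1.0, 1.0)
        expected = 0.5 * (np.exp(-1.0) + 1.0 / np.sqrt(2 * np.pi))
        assert val == pytest.approx(expected, abs=1e-9)
        assert val == pytest.approx(0.383411, abs=1e-6)

    @pytest.mark.parametrize(
        "bad", [dict(lam=1.5), dict(shape=-1.0), dict(rate=0.0), dict(sd=0.0)]
    )
    def test_domain_validation(self, bad):
        kwargs = dict(lam=0.5, shape=1.0, rate=1.0, mean=0.0, sd=1.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            mixture_pdf(1.0, **kwargs)


class TestGeneLoglik:
    def test_single_point(self):
        # lam=0: normal density at its mean with sd 1/sqrt(2 pi) ... use direct value
        val = gene_loglik(np.array([1.0]), 0.5, 1.0, 1.0, 1.0, 1.0)
        assert val == pytest.approx(np.log(mixture_pdf(1.0, 0.5, 1.0, 1.0, 1.0, 1.0)))

    def test_additive_over_cells(self):
        y1 = draw_mixture(30, 0.4, 2, 4, 1.5, 0.3, 0)
        y2 = draw_mixture(20, 0.4, 2, 4, 1.5, 0.3, 1)
        params = (0.4, 2.0, 4.0, 1.5, 0.3)
        assert gene_loglik(np.concatenate([y1, y2]), *params) == pytest.approx(
            gene_loglik(y1, *params) + gene_loglik(y2, *params)
        )

    def test_matches_pointwise_loop(self):
        y = draw_mixture(50, 0.3, 2, 8, 2.0, 0.3, 2)
        params = (0.3, 2.0, 8.0, 2.0, 0.3)
        loop = sum(np.log(mixture_pdf(v, *params)) for v in y)
        assert gene_loglik(y, *params) == pytest.approx(loop)


class TestEMFit:
    def test_recovers_known_parameters(self):
        y = draw_mixture(2000, 0.3, 2.0, 8.0, 2.0, 0.3, seed=7)
        fit = fit_mixture_em(y)
        assert fit["lam"] == pytest.approx(0.3, abs=0.05)
        assert fit["normal_mean"] == pytest.approx(2.0, abs=0.1)

    def test_pure_normal_collapses_lambda(self):
        y = np.abs(np.random.default_rng(8).normal(2.0, 0.3, 2000)) + 1e-6
        assert fit_mixture_em(y)["lam"] <= 0.05

    def test_loglik_trace_non_decreasing(self):
        y = draw_mixture(800, 0.4, 1.5, 5.0, 1.8, 0.25, seed=3)
        trace = np.array(fit_mixture_em(y)["loglik_trace"])
        assert np.all(np.diff(trace) >= -1e-8)

    def test_final_loglik_at_least_initial(self):
        y = draw_mixture(500, 0.35, 2.0, 6.0, 1.6, 0.3, seed=4)
        fit = fit_mixture_em(y)
        assert fit["loglik"] >= fit["loglik_trace"][0] - 1e-8

    def test_degenerate_column_flagged(self):
        fit = fit_mixture_em(np.full(50, 0.3))
        assert fit["degenerate"]
        assert 0.01 <= fit["lam"] <= 0.99

    def test_too_few_cells_falls_back(self):
        fit = fit_mixture_em(np.linspace(0.1, 1, 5))
        assert fit["degenerate"]


@pytest.fixture(scope="module")
def bimodal_norm():
    sim = simulate_bimodal(BimodalSimConfig(n_cells=200, n_genes=150, seed=0))
    counts = ti.filter_qc(sim.observed_counts)
    norm = ti.normalize(counts)
    from topicimpute.synthetic import restrict_to_genes

    return restrict_to_genes(sim, counts.gene_ids), norm


class TestMixtureNet:
    def test_deterministic_given_seed(self, bimodal_norm):
        _, norm = bimodal_norm
        cfg = MixtureNetConfig(epochs=30, seed=5)
        p1, _ = fit_mixture_net(norm.y_lib_log, cfg)
        p2, _ = fit_mixture_net(norm.y_lib_log, cfg)
        np.testing.assert_array_equal(p1.lam, p2.lam)
        np.testing.assert_array_equal(p1.normal_mean, p2.normal_mean)

    def test_agrees_with_em_reference(self, bimodal_norm):
        _, norm = bimodal_norm
        em = fit_mixture_em_all(norm.y_lib_log)
        net_params, _ = fit_mixture_net(norm.y_lib_log)
        assert np.median(np.abs(net_params.lam - em.lam)) <= 0.1
        em_mask = dropout_rates(norm.y_lib_log, em).mask
        net_mask = dropout_rates(norm.y_lib_log, net_params).mask
        assert (em_mask == net_mask).mean() >= 0.9

    def test_constant_gene_uses_degenerate_path(self):
        rng = np.random.default_rng(0)
        y = np.column_stack(
            [np.full(60, 0.3), rng.uniform(0.1, 2.0, 60), rng.uniform(0.1, 2.0, 60)]
        )
        params, _ = fit_mixture_net(y, MixtureNetConfig(epochs=10))
        assert params.degenerate[0] and not params.degenerate[1:].any()

    def test_predict_matches_training_output(self, bimodal_norm):
        _, norm = bimodal_norm
        params, net = fit_mixture_net(norm.y_lib_log, MixtureNetConfig(epochs=30))
        again = net.predict(norm.y_lib_log)
        np.testing.assert_array_equal(params.lam, again.lam)


class TestDropoutRates:
    def test_symmetric_point_gives_half(self):
        # choose y where Gamma(2,2) and Normal pdfs coincide
        y = 1.0
        g = gamma_dist.pdf(y, a=2.0, scale=0.5)
        params = ti.GeneMixtureParams(
            lam=np.array([0.5]),
            gamma_shape=np.array([2.0]),
            gamma_rate=np.array([2.0]),
            normal_mean=np.array([y]),
            normal_sd=np.array([1.0 / (g * np.sqrt(2 * np.pi))]),
            loglik=np.zeros(1),
        )
        est = dropout_rates(np.array([[y]]), params)
        assert est.rates[0, 0] == pytest.approx(0.5, abs=1e-9)

    def test_tiny_lambda_never_calls_dropout(self):
        params = ti.GeneMixtureParams(
            lam=np.array([1e-3]),
            gamma_shape=np.array([1.0]),
            gamma_rate=np.array([5.0]),
            normal_mean=np.array([1.0]),
            normal_sd=np.array([0.3]),
            loglik=np.zeros(1),
        )
        est = dropout_rates(np.array([[0.9], [1.1]]), params, t=0.5)
        assert not est.mask.any()

    def test_matches_direct_evaluation(self):
        rng = np.random.default_rng(6)
        y = rng.uniform(0.05, 2.5, size=(3, 2))
        params = ti.GeneMixtureParams(
            lam=np.array([0.3, 0.6]),
            gamma_shape=np.array([1.2, 2.0]),
            gamma_rate=np.array([4.0, 6.0]),
            normal_mean=np.array([1.5, 0.8]),
            normal_sd=np.array([0.3, 0.2]),
            loglik=np.zeros(2),
        )
        est = dropout_rates(y, params, t=0.5)
        for j in range(2):
            g = params.lam[j] * gamma_dist.pdf(
                y[:, j], a=params.gamma_shape[j], scale=1 / params.gamma_rate[j]
            )
            n = (1 - params.lam[j]) * norm_dist.pdf(
                y[:, j], params.normal_mean[j], params.normal_sd[j]
            )
            np.testing.assert_allclose(est.rates[:, j], g / (g + n), rtol=1e-9)
        np.testing.assert_array_equal(est.mask, est.rates >= 0.5)

    def test_rates_strictly_inside_unit_interval(self, bimodal_norm):
        _, norm = bimodal_norm
        em = fit_mixture_em_all(norm.y_lib_log)
        est = dropout_rates(norm.y_lib_log, em)
        assert np.all(est.rates > 0) and np.all(est.rates < 1)

    def test_threshold_domain(self):
        params = ti.GeneMixtureParams(
            lam=np.array([0.5]), gamma_shape=np.array([1.0]), gamma_rate=np.array([1.0]),
            normal_mean=np.array([1.0]), normal_sd=np.array([0.3]), loglik=np.zeros(1),
        )
        with pytest.raises(ValueError):
            dropout_rates(np.array([[1.0]]), params, t=0.0)
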