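"""Per-gene Gamma-Normal dropout mixtures and entry-level dropout probabilities.

On the log scale each gene j is modelled as

    f_j(y) = lambda_j Gamma(y; alpha_j, beta_j) + (1 - lambda_j) Normal(y; mu_j, sigma_j)

with the Gamma component (shape-rate parameterization) absorbing
dropout-suppressed values near log10(1.01) and the Normal component the true
expression bulk.  The posterior probability that entry (i, j) came from the
Gamma component,

    d_ij = lambda_j g(Y_ij) / (lambda_j g(Y_ij) + (1 - lambda_j) n(Y_ij)),

is the dropout rate; entries with d_ij >= t form the dropout mask.

Two fitters are provided: a per-gene EM (the reference) and an amortized
network that maps a fixed-length per-gene summary vector to the five mixture
parameters, trained on the same negative log-likelihood.  The amortized form
transfers across datasets with different cell counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln
from scipy.stats import gamma as gamma_dist, norm as norm_dist

from ._nn import MLP, Adam, sigmoid, softplus

LAM_MIN, LAM_MAX = 1e-3, 1 - 1e-3
# scale floors: values are log10 of (normalized) integer counts, so a component
# narrower than ~0.05 dex claims sub-count precision; flooring both component
# spreads keeps densities finite and the d_ij ranking informative
SD_FLOOR = 0.05
GAMMA_SD_FLOOR = 0.05
DENSITY_FLOOR = 1e-300


@dataclass
class GeneMixtureParams:
    """Estimated (lambda, alpha, beta, mu, sigma) per gene, plus fit diagnostics."""

    lam: np.ndarray
    gamma_shape: np.ndarray
    gamma_rate: np.ndarray
    normal_mean: np.ndarray
    normal_sd: np.ndarray
    loglik: np.ndarray
    degenerate: np.ndarray = None  # bool flags for columns handled by the fallback path

    def __post_init__(self):
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.lam), dtype=bool)

    def gene(self, j: int) -> tuple[float, float, float, float, float]:
        return (
            float(self.lam[j]),
            float(self.gamma_shape[j]),
            float(self.gamma_rate[j]),
            float(self.normal_mean[j]),
            float(self.normal_sd[j]),
        )


@dataclass
class DropoutEstimate:
    rates: np.ndarray  # (I, J) in (0, 1)
    threshold: float
    mask: np.ndarray  # rates >= threshold


def _check_params(lam, shape, rate, sd) -> None:
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda {lam} outside [0, 1]")
    if shape <= 0 or rate <= 0:
        raise ValueError(f"Gamma parameters must be positive (shape={shape}, rate={rate})")
    if sd <= 0:
        raise ValueError(f"normal sd must be positive (sd={sd})")


def mixture_pdf(y, lam: float, shape: float, rate: float, mean: float, sd: float):
    """Density of the two-component mixture at y > 0."""
    _check_params(lam, shape, rate, sd)
    g = gamma_dist.pdf(y, a=shape, scale=1.0 / rate)
    n = norm_dist.pdf(y, loc=mean, scale=sd)
    return lam * g + (1.0 - lam) * n


def gene_loglik(y_col: np.ndarray, lam: float, shape: float, rate: float, mean: float, sd: float) -> float:
    """Sum of log mixture densities over the gene's values in all cells."""
    f = mixture_pdf(np.asarray(y_col, dtype=float), lam, shape, rate, mean, sd)
    return float(np.sum(np.log(np.maximum(f, DENSITY_FLOOR))))


def _weighted_gamma_moments(y, w) -> tuple[float, float]:
    """Responsibility-weighted moment-matching Gamma update: alpha=m^2/v, beta=m/v.

    The variance is floored at GAMMA_SD_FLOOR^2 so a pile-up of identical
    values (the transformed-zero plateau) cannot collapse the component into
    a near-delta, and the mean is kept >= the sd (shape >= 1) so the density
    stays bounded near zero instead of diverging and absorbing the plateau
    regardless of the Normal component's fit.
    """
    wsum = max(w.sum(), 1e-12)
    m = float((w * y).sum() / wsum)
    v = float((w * (y - m) ** 2).sum() / wsum)
    v = max(v, GAMMA_SD_FLOOR**2)
    m = max(m, np.sqrt(v))
    return m * m / v, m / v


def fit_mixture_em(
    y_col: np.ndarray, max_iter: int = 200, tol: float = 1e-6, seed: int = 0
) -> dict:
    """EM fit of the Gamma-Normal mixture to one gene column (all y > 0).

    Initialization splits values at the observed-zero plateau (the minimum of
    the column); lambda and the Normal parameters use exact weighted M-steps,
    the Gamma uses weighted moment matching with a fallback that retains the
    previous Gamma parameters whenever moment matching would lower the
    likelihood, keeping the log-likelihood non-decreasing across iterations.
    """
    y = np.asarray(y_col, dtype=float)
    if np.any(y <= 0):
        raise ValueError("mixture is fit on the log scale where all values are > 0")
    if y.size < 10 or np.allclose(y, y[0]):
        lam = min(max(0.5, 0.01), 0.99)
        shape, rate = _weighted_gamma_moments(y, np.ones_like(y))
        mean, sd = float(y.mean()), max(float(y.std()), SD_FLOOR)
        ll = gene_loglik(y, lam, shape, rate, mean, sd)
        return dict(
            lam=lam, gamma_shape=shape, gamma_rate=rate, normal_mean=mean,
            normal_sd=sd, loglik=ll, degenerate=True, loglik_trace=[ll],
        )

    # start from the zero plateau when one exists, else split at the median
    low = y <= (y.min() + 1e-9)
    if low.all() or low.mean() < 0.05:
        low = y <= np.median(y)
        if low.all():
            low = y < np.median(y)
    lam = float(np.clip(low.mean(), 0.1, 0.9))
    shape, rate = _weighted_gamma_moments(y, low.astype(float))
    mean = float(y[~low].mean())
    sd = max(float(y[~low].std()), SD_FLOOR)

    ll = gene_loglik(y, lam, shape, rate, mean, sd)
    trace = [ll]
    for _ in range(max_iter):
        g = lam * gamma_dist.pdf(y, a=shape, scale=1.0 / rate)
        n = (1.0 - lam) * norm_dist.pdf(y, loc=mean, scale=sd)
        denom = np.maximum(g + n, DENSITY_FLOOR)
        r = g / denom

        lam_new = float(np.clip(r.mean(), LAM_MIN, LAM_MAX))
        w_n = 1.0 - r
        wsum = max(w_n.sum(), 1e-12)
        mean_new = float((w_n * y).sum() / wsum)
        sd_new = max(float(np.sqrt((w_n * (y - mean_new) ** 2).sum() / wsum)), SD_FLOOR)
        shape_new, rate_new = _weighted_gamma_moments(y, r)

        ll_new = gene_loglik(y, lam_new, shape_new, rate_new, mean_new, sd_new)
        if ll_new < ll - 1e-10:
            # moment matching overshot: keep the previous Gamma, redo exact steps
            ll_partial = gene_loglik(y, lam_new, shape, rate, mean_new, sd_new)
            if ll_partial >= ll - 1e-10:
                shape_new, rate_new, ll_new = shape, rate, ll_partial
            else:
                trace.append(ll)
                break
        lam, shape, rate, mean, sd = lam_new, shape_new, rate_new, mean_new, sd_new
        trace.append(ll_new)
        if abs(ll_new - ll) < tol:
            ll = ll_new
            break
        ll = ll_new

    # parsimony guard: when a single Normal explains the column essentially as
    # well as the mixture (BIC on the 3 extra parameters), the dropout
    # component is spurious and lambda collapses to its floor
    mean0 = float(y.mean())
    sd0 = max(float(y.std()), SD_FLOOR)
    ll0 = float(np.sum(np.log(np.maximum(norm_dist.pdf(y, loc=mean0, scale=sd0), DENSITY_FLOOR))))
    if ll - ll0 < 1.5 * np.log(y.size) and ll0 >= trace[0]:
        lam, mean, sd = LAM_MIN, mean0, sd0
        ll = gene_loglik(y, lam, shape, rate, mean, sd)

    return dict(
        lam=lam, gamma_shape=shape, gamma_rate=rate, normal_mean=mean,
        normal_sd=sd, loglik=ll, degenerate=False, loglik_trace=trace,
    )


def fit_mixture_em_all(y_log: np.ndarray, max_iter: int = 200, tol: float = 1e-6) -> GeneMixtureParams:
    """Column-wise EM over a full matrix; the reference fitter."""
    fits = [fit_mixture_em(y_log[:, j], max_iter=max_iter, tol=tol) for j in range(y_log.shape[1])]
    return GeneMixtureParams(
        lam=np.array([f["lam"] for f in fits]),
        gamma_shape=np.array([f["gamma_shape"] for f in fits]),
        gamma_rate=np.array([f["gamma_rate"] for f in fits]),
        normal_mean=np.array([f["normal_mean"] for f in fits]),
        normal_sd=np.array([f["normal_sd"] for f in fits]),
        loglik=np.array([f["loglik"] for f in fits]),
        degenerate=np.array([f["degenerate"] for f in fits]),
    )


@dataclass
class MixtureNetConfig:
    hidden_size: int = 32
    learning_rate: float = 1e-2
    epochs: int = 400
    seed: int = 0


N_FEATURES = 13  # mean, var, zero-fraction, 9 inner deciles, log10(n_cells)


def gene_summaries(y_log: np.ndarray) -> np.ndarray:
    """Fixed-length per-gene summary vector; input of the amortized network."""
    n_cells = y_log.shape[0]
    zero_level = y_log.min()
    deciles = np.percentile(y_log, np.arange(10, 100, 10), axis=0).T  # (J, 9)
    feats = np.column_stack(
        [
            y_log.mean(axis=0),
            y_log.var(axis=0),
            (y_log <= zero_level + 1e-9).mean(axis=0),
            deciles,
            np.full(y_log.shape[1], np.log10(n_cells)),
        ]
    )
    return feats


class MixtureNet:
    """Amortized mapper: per-gene summary vector -> (lambda, alpha, beta, mu, sigma).

    The network emits five raw values per gene; link functions keep every
    parameter in its domain: sigmoid for lambda, identity for the Normal
    mean, softplus floors for the scales.  The Gamma component is
    parameterized by its mean and standard deviation (sd floored at
    GAMMA_SD_FLOOR, mirroring the EM fitter's guard) and converted to
    shape/rate, so the fitted dropout component can never sharpen into a
    delta at the transformed-zero plateau.
    """

    def __init__(self, config: MixtureNetConfig | None = None):
        self.config = config or MixtureNetConfig()
        rng = np.random.default_rng(self.config.seed)
        h = self.config.hidden_size
        self.mlp = MLP([N_FEATURES, h, h, 5], rng)
        out_bias = self.mlp.layers[-1].b
        # start near lambda 0.3, Gamma mean 0.3 / sd 0.2, Normal mean 0 / sd 0.3
        out_bias[:] = [-0.85, -2.25, -1.82, 0.0, -1.26]
        self.feat_mean = np.zeros(N_FEATURES)
        self.feat_std = np.ones(N_FEATURES)

    def _standardize(self, feats: np.ndarray) -> np.ndarray:
        return (feats - self.feat_mean) / self.feat_std

    def _raw_to_params(self, raw: np.ndarray, gene_means: np.ndarray):
        lam = np.clip(sigmoid(raw[:, 0]), LAM_MIN, LAM_MAX)
        gs = softplus(raw[:, 2]) + GAMMA_SD_FLOOR  # Gamma sd
        gm = gs + softplus(raw[:, 1])  # Gamma mean >= sd, i.e. shape >= 1
        shape = gm**2 / gs**2
        rate = gm / gs**2
        # the Normal head predicts a residual from the empirical gene mean,
        # anchoring the Normal on the expression bulk from the first step so
        # the two components cannot swap roles during optimization
        mean = raw[:, 3] + gene_means
        sd = softplus(raw[:, 4]) + SD_FLOOR
        return lam, shape, rate, mean, sd

    def predict(self, y_log: np.ndarray) -> GeneMixtureParams:
        feats_raw = gene_summaries(y_log)
        raw = self.mlp.forward(self._standardize(feats_raw))
        lam, shape, rate, mean, sd = self._raw_to_params(raw, feats_raw[:, 0])
        ll = _matrix_loglik_per_gene(y_log, lam, shape, rate, mean, sd)
        return GeneMixtureParams(lam, shape, rate, mean, sd, ll)

    def fit(self, y_log: np.ndarray) -> GeneMixtureParams:
        """Minimize sum_j -gene_loglik(j) over the network weights."""
        y = np.asarray(y_log, dtype=float)
        n_cells, n_genes = y.shape
        feats_raw = gene_summaries(y)
        self.feat_mean = feats_raw.mean(axis=0)
        self.feat_std = np.maximum(feats_raw.std(axis=0), 1e-8)
        feats = self._standardize(feats_raw)

        const = y.std(axis=0) < 1e-12
        train_cols = ~const
        opt = Adam(lr=self.config.learning_rate)
        scale = 1.0 / (n_cells * max(train_cols.sum(), 1))

        for epoch in range(self.config.epochs):
            raw = self.mlp.forward(feats)
            lam, shape, rate, mean, sd = self._raw_to_params(raw, feats_raw[:, 0])

            log_g = _gamma_logpdf(y, shape, rate)
            log_n = _normal_logpdf(y, mean, sd)
            a = np.log(lam) + log_g
            b = np.log1p(-lam) + log_n
            m = np.maximum(a, b)
            log_f = m + np.log(np.exp(a - m) + np.exp(b - m))
            loss = -np.sum(log_f[:, train_cols]) * scale / 1.0
            if not np.isfinite(loss):
                bad = int(np.argwhere(~np.isfinite(log_f).all(axis=0))[0])
                raise FloatingPointError(f"non-finite mixture loss at gene {bad}, epoch {epoch}")

            r = np.exp(a - log_f)  # responsibility of the Gamma component, (I, J)
            # tempering: early in training neither component may monopolize a
            # point, so the Normal cannot be starved of gradient and banished
            # from the data range before the heads differentiate per gene
            eps = 0.25 * max(0.0, 1.0 - 2.0 * epoch / self.config.epochs)
            if eps > 0.0:
                r = np.clip(r, eps, 1.0 - eps)
            one_r = 1.0 - r
            # d(-log f)/d(param_j), summed over cells
            d_lam = -(r / lam - one_r / (1.0 - lam)).sum(axis=0)
            d_shape = -(r * (np.log(rate) + np.log(y) - digamma(shape))).sum(axis=0)
            d_rate = -(r * (shape / rate - y)).sum(axis=0)
            d_mean = -(one_r * (y - mean) / sd**2).sum(axis=0)
            d_sd = -(one_r * ((y - mean) ** 2 / sd**3 - 1.0 / sd)).sum(axis=0)

            gs = softplus(raw[:, 2]) + GAMMA_SD_FLOOR
            gm = gs + softplus(raw[:, 1])
            d_gm = d_shape * 2.0 * gm / gs**2 + d_rate / gs**2
            d_gs = -(d_shape * 2.0 * gm**2 + d_rate * 2.0 * gm) / gs**3
            grad = np.zeros((n_genes, 5))
            grad[:, 0] = d_lam * lam * (1.0 - lam)
            grad[:, 1] = d_gm * sigmoid(raw[:, 1])
            grad[:, 2] = (d_gm + d_gs) * sigmoid(raw[:, 2])  # gm rides on gs
            grad[:, 3] = d_mean
            grad[:, 4] = d_sd * sigmoid(raw[:, 4])
            grad[const] = 0.0
            grad *= scale

            self.mlp.backward(grad)
            opt.step(self.mlp.params)

        params = self.predict(y)
        params.degenerate = const
        if const.any():
            # constant columns: spike Gamma at the value, floored Normal
            for j in np.where(const)[0]:
                shape_j, rate_j = _weighted_gamma_moments(y[:, j], np.ones(n_cells))
                params.lam[j] = 0.5
                params.gamma_shape[j] = shape_j
                params.gamma_rate[j] = rate_j
                params.normal_mean[j] = y[:, j].mean()
                params.normal_sd[j] = SD_FLOOR
                params.loglik[j] = gene_loglik(y[:, j], *params.gene(j))
        return params

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {"feat_mean": self.feat_mean, "feat_std": self.feat_std}
        dense = [l for l in self.mlp.layers if hasattr(l, "W")]
        for k, layer in enumerate(dense):
            arrays[f"mix_W{k}"] = layer.W
            arrays[f"mix_b{k}"] = layer.b
        return arrays

    def load_arrays(self, arrays) -> None:
        self.feat_mean = np.asarray(arrays["feat_mean"], dtype=float)
        self.feat_std = np.asarray(arrays["feat_std"], dtype=float)
        dense = [l for l in self.mlp.layers if hasattr(l, "W")]
        for k, layer in enumerate(dense):
            layer.W = np.asarray(arrays[f"mix_W{k}"], dtype=float)
            layer.b = np.asarray(arrays[f"mix_b{k}"], dtype=float)


def fit_mixture_net(y_log: np.ndarray, config: MixtureNetConfig | None = None):
    """Train the amortized mixture network; returns (GeneMixtureParams, MixtureNet)."""
    net = MixtureNet(config)
    params = net.fit(np.asarray(y_log, dtype=float))
    return params, net


def _gamma_logpdf(y, shape, rate):
    return shape * np.log(rate) + (shape - 1.0) * np.log(y) - rate * y - gammaln(shape)


def _normal_logpdf(y, mean, sd):
    return -0.5 * ((y - mean) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2.0 * np.pi)


def _matrix_loglik_per_gene(y, lam, shape, rate, mean, sd):
    a = np.log(lam) + _gamma_logpdf(y, shape, rate)
    b = np.log1p(-lam) + _normal_logpdf(y, mean, sd)
    m = np.maximum(a, b)
    return (m + np.log(np.exp(a - m) + np.exp(b - m))).sum(axis=0)


def dropout_rates(y_log: np.ndarray, params: GeneMixtureParams, t: float = 0.5) -> DropoutEstimate:
    """Per-entry dropout probabilities d_ij and the thresholded mask.

    Computed in log space: d = sigmoid(log(lam g) - log((1-lam) n)), which
    preserves the ranking of entries even where one component underflows.
    Entries where both component densities vanish fall back to d = lambda_j.
    """
    if not 0.0 < t < 1.0:
        raise ValueError("threshold t must lie in (0, 1)")
    y = np.asarray(y_log, dtype=float)
    lam, shape, rate, mean, sd = (
        params.lam, params.gamma_shape, params.gamma_rate, params.normal_mean, params.normal_sd
    )
    log_g = np.log(lam) + _gamma_logpdf(y, shape, rate)
    log_n = np.log1p(-lam) + _normal_logpdf(y, mean, sd)
    both_tiny = (log_g < np.log(DENSITY_FLOOR)) & (log_n < np.log(DENSITY_FLOOR))
    d = sigmoid(log_g - log_n)
    d = np.clip(d, 1e-15, 1.0 - 1e-15)
    if both_tiny.any():
        d = np.where(both_tiny, np.broadcast_to(lam, d.shape), d)
    return DropoutEstimate(rates=d, threshold=float(t), mask=d >= t)


def write_mixture_report(params: GeneMixtureParams, gene_ids: list[str], path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "gene_id": gene_ids,
            "lam": params.lam,
            "gamma_shape": params.gamma_shape,
            "gamma_rate": params.gamma_rate,
            "normal_mean": params.normal_mean,
            "normal_sd": params.normal_sd,
            "loglik": params.loglik,
        }
    ).to_csv(path, sep="\t", index=False)
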