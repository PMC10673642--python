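"""Amortized variational inference of logistic-normal cell-topic mixtures.

Each cell c carries a latent Gaussian vector delta_c ~ N(0, I) whose softmax
theta_c = softmax(delta_c) is its mixture over N topics; a topic k is a
probability distribution beta_k over genes, so a cell's expression profile is
the categorical mixture p(gene j | c) = sum_k theta_ck beta_kj.  A two-layer
feed-forward encoder maps the cell-normalized profile Y^C_c to the variational
posterior parameters (mu_c, log sigma_c^2); training maximizes the ELBO

    E_q[log p(Y | theta)] - KL[q(delta | Y) || N(0, I)]

by stochastic gradient ascent with the reparameterization trick (one Monte
Carlo sample per cell per step) and a linear KL warm-up over the first third
of the epochs.  Downstream consumers use the deterministic point estimate
theta = softmax(mu).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import Adam, Dense, ReLU, softmax, softmax_backward
from .data_io import NormalizedData

SCHEMA_VERSION = 1


@dataclass
class TopicModelConfig:
    n_topics: int = 50
    hidden_size: int = 128
    learning_rate: float = 1e-2
    epochs: int = 300
    batch_size: int = 64
    seed: int = 0
    kl_weight: float = 1.0  # warm-up endpoint
    n_restarts: int = 3  # independent fits; the one with the best final ELBO wins

    def __post_init__(self) -> None:
        if self.n_topics < 2:
            raise ValueError("n_topics must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.kl_weight <= 1.0:
            raise ValueError("kl_weight must lie in [0, 1]")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


class _Encoder:
    """Two hidden ReLU layers then linear heads for mu and log sigma^2."""

    def __init__(self, n_genes: int, hidden: int, n_topics: int, rng: np.random.Generator):
        self.trunk = [Dense(n_genes, hidden, rng), ReLU(), Dense(hidden, hidden, rng), ReLU()]
        self.mu_head = Dense(hidden, n_topics, rng, scale=1e-2)
        self.lv_head = Dense(hidden, n_topics, rng, scale=1e-2)

    def forward(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = y
        for layer in self.trunk:
            h = layer.forward(h)
        return self.mu_head.forward(h), self.lv_head.forward(h)

    def backward(self, g_mu: np.ndarray, g_lv: np.ndarray) -> None:
        g = self.mu_head.backward(g_mu) + self.lv_head.backward(g_lv)
        for layer in reversed(self.trunk):
            g = layer.backward(g)

    @property
    def params(self):
        out = []
        for layer in self.trunk:
            if isinstance(layer, Dense):
                out.extend(layer.params)
        out.extend(self.mu_head.params)
        out.extend(self.lv_head.params)
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {}
        dense = [l for l in self.trunk if isinstance(l, Dense)] + [self.mu_head, self.lv_head]
        for k, layer in enumerate(dense):
            arrays[f"W{k}"] = layer.W
            arrays[f"b{k}"] = layer.b
        return arrays

    def load_arrays(self, arrays) -> None:
        dense = [l for l in self.trunk if isinstance(l, Dense)] + [self.mu_head, self.lv_head]
        for k, layer in enumerate(dense):
            layer.W = np.asarray(arrays[f"W{k}"], dtype=float)
            layer.b = np.asarray(arrays[f"b{k}"], dtype=float)


@dataclass
class TopicModelState:
    encoder: _Encoder
    beta_logits: np.ndarray  # (N, J); topic_gene = softmax over genes
    gene_ids: list[str]
    config: TopicModelConfig
    training_log: list[float] = field(default_factory=list)

    @property
    def topic_gene(self) -> np.ndarray:
        return softmax(self.beta_logits, axis=1)


@dataclass
class TopicPosterior:
    mu: np.ndarray
    log_var: np.ndarray
    theta: np.ndarray


def encode(y_cell_rows: np.ndarray, state: TopicModelState) -> tuple[np.ndarray, np.ndarray]:
    """Map cell-normalized profiles to variational (mu, log sigma^2)."""
    y = np.atleast_2d(np.asarray(y_cell_rows, dtype=float))
    if y.shape[1] != len(state.gene_ids):
        raise ValueError(f"expected {len(state.gene_ids)} genes, got {y.shape[1]}")
    return state.encoder.forward(y)


def reparameterize_theta(
    mu: np.ndarray, log_var: np.ndarray, n_samples: int = 1, rng_seed: int = 0
) -> np.ndarray:
    """Draw theta = softmax(mu + sigma * eps) samples; shape (n_samples, N)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(rng_seed)
    mu = np.asarray(mu, dtype=float)
    sigma = np.exp(0.5 * np.asarray(log_var, dtype=float))
    eps = rng.standard_normal((n_samples,) + mu.shape)
    return softmax(mu + sigma * eps, axis=-1)


def reconstruction_loglik(y_cell_row: np.ndarray, theta: np.ndarray, topic_gene: np.ndarray) -> float:
    """sum_j y_j log(sum_k theta_k beta_kj) — the ELBO's data term for one cell."""
    theta = np.asarray(theta, dtype=float)
    if not np.isclose(theta.sum(), 1.0, atol=1e-6) or np.any(theta < 0):
        raise ValueError("theta must be a probability vector")
    p = theta @ topic_gene
    y = np.asarray(y_cell_row, dtype=float)
    return float(np.sum(y * np.log(np.maximum(p, 1e-300)), where=y > 0))


def kl_to_standard_normal(mu: np.ndarray, log_var: np.ndarray) -> float:
    """KL(N(mu, diag(sigma^2)) || N(0, I)) = 0.5 sum(mu^2 + sigma^2 - log sigma^2 - 1)."""
    mu = np.asarray(mu, dtype=float)
    log_var = np.asarray(log_var, dtype=float)
    return float(0.5 * np.sum(mu**2 + np.exp(log_var) - log_var - 1.0))


def _full_elbo(y: np.ndarray, w: np.ndarray, state: TopicModelState) -> float:
    """Deterministic per-cell mean ELBO at theta = softmax(mu); used for the epoch log."""
    mu, lv = state.encoder.forward(y)
    theta = softmax(mu, axis=1)
    p = np.maximum(theta @ state.topic_gene, 1e-300)
    recon = np.sum(w * np.log(p))
    kl = 0.5 * np.sum(mu**2 + np.exp(lv) - lv - 1.0)
    return float((recon - kl) / y.shape[0])


def train(
    normalized: NormalizedData, config: TopicModelConfig
) -> tuple[TopicModelState, TopicPosterior]:
    """Fit encoder and topic-gene matrix by minibatch ELBO ascent.

    The encoder reads the cell-normalized profiles Y^C; the multinomial data
    term is weighted by each cell's observed counts (profile times library
    size), the bag-of-genes convention that keeps the reconstruction term on
    the count scale and the KL regularizer from collapsing the posterior.

    ``config.n_restarts`` independent fits are run from different
    initializations (all derived from ``config.seed``) and the one ending at
    the highest ELBO is kept — runs that merge topics land hundreds of nats
    below well-separated solutions, so the selection is unambiguous.
    """
    best: TopicModelState | None = None
    for restart in range(config.n_restarts):
        state = _train_once(normalized, config, restart)
        if best is None or state.training_log[-1] > best.training_log[-1]:
            best = state
    return best, infer_theta(normalized, best)


def _train_once(
    normalized: NormalizedData, config: TopicModelConfig, restart: int
) -> TopicModelState:
    y = np.asarray(normalized.y_cell, dtype=float)
    n_cells, n_genes = y.shape
    if normalized.library_sizes is not None:
        row = np.maximum(y.sum(axis=1, keepdims=True), 1e-12)
        w = y * (np.asarray(normalized.library_sizes, dtype=float)[:, None] / row)
    else:
        w = y
    root = np.random.SeedSequence([config.seed, restart])
    init_rng, shuffle_rng, noise_rng = (np.random.default_rng(s) for s in root.spawn(3))

    enc = _Encoder(n_genes, config.hidden_size, config.n_topics, init_rng)
    beta_logits = init_rng.normal(0.0, 0.1, size=(config.n_topics, n_genes))
    g_beta_logits = np.zeros_like(beta_logits)
    state = TopicModelState(enc, beta_logits, list(normalized.gene_ids), config)

    opt = Adam(lr=config.learning_rate)
    batch = min(config.batch_size, n_cells)
    warmup = max(1, config.epochs // 3)

    for epoch in range(config.epochs):
        klw = config.kl_weight * min(1.0, (epoch + 1) / warmup)
        order = shuffle_rng.permutation(n_cells)
        for start in range(0, n_cells, batch):
            idx = order[start : start + batch]
            yb = y[idx]
            wb = w[idx]
            b = len(idx)

            mu, lv = enc.forward(yb)
            sigma = np.exp(0.5 * lv)
            eps = noise_rng.standard_normal(mu.shape)
            delta = mu + sigma * eps
            theta = softmax(delta, axis=1)
            beta = softmax(beta_logits, axis=1)
            p = np.maximum(theta @ beta, 1e-300)

            # minimize mean(-count-weighted recon + w * KL)
            gp = -(wb / p) / b
            g_theta = gp @ beta.T
            g_beta = theta.T @ gp
            g_delta = softmax_backward(theta, g_theta, axis=1)
            g_mu = g_delta + klw * mu / b
            g_lv = g_delta * 0.5 * sigma * eps + klw * 0.5 * (np.exp(lv) - 1.0) / b
            enc.backward(g_mu, g_lv)
            g_beta_logits[:] = softmax_backward(beta, g_beta, axis=1)

            params = enc.params + [(beta_logits, g_beta_logits)]
            opt.step(params)

        elbo = _full_elbo(y, w, state)
        if not np.isfinite(elbo):
            raise FloatingPointError(f"non-finite ELBO at epoch {epoch}")
        state.training_log.append(elbo)

    return state


def infer_theta(normalized: NormalizedData, state: TopicModelState) -> TopicPosterior:
    """Deterministic posterior: theta = softmax(mu), no sampling, no updates."""
    y = np.asarray(normalized.y_cell, dtype=float)
    if y.shape[1] != len(state.gene_ids):
        raise ValueError(
            f"gene dimension {y.shape[1]} != model's {len(state.gene_ids)}; "
            "align genes first (transfer.align_genes)"
        )
    mu, lv = state.encoder.forward(y)
    return TopicPosterior(mu=mu, log_var=lv, theta=softmax(mu, axis=1))


def save_model(state: TopicModelState, model_dir: str) -> None:
    os.makedirs(model_dir, exist_ok=True)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "gene_ids": state.gene_ids,
        "config": asdict(state.config),
        "training_log": state.training_log,
    }
    with open(os.path.join(model_dir, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    arrays = dict(state.encoder.state_arrays())
    arrays["beta_logits"] = state.beta_logits
    np.savez(os.path.join(model_dir, "weights.npz"), **arrays)


def load_model(model_dir: str) -> TopicModelState:
    meta_path = os.path.join(model_dir, "meta.json")
    try:
        with open(meta_path) as fh:
            meta = json.load(fh)
    except OSError as e:
        raise IOError(f"cannot read model metadata: {e}") from e
    for key in ("schema_version", "gene_ids", "config"):
        if key not in meta:
            raise ValueError(f"model metadata missing field {key!r}")
    if meta["schema_version"] != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {meta['schema_version']}")
    config = TopicModelConfig(**meta["config"])
    gene_ids = list(meta["gene_ids"])
    rng = np.random.default_rng(0)
    enc = _Encoder(len(gene_ids), config.hidden_size, config.n_topics, rng)
    with np.load(os.path.join(model_dir, "weights.npz")) as arrays:
        enc.load_arrays(arrays)
        beta_logits = np.asarray(arrays["beta_logits"], dtype=float)
    state = TopicModelState(enc, beta_logits, gene_ids, config, list(meta.get("training_log", [])))
    return state
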