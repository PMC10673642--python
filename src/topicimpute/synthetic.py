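"""Topic-structured scRNA-seq simulator with ground-truth dropout masks.

Cells are drawn from a logistic-normal topic mixture: each topic k has a gene
distribution beta_k ~ Dirichlet(concentration) (small concentration gives
well-separated, sparse topics); each cell gets a dominant topic, logits
delta ~ Normal(topic-mean logits, sd), theta = softmax(delta), and counts
~ Multinomial(library size, theta beta) with lognormal library sizes.

Dropout is then injected per gene: lambda_j is drawn uniformly from a
configured range and each positive entry is zeroed independently with
probability lambda_j * exp(-count / decay) — low counts are the most likely
to drop, which is what makes separating injected zeros from biological zeros
nontrivial.  Every zeroed entry is recorded in a Boolean mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr, spearmanr

from .data_io import CountMatrix

DOMINANT_LOGIT = 3.0  # mean logit advantage of a cell's dominant topic


@dataclass
class SimulationConfig:
    n_cells: int = 300
    n_genes: int = 500
    n_topics: int = 3
    topic_concentration: float = 0.05
    theta_logit_sd: float = 0.5
    library_size_log_mean: float = float(np.log(2000.0))
    library_size_log_sd: float = 0.3
    dropout_lambda_range: tuple[float, float] = (0.2, 0.5)
    dropout_decay: float | None = 5.0  # None: drop positives uniformly at rate lambda_j
    seed: int = 0
    # when set, the topic-gene matrix beta is drawn from this seed instead of
    # `seed`, so two datasets can share their biology (same expression
    # programs) while drawing independent cells — the transfer-learning setting
    structure_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_topics > self.n_genes:
            raise ValueError("n_topics cannot exceed n_genes")
        lo, hi = self.dropout_lambda_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("dropout_lambda_range must lie within [0, 1)")


@dataclass
class SimulatedDataset:
    true_counts: CountMatrix
    observed_counts: CountMatrix
    dropout_mask: np.ndarray  # True where an entry was zeroed by injection
    true_theta: np.ndarray
    true_beta: np.ndarray
    true_lambda: np.ndarray
    labels: np.ndarray  # dominant-topic label per cell
    library_sizes: np.ndarray = None
    config: SimulationConfig = None


def simulate(config: SimulationConfig) -> SimulatedDataset:
    rng = np.random.default_rng(config.seed)
    n, j, k = config.n_cells, config.n_genes, config.n_topics

    structure_rng = (
        rng if config.structure_seed is None else np.random.default_rng(config.structure_seed)
    )
    beta = structure_rng.dirichlet(np.full(j, config.topic_concentration), size=k)
    dominant = rng.integers(0, k, size=n)
    mean_logits = np.zeros((n, k))
    mean_logits[np.arange(n), dominant] = DOMINANT_LOGIT
    delta = mean_logits + rng.normal(0.0, config.theta_logit_sd, size=(n, k))
    theta = np.exp(delta - delta.max(axis=1, keepdims=True))
    theta /= theta.sum(axis=1, keepdims=True)

    libs = np.maximum(
        rng.lognormal(config.library_size_log_mean, config.library_size_log_sd, size=n), 1.0
    ).astype(int)
    probs = theta @ beta
    true = np.empty((n, j))
    for i in range(n):
        true[i] = rng.multinomial(libs[i], probs[i])

    lo, hi = config.dropout_lambda_range
    lam = rng.uniform(lo, hi, size=j)
    if config.dropout_decay is None:
        p_drop = np.broadcast_to(lam[None, :], true.shape)
    else:
        p_drop = lam[None, :] * np.exp(-true / config.dropout_decay)
    mask = (true > 0) & (rng.random(size=true.shape) < p_drop)
    observed = np.where(mask, 0.0, true)

    cells = [f"cell_{i}" for i in range(n)]
    genes = [f"gene_{g}" for g in range(j)]
    labels = np.argmax(theta, axis=1)
    return SimulatedDataset(
        true_counts=CountMatrix(true, cells, genes),
        observed_counts=CountMatrix(observed, cells, genes),
        dropout_mask=mask,
        true_theta=theta,
        true_beta=beta,
        true_lambda=lam,
        labels=labels,
        library_sizes=libs,
        config=config,
    )


@dataclass
class BimodalSimConfig:
    """Per-gene mixture-world fixture for dropout-detection studies.

    Genes come in two classes.  Expressed genes have log10 counts drawn from
    a tight Normal with mean >= 1.5 (high expression, low variation) — their
    observed zeros can only be technical dropouts.  Sparse genes have
    low-rate Poisson counts — their zeros are overwhelmingly biological.
    Dropout is injected per gene with probability lambda_j on positive
    entries, and every injected zero is recorded, so a detector's ability to
    separate the two kinds of zeros can be scored exactly.
    """

    n_cells: int = 300
    n_genes: int = 500
    expressed_fraction: float = 0.6
    expressed_log_mean_range: tuple[float, float] = (1.5, 2.5)
    expressed_log_sd_range: tuple[float, float] = (0.15, 0.35)
    sparse_rate_range: tuple[float, float] = (0.05, 0.5)
    dropout_lambda_range: tuple[float, float] = (0.2, 0.5)
    seed: int = 0


def simulate_bimodal(config: BimodalSimConfig) -> SimulatedDataset:
    """Draw the two-class gene world described by BimodalSimConfig."""
    rng = np.random.default_rng(config.seed)
    n, j = config.n_cells, config.n_genes
    expressed = rng.random(j) < config.expressed_fraction

    true = np.zeros((n, j))
    lo, hi = config.expressed_log_mean_range
    mu = rng.uniform(lo, hi, size=j)
    sd = rng.uniform(*config.expressed_log_sd_range, size=j)
    rate = rng.uniform(*config.sparse_rate_range, size=j)
    for g in range(j):
        if expressed[g]:
            true[:, g] = np.round(10 ** rng.normal(mu[g], sd[g], size=n))
        else:
            true[:, g] = rng.poisson(rate[g], size=n)

    lam = rng.uniform(*config.dropout_lambda_range, size=j)
    mask = (true > 0) & (rng.random(size=true.shape) < lam[None, :])
    observed = np.where(mask, 0.0, true)

    cells = [f"cell_{i}" for i in range(n)]
    genes = [f"gene_{g}" for g in range(j)]
    return SimulatedDataset(
        true_counts=CountMatrix(true, cells, genes),
        observed_counts=CountMatrix(observed, cells, genes),
        dropout_mask=mask,
        true_theta=np.ones((n, 1)),
        true_beta=np.ones((1, j)) / j,
        true_lambda=lam,
        labels=np.zeros(n, dtype=int),
        library_sizes=true.sum(axis=1).astype(int),
        config=None,
    )


def restrict_to_genes(sim: SimulatedDataset, gene_ids: list[str]) -> SimulatedDataset:
    """Subset a SimulatedDataset to the given genes (e.g. the post-QC survivors)."""
    pos = {g: i for i, g in enumerate(sim.observed_counts.gene_ids)}
    keep = [pos[g] for g in gene_ids]
    cells = sim.observed_counts.cell_ids
    return SimulatedDataset(
        true_counts=CountMatrix(sim.true_counts.values[:, keep], cells, list(gene_ids)),
        observed_counts=CountMatrix(sim.observed_counts.values[:, keep], cells, list(gene_ids)),
        dropout_mask=sim.dropout_mask[:, keep],
        true_theta=sim.true_theta,
        true_beta=sim.true_beta[:, keep],
        true_lambda=sim.true_lambda[keep],
        labels=sim.labels,
        library_sizes=sim.library_sizes,
        config=sim.config,
    )


def _masked_correlations(imputed_values: np.ndarray, sim: SimulatedDataset):
    """Per-gene and global Pearson/Spearman between imputed and true values on the mask."""
    mask = sim.dropout_mask
    truth = sim.true_counts.values
    per_gene = []
    for g in range(mask.shape[1]):
        m = mask[:, g]
        if m.sum() < 3:
            continue
        t, v = truth[m, g], imputed_values[m, g]
        if np.std(t) == 0 or np.std(v) == 0:
            per_gene.append(0.0)
            continue
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = pearsonr(t, v)[0]
        per_gene.append(float(r) if np.isfinite(r) else 0.0)
    t_all, v_all = truth[mask], imputed_values[mask]
    if t_all.size >= 3 and np.std(t_all) > 0 and np.std(v_all) > 0:
        global_pearson = float(pearsonr(t_all, v_all)[0])
        global_spearman = float(spearmanr(t_all, v_all)[0])
    else:
        global_pearson = global_spearman = 0.0
    return per_gene, global_pearson, global_spearman


def score_against_truth(imputed, sim: SimulatedDataset, dropout=None) -> dict:
    """Score an ImputedMatrix (or raw matrix) against the simulator's ground truth.

    Reports per-gene and global correlations on masked entries, the
    zeros-left-in-place baseline, and — when a DropoutEstimate is supplied —
    the ROC AUC of d_ij for separating injected-dropout zeros from biological
    zeros among observed zero entries.
    """
    values = imputed.values if hasattr(imputed, "values") else np.asarray(imputed, dtype=float)
    if values.shape != sim.dropout_mask.shape:
        raise ValueError("imputed matrix shape does not match the simulation")
    if not sim.dropout_mask.any():
        return {"note": "nothing to score: empty dropout mask"}

    per_gene, global_pearson, global_spearman = _masked_correlations(values, sim)
    baseline_per_gene, baseline_global, _ = _masked_correlations(
        sim.observed_counts.values, sim
    )
    report = {
        "median_per_gene_pearson": float(np.median(per_gene)) if per_gene else 0.0,
        "global_pearson": global_pearson,
        "global_spearman": global_spearman,
        "baseline_median_per_gene_pearson": (
            float(np.median(baseline_per_gene)) if baseline_per_gene else 0.0
        ),
        "baseline_global_pearson": baseline_global,
        "n_masked": int(sim.dropout_mask.sum()),
        "n_genes_scored": len(per_gene),
    }
    if dropout is not None:
        report["dropout_auc"] = dropout_detection_auc(dropout, sim)
    return report


def dropout_detection_auc(dropout, sim: SimulatedDataset) -> float:
    """ROC AUC of d_ij separating injected zeros from biological zeros."""
    from sklearn.metrics import roc_auc_score

    zeros = sim.observed_counts.values == 0
    labels = sim.dropout_mask[zeros].astype(int)
    if labels.min() == labels.max():
        return float("nan")
    return float(roc_auc_score(labels, dropout.rates[zeros]))
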