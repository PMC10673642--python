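"""Apply a trained model to an unseen dataset.

The encoder and the amortized mixture network are trained once on a source
dataset and frozen; a target dataset is aligned to the model's gene
vocabulary (shared genes reordered, model genes missing from the target
zero-filled, extra target genes dropped), theta is inferred with the frozen
encoder, mixture parameters come from the frozen amortized network (or a
per-gene EM refit on the target), and imputation proceeds as usual.  No
weights are updated on the target.

Dataset-level diagnostics (mean / variance / sd and a binned empirical value
distribution with a total-variation distance) help judge how far the target
strays from the training data.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .data_io import CountMatrix
from .dropout_mixture import MixtureNet
from .imputation import PipelineConfig, PipelineResult, impute_pipeline
from .topic_model import TopicModelState, load_model, save_model

logger = logging.getLogger(__name__)


@dataclass
class GeneAlignment:
    shared: list[str]
    missing: list[str]  # model genes absent from the target (zero-filled)
    dropped: list[str]  # target genes absent from the model
    mapping: dict[int, int]  # target column -> model column


def align_genes(
    target: CountMatrix, state: TopicModelState, case_insensitive: bool = False
) -> tuple[GeneAlignment, CountMatrix]:
    """Reorder target columns to the model's gene order, zero-filling gaps."""
    key = (lambda g: g.upper()) if case_insensitive else (lambda g: g)
    target_pos = {key(g): idx for idx, g in enumerate(target.gene_ids)}
    model_genes = state.gene_ids

    shared, missing = [], []
    mapping: dict[int, int] = {}
    aligned = np.zeros((target.n_cells, len(model_genes)))
    for m_idx, g in enumerate(model_genes):
        t_idx = target_pos.get(key(g))
        if t_idx is None:
            missing.append(g)
        else:
            shared.append(g)
            mapping[t_idx] = m_idx
            aligned[:, m_idx] = target.values[:, t_idx]
    if not shared:
        raise ValueError(
            "no shared genes between target and model; try case_insensitive=True "
            "or map orthologs upstream"
        )
    dropped = [g for idx, g in enumerate(target.gene_ids) if idx not in mapping]
    logger.info(
        "gene alignment: %d shared, %d zero-filled, %d dropped",
        len(shared), len(missing), len(dropped),
    )
    alignment = GeneAlignment(shared=shared, missing=missing, dropped=dropped, mapping=mapping)
    return alignment, CountMatrix(aligned, list(target.cell_ids), list(model_genes))


def save_bundle(model_dir: str, state: TopicModelState, mixture_net: MixtureNet | None) -> None:
    """Persist the topic model and (optionally) the mixture network together."""
    save_model(state, model_dir)
    if mixture_net is not None:
        np.savez(os.path.join(model_dir, "mixture.npz"), **mixture_net.state_arrays())
        with open(os.path.join(model_dir, "mixture.json"), "w") as fh:
            json.dump(
                {
                    "hidden_size": mixture_net.config.hidden_size,
                    "epochs": mixture_net.config.epochs,
                    "learning_rate": mixture_net.config.learning_rate,
                    "seed": mixture_net.config.seed,
                },
                fh, indent=1, sort_keys=True,
            )


def load_bundle(model_dir: str) -> tuple[TopicModelState, MixtureNet | None]:
    state = load_model(model_dir)
    net = None
    mix_path = os.path.join(model_dir, "mixture.npz")
    if os.path.exists(mix_path):
        from .dropout_mixture import MixtureNetConfig

        with open(os.path.join(model_dir, "mixture.json")) as fh:
            cfg = MixtureNetConfig(**json.load(fh))
        net = MixtureNet(cfg)
        with np.load(mix_path) as arrays:
            net.load_arrays(arrays)
    return state, net


def transfer_impute(
    target: CountMatrix, model_dir: str, config: PipelineConfig | None = None,
    case_insensitive: bool = False,
) -> tuple[PipelineResult, GeneAlignment]:
    """Impute a target dataset with a frozen, previously trained model."""
    config = config or PipelineConfig()
    state, net = load_bundle(model_dir)
    alignment, aligned = align_genes(target, state, case_insensitive=case_insensitive)
    # QC must not drop genes: the frozen encoder needs the full vocabulary
    cfg = PipelineConfig(**{**config.__dict__, "min_cells_per_gene": 0})
    if cfg.fit != "em" and net is None:
        raise ValueError("model bundle has no mixture network; rerun with fit='em'")
    result = impute_pipeline(aligned, cfg, state=state, mixture_net=net)
    return result, alignment


@dataclass
class DatasetStats:
    mean: float
    variance: float
    standard_deviation: float
    histogram: np.ndarray  # empirical probabilities, sums to 1
    bin_edges: np.ndarray


def dataset_stats(x: CountMatrix, bins: int = 50, value_range=None) -> DatasetStats:
    """Population moments and a binned empirical value distribution over all entries."""
    vals = np.asarray(x.values if hasattr(x, "values") else x, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("empty matrix")
    mean = float(vals.mean())
    var = float(vals.var())  # population convention: divide by n
    counts, edges = np.histogram(vals, bins=bins, range=value_range)
    return DatasetStats(
        mean=mean,
        variance=var,
        standard_deviation=float(np.sqrt(var)),
        histogram=counts / vals.size,
        bin_edges=edges,
    )


def compare_stats(a: DatasetStats, b: DatasetStats) -> dict:
    """Side-by-side moments plus total-variation distance between the histograms."""
    if a.bin_edges.shape != b.bin_edges.shape or not np.allclose(a.bin_edges, b.bin_edges):
        raise ValueError(
            "histograms use different bins; compute both with a shared value_range"
        )
    tv = 0.5 * float(np.abs(a.histogram - b.histogram).sum())
    return {
        "mean": (a.mean, b.mean),
        "variance": (a.variance, b.variance),
        "standard_deviation": (a.standard_deviation, b.standard_deviation),
        "total_variation": tv,
    }


def compare_datasets(x_a: CountMatrix, x_b: CountMatrix, bins: int = 50) -> dict:
    """Convenience: stats for two matrices on a shared histogram range."""
    hi = max(float(np.max(x_a.values)), float(np.max(x_b.values)))
    rng = (0.0, hi if hi > 0 else 1.0)
    return compare_stats(
        dataset_stats(x_a, bins=bins, value_range=rng),
        dataset_stats(x_b, bins=bins, value_range=rng),
    )
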