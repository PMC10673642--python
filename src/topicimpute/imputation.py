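"""Topic-space cell similarity and donor-based imputation.

A dropout-flagged entry (i, j) is filled by scanning cells i' != i in order of
increasing Euclidean distance between their topic mixtures, z_ii' =
||theta_i - theta_i'||, and copying X_i'j from the first cell whose own entry
for gene j is confidently non-dropout (d_i'j < t).  Entries not flagged as
dropout are never touched, and when no qualifying donor exists the original
value is kept — the method only replaces values it believes are missing.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data_io import CountMatrix, NormalizedData, filter_qc, normalize
from .dropout_mixture import (
    DropoutEstimate,
    GeneMixtureParams,
    MixtureNet,
    MixtureNetConfig,
    fit_mixture_em_all,
    fit_mixture_net,
)
from .topic_model import TopicModelConfig, TopicModelState, TopicPosterior, infer_theta, train

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    z: np.ndarray  # (I, I) symmetric Euclidean distances between theta rows


@dataclass
class ImputedMatrix:
    values: np.ndarray  # raw count scale
    imputed_mask: np.ndarray  # True where an entry was changed
    donor_index: np.ndarray  # donor cell per flagged entry; -1 where none found


def similarity(theta: np.ndarray) -> SimilarityMatrix:
    """Pairwise Euclidean distances between cell-topic mixtures (smaller = more similar)."""
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2 or theta.shape[0] < 2:
        raise ValueError("need at least 2 cells to compute similarities")
    return SimilarityMatrix(z=squareform(pdist(theta, metric="euclidean")))


def impute(
    x: CountMatrix,
    dropout: DropoutEstimate,
    sim: SimilarityMatrix,
    k: int = 1,
    library_scale: bool = False,
) -> ImputedMatrix:
    """Replace each flagged entry with values borrowed from qualifying donors.

    Candidates are scanned in ascending distance; ties resolve to the lower
    cell index (stable sort).  A donor qualifies for gene j when its own
    dropout rate there is below the threshold.  The defaults reproduce the
    strict rule — copy the single nearest qualifying donor's raw value.  Two
    refinements are available and used by the pipeline: ``k>1`` averages the
    first k qualifying donors (damping the sampling noise of any one cell),
    and ``library_scale`` borrows the donor's depth-adjusted expression
    X_i'j * L_i / L_i' instead of its raw count, so a deep donor does not
    inflate a shallow recipient.  ``donor_index`` records the nearest donor.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = x.values
    n_cells, n_genes = values.shape
    if dropout.rates.shape != values.shape or sim.z.shape != (n_cells, n_cells):
        raise ValueError("shape mismatch between counts, dropout estimate and similarities")

    out = values.copy()
    imputed_mask = np.zeros_like(dropout.mask)
    donor_index = np.full((n_cells, n_genes), -1, dtype=np.int64)
    confident = dropout.rates < dropout.threshold  # donor eligibility per entry
    libs = np.maximum(values.sum(axis=1), 1.0)

    for i in range(n_cells):
        flagged = np.flatnonzero(dropout.mask[i])
        if flagged.size == 0:
            continue
        order = np.argsort(sim.z[i], kind="stable")
        order = order[order != i]
        ok = confident[order][:, flagged]  # (I-1, m)
        has_donor = ok.any(axis=0)
        nearest = order[ok.argmax(axis=0)]
        cols = flagged[has_donor]
        if k == 1:
            dcells = nearest[has_donor]
            new_vals = values[dcells, cols]
            if library_scale:
                new_vals = new_vals * libs[i] / libs[dcells]
        else:
            new_vals = np.empty(cols.size)
            for idx, pos in enumerate(np.flatnonzero(has_donor)):
                dcells = order[np.flatnonzero(ok[:, pos])[:k]]
                j = flagged[pos]
                if library_scale:
                    new_vals[idx] = float(np.mean(values[dcells, j] / libs[dcells]) * libs[i])
                else:
                    new_vals[idx] = float(values[dcells, j].mean())
        changed = new_vals != out[i, cols]
        out[i, cols] = new_vals
        imputed_mask[i, cols] = changed
        donor_index[i, cols] = nearest[has_donor]
    logger.info("imputed %d of %d flagged entries", int(imputed_mask.sum()), int(dropout.mask.sum()))
    return ImputedMatrix(values=out, imputed_mask=imputed_mask, donor_index=donor_index)


@dataclass
class PipelineConfig:
    """End-to-end settings: QC -> normalize -> topic model -> mixture -> impute."""

    min_counts_per_cell: int = 1
    min_cells_per_gene: int = 1
    cell_target: float = 1.0
    n_topics: int = 50
    hidden_size: int = 128
    epochs: int = 300
    batch_size: int = 64
    learning_rate: float = 1e-2
    fit: str = "net"  # mixture fitter: amortized net or per-gene EM
    mixture_epochs: int = 400
    mixture_input: str = "library"  # fit on y_lib_log (default) or gene-normalized y_log
    threshold: float = 0.5
    n_donors: int = 5  # donors averaged per imputed entry (1 = strict nearest-donor copy)
    library_scale: bool = True  # borrow depth-adjusted expression, not raw counts
    seed: int = 0

    def topic_config(self) -> TopicModelConfig:
        return TopicModelConfig(
            n_topics=self.n_topics,
            hidden_size=self.hidden_size,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.seed,
        )


@dataclass
class PipelineResult:
    imputed: ImputedMatrix
    counts: CountMatrix  # post-QC counts the imputation ran on
    normalized: NormalizedData
    state: TopicModelState
    posterior: TopicPosterior
    mixture: GeneMixtureParams
    mixture_net: MixtureNet | None
    dropout: DropoutEstimate
    similarity: SimilarityMatrix


def impute_pipeline(
    counts: CountMatrix,
    config: PipelineConfig | None = None,
    state: TopicModelState | None = None,
    mixture_net: MixtureNet | None = None,
) -> PipelineResult:
    """Run the full imputation workflow on a count matrix.

    Passing a trained ``state`` (and optionally ``mixture_net``) skips
    training and reuses the given model deterministically.
    """
    config = config or PipelineConfig()
    filtered = filter_qc(counts, config.min_counts_per_cell, config.min_cells_per_gene)
    norm = normalize(filtered, cell_target=config.cell_target)

    if state is None:
        state, posterior = train(norm, config.topic_config())
    else:
        posterior = infer_theta(norm, state)

    y_mix = norm.y_lib_log if config.mixture_input == "library" else norm.y_log
    if config.fit == "em":
        mixture = fit_mixture_em_all(y_mix)
        net = mixture_net
    elif mixture_net is not None:
        mixture = mixture_net.predict(y_mix)
        net = mixture_net
    else:
        mixture, net = fit_mixture_net(
            y_mix, MixtureNetConfig(epochs=config.mixture_epochs, seed=config.seed)
        )

    from .dropout_mixture import dropout_rates

    est = dropout_rates(y_mix, mixture, t=config.threshold)
    sim = similarity(posterior.theta)
    imp = impute(filtered, est, sim, k=config.n_donors, library_scale=config.library_scale)
    return PipelineResult(
        imputed=imp,
        counts=filtered,
        normalized=norm,
        state=state,
        posterior=posterior,
        mixture=mixture,
        mixture_net=net,
        dropout=est,
        similarity=sim,
    )


def write_donor_table(result: PipelineResult, path: str) -> None:
    """donors.tsv: one row per imputed entry (cell, gene, donor, distance, d_value)."""
    import pandas as pd

    rows = []
    cells = result.counts.cell_ids
    genes = result.counts.gene_ids
    for i, j in np.argwhere(result.imputed.donor_index >= 0):
        d = result.imputed.donor_index[i, j]
        rows.append(
            (cells[i], genes[j], cells[d], result.similarity.z[i, d], result.dropout.rates[d, j])
        )
    pd.DataFrame(rows, columns=["cell", "gene", "donor", "distance", "d_value"]).to_csv(
        path, sep="\t", index=False
    )
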