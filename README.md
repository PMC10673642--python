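# topicimpute

Dropout imputation for single-cell RNA-seq count matrices.

Single-cell sequencing misses a large share of the transcripts a cell
actually expressed, leaving false zeros ("dropouts") scattered through the
count matrix alongside genuine biological zeros.  Treating every zero as
missing smears real cell-type structure; leaving them all in place distorts
downstream clustering and differential expression.  `topicimpute` takes the
middle road: it decides, entry by entry, which zeros look technical, and
replaces only those — every other entry stays bit-identical.

The method has three parts:

1. **A neural topic model** embeds each cell as a mixture θ_c over N latent
   expression programs: δ_c ~ N(0, I), θ_c = softmax(δ_c), and
   p(gene j | c) = Σ_k θ_ck β_kj with per-topic gene distributions β_k.  A
   two-layer amortized encoder infers q(δ_c | y_c) = N(μ_c, diag σ²_c) and is
   trained by maximizing the ELBO E[log p(Y | θ)] − KL[q ‖ p] with the
   reparameterization trick.
2. **A per-gene Gamma–Normal mixture** on log-transformed expression,
   f_j(y) = λ_j Gamma(y; α_j, β_j) + (1 − λ_j) Normal(y; μ_j, σ_j), gives
   each entry a dropout probability d_ij (the Gamma component's posterior);
   entries with d_ij ≥ t (default 0.5) are flagged.  The mixture parameters
   come from a small amortized network over per-gene summary statistics (a
   per-gene EM fitter is the cross-checked reference), so a trained model
   transfers to datasets of any size.
3. **Donor-based imputation**: a flagged entry of cell i is filled from the
   most similar cells — smallest Euclidean distance ‖θ_i − θ_i'‖ — whose own
   measurement of that gene is confident (d_i'j < t).

A trained model (encoder, β, mixture network) can be saved and applied to an
unseen dataset after gene alignment, with no retraining.

Intended users: computational biologists preprocessing scRNA-seq matrices
(CSV/TSV, Matrix Market, or h5ad), and methods developers who want the
pieces — topic model, dropout mixture, partition metrics (ARI/RI/MI/NMI/
AMI/FMS), synthetic benchmarks — as an importable library.

## Worked example

`examples/impute_synthetic.py` simulates a 3-topic dataset, zeroes 30% of
the positive entries while recording the ground-truth mask, and runs the
full pipeline:

```python
import topicimpute as ti
from topicimpute.synthetic import restrict_to_genes

sim = ti.simulate(ti.SimulationConfig(seed=0, dropout_lambda_range=(0.3, 0.3),
                                      dropout_decay=None))
result = ti.impute_pipeline(sim.observed_counts,
                            ti.PipelineConfig(n_topics=3, epochs=300, seed=0))
report = ti.score_against_truth(result.imputed,
                                restrict_to_genes(sim, result.counts.gene_ids))
```

which prints:

```
simulated 300 cells x 500 genes, 13182 entries zeroed by injected dropout
entries flagged as dropout: 79475
entries imputed:           73775
median per-gene Pearson r on masked entries: 0.601
global Pearson r on masked entries:          0.977
zeros-left-in-place baseline:                0.000
```

Reading the numbers: the simulator destroyed 13,182 measured values; the
pipeline flagged every entry whose dropout probability cleared t = 0.5
(most zeros, including cross-cell-type ones — the known behavior of
per-gene mixtures) and filled those with qualified donors.  On exactly the
entries that were truly destroyed, the filled values correlate with the
hidden truth at r = 0.98 globally and a median r = 0.60 within genes,
against a 0.00 do-nothing baseline.

The other examples each run one capability and print what it means:
`detect_dropouts.py` (mixture fitting and detection AUC on a fixture where
the right answer is known), `transfer_model.py` (frozen-model imputation of
an unseen dataset vs training on it directly), `evaluate_clustering.py`
(partition metrics on k-means over θ).

## Command line

A thin CLI wraps the same pipeline for shell use:

```bash
topicimpute simulate --cells 300 --genes 500 --topics 3 --seed 0 --out sim/
topicimpute impute --input sim/observed.csv --topics 3 --threshold 0.5 \
    --seed 0 --out run/
topicimpute transfer --model run_model/ --target other.csv --out out/
topicimpute evaluate --labels labels.tsv
topicimpute stats --input a.csv --other b.csv
```

Every run writes a `manifest.json` (options, seed, input checksums, stage
timings) sufficient to replay it.

## Layout

- `src/topicimpute/` — the library: `data_io`, `topic_model`,
  `dropout_mixture`, `imputation`, `metrics`, `transfer`, `synthetic`, `cli`
- `docs/methods.md` — the model, defaults, numerical choices and limitations
- `examples/` — one short narrative script per capability
- `tests/` — unit, property and end-to-end benchmark tests
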