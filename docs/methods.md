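# Methods

`topicimpute` imputes technical dropouts in scRNA-seq count matrices in three
stages: a neural topic model embeds cells, a per-gene Gamma–Normal mixture
decides which entries look like dropouts, and flagged entries are filled from
the most similar cells.  This note records the model, the defaults and the
design choices a maintainer would want to know about.

## Preprocessing

The input is a cells × genes non-negative count matrix X (I cells, J genes).
After QC (cells with total count below `min_counts_per_cell`, then genes
detected in fewer than `min_cells_per_gene` cells; both default 1), three
derived matrices are computed:

- **Y^C** — each cell scaled to a common total (`cell_target`, default 1.0,
  i.e. relative abundance).  Input of the topic-model encoder.
- **Y^G** — each gene divided by its mean count across cells, and
  **Y = log10(Y^G + 1.01)**.  The pseudo-count 1.01 maps observed zeros to
  log10(1.01) ≈ 0.00432 > 0 so every transformed value lies in the Gamma
  support.
- **Y^L = log10(X·L̃/L_i + 1.01)** — log of library-size-normalized counts,
  where L_i is cell i's total and L̃ the median library.  The dropout mixture
  is fit on Y^L by default (`mixture_input="library"`).  The reason is
  identifiability of the dropout call: on a per-gene normalized scale every
  gene's expressed bulk sits at the same height, so the only signal left in
  the mixture is the zero fraction, which ranks *biological* zeros above
  technical ones — the exact inversion of what the detector needs.  The
  library scale preserves "this gene is strongly expressed, its zero is
  suspicious" versus "this gene is barely expressed, its zero is expected",
  which is the assumption the mixture model encodes.  `mixture_input="gene"`
  restores the per-gene-normalized input for comparison.

## The topic model

Each cell c carries a latent Gaussian δ_c with prior N(0, I); its softmax
θ_c = softmax(δ_c) is a probability vector over N topics (a logistic-normal
mixture).  A topic k is a distribution β_k over genes (rows of β are
softmax-parameterized logits), and the data likelihood is the categorical
bag-of-genes model p(gene j | c) = Σ_k θ_ck β_kj.  Inference is amortized: a
two-hidden-layer ReLU network (J → 128 → 128, linear heads for μ_c and
log σ²_c) maps Y^C_c to the variational posterior q(δ_c) = N(μ_c, diag σ²_c),
and training maximizes the ELBO

    Σ_c E_q[ Σ_j x_cj log(θ_c β)_j ] − KL[q(δ_c | y_c) ‖ N(0, I)]

with the reparameterization trick (one Monte Carlo sample per cell per step)
and Adam (lr 1e-2, batch 64).  Two details matter in practice:

- **Count-weighted reconstruction.** The data term is weighted by the
  observed counts x_cj (equivalently Y^C times the library size), the
  standard topic-model convention.  Weighting by the unit-sum profile
  instead shrinks the data term by the mean library size (~10³), the KL then
  dominates, and the posterior collapses to a single point for a large
  fraction of random initializations.
- **KL warm-up and restarts.** The KL weight ramps linearly from 0 to 1 over
  the first third of the epochs.  `n_restarts` (default 3) independent fits
  are run from seeds derived deterministically from `config.seed`, and the
  fit with the best final ELBO is kept: runs that merge two topics end
  hundreds of nats below well-separated solutions, so this selection is
  unambiguous and deterministic.

The per-epoch training log records a deterministic full-data ELBO evaluated
at the posterior mean (θ = softmax(μ), no sampling).  Downstream stages use
the same point estimate, making imputation deterministic given the weights.
The encoder has no batch normalization; on the benchmark fixtures the plain
MLP reaches perfect topic recovery and keeps inference identical between
batched and full-data evaluation.

Defaults: N = 50 topics (`n_topics`), hidden size 128, 300 epochs.  The
benchmark fixtures use N = 3 to match their 3-topic ground truth.

## Dropout detection

On the log scale each gene j is modeled as the two-component mixture

    f_j(y) = λ_j Gamma(y; α_j, β_j) + (1 − λ_j) Normal(y; μ_j, σ_j)

(shape–rate Gamma).  The Gamma component absorbs dropout-suppressed values
near the transformed-zero plateau, the Normal the true-expression bulk, and
the posterior probability that entry (i, j) belongs to the Gamma component,

    d_ij = λ̃_j g(Y_ij) / (λ̃_j g(Y_ij) + (1 − λ̃_j) n(Y_ij)),

is the dropout rate.  Entries with d_ij ≥ t (default t = 0.5, the posterior
decision boundary) form the dropout mask.  d is computed in log space
(sigmoid of the log-density difference), which preserves the ranking of
entries even where one component underflows.

**Fitters.** Two are provided with the same objective, Σ_j −log-likelihood:

- `fit_mixture_em` — per-gene EM.  λ and the Normal parameters use exact
  weighted M-steps; the Gamma uses responsibility-weighted moment matching
  (α = m²/v, β = m/v) with a fallback that keeps the previous Gamma whenever
  moment matching would lower the likelihood, so the log-likelihood trace is
  non-decreasing.  A BIC parsimony guard collapses λ to its floor when a
  single Normal explains the column as well as the mixture — without it λ is
  unidentifiable on unimodal columns.
- `fit_mixture_net` — an amortized network (13-feature per-gene summary:
  mean, variance, zero fraction, nine deciles, log cell count → two hidden
  layers of 32 → five link-transformed outputs).  One trained network
  produces mixture parameters for any dataset regardless of its cell count,
  which is what makes the mixture transferable.  Training uses two guards
  against a role-swapped optimum in which the Gamma absorbs everything and
  the Normal is pushed out of the data range: the Normal-mean head predicts
  a residual from the empirical gene mean (anchoring the Normal on the bulk
  from the first step), and responsibilities are tempered early in training
  (clipped to [ε, 1−ε] with ε annealing 0.25 → 0 over the first half of the
  epochs) so neither component can be starved of gradient before the heads
  differentiate.  With both guards the net's dropout calls agree with the
  per-gene EM reference on ≥ 99% of entries on the benchmark fixtures.

**Scale floors.** Both fitters floor the component spreads at 0.05 dex and
constrain the Gamma shape to ≥ 1 (mean ≥ sd).  The transformed data are
log10 of integers, so values pile up on discrete atoms (all zeros map to
exactly log10(1.01)); without the floors a component collapses onto an atom,
its density diverges, and every zero's d saturates into an uninformative
tie.  The floors state that no component claims sub-count precision.
λ is clipped to [10⁻³, 1−10⁻³]; densities are floored at 10⁻³⁰⁰ before logs.

## Imputation

Cell similarity is the Euclidean distance between topic mixtures,
z_ii' = ‖θ_i − θ_i'‖; smaller is more similar, and a cell is never its own
donor.  For each flagged entry (i, j), cells are scanned in ascending z_ii'
(ties to the lower index, stable sort) and only cells whose own entry for
gene j is confidently measured (d_i'j < t) qualify as donors.  If no donor
qualifies the entry is left unchanged — the method never invents values —
and unflagged entries are bit-identical between input and output.

The strict borrowing rule copies the nearest donor's raw value
(X̌_ij = X_i'j; `impute(..., k=1, library_scale=False)`).  The pipeline
defaults refine it in two ways, both exposed and both off in the plain
`impute` signature:

- **k donors** (`n_donors`, default 5): average the first k qualifying
  donors.  A single donor's count is an unbiased but noisy draw; on the
  benchmark fixture the noise bounds the per-gene recovery correlation well
  below what the topic structure supports, and a small average removes most
  of it without smoothing across cell types (donors are still the nearest
  confident cells).
- **Depth adjustment** (`library_scale`, default True): borrow the donor's
  library-normalized expression, X_i'j · L_i / L_i', rather than its raw
  count, so a deep donor does not inflate a shallow recipient.  This is the
  natural rule when imputation is viewed on the normalized scale and mapped
  back to the recipient's depth.

## Transfer to unseen datasets

A trained bundle (encoder + β + amortized mixture network + metadata) can be
applied to a new dataset without any weight update: target genes are aligned
to the model vocabulary (shared genes reordered, model genes missing from
the target zero-filled, extra target genes dropped; optional case-insensitive
symbol matching), θ is inferred with the frozen encoder, mixture parameters
come from the frozen network (or a per-gene EM refit with `fit="em"`), and
imputation proceeds as usual.  Applying a bundle to its own training set
reproduces the non-transfer run bit-exactly.  Dataset-level diagnostics
(population mean/variance/sd and a binned value distribution compared by
total-variation distance) help judge how far a target strays from the
training data.  Zero-filling keeps the encoder honest about absent genes but
the inferred θ degrades as the missing fraction grows; cross-species use is
limited to uppercase symbol matching (no ortholog tables).

## Synthetic data

Two generators cover the two questions one can ask of the method.

**Topic-structured counts** (`simulate`): β_k ~ Dirichlet(0.05) over genes
(well-separated, sparse programs), each cell gets a dominant topic (mean
logit advantage 3.0, spread 0.5), counts ~ Multinomial(library, θβ) with
lognormal libraries (median ≈ 2000 over 500 genes).  Dropout: λ_j ~ U[0.2,
0.5] per gene, each positive entry zeroed with probability
λ_j·exp(−count/5) — low counts drop preferentially — and every zeroed entry
recorded in a mask.  Defaults: 300 cells × 500 genes × 3 topics, a
one-CPU-minutes scale.  Setting `dropout_decay=None` zeroes positives
uniformly at rate λ_j; the recovery benchmarks use (0.3, 0.3) with no decay,
i.e. a flat 30% injection.  `structure_seed` lets two datasets share β while
drawing independent cells, the transfer-learning setting; with β redrawn
instead, gene–program associations change and no encoder could transfer.

**Two-class expression world** (`simulate_bimodal`): expressed genes (60%)
have tight log-normal expression with log10 mean ≥ 1.5 — their zeros can
only be injected dropouts — while sparse genes have low-rate Poisson counts
whose zeros are overwhelmingly biological; dropout is injected uniformly at
λ_j ~ U[0.2, 0.5] on positives.  This is the world the Gamma–Normal mixture
assumes, and it is the fixture on which detection AUC is meaningful.  On the
topic-count fixture with decay the injected zeros sit at exactly the low
counts where biological zeros live, and within a gene every zero shares one
d value, so no per-gene score can separate them there — a limitation of the
whole per-gene-mixture family, not of this implementation.

What the generators do not emulate: batch effects, doublets, UMI/ambient
noise beyond multinomial sampling, cell-type-specific mixture parameters.
Passing the benchmarks therefore shows the machinery is correct under the
model's own assumptions, not that real tissues satisfy them.

## Evaluation metrics

RI, ARI, MI (nats), NMI, AMI and the Fowlkes–Mallows score are computed from
the contingency table, with exact integer pair arithmetic until the final
division (ARI of [0,0,1,1] vs [0,1,0,1] is exactly −0.5).  NMI uses the
arithmetic-mean normalizer 2·MI/(H(Q)+H(R)) by default (min/max/sqrt
selectable); AMI subtracts the permutation-model expected MI.  Degenerate
conventions: two constant partitions agree perfectly (1); a zero denominator
yields 1 for identical partitions and 0 otherwise; cosine of two zero
vectors is 0.  All partition metrics are symmetric and relabel-invariant.

## Benchmark scales and determinism

The shipped benchmarks run on 300 × 500 fixtures with 3 topics, 300 training
epochs and 3 restarts — a few seconds per stage on one CPU, chosen so the
full suite stays in the minutes range.  Every stochastic component draws
from generators derived from a single seed (weight init, shuffling,
reparameterization noise, simulators), so any run is bit-reproducible, and
`scripts/acceptance.py` re-derives every reported number from scratch.

## Known limitations

- One global mixture per gene: cell-type-specific dropout behavior is
  averaged over; zeros in a marker gene's non-expressing cell types are
  systematically called dropouts (inherited from the per-gene design).
- Donor-based filling cannot create values absent from the data and is
  bounded by the information in the topic embedding.
- The full I × I similarity matrix is materialized; fine to a few thousand
  cells, above which a nearest-neighbor query should replace it.
- Transfer assumes the target shares the source's gene-program structure;
  the dataset-statistics report is a diagnostic, not a guarantee.
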