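# Methods

## Model

A candidate m6A site is a bag B = {x_1, …, x_k} of per-read feature vectors
(k ≥ 1 reads); the bag label Y is 1 iff at least one read is modified. The
model has four pieces:

1. **Instance embedding.** h = f_φ(x): two fully connected layers
   D → M → M with ReLU activations (defaults D = 40, M = 16). The
   architecture is deliberately small; a fully connected stack is sufficient
   for tabular per-read features, and held-out performance did not improve
   with a wider embedding (M = 32 was tried).
2. **Gated-tanh attention.** atts_j = w_attᵀ tanh(V h_j) with V ∈ R^{L×M},
   w_att ∈ R^L (default L = 8); a = softmax(atts). The pooled bag embedding
   z = Σ_j a_j h_j feeds a logistic bag classifier P = σ(cᵀz). The softmax
   makes the weights sum to one, so pooling is invariant to bag size, and
   the whole forward pass is permutation-invariant.
3. **Instance probabilities.** Platt scaling f_j = σ(α·atts_j + β) with two
   scalars shared across bags (init α = 1, β = 0; α is left unconstrained).
4. **Rank-weighted Noisy-OR.** F(B) = 1 − Π_j (1 − f_j)^{w_j}. Ranks of f
   ascending (ties broken by instance index — a stable sort, so results are
   deterministic), normalized to u_j = rank_j/(k−1); weight function
   S(u) = N(u; 0, 0.1) + N(u; 1, 0.1) (Gaussian densities, σ = 0.1);
   w_j = S(u_j)/Σ_q S(u_q). For k = 1 the normalized rank is undefined and
   w = [1], so F = f_1. The two-peaked S gives essentially all weight to the
   highest- and lowest-ranked reads (the middle of a k ≥ 5 bag gets < 1e-3),
   which keeps F on one scale across read depths — the plain Noisy-OR tends
   to 1 as k grows even for small f.

Losses: L_m is the Bernoulli cross-entropy of the bag classifier P on
labeled bags; L_p = −[Σ_{B∈P} log F(B) + Σ_{B∈R} log(1 − F(B))] +
λ(α² + β²); L = L_m + L_p. Probabilities are clipped at ε = 1e-7 before
logs; softmax subtracts the max score first.

The reported site probability at inference is F(B); the classifier head P is
used only inside L_m. Instance-level scores are the Platt probabilities f.

## Positive-unlabeled training

Only a fraction of truly modified sites carry a positive label (the label
frequency); everything else is unlabeled. Each epoch:

1. score all unlabeled training bags with F(B);
2. take the |P| lowest-scoring as reliable negatives R (|R| = |P| exactly,
   giving balanced classes; ties broken by bag id);
3. minimize L by mini-batch Adam over shuffled (positive, reliable-negative)
   pairs, so every gradient step sees balanced classes.

Rank weights w_j are recomputed every forward pass but treated as constants
under backpropagation (the ranking is not differentiable). L_m uses the
labeled positives and the current R — the only bag labels available in PU
mode.

Four training-stability choices matter and are this package's own design;
the underlying objective is unchanged by all of them:

* **Anchored first R.** An untrained network scores bags arbitrarily; if the
  first R happens to contain many hidden positives, training can lock into a
  label-inverted solution (observed directly: validation AUC 0.15 at epoch
  0). The first R is therefore chosen model-free, in the spirit of two-step
  PU learning: each bag is summarized by its per-feature mean and spread, a
  regularized logistic regression separates labeled-positive summaries from
  the unlabeled pool, and the lowest-scoring unlabeled bags seed R. R is
  held fixed during warm-up, then refreshed per epoch from model scores.
* **Noisy-OR warm-up.** The two-peaked weighting also gives weight ~0.5 to
  the *lowest*-ranked read of a positive bag, so early in training the
  gradient pushes the least-modified-looking read's probability up, which
  scrambles the instance ranking before it forms. A well-separated solution
  is a stable low-loss point of the weighted objective; to reach its basin,
  the first third of epochs trains L_p with the plain Noisy-OR gradient,
  after which the rank-weighted variant takes over. (Training arms that
  target the plain Noisy-OR or mean/max pooling skip the bridge.)
* **Regularization.** L2 weight decay 3e-3 on W1, W2, V, w_att, c keeps
  attention scores in the responsive range of the softmax/sigmoid (without
  it, atts spreads over ±7, the softmax becomes one-hot, Platt probabilities
  pin to 0/1 and gradients vanish at the clip). Each epoch also trains on a
  random 70% read subsample of every bag.
* **Ensembling.** PU training at a few hundred bags is seed-sensitive, so
  predictions average an ensemble of 5 restarts whose seeds (and bootstrap
  resamples for the R anchor) derive deterministically from the config seed.

Defaults: Adam lr 1e-2, 60 epochs (100 in the benchmark experiments), batch
32 bags, λ = 1e-3. Training aborts with a diagnostic on a non-finite loss.
Two runs with the same config and data are bit-identical.

## Feature extraction

Candidate sites are RRACH occurrences (R ∈ {A,G}, H ∈ {A,C,T}, the central A
the candidate) on transcript references, 0-based coordinates, forward strand
(DRS reads map to transcript space); U → T at ingest; overlapping motif
windows are all kept. Per read and site, 40 features:

* signal, per position −2…+2: median, population SD, mean and count of the
  raw current samples assigned to that base. Population (not sample) SD
  matches event-level summaries of re-squiggle tooling. "Count" is the raw
  sample count (a dwell proxy).
* alignment, per position: base quality, mismatch, insertion-adjacent and
  deletion indicators, computed per read (0/1), not per site.
* A base deleted in a read contributes the sentinel (0, 0, 0, 0) and quality
  0 with deletion 1.

Sites with fewer than `min_reads` covering reads are dropped (3/5/20 are the
conventional thresholds; a read covers a site when it has an alignment
record at all five motif positions). Input dialects: an eventalign-like
signal table, a sam2tsv-like per-base alignment table, or the package's
long-format 40-feature TSV.

**Normalization.** Features are z-scored on the training bags. For
40-feature data the signal medians and means are first centered on their
within-site mean: absolute current levels are 5-mer-specific (range tens of
pA versus a modification shift of a few pA), so uncentered they act as a
site fingerprint that a flexible model memorizes instead of learning the
modification effect — cross-site transfer then fails. Within-site centering
is the analogue of the control-comparison step in signal-level callers. Its
cost: a site modified at ~100% stoichiometry loses most of its centered
signal contrast (the alignment-error features still carry signal); the
benchmark uses 50% stoichiometry where the effect is strongest.

## Synthetic data

The m6A generator emulates the *downstream tables* of a DRS pipeline, not
pore physics. Random transcripts (default 25 × 800 nt ≈ 225 RRACH sites) are
scanned; each site is modified with probability 0.5; a modified site assigns
a stoichiometry fraction of its reads (depth uniform 10–30) the modification
effect: the central base's current mean shifts by `signal_shift_sd` × the
base's SD, and base-calling degrades (mismatch 0.02 → 0.17, deletion
0.01 → 0.05, insertion 0.01 → 0.035, quality −5 at error_inflation 0.5).
Per-5-mer current means (80–120 pA) and SDs (1.5–3 pA) come from a fixed
seeded stand-in pore-model table; dwell is geometric with mean 8 samples.
With shift 0 and error inflation 0, modified and unmodified reads are drawn
from identical distributions — the null used for calibration.

What the generator does **not** model: carry-over of the modification effect
to neighboring positions within the pore, sequence-dependent error profiles,
read-level coverage gaps in the middle of a motif, multiple sites per read,
or alignment artifacts. Passing benchmarks therefore show that the method
recovers a localized per-read signal-plus-error effect under PU supervision
at realistic depth and stoichiometry — not that it reaches any particular
accuracy on real cell-line data.

## Benchmarks

`pumil.experiments` fixes the protocol: ~225 sites, depth 10–30, 2-SD shift,
stoichiometry 0.5, label frequency 0.3, stratified 5-fold cross-validation
with an ensemble per fold; each fold's held-out ROC AUC is computed
separately and averaged (pooling scores across fold models would mix their
calibrations), giving one value per scenario seed, averaged over 3 seeds
(site level and read level). The no-effect calibration averages 5 seeds: a
single finite dataset carries chance bag-feature/label associations worth a
few AUC points, which any in-dataset cross-validation surfaces.
The ablation swaps only the pooling layer (rank-weighted vs. plain Noisy-OR)
with data, folds, seeds and schedule held identical, on a harder 0.5-SD
shift, 5 seeds. Problem sizes were chosen so the whole benchmark suite runs
in minutes on one CPU.

## Numerical and degenerate cases

* ε = 1e-7 clipping before every log and before the Noisy-OR exponent; the
  clip zeroes the corresponding gradient.
* k = 1 bags: attention weight [1.0], F = f_1.
* Constant features get SD 1 in the normalizer (pass through centered).
* Ties in instance probabilities: stable sort by (probability, index).
* Reliable-negative ties at the cutoff: bag-id order.
* Biases initialize at 0.01, keeping ReLU units off the exact kink (dead
  units also make finite-difference gradient checks disagree at 0).
* `epochs=0` returns the initialized model and an empty report.

## Known limitations

* The attention-score bottleneck caps read-level (instance) recovery below
  a fully supervised classifier on the same features (~0.82 vs ~0.92 ROC AUC
  on the benchmark); bag-level supervision at 30% label frequency simply
  carries less information.
* Within-site centering assumes the majority signal level approximates the
  unmodified level; near-100% stoichiometry sites violate this.
* The sam2tsv-like reader expects one record per (read, reference position);
  split alignments and supplementary records are out of scope.
* Genomic (as opposed to transcriptomic) coordinates, strand handling and
  liftover are out of scope.
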