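# Methods

This note documents the models, statistics and numerical choices behind
`snpdeep`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where several defensible options existed.

## Problem setting

The package classifies samples as Case or Control from SNP-array genotype
calls. A dataset is a categorical matrix (SNPs × samples, cells in
{AA, AB, BB, NC}) plus a per-sample binary phenotype. Real panels are
extremely wide (10⁵–10⁶ SNPs) and short (tens to hundreds of samples), so
the pipeline is built around aggressive feature selection and around
keeping every label-dependent fit inside the cross-validation training
fold.

## Cleaning

Order is fixed: invariant-SNP removal → No-Call filter → mode imputation.

* **Invariant SNPs** are judged on called (non-NC) cells: a SNP that is
  all-AA apart from No-Calls carries no genotype signal either way, so it
  is removed before imputation could manufacture variability. The removal
  count is logged for audit.
* **No-Call filter**: a SNP is removed when its NC fraction is *strictly
  greater* than the threshold (default 0.10); a SNP at exactly 10 % is
  retained.
* **Imputation** replaces each NC with the SNP's most common called
  genotype; ties break deterministically in the order AA < AB < BB.

## Mean encoding and leakage

Each genotype of each SNP is encoded as E(G), the proportion of Case
samples among samples carrying G in the *fitting subset*. Two properties
follow directly and are enforced by tests: every encoded value lies in
[0, 1], and per SNP, Σ_G E(G)·count(G) equals the number of Case samples in
the fitting subset.

E(G) is a target encoding: fitted on all samples it injects each sample's
own label into its features. The package therefore has two modes:

* **fold-safe (default)** — the encoding (and the feature selection, and
  the model) are fitted per CV training fold; held-out samples are encoded
  with the training-fold map. A genotype unseen at fit time receives the
  training fold's case prevalence — the minimal-assumption prior.
* **global** — encoding and selection fitted once on the full dataset,
  provided because it mirrors a common practice. On label-independent
  synthetic data with many SNPs and few samples this mode inflates CV
  accuracy dramatically (the acceptance suite measures a gap of ≈ 0.2–0.3
  accuracy at 400 null SNPs × 60 samples) while the fold-safe mode stays at
  the majority rate. The inflation needs the p ≫ n regime: with only a few
  dozen candidate SNPs, globally selected features generalize across folds
  and the gap shrinks into the noise.

Whether encodings and selections should be fitted globally or per fold is
genuinely ambiguous in much of the applied literature; providing both
behind one flag, with fold-safe as default, is this package's resolution.

## Feature selection

* **AMGM ratio** (relevance): mean(x)/gmean(x) of a SNP's encoded values,
  ≥ 1 with equality iff constant; larger for more variable features. The
  geometric mean is computed in log space. Encodings can be exactly 0, so
  a configurable ε = 10⁻⁶ is added first.
* **Cosine redundancy** (uniqueness): a greedy pass in rank order keeps a
  SNP iff its maximum cosine similarity to already-kept SNPs is < τ
  (default 0.95), stopping at the requested size; if the pool is exhausted
  the remaining slots are filled from the skipped SNPs in rank order, with
  a warning. Note that mean-encoded vectors are non-negative with similar
  means, so raw cosine similarities sit close to 1 and the filter
  frequently exercises its fill rule; τ is exposed for users who want a
  stricter notion of redundancy. The default staging is 1000 intermediate →
  100 final features.
* **Autoencoder + L1**: a single-hidden-layer autoencoder (tanh encoder,
  linear decoder, MSE loss) with an L1 penalty (λ = 10⁻³) on encoder
  weights; a feature's score is its total absolute first-layer weight.
  Columns are mean-centered but *not* variance-scaled: for mean-encoded
  SNPs the association signal lives precisely in column variance (a
  label-associated SNP has widely spread E(G) values, a null SNP's are all
  near the case prevalence), and unit-scaling every column erases it.
  A narrow bottleneck (default ceil(d/16), at least 2) forces the encoder
  to spend capacity on high-variance, mutually reconstructable structure.
  Defaults: 150 epochs, Adam at 10⁻², batch 32, seeded.
* **ReliefF**: for every probe sample, the k = 10 nearest same-class
  neighbors (hits) and k nearest other-class neighbors (misses, weighted by
  class priors) update each feature's weight by mean miss-difference minus
  mean hit-difference. Differences are range-normalized (hence invariance
  to positive rescaling); distances are Manhattan on normalized values;
  neighbor ties resolve by stable sort. All samples are probed by default,
  making the weights deterministic.
* **CMIM**: greedy conditional-mutual-information maximization on the raw
  genotype categories (plug-in entropies in bits): first argmax I(F;Y),
  then argmax_F min_{S∈selected} I(F;Y|S). Chi-squared and
  mutual-information rankings likewise run on the 3×2 genotype-by-class
  contingency tables. Running the information-theoretic selectors on
  categories rather than encodings keeps the selector itself free of
  encoding-induced label leakage.
* **SVM-RFE**: repeatedly fit a linear soft-margin SVM (C = 1) and drop the
  ⌈0.1 · surviving⌉ features with smallest |weight| until the target size
  remains. The hybrid runs CMIM to an intermediate pool (default 1000,
  capped at the pool size), then SVM-RFE.

All selectors break score ties by SNP id, which makes every selection
invariant to the order SNPs appear in the input file.

## Model zoo

All architectures train with binary cross-entropy (numerically stable
logits form), Adam with the spec's learning rate, per-epoch shuffled
mini-batches, and dropout; (data, spec, seed) fully determine the fitted
parameters. The networks run on a small reverse-mode autodiff engine over
float64 numpy arrays — single-threaded, deterministic, and fast enough for
panels of ≤ a few thousand selected SNPs.

* **FNN**: two ReLU layers (`neurons_1`, `neurons_2`) with dropout, linear
  output.
* **Autoencoder classifiers** (`ae_baseline`, `ae_bayes`, `ae_sparse`):
  pre-train a one-hidden-layer autoencoder (tanh encoder — saturating but
  free of dead units even at a bottleneck of one — linear decoder, MSE),
  freeze the encoder, train a logistic head on the bottleneck codes.
  The baseline's "structure adapts to the data" as bottleneck =
  ⌈n_features/4⌉ unless pinned. `ae_bayes` is the same architecture, meant
  to be configured by the Bayesian search; `ae_sparse` adds an L1 activity
  penalty (10⁻⁴) on bottleneck activations during pre-training.
* **Recurrent** (`gru`, `bilstm`): the feature vector is consumed as a
  length-d sequence of scalars in SNP order. SNPs have no intrinsic order;
  this is a convention, stated here so nobody mistakes it for biology. GRU
  uses the final hidden state; Bi-LSTM concatenates final forward and
  backward states. LSTM forget-gate biases start at 1.
* **Convolutional** (`cnn`, `resnet`): 1-D convolutions over the feature
  axis, 16 channels; CNN is conv → ReLU → global average pool → linear;
  ResNet adds a stem convolution and two same-padded residual blocks with
  identity skips (hence the odd-filter-size requirement).
* **Stacked** (`stacked_ae_fnn`, `stacked_ae_bilstm`): autoencoder
  pre-training, encoder frozen, then the FNN or Bi-LSTM head trained on the
  codes — the simplest reading of optimizing each component individually
  before integration.

Default hyperparameters (epochs 100, dropout 0.3, batch 32, learning rate
10⁻³, neurons 64/32, units 32, filter size 3) are package defaults, all
overridable per spec; they are *not* tuned per dataset.

**Bayesian search** is sequential model-based optimization: a third of the
budget (≥ 3 trials) of random exploration, then expected-improvement
maximization under a Matérn-5/2 Gaussian-process surrogate over the
normalized hyperparameter cube (learning rate on a log scale). The
objective is mean 3-fold stratified CV accuracy on the training data; the
full trial log is returned with the best spec.

## Evaluation

Stratified five-fold CV (folds differ by ≤ 1 in size and in per-class
counts, seeded). Stratification is a deliberate choice: with imbalanced
panels an unstratified split can produce single-class test folds, which is
also why each metric with a 0/0 denominator is reported as 0 *and flagged*
rather than raised — all-one-class folds are a reportable outcome, not a
crash. Metrics: accuracy, sensitivity (Case recall), specificity (Control
recall), F1; fold metrics are averaged arithmetically and per-fold values
retained. The identity accuracy = (sens·P + spec·N)/(P+N) is enforced in
tests to 10⁻¹².

## Synthetic data

The generator emulates a balanced case/control SNP-array panel:

* per-SNP minor-allele frequency drawn uniformly from (0.05, 0.5] by
  default (real allele-frequency spectra are not uniform; the default is a
  simple, documented choice);
* genotypes sampled independently per SNP under Hardy–Weinberg proportions
  ((1−q)², 2q(1−q), q²);
* the minor "B" allele is always the risk allele; a sample's risk dosage is
  its B-allele count;
* labels drawn from logit P(Case) = α + log(causal_effect)·Σ dosage over
  causal SNPs, with α calibrated by root-finding so the expected case
  fraction matches the config (Brent's method on the mean predicted risk,
  which is strictly increasing in α);
* No-Calls injected independently per cell at the configured rate.

What it does **not** emulate: linkage disequilibrium (SNPs are
independent), population stratification, genotyping-error structure,
sex chromosomes, or realistic allele-frequency spectra. Tests passing on
this generator therefore demonstrate algorithmic correctness and
calibration, not performance on real cohorts — in particular, redundancy
filters face much harder problems on real LD structure than here.

One statistical subtlety: because odds ratios are non-collapsible, the
*marginal* BB-vs-AA odds ratio of a causal SNP is attenuated below
causal_effect² when other causal SNPs exist and the baseline risk is high;
the planted conditional effect is recovered by a joint logistic fit (the
test oracle does exactly this at n = 50 000 and sees per-allele odds ratios
within ~5 % of the planted value).

## Problem sizes used in the test suite

The statistical suites run at sizes chosen to make their effects decisive:
recovery of planted SNPs uses 400 samples × 120 SNPs with 5 causal SNPs of
per-allele odds 4 over 20 seeds (chance recall ≈ 0.04); null calibration
uses 60 × 50 null panels over 20 seeds; the leakage demonstration uses
60 × 400 null panels, where global selection from many candidates is the
textbook optimistic-bias regime. The two-step selection flow is exercised
on an 1100-SNP panel so the 1000 → 100 staging is non-trivial.

## Known limitations

* The autodiff engine is minimal by design: no GPU, no threading, only the
  operations the zoo needs; recurrent models are the slowest members
  (Python-level loop over the feature sequence).
* CMIM is O(selected × remaining) with per-pair stratified tables; for
  very large intermediate pools the hybrid's first stage dominates runtime.
* `ae_bayes` shares code with `ae_baseline`; the difference is where its
  hyperparameters come from, not its topology.
* The CSV reader accepts only the documented GEO-export dialect; SOFT /
  series-matrix parsing and PLINK formats are out of scope, as is any
  multi-class phenotype (a status map collapses multi-status phenotypes to
  binary at ingestion).
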