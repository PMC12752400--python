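# Methods

This note documents the models, the synthetic data generator, the
numerical choices and the study conditions used by the test suite and by
`scripts/acceptance.py`, in the order the pipeline runs.

## Synthetic multi-cohort generator (`gwaskd.simulate`)

**What it emulates.** Several case/control genotyping cohorts drawn from
related but non-identical populations: a shared rsID universe;
cohort-specific minor-allele frequencies (`maf[c,j] = clip(base_maf[j] +
shift[c,j], 0.01, 0.99)`, `base_maf ~ Uniform(base_maf_range)`, `shift ~
Normal(0, cohort_maf_shift_sd^2)`); independent dosages `Binomial(2,
maf)`; a logistic liability `sum_causal beta_j g_j + sum_pairs gamma
g_a g_b + c` with labels `Bernoulli(sigmoid(liability))`; class imbalance
per cohort; and uniformly missing genotypes.

**Intercept.** Per-sample uniforms are drawn first and the intercept `c`
is found by bisection on the *realised* case count given those uniforms,
so each cohort's case count matches the requested fraction to within one
sample while labels remain Bernoulli draws from the logistic model
conditional on `c`. A configuration whose case fraction is unreachable
(tied liabilities) raises.

**Effect heterogeneity.** `effect_size_multiplier_per_cohort` accepts one
scalar per cohort, or one vector of length `n_causal` per cohort. Zeros in
a vector make a causal SNP *cohort-private* — the mechanism used to model
cohorts whose risk loci only partly overlap (real dementia cohorts differ
in which known risk SNPs their platforms even carry). Epistasis is encoded
as products of raw dosages, giving tree learners and the wide path's
cross-products a non-additive signal to exploit.

**Defaults.** Five cohorts with sample sizes (1462, 534, 1386, 240, 1310)
and case fractions (0.617, 0.672, 0.595, 0.696, 0.573) — magnitudes
matching published dementia genotyping cohorts; 29,630 SNPs with MAF in
(0.05, 0.5); 50 causal SNPs with alternating log-odds effects of ±0.25;
MAF shift SD 0.05; 2% missingness. Tests and the acceptance script use
explicitly smaller configurations (below).

**What it does not emulate.** Linkage-disequilibrium block structure,
imputation quality, ancestry principal components, X-chromosome dosage
rules, genotyping batch effects. Passing tests therefore demonstrate the
pipeline's statistical machinery under idealised independence, not
performance on real LD-structured genomes.

## Preprocessing (`gwaskd.io_preprocess`)

* **Harmonisation** restricts all cohorts to the lexicographically sorted
  intersection of their rsID sets (idempotent; empty intersection errors).
* **Imputation** fills missing dosages with per-SNP observed means
  (preserving each SNP's mean exactly; real-valued fills allowed) or the
  mean of the `k` nearest neighbours, distance = root mean squared
  difference over mutually observed SNPs (per-pair normalisation keeps
  pairs with different overlaps comparable). Inside evaluation pipelines,
  means are fit on training data only and applied to held-out data.
* **Balancing** is the two-stage scheme: oversample the minority class
  with replacement up to `rho * majority` (default `rho = 0.8`), then
  undersample the majority without replacement to the new minority count.
  Every output row is a copy of an input row. By default balancing applies
  to training partitions only, after splitting; `balance_eval=True`
  reproduces balanced-evaluation variants.
* **Splits** are stratified 80/20 (proportions within one sample) and
  stratified k-fold (default 5), both seeded.

## Feature selection (`gwaskd.select`)

* **F-score** = one-way ANOVA F across the two label groups (for two
  groups, identically the squared pooled-variance t). Constant SNPs score
  0; zero within-group variance with non-zero separation is mapped to
  (max finite score + 1) so ranking stays total.
* **Mutual information** = plug-in discrete MI in nats on the 3-level
  dosage (imputed real values binned to the nearest of {0,1,2}); no
  continuous estimator is used because dosages are ordinal with 3 levels.
* **Association scan** = Cochran–Armitage trend test with weights
  (0,1,2): the case dosage sum is centred and scaled by its
  finite-population (hypergeometric) null moments, two-sided normal
  p-values; zero-variance SNPs get p = 1. The statistic is discrete, so
  null p-values are uniform up to atoms (tests check the KS distance and
  the 5% tail rather than a KS p-value).
* **Cross-cohort selection**: intersect every cohort's top-*m* list, rank
  the survivors by mean per-cohort rank (ties lexicographic), keep the
  best *k*. If fewer than *k* survive, all are returned and a shortfall
  is flagged. *m* is a free knob: the procedure's endpoint (e.g. "75
  common SNPs") does not determine *m*, so it is exposed in the config.

## Teacher and student networks (`gwaskd.models`)

Architecture per the equations in the README: wide linear path over
`[x, phi(x)]`; deep path embedding each SNP's scalar dosage into a learned
per-position affine token (width `embedding_dim`), optional multi-head
scaled dot-product self-attention over the SNP tokens (no residual
connection, layer norm or projection biases — the attention block is
exactly `concat_i softmax(XW_Q^i (XW_K^i)^T / sqrt(d_k)) XW_V^i · W_O`),
global average pooling, dense ReLU/GELU layers with inverted dropout;
fused scalar logit `w_out^T a^(L) + y_wide + b`.

* **Logit convention.** The scalar fused logit `z` is reported as the
  class pair `(0, z)`, making the two-class temperature-1 softmax equal
  the sigmoid output exactly; this couples the forward pass to the
  distillation softmax without a second output head.
* **Wide cross-products.** Which SNP pairs enter `phi(x)` is a design
  choice; the scenario pipeline defaults to all pairs among the top-10
  F-score SNPs of the balanced source training split (45 pairs) —
  bounded width, signal-bearing pairs.
* **Default sizes.** Teacher: embed 16, 4 heads, key dim 8, hidden
  [128, 64], dropout 0.1. Student via shrink factors (heads, layers,
  widths each halved by default); construction verifies the student has
  strictly fewer parameters than its teacher and errors otherwise.
* **Training.** Manual-backprop Adam (lr 0.01, batch 64), seeded
  shuffling and dropout, early stopping on validation loss (patience 10)
  with best-weight restoration. All gradients are hand-derived and were
  verified against central finite differences to ~1e-7 relative error.
* **Feature extraction.** Named layers: `embedding`, `attention`,
  `pooled`, `hidden_i`, and `fusion` = last hidden activations
  concatenated with the wide-path score. The default extraction layer is
  the last hidden layer; the evaluation pipeline feeds `fusion` to the
  downstream trees because the wide path carries most of the linear
  (polygenic-score-like) signal in this architecture, and features that
  omit it underperform the teacher itself.

## Distillation (`gwaskd.distill`)

Combined objective `alpha * L_CE(labels, student at T=1) + (1 - alpha) *
L_distill(teacher at T, student at T)` with `L_distill` the
teacher-weighted cross-entropy (log clamped at 1e-12). Two deliberate
choices:

* **No T² gradient rescaling.** Classic distillation multiplies the soft
  term by T² to balance gradient magnitudes; the objective implemented
  here omits it, exactly as written above. At fixed `alpha` the soft
  term's gradients therefore shrink as 1/T — users sweeping large T
  should co-tune `alpha`.
* **Student trains on the target training split** with teacher logits
  from the source-trained teacher (inference mode). This is what makes
  the student a *transfer* model: hard labels supply target supervision,
  soft targets supply source knowledge. A same-cohort distillation run is
  just `run_scenario` with source == target data passed as two cohorts.

`tune_alpha` grid-searches `alpha` (default grid 0.1..1.0 step 0.1) on
validation macro-F1, ties resolved toward the smaller `alpha` (more
distillation); the scenario runner can wrap this in stratified k-fold.

## Evaluation (`gwaskd.evaluate`)

`run_scenario` executes: harmonise → stratified 80/20 splits of the
concatenated source and target → balance training partitions → impute
with train-fit means → optional top-n F-score selection on the balanced
source train → train teacher (early stopping on the source held-out
split) → distill student on the target training split → extract fusion
features → fit GB/DT/RF/XGBoost on source-train features → evaluate all
six models on the target test split.

* **Metrics.** Accuracy; *macro-averaged* precision/recall/F1 (macro
  reproduces the near-identical Acc≈Prec≈Rec≈F1 pattern seen on balanced
  test sets); specificity TN/(TN+FP); AUC as the Mann–Whitney rank
  statistic with 0.5 tie credit; threshold 0.5 for the confusion matrix.
  Every report is internally audited: scalar metrics must reproduce from
  the stored confusion matrix.
* **Leakage audit.** Each fitting step records the sample ids it
  consumed; the result carries these sets so tests can assert that target
  test rows never touch selection, imputation statistics, balancing, or
  any model fit. (With `eval_full_target=True` the evaluation set is the
  whole target cohort and necessarily overlaps the student's training
  split; that reading is available behind the flag but not audited.)
* **Downstream classifiers** use library defaults plus a fixed seed.
* **Ablation** re-runs the scenario over a grid of feature-subset sizes
  (ranked by F-score on the balanced source train) × attention on/off,
  and emits a tidy (size, attention, model, metric, value) table.

## Attribution (`gwaskd.interpret`)

Permutation-sampling Shapley values with antithetic pairs, explaining the
student's positive-class probability. For each sampled permutation (and
its reverse) one background row is substituted feature-by-feature toward
the explained sample; each SNP is credited the output change at its
switch. One shared permutation set is drawn for all explained samples
(estimates are invariant to explain-row order), and background rows are
cycled in a balanced design, which makes local accuracy exact up to float
error: per sample, `sum_j shap_j + mean_background f = f(x)`. A SNP the
network provably ignores (zero embedding row, absent from wide inputs)
receives exactly zero. Defaults: 100-sample seeded background from the
target training split, 32 antithetic permutation pairs. Estimator
variance shrinks as 1/sqrt(pairs); duplicate-feature symmetry holds to
sampling tolerance. Different Shapley estimators (kernel-weighted,
gradient-based) can rank mid-list SNPs differently; rankings here are
specific to the sampling estimator.

## Study conditions used by tests and the acceptance script

Problem sizes are chosen to exercise each claim at desk scale on one CPU:

* **Causal recovery.** 5 cohorts × 2000 samples, 2000 SNPs, 10 shared
  causal SNPs (beta = 1), MAF shift SD 0.05; selection with m = 50,
  k = 10; 10 seeds (5 in the acceptance script's mean).
* **Teacher learnability.** 1 cohort, 2000 training / 500 held-out
  samples, 75 SNPs, 10 causal (beta = 1) at MAF 0.4–0.5 (liability SD
  ≈ 2.2, Bayes-optimal AUC ≈ 0.88 for this generative model — the
  ceiling any classifier can reach); teacher embed 8 / 2 heads / hidden
  [32, 16], 30 epochs; median held-out AUC ≥ 0.85 across seeds.
* **Transfer direction of effect.** 2 cohorts × 800, 75 SNPs, 10 causal
  (beta = 0.8), MAF shift SD 0.1, and partially overlapping causal sets
  (source active on causal SNPs 1–6, target on 5–10): the condition in
  which a source-only model genuinely degrades. Student (T = 4,
  alpha = 0.5, 25 epochs) vs teacher mean target accuracy over 10 seeds.
  With fully shared causal architecture and mild shift the teacher
  transfers well and the effect is absent — the direction of effect is a
  statement about heterogeneous cohorts, not about any shift.
* **Deep-feature advantage.** 2 cohorts × 800, 600 SNPs, 150 small
  additive effects (beta = 0.18) plus 3 epistatic pairs (gamma = 0.8),
  MAF shift SD 0.1 — a polygenic regime where greedy trees on raw
  dosages struggle to accumulate many small effects while the teacher's
  fusion representation hands them the aggregated score. Teacher here is
  attention-free (embed 4, hidden [16, 8]): self-attention over 600
  tokens costs two orders of magnitude more than the rest of the pipeline
  and the mechanism under test (fused representation vs raw dosages) does
  not involve it. Median accuracy gain of the four tree models over the
  same trees on raw dosages, 10 seeds.
* **End-to-end smoke.** 2 cohorts × 200 samples, 100 SNPs, full CLI
  chain simulate → select → evaluate → train-teacher → distill → explain,
  plus a bit-identical manifest rerun of the simulation.

## Known limitations

* No LD structure in the simulator: feature-selection behaviour on real
  genomes (where causal signal smears over correlated SNPs) is untested.
* The networks are CPU numpy; they are sized for hundreds-to-thousands of
  samples and up to a few thousand SNPs, not biobank scale. Attention
  cost grows quadratically in the SNP count.
* Binary phenotypes only; no covariates (age, sex, ancestry PCs).
* `tune_alpha` retrains one student per grid point per fold — the full
  10-point grid with 5-fold selection is the most expensive path in the
  package; scenario runs default to a fixed `alpha` unless tuning is
  requested.
* Minibatch training is deterministic given seeds on a fixed platform;
  bit-identical reproduction across BLAS builds is not guaranteed for
  trained weights (the simulator's outputs are bit-reproducible
  everywhere).
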