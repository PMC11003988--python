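# Methods

`drugsens` predicts per-compound drug sensitivity (area under the
dose-response curve, AUC; larger = more resistant) from bulk gene
expression. This note records the model, the conventions, and the design
choices a maintainer would want explained.

## Feature engineering: single-sample gene-set enrichment

Expression is expected on the log2(TPM+1) scale (`log_transform` converts
linear TPM). For each sample, genes are ranked by expression descending and
the enrichment score of a gene set S over N genes is

    ES(S) = sum_{i=1..N} [ P_hit(i) - P_miss(i) ]
    P_hit(i)  = sum_{g in S, rank(g) <= i} w(g)^alpha / sum_{g in S} w(g)^alpha
    P_miss(i) = |{g not in S, rank(g) <= i}| / (N - |S|)

with rank weights `w(g) = N - position(g) + 1`. Conventions:

* **Rank weights, not raw expression.** Using the rank-transformed values
  makes scores invariant to monotone rescaling of expression and robust to
  heavy-tailed transcripts; this is the standard single-sample enrichment
  behaviour.
* **alpha = 0.75 by default** (configurable), the customary single-sample
  weighting exponent. At `alpha = 0` the score reduces to a difference of
  unweighted ECDFs.
* **Ties** in expression are broken by gene-ID lexicographic order so
  results are deterministic across platforms.
* **Set-size bounds (5, 2000)** after intersecting each set with the
  matrix's genes: smaller sets give noisy scores, an all-gene set leaves
  the out-of-set ECDF undefined. Dropped sets are logged.
* **No across-collection ES renormalization**: the downstream [0,1]
  min-max scaling supersedes it.

Features (sets x samples) are min-max scaled to [0,1] **on the training
cohort only**; query samples reuse the training minima/maxima and values
outside the training range are clipped. This gives both cohorts one scaling
convention without leaking query statistics into the fit. Constant training
features are flagged and mapped to 0. Optional clinical covariates (age,
sex, mutation flags) are appended as `meta:` features — numeric columns
min-max scaled with training statistics (missing -> training median),
categorical columns one-hot over training levels (missing -> all-zero row).

## Training: nine families, random search, repeated k-fold

Each compound trains independently (mechanisms of action differ, so the
best algorithm differs per compound). The fixed roster has nine base
families: three gradient-boosted tree variants (standard, extremely
randomized splits, and a large-capacity configuration), two k-nearest-
neighbour variants (uniform and distance weighting), two feed-forward
neural-network architectures (one and two hidden layers; the regression
target is internally standardized because adam on a far-from-zero AUC scale
stalls at desk-scale epoch budgets), a random forest, and extremely
randomized trees.

Per family, `n_trials` hyperparameter draws are sampled from the versioned
search spaces in `search_spaces.yaml`; each trial is scored by out-of-fold
(OOF) mean squared error under `repeats` x `k`-fold cross-validation
(per-sample OOF prediction = mean over the repeats that held it out). The
best trial's OOF vector and fold models are retained. The validation score
is -MSE of the OOF predictions (closer to zero is better); whether to score
on OOF or an inner holdout was an open choice — OOF was chosen and is
recorded in bundle provenance.

Defaults are desk-scale: `k=5, repeats=1, n_trials=16`. Large-cohort runs
use the flags (`repeats=3, n_trials=512`). Deployed predictions per family
are the mean over that family's fold models (bagging); this is also what
the second stacking level combines.

## Stack-two weighted ensemble

Weights over the nine families are fit by greedy forward selection **with
replacement** on the OOF matrix: start empty, repeatedly add the family
minimizing the running average's OOF MSE (budget 100 picks, ties broken by
roster order), return the best ensemble seen. Because the first pick is the
best single family and the best-so-far is tracked, the ensemble's OOF MSE
never exceeds the best base model's — asserted on every fit. The level-2
model is deliberately restricted to a convex combination (no level-2
learner), which keeps that guarantee and matches the "weighted ensemble"
contract. Empirically the greedy optimum also undercuts a dense
step-0.05 grid search over the weight simplex on random fixtures.

## Permutation importance and feature reduction

Importance of a feature is the drop in the deployed ensemble's score
(-MSE) when that feature's column is permuted, averaged over
`n_shuffle_sets` independent shuffles of a subsample (`subsample_size`
capped at n; full-scale convention is 5000 / 10 shuffle sets). The
shuffle-set distribution gives a dispersion and a one-sided t-test p-value
(H0: importance <= 0). Importance is computed against the ensemble — not
each base model — because the ranking must serve the bundle actually
deployed. Permutation RNGs derive from the master seed plus the feature
index.

Reduction keeps the top `max(1, floor(p*F))` features (presets p = 0.20,
0.10, 0.03; floor-with-minimum-1 because the rounding rule was
unspecified). Retraining re-runs the full hyperparameter search on the
restricted columns (the alternative — reusing tuned settings — is
supported by passing the previous parameters, but full re-search is the
default and is recorded in provenance). The restricted columns keep their
original order so that p = 1.0 reproduces the unreduced run bit for bit.

## Workflow conditions

Three training conditions are supported end to end: `base`; `glioma_plus`,
which narrows the training cohort to samples whose metadata disease label
matches a configured value (a disease-matched subset is expected to be more
homogeneous, at the cost of sample size); and `metadata_plus`, which
appends encoded clinical covariates (`meta:` features) to the enrichment
matrix for both training and query cohorts using training-fitted encoders.
The condition is recorded in every bundle's provenance.

## Downstream evaluation

* `regress_ic50_vs_auc`: OLS of log2(IC50) on predicted AUC
  (scipy linregress); R^2 equals the squared Pearson correlation, an
  identity the tests assert. Non-positive IC50 is an error; a constant
  predictor yields R^2 = 0 with a degeneracy flag.
* `response_embedding`: 2-D PCA (exact, deterministic) or t-SNE (seeded;
  default perplexity 30 capped at (n-1)/3) of items-by-profile matrices.
  Profiles are standardized per column by default — for patient-level
  embeddings of predicted AUC matrices this standardizes each compound
  before projection, a convention chosen here.
* `feature_contrast`: per group, a standardized one-vs-rest mean difference
  (difference of means over pooled SD, variance floor 1e-8). This statistic
  is this package's convention for "which features separate the groups",
  chosen for interpretability; it makes no biological-effect claim.

## Synthetic cohorts

The generator emulates the statistical shape of public training resources:
per sample one standard-normal latent activity per gene set; expression =
per-gene baseline (uniform 2..8 log2 units) + loading x activity for set
members + Gaussian noise, clipped at 0 (log2(TPM+1) nonnegativity); AUC_c =
beta0_c + sum over driver sets of beta x activity + Gaussian noise; labels
thinned at the missing fraction; an optional query cohort receives an
additive per-gene batch shift. Defaults (the study conditions for the test
suite): 1000 genes, 50 sets of 20 genes, loading 0.8, expression noise SD
0.3, AUC noise SD 0.3, baseline AUC 8 with effect sizes ~1-1.5 (a positive,
CTRP-like resistance scale), 10% missing labels, batch shift SD 0.5.

What it does **not** emulate: gene-gene correlation beyond set-driven
structure, dose-response curves (AUC is generated directly), count noise,
and real batch effects beyond an additive shift. Passing tests therefore
demonstrate that the machinery recovers planted signal under these
idealized conditions, not performance on real cohorts.

## Benchmark scenario sizes

The replication scenarios in `drugsens.benchmarks` are sized for a
single-CPU desk run:

* **Ensemble superiority**: 150 training samples, 400 held-out samples, 40
  sets, two driver pathways, `n_trials=4, repeats=3`; 20 seeded
  replicates. The large held-out cohort keeps the per-family MSE estimates
  tight enough that the comparison measures skill rather than evaluation
  noise. Held-out error is measured against the noiseless generative AUC.
* **Feature reduction**: 100 samples, 300 sets of 10 genes drawn from 1500
  genes (5 drivers at beta 1.0, 295 nuisance), `n_trials=2`; top-3%
  retention (9 of 300); 10 seeded replicates; importance with 4 shuffle
  sets on the full cohort. The gene pool is sized so sets overlap little —
  heavy overlap makes each set's score a mixture of several activities and
  the "driver" label ill-defined.
* **Recovery**: 200 training / 60 held-out samples, 20 near-disjoint sets
  over 800 genes; the strong-signal variant is fully noiseless with
  loading 1.0, the null variant replaces labels with i.i.d. noise.

## Numerical and degenerate-input conventions

Duplicate gene rows collapse to the highest-mean row (logged). Blank or
"NA" AUC cells are missing records; conflicting duplicate labels are an
error. Constant label vectors train with a warning (every family fits the
constant). Seeds everywhere derive deterministically from a master seed
(per compound: master + compound-ID hash, kept below 2^31), so per-compound
parallel scheduling cannot change numeric results. Neural-net determinism
is platform-conditional (single-threaded BLAS assumed); manifests are
byte-stable on one platform.

## Known limitations

* Gene identifiers are matched exactly and case-sensitively; no
  symbol/alias mapping.
* The extra symmetric-tree boosting variants and the "wider nonlinear
  feature" condition explored in large-cohort practice are out of scope;
  the roster is fixed at nine families.
* Validation-score magnitudes depend on the AUC scale of the label source;
  only comparisons between conditions are meaningful.
* t-SNE coordinates are seed-reproducible but not comparable across
  scikit-learn versions.
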