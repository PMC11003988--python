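"""Train one compound's nine-family predictor and its weighted ensemble.

Features are scaled to [0,1], each learner family is tuned by random search
under k-fold cross-validation, and a stack-two convex ensemble is fit on
the out-of-fold predictions. Validation scores are negative OOF MSE: closer
to zero is better, and the ensemble is never worse than the best single
family on the training OOF by construction.
"""

from drugsens import (
    SyntheticSpec,
    TrainingConfig,
    align_training_pairs,
    fit_predictor,
    simulate_cohort,
    ssgsea_matrix,
)

spec = SyntheticSpec(
    n_samples=100,
    n_genes=400,
    n_sets=20,
    set_size=15,
    drivers={"alkylator_x": {"SET0001": 1.5, "SET0003": 0.8}},
    seed=13,
)
expression, gene_sets, labels, _, truth = simulate_cohort(spec)
features = ssgsea_matrix(expression, gene_sets).as_features()

paired, y = align_training_pairs(features.T, labels, "alkylator_x")
config = TrainingConfig(k=5, repeats=1, n_trials=2, seed=99)
bundle = fit_predictor(features.loc[paired], y, config, "alkylator_x")

print("validation scores (negative OOF MSE; closer to 0 is better):")
for family, score in sorted(bundle.validation_scores.items(), key=lambda kv: -kv[1]):
    marker = " <- stack-two ensemble" if family == "weighted_ensemble" else ""
    print(f"  {family:20s} {score:8.4f}{marker}")

print("\nensemble weights (convex combination over families):")
for family, w in bundle.ensemble.weights.items():
    if w > 0:
        print(f"  {family:20s} {w:.3f}")

pred = bundle.predict(features.loc[paired][:5])
print("\npredicted AUC for the first five training samples "
      "(larger = more resistant):")
for sid, p in zip(paired[:5], pred):
    print(f"  {sid}: {p:.2f}")
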