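"""Downstream evaluation: IC50 regression, response embeddings, contrasts.

Shows the three interpretation tools on constructed inputs: an ordinary
least-squares fit of measured log2(IC50) against predicted AUC, a 2-D PCA
embedding of compound response profiles with two planted mechanism
clusters, and a group-wise standardized feature contrast.
"""

import numpy as np
import pandas as pd

from drugsens import feature_contrast, regress_ic50_vs_auc, response_embedding

rng = np.random.default_rng(3)

# --- IC50 vs predicted AUC -------------------------------------------------
predicted_auc = rng.uniform(6, 12, size=9)
log2_ic50 = 1.8 * predicted_auc - 10 + rng.normal(scale=0.6, size=9)
report = regress_ic50_vs_auc(2.0**log2_ic50, predicted_auc, condition="demo")
print("log2(IC50) ~ predicted AUC (9 compounds):")
print(f"  slope={report.slope:.2f} intercept={report.intercept:.2f} "
      f"R^2={report.r_squared:.3f} n={report.n}")
print("  (high R^2: the predicted resistance ordering matches measured potency)")

# --- embedding of compound response profiles --------------------------------
profiles = pd.DataFrame(
    np.vstack([rng.normal(2, 0.3, size=(5, 30)), rng.normal(-2, 0.3, size=(5, 30))]),
    index=[f"mechA_{i}" for i in range(5)] + [f"mechB_{i}" for i in range(5)],
)
emb = response_embedding(profiles, method="pca", seed=0)
print("\nPCA of compound response profiles (two planted mechanism groups):")
print(emb.coordinates.round(2).to_string())
print(f"  explained variance: {[round(v, 3) for v in emb.explained_variance]}")
print("  (group A and group B separate along the first axis)")

# --- group-wise feature contrast --------------------------------------------
feats = pd.DataFrame(rng.uniform(size=(12, 4)),
                     index=[f"s{i}" for i in range(12)],
                     columns=["angiogenesis", "hypoxia", "cytokine", "glycolysis"])
groups = pd.Series(["co_culture"] * 6 + ["sphere"] * 6, index=feats.index)
feats.loc[groups == "co_culture", "angiogenesis"] += 2.0
contrasts = feature_contrast(feats, groups, top_k=2)
print("\ntop contrasting features per group (standardized one-vs-rest mean diff):")
for group, table in contrasts.items():
    row = table.iloc[0]
    print(f"  {group}: {row['feature']} ({row['contrast']:+.2f})")
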