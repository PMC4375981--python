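"""PCA preprocessing and multivariate regression trees.

Reduces the eight growth/branch traits to two principal components, then
partitions genotype-level multivariate phenotypes (PC1, PC2, BS, BF,
I-20, delta-13C) twice: once with geography (latitude, longitude,
altitude) and once with climate variables as predictors, each to five
leaves, reporting explained variance, per-node equivalent splits, and
leaf trait profiles.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from gardenqg import mrt, traits

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
pheno = pd.read_csv(OUT / "phenotypes.csv")
predictors = pd.read_csv(OUT / "predictors.csv", index_col=0)

means = pheno.groupby(["population", "genotype"])[traits.TRAIT_NAMES].mean()
pca = mrt.pca_growth(means[traits.GROWTH_BRANCH_TRAITS], n_components=2)
print(f"PCA: first two components explain "
      f"{100 * pca.cumulative_fraction:.1f}% of growth/branch variance")

responses = pd.concat([pca.scores, means[["BS", "BF", "I20", "d13C"]]], axis=1).dropna()
pred_rows = predictors.loc[
    responses.index.get_level_values("population")
].set_index(responses.index)

for label, cols in (
    ("geography", ["latitude", "longitude", "altitude"]),
    ("climate", [c for c in predictors.columns if c.startswith("clim")]),
):
    tree = mrt.fit_mrt(responses, pred_rows[cols], max_leaves=5, min_node_size=5)
    tree.to_json(OUT / f"mrt_{label}.json")
    mrt.leaf_profiles(tree, responses).to_csv(
        OUT / f"mrt_{label}_profiles.csv", index=False
    )
    equiv = mrt.surrogate_equivalent_splits(tree, responses, pred_rows[cols])
    print(f"\n{label} tree: {tree.n_leaves} leaves, "
          f"{100 * tree.variance_explained:.1f}% variance explained")
    print(tree.render())
    root_alt = [v for v, _ in equiv[tree.root.node_id] if v != tree.root.split_var]
    if root_alt:
        print(f"root split equivalently possible on: {sorted(set(root_alt))}")
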