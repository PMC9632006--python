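"""Re-represent samples by the tree leaves they fall into (one-of-K per tree).

A first boosted ensemble is fit on the original features; each sample is then
encoded by one binary block per tree with a single 1 marking its leaf.  The
encoding is concatenated with the original features for the final model.
"""

import numpy as np

from xgbcda import (
    BoosterParams,
    FeatureBooster,
    LeafColumnMap,
    one_hot_leaves,
    sample_negatives,
    stack_features,
    SyntheticConfig,
    generate_dataset,
)
from xgbcda.features import FeatureConfig, build_pair_features

ds = generate_dataset(SyntheticConfig(n_circ=50, n_dis=20, seed=5))
pos = ds.assoc.positive_pairs()
pairs = pos + sample_negatives(ds.assoc, len(pos), seed=5)
labels = np.array([1] * len(pos) + [0] * len(pos))
table = build_pair_features(ds.assoc, ds.expr, ds.dsim, pairs, labels, FeatureConfig())

params = BoosterParams(n_estimators=50).to_xgb_kwargs()
fb = FeatureBooster(params, seed=0).fit(table.values, labels)
enc = fb.encode(table.values)
print(f"{fb.leaf_map.n_trees} trees, {fb.leaf_map.total_leaves} leaves total")
print(f"every row sums to the tree count: {sorted({int(s) for s in enc.values.sum(axis=1)})}")

stacked = stack_features(table, enc)
print(f"stacked width: {table.width} original + {fb.leaf_map.total_leaves} latent "
      f"= {stacked.width}")

# the toy layout: tree with 3 leaves + tree with 2 leaves,
# sample in leaf 1 of the first and leaf 2 of the second
stub = LeafColumnMap([np.array([1, 3, 4]), np.array([1, 2])])
print("toy encoding:", one_hot_leaves(np.array([[1, 2]]), stub).values[0].tolist())
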