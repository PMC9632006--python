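"""Boosted-tree leaf embedding: one-of-K leaf membership per tree.

A first gradient-boosted classifier is fit on the original pair features.
Each sample is then re-represented by which leaf it falls into in each tree
of the ensemble: one binary block of columns per tree, exactly one 1 per
block.  For an ensemble whose first tree has three leaves and whose second
has two, a sample landing in leaf 1 of tree 1 and leaf 2 of tree 2 encodes
as [1, 0, 0, 0, 1].  These latent features are concatenated with the
original features for the final classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xgboost as xgb

from .errors import ValidationError, XgbcdaError
from .features import PairFeatureTable

__all__ = ["LeafColumnMap", "LeafEncoding", "FeatureBooster", "one_hot_leaves", "stack_features"]


@dataclass
class LeafColumnMap:
    """Dense column layout of every leaf of every tree, fixed at fit time.

    ``tree_leaves[t]`` lists tree ``t``'s native leaf node ids in ascending
    order; the encoding column of (tree t, leaf id L) is
    ``offset(t) + tree_leaves[t].index(L)``.
    """

    tree_leaves: list[np.ndarray]

    def __post_init__(self) -> None:
        self.tree_leaves = [np.asarray(l) for l in self.tree_leaves]
        if any(l.size == 0 for l in self.tree_leaves):
            raise ValidationError("every tree must have at least one leaf")

    @property
    def n_trees(self) -> int:
        return len(self.tree_leaves)

    @property
    def total_leaves(self) -> int:
        return int(sum(l.size for l in self.tree_leaves))

    @property
    def columns(self) -> list[tuple[int, int]]:
        """(tree index, leaf position) for every encoding column, tree-major."""
        return [(t, p) for t, leaves in enumerate(self.tree_leaves) for p in range(leaves.size)]


@dataclass
class LeafEncoding:
    """Binary n_samples x total_leaves matrix, one 1 per tree per sample."""

    columns: list[tuple[int, int]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValidationError("leaf encoding shape does not match its column map")

    @property
    def n_trees(self) -> int:
        return len({t for t, _ in self.columns})


def one_hot_leaves(leaf_matrix: np.ndarray, leaf_map: LeafColumnMap) -> LeafEncoding:
    """Expand per-tree leaf assignments into the one-of-K encoding.

    ``leaf_matrix[s, t]`` is the native leaf id sample ``s`` reaches in tree
    ``t``.  A leaf id absent from the fit-time map cannot occur for a tree
    traversal and is reported as an internal error.
    """
    leaf_matrix = np.atleast_2d(np.asarray(leaf_matrix))
    if leaf_matrix.shape[1] != leaf_map.n_trees:
        raise ValidationError(
            f"leaf matrix has {leaf_matrix.shape[1]} trees, map has {leaf_map.n_trees}"
        )
    n = leaf_matrix.shape[0]
    out = np.zeros((n, leaf_map.total_leaves), dtype=np.uint8)
    offset = 0
    for t, leaves in enumerate(leaf_map.tree_leaves):
        pos = np.searchsorted(leaves, leaf_matrix[:, t])
        bad = (pos >= leaves.size) | (leaves[np.minimum(pos, leaves.size - 1)] != leaf_matrix[:, t])
        if bad.any():
            raise XgbcdaError(
                f"internal error: unseen leaf id {leaf_matrix[bad, t][0]} in tree {t}"
            )
        out[np.arange(n), offset + pos] = 1
        offset += leaves.size
    return LeafEncoding(leaf_map.columns, out)


class FeatureBooster:
    """First-stage boosted classifier used only as a leaf-embedding extractor."""

    def __init__(self, xgb_params: dict, seed: int = 0):
        self.xgb_params = dict(xgb_params)
        self.seed = seed
        self.model: xgb.XGBClassifier | None = None
        self.leaf_map: LeafColumnMap | None = None
        self._n_features: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FeatureBooster":
        X = np.asarray(X)
        y = np.asarray(y)
        if X.shape[0] < 2:
            raise ValidationError("need >= 2 samples to fit the feature booster")
        if len(np.unique(y)) < 2:
            raise ValidationError("feature booster needs both classes present")
        self.model = xgb.XGBClassifier(random_state=self.seed, **self.xgb_params)
        self.model.fit(X, y)
        self._n_features = X.shape[1]
        booster = self.model.get_booster()
        df = booster.trees_to_dataframe()
        leaves = df[df["Feature"] == "Leaf"]
        n_trees = int(df["Tree"].max()) + 1
        tree_leaves = [
            np.sort(leaves.loc[leaves["Tree"] == t, "Node"].to_numpy()) for t in range(n_trees)
        ]
        self.leaf_map = LeafColumnMap(tree_leaves)
        return self

    def encode(self, X: np.ndarray) -> LeafEncoding:
        """One-of-K leaf membership of each row of X in every tree."""
        if self.model is None or self.leaf_map is None:
            raise ValidationError("feature booster is not fitted")
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self._n_features:
            raise ValidationError(
                f"expected {self._n_features} feature columns, got {X.shape[1] if X.ndim == 2 else 'non-2D input'}"
            )
        leaf_matrix = self.model.apply(X)
        return one_hot_leaves(leaf_matrix, self.leaf_map)


def stack_features(original: PairFeatureTable, encoding: LeafEncoding) -> PairFeatureTable:
    """Concatenate original feature columns with the leaf encoding columns."""
    if encoding.values.shape[0] != len(original.pairs):
        raise ValidationError(
            f"row mismatch: {len(original.pairs)} feature rows vs "
            f"{encoding.values.shape[0]} encoded rows"
        )
    leaf_cols = [f"leaf_t{t}_l{p}" for t, p in encoding.columns]
    values = np.hstack([original.values, encoding.values.astype(np.float32)])
    return PairFeatureTable(
        list(original.pairs), list(original.columns) + leaf_cols, values, original.labels
    )
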