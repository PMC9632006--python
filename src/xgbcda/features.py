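"""Per-pair feature engineering from the similarity networks and A.

Each (circRNA, disease) candidate pair is described by the concatenation of

* a statistical/graph block for the circRNA node of the integrated circRNA
  similarity matrix CS, and the same block for the disease node of DS:
  mean similarity, 10-bin histogram of similarities, neighbor count in the
  thresholded similarity graph, degree/closeness/betweenness centrality,
  and the mean + histogram of the top-k most similar nodes (k = 10);
* the circRNA's row of W and the disease's column of H from a rank-r
  non-negative matrix factorization A ~ W H of the association matrix.

The similarity graph places an (unweighted, undirected) edge between two
nodes whenever their similarity strictly exceeds the global mean of the
off-diagonal entries of the similarity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.decomposition import NMF

from .errors import ValidationError
from .io_data import AssociationMatrix, ExpressionProfileSet, SimilarityMatrix
from .similarity import (
    GipConfig,
    PearsonConfig,
    expand_similarity,
    expression_profile_similarity,
    gip_kernel,
    integrate_similarity,
)

__all__ = [
    "FeatureConfig",
    "NmfLatent",
    "PairFeatureTable",
    "similarity_stats",
    "build_similarity_graph",
    "centrality_features",
    "all_centralities",
    "topk_neighbor_stats",
    "nmf_latent",
    "assemble_pair_features",
    "build_pair_features",
]


@dataclass
class FeatureConfig:
    """Settings for the feature blocks; defaults match the method's choices."""

    n_bins: int = 10
    top_k: int = 10
    nmf_rank: int = 8
    nmf_seed: int = 42
    nmf_max_iter: int = 500
    nmf_tol: float = 1e-6
    pearson_threshold: float = 0.4
    gamma_prime_circ: float = 1.0
    gamma_prime_disease: float = 1.0


@dataclass
class NmfLatent:
    """Non-negative factors A ~ circ_factors @ disease_factors."""

    circ_ids: list[str]
    disease_ids: list[str]
    circ_factors: np.ndarray  # n_circ x rank
    disease_factors: np.ndarray  # rank x n_disease
    rank: int

    def circ_vector(self, circ: str) -> np.ndarray:
        return self.circ_factors[self.circ_ids.index(circ)]

    def disease_vector(self, disease: str) -> np.ndarray:
        return self.disease_factors[:, self.disease_ids.index(disease)]


@dataclass
class PairFeatureTable:
    """One feature row per (circRNA, disease) candidate pair."""

    pairs: list[tuple[str, str]]
    columns: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None  # 1/0, or None for unlabeled candidates

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != (len(self.pairs), len(self.columns)):
            raise ValidationError("feature matrix shape does not match pairs/columns")
        if not np.isfinite(self.values).all():
            raise ValidationError("feature table contains non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (len(self.pairs),):
                raise ValidationError("labels length does not match pair count")

    @property
    def width(self) -> int:
        return len(self.columns)

    def subset(self, idx: Sequence[int]) -> "PairFeatureTable":
        idx = np.asarray(idx, dtype=int)
        return PairFeatureTable(
            [self.pairs[i] for i in idx],
            list(self.columns),
            self.values[idx],
            None if self.labels is None else self.labels[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "circRNA", [c for c, _ in self.pairs])
        df.insert(1, "disease", [d for _, d in self.pairs])
        if self.labels is not None:
            df["label"] = self.labels
        return df

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), sep="\t", index=False, float_format="%.8g")


def _offdiag_row(sim: SimilarityMatrix, node: str) -> np.ndarray:
    i = sim.index_of(node)
    return np.delete(sim.values[i], i)


def similarity_stats(
    sim: SimilarityMatrix, node: str, n_bins: int = 10
) -> tuple[float, np.ndarray]:
    """Mean and equal-width histogram over [0, 1] of a node's similarities.

    Self-similarity (the diagonal) is excluded.  A single-node network has no
    neighbors: the mean is 0 and the histogram all-zero.
    """
    vals = _offdiag_row(sim, node)
    if vals.size == 0:
        return 0.0, np.zeros(n_bins, dtype=float)
    hist, _ = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    return float(vals.mean()), hist.astype(float)


def build_similarity_graph(sim: SimilarityMatrix) -> nx.Graph:
    """Unweighted graph with an edge wherever similarity exceeds the global mean.

    The threshold is the mean of the off-diagonal entries of the whole matrix;
    the comparison is strict, so a perfectly uniform matrix yields no edges.
    """
    n = sim.n
    if n < 2:
        raise ValidationError("similarity graph needs >= 2 nodes")
    vals = sim.values
    off = vals[~np.eye(n, dtype=bool)]
    mean = off.mean()
    g = nx.Graph()
    g.add_nodes_from(sim.ids)
    rows, cols = np.nonzero(np.triu(vals > mean, k=1))
    g.add_edges_from((sim.ids[i], sim.ids[j]) for i, j in zip(rows, cols))
    return g


def all_centralities(graph: nx.Graph) -> dict[str, tuple[int, float, float, float]]:
    """(n_neighbors, degree, closeness, betweenness) for every node.

    Degree centrality is degree/(n-1).  Closeness uses the improved
    (Wasserman-Faust) convention: within-component closeness scaled by
    (component size - 1)/(n - 1), so isolated nodes score 0.  Betweenness is
    normalized shortest-path betweenness.
    """
    deg = nx.degree_centrality(graph)
    clo = nx.closeness_centrality(graph, wf_improved=True)
    bet = nx.betweenness_centrality(graph, normalized=True)
    return {
        v: (graph.degree(v), deg[v], clo[v], bet[v]) for v in graph.nodes
    }


def centrality_features(graph: nx.Graph, node: str) -> tuple[int, float, float, float]:
    """Neighbor count plus the three normalized centralities of one node."""
    if node not in graph:
        raise KeyError(f"unknown node id {node!r}")
    return all_centralities(graph)[node]


def topk_neighbor_stats(
    sim: SimilarityMatrix, node: str, k: int = 10, n_bins: int = 10
) -> tuple[float, np.ndarray]:
    """Mean and histogram of the node's k highest similarity scores.

    Self is excluded; ties are broken by id order; if fewer than k other
    nodes exist, all of them are used.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    vals = _offdiag_row(sim, node)
    if vals.size == 0:
        return 0.0, np.zeros(n_bins, dtype=float)
    order = np.argsort(-vals, kind="stable")  # stable sort -> id-order tie-break
    top = vals[order[: min(k, vals.size)]]
    hist, _ = np.histogram(top, bins=n_bins, range=(0.0, 1.0))
    return float(top.mean()), hist.astype(float)


def nmf_latent(
    assoc: AssociationMatrix,
    rank: int = 8,
    seed: int = 42,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NmfLatent:
    """Rank-r non-negative factorization of A by multiplicative updates.

    Deterministic given ``seed`` (random non-negative initialization).  The
    all-zero matrix factors exactly into zero factors and skips the solver.
    """
    n_c, n_d = assoc.values.shape
    if not 1 <= rank <= min(n_c, n_d):
        raise ValidationError(f"NMF rank must lie in [1, {min(n_c, n_d)}], got {rank}")
    A = assoc.values.astype(float)
    if not A.any():
        W = np.zeros((n_c, rank))
        H = np.zeros((rank, n_d))
    else:
        model = NMF(
            n_components=rank,
            init="random",
            solver="mu",
            beta_loss="frobenius",
            max_iter=max_iter,
            tol=tol,
            random_state=seed,
        )
        W = model.fit_transform(A)
        H = model.components_
    return NmfLatent(list(assoc.circ_ids), list(assoc.disease_ids), W, H, rank)


_BLOCK_FIELDS = ("mean_sim", "hist", "n_neighbors", "degree_c", "closeness_c", "betweenness_c", "topk_mean", "topk_hist")


def _node_block_columns(prefix: str, n_bins: int) -> list[str]:
    cols = [f"{prefix}_mean_sim"]
    cols += [f"{prefix}_hist_{b}" for b in range(n_bins)]
    cols += [f"{prefix}_n_neighbors", f"{prefix}_degree_c", f"{prefix}_closeness_c", f"{prefix}_betweenness_c"]
    cols += [f"{prefix}_topk_mean"]
    cols += [f"{prefix}_topk_hist_{b}" for b in range(n_bins)]
    return cols


def _node_blocks(sim: SimilarityMatrix, n_bins: int, k: int) -> dict[str, np.ndarray]:
    """Full statistical/graph feature block for every node of one network."""
    graph = build_similarity_graph(sim)
    cents = all_centralities(graph)
    blocks: dict[str, np.ndarray] = {}
    for node in sim.ids:
        mean_sim, hist = similarity_stats(sim, node, n_bins)
        nn, deg, clo, bet = cents[node]
        tk_mean, tk_hist = topk_neighbor_stats(sim, node, k, n_bins)
        blocks[node] = np.concatenate(
            [[mean_sim], hist, [nn, deg, clo, bet, tk_mean], tk_hist]
        )
    return blocks


def assemble_pair_features(
    cs: SimilarityMatrix,
    ds: SimilarityMatrix,
    latent: NmfLatent,
    pairs: Sequence[tuple[str, str]],
    labels: Sequence[int] | None = None,
    n_bins: int = 10,
    top_k: int = 10,
) -> PairFeatureTable:
    """Concatenate node blocks and NMF latents into one row per pair.

    Column order (fixed): circRNA block, disease block, circRNA latent row,
    disease latent column.  Total width is 2*(2*n_bins + 6) + 2*rank.
    """
    circ_blocks = _node_blocks(cs, n_bins, top_k)
    dis_blocks = _node_blocks(ds, n_bins, top_k)
    rows = []
    for c, d in pairs:
        if c not in circ_blocks:
            raise KeyError(f"unknown circRNA id {c!r}")
        if d not in dis_blocks:
            raise KeyError(f"unknown disease id {d!r}")
        rows.append(
            np.concatenate(
                [circ_blocks[c], dis_blocks[d], latent.circ_vector(c), latent.disease_vector(d)]
            )
        )
    columns = (
        _node_block_columns("circ", n_bins)
        + _node_block_columns("dis", n_bins)
        + [f"circ_nmf_{r}" for r in range(latent.rank)]
        + [f"dis_nmf_{r}" for r in range(latent.rank)]
    )
    values = np.asarray(rows, dtype=np.float32).reshape(len(pairs), len(columns))
    return PairFeatureTable(list(pairs), columns, values, None if labels is None else np.asarray(labels))


def build_pair_features(
    assoc: AssociationMatrix,
    expr: ExpressionProfileSet | None,
    dsim_semantic: SimilarityMatrix | None,
    pairs: Sequence[tuple[str, str]],
    labels: Sequence[int] | None = None,
    cfg: FeatureConfig | None = None,
) -> PairFeatureTable:
    """End-to-end feature construction from the three input tables.

    Builds CS (expression-profile similarity with GIP fallback) and DS
    (semantic similarity with GIP fallback) from the given association
    matrix — pass a masked A here to keep held-out test associations out of
    the kernels and the NMF — then assembles the pair feature table.
    """
    cfg = cfg or FeatureConfig()
    cs_gip = gip_kernel(assoc, "circRNA", GipConfig(cfg.gamma_prime_circ))
    if expr is not None and len(expr.circ_ids) > 0:
        cs_ep = expression_profile_similarity(expr, PearsonConfig(cfg.pearson_threshold))
        cs_ep = expand_similarity(cs_ep, assoc.circ_ids)
        cs = integrate_similarity(cs_ep, cs_gip)
    else:
        cs = cs_gip
    ds_gip = gip_kernel(assoc, "disease", GipConfig(cfg.gamma_prime_disease))
    if dsim_semantic is not None:
        if dsim_semantic.ids != assoc.disease_ids:
            dsim_semantic = expand_similarity(dsim_semantic, assoc.disease_ids)
        ds = integrate_similarity(dsim_semantic, ds_gip)
    else:
        ds = ds_gip
    latent = nmf_latent(assoc, cfg.nmf_rank, cfg.nmf_seed, cfg.nmf_max_iter, cfg.nmf_tol)
    return assemble_pair_features(cs, ds, latent, pairs, labels, cfg.n_bins, cfg.top_k)
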