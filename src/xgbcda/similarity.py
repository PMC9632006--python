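"""Similarity networks: expression-profile, GIP kernel, and their integration.

Three similarity notions are combined into the integrated circRNA matrix CS
and disease matrix DS:

* **Expression-profile similarity** CS_EP: Pearson correlation between two
  circRNA expression profiles, binarized at a threshold (default 0.4) —
  entries are 1 where the correlation strictly exceeds the threshold, else 0.
* **Gaussian interaction-profile (GIP) kernel similarity**:
  ``K(i, j) = exp(-gamma * ||y_i - y_j||^2)`` where ``y`` are the binary
  interaction profiles (rows of A for circRNAs, columns for diseases) and the
  bandwidth ``gamma = gamma' / mean_i ||y_i||^2`` is normalized by the mean
  squared profile norm; ``gamma' = 1`` by the van Laarhoven convention.
* **Integration**: the primary similarity (expression or semantic) is kept
  wherever it is nonzero; the GIP kernel fills in everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io_data import AssociationMatrix, ExpressionProfileSet, SimilarityMatrix

__all__ = [
    "GipConfig",
    "PearsonConfig",
    "expression_profile_similarity",
    "gip_kernel",
    "integrate_similarity",
    "expand_similarity",
]


@dataclass
class GipConfig:
    """Bandwidth numerator gamma' of the GIP kernel (must be positive)."""

    gamma_prime: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma_prime > 0:
            raise ValidationError("gamma_prime must be > 0")


@dataclass
class PearsonConfig:
    """Binarization threshold for expression-profile Pearson correlation."""

    threshold: float = 0.4

    def __post_init__(self) -> None:
        if not -1.0 <= self.threshold <= 1.0:
            raise ValidationError("Pearson threshold must lie in [-1, 1]")


def expression_profile_similarity(
    expr: ExpressionProfileSet, cfg: PearsonConfig | None = None
) -> SimilarityMatrix:
    """Binarized Pearson similarity CS_EP between circRNA expression profiles.

    CS_EP(i, j) = 1 if r(X_i, X_j) > threshold else 0; the diagonal is forced
    to 1.  Constant (zero-variance) profiles have r defined as 0, so they
    never clear the threshold and the integrated similarity falls back to the
    GIP kernel for them.
    """
    cfg = cfg or PearsonConfig()
    X = expr.values
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    r = np.atleast_2d(r)
    r = np.nan_to_num(r, nan=0.0)  # zero-variance profiles -> r := 0
    sim = (r > cfg.threshold).astype(float)
    sim = np.maximum(sim, sim.T)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(list(expr.circ_ids), sim)


def gip_kernel(
    assoc: AssociationMatrix, axis: str, cfg: GipConfig | None = None
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over rows or columns of A.

    Parameters
    ----------
    axis
        ``"circRNA"`` takes profiles as rows of A, ``"disease"`` as columns.
    """
    cfg = cfg or GipConfig()
    if axis == "circRNA":
        profiles = assoc.values.astype(float)
        ids = assoc.circ_ids
    elif axis == "disease":
        profiles = assoc.values.T.astype(float)
        ids = assoc.disease_ids
    else:
        raise ValidationError(f"axis must be 'circRNA' or 'disease', got {axis!r}")
    norms2 = np.einsum("ij,ij->i", profiles, profiles)
    mean_norm2 = norms2.mean()
    if mean_norm2 == 0:
        raise ValidationError("GIP bandwidth undefined (division by zero)")
    gamma = cfg.gamma_prime / mean_norm2
    # ||y_i - y_j||^2 via the Gram matrix; clip tiny negative round-off
    sq_dist = norms2[:, None] + norms2[None, :] - 2.0 * profiles @ profiles.T
    sq_dist = np.maximum(sq_dist, 0.0)
    K = np.exp(-gamma * sq_dist)
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return SimilarityMatrix(list(ids), K)


def integrate_similarity(
    primary: SimilarityMatrix, fallback: SimilarityMatrix
) -> SimilarityMatrix:
    """Piecewise fusion: primary where nonzero, fallback elsewhere."""
    if primary.ids != fallback.ids:
        raise ValidationError("integrate_similarity: id sets/order differ between inputs")
    out = np.where(primary.values != 0, primary.values, fallback.values)
    return SimilarityMatrix(list(primary.ids), out)


def expand_similarity(sim: SimilarityMatrix, ids: Sequence[str]) -> SimilarityMatrix:
    """Embed ``sim`` into a larger id universe.

    Entries involving an id absent from ``sim`` are 0 off-diagonal (so the
    integrated similarity falls back to the GIP kernel there) and 1 on the
    diagonal (self-similarity).
    """
    ids = list(ids)
    missing = set(sim.ids) - set(ids)
    if missing:
        raise ValidationError(f"expand_similarity: target universe lacks ids {sorted(missing)}")
    pos = {node: k for k, node in enumerate(ids)}
    out = np.zeros((len(ids), len(ids)))
    np.fill_diagonal(out, 1.0)
    idx = np.array([pos[node] for node in sim.ids], dtype=int)
    out[np.ix_(idx, idx)] = sim.values
    return SimilarityMatrix(ids, out)
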