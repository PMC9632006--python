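"""Synthetic benchmark generator with planted block structure.

The generator emulates the structure the method exploits — similar circRNAs
associate with similar diseases — at desk scale.  circRNAs and diseases are
assigned round-robin to groups; each circRNA group is matched to the disease
group with the same index.  Associations inside a matched block occur with
probability ``p_in`` and outside with ``p_out`` (defaults 0.3 / 0.01, giving
roughly the sparsity of curated circRNA-disease catalogs).  Expression
profiles share a per-group template with Gaussian noise tuned so the
expected within-group Pearson correlation is about ``rho_in``; the disease
similarity matrix is ``sim_in`` within groups and ``sim_out`` across, with a
unit diagonal.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io_data import AssociationMatrix, ExpressionProfileSet, SimilarityMatrix

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset", "heldout_split"]


@dataclass
class SyntheticConfig:
    n_circ: int = 200
    n_dis: int = 60
    n_samples: int = 49
    n_circ_groups: int = 5
    n_dis_groups: int = 5
    p_in: float = 0.3
    p_out: float = 0.01
    rho_in: float = 0.8
    sim_in: float = 0.7
    sim_out: float = 0.1
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValidationError("need 0 <= p_out < p_in <= 1")
        if not (0 <= self.rho_in < 1):
            raise ValidationError("need 0 <= rho_in < 1")
        if not (0 <= self.sim_out < self.sim_in <= 1):
            raise ValidationError("need 0 <= sim_out < sim_in <= 1")
        if min(self.n_circ, self.n_dis, self.n_samples, self.n_circ_groups, self.n_dis_groups) < 1:
            raise ValidationError("all sizes must be >= 1")
        if self.n_samples < 2:
            raise ValidationError("need >= 2 expression samples")


@dataclass
class SyntheticDataset:
    assoc: AssociationMatrix
    expr: ExpressionProfileSet
    dsim: SimilarityMatrix
    circ_groups: np.ndarray = field(default_factory=lambda: np.array([]))
    dis_groups: np.ndarray = field(default_factory=lambda: np.array([]))

    def __iter__(self):
        return iter((self.assoc, self.expr, self.dsim))


def generate_dataset(cfg: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate association, expression and disease-similarity tables."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    circ_ids = [f"circ_{i:04d}" for i in range(cfg.n_circ)]
    dis_ids = [f"disease_{j:03d}" for j in range(cfg.n_dis)]
    circ_groups = np.arange(cfg.n_circ) % cfg.n_circ_groups
    dis_groups = np.arange(cfg.n_dis) % cfg.n_dis_groups

    matched = circ_groups[:, None] == dis_groups[None, :]
    probs = np.where(matched, cfg.p_in, cfg.p_out)
    A = (rng.random((cfg.n_circ, cfg.n_dis)) < probs).astype(np.int8)
    assoc = AssociationMatrix(circ_ids, dis_ids, A)

    # profile = sqrt(rho) * group template + sqrt(1-rho) * noise
    # -> expected within-group Pearson ~ rho_in
    templates = rng.standard_normal((cfg.n_circ_groups, cfg.n_samples))
    noise = rng.standard_normal((cfg.n_circ, cfg.n_samples))
    X = np.sqrt(cfg.rho_in) * templates[circ_groups] + np.sqrt(1 - cfg.rho_in) * noise
    expr = ExpressionProfileSet(circ_ids, [f"sample_{s:02d}" for s in range(cfg.n_samples)], X)

    D = np.where(dis_groups[:, None] == dis_groups[None, :], cfg.sim_in, cfg.sim_out)
    np.fill_diagonal(D, 1.0)
    dsim = SimilarityMatrix(dis_ids, D.astype(float))

    return SyntheticDataset(assoc, expr, dsim, circ_groups, dis_groups)


def heldout_split(
    dataset: SyntheticDataset, fraction: float, seed: int = 0
) -> tuple[SyntheticDataset, list[tuple[str, str]]]:
    """Zero a fraction of the positive associations and return them separately.

    The number held out is round(fraction * n_positives); held-out pairs are
    disjoint from the remaining training positives.
    """
    if not 0 < fraction < 1:
        raise ValidationError("fraction must lie in (0, 1)")
    positives = dataset.assoc.positive_pairs()
    n_hold = round(fraction * len(positives))
    if len(positives) - n_hold < 1:
        raise ValidationError("too few positives to hold any out")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(positives), size=n_hold, replace=False)
    held = [positives[i] for i in sorted(idx)]
    train = SyntheticDataset(
        dataset.assoc.with_zeroed(held),
        dataset.expr,
        dataset.dsim,
        dataset.circ_groups,
        dataset.dis_groups,
    )
    return train, held
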