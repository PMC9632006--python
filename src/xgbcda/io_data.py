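"""Input tables and core matrix containers.

The pipeline consumes three tables:

* a binary circRNA x disease association matrix ``A`` (edge list or labeled
  matrix), whose rows are circRNA interaction profiles and whose columns are
  disease interaction profiles;
* a circRNA expression-profile matrix (circRNA x sample);
* a precomputed square disease-disease semantic similarity matrix.

All files are UTF-8 TSV/CSV with a header row and first-column row labels
(matrices) or two columns (edge lists; an optional third column is ignored).
Identifiers are matched by exact string equality after whitespace trimming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationMatrix",
    "ExpressionProfileSet",
    "SimilarityMatrix",
    "HarmonizedData",
    "load_association_table",
    "save_association_table",
    "load_expression_profiles",
    "save_expression_profiles",
    "load_similarity_matrix",
    "save_similarity_matrix",
    "harmonize_ids",
]

_SYMMETRY_TOL = 1e-9


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i).strip() for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate {what} identifiers: {dupes}")
    return ids


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


@dataclass
class AssociationMatrix:
    """Binary circRNA x disease association matrix A.

    ``values[i, j] == 1`` iff circRNA ``circ_ids[i]`` is associated with
    disease ``disease_ids[j]``. Row ``i`` is the interaction profile of a
    circRNA; column ``j`` is the interaction profile of a disease.
    """

    circ_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.circ_ids = _check_unique(self.circ_ids, "circRNA")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.circ_ids), len(self.disease_ids)):
            raise ValidationError(
                f"association matrix shape {self.values.shape} does not match "
                f"{len(self.circ_ids)} circRNAs x {len(self.disease_ids)} diseases"
            )
        if self.values.size == 0:
            raise ValidationError("association matrix must have >= 1 row and column")
        if not np.isin(self.values, (0, 1)).all():
            bad = self.values[~np.isin(self.values, (0, 1))].flat[0]
            raise ValidationError(f"association matrix entries must be 0/1, found {bad!r}")
        self.values = self.values.astype(np.int8)

    @property
    def n_circ(self) -> int:
        return len(self.circ_ids)

    @property
    def n_disease(self) -> int:
        return len(self.disease_ids)

    def positive_pairs(self) -> list[tuple[str, str]]:
        """All (circRNA id, disease id) pairs with a known association."""
        rows, cols = np.nonzero(self.values)
        return [(self.circ_ids[r], self.disease_ids[c]) for r, c in zip(rows, cols)]

    def with_zeroed(self, pairs: Iterable[tuple[str, str]]) -> "AssociationMatrix":
        """Copy of A with the given cells set to 0 (mask held-out positives)."""
        vals = self.values.copy()
        ci = {c: i for i, c in enumerate(self.circ_ids)}
        di = {d: j for j, d in enumerate(self.disease_ids)}
        for c, d in pairs:
            vals[ci[c], di[d]] = 0
        return AssociationMatrix(list(self.circ_ids), list(self.disease_ids), vals)


@dataclass
class ExpressionProfileSet:
    """Real-valued circRNA x sample expression matrix."""

    circ_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.circ_ids = _check_unique(self.circ_ids, "circRNA")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.circ_ids), len(self.sample_ids)):
            raise ValidationError("expression matrix shape does not match its labels")
        if len(self.sample_ids) < 2:
            raise ValidationError(
                "expression profiles need >= 2 samples (Pearson correlation "
                "is undefined on a single point)"
            )
        if not np.isfinite(self.values).all():
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value at circRNA {self.circ_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with entries in [0, 1]."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = _check_unique(self.ids, "node")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("similarity matrix must be square and match its ids")
        if not np.allclose(self.values, self.values.T, atol=_SYMMETRY_TOL):
            raise ValidationError("similarity matrix is not symmetric")
        if self.values.min() < -_SYMMETRY_TOL or self.values.max() > 1 + _SYMMETRY_TOL:
            raise ValidationError("similarity entries must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, node: str) -> int:
        try:
            return self.ids.index(node)
        except ValueError:
            raise KeyError(f"unknown node id {node!r}") from None


def load_association_table(
    path: str | Path,
    format: str = "edge_list",
    circ_ids: Sequence[str] | None = None,
    disease_ids: Sequence[str] | None = None,
) -> AssociationMatrix:
    """Read an association table from an edge list or a labeled binary matrix.

    Edge-list files have a header and two columns (circRNA id, disease id); a
    third column, if present, is ignored.  Identifier order is first-appearance
    order unless an explicit id universe is supplied (which also allows an
    empty edge list).  Duplicate pairs are collapsed with a logged warning.
    """
    path = Path(path)
    if format == "edge_list":
        pairs: list[tuple[str, str]] = []
        with open(path, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
        sep = "\t" if (lines and "\t" in lines[0]) else ("," if lines and "," in lines[0] else _sep_for(path))
        for lineno, line in enumerate(lines[1:], start=2):  # line 1 is the header
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ParseError(f"{path}:{lineno}: expected two columns (circRNA id, disease id)")
            pairs.append((parts[0], parts[1]))
        seen = set()
        deduped = []
        for p in pairs:
            if p in seen:
                logger.warning("duplicate association %s ignored", p)
            else:
                seen.add(p)
                deduped.append(p)
        circ = list(circ_ids) if circ_ids is not None else list(dict.fromkeys(c for c, _ in deduped))
        dis = list(disease_ids) if disease_ids is not None else list(dict.fromkeys(d for _, d in deduped))
        if not circ or not dis:
            raise ValidationError("empty edge list requires an explicit id universe")
        ci = {c: i for i, c in enumerate(circ)}
        di = {d: j for j, d in enumerate(dis)}
        vals = np.zeros((len(circ), len(dis)), dtype=np.int8)
        for c, d in deduped:
            if c not in ci or d not in di:
                raise ValidationError(f"pair ({c!r}, {d!r}) outside the declared id universe")
            vals[ci[c], di[d]] = 1
        return AssociationMatrix(circ, dis, vals)
    if format == "matrix":
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
        arr = df.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise ValidationError(
                f"{path}: non-binary cell at row {df.index[bad[0]]!r}, "
                f"column {df.columns[bad[1]]!r}"
            )
        return AssociationMatrix([str(i) for i in df.index], [str(c) for c in df.columns], arr)
    raise ValidationError(f"unknown association format {format!r}")


def save_association_table(assoc: AssociationMatrix, path: str | Path, format: str = "matrix") -> None:
    path = Path(path)
    sep = _sep_for(path)
    if format == "matrix":
        pd.DataFrame(assoc.values, index=assoc.circ_ids, columns=assoc.disease_ids).to_csv(path, sep=sep)
    elif format == "edge_list":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"circRNA{sep}disease\n")
            for c, d in assoc.positive_pairs():
                fh.write(f"{c}{sep}{d}\n")
    else:
        raise ValidationError(f"unknown association format {format!r}")


def load_expression_profiles(path: str | Path) -> ExpressionProfileSet:
    """Read a circRNA x sample numeric matrix with row labels and a header."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expression table needs >= 2 sample columns")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric or missing cell at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return ExpressionProfileSet(
        [str(i) for i in df.index], [str(c) for c in df.columns], numeric.to_numpy()
    )


def save_expression_profiles(expr: ExpressionProfileSet, path: str | Path) -> None:
    pd.DataFrame(expr.values, index=expr.circ_ids, columns=expr.sample_ids).to_csv(
        Path(path), sep=_sep_for(path), float_format="%.17g"
    )


def load_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    """Read a labeled square similarity matrix."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValidationError(f"{path}: row and column labels differ")
    return SimilarityMatrix(ids, df.to_numpy(dtype=float))


def save_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids).to_csv(
        Path(path), sep=_sep_for(path), float_format="%.17g"
    )


@dataclass
class HarmonizedData:
    """Result of :func:`harmonize_ids`, including the dropped-id report."""

    assoc: AssociationMatrix
    expr: ExpressionProfileSet
    dsim: SimilarityMatrix
    dropped: dict = field(default_factory=dict)

    def __iter__(self):
        return iter((self.assoc, self.expr, self.dsim))


def harmonize_ids(
    assoc: AssociationMatrix,
    expr: ExpressionProfileSet,
    dsim: SimilarityMatrix,
) -> HarmonizedData:
    """Restrict the three tables to a consistent identifier universe.

    Diseases absent from the semantic similarity matrix are dropped from the
    association matrix (and vice versa).  circRNAs absent from the expression
    set are KEPT: their expression-similarity row is all zero, so the
    integrated circRNA similarity falls back to the interaction-profile
    kernel for them.  The expression set is restricted to circRNAs present in
    the association matrix, in association-matrix order.
    """
    shared_dis = [d for d in assoc.disease_ids if d in set(dsim.ids)]
    if not shared_dis:
        raise ValidationError("no disease ids shared between associations and disease similarity")
    dropped = {
        "diseases_without_similarity": [d for d in assoc.disease_ids if d not in set(dsim.ids)],
        "similarity_diseases_without_association": [d for d in dsim.ids if d not in set(assoc.disease_ids)],
        "circ_without_expression": [c for c in assoc.circ_ids if c not in set(expr.circ_ids)],
        "expression_circ_without_association": [c for c in expr.circ_ids if c not in set(assoc.circ_ids)],
    }
    dis_cols = [assoc.disease_ids.index(d) for d in shared_dis]
    assoc2 = AssociationMatrix(list(assoc.circ_ids), shared_dis, assoc.values[:, dis_cols])

    keep_expr = [c for c in assoc.circ_ids if c in set(expr.circ_ids)]
    expr_rows = [expr.circ_ids.index(c) for c in keep_expr]
    expr2 = ExpressionProfileSet(keep_expr, list(expr.sample_ids), expr.values[expr_rows])

    dsim_idx = [dsim.ids.index(d) for d in shared_dis]
    dsim2 = SimilarityMatrix(shared_dis, dsim.values[np.ix_(dsim_idx, dsim_idx)])

    for key, ids in dropped.items():
        if ids:
            logger.info("harmonize_ids: %s -> dropped %d ids", key, len(ids))
    return HarmonizedData(assoc2, expr2, dsim2, dropped)
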