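"""Dataset container and readers/writers for the benchmark matrix dialect.

The on-disk dialect is the one used by the enzyme / ion-channel / GPCR /
nuclear-receptor chemogenomic benchmarks: tab-delimited text, first header
row holding column IDs, first column holding row IDs, numeric cells.
Interaction matrices are binary; similarity matrices are square, symmetric,
in [0, 1] with unit diagonal.

Internally the orientation is fixed: drugs are always rows of the
interaction matrix ``A`` and the loaders normalize towards that.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DTIDataset",
    "NewDrugQuery",
    "FormatError",
    "load_interaction_matrix",
    "load_similarity_matrix",
    "load_dataset",
    "average_similarities",
    "write_matrix",
    "write_predictions",
    "write_metrics_json",
]

#: tolerated asymmetry in a similarity matrix before it is treated as an error
SYMMETRY_TOL = 1e-8
#: tolerated deviation of similarity diagonals from 1 before a warning is raised
DIAGONAL_TOL = 1e-6


class FormatError(ValueError):
    """A matrix file violates the benchmark dialect."""


@dataclass
class DTIDataset:
    """A drug–target interaction dataset.

    Attributes
    ----------
    drug_ids, target_ids : list of str
        Ordered identifiers; ``m = len(drug_ids)``, ``n = len(target_ids)``.
    A : (m, n) ndarray of 0/1
        Interaction matrix, ``A[i, j] = 1`` iff drug ``i`` is known to
        interact with target ``j``. Unlabeled pairs are 0.
    drug_sim : (m, m) ndarray
        Pairwise drug similarities in [0, 1], symmetric, unit diagonal.
    target_sim : (n, n) ndarray
        Pairwise target similarities, same conventions.
    """

    drug_ids: list[str]
    target_ids: list[str]
    A: np.ndarray
    drug_sim: np.ndarray
    target_sim: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        self.drug_sim = np.asarray(self.drug_sim, dtype=float)
        self.target_sim = np.asarray(self.target_sim, dtype=float)
        m, n = len(self.drug_ids), len(self.target_ids)
        if self.A.shape != (m, n):
            raise FormatError(
                f"interaction matrix shape {self.A.shape} does not match "
                f"{m} drugs x {n} targets"
            )
        if not np.isin(self.A, (0, 1)).all():
            raise FormatError("interaction matrix contains non-binary cells")
        self.A = self.A.astype(np.int8)
        for name, sim, size in (
            ("drug_sim", self.drug_sim, m),
            ("target_sim", self.target_sim, n),
        ):
            if sim.shape != (size, size):
                raise FormatError(f"{name} has shape {sim.shape}, expected ({size}, {size})")
            if not np.allclose(sim, sim.T, atol=SYMMETRY_TOL, rtol=0):
                raise FormatError(f"{name} is not symmetric within {SYMMETRY_TOL}")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)


@dataclass
class NewDrugQuery:
    """A truly new drug: an identifier plus similarities to the m training drugs."""

    drug_id: str
    sim_row: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.sim_row = np.asarray(self.sim_row, dtype=float).ravel()
        if self.sim_row.size and (self.sim_row.min() < 0 or self.sim_row.max() > 1):
            raise ValueError(f"similarities for {self.drug_id!r} fall outside [0, 1]")


def _read_table(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged or incomplete rows")
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if len(set(row_ids)) != len(row_ids) or len(set(col_ids)) != len(col_ids):
        raise FormatError(f"{path}: duplicate row or column IDs")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    return row_ids, col_ids, values


def load_interaction_matrix(
    path: str | Path,
    orientation: str = "drugs_as_rows",
    target_ids: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a binary interaction matrix, normalizing drugs to rows.

    Parameters
    ----------
    orientation : {"drugs_as_rows", "targets_as_rows", "auto"}
        With ``auto``, the file is transposed when its row-ID vocabulary
        matches ``target_ids`` (taken from the accompanying target-similarity
        file); shape is deliberately not used as a heuristic.

    Returns
    -------
    (A, drug_ids, target_ids) with drugs as rows.
    """
    row_ids, col_ids, values = _read_table(path)
    if not np.isin(values, (0.0, 1.0)).all():
        bad = values[~np.isin(values, (0.0, 1.0))][0]
        raise FormatError(f"{path}: non-binary interaction cell {bad!r}")
    if orientation == "auto":
        if target_ids is None:
            raise ValueError("orientation='auto' requires the target-ID vocabulary")
        vocab = set(target_ids)
        rows_are_targets = set(row_ids) <= vocab
        cols_are_targets = set(col_ids) <= vocab
        if rows_are_targets == cols_are_targets:
            raise FormatError(
                f"{path}: cannot orient, row and column IDs are "
                f"{'both' if rows_are_targets else 'neither'} target IDs"
            )
        orientation = "targets_as_rows" if rows_are_targets else "drugs_as_rows"
    if orientation == "targets_as_rows":
        return values.T.astype(np.int8), col_ids, row_ids
    if orientation != "drugs_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return values.astype(np.int8), row_ids, col_ids


def load_similarity_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a square similarity matrix.

    Asymmetry up to ``SYMMETRY_TOL`` is repaired by averaging with the
    transpose; larger asymmetry is an error. A diagonal off 1 by more than
    ``DIAGONAL_TOL`` triggers a warning but the values are kept. Values
    outside [0, 1] are clipped with a warning.
    """
    row_ids, col_ids, values = _read_table(path)
    if values.shape[0] != values.shape[1]:
        raise FormatError(f"{path}: similarity matrix is not square {values.shape}")
    if row_ids != col_ids:
        raise FormatError(f"{path}: row and column IDs differ")
    asym = np.abs(values - values.T).max() if values.size else 0.0
    if asym > SYMMETRY_TOL:
        raise FormatError(f"{path}: asymmetry {asym:.3g} exceeds {SYMMETRY_TOL}")
    values = (values + values.T) / 2.0
    diag_dev = np.abs(np.diag(values) - 1.0).max() if values.size else 0.0
    if diag_dev > DIAGONAL_TOL:
        warnings.warn(
            f"{path}: similarity diagonal deviates from 1 by up to {diag_dev:.3g}; kept",
            stacklevel=2,
        )
    if values.size and (values.min() < 0 or values.max() > 1):
        warnings.warn(
            f"{path}: similarities outside [0, 1] clipped "
            f"(range [{values.min():.3g}, {values.max():.3g}])",
            stacklevel=2,
        )
        values = np.clip(values, 0.0, 1.0)
    return values, row_ids


def load_dataset(
    interaction_path: str | Path,
    drug_sim_path: str | Path,
    target_sim_path: str | Path,
    orientation: str = "auto",
) -> DTIDataset:
    """Assemble a :class:`DTIDataset` from the three benchmark files."""
    drug_sim, drug_ids = load_similarity_matrix(drug_sim_path)
    target_sim, target_ids = load_similarity_matrix(target_sim_path)
    A, a_drugs, a_targets = load_interaction_matrix(
        interaction_path, orientation=orientation, target_ids=target_ids
    )
    if a_drugs != drug_ids or a_targets != target_ids:
        # align to similarity-file order; IDs must agree as sets
        if set(a_drugs) != set(drug_ids) or set(a_targets) != set(target_ids):
            raise FormatError("interaction-matrix IDs do not match similarity files")
        di = [a_drugs.index(d) for d in drug_ids]
        ti = [a_targets.index(t) for t in target_ids]
        A = A[np.ix_(di, ti)]
    return DTIDataset(drug_ids, target_ids, A, drug_sim, target_sim)


def average_similarities(
    sim1: np.ndarray,
    sim2: np.ndarray,
    ids1: Sequence[str] | None = None,
    ids2: Sequence[str] | None = None,
) -> np.ndarray:
    """Elementwise mean of two similarity matrices over the same entities.

    Used to fuse a structure/sequence-based similarity with an
    annotation-based one (e.g. ATC codes for drugs, functional categories
    for targets). Shapes and ID orderings must agree exactly; matrices with
    permuted IDs are rejected rather than silently realigned.
    """
    sim1 = np.asarray(sim1, dtype=float)
    sim2 = np.asarray(sim2, dtype=float)
    if sim1.shape != sim2.shape:
        raise ValueError(f"shape mismatch {sim1.shape} vs {sim2.shape}")
    if ids1 is not None and ids2 is not None and list(ids1) != list(ids2):
        raise ValueError("ID orderings differ between the two similarity matrices")
    return (sim1 + sim2) / 2.0


def write_matrix(
    path: str | Path,
    matrix: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
) -> None:
    """Write a matrix in the benchmark tab-delimited dialect."""
    mat = np.asarray(matrix)
    df = pd.DataFrame(mat, index=list(row_ids), columns=list(col_ids))
    fmt = "%d" if np.issubdtype(mat.dtype, np.integer) else "%.17g"
    df.to_csv(path, sep="\t", float_format=fmt.replace("%d", "%.17g"))


def write_predictions(
    path: str | Path,
    drug_ids: Sequence[str],
    target_ids: Sequence[str],
    scores: np.ndarray,
) -> None:
    """Write scores as a 3-column TSV: drug_id, target_id, score."""
    scores = np.asarray(scores)
    with open(path, "w") as fh:
        fh.write("drug_id\ttarget_id\tscore\n")
        for i, d in enumerate(drug_ids):
            for j, t in enumerate(target_ids):
                fh.write(f"{d}\t{t}\t{scores[i, j]:.10g}\n")


def write_metrics_json(path: str | Path, report: dict) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default, allow_nan=True)
        fh.write("\n")
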