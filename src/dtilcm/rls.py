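"""Regularized least-squares (RLS) scorer — the classifier behind every layer.

For a target (or super-target) with training labels ``Y`` over ``p`` drugs
and a kernel ``K`` taken directly from the drug-similarity matrix, the
confidence score of a query drug ``x`` with similarity row ``k_x`` is

    f(x) = k_x (K + lambda I)^{-1} Y

The system matrix ``K + lambda I`` does not depend on the label vector, so
one factorization is shared by every classifier trained on the same set of
drugs; only the right-hand side ``Y`` changes per target.

Benchmark similarity matrices are not guaranteed positive semidefinite, so
the factorization tries Cholesky first and falls back to a least-squares
solve when that fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["RLSModel", "KernelFactorization", "fit_rls", "score_rls"]

DEFAULT_LAMBDA = 0.5

_SYM_TOL = 1e-8


class KernelFactorization:
    """A reusable factorization of ``K + lambda I``.

    ``solve`` accepts one label vector or a (p, n) stack of label columns,
    solving all targets in a single triangular sweep.
    """

    def __init__(self, kernel: np.ndarray, lam: float = DEFAULT_LAMBDA):
        kernel = np.asarray(kernel, dtype=float)
        if kernel.ndim != 2 or kernel.shape[0] != kernel.shape[1]:
            raise ValueError(f"kernel must be square, got {kernel.shape}")
        if kernel.size and np.abs(kernel - kernel.T).max() > _SYM_TOL:
            raise ValueError("kernel is not symmetric")
        if lam < 0:
            raise ValueError("lambda must be nonnegative")
        self.kernel = kernel
        self.lam = float(lam)
        self.p = kernel.shape[0]
        system = kernel + lam * np.eye(self.p)
        self._cho = None
        self._system = system
        try:
            self._cho = linalg.cho_factor(system, lower=True, check_finite=False)
        except linalg.LinAlgError:
            # indefinite or singular system: keep the matrix, solve by lstsq
            self._cho = None

    def solve(self, labels: np.ndarray) -> np.ndarray:
        y = np.asarray(labels, dtype=float)
        if y.shape[0] != self.p:
            raise ValueError(f"labels length {y.shape[0]} != training size {self.p}")
        if self._cho is not None:
            return linalg.cho_solve(self._cho, y, check_finite=False)
        w, *_ = linalg.lstsq(self._system, y, check_finite=False)
        return w


@dataclass
class RLSModel:
    """A fitted per-target classifier.

    ``train_indices`` (optional) records which drugs of a larger fold the
    model was restricted to — the Spy-based classifiers train only on
    positives plus reliable negatives, so their kernel is a submatrix.
    """

    train_kernel: np.ndarray
    labels: np.ndarray
    lam: float
    solved_weights: np.ndarray
    train_indices: np.ndarray | None = None

    def residual(self) -> float:
        system = self.train_kernel + self.lam * np.eye(self.train_kernel.shape[0])
        return float(np.linalg.norm(system @ self.solved_weights - self.labels))


def fit_rls(
    train_kernel: np.ndarray,
    labels: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    factorization: KernelFactorization | None = None,
    train_indices: np.ndarray | None = None,
) -> RLSModel:
    """Solve ``(K + lambda I) w = Y`` for the weight vector.

    Pass a prebuilt ``factorization`` (of the same kernel and lambda) to
    amortize the solve across targets.
    """
    if factorization is None:
        factorization = KernelFactorization(train_kernel, lam)
    labels = np.asarray(labels, dtype=float).ravel()
    w = factorization.solve(labels)
    return RLSModel(
        train_kernel=factorization.kernel,
        labels=labels,
        lam=factorization.lam,
        solved_weights=w,
        train_indices=train_indices,
    )


def score_rls(model: RLSModel, test_rows: np.ndarray) -> np.ndarray:
    """Score query drugs: similarities-to-training-drugs times solved weights."""
    rows = np.atleast_2d(np.asarray(test_rows, dtype=float))
    if rows.shape[1] != model.solved_weights.shape[0]:
        raise ValueError(
            f"test rows have {rows.shape[1]} columns, model was trained on "
            f"{model.solved_weights.shape[0]} drugs"
        )
    return rows @ model.solved_weights
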