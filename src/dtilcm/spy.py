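"""Spy strategy: mining reliable negatives from unlabeled drug–target pairs.

Treating every unlabeled pair as a negative puts the (few) uncollected true
interactions on the wrong side of the decision boundary. The Spy technique
plants a fraction of the known positives ("spies") into the unlabeled pool,
scores the pool with an ordinary classifier, and takes the minimum spy score
as a threshold: unlabeled drugs scoring strictly below it behave unlike any
known positive and are kept as reliable negatives (RN). The final per-target
classifier is trained on positives and RN only; ambiguous unlabeled drugs
are excluded from training altogether.

Because every local classifier shares one drug-similarity kernel, a single
unified threshold is estimated — from the target with the most interacting
drugs — instead of one threshold per target. The spy draw is repeated
(default 10 times at a 10 % spy fraction) and the repetition thresholds are
averaged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .rls import DEFAULT_LAMBDA, KernelFactorization, RLSModel, fit_rls

logger = logging.getLogger(__name__)

__all__ = [
    "SpyConfig",
    "SpyThreshold",
    "estimate_spy_threshold",
    "identify_reliable_negatives",
    "train_spy_classifiers",
    "score_target_models",
]


@dataclass
class SpyConfig:
    spy_fraction: float = 0.10
    repetitions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.spy_fraction < 1:
            raise ValueError("spy_fraction must be in (0, 1)")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class SpyThreshold:
    """The unified score threshold and the per-repetition minima behind it."""

    t: float
    per_rep_minima: list[float] = field(default_factory=list)
    source_target: int = -1


def _rep_rng(seed: int, rep: int) -> np.random.Generator:
    # deterministic sub-stream per repetition so the 10-draw average replays
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(rep)]))


def estimate_spy_threshold(
    A_train: np.ndarray,
    train_kernel: np.ndarray,
    config: SpyConfig,
    lam: float = DEFAULT_LAMBDA,
    factorization: KernelFactorization | None = None,
) -> SpyThreshold:
    """Estimate the unified RN threshold from the maximum-degree target.

    Per repetition, ``ceil(spy_fraction * |P|)`` spies (at least one) are
    drawn without replacement from the positives P of that target and
    relabeled as unlabeled; an ordinary classifier (remaining positives = 1,
    everything else = 0) scores the spies, and the repetition's threshold is
    the minimum spy score. The final ``t`` is the mean over repetitions.
    """
    A_train = np.asarray(A_train)
    degrees = A_train.sum(axis=0)
    j = int(np.argmax(degrees))  # ties: lowest target index
    positives = np.flatnonzero(A_train[:, j] == 1)
    if positives.size < 2:
        raise ValueError(
            f"max-degree target (index {j}) has only {positives.size} positive(s); "
            "spy threshold estimation needs at least 2 — use a larger dataset"
        )
    n_spies = max(1, math.ceil(config.spy_fraction * positives.size))
    if n_spies >= positives.size:
        raise ValueError(
            f"spy draw of {n_spies} would empty the positive set of size {positives.size}"
        )
    if factorization is None:
        factorization = KernelFactorization(train_kernel, lam)
    minima: list[float] = []
    for rep in range(config.repetitions):
        rng = _rep_rng(config.seed, rep)
        spies = rng.choice(positives, size=n_spies, replace=False)
        labels = A_train[:, j].astype(float)
        labels[spies] = 0.0
        weights = factorization.solve(labels)
        spy_scores = factorization.kernel[spies] @ weights
        minima.append(float(spy_scores.min()))
    t = float(np.mean(minima))
    logger.info(
        "spy threshold t=%.6g from target %d (%d positives, %d spies, %d reps)",
        t, j, positives.size, n_spies, config.repetitions,
    )
    return SpyThreshold(t=t, per_rep_minima=minima, source_target=j)


def identify_reliable_negatives(
    A_train: np.ndarray,
    train_kernel: np.ndarray,
    threshold: SpyThreshold,
    lam: float = DEFAULT_LAMBDA,
    factorization: KernelFactorization | None = None,
) -> np.ndarray:
    """Per-target mask of reliable negatives among the unlabeled drugs.

    For each target, the ordinary local classifier (positives = 1,
    unlabeled = 0) scores every unlabeled drug; those scoring strictly
    below ``t`` form RN. Ties at exactly ``t`` stay unlabeled.
    """
    A_train = np.asarray(A_train)
    if factorization is None:
        factorization = KernelFactorization(train_kernel, lam)
    weights = factorization.solve(A_train.astype(float))  # one sweep, all targets
    scores = factorization.kernel @ weights
    unlabeled = A_train == 0
    return unlabeled & (scores < threshold.t)


def train_spy_classifiers(
    A_train: np.ndarray,
    train_kernel: np.ndarray,
    rn: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    factorization: KernelFactorization | None = None,
) -> list[RLSModel]:
    """Final per-target classifiers trained on positives plus RN only.

    A target whose RN set is empty falls back to the ordinary classifier
    over all training drugs (with a logged warning); the rest restrict
    kernel and labels to ``P_j ∪ RN_j``.
    """
    A_train = np.asarray(A_train)
    rn = np.asarray(rn, dtype=bool)
    if rn.shape != A_train.shape:
        raise ValueError("RN mask shape does not match the interaction matrix")
    if (rn & (A_train == 1)).any():
        raise ValueError("RN mask overlaps the positive set")
    kernel = np.asarray(train_kernel, dtype=float)
    if factorization is None:
        factorization = KernelFactorization(kernel, lam)
    models: list[RLSModel] = []
    for j in range(A_train.shape[1]):
        pos = A_train[:, j] == 1
        if not rn[:, j].any() or not pos.any():
            if not rn[:, j].any():
                logger.warning(
                    "target %d: empty RN set, falling back to the ordinary classifier", j
                )
            models.append(
                fit_rls(kernel, A_train[:, j], lam, factorization=factorization)
            )
            continue
        keep = np.flatnonzero(pos | rn[:, j])
        sub_kernel = kernel[np.ix_(keep, keep)]
        try:
            models.append(
                fit_rls(sub_kernel, A_train[keep, j], lam, train_indices=keep)
            )
        except np.linalg.LinAlgError as exc:  # pragma: no cover - lstsq fallback
            raise np.linalg.LinAlgError(f"singular system for target {j}: {exc}")
    return models


def score_target_models(models: list[RLSModel], test_rows: np.ndarray) -> np.ndarray:
    """Score query drugs against a per-target model collection.

    ``test_rows`` holds similarities to the full training-drug set; models
    restricted to a drug subset pick out their columns via ``train_indices``.
    """
    rows = np.atleast_2d(np.asarray(test_rows, dtype=float))
    out = np.empty((rows.shape[0], len(models)))
    for j, model in enumerate(models):
        cols = rows if model.train_indices is None else rows[:, model.train_indices]
        out[:, j] = cols @ model.solved_weights
    return out
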