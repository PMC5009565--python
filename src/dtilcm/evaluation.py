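"""Ranking-based evaluation: AUC, AUPR, Coverage and its baselines.

Coverage is the measure built for data with missing interactions: for each
test drug it asks how far down the ranked target list one must go to cover
*all* of the drug's true targets,

    Coverage = (1/p) * sum_i max_{t in T_i} rank(d_i, t)  -  1,

lower is better. A missing interaction that is not the worst-ranked
positive leaves Coverage unchanged, while AUC and especially AUPR move.

Ranks are pessimistic (maximum competition rank): rank 1 is the highest
score, and every member of a tie group receives the group's worst rank.
This makes the oracle baseline well defined even though an oracle scores
all of a drug's positives identically.

Baselines: ``oracle_coverage`` scores equal the 0/1 labels (mean positive
count minus 1 under the pessimistic tie rule); ``random_coverage`` is the
expectation under uniform random scores, estimated by Monte Carlo and also
given in closed form, E[max rank of k uniform ranks among n] = k(n+1)/(k+1).
The normalized Coverage NC = (C - C_oracle)/(C_random - C_oracle) maps the
oracle to 0 and random scoring to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "pessimistic_ranks",
    "auc",
    "aupr",
    "coverage",
    "oracle_coverage",
    "random_coverage",
    "RandomCoverageEstimate",
    "normalized_coverage",
    "MetricsReport",
]


def pessimistic_ranks(scores: np.ndarray) -> np.ndarray:
    """Maximum competition ranks, rank 1 = highest score, ties -> worst rank.

    Accepts a vector or a (drugs, targets) matrix ranked row-wise.
    """
    s = np.asarray(scores, dtype=float)
    squeeze = s.ndim == 1
    s = np.atleast_2d(s)
    n = s.shape[1]
    ranks = np.empty_like(s, dtype=int)
    for i in range(s.shape[0]):
        asc = np.sort(s[i])
        # rank = number of entries with score >= own score
        ranks[i] = n - np.searchsorted(asc, s[i], side="left")
    return ranks[0] if squeeze else ranks


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-aware AUC: (wins + 0.5 * ties) over all positive–negative pairs.

    Computed from average ranks in O(n log n); exactly equals brute-force
    pair counting. Returns NaN when only one class is present.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    r = rankdata(scores, method="average")
    return float((r[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average precision under the pessimistic tie ordering.

    Tied scores are ordered negatives-first, so tied positives take the
    worst positions — consistent with :func:`pessimistic_ranks`. Returns
    NaN when there is no positive.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if labels.sum() == 0:
        return float("nan")
    order = np.lexsort((labels, -scores))  # descending score, negatives before ties
    lab = labels[order]
    tp = np.cumsum(lab)
    precision = tp / np.arange(1, lab.size + 1)
    return float(precision[lab == 1].mean())


def _worst_positive_ranks(score_matrix: np.ndarray, label_matrix: np.ndarray) -> np.ndarray:
    """Per counted drug, the pessimistic rank of its worst-ranked true target."""
    scores = np.atleast_2d(np.asarray(score_matrix, dtype=float))
    labels = np.atleast_2d(np.asarray(label_matrix))
    if scores.shape != labels.shape:
        raise ValueError("score and label matrices must have identical shapes")
    if scores.shape[0] == 0:
        raise ValueError("empty test set")
    counts = labels.sum(axis=1)
    keep = counts > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("coverage: excluding %d drug(s) with no true targets", dropped)
    if not keep.any():
        raise ValueError("no test drug has a true target")
    ranks = pessimistic_ranks(scores[keep])
    masked = np.where(labels[keep] == 1, ranks, 0)
    return masked.max(axis=1)


def coverage(
    score_matrix: np.ndarray,
    label_matrix: np.ndarray,
    subtract_one: bool = True,
) -> float:
    """Mean worst true-target rank over test drugs, minus one.

    Drugs with no true target are excluded from the average (and logged).
    ``subtract_one=False`` drops the trailing constant for anyone
    reconciling reports that omit it.
    """
    worst = _worst_positive_ranks(score_matrix, label_matrix)
    return float(worst.mean() - (1.0 if subtract_one else 0.0))


def oracle_coverage(label_matrix: np.ndarray, subtract_one: bool = True) -> float:
    """Coverage of a perfect scorer (scores equal to the labels).

    Under the pessimistic tie rule, a drug with k positives has worst
    positive rank k, so this is the mean positive count minus one.
    """
    return coverage(np.asarray(label_matrix, dtype=float), label_matrix, subtract_one)


@dataclass
class RandomCoverageEstimate:
    """Monte-Carlo estimate of random-scorer Coverage plus its closed form."""

    monte_carlo: float
    closed_form: float
    reps: int
    per_rep: list[float] = field(default_factory=list)

    @property
    def standard_error(self) -> float:
        if self.reps < 2:
            return float("nan")
        return float(np.std(self.per_rep, ddof=1) / np.sqrt(self.reps))


def random_coverage(
    label_matrix: np.ndarray,
    reps: int = 100,
    seed: int = 0,
    subtract_one: bool = True,
) -> RandomCoverageEstimate:
    """Coverage of a scorer assigning i.i.d. uniform scores to every pair.

    The closed form uses E[max of k uniformly placed ranks among n] =
    k(n+1)/(k+1), averaged over counted drugs.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    labels = np.atleast_2d(np.asarray(label_matrix))
    n = labels.shape[1]
    counts = labels.sum(axis=1)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("no test drug has a true target")
    offset = 1.0 if subtract_one else 0.0
    closed = float(np.mean(counts * (n + 1) / (counts + 1.0)) - offset)
    rng = np.random.default_rng(seed)
    per_rep = [
        coverage(rng.random(labels.shape), labels, subtract_one) for _ in range(reps)
    ]
    return RandomCoverageEstimate(
        monte_carlo=float(np.mean(per_rep)),
        closed_form=closed,
        reps=reps,
        per_rep=per_rep,
    )


def normalized_coverage(cov: float, c_oracle: float, c_random: float) -> float:
    """NC = (Coverage - C_oracle)/(C_random - C_oracle); NaN if baselines degenerate."""
    if not c_random > c_oracle:
        return float("nan")
    return float((cov - c_oracle) / (c_random - c_oracle))


@dataclass
class MetricsReport:
    """Aggregated evaluation of one model variant, with per-fold breakdown."""

    auc: float = float("nan")
    aupr: float = float("nan")
    coverage: float = float("nan")
    c_random: float = float("nan")
    c_oracle: float = float("nan")
    nc: float = float("nan")
    c_over_n_targets: float = float("nan")
    per_drug_auc: float = float("nan")
    folds: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "aupr": self.aupr,
            "coverage": self.coverage,
            "c_random": self.c_random,
            "c_oracle": self.c_oracle,
            "nc": self.nc,
            "c_over_n_targets": self.c_over_n_targets,
            "per_drug_auc": self.per_drug_auc,
            "folds": self.folds,
            "config": self.config,
        }
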