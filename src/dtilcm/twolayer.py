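"""Two-layer fusion of per-target and per-super-target confidence scores.

The final confidence that a new drug ``d_x`` interacts with target ``t_j``
belonging to an *accepted* super-target ``st_q`` is the geometric mean

    S(d_x, t_j) = sqrt( S(d_x, st_q) * S(d_x, t_j) )

of the top-layer (super-target) and bottom-layer (target) scores. For a
rejected super-target the bottom-layer score is used alone. Raw RLS scores
can stray outside [0, 1]; before fusion each layer is brought into [0, 1]
by a strictly increasing min–max map (the identity when the scores already
lie in [0, 1]) so the square root stays real. A strictly monotone map is
used rather than hard clipping because clipping collapses every
below-zero score into one tie group at 0, and under the pessimistic
(maximum) tie rank a true target caught in that group is charged the
group's worst rank — an evaluation artifact, not a model property.

Four model variants are exposed:

========== ============ =============
variant     bottom layer  top layer
========== ============ =============
rls         ordinary      —
spy         Spy-based     —
super       ordinary      super-target
comb        Spy-based     super-target
========== ============ =============
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import DTIDataset, NewDrugQuery
from .rls import DEFAULT_LAMBDA, KernelFactorization, fit_rls, score_rls
from .spy import (
    SpyConfig,
    SpyThreshold,
    estimate_spy_threshold,
    identify_reliable_negatives,
    score_target_models,
    train_spy_classifiers,
)
from .supertarget import (
    DEFAULT_CUT_SIMILARITY,
    DEFAULT_K_NEIGHBORS,
    SuperTargetLayer,
    build_supertarget_layer,
    train_supertarget_classifiers,
)

__all__ = ["ModelVariant", "PredictConfig", "ScoreMatrix", "fuse_scores", "predict_scores", "predict"]


class ModelVariant(str, enum.Enum):
    RLS = "rls"            # ordinary bottom layer only
    SPY = "spy"            # Spy bottom layer only
    SUPER = "super"        # ordinary bottom layer fused with top layer
    COMB = "comb"          # Spy bottom layer fused with top layer

    @property
    def uses_spy(self) -> bool:
        return self in (ModelVariant.SPY, ModelVariant.COMB)

    @property
    def uses_supertarget(self) -> bool:
        return self in (ModelVariant.SUPER, ModelVariant.COMB)


@dataclass
class PredictConfig:
    """Hyperparameters of the two-layer model (defaults are the standard ones)."""

    lam: float = DEFAULT_LAMBDA
    spy_fraction: float = 0.10
    spy_reps: int = 10
    cut_similarity: float = DEFAULT_CUT_SIMILARITY
    supertarget_k: int = DEFAULT_K_NEIGHBORS
    seed: int = 0


@dataclass
class ScoreMatrix:
    drug_ids: list[str]
    target_ids: list[str]
    scores: np.ndarray
    spy_threshold: SpyThreshold | None = None
    layer: SuperTargetLayer | None = None
    extra: dict = field(default_factory=dict)


def _to_unit_interval(scores: np.ndarray) -> np.ndarray:
    """Strictly increasing map into [0, 1]; identity if already inside."""
    mn, mx = scores.min(), scores.max()
    if mn >= 0.0 and mx <= 1.0:
        return scores
    if mx == mn:
        return np.clip(scores, 0.0, 1.0)
    return (scores - mn) / (mx - mn)


def fuse_scores(
    bottom: np.ndarray,
    top: np.ndarray,
    partition: np.ndarray,
    accepted: np.ndarray,
) -> np.ndarray:
    """Geometric-mean fusion per target, falling back on rejection.

    ``bottom`` is (q_drugs, n_targets), ``top`` is (q_drugs, Q). Each layer
    is first brought into [0, 1] by an order-preserving min–max map (a
    no-op for scores already in range); a target in a rejected super-target
    keeps its mapped bottom score. When no super-target is accepted the
    bottom scores are returned untouched.
    """
    bottom = np.atleast_2d(np.asarray(bottom, dtype=float))
    top = np.atleast_2d(np.asarray(top, dtype=float))
    partition = np.asarray(partition, dtype=int)
    accepted = np.asarray(accepted, dtype=bool)
    if partition.shape[0] != bottom.shape[1]:
        raise ValueError("every target must map to a super-target")
    if partition.size and partition.max() >= top.shape[1]:
        raise ValueError("partition refers to a super-target with no top-layer score")
    if not accepted.any():
        return bottom.copy()
    b = _to_unit_interval(bottom)
    t = _to_unit_interval(top)
    fused = b.copy()
    use_top = accepted[partition]  # per-target flag
    fused[:, use_top] = np.sqrt(t[:, partition[use_top]] * b[:, use_top])
    return fused


def predict_scores(
    variant: ModelVariant | str,
    A_train: np.ndarray,
    drug_sim_train: np.ndarray,
    target_sim: np.ndarray,
    test_rows: np.ndarray,
    config: PredictConfig | None = None,
) -> tuple[np.ndarray, dict]:
    """End-to-end scoring of query drugs against all known targets.

    ``test_rows`` holds each query drug's similarities to the training
    drugs, ordered like the rows of ``drug_sim_train``. Returns the score
    matrix plus a diagnostics dict (spy threshold, super-target layer).
    """
    variant = ModelVariant(variant)
    config = config or PredictConfig()
    A_train = np.asarray(A_train)
    kernel = np.asarray(drug_sim_train, dtype=float)
    test_rows = np.atleast_2d(np.asarray(test_rows, dtype=float))
    factor = KernelFactorization(kernel, config.lam)
    info: dict = {"variant": variant.value}

    if variant.uses_spy:
        spy_cfg = SpyConfig(
            spy_fraction=config.spy_fraction,
            repetitions=config.spy_reps,
            seed=config.seed,
        )
        threshold = estimate_spy_threshold(
            A_train, kernel, spy_cfg, config.lam, factorization=factor
        )
        rn = identify_reliable_negatives(
            A_train, kernel, threshold, config.lam, factorization=factor
        )
        models = train_spy_classifiers(A_train, kernel, rn, config.lam, factorization=factor)
        bottom = score_target_models(models, test_rows)
        info["spy_threshold"] = threshold
        info["rn_fraction"] = float(rn.sum() / max(1, (A_train == 0).sum()))
    else:
        weights = factor.solve(A_train.astype(float))
        bottom = test_rows @ weights

    if variant.uses_supertarget:
        layer = build_supertarget_layer(
            A_train, kernel, target_sim, config.cut_similarity, config.supertarget_k
        )
        st_models = train_supertarget_classifiers(
            layer.cleaned, kernel, config.lam, factorization=factor
        )
        top = np.column_stack([score_rls(m, test_rows) for m in st_models])
        scores = fuse_scores(bottom, top, layer.partition, layer.accepted)
        info["layer"] = layer
    else:
        scores = bottom

    return scores, info


def predict(
    variant: ModelVariant | str,
    dataset: DTIDataset,
    queries: Sequence[NewDrugQuery],
    config: PredictConfig | None = None,
) -> ScoreMatrix:
    """Score truly new drugs (given their similarity rows) against known targets."""
    rows = np.vstack([q.sim_row for q in queries])
    if rows.shape[1] != dataset.n_drugs:
        raise ValueError(
            f"query similarity rows have length {rows.shape[1]}, dataset has "
            f"{dataset.n_drugs} drugs"
        )
    scores, info = predict_scores(
        variant, dataset.A, dataset.drug_sim, dataset.target_sim, rows, config
    )
    return ScoreMatrix(
        drug_ids=[q.drug_id for q in queries],
        target_ids=list(dataset.target_ids),
        scores=scores,
        spy_threshold=info.get("spy_threshold"),
        layer=info.get("layer"),
        extra={k: v for k, v in info.items() if k not in ("spy_threshold", "layer")},
    )
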