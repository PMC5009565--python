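"""Super-target layer: grouping similar targets to pool their positives.

Most protein targets interact with only a handful of drugs, so per-target
classifiers are trained on badly imbalanced data. Clustering similar
targets into *super-targets* and taking the column-wise union of their
interaction profiles pools the positives of the whole group, giving the
top-layer classifiers a less biased decision boundary.

Two refinements guard the pooling:

* **Fake-interaction cleaning** — a drug linked to a super-target whose
  top-K most-similar drugs include none of the group's other interactors is
  treated as spurious for the group and its union link is removed.
* **Adaptive acceptance** — for each super-target the mean number of
  nearest-neighbor co-interactors (n-tilde) is computed over its interacting
  drugs; groups with n-tilde < K/2 are rejected and their member targets
  fall back to the bottom layer alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .rls import DEFAULT_LAMBDA, KernelFactorization, RLSModel, fit_rls

logger = logging.getLogger(__name__)

__all__ = [
    "SuperTargetLayer",
    "cluster_targets",
    "build_union_adjacency",
    "top_k_neighbors",
    "mark_fake_interactions",
    "acceptance_flags",
    "train_supertarget_classifiers",
    "build_supertarget_layer",
]

DEFAULT_CUT_SIMILARITY = 0.6
DEFAULT_K_NEIGHBORS = 3


@dataclass
class SuperTargetLayer:
    """Partition, union adjacency, cleaning mask and acceptance flags."""

    partition: np.ndarray          # target index -> super-target index (0..Q-1)
    union_adjacency: np.ndarray    # m x Q binary, before cleaning
    fake_mask: np.ndarray          # m x Q binary, marked fake interactions
    cleaned: np.ndarray            # union_adjacency AND NOT fake_mask
    accepted: np.ndarray           # length-Q bool
    n_tilde: np.ndarray            # length-Q mean neighbor co-interactor counts
    k_neighbors: int = DEFAULT_K_NEIGHBORS

    @property
    def n_super_targets(self) -> int:
        return int(self.partition.max()) + 1 if self.partition.size else 0


def cluster_targets(target_sim: np.ndarray, cut_similarity: float = DEFAULT_CUT_SIMILARITY) -> np.ndarray:
    """Partition targets by average-linkage clustering on 1 - similarity.

    The dendrogram is cut at distance ``1 - cut_similarity``; singleton
    clusters are allowed. Returns 0-based super-target labels.
    """
    if not 0 < cut_similarity < 1:
        raise ValueError("cut_similarity must lie in (0, 1)")
    sim = np.asarray(target_sim, dtype=float)
    n = sim.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    dist = 1.0 - (sim + sim.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")
    labels = fcluster(tree, t=1.0 - cut_similarity, criterion="distance")
    # renumber to 0..Q-1 in order of first appearance for determinism
    _, first = np.unique(labels, return_index=True)
    remap = {labels[i]: rank for rank, i in enumerate(np.sort(first))}
    return np.array([remap[l] for l in labels], dtype=int)


def build_union_adjacency(A: np.ndarray, partition: np.ndarray) -> np.ndarray:
    """Column-wise OR of the interaction matrix per super-target."""
    A = np.asarray(A)
    partition = np.asarray(partition, dtype=int)
    if partition.shape[0] != A.shape[1]:
        raise ValueError("partition does not cover all targets")
    Q = partition.max() + 1
    B = np.zeros((A.shape[0], Q), dtype=np.int8)
    for q in range(Q):
        B[:, q] = A[:, partition == q].any(axis=1)
    return B


def top_k_neighbors(drug_sim: np.ndarray, k: int) -> np.ndarray:
    """(m, k) indices of each drug's k most-similar other drugs.

    Self is excluded; ties in similarity break by ascending drug index so
    the neighborhood is deterministic.
    """
    sim = np.asarray(drug_sim, dtype=float)
    m = sim.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= m:
        raise ValueError(f"k = {k} must be smaller than the number of drugs {m}")
    out = np.empty((m, k), dtype=int)
    idx = np.arange(m)
    for u in range(m):
        others = idx[idx != u]
        # lexsort: last key dominates -> descending similarity, then ascending index
        order = np.lexsort((others, -sim[u, others]))
        out[u] = others[order[:k]]
    return out


def mark_fake_interactions(B: np.ndarray, drug_sim: np.ndarray, k: int = DEFAULT_K_NEIGHBORS) -> np.ndarray:
    """Flag drug–super-target links unsupported by the drug's neighborhood.

    A link (u, q) is fake when none of u's top-k nearest neighbors is among
    the *other* drugs interacting with q. A super-target with a single
    interacting drug therefore has that link marked fake.
    """
    B = np.asarray(B)
    neighbors = top_k_neighbors(drug_sim, k)
    fake = np.zeros_like(B, dtype=np.int8)
    for q in range(B.shape[1]):
        interactors = np.flatnonzero(B[:, q] == 1)
        for u in interactors:
            others = set(interactors) - {u}
            if not others.intersection(neighbors[u]):
                fake[u, q] = 1
    return fake


def acceptance_flags(
    B_cleaned: np.ndarray, drug_sim: np.ndarray, k: int = DEFAULT_K_NEIGHBORS
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive rule deciding where the super-target layer applies.

    For each super-target q, ``n_u`` counts how many of drug u's top-k
    neighbors co-interact with q; their mean over q's interacting drugs is
    n-tilde. q is accepted iff n-tilde >= k/2. Super-targets with no
    interacting drugs (everything cleaned away) are rejected.
    """
    B_cleaned = np.asarray(B_cleaned)
    neighbors = top_k_neighbors(drug_sim, k)
    Q = B_cleaned.shape[1]
    n_tilde = np.zeros(Q)
    accepted = np.zeros(Q, dtype=bool)
    for q in range(Q):
        interactors = np.flatnonzero(B_cleaned[:, q] == 1)
        if interactors.size == 0:
            continue
        counts = [
            np.isin(neighbors[u], interactors[interactors != u]).sum()
            for u in interactors
        ]
        n_tilde[q] = float(np.mean(counts))
        accepted[q] = n_tilde[q] >= k / 2.0
    return accepted, n_tilde


def train_supertarget_classifiers(
    B_cleaned: np.ndarray,
    train_kernel: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    factorization: KernelFactorization | None = None,
) -> list[RLSModel]:
    """Ordinary (non-Spy) classifiers, one per super-target, on all training drugs."""
    B_cleaned = np.asarray(B_cleaned)
    if factorization is None:
        factorization = KernelFactorization(train_kernel, lam)
    return [
        fit_rls(train_kernel, B_cleaned[:, q], lam, factorization=factorization)
        for q in range(B_cleaned.shape[1])
    ]


def build_supertarget_layer(
    A_train: np.ndarray,
    drug_sim_train: np.ndarray,
    target_sim: np.ndarray,
    cut_similarity: float = DEFAULT_CUT_SIMILARITY,
    k: int = DEFAULT_K_NEIGHBORS,
) -> SuperTargetLayer:
    """Cluster, pool, clean and flag in the order the model prescribes.

    Fake interactions are removed first; the acceptance rule then runs on
    the cleaned adjacency so that spurious links do not inflate n-tilde.
    """
    partition = cluster_targets(target_sim, cut_similarity)
    B = build_union_adjacency(A_train, partition)
    fake = mark_fake_interactions(B, drug_sim_train, k)
    cleaned = (B.astype(bool) & ~fake.astype(bool)).astype(np.int8)
    accepted, n_tilde = acceptance_flags(cleaned, drug_sim_train, k)
    logger.info(
        "super-target layer: %d super-targets, %d fake links removed, %d accepted",
        B.shape[1], int(fake.sum()), int(accepted.sum()),
    )
    return SuperTargetLayer(
        partition=partition,
        union_adjacency=B,
        fake_mask=fake,
        cleaned=cleaned,
        accepted=accepted,
        n_tilde=n_tilde,
        k_neighbors=k,
    )
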