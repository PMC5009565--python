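# Methods

## Problem setting

Given m drugs, n protein targets, a binary interaction matrix A (drugs as
rows), a drug-similarity matrix and a target-similarity matrix, the task is
the cold-start one: score every known target for a *new* drug that has no
interaction of its own and enters only through its similarity row to the m
training drugs. Curated interaction data systematically under-report true
interactions; the package treats these uncollected positives ("missing
interactions") as the central nuisance, both in training (they sit in the
negative pool) and in evaluation (they surface as highly-scored "false"
positives).

## Base classifier

Every classifier in both layers is regularized least squares on the drug
similarity used directly as a kernel: weights w = (K + λI)⁻¹Y, score
f(x) = k_x·w. Defaults: λ = 0.5. The similarity matrix is not repaired to
be positive semidefinite; the λI ridge regularizes the solve, a Cholesky
factorization is attempted first and a least-squares solve is the fallback
for indefinite or singular systems. Because K + λI does not depend on the
label column, one factorization is shared by all per-target, per-super-target
and spy-repetition fits over the same training drugs; only the Spy-based
final classifiers, which restrict the kernel to positives ∪ reliable
negatives, solve their own smaller systems.

## Spy layer (bottom)

A unified threshold t is estimated from the target with the most interacting
drugs: per repetition (10 by default), ceil(0.10·|P|) positives — at least
one — are relabeled unlabeled, the ordinary classifier is refit, and the
repetition's threshold is the minimum score among the planted spies; t is
the mean over repetitions. Each repetition draws from its own deterministic
sub-stream of the run seed, so the average replays exactly. For every
target, the ordinary classifier then scores its unlabeled drugs and those
strictly below t become reliable negatives (ties at t stay unlabeled); the
final classifier trains on positives plus reliable negatives only, with the
ambiguous remainder excluded. A target with an empty reliable-negative set
(or no positives) falls back to the ordinary classifier with a logged
warning. The threshold is re-estimated inside every cross-validation fold
from training drugs alone.

Estimating t once, on the maximum-degree target, rather than per target is
justified by the shared kernel: the preliminary scoring model differs across
targets only through its label vector, and the max-degree target gives the
most stable spy-score distribution. Per-target spy injection would multiply
cost without changing the decision rule.

## Super-target layer (top)

Targets are partitioned by average-linkage agglomerative clustering on
distance 1 − similarity, cut at distance 1 − cut_similarity
(default cut_similarity = 0.6; singletons allowed). The linkage and cut are
deliberate, exposed choices — deterministic and respecting the similarity
matrix directly — not a reproduction of any particular published
clustering. The drug–super-target adjacency is the column-wise union of the
member targets' profiles. Two guards apply, in this order:

1. **Fake-interaction cleaning.** A union link (u, q) is removed when none
   of u's top-K most-similar other drugs (K = 3; ties broken by ascending
   drug index for determinism) is among q's other interactors. A
   super-target with a single interactor loses that link.
2. **Adaptive acceptance.** On the *cleaned* adjacency, ñ_q averages, over
   q's interacting drugs, the number of top-K neighbors that co-interact
   with q; q is accepted iff ñ_q ≥ K/2. Cleaning runs first so spurious
   links do not inflate ñ_q; super-targets emptied by cleaning are
   rejected.

Per-super-target classifiers are ordinary RLS fits on the cleaned columns
over all training drugs (no Spy at this level: pooled positives already
address the imbalance the top layer exists for).

## Fusion and score normalization

For a target in an accepted super-target the final confidence is
sqrt(S_top·S_bottom); in a rejected one, the bottom score alone. The square
root needs nonnegative inputs, and raw RLS scores can be negative or exceed
one. Each layer is therefore mapped into [0, 1] by a *strictly increasing*
min–max transform (the identity when scores are already in range). Hard
clipping was rejected after measurement: it collapses every below-zero
score into a single tie group at 0, and under the pessimistic maximum-rank
tie rule a true target caught in that group is charged the whole group's
worst rank — on the synthetic study conditions this artifact alone made the
fused variants' Coverage worse than the plain model's (≈18.7 vs 17.5),
while the order-preserving map puts it at ≈14.0. When no super-target is
accepted, fusion is the identity on the bottom scores, so the combined
variant reduces exactly to the Spy-only variant.

## Evaluation

* Ranks are pessimistic maximum competition ranks (rank 1 best; every
  member of a tie group gets the group's worst rank). This convention makes
  the oracle baseline well defined when all of a drug's positives tie at
  score 1.
* AUC is tie-aware pair counting, (wins + ½·ties)/(n_pos·n_neg), computed
  from average ranks in O(n log n) and exactly equal to brute-force
  enumeration.
* AUPR is average precision with tied scores ordered negatives-first,
  consistent with the pessimistic rank rule.
* Coverage is the mean, over test drugs with at least one true target, of
  the worst-ranked true target's rank, minus one; drugs with no true target
  are excluded from p and logged. A `subtract_one=False` switch drops the
  trailing constant for reconciliation with conventions that omit it.
* Baselines: C_oracle = mean positive count − 1 (labels as scores under the
  pessimistic rule); C_random is reported both as a Monte-Carlo mean over
  uniform score matrices and in closed form, mean_i kᵢ(n+1)/(kᵢ+1) − 1.
  Cross-validation reports use the closed form (deterministic and exact in
  expectation). NC = (C − C_oracle)/(C_random − C_oracle); C/#T is also
  reported.
* In cross-validation, AUC/AUPR are pooled over all (test drug, target)
  pairs of a fold and averaged over folds; a per-drug mean AUC is reported
  as a diagnostic.

A note on sensitivity: Coverage is *exactly* invariant to relabeling any
positive that is not the drug's worst-ranked one — a theorem under the
pessimistic rank rule, verified exhaustively in the tests. AUC and AUPR
move under such relabeling in all but a small fraction (≈1%) of cases where
the pair-count fractions coincide exactly (e.g. 14/21 = 16/24); they are
sensitive generically, not universally.

## Cross-validation protocol

Drugs are shuffled once per seed and block-partitioned into 5 folds (sizes
differ by at most one). Per fold, every training structure — interaction
rows, the drug-similarity submatrix, the spy threshold, the super-target
union/cleaning/acceptance — is rebuilt from training drugs only; the
target-side clustering uses the full target similarity, which involves no
drugs. Test drugs contribute only their similarity rows to training drugs.
All four variants can be run on one shared fold plan so comparisons are
paired. An optional separate evaluation-label matrix lets synthetic runs
train on the occluded matrix and score against the revealed truth.

## Synthetic data

The generator emulates the two properties the model relies on — block
structure (similar drugs bind similar targets) and sparsity — plus the
nuisance it targets: a ledgered fraction of true interactions flipped to 0.
Defaults: 100 drugs in 5 round-robin clusters, 40 targets in 4; similarity
0.9 within / 0.1 between cluster, symmetric Gaussian noise (sd 0.02) added
before clipping to [0, 1] (mass at the bounds is accepted); each drug
cluster preferentially binds one target cluster with probability 0.15
against 0.01 off-block, plus a 0.005 background, giving a few-percent
density in which most targets bind a handful of drugs — the imbalance
regime of the curated enzyme/ion-channel/GPCR/nuclear-receptor benchmarks.
Hidden interactions are drawn uniformly among the 1-cells (no per-drug
stratification), so occlusion is structurally unbiased. Everything derives
from one seeded generator; hiding consumes the stream last, so revealing a
hidden run reproduces the matrix generated with hiding disabled at the same
seed.

What the generator does **not** emulate: real chemical similarity spectra
(fingerprint-scale gradation rather than two-level blocks), power-law drug
and target degree distributions, promiscuous hub drugs, and annotation
noise in the similarity matrices themselves. Tests passing on this family
therefore demonstrate the machinery's correctness and the direction of the
strategies' effects under clustered, occluded data — not performance claims
transferable to any particular real benchmark.

## Numerical and degenerate-case choices

* Similarity files: asymmetry ≤ 1e-8 is symmetrized by averaging, more is
  an error; off-unit diagonals warn but are kept; out-of-range values are
  clipped with a warning.
* λ = 0 is accepted only when the kernel happens to be invertible (the
  least-squares fallback otherwise returns the minimum-norm solution).
* Nearest-neighbor ties break by ascending drug index; cluster labels are
  renumbered by first appearance — both purely for determinism.
* Folds with targets that lose every positive are tolerated: those
  classifiers are all-negative (zero weights) and logged.
* All random draws (generator, fold shuffle, spy repetitions, Monte-Carlo
  baseline) flow from explicit seeds; spy repetition r uses the sub-stream
  (seed, r), and each CV fold derives its own sub-seed.

## Problem sizes

The shipped study conditions — 100 drugs × 40 targets, 5-fold
cross-validation, 10 spy repetitions, 10-seed replications for the
stochastic checks — complete in seconds while leaving every component
(threshold estimation, cleaning, acceptance, fusion, baselines) exercised
at realistic sparsity. Larger instances scale as one m × m factorization
plus n + Q triangular solves per fold.

## Known limitations

* The unified spy threshold assumes one shared drug kernel; with per-target
  kernels it would not be justified.
* Geometric fusion ranks targets across accepted and rejected super-targets
  on different scales; the min–max map bounds but does not remove this
  cross-group incommensurability.
* Coverage is undefined for drugs with no true targets; they are silently
  (but loggedly) excluded, which can flatter models on very sparse test
  folds.
* The transposed scenario (new targets for known drugs) is structurally
  symmetric but untested here; transpose at your own risk.
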