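"""Screening-power and docking-power metrics.

Evaluates how well a scoring protocol separates actives from decoys (ROC
curve / AUC, enrichment factor) and whether it reproduces a crystallographic
ligand pose (best-scoring-pose RMSD against a success threshold).

Scores follow the docking convention: lower is better.  AUC is computed by
the Mann–Whitney rank formulation with midranks for ties, which coincides
exactly with the trapezoidal area under the full step ROC curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import InputError, MetricError, PairingError
from .structure import heavy_atom_rmsd

__all__ = [
    "ScoredLabelSet",
    "RocResult",
    "roc_auc",
    "enrichment_factor",
    "pose_recovery",
]


@dataclass
class ScoredLabelSet:
    """Scored compounds with active/decoy labels (lower score = better)."""

    ids: list[str]
    scores: np.ndarray
    is_active: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.is_active = np.asarray(self.is_active, dtype=bool)
        if not (len(self.ids) == self.scores.size == self.is_active.size):
            raise InputError("ids, scores and labels must have equal length")
        if not np.all(np.isfinite(self.scores)):
            raise InputError("scores must be finite")

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, float, bool]]
    ) -> "ScoredLabelSet":
        ids = [r[0] for r in records]
        return cls(ids, np.array([r[1] for r in records]), np.array([r[2] for r in records]))

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_actives(self) -> int:
        return int(self.is_active.sum())

    @property
    def n_decoys(self) -> int:
        return int((~self.is_active).sum())


@dataclass
class RocResult:
    """AUC plus the stepwise ROC curve as (FPR, TPR) pairs."""

    auc: float
    curve: np.ndarray  # (k, 2) array of (fpr, tpr), from (0,0) to (1,1)


def roc_auc(data: ScoredLabelSet, lower_is_better: bool = True) -> RocResult:
    """ROC curve and AUC for an active/decoy score table.

    AUC is the probability that a random active outscores a random decoy
    (ties count half), computed from midranks; ``curve`` is the standard
    stepwise ROC whose trapezoidal area equals the same number.
    """
    if data.n_actives == 0 or data.n_decoys == 0:
        raise MetricError("AUC requires at least one active and one decoy")
    scores = data.scores if lower_is_better else -data.scores
    # rank ascending: good (low) scores get low ranks
    ranks = rankdata(scores, method="average")
    active_rank_sum = float(ranks[data.is_active].sum())
    n_a, n_d = data.n_actives, data.n_decoys
    # pairs where the active is ranked worse than a decoy (+ half-ties)
    u_worse = active_rank_sum - n_a * (n_a + 1) / 2.0
    auc = 1.0 - u_worse / (n_a * n_d)
    fpr, tpr, _ = _sk_roc_curve(data.is_active.astype(int), -scores)
    curve = np.column_stack([fpr, tpr])
    return RocResult(auc=float(auc), curve=curve)


def enrichment_factor(data: ScoredLabelSet, fraction: float) -> float:
    """Fold over-representation of actives in the best-scored ``fraction``.

    The top set holds ``ceil(fraction * n)`` compounds; ties at the cut are
    resolved by stable input order.  EF = (hit rate in top) / (hit rate
    overall); EF at fraction 1.0 is exactly 1.
    """
    if not 0 < fraction <= 1:
        raise InputError(f"fraction must be in (0, 1], got {fraction}")
    if data.n_actives == 0 or data.n_decoys == 0:
        raise MetricError("enrichment requires both classes")
    n = len(data)
    k = math.ceil(fraction * n)
    order = np.argsort(data.scores, kind="stable")
    top_active = int(data.is_active[order[:k]].sum())
    return (top_active / data.n_actives) / fraction


def pose_recovery(
    reference_pose: Sequence[Sequence[float]],
    candidate_poses: Sequence[tuple[float, Sequence[Sequence[float]]]],
    threshold: float = 2.0,
) -> tuple[float, bool]:
    """Redocking success test.

    ``candidate_poses`` are (score, coordinates) pairs in the receptor frame
    with atoms matched to the reference order.  The judged pose is the
    best-scoring one — not the closest one — and success means its
    heavy-atom RMSD is strictly below ``threshold`` Å.
    Returns ``(best_pose_rmsd, success)``.
    """
    if not candidate_poses:
        raise InputError("candidate pose list is empty")
    ref = np.asarray(reference_pose, dtype=float)
    for _, coords in candidate_poses:
        if np.asarray(coords, dtype=float).shape != ref.shape:
            raise PairingError("candidate pose atom count differs from reference")
    best_idx = min(range(len(candidate_poses)), key=lambda i: candidate_poses[i][0])
    rmsd = heavy_atom_rmsd(ref, candidate_poses[best_idx][1])
    return rmsd, rmsd < threshold
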