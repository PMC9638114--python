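"""Staged virtual-screening funnel.

Mirrors the published PARP-1 campaign: a drug-likeness prefilter, a chain of
ranked retention stages standing in for progressively more expensive docking
protocols (HTVS → SP → XP in the original, each keeping a fixed fraction of
survivors), truncation to the best candidates, affinity rescoring with the
three-term linear model, and descriptor-space k-means clustering to pick
chemically diverse representatives.

Docking itself is out of scope: each retention stage takes a *scorer* — any
callable mapping a batch of compounds to one score per compound (lower is
better).  Everything downstream is deterministic given the library order and
the clustering seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .affinity import AffinityResults
from .energy import GroupEnergyFeatures
from .errors import InputError, SchemaError

__all__ = [
    "CompoundRecord",
    "FunnelConfig",
    "FunnelReport",
    "lipinski_violations",
    "lipinski_filter",
    "retention_stage",
    "rescore_and_rank",
    "cluster_representatives",
    "run_funnel",
]

#: A stage scorer: batch of compounds -> one finite score each, lower = better.
Scorer = Callable[[Sequence["CompoundRecord"]], Sequence[float]]


@dataclass
class CompoundRecord:
    """One library compound with drug-likeness properties and descriptors."""

    id: str
    mw: float
    logp: float
    hbd: int
    hba: int
    smiles: str | None = None
    descriptor_vector: np.ndarray | None = None
    stage_scores: dict[str, float] = field(default_factory=dict)
    alive: bool = True
    drop_reason: str | None = None


@dataclass
class FunnelConfig:
    """Stage layout of the screening funnel.

    Defaults follow the published campaign: retention 10%/10%/20% over three
    docking stages, the best 2000 forwarded to rescoring, the best 500
    clustered, 20 representatives picked.
    """

    stages: list[tuple[str, float]] = field(
        default_factory=lambda: [("HTVS", 0.10), ("SP", 0.10), ("XP", 0.20)]
    )
    final_top_n: int = 2000
    top_n_after_rescore: int = 500
    cluster_k: int = 20
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name, frac in self.stages:
            if not 0 < frac <= 1:
                raise InputError(f"stage {name!r}: retention fraction {frac} not in (0, 1]")
        if self.final_top_n <= 0 or self.top_n_after_rescore <= 0 or self.cluster_k <= 0:
            raise InputError("top-N and cluster_k must be positive")


@dataclass
class FunnelReport:
    """Per-stage bookkeeping of one funnel run."""

    stage_counts: list[tuple[str, int]] = field(default_factory=list)
    survivors: list[CompoundRecord] = field(default_factory=list)
    representatives: list[tuple[int, CompoundRecord, int]] = field(default_factory=list)
    dropped: dict[str, str] = field(default_factory=dict)

    def record_stage(self, name: str, survivors: list[CompoundRecord]) -> None:
        self.stage_counts.append((name, len(survivors)))
        self.survivors = survivors

    def record_drop(self, compound: CompoundRecord, reason: str) -> None:
        compound.alive = False
        compound.drop_reason = reason
        self.dropped[compound.id] = reason


LIPINSKI_RULES = (
    ("mw", 500.0),
    ("logp", 5.0),
    ("hbd", 5),
    ("hba", 10),
)


def lipinski_violations(compound: CompoundRecord) -> int:
    """Number of rule-of-five violations (boundaries closed: 500/5/5/10 pass)."""
    count = 0
    for attr, limit in LIPINSKI_RULES:
        value = getattr(compound, attr)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise InputError(f"{compound.id}: missing property {attr!r}")
        if value > limit:
            count += 1
    return count


def lipinski_filter(
    library: Sequence[CompoundRecord],
    max_violations: int = 0,
    report: FunnelReport | None = None,
) -> list[CompoundRecord]:
    """Drug-likeness prefilter; compounds failing a property check are
    collected in the report rather than aborting the batch."""
    survivors = []
    for compound in library:
        try:
            violations = lipinski_violations(compound)
        except InputError as exc:
            if report is not None:
                report.record_drop(compound, str(exc))
            else:
                compound.alive = False
                compound.drop_reason = str(exc)
            continue
        if violations <= max_violations:
            survivors.append(compound)
        elif report is not None:
            report.record_drop(compound, f"{violations} Lipinski violation(s)")
        else:
            compound.alive = False
            compound.drop_reason = f"{violations} Lipinski violation(s)"
    return survivors


def _take_best(
    library: Sequence[CompoundRecord], scores: Sequence[float], k: int
) -> list[CompoundRecord]:
    order = np.argsort(np.asarray(scores, dtype=float), kind="stable")
    return [library[i] for i in order[:k]]


def retention_stage(
    library: Sequence[CompoundRecord],
    scorer: Scorer,
    fraction: float,
    stage_name: str,
    strict: bool = False,
    report: FunnelReport | None = None,
) -> list[CompoundRecord]:
    """Score the batch and keep the best ``ceil(fraction * n)``.

    Scores are recorded under ``stage_name``; a non-finite score drops the
    compound (or aborts in strict mode).  Ties at the cut are broken by
    stable input order; survivors come back in ascending score order.
    """
    if not 0 < fraction <= 1:
        raise InputError(f"fraction must be in (0, 1], got {fraction}")
    if not library:
        raise InputError(f"stage {stage_name!r}: empty library")
    scores = list(scorer(library))
    if len(scores) != len(library):
        raise InputError(f"stage {stage_name!r}: scorer returned {len(scores)} scores for {len(library)} compounds")
    scored: list[CompoundRecord] = []
    kept_scores: list[float] = []
    for compound, score in zip(library, scores):
        score = float(score)
        if not math.isfinite(score):
            if strict:
                raise InputError(f"stage {stage_name!r}: non-finite score for {compound.id}")
            reason = f"stage {stage_name}: scorer failed"
            if report is not None:
                report.record_drop(compound, reason)
            else:
                compound.alive = False
                compound.drop_reason = reason
            continue
        compound.stage_scores[stage_name] = score
        scored.append(compound)
        kept_scores.append(score)
    k = math.ceil(fraction * len(scored)) if scored else 0
    survivors = _take_best(scored, kept_scores, k)
    survivor_set = {id(c) for c in survivors}
    for compound in scored:
        if id(compound) not in survivor_set:
            reason = f"stage {stage_name}: below retention cut"
            if report is not None:
                report.record_drop(compound, reason)
            else:
                compound.alive = False
                compound.drop_reason = reason
    return survivors


def rescore_and_rank(
    library: Sequence[CompoundRecord],
    model: AffinityResults,
    features_by_id: dict[str, GroupEnergyFeatures],
    top_n: int,
    report: FunnelReport | None = None,
) -> list[CompoundRecord]:
    """Re-rank survivors by the linear affinity model; keep the best ``top_n``.

    Compounds without residue-group features cannot be rescored and are
    dropped with a logged reason.
    """
    if not features_by_id:
        raise InputError("empty feature map")
    scored: list[CompoundRecord] = []
    scores: list[float] = []
    for compound in library:
        features = features_by_id.get(compound.id)
        if features is None:
            reason = "rescore: no group-energy features"
            if report is not None:
                report.record_drop(compound, reason)
            else:
                compound.alive = False
                compound.drop_reason = reason
            continue
        pred = model.predict(features)
        compound.stage_scores["rescore"] = pred
        scored.append(compound)
        scores.append(pred)
    return _take_best(scored, scores, min(top_n, len(scored)))


def cluster_representatives(
    library: Sequence[CompoundRecord], k: int, seed: int
) -> list[tuple[int, CompoundRecord, int]]:
    """k-means in descriptor space; pick the member nearest each centroid.

    Returns (cluster id, representative, member count) triples, one per
    cluster, deterministic for a given seed.
    """
    if k > len(library):
        raise InputError(f"k={k} exceeds library size {len(library)}")
    vectors = []
    for compound in library:
        if compound.descriptor_vector is None:
            raise SchemaError(f"{compound.id}: no descriptor vector")
        vectors.append(np.asarray(compound.descriptor_vector, dtype=float))
    lengths = {v.shape for v in vectors}
    if len(lengths) != 1:
        raise SchemaError(f"heterogeneous descriptor lengths: {sorted(lengths)}")
    X = np.stack(vectors)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    out = []
    for cluster_id in range(k):
        members = np.flatnonzero(labels == cluster_id)
        dists = np.linalg.norm(X[members] - km.cluster_centers_[cluster_id], axis=1)
        rep = members[int(np.argmin(dists))]  # argmin is stable: first minimum
        out.append((cluster_id, library[rep], members.size))
    return out


def run_funnel(
    library: Sequence[CompoundRecord],
    config: FunnelConfig,
    scorers: dict[str, Scorer],
    model: AffinityResults | None = None,
    features_by_id: dict[str, GroupEnergyFeatures] | None = None,
) -> FunnelReport:
    """Run the full funnel and return a stage-by-stage report.

    Order: Lipinski prefilter → retention stages → truncate to
    ``final_top_n`` by the last stage score → linear-model rescoring to
    ``top_n_after_rescore`` → k-means representatives.  Rescoring is skipped
    with a warning when no model/features are supplied; clustering is skipped
    when survivors lack descriptors.
    """
    for name, _ in config.stages:
        if name not in scorers:
            raise InputError(f"no scorer supplied for stage {name!r}")
    report = FunnelReport()
    report.record_stage("input", list(library))
    survivors = lipinski_filter(library, report=report)
    report.record_stage("lipinski", survivors)
    if not survivors:
        warnings.warn("funnel empty after Lipinski prefilter", stacklevel=2)
        return report

    for name, fraction in config.stages:
        survivors = retention_stage(
            survivors, scorers[name], fraction, name, report=report
        )
        report.record_stage(name, survivors)
        if not survivors:
            warnings.warn(f"funnel empty after stage {name!r}", stacklevel=2)
            return report

    if len(survivors) > config.final_top_n:
        last_stage = config.stages[-1][0]
        scores = [c.stage_scores[last_stage] for c in survivors]
        survivors = _take_best(survivors, scores, config.final_top_n)
    report.record_stage("top_for_rescoring", survivors)

    if model is not None and features_by_id is not None:
        survivors = rescore_and_rank(
            survivors, model, features_by_id, config.top_n_after_rescore, report=report
        )
        report.record_stage("rescore", survivors)
        if not survivors:
            warnings.warn("funnel empty after rescoring", stacklevel=2)
            return report
    else:
        warnings.warn("no affinity model supplied; rescoring stage skipped", stacklevel=2)

    if all(c.descriptor_vector is not None for c in survivors):
        k = min(config.cluster_k, len(survivors))
        report.representatives = cluster_representatives(
            survivors, k, config.random_seed
        )
        report.record_stage("representatives", [r[1] for r in report.representatives])
    else:
        warnings.warn("survivors lack descriptor vectors; clustering skipped", stacklevel=2)
    return report
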