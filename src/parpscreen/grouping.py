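"""Three-group classification of binding-pocket residues.

Pocket residues are partitioned into an electrostatic group (charged side
chains whose contribution perturbs binding), a non-electrostatic group
(uncharged residues with salient contributions) and a remainder.  Summing
per-residue energies over the partition reduces a complex's decomposition
to the (E_ele, E_nonele, E_other) feature triple consumed by the affinity
model.

Two modes:

* ``explicit`` — the electrostatic set is given outright (the shipped
  PARP-1 scheme lists the eight charged pocket residues with clear
  energetic perturbation: Glu763, Asp766, Asp770, Glu988, Arg865, Arg878,
  Lys893, Lys903);
* ``rule-based`` — a residue is electrostatic iff its residue type is
  charged (ASP/GLU/LYS/ARG; histidine counts as uncharged here) and its
  mean contribution magnitude across the panel reaches a threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .energy import ComplexEnergyTable, GroupEnergyFeatures, ResidueKey
from .errors import InputError

__all__ = [
    "GroupingScheme",
    "GroupAssignment",
    "assign_groups",
    "group_sums",
    "default_parp1_scheme",
    "ELE",
    "NONELE",
    "OTHER",
]

ELE = "ELE"
NONELE = "NONELE"
OTHER = "OTHER"

DEFAULT_CHARGED_RESIDUES = frozenset({"ASP", "GLU", "LYS", "ARG"})


def _normalize_label(item) -> str:
    """Accept ``Glu763``-style labels or ResidueKey and return ``GLU763``."""
    if isinstance(item, ResidueKey):
        return f"{item.resname.upper()}{item.resnum}"
    return str(item).upper()


@dataclass(frozen=True)
class GroupingScheme:
    """Configuration of the three-group residue partition."""

    mode: str = "rule-based"
    electrostatic_set: frozenset[str] = frozenset()
    charged_residue_names: frozenset[str] = DEFAULT_CHARGED_RESIDUES
    contribution_threshold: float = 0.25  # kcal/mol, closed boundary

    def __post_init__(self) -> None:
        if self.mode not in ("explicit", "rule-based"):
            raise InputError(f"unknown grouping mode {self.mode!r}")
        if self.contribution_threshold < 0:
            raise InputError("contribution_threshold must be >= 0")
        if self.mode == "explicit" and not self.electrostatic_set:
            raise InputError("explicit mode requires a non-empty electrostatic_set")
        object.__setattr__(
            self,
            "electrostatic_set",
            frozenset(_normalize_label(x) for x in self.electrostatic_set),
        )
        object.__setattr__(
            self, "charged_residue_names", frozenset(s.upper() for s in self.charged_residue_names)
        )

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "electrostatic_set": sorted(self.electrostatic_set),
            "charged_residue_names": sorted(self.charged_residue_names),
            "contribution_threshold": self.contribution_threshold,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GroupingScheme":
        return cls(
            mode=data.get("mode", "rule-based"),
            electrostatic_set=frozenset(data.get("electrostatic_set", ())),
            charged_residue_names=frozenset(
                data.get("charged_residue_names", DEFAULT_CHARGED_RESIDUES)
            ),
            contribution_threshold=float(data.get("contribution_threshold", 0.25)),
        )


@dataclass
class GroupAssignment:
    """Residue → {ELE, NONELE, OTHER} labels for one panel."""

    labels: dict[ResidueKey, str] = field(default_factory=dict)

    def __getitem__(self, key: ResidueKey) -> str:
        return self.labels[key]

    def get(self, key: ResidueKey, default: str | None = None) -> str | None:
        return self.labels.get(key, default)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [k.chain for k in self.labels],
                "resnum": [k.resnum for k in self.labels],
                "resname": [k.resname for k in self.labels],
                "label": list(self.labels.values()),
            }
        )


def default_parp1_scheme() -> GroupingScheme:
    """Explicit scheme with the eight electrostatic PARP-1 pocket residues.

    Four acidic residues favour binding (Glu763, Asp766, Asp770, Glu988 —
    the first three sit on the αF helix of the helical domain) and four
    basic residues oppose it (Arg865, Arg878, Lys893, Lys903).
    """
    return GroupingScheme(
        mode="explicit",
        electrostatic_set=frozenset(
            {
                "Glu763",
                "Asp766",
                "Asp770",
                "Glu988",
                "Arg865",
                "Arg878",
                "Lys893",
                "Lys903",
            }
        ),
    )


def _mean_contributions(panel: list[ComplexEnergyTable]) -> dict[ResidueKey, float]:
    sums: dict[ResidueKey, list[float]] = {}
    for table in panel:
        for key, energy in table.entries.items():
            sums.setdefault(key, []).append(energy)
    return {key: math.fsum(vals) / len(vals) for key, vals in sums.items()}


def assign_groups(
    panel: list[ComplexEnergyTable], scheme: GroupingScheme
) -> GroupAssignment:
    """Label every residue appearing in the panel.

    The salience statistic is the mean contribution over the complexes in
    which the residue appears; the magnitude test uses a closed boundary
    (``|mean| >= threshold`` is salient).  Order of complexes is irrelevant.
    """
    if not panel:
        raise InputError("cannot assign groups on an empty panel")
    means = _mean_contributions(panel)
    labels: dict[ResidueKey, str] = {}
    thr = scheme.contribution_threshold
    for key, mean in means.items():
        label_key = _normalize_label(key)
        salient = abs(mean) >= thr
        if scheme.mode == "explicit":
            if label_key in scheme.electrostatic_set:
                labels[key] = ELE
            elif salient:
                labels[key] = NONELE
            else:
                labels[key] = OTHER
        else:
            charged = key.resname.upper() in scheme.charged_residue_names
            if charged and salient:
                labels[key] = ELE
            elif not charged and salient:
                labels[key] = NONELE
            else:
                labels[key] = OTHER
    return GroupAssignment(labels)


def group_sums(
    table: ComplexEnergyTable, assignment: GroupAssignment
) -> GroupEnergyFeatures:
    """Reduce one complex's decomposition to its group-sum feature triple.

    Residues without a label fall into OTHER with a warning, so the
    partition always conserves the table total.
    """
    buckets: dict[str, list[float]] = {ELE: [], NONELE: [], OTHER: []}
    for key, energy in table.entries.items():
        label = assignment.get(key)
        if label is None:
            warnings.warn(
                f"{table.complex_id}: residue {key.label} has no group label; counted as OTHER",
                stacklevel=2,
            )
            label = OTHER
        buckets[label].append(energy)
    return GroupEnergyFeatures(
        complex_id=table.complex_id,
        e_ele=math.fsum(buckets[ELE]),
        e_nonele=math.fsum(buckets[NONELE]),
        e_other=math.fsum(buckets[OTHER]),
    )
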