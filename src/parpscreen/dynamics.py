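"""Normalized per-residue flexibility profiles.

Crystallographic B-factors (and MD-derived RMSF values) are only comparable
across structures after normalization; here "normalized" means the per-chain
z-score of per-residue backbone means, using the population (n) standard
deviation.  Z-scoring is affine-invariant, so profiles from structures
refined at different overall temperature-factor scales overlay directly, and
B-factor and RMSF profiles land on a common scale.

Segment annotations (e.g. the αA–αF helices of the PARP-1 helical domain)
project a profile onto named regions; ensemble averaging over many complex
structures extracts the flexibility signature common to ligand binding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import ResidueKey
from .errors import DomainError, InputError, NormalizationError, SchemaError
from .structure import Structure

__all__ = [
    "FlexProfile",
    "bfactor_profile",
    "rmsf_profile",
    "ensemble_mean_profile",
    "segment_summary",
    "overlay_profiles",
    "default_hd_annotation",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Segment name -> list of closed residue-number intervals.
SegmentAnnotation = dict[str, list[tuple[int, int]]]


@dataclass
class FlexProfile:
    """Ordered per-residue raw and normalized flexibility values."""

    structure_id: str
    kind: str  # "bfactor" | "rmsf"
    residues: list[ResidueKey]
    raw: np.ndarray
    normalized: np.ndarray
    coverage: np.ndarray | None = None  # profiles per residue, for ensembles

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        if not (len(self.residues) == self.raw.size == self.normalized.size):
            raise InputError("residues, raw and normalized must have equal length")

    def __len__(self) -> int:
        return len(self.residues)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chain": [r.chain for r in self.residues],
                "resnum": [r.resnum for r in self.residues],
                "resname": [r.resname for r in self.residues],
                "raw": self.raw,
                "normalized": self.normalized,
            }
        )
        if self.coverage is not None:
            df["coverage"] = self.coverage
        return df


def _zscore(values: np.ndarray, what: str) -> np.ndarray:
    sd = values.std()  # population SD: fixed convention for cross-structure work
    if sd == 0:
        raise NormalizationError(f"{what}: values are constant, cannot z-score")
    return (values - values.mean()) / sd


def bfactor_profile(structure: Structure, chain: str) -> FlexProfile:
    """Z-scored backbone B-factor profile of one chain.

    The raw value per residue is the mean B-factor over its backbone atoms
    (N, CA, C, O); residues without any backbone atom are skipped with a
    warning.  Requires at least three residues.
    """
    if chain not in structure.chains:
        raise InputError(f"{structure.id}: no chain {chain!r}")
    residues: list[ResidueKey] = []
    raw: list[float] = []
    seen: dict[tuple[str, str], list[float]] = {}
    order: list[tuple[ResidueKey, tuple[str, str]]] = []
    for atom in structure.atoms:
        if atom.chain != chain or atom.is_hetero:
            continue
        key = (atom.chain, atom.residue_id)
        if key not in seen:
            seen[key] = []
            order.append(
                (ResidueKey(atom.chain, atom.residue_number, atom.residue_name), key)
            )
        if atom.name in BACKBONE_ATOMS:
            seen[key].append(atom.b_factor)
    for rkey, key in order:
        values = seen[key]
        if not values:
            warnings.warn(
                f"{structure.id}: residue {rkey.label} has no backbone atoms; skipped",
                stacklevel=2,
            )
            continue
        residues.append(rkey)
        raw.append(float(np.mean(values)))
    if len(residues) < 3:
        raise InputError(f"{structure.id} chain {chain!r}: need >= 3 profiled residues")
    raw_arr = np.array(raw)
    return FlexProfile(structure.id, "bfactor", residues, raw_arr, _zscore(raw_arr, structure.id))


def rmsf_profile(source: pd.DataFrame | str | Path, structure_id: str = "rmsf") -> FlexProfile:
    """Z-scored RMSF profile from a (chain, resnum, resname, rmsf) table.

    Accepts a DataFrame or a CSV path.  The normalization is identical to
    :func:`bfactor_profile`, so the two kinds overlay directly.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    required = {"chain", "resnum", "resname", "rmsf"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"RMSF table missing columns {sorted(missing)}")
    values = df["rmsf"].to_numpy(dtype=float)
    if values.size < 3:
        raise InputError("need >= 3 residues for an RMSF profile")
    if np.any(values < 0):
        raise DomainError("RMSF values must be non-negative")
    residues = [
        ResidueKey(str(c), int(n), str(r).upper())
        for c, n, r in zip(df["chain"], df["resnum"], df["resname"])
    ]
    return FlexProfile(structure_id, "rmsf", residues, values, _zscore(values, structure_id))


def ensemble_mean_profile(profiles: list[FlexProfile]) -> FlexProfile:
    """Residue-wise mean of normalized values across profiles.

    Alignment is by residue number; each residue's mean runs over the
    profiles that contain it, with the coverage count recorded.  The result
    is itself on the z-score scale but is not re-normalized (its spread
    shrinks as incoherent fluctuation averages out).
    """
    if len(profiles) < 2:
        raise InputError("ensemble mean needs at least two profiles")
    by_resnum: dict[int, list[float]] = {}
    names: dict[int, ResidueKey] = {}
    for profile in profiles:
        for rkey, value in zip(profile.residues, profile.normalized):
            by_resnum.setdefault(rkey.resnum, []).append(float(value))
            names.setdefault(rkey.resnum, rkey)
    if not any(len(v) >= 2 for v in by_resnum.values()):
        raise InputError("profiles share no residue numbers")
    resnums = sorted(by_resnum)
    mean = np.array([np.mean(by_resnum[r]) for r in resnums])
    coverage = np.array([len(by_resnum[r]) for r in resnums])
    residues = [names[r] for r in resnums]
    return FlexProfile(
        structure_id="ensemble_mean",
        kind=profiles[0].kind,
        residues=residues,
        raw=mean,
        normalized=mean,
        coverage=coverage,
    )


def segment_summary(
    profile: FlexProfile, annotation: SegmentAnnotation
) -> dict[str, float]:
    """Mean normalized flexibility per annotated segment.

    Interval boundaries are closed; a segment matching no profiled residue
    is omitted with a warning.
    """
    out: dict[str, float] = {}
    resnums = np.array([r.resnum for r in profile.residues])
    for name, intervals in annotation.items():
        if isinstance(intervals, tuple):
            intervals = [intervals]
        mask = np.zeros(resnums.size, dtype=bool)
        for start, end in intervals:
            mask |= (resnums >= start) & (resnums <= end)
        if not mask.any():
            warnings.warn(f"segment {name!r} matches no profiled residue; omitted", stacklevel=2)
            continue
        out[name] = float(profile.normalized[mask].mean())
    return out


def overlay_profiles(a: FlexProfile, b: FlexProfile) -> pd.DataFrame:
    """Pair two profiles on shared residue numbers (inner join, no gaps)."""
    da = a.to_dataframe()[["resnum", "normalized"]].rename(columns={"normalized": a.kind})
    db = b.to_dataframe()[["resnum", "normalized"]].rename(columns={"normalized": b.kind})
    return da.merge(db, on="resnum", how="inner")


def default_hd_annotation() -> SegmentAnnotation:
    """Placeholder helix annotation for the PARP-1 catalytic domain.

    The helical-domain helix boundaries (αA–αF) are approximate intervals on
    the catalytic-domain numbering and are NOT curated against a structure;
    edit them before drawing biological conclusions.  The ART interval spans
    the ADP-ribosyl transferase domain.
    """
    return {
        "aA": [(662, 680)],
        "aB": [(688, 706)],
        "aC": [(708, 717)],
        "aD": [(720, 736)],
        "aE": [(741, 751)],
        "aF": [(760, 784)],
        "ART": [(785, 1011)],
    }
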