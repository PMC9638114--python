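"""Aggregation of MM/GBSA end-point energies.

Takes per-snapshot energy terms from an equilibrium trajectory segment
(electrostatic ΔE_ele, van der Waals ΔE_vdw, polar solvation ΔE_ele,sol and
nonpolar solvation ΔE_nonpl,sol, all kcal/mol) and reduces them to the
mean ± SD summary customarily tabulated, with the binding enthalpy

    ΔH = ΔE_ele + ΔE_vdw + ΔE_ele,sol + ΔE_nonpl,sol

summed per snapshot before averaging.  Entropy is not modelled.  Differences
between compounds propagate SDs as root-sum-square under an independence
assumption.  Per-residue decompositions are ranked and cross-tabulated for
hot-spot comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import ResidueKey
from .errors import InputError, SchemaError

__all__ = [
    "TERM_NAMES",
    "SnapshotEnergies",
    "EnergySummary",
    "EnergyDifference",
    "summarize",
    "total_from_means",
    "pairwise_difference",
    "per_residue_ranking",
    "read_snapshot_csv",
]

TERM_NAMES = ("e_ele", "e_vdw", "e_ele_sol", "e_nonpl_sol")


@dataclass
class SnapshotEnergies:
    """Per-snapshot MM/GBSA terms for one compound, shape (n_snapshots, 4)."""

    compound_id: str
    terms: np.ndarray

    def __post_init__(self) -> None:
        self.terms = np.atleast_2d(np.asarray(self.terms, dtype=float))
        if self.terms.shape[1] != len(TERM_NAMES):
            raise InputError(
                f"{self.compound_id}: expected {len(TERM_NAMES)} term columns, got {self.terms.shape[1]}"
            )
        if not np.all(np.isfinite(self.terms)):
            raise InputError(f"{self.compound_id}: non-finite snapshot energies")

    @property
    def n_snapshots(self) -> int:
        return self.terms.shape[0]


@dataclass
class EnergySummary:
    """Mean ± SD per term plus the enthalpy total, kcal/mol."""

    compound_id: str
    term_means: pd.Series
    term_sds: pd.Series
    dh_mean: float
    dh_sd: float
    n_snapshots: int

    def to_dict(self) -> dict:
        return {
            "compound_id": self.compound_id,
            "n_snapshots": self.n_snapshots,
            **{f"{t}_mean": float(self.term_means[t]) for t in TERM_NAMES},
            **{f"{t}_sd": float(self.term_sds[t]) for t in TERM_NAMES},
            "dh_mean": self.dh_mean,
            "dh_sd": self.dh_sd,
        }


@dataclass
class EnergyDifference:
    """Term-wise and total differences between two summaries."""

    pair: tuple[str, str]
    term_diff_means: pd.Series
    term_diff_sds: pd.Series
    dh_diff_mean: float
    dh_diff_sd: float


def summarize(snapshots: SnapshotEnergies) -> EnergySummary:
    """Mean and sample SD (n−1) per term and for the per-snapshot ΔH.

    By linearity the ΔH mean equals the sum of term means; this identity is
    asserted internally on every call.
    """
    if snapshots.n_snapshots < 2:
        raise InputError(f"{snapshots.compound_id}: need >= 2 snapshots for SDs")
    terms = snapshots.terms
    means = pd.Series(terms.mean(axis=0), index=TERM_NAMES)
    sds = pd.Series(terms.std(axis=0, ddof=1), index=TERM_NAMES)
    dh = terms.sum(axis=1)
    dh_mean = float(dh.mean())
    assert math.isclose(dh_mean, float(means.sum()), rel_tol=0, abs_tol=1e-9)
    return EnergySummary(
        compound_id=snapshots.compound_id,
        term_means=means,
        term_sds=sds,
        dh_mean=dh_mean,
        dh_sd=float(dh.std(ddof=1)),
        n_snapshots=snapshots.n_snapshots,
    )


def total_from_means(term_means) -> float:
    """Enthalpy total as the arithmetic sum of the four term means."""
    values = np.asarray(list(term_means), dtype=float)
    if values.shape != (4,) or not np.all(np.isfinite(values)):
        raise InputError("total_from_means expects four finite term means")
    return float(values.sum())


def pairwise_difference(a: EnergySummary, b: EnergySummary) -> EnergyDifference:
    """a − b per term and in total; SDs propagate as sqrt(sa² + sb²)."""
    diff_means = a.term_means - b.term_means
    diff_sds = np.sqrt(a.term_sds**2 + b.term_sds**2)
    return EnergyDifference(
        pair=(a.compound_id, b.compound_id),
        term_diff_means=diff_means,
        term_diff_sds=diff_sds,
        dh_diff_mean=a.dh_mean - b.dh_mean,
        dh_diff_sd=float(math.hypot(a.dh_sd, b.dh_sd)),
    )


def read_snapshot_csv(path: str | Path) -> dict[str, SnapshotEnergies]:
    """Read per-snapshot term streams from CSV.

    Expected columns: ``compound_id,frame,e_ele,e_vdw,e_ele_sol,e_nonpl_sol``;
    frames are kept in file order per compound.
    """
    df = pd.read_csv(path)
    required = {"compound_id", *TERM_NAMES}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for cid, group in df.groupby("compound_id", sort=False):
        out[str(cid)] = SnapshotEnergies(str(cid), group[list(TERM_NAMES)].to_numpy(dtype=float))
    return out


def per_residue_ranking(
    decomposition: pd.DataFrame,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Rank per-residue contributions and cross-tabulate them across compounds.

    ``decomposition`` needs columns compound_id, chain, resnum, resname,
    energy.  Returns per-compound tables sorted most-favourable-first
    (ascending energy) and a residue × compound matrix with NaN marking a
    residue absent from a compound's decomposition.  A duplicated
    (compound, residue) pair is a schema error.
    """
    required = {"compound_id", "chain", "resnum", "resname", "energy"}
    missing = required - set(decomposition.columns)
    if missing:
        raise SchemaError(f"decomposition missing columns {sorted(missing)}")
    if decomposition.empty:
        raise InputError("empty decomposition table")
    energies = decomposition["energy"].to_numpy(dtype=float)
    if not np.all(np.isfinite(energies)):
        raise InputError("decomposition energies must be finite")
    df = decomposition.copy()
    df["residue"] = [
        ResidueKey(str(c), int(n), str(r).upper()).label
        for c, n, r in zip(df["chain"], df["resnum"], df["resname"])
    ]
    dupes = df.duplicated(subset=["compound_id", "chain", "resnum", "resname"])
    if dupes.any():
        first = df[dupes].iloc[0]
        raise SchemaError(
            f"duplicate residue {first['residue']} for compound {first['compound_id']}"
        )
    ranked = {
        str(cid): group.sort_values("energy", kind="stable")[
            ["residue", "energy"]
        ].reset_index(drop=True)
        for cid, group in df.groupby("compound_id", sort=False)
    }
    matrix = df.pivot_table(
        index="residue", columns="compound_id", values="energy", aggfunc="first"
    )
    # order residues by their most favourable contribution anywhere
    matrix = matrix.loc[matrix.min(axis=1).sort_values(kind="stable").index]
    return ranked, matrix
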