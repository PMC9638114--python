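"""Per-residue energy decomposition tables and bundled reference data.

The central currencies of the rescoring pipeline:

* :class:`ComplexEnergyTable` — one protein–ligand complex's per-residue
  interaction-energy decomposition (kcal/mol, keyed by residue identity);
* :class:`GroupEnergyFeatures` — the reduced (E_ele, E_nonele, E_other)
  triple for one complex, optionally with an experimental affinity;
* :class:`EnergyPanel` — an ordered collection of feature rows, the input
  to the linear affinity model.

Two published reference tables for the PARP-1 catalytic domain ship as
package data: the 33-complex group-energy panel (15 rows with experimental
affinities) and the MM/GBSA term summary for the four screening hits.
Values are stored as decimal strings and parsed once, so comparisons at the
printed precision (2 decimals) are free of float-literal drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, NamedTuple

import math
import numpy as np
import pandas as pd

from .errors import FormatError, InputError, SchemaError

__all__ = [
    "ResidueKey",
    "ComplexEnergyTable",
    "GroupEnergyFeatures",
    "EnergyPanel",
    "read_energy_csv",
    "write_energy_csv",
    "load_table1_fixture",
    "load_table1_dataframe",
    "load_table2_fixture",
    "PUBLISHED_HIT_COMPOUNDS",
]

#: Chemdiv codes of the four experimentally confirmed screening hits.
PUBLISHED_HIT_COMPOUNDS = ("8012-0567", "8018-7603", "8018-7168", "8018-6529")

ENERGY_CSV_COLUMNS = ("complex_id", "ligand_id", "chain", "resnum", "resname", "energy")


class ResidueKey(NamedTuple):
    """Identity of one residue within a complex table."""

    chain: str
    resnum: int
    resname: str

    @property
    def label(self) -> str:
        """Human-style residue label, e.g. ``Glu763``."""
        return f"{self.resname.capitalize()}{self.resnum}"


@dataclass
class ComplexEnergyTable:
    """Per-residue interaction energies (kcal/mol) for one complex."""

    complex_id: str
    ligand_id: str
    entries: dict[ResidueKey, float]
    total_score: float | None = None

    def __post_init__(self) -> None:
        if not self.entries:
            raise InputError(f"{self.complex_id}: energy table has no residue entries")
        for key, value in self.entries.items():
            if not math.isfinite(value):
                raise InputError(f"{self.complex_id}/{key.label}: energy is not finite")

    @property
    def total(self) -> float:
        """Sum of all residue contributions (not the docking score)."""
        return math.fsum(self.entries.values())


@dataclass(frozen=True)
class GroupEnergyFeatures:
    """The three residue-group energy sums for one complex, kcal/mol."""

    complex_id: str
    e_ele: float
    e_nonele: float
    e_other: float
    experimental_dg: float | None = None

    def __post_init__(self) -> None:
        for name in ("e_ele", "e_nonele", "e_other"):
            if not math.isfinite(getattr(self, name)):
                raise InputError(f"{self.complex_id}: {name} is not finite")
        if self.experimental_dg is not None and not math.isfinite(self.experimental_dg):
            raise InputError(f"{self.complex_id}: experimental_dg is not finite")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.e_ele, self.e_nonele, self.e_other])


@dataclass
class EnergyPanel:
    """Ordered collection of group-energy feature rows with unique ids."""

    rows: list[GroupEnergyFeatures]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.complex_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate complex ids in panel: {dupes}")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[GroupEnergyFeatures]:
        return iter(self.rows)

    def labeled(self) -> "EnergyPanel":
        """Sub-panel of rows that carry an experimental affinity."""
        return EnergyPanel(
            [r for r in self.rows if r.experimental_dg is not None],
            provenance=self.provenance,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "complex_id": [r.complex_id for r in self.rows],
                "e_ele": [r.e_ele for r in self.rows],
                "e_nonele": [r.e_nonele for r in self.rows],
                "e_other": [r.e_other for r in self.rows],
                "experimental_dg": [r.experimental_dg for r in self.rows],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "EnergyPanel":
        required = {"complex_id", "e_ele", "e_nonele", "e_other"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"panel is missing columns: {sorted(missing)}")
        rows = []
        for _, rec in df.iterrows():
            dg = rec.get("experimental_dg")
            if dg is None or (isinstance(dg, float) and math.isnan(dg)):
                dg = None
            else:
                dg = float(dg)
            rows.append(
                GroupEnergyFeatures(
                    complex_id=str(rec["complex_id"]),
                    e_ele=float(rec["e_ele"]),
                    e_nonele=float(rec["e_nonele"]),
                    e_other=float(rec["e_other"]),
                    experimental_dg=dg,
                )
            )
        return cls(rows, provenance=provenance)


def _normalize_minus(text: str) -> str:
    # published tables use U+2212; normalize before parsing
    return text.replace("−", "-")


def read_energy_csv(path: str | Path) -> list[ComplexEnergyTable]:
    """Read per-residue energy tables from CSV.

    Expected header: ``complex_id,ligand_id,chain,resnum,resname,energy``
    with an optional ``total_score`` column.  Rows are grouped by complex in
    file order; a duplicated (complex, residue) pair is a schema error.
    """
    df = pd.read_csv(path, dtype=str)
    missing = set(ENERGY_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    has_total = "total_score" in df.columns

    tables: dict[str, dict[ResidueKey, float]] = {}
    ligands: dict[str, str] = {}
    totals: dict[str, float | None] = {}
    for i, rec in df.iterrows():
        rownum = i + 2  # header is line 1
        cid = str(rec["complex_id"])
        raw = _normalize_minus(str(rec["energy"]))
        try:
            energy = float(raw)
        except ValueError:
            raise FormatError(f"{path} row {rownum}: non-numeric energy {raw!r}") from None
        try:
            resnum = int(str(rec["resnum"]))
        except ValueError:
            raise FormatError(f"{path} row {rownum}: non-integer resnum {rec['resnum']!r}") from None
        key = ResidueKey(str(rec["chain"]), resnum, str(rec["resname"]).upper())
        entries = tables.setdefault(cid, {})
        if key in entries:
            raise SchemaError(f"{path} row {rownum}: duplicate residue {key.label} for {cid}")
        entries[key] = energy
        ligands.setdefault(cid, str(rec["ligand_id"]))
        if has_total and cid not in totals:
            val = rec.get("total_score")
            totals[cid] = None if pd.isna(val) else float(_normalize_minus(str(val)))

    return [
        ComplexEnergyTable(
            complex_id=cid,
            ligand_id=ligands[cid],
            entries=entries,
            total_score=totals.get(cid),
        )
        for cid, entries in tables.items()
    ]


def write_energy_csv(tables: list[ComplexEnergyTable], path: str | Path) -> None:
    """Inverse of :func:`read_energy_csv` on valid tables."""
    records = []
    for table in tables:
        for key, energy in table.entries.items():
            rec = {
                "complex_id": table.complex_id,
                "ligand_id": table.ligand_id,
                "chain": key.chain,
                "resnum": key.resnum,
                "resname": key.resname,
                "energy": repr(energy),
            }
            if table.total_score is not None:
                rec["total_score"] = repr(table.total_score)
            records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False)


def _data_path(name: str):
    return resources.files("parpscreen.data").joinpath(name)


def load_table1_dataframe() -> pd.DataFrame:
    """The published 33-complex group-energy panel, including the published
    model predictions, at printed (2-decimal) precision."""
    with resources.as_file(_data_path("table1.csv")) as p:
        df = pd.read_csv(p)
    return df


def load_table1_fixture() -> EnergyPanel:
    """The published group-energy panel as an :class:`EnergyPanel`.

    33 complexes; 15 rows carry an experimental binding free energy derived
    from averaged IC50 measurements.
    """
    df = load_table1_dataframe()
    return EnergyPanel.from_dataframe(df, provenance="published PARP-1 panel")


def load_table2_fixture() -> dict[str, dict[str, tuple[float, float]]]:
    """Published MM/GBSA term summary for the four screening hits.

    Returns ``{compound_id: {term: (mean, sd)}}`` with terms ``e_ele``,
    ``e_vdw``, ``e_ele_sol``, ``e_nonpl_sol`` and the enthalpy total ``dh``,
    all in kcal/mol.
    """
    with resources.as_file(_data_path("table2.csv")) as p:
        df = pd.read_csv(p)
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for _, rec in df.iterrows():
        out.setdefault(str(rec["compound_id"]), {})[str(rec["term"])] = (
            float(rec["mean"]),
            float(rec["sd"]),
        )
    return out
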