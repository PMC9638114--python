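"""Synthetic-data generators for every pipeline stage.

Each generator is a pure function of its arguments (seeded
``numpy.random.Generator``; same arguments, same output bit-for-bit) and
produces data with the statistical structure the corresponding analysis
assumes:

* group-energy panels from a known 3-coefficient linear model plus Gaussian
  noise, together with per-residue tables whose group sums reproduce the
  panel features exactly by construction;
* active/decoy score sets with controllable separation ``d`` (expected
  AUC = Φ(d/√2));
* compound libraries with drug-likeness properties and descriptor blobs for
  clustering;
* multi-structure B-factor ensembles with planted per-segment flexibility
  effects, emitted as real :class:`~parpscreen.structure.Structure` objects
  so they round-trip through PDB I/O;
* per-snapshot MM/GBSA term streams.

Defaults mirror the published study conditions: a 33-complex panel on the
published feature ranges, 40 actives vs 1990 decoys, retention fractions
10/10/20%, 200 MM/GBSA snapshots.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .energy import ComplexEnergyTable, EnergyPanel, GroupEnergyFeatures, ResidueKey
from .errors import InputError
from .funnel import CompoundRecord, Scorer
from .grouping import ELE, NONELE, OTHER, GroupAssignment, group_sums
from .mmgbsa import TERM_NAMES, SnapshotEnergies
from .screening import ScoredLabelSet
from .structure import Atom, Structure

__all__ = [
    "SyntheticPanel",
    "gen_energy_panel",
    "gen_active_decoy_scores",
    "gen_compound_library",
    "gen_flex_profiles",
    "gen_snapshot_energies",
    "toy_scorer",
    "DEFAULT_FEATURE_RANGES",
]

#: Uniform sampling ranges for (E_ele, E_nonele, E_other), kcal/mol —
#: the extremes of the published 33-complex panel.
DEFAULT_FEATURE_RANGES = {
    "e_ele": (-56.0, -2.0),
    "e_nonele": (-55.0, -21.0),
    "e_other": (-3.0, 4.0),
}

# residue rosters used for synthetic per-residue tables (catalytic-domain
# numbering; ELE = the eight charged pocket residues, NONELE = the core
# uncharged interaction residues)
_ELE_RESIDUES = [
    ("GLU", 763), ("ASP", 766), ("ASP", 770), ("ARG", 865),
    ("ARG", 878), ("LYS", 893), ("LYS", 903), ("GLU", 988),
]
_NONELE_RESIDUES = [
    ("HIS", 862), ("GLY", 863), ("TYR", 896), ("PHE", 897),
    ("SER", 904), ("TYR", 907),
]
_OTHER_RESIDUES = [
    ("ALA", 755), ("LEU", 765), ("GLY", 780), ("VAL", 803),
    ("THR", 868), ("ILE", 872), ("PRO", 881), ("LEU", 886),
    ("ALA", 925), ("VAL", 933),
]


@dataclass
class SyntheticPanel:
    """A generated panel with its ground truth."""

    panel: EnergyPanel
    tables: list[ComplexEnergyTable]
    assignment: GroupAssignment
    true_coeffs: tuple[float, float, float, float]
    noise_sd: float


def _split_total(rng: np.random.Generator, total: float, k: int) -> np.ndarray:
    """Split ``total`` into k random parts of matching sign."""
    weights = rng.dirichlet(np.ones(k))
    return weights * total


def gen_energy_panel(
    seed: int,
    n: int = 33,
    true_coeffs: tuple[float, float, float, float] = (0.067, 0.104, 0.457, -3.615),
    noise_sd: float = 0.5,
    feature_ranges: dict[str, tuple[float, float]] | None = None,
) -> SyntheticPanel:
    """Generate a group-energy panel from a known linear model.

    Per-residue tables are generated first (group targets drawn uniformly in
    ``feature_ranges`` and split across the roster); the panel features are
    then *computed* from those tables with the generating assignment, so
    ``group_sums`` reproduces them exactly.  Experimental affinities are the
    linear model plus N(0, noise_sd²) noise.
    """
    if noise_sd < 0:
        raise InputError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    ranges = feature_ranges or DEFAULT_FEATURE_RANGES
    roster = {
        ELE: [ResidueKey("A", num, name) for name, num in _ELE_RESIDUES],
        NONELE: [ResidueKey("A", num, name) for name, num in _NONELE_RESIDUES],
        OTHER: [ResidueKey("A", num, name) for name, num in _OTHER_RESIDUES],
    }
    assignment = GroupAssignment(
        {key: label for label, keys in roster.items() for key in keys}
    )
    c1, c2, c3, c0 = true_coeffs
    tables: list[ComplexEnergyTable] = []
    rows: list[GroupEnergyFeatures] = []
    for i in range(n):
        cid = f"SYN{i:04d}"
        entries: dict[ResidueKey, float] = {}
        for label, (lo, hi) in zip((ELE, NONELE, OTHER), (ranges["e_ele"], ranges["e_nonele"], ranges["e_other"])):
            total = rng.uniform(lo, hi)
            parts = _split_total(rng, total, len(roster[label]))
            for key, part in zip(roster[label], parts):
                entries[key] = float(part)
        table = ComplexEnergyTable(complex_id=cid, ligand_id=f"LIG{i:04d}", entries=entries)
        features = group_sums(table, assignment)
        dg = (
            c1 * features.e_ele
            + c2 * features.e_nonele
            + c3 * features.e_other
            + c0
            + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        )
        rows.append(
            GroupEnergyFeatures(
                complex_id=cid,
                e_ele=features.e_ele,
                e_nonele=features.e_nonele,
                e_other=features.e_other,
                experimental_dg=float(dg),
            )
        )
        tables.append(table)
    return SyntheticPanel(
        panel=EnergyPanel(rows, provenance=f"synthetic(seed={seed})"),
        tables=tables,
        assignment=assignment,
        true_coeffs=true_coeffs,
        noise_sd=noise_sd,
    )


def gen_active_decoy_scores(
    seed: int,
    n_actives: int = 40,
    n_decoys: int = 1990,
    separation: float = 1.0,
) -> ScoredLabelSet:
    """Gaussian active/decoy scores with mean shift ``separation`` (SD units).

    Decoys score N(0, 1), actives N(−separation, 1) (lower is better), so
    the expected AUC is Φ(separation/√2).
    """
    if n_actives < 1 or n_decoys < 1:
        raise InputError("need at least one active and one decoy")
    rng = np.random.default_rng(seed)
    active_scores = rng.normal(-separation, 1.0, n_actives)
    decoy_scores = rng.normal(0.0, 1.0, n_decoys)
    ids = [f"active_{i}" for i in range(n_actives)] + [f"decoy_{i}" for i in range(n_decoys)]
    return ScoredLabelSet(
        ids=ids,
        scores=np.concatenate([active_scores, decoy_scores]),
        is_active=np.concatenate(
            [np.ones(n_actives, dtype=bool), np.zeros(n_decoys, dtype=bool)]
        ),
    )


def gen_compound_library(
    seed: int,
    n: int = 1000,
    frac_lipinski_fail: float = 0.0,
    k_blobs: int = 3,
    blob_separation: float = 10.0,
    blob_sd: float = 1.0,
    descriptor_dim: int = 8,
) -> list[CompoundRecord]:
    """Generate a compound library with properties and descriptor blobs.

    Each compound fails the rule-of-five with probability
    ``frac_lipinski_fail`` (one randomly chosen rule is violated).
    Descriptor vectors are drawn from ``k_blobs`` spherical Gaussian blobs
    with SD ``blob_sd`` whose centres sit ``blob_separation`` apart along the
    first descriptor axis, so well-separated blobs are exactly recoverable
    by k-means.
    """
    if not 0 <= frac_lipinski_fail <= 1:
        raise InputError("frac_lipinski_fail must be in [0, 1]")
    rng = np.random.default_rng(seed)
    library: list[CompoundRecord] = []
    for i in range(n):
        mw = rng.uniform(200.0, 500.0)
        logp = rng.uniform(-1.0, 5.0)
        hbd = int(rng.integers(0, 6))
        hba = int(rng.integers(0, 11))
        if rng.random() < frac_lipinski_fail:
            rule = rng.integers(0, 4)
            if rule == 0:
                mw = rng.uniform(500.5, 900.0)
            elif rule == 1:
                logp = rng.uniform(5.5, 9.0)
            elif rule == 2:
                hbd = int(rng.integers(6, 12))
            else:
                hba = int(rng.integers(11, 18))
        blob = int(rng.integers(0, k_blobs))
        center = np.zeros(descriptor_dim)
        center[0] = blob * blob_separation
        descriptor = center + rng.normal(0.0, blob_sd, descriptor_dim)
        library.append(
            CompoundRecord(
                id=f"cmpd_{i:05d}",
                mw=float(mw),
                logp=float(logp),
                hbd=hbd,
                hba=hba,
                descriptor_vector=descriptor,
            )
        )
    return library


def toy_scorer(stage_name: str, seed: int = 0) -> Scorer:
    """Deterministic stand-in scorer for funnel testing.

    Scores are uniform pseudo-random in [0, 1), derived by hashing
    (stage, seed, compound id) — stable across processes and library order.
    """

    def score_batch(batch: Sequence[CompoundRecord]) -> list[float]:
        out = []
        for compound in batch:
            digest = hashlib.blake2b(
                f"{stage_name}:{seed}:{compound.id}".encode(), digest_size=8
            ).digest()
            out.append(int.from_bytes(digest, "big") / 2**64)
        return out

    return score_batch


def gen_flex_profiles(
    seed: int,
    n_structures: int = 10,
    segment_effects: dict[str, float] | None = None,
    annotation: dict[str, list[tuple[int, int]]] | None = None,
    resnum_range: tuple[int, int] = (662, 1011),
    baseline_b: float = 20.0,
    noise_sd: float = 5.0,
    chain: str = "A",
) -> list[Structure]:
    """Generate structures with planted segment-level flexibility effects.

    Backbone B-factors are ``baseline_b + effect·noise_sd + N(0, noise_sd²)``
    (clipped at 0.01), where ``effect`` is the entry of ``segment_effects``
    for the segment containing the residue (0 elsewhere), i.e. effects are
    expressed in noise-SD units.  Values are rounded to PDB precision so the
    structures round-trip exactly through :func:`~parpscreen.structure.write_pdb`.
    """
    from .dynamics import default_hd_annotation

    effects = segment_effects or {}
    annot = annotation or default_hd_annotation()
    for name in effects:
        if name not in annot:
            raise InputError(f"segment_effects names unknown segment {name!r}")
    rng = np.random.default_rng(seed)
    lo, hi = resnum_range

    def effect_for(resnum: int) -> float:
        for name, intervals in annot.items():
            for start, end in intervals:
                if start <= resnum <= end:
                    return float(effects.get(name, 0.0))
        return 0.0

    structures = []
    for s in range(n_structures):
        atoms: list[Atom] = []
        serial = 1
        for resnum in range(lo, hi + 1):
            b = baseline_b + effect_for(resnum) * noise_sd + rng.normal(0.0, noise_sd)
            b = round(max(b, 0.01), 2)
            base = np.array([(resnum - lo) * 1.5, 10.0 * (s % 7), 0.0])
            for k, name in enumerate(("N", "CA", "C", "O")):
                coords = np.round(base + np.array([0.3 * k, 0.4 * (k % 2), 0.2 * k]), 3)
                atoms.append(
                    Atom(
                        serial=serial,
                        name=name,
                        element=name[0],
                        residue_name="ALA",
                        chain=chain,
                        residue_number=resnum,
                        coordinates=coords,
                        b_factor=b,
                        is_hetero=False,
                    )
                )
                serial += 1
        structures.append(Structure(id=f"synthetic_{s:02d}", atoms=atoms))
    return structures


def gen_snapshot_energies(
    seed: int,
    means: Sequence[float],
    sds: Sequence[float],
    n_snapshots: int = 200,
    compound_id: str = "synthetic",
) -> SnapshotEnergies:
    """Independent Gaussian per-term snapshot streams.

    ``means`` and ``sds`` follow the term order ``(e_ele, e_vdw, e_ele_sol,
    e_nonpl_sol)``; 200 snapshots mirrors sampling one frame per 0.1 ns over
    a 20 ns equilibrium segment.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if means.shape != (len(TERM_NAMES),) or sds.shape != (len(TERM_NAMES),):
        raise InputError(f"means and sds must have length {len(TERM_NAMES)}")
    if np.any(sds < 0):
        raise InputError("sds must be >= 0")
    rng = np.random.default_rng(seed)
    terms = rng.normal(means, sds, size=(n_snapshots, len(TERM_NAMES)))
    return SnapshotEnergies(compound_id=compound_id, terms=terms)
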