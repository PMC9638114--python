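import numpy as np
import pandas as pd
import pytest

from parpscreen.dynamics import (
    bfactor_profile,
    default_hd_annotation,
    ensemble_mean_profile,
    overlay_profiles,
    rmsf_profile,
    segment_summary,
)
from parpscreen.errors import DomainError, InputError, NormalizationError
from parpscreen.structure import Structure
from parpscreen.simulate import gen_flex_profiles

from conftest import make_atom


def chain_with_bfactors(bfactors, chain="A", start=1):
    atoms = []
    serial = 1
    for i, b in enumerate(bfactors):
        for name in ("N", "CA", "C", "O"):
            atoms.append(
                make_atom(
                    serial=serial,
                    name=name,
                    element=name[0],
                    chain=chain,
                    residue_number=start + i,
                    coordinates=(float(i), 0.0, 0.0),
                    b_factor=float(b),
                )
            )
            serial += 1
    return Structure(id="toy", atoms=atoms)


class TestBfactorProfile:
    def test_linear_ramp_z_scores(self):
        n = 100
        profile = bfactor_profile(chain_with_bfactors(range(1, n + 1)), "A")
        assert profile.normalized.mean() == pytest.approx(0.0, abs=1e-12)
        assert profile.normalized.std() == pytest.approx(1.0, abs=1e-12)
        # closed form: z_i = (i - mean) / sqrt((n^2 - 1)/12)
        idx = np.arange(1, n + 1)
        expected = (idx - idx.mean()) / np.sqrt((n**2 - 1) / 12)
        np.testing.assert_allclose(profile.normalized, expected, atol=1e-12)

    def test_three_residue_hand_case(self):
        profile = bfactor_profile(chain_with_bfactors([10.0, 20.0, 30.0]), "A")
        # population SD of {10,20,30} is sqrt(200/3)
        expected = np.array([-1.0, 0.0, 1.0]) * (10.0 / np.sqrt(200.0 / 3.0))
        np.testing.assert_allclose(profile.normalized, expected, atol=1e-12)

    def test_constant_bfactors_rejected(self):
        with pytest.raises(NormalizationError):
            bfactor_profile(chain_with_bfactors([7.0, 7.0, 7.0, 7.0]), "A")

    def test_backbone_mean_not_all_atoms(self):
        structure = chain_with_bfactors([10.0, 20.0, 30.0])
        # add a wild side-chain B on residue 1; backbone mean must ignore it
        structure.atoms.append(
            make_atom(serial=99, name="CB", element="C", residue_number=1, b_factor=999.0)
        )
        profile = bfactor_profile(structure, "A")
        assert profile.raw[0] == pytest.approx(10.0)

    def test_missing_chain(self):
        with pytest.raises(InputError):
            bfactor_profile(chain_with_bfactors([1.0, 2.0, 3.0]), "Z")

    def test_affine_invariance(self, rng):
        b = rng.uniform(5, 80, 40)
        base = bfactor_profile(chain_with_bfactors(b), "A").normalized
        scaled = bfactor_profile(chain_with_bfactors(3.5 * b + 11.0), "A").normalized
        np.testing.assert_allclose(scaled, base, atol=1e-9)

    def test_idempotent_normalization(self, rng):
        b = rng.uniform(5, 80, 40)
        once = bfactor_profile(chain_with_bfactors(b), "A").normalized
        twice = bfactor_profile(chain_with_bfactors(once), "A").normalized
        np.testing.assert_allclose(twice, once, atol=1e-9)


class TestRmsfProfile:
    def test_ramp_normalizes_like_bfactor(self):
        df = pd.DataFrame(
            {
                "chain": "A",
                "resnum": range(1, 22),
                "resname": "ALA",
                "rmsf": np.linspace(0.5, 2.5, 21),
            }
        )
        profile = rmsf_profile(df)
        assert profile.kind == "rmsf"
        assert profile.normalized.mean() == pytest.approx(0.0, abs=1e-12)
        assert profile.normalized.std() == pytest.approx(1.0, abs=1e-12)

    def test_negative_rmsf_rejected(self):
        df = pd.DataFrame(
            {"chain": "A", "resnum": [1, 2, 3], "resname": "ALA", "rmsf": [0.1, -0.2, 0.3]}
        )
        with pytest.raises(DomainError):
            rmsf_profile(df)

    def test_constant_rmsf_rejected(self):
        df = pd.DataFrame(
            {"chain": "A", "resnum": [1, 2, 3], "resname": "ALA", "rmsf": [1.0, 1.0, 1.0]}
        )
        with pytest.raises(NormalizationError):
            rmsf_profile(df)

    def test_overlay_with_bfactor_profile(self):
        bprof = bfactor_profile(chain_with_bfactors([10.0, 20.0, 30.0]), "A")
        df = pd.DataFrame(
            {"chain": "A", "resnum": [1, 2, 3], "resname": "ALA", "rmsf": [0.5, 1.5, 1.0]}
        )
        paired = overlay_profiles(rmsf_profile(df), bprof)
        assert len(paired) == 3
        assert not paired.isna().any().any()
        assert set(paired.columns) == {"resnum", "rmsf", "bfactor"}


class TestEnsembleMean:
    def test_identical_profiles_idempotent(self):
        profile = bfactor_profile(chain_with_bfactors([10.0, 20.0, 30.0]), "A")
        mean = ensemble_mean_profile([profile, profile])
        np.testing.assert_allclose(mean.normalized, profile.normalized)
        assert list(mean.coverage) == [2, 2, 2]

    def test_opposite_profiles_cancel(self):
        up = bfactor_profile(chain_with_bfactors([10.0, 20.0, 30.0]), "A")
        down = bfactor_profile(chain_with_bfactors([30.0, 20.0, 10.0]), "A")
        mean = ensemble_mean_profile([up, down])
        np.testing.assert_allclose(mean.normalized, np.zeros(3), atol=1e-12)

    def test_matches_brute_force_average(self, rng):
        profiles = [
            bfactor_profile(chain_with_bfactors(rng.uniform(5, 60, 25)), "A")
            for _ in range(10)
        ]
        mean = ensemble_mean_profile(profiles)
        stacked = np.stack([p.normalized for p in profiles])
        np.testing.assert_allclose(mean.normalized, stacked.mean(axis=0), atol=1e-12)

    def test_disjoint_numbering_rejected(self):
        a = bfactor_profile(chain_with_bfactors([1.0, 2.0, 3.0], start=1), "A")
        b = bfactor_profile(chain_with_bfactors([1.0, 2.0, 3.0], start=100), "A")
        with pytest.raises(InputError):
            ensemble_mean_profile([a, b])


class TestSegmentSummary:
    def test_single_residue_segment(self):
        profile = bfactor_profile(chain_with_bfactors([10.0, 20.0, 30.0]), "A")
        summary = segment_summary(profile, {"first": [(1, 1)]})
        assert summary["first"] == pytest.approx(profile.normalized[0])

    def test_whole_chain_segment_is_zero(self, rng):
        profile = bfactor_profile(chain_with_bfactors(rng.uniform(5, 60, 30)), "A")
        summary = segment_summary(profile, {"all": [(1, 30)]})
        assert summary["all"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_mask(self, rng):
        values = rng.uniform(5, 60, 50)
        profile = bfactor_profile(chain_with_bfactors(values), "A")
        annotation = {"s1": [(3, 9), (20, 25)], "s2": [(30, 45)]}
        summary = segment_summary(profile, annotation)
        resnums = np.arange(1, 51)
        for name, intervals in annotation.items():
            mask = np.zeros(50, dtype=bool)
            for lo, hi in intervals:
                mask |= (resnums >= lo) & (resnums <= hi)
            assert summary[name] == pytest.approx(profile.normalized[mask].mean())

    def test_unmatched_segment_warns_and_is_omitted(self):
        profile = bfactor_profile(chain_with_bfactors([10.0, 20.0, 30.0]), "A")
        with pytest.warns(UserWarning, match="ghost"):
            summary = segment_summary(profile, {"ghost": [(500, 600)]})
        assert "ghost" not in summary


class TestPlantedEffects:
    def test_planted_segment_ranks_most_flexible(self):
        structures = gen_flex_profiles(seed=4, n_structures=10, segment_effects={"aF": 2.0})
        profiles = [bfactor_profile(s, "A") for s in structures]
        mean = ensemble_mean_profile(profiles)
        summary = segment_summary(mean, default_hd_annotation())
        assert max(summary, key=summary.get) == "aF"

    def test_zero_effects_stay_flat(self):
        structures = gen_flex_profiles(seed=4, n_structures=10)
        profiles = [bfactor_profile(s, "A") for s in structures]
        summary = segment_summary(ensemble_mean_profile(profiles), default_hd_annotation())
        assert max(abs(v) for v in summary.values()) < 0.25
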