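import math
import warnings

import numpy as np
import pytest

from parpscreen.affinity import AffinityResults, published_parp1_model
from parpscreen.energy import GroupEnergyFeatures
from parpscreen.errors import InputError, SchemaError
from parpscreen.funnel import (
    CompoundRecord,
    FunnelConfig,
    cluster_representatives,
    lipinski_filter,
    rescore_and_rank,
    retention_stage,
    run_funnel,
)
from parpscreen.simulate import gen_compound_library, toy_scorer


def compound(id="c", mw=350.0, logp=2.0, hbd=2, hba=5, **kwargs):
    return CompoundRecord(id=id, mw=mw, logp=logp, hbd=hbd, hba=hba, **kwargs)


class TestLipinski:
    @pytest.mark.parametrize(
        "props, survives",
        [
            (dict(mw=350, logp=2, hbd=2, hba=5), True),
            (dict(mw=600, logp=2, hbd=2, hba=5), False),
            (dict(mw=500.0, logp=5.0, hbd=5, hba=10), True),  # closed boundaries
            (dict(mw=350, logp=5.1, hbd=6, hba=5), False),
        ],
    )
    def test_rule_of_five(self, props, survives):
        survivors = lipinski_filter([compound(**props)])
        assert bool(survivors) is survives

    def test_max_violations_relaxation(self):
        c = compound(mw=600, logp=2, hbd=2, hba=5)
        assert lipinski_filter([c], max_violations=1) == [c]

    def test_missing_property_collected_not_raised(self):
        bad = compound(id="bad", mw=float("nan"))
        good = compound(id="good")
        survivors = lipinski_filter([bad, good])
        assert [c.id for c in survivors] == ["good"]
        assert bad.alive is False and "missing property" in bad.drop_reason


class TestRetentionStage:
    def test_keeps_ceiling_of_fraction(self):
        library = [compound(id=f"c{i}") for i in range(100)]
        scorer = lambda batch: [float(i) for i in range(len(batch))]
        survivors = retention_stage(library, scorer, 0.1, "S")
        assert [c.id for c in survivors] == [f"c{i}" for i in range(10)]
        assert all(c.stage_scores["S"] == float(i) for i, c in enumerate(survivors))

    def test_fraction_one_sorts_everything(self):
        library = [compound(id=f"c{i}") for i in range(5)]
        scorer = lambda batch: [4.0, 3.0, 2.0, 1.0, 0.0]
        survivors = retention_stage(library, scorer, 1.0, "S")
        assert [c.id for c in survivors] == ["c4", "c3", "c2", "c1", "c0"]

    def test_adversarial_ties_match_stable_sort(self):
        # a tie block straddles the retention cut
        library = [compound(id=f"c{i}") for i in range(10)]
        scores = [0.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 2.0, 2.0, 0.5]
        survivors = retention_stage(library, lambda b: scores, 0.3, "S")
        order = np.argsort(np.array(scores), kind="stable")[:3]
        assert [c.id for c in survivors] == [f"c{i}" for i in order]

    def test_failed_scorer_drops_compound(self):
        library = [compound(id="ok"), compound(id="broken")]
        survivors = retention_stage(library, lambda b: [0.5, float("nan")], 1.0, "S")
        assert [c.id for c in survivors] == ["ok"]
        assert library[1].alive is False

    def test_strict_mode_aborts(self):
        library = [compound(id="broken")]
        with pytest.raises(InputError):
            retention_stage(library, lambda b: [float("nan")], 1.0, "S", strict=True)


class TestRescoreAndRank:
    def test_best_predicted_affinity_wins(self):
        model = published_parp1_model()
        features = {
            "deep": GroupEnergyFeatures("deep", -33.44, -50.87, 0.08),  # predicts -11.11
            "shallow": GroupEnergyFeatures("shallow", -27.60, -31.85, -1.51),  # predicts -9.47
        }
        library = [compound(id="shallow"), compound(id="deep")]
        top = rescore_and_rank(library, model, features, top_n=1)
        assert [c.id for c in top] == ["deep"]
        assert top[0].stage_scores["rescore"] == pytest.approx(-11.11, abs=0.01)

    def test_top_n_beyond_size_returns_all_sorted(self, rng):
        model = AffinityResults.from_coefficients(1.0, 1.0, 1.0, 0.0)
        library = [compound(id=f"c{i}") for i in range(50)]
        features = {
            c.id: GroupEnergyFeatures(c.id, *rng.normal(size=3)) for c in library
        }
        ranked = rescore_and_rank(library, model, features, top_n=100)
        predictions = [model.predict(features[c.id]) for c in ranked]
        assert predictions == sorted(predictions)
        assert len(ranked) == 50

    def test_missing_features_dropped(self):
        model = published_parp1_model()
        library = [compound(id="known"), compound(id="unknown")]
        features = {"known": GroupEnergyFeatures("known", -10.0, -30.0, 0.0)}
        kept = rescore_and_rank(library, model, features, top_n=10)
        assert [c.id for c in kept] == ["known"]

    def test_empty_feature_map(self):
        with pytest.raises(InputError):
            rescore_and_rank([compound()], published_parp1_model(), {}, top_n=1)


class TestClusterRepresentatives:
    def test_separated_blobs_recovered_exactly(self):
        library = gen_compound_library(seed=7, n=120, k_blobs=3, blob_separation=10.0, blob_sd=1.0)
        reps = cluster_representatives(library, k=3, seed=0)
        assert len(reps) == 3
        # blob identity is recoverable from the first descriptor coordinate
        def blob_of(c):
            return int(round(c.descriptor_vector[0] / 10.0))

        rep_blobs = set()
        for cluster_id, rep, count in reps:
            members = [c for c in library if blob_of(c) == blob_of(rep)]
            assert count == len(members)
            # representative is the member nearest the blob's k-means centroid
            rep_blobs.add(blob_of(rep))
        assert rep_blobs == {0, 1, 2}

    def test_k_equals_n(self):
        library = gen_compound_library(seed=8, n=5)
        reps = cluster_representatives(library, k=5, seed=0)
        assert sorted(r.id for _, r, _ in reps) == sorted(c.id for c in library)
        assert all(count == 1 for _, _, count in reps)

    def test_duplicates_single_cluster(self):
        library = [compound(id=f"c{i}", descriptor_vector=np.ones(4)) for i in range(6)]
        reps = cluster_representatives(library, k=1, seed=0)
        assert len(reps) == 1 and reps[0][2] == 6

    def test_k_larger_than_n(self):
        with pytest.raises(InputError):
            cluster_representatives([compound(descriptor_vector=np.ones(2))], k=2, seed=0)

    def test_heterogeneous_vectors(self):
        library = [
            compound(id="a", descriptor_vector=np.ones(2)),
            compound(id="b", descriptor_vector=np.ones(3)),
        ]
        with pytest.raises(SchemaError):
            cluster_representatives(library, k=1, seed=0)

    def test_deterministic_given_seed(self):
        library = gen_compound_library(seed=9, n=60)
        a = cluster_representatives(library, k=4, seed=3)
        b = cluster_representatives(library, k=4, seed=3)
        assert [(cid, rep.id, n) for cid, rep, n in a] == [(cid, rep.id, n) for cid, rep, n in b]


class TestRunFunnel:
    def stage_scorers(self, config, seed=0):
        return {name: toy_scorer(name, seed) for name, _ in config.stages}

    def test_survivor_counts_follow_ceilings(self):
        library = gen_compound_library(seed=5, n=1000)
        config = FunnelConfig()
        report = run_funnel(library, config, self.stage_scorers(config))
        counts = dict(report.stage_counts)
        assert counts["lipinski"] == 1000
        assert counts["HTVS"] == 100
        assert counts["SP"] == 10
        assert counts["XP"] == 2

    def test_all_fail_lipinski_gives_empty_report(self):
        library = [compound(id=f"c{i}", mw=700.0) for i in range(10)]
        config = FunnelConfig()
        with pytest.warns(UserWarning, match="empty after Lipinski"):
            report = run_funnel(library, config, self.stage_scorers(config))
        assert dict(report.stage_counts)["lipinski"] == 0
        assert report.survivors == []

    def test_planted_actives_survive_to_representatives(self):
        # 1000 compounds -> 100 -> 10 -> 2 survive the retention chain; the
        # two planted actives always score best, so they must be the two
        # survivors and hence the two cluster representatives
        library = gen_compound_library(seed=6, n=1000)
        planted = {c.id for c in library[:2]}
        config = FunnelConfig(cluster_k=2, random_seed=0)

        def planted_scorer(name):
            base = toy_scorer(name, seed=6)

            def score(batch):
                return [
                    -1000.0 if c.id in planted else s
                    for c, s in zip(batch, base(batch))
                ]

            return score

        scorers = {name: planted_scorer(name) for name, _ in config.stages}
        model = AffinityResults.from_coefficients(1.0, 1.0, 1.0, 0.0)
        features = {
            c.id: GroupEnergyFeatures(
                c.id, -100.0 if c.id in planted else 0.0, 0.0, 0.0
            )
            for c in library
        }
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # the run must be warning-free
            report = run_funnel(library, config, scorers, model=model, features_by_id=features)
        final_ids = {rep.id for _, rep, _ in report.representatives}
        assert final_ids == planted

    def test_missing_scorer_rejected(self):
        config = FunnelConfig()
        with pytest.raises(InputError, match="no scorer"):
            run_funnel([compound()], config, {})

    def test_deterministic_given_seed(self):
        library = gen_compound_library(seed=10, n=300)
        config = FunnelConfig(cluster_k=2)
        r1 = run_funnel(library, config, self.stage_scorers(config))
        library2 = gen_compound_library(seed=10, n=300)
        r2 = run_funnel(library2, config, self.stage_scorers(config))
        assert [c.id for c in r1.survivors] == [c.id for c in r2.survivors]
        assert r1.stage_counts == r2.stage_counts
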