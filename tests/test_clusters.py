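import numpy as np
import pytest

from pairlens.align import sequence_identity
from pairlens.clusters import (
    AllocationUnit,
    ClusterConfig,
    SplitConfig,
    allocate_splits,
    greedy_cluster,
    hierarchical_split_prep,
    leakage_check,
)
from pairlens.simulate import SimulationConfig, simulate_paired_repertoire

from helpers import mk_chain

AA = list("ACDEFGHIKLMNPQRSTVWY")


class TestGreedyCluster:
    def test_exact_threshold_one_cluster_per_unique_sequence(self):
        seqs = ["AAAA", "CCCC", "AAAA", "DDDD", "CCCC"]
        clusters = greedy_cluster(seqs, 1.0)
        assert len(clusters) == 3
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 2, 2]

    def test_mutually_distant_sequences_stay_singletons(self):
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(AA, 40)) for _ in range(12)]
        clusters = greedy_cluster(seqs, 0.9)
        assert len(clusters) == 12

    def test_membership_contract_on_random_toy(self):
        """Every member must reach the threshold against its centroid —
        re-checked with an independent all-pairs identity pass."""
        rng = np.random.default_rng(2)
        base = ["".join(rng.choice(AA, 60)) for _ in range(6)]
        seqs = []
        for b in base:
            for _ in range(8):
                s = list(b)
                for pos in rng.choice(60, 6, replace=False):
                    s[pos] = rng.choice(AA)
                seqs.append("".join(s))
        rng.shuffle(seqs)
        seqs = seqs[:50]
        clusters = greedy_cluster(seqs, 0.7)
        for c in clusters:
            for m in c.members:
                assert sequence_identity(seqs[m], seqs[c.centroid]) >= 0.7

    def test_deterministic_under_input_permutation(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(AA, 30)) for _ in range(15)]
        a = greedy_cluster(seqs, 0.5)
        perm = list(rng.permutation(len(seqs)))
        b = greedy_cluster([seqs[i] for i in perm], 0.5)
        canon_a = sorted(tuple(sorted(seqs[m] for m in c.members)) for c in a)
        canon_b = sorted(
            tuple(sorted(seqs[perm[m]] for m in c.members)) for c in b
        )
        assert canon_a == canon_b

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            greedy_cluster([], 0.5)


def test_cluster_config_validation():
    with pytest.raises(ValueError):
        ClusterConfig(thresholds=(0.5, 0.7))  # not decreasing
    with pytest.raises(ValueError):
        ClusterConfig(thresholds=())
    with pytest.raises(ValueError):
        SplitConfig(fractions=(0.8, 0.3, 0.1))


class TestHierarchy:
    def test_identical_cdr3s_collapse_in_stage_one(self):
        recs = [
            mk_chain(seq="ACDEFGHIKL", cdr3="CCCC", record_id=f"r{i}") for i in range(5)
        ]
        units = hierarchical_split_prep(recs, ClusterConfig(thresholds=(1.0,), cluster_on="cdr3"))
        assert len(units) == 1
        assert units[0].size == 5

    def test_three_tier_toy_matches_hand_trace(self):
        """Two sequence families with family-specific CDR3 variants: stage 1
        collapses identical CDR3s, stage 2 (70%) merges variants within a
        family, stage 3 (50%) keeps the families apart, units = families."""
        rng = np.random.default_rng(4)
        fam1 = "".join(rng.choice(AA, 50))
        fam2 = "".join(rng.choice(AA, 50))
        cdr3s = {0: ("AAAA", "CCCC"), 1: ("DDDD", "EEEE")}
        recs = []
        for f, fam in enumerate((fam1, fam2)):
            for cdr3 in cdr3s[f]:
                for i in range(3):
                    recs.append(
                        mk_chain(seq=fam + cdr3, cdr3=cdr3, record_id=f"f{f}{cdr3[0]}i{i}")
                    )
        units = hierarchical_split_prep(recs, ClusterConfig())
        assert len(units) == 2
        memberships = sorted(
            tuple(sorted(recs[i].record_id[:2] for i in u.record_indices)) for u in units
        )
        assert memberships == [("f0",) * 6, ("f1",) * 6]

    def test_units_partition_records(self, db):
        cfg = SimulationConfig(n_pairs=80, seed=13)
        heavies = [p.heavy for p in simulate_paired_repertoire(cfg, db)]
        units = hierarchical_split_prep(heavies, ClusterConfig())
        seen = sorted(i for u in units for i in u.record_indices)
        assert seen == list(range(len(heavies)))

    def test_empty_cdr3_rejected_when_stage_one_uses_cdr3(self):
        with pytest.raises(ValueError):
            hierarchical_split_prep([mk_chain(cdr3="")], ClusterConfig())


class TestAllocate:
    def _units(self, sizes):
        recs, units, pos = [], [], 0
        for u, size in enumerate(sizes):
            idx = []
            for _ in range(size):
                recs.append(mk_chain(record_id=f"r{pos:03d}"))
                idx.append(pos)
                pos += 1
            units.append(AllocationUnit(unit_id=u, record_indices=idx))
        return units, recs

    def test_target_fill_trace_five_three_two(self):
        units, recs = self._units([5, 3, 2])
        res = allocate_splits(units, recs, SplitConfig(fractions=(0.8, 0.1, 0.1)))
        # train target 8 -> units of 5 and 3; val target 1 -> unit of 2 overfills
        assert res.achieved_fractions == pytest.approx((0.8, 0.2, 0.0))
        assert res.warnings  # overfill is reported
        by_split = {s: sum(1 for v in res.labels.values() if v == s) for s in ("train", "val", "test")}
        assert by_split == {"train": 8, "val": 2, "test": 0}

    def test_single_unit_goes_to_train_with_warning(self):
        units, recs = self._units([10])
        res = allocate_splits(units, recs, SplitConfig())
        assert set(res.labels.values()) == {"train"}
        assert res.warnings

    def test_units_never_straddle_splits(self, db):
        cfg = SimulationConfig(n_pairs=100, seed=14)
        heavies = [p.heavy for p in simulate_paired_repertoire(cfg, db)]
        units = hierarchical_split_prep(heavies, ClusterConfig())
        res = allocate_splits(units, heavies, SplitConfig(), seed=14)
        for u in units:
            labels = {res.labels[heavies[i].record_id] for i in u.record_indices}
            assert len(labels) == 1

    def test_random_policy_approaches_targets_on_singletons(self):
        units, recs = self._units([1] * 400)
        res = allocate_splits(units, recs, SplitConfig(policy="random"), seed=0)
        for achieved, target in zip(res.achieved_fractions, (0.8, 0.1, 0.1)):
            assert abs(achieved - target) < 0.05


class TestLeakage:
    def test_no_violations_on_distinct_records_at_full_identity(self):
        rng = np.random.default_rng(8)
        recs = [mk_chain(seq="".join(rng.choice(AA, 30)), record_id=f"r{i}") for i in range(10)]
        labels = {r.record_id: ("train" if i < 5 else "test") for i, r in enumerate(recs)}
        assert leakage_check(recs, labels, 1.0) == []

    def test_planted_near_duplicate_across_splits_found(self):
        rng = np.random.default_rng(9)
        base = "".join(rng.choice(AA, 60))
        twin = base[:-1] + ("A" if base[-1] != "A" else "C")
        recs = [
            mk_chain(seq=base, record_id="orig"),
            mk_chain(seq=twin, record_id="twin"),
            mk_chain(seq="".join(rng.choice(AA, 60)), record_id="other"),
        ]
        labels = {"orig": "train", "twin": "test", "other": "test"}
        violations = leakage_check(recs, labels, 0.5)
        assert len(violations) == 1
        a, b, *_ , ident = violations[0]
        assert {a, b} == {"orig", "twin"}
        assert ident > 0.9
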