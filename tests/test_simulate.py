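import numpy as np
import pytest
from scipy import stats as sps

from pairlens.align import sequence_identity
from pairlens.records import CANONICAL_AA
from pairlens.restriction import top_usage
from pairlens.simulate import (
    SimulationConfig,
    apply_label_noise,
    build_germline_db,
    couple_map,
    global_family_frequencies,
    simulate_candidate_sets,
    simulate_paired_repertoire,
)

from helpers import mk_chain


class TestGermlineDB:
    def test_seed_reproducibility(self):
        assert build_germline_db(seed=5) == build_germline_db(seed=5)
        assert build_germline_db(seed=5) != build_germline_db(seed=6)

    def test_same_locus_templates_below_seventy_percent_identity(self, db):
        """Distinct V templates of one locus must stay separable at the 70%
        clustering threshold (checked with the alignment module itself)."""
        for locus in ("IGH", "IGK", "IGL"):
            vs = db.v_for_locus(locus)
            for i in range(len(vs)):
                for j in range(i + 1, len(vs)):
                    assert sequence_identity(vs[i].sequence_aa, vs[j].sequence_aa) < 0.7

    def test_template_structure(self, db):
        for g in db.v_genes:
            assert set(g.sequence_aa) <= CANONICAL_AA
            widths = [e - s for s, e in g.region_bounds]
            assert g.region_bounds[-1][1] == len(g.sequence_aa)
            assert max(widths[:5]) == widths[4]  # FR3 is the longest region
        families = {}
        for g in db.v_genes:
            families.setdefault(g.locus, set()).add(g.family)
        assert all(len(f) >= 2 for f in families.values())

    def test_single_gene_per_locus_rejected(self):
        with pytest.raises(ValueError):
            build_germline_db(n_v_per_locus=1)


class TestPairedRepertoire:
    def test_seed_reproducibility(self, db):
        cfg = SimulationConfig(n_pairs=50, seed=9)
        assert simulate_paired_repertoire(cfg, db) == simulate_paired_repertoire(cfg, db)
        other = SimulationConfig(n_pairs=50, seed=10)
        assert simulate_paired_repertoire(cfg, db) != simulate_paired_repertoire(other, db)

    def test_full_coupling_is_an_injective_gene_map(self, db):
        cfg = SimulationConfig(n_pairs=300, seed=2, kappa_coupling=1.0, mu_naive=0.0, mu_memory=0.0)
        pairs = simulate_paired_repertoire(cfg, db)
        mapping = {}
        for p in pairs:
            mapping.setdefault(p.heavy.v_call, set()).add(p.light.v_call)
        assert all(len(v) == 1 for v in mapping.values())
        images = [next(iter(v)) for v in mapping.values()]
        assert len(set(images)) == len(images)  # injective
        cm = couple_map(db, cfg.seed)
        assert all(cm[h].name in v for h, v in mapping.items())

    def test_zero_mutation_naive_chains_match_germline_outside_cdr3(self, db):
        cfg = SimulationConfig(n_pairs=40, seed=3, mu_naive=0.0, frac_memory=0.0)
        for p in simulate_paired_repertoire(cfg, db):
            for rec in (p.heavy, p.light):
                v = db.v_by_name(rec.v_call)
                s, e = rec.region_bounds[-1]
                assert rec.sequence_aa[:s] == v.core
                j = next(g for g in db.j_for_locus(rec.locus) if g.name == rec.j_call)
                assert rec.sequence_aa[e:] == j.sequence_aa

    def test_records_validate_and_memory_more_mutated(self, db):
        cfg = SimulationConfig(n_pairs=300, seed=4, mu_naive=0.02, mu_memory=0.08)
        pairs = simulate_paired_repertoire(cfg, db)
        for p in pairs[:30]:
            p.validate()
        # mean identity to own germline V core: memory < naive, gap ~ mu gap
        def v_identity(rec):
            core = db.v_by_name(rec.v_call).core
            return sequence_identity(rec.sequence_aa[: len(core)], core)

        naive = [v_identity(p.heavy) for p in pairs if p.heavy.maturation_true == "naive"]
        memory = [v_identity(p.heavy) for p in pairs if p.heavy.maturation_true == "memory"]
        gap = np.mean(naive) - np.mean(memory)
        assert 0.02 < gap < 0.11  # expectation 0.06, wide Monte-Carlo margin


class TestLabelNoise:
    def test_perfect_accuracy_copies_truth(self, small_pairs):
        chains = [c for p in small_pairs[:50] for c in (p.heavy, p.light)]
        out = apply_label_noise(chains, 1.0, 1.0, seed=0)
        assert all(r.maturation_pred == r.maturation_true for r in out)

    def test_half_accuracy_flips_half_within_binomial_bounds(self):
        n = 10000
        chains = [
            mk_chain(record_id=f"c{i}", mat_true="naive") for i in range(n)
        ]
        out = apply_label_noise(chains, 0.5, 0.5, seed=1)
        flipped = sum(r.maturation_pred != r.maturation_true for r in out)
        sigma = np.sqrt(n * 0.25)
        assert abs(flipped - n / 2) < 3 * sigma

    def test_unknown_truth_stays_unknown(self):
        out = apply_label_noise([mk_chain(mat_true="unknown")], 0.0, 0.0, seed=0)
        assert out[0].maturation_pred == "unknown"

    def test_invalid_accuracy_rejected(self):
        with pytest.raises(ValueError):
            apply_label_noise([], 1.2, 0.5, seed=0)

    def test_reported_classifier_accuracies_are_the_defaults(self):
        cfg = SimulationConfig().to_dict()
        assert cfg["acc_heavy"] == 0.9231
        assert cfg["acc_light"] == 0.7917


class TestCandidateSets:
    def test_full_restriction_gives_pure_sets(self, db, small_pairs):
        cfg = SimulationConfig(
            n_pairs=len(small_pairs), seed=11,
            rho_restriction_naive=1.0, rho_restriction_memory=1.0,
        )
        sets = simulate_candidate_sets(small_pairs, cfg, db)
        for s in sets:
            assert top_usage(s).proportion == 1.0

    def test_zero_restriction_matches_multinomial_expectation(self, db, small_pairs):
        """At rho=0 candidate families are i.i.d. from the global frequency,
        so P(top family count >= 8 of 10) has a closed form: the >=8 events
        are disjoint across families, giving sum_f P(Binom(10, p_f) >= 8)."""
        cfg = SimulationConfig(
            n_pairs=len(small_pairs), seed=11,
            rho_restriction_naive=0.0, rho_restriction_memory=0.0,
        )
        sets = simulate_candidate_sets(small_pairs, cfg, db)
        observed = np.mean([top_usage(s).proportion >= 0.8 for s in sets])
        _, probs = global_family_frequencies(db, cfg.frac_kappa_locus)
        expected = sum(1 - sps.binom.cdf(7, 10, p) for p in probs)
        sigma = np.sqrt(expected * (1 - expected) / len(sets))
        assert abs(observed - expected) < 4 * sigma + 1e-9

    def test_candidate_records_validate_and_k_respected(self, db, small_pairs):
        cfg = SimulationConfig(n_pairs=len(small_pairs), seed=11, k_candidates=3)
        sets = simulate_candidate_sets(small_pairs, cfg, db)
        assert all(s.k == 3 for s in sets)
        for s in sets[:10]:
            s.validate()


def test_config_fraction_validation():
    with pytest.raises(ValueError):
        SimulationConfig(frac_memory=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(cdr3_len_range=(5, 2))
    with pytest.raises(ValueError):
        SimulationConfig(k_candidates=0)
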