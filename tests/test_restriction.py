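from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairlens.restriction import (
    RestrictionConfig,
    assign_group,
    permutation_null,
    permutation_pvalue,
    restricted_fraction,
    top_usage,
)

from helpers import mk_candidate_set


class TestTopUsage:
    def test_eight_of_ten_hits_inclusive_boundary(self):
        cset = mk_candidate_set("naive", ["IGKV1"] * 8 + ["IGKV2"] * 2)
        usage = top_usage(cset)
        assert usage.name == "IGKV1"
        assert usage.proportion == pytest.approx(0.8)
        assert usage.eligible and not usage.tied
        assert usage.proportion >= RestrictionConfig().threshold  # restricted

    def test_three_candidates_ineligible(self):
        cset = mk_candidate_set("naive", ["IGKV1"] * 3)
        assert not top_usage(cset).eligible

    def test_five_five_tie_flagged_lexicographic(self):
        cset = mk_candidate_set("naive", ["IGLV2"] * 5 + ["IGKV1"] * 5)
        usage = top_usage(cset)
        assert usage.tied
        assert usage.name == "IGKV1"
        assert usage.proportion == 0.5

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            top_usage(mk_candidate_set("naive", []))

    def test_gene_level_resolution(self):
        cset = mk_candidate_set("naive", ["IGKV1"] * 10)
        assert top_usage(cset, level="v_gene").proportion == 1.0


def test_group_assignment_by_heavy_and_majority_candidate_state():
    s = mk_candidate_set("memory", ["IGKV1"] * 4, ["naive"] * 3 + ["memory"])
    assert assign_group(s) == ("mismatch_memory", False)
    s = mk_candidate_set("naive", ["IGKV1"] * 4, ["naive"] * 3 + ["memory"])
    assert assign_group(s) == ("match_naive", False)
    tie = mk_candidate_set("naive", ["IGKV1"] * 4, ["memory", "naive", "memory", "naive"])
    group, tied = assign_group(tie)
    assert tied and group == "mismatch_naive"  # tie resolves to first candidate


def test_restricted_fraction_hand_built_sets():
    sets = (
        [mk_candidate_set("naive", ["IGKV1"] * 9 + ["IGKV2"], set_id=f"r{i}") for i in range(3)]
        + [mk_candidate_set("naive", ["IGKV1"] * 5 + ["IGKV2"] * 5, set_id=f"u{i}") for i in range(2)]
    )
    out = restricted_fraction(sets, RestrictionConfig())
    row = out[out.group == "match_naive"].iloc[0]
    assert row.n_eligible == 5
    assert row.n_restricted == 3
    assert row.fraction_restricted == pytest.approx(0.6)


def test_small_sets_excluded_everywhere():
    sets = [mk_candidate_set("naive", ["IGKV1"] * 3, set_id=f"s{i}") for i in range(4)]
    out = restricted_fraction(sets, RestrictionConfig())
    assert (out.n_eligible == 0).all()
    assert out.fraction_restricted.isna().all()


class TestPermutationNull:
    def test_single_family_group_invariant_under_permutation(self):
        sets = [mk_candidate_set("naive", ["IGKV1"] * 10, set_id=f"s{i}") for i in range(3)]
        draws = permutation_null(sets, RestrictionConfig(m_permutations=50, seed=0))
        assert (draws == 1.0).all()

    def test_matches_exhaustive_enumeration_two_sets_k_two(self):
        """Two sets {A,A} and {B,B}: of the 4!/(2!2!)-type re-deals, the
        restricted fraction is 1 iff set one is dealt a pure pair, which
        happens with probability 1/3 (else both sets are mixed, fraction 0)."""
        sets = [
            mk_candidate_set("naive", ["IGKV1", "IGKV1"], set_id="a"),
            mk_candidate_set("naive", ["IGKV2", "IGKV2"], set_id="b"),
        ]
        labels = ["A", "A", "B", "B"]
        exact = np.mean([
            1.0 if perm[0] == perm[1] else 0.0 for perm in permutations(labels)
        ])
        assert exact == pytest.approx(1 / 3)
        cfg = RestrictionConfig(m_permutations=3000, min_candidates=2, seed=1)
        draws = permutation_null(sets, cfg)
        assert set(np.unique(draws)) <= {0.0, 1.0}
        sigma = np.sqrt(exact * (1 - exact) / len(draws))
        assert abs(draws.mean() - exact) < 4 * sigma

    def test_seeded_null_reproducible(self):
        sets = [
            mk_candidate_set("naive", ["IGKV1"] * 5 + ["IGKV2"] * 5, set_id=f"s{i}")
            for i in range(4)
        ]
        cfg = RestrictionConfig(m_permutations=100, seed=9)
        assert (permutation_null(sets, cfg) == permutation_null(sets, cfg)).all()

    def test_single_set_degenerate(self):
        with pytest.raises(ValueError):
            permutation_null([mk_candidate_set("naive", ["IGKV1"] * 10)], RestrictionConfig())

    def test_block_mode_is_invariant(self):
        sets = [
            mk_candidate_set("naive", ["IGKV1"] * 9 + ["IGKV2"], set_id="a"),
            mk_candidate_set("naive", ["IGKV2"] * 5 + ["IGKV3"] * 5, set_id="b"),
        ]
        cfg = RestrictionConfig(m_permutations=20, seed=0, block=True)
        observed = restricted_fraction(sets, cfg).fraction_restricted.dropna().iloc[0]
        assert (permutation_null(sets, cfg) == observed).all()


class TestPermutationPvalue:
    def test_add_one_correction_extremes(self):
        res = permutation_pvalue(1.0, np.zeros(10000))
        assert res.b == 0
        assert res.p_value == pytest.approx(9.999000e-05, abs=1e-12)
        res = permutation_pvalue(0.0, np.zeros(10000))  # every draw >= observed
        assert res.p_value == 1.0

    def test_direct_arithmetic(self):
        draws = np.array([1.0] * 4 + [0.0] * 95)
        res = permutation_pvalue(0.5, draws)
        assert res.b == 4 and res.m == 99
        assert res.p_value == pytest.approx(0.05)

    def test_ties_count_toward_b(self):
        res = permutation_pvalue(0.5, np.array([0.5, 0.4, 0.6]))
        assert res.b == 2

    def test_stars_tiers(self):
        assert permutation_pvalue(1.0, np.zeros(10000)).stars == "***"
        assert permutation_pvalue(1.0, np.zeros(200)).stars == "**"
        assert permutation_pvalue(1.0, np.zeros(30)).stars == "*"
        assert permutation_pvalue(0.0, np.zeros(30)).stars == ""

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        b=st.integers(min_value=0, max_value=50),
        m=st.integers(min_value=1, max_value=50),
    )
    def test_pvalue_always_in_unit_interval_excluding_zero(self, b, m):
        b = min(b, m)
        draws = np.array([1.0] * b + [-1.0] * (m - b))
        res = permutation_pvalue(0.5, draws)
        assert 0.0 < res.p_value <= 1.0
        assert res.p_value == pytest.approx((b + 1) / (m + 1))
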