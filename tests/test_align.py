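import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairlens.align import (
    Alignment,
    AlignmentInputError,
    ScoringScheme,
    global_align,
    identity_upper_bound,
    lcs_length,
    percent_identity,
    recovery_profile,
    region_identity,
    sequence_identity,
)

from helpers import brute_force_align_score, lcs_dp, mk_chain

AA = "ACDEFGHIKLMNPQRSTVWY"
aa_text = st.text(alphabet=AA, max_size=7)


def test_identical_sequences_score_and_identity():
    aln = global_align("ACDE", "ACDE", ScoringScheme(match=1, mismatch=-1))
    assert aln.score == 4
    assert aln.identity == 1.0
    assert aln.aligned_a == aln.aligned_b == "ACDE"
    assert aln.column_map == (0, 1, 2, 3)


def test_empty_vs_nonempty_costs_one_gap_run():
    scheme = ScoringScheme(gap_open=-10, gap_extend=-4)
    aln = global_align("", "ACDE", scheme)
    assert aln.score == -10 + 3 * -4
    assert aln.identity == 0.0
    assert aln.aligned_a == "----"
    aln2 = global_align("ACDE", "", scheme)
    assert aln2.score == aln.score
    assert global_align("", "").identity == 1.0


def test_percent_identity_counts_gap_columns_against_identity():
    aln = Alignment("AC-E", "ACDE", 0.0, 0.0, (0, 1, 2, 3))
    assert percent_identity(aln) == 0.75


def test_disjoint_alphabets_equal_length_zero_identity():
    aln = global_align("AAAA", "CCCC")
    assert aln.identity == 0.0


def test_non_canonical_input_rejected():
    with pytest.raises(AlignmentInputError):
        global_align("ACXDE", "ACDE")


def test_invalid_gap_convention_rejected():
    with pytest.raises(ValueError):
        ScoringScheme(gap_open=-2, gap_extend=-4)  # opening cheaper than extending
    with pytest.raises(ValueError):
        ScoringScheme(gap_open=1.0)


@pytest.mark.parametrize(
    "scheme",
    [
        ScoringScheme(match=1, mismatch=-1, gap_open=-10, gap_extend=-4),
        ScoringScheme(match=2, mismatch=-3, gap_open=-5, gap_extend=-1),
        ScoringScheme(match=1, mismatch=0, gap_open=-2, gap_extend=-2),
    ],
)
def test_alignment_score_matches_brute_force_enumeration(scheme):
    """Optimal affine-gap score equals exhaustive enumeration (short pairs)."""
    rng = np.random.default_rng(0)
    seqs = ["".join(rng.choice(list(AA), size=n)) for n in [0, 1, 2, 3, 4, 5, 5]]
    for i in range(len(seqs)):
        for j in range(i, len(seqs)):
            expected = brute_force_align_score(
                seqs[i], seqs[j], scheme.match, scheme.mismatch,
                scheme.gap_open, scheme.gap_extend,
            )
            assert global_align(seqs[i], seqs[j], scheme).score == pytest.approx(expected)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(a=aa_text, b=aa_text)
def test_alignment_score_symmetric(a, b):
    scheme = ScoringScheme()
    assert global_align(a, b, scheme).score == pytest.approx(global_align(b, a, scheme).score)


@settings(deadline=None, derandomize=True, max_examples=80)
@given(a=st.text(alphabet="ACDEFG", max_size=12), b=st.text(alphabet="ACDEFG", max_size=12))
def test_bit_parallel_lcs_matches_textbook_dp(a, b):
    assert lcs_length(a, b) == lcs_dp(a, b)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(a=st.text(alphabet=AA, min_size=1, max_size=12), b=st.text(alphabet=AA, min_size=1, max_size=12))
def test_identity_upper_bounds_never_below_true_identity(a, b):
    ident = sequence_identity(a, b)
    assert identity_upper_bound(a, b) >= ident - 1e-12
    assert identity_upper_bound(a, b, tight=True) >= ident - 1e-12


def test_batched_lcs_kernel_matches_pure_python():
    from pairlens._lcsbatch import lcs_lengths

    rng = np.random.default_rng(3)
    seqs = ["".join(rng.choice(list(AA), size=int(n))) for n in rng.integers(1, 200, 30)]
    pairs = np.array([(i, j) for i in range(30) for j in range(i + 1, 30)])
    got = lcs_lengths(seqs, pairs)
    expected = [lcs_length(seqs[i], seqs[j]) for i, j in pairs]
    assert got.tolist() == expected


# ---------------------------------------------------------------------------
# Region-wise identity

BOUNDS = ((0, 3), (3, 5), (5, 8), (8, 10), (10, 14), (14, 18))


def test_region_identity_all_one_for_identical_sequences():
    ref = "ACDEFGHIKLMNPQRSTV"
    aln = global_align(ref, ref)
    regions = region_identity(aln, BOUNDS)
    assert all(v == 1.0 for v in regions.values())


def test_mismatches_confined_to_cdr3_leave_frameworks_intact():
    ref = "ACDEFGHIKLMNPQRSTV"
    gen = ref[:14] + "WWWW"  # corrupt the CDR3 region only
    aln = global_align(gen, ref)
    regions = region_identity(aln, BOUNDS)
    assert regions["FR1"] == regions["FR2"] == regions["FR3"] == 1.0
    assert regions["CDR3"] < 1.0


def test_region_identities_match_column_level_recount():
    """Per-region values recompose exactly from an independent column count."""
    rng = np.random.default_rng(7)
    ref = "".join(rng.choice(list(AA), size=18))
    gen = "".join(rng.choice(list(AA), size=16))
    aln = global_align(gen, ref)
    regions = region_identity(aln, BOUNDS)
    ncols = len(aln.aligned_a)

    def col_of(pos):
        return aln.column_map[pos] if pos < len(ref) else ncols

    total_match = total_cols = 0
    for name, (s, e) in zip(regions, BOUNDS):
        c0, c1 = col_of(s), col_of(e)
        matches = sum(
            1
            for k in range(c0, c1)
            if aln.aligned_a[k] == aln.aligned_b[k] and aln.aligned_a[k] != "-"
        )
        if c1 > c0:
            assert regions[name] == pytest.approx(matches / (c1 - c0))
        total_match += matches
        total_cols += c1 - c0
    # weighted recomposition over the covered columns
    weighted = sum(
        regions[name] * (col_of(e) - col_of(s)) for name, (s, e) in zip(regions, BOUNDS)
    )
    assert weighted == pytest.approx(total_match)


def test_region_outside_reference_raises():
    aln = global_align("ACDE", "ACDE")
    with pytest.raises(ValueError):
        region_identity(aln, (((0, 99),) * 6))


def test_recovery_profile_strata_and_means():
    bounds = BOUNDS
    ref_seq = "ACDEFGHIKLMNPQRSTV"
    ref1 = mk_chain(seq=ref_seq, bounds=bounds, record_id="a", mat_pred="naive")
    gen1 = mk_chain(seq=ref_seq, record_id="ga")  # identical -> all 1.0
    ref2 = mk_chain(seq=ref_seq, bounds=bounds, record_id="b", mat_pred="memory")
    gen2 = mk_chain(seq=ref_seq[:14] + "WWWW", record_id="gb")
    summary, identities = recovery_profile([(gen1, ref1), (gen2, ref2)])
    naive = summary[(summary.maturation_pred == "naive") & (summary.region == "full")]
    assert naive["mean_identity"].item() == 1.0
    assert naive["n"].item() == 1
    memory_cdr3 = summary[(summary.maturation_pred == "memory") & (summary.region == "CDR3")]
    assert memory_cdr3["mean_identity"].item() == 0.0
    # histogram column encodes counts over 20 bins
    assert sum(int(x) for x in naive["histogram"].item().split(",")) == 1
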