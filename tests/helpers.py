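"""Shared test helpers: record builders and independent oracles."""

from __future__ import annotations

from typing import Optional, Tuple

from pairlens.records import REGION_NAMES, CandidateSet, ChainRecord, PairedRecord


def mk_chain(
    seq: str = "ACDEFGHIKL",
    chain: str = "light",
    locus: str = "IGK",
    v_call: str = "IGKV1-1",
    j_call: str = "IGKJ1",
    cdr3: str = "",
    bounds: Optional[Tuple[Tuple[int, int], ...]] = None,
    donor: str = "D1",
    record_id: str = "r1",
    mat_true: str = "unknown",
    mat_pred: str = "unknown",
) -> ChainRecord:
    return ChainRecord(
        record_id=record_id,
        sequence_aa=seq,
        chain=chain,
        locus=locus,
        v_call=v_call,
        j_call=j_call,
        cdr3_aa=cdr3,
        region_bounds=bounds,
        donor_id=donor,
        maturation_true=mat_true,
        maturation_pred=mat_pred,
    )


def mk_pair(
    pair_id: str = "p1",
    cdrh3: str = "CARW",
    heavy_v: str = "IGHV1-1",
    light_v: str = "IGKV1-1",
    donor: str = "D1",
    heavy_state: str = "naive",
    heavy_seq: str = "ACDEFGHIKL",
    light_seq: str = "ACDEFGHIKL",
) -> PairedRecord:
    heavy = mk_chain(
        seq=heavy_seq, chain="heavy", locus="IGH", v_call=heavy_v, j_call="IGHJ1",
        cdr3=cdrh3, donor=donor, record_id=f"{pair_id}H",
        mat_true=heavy_state, mat_pred=heavy_state,
    )
    light = mk_chain(
        seq=light_seq, chain="light", locus="IGK", v_call=light_v, j_call="IGKJ1",
        donor=donor, record_id=f"{pair_id}L",
        mat_true=heavy_state, mat_pred=heavy_state,
    )
    return PairedRecord(pair_id=pair_id, heavy=heavy, light=light)


def mk_candidate_set(
    heavy_state: str,
    candidate_families: list,
    candidate_states: Optional[list] = None,
    set_id: str = "s1",
) -> CandidateSet:
    """Candidate set with the given light V families (e.g. ["IGKV1"] * 8)."""
    heavy = mk_chain(
        chain="heavy", locus="IGH", v_call="IGHV1-1", j_call="IGHJ1",
        record_id=f"{set_id}H", mat_true=heavy_state, mat_pred=heavy_state,
    )
    if candidate_states is None:
        candidate_states = [heavy_state] * len(candidate_families)
    cands = tuple(
        mk_chain(
            chain="light",
            locus="IGK" if fam.startswith("IGK") else "IGL",
            v_call=f"{fam}-1",
            j_call="IGKJ1",
            record_id=f"{set_id}C{i}",
            mat_true=st,
            mat_pred=st,
        )
        for i, (fam, st) in enumerate(zip(candidate_families, candidate_states))
    )
    return CandidateSet(heavy=heavy, candidates=cands)


def brute_force_align_score(a: str, b: str, match: float, mismatch: float,
                            gap_open: float, gap_extend: float) -> float:
    """Exhaustive enumeration of every global alignment (affine gap costs).

    A gap run of length L costs gap_open + (L - 1) * gap_extend; a gap run
    in one sequence followed immediately by one in the other counts as two
    runs.  Exponential — only for short sequences.
    """
    la, lb = len(a), len(b)

    def rec(i: int, j: int, last: str) -> float:
        if i == la and j == lb:
            return 0.0
        best = float("-inf")
        if i < la and j < lb:
            s = (match if a[i] == b[j] else mismatch) + rec(i + 1, j + 1, "M")
            best = max(best, s)
        if i < la:  # gap in b
            cost = gap_extend if last == "A" else gap_open
            best = max(best, cost + rec(i + 1, j, "A"))
        if j < lb:  # gap in a
            cost = gap_extend if last == "B" else gap_open
            best = max(best, cost + rec(i, j + 1, "B"))
        return best

    return rec(0, 0, "M")


def lcs_dp(a: str, b: str) -> int:
    """Textbook quadratic LCS, the oracle for the bit-parallel version."""
    m = len(a)
    prev = [0] * (m + 1)
    for cb in b:
        cur = [0] * (m + 1)
        for i, ca in enumerate(a, 1):
            cur[i] = prev[i - 1] + 1 if ca == cb else max(prev[i], cur[i - 1])
        prev = cur
    return prev[m]
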