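"""Maturation-state concordance between heavy chains and their generated
light-chain candidates, and the maturity-matched selection rule.

The selection rule mirrors generator evaluation practice: the *first*
candidate (in generation order) whose predicted maturation state matches
the heavy chain's is selected; if none matches, the first candidate is
used as a flagged fallback and excluded from matched-only summaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .records import CandidateSet, ChainRecord, heavy_state

__all__ = [
    "SelectionResult",
    "ConcordanceTable",
    "select_matching_candidate",
    "concordance_table",
]

STATES = ("naive", "memory")


def _cand_state(c: ChainRecord) -> str:
    return c.maturation_pred if c.maturation_pred != "unknown" else c.maturation_true


@dataclass(frozen=True)
class SelectionResult:
    candidate: ChainRecord
    index: int
    matched: bool


def select_matching_candidate(hstate: str, cset: CandidateSet) -> SelectionResult:
    """First candidate whose predicted state matches the heavy chain's."""
    if cset.k == 0:
        raise ValueError(f"{cset.heavy.record_id}: empty candidate set")
    for i, cand in enumerate(cset.candidates):
        if _cand_state(cand) == hstate:
            return SelectionResult(candidate=cand, index=i, matched=True)
    return SelectionResult(candidate=cset.candidates[0], index=0, matched=False)


@dataclass(frozen=True)
class ConcordanceTable:
    """Heavy-state -> candidate-state flow counts and fractions.

    ``candidate_counts[(h, c)]`` counts candidates with predicted state
    ``c`` generated for heavy chains of state ``h``; ``row_fractions``
    normalises within each heavy state (rows sum to 1 where populated) and
    ``global_fractions`` over all candidates.  ``selected_counts`` holds the
    same flows restricted to the maturity-match-selected candidate of each
    set with at least one matching candidate, and ``coverage`` is the
    fraction of sets that had one.
    """

    candidate_counts: Dict[Tuple[str, str], int]
    row_fractions: Dict[Tuple[str, str], float]
    global_fractions: Dict[Tuple[str, str], float]
    selected_counts: Dict[Tuple[str, str], int]
    n_sets: int
    n_matched_sets: int

    @property
    def coverage(self) -> float:
        return self.n_matched_sets / self.n_sets if self.n_sets else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for h in STATES:
            for c in STATES:
                key = (h, c)
                rows.append(
                    {
                        "heavy_state": h,
                        "candidate_state": c,
                        "n_candidates": self.candidate_counts.get(key, 0),
                        "row_fraction": self.row_fractions.get(key, float("nan")),
                        "global_fraction": self.global_fractions.get(key, 0.0),
                        "n_selected": self.selected_counts.get(key, 0),
                    }
                )
        return pd.DataFrame(rows)


def concordance_table(sets: Sequence[CandidateSet]) -> ConcordanceTable:
    """Tally candidate maturation states against their heavy chains.

    Sets whose heavy chain has an unknown state are skipped.
    """
    cand_counts: Counter = Counter()
    sel_counts: Counter = Counter()
    n_sets = n_matched = 0
    for cset in sets:
        h = heavy_state(cset.heavy)
        if h == "unknown":
            continue
        n_sets += 1
        for cand in cset.candidates:
            cand_counts[(h, _cand_state(cand))] += 1
        sel = select_matching_candidate(h, cset)
        if sel.matched:
            n_matched += 1
            sel_counts[(h, _cand_state(sel.candidate))] += 1

    row_fracs: Dict[Tuple[str, str], float] = {}
    for h in STATES:
        row_total = sum(cand_counts.get((h, c), 0) for c in STATES)
        if row_total:
            for c in STATES:
                row_fracs[(h, c)] = cand_counts.get((h, c), 0) / row_total
    total = sum(cand_counts.values())
    global_fracs = {k: v / total for k, v in cand_counts.items()} if total else {}
    return ConcordanceTable(
        candidate_counts=dict(cand_counts),
        row_fractions=row_fracs,
        global_fractions=global_fracs,
        selected_counts=dict(sel_counts),
        n_sets=n_sets,
        n_matched_sets=n_matched,
    )
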