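"""V-gene(-family) restriction of generated light-chain candidate sets and
its permutation-test null.

A heavy chain is *restricted* when at least 80 % (inclusive) of its >= 4
candidate light chains use the same V gene or V gene family.  Restricted
fractions are reported within four maturation-pairing groups (heavy state x
majority candidate state).  The null distribution re-assigns candidate
sequences to heavy chains uniformly within a group, preserving each set's
size; the p-value uses the add-one permutation correction
``p = (b + 1) / (m + 1)`` where ``b`` counts null draws at or above the
observed fraction — never zero, never above one.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import CandidateSet, heavy_state

__all__ = [
    "RestrictionConfig",
    "TopUsage",
    "PermutationResult",
    "top_usage",
    "assign_group",
    "restricted_fraction",
    "permutation_null",
    "permutation_pvalue",
    "run_restriction_analysis",
]

GROUPS = ("match_naive", "match_memory", "mismatch_naive", "mismatch_memory")


@dataclass(frozen=True)
class RestrictionConfig:
    """Parameters of the restriction statistic and its permutation test.

    ``threshold`` is inclusive (>= 80 %); sets with fewer than
    ``min_candidates`` candidates are excluded from numerator and
    denominator alike.  ``block=True`` permutes intact candidate sets
    instead of individual sequences (a diagnostic mode: the restricted
    fraction is invariant under it by construction).
    """

    threshold: float = 0.80
    min_candidates: int = 4
    level: str = "v_family"  # "v_family" | "v_gene"
    m_permutations: int = 10000
    seed: int = 0
    block: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must be in (0, 1]")
        if self.min_candidates < 1:
            raise ValueError("min_candidates must be >= 1")
        if self.m_permutations < 1:
            raise ValueError("m_permutations must be >= 1")
        if self.level not in ("v_family", "v_gene"):
            raise ValueError("level must be 'v_family' or 'v_gene'")

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class TopUsage:
    name: str
    proportion: float
    eligible: bool
    tied: bool


def _labels(cset: CandidateSet, level: str) -> List[str]:
    if level == "v_gene":
        return [c.v_call for c in cset.candidates]
    return [c.v_family for c in cset.candidates]


def top_usage(cset: CandidateSet, level: str = "v_family", min_candidates: int = 4) -> TopUsage:
    """Most frequent V gene/family among a set's candidates.

    The proportion is the top count over ``k``; ties on the maximum keep
    the lexicographically first name and set the ``tied`` flag.
    """
    if cset.k == 0:
        raise ValueError(f"{cset.heavy.record_id}: empty candidate set")
    counts = Counter(_labels(cset, level))
    top_count = max(counts.values())
    top_names = sorted(name for name, c in counts.items() if c == top_count)
    return TopUsage(
        name=top_names[0],
        proportion=top_count / cset.k,
        eligible=cset.k >= min_candidates,
        tied=len(top_names) > 1,
    )


def candidate_majority_state(cset: CandidateSet) -> str:
    """Majority predicted maturation state of the candidates.

    Ties resolve to the first candidate's state (generation order), which
    is flagged by :func:`assign_group`'s second return value.
    """
    counts = Counter(
        c.maturation_pred if c.maturation_pred != "unknown" else c.maturation_true
        for c in cset.candidates
    )
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        first = cset.candidates[0]
        return first.maturation_pred if first.maturation_pred != "unknown" else first.maturation_true
    return top[0][0]


def assign_group(cset: CandidateSet) -> Tuple[str, bool]:
    """Maturation-pairing group of a set, plus a candidate-tie flag.

    Groups: both naive (``match_naive``), both memory (``match_memory``),
    naive heavy with memory candidates (``mismatch_naive``), memory heavy
    with naive candidates (``mismatch_memory``).
    """
    h = heavy_state(cset.heavy)
    counts = Counter(
        c.maturation_pred if c.maturation_pred != "unknown" else c.maturation_true
        for c in cset.candidates
    )
    top = counts.most_common()
    tied = len(top) > 1 and top[0][1] == top[1][1]
    c = candidate_majority_state(cset)
    if h == c:
        return (f"match_{h}", tied)
    return (f"mismatch_{h}", tied)


def restricted_fraction(
    sets: Sequence[CandidateSet],
    config: RestrictionConfig,
    groups: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-group fraction of eligible sets meeting the restriction threshold.

    ``groups`` may supply precomputed group labels (same order as ``sets``);
    otherwise :func:`assign_group` is applied.  Groups without eligible sets
    report ``n_eligible=0`` and an undefined (NaN) fraction.
    """
    if groups is None:
        groups = [assign_group(s)[0] for s in sets]
    rows = []
    for group in GROUPS:
        members = [s for s, g in zip(sets, groups) if g == group]
        eligible = [s for s in members if s.k >= config.min_candidates]
        n_restricted = sum(
            1
            for s in eligible
            if top_usage(s, config.level, config.min_candidates).proportion
            >= config.threshold
        )
        rows.append(
            {
                "group": group,
                "n_sets": len(members),
                "n_eligible": len(eligible),
                "n_restricted": n_restricted,
                "fraction_restricted": (
                    n_restricted / len(eligible) if eligible else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def _restricted_fraction_of_labels(
    label_codes: np.ndarray, sizes: Sequence[int], threshold: float, min_candidates: int,
    n_labels: int,
) -> float:
    """Restricted fraction after dealing pooled label codes back by sizes."""
    n_eligible = n_restricted = 0
    pos = 0
    for k in sizes:
        chunk = label_codes[pos : pos + k]
        pos += k
        if k < min_candidates:
            continue
        n_eligible += 1
        top = np.bincount(chunk, minlength=n_labels).max()
        if top / k >= threshold:
            n_restricted += 1
    return n_restricted / n_eligible if n_eligible else float("nan")


def permutation_null(
    sets: Sequence[CandidateSet], config: RestrictionConfig
) -> np.ndarray:
    """Null draws of the restricted fraction within one group of sets.

    Each iteration pools the group's candidate V labels, permutes them
    uniformly, re-deals them to the heavy chains preserving each set's
    original size, and recomputes the restricted fraction.  With
    ``config.block`` the intact sets are permuted among heavy chains
    instead — which leaves every set's composition, and hence the statistic,
    unchanged (useful only as a sanity control).
    """
    if len(sets) < 2:
        raise ValueError("permutation null degenerate for fewer than 2 sets")
    rng = np.random.default_rng([int(config.seed), 5])
    sizes = [s.k for s in sets]
    labels = [lab for s in sets for lab in _labels(s, config.level)]
    uniq = sorted(set(labels))
    code = {name: i for i, name in enumerate(uniq)}
    codes = np.array([code[lab] for lab in labels], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    draws = np.empty(config.m_permutations)
    for it in range(config.m_permutations):
        if config.block:
            order = rng.permutation(len(sets))
            permuted = np.concatenate([codes[offsets[j] : offsets[j + 1]] for j in order])
            dealt_sizes = [sizes[j] for j in order]
        else:
            permuted = codes[rng.permutation(len(codes))]
            dealt_sizes = sizes
        draws[it] = _restricted_fraction_of_labels(
            permuted, dealt_sizes, config.threshold, config.min_candidates, len(uniq)
        )
    return draws


@dataclass(frozen=True)
class PermutationResult:
    group: str
    observed: float
    b: int
    m: int
    p_value: float
    stars: str
    null_draws: Tuple[float, ...] = ()


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def permutation_pvalue(
    observed: float, null_draws: Sequence[float], group: str = ""
) -> PermutationResult:
    """Add-one-corrected permutation p-value.

    ``b`` counts null draws equal to or exceeding the observed statistic
    (the conservative tie rule) and ``p = (b + 1) / (m + 1)``, so p lies in
    (0, 1] by construction: with b = 0 and m = 10,000 it equals
    9.999000e-05 exactly.
    """
    draws = np.asarray(null_draws, dtype=float)
    m = len(draws)
    if m < 1:
        raise ValueError("need at least one null draw")
    b = int(np.sum(draws >= observed))
    p = (b + 1) / (m + 1)
    return PermutationResult(
        group=group, observed=float(observed), b=b, m=m, p_value=p,
        stars=_stars(p), null_draws=tuple(float(x) for x in draws),
    )


def run_restriction_analysis(
    sets: Sequence[CandidateSet], config: RestrictionConfig
) -> Tuple[pd.DataFrame, Dict[str, PermutationResult]]:
    """Observed restricted fractions plus the permutation test per group.

    Groups with fewer than two eligible sets are reported without a test.
    """
    group_labels = [assign_group(s)[0] for s in sets]
    observed = restricted_fraction(sets, config, group_labels)
    results: Dict[str, PermutationResult] = {}
    rows = []
    for _, row in observed.iterrows():
        group = row["group"]
        members = [
            s
            for s, g in zip(sets, group_labels)
            if g == group and s.k >= config.min_candidates
        ]
        entry = dict(row)
        if len(members) >= 2 and np.isfinite(row["fraction_restricted"]):
            null = permutation_null(members, config)
            res = permutation_pvalue(row["fraction_restricted"], null, group)
            results[group] = res
            entry.update(
                {"b": res.b, "m": res.m, "p_value": res.p_value, "stars": res.stars}
            )
        else:
            entry.update({"b": None, "m": None, "p_value": None, "stars": None})
        rows.append(entry)
    return pd.DataFrame(rows), results
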