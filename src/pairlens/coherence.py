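"""Heavy-light V-gene pairing coherence.

Heavy chains are grouped by exact (CDRH3, heavy V gene); groups with a
single member or a single donor are removed.  A group is *coherent* when
every member uses the identical light V gene, and coherence is the fraction
of coherent groups, reported per maturation stratum.  The analytic chance
baseline is the probability that all members of a group independently draw
the same light V gene from the global frequency vector.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import ChainRecord, PairedRecord, heavy_state

logger = logging.getLogger("pairlens.coherence")

__all__ = [
    "CoherenceGroup",
    "CoherenceReport",
    "build_groups",
    "coherence",
    "coherence_frame",
    "group_frame",
    "chance_coherence",
    "empirical_light_v_frequencies",
]


class MetadataError(ValueError):
    """A record lacks metadata (donor) the grouping filters require."""


@dataclass(frozen=True)
class CoherenceGroup:
    key: Tuple[str, str]  # (CDRH3 aa, heavy v_call)
    members: Tuple[PairedRecord, ...]

    @property
    def donors(self) -> frozenset:
        return frozenset(m.heavy.donor_id for m in self.members)

    @property
    def light_v_calls(self) -> Counter:
        return Counter(m.light.v_call for m in self.members)

    @property
    def is_coherent(self) -> bool:
        return len(set(m.light.v_call for m in self.members)) == 1

    @property
    def size(self) -> int:
        return len(self.members)

    def stratum(self) -> str:
        """Majority heavy-chain maturation label; ties give ``mixed``."""
        counts = Counter(heavy_state(m.heavy) for m in self.members)
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            return "mixed"
        return top[0][0]


@dataclass(frozen=True)
class CoherenceReport:
    stratum: str
    n_groups: int
    n_coherent: int

    @property
    def coherence(self) -> float:
        return self.n_coherent / self.n_groups


def build_groups(pairs: Sequence[PairedRecord]) -> List[CoherenceGroup]:
    """Group pairs by exact (CDRH3, heavy V gene) and apply the filters.

    Singleton groups and groups drawn from a single donor are removed; the
    removal counts are logged because they set the statistic's denominator.
    """
    for p in pairs:
        if not p.heavy.donor_id:
            raise MetadataError(f"{p.heavy.record_id}: donor_id required for coherence grouping")
    keyed: Dict[Tuple[str, str], List[PairedRecord]] = {}
    for p in pairs:
        keyed.setdefault((p.heavy.cdr3_aa, p.heavy.v_call), []).append(p)

    groups: List[CoherenceGroup] = []
    n_singleton = n_single_donor = 0
    for key in sorted(keyed):
        members = keyed[key]
        if len(members) < 2:
            n_singleton += 1
            continue
        if len({m.heavy.donor_id for m in members}) < 2:
            n_single_donor += 1
            continue
        groups.append(CoherenceGroup(key=key, members=tuple(members)))
    logger.info(
        "grouping: %d groups kept, %d singleton groups removed, %d single-donor groups removed",
        len(groups), n_singleton, n_single_donor,
    )
    return groups


def coherence(groups: Sequence[CoherenceGroup]) -> Dict[str, CoherenceReport]:
    """Per-stratum coherence: fraction of groups with identical light V use.

    Strata come from each group's majority heavy-chain maturation label
    (classifier prediction when available); tied groups form the ``mixed``
    stratum.  Strata with zero groups are simply absent from the result.
    """
    if not groups:
        logger.warning("coherence: no groups after filtering")
        return {}
    by_stratum: Dict[str, List[CoherenceGroup]] = {}
    for g in groups:
        by_stratum.setdefault(g.stratum(), []).append(g)
    return {
        stratum: CoherenceReport(
            stratum=stratum,
            n_groups=len(gs),
            n_coherent=sum(1 for g in gs if g.is_coherent),
        )
        for stratum, gs in sorted(by_stratum.items())
    }


def coherence_frame(groups: Sequence[CoherenceGroup]) -> pd.DataFrame:
    """Coherence reports as a tidy table (one row per stratum)."""
    reports = coherence(groups)
    return pd.DataFrame(
        [
            {
                "stratum": rep.stratum,
                "n_groups": rep.n_groups,
                "n_coherent": rep.n_coherent,
                "coherence": rep.coherence,
            }
            for rep in reports.values()
        ],
        columns=["stratum", "n_groups", "n_coherent", "coherence"],
    )


def group_frame(groups: Sequence[CoherenceGroup]) -> pd.DataFrame:
    """Group-level detail table: key, size, donors, coherent flag."""
    return pd.DataFrame(
        [
            {
                "cdrh3_aa": g.key[0],
                "heavy_v_call": g.key[1],
                "size": g.size,
                "n_donors": len(g.donors),
                "stratum": g.stratum(),
                "coherent": g.is_coherent,
            }
            for g in groups
        ],
        columns=["cdrh3_aa", "heavy_v_call", "size", "n_donors", "stratum", "coherent"],
    )


def chance_coherence(
    groups: Sequence[CoherenceGroup], light_v_frequencies: Mapping[str, float]
) -> float:
    """Expected coherence if members drew light V genes independently.

    For a group of size ``s`` the probability that all members share one
    gene is ``sum_v f_v ** s``; the baseline is the mean over groups.  With
    a uniform frequency over ``G`` genes and all groups of size 2 this is
    exactly ``1 / G``.
    """
    if not groups:
        return float("nan")
    freqs = np.asarray(list(light_v_frequencies.values()), dtype=float)
    per_group = [float(np.sum(freqs ** g.size)) for g in groups]
    return float(np.mean(per_group))


def empirical_light_v_frequencies(pairs: Sequence[PairedRecord]) -> Dict[str, float]:
    """Observed light V gene frequency vector over a repertoire."""
    counts = Counter(p.light.v_call for p in pairs)
    total = sum(counts.values())
    return {v: c / total for v, c in sorted(counts.items())}
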