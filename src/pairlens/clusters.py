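"""Greedy identity clustering, hierarchical cluster-then-allocate data
splits, and a cross-split leakage audit.

The clustering is desk-scale greedy centroid clustering: sequences are
processed in canonical order (length-descending, then lexicographic) and
each joins the first existing centroid whose global-alignment identity
reaches the threshold, else founds a new cluster.  This replaces k-mer
linkage clustering used at repertoire scale — the membership contract
(every member >= threshold identity to its centroid) is what downstream
splitting relies on, and is exact here.

The hierarchical split mirrors the usual redundancy-reduction recipe:
CDR3s clustered at 100 % identity, the surviving centroids' full sequences
at 70 %, then 50 %; the final-stage clusters become indivisible allocation
units so near-identical sequences can never straddle a train/test boundary.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .align import (
    DEFAULT_SCORING,
    ScoringScheme,
    identity_at_least,
    identity_upper_bound,
    sequence_identity,
)
from .records import ChainRecord, PairedRecord

logger = logging.getLogger("pairlens.clusters")

__all__ = [
    "ClusterConfig",
    "SplitConfig",
    "Cluster",
    "AllocationUnit",
    "SplitResult",
    "greedy_cluster",
    "hierarchical_split_prep",
    "allocate_splits",
    "leakage_check",
]


@dataclass(frozen=True)
class ClusterConfig:
    """Hierarchical clustering thresholds and what stage 1 clusters on.

    Thresholds must be strictly decreasing.  ``cluster_on`` selects the
    stage-1 sequence: the CDR3 (default, the unpaired-repertoire recipe),
    the full chain, or the concatenated heavy+light pair (for paired
    allocation at a single low threshold such as 30 %).
    """

    thresholds: Tuple[float, ...] = (1.00, 0.70, 0.50)
    cluster_on: str = "cdr3"  # "cdr3" | "full_chain" | "full_pair"
    identity_mode: str = "aligned_nw"  # "aligned_nw" | "exact"

    def __post_init__(self) -> None:
        if not self.thresholds:
            raise ValueError("at least one threshold required")
        for t in self.thresholds:
            if not (0.0 < t <= 1.0):
                raise ValueError(f"threshold {t} outside (0, 1]")
        if any(a <= b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly decreasing")
        if self.cluster_on not in ("cdr3", "full_chain", "full_pair"):
            raise ValueError(f"unknown cluster_on {self.cluster_on!r}")
        if self.identity_mode not in ("aligned_nw", "exact"):
            raise ValueError(f"unknown identity_mode {self.identity_mode!r}")

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SplitConfig:
    fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1)  # train, val, test
    policy: str = "largest_first_train"  # or "random"

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.policy not in ("largest_first_train", "random"):
            raise ValueError(f"unknown policy {self.policy!r}")

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


@dataclass
class Cluster:
    centroid: int  # index into the input list
    members: List[int] = field(default_factory=list)  # includes the centroid


def _canonical_order(seqs: Sequence[str]) -> List[int]:
    return sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), seqs[i], i))


def greedy_cluster(
    seqs: Sequence[str],
    threshold: float,
    identity_mode: str = "aligned_nw",
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> List[Cluster]:
    """Greedy first-fit centroid clustering at an identity threshold.

    Sequences are visited length-descending then lexicographic (so the
    result depends only on the input multiset); each joins the first
    centroid with identity >= threshold, else founds a cluster.  At
    threshold 1.0 identity under the total-columns convention requires
    exact equality, so hashing replaces alignment.
    """
    if len(seqs) == 0:
        raise ValueError("no sequences to cluster")
    clusters: List[Cluster] = []
    if threshold >= 1.0 or identity_mode == "exact":
        by_seq: Dict[str, Cluster] = {}
        for i in _canonical_order(seqs):
            c = by_seq.get(seqs[i])
            if c is None:
                c = Cluster(centroid=i, members=[i])
                by_seq[seqs[i]] = c
                clusters.append(c)
            else:
                c.members.append(i)
        return clusters
    for i in _canonical_order(seqs):
        for c in clusters:
            if identity_at_least(seqs[i], seqs[c.centroid], threshold, scoring):
                c.members.append(i)
                break
        else:
            clusters.append(Cluster(centroid=i, members=[i]))
    return clusters


RecordLike = Union[ChainRecord, PairedRecord]


def _stage1_seq(rec: RecordLike, cluster_on: str) -> str:
    if isinstance(rec, PairedRecord):
        if cluster_on == "cdr3":
            return rec.heavy.cdr3_aa
        return rec.heavy.sequence_aa + rec.light.sequence_aa
    if cluster_on == "cdr3":
        return rec.cdr3_aa
    return rec.sequence_aa


def _full_seq(rec: RecordLike) -> str:
    if isinstance(rec, PairedRecord):
        return rec.heavy.sequence_aa + rec.light.sequence_aa
    return rec.sequence_aa


def _record_id(rec: RecordLike) -> str:
    return rec.pair_id if isinstance(rec, PairedRecord) else rec.record_id


@dataclass
class AllocationUnit:
    unit_id: int
    record_indices: List[int]

    @property
    def size(self) -> int:
        return len(self.record_indices)


def hierarchical_split_prep(
    records: Sequence[RecordLike],
    config: ClusterConfig = ClusterConfig(),
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> List[AllocationUnit]:
    """Build indivisible allocation units by staged clustering.

    Stage 1 clusters the ``cluster_on`` sequence at ``thresholds[0]``; each
    later stage clusters the *centroid* full sequences of the previous
    stage.  The final stage's clusters are returned as allocation units
    carrying every descendant record, which together partition the input.
    """
    if not records:
        raise ValueError("no records to split")
    if config.cluster_on == "cdr3":
        for rec in records:
            if not _stage1_seq(rec, "cdr3"):
                raise ValueError(f"{_record_id(rec)}: empty CDR3 but cluster_on='cdr3'")

    # descendants[i] = record indices represented by current element i
    current_seqs = [_stage1_seq(r, config.cluster_on) for r in records]
    descendants: List[List[int]] = [[i] for i in range(len(records))]
    for stage, threshold in enumerate(config.thresholds):
        clusters = greedy_cluster(current_seqs, threshold, config.identity_mode, scoring)
        new_seqs: List[str] = []
        new_desc: List[List[int]] = []
        for c in clusters:
            merged: List[int] = []
            for m in c.members:
                merged.extend(descendants[m])
            # subsequent stages cluster the centroid's *full* sequence; the
            # centroid element is represented by its own first record
            new_seqs.append(_full_seq(records[descendants[c.centroid][0]]))
            new_desc.append(sorted(merged))
        current_seqs, descendants = new_seqs, new_desc

    # Close the final-stage clusters under single linkage at the allocation
    # threshold: greedy centroid clusters only guarantee member-to-centroid
    # identity, so two clusters can still contain a cross pair above the
    # threshold (e.g. heavily mutated outliers).  Merging such clusters makes
    # the downstream no-leakage contract a construction guarantee.
    t_final = config.thresholds[-1]
    full_seqs = [_full_seq(r) for r in records]
    unit_of = {}
    for u, desc in enumerate(descendants):
        for i in desc:
            unit_of[i] = u
    cross = [
        (i, j)
        for i in range(len(records))
        for j in range(i + 1, len(records))
        if unit_of[i] != unit_of[j]
    ]
    parent = list(range(len(descendants)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in _screened_pairs(full_seqs, cross, t_final):
        if find(unit_of[i]) != find(unit_of[j]) and identity_at_least(
            full_seqs[i], full_seqs[j], t_final, scoring
        ):
            parent[find(unit_of[j])] = find(unit_of[i])

    merged: Dict[int, List[int]] = {}
    for u, desc in enumerate(descendants):
        merged.setdefault(find(u), []).extend(desc)
    return [
        AllocationUnit(unit_id=new_id, record_indices=sorted(desc))
        for new_id, (_, desc) in enumerate(sorted(merged.items()))
    ]


def _screened_pairs(seqs: Sequence[str], pairs, threshold: float):
    """Pairs surviving the LCS identity upper-bound screen.

    The bound (matches cannot exceed the LCS length, columns are at least
    the longer length) is exact-safe, so screened-out pairs provably fall
    below the threshold.  Uses the batched numba kernel when sequences fit.
    """
    if not pairs:
        return []
    import numpy as _np

    from ._lcsbatch import MAX_LEN, encode_sequences, lcs_lengths

    if max(len(s) for s in seqs) > MAX_LEN:
        return [
            (i, j)
            for i, j in pairs
            if identity_upper_bound(seqs[i], seqs[j], tight=True) >= threshold
        ]
    arr = _np.asarray(pairs, dtype=_np.int64)
    encoded = encode_sequences(seqs)
    lcs = lcs_lengths(seqs, arr, encoded)
    lens = encoded[2]
    bound = lcs / _np.maximum(lens[arr[:, 0]], lens[arr[:, 1]])
    keep = bound >= threshold
    return [tuple(p) for p in arr[keep]]


@dataclass
class SplitResult:
    labels: Dict[str, str]  # record id -> train|val|test
    unit_of: Dict[str, int]
    achieved_fractions: Tuple[float, float, float]
    warnings: List[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"record_id": rid, "split": self.labels[rid], "unit_id": self.unit_of[rid]}
                for rid in sorted(self.labels)
            ]
        )


SPLIT_NAMES = ("train", "val", "test")


def allocate_splits(
    units: Sequence[AllocationUnit],
    records: Sequence[RecordLike],
    config: SplitConfig = SplitConfig(),
    seed: int = 0,
) -> SplitResult:
    """Assign whole allocation units to train/validation/test.

    ``largest_first_train`` sorts units by size descending (ties by first
    record id) and fills each split in order while it is below its record
    count target, so larger clusters land in training; the last split
    absorbs any remainder.  ``random`` uses a seeded shuffle instead of the
    size sort.  A unit larger than the biggest split target is warned about
    and assigned to train.
    """
    total = sum(u.size for u in units)
    targets = [f * total for f in config.fractions]
    warnings: List[str] = []

    def unit_key(u: AllocationUnit) -> Tuple[int, str]:
        return (-u.size, _record_id(records[u.record_indices[0]]))

    if config.policy == "largest_first_train":
        ordered = sorted(units, key=unit_key)
    else:
        ordered = list(units)
        rng = np.random.default_rng([int(seed), 6])
        rng.shuffle(ordered)

    max_target = max(targets)
    counts = [0, 0, 0]
    labels: Dict[str, str] = {}
    unit_of: Dict[str, int] = {}
    for u in ordered:
        if u.size > max_target:
            warnings.append(
                f"unit {u.unit_id} ({u.size} records) exceeds the largest split target "
                f"({max_target:.1f}); assigned to train"
            )
            split_idx = 0
        else:
            split_idx = next(
                (i for i in range(3) if counts[i] < targets[i]), 2
            )
        counts[split_idx] += u.size
        for ri in u.record_indices:
            rid = _record_id(records[ri])
            labels[rid] = SPLIT_NAMES[split_idx]
            unit_of[rid] = u.unit_id
    for i, name in enumerate(SPLIT_NAMES):
        if counts[i] > targets[i] + 1e-9:
            warnings.append(
                f"{name} overfilled: {counts[i]} records against a target of {targets[i]:.1f} "
                "(units are indivisible)"
            )
    for w in warnings:
        logger.warning(w)
    achieved = tuple(c / total for c in counts)
    return SplitResult(labels=labels, unit_of=unit_of, achieved_fractions=achieved, warnings=warnings)


def leakage_check(
    records: Sequence[RecordLike],
    labels: Dict[str, str],
    threshold: float,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> List[Tuple[str, str, str, str, float]]:
    """All cross-split record pairs with identity >= threshold.

    Exhaustive over cross-split pairs, with a provably safe edit-distance
    screen discarding pairs whose identity upper bound is already below the
    threshold; survivors get the full affine alignment.  An empty list is
    the expected outcome after cluster-based allocation.
    """
    ids = [_record_id(r) for r in records]
    seqs = [_full_seq(r) for r in records]
    n = len(records)
    cross = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if labels[ids[i]] != labels[ids[j]]
    ]
    violations = []
    for i, j in _screened_pairs(seqs, cross, threshold):
        ident = sequence_identity(seqs[i], seqs[j], scoring)
        if ident >= threshold:
            violations.append((ids[i], ids[j], labels[ids[i]], labels[ids[j]], ident))
    return violations
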