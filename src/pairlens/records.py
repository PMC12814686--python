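"""Core domain types for paired-chain antibody repertoire analysis.

A :class:`ChainRecord` is one immunoglobulin chain (heavy or light) as an
amino-acid sequence with its V/J gene annotation, framework/CDR region
boundaries, donor of origin, and B-cell maturation labels (ground truth and
classifier prediction).  A :class:`PairedRecord` links the heavy and light
chain of one antibody; a :class:`CandidateSet` holds the ``k`` generated
light-chain candidates proposed for one heavy chain, in generation order.

All coordinates are 0-based half-open intervals on the amino-acid sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

__all__ = [
    "CANONICAL_AA",
    "REGION_NAMES",
    "RecordValidationError",
    "ChainRecord",
    "PairedRecord",
    "CandidateSet",
]

#: The 20 canonical amino-acid one-letter codes.  Anything else (B, J, O, U,
#: X, Z, gap characters, ...) makes a record invalid: such rows are rejected
#: on read rather than masked.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Variable-domain region names, N- to C-terminal order.
REGION_NAMES = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3")

MATURATION_STATES = ("naive", "memory", "unknown")

RegionBounds = Tuple[Tuple[int, int], ...]


class RecordValidationError(ValueError):
    """Raised when a chain record violates a structural invariant."""


def is_canonical(seq: str) -> bool:
    """True if ``seq`` contains only the 20 canonical amino-acid letters."""
    return all(c in CANONICAL_AA for c in seq)


def v_family_of(v_call: str) -> str:
    """Family name of a V gene call: the prefix before the first ``-``.

    ``IGKV3-11`` -> ``IGKV3``.  Calls without a ``-`` are their own family.
    """
    return v_call.split("-", 1)[0]


@dataclass(frozen=True)
class ChainRecord:
    """One antibody chain (heavy or light) with annotations.

    ``region_bounds`` holds six 0-based half-open ``(start, end)`` intervals
    over ``sequence_aa`` for FR1, CDR1, FR2, CDR2, FR3 and CDR3, in that
    order; residues past CDR3 (the J-encoded FR4 tail) are not covered.  It
    may be ``None`` for records read from sources that do not annotate
    regions; stages that need boundaries then raise.
    """

    record_id: str
    sequence_aa: str
    chain: str  # "heavy" | "light"
    locus: str  # "IGH" | "IGK" | "IGL"
    v_call: str
    j_call: str
    cdr3_aa: str = ""
    region_bounds: Optional[RegionBounds] = None
    donor_id: str = ""
    maturation_true: str = "unknown"
    maturation_pred: str = "unknown"

    @property
    def v_family(self) -> str:
        return v_family_of(self.v_call)

    def validate(self) -> None:
        """Raise :class:`RecordValidationError` on any invariant violation."""
        if self.chain not in ("heavy", "light"):
            raise RecordValidationError(
                f"{self.record_id}: chain must be 'heavy' or 'light', got {self.chain!r}"
            )
        if self.locus not in ("IGH", "IGK", "IGL"):
            raise RecordValidationError(
                f"{self.record_id}: unknown locus {self.locus!r}"
            )
        if (self.locus == "IGH") != (self.chain == "heavy"):
            raise RecordValidationError(
                f"{self.record_id}: locus {self.locus} inconsistent with chain {self.chain}"
            )
        if not is_canonical(self.sequence_aa):
            bad = sorted(set(self.sequence_aa) - CANONICAL_AA)
            raise RecordValidationError(
                f"{self.record_id}: non-canonical residues {bad} in sequence"
            )
        if self.cdr3_aa and not is_canonical(self.cdr3_aa):
            raise RecordValidationError(
                f"{self.record_id}: non-canonical residues in cdr3_aa"
            )
        for label, value in (
            ("maturation_true", self.maturation_true),
            ("maturation_pred", self.maturation_pred),
        ):
            if value not in MATURATION_STATES:
                raise RecordValidationError(
                    f"{self.record_id}: {label} must be one of {MATURATION_STATES}"
                )
        if self.region_bounds is not None:
            self._validate_bounds()

    def _validate_bounds(self) -> None:
        bounds = self.region_bounds
        assert bounds is not None
        if len(bounds) != len(REGION_NAMES):
            raise RecordValidationError(
                f"{self.record_id}: expected {len(REGION_NAMES)} region intervals, "
                f"got {len(bounds)}"
            )
        prev_end = 0
        for name, (start, end) in zip(REGION_NAMES, bounds):
            if not (0 <= start <= end <= len(self.sequence_aa)):
                raise RecordValidationError(
                    f"{self.record_id}: {name} bounds ({start}, {end}) outside "
                    f"sequence of length {len(self.sequence_aa)}"
                )
            if start < prev_end:
                raise RecordValidationError(
                    f"{self.record_id}: {name} overlaps or precedes the previous region"
                )
            prev_end = end

    # convenience accessors ------------------------------------------------

    def region(self, name: str) -> Tuple[int, int]:
        if self.region_bounds is None:
            raise RecordValidationError(f"{self.record_id}: no region bounds")
        return self.region_bounds[REGION_NAMES.index(name)]

    @property
    def cdr3_start(self) -> int:
        return self.region("CDR3")[0]

    @property
    def cdr3_end(self) -> int:
        return self.region("CDR3")[1]

    def with_pred(self, maturation_pred: str) -> "ChainRecord":
        return replace(self, maturation_pred=maturation_pred)


@dataclass(frozen=True)
class PairedRecord:
    """A heavy chain and its natively paired light chain."""

    pair_id: str
    heavy: ChainRecord
    light: ChainRecord

    def validate(self) -> None:
        if self.heavy.chain != "heavy":
            raise RecordValidationError(f"{self.pair_id}: heavy slot holds a {self.heavy.chain} chain")
        if self.light.chain != "light":
            raise RecordValidationError(f"{self.pair_id}: light slot holds a {self.light.chain} chain")
        self.heavy.validate()
        self.light.validate()


@dataclass(frozen=True)
class CandidateSet:
    """One heavy chain plus its generated light-chain candidates.

    Candidate order is generation order and is meaningful: the
    maturity-matched selection rule takes the *first* candidate whose
    predicted state matches the heavy chain.
    """

    heavy: ChainRecord
    candidates: Tuple[ChainRecord, ...] = field(default_factory=tuple)

    @property
    def k(self) -> int:
        return len(self.candidates)

    def validate(self) -> None:
        self.heavy.validate()
        if self.heavy.chain != "heavy":
            raise RecordValidationError(f"{self.heavy.record_id}: candidate set on a light chain")
        for c in self.candidates:
            if c.chain != "light":
                raise RecordValidationError(f"{c.record_id}: candidate is not a light chain")
            c.validate()


def heavy_state(record: ChainRecord) -> str:
    """Maturation label used by downstream stratification.

    The classifier prediction when available, otherwise the true label —
    mirroring analyses run on repertoires whose states come from a trained
    classifier rather than sorting.
    """
    return record.maturation_pred if record.maturation_pred != "unknown" else record.maturation_true


def iter_chains(pairs: Iterable[PairedRecord]) -> Iterable[ChainRecord]:
    for p in pairs:
        yield p.heavy
        yield p.light
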