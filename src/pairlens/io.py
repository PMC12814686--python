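"""Readers and writers for AIRR Rearrangement TSV, a two-chain CSV dialect,
germline FASTA with a region sidecar table, and the run manifest.

Rows whose sequences contain non-canonical residues are rejected on read —
counted and logged, never silently dropped.  Pair linkage accepts a
``cell_id`` column first (paired-download convention) and falls back to
``pair_id``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    REGION_NAMES,
    CandidateSet,
    ChainRecord,
    PairedRecord,
    RecordValidationError,
)
from .simulate import GermlineDB, GermlineJGene, GermlineVGene

logger = logging.getLogger("pairlens.io")

__all__ = [
    "FormatError",
    "LinkageError",
    "ReadStats",
    "read_paired_table",
    "write_paired_table",
    "read_candidate_table",
    "write_candidate_table",
    "write_germline_db",
    "read_germline_db",
    "write_results",
]


class FormatError(ValueError):
    """A required column is missing or malformed."""


class LinkageError(ValueError):
    """Rows cannot be paired into heavy+light records."""


@dataclass
class ReadStats:
    n_rows: int = 0
    n_pairs: int = 0
    rejected: int = 0
    reject_reasons: List[str] = field(default_factory=list)


_AIRR_SEQ_COLS = ("sequence_alignment_aa", "sequence_aa")
_AIRR_CDR3_COLS = ("junction_aa", "cdr3_aa")
_LINKAGE_COLS = ("cell_id", "pair_id")

_BOUND_COLS = [
    f"{region.lower()}_{edge}" for region in REGION_NAMES for edge in ("start", "end")
]


def _pick_column(df: pd.DataFrame, options: Sequence[str], what: str) -> str:
    for col in options:
        if col in df.columns:
            return col
    raise FormatError(f"missing mandatory column for {what}: expected one of {list(options)}")


def _bounds_from_row(row: pd.Series) -> Optional[Tuple[Tuple[int, int], ...]]:
    if not all(c in row.index and pd.notna(row[c]) for c in _BOUND_COLS):
        return None
    return tuple(
        (int(row[f"{r.lower()}_start"]), int(row[f"{r.lower()}_end"])) for r in REGION_NAMES
    )


def _chain_from_airr_row(row: pd.Series, seq_col: str, cdr3_col: str) -> ChainRecord:
    locus = str(row["locus"])
    rec = ChainRecord(
        record_id=str(row.get("sequence_id", row.name)),
        sequence_aa=str(row[seq_col]),
        chain="heavy" if locus == "IGH" else "light",
        locus=locus,
        v_call=str(row["v_call"]),
        j_call=str(row["j_call"]),
        cdr3_aa="" if pd.isna(row[cdr3_col]) else str(row[cdr3_col]),
        region_bounds=_bounds_from_row(row),
        donor_id="" if "donor_id" not in row.index or pd.isna(row["donor_id"]) else str(row["donor_id"]),
        maturation_true=str(row.get("maturation_true", "unknown") or "unknown"),
        maturation_pred=str(row.get("maturation_pred", "unknown") or "unknown"),
    )
    rec.validate()
    return rec


def read_paired_table(
    path: Union[str, Path],
    dialect: str = "airr",
    return_stats: bool = False,
):
    """Read a paired-chain table into :class:`PairedRecord` objects.

    ``dialect="airr"`` expects one row per chain (AIRR Rearrangement TSV)
    with a ``cell_id`` or ``pair_id`` linkage column; ``dialect="csv"``
    expects one row per pair with ``pair_id``, ``heavy_seq``, ``light_seq``
    and optional annotation columns.

    Invalid records (non-canonical residues, inconsistent annotations) are
    rejected and counted; a heavy row without a light partner (or vice
    versa) raises :class:`LinkageError` listing the orphans.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "airr":
        pairs, stats = _read_airr(path)
    elif dialect == "csv":
        pairs, stats = _read_csv(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if stats.rejected:
        logger.warning(
            "%s: rejected %d of %d rows (%s)",
            path.name, stats.rejected, stats.n_rows, "; ".join(stats.reject_reasons[:5]),
        )
    logger.info("%s: read %d pairs", path.name, stats.n_pairs)
    return (pairs, stats) if return_stats else pairs


def _read_airr(path: Path) -> Tuple[List[PairedRecord], ReadStats]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    stats = ReadStats(n_rows=len(df))
    for col in ("v_call", "j_call", "locus"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column: {col}")
    seq_col = _pick_column(df, _AIRR_SEQ_COLS, "amino-acid sequence")
    cdr3_col = _pick_column(df, _AIRR_CDR3_COLS, "CDR3/junction")
    link_col = _pick_column(df, _LINKAGE_COLS, "pair linkage")

    by_pair: Dict[str, Dict[str, pd.Series]] = {}
    for _, row in df.iterrows():
        key = str(row[link_col])
        slot = "heavy" if str(row["locus"]) == "IGH" else "light"
        by_pair.setdefault(key, {})[slot] = row

    orphans = [
        key for key, slots in by_pair.items() if "heavy" not in slots or "light" not in slots
    ]
    if orphans:
        raise LinkageError(f"unpairable rows for linkage IDs: {sorted(orphans)}")

    pairs: List[PairedRecord] = []
    for key in by_pair:  # preserves file order (dict insertion order)
        slots = by_pair[key]
        try:
            heavy = _chain_from_airr_row(slots["heavy"], seq_col, cdr3_col)
            light = _chain_from_airr_row(slots["light"], seq_col, cdr3_col)
        except RecordValidationError as err:
            stats.rejected += 1
            stats.reject_reasons.append(str(err))
            continue
        pairs.append(PairedRecord(pair_id=key, heavy=heavy, light=light))
    stats.n_pairs = len(pairs)
    return pairs, stats


def _read_csv(path: Path) -> Tuple[List[PairedRecord], ReadStats]:
    df = pd.read_csv(path, dtype=str)
    stats = ReadStats(n_rows=len(df))
    for col in ("pair_id", "heavy_seq", "light_seq"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column: {col}")

    def get(row, col, default=""):
        return default if col not in row.index or pd.isna(row[col]) else str(row[col])

    pairs: List[PairedRecord] = []
    for _, row in df.iterrows():
        pid = str(row["pair_id"])
        try:
            heavy = ChainRecord(
                record_id=f"{pid}H",
                sequence_aa=str(row["heavy_seq"]),
                chain="heavy",
                locus="IGH",
                v_call=get(row, "heavy_v_call", "IGHV0-0"),
                j_call=get(row, "heavy_j_call", "IGHJ0"),
                cdr3_aa=get(row, "heavy_cdr3"),
                donor_id=get(row, "donor_id"),
                maturation_true=get(row, "heavy_maturation_true", "unknown"),
                maturation_pred=get(row, "heavy_maturation_pred", "unknown"),
            )
            light = ChainRecord(
                record_id=f"{pid}L",
                sequence_aa=str(row["light_seq"]),
                chain="light",
                locus=get(row, "light_locus", "IGK"),
                v_call=get(row, "light_v_call", "IGKV0-0"),
                j_call=get(row, "light_j_call", "IGKJ0"),
                cdr3_aa=get(row, "light_cdr3"),
                donor_id=get(row, "donor_id"),
                maturation_true=get(row, "light_maturation_true", "unknown"),
                maturation_pred=get(row, "light_maturation_pred", "unknown"),
            )
            heavy.validate()
            light.validate()
        except RecordValidationError as err:
            stats.rejected += 1
            stats.reject_reasons.append(str(err))
            continue
        pairs.append(PairedRecord(pair_id=pid, heavy=heavy, light=light))
    stats.n_pairs = len(pairs)
    return pairs, stats


# ---------------------------------------------------------------------------
# Writing


def _chain_to_row(rec: ChainRecord, link_key: str) -> Dict[str, object]:
    row: Dict[str, object] = {
        "sequence_id": rec.record_id,
        "cell_id": link_key,
        "locus": rec.locus,
        "v_call": rec.v_call,
        "j_call": rec.j_call,
        "sequence_aa": rec.sequence_aa,
        "cdr3_aa": rec.cdr3_aa,
        "donor_id": rec.donor_id,
        "maturation_true": rec.maturation_true,
        "maturation_pred": rec.maturation_pred,
    }
    if rec.region_bounds is not None:
        for name, (start, end) in zip(REGION_NAMES, rec.region_bounds):
            row[f"{name.lower()}_start"] = start
            row[f"{name.lower()}_end"] = end
    return row


def write_paired_table(pairs: Sequence[PairedRecord], path: Union[str, Path]) -> None:
    """Write pairs as AIRR-style TSV, one row per chain, linked by cell_id."""
    rows = []
    for p in pairs:
        rows.append(_chain_to_row(p.heavy, p.pair_id))
        rows.append(_chain_to_row(p.light, p.pair_id))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_candidate_table(sets: Sequence[CandidateSet], path: Union[str, Path]) -> None:
    """Write candidate light chains, one row per candidate.

    ``cell_id`` links candidates to their heavy chain's record id;
    ``candidate_rank`` preserves generation order.
    """
    rows = []
    for s in sets:
        for rank, cand in enumerate(s.candidates):
            row = _chain_to_row(cand, s.heavy.record_id)
            row["candidate_rank"] = rank
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_candidate_table(
    path: Union[str, Path], heavies: Mapping[str, ChainRecord]
) -> List[CandidateSet]:
    """Read a candidate table back, attaching each set to its heavy chain."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    seq_col = _pick_column(df, _AIRR_SEQ_COLS, "amino-acid sequence")
    cdr3_col = _pick_column(df, _AIRR_CDR3_COLS, "CDR3/junction")
    if "cell_id" not in df.columns:
        raise FormatError("missing mandatory column: cell_id")
    df["candidate_rank"] = df.get("candidate_rank", 0)
    grouped: Dict[str, List[Tuple[int, ChainRecord]]] = {}
    for _, row in df.iterrows():
        cand = _chain_from_airr_row(row, seq_col, cdr3_col)
        grouped.setdefault(str(row["cell_id"]), []).append((int(row["candidate_rank"]), cand))
    sets = []
    for hid in grouped:
        if hid not in heavies:
            raise LinkageError(f"candidate rows reference unknown heavy chain {hid}")
        cands = tuple(c for _, c in sorted(grouped[hid], key=lambda t: t[0]))
        sets.append(CandidateSet(heavy=heavies[hid], candidates=cands))
    return sets


def write_germline_db(db: GermlineDB, fasta_path: Union[str, Path], regions_path: Union[str, Path]) -> None:
    """Write germline templates as FASTA plus a region-annotation sidecar TSV."""
    records = []
    for g in db.v_genes:
        records.append(SeqRecord(Seq(g.sequence_aa), id=g.name, description=f"{g.locus} V"))
    for g in db.j_genes:
        records.append(SeqRecord(Seq(g.sequence_aa), id=g.name, description=f"{g.locus} J"))
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = []
    for g in db.v_genes:
        row: Dict[str, object] = {
            "name": g.name, "segment": "V", "locus": g.locus, "family": g.family,
        }
        for name, (start, end) in zip(REGION_NAMES, g.region_bounds):
            row[f"{name.lower()}_start"] = start
            row[f"{name.lower()}_end"] = end
        rows.append(row)
    for g in db.j_genes:
        rows.append({"name": g.name, "segment": "J", "locus": g.locus, "family": ""})
    df = pd.DataFrame(rows)
    for col in df.columns:
        if col.endswith(("_start", "_end")):
            df[col] = df[col].astype("Int64")  # keep ints despite J-row gaps
    df.to_csv(regions_path, sep="\t", index=False, lineterminator="\n")


def read_germline_db(fasta_path: Union[str, Path], regions_path: Union[str, Path]) -> GermlineDB:
    seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
    df = pd.read_csv(Path(regions_path), sep="\t", dtype=str)
    v_genes, j_genes = [], []
    for _, row in df.iterrows():
        name = str(row["name"])
        if name not in seqs:
            raise FormatError(f"germline {name} in regions table but not in FASTA")
        if str(row["segment"]) == "V":
            bounds = tuple(
                (int(row[f"{r.lower()}_start"]), int(row[f"{r.lower()}_end"]))
                for r in REGION_NAMES
            )
            v_genes.append(
                GermlineVGene(
                    name=name, family=str(row["family"]), locus=str(row["locus"]),
                    sequence_aa=seqs[name], region_bounds=bounds,
                )
            )
        else:
            j_genes.append(GermlineJGene(name=name, locus=str(row["locus"]), sequence_aa=seqs[name]))
    return GermlineDB(v_genes=tuple(v_genes), j_genes=tuple(j_genes))


# ---------------------------------------------------------------------------
# Result tables and manifest


def config_hash(config_dict: Mapping) -> str:
    """SHA-256 over the canonical JSON encoding of a configuration."""
    canonical = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: Union[str, Path],
    config_dict: Optional[Mapping] = None,
    seed: Optional[int] = None,
) -> Dict:
    """Write each result table as TSV and a JSON manifest describing the run.

    The manifest records the configuration hash, the seed, and per-table row
    counts; reruns under the same seed and configuration produce
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "config_hash": config_hash(config_dict) if config_dict is not None else None,
        "seed": seed,
        "tables": {},
    }
    for name in sorted(tables):
        path = out_dir / f"{name}.tsv"
        tables[name].to_csv(path, sep="\t", index=False, lineterminator="\n")
        manifest["tables"][name] = {"file": path.name, "n_rows": int(len(tables[name]))}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
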