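"""End-to-end pipeline driver.

Stage order: simulate (or load) -> label noise -> candidate generation ->
region-wise recovery -> germline-identity correlation regimes -> pairing
coherence -> restriction + permutation test -> maturation concordance ->
hierarchical clustering and split allocation with leakage audit.  Every
stage consumes the previous stage's typed outputs and each is runnable
standalone from files through the CLI; the driver wires them together and
writes one TSV per stage plus a JSON manifest.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .align import recovery_profile
from .coherence import build_groups, coherence_frame, group_frame
from .concordance import concordance_table, select_matching_candidate
from .germline import compare_regimes, germline_correlation, germline_identity_table, shuffle_pairs
from .clusters import allocate_splits, hierarchical_split_prep, leakage_check
from .config import PipelineConfig
from .io import (
    read_candidate_table,
    read_paired_table,
    write_candidate_table,
    write_germline_db,
    write_paired_table,
    write_results,
)
from .records import CandidateSet, PairedRecord, heavy_state
from .restriction import run_restriction_analysis
from .simulate import (
    build_germline_db,
    noisy_candidate_sets,
    noisy_pairs,
    simulate_candidate_sets,
    simulate_paired_repertoire,
)

logger = logging.getLogger("pairlens.pipeline")

__all__ = ["run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, out_dir: Union[str, Path]) -> Dict:
    """Execute every stage and write per-stage TSVs plus a manifest.

    Returns the manifest dictionary.  Reruns with the same configuration
    and seed produce byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables: Dict[str, pd.DataFrame] = {}
    sim = config.simulation

    stage = "germline_db"
    try:
        db = build_germline_db(config.n_v_per_locus, config.n_j_per_locus, seed=config.seed)
        write_germline_db(db, out_dir / "germline.fasta", out_dir / "germline_regions.tsv")
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "simulate"
    try:
        if config.input_pairs:
            pairs: List[PairedRecord] = read_paired_table(
                config.input_pairs, dialect=config.input_dialect
            )
        else:
            pairs = simulate_paired_repertoire(sim, db)
            pairs = noisy_pairs(pairs, sim)
        write_paired_table(pairs, out_dir / "pairs.airr.tsv")
        heavies = {p.heavy.record_id: p.heavy for p in pairs}
        if config.input_candidates:
            sets: List[CandidateSet] = read_candidate_table(config.input_candidates, heavies)
        else:
            sets = simulate_candidate_sets(pairs, sim, db)
            sets = noisy_candidate_sets(sets, sim)
        write_candidate_table(sets, out_dir / "candidates.airr.tsv")
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "recover"
    try:
        selections = [
            select_matching_candidate(heavy_state(p.heavy), s)
            for p, s in zip(pairs, sets)
        ]
        gen_ref = [
            (sel.candidate, p.light) for sel, p in zip(selections, pairs)
        ]
        summary, identities = recovery_profile(gen_ref, config.scoring)
        tables["recovery_summary"] = summary
        tables["recovery_identities"] = identities
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "germline"
    try:
        chains = (
            [p.heavy for p in pairs]
            + [p.light for p in pairs]
            + [sel.candidate for sel in selections]
        )
        seen = set()
        unique_chains = [
            c for c in chains if not (c.record_id in seen or seen.add(c.record_id))
        ]
        ident_table = germline_identity_table(
            unique_chains, db, config.scoring, config.germline_combine
        )
        tables["germline_identities"] = ident_table
        native = germline_correlation(pairs, db, "native", identities=ident_table)
        shuffled = germline_correlation(
            shuffle_pairs(pairs, config.seed), db, "shuffled", identities=ident_table
        )
        generated_pairs = [
            PairedRecord(pair_id=p.pair_id, heavy=p.heavy, light=sel.candidate)
            for p, sel in zip(pairs, selections)
        ]
        generated = germline_correlation(
            generated_pairs, db, "generated", identities=ident_table
        )
        regimes, ordering = compare_regimes(native, shuffled, generated)
        regimes["expected_ordering"] = ordering
        tables["germline_regimes"] = regimes
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "coherence"
    try:
        groups = build_groups(pairs)
        tables["coherence"] = coherence_frame(groups)
        tables["coherence_groups"] = group_frame(groups)
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "restriction"
    try:
        restriction_table, perm_results = run_restriction_analysis(sets, config.restriction)
        tables["restriction"] = restriction_table
        null_rows = [
            {"group": g, "draw": i, "fraction_restricted": x}
            for g, res in perm_results.items()
            for i, x in enumerate(res.null_draws)
        ]
        tables["restriction_null"] = pd.DataFrame(
            null_rows, columns=["group", "draw", "fraction_restricted"]
        )
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "concordance"
    try:
        tables["concordance"] = concordance_table(sets).to_frame()
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "split"
    try:
        heavies_list = [p.heavy for p in pairs]
        units = hierarchical_split_prep(heavies_list, config.clustering, config.scoring)
        split = allocate_splits(units, heavies_list, config.splitting, seed=config.seed)
        tables["splits"] = split.to_frame()
        violations = leakage_check(
            heavies_list, split.labels, config.clustering.thresholds[-1], config.scoring
        )
        tables["leakage"] = pd.DataFrame(
            violations, columns=["record_a", "record_b", "split_a", "split_b", "identity"]
        )
    except Exception as err:
        raise StageError(stage, err) from err

    manifest = write_results(tables, out_dir, config.to_dict(), seed=config.seed)
    logger.info("pipeline complete: %d tables in %s", len(tables), out_dir)
    return manifest
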