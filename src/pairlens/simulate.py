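"""Synthetic paired-repertoire and candidate-set simulator.

This module generates antibody heavy/light chain pairs and per-heavy-chain
sets of generated light-chain candidates with the statistical structure the
downstream analyses measure, so every pipeline stage is testable without
external repertoire downloads:

* **Germline database** — random amino-acid V/J templates per locus (IGH,
  IGK, IGL) with framework/CDR region annotations, mutually < 70 % identical
  within a locus so identity-threshold clustering is meaningful.
* **V(D)J-like assembly** — each chain is a V template (FR1..FR3) plus a
  random CDR3 junction plus a J template.
* **Somatic hypermutation** — i.i.d. per-site substitutions whose rate is
  the maturation-state rate (``mu_naive`` / ``mu_memory``) scaled by a
  latent exponential intensity mixing a pair-shared and a chain-private
  component; the shared fraction ``rho_shared`` drives the heavy-light
  germline-identity correlation.
* **Heavy-to-light V-gene coupling** — with probability ``kappa_coupling``
  the light V gene is taken from a fixed injective map of the heavy V gene,
  otherwise drawn at random; at kappa = 1 the pairing-coherence statistic is
  exactly 1 by construction.
* **Candidate V-gene restriction** — each candidate's V family comes from a
  two-component mixture of a heavy-chain-specific preferred family (weight
  ``rho_restriction_<state>``) and the global family frequency.
* **Classifier label noise** — predicted maturation states equal the truth
  with the configured per-chain-type accuracy, emulating imperfect
  naive/memory classifiers.

All randomness flows from ``numpy.random.default_rng`` seeded by the
configuration seed; pre-drawing every random array in a fixed order gives
common random numbers across parameter settings (the draws consumed do not
depend on parameter values), which makes monotonicity properties testable
without Monte-Carlo seams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .align import identity_upper_bound, sequence_identity
from .records import (
    CANONICAL_AA,
    REGION_NAMES,
    CandidateSet,
    ChainRecord,
    PairedRecord,
)

__all__ = [
    "GermlineVGene",
    "GermlineJGene",
    "GermlineDB",
    "SimulationConfig",
    "GermlineGenerationError",
    "build_germline_db",
    "simulate_paired_repertoire",
    "simulate_candidate_sets",
    "apply_label_noise",
    "noisy_pairs",
    "noisy_candidate_sets",
    "global_family_frequencies",
    "couple_map",
]

AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_BYTES = np.frombuffer(AA.encode(), dtype="S1")

# Fixed variable-domain architecture of the synthetic templates (residues).
# FR3 is the longest region, as in real variable domains.
_REGION_LENGTHS = {"FR1": 25, "CDR1": 8, "FR2": 17, "CDR2": 8, "FR3": 38}
V_CORE_LEN = sum(_REGION_LENGTHS.values())  # 96, FR1..FR3
V_CDR3_STUB = 4  # germline-encoded start of CDR3 kept on the template
J_LEN = 12

_V_CORE_BOUNDS: Tuple[Tuple[int, int], ...] = ()
_pos = 0
for _name in ("FR1", "CDR1", "FR2", "CDR2", "FR3"):
    _V_CORE_BOUNDS += ((_pos, _pos + _REGION_LENGTHS[_name]),)
    _pos += _REGION_LENGTHS[_name]
del _pos, _name


class GermlineGenerationError(RuntimeError):
    """Raised when a germline set satisfying the diversity bound cannot be built."""


@dataclass(frozen=True)
class GermlineVGene:
    name: str
    family: str
    locus: str
    sequence_aa: str
    region_bounds: Tuple[Tuple[int, int], ...]

    @property
    def core(self) -> str:
        """FR1..FR3 portion (the part retained in assembled chains)."""
        return self.sequence_aa[: self.region_bounds[-1][0]]


@dataclass(frozen=True)
class GermlineJGene:
    name: str
    locus: str
    sequence_aa: str


@dataclass(frozen=True)
class GermlineDB:
    """Synthetic germline V and J gene templates for IGH, IGK and IGL."""

    v_genes: Tuple[GermlineVGene, ...]
    j_genes: Tuple[GermlineJGene, ...]

    def v_for_locus(self, locus: str) -> List[GermlineVGene]:
        return sorted((g for g in self.v_genes if g.locus == locus), key=lambda g: g.name)

    def j_for_locus(self, locus: str) -> List[GermlineJGene]:
        return sorted((g for g in self.j_genes if g.locus == locus), key=lambda g: g.name)

    def light_v_genes(self) -> List[GermlineVGene]:
        """All IGK and IGL V genes, ordered by (locus, name)."""
        return sorted(
            (g for g in self.v_genes if g.locus in ("IGK", "IGL")),
            key=lambda g: (g.locus, g.name),
        )

    def v_by_name(self, name: str) -> GermlineVGene:
        for g in self.v_genes:
            if g.name == name:
                return g
        raise KeyError(name)


def build_germline_db(
    n_v_per_locus: int = 8,
    n_j_per_locus: int = 4,
    seed: int = 0,
    max_pairwise_identity: float = 0.7,
    max_attempts: int = 200,
) -> GermlineDB:
    """Generate a seeded random germline database.

    Same-locus V templates are rejection-sampled until all pairwise
    global-alignment identities fall below ``max_pairwise_identity``
    (default 0.7, so the 70 % clustering threshold separates genes).
    Each locus carries at least two V families, assigned round-robin.
    """
    if n_v_per_locus < 2:
        raise ValueError("n_v_per_locus must be >= 2 (each locus needs >= 2 V families)")
    if n_j_per_locus < 1:
        raise ValueError("n_j_per_locus must be >= 1")
    rng = np.random.default_rng([int(seed), 0])
    template_len = V_CORE_LEN + V_CDR3_STUB
    bounds = _V_CORE_BOUNDS + ((V_CORE_LEN, template_len),)
    n_families = max(2, min(4, n_v_per_locus))

    v_genes: List[GermlineVGene] = []
    for locus in ("IGH", "IGK", "IGL"):
        accepted: List[str] = []
        for i in range(n_v_per_locus):
            for _ in range(max_attempts):
                seq = _AA_BYTES[rng.integers(0, 20, template_len)].tobytes().decode()
                if all(
                    identity_upper_bound(seq, prev) < max_pairwise_identity
                    or sequence_identity(seq, prev) < max_pairwise_identity
                    for prev in accepted
                ):
                    accepted.append(seq)
                    break
            else:
                raise GermlineGenerationError(
                    f"could not generate {n_v_per_locus} {locus} V templates below "
                    f"{max_pairwise_identity:.0%} pairwise identity"
                )
            family = f"{locus}V{(i % n_families) + 1}"
            v_genes.append(
                GermlineVGene(
                    name=f"{family}-{i + 1}",
                    family=family,
                    locus=locus,
                    sequence_aa=accepted[-1],
                    region_bounds=bounds,
                )
            )

    j_genes: List[GermlineJGene] = []
    for locus in ("IGH", "IGK", "IGL"):
        for i in range(n_j_per_locus):
            seq = _AA_BYTES[rng.integers(0, 20, J_LEN)].tobytes().decode()
            j_genes.append(GermlineJGene(name=f"{locus}J{i + 1}", locus=locus, sequence_aa=seq))

    return GermlineDB(v_genes=tuple(v_genes), j_genes=tuple(j_genes))


# ---------------------------------------------------------------------------
# Simulation configuration


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the paired-repertoire and candidate-set simulator.

    Classifier-noise accuracies default to the reported overall accuracies
    of the heavy-chain (92.31 %) and light-chain (79.17 %) maturation
    classifiers this channel emulates.  ``rho_shared`` is the fraction of
    the expected somatic-hypermutation load shared between the two chains
    of a pair; ``kappa_coupling`` is the probability that a pair's light V
    gene is determined by the heavy V gene through a fixed injective map.
    """

    n_pairs: int = 500
    n_donors: int = 10
    k_candidates: int = 10
    frac_memory: float = 0.5
    mu_naive: float = 0.02
    mu_memory: float = 0.08
    rho_shared: float = 0.6
    kappa_coupling: float = 0.6
    rho_restriction_naive: float = 0.05
    rho_restriction_memory: float = 0.6
    acc_heavy: float = 0.9231
    acc_light: float = 0.7917
    frac_kappa_locus: float = 0.6
    cdr3_len_range: Tuple[int, int] = (8, 16)
    replicate_rate: float = 0.4
    cand_frac_memory_given_naive_heavy: Optional[float] = None
    cand_frac_memory_given_memory_heavy: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "frac_memory": self.frac_memory,
            "rho_shared": self.rho_shared,
            "kappa_coupling": self.kappa_coupling,
            "rho_restriction_naive": self.rho_restriction_naive,
            "rho_restriction_memory": self.rho_restriction_memory,
            "acc_heavy": self.acc_heavy,
            "acc_light": self.acc_light,
            "frac_kappa_locus": self.frac_kappa_locus,
            "replicate_rate": self.replicate_rate,
            "mu_naive": self.mu_naive,
            "mu_memory": self.mu_memory,
        }
        for name, value in fracs.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("cand_frac_memory_given_naive_heavy", "cand_frac_memory_given_memory_heavy"):
            value = getattr(self, name)
            if value is not None and not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_pairs < 1 or self.n_donors < 1 or self.k_candidates < 1:
            raise ValueError("n_pairs, n_donors and k_candidates must be >= 1")
        lo, hi = self.cdr3_len_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid cdr3_len_range {self.cdr3_len_range}")

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Sequence assembly helpers


_AA_INDEX = {c: i for i, c in enumerate(AA)}


def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX[c] for c in seq], dtype=np.int64)


def _decode(codes: np.ndarray) -> str:
    return _AA_BYTES[codes].tobytes().decode()


def _chain_bounds(cdr3_len: int) -> Tuple[Tuple[int, int], ...]:
    return _V_CORE_BOUNDS + ((V_CORE_LEN, V_CORE_LEN + cdr3_len),)


def _assemble(
    v_core_codes: np.ndarray,
    cdr3_codes: np.ndarray,
    j_codes: np.ndarray,
    rate: float,
    mut_u_row: np.ndarray,
    mut_r_row: np.ndarray,
) -> np.ndarray:
    codes = np.concatenate([v_core_codes, cdr3_codes, j_codes])
    if rate > 0:
        mask = mut_u_row[: len(codes)] < rate
        if mask.any():
            codes = codes.copy()
            # substitute with one of the 19 other residues, never the original
            codes[mask] = (codes[mask] + 1 + mut_r_row[: len(codes)][mask]) % 20
    return codes


def couple_map(db: GermlineDB, seed: int) -> Dict[str, GermlineVGene]:
    """Fixed injective heavy-V -> light-V map, determined by the seed."""
    heavy_vs = db.v_for_locus("IGH")
    light_vs = db.light_v_genes()
    if len(light_vs) < len(heavy_vs):
        raise ValueError("need at least as many light V genes as heavy V genes for coupling")
    rng = np.random.default_rng([int(seed), 10])
    perm = rng.permutation(len(light_vs))
    return {hv.name: light_vs[perm[i]] for i, hv in enumerate(heavy_vs)}


# ---------------------------------------------------------------------------
# Paired-repertoire simulation


def simulate_paired_repertoire(config: SimulationConfig, db: GermlineDB) -> List[PairedRecord]:
    """Simulate ``config.n_pairs`` donor-annotated heavy/light pairs.

    A configurable fraction of pairs (``replicate_rate``) replicates the
    heavy V/J genes and CDRH3 junction of an earlier pair while drawing an
    independent donor — this seeds the multi-member, multi-donor CDRH3
    groups the pairing-coherence statistic is defined on.
    """
    n = config.n_pairs
    lo, hi = config.cdr3_len_range
    heavy_vs = db.v_for_locus("IGH")
    heavy_js = db.j_for_locus("IGH")
    kappa_vs = db.v_for_locus("IGK")
    lambda_vs = db.v_for_locus("IGL")
    kappa_js = db.j_for_locus("IGK")
    lambda_js = db.j_for_locus("IGL")
    cmap = couple_map(db, config.seed)
    lmax = V_CORE_LEN + hi + J_LEN

    rng = np.random.default_rng([int(config.seed), 1])
    # fixed draw order and shapes: the arrays consumed do not depend on any
    # tunable rate, so runs at different parameter values share randomness
    donor_idx = rng.integers(0, config.n_donors, n)
    state_u = rng.random(n)
    hv_idx = rng.integers(0, len(heavy_vs), n)
    hj_idx = rng.integers(0, len(heavy_js), n)
    h_len = rng.integers(lo, hi + 1, n)
    h_cdr3 = rng.integers(0, 20, (n, hi))
    rep_u = rng.random(n)
    src_u = rng.random(n)
    couple_u = rng.random(n)
    locus_u = rng.random(n)
    lv_u = rng.random(n)
    lj_u = rng.random(n)
    l_len = rng.integers(lo, hi + 1, n)
    l_cdr3 = rng.integers(0, 20, (n, hi))
    g_pair = rng.standard_exponential(n)
    g_heavy = rng.standard_exponential(n)
    g_light = rng.standard_exponential(n)
    mut_u_h = rng.random((n, lmax))
    mut_r_h = rng.integers(0, 19, (n, lmax))
    mut_u_l = rng.random((n, lmax))
    mut_r_l = rng.integers(0, 19, (n, lmax))

    # replicate earlier clonotypes (heavy V/J + CDRH3), keeping donors fresh
    for i in range(1, n):
        if rep_u[i] < config.replicate_rate:
            j = int(src_u[i] * i)
            hv_idx[i] = hv_idx[j]
            hj_idx[i] = hj_idx[j]
            h_len[i] = h_len[j]
            h_cdr3[i] = h_cdr3[j]

    hv_cores = [_encode(g.core) for g in heavy_vs]
    hj_codes = [_encode(g.sequence_aa) for g in heavy_js]
    light_core_cache = {g.name: _encode(g.core) for g in db.light_v_genes()}
    kj_codes = [_encode(g.sequence_aa) for g in kappa_js]
    lj_codes = [_encode(g.sequence_aa) for g in lambda_js]

    rho = config.rho_shared
    pairs: List[PairedRecord] = []
    for i in range(n):
        memory = state_u[i] < config.frac_memory
        mu = config.mu_memory if memory else config.mu_naive
        shared = rho * g_pair[i]
        rate_h = min(mu * (shared + (1.0 - rho) * g_heavy[i]), 0.9)
        rate_l = min(mu * (shared + (1.0 - rho) * g_light[i]), 0.9)
        state = "memory" if memory else "naive"
        donor = f"D{donor_idx[i]:03d}"

        hv = heavy_vs[hv_idx[i]]
        hj = heavy_js[hj_idx[i]]
        h_codes = _assemble(
            hv_cores[hv_idx[i]], h_cdr3[i, : h_len[i]], hj_codes[hj_idx[i]],
            rate_h, mut_u_h[i], mut_r_h[i],
        )
        h_bounds = _chain_bounds(int(h_len[i]))
        h_seq = _decode(h_codes)
        heavy = ChainRecord(
            record_id=f"P{i:06d}H",
            sequence_aa=h_seq,
            chain="heavy",
            locus="IGH",
            v_call=hv.name,
            j_call=hj.name,
            cdr3_aa=h_seq[V_CORE_LEN : V_CORE_LEN + int(h_len[i])],
            region_bounds=h_bounds,
            donor_id=donor,
            maturation_true=state,
        )

        if couple_u[i] < config.kappa_coupling:
            lv = cmap[hv.name]
        elif locus_u[i] < config.frac_kappa_locus:
            lv = kappa_vs[int(lv_u[i] * len(kappa_vs))]
        else:
            lv = lambda_vs[int(lv_u[i] * len(lambda_vs))]
        l_js = kj_codes if lv.locus == "IGK" else lj_codes
        l_j_genes = kappa_js if lv.locus == "IGK" else lambda_js
        lj_i = int(lj_u[i] * len(l_js))
        l_codes = _assemble(
            light_core_cache[lv.name], l_cdr3[i, : l_len[i]], l_js[lj_i],
            rate_l, mut_u_l[i], mut_r_l[i],
        )
        l_seq = _decode(l_codes)
        light = ChainRecord(
            record_id=f"P{i:06d}L",
            sequence_aa=l_seq,
            chain="light",
            locus=lv.locus,
            v_call=lv.name,
            j_call=l_j_genes[lj_i].name,
            cdr3_aa=l_seq[V_CORE_LEN : V_CORE_LEN + int(l_len[i])],
            region_bounds=_chain_bounds(int(l_len[i])),
            donor_id=donor,
            maturation_true=state,
        )
        pairs.append(PairedRecord(pair_id=f"P{i:06d}", heavy=heavy, light=light))
    return pairs


# ---------------------------------------------------------------------------
# Candidate-set simulation


def global_family_frequencies(
    db: GermlineDB, frac_kappa_locus: float
) -> Tuple[List[str], np.ndarray]:
    """Light V-family frequency vector implied by the locus mix.

    A family's probability is the locus weight (``frac_kappa_locus`` for
    IGK) split uniformly over that locus's families.  This is the closed
    form the rho=0 candidate mixture draws from, so chance-level restriction
    rates can be computed analytically.
    """
    families: List[str] = []
    probs: List[float] = []
    for locus, weight in (("IGK", frac_kappa_locus), ("IGL", 1.0 - frac_kappa_locus)):
        fams = sorted({g.family for g in db.v_for_locus(locus)})
        for fam in fams:
            families.append(fam)
            probs.append(weight / len(fams))
    return families, np.asarray(probs)


def simulate_candidate_sets(
    pairs: Sequence[PairedRecord], config: SimulationConfig, db: GermlineDB
) -> List[CandidateSet]:
    """Simulate ``k_candidates`` generated light chains per heavy chain.

    Each candidate's V family is the heavy chain's preferred family with
    probability ``rho_restriction_<heavy state>`` and a draw from the global
    family frequency otherwise; genes within a family are uniform.
    Candidate maturation states default to the repertoire memory fraction,
    independent of the heavy state, unless the per-heavy-state overrides are
    set.
    """
    n = len(pairs)
    k = config.k_candidates
    lo, hi = config.cdr3_len_range
    lmax = V_CORE_LEN + hi + J_LEN
    families, fam_probs = global_family_frequencies(db, config.frac_kappa_locus)
    fam_cum = np.cumsum(fam_probs)
    genes_by_family: Dict[str, List[GermlineVGene]] = {
        fam: [g for g in db.light_v_genes() if g.family == fam] for fam in families
    }
    core_cache = {g.name: _encode(g.core) for g in db.light_v_genes()}
    js_by_locus = {
        "IGK": db.j_for_locus("IGK"),
        "IGL": db.j_for_locus("IGL"),
    }
    j_codes = {loc: [_encode(g.sequence_aa) for g in js] for loc, js in js_by_locus.items()}

    rng = np.random.default_rng([int(config.seed), 2])
    pref_u = rng.random(n)
    restrict_u = rng.random((n, k))
    fam_u = rng.random((n, k))
    gene_u = rng.random((n, k))
    j_u = rng.random((n, k))
    state_u = rng.random((n, k))
    len_arr = rng.integers(lo, hi + 1, (n, k))
    letters = rng.integers(0, 20, (n, k, hi))
    g_c = rng.standard_exponential((n, k))
    mut_u = rng.random((n, k, lmax))
    mut_r = rng.integers(0, 19, (n, k, lmax))

    sets: List[CandidateSet] = []
    for i, pair in enumerate(pairs):
        hstate = pair.heavy.maturation_true
        rho = (
            config.rho_restriction_memory
            if hstate == "memory"
            else config.rho_restriction_naive
        )
        if hstate == "memory":
            p_mem = (
                config.cand_frac_memory_given_memory_heavy
                if config.cand_frac_memory_given_memory_heavy is not None
                else config.frac_memory
            )
        else:
            p_mem = (
                config.cand_frac_memory_given_naive_heavy
                if config.cand_frac_memory_given_naive_heavy is not None
                else config.frac_memory
            )
        preferred = families[int(np.searchsorted(fam_cum, pref_u[i] * fam_cum[-1]))]
        candidates = []
        for j in range(k):
            if restrict_u[i, j] < rho:
                fam = preferred
            else:
                fam = families[int(np.searchsorted(fam_cum, fam_u[i, j] * fam_cum[-1]))]
            genes = genes_by_family[fam]
            gene = genes[int(gene_u[i, j] * len(genes))]
            js = js_by_locus[gene.locus]
            jg = js[int(j_u[i, j] * len(js))]
            state = "memory" if state_u[i, j] < p_mem else "naive"
            mu = config.mu_memory if state == "memory" else config.mu_naive
            rate = min(mu * g_c[i, j], 0.9)
            L = int(len_arr[i, j])
            codes = _assemble(
                core_cache[gene.name], letters[i, j, :L],
                j_codes[gene.locus][js.index(jg)], rate, mut_u[i, j], mut_r[i, j],
            )
            seq = _decode(codes)
            candidates.append(
                ChainRecord(
                    record_id=f"{pair.pair_id}C{j:02d}",
                    sequence_aa=seq,
                    chain="light",
                    locus=gene.locus,
                    v_call=gene.name,
                    j_call=jg.name,
                    cdr3_aa=seq[V_CORE_LEN : V_CORE_LEN + L],
                    region_bounds=_chain_bounds(L),
                    donor_id=pair.heavy.donor_id,
                    maturation_true=state,
                )
            )
        sets.append(CandidateSet(heavy=pair.heavy, candidates=tuple(candidates)))
    return sets


# ---------------------------------------------------------------------------
# Classifier label-noise channel


def apply_label_noise(
    records: Sequence[ChainRecord],
    acc_heavy: float,
    acc_light: float,
    seed: int,
) -> List[ChainRecord]:
    """Set ``maturation_pred`` by corrupting ``maturation_true``.

    Each record's prediction equals its true state with the per-chain-type
    accuracy and is flipped otherwise, independently across records.
    Records with unknown true state keep an unknown prediction (a draw is
    still consumed so downstream randomness is unaffected by their count).
    """
    for name, acc in (("acc_heavy", acc_heavy), ("acc_light", acc_light)):
        if not (0.0 <= acc <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {acc}")
    rng = np.random.default_rng([int(seed), 3])
    u = rng.random(len(records))
    out: List[ChainRecord] = []
    flip = {"naive": "memory", "memory": "naive"}
    for i, rec in enumerate(records):
        if rec.maturation_true == "unknown":
            out.append(rec.with_pred("unknown"))
            continue
        acc = acc_heavy if rec.chain == "heavy" else acc_light
        pred = rec.maturation_true if u[i] < acc else flip[rec.maturation_true]
        out.append(rec.with_pred(pred))
    return out


def noisy_pairs(pairs: Sequence[PairedRecord], config: SimulationConfig) -> List[PairedRecord]:
    """Label-noise both chains of each pair (convenience wrapper)."""
    chains = [c for p in pairs for c in (p.heavy, p.light)]
    noised = apply_label_noise(chains, config.acc_heavy, config.acc_light, config.seed)
    return [
        PairedRecord(pair_id=p.pair_id, heavy=noised[2 * i], light=noised[2 * i + 1])
        for i, p in enumerate(pairs)
    ]


def noisy_candidate_sets(
    sets: Sequence[CandidateSet], config: SimulationConfig
) -> List[CandidateSet]:
    """Label-noise every candidate (heavy chains are noised with the pairs)."""
    flat = [c for s in sets for c in s.candidates]
    noised = apply_label_noise(flat, config.acc_heavy, config.acc_light, int(config.seed) + 1)
    out: List[CandidateSet] = []
    pos = 0
    for s in sets:
        out.append(CandidateSet(heavy=s.heavy, candidates=tuple(noised[pos : pos + s.k])))
        pos += s.k
    return out
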