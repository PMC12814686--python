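# Methods

This note documents the models, conventions and design decisions behind
`pairlens`.  Nothing here reports an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Sequence model and the synthetic repertoire

The simulator exists so that every analysis stage has inputs with known
ground truth.  It emulates the *statistical* structure the analyses
measure, not the biophysics of real antibodies.

**Germline templates.**  Each locus (IGH, IGK, IGL) carries `n_v_per_locus`
V templates (default 8) and `n_j_per_locus` J templates (default 4) of
uniformly random amino acids.  V templates are 100 residues partitioned as
FR1 25, CDR1 8, FR2 17, CDR2 8, FR3 38 (the longest region, as in real
variable domains), plus a 4-residue germline CDR3 stub; J templates are 12
residues.  Same-locus V templates are rejection-sampled to pairwise
global-alignment identity below 0.7 so that the 70 % clustering threshold
separates genes.  Because the templates are mutually random (≈ 15–25 %
pairwise identity), chains built on different V genes are far apart — this
is deliberate: it makes identity-threshold clustering and leakage audits
discriminative at desk scale.  Real germline genes share far more framework
similarity; consequences are noted under *Limitations*.

**Chain assembly.**  A chain is V-template FR1..FR3 (96 aa) + a random CDR3
junction (length uniform on `cdr3_len_range`, default 8–16) + a J template.
Region bounds are therefore exact by construction, which is what lets the
region-projection logic be tested against ground truth.

**Somatic hypermutation.**  Substitutions are i.i.d. per site.  A pair's
maturation state (memory with probability `frac_memory`, default 0.5) sets
the base rate μ (`mu_naive` 0.02, `mu_memory` 0.08 — giving the expected
≈ 6-percentage-point germline-identity gap between states).  The realized
per-chain rate is μ · (ρ·G + (1−ρ)·g), with G an exponential(1) intensity
shared by the pair, g chain-private, and ρ = `rho_shared` (default 0.6).
The shared intensity is what produces the heavy–light germline-identity
correlation; at ρ = 0 with a single maturation state the two chains'
identities are independent.  Mutation hotspots, indels, and lineage
structure are not modelled — the downstream statistics only depend on
mutation *load*.

**Heavy→light coupling.**  With probability κ = `kappa_coupling` the light
V gene is `couple_map(heavy V)`, a per-seed fixed injective map; otherwise
the locus is κ-chain with probability `frac_kappa_locus` (0.6, the human
κ:λ ratio) and the gene uniform within the locus.  Injectivity makes the
κ = 1 coherence limit exactly 1 and testable.

**CDRH3 replicates.**  With probability `replicate_rate` (0.4) a pair
copies the heavy V/J and CDRH3 of a random earlier pair while drawing a
fresh donor (`n_donors` default 10).  This populates the multi-member,
multi-donor groups the coherence statistic is defined on; an all-singleton
repertoire would leave it undefined.

**Candidate sets.**  Each heavy chain receives `k_candidates` (10)
simulated light chains.  A candidate's V family is the heavy chain's
*preferred family* (drawn once per heavy chain from the global family
frequency) with probability `rho_restriction_<state>` (memory 0.6, naive
0.05), else an independent draw from that global frequency — the
closed-form mixture that makes chance-level restriction rates computable
exactly.  Candidate maturation states default to the repertoire memory
fraction, independent of the heavy state; per-heavy-state overrides exist
to reproduce directional concordance biases without hard-coding them.
Candidates are *not* conditioned on the true partner light chain: the
simulator emulates the combinatorial structure of generated candidate
sets, not a trained generator's sequence fidelity, so absolute
candidate-to-reference recovery identities on simulations are low
(≈ 0.1–0.2).  The recovery machinery itself is verified on constructed
pairs with known per-region identities.

**Label noise.**  Predicted maturation states equal the truth with
probability `acc_heavy` = 0.9231 and `acc_light` = 0.7917 — the overall
accuracies of the heavy- and light-chain maturation classifiers this
channel stands in for — and are flipped otherwise, independently per chain.

**Randomness.**  All draws flow from `numpy.random.default_rng` seeded by
the configuration seed (stream-separated per stage).  Every random array is
pre-drawn in a fixed order whose shapes do not depend on rate parameters,
so runs at different κ, ρ or μ share randomness (common random numbers).
This is why monotonicity properties (coherence vs κ, restriction vs ρ) can
be asserted across a parameter grid at a single seed with only a 0.01
slack for the rare discrete flips CRN cannot remove.

## Alignment conventions

Global Needleman–Wunsch with affine gaps, computed by
`Bio.Align.PairwiseAligner`: a gap run of length L costs
`gap_open + (L−1)·gap_extend`, defaults −10/−4, end gaps penalized.  The
default substitution model is +1/−1 match/mismatch; BLOSUM62 is available
by flag.  Scores are exactly optimal (verified against exhaustive
enumeration of all alignments for short sequences across five schemes).
Ties between co-optimal alignments resolve to the aligner's deterministic
first traceback.

**Identity denominator.**  Percent identity is identical columns divided by
*total alignment columns*, so gaps count against identity, everywhere in
the package (recovery, germline assignment, clustering, leakage).  Two
empty sequences have identity 1 by convention; empty vs non-empty is 0.

**Region projection.**  Region bounds are trusted only on the reference
chain and projected through the alignment's column map; insertions in the
query inside a region count as columns of that region, insertions at a
boundary belong to the downstream region.  Region identities, weighted by
column counts, recompose the identity over the covered columns exactly.

**Germline identity.**  `closest_germline` re-aligns the chain's V span
(sequence up to the CDR3 start, when region bounds exist) against every
same-locus V template and keeps the best identity, ties to the first gene
name; likewise the post-CDR3 tail against J templates.  The correlation
analyses use the span-length-weighted V+J combination by default
(`v_only`/`j_only` are available) — the axis convention is configurable
because reasonable annotators differ here.

## Statistics

**Coherence.**  Groups are keyed by *exact* (CDRH3 amino-acid sequence,
heavy V gene); singleton and single-donor groups are removed (counts
logged, since they set the denominator).  A group is coherent when all
members share the identical light V gene (gene level, not family; a family
flag exists).  Strata come from the group's majority heavy-chain label —
the classifier prediction when present, else truth; ties form a separate
`mixed` stratum rather than being dropped.  The chance baseline is the
mean over groups of Σ_v f_v^size for a supplied light-V frequency vector.

**Restriction and the permutation test.**  Threshold ≥ 0.80 *inclusive*;
sets with fewer than 4 candidates are excluded from numerator and
denominator.  Sets are grouped by (heavy predicted state × majority
candidate predicted state).  The null permutes individual candidate
sequences within a group and re-deals them preserving each set's size; a
`block` mode permuting intact sets is provided for completeness but is a
sanity control only — it provably leaves the statistic unchanged.  The
p-value is (b+1)/(m+1) with b counting draws ≥ observed (ties count,
the conservative reading), so p ∈ (0, 1] always; significance tiers at
0.05/0.01/0.001.  Under an exchangeable null the p-values are
stochastically conservative.

**Shuffled-pair null.**  A rejection-sampled random derangement: no light
chain keeps its original heavy partner, and the light-chain multiset — and
hence both marginal identity distributions — is preserved exactly, so any
change in r is purely relational.

**Concordance.**  The selection rule takes the first candidate (generation
order) whose predicted state matches the heavy chain's; if none matches,
the first candidate is a flagged fallback excluded from matched-only
outputs.  Flow tables are emitted both row-normalised and globally
normalised since either convention is defensible.

## Clustering and splits

Greedy first-fit centroid clustering in canonical order
(length-descending, then lexicographic): each sequence joins the first
centroid at identity ≥ threshold, else founds a cluster.  This is a
desk-scale replacement for k-mer linkage clustering of repertoire-scale
data; the contract is the membership invariant (member ↔ centroid identity
≥ threshold), not equivalence with any particular large-scale tool.  At
threshold 1.0 identity requires exact equality, so hashing is used.

The hierarchy clusters CDR3s at 100 %, then the centroids' full sequences
at 70 %, then 50 %.  Because greedy clusters only bound member-to-centroid
identity, two final-stage clusters can still contain a cross pair above
the allocation threshold (heavily mutated outliers sit between clusters).
The final-stage clusters are therefore *closed under single linkage* at
the allocation threshold before becoming allocation units — making the
no-leakage guarantee a construction property, which the audit then
verifies rather than hopes for.

Allocation fills train, then validation, then test, visiting units largest
first (ties by first record id), adding units while a split is under its
record-count target; the last split absorbs the remainder, indivisible
units may overfill a split (warned), and a unit larger than the largest
target goes to train with a warning.  A seeded `random` unit order is
available.  Achieved fractions are always reported.

The leakage audit is exhaustive over cross-split pairs.  Two exact-safe
screens make it fast: for any global alignment with M matches, X
mismatches and G gap columns, |a|+|b| = 2M+2X+G and X+G ≥ the Levenshtein
distance d, so identity ≤ (|a|+|b|−d)/(2·max|·|); and M ≤ LCS(a, b), so
identity ≤ LCS/max|·|.  The LCS screen runs as a batched bit-parallel
kernel (numba) at about a microsecond per pair; survivors get the full
affine alignment.  Screened-out pairs provably cannot violate the
threshold, so the audit equals the unscreened computation.

## Problem sizes and numerical choices

The test suite runs the acceptance-grade checks at n = 2,000 pairs
(coherence grid), n = 5,000 (germline regimes), n = 800 plus twenty
n = 300 null datasets (restriction, m = 1,000 and m = 200 permutations),
and 100 seeds × 500 sequences (leakage); the acceptance script uses
n = 3,000 for the germline regimes and 10 seeds for the leakage count as
its own reporting sizes.  Monte-Carlo tolerances are set at 3–4 σ of the
relevant binomial/correlation sampling error.  Floating-point comparisons
on restricted fractions use exact arithmetic (counts over k), so the ≥
threshold comparison is safe at the 0.8 boundary.

## Limitations

* Random germline templates lack the framework similarity of real V genes;
  absolute identities between different-gene chains are much lower than in
  real repertoires, and clustering at 70 %/50 % is correspondingly easier.
  Passing tests demonstrate the statistics' correctness and
  direction-recovery, not real-data effect sizes.
* The SHM model has no hotspots, no indels, and no clonal lineages.
* Candidate sets emulate combinatorial structure (restriction,
  concordance), not generator sequence fidelity; recovery identities on
  simulations are correspondingly low.
* Real-data headline values (coherence percentages, region-mean
  identities, restriction bar heights, classifier accuracies beyond their
  use as noise rates) require external databases and trained models and
  are out of scope; the package reproduces their property surface —
  orderings, nulls, exact corrections — on simulation.
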