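# pairlens

Statistics of antibody heavy–light chain pairing: who pairs with whom, how
tightly, and how to evaluate generated light chains without fooling yourself.

## The problem

An antibody is a heavy chain (HC) paired with a κ or λ light chain (LC).
Pairing is not random: during affinity maturation both chains mutate away
from their germline genes together, and in memory B cells identical heavy
V genes preferentially associate with specific light V genes.  Generative
models that propose light chains for a given heavy chain should reproduce
this structure — and evaluating them requires a stack of repertoire
statistics plus data splits that do not leak near-identical sequences
between training and test sets.

`pairlens` implements that stack as a tested, seeded pipeline:

* **Region-wise recovery** — global Needleman–Wunsch alignment with affine
  gap costs (gap open −10, extend −4; a gap run of length *L* costs
  *open* + (*L*−1)·*extend*), percent identity = identical columns /
  alignment columns, profiled per framework/CDR region (FR1–FR3, CDR1–CDR3)
  by projecting reference region bounds through the alignment.
* **Germline-identity co-convergence** — each chain's percent identity to
  its closest germline V and J genes; Pearson *r* between heavy and light
  identities for native pairs, derangement-shuffled pairs (the null: no
  chain keeps its partner, marginals preserved exactly), and generated
  pairs.
* **Pairing coherence** — group HCs by exact (CDRH3, heavy V gene), drop
  singleton and single-donor groups, and report the fraction of groups in
  which every member uses the identical light V gene, per maturation
  stratum, against the analytic chance baseline
  E[Σ<sub>v</sub> f<sub>v</sub><sup>s</sup>].
* **V-gene restriction with a permutation null** — a heavy chain is
  *restricted* when ≥ 80 % of its ≥ 4 generated LCs share one V gene
  family; the null re-deals candidate sequences to heavy chains within a
  maturation-pairing group, and *p* = (*b*+1)/(*m*+1) where *b* counts null
  draws at or above the observed fraction (never zero by construction).
* **Maturation concordance** — heavy-state → candidate-state flow tables
  and the first-maturity-matched candidate selection rule.
* **Leakage-free splits** — hierarchical identity clustering (CDR3 at
  100 %, then full sequences of centroids at 70 %, then 50 %), allocation
  of whole clusters to train/validation/test (80/10/10, largest clusters
  to training), and an exhaustive cross-split identity audit.

Everything runs on a built-in synthetic paired-repertoire simulator
(V-template + junction + J-template assembly, maturation-dependent somatic
hypermutation with a pair-shared intensity, tunable heavy→light V-gene
coupling, candidate V-family restriction, classifier label noise at the
92.31 % / 79.17 % heavy/light accuracies), so every stage is testable
offline; real AIRR Rearrangement TSV tables can be substituted for the
simulator at any stage.

## Worked example

```python
from pairlens import (
    SimulationConfig, build_germline_db, simulate_paired_repertoire,
    build_groups, chance_coherence,
)
from pairlens.coherence import empirical_light_v_frequencies

db = build_germline_db(seed=1)

for kappa in (0.0, 1.0):
    cfg = SimulationConfig(n_pairs=2000, seed=1, kappa_coupling=kappa,
                           mu_naive=0.0, mu_memory=0.0)
    pairs = simulate_paired_repertoire(cfg, db)
    groups = build_groups(pairs)
    coh = sum(g.is_coherent for g in groups) / len(groups)
    chance = chance_coherence(groups, empirical_light_v_frequencies(pairs))
    print(f"kappa={kappa:.1f}  coherence={coh:.4f}  chance={chance:.4f}")
```

prints

```
kappa=0.0  coherence=0.0294  chance=0.0364
kappa=1.0  coherence=1.0000  chance=0.0721
```

With no heavy→light coupling (κ = 0) the observed coherence sits at the
analytic chance baseline — groups agree on a light V gene only by
accident — while a deterministic coupling (κ = 1) makes every multi-member,
multi-donor CDRH3 group coherent.

The same stack runs end to end from the shell:

```bash
pairlens run -c config.yaml -o out/        # full pipeline + manifest
pairlens simulate -o out/ --n-pairs 500 --seed 1
pairlens coherence --pairs out/pairs.airr.tsv -o out/
pairlens split --in out/pairs.airr.tsv --thresholds 1.0,0.7,0.5 --seed 1 -o out/
```

Each stage writes TSV tables plus a JSON manifest with the configuration
hash and seed; a rerun under the same seed is byte-identical.

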