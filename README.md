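# quartetree

Quartet-score species tree inference from single-copy gene trees, with a
multispecies-coalescent (MSC) simulator for fully synthetic testing.

Given a file of unrooted gene trees (Newick, one per line, polytomies,
branch lengths and support labels allowed), `quartetree` finds the binary
species tree maximizing the (optionally weighted) quartet support score —
the summed weight, over all gene trees and all species quadruples, of
gene-tree quartets that agree with the species tree — and annotates each
internal branch with quartet frequencies, a coalescent-unit length, and a
local posterior probability.

## How it works

* **Scoring.** Two independent routes compute the score. The oracle
  (`brute_force_score`) enumerates every quadruple. The production scorer
  (`fast_score`) never lists quartets: every agreeing quartet is anchored
  at the two species-tree nodes where its pairs coalesce, so the score is
  half the sum of per-node *tripartition gains*, each computed per gene
  tree by a linear-time two-pass dynamic program. Agreement of the two
  routes (exact in unit mode, 1e-9 relative for weighted modes) is the
  central correctness contract of the test suite.
* **Weighting.** `unit` counts each resolved quartet once; `support`
  multiplies the supports of the gene-tree branches joining the quartet's
  two pairs; `hybrid` further downweights by `exp(-L)` with `L` the total
  terminal path length of the induced quartet subtree.
* **Search.** Greedy stepwise placement builds several initial trees from
  random insertion orders, each is refined by best-improvement NNI sweeps,
  and a dynamic program over the bipartitions collected from the refined
  trees (plus a completion round) returns the optimal tree within that
  constraint set.
* **Annotation.** Per internal branch: quartet-frequency masses f1/f2/f3,
  coalescent-unit length `d = -ln(1.5 (1 - f1))` (clamped to [0, 10]),
  and a local posterior probability from numerical Bayesian integration
  (uniform topology prior, Exp(1) prior on `d`).
* **Simulation.** A seeded coalescent-in-species-tree sampler (rates
  `j(j-1)/2`), plus an error model adding random NNIs, synthetic Beta
  supports (high on untouched branches, low on perturbed ones), and
  species dropout. Multiple individuals per species are supported
  throughout via a two-column individual-to-species map.

## Command line

```sh
# simulate 1000 MSC gene trees from a species tree in coalescent units
quartetree simulate --species-tree model.nwk --k 1000 --seed 1 -o genes.nwk

# infer the species tree (auto weighting: hybrid when supports exist)
quartetree infer --genes genes.nwk -o species.nwk --seed 1 --report run.json

# score a fixed species tree / annotate its branches
quartetree score --species-tree species.nwk --genes genes.nwk
quartetree annotate --species-tree species.nwk --genes genes.nwk \
    --label-mode full -o annotated.nwk
```

Useful options: `--map FILE` (individual-to-species map), `--weight
unit|support|hybrid`, `--support-scale auto|prob|percent`, `--contract
THRESH` (collapse low-support gene tree branches), `--rounds R` (initial
trees). All randomness flows from `--seed`; identical seed and input give
byte-identical output. Exit codes: 0 success, 1 data error, 2 usage error.

## Layout

```
src/quartetree/
  treeio.py        Newick I/O, bipartitions/tripartitions, taxon maps,
                   support-threshold contraction
  quartet_core.py  weight schemes, brute-force oracle, anchored fast scorer
  search.py        placement, NNI, constraint set, optimal-tree DP
  annotate.py      quartet frequencies, coalescent lengths, local PP
  msc_sim.py       MSC gene tree simulator and error model
  cli.py           infer / score / annotate / simulate subcommands
```
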