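# paleotempo

Tempo and mode of morphological evolution in fossil clades: phylogeny-based
rates of discrete character change through geologic time, morphological
disparity and morphospace, and diversity–disparity dynamics — with a
synthetic fossil-clade generator that makes every stage verifiable by
parameter recovery.

## Who this is for

Palaeobiologists with (a) a NEXUS matrix of unordered multistate characters
scored for fossil taxa, (b) a sample of time-calibrated trees (e.g. a
Bayesian tip-dating posterior) with tips at occurrence ages, and (c) a
chronostratigraphic bin table, who want to ask: *when* was morphological
evolution fast or slow, was there an early burst, and did disparity keep
pace with taxonomic diversification?

## The statistics at its core

**Rates.** For each tree, ancestral states of every informative character
are reconstructed by maximum likelihood under the symmetric Mk model (the
per-character rate itself fitted by 1-D ML). The rate on a branch is

&nbsp;&nbsp;&nbsp;&nbsp;rate = changes / (duration × proportion comparable),

where a change is a difference between endpoint states and a character is
comparable when determinate at both ends. Branches are sliced at time-bin
boundaries; each bin b accumulates opportunity T_b = Σ (segment duration ×
p) and changes C_b. Bin b's pooled rate λ̂_b = C_b/T_b is tested against
the pooled remainder with a Poisson likelihood-ratio test (χ², 1 df,
α = 0.01, Benjamini–Hochberg adjusted p reported alongside). Over a sample
of trees, a bin is called HIGH or LOW when >55% of trees agree on a
significant deviation in the same direction; otherwise BACKGROUND.

**Disparity.** Pairwise Gower distances d_ij = (number of differing
comparable characters)/(number of comparable characters); disparity of a
taxon set is the mean squared pairwise distance, bootstrapped over taxa.
Morphospace is principal coordinates analysis of the Gower matrix (%
variance over positive eigenvalues; optional Cailliez correction), with
Brownian-motion ML ancestral scores for phylomorphospace.

**Diversity–disparity.** Range-through taxon counts per bin with
bootstrap intervals; the trajectory plots range-standardized ln(diversity)
against range-standardized disparity, where constant-rate evolution
predicts the 1:1 diagonal. Paired bootstrap intervals on the deviation
classify bins above/on/below the line.

The synthetic module generates birth–death clades with dated fossil tips,
evolves characters under Mk with per-bin rate multipliers (early bursts,
isolated spikes), injects missing data, fabricates posterior-like tree
samples by age jitter, and keeps an exact ledger of every realized change —
the ground truth the estimators are scored against.

## Worked example

`examples/02_rates_through_time.py` simulates an 82-taxon, 92-character
clade whose change rate is multiplied by 2.5 in bin 10 of 13, then runs the
full rate pipeline over 25 jittered trees:

```
82 taxa, 92 characters, 25 trees

  bin  mean_rate_per_char  frac_high  frac_low      class
bin01            0.000853        0.0       0.0 BACKGROUND
bin02            0.002552        0.0       0.0 BACKGROUND
...
bin09            0.001088        0.0       0.0 BACKGROUND
bin10            0.003384        1.0       0.0       HIGH
bin11            0.001980        0.0       0.0 BACKGROUND
bin12            0.001547        0.0       0.0 BACKGROUND
bin13            0.001409        0.0       0.0 BACKGROUND
```

`mean_rate_per_char` is the cross-tree mean rate in changes/character/Myr:
background bins sit near the simulated base rate (0.001), and the planted
bin is recovered as the only HIGH call — every one of the 25 trees found
its rate significantly elevated (`frac_high = 1.0`). The other examples
cover the generator (`01`), morphospace and disparity (`03`), and the
diversity–disparity trajectory (`04`).

The same stages are scriptable from the shell:

```bash
paleotempo simulate --seed 1 --out sim/
paleotempo rates --matrix sim/matrix.nex --trees sim/trees.nex \
    --timescale sim/timescale.tsv --n-trees 25 --out rates/
paleotempo run --seed 1 --out bundle/     # all-in-one, reproducible bundle
```

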