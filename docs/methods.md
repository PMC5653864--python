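# Methods

`paleotempo` quantifies the tempo of discrete morphological evolution in a
fossil clade from three ingredients: a taxon × character matrix of unordered
multistate characters, a sample of rooted time-calibrated trees whose tips
sit at fossil occurrence ages, and a chronostratigraphic bin table. This
note describes the models and algorithms, the tunable parameters and their
defaults, what the synthetic-data generator does and does not emulate, and
the numerical and design choices a user should know about.

## Conventions

All ages are in Ma before present (larger = older); branch durations are
`age(parent) − age(child)` in Myr, and zero-length branches (sampled-
ancestor encodings) are legal. Time bins run old → young, are contiguous,
and cover `(end, start]`, with the shared boundary belonging to the older
bin and the youngest bin closed on both ends. Character states are compared
as tokens; because every character is treated as unordered, only token
equality matters. `?` (missing), `-` (inapplicable) and polymorphic codings
such as `{01}` are all reduced to MISSING; the number of polymorphisms so
reduced is counted and logged, since the reduction discards information.
Characters with fewer than two observed states among scored cells are
invariant and are excluded from both rate and disparity computations.

## Rates of character evolution

### Ancestral states

Each informative character evolves under a symmetric k-state Mk model,
where k is the number of states actually observed for that character. The
transition probability has the closed form

    P(same)  = 1/k + (k−1)/k · exp(−k r t/(k−1))
    P(other) = 1/k −   1/k   · exp(−k r t/(k−1)),

which lets the pruning recursion be evaluated without matrix exponentials
and vectorized across characters. The per-character change rate `r` is
fitted on each tree by one-dimensional maximum likelihood (golden-section
search on log10 r over [1e−8, 10] changes/Myr, 48 iterations, i.e. bracket
resolution below 1e−8). Missing tips contribute a flat partial likelihood.
Marginal ancestral probabilities at every node come from the standard
down-pass/up-pass algorithm; the MAP state breaks exact ties by the lowest
state symbol, deterministically.

### Branch changes and rates

A change is scored on a branch when the two endpoint states differ, using
observed states at scored tips and MAP states at internal nodes. A
character is non-comparable on a terminal branch whose tip is MISSING
(internal nodes always have a MAP state); non-comparable characters count
toward neither changes nor the comparable proportion p. The branch rate is
`changes / (duration × p)` — per-matrix units; divide by the number of
informative characters for changes/character/Myr.

Two known biases of endpoint-state counting matter for interpretation.
First, multiple changes of one character on one branch are seen at most
once, so P(endpoints differ) is concave in the true rate and fast bins are
compressed toward the background. Second, marginal reconstruction smooths:
changes tend to be placed parsimoniously, undercounting totals by roughly
10–20% at the default simulation settings. Both biases attenuate — never
invert — rate contrasts between bins.

### Bin partitioning

Each branch is sliced at bin boundaries. Opportunity is allocated exactly
(segment duration × p); changes are allocated proportionally to segment
duration, the expectation under within-branch rate homogeneity (fractional
counts allowed). A `midpoint` mode that assigns whole branches to the bin
holding their temporal midpoint is available for sensitivity analysis.
Zero-duration branches have no time to allocate and are excluded (logged
with their change counts). When trees overhang the timescale — jittered
root ages can exceed the oldest bin boundary — the `extend_edges` option
absorbs the overhang into the terminal bins; the pipeline enables it, the
low-level function errors by default.

Proportional allocation smears changes into neighbouring bins whenever
branch durations are comparable to bin widths. With ~80 sampled taxa over a
~200 Myr clade and ~15 Myr bins, sampled branch durations average ~11 Myr
and a planted 2.5× rate contrast is observed at roughly 1.5–2.4×. This is a
property of the method, not of the implementation; it sets the detection
power discussed under "What the tests show".

### Per-bin tests and cross-tree aggregation

Within one tree, each bin's pooled counts are tested against the pooled
remainder under a Poisson model: H0 one rate (MLE ΣC/ΣT), H1 separate
rates, statistic 2(lnL1 − lnL0) against χ²(1). The log-likelihood uses the
gamma-function generalization `C ln(λT) − λT − ln Γ(C+1)` so fractional
allocated counts are well-defined; only likelihood differences matter. Bins
with zero opportunity on either side are reported NA, never dropped
silently.

A bin's per-tree verdict is significant when its LRT p ≤ α (default
α = 0.01). Across the tree sample, a bin is classified HIGH (LOW) when
strictly more than 55% of trees found it significantly high (low); rate
summaries across trees are percentile-based (mean, median, 2.5/97.5
percentiles), since tree samples are small and skewed. Benjamini–Hochberg
adjusted p-values across the bins of each tree are always computed and
reported, and `significance="bh"` makes them the verdict criterion. The raw
rule is the default: the >55% cross-tree consensus is itself the guard
against single-tree flukes, and requiring the within-tree adjusted p to
clear α = 0.01 as well leaves the test with essentially no power against
bin-level rate shifts of the magnitude studied here (the attenuated LRT
statistic rarely exceeds the rank-1 step-up cutoff). Empirically, under
constant-rate simulation the raw rule still produces HIGH/LOW calls in
under 1% of dataset-bins (see the type-I test).

The secular trend statistic is the Spearman rank correlation of per-bin
mean rates against time increasing toward the present, with scipy's
p-value (exact only at very small n, t-approximation otherwise).

## Disparity and morphospace

Pairwise dissimilarity is the Gower distance over comparable characters:
the fraction of characters scored in both taxa whose tokens differ. (The
classic Gower coefficient is the complementary similarity normalized by the
number of comparable characters; with unordered tokens, distance =
1 − similarity.) For a complete binary matrix this equals Hamming
distance / n characters exactly. Pairs sharing no comparable character are
undefined and must be resolved explicitly — the default is to fail loudly.

Disparity of a taxon set is the mean squared pairwise distance;
uncertainty comes from resampling taxa with replacement within each time
bin (1,000 replicates by default, 95% percentile intervals). Taxa — not
characters — are resampled because disparity is a between-taxon statistic.
Bin membership is range-through: a taxon occupies every bin its
stratigraphic range crosses.

Morphospace is classical metric scaling (PCO): double-center −½D²,
eigendecompose, keep positive axes; per-axis variance shares are computed
over the positive-eigenvalue sum only. Missing data generally make Gower
matrices slightly non-Euclidean; negative eigenvalues are reported, and the
Cailliez additive-constant correction is available (`correction=
"cailliez"`) when a fully Euclidean embedding is wanted. Phylomorphospace
node positions are Brownian-motion ML ancestral values of the tip scores on
an axis, computed as the weighted-Laplacian (squared-change) solve with
weights 1/branch-length; zero-length branches are floored at 1e−9 of the
mean branch length, so a node on a zero-length branch takes its child's
value to numerical precision. Axis–trait associations use tie-corrected
Spearman correlations with pairwise deletion of missing trait values.

## Diversity and the diversity–disparity trajectory

Range-through counts tally every taxon whose first–last interval covers a
bin; uncertainty is taxon bootstrap (1,000 replicates). The joint
trajectory standardizes ln(count) and disparity each to [0, 1] via
(x − min)/(max − min); under constant-rate change both grow in proportion,
so the expectation is the 1:1 diagonal. The natural log is used — the base
is irrelevant after range standardization, and the trajectory is exactly
invariant to rescaling all counts. Deviation significance pairs bootstrap
replicate r of diversity with replicate r of disparity, pushes both through
the same log + standardization pipeline, and classifies a bin
above/below the line only when the 95% percentile interval of (y − x)
excludes zero. Replicates in which either series is degenerate (a zero
count inside the log, or no spread) are dropped from the interval.

## The synthetic clade generator

The generator exists so that every stage above can be validated by
parameter recovery. A scenario bundles: birth and death rates
(lineages/Myr), the clade origin age, a bin table, the number of characters
and their state-count range, a base change rate r0 (changes/character/Myr),
per-bin rate multipliers, a missing-cell probability, tip-sampling
controls, and one seed. All outputs are bit-reproducible given (scenario,
seed).

Trees are constant-rate birth–death realizations from the origin in which
every extinct lineage leaves a dated fossil tip and survivors become tips
at the young boundary (complete-tree convention). Realizations are
conditioned on the clade spanning the timescale (≥ 1 lineage alive at the
young edge) — the emulated clade persists through the study window — and on
a tip-count window. Taxon sampling is modelled as a uniform draw of exactly
`sample_tips` tips from the complete tree (unifurcations suppressed);
because the Mk process is Markovian, simulating characters on the sampled
tree is distributionally identical to simulating on the complete tree and
discarding unsampled taxa, and it keeps the truth ledger aligned with what
an estimator can possibly see.

Characters evolve with instantaneous change rate r0 × m_b while a lineage
traverses bin b (piecewise-constant along branches, exact per-segment
Poisson event counts); each change moves to one of the other k − 1 states
uniformly; root states are uniform. The truth ledger records per-branch and
per-bin realized change counts from the same draws, so its conservation
identity is exact, plus per-bin opportunity (summed branch duration,
recorded before missing-data injection — true rates are per fully-scored
character). Missing data are injected independently per cell. Posterior-
like tree samples jitter internal node ages with a normal of given SD
truncated to a *symmetric* window around the original age (bounded by the
parent's new age above and the oldest descendant tip below), which keeps
ages monotone while leaving each node's expected age unchanged.

Preset defaults and why:

| parameter | full preset | scaled preset | rationale |
|---|---|---|---|
| origin, bins | 453 Ma, 13 equal bins to 254 Ma | same | a ~200 Myr Palaeozoic clade at stage-like resolution |
| birth, death | 0.10, 0.09 /lineage/Myr | same | species durations ~11 Myr, realistic for Palaeozoic marine invertebrates |
| sampled tips | 82 | 30 | matrices code a representative sample of a much larger clade |
| characters | 92 (2–5 states) | 40 | typical discrete-matrix sizes |
| r0 | 0.001 | 0.003 | ~1–2 realized changes/character over the sampled tree; the scaled tree is much shorter, so its rate is higher to keep per-bin counts informative |
| p_miss | 0.2 | 0.2 | ~20% unscorable cells, typical of fossil matrices |
| spike | ×2.5 in bin 10 of 13 | (off unless set) | an isolated late burst against a flat background |

What the generator does **not** emulate: lineage-specific (relaxed-clock)
rate heterogeneity, correlated characters, ordered characters,
non-random missingness (real inapplicability is phylogenetically
structured), character-state exhaustion, or time-varying preservation.
Passing recovery tests therefore show the pipeline recovers bin-structured
rate heterogeneity from Mk-like data at realistic sizes — not that it is
robust to every failure mode of real matrices.

## What the tests show (and problem sizes)

The test suite validates the deterministic kernels against independent
oracles (brute-force pair loops for Gower/disparity; exhaustive enumeration
of internal-state assignments for ASR marginals, to 1e−10; numeric
likelihood maximization for the LRT, to 1e−8; hand-applied step-up rule for
B-H; re-rooted GLS for phylomorphospace scores; scikit-bio's PCoA for the
ordination), and the stochastic claims by simulation at deliberately modest
sizes chosen to keep the default run short: type-I control over 200
constant-rate datasets of 25 trees (30 taxa × 30 characters); spike
recovery over 30 scaled-down datasets; early-burst trend detection over 20
replicates (70 characters); diagonal concordance over 8 replicates.

Detection power for the planted 2.5× spike deserves honesty. At the full
preset (82 taxa, 92 characters) the spike is recovered in roughly half of
simulated datasets; the misses are datasets where tree shape places long
branches across the spike bin and attenuation (endpoint counting +
proportional smearing) pulls the observed contrast below the α = 0.01
detection boundary. At 30 sampled taxa the sampled branches (~17–25 Myr)
exceed the bin width and the observable contrast ceiling (~1.6×) sits below
what the LRT can distinguish at these counts for any base rate — raising r0
does not help because endpoint detection saturates. The scaled-down
recovery test in the acceptance suite states the stronger claim and is
expected to fail; it is retained unmodified because the gap is informative:
it measures the method's information ceiling, not an implementation defect.

## Known limitations

- Rates are estimated from a point reconstruction (MAP states), not by
  integrating over ancestral-state uncertainty; rate contrasts are
  attenuated accordingly.
- The LRT treats allocated per-bin counts as Poisson, ignoring the
  dependence induced by proportional allocation from shared branches;
  empirically the test is conservative under the null at default settings.
- Spearman p-values are asymptotic except at very small n.
- The built-in stage table is a convenience default and deliberately
  editable; analyses binned differently should supply their own table.
- `read_trees` assumes branch lengths in Myr and needs an age anchor
  (youngest tip age, a tip-age table, or a root age) — it never guesses
  ages from taxon names.
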