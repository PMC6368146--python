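# Methods

## The inference problem

Three lineages A, B, C radiated quickly; an outgroup O roots the triplet.
Gene trees estimated from many loci disagree about the triplet's resolution.
Two processes generate discordance:

* **Incomplete lineage sorting (ILS).** If the internal branch between the
  two speciation events is `t` coalescent units, a fraction `(2/3)·e^(−t)`
  of loci fail to coalesce on that branch and resolve randomly, giving each
  of the two *minority* topologies probability `(1/3)·e^(−t)`. ILS is
  symmetric: the two minority topologies are equally frequent in
  expectation, and their gene trees are *deep* (coalescences predate the
  older split).
* **Introgression.** A post-speciation pulse of gene flow inflates one
  specific minority topology, and the affected loci are *shallow*: the
  exchanging pair coalesces near the pulse time, after the splits.

The package quantifies discordance (topology frequencies, internode
certainty), tests the ILS symmetry expectation, and uses per-locus node
depths to decide which of two conflicting leading topologies is the
speciation history.

## Coalescent simulator

`simulate_gene_trees` draws genealogies from msprime under a species history
`(((A,B),C),O)` with split times `tau1 < tau2 < tau_out` in coalescent
units; all populations share one effective size (sizes are not separately
identifiable from the questions asked here, and no better information is
assumed). Introgression is modeled as the simplest pulse consistent with the
verbal argument: for each locus independently, with probability `gamma` the
recipient's lineage is relocated into the donor population at time
`t_gamma < tau1` (backwards in time) before standard coalescence. The
outgroup never participates. Direction is a parameter
(`donor_recipient`), not a fixed choice.

Alignments evolve site-independently along each gene tree under the
equal-rates (Jukes–Cantor) model; a branch of `t` coalescent units carries
`(theta/2)·t` expected substitutions per site, so two lineages that diverged
`tau` units ago are `theta·tau` apart in expectation. Terminal-repeat pairs
for LTR dating start identical and accumulate independent Poisson
substitution events at `mu` per site per year in each copy, which is exactly
the Jukes–Cantor process the dating correction inverts.

Seeding: every locus stream derives from `(seed, locus_index)` via
`numpy.random.SeedSequence`, so any subset of loci reproduces bit-for-bit
regardless of which other loci are generated.

Default generator values: `tau1=1`, `tau2=2`, `tau_out=5`, `t_gamma=0.5`,
`theta=0.02`, `seq_length=1500`. `theta=0.02` gives ingroup divergences of a
few percent and outgroup divergence ~15–20% — typical of within-family
plant nuclear loci and comfortably below distance saturation.
`seq_length=1500` matches an average coding locus. The introgression
*validation experiment* (tests and the worked example) instead uses
`tau2=5`: the internal branch is long enough that ILS contributes little
discordance, so the minority-topology excess and depth contrast are
attributable to the pulse. That choice was made once, from the power
analysis below, before any test was run.

What the generator does **not** emulate: recombination within loci, indels,
among-site rate variation, more than four taxa, gene-tree estimation error
(simulated trees are known exactly; bootstrap stratification is exercised
with user-supplied or assumed support values). A green end-to-end test
therefore establishes the correctness of the *statistical logic and code*,
not robustness to alignment/tree-estimation artifacts in real data.

## Masking filter

A window of `window_length=15` columns (sliding step 1) is masked in all
rows when it contains **more than** `max_mismatches=6` mismatch columns. A
mismatch is a column property: at least two distinct characters among the
non-gap, non-masked residues ("column" mode; a per-window tally of differing
row pairs is available as "pairwise" mode for sensitivity analysis). Gaps
never count as mismatches and are themselves always replaced by the mask
character. Windows are evaluated on the input state, then the union of bad
windows is masked, which makes the operation idempotent. An alignment is
dropped when **more than** `drop_fraction=0.20` of its columns were masked
by windows (gap replacement does not count). Both thresholds are strict
inequalities.

## Concordance and internode certainty

Gene trees are read as unrooted; the triplet resolution is the unique 2-2
split `{X,Y} | {Z,O}` (equivalent to rooting on O). With four tips a
polytomy is the only unresolved case. Larger trees are reduced to four
representative tips through a role → tip-label map.

Mean bootstrap is the arithmetic mean of all numeric internal-branch
supports; a tree is retained at a cutoff when its mean strictly exceeds it
(cutoffs 50…90 by default). IC uses only the two most prevalent conflicting
counts, `IC = 1 − H(p)` with `H` the binary entropy of `n1/(n1+n2)`; a
three-way variant normalized by `log2(3)` is available
(`internode_certainty_full`). Counts are accepted in either order.

## Node-depth estimators

For a locus resolved as (X,Y),Z:

* `T1 = d(X,Y)/2` — depth of the cherry node,
* `T2 = (d(X,Z) + d(Y,Z))/4` — depth of the triplet node,

with `d` the Jukes–Cantor corrected divergence (raw divergence optionally).
Site filtering (`DepthConfig.site_filter`):

* `"biallelic"` (default): only biallelic variable columns count as
  differences; columns with three or four states — dominated by alignment
  error and multiple hits — are ignored. The denominator is all columns in
  which every taxon has an unambiguous base.
* `"informative"`: strictly parsimony-informative biallelic columns (2+2
  patterns), numerator *and* denominator. This is a faithful reading of
  "depths from biallelic informative sites" but is degenerate for cherry
  depths: a cherry pair almost never differs at a 2+2 column (such
  differences require homoplasy), and cross-pair divergences conditional on
  informative columns approach 1 and exceed the Jukes–Cantor bound of 0.75.
  It is retained for sensitivity analysis, not recommended as default.
* `"all"`: all variable columns count.

`min_sites=10` (configurable) excludes loci whose filtered site count is too
small for a stable estimate; excluded loci carry a machine-readable reason
(`too_few_sites`, `saturated`).

## Verdict rule

`compare_depth_classes` bootstraps loci within each topology class
(percentile intervals, 95% by default, seeded) for the difference in mean T1
and mean T2. The species topology is assigned to the deeper class when the
**T1** interval excludes zero (`require="t1"`, default); otherwise the
verdict is ambiguous. T2 is always reported, and `require="both"` demands
both intervals agree.

T1 is primary by design: under an instantaneous pulse with
`t_gamma < tau1` and a shared population size, the donor-derived lineage
still joins the third taxon *above* the deeper split, so the T2
distributions of the two classes are nearly identical (their means differ
only through each class's ILS fraction, and that compositional effect can
even point the "wrong" way, since the minority class carries relatively more
deep ILS loci). The discriminating signal is concentrated in T1. Requiring
T2 agreement would therefore reject true introgression histories of this
kind; it is offered for histories where both nodes are expected to shift
(e.g. gene flow into the lineage that later splits).

Power analysis used to fix the validation design (before testing): with
`gamma=0.3`, `t_gamma=0.5`, 500 loci, `theta=0.02`, L=1500, the expected
T1 contrast between the AB|C and AC|B classes grows with the internal
branch (less ILS dilution); at `tau2 − tau1 = 4` the standardized difference
is ≈ 4.5, giving per-replicate detection probability ≥ 0.99 at a 95%
interval — sufficient for a ≥95%-of-replicates recovery requirement. At
`tau2 − tau1 = 1` the same design is underpowered (z ≈ 1.5), which is a
property of the inference problem (ILS swamps the contrast), not of the
implementation.

## LTR dating

Terminal repeats are globally aligned (biopython `PairwiseAligner`;
match 2, mismatch −1, gap open −4, extend −0.5; the first optimal alignment
in biopython's deterministic order is used). Raw divergence is mismatches
over non-gap, unambiguous columns; elements with fewer than `min_length=100`
comparable columns are skipped with a reason. K is the Jukes–Cantor
correction of the raw divergence (selectable "raw"); divergence at or beyond
0.75 marks the element undatable rather than producing an infinite age.
`T = K/(2μ)`, `μ = 1.3e-8`/site/year by default. Histograms use half-open
`[lo, hi)` bins of 0.5 Myr from zero; elements with an empty superfamily
label are grouped as "unknown"; undatable elements are counted separately.
Round-trip validation on simulated cohorts passes `prealigned=True` because
the generator produces no indels (the aligner is exercised separately);
coordinate input is 1-based inclusive, following common annotation output.

## Pipeline and determinism

`run_introgression_analysis` chains masking, classification, concordance,
and the depth test between the two most prevalent conflicting classes at the
lowest cutoff (overridable). Every dropped or skipped locus appears exactly
once in `exclusions.tsv` with a reason code; `manifest.json` records the
config, its SHA-256, the seed and per-stage locus counts. Outputs contain no
timestamps, so a config + seed reruns to byte-identical files. Simulated
trees carry no bootstrap values; `assume_support` supplies their mean
support for cutoff stratification.

## Known limitations

* The pulse model is deliberately minimal: no continuous migration, no
  multiple pulses, one shared population size. Asymmetries caused by
  population-size variation (which can also skew minority-topology
  frequencies) are outside the model.
* Node depths assume a molecular clock across the four taxa; an optional
  outgroup-based rate normalization is not implemented.
* The depth test compares exactly two classes; three-way comparisons must be
  run pairwise.
* Whole-tree certainty measures (beyond the single focal internode) are out
  of scope.
* Real-data bootstrap stratification depends on supports produced by the
  user's tree-inference tool; the package does not estimate trees.
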