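# introdepth

Comparative-phylogenomic toolkit for a recurring question in rapid
radiations: when three lineages (A, B, C) show massive gene-tree
discordance, is the conflict explained by incomplete lineage sorting (ILS)
alone, or did introgression follow speciation — and which of the conflicting
topologies is the true species branching order?

The package provides four analysis stages plus a seeded synthetic-data
generator so the whole chain can be validated end to end with known ground
truth:

1. **Alignment masking** (`introdepth.mask`) — a sliding-window quality
   filter: any 15-bp window with more than six mismatch columns (gaps and
   masked characters do not count) is masked to `N` in all rows; an
   alignment with more than 20% of its columns masked is dropped.
2. **Concordance** (`introdepth.concordance`) — classifies each gene tree's
   resolution of the triplet {A, B, C} rooted by an outgroup O, stratifies
   by mean internal-branch bootstrap support, and computes internode
   certainty from the two most prevalent conflicting resolutions:
   `IC = 1 + p·log2(p) + q·log2(q)` with `p = n1/(n1+n2)`. IC is 1 with no
   conflict and 0 when the two leading topologies are equally frequent.
   Under ILS alone the two minority topologies are expected at equal
   frequency `(1/3)·exp(−t)` for an internal branch of `t` coalescent units;
   an excess of one minority topology implicates gene flow.
3. **Node-depth test** (`introdepth.depth`) — per-locus divergence depths of
   the two internal nodes of the rooted triplet, `T1 = d(X,Y)/2` for the
   cherry pair and `T2 = (d(X,Z)+d(Y,Z))/4`, with `d` a Jukes–Cantor
   corrected distance over filtered biallelic sites. Loci whose topology
   reflects speciation are deeper on average than loci whose topology was
   produced by introgression; a bootstrap over loci on the difference in
   mean T1 between the two leading topology classes decides which class is
   the species tree (or returns "ambiguous").
4. **LTR insertion dating** (`introdepth.ltr`) — the terminal repeats of an
   LTR retrotransposon are identical at insertion, so their corrected
   divergence K dates the element: `T = K / (2μ)` with
   `μ = 1.3 × 10⁻⁸` substitutions/site/year by default; ages are summarized
   as per-superfamily histograms.

`introdepth.simulate` draws gene trees from a 3-taxon + outgroup
multispecies coalescent (via msprime) with an optional instantaneous
introgression pulse, evolves gap-free alignments along them under the
equal-rates substitution model, and generates terminal-repeat pairs of known
age. `introdepth.pipeline` chains mask → classify → concordance → depth test
from one JSON config with a deterministic manifest and exclusion log.

## Worked example

Simulate a 300-locus dataset with species tree ((A,B),C), a 30% pulse of
C→A introgression, and run the full pipeline:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

prints (seed 1):

```
concordance at lowest cutoff:
  n AB|C=179  AC|B=92  BC|A=1  IC=0.0757
depth-test verdict: species topology = AB|C
  mean T1 {'AB|C': 0.014682923179035553, 'AC|B': 0.011049886760293164}
  mean T2 {'AB|C': 0.04545783390898658, 'AC|B': 0.046155477275421575}
LTR round trip: true age 1.0 Myr, mean estimate 1.003 Myr
```

Reading this: the two leading topologies AB|C and AC|B are both common
(IC near zero — heavy conflict), but the minority topologies are wildly
asymmetric (92 vs 1), which ILS cannot produce; and the AC|B class is
significantly *shallower* at T1 (0.011 vs 0.015 substitutions/site), so the
depth test correctly identifies AB|C as the speciation topology and AC|B as
introgression-driven — matching the simulation's ground truth. The LTR
cohort simulated at 1.0 Myr is re-dated at 1.003 Myr.

The same stages are available as CLI subcommands
(`introdepth simulate | mask | concord | depthtest | ltrdate | run`).

`scripts/acceptance.py` regenerates the synthetic dataset from the given
seed, reruns the whole pipeline and the LTR round trip from scratch, and
writes its results JSON to `--out`.

See `docs/methods.md` for the models, estimators, defaults and their
rationale, and known limitations.
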