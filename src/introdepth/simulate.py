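"""Synthetic data with known ground truth.

Three generators, all seeded and bit-reproducible:

* :func:`simulate_gene_trees` — gene trees for a species history
  ``(((A,B),C),O)`` under the multispecies coalescent, with an optional
  instantaneous introgression pulse between two ingroup lineages. Genealogies
  are simulated with msprime; times are in coalescent units (all populations
  share one effective size).
* :func:`simulate_alignments` — gap-free nucleotide alignments evolved
  site-independently along each gene tree under the one-parameter
  (equal-rates) substitution model.
* :func:`simulate_ltr_pairs` — pairs of terminal-repeat sequences that start
  identical and diverge independently for a known number of years at a known
  per-site yearly rate, emulating the mutational history that LTR insertion
  dating inverts.

Seeding: one master seed; the stream for locus ``i`` is derived from
``(seed, i)`` via :class:`numpy.random.SeedSequence`, so any subset of loci
is reproducible independently of the rest.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import msprime
import numpy as np
import pandas as pd

from .distances import jc_identity_prob
from .triplet import INGROUP, ROLES, TripletTopology

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated species history and mutation process.

    Times are in coalescent units (one unit = N generations for the shared
    haploid effective size N). ``theta`` is the population-scaled mutation
    rate per site: a branch of length ``t`` coalescent units accumulates
    ``(theta / 2) * t`` expected substitutions per site, so two sequences
    whose lineages diverged ``tau`` units ago have expected divergence
    ``theta * tau``.
    """

    tau1: float = 1.0          # (A,B) split
    tau2: float = 2.0          # ((A,B),C) split
    tau_out: float = 5.0       # outgroup split
    gamma: float = 0.0         # introgression probability per lineage
    t_gamma: float = 0.5       # pulse time, 0 < t_gamma < tau1
    donor_recipient: tuple[str, str] = ("C", "A")
    n_loci: int = 100
    seq_length: int = 1500
    theta: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.t_gamma < self.tau1 < self.tau2 < self.tau_out):
            raise ValueError(
                "times must satisfy 0 < t_gamma < tau1 < tau2 < tau_out; got "
                f"t_gamma={self.t_gamma}, tau1={self.tau1}, tau2={self.tau2}, "
                f"tau_out={self.tau_out}"
            )
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1]; got {self.gamma}")
        if self.n_loci < 1:
            raise ValueError(f"n_loci must be >= 1; got {self.n_loci}")
        if self.seq_length < 1:
            raise ValueError(f"seq_length must be >= 1; got {self.seq_length}")
        if self.theta <= 0:
            raise ValueError(f"theta must be > 0; got {self.theta}")
        donor, recipient = self.donor_recipient
        if donor not in INGROUP or recipient not in INGROUP or donor == recipient:
            raise ValueError(
                f"donor_recipient must be an ordered pair of distinct taxa from "
                f"{INGROUP}; got {self.donor_recipient}"
            )
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError(f"seed must be an integer; got {self.seed!r}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["donor_recipient"] = list(self.donor_recipient)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        if "donor_recipient" in d:
            d["donor_recipient"] = tuple(d["donor_recipient"])
        return cls(**d)


@dataclasses.dataclass
class SimulatedLocus:
    """One simulated locus: rooted gene tree, truth labels, and (optionally)
    its alignment.

    ``edges`` stores the tree as ``(parent, child, branch_length)`` triples in
    a fixed preorder (branch lengths in coalescent units); ``tip_labels`` maps
    node index to role name for the four tips. The newick string carries the
    same tree with branch lengths.
    """

    locus_id: str
    index: int
    newick: str
    topology_truth: TripletTopology
    introgressed: bool
    tree_height: float
    edges: tuple[tuple[int, int, float], ...]
    root: int
    tip_labels: dict[int, str]
    alignment: dict[str, str] | None = None


@dataclasses.dataclass
class LTRPairTruth:
    """A simulated 5'/3' terminal-repeat pair with known insertion age."""

    element_id: str
    seq5: str
    seq3: str
    true_age_years: float
    mu_per_site_per_year: float


def _demography(config: SimulationConfig, introgressed: bool) -> msprime.Demography:
    dem = msprime.Demography()
    for name in ("A", "B", "C", "O", "AB", "ABC", "ROOT"):
        dem.add_population(name=name, initial_size=1.0)
    if introgressed:
        donor, recipient = config.donor_recipient
        # Backwards in time the recipient's lineage moves into the donor
        # population at the pulse time.
        dem.add_mass_migration(
            time=config.t_gamma, source=recipient, dest=donor, proportion=1.0
        )
    dem.add_population_split(time=config.tau1, derived=["A", "B"], ancestral="AB")
    dem.add_population_split(time=config.tau2, derived=["AB", "C"], ancestral="ABC")
    dem.add_population_split(time=config.tau_out, derived=["ABC", "O"], ancestral="ROOT")
    return dem


def _locus_streams(config: SimulationConfig, index: int):
    """Two independent child streams for locus ``index``: (ancestry, sequence)."""
    ss = np.random.SeedSequence(entropy=int(config.seed), spawn_key=(index,))
    return ss.spawn(2)


def _extract_tree(ts, labels: dict[int, str]):
    """Preorder edge list, newick string, truth topology and height."""
    tree = ts.first()
    root = tree.root
    edges: list[tuple[int, int, float]] = []
    for u in tree.nodes(order="preorder"):
        if u != root:
            edges.append((tree.parent(u), u, tree.branch_length(u)))

    def _newick(u: int) -> str:
        if tree.is_leaf(u):
            return labels[u]
        parts = ",".join(
            f"{_newick(v)}:{tree.branch_length(v):.10g}" for v in tree.children(u)
        )
        return f"({parts})"

    by_label = {lab: node for node, lab in labels.items()}
    pairs = [("A", "B"), ("A", "C"), ("B", "C")]
    tmrcas = {p: tree.tmrca(by_label[p[0]], by_label[p[1]]) for p in pairs}
    cherry = min(tmrcas, key=tmrcas.get)
    topo = TripletTopology.from_cherry(*cherry)
    return tuple(edges), root, _newick(root) + ";", topo, tree.time(root)


def simulate_gene_trees(config: SimulationConfig) -> list[SimulatedLocus]:
    """Draw ``config.n_loci`` gene trees from the coalescent with an optional
    introgression pulse.

    For each locus, with probability ``gamma`` the recipient lineage is
    relocated to the donor population at ``t_gamma`` before coalescence
    proceeds within and above populations. The returned loci carry no
    alignments; pass them to :func:`simulate_alignments`.
    """
    demographies = {
        False: _demography(config, introgressed=False),
        True: _demography(config, introgressed=True),
    }
    samples = [
        msprime.SampleSet(1, population=p, ploidy=1) for p in ("A", "B", "C", "O")
    ]
    loci = []
    width = max(4, len(str(config.n_loci - 1)))
    for i in range(config.n_loci):
        anc_ss, _ = _locus_streams(config, i)
        rng = np.random.default_rng(anc_ss)
        introgressed = bool(config.gamma > 0 and rng.random() < config.gamma)
        msp_seed = int(rng.integers(1, 2**31 - 1))
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=demographies[introgressed],
            ploidy=1,
            random_seed=msp_seed,
        )
        labels = {int(u): lab for u, lab in zip(ts.samples(), ("A", "B", "C", "O"))}
        edges, root, newick, topo, height = _extract_tree(ts, labels)
        loci.append(
            SimulatedLocus(
                locus_id=f"locus_{i:0{width}d}",
                index=i,
                newick=newick,
                topology_truth=topo,
                introgressed=introgressed,
                tree_height=height,
                edges=edges,
                root=root,
                tip_labels=labels,
            )
        )
    return loci


def _evolve_along(locus: SimulatedLocus, theta: float, length: int, rng) -> dict[str, str]:
    """Site-independent equal-rates evolution along the locus tree.

    A branch of ``t`` coalescent units applies ``d = (theta/2) t`` expected
    substitutions per site; each changed site moves to one of the other three
    bases uniformly.
    """
    states: dict[int, np.ndarray] = {locus.root: rng.integers(0, 4, size=length)}
    for parent, child, bl in locus.edges:
        d = 0.5 * theta * bl
        p_same = jc_identity_prob(d)
        s = states[parent].copy()
        changed = rng.random(length) >= p_same
        n = int(changed.sum())
        if n:
            s[changed] = (s[changed] + rng.integers(1, 4, size=n)) % 4
        states[child] = s
    return {
        lab: _BASES[states[node]].tobytes().decode()
        for node, lab in sorted(locus.tip_labels.items())
    }


def simulate_alignments(
    loci: Sequence[SimulatedLocus], config: SimulationConfig
) -> list[SimulatedLocus]:
    """Attach a simulated gap-free alignment (A, B, C, O) to each locus.

    Loci are modified in place and returned. The per-locus random stream is
    derived from ``(config.seed, locus.index)``, independent of list order.
    """
    if len(loci) == 0:
        raise ValueError("empty locus list")
    for locus in loci:
        _, seq_ss = _locus_streams(config, locus.index)
        rng = np.random.default_rng(seq_ss)
        locus.alignment = _evolve_along(locus, config.theta, config.seq_length, rng)
    return list(loci)


def simulate_ltr_pairs(
    n: int,
    true_age_years: float,
    mu: float = 1.3e-8,
    length: int = 5000,
    seed: int = 0,
) -> list[LTRPairTruth]:
    """Simulate ``n`` terminal-repeat pairs of a known insertion age.

    Each pair starts as one random sequence (the element at insertion, when
    its two terminal repeats are identical); each copy then accumulates
    Poisson-distributed substitution events independently for
    ``true_age_years`` at ``mu`` events per site per year, every event moving
    the site to one of the other three bases uniformly. No indels.
    """
    if true_age_years < 0:
        raise ValueError(f"true_age_years must be >= 0; got {true_age_years}")
    if mu <= 0:
        raise ValueError(f"mu must be > 0; got {mu}")
    if length < 1:
        raise ValueError(f"length must be >= 1; got {length}")
    pairs = []
    lam = mu * true_age_years
    width = max(4, len(str(max(n - 1, 0))))
    for i in range(n):
        ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(i,))
        rng = np.random.default_rng(ss)
        ancestral = rng.integers(0, 4, size=length)
        copies = []
        for _ in range(2):
            counts = rng.poisson(lam, size=length)
            s = ancestral.copy()
            for k in range(int(counts.max()) if length else 0):
                hit = counts > k
                m = int(hit.sum())
                s[hit] = (s[hit] + rng.integers(1, 4, size=m)) % 4
            copies.append(_BASES[s].tobytes().decode())
        pairs.append(
            LTRPairTruth(
                element_id=f"elem_{i:0{width}d}",
                seq5=copies[0],
                seq3=copies[1],
                true_age_years=float(true_age_years),
                mu_per_site_per_year=float(mu),
            )
        )
    return pairs


def write_dataset(loci: Sequence[SimulatedLocus], outdir: str | Path) -> None:
    """Write per-locus FASTA alignments, newick trees and a truth table.

    Layout: ``<outdir>/alignments/<locus_id>.fasta``,
    ``<outdir>/trees/<locus_id>.nwk`` and ``<outdir>/truth.tsv`` with columns
    locus_id, topology_truth, introgressed, tree_height.
    """
    outdir = Path(outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    (outdir / "trees").mkdir(parents=True, exist_ok=True)
    rows = []
    for locus in loci:
        (outdir / "trees" / f"{locus.locus_id}.nwk").write_text(locus.newick + "\n")
        if locus.alignment is not None:
            lines = []
            for role in ROLES:
                lines.append(f">{role}")
                lines.append(locus.alignment[role])
            (outdir / "alignments" / f"{locus.locus_id}.fasta").write_text(
                "\n".join(lines) + "\n"
            )
        rows.append(
            {
                "locus_id": locus.locus_id,
                "topology_truth": locus.topology_truth.value,
                "introgressed": locus.introgressed,
                "tree_height": locus.tree_height,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)
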