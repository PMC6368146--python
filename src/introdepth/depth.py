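"""Node-depth (T1/T2) test separating introgression from ILS.

For a gene tree resolving the triplet as (X,Y),Z the two internal nodes are
the cherry ancestor (depth T1) and the triplet ancestor (depth T2). Under a
molecular clock, loci whose topology reflects the speciation order have
deeper node depths on average than loci whose topology was created by
post-speciation gene flow, because introgression replaces one lineage with a
much younger copy. Incomplete lineage sorting alone produces the two
minority topologies at equal frequency and equal mean depth — so comparing
the per-class means of T1 (and T2) distinguishes the two processes.

Depths are clock-based pairwise estimates on a filtered site set:

    T1 = d(X, Y) / 2,      T2 = (d(X, Z) + d(Y, Z)) / 4,

where ``d`` is a corrected divergence (one-parameter correction by default).
By default only biallelic variable columns contribute differences — columns
with three or four states are treated as unreliable (alignment error or
recurrent mutation) and ignored — while the denominator is all columns where
every taxon has an unambiguous base. A stricter parsimony-informative filter
and an unfiltered mode are available (see :class:`DepthConfig`).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import jc_correct
from .triplet import TripletTopology

_VALID = np.frombuffer(b"ACGT", dtype="S1")


class DepthEstimationError(ValueError):
    """Locus cannot yield a depth estimate; ``reason`` is machine-readable."""

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


@dataclasses.dataclass(frozen=True)
class DepthConfig:
    min_sites: int = 10
    site_filter: str = "biallelic"  # "biallelic" | "informative" | "all"
    correction: str = "jc"          # "jc" | "raw"

    def __post_init__(self) -> None:
        if self.min_sites < 0:
            raise ValueError("min_sites must be >= 0")
        if self.site_filter not in ("biallelic", "informative", "all"):
            raise ValueError(f"unknown site_filter {self.site_filter!r}")
        if self.correction not in ("jc", "raw"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclasses.dataclass
class DepthEstimate:
    locus_id: str
    topology: TripletTopology
    t1: float
    t2: float
    n_sites_used: int


@dataclasses.dataclass
class IntrogressionVerdict:
    """Outcome of comparing node depths between two topology classes."""

    class1: TripletTopology
    class2: TripletTopology
    n1: int
    n2: int
    mean_t1: dict[str, float]
    mean_t2: dict[str, float]
    diff_t1: float                       # class1 - class2
    diff_t2: float
    ci_t1: tuple[float, float]
    ci_t2: tuple[float, float]
    inferred_species_topology: TripletTopology | None
    inferred_introgressed_topology: TripletTopology | None
    ambiguous: bool
    ci_level: float
    n_boot: int
    seed: int

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["class1"] = self.class1.value
        d["class2"] = self.class2.value
        d["inferred_species_topology"] = (
            None if self.inferred_species_topology is None
            else self.inferred_species_topology.value
        )
        d["inferred_introgressed_topology"] = (
            None if self.inferred_introgressed_topology is None
            else self.inferred_introgressed_topology.value
        )
        d["ci_t1"] = list(self.ci_t1)
        d["ci_t2"] = list(self.ci_t2)
        return json.dumps(d, indent=2, sort_keys=True)


def _matrix(alignment: Mapping[str, str]) -> np.ndarray:
    for role in ("A", "B", "C", "O"):
        if role not in alignment:
            raise ValueError(f"alignment is missing taxon {role!r}")
    rows = [alignment[r] for r in ("A", "B", "C", "O")]
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged alignment")
    return np.frombuffer("".join(rows).upper().encode(), dtype="S1").reshape(4, -1)


def _site_classes(mat: np.ndarray):
    """Per-column validity and allele-count classification for 4 taxa."""
    valid = np.zeros(mat.shape[1], dtype=bool)
    counts = np.zeros((4, mat.shape[1]), dtype=np.int8)
    for k, base in enumerate(_VALID):
        eq = mat == base
        counts[k] = eq.sum(axis=0)
    valid = counts.sum(axis=0) == 4  # every row an unambiguous base
    present = counts > 0
    n_alleles = present.sum(axis=0)
    biallelic = valid & (n_alleles == 2)
    informative = biallelic & ((counts == 1).sum(axis=0) == 0)  # 2+2 pattern
    variable = valid & (n_alleles >= 2)
    return valid, variable, biallelic, informative


def biallelic_informative_sites(alignment: Mapping[str, str]) -> np.ndarray:
    """Column indices with exactly two states, each carried by >= 2 taxa.

    Columns containing gaps, mask characters or ambiguity codes in any row
    are excluded. These are the parsimony-informative biallelic patterns of
    a four-taxon alignment (2+2 allele configurations).
    """
    mat = _matrix(alignment)
    _, _, _, informative = _site_classes(mat)
    return np.flatnonzero(informative)


def estimate_depths(
    alignment: Mapping[str, str],
    topology: TripletTopology,
    config: DepthConfig = DepthConfig(),
    locus_id: str = "",
) -> DepthEstimate:
    """Clock-based T1/T2 estimate for one locus given its triplet topology.

    Raises :class:`DepthEstimationError` (reason ``too_few_sites`` or
    ``saturated``) when the locus cannot be used; callers running many loci
    should catch it and log the exclusion.
    """
    if topology is TripletTopology.UNRESOLVED:
        raise ValueError("cannot estimate depths for an UNRESOLVED topology")
    mat = _matrix(alignment)
    valid, variable, biallelic, informative = _site_classes(mat)
    if config.site_filter == "informative":
        used, denom_mask = informative, informative
    elif config.site_filter == "biallelic":
        used, denom_mask = biallelic, valid
    else:
        used, denom_mask = variable, valid
    n_used = int(used.sum())
    denom = int(denom_mask.sum())
    if n_used < config.min_sites or denom == 0:
        raise DepthEstimationError(
            "too_few_sites",
            f"locus {locus_id or '<anon>'}: {n_used} usable sites "
            f"< min_sites={config.min_sites}",
        )

    roles = {"A": 0, "B": 1, "C": 2, "O": 3}
    x, y = (roles[r] for r in topology.cherry)
    z = roles[topology.odd_taxon]

    def dist(i: int, j: int) -> float:
        p = float((used & (mat[i] != mat[j])).sum()) / denom
        if config.correction == "raw":
            return p
        d = jc_correct(p)
        if np.isnan(d):
            raise DepthEstimationError(
                "saturated",
                f"locus {locus_id or '<anon>'}: divergence {p:.3f} is beyond "
                "the one-parameter correction bound (0.75)",
            )
        return d

    t1 = dist(x, y) / 2.0
    t2 = (dist(x, z) + dist(y, z)) / 4.0
    return DepthEstimate(
        locus_id=locus_id,
        topology=topology,
        t1=t1,
        t2=t2,
        n_sites_used=n_used,
    )


def compare_depth_classes(
    depths: Sequence[DepthEstimate],
    class1: TripletTopology,
    class2: TripletTopology,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    require: str = "t1",
) -> IntrogressionVerdict:
    """Bootstrap the difference in mean T1/T2 between two topology classes.

    Nonparametric resampling over loci (within each class) yields percentile
    confidence intervals for the differences of means. The species topology
    is assigned to the deeper class when the T1 interval excludes zero
    (``require="t1"``, default — T1 carries the introgression signal under
    an instantaneous-pulse model); ``require="both"`` additionally demands
    that the T2 interval excludes zero on the same side. Otherwise the
    verdict is ambiguous.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if require not in ("t1", "both"):
        raise ValueError(f"unknown require mode {require!r}")
    g1 = [d for d in depths if d.topology is class1]
    g2 = [d for d in depths if d.topology is class2]
    for name, grp in ((class1, g1), (class2, g2)):
        if not grp:
            raise ValueError(f"no depth estimates in class {name.value}")
    a1 = np.array([[d.t1, d.t2] for d in g1])
    a2 = np.array([[d.t1, d.t2] for d in g2])

    rng = np.random.default_rng(seed)
    n1, n2 = len(g1), len(g2)
    idx1 = rng.integers(0, n1, size=(n_boot, n1))
    idx2 = rng.integers(0, n2, size=(n_boot, n2))
    boot_diff = a1[idx1].mean(axis=1) - a2[idx2].mean(axis=1)
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    ci = np.quantile(boot_diff, [lo_q, hi_q], axis=0)
    ci_t1 = (float(ci[0, 0]), float(ci[1, 0]))
    ci_t2 = (float(ci[0, 1]), float(ci[1, 1]))

    def _side(interval: tuple[float, float]) -> int:
        lo, hi = interval
        if lo > 0:
            return 1
        if hi < 0:
            return -1
        return 0

    s1, s2 = _side(ci_t1), _side(ci_t2)
    species = None
    if require == "t1":
        decided = s1 != 0
    else:
        decided = s1 != 0 and s2 == s1
    if decided:
        species = class1 if s1 > 0 else class2
    introgressed = None
    if species is not None:
        introgressed = class2 if species is class1 else class1

    return IntrogressionVerdict(
        class1=class1,
        class2=class2,
        n1=n1,
        n2=n2,
        mean_t1={class1.value: float(a1[:, 0].mean()), class2.value: float(a2[:, 0].mean())},
        mean_t2={class1.value: float(a1[:, 1].mean()), class2.value: float(a2[:, 1].mean())},
        diff_t1=float(a1[:, 0].mean() - a2[:, 0].mean()),
        diff_t2=float(a1[:, 1].mean() - a2[:, 1].mean()),
        ci_t1=ci_t1,
        ci_t2=ci_t2,
        inferred_species_topology=species,
        inferred_introgressed_topology=introgressed,
        ambiguous=species is None,
        ci_level=ci_level,
        n_boot=n_boot,
        seed=seed,
    )


def depths_to_tsv(depths: Sequence[DepthEstimate], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "locus_id": d.locus_id,
                "topology": d.topology.value,
                "t1": d.t1,
                "t2": d.t2,
                "n_sites_used": d.n_sites_used,
            }
            for d in depths
        ],
        columns=["locus_id", "topology", "t1", "t2", "n_sites_used"],
    ).to_csv(path, sep="\t", index=False)
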