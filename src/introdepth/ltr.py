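"""LTR retrotransposon insertion-age dating.

At insertion the two long terminal repeats of an LTR retrotransposon are
identical; they then diverge neutrally. Aligning the 5' and 3' repeats of a
full-length element and correcting their divergence K therefore dates the
insertion:

    T = K / (2 * mu),

with mu the substitution rate per site per year (default 1.3e-8, a standard
plant nuclear rate). The factor 2 counts the two independently evolving
copies. Detection of full-length elements is upstream of this module; inputs
are either paired repeat sequences or coordinates into a genome FASTA.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

from .distances import SATURATION_BOUND, jc_correct
from .simulate import LTRPairTruth

DEFAULT_MU = 1.3e-8
IUPAC = set("ACGTURYSWKMBDHVN")


class ElementSkipped(ValueError):
    """Element cannot be dated; ``reason`` is machine-readable."""

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


@dataclasses.dataclass
class LTRAgeEstimate:
    element_id: str
    raw_divergence: float
    k: float                    # corrected divergence, substitutions/site
    mu: float
    t_years: float              # k / (2 mu); nan when undatable
    aligned_length: int         # non-gap columns compared
    undatable: bool = False
    superfamily: str = "unknown"


@dataclasses.dataclass
class AgeDistribution:
    """Fixed-width insertion-age histogram, per superfamily."""

    bin_edges: np.ndarray                 # years; half-open [lo, hi) bins
    counts: dict[str, np.ndarray]
    n_undatable: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fam in sorted(self.counts):
            for i in range(len(self.bin_edges) - 1):
                rows.append(
                    {
                        "superfamily": fam,
                        "bin_start_years": float(self.bin_edges[i]),
                        "bin_end_years": float(self.bin_edges[i + 1]),
                        "count": int(self.counts[fam][i]),
                    }
                )
        return pd.DataFrame(
            rows, columns=["superfamily", "bin_start_years", "bin_end_years", "count"]
        )


def _check_nucleotide(seq: str, name: str) -> str:
    s = seq.upper()
    bad = set(s) - IUPAC
    if bad:
        raise ValueError(f"{name} contains non-IUPAC characters: {sorted(bad)}")
    if not s:
        raise ValueError(f"{name} is empty")
    return s


def align_terminal_repeats(
    seq5: str,
    seq3: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -0.5,
) -> tuple[str, str]:
    """Global pairwise alignment of the two terminal repeats.

    Returns the two gapped rows. The first optimal alignment in biopython's
    deterministic enumeration order is used, which prefers matches over
    substitutions over gaps under the default scores.
    """
    s5 = _check_nucleotide(seq5, "seq5")
    s3 = _check_nucleotide(seq3, "seq3")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    alignment = aligner.align(s5, s3)[0]
    return str(alignment[0]), str(alignment[1])


def divergence_from_alignment(row5: str, row3: str) -> tuple[float, int]:
    """Raw mismatch proportion over non-gap, unambiguous aligned columns."""
    a = np.frombuffer(row5.upper().encode(), dtype="S1")
    b = np.frombuffer(row3.upper().encode(), dtype="S1")
    if a.shape != b.shape:
        raise ValueError("aligned rows differ in length")
    acgt = np.frombuffer(b"ACGT", dtype="S1")
    ok = np.isin(a, acgt) & np.isin(b, acgt)
    n = int(ok.sum())
    if n == 0:
        return 0.0, 0
    mism = int((ok & (a != b)).sum())
    return mism / n, n


def estimate_insertion_age(
    pair: "LTRPairTruth | tuple[str, str]",
    mu: float = DEFAULT_MU,
    correction: str = "jc",
    min_length: int = 100,
    element_id: str = "",
    superfamily: str = "",
    prealigned: bool = False,
) -> LTRAgeEstimate:
    """Date one element from its terminal-repeat pair.

    ``pair`` is an (seq5, seq3) tuple or an :class:`LTRPairTruth`. Unless
    ``prealigned``, the repeats are globally aligned first. Raises
    :class:`ElementSkipped` (reason ``too_short``) if fewer than
    ``min_length`` columns are comparable; saturated divergence (beyond the
    correction's validity bound) marks the element undatable rather than
    raising.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if correction not in ("jc", "raw"):
        raise ValueError(f"unknown correction {correction!r}")
    if isinstance(pair, LTRPairTruth):
        seq5, seq3 = pair.seq5, pair.seq3
        element_id = element_id or pair.element_id
    else:
        seq5, seq3 = pair
    if prealigned:
        row5, row3 = seq5, seq3
    else:
        row5, row3 = align_terminal_repeats(seq5, seq3)
    p, n = divergence_from_alignment(row5, row3)
    if n < min_length:
        raise ElementSkipped(
            "too_short",
            f"element {element_id or '<anon>'}: aligned overlap {n} < {min_length}",
        )
    undatable = False
    if correction == "raw":
        k = p
    else:
        if p >= SATURATION_BOUND:
            undatable = True
            k = float("nan")
        else:
            k = jc_correct(p)
    t_years = k / (2.0 * mu) if not undatable else float("nan")
    return LTRAgeEstimate(
        element_id=element_id,
        raw_divergence=p,
        k=k,
        mu=mu,
        t_years=t_years,
        aligned_length=n,
        undatable=undatable,
        superfamily=superfamily.strip() or "unknown",
    )


def age_histogram(
    estimates: Sequence[LTRAgeEstimate],
    bin_width_years: float = 5e5,
    by_superfamily: bool = True,
) -> AgeDistribution:
    """Half-open fixed-width histogram of insertion ages starting at 0 years.

    Undatable elements are excluded from the bins and counted separately.
    """
    if bin_width_years <= 0:
        raise ValueError("bin_width_years must be > 0")
    if not estimates:
        raise ValueError("no estimates supplied")
    datable = [e for e in estimates if not e.undatable]
    n_undatable = len(estimates) - len(datable)
    max_age = max((e.t_years for e in datable), default=0.0)
    n_bins = max(1, int(np.floor(max_age / bin_width_years)) + 1)
    edges = np.arange(n_bins + 1, dtype=float) * bin_width_years
    counts: dict[str, np.ndarray] = {}
    for e in datable:
        fam = e.superfamily if by_superfamily else "all"
        if fam not in counts:
            counts[fam] = np.zeros(n_bins, dtype=int)
        idx = min(int(e.t_years // bin_width_years), n_bins - 1)
        counts[fam][idx] += 1
    return AgeDistribution(bin_edges=edges, counts=counts, n_undatable=n_undatable)


def read_pairs_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Read paired repeats from FASTA with ids ``<element_id>/5prime`` and
    ``<element_id>/3prime``. Returns (element_id, seq5, seq3) triples."""
    by_element: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "/" not in rec.id:
            raise ValueError(f"record id {rec.id!r} is not <element>/<5prime|3prime>")
        element, end = rec.id.rsplit("/", 1)
        if end not in ("5prime", "3prime"):
            raise ValueError(f"record id {rec.id!r} must end in /5prime or /3prime")
        by_element.setdefault(element, {})[end] = str(rec.seq)
    out = []
    for element in sorted(by_element):
        ends = by_element[element]
        if set(ends) != {"5prime", "3prime"}:
            raise ValueError(f"element {element!r} is missing one terminal repeat")
        out.append((element, ends["5prime"], ends["3prime"]))
    return out


def read_elements_table(
    tsv_path: str | Path, genome_fasta: str | Path
) -> list[tuple[str, str, str, str]]:
    """Read full-length elements from a coordinate table plus genome FASTA.

    Columns: element_id, contig, ltr5_start, ltr5_end, ltr3_start, ltr3_end,
    superfamily. Coordinates are 1-based inclusive (the convention of common
    LTR annotation output). Returns (element_id, seq5, seq3, superfamily).
    """
    table = pd.read_csv(tsv_path, sep="\t")
    required = [
        "element_id", "contig", "ltr5_start", "ltr5_end",
        "ltr3_start", "ltr3_end", "superfamily",
    ]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"element table is missing column(s) {missing}")
    genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    out = []
    for row in table.itertuples(index=False):
        if row.contig not in genome:
            raise ValueError(f"contig {row.contig!r} not in genome FASTA")
        contig = genome[row.contig]
        seq5 = contig[int(row.ltr5_start) - 1 : int(row.ltr5_end)]
        seq3 = contig[int(row.ltr3_start) - 1 : int(row.ltr3_end)]
        fam = "" if pd.isna(row.superfamily) else str(row.superfamily)
        out.append((str(row.element_id), seq5, seq3, fam))
    return out


def estimates_to_tsv(estimates: Sequence[LTRAgeEstimate], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "element_id": e.element_id,
                "superfamily": e.superfamily,
                "raw_divergence": e.raw_divergence,
                "k": e.k,
                "mu": e.mu,
                "t_years": e.t_years,
                "aligned_length": e.aligned_length,
                "undatable": e.undatable,
            }
            for e in estimates
        ],
        columns=[
            "element_id", "superfamily", "raw_divergence", "k", "mu",
            "t_years", "aligned_length", "undatable",
        ],
    ).to_csv(path, sep="\t", index=False)
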