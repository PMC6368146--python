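"""Sliding-window alignment masking and the drop rule.

Quality control for codon alignments ahead of any tree/site computation:
every window of ``window_length`` columns (step 1 by default) is checked for
mismatches; a window with more than ``max_mismatches`` is masked (all rows,
all columns of the window) with ``mask_char``. Gap characters are always
replaced by the mask character. An alignment with more than ``drop_fraction``
of its columns masked by windows is flagged for removal.

A "mismatch" is, by default, a column in which the non-gap, non-masked
characters are not all identical (a column property, counted once however
many rows disagree). A pairwise mode — tallying differing row pairs per
window instead — is available for sensitivity analysis.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

GAP_CHARS = b"-.?"


@dataclasses.dataclass(frozen=True)
class MaskingConfig:
    window_length: int = 15
    max_mismatches: int = 6
    drop_fraction: float = 0.20
    mask_char: str = "N"
    step: int = 1
    mode: str = "column"  # or "pairwise"

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if not 0 <= self.max_mismatches:
            raise ValueError("max_mismatches must be >= 0")
        if self.mode == "column" and self.max_mismatches > self.window_length:
            raise ValueError("max_mismatches cannot exceed window_length")
        if not 0.0 <= self.drop_fraction <= 1.0:
            raise ValueError("drop_fraction must be in [0, 1]")
        if len(self.mask_char) != 1:
            raise ValueError("mask_char must be a single character")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.mode not in ("column", "pairwise"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclasses.dataclass
class MaskedAlignment:
    """Masked rows plus the masking summary used by the drop rule."""

    sequences: dict[str, str]
    masked_fraction: float
    dropped: bool
    masked_columns: np.ndarray  # column indices masked by the window rule


def _to_matrix(alignment: Mapping[str, str] | Iterable[str]) -> tuple[list[str], np.ndarray]:
    if isinstance(alignment, Mapping):
        names = list(alignment.keys())
        rows = [alignment[n] for n in names]
    else:
        rows = list(alignment)
        names = [str(i) for i in range(len(rows))]
    if len(rows) == 0:
        raise ValueError("empty alignment")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    mat = np.frombuffer("".join(rows).upper().encode(), dtype="S1").reshape(
        len(rows), -1
    )
    return names, mat.copy()


def _ignore_mask(mat: np.ndarray, mask_char: str) -> np.ndarray:
    """True where a character does not participate in mismatch counting."""
    ignore = np.zeros(mat.shape, dtype=bool)
    for g in GAP_CHARS:
        ignore |= mat == bytes([g])
    ignore |= mat == mask_char.upper().encode()
    ignore |= mat == b"N"
    return ignore


def _variable_columns(mat: np.ndarray, ignore: np.ndarray) -> np.ndarray:
    """Boolean per column: >= 2 distinct characters among non-ignored rows."""
    vals = mat.view(np.uint8)
    lo = np.where(ignore, 255, vals).min(axis=0)
    hi = np.where(ignore, 0, vals).max(axis=0)
    n = (~ignore).sum(axis=0)
    return (n >= 2) & (hi > lo)


def _pairwise_tally(mat: np.ndarray, ignore: np.ndarray) -> np.ndarray:
    """Per-column count of differing row pairs (non-ignored characters only)."""
    nrows = mat.shape[0]
    tally = np.zeros(mat.shape[1], dtype=np.int64)
    for i in range(nrows):
        for j in range(i + 1, nrows):
            ok = ~(ignore[i] | ignore[j])
            tally += ok & (mat[i] != mat[j])
    return tally


def count_window_mismatches(
    alignment_slice: Mapping[str, str] | Iterable[str],
    mask_char: str = "N",
    mode: str = "column",
) -> int:
    """Count mismatches in a slice of alignment columns.

    In ``column`` mode (default) this is the number of columns that are
    variable among non-gap, non-masked characters; a column whose non-gap
    characters are all identical contributes 0, as does a column whose only
    variation involves gaps or masked characters. ``pairwise`` mode returns
    the tally of differing row pairs summed over columns.
    """
    _, mat = _to_matrix(alignment_slice)
    if mat.shape[0] < 2:
        raise ValueError("alignment slice must have at least 2 rows")
    ignore = _ignore_mask(mat, mask_char)
    if mode == "column":
        return int(_variable_columns(mat, ignore).sum())
    if mode == "pairwise":
        return int(_pairwise_tally(mat, ignore).sum())
    raise ValueError(f"unknown mode {mode!r}")


def mask_alignment(
    alignment: Mapping[str, str] | Iterable[str],
    config: MaskingConfig = MaskingConfig(),
) -> MaskedAlignment:
    """Apply the sliding-window mask and the drop rule to one alignment.

    All windows are evaluated on the input alignment (gaps already treated as
    masked); the union of offending windows is then masked in every row.
    ``masked_fraction`` counts only columns masked by the window rule — the
    unconditional gap replacement does not contribute. The alignment is
    flagged ``dropped`` when ``masked_fraction`` strictly exceeds
    ``config.drop_fraction``.
    """
    names, mat = _to_matrix(alignment)
    if mat.shape[0] < 2:
        raise ValueError("alignment must have at least 2 rows")
    ncol = mat.shape[1]
    if ncol < config.window_length:
        raise ValueError(
            f"alignment length {ncol} is shorter than window_length "
            f"{config.window_length}"
        )
    ignore = _ignore_mask(mat, config.mask_char)
    if config.mode == "column":
        per_col = _variable_columns(mat, ignore).astype(np.int64)
    else:
        per_col = _pairwise_tally(mat, ignore)
    csum = np.concatenate([[0], np.cumsum(per_col)])
    starts = np.arange(0, ncol - config.window_length + 1, config.step)
    counts = csum[starts + config.window_length] - csum[starts]
    bad = starts[counts > config.max_mismatches]

    masked = np.zeros(ncol, dtype=bool)
    for s in bad:
        masked[s : s + config.window_length] = True

    out = mat.copy()
    mask_byte = config.mask_char.upper().encode()
    for g in GAP_CHARS:
        out[out == bytes([g])] = mask_byte
    out[:, masked] = mask_byte

    masked_fraction = float(masked.sum()) / ncol
    sequences = {
        name: out[i].tobytes().decode() for i, name in enumerate(names)
    }
    return MaskedAlignment(
        sequences=sequences,
        masked_fraction=masked_fraction,
        dropped=masked_fraction > config.drop_fraction,
        masked_columns=np.flatnonzero(masked),
    )


def read_fasta_alignment(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA file into an ordered name -> row mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta_alignment(alignment: Mapping[str, str], path: str | Path) -> None:
    lines = []
    for name, seq in alignment.items():
        lines.append(f">{name}")
        lines.append(seq)
    Path(path).write_text("\n".join(lines) + "\n")


def mask_directory(
    indir: str | Path,
    outdir: str | Path,
    config: MaskingConfig = MaskingConfig(),
) -> pd.DataFrame:
    """Mask every FASTA alignment in ``indir``; write kept loci and a report.

    Returns the report table (locus_id, masked_fraction, dropped). Dropped
    loci are reported but not written to ``outdir``.
    """
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    paths = sorted(list(indir.glob("*.fasta")) + list(indir.glob("*.fa")))
    for path in paths:
        result = mask_alignment(read_fasta_alignment(path), config)
        locus_id = path.stem
        rows.append(
            {
                "locus_id": locus_id,
                "masked_fraction": result.masked_fraction,
                "dropped": result.dropped,
            }
        )
        if not result.dropped:
            write_fasta_alignment(result.sequences, outdir / path.name)
    report = pd.DataFrame(rows, columns=["locus_id", "masked_fraction", "dropped"])
    report.to_csv(outdir / "masking_report.tsv", sep="\t", index=False)
    return report
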