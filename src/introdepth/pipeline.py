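"""End-to-end orchestration: mask -> classify -> concordance -> depth test.

The pipeline consumes per-locus FASTA alignments and matching newick gene
trees (trees are inputs, never inferred here), applies the sliding-window
mask and the drop rule, classifies each retained locus's triplet topology,
summarizes concordance across bootstrap cutoffs, and runs the node-depth
introgression test on the two most prevalent conflicting topology classes.

Every run writes a reproducibility manifest (config hash, seed, per-stage
locus counts) and an exclusion log in which each dropped or skipped locus
appears exactly once with a machine-readable reason code. Output files
contain no timestamps, so identical configs and seeds produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .concordance import DEFAULT_CUTOFFS, summarize_concordance
from .depth import (
    DepthConfig,
    DepthEstimate,
    DepthEstimationError,
    IntrogressionVerdict,
    compare_depth_classes,
    depths_to_tsv,
    estimate_depths,
)
from .mask import MaskingConfig, mask_alignment, read_fasta_alignment
from .triplet import ROLES, TripletTopology

logger = logging.getLogger("introdepth.pipeline")


@dataclasses.dataclass
class PipelineConfig:
    alignments_dir: str
    trees_path: str                       # directory of .nwk or one-per-line file
    taxon_map: dict[str, str]             # role (A,B,C,O) -> tip label
    out_dir: str
    masking: MaskingConfig = MaskingConfig()
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    depth: DepthConfig = DepthConfig()
    n_boot: int = 1000
    seed: int = 0
    assume_support: float | None = None   # mean support for unannotated trees
    compare_classes: tuple[str, str] | None = None  # override e.g. ("AB|C","AC|B")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json_file(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        if "masking" in d:
            d["masking"] = MaskingConfig(**d["masking"])
        if "depth" in d:
            d["depth"] = DepthConfig(**d["depth"])
        if "cutoffs" in d:
            d["cutoffs"] = tuple(d["cutoffs"])
        if d.get("compare_classes"):
            d["compare_classes"] = tuple(d["compare_classes"])
        return cls(**d)


def validate_config(config: PipelineConfig) -> list[str]:
    """Every violated invariant as a message; empty iff the config is runnable."""
    issues = []
    for role in ROLES:
        if role not in config.taxon_map:
            issues.append(f"taxon_map is missing role {role!r}")
    tips = [config.taxon_map[r] for r in ROLES if r in config.taxon_map]
    if len(set(tips)) != len(tips):
        issues.append("taxon_map assigns the same tip to several roles")
    if not Path(config.alignments_dir).is_dir():
        issues.append(f"alignments_dir does not exist: {config.alignments_dir}")
    if not Path(config.trees_path).exists():
        issues.append(f"trees_path does not exist: {config.trees_path}")
    if config.n_boot < 100:
        issues.append(f"n_boot must be >= 100 (got {config.n_boot})")
    if not config.cutoffs:
        issues.append("cutoffs must be non-empty")
    if config.compare_classes is not None:
        for c in config.compare_classes:
            try:
                TripletTopology.from_string(c)
            except ValueError:
                issues.append(f"unknown topology in compare_classes: {c!r}")
    return issues


@dataclasses.dataclass
class PipelineResult:
    verdict: IntrogressionVerdict | None
    concordance_table: pd.DataFrame
    depths: list[DepthEstimate]
    manifest: dict
    out_dir: Path


def _find_tree(trees_path: Path, locus_id: str, line_trees: dict[str, str]) -> str | None:
    if trees_path.is_dir():
        f = trees_path / f"{locus_id}.nwk"
        return f.read_text().strip() if f.exists() else None
    return line_trees.get(locus_id)


def run_introgression_analysis(config: PipelineConfig) -> PipelineResult:
    """Run the full mask -> concordance -> depth-test analysis.

    Writes masking_report.tsv, topologies.tsv, concordance.tsv, depths.tsv,
    verdict.json, exclusions.tsv and manifest.json to ``config.out_dir``.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid pipeline config: " + "; ".join(issues))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trees_path = Path(config.trees_path)
    line_trees: dict[str, str] = {}
    if trees_path.is_file():
        for i, line in enumerate(trees_path.read_text().splitlines()):
            if line.strip():
                line_trees[f"tree_{i}"] = line.strip()

    align_paths = sorted(
        list(Path(config.alignments_dir).glob("*.fasta"))
        + list(Path(config.alignments_dir).glob("*.fa"))
    )
    exclusions: list[dict] = []
    mask_rows: list[dict] = []
    kept: list[tuple[str, dict[str, str], str]] = []  # id, role-keyed alignment, newick

    for path in align_paths:
        locus_id = path.stem
        raw = read_fasta_alignment(path)
        missing = [r for r in ROLES if config.taxon_map[r] not in raw]
        if missing:
            exclusions.append(
                {"stage": "input", "locus_id": locus_id, "reason": "missing_taxa"}
            )
            logger.warning("stage=input locus=%s reason=missing_taxa %s", locus_id, missing)
            continue
        newick = _find_tree(trees_path, locus_id, line_trees)
        if newick is None:
            exclusions.append(
                {"stage": "input", "locus_id": locus_id, "reason": "missing_tree"}
            )
            logger.warning("stage=input locus=%s reason=missing_tree", locus_id)
            continue
        role_alignment = {r: raw[config.taxon_map[r]] for r in ROLES}
        masked = mask_alignment(role_alignment, config.masking)
        mask_rows.append(
            {
                "locus_id": locus_id,
                "masked_fraction": masked.masked_fraction,
                "dropped": masked.dropped,
            }
        )
        if masked.dropped:
            exclusions.append(
                {"stage": "mask", "locus_id": locus_id, "reason": "masked_fraction"}
            )
            logger.info(
                "stage=mask locus=%s reason=masked_fraction fraction=%.3f",
                locus_id, masked.masked_fraction,
            )
            continue
        kept.append((locus_id, masked.sequences, newick))

    if not kept:
        raise ValueError("zero loci survived input checks and masking")
    pd.DataFrame(
        mask_rows, columns=["locus_id", "masked_fraction", "dropped"]
    ).to_csv(out / "masking_report.tsv", sep="\t", index=False)

    # classification + concordance (tips already renamed to roles)
    summary = summarize_concordance(
        [nwk for _, _, nwk in kept],
        cutoffs=config.cutoffs,
        assume_support=config.assume_support,
        locus_ids=[lid for lid, _, _ in kept],
    )
    summary.per_tree.to_csv(out / "topologies.tsv", sep="\t", index=False)
    summary.table.to_csv(out / "concordance.tsv", sep="\t", index=False)

    # pick the two most prevalent conflicting classes at the lowest cutoff
    if config.compare_classes is not None:
        class1, class2 = (TripletTopology.from_string(c) for c in config.compare_classes)
    else:
        low = summary.table.iloc[summary.table["cutoff"].to_numpy().argmin()]
        counts = {t: int(low[f"n_{t.value}"]) for t in
                  (TripletTopology.AB_C, TripletTopology.AC_B, TripletTopology.BC_A)}
        ordered = sorted(counts, key=lambda t: (-counts[t], t.value))
        class1, class2 = ordered[0], ordered[1]

    topo_by_locus = dict(
        zip(summary.per_tree["locus_id"], summary.per_tree["topology"])
    )
    depths: list[DepthEstimate] = []
    for locus_id, alignment, _ in kept:
        topo = TripletTopology.from_string(topo_by_locus[locus_id])
        if topo not in (class1, class2):
            continue
        try:
            depths.append(
                estimate_depths(alignment, topo, config.depth, locus_id=locus_id)
            )
        except DepthEstimationError as err:
            exclusions.append(
                {"stage": "depth", "locus_id": locus_id, "reason": err.reason}
            )
            logger.info("stage=depth locus=%s reason=%s", locus_id, err.reason)
    depths_to_tsv(depths, out / "depths.tsv")

    verdict: IntrogressionVerdict | None = None
    try:
        verdict = compare_depth_classes(
            depths, class1, class2, n_boot=config.n_boot, seed=config.seed
        )
        (out / "verdict.json").write_text(verdict.to_json() + "\n")
    except ValueError as err:
        logger.warning("depth comparison not possible: %s", err)
        (out / "verdict.json").write_text(
            json.dumps({"error": str(err)}, indent=2) + "\n"
        )

    pd.DataFrame(
        exclusions, columns=["stage", "locus_id", "reason"]
    ).to_csv(out / "exclusions.tsv", sep="\t", index=False)

    config_json = config.to_json()
    manifest = {
        "package_version": __version__,
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "compared_classes": [class1.value, class2.value],
        "stage_counts": {
            "input_alignments": len(align_paths),
            "masked_retained": len(kept),
            "depth_estimates": len(depths),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        verdict=verdict,
        concordance_table=summary.table,
        depths=depths,
        manifest=manifest,
        out_dir=out,
    )
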