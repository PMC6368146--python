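"""Gene-tree concordance around the focal triplet.

Each gene tree is reduced to the four roles A, B, C (ingroup triplet) and O
(outgroup) and classified by which rooted resolution of the triplet it
supports. Trees are then stratified by their mean internal-branch bootstrap
support, and internode certainty (IC) is computed for the focal internode
from the two most prevalent conflicting resolutions:

    IC = 1 + p*log2(p) + q*log2(q),   p = n1/(n1+n2), q = 1-p,

with 0*log2(0) = 0. IC is 1 when all trees agree and 0 when the two leading
resolutions are equally frequent.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .triplet import RESOLVED, ROLES, TripletTopology

DEFAULT_CUTOFFS = (50.0, 60.0, 70.0, 80.0, 90.0)


def _as_tree(tree: "dendropy.Tree | str") -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    try:
        return dendropy.Tree.get(data=tree, schema="newick")
    except dendropy.utility.error.DataParseError as err:  # e.g. duplicate tip labels
        raise ValueError(f"could not parse newick tree: {err}") from err


def _role_leaves(
    tree: dendropy.Tree, taxon_map: Mapping[str, str] | None
) -> dict[str, dendropy.Node]:
    """Locate the leaf node for each role; error names any missing/duplicate."""
    taxon_map = dict(taxon_map) if taxon_map else {r: r for r in ROLES}
    for role in ROLES:
        if role not in taxon_map:
            raise ValueError(f"taxon map is missing role {role!r}")
    wanted = {taxon_map[role]: role for role in ROLES}
    if len(wanted) != len(ROLES):
        raise ValueError(f"taxon map assigns one tip to several roles: {taxon_map}")
    found: dict[str, dendropy.Node] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else leaf.label
        role = wanted.get(label)
        if role is None:
            continue
        if role in found:
            raise ValueError(f"tip label {label!r} (role {role}) appears more than once")
        found[role] = leaf
    missing = [wanted[t] for t in wanted if wanted[t] not in found]
    if missing:
        raise ValueError(f"tree is missing tip(s) for role(s): {sorted(missing)}")
    return found


def classify_triplet(
    tree: "dendropy.Tree | str", taxon_map: Mapping[str, str] | None = None
) -> TripletTopology:
    """Which resolution of {A, B, C} (rooted by O) does this tree support?

    Works on rooted or unrooted newick: the input rooting is ignored and the
    triplet resolution is read from the unique 2-2 split separating a cherry
    pair of the ingroup from the third taxon plus the outgroup (equivalent
    to re-rooting on O). Trees whose relevant node is a polytomy are
    UNRESOLVED. Extra tips are ignored; ``taxon_map`` (role -> tip label)
    selects the four representatives.
    """
    tree = _as_tree(tree)
    leaves = _role_leaves(tree, taxon_map)
    node_of = {id(node): role for role, node in leaves.items()}
    full = frozenset(ROLES)
    ingroup_pairs = {
        frozenset(t.cherry): t for t in RESOLVED
    }

    # role set under every node, bottom-up
    role_sets: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            role_sets[id(node)] = frozenset(
                [node_of[id(node)]] if id(node) in node_of else []
            )
        else:
            acc: set[str] = set()
            for child in node.child_nodes():
                acc |= role_sets[id(child)]
            role_sets[id(node)] = frozenset(acc)

    hits = set()
    for node in tree.preorder_node_iter():
        s = role_sets[id(node)]
        for side in (s, full - s):
            topo = ingroup_pairs.get(side)  # side == {X, Y} <=> split XY | Z,O
            if topo is not None:
                hits.add(topo)
    if len(hits) > 1:
        raise ValueError(f"conflicting splits in one tree: {sorted(h.value for h in hits)}")
    return hits.pop() if hits else TripletTopology.UNRESOLVED


def mean_bootstrap(tree: "dendropy.Tree | str") -> float:
    """Arithmetic mean of the support values on internal branches.

    Supports are read from internal node labels (the common newick dialect)
    or, failing that, from a ``support`` annotation on the node. Raises if
    the tree carries no numeric support value at all.
    """
    tree = _as_tree(tree)
    values = []
    root = tree.seed_node
    for node in tree.preorder_internal_node_iter():
        if node is root:
            continue
        raw = node.label
        if raw is None:
            ann = node.annotations.get_value("support")
            raw = ann if ann is not None else None
        if raw is None:
            continue
        try:
            values.append(float(raw))
        except (TypeError, ValueError):
            continue
    if not values:
        raise ValueError("tree has no numeric internal-branch support values")
    return sum(values) / len(values)


def internode_certainty(n1: float, n2: float) -> float:
    """IC of the focal internode from the two leading conflicting counts.

    Accepts the counts in either order; ``n1 + n2`` must be positive.
    """
    hi, lo = max(n1, n2), min(n1, n2)
    if lo < 0:
        raise ValueError("counts must be non-negative")
    if hi == 0:
        raise ValueError("at least one count must be positive")
    p = hi / (hi + lo)
    q = 1.0 - p
    h = 0.0
    for x in (p, q):
        if x > 0:
            h -= x * math.log2(x)
    return 1.0 - h


def internode_certainty_full(counts: Sequence[float]) -> float:
    """Three-way IC variant: 1 - H(p)/log2(k) over all supplied counts."""
    counts = [c for c in counts if c > 0]
    if not counts:
        raise ValueError("at least one count must be positive")
    if len(counts) == 1:
        return 1.0
    total = sum(counts)
    h = -sum((c / total) * math.log2(c / total) for c in counts)
    return 1.0 - h / math.log2(len(counts))


@dataclasses.dataclass
class ConcordanceSummary:
    """Per-cutoff topology counts, proportions over resolved trees, and IC."""

    table: pd.DataFrame          # one row per cutoff
    per_tree: pd.DataFrame       # locus_id, topology, mean_bootstrap

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def summarize_concordance(
    trees: Iterable["dendropy.Tree | str"],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    taxon_map: Mapping[str, str] | None = None,
    assume_support: float | None = None,
    locus_ids: Sequence[str] | None = None,
) -> ConcordanceSummary:
    """Classify every tree and tabulate topology frequencies per bootstrap cutoff.

    A tree is retained at a cutoff when its mean bootstrap strictly exceeds
    the cutoff. ``assume_support`` supplies the mean support for trees with
    no annotated values (e.g. simulated trees); without it such trees raise.
    Proportions are over the three resolved classes; IC uses the two most
    prevalent of them. A cutoff retaining no resolved tree gets NaN
    proportions and IC rather than an error.
    """
    rows = []
    for i, tree in enumerate(trees):
        t = _as_tree(tree)
        topo = classify_triplet(t, taxon_map)
        try:
            mbs = mean_bootstrap(t)
        except ValueError:
            if assume_support is None:
                raise
            mbs = float(assume_support)
        locus_id = locus_ids[i] if locus_ids is not None else f"tree_{i}"
        rows.append({"locus_id": locus_id, "topology": topo.value, "mean_bootstrap": mbs})
    per_tree = pd.DataFrame(rows, columns=["locus_id", "topology", "mean_bootstrap"])
    if per_tree.empty:
        raise ValueError("no trees supplied")

    out = []
    for cutoff in cutoffs:
        kept = per_tree[per_tree["mean_bootstrap"] > cutoff]
        counts = {t.value: int((kept["topology"] == t.value).sum()) for t in TripletTopology}
        resolved = [counts[t.value] for t in RESOLVED]
        n_res = sum(resolved)
        row = {
            "cutoff": float(cutoff),
            "n_AB|C": counts["AB|C"],
            "n_AC|B": counts["AC|B"],
            "n_BC|A": counts["BC|A"],
            "n_unresolved": counts["UNRESOLVED"],
        }
        if n_res > 0:
            row["p_AB|C"] = counts["AB|C"] / n_res
            row["p_AC|B"] = counts["AC|B"] / n_res
            row["p_BC|A"] = counts["BC|A"] / n_res
            top2 = sorted(resolved, reverse=True)[:2]
            row["ic"] = internode_certainty(top2[0], top2[1]) if top2[0] > 0 else float("nan")
        else:
            row["p_AB|C"] = row["p_AC|B"] = row["p_BC|A"] = float("nan")
            row["ic"] = float("nan")
        out.append(row)
    return ConcordanceSummary(table=pd.DataFrame(out), per_tree=per_tree)


def read_trees(path: str | Path) -> tuple[list[str], list[str]]:
    """Read newick trees from a directory of ``.nwk`` files or a single file
    (one tree per line). Returns (locus_ids, newick_strings)."""
    path = Path(path)
    ids, newicks = [], []
    if path.is_dir():
        for f in sorted(path.glob("*.nwk")):
            ids.append(f.stem)
            newicks.append(f.read_text().strip())
    else:
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if line:
                ids.append(f"tree_{i}")
                newicks.append(line)
    if not newicks:
        raise ValueError(f"no trees found at {path}")
    return ids, newicks
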