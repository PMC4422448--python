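"""Topological hypothesis engine.

Single-tree predicates (monophyly, sisterhood, basal position, intruder
placement, adjacency, group splitting) and their tally across a tree
ensemble.  This is the inferential core of the segment-wise approach: a
lateral transfer shows up as a taxon placed inside a foreign group's clade in
trees of *both* protein segments, while a domain rearrangement shows up in
only one segment's trees — so each predicate is counted per ensemble
partition (seg1 trees vs seg2 trees) and the asymmetry carries the signal.

All predicates operate on rooted trees; :func:`root_tree` provides midpoint
(default) or outgroup rooting.  Group membership comes from a
:class:`GroupMap` (taxon code -> taxonomic label).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from skbio import TreeNode

from .errors import NoSisterError, TreeError
from .seqio import TaxonRecord
from .trees import PhyloTree, TreeEnsemble


class GroupMap:
    """Assignment of every taxon code to exactly one group label."""

    def __init__(self, assignment: Mapping[str, str]):
        self.assignment = dict(assignment)

    @classmethod
    def from_records(cls, records: Iterable[TaxonRecord]) -> "GroupMap":
        return cls({r.code: r.group for r in records})

    def groups(self) -> set[str]:
        return set(self.assignment.values())

    def members(self, group: str) -> set[str]:
        if group not in self.groups():
            raise TreeError(f"unknown group label {group!r}")
        return {c for c, g in self.assignment.items() if g == group}

    def __getitem__(self, code: str) -> str:
        return self.assignment[code]

    def __contains__(self, code: str) -> bool:
        return code in self.assignment


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def root_tree(
    tree: PhyloTree,
    strategy: str = "midpoint",
    outgroup: Iterable[str] | None = None,
) -> PhyloTree:
    """Root a tree by midpoint (default) or by an outgroup.

    Midpoint rooting places the root halfway along the longest leaf-to-leaf
    path; outgroup rooting places it on the edge separating the outgroup's
    ancestor from everything else (the outgroup must be separable).
    """
    t = tree.tree
    if strategy == "midpoint":
        if len(list(t.tips())) == 2:
            # halfway along the single path between the two leaves
            a, b = t.tips()
            total = (a.length or 0.0) + (b.length or 0.0)
            new_a = TreeNode(name=a.name, length=total / 2)
            new_b = TreeNode(name=b.name, length=total / 2)
            rooted = TreeNode(children=[new_a, new_b])
        else:
            rooted = t.copy().root_at_midpoint(branch_attrs=[], reset=True)
    elif strategy == "outgroup":
        if not outgroup:
            raise ValueError("outgroup strategy needs an outgroup code set")
        outgroup = list(outgroup)
        tips = {x.name for x in t.tips()}
        missing = [o for o in outgroup if o not in tips]
        if missing:
            raise TreeError(f"outgroup taxa not in tree: {missing}")
        try:
            rooted = t.copy().root_by_outgroup(outgroup, branch_attrs=[])
        except Exception as exc:
            raise TreeError(f"outgroup not separable: {exc}") from None
    else:
        raise ValueError(f"unknown rooting strategy {strategy!r}")
    prov = dict(tree.provenance)
    prov["rooting"] = strategy
    return PhyloTree(rooted, prov)


# ---------------------------------------------------------------------------
# per-tree predicates
# ---------------------------------------------------------------------------

def _leaf_sets(tree: TreeNode) -> list[frozenset]:
    """Leaf-name set of every clade (all nodes incl. tips and root), postorder."""
    sets = []
    cache: dict[int, frozenset] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            s = frozenset((node.name,))
        else:
            s = frozenset().union(*(cache[id(c)] for c in node.children))
        cache[id(node)] = s
        sets.append(s)
    return sets


def _tree_leaves(tree: PhyloTree | TreeNode) -> TreeNode:
    return tree.tree if isinstance(tree, PhyloTree) else tree


def _group_leaves(tree: TreeNode, group: str, gm: GroupMap) -> frozenset:
    present = frozenset(
        t.name for t in tree.tips() if gm.assignment.get(t.name) == group
    )
    if not present:
        raise TreeError(f"no leaf of group {group!r} in tree")
    return present


def is_monophyletic(
    tree: PhyloTree | TreeNode,
    group: str,
    gm: GroupMap,
    max_outliers: int = 0,
) -> tuple[bool, frozenset | None]:
    """Does some clade contain all group leaves with <= max_outliers others?

    Returns ``(verdict, witness)`` where the witness is the smallest such
    clade (ties broken toward the first in postorder, which only matters on
    multifurcating consensus trees).
    """
    t = _tree_leaves(tree)
    members = _group_leaves(t, group, gm)
    best: frozenset | None = None
    for clade in _leaf_sets(t):
        if members <= clade and len(clade - members) <= max_outliers:
            if best is None or len(clade) < len(best):
                best = clade
    return (best is not None), best


def sister_group(
    tree: PhyloTree | TreeNode,
    group: str,
    gm: GroupMap,
    max_outliers: int = 0,
) -> frozenset:
    """Leaf set of the sibling of the group's witness clade.

    Only defined when the group is monophyletic (within the outlier
    allowance); otherwise :class:`NoSisterError` is raised.  The witness
    being the whole tree (group spans a root child split) also leaves no
    sister defined.
    """
    t = _tree_leaves(tree)
    members = _group_leaves(t, group, gm)
    ok, witness = is_monophyletic(t, group, gm, max_outliers)
    if not ok:
        raise NoSisterError(f"group {group!r} not monophyletic within allowance")
    # locate the witness node
    cache: dict[int, frozenset] = {}
    target = None
    for node in t.postorder(include_self=True):
        if node.is_tip():
            s = frozenset((node.name,))
        else:
            s = frozenset().union(*(cache[id(c)] for c in node.children))
        cache[id(node)] = s
        if s == witness and target is None:
            target = node
    if target is None or target.parent is None:
        raise NoSisterError(f"group {group!r} witness is the whole tree; no sister")
    sibs = [c for c in target.parent.children if c is not target]
    return frozenset().union(*(cache[id(s)] for s in sibs))


def is_sister_of(
    tree: PhyloTree | TreeNode,
    group_a: str,
    group_b: str,
    gm: GroupMap,
    mode: str = "strict",
    max_outliers: int = 0,
) -> bool:
    """Is group A's sister composed (entirely / in strict majority) of B leaves?"""
    if mode not in ("strict", "majority"):
        raise ValueError(f"mode must be 'strict' or 'majority', got {mode!r}")
    t = _tree_leaves(tree)
    _group_leaves(t, group_b, gm)  # validates B is present
    sister = sister_group(t, group_a, gm, max_outliers)
    n_b = sum(1 for leaf in sister if gm.assignment.get(leaf) == group_b)
    if mode == "strict":
        return n_b == len(sister)
    return n_b > len(sister) / 2


def is_basal(
    tree: PhyloTree | TreeNode,
    group: str,
    gm: GroupMap,
    max_outliers: int = 0,
) -> bool:
    """Does one child clade of the root consist of group members
    (with at most ``max_outliers`` exceptions)?

    This is the strict "at the base, most distantly related to all others"
    reading: the group (or a pure block of it) forms one side of the root
    split.
    """
    t = _tree_leaves(tree)
    _group_leaves(t, group, gm)
    if not t.children:
        raise TreeError("cannot evaluate basal position on a single leaf")
    for child in t.children:
        leaves = frozenset(x.name for x in child.tips()) or frozenset((child.name,))
        non_members = [x for x in leaves if gm.assignment.get(x) != group]
        if len(non_members) <= max_outliers and len(non_members) < len(leaves):
            return True
    return False


def placed_within(
    tree: PhyloTree | TreeNode,
    taxon: str,
    group: str,
    gm: GroupMap,
) -> bool:
    """Does ``taxon`` lie inside the smallest clade spanning the group?

    This is the "X among Y" intruder pattern of lateral transfer.  When
    ``group`` is the taxon's own label, the taxon itself is excluded from the
    group leaves first, so ``not placed_within(x, own_group)`` expresses the
    "X outside its own group" pattern.
    """
    t = _tree_leaves(tree)
    tips = {x.name for x in t.tips()}
    if taxon not in tips:
        raise TreeError(f"taxon {taxon!r} not in tree")
    members = _group_leaves(t, group, gm) - {taxon}
    if not members:
        raise TreeError(f"group {group!r} has no members besides {taxon!r}")
    # smallest clade containing all members = MRCA clade
    best = None
    for clade in _leaf_sets(t):
        if members <= clade and (best is None or len(clade) < len(best)):
            best = clade
    return taxon in best


def are_adjacent(
    tree: PhyloTree | TreeNode,
    taxon_a: str,
    taxon_b: str,
    max_clade_size: int = 2,
) -> bool:
    """Do two taxa sit next to each other (their MRCA clade has few leaves)?

    The default (2) is the strict cherry reading of "next to each other";
    larger values allow small intervening clades.
    """
    t = _tree_leaves(tree)
    tips = {x.name for x in t.tips()}
    for taxon in (taxon_a, taxon_b):
        if taxon not in tips:
            raise TreeError(f"taxon {taxon!r} not in tree")
    pair = {taxon_a, taxon_b}
    best = None
    for clade in _leaf_sets(t):
        if pair <= clade and (best is None or len(clade) < len(best)):
            best = clade
    return len(best) <= max_clade_size


def split_count(tree: PhyloTree | TreeNode, group: str, gm: GroupMap) -> int:
    """Number of maximal pure-group clades (1 = monophyletic)."""
    t = _tree_leaves(tree)
    _group_leaves(t, group, gm)
    pure: dict[int, bool] = {}
    count = 0
    for node in t.postorder(include_self=True):
        if node.is_tip():
            pure[id(node)] = gm.assignment.get(node.name) == group
        else:
            pure[id(node)] = all(pure[id(c)] for c in node.children)
    for node in t.postorder(include_self=True):
        if pure[id(node)] and (node.parent is None or not pure[id(node.parent)]):
            count += 1
    return count


# ---------------------------------------------------------------------------
# hypotheses and tallies
# ---------------------------------------------------------------------------

HYPOTHESIS_KINDS = (
    "monophyly",
    "sister_of",
    "basal",
    "placed_within",
    "adjacent",
    "split_count_in_range",
)


@dataclass
class Hypothesis:
    """One testable topological statement, e.g. "streptophytes sister of
    cyanobacteria" or "taxon X placed within group Y".

    ``subjects`` are group labels and/or taxon codes depending on ``kind``;
    ``params`` holds the per-kind knobs (max_outliers, mode, max_clade_size,
    lo/hi for split counts, negate for "outside" readings).
    """

    kind: str
    subjects: list[str]
    params: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in HYPOTHESIS_KINDS:
            raise ValueError(f"unknown hypothesis kind {self.kind!r}")
        n_needed = {"monophyly": 1, "sister_of": 2, "basal": 1,
                    "placed_within": 2, "adjacent": 2, "split_count_in_range": 1}
        if len(self.subjects) != n_needed[self.kind]:
            raise ValueError(
                f"{self.kind} needs {n_needed[self.kind]} subject(s), "
                f"got {self.subjects}"
            )
        if not self.name:
            self.name = f"{self.kind}({', '.join(self.subjects)})"

    def applicable(self, tree: PhyloTree, gm: GroupMap) -> bool:
        """All subject taxa/groups represented in this tree's leaf set?"""
        tips = set(tree.leaf_names)
        for s in self.subjects:
            if s in gm.groups():
                if not any(gm.assignment.get(x) == s for x in tips):
                    return False
            elif s not in tips:
                return False
        return True

    def evaluate(self, tree: PhyloTree, gm: GroupMap) -> bool:
        p = self.params
        if self.kind == "monophyly":
            ok, _ = is_monophyletic(
                tree, self.subjects[0], gm, p.get("max_outliers", 0)
            )
            return ok
        if self.kind == "sister_of":
            try:
                return is_sister_of(
                    tree, self.subjects[0], self.subjects[1], gm,
                    mode=p.get("mode", "strict"),
                    max_outliers=p.get("max_outliers", 0),
                )
            except NoSisterError:
                return False
        if self.kind == "basal":
            return is_basal(tree, self.subjects[0], gm, p.get("max_outliers", 0))
        if self.kind == "placed_within":
            verdict = placed_within(tree, self.subjects[0], self.subjects[1], gm)
            return (not verdict) if p.get("negate", False) else verdict
        if self.kind == "adjacent":
            return are_adjacent(
                tree, self.subjects[0], self.subjects[1],
                p.get("max_clade_size", 2),
            )
        if self.kind == "split_count_in_range":
            k = split_count(tree, self.subjects[0], gm)
            return p.get("lo", 1) <= k <= p.get("hi", k)
        raise AssertionError(self.kind)


@dataclass
class TallyTable:
    """Per-hypothesis counts across ensemble partitions (the Tables-style
    two-column layout: count of supporting trees / applicable trees)."""

    counts: pd.DataFrame      # rows: hypothesis name, cols: partition
    denominators: pd.DataFrame
    rooting: str = "midpoint"

    def to_dataframe(self) -> pd.DataFrame:
        out = {}
        for col in self.counts.columns:
            out[f"{col}_count"] = self.counts[col]
            out[f"{col}_of"] = self.denominators[col]
        return pd.DataFrame(out, index=self.counts.index)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "hypothesis"
        df.to_csv(path, sep="\t")


def tally_ensemble(
    partitions: Mapping[str, TreeEnsemble],
    hypotheses: list[Hypothesis],
    gm: GroupMap,
    rooting: str = "midpoint",
    outgroup: Iterable[str] | None = None,
) -> TallyTable:
    """Count, per partition, in how many trees each hypothesis holds.

    Trees are rooted (midpoint by default) before evaluation; trees missing a
    hypothesis's subject taxa shrink that cell's denominator.  Evaluation
    errors on an applicable tree (e.g. no defined sister) count as the
    hypothesis not holding.
    """
    if not partitions:
        raise ValueError("no ensemble partitions given")
    for name, ens in partitions.items():
        if len(ens) == 0:
            raise ValueError(f"partition {name!r} is empty")
    rooted: dict[str, list[PhyloTree]] = {}
    for name, ens in partitions.items():
        rooted[name] = [
            t if (rooting == "asis" and t.is_rooted) else root_tree(t, rooting, outgroup)
            for t in ens
        ]
    names = [h.name for h in hypotheses]
    counts = pd.DataFrame(0, index=names, columns=list(partitions), dtype=int)
    denoms = pd.DataFrame(0, index=names, columns=list(partitions), dtype=int)
    for pname, trees in rooted.items():
        for h in hypotheses:
            for t in trees:
                if not h.applicable(t, gm):
                    continue
                denoms.loc[h.name, pname] += 1
                try:
                    if h.evaluate(t, gm):
                        counts.loc[h.name, pname] += 1
                except NoSisterError:
                    pass
    return TallyTable(counts, denoms, rooting=rooting)


def hypotheses_from_config(items: list[dict]) -> list[Hypothesis]:
    """Build hypotheses from config dicts ({kind, subjects, params, name})."""
    out = []
    for item in items:
        out.append(
            Hypothesis(
                kind=item["kind"],
                subjects=list(item["subjects"]),
                params=dict(item.get("params", {})),
                name=item.get("name", ""),
            )
        )
    return out
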