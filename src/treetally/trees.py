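"""Tree containers and Newick I/O.

Trees are scikit-bio :class:`~skbio.TreeNode` objects wrapped in a thin
:class:`PhyloTree` dataclass that carries provenance tags (which segment,
which method, which replicate produced the tree).  An unrooted tree is
represented, as usual, by a root node of degree 3+; a rooted tree has a
degree-2 root.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from skbio import TreeNode

from .errors import TreeError


@dataclass
class PhyloTree:
    """A leaf-labeled tree plus provenance tags.

    ``tree`` is a scikit-bio TreeNode; internal nodes may carry ``support``
    (a fraction in [0, 1]) set by consensus or bootstrap tallying.
    """

    tree: TreeNode
    provenance: dict = field(default_factory=dict)

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    @property
    def is_rooted(self) -> bool:
        return len(self.tree.children) == 2

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.tree.copy(), dict(self.provenance))

    def splits(self) -> set[frozenset]:
        """Nontrivial unrooted bipartitions, each given as the side that does
        not contain the lexicographically smallest leaf."""
        leaves = frozenset(self.leaf_names)
        if len(leaves) != len(self.leaf_names):
            raise TreeError("duplicate leaf labels")
        ref = min(leaves)
        out: set[frozenset] = set()
        for node in self.tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = leaves - side
            # trivial splits (single leaf / all-but-ref) carry no information;
            # a rooted tree's two root children collapse to the same split
            if 1 < len(side) < len(leaves) - 1:
                out.add(side)
        return out

    def newick(self) -> str:
        buf = io.StringIO()
        _prepare_supports_for_write(self.tree)
        self.tree.write(buf)
        return buf.getvalue().strip()


def _prepare_supports_for_write(tree: TreeNode) -> None:
    """Expose fractional supports as internal-node labels for Newick output."""
    for node in tree.non_tips(include_self=False):
        sup = getattr(node, "support", None)
        if sup is not None and node.name is None:
            node.name = f"{sup:g}"


def _check_unique_leaves(tree: TreeNode, where: str = "") -> None:
    names = [t.name for t in tree.tips()]
    seen: set[str] = set()
    for n in names:
        if n is None:
            raise TreeError(f"unnamed leaf{where}")
        if n in seen:
            raise TreeError(f"duplicate leaf {n!r}{where}")
        seen.add(n)


def parse_newick(text: str, where: str = "") -> TreeNode:
    """Parse one Newick string; numeric internal labels become supports."""
    try:
        tree = TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:  # skbio raises format-specific subclasses
        raise TreeError(f"could not parse Newick{where}: {exc}") from None
    _check_unique_leaves(tree, where)
    tree.assign_supports()
    for node in tree.non_tips(include_self=False):
        if node.support is not None and node.support > 1:
            node.support = node.support / 100.0  # percent-style supports
    return tree


@dataclass
class TreeEnsemble:
    """A list of PhyloTree objects analysed jointly (e.g. all seg1 trees)."""

    trees: list[PhyloTree]

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeError("ensemble needs at least one tree")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[PhyloTree]:
        return iter(self.trees)

    @property
    def shared_label_set(self) -> frozenset:
        sets = [frozenset(t.leaf_names) for t in self.trees]
        shared = sets[0]
        for s in sets[1:]:
            shared &= s
        return shared


def read_newick(path: str | Path) -> TreeEnsemble:
    """Read a file of Newick trees (one per line) into an ensemble.

    Each tree is tagged with its ordinal position in the file.
    """
    path = Path(path)
    trees: list[PhyloTree] = []
    with open(path) as fh:
        text = fh.read()
    # split on ';' so multi-line single trees also parse
    chunks = [c.strip() for c in text.split(";") if c.strip()]
    if not chunks:
        raise TreeError(f"no trees found in {path}")
    for i, chunk in enumerate(chunks):
        tree = parse_newick(chunk + ";", where=f" (tree {i + 1} in {path})")
        trees.append(PhyloTree(tree, {"source": str(path), "ordinal": i}))
    return TreeEnsemble(trees)


def write_newick(ensemble: TreeEnsemble | Iterable[PhyloTree], path: str | Path) -> None:
    trees = ensemble.trees if isinstance(ensemble, TreeEnsemble) else list(ensemble)
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.newick() + "\n")
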