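"""Independent brute-force oracles used by the test suite.

Trees here are plain nested tuples (leaf = label string, internal node =
2-tuple of children); weighted trees carry a parallel dict of branch lengths
keyed by the subtree tuple.  Everything is computed by explicit enumeration,
never by calling the package under test.
"""

from __future__ import annotations

import itertools
import random
from fractions import Fraction

import numpy as np

Leaf = str


# ---------------------------------------------------------------------------
# enumeration of rooted binary trees
# ---------------------------------------------------------------------------

def insert_everywhere(t, lab):
    """All rooted trees obtained by attaching ``lab`` on any edge of t
    (including above the root)."""
    out = [(t, lab)]
    if not isinstance(t, str):
        a, b = t
        out += [(x, b) for x in insert_everywhere(a, lab)]
        out += [(a, y) for y in insert_everywhere(b, lab)]
    return out


def all_rooted_trees(labels):
    """Every rooted binary topology on the given labels ((2n-3)!! trees)."""
    trees = [labels[0]]
    for lab in labels[1:]:
        trees = [u for t in trees for u in insert_everywhere(t, lab)]
    return trees


def leaves(t) -> frozenset:
    if isinstance(t, str):
        return frozenset((t,))
    return leaves(t[0]) | leaves(t[1])


def clades(t) -> list:
    """Every clade (leaf sets of all nodes, tips and root included)."""
    if isinstance(t, str):
        return [frozenset((t,))]
    out = clades(t[0]) + clades(t[1])
    out.append(leaves(t))
    return out


def to_newick(t, lengths=None) -> str:
    def rec(node):
        if isinstance(node, str):
            base = node
        else:
            base = "(" + ",".join(rec(c) for c in node) + ")"
        if lengths is not None and node in lengths:
            base += f":{lengths[node]!r}"
        return base

    return rec(t) + ";"


# ---------------------------------------------------------------------------
# brute-force predicates (explicit clade enumeration)
# ---------------------------------------------------------------------------

def bf_monophyletic(t, members: frozenset, max_outliers: int = 0):
    cands = [
        c for c in clades(t)
        if members <= c and len(c - members) <= max_outliers
    ]
    if not cands:
        return False, None
    return True, min(cands, key=len)


def bf_sister(t, members: frozenset, max_outliers: int = 0):
    """Sister leaf set of the smallest witness clade, or None."""
    ok, witness = bf_monophyletic(t, members, max_outliers)
    if not ok:
        return None

    def find(node, parent_other):
        nl = frozenset((node,)) if isinstance(node, str) else leaves(node)
        if nl == witness:
            return parent_other
        if isinstance(node, str):
            return None
        a, b = node
        return find(a, leaves(b)) or find(b, leaves(a))

    return find(t, None)


def bf_is_sister_of(t, members_a, label_b: str, labels: dict, mode="strict",
                    max_outliers=0):
    sister = bf_sister(t, members_a, max_outliers)
    if not sister:
        return False
    n_b = sum(1 for x in sister if labels[x] == label_b)
    if mode == "strict":
        return n_b == len(sister)
    return n_b > len(sister) / 2


def bf_basal(t, group_label: str, labels: dict, max_outliers: int = 0):
    a, b = t
    for child in (a, b):
        cl = frozenset((child,)) if isinstance(child, str) else leaves(child)
        non = [x for x in cl if labels[x] != group_label]
        if len(non) <= max_outliers and len(non) < len(cl):
            return True
    return False


def bf_within(t, taxon: str, members: frozenset):
    members = members - {taxon}
    cands = [c for c in clades(t) if members <= c]
    return taxon in min(cands, key=len)


def bf_adjacent(t, a: str, b: str, max_clade_size: int = 2):
    cands = [c for c in clades(t) if a in c and b in c]
    return len(min(cands, key=len)) <= max_clade_size


def bf_split_count(t, group_label: str, labels: dict):
    """Maximal all-group clades, counted recursively."""

    def pure(node):
        if isinstance(node, str):
            return labels[node] == group_label
        return pure(node[0]) and pure(node[1])

    def count(node):
        if pure(node):
            return 1
        if isinstance(node, str):
            return 0
        return count(node[0]) + count(node[1])

    return count(t)


# ---------------------------------------------------------------------------
# split tallies (consensus oracle)
# ---------------------------------------------------------------------------

def bf_splits(t) -> set:
    """Nontrivial unrooted bipartitions of a (rooted) tuple tree, oriented
    away from the lexicographically smallest leaf."""
    all_leaves = leaves(t)
    ref = min(all_leaves)
    out = set()
    for c in clades(t):
        side = all_leaves - c if ref in c else c
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return out


def bf_split_tally(trees) -> dict:
    tally: dict = {}
    for t in trees:
        for s in bf_splits(t):
            tally[s] = tally.get(s, 0) + 1
    return tally


# ---------------------------------------------------------------------------
# weighted random trees and path distances (NJ / least-squares oracles)
# ---------------------------------------------------------------------------

def random_weighted_tree(labels, rng: random.Random, lo=0.1, hi=1.0):
    """Random rooted binary topology with positive branch lengths.

    Returns (tuple_tree, lengths) where lengths maps each subtree (node) to
    the length of the edge above it; the root has no entry.
    """
    trees = all_rooted_trees(list(labels))
    t = trees[rng.randrange(len(trees))]
    lengths = {}

    def assign(node, is_root=False):
        if not is_root:
            lengths[node] = rng.uniform(lo, hi)
        if not isinstance(node, str):
            assign(node[0])
            assign(node[1])

    assign(t, is_root=True)
    return t, lengths


def random_topology(labels, rng: random.Random):
    """One uniformly-ish random rooted binary topology (sequential insertion
    at a random edge) — cheap for larger n where full enumeration explodes."""
    t = labels[0]
    for lab in labels[1:]:
        options = insert_everywhere(t, lab)
        t = options[rng.randrange(len(options))]
    return t


def path_distance_matrix(t, lengths, order):
    """Leaf-to-leaf path lengths by explicit root-path differencing."""

    def paths(node, prefix, acc):
        acc[node if isinstance(node, str) else id(node)] = prefix + [node]
        if not isinstance(node, str):
            for c in node:
                paths(c, prefix + [node], acc)

    node_paths: dict = {}
    paths(t, [], node_paths)

    def depth(node):
        # sum of edge lengths from the root down to ``node``
        key = node if isinstance(node, str) else id(node)
        return sum(lengths[step] for step in node_paths[key][1:])

    n = len(order)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = node_paths[order[i]], node_paths[order[j]]
            lca = None
            for a, b in zip(pi, pj):
                if a is b:
                    lca = a
                else:
                    break
            D[i, j] = D[j, i] = (
                depth(order[i]) + depth(order[j]) - 2 * depth(lca)
            )
    return D


# ---------------------------------------------------------------------------
# Fitch parsimony by exhaustive assignment
# ---------------------------------------------------------------------------

def bf_fitch_column(t, states: dict, alphabet) -> int:
    """Minimum changes for one column by trying every internal assignment."""
    internals = []

    def collect(node):
        if isinstance(node, str):
            return
        internals.append(node)
        collect(node[0])
        collect(node[1])

    collect(t)
    present = [a for a in alphabet]
    best = None
    for combo in itertools.product(present, repeat=len(internals)):
        assign = dict(zip(map(id, internals), combo))

        def state_of(node):
            if isinstance(node, str):
                return states.get(node)
            return assign[id(node)]

        def changes(node):
            if isinstance(node, str):
                return 0
            total = 0
            for c in node:
                cs = state_of(c)
                if cs is not None and cs != state_of(node):
                    total += 1
                total += changes(c)
            return total

        score = changes(t)
        if best is None or score < best:
            best = score
    return best
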