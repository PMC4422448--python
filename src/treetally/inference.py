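"""Tree building: neighbor-joining, least-squares branch lengths,
majority-rule consensus, Fitch parsimony scoring, and ensemble assembly.

The analysis philosophy is deliberately ensemble-based: no single distance
model or tree program is trusted; instead several methods are run on the same
filtered alignment and downstream hypotheses are tallied across all resulting
trees.  The in-repo method axis is distance-model x bootstrap-consensus;
external tree programs can be attached through a command-template adapter.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .alignment import MISSING, SegmentAlignment, bootstrap_indices, write_alignment
from .distances import (
    DEFAULT_MAX_DISTANCE,
    DistanceMatrix,
    EmpiricalModel,
    distance_matrix,
    kimura_matrix_from_p,
    p_distances_from_tables,
    pair_mismatch_tables,
)
from .errors import DataError, TreeError
from .trees import PhyloTree, TreeEnsemble, parse_newick


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou & Nei neighbor-joining on a distance matrix.

    Returns an unrooted tree (degree-3 root).  On an additive matrix the
    generating topology is recovered with exact branch lengths.  Negative
    branch-length estimates are clamped to zero.  Ties in the Q criterion are
    broken toward the lowest (i, j) index pair under the current label
    ordering, so runs are reproducible.
    """
    n = len(dm.labels)
    if n < 3:
        raise TreeError("neighbor joining needs at least 3 labels")
    # work matrix grows as joined nodes are appended
    size = 2 * n - 2
    D = np.zeros((size, size))
    D[:n, :n] = dm.d
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    active = list(range(n))
    nxt = n
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        k = int(np.argmin(Q))  # row-major scan = lowest (i, j) tie-break
        i, j = divmod(k, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        ai, aj = active[i], active[j]
        child_i, child_j = nodes[ai], nodes[aj]
        child_i.length = max(li, 0.0)
        child_j.length = max(lj, 0.0)
        new = TreeNode(children=[child_i, child_j])
        nodes.append(new)
        D = D if nxt < size else np.pad(D, ((0, 1), (0, 1)))
        for idx, a in enumerate(active):
            if a in (ai, aj):
                continue
            D[nxt, a] = D[a, nxt] = (sub[i, idx] + sub[j, idx] - dij) / 2
        active = [a for a in active if a not in (ai, aj)] + [nxt]
        nxt += 1
    # final three-point join
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = max(length, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root, {"method": "nj"})


# ---------------------------------------------------------------------------
# least-squares branch lengths on a fixed topology
# ---------------------------------------------------------------------------

def least_squares_branch_lengths(topology: PhyloTree, dm: DistanceMatrix) -> PhyloTree:
    """Fit branch lengths on a fixed topology by unweighted least squares.

    Path lengths between every leaf pair are matched to the distance matrix
    in the least-squares sense (minimum-norm solution when the system is
    rank-deficient, e.g. the two root edges of a rooted tree); negative
    estimates are then clamped to zero.  The topology itself is not changed,
    so it works for the multifurcating consensus trees this package feeds it.
    """
    out = topology.copy()
    tree = out.tree
    tips = {t.name for t in tree.tips()}
    if tips != set(dm.labels):
        raise TreeError(
            f"topology leaves do not match distance-matrix labels "
            f"(only in tree: {sorted(tips - set(dm.labels))[:3]}, "
            f"only in matrix: {sorted(set(dm.labels) - tips)[:3]})"
        )
    edges = [node for node in tree.traverse(include_self=False)]
    below = {}
    for node in tree.postorder(include_self=False):
        below[id(node)] = (
            frozenset([node.name]) if node.is_tip() else
            frozenset().union(*(below[id(c)] for c in node.children))
        )
    labels = dm.labels
    idx = {lab: i for i, lab in enumerate(labels)}
    pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    A = np.zeros((len(pairs), len(edges)))
    for e, node in enumerate(edges):
        s = below[id(node)]
        for k, (i, j) in enumerate(pairs):
            # edge lies on the i-j path iff it separates i from j
            if (labels[i] in s) != (labels[j] in s):
                A[k, e] = 1.0
    y = np.array([dm.d[i, j] for i, j in pairs])
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    for e, node in enumerate(edges):
        node.length = float(max(x[e], 0.0))
    out.provenance = dict(topology.provenance)
    return out


# ---------------------------------------------------------------------------
# majority-rule consensus
# ---------------------------------------------------------------------------

def majority_rule_consensus(
    trees: list[PhyloTree], threshold: float = 0.5
) -> PhyloTree:
    """Majority-rule consensus of trees on an identical leaf set.

    The consensus contains exactly the nontrivial bipartitions occurring in
    strictly more than ``threshold`` of the input trees (so a split present
    in exactly half is excluded at the default), each annotated with its
    occurrence fraction as support.  The result may be multifurcating and is
    returned unrooted (leaf-star orientation around the reference leaf).
    """
    if len(trees) < 2:
        raise TreeError("consensus needs at least 2 trees")
    if not 0.5 <= threshold < 1.0:
        raise ValueError("threshold must be in [0.5, 1)")
    leaf_sets = [frozenset(t.leaf_names) for t in trees]
    if any(s != leaf_sets[0] for s in leaf_sets[1:]):
        raise TreeError("consensus requires an identical leaf set in every tree")
    leaves = leaf_sets[0]
    counts: dict[frozenset, int] = {}
    for t in trees:
        for s in t.splits():
            counts[s] = counts.get(s, 0) + 1
    n = len(trees)
    selected = {s: c / n for s, c in counts.items() if c / n > threshold}
    # splits above 50% are pairwise compatible; oriented away from the
    # reference leaf they form a laminar family, so a recursive build works
    clades = sorted(selected, key=len, reverse=True)

    def _build(members: frozenset, sub: list[frozenset]) -> TreeNode:
        node = TreeNode()
        maximal = [
            c for c in sub if not any(c < d for d in sub if d != c)
        ]
        covered: set = set()
        for c in maximal:
            child = _build(c, [d for d in sub if d < c])
            child.support = selected[c]
            node.append(child)
            covered |= c
        for leaf in sorted(members - covered):
            node.append(TreeNode(name=leaf))
        return node

    root = _build(leaves, clades)
    return PhyloTree(root, {"method": "majority-consensus", "n_trees": n})


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

def fitch_parsimony_score(tree: PhyloTree | TreeNode, aln: SegmentAlignment) -> int:
    """Minimum number of state changes over all columns (Fitch bottom-up pass).

    Gaps and X are missing data and contribute nothing.  The tree may be
    rooted anywhere; the score is root-invariant on binary trees.
    """
    root = tree.tree if isinstance(tree, PhyloTree) else tree
    leaf_names = [t.name for t in root.tips()]
    for name in leaf_names:
        if name not in aln.rows:
            raise DataError(f"tree leaf {name!r} missing from alignment")
    total = 0
    rows = aln.rows
    for col in range(aln.n_cols):
        changes = 0

        def down(node) -> frozenset:
            nonlocal changes
            if node.is_tip():
                ch = rows[node.name][col]
                return frozenset() if ch in MISSING else frozenset((ch,))
            state: frozenset = frozenset()
            for child in node.children:
                cs = down(child)
                if not cs:
                    continue
                if not state:
                    state = cs
                    continue
                inter = state & cs
                if inter:
                    state = inter
                else:
                    state = state | cs
                    changes += 1
            return state

        down(root)
        total += changes
    return total


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class ExternalAdapter:
    """Attach an external tree program via a shell command template.

    The template must contain ``{in}`` (aligned FASTA written by us) and
    ``{out}`` (Newick file the program must produce), e.g.
    ``"fasttree {in} > {out}"``.
    """

    name: str
    command_template: str

    def run(self, aln: SegmentAlignment) -> PhyloTree:
        with tempfile.TemporaryDirectory() as tmp:
            fin = Path(tmp) / "aln.fasta"
            fout = Path(tmp) / "tree.nwk"
            write_alignment(aln, fin)
            cmd = self.command_template.replace("{in}", str(fin)).replace(
                "{out}", str(fout)
            )
            proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
            if proc.returncode != 0 or not fout.exists():
                raise TreeError(
                    f"adapter {self.name!r} failed (exit {proc.returncode}): "
                    f"{proc.stderr[:500]}"
                )
            tree = parse_newick(fout.read_text(), where=f" (adapter {self.name})")
        return PhyloTree(tree, {"method": f"adapter:{self.name}"})


@dataclass
class EnsembleConfig:
    """Which trees to build from one filtered alignment."""

    models: list[str] = field(default_factory=lambda: ["kimura", "p"])
    bootstrap: int = 100
    seed: int = 0
    consensus_threshold: float = 0.5
    max_distance: float = DEFAULT_MAX_DISTANCE
    empirical: EmpiricalModel | None = None
    adapters: list[ExternalAdapter] = field(default_factory=list)
    segment: str = ""


def build_ensemble(aln: SegmentAlignment, config: EnsembleConfig) -> TreeEnsemble:
    """Build one tree per configured method.

    For each distance model: ``bootstrap`` replicate alignments are drawn,
    neighbor-joining is run on each, the majority-rule consensus is taken and
    its branch lengths are then fitted by least squares against the
    full-alignment distance matrix (mirroring the user-tree re-estimation
    step of classic pipelines).  With ``bootstrap=0`` the single NJ tree on
    the full alignment is used instead.  Replicate ``r`` of model ``m`` draws
    its columns from ``default_rng([seed, m, r])``.
    """
    if not config.models and not config.adapters:
        raise ValueError("ensemble config needs at least one model or adapter")
    trees: list[PhyloTree] = []
    labels = aln.codes
    shared, mismatch, pairs = pair_mismatch_tables(aln)
    for mi, model in enumerate(config.models):
        full_dm = distance_matrix(
            aln, model, empirical=config.empirical, max_distance=config.max_distance
        )
        if config.bootstrap == 0:
            tree = neighbor_joining(full_dm)
        else:
            reps: list[PhyloTree] = []
            for r in range(config.bootstrap):
                rng = np.random.default_rng([config.seed, mi, r])
                idx = rng.integers(0, aln.n_cols, size=aln.n_cols)
                if model in ("p", "kimura"):
                    P = p_distances_from_tables(
                        shared, mismatch, pairs, len(labels), idx, labels
                    )
                    D = P if model == "p" else kimura_matrix_from_p(
                        P, config.max_distance
                    )
                    rep_dm = DistanceMatrix(labels, D)
                else:
                    rep_aln = aln.take_columns([int(i) for i in idx])
                    rep_dm = distance_matrix(
                        rep_aln, model, config.empirical, config.max_distance
                    )
                reps.append(neighbor_joining(rep_dm))
            tree = majority_rule_consensus(reps, config.consensus_threshold)
            tree = least_squares_branch_lengths(tree, full_dm)
        tree.provenance = {
            "segment": config.segment,
            "method": f"nj+boot{config.bootstrap}" if config.bootstrap else "nj",
            "matrix": model,
            "replicates": config.bootstrap,
        }
        trees.append(tree)
    for adapter in config.adapters:
        t = adapter.run(aln)
        t.provenance["segment"] = config.segment
        trees.append(t)
    return TreeEnsemble(trees)
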