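"""Ground-truth simulator: species trees with planted lateral transfers,
segment-scoped domain rearrangements and gene duplications, plus sequence
evolution with rate heterogeneity and indels.

The generator emulates the structure of a two-segment (N-terminal
photosensory / C-terminal kinase) protein family: every taxon carries two
homologous segments whose gene trees agree except where an event was
planted.  A whole-gene lateral transfer (HGT) moves a lineage in *both*
segment trees; a rearrangement (domain shuffle / fusion) moves it in only
the scoped segment's tree — exactly the cross-segment discordance the
analysis pipeline is designed to detect.  Every planted event is recorded in
an :class:`EventLog` so recovery can be scored against truth.

Randomness: one master seed; the species tree uses ``seed + 1``, event
placement ``seed + 2`` and sequence evolution ``seed + 3`` (segment ``k``
uses ``default_rng([seed + 3, k])``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import special, stats
from skbio import TreeNode

from .alignment import GAP, SegmentAlignment
from .errors import DataError, TreetallyError
from .seqio import (
    AMINO_ACIDS,
    PHY_CLASSES,
    SequenceSet,
    TaxonRecord,
    make_taxon_code,
    write_fasta,
    write_taxon_table,
)
from .alignment import write_alignment
from .trees import PhyloTree, TreeEnsemble, write_newick

EVENT_TYPES = ("hgt", "rearrangement", "duplication")


@dataclass
class SimEvent:
    """One planted evolutionary event (ground truth)."""

    type: str
    donor: str        # leaf code identifying the donor lineage
    recipient: str    # leaf code identifying the moved / duplicated lineage
    time: float       # depth from the root, in branch-length units
    segment_scope: str  # both | seg1 | seg2

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if self.donor == self.recipient:
            raise ValueError("donor and recipient must differ")
        if self.type == "rearrangement" and self.segment_scope == "both":
            raise ValueError("a rearrangement must be scoped to one segment")


@dataclass
class EventLog:
    events: list[SimEvent] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("type\tdonor\trecipient\ttime\tsegment_scope\n")
            for e in self.events:
                fh.write(
                    f"{e.type}\t{e.donor}\t{e.recipient}\t{e.time:.6f}\t{e.segment_scope}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EventLog":
        events = []
        with open(path) as fh:
            header = fh.readline()
            for ln in fh:
                t, d, r, time, scope = ln.rstrip("\n").split("\t")
                events.append(SimEvent(t, d, r, float(time), scope))
        return cls(events)


@dataclass
class SimConfig:
    """Simulation conditions.

    Defaults describe a moderate-divergence 12-taxon family: root-to-tip
    depth 0.5 expected substitutions per site, 300 residues per segment,
    4 discrete gamma rate categories of shape 1.0, and a light indel process
    (0.01 events/site per unit branch length, mean length 3).  Planted-event
    times are drawn in the (0.5, 0.9) fraction of tree depth: transfers
    close to the root leave no topological trace and are not what the
    detection problem is about.
    """

    n_taxa: int = 12
    birth_rate: float = 1.0
    tree_depth: float = 0.5
    seq_length: int = 300
    n_rate_categories: int = 4
    gamma_shape: float = 1.0
    indel_rate: float = 0.01
    indel_mean_length: float = 3.0
    n_hgt: int = 0
    n_rearrangement: int = 0
    n_duplication: int = 0
    rearrangement_scope: str = "seg2"
    n_groups: int = 4
    event_time_window: tuple[float, float] = (0.5, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise DataError("n_taxa must be >= 4")
        for name in ("birth_rate", "tree_depth", "indel_rate", "gamma_shape"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")
        if self.seq_length < 1:
            raise DataError("seq_length must be >= 1")
        if not 2 <= self.n_groups <= self.n_taxa:
            raise DataError("n_groups must be between 2 and n_taxa")


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def _tips_or_self(node: TreeNode) -> list[TreeNode]:
    tips = list(node.tips())
    return tips if tips else [node]


def _annotate_times(tree: TreeNode) -> None:
    for node in tree.preorder(include_self=True):
        if node.parent is None:
            node.time = 0.0
        else:
            node.time = node.parent.time + (node.length or 0.0)


def _clone(node: TreeNode) -> TreeNode:
    new = TreeNode(name=node.name, length=node.length)
    new.time = getattr(node, "time", None)
    for c in node.children:
        new.append(_clone(c))
    return new


def simulate_species_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    tree_depth: float | None = None,
) -> PhyloTree:
    """Yule (pure-birth) ultrametric species tree, rescaled to ``tree_depth``.

    Leaves are named with the 5-letter species-code convention from
    deterministic synthetic binomials (``Aarus simulans`` -> ``AarSiPhy``),
    assigned in leaf preorder.
    """
    if n_taxa < 4:
        raise DataError("n_taxa must be >= 4")
    if birth_rate <= 0:
        raise DataError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    root.time = 0.0
    open_lineages: list[TreeNode] = []
    for _ in range(2):
        child = TreeNode()
        root.append(child)
        open_lineages.append(child)
    start = {id(c): 0.0 for c in open_lineages}
    t = 0.0
    while len(open_lineages) < n_taxa:
        k = len(open_lineages)
        t += rng.exponential(1.0 / (birth_rate * k))
        pick = int(rng.integers(k))
        node = open_lineages.pop(pick)
        node.time = t
        node.length = t - start.pop(id(node))
        for _ in range(2):
            child = TreeNode()
            node.append(child)
            open_lineages.append(child)
            start[id(child)] = t
    t_end = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    for node in open_lineages:
        node.time = t_end
        node.length = t_end - start.pop(id(node))
    if tree_depth is not None and t_end > 0:
        factor = tree_depth / t_end
        for node in root.traverse(include_self=True):
            node.time *= factor
            if node.length is not None:
                node.length *= factor
    # deterministic synthetic binomials -> 5-letter codes
    for i, leaf in enumerate(root.tips()):
        genus = (
            "ABCDEFGHIJKLMNOPQRSTUVWXYZ"[i // 26]
            + "abcdefghijklmnopqrstuvwxyz"[i % 26]
            + "rus"
        )
        leaf.name = make_taxon_code(f"{genus} simulans", 1, "Phy")
        leaf.species = f"{genus} simulans"
    return PhyloTree(root, {"method": "yule", "seed": seed})


def assign_groups(species_tree: PhyloTree, n_groups: int) -> dict[str, str]:
    """Label leaves by basal subtree: cut the earliest ``n_groups - 1``
    divergences so each of the resulting subtrees is one taxonomic group."""
    root = species_tree.tree
    _annotate_times(root)
    subtree_roots: list[TreeNode] = [root]
    while len(subtree_roots) < n_groups:
        internals = [n for n in subtree_roots if n.children]
        if not internals:
            raise DataError("n_groups exceeds the number of available subtrees")
        node = min(internals, key=lambda n: n.time)
        subtree_roots.remove(node)
        subtree_roots.extend(node.children)
    subtree_roots.sort(key=lambda n: min(t.name for t in _tips_or_self(n)))
    gm: dict[str, str] = {}
    for gi, node in enumerate(subtree_roots, start=1):
        for leaf in _tips_or_self(node):
            gm[leaf.name] = f"G{gi}"
    return gm


# ---------------------------------------------------------------------------
# event planting
# ---------------------------------------------------------------------------

def _edge_above(root: TreeNode, leaf_name: str, t: float) -> TreeNode:
    """The child node of the edge on the leaf's root path spanning time t."""
    node = next(x for x in root.tips() if x.name == leaf_name)
    while node.parent is not None and node.parent.time > t:
        node = node.parent
    if node.parent is None:
        raise TreetallyError(f"no edge above {leaf_name!r} spans time {t}")
    return node


def _suppress_unary(node: TreeNode) -> None:
    """Merge a degree-2 internal node into its single child."""
    (child,) = node.children
    parent = node.parent
    node.remove(child)
    child.length = (child.length or 0.0) + (node.length or 0.0)
    parent.remove(node)
    parent.append(child)


def _regraft(root: TreeNode, recipient_leaf: str, donor_leaf: str, t: float) -> None:
    """Prune the recipient's subtree at time t and regraft onto the donor
    lineage at the same time (absolute node times are preserved)."""
    rec = _edge_above(root, recipient_leaf, t)
    rec_parent = rec.parent
    rec_parent.remove(rec)
    if len(rec_parent.children) == 1 and rec_parent.parent is not None:
        _suppress_unary(rec_parent)
    elif len(rec_parent.children) == 1:
        # pruning directly below the root: promote the remaining child so the
        # root keeps degree 2 (its absolute time moves to the child's)
        (child,) = rec_parent.children
        rec_parent.remove(child)
        if child.is_tip():
            rec_parent.append(child)
        else:
            for c in list(child.children):
                child.remove(c)
                rec_parent.append(c)
            rec_parent.time = child.time
    don = _edge_above(root, donor_leaf, t)
    don_parent = don.parent
    don_parent.remove(don)
    mid = TreeNode(length=t - don_parent.time)
    mid.time = t
    don_parent.append(mid)
    don.length = don.time - t
    rec.length = rec.time - t
    mid.append(don)
    mid.append(rec)


def _duplicate(root: TreeNode, leaf_name: str, t: float) -> None:
    """Insert a duplication node at time t on the leaf's pendant edge and
    attach a second copy named ``<leaf>d``."""
    leaf = next(x for x in root.tips() if x.name == leaf_name)
    parent = leaf.parent
    if not parent.time < t < leaf.time:
        raise TreetallyError(f"time {t} not on pendant edge of {leaf_name!r}")
    parent.remove(leaf)
    mid = TreeNode(length=t - parent.time)
    mid.time = t
    parent.append(mid)
    leaf.length = leaf.time - t
    copy = TreeNode(name=leaf_name + "d", length=leaf.time - t)
    copy.time = leaf.time
    mid.append(leaf)
    mid.append(copy)


def plant_events(
    species_tree: PhyloTree,
    config: SimConfig,
    seed: int,
    group_map: dict[str, str] | None = None,
) -> tuple[PhyloTree, PhyloTree, EventLog]:
    """Plant the configured HGT / rearrangement / duplication events.

    Returns the two segment gene trees and the ground-truth event log.  HGT
    and duplications act on both segment trees; a rearrangement acts only on
    the scoped segment's tree, leaving the other segment at the species
    placement — the planted cross-segment discordance.

    Event lineages are drawn so that donor and recipient sit in different
    taxonomic groups and each lineage's subtree is pure for its own group
    (otherwise the event would be undetectable as an intergroup intruder);
    across events, the involved groups are kept distinct whenever enough
    groups exist.  Raises when no valid placement can be drawn.
    """
    rng = np.random.default_rng(seed)
    root = species_tree.tree
    _annotate_times(root)
    gm = group_map or assign_groups(species_tree, config.n_groups)
    depth = max(t.time for t in root.tips())
    lo, hi = config.event_time_window
    n_events = config.n_hgt + config.n_rearrangement + config.n_duplication
    leaf_names = [t.name for t in root.tips()]

    def _subtree_pure(leaf: str, t: float) -> bool:
        node = _edge_above(root, leaf, t)
        grp = gm[leaf]
        return all(gm[x.name] == grp for x in _tips_or_self(node))

    def _below_group_crown(leaf: str, t: float) -> bool:
        # the donor edge must subtend a strict subset of the donor's group:
        # a transfer onto the group's stem lineage makes the recipient sister
        # to the whole group rather than an intruder nested inside it
        node = _edge_above(root, leaf, t)
        grp = gm[leaf]
        subtended = {x.name for x in _tips_or_self(node)}
        members = {name for name, g in gm.items() if g == grp}
        return subtended < members

    events: list[SimEvent] = []
    types = (["hgt"] * config.n_hgt
             + ["rearrangement"] * config.n_rearrangement
             + ["duplication"] * config.n_duplication)
    # fail fast on hard trees: the dataset generator redraws the species
    # tree when no placement exists, so long rejection runs are wasted work
    for attempt in range(40):
        events = []
        used_groups: set[str] = set()
        used_edges: set[int] = set()
        ok = True
        for etype in types:
            placed = False
            for _ in range(100):
                t = depth * rng.uniform(lo, hi)
                if etype == "duplication":
                    leaf_name = leaf_names[int(rng.integers(len(leaf_names)))]
                    leaf = next(x for x in root.tips() if x.name == leaf_name)
                    if not leaf.parent.time < t < leaf.time:
                        continue
                    if id(leaf) in used_edges:
                        continue
                    used_edges.add(id(leaf))
                    events.append(
                        SimEvent("duplication", leaf_name, leaf_name + "d", t, "both")
                    )
                    placed = True
                    break
                pick = rng.choice(len(leaf_names), size=2, replace=False)
                rec_leaf = leaf_names[int(pick[0])]
                don_leaf = leaf_names[int(pick[1])]
                if gm[rec_leaf] == gm[don_leaf]:
                    continue
                # keep events on groups not already involved when possible
                if len(gm) and len(set(gm.values())) >= len(used_groups) + 2:
                    if gm[rec_leaf] in used_groups or gm[don_leaf] in used_groups:
                        continue
                rec_edge = _edge_above(root, rec_leaf, t)
                don_edge = _edge_above(root, don_leaf, t)
                if rec_edge is don_edge:
                    continue
                # pruning a root child collapses the root split and can
                # orphan the donor edge; disallow such placements
                if rec_edge.parent.parent is None:
                    continue
                if id(rec_edge) in used_edges or id(don_edge) in used_edges:
                    continue
                if not (_subtree_pure(rec_leaf, t) and _subtree_pure(don_leaf, t)):
                    continue
                if not _below_group_crown(don_leaf, t):
                    continue
                used_edges.update((id(rec_edge), id(don_edge)))
                used_groups.update((gm[rec_leaf], gm[don_leaf]))
                scope = "both" if etype == "hgt" else config.rearrangement_scope
                events.append(SimEvent(etype, don_leaf, rec_leaf, t, scope))
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            break
    else:
        raise TreetallyError(
            f"could not place {n_events} events on this tree; "
            "reduce event counts or widen the time window"
        )

    events.sort(key=lambda e: e.time)
    gene1 = _clone(root)
    gene2 = _clone(root)
    for e in events:
        targets = []
        if e.type == "duplication":
            for g in (gene1, gene2):
                _duplicate(g, e.donor, e.time)
            continue
        if e.segment_scope in ("both", "seg1"):
            targets.append(gene1)
        if e.segment_scope in ("both", "seg2"):
            targets.append(gene2)
        for g in targets:
            _regraft(g, e.recipient, e.donor, e.time)
    p1 = PhyloTree(gene1, {"segment": "seg1", "method": "true-gene-tree"})
    p2 = PhyloTree(gene2, {"segment": "seg2", "method": "true-gene-tree"})
    return p1, p2, EventLog(events)


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _discrete_gamma_rates(shape: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability discrete gamma categories (mean 1)."""
    if k == 1 or shape <= 0:
        return np.ones(max(k, 1))
    # boundaries in x-units of Gamma(shape, scale=1/shape)
    qs = stats.gamma.ppf(np.linspace(0, 1, k + 1), shape, scale=1.0 / shape)
    upper = special.gammainc(shape + 1, qs[1:] * shape)
    lower = special.gammainc(shape + 1, qs[:-1] * shape)
    rates = k * (upper - lower)
    return rates / rates.mean()


def evolve_sequences(
    gene_tree: PhyloTree,
    config: SimConfig,
    seed,
) -> tuple[SegmentAlignment, SequenceSet]:
    """Evolve one segment along a gene tree; returns the TRUE alignment
    (indels produce gap structure) and the ungapped leaf sequences.

    The substitution process is the 20-state uniform-exchangeability chain
    (protein Jukes-Cantor) with per-column rates drawn from a discrete gamma;
    indel events are Poisson per branch with geometric lengths, and every
    insertion opens an all-gap column block in the other rows of the true
    alignment.  Substitutions are applied along a branch before its indels;
    freshly inserted columns start at stationarity.
    """
    if config.seq_length < 1:
        raise DataError("seq_length must be >= 1")
    rng = np.random.default_rng(seed)
    root = gene_tree.tree
    k = config.n_rate_categories
    cat_rates = _discrete_gamma_rates(config.gamma_shape, k)
    L0 = config.seq_length
    master: list[int] = list(range(L0))
    col_rate: dict[int, float] = {
        i: float(cat_rates[rng.integers(k)]) for i in range(L0)
    }
    next_id = L0
    root_states = rng.integers(0, 20, size=L0)
    leaf_rows: dict[str, dict[int, int]] = {}

    def _substitute(states: np.ndarray, ids: list[int], b: float) -> np.ndarray:
        if b <= 0 or len(ids) == 0:
            return states.copy()
        rates = np.array([col_rate[i] for i in ids])
        p_change = (19 / 20) * (1 - np.exp(-(20 / 19) * b * rates))
        change = rng.random(len(ids)) < p_change
        out = states.copy()
        if change.any():
            shift = 1 + rng.integers(0, 19, size=int(change.sum()))
            out[change] = (out[change] + shift) % 20
        return out

    def _indels(states: np.ndarray, ids: list[int], b: float):
        nonlocal next_id
        if config.indel_rate <= 0 or b <= 0:
            return states, ids
        ids = list(ids)
        states = list(states)
        n_events = rng.poisson(config.indel_rate * b * (len(ids) + 1))
        for _ in range(n_events):
            length = int(rng.geometric(1.0 / config.indel_mean_length))
            if rng.random() < 0.5 and ids:  # deletion
                pos = int(rng.integers(len(ids)))
                del ids[pos : pos + length]
                del states[pos : pos + length]
            else:  # insertion
                pos = int(rng.integers(len(ids) + 1))
                new_ids = list(range(next_id, next_id + length))
                next_id += length
                for nid in new_ids:
                    col_rate[nid] = float(cat_rates[rng.integers(k)])
                # place new columns in the master order right after the
                # column preceding the insertion point in this lineage
                if pos == 0:
                    anchor = master.index(ids[0]) if ids else len(master)
                else:
                    anchor = master.index(ids[pos - 1]) + 1
                master[anchor:anchor] = new_ids
                ids[pos:pos] = new_ids
                states[pos:pos] = list(rng.integers(0, 20, size=length))
        return np.array(states, dtype=int), ids

    def _walk(node: TreeNode, states: np.ndarray, ids: list[int]) -> None:
        nonlocal leaf_rows
        if node.is_tip():
            leaf_rows[node.name] = dict(zip(ids, states.tolist()))
            return
        for child in node.children:
            b = child.length or 0.0
            st = _substitute(states, ids, b)
            st, new_ids = _indels(st, ids, b)
            _walk(child, st, new_ids)

    _walk(root, root_states, master[:])
    if any(len(r) == 0 for r in leaf_rows.values()):
        raise DataError("a lineage lost its entire segment to deletions")
    rows = {}
    for name, mapping in leaf_rows.items():
        rows[name] = "".join(
            AMINO_ACIDS[mapping[cid]] if cid in mapping else GAP for cid in master
        )
    aln = SegmentAlignment(rows)
    return aln, aln.ungapped()


# ---------------------------------------------------------------------------
# end-to-end dataset generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Everything one simulated family comprises, plus ground truth."""

    config: SimConfig
    species_tree: PhyloTree
    gene_trees: dict[str, PhyloTree]
    alignments: dict[str, SegmentAlignment]
    proteins: SequenceSet
    records: list[TaxonRecord]
    group_map: dict[str, str]
    event_log: EventLog

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write all files plus a checksum manifest; returns the manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_newick(TreeEnsemble([self.species_tree]), outdir / "species.nwk")
        for seg, tree in self.gene_trees.items():
            write_newick(TreeEnsemble([tree]), outdir / f"gene_{seg}.nwk")
        for seg, aln in self.alignments.items():
            write_alignment(aln, outdir / f"{seg}_true_alignment.fasta")
            write_fasta(aln.ungapped(), outdir / f"{seg}.fasta")
        write_fasta(self.proteins, outdir / "proteins.fasta")
        write_taxon_table(self.records, outdir / "taxa.tsv")
        self.event_log.to_tsv(outdir / "events.tsv")
        manifest = {}
        for p in sorted(outdir.iterdir()):
            if p.name == "manifest.json" or p.is_dir():
                continue
            manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Simulate a full two-segment dataset with planted events.

    Substreams of the master seed: species tree ``seed+1``, events
    ``seed+2``, segment k sequences ``[seed+3, k]``.
    """
    # not every Yule tree can host the requested events (a group whose crown
    # postdates the event window cannot donate an identifiable transfer), so
    # species trees are redrawn deterministically until placement succeeds
    last_err: Exception | None = None
    for redraw in range(50):
        species = simulate_species_tree(
            config.n_taxa,
            config.birth_rate,
            [config.seed + 1, redraw],
            config.tree_depth,
        )
        gm = assign_groups(species, config.n_groups)
        try:
            gene1, gene2, log = plant_events(species, config, config.seed + 2, gm)
            break
        except TreetallyError as exc:
            last_err = exc
    else:
        raise TreetallyError(
            f"no species tree hosting the requested events after 50 draws: {last_err}"
        )
    aln1, _ = evolve_sequences(gene1, config, [config.seed + 3, 0])
    aln2, _ = evolve_sequences(gene2, config, [config.seed + 3, 1])

    # full protein = seg1 + seg2 residues; per-taxon 1-based coordinates
    proteins = SequenceSet()
    records: list[TaxonRecord] = []
    group_of = dict(gm)
    for e in log.events:
        if e.type == "duplication":
            group_of[e.recipient] = group_of[e.donor]
    class_of = {
        g: PHY_CLASSES[i % len(PHY_CLASSES)]
        for i, g in enumerate(sorted(set(group_of.values())))
    }
    species_of = {
        t.name: getattr(t, "species", t.name) for t in species.tree.tips()
    }
    for e in log.events:
        if e.type == "duplication":
            species_of[e.recipient] = species_of.get(e.donor, e.donor)
    for code in aln1.codes:
        s1 = aln1.rows[code].replace(GAP, "")
        s2 = aln2.rows[code].replace(GAP, "")
        proteins.add(code, s1 + s2)
        grp = group_of[code]
        records.append(
            TaxonRecord(
                code=code,
                species=species_of.get(code, code),
                group=grp,
                phy_class=class_of[grp],
                seg1_range=(1, len(s1)),
                seg2_range=(len(s1) + 1, len(s1) + len(s2)),
            )
        )
    return SyntheticDataset(
        config=config,
        species_tree=species,
        gene_trees={"seg1": gene1, "seg2": gene2},
        alignments={"seg1": aln1, "seg2": aln2},
        proteins=proteins,
        records=records,
        group_map=group_of,
        event_log=log,
    )
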