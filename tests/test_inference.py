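"""Neighbor joining, least-squares branch lengths, consensus, Fitch."""

import itertools
import random

import numpy as np
import pytest

from oracles import (
    all_rooted_trees,
    bf_fitch_column,
    bf_split_tally,
    bf_splits,
    path_distance_matrix,
    random_weighted_tree,
    to_newick,
)
from treetally import (
    DataError,
    DistanceMatrix,
    EnsembleConfig,
    ExternalAdapter,
    PhyloTree,
    SegmentAlignment,
    TreeError,
    build_ensemble,
    fitch_parsimony_score,
    least_squares_branch_lengths,
    majority_rule_consensus,
    neighbor_joining,
    parse_newick,
    read_newick,
    write_newick,
)


def tree_from_tuple(t, lengths=None) -> PhyloTree:
    return PhyloTree(parse_newick(to_newick(t, lengths)))


def nj_path_matrix(tree: PhyloTree, order):
    """Path-length matrix of a PhyloTree, via per-tip depth accumulation."""
    root = tree.tree
    tips = {t.name: t for t in root.tips()}
    n = len(order)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = tips[order[i]], tips[order[j]]
            lca = root.lowest_common_ancestor([a, b])
            d = a.accumulate_to_ancestor(lca) + b.accumulate_to_ancestor(lca)
            D[i, j] = D[j, i] = d
    return D


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        lengths = {t.name: t.length for t in tree.tree.tips()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)  # = 1
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)  # = 2
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)  # = 3

    def test_additive_five_taxon_matrix_is_least_squares_optimum(self):
        """NJ on an additive matrix must hit the best-fitting of all 15
        unrooted 5-leaf topologies (least-squares residual 0)."""
        rng = random.Random(42)
        labels = ["A", "B", "C", "D", "E"]
        t, lengths = random_weighted_tree(labels, rng)
        D = path_distance_matrix(t, lengths, labels)
        dm = DistanceMatrix(labels, D)
        nj = neighbor_joining(dm)
        # brute force: fit branch lengths on every topology, find min residual
        best = None
        for topo in {tuple(sorted(map(str, bf_splits(x)))): x
                     for x in all_rooted_trees(labels)}.values():
            fitted = least_squares_branch_lengths(tree_from_tuple(topo), dm)
            resid = np.abs(nj_path_matrix(fitted, labels) - D).max()
            key = frozenset(map(frozenset, bf_splits(topo)))
            if best is None or resid < best[0]:
                best = (resid, key)
        assert best[0] == pytest.approx(0, abs=1e-9)
        assert frozenset(map(frozenset, nj.splits())) == best[1]

    def test_all_equal_matrix_deterministic_tie_break(self):
        labels = list("ABCDE")
        d = np.ones((5, 5)) - np.eye(5)
        t1 = neighbor_joining(DistanceMatrix(labels, d.copy()))
        t2 = neighbor_joining(DistanceMatrix(labels, d.copy()))
        assert t1.newick() == t2.newick()
        # lowest index pair joined first -> A and B form a cherry
        assert frozenset(["A", "B"]) in {
            frozenset(x.name for x in n.tips())
            for n in t1.tree.non_tips(include_self=False)
        }

    def test_non_symmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(DataError):
            DistanceMatrix(["a", "b", "c"], d)

    @pytest.mark.parametrize("n_leaves", [4, 6, 8, 10])
    def test_consistency_on_random_additive_matrices(self, n_leaves):
        rng = random.Random(n_leaves)
        labels = [f"t{i}" for i in range(n_leaves)]
        for rep in range(5):
            from oracles import random_topology
            topo = random_topology(labels, rng)
            lengths = {}

            def assign(node, is_root=True):
                if not is_root:
                    lengths[node] = rng.uniform(0.1, 1.0)
                if not isinstance(node, str):
                    assign(node[0], False)
                    assign(node[1], False)

            assign(topo)
            D = path_distance_matrix(topo, lengths, labels)
            nj = neighbor_joining(DistanceMatrix(labels, D))
            assert frozenset(map(frozenset, nj.splits())) == frozenset(
                map(frozenset, bf_splits(topo))
            )
            assert np.abs(nj_path_matrix(nj, labels) - D).max() < 1e-9

    def test_skbio_nj_cross_check(self):
        """Independent route: scikit-bio's own NJ agrees on topology."""
        import skbio

        rng = random.Random(99)
        labels = [f"t{i}" for i in range(7)]
        from oracles import random_topology
        topo = random_topology(labels, rng)
        lengths = {}

        def assign(node, is_root=True):
            if not is_root:
                lengths[node] = rng.uniform(0.2, 1.0)
            if not isinstance(node, str):
                assign(node[0], False)
                assign(node[1], False)

        assign(topo)
        D = path_distance_matrix(topo, lengths, labels)
        ours = neighbor_joining(DistanceMatrix(labels, D))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        assert ours.tree.compare_rfd(theirs) == 0


class TestLeastSquares:
    def test_additive_matrix_reproduces_exact_lengths(self):
        rng = random.Random(5)
        labels = list("ABCD")
        t, lengths = random_weighted_tree(labels, rng)
        D = path_distance_matrix(t, lengths, labels)
        fitted = least_squares_branch_lengths(
            tree_from_tuple(t), DistanceMatrix(labels, D)
        )
        assert np.abs(nj_path_matrix(fitted, labels) - D).max() < 1e-9

    def test_four_taxon_normal_equations_oracle(self):
        """Unrooted 4-taxon fit matches an explicit lstsq on the 5-edge
        incidence system built independently."""
        labels = list("ABCD")
        tree = PhyloTree(parse_newick("((A:1,B:1):1,(C:1,D:1):1);"))
        rng = np.random.default_rng(3)
        D = np.zeros((4, 4))
        vals = rng.uniform(0.5, 2.0, size=6)
        for k, (i, j) in enumerate(itertools.combinations(range(4), 2)):
            D[i, j] = D[j, i] = vals[k]
        dm = DistanceMatrix(labels, D)
        fitted = least_squares_branch_lengths(tree, dm)
        # independent design matrix: edges = A,B,C,D pendant + AB internal
        # pairs in index order: AB AC AD BC BD CD
        A_mat = np.array(
            [
                [1, 1, 0, 0, 0],
                [1, 0, 1, 0, 1],
                [1, 0, 0, 1, 1],
                [0, 1, 1, 0, 1],
                [0, 1, 0, 1, 1],
                [0, 0, 1, 1, 0],
            ],
            dtype=float,
        )
        y = np.array([D[0, 1], D[0, 2], D[0, 3], D[1, 2], D[1, 3], D[2, 3]])
        x = np.linalg.lstsq(A_mat, y, rcond=None)[0]
        expect = np.maximum(x, 0)
        got = {t.name: t.length for t in fitted.tree.tips()}
        assert got["A"] == pytest.approx(expect[0], abs=1e-9)
        assert got["B"] == pytest.approx(expect[1], abs=1e-9)
        assert got["C"] == pytest.approx(expect[2], abs=1e-9)
        assert got["D"] == pytest.approx(expect[3], abs=1e-9)
        internal = [
            n.length
            for n in fitted.tree.non_tips(include_self=False)
        ]
        # the rooted tree has two root-edges sharing the internal edge's role
        assert sum(internal) == pytest.approx(max(x[4], 0), abs=1e-9)

    def test_negative_internal_edge_clamped_to_zero(self):
        labels = list("ABCD")
        tree = PhyloTree(parse_newick("((A:1,B:1):1,(C:1,D:1):1);"))
        # star-like distances force a negative internal edge estimate
        D = np.array(
            [
                [0, 2.0, 1.0, 1.0],
                [2.0, 0, 1.0, 1.0],
                [1.0, 1.0, 0, 2.0],
                [1.0, 1.0, 2.0, 0],
            ]
        )
        fitted = least_squares_branch_lengths(tree, DistanceMatrix(labels, D))
        assert all(
            n.length >= 0 for n in fitted.tree.traverse(include_self=False)
        )
        internal = sum(
            n.length for n in fitted.tree.non_tips(include_self=False)
        )
        assert internal == pytest.approx(0.0, abs=1e-9)

    def test_leaf_mismatch_errors(self):
        tree = PhyloTree(parse_newick("((A:1,B:1):1,C:1);"))
        dm = DistanceMatrix(list("ABD"), np.zeros((3, 3)))
        with pytest.raises(TreeError):
            least_squares_branch_lengths(tree, dm)


class TestConsensus:
    def test_identical_trees_full_support(self):
        trees = [PhyloTree(parse_newick("((A:1,B:1):1,(C:1,D:1):1);")) for _ in range(5)]
        cons = majority_rule_consensus(trees)
        assert cons.splits() == trees[0].splits()
        sups = [n.support for n in cons.tree.non_tips(include_self=False)
                if n.support is not None]
        assert sups and all(s == 1.0 for s in sups)

    def test_two_thirds_split_included_with_support(self):
        t1 = PhyloTree(parse_newick("((A,B),(C,D));"))
        t2 = PhyloTree(parse_newick("((A,B),(C,D));"))
        t3 = PhyloTree(parse_newick("((A,C),(B,D));"))
        cons = majority_rule_consensus([t1, t2, t3])
        assert cons.splits() == t1.splits()
        (node,) = [n for n in cons.tree.non_tips(include_self=False)
                   if n.support is not None]
        assert node.support == pytest.approx(2 / 3)

    def test_exactly_half_excluded(self):
        t1 = PhyloTree(parse_newick("((A,B),(C,D));"))
        t2 = PhyloTree(parse_newick("((A,C),(B,D));"))
        cons = majority_rule_consensus([t1, t2])
        assert cons.splits() == set()

    def test_differing_leaf_sets_rejected(self):
        t1 = PhyloTree(parse_newick("((A,B),(C,D));"))
        t2 = PhyloTree(parse_newick("((A,B),(C,E));"))
        with pytest.raises(TreeError):
            majority_rule_consensus([t1, t2])

    def test_random_ensembles_match_brute_force_tally(self):
        from oracles import random_topology

        rng = random.Random(17)
        labels = [f"x{i}" for i in range(7)]
        for rep in range(20):
            tuples = [random_topology(labels, rng) for _ in range(7)]
            trees = [tree_from_tuple(t) for t in tuples]
            tally = bf_split_tally(tuples)
            cons = majority_rule_consensus(trees, 0.5)
            expect = {s for s, c in tally.items() if c / len(tuples) > 0.5}
            assert cons.splits() == expect
            # supports equal occurrence fractions
            leaves = frozenset(labels)
            for node in cons.tree.non_tips(include_self=False):
                side = frozenset(x.name for x in node.tips())
                key = side if min(labels) not in side else leaves - side
                if node.support is not None:
                    assert node.support == pytest.approx(tally[key] / len(tuples))

    def test_threshold_monotonicity(self):
        from oracles import random_topology

        rng = random.Random(23)
        labels = [f"x{i}" for i in range(7)]
        tuples = [random_topology(labels, rng) for _ in range(9)]
        trees = [tree_from_tuple(t) for t in tuples]
        prev = None
        for thr in (0.5, 0.6, 0.75, 0.9):
            splits = majority_rule_consensus(trees, thr).splits()
            if prev is not None:
                assert splits <= prev
            prev = splits

    def test_skbio_majority_rule_cross_check(self):
        """Independent route: scikit-bio's majority_rule yields the same
        split set on a random ensemble."""
        import skbio
        from oracles import random_topology

        rng = random.Random(31)
        labels = [f"x{i}" for i in range(6)]
        tuples = [random_topology(labels, rng) for _ in range(5)]
        ours = majority_rule_consensus([tree_from_tuple(t) for t in tuples])
        theirs = skbio.tree.majority_rule(
            [parse_newick(to_newick(t)) for t in tuples]
        )[0]
        assert PhyloTree(theirs).splits() == ours.splits()


class TestFitch:
    def test_invariant_column_zero_changes(self):
        tree = PhyloTree(parse_newick("((A,B),(C,D));"))
        aln = SegmentAlignment({c: "A" for c in "ABCD"})
        assert fitch_parsimony_score(tree, aln) == 0

    def test_one_change_for_clean_split(self):
        tree = PhyloTree(parse_newick("((A1,A2),(B1,B2));"))
        aln = SegmentAlignment({"A1": "A", "A2": "A", "B1": "C", "B2": "C"})
        assert fitch_parsimony_score(tree, aln) == 1

    def test_gaps_contribute_nothing(self):
        tree = PhyloTree(parse_newick("((A,B),(C,D));"))
        aln = SegmentAlignment({"A": "A", "B": "-", "C": "-", "D": "A"})
        assert fitch_parsimony_score(tree, aln) == 0

    def test_matches_exhaustive_assignment_on_small_trees(self):
        rng = random.Random(7)
        alphabet = "ACD"
        for n in (4, 5, 6):
            labels = [f"t{i}" for i in range(n)]
            from oracles import random_topology

            for rep in range(3):
                topo = random_topology(labels, rng)
                col = {lab: rng.choice(alphabet) for lab in labels}
                aln = SegmentAlignment({lab: col[lab] for lab in labels})
                expect = bf_fitch_column(topo, col, alphabet)
                got = fitch_parsimony_score(tree_from_tuple(topo), aln)
                assert got == expect

    def test_invariant_under_rerooting(self):
        newick = "((A,B),((C,D),E));"
        tree = parse_newick(newick)
        aln = SegmentAlignment(
            {"A": "AC", "B": "CC", "C": "AD", "D": "DD", "E": "AC"}
        )
        base = fitch_parsimony_score(PhyloTree(tree), aln)
        for tip_name in "ABCDE":
            c = tree.copy()
            tip = next(t for t in c.tips() if t.name == tip_name)
            rerooted = c.root_at(tip.parent)
            assert fitch_parsimony_score(PhyloTree(rerooted), aln) == base

    def test_missing_leaf_errors(self):
        tree = PhyloTree(parse_newick("((A,B),(C,D));"))
        aln = SegmentAlignment({"A": "A", "B": "A", "C": "A"})
        with pytest.raises(DataError):
            fitch_parsimony_score(tree, aln)


class TestNewickIO:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1)0.9:1,C:2);\n")
        ens = read_newick(p)
        out = tmp_path / "o.nwk"
        write_newick(ens, out)
        again = read_newick(out)
        assert again.trees[0].splits() == ens.trees[0].splits()
        a = {t.name: t.length for t in again.trees[0].tree.tips()}
        assert a == {"A": 1.0, "B": 1.0, "C": 2.0}

    def test_duplicate_leaf_rejected(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,A:1):1,C:2);\n")
        with pytest.raises(TreeError, match="duplicate"):
            read_newick(p)

    def test_unbalanced_parentheses_rejected(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1:1,C:2(;\n")
        with pytest.raises(TreeError):
            read_newick(p)

    def test_multi_tree_file_has_ordinals(self, tmp_path):
        p = tmp_path / "many.nwk"
        p.write_text("".join("((A,B),(C,D));\n" for _ in range(17)))
        ens = read_newick(p)
        assert len(ens) == 17
        assert [t.provenance["ordinal"] for t in ens] == list(range(17))


class TestBuildEnsemble:
    @pytest.fixture
    def aln(self):
        rng = np.random.default_rng(0)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        base = [rng.integers(20) for _ in range(60)]
        rows = {}
        for i in range(6):
            seq = [
                (b + rng.integers(3)) % 20 if rng.random() < 0.3 else b
                for b in base
            ]
            rows[f"t{i}"] = "".join(aas[s] for s in seq)
        return SegmentAlignment(rows)

    def test_two_models_two_consensus_trees(self, aln):
        ens = build_ensemble(aln, EnsembleConfig(models=["p", "kimura"], bootstrap=10, seed=1))
        assert len(ens) == 2
        tags = [(t.provenance["matrix"], t.provenance["method"]) for t in ens]
        assert len(set(tags)) == 2

    def test_deterministic_across_runs(self, aln):
        c = EnsembleConfig(models=["p", "kimura"], bootstrap=10, seed=5)
        e1 = build_ensemble(aln, c)
        e2 = build_ensemble(aln, c)
        assert [t.newick() for t in e1] == [t.newick() for t in e2]

    def test_bootstrap_zero_gives_plain_nj(self, aln):
        ens = build_ensemble(aln, EnsembleConfig(models=["kimura"], bootstrap=0))
        assert len(ens) == 1 and ens.trees[0].provenance["method"] == "nj"

    def test_empty_config_rejected(self, aln):
        with pytest.raises(ValueError):
            build_ensemble(aln, EnsembleConfig(models=[], bootstrap=0))

    def test_supports_equal_direct_recount(self, aln):
        """Consensus supports equal the fraction of bootstrap NJ trees
        carrying the split, recounted via an independent replicate run."""
        from treetally.alignment import bootstrap_indices
        from treetally import distance_matrix

        cfg = EnsembleConfig(models=["p"], bootstrap=20, seed=9)
        (cons,) = build_ensemble(aln, cfg).trees
        # regenerate the replicate NJ trees exactly as the ensemble does
        reps = []
        for r in range(cfg.bootstrap):
            rng = np.random.default_rng([cfg.seed, 0, r])
            idx = [int(i) for i in rng.integers(0, aln.n_cols, size=aln.n_cols)]
            rep = aln.take_columns(idx)
            reps.append(neighbor_joining(distance_matrix(rep, "p")))
        leaves = frozenset(aln.codes)
        for node in cons.tree.non_tips(include_self=False):
            if node.support is None:
                continue
            side = frozenset(x.name for x in node.tips())
            key = side if min(leaves) not in side else leaves - side
            frac = sum(key in t.splits() for t in reps) / len(reps)
            assert node.support == pytest.approx(frac)
            assert 0.0 <= node.support <= 1.0

    def test_external_adapter_runs_command(self, aln, tmp_path):
        adapter = ExternalAdapter(
            "toy", "printf '((t0:1,t1:1):1,(t2:1,(t3:1,(t4:1,t5:1):1):1):1);' > {out}"
        )
        ens = build_ensemble(
            aln, EnsembleConfig(models=[], bootstrap=0, adapters=[adapter])
        )
        assert len(ens) == 1
        assert ens.trees[0].provenance["method"] == "adapter:toy"
        assert set(ens.trees[0].leaf_names) == set(aln.codes)

    def test_failing_adapter_raises(self, aln):
        adapter = ExternalAdapter("bad", "false")
        with pytest.raises(TreeError, match="bad"):
            build_ensemble(
                aln, EnsembleConfig(models=[], bootstrap=0, adapters=[adapter])
            )
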