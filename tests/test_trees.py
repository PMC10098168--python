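import numpy as np
import pytest

from conftest import mad_grid_oracle, random_metric_tree
from phyloclock.trees import (
    Clade,
    NewickParseError,
    PhyloTree,
    TaxonAnnotation,
    clade_composition,
    find_monophyletic_clades,
    mad_root,
    read_annotations,
    subsample_clades,
    write_annotations,
)


class TestNewick:
    def test_minimal_two_tip(self):
        tree = PhyloTree.from_newick("(A:1,B:2);")
        assert tree.tip_labels == ["A", "B"]
        lengths = {n.label: n.length for n in tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0}

    def test_internal_label_passthrough(self):
        tree = PhyloTree.from_newick("((A:1,B:1)90:1,C:2);")
        internal = [n for n in tree.postorder() if not n.is_tip and n.parent]
        assert internal[0].label == "90"
        assert "90" in tree.to_newick()

    def test_quoted_labels(self):
        tree = PhyloTree.from_newick("('sp one':1,'sp two':2);")
        assert tree.tip_labels == ["sp one", "sp two"]
        again = PhyloTree.from_newick(tree.to_newick())
        assert again.tip_labels == ["sp one", "sp two"]

    @pytest.mark.parametrize("bad", ["((A:1,B:2);", "(A:1,B:2", "(A:1,'B:2);"])
    def test_malformed_raises(self, bad):
        with pytest.raises(NewickParseError):
            PhyloTree.from_newick(bad)

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PhyloTree.from_newick("(A:1,A:2);")

    def test_round_trip_random_trees(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 12))
            tree = random_metric_tree(n, rng)
            text = tree.to_newick()
            reparsed = PhyloTree.from_newick(text)
            assert reparsed.to_newick() == text


class TestMADRooting:
    def test_perfect_clock_quartet(self, quartet):
        placement, rooted = mad_root(quartet)
        assert placement.mad == pytest.approx(0.0, abs=1e-12)
        assert placement.edge_tips in ({"A", "B"}, {"C", "D"})
        assert placement.rho == pytest.approx(1.0)
        # rooted tree is ultrametric about the new root
        _, dmat = rooted.tip_distance_matrix()
        root_depths = {}
        for tip in rooted.tips():
            d, node = 0.0, tip
            while node.parent is not None:
                d += node.length
                node = node.parent
            root_depths[tip.label] = d
        assert np.allclose(list(root_depths.values()), 2.0)

    def test_symmetric_cherry_midpoint(self):
        tree = PhyloTree.from_newick("((A:1,B:1):0.5,C:1,D:1);")
        placement, _ = mad_root(tree)
        assert placement.mad == pytest.approx(0.0, abs=1e-12)
        assert placement.rho == pytest.approx(0.25)

    def test_too_few_tips(self):
        with pytest.raises(ValueError, match="3 tips"):
            mad_root(PhyloTree.from_newick("(A:1,B:2);"))

    def test_all_zero_lengths(self):
        with pytest.raises(ValueError, match="zero"):
            mad_root(PhyloTree.from_newick("((A:0,B:0):0,C:0,D:0);"))

    def test_matches_grid_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 9))
            tree = random_metric_tree(n, rng)
            placement, _ = mad_root(tree)
            tipset, rho, mad = mad_grid_oracle(tree, grid_step_frac=1e-3)
            all_tips = set(tree.tip_labels)
            assert placement.edge_tips in (tipset, frozenset(all_tips - tipset))
            assert placement.mad == pytest.approx(mad, rel=1e-3)

    def test_clock_tree_recovers_true_root(self, rng):
        from phyloclock.synth import simulate_time_tree

        for seed in range(5):
            chrono = simulate_time_tree(8, 100.0, seed=seed)
            chrono.set_lengths_from_ages()
            true_split = {frozenset(t.label for t in _tips_of(c)) for c in chrono.root.children}
            placement, _ = mad_root(chrono)
            assert placement.mad == pytest.approx(0.0, abs=1e-9)
            assert placement.edge_tips in true_split or (
                frozenset(chrono.tip_labels) - placement.edge_tips
            ) in true_split


def _tips_of(node):
    return [n for n in _walk(node) if n.is_tip]


def _walk(node):
    yield node
    for c in node.children:
        yield from _walk(c)


def _annotate(values, rank="genus"):
    return {
        label: TaxonAnnotation(label=label, ranks={rank: v})
        for label, v in values.items()
    }


class TestMonophyly:
    def test_simple_block(self):
        tree = PhyloTree.from_newick("(((a1:1,a2:1):1,a3:1):1,b1:1);")
        ann = _annotate({"a1": "a", "a2": "a", "a3": "a", "b1": "b"})
        clades = find_monophyletic_clades(tree, ann, "genus")
        by_value = {c.value: set(c.tips) for c in clades}
        assert by_value["a"] == {"a1", "a2", "a3"}
        assert by_value["b"] == {"b1"}

    def test_interleaved_only_singletons(self):
        tree = PhyloTree.from_newick("(((a1:1,b1:1):1,a2:1):1,b2:1);")
        ann = _annotate({"a1": "a", "b1": "b", "a2": "a", "b2": "b"})
        clades = find_monophyletic_clades(tree, ann, "genus")
        assert all(len(c.tips) == 1 for c in clades)

    def test_unknown_never_joins(self):
        tree = PhyloTree.from_newick("((a1:1,a2:1):1,(a3:1,b1:1):1);")
        ann = _annotate({"a1": "a", "a2": "a", "a3": "", "b1": "b"})
        clades = find_monophyletic_clades(tree, ann, "genus")
        tipsets = [set(c.tips) for c in clades]
        assert {"a1", "a2"} in tipsets
        assert all("a3" not in s for s in tipsets)

    def test_missing_rank_errors(self):
        tree = PhyloTree.from_newick("(a1:1,a2:1);")
        ann = _annotate({"a1": "a", "a2": "a"}, rank="genus")
        with pytest.raises(KeyError, match="phylum"):
            find_monophyletic_clades(tree, ann, "phylum")

    def test_planted_blocks_vs_node_scan_oracle(self, rng):
        from phyloclock.synth import make_taxonomy_fixture, simulate_time_tree

        for seed in range(10):
            tree = simulate_time_tree(14, 1.0, seed=seed)
            try:
                ann, truth = make_taxonomy_fixture(
                    tree, order_block_sizes=(4, 3), seed=seed
                )
            except ValueError:
                continue
            clades = find_monophyletic_clades(tree, ann, "order")
            found = {frozenset(c.tips) for c in clades if len(c.tips) > 1}
            planted = {frozenset(b["tips"]) for b in truth["blocks"]}
            assert planted <= found
            # oracle: exhaustive per-node scan
            oracle = set()
            for node in tree.preorder():
                tips = [t.label for t in _tips_of(node)]
                vals = {ann[t].value("order") for t in tips}
                if len(vals) == 1 and None not in vals and len(tips) > 1:
                    parent_ok = True
                    if node.parent is not None:
                        ptips = [t.label for t in _tips_of(node.parent)]
                        pvals = {ann[t].value("order") for t in ptips}
                        parent_ok = not (len(pvals) == 1 and None not in pvals)
                    if parent_ok:
                        oracle.add(frozenset(tips))
            assert found == oracle


class TestSubsample:
    def test_keep_two_of_five(self):
        tree = PhyloTree.from_newick(
            "((a1:1,(a2:1,(a3:1,(a4:1,a5:1):1):1):1):1,b1:1);"
        )
        clade = Clade(tips=("a1", "a2", "a3", "a4", "a5"), value="a", share=1.0, node=None)
        kept = subsample_clades(tree, [clade], k=2)
        assert len(kept & {"a1", "a2", "a3", "a4", "a5"}) == 2
        assert "b1" in kept

    def test_singleton_clade(self):
        tree = PhyloTree.from_newick("((a1:1,b1:1):1,c1:1);")
        kept = subsample_clades(tree, [("a1",)], k=2)
        assert kept == {"a1", "b1", "c1"}

    def test_k1_count_oracle(self):
        newick = (
            "(((a1:1,a2:1):1,(a3:1,a4:1):1):1,"
            "((b1:1,b2:1):1,(c1:1,(x1:1,(x2:1,x3:1):1):1):1):1);"
        )
        tree = PhyloTree.from_newick(newick)
        clades = [("a1", "a2", "a3", "a4"), ("b1", "b2"), ("c1",)]
        kept = subsample_clades(tree, clades, k=1)
        assert len(kept) == 3 + 3  # one per clade + 3 background tips
        assert {"x1", "x2", "x3"} <= kept

    def test_k2_keeps_maximally_divergent_pair(self):
        tree = PhyloTree.from_newick("((a1:10,(a2:1,a3:1):1):1,b1:1);")
        clade = ("a1", "a2", "a3")
        kept = subsample_clades(tree, [clade], k=2)
        # a1 is far from both; pair (a1, a2) wins by lexicographic tie-break
        assert "a1" in kept
        assert kept & {"a2", "a3"} == {"a2"}

    def test_background_tips_never_removed(self, rng):
        tree = random_metric_tree(10, rng)
        labels = tree.tip_labels
        clade = tuple(labels[:4])
        kept = subsample_clades(tree, [clade], k=2)
        assert set(labels[4:]) <= kept
        assert len(kept) == 2 + len(labels) - 4


class TestCladeComposition:
    def test_70_percent_clade(self):
        tips = [f"p{i}" for i in range(7)] + [f"q{i}" for i in range(3)]
        inner = ",".join(f"{t}:1" for t in tips)
        # caterpillar containing all 10 under one node, plus outgroup
        tree = PhyloTree.from_newick(f"(({inner}):1,out:1);")
        ann = _annotate(
            {**{f"p{i}": "P" for i in range(7)}, **{f"q{i}": "Q" for i in range(3)}, "out": "R"},
            rank="phylum",
        )
        clades = clade_composition(tree, ann, "phylum", threshold=0.67)
        shares = {c.value: c.share for c in clades if len(c.tips) == 10}
        assert shares == {"P": pytest.approx(0.70)}

    def test_pure_clade_share_one(self):
        tree = PhyloTree.from_newick("((p1:1,p2:1):1,q1:1);")
        ann = _annotate({"p1": "P", "p2": "P", "q1": "Q"}, rank="phylum")
        clades = clade_composition(tree, ann, "phylum")
        best = {frozenset(c.tips): c.share for c in clades}
        assert best[frozenset({"p1", "p2"})] == 1.0

    def test_nested_maximality(self):
        # parent share 0.60 (3 of 5), child share 0.75 (3 of 4)
        tree = PhyloTree.from_newick("(((p1:1,p2:1,p3:1,q1:1):1,q2:1):1,out:1);")
        ann = _annotate(
            {"p1": "P", "p2": "P", "p3": "P", "q1": "Q", "q2": "Q", "out": "R"},
            rank="phylum",
        )
        clades = clade_composition(tree, ann, "phylum", threshold=0.67)
        labeled = [c for c in clades if c.value == "P" and len(c.tips) > 1]
        assert len(labeled) == 1
        assert set(labeled[0].tips) == {"p1", "p2", "p3", "q1"}
        assert labeled[0].share == pytest.approx(0.75)

    def test_disjoint_and_maximal(self, rng):
        from phyloclock.synth import make_taxonomy_fixture

        tree = random_metric_tree(16, rng)
        ann, _ = make_taxonomy_fixture(tree, order_block_sizes=(), n_hgt=0, seed=1)
        clades = clade_composition(tree, ann, "domain", threshold=0.67)
        seen = set()
        for c in clades:
            assert not (seen & set(c.tips)), "clades overlap"
            seen |= set(c.tips)

    def test_threshold_validation(self, quartet):
        ann = _annotate({t: "X" for t in quartet.tip_labels}, rank="phylum")
        with pytest.raises(ValueError):
            clade_composition(quartet, ann, "phylum", threshold=1.5)


class TestAnnotationsIO:
    def test_round_trip(self, tmp_path):
        ann = {
            "t1": TaxonAnnotation("t1", {"genus": "Bacillus", "phylum": "Firmicutes"}),
            "t2": TaxonAnnotation("t2", {"genus": "Neurospora", "phylum": "Ascomycota"}),
        }
        path = tmp_path / "ann.tsv"
        write_annotations(ann, path)
        back = read_annotations(path)
        assert back["t1"].value("genus") == "Bacillus"
        assert back["t2"].value("phylum") == "Ascomycota"
        assert back["t1"].value("domain") is None
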