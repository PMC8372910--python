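import itertools

import dendropy
import numpy as np
import pytest

from plastome_hotspots.distances import DistanceMatrix
from plastome_hotspots.trees import (
    CladeDefinition,
    TreeError,
    backbone_match,
    collapse_clade,
    is_monophyletic,
    neighbor_joining,
    prune,
    read_newick,
    rf_distance,
    root_with_outgroup,
    splits,
    write_newick,
)

# ---------------------------------------------------------------------------
# oracle helpers


def all_rooted_topologies(labels):
    """Every rooted binary topology over labels, as nested tuples."""
    if len(labels) == 1:
        return [labels[0]]
    out = []
    first, rest = labels[0], labels[1:]
    for k in range(1, len(rest) + 1):
        for left_rest in itertools.combinations(rest, k - 1):
            left = [first, *left_rest]
            right = [l for l in rest if l not in left_rest]
            if not right:
                continue
            for lt in all_rooted_topologies(left):
                for rt in all_rooted_topologies(right):
                    out.append((lt, rt))
    return out


def topo_to_newick(t):
    if isinstance(t, str):
        return t
    return "(" + ",".join(topo_to_newick(c) for c in t) + ")"


def clades_of(t):
    """Oracle clade sets via independent recursion over the tuple topology."""
    if isinstance(t, str):
        return [frozenset([t])]
    subs = [clades_of(c) for c in t]
    merged = [s for lst in subs for s in lst]
    merged.append(frozenset().union(*(lst[-1] for lst in subs)))
    return merged


def random_additive_tree(rng, labels):
    """Random binary tree newick with strictly positive branch lengths."""
    nodes = [f"{l}:{rng.uniform(0.2, 2.0):.4f}" for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.2, 2.0):.4f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return "(" + ",".join(nodes) + ");"


def patristic(tree):
    """Leaf-to-leaf path lengths from my Tree structure (direct recursion)."""
    dists = {}

    def collect(node):
        if node.is_leaf():
            return {node.label: 0.0}
        sub = []
        for c in node.children:
            d = collect(c)
            sub.append({k: v + (c.length or 0.0) for k, v in d.items()})
        for a, b in itertools.combinations(range(len(sub)), 2):
            for x, dx in sub[a].items():
                for y, dy in sub[b].items():
                    dists[frozenset((x, y))] = dx + dy
        merged = {}
        for d in sub:
            merged.update(d)
        return merged

    collect(tree.root)
    return dists


# ---------------------------------------------------------------------------


class TestNewickIO:
    def test_basic_parse(self):
        t = read_newick("((A,B),(C,D));")
        assert t.leaf_set() == {"A", "B", "C", "D"}

    def test_canonical_roundtrip(self):
        text = write_newick(read_newick("((D,C),(B,A));"))
        assert text == "((A,B),(C,D));"
        assert write_newick(read_newick(text)) == text

    def test_support_and_length_preserved(self):
        t = read_newick("((A:0.1,B:0.2)100:0.01,C:0.3);")
        out = write_newick(t)
        assert "100:0.01" in out
        assert "B:0.2" in out

    def test_quoted_labels(self):
        t = read_newick("('Taxillus chinensis A':0.1,B:0.2);")
        assert "Taxillus chinensis A" in t.leaf_set()
        assert "'Taxillus chinensis A'" in write_newick(t)

    def test_unbalanced_parens_error(self):
        with pytest.raises(TreeError, match="Newick"):
            read_newick("((A,B),(C,D);")

    def test_duplicate_leaves_error(self):
        with pytest.raises(TreeError, match="duplicate"):
            read_newick("((A,B),(A,C));")


class TestNeighborJoining:
    def _dm(self, taxa, d):
        return DistanceMatrix(taxa, np.asarray(d, dtype=float), "p")

    def test_three_taxa_closed_form(self):
        # d(a,b)=3, d(a,c)=4, d(b,c)=5 -> la=1, lb=2, lc=3
        dm = self._dm(["a", "b", "c"], [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        t = neighbor_joining(dm)
        d = patristic(t)
        assert d[frozenset(("a", "b"))] == pytest.approx(3)
        assert d[frozenset(("a", "c"))] == pytest.approx(4)
        assert d[frozenset(("b", "c"))] == pytest.approx(5)

    def test_additive_four_taxon_recovery(self):
        ref = read_newick("((A:1,B:2):1,(C:3,D:4));")
        dd = patristic(ref)
        taxa = ["A", "B", "C", "D"]
        mat = [[dd.get(frozenset((x, y)), 0.0) for y in taxa] for x in taxa]
        t = neighbor_joining(self._dm(taxa, mat))
        assert frozenset({frozenset("AB"), frozenset("CD")}) in splits(t)
        got = patristic(t)
        for pair, val in dd.items():
            assert got[pair] == pytest.approx(val, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_additive_matrices_recovered(self, seed):
        rng = np.random.default_rng(seed)
        labels = list("ABCDEF")
        ref = read_newick(random_additive_tree(rng, labels))
        dd = patristic(ref)
        mat = [
            [dd.get(frozenset((x, y)), 0.0) for y in labels] for x in labels
        ]
        t = neighbor_joining(self._dm(labels, mat))
        # NJ is exact on additive matrices: same unrooted topology, exact paths
        assert rf_distance(t, ref) == 0
        got = patristic(t)
        for pair, val in dd.items():
            assert got[pair] == pytest.approx(val, abs=1e-9)

    def test_leaf_set_conserved(self):
        rng = np.random.default_rng(7)
        labels = [f"t{i}" for i in range(8)]
        ref = read_newick(random_additive_tree(rng, labels))
        dd = patristic(ref)
        mat = [
            [dd.get(frozenset((x, y)), 0.0) for y in labels] for x in labels
        ]
        assert neighbor_joining(self._dm(labels, mat)).leaf_set() == set(labels)

    def test_refuses_undefined_entries(self):
        d = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        with pytest.raises(TreeError, match="undefined"):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], d, "K2P"))

    def test_needs_three_taxa(self):
        with pytest.raises(TreeError):
            neighbor_joining(self._dm(["a", "b"], [[0, 1], [1, 0]]))


class TestRooting:
    def test_outgroup_becomes_root_child(self):
        t = root_with_outgroup(read_newick("((A,B),(C,O));"), {"O"})
        kids = t.root.children
        labels = [k.label for k in kids if k.is_leaf()]
        assert labels == ["O"] or labels == ["O", None]
        assert t.rooted

    def test_rotation_invariance(self):
        a = root_with_outgroup(read_newick("((A,B),(C,O));"), {"O"})
        b = root_with_outgroup(read_newick("((O,C),(B,A));"), {"O"})
        assert write_newick(a) == write_newick(b)

    def test_multi_taxon_outgroup(self):
        t = root_with_outgroup(read_newick("((A,B),(O1,O2));"), {"O1", "O2"})
        assert is_monophyletic(t, {"O1", "O2"})
        assert is_monophyletic(t, {"A", "B"})

    def test_non_separable_outgroup_errors(self):
        with pytest.raises(TreeError, match="monophyletic"):
            root_with_outgroup(read_newick("((A,O1),(O2,B));"), {"O1", "O2"})

    def test_unknown_outgroup_taxon_errors(self):
        with pytest.raises(TreeError, match="X"):
            root_with_outgroup(read_newick("((A,B),C);"), {"X"})

    @pytest.mark.parametrize("seed", range(5))
    def test_rerooting_is_idempotent(self, seed):
        rng = np.random.default_rng(200 + seed)
        labels = [f"t{i}" for i in range(7)]
        t = read_newick(random_additive_tree(rng, labels))
        og = {labels[int(rng.integers(len(labels)))]}
        once = root_with_outgroup(t, og)
        twice = root_with_outgroup(once, og)
        assert write_newick(once) == write_newick(twice)


class TestMonophyly:
    def test_textbook_cases(self):
        t = read_newick("((A,B),(C,D));")
        assert is_monophyletic(t, {"A", "B"})
        assert not is_monophyletic(t, {"A", "C"})

    def test_unknown_taxon_named_in_error(self):
        with pytest.raises(TreeError, match="Z"):
            is_monophyletic(read_newick("((A,B),C);"), {"A", "Z"})

    def test_exhaustive_five_leaf_oracle(self):
        labels = list("ABCDE")
        for topo in all_rooted_topologies(labels):
            t = read_newick(topo_to_newick(topo) + ";")
            truth = set(clades_of(topo))
            truth.add(frozenset(labels))
            for r in range(1, 6):
                for sub in itertools.combinations(labels, r):
                    want = frozenset(sub) in truth
                    assert is_monophyletic(t, set(sub)) == want

    def test_invariant_under_leaf_order(self):
        a = read_newick("((A,B),((C,D),E));")
        b = read_newick("((E,(D,C)),(B,A));")
        for taxa in ({"C", "D"}, {"C", "D", "E"}, {"A", "C"}):
            assert is_monophyletic(a, taxa) == is_monophyletic(b, taxa)

    def test_polytomy_counts_only_exact_node(self):
        t = read_newick("((A,B,C),D);")
        assert is_monophyletic(t, {"A", "B", "C"})
        assert not is_monophyletic(t, {"A", "B"})


class TestSplitsAndRF:
    def test_rf_self_zero_and_symmetry(self):
        a = read_newick("((A,B),(C,(D,E)));")
        b = read_newick("((A,C),(B,(D,E)));")
        assert rf_distance(a, a) == 0
        assert rf_distance(a, b) == rf_distance(b, a) > 0

    def test_leaf_mismatch_errors(self):
        with pytest.raises(TreeError, match="differ"):
            rf_distance(read_newick("((A,B),C);"), read_newick("((A,B),D);"))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_dendropy_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        labels = [f"t{i}" for i in range(8)]
        n1 = random_additive_tree(rng, labels)
        n2 = random_additive_tree(rng, labels)
        mine = rf_distance(read_newick(n1), read_newick(n2))
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=n1, schema="newick", taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=n2, schema="newick", taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        want = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert mine == want

    def test_split_enumeration_small_case(self):
        t = read_newick("((A,B),(C,D),E);")
        assert splits(t) == {
            frozenset({frozenset("AB"), frozenset("CDE")}),
            frozenset({frozenset("CD"), frozenset("ABE")}),
        }


class TestPruneCollapse:
    def test_prune_keeps_lengths_additive(self):
        t = read_newick("((A:1,B:2):3,(C:4,D:5):6);")
        p = prune(t, {"A", "C", "D"})
        d = patristic(p)
        assert d[frozenset(("A", "C"))] == pytest.approx(1 + 3 + 6 + 4)

    def test_collapse_clade_replaces_subtree(self):
        t = read_newick("(((A,B),C),(D,E));")
        c = collapse_clade(t, {"A", "B"}, "AB")
        assert c.leaf_set() == {"AB", "C", "D", "E"}
        assert is_monophyletic(c, {"AB", "C"})

    def test_collapse_requires_monophyly(self):
        with pytest.raises(TreeError, match="monophyletic"):
            collapse_clade(read_newick("((A,C),(B,D));"), {"A", "B"}, "AB")


class TestCladeDefinition:
    def test_overlap_rejected(self):
        with pytest.raises(TreeError, match="overlap"):
            CladeDefinition(
                clades={"I": {"A", "B"}, "II": {"B", "C"}}, outgroup={"O"}
            )

    def test_json_roundtrip(self, tmp_path):
        cd = CladeDefinition(
            clades={"I": {"A", "B"}, "II": {"C", "D"}},
            outgroup={"O"},
            excluded={"X"},
        )
        p = tmp_path / "clades.json"
        cd.to_json(p)
        back = CladeDefinition.from_json(p)
        assert back == cd


class TestBackboneMatch:
    CD = CladeDefinition(
        clades={
            "I": {"A1", "A2"},
            "II": {"B1", "B2"},
            "III": {"C1", "C2"},
        },
        outgroup={"O"},
    )
    REF = "((((A1,A2),(B1,B2)),(C1,C2)),O);"

    def test_identity_matches(self):
        ref = read_newick(self.REF)
        assert backbone_match(ref, read_newick(self.REF), self.CD)

    def test_wrong_backbone_with_monophyletic_clades(self):
        # clades intact but (I,(II,III)) instead of ((I,II),III)
        cand = read_newick("(((A1,A2),((B1,B2),(C1,C2))),O);")
        ref = read_newick(self.REF)
        assert not backbone_match(cand, ref, self.CD)
        # the clade points would still all be earned
        rooted = root_with_outgroup(cand, {"O"})
        for taxa in self.CD.clades.values():
            assert is_monophyletic(rooted, taxa)

    def test_broken_clade_fails_regardless(self):
        cand = read_newick("((((A1,B1),(A2,B2)),(C1,C2)),O);")
        assert not backbone_match(cand, read_newick(self.REF), self.CD)

    def test_extra_taxa_ignored(self):
        cand = read_newick("(((((A1,A2),X9),(B1,B2)),(C1,C2)),O);")
        assert backbone_match(cand, read_newick(self.REF), self.CD)

    def test_excluded_taxa_pruned_first(self):
        cd = CladeDefinition(
            clades=self.CD.clades, outgroup={"O"}, excluded={"X9"}
        )
        # X9 breaks clade I unless pruned
        cand = read_newick("((((A1,(X9,A2)),(B1,B2)),(C1,C2)),O);")
        assert backbone_match(cand, read_newick(self.REF), cd)

    def test_inconsistent_reference_raises(self):
        bad_ref = read_newick("((((A1,B1),(A2,B2)),(C1,C2)),O);")
        with pytest.raises(TreeError, match="reference"):
            backbone_match(read_newick(self.REF), bad_ref, self.CD)
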