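"""Trees: Newick I/O, neighbor joining, rooting, monophyly, backbone matching.

Newick parsing is delegated to dendropy; everything downstream (canonical
writing, rerooting, pruning, clade collapsing, Robinson-Foulds comparison and
the Saitou-Nei neighbor-joining builder) operates on a minimal node structure
so the scoring semantics are fully under this package's control.

Internal-node ``label`` holds the support/annotation of the edge above the
node; supports are carried through rooting and pruning but never used in any
scoring decision.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .distances import DistanceMatrix


class TreeError(ValueError):
    pass


@dataclass
class Node:
    label: str | None = None
    length: float | None = None
    children: list["Node"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    root: Node
    rooted: bool = False

    def leaves(self) -> list[Node]:
        out: list[Node] = []

        def walk(n: Node) -> None:
            if n.is_leaf():
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaf_labels())

    def copy(self) -> "Tree":
        def dup(n: Node) -> Node:
            return Node(n.label, n.length, [dup(c) for c in n.children])

        return Tree(dup(self.root), self.rooted)


# ---------------------------------------------------------------------------
# Newick I/O

_UNQUOTED_OK = re.compile(r"^[A-Za-z0-9_.\-+|]+$")


def _quote(label: str) -> str:
    if _UNQUOTED_OK.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _fmt_len(x: float) -> str:
    return f"{x:.10g}"


def read_newick(text: str) -> Tree:
    """Parse a Newick string (branch lengths, support labels, quoted labels)."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"invalid Newick: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise TreeError("leaf without a label in Newick input")
            return Node(dnode.taxon.label, dnode.edge.length)
        return Node(
            dnode.label,
            dnode.edge.length,
            [convert(c) for c in dnode.child_nodes()],
        )

    root = convert(dtree.seed_node)
    tree = Tree(root, rooted=len(root.children) == 2)
    labels = tree.leaf_labels()
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise TreeError(f"duplicate leaf labels: {dupes}")
    if len(labels) < 2:
        raise TreeError("a tree needs at least 2 leaves")
    return tree


def read_newick_file(path: str | Path) -> Tree:
    return read_newick(Path(path).read_text())


def _min_leaf(n: Node) -> str:
    if n.is_leaf():
        return n.label
    return min(_min_leaf(c) for c in n.children)


def write_newick(tree: Tree) -> str:
    """Canonical Newick: children ordered by smallest descendant leaf label."""

    def render(n: Node) -> str:
        if n.is_leaf():
            s = _quote(n.label)
        else:
            kids = sorted(n.children, key=_min_leaf)
            s = "(" + ",".join(render(c) for c in kids) + ")"
            if n.label:
                s += _quote(n.label)
        if n.length is not None:
            s += ":" + _fmt_len(n.length)
        return s

    kids = sorted(tree.root.children, key=_min_leaf)
    body = "(" + ",".join(render(c) for c in kids) + ")"
    if tree.root.label:
        body += _quote(tree.root.label)
    return body + ";"


def write_newick_file(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Undirected view (for rooting and bipartitions)


class _Graph:
    """Undirected tree graph; edge attrs are (length, support label)."""

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, tuple[float | None, str | None]]] = {}
        self.leaf_label: dict[int, str] = {}
        self._next = 0

    def new_node(self) -> int:
        i = self._next
        self._next += 1
        self.adj[i] = {}
        return i

    def add_edge(self, u: int, v: int, length, support) -> None:
        self.adj[u][v] = (length, support)
        self.adj[v][u] = (length, support)

    def remove_node(self, u: int) -> None:
        for v in list(self.adj[u]):
            del self.adj[v][u]
        del self.adj[u]

    def edges(self) -> list[tuple[int, int]]:
        out = []
        for u in self.adj:
            for v in self.adj[u]:
                if u < v:
                    out.append((u, v))
        return out

    def side_leaves(self, u: int, away_from: int) -> frozenset[str]:
        """Leaf labels reachable from u without crossing the edge to away_from."""
        seen = {away_from, u}
        stack = [u]
        labels = []
        while stack:
            x = stack.pop()
            if x in self.leaf_label:
                labels.append(self.leaf_label[x])
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(labels)


def _to_graph(tree: Tree) -> _Graph:
    g = _Graph()

    def build(node: Node) -> int:
        nid = g.new_node()
        if node.is_leaf():
            g.leaf_label[nid] = node.label
        for c in node.children:
            cid = build(c)
            g.add_edge(nid, cid, c.length, None if c.is_leaf() else c.label)
        return nid

    root_id = build(tree.root)
    # splice a degree-2 root so the graph is a proper unrooted tree
    if len(g.adj[root_id]) == 2:
        (u, (lu, su)), (v, (lv, sv)) = g.adj[root_id].items()
        length = None
        if lu is not None or lv is not None:
            length = (lu or 0.0) + (lv or 0.0)
        g.remove_node(root_id)
        g.add_edge(u, v, length, su if su is not None else sv)
    return g


def _subtree_from(g: _Graph, x: int, parent: int, length, support) -> Node:
    if x in g.leaf_label:
        return Node(g.leaf_label[x], length)
    kids = [
        _subtree_from(g, y, x, l, s)
        for y, (l, s) in g.adj[x].items()
        if y != parent
    ]
    return Node(support, length, kids)


def _root_at_edge(g: _Graph, u: int, v: int) -> Tree:
    length, support = g.adj[u][v]
    half = None if length is None else length / 2.0
    left = _subtree_from(g, u, v, half, support if u not in g.leaf_label else None)
    if u in g.leaf_label:
        left = Node(g.leaf_label[u], half)
    right = _subtree_from(g, v, u, half, support if v not in g.leaf_label else None)
    if v in g.leaf_label:
        right = Node(g.leaf_label[v], half)
    return Tree(Node(None, None, [left, right]), rooted=True)


def splits(tree: Tree) -> set[frozenset[frozenset[str]]]:
    """Nontrivial unrooted bipartitions as {side, complement} pairs."""
    g = _to_graph(tree)
    all_leaves = frozenset(g.leaf_label.values())
    out: set[frozenset[frozenset[str]]] = set()
    for u, v in g.edges():
        side = g.side_leaves(u, away_from=v)
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(frozenset({side, all_leaves - side}))
    return out


def rf_distance(a: Tree, b: Tree) -> int:
    """Robinson-Foulds distance (symmetric difference of bipartition sets)."""
    if a.leaf_set() != b.leaf_set():
        raise TreeError(
            f"leaf sets differ: {sorted(a.leaf_set() ^ b.leaf_set())}"
        )
    return len(splits(a) ^ splits(b))


# ---------------------------------------------------------------------------
# Rooting, monophyly, pruning, collapsing


def root_with_outgroup(tree: Tree, outgroup) -> Tree:
    """Root on the edge separating the outgroup from all other taxa."""
    outgroup = frozenset(outgroup)
    leaves = tree.leaf_set()
    unknown = outgroup - leaves
    if unknown:
        raise TreeError(f"outgroup taxa not in tree: {sorted(unknown)}")
    if not outgroup or outgroup == leaves:
        raise TreeError("outgroup must be a nonempty proper subset of the leaves")
    g = _to_graph(tree)
    for u, v in g.edges():
        side = g.side_leaves(u, away_from=v)
        if side == outgroup or leaves - side == outgroup:
            return _root_at_edge(g, u, v)
    raise TreeError("outgroup not monophyletic on any rooting")


def _clades(tree: Tree) -> list[frozenset[str]]:
    out: list[frozenset[str]] = []

    def walk(n: Node) -> frozenset[str]:
        if n.is_leaf():
            s = frozenset([n.label])
        else:
            s = frozenset().union(*(walk(c) for c in n.children))
        out.append(s)
        return s

    walk(tree.root)
    return out


def is_monophyletic(tree: Tree, taxa) -> bool:
    """True iff some node's descendant leaf set equals ``taxa`` exactly.

    The tree is scored as rooted at its current root.
    """
    taxa = frozenset(taxa)
    leaves = tree.leaf_set()
    unknown = taxa - leaves
    if unknown:
        raise TreeError(f"taxa not in tree: {sorted(unknown)}")
    if not taxa:
        raise TreeError("empty taxon set")
    return taxa in set(_clades(tree))


def prune(tree: Tree, keep) -> Tree:
    """Restrict to ``keep`` leaves, suppressing unifurcations (lengths add)."""
    keep = frozenset(keep)
    unknown = keep - tree.leaf_set()
    if unknown:
        raise TreeError(f"taxa not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise TreeError("cannot prune a tree down to fewer than 2 leaves")

    def rec(n: Node) -> Node | None:
        if n.is_leaf():
            return Node(n.label, n.length) if n.label in keep else None
        kids = [k for k in (rec(c) for c in n.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            child = kids[0]
            if child.length is None and n.length is None:
                length = None
            else:
                length = (child.length or 0.0) + (n.length or 0.0)
            return Node(child.label, length, child.children)
        return Node(n.label, n.length, kids)

    root = rec(tree.root)
    if root is None:
        raise TreeError("pruned away the whole tree")
    while len(root.children) == 1:
        root = root.children[0]
        root.length = None
    root.length = None
    return Tree(root, tree.rooted)


def rename_leaf(tree: Tree, old: str, new: str) -> Tree:
    t = tree.copy()
    for leaf in t.leaves():
        if leaf.label == old:
            leaf.label = new
            return t
    raise TreeError(f"no leaf named {old!r}")


def collapse_clade(tree: Tree, taxa, placeholder: str) -> Tree:
    """Replace a monophyletic taxon set by a single placeholder leaf."""
    taxa = frozenset(taxa)
    if not is_monophyletic(tree, taxa):
        raise TreeError(f"cannot collapse non-monophyletic set {sorted(taxa)}")
    rep = min(taxa)
    remainder = tree.leaf_set() - taxa | {rep}
    return rename_leaf(prune(tree, remainder), rep, placeholder)


# ---------------------------------------------------------------------------
# Clade definitions


@dataclass
class CladeDefinition:
    """Named taxon sets plus outgroup and excluded taxa (pruned pre-scoring)."""

    clades: dict[str, frozenset[str]]
    outgroup: frozenset[str]
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.clades = {k: frozenset(v) for k, v in self.clades.items()}
        self.outgroup = frozenset(self.outgroup)
        self.excluded = frozenset(self.excluded)
        names = list(self.clades)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                inter = self.clades[a] & self.clades[b]
                if inter:
                    raise TreeError(
                        f"clades {a!r} and {b!r} overlap: {sorted(inter)}"
                    )
            if self.clades[a] & self.outgroup:
                raise TreeError(f"clade {a!r} overlaps the outgroup")
        if not self.outgroup:
            raise TreeError("outgroup must be nonempty")

    def all_scored_taxa(self) -> frozenset[str]:
        return frozenset().union(*self.clades.values(), self.outgroup)

    @classmethod
    def from_json(cls, path: str | Path) -> "CladeDefinition":
        data = json.loads(Path(path).read_text())
        return cls(
            clades={k: frozenset(v) for k, v in data["clades"].items()},
            outgroup=frozenset(data["outgroup"]),
            excluded=frozenset(data.get("excluded", [])),
        )

    def to_json(self, path: str | Path) -> None:
        data = {
            "clades": {k: sorted(v) for k, v in self.clades.items()},
            "outgroup": sorted(self.outgroup),
            "excluded": sorted(self.excluded),
        }
        Path(path).write_text(json.dumps(data, indent=1) + "\n")


def prepare_for_scoring(tree: Tree, clades: CladeDefinition) -> Tree:
    """Prune excluded taxa and root with the designated outgroup."""
    t = tree
    to_drop = clades.excluded & t.leaf_set()
    if to_drop:
        t = prune(t, t.leaf_set() - to_drop)
    return root_with_outgroup(t, clades.outgroup & t.leaf_set())


def backbone_match(
    candidate: Tree, reference: Tree, clades: CladeDefinition
) -> bool:
    """Topology agreement after collapsing each clade to a placeholder leaf.

    Requires every defined clade monophyletic in both trees (False if the
    candidate breaks one; an error if the reference does, since then the
    clade definition is inconsistent with the reference). The outgroup is
    collapsed too; leaves in no set are pruned; agreement means RF == 0 on
    the collapsed trees.
    """
    cand = prepare_for_scoring(candidate, clades)
    ref = prepare_for_scoring(reference, clades)
    for name, taxa in clades.clades.items():
        if not is_monophyletic(ref, taxa):
            raise TreeError(
                f"clade {name!r} is not monophyletic in the reference tree"
            )
        if not is_monophyletic(cand, taxa):
            return False
    for name, taxa in clades.clades.items():
        cand = collapse_clade(cand, taxa, name)
        ref = collapse_clade(ref, taxa, name)
    og_cand = clades.outgroup & cand.leaf_set()
    og_ref = clades.outgroup & ref.leaf_set()
    cand = collapse_clade(cand, og_cand, "#outgroup")
    ref = collapse_clade(ref, og_ref, "#outgroup")
    placeholders = set(clades.clades) | {"#outgroup"}
    cand = prune(cand, placeholders & cand.leaf_set())
    ref = prune(ref, placeholders & ref.leaf_set())
    return rf_distance(cand, ref) == 0


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei agglomeration.

    Negative branch lengths are clamped to 0 with the deficit moved to the
    sister edge; ties in the Q criterion break toward the lowest (row, col)
    index pair in the current matrix.
    """
    if dm.n < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")
    if dm.has_undefined():
        raise TreeError(
            "distance matrix contains undefined (saturated) entries; "
            "refusing to build a tree"
        )
    D = dm.d.astype(float).copy()
    items = [_quote(t) for t in dm.taxa]
    active = list(range(len(items)))
    Dfull = {(i, j): D[i, j] for i in range(len(items)) for j in range(len(items))}

    def dist(i: int, j: int) -> float:
        return Dfull[(i, j)] if i <= j else Dfull[(j, i)]

    next_id = len(items)
    subtree = {i: items[i] for i in active}
    while len(active) > 2:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = dist(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
            if li < 0.0:
                li = 0.0
        u = next_id
        next_id += 1
        subtree[u] = f"({subtree[i]}:{_fmt_len(li)},{subtree[j]}:{_fmt_len(lj)})"
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dist(i, k) + dist(j, k) - dij)
            Dfull[(min(u, k), max(u, k))] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [u]
    a, b = active
    dab = max(dist(a, b), 0.0)
    # attach the remaining pair across the last edge; if one side is a
    # composite node, fold the other into it so the root is a trifurcation
    if subtree[b].startswith("("):
        a, b = b, a
    if subtree[a].startswith("("):
        newick = f"({subtree[a][1:-1]},{subtree[b]}:{_fmt_len(dab)});"
    else:  # pragma: no cover - n >= 3 always leaves one composite
        newick = f"({subtree[a]}:{_fmt_len(dab/2)},{subtree[b]}:{_fmt_len(dab/2)});"
    return read_newick(newick)


# ---------------------------------------------------------------------------
# NJ pipeline helper


def nj_tree_from_alignment(aln, model: str = "K2P", deletion: str = "pairwise") -> Tree:
    from .distances import distance_matrix

    return neighbor_joining(distance_matrix(aln, model=model, deletion=deletion))
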