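"""Gene content and structure: parsimony event mapping and IR detection.

``map_events`` assigns 3-state (intact/pseudogene/absent) ancestral states by
unit-cost Sankoff parsimony and reports state changes per branch under
DELTRAN disambiguation. ``find_ir`` locates the quadripartite
LSC/IRb/SSC/IRa architecture from the longest pair of disjoint, exactly
reverse-complementary repeats on the circle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .seqio import AnnotatedPlastome, SequenceRecord, reverse_complement
from .trees import Node, Tree

STATES = ("intact", "pseudogene", "absent")
_STATE_CODES = {"1": "intact", "P": "pseudogene", "0": "absent"}
_CODE_OF = {v: k for k, v in _STATE_CODES.items()}


class GeneContentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Presence matrix


@dataclass
class PresenceMatrix:
    """taxa x genes state table; values in {intact, pseudogene, absent}."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.empty:
            raise GeneContentError("presence matrix is empty")
        bad = set(self.df.values.ravel()) - set(STATES)
        if bad:
            raise GeneContentError(f"illegal states in presence matrix: {sorted(bad)}")

    @property
    def taxa(self) -> list[str]:
        return list(self.df.index)

    @property
    def genes(self) -> list[str]:
        return list(self.df.columns)

    def state(self, taxon: str, gene: str) -> str:
        return self.df.at[taxon, gene]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls(df.map(lambda v: _STATE_CODES.get(v, v)))

    def to_tsv(self, path: str | Path) -> None:
        self.df.map(_CODE_OF.get).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Parsimony event mapping


@dataclass(frozen=True)
class Event:
    branch: frozenset[str]  # descendant leaf set of the branch's child node
    gene: str
    from_state: str
    to_state: str


@dataclass
class EventMapping:
    events: list[Event]
    min_changes: dict[str, int]  # per gene
    ambiguous_nodes: dict[str, int]  # per gene: nodes with >1 optimal state

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("branch\tgene\tfrom_state\tto_state\n")
            for ev in sorted(
                self.events, key=lambda e: (e.gene, sorted(e.branch))
            ):
                fh.write(
                    f"{','.join(sorted(ev.branch))}\t{ev.gene}\t"
                    f"{ev.from_state}\t{ev.to_state}\n"
                )


def map_events(
    tree: Tree, pm: PresenceMatrix, outgroup=None
) -> EventMapping:
    """Minimum-change state assignment per gene; events are branch changes.

    Unordered 3-state parsimony with equal costs. When ``outgroup`` is given
    and every outgroup leaf is intact for a gene, the root state is fixed to
    intact. Among equally parsimonious assignments the one delaying changes
    toward the tips (DELTRAN: a child keeps its parent's state whenever that
    is optimal) is reported; the number of nodes with several optimal states
    is logged per gene.
    """
    leaves = tree.leaf_labels()
    missing = set(leaves) - set(pm.taxa)
    if missing:
        raise GeneContentError(
            f"tree leaves missing from presence matrix: {sorted(missing)}"
        )
    outgroup = frozenset(outgroup) if outgroup else frozenset()
    events: list[Event] = []
    min_changes: dict[str, int] = {}
    ambiguous: dict[str, int] = {}

    for gene in pm.genes:
        cost: dict[int, list[float]] = {}
        below: dict[int, frozenset[str]] = {}

        def down(node: Node) -> None:
            if node.is_leaf():
                s = pm.state(node.label, gene)
                cost[id(node)] = [0.0 if t == s else math.inf for t in STATES]
                below[id(node)] = frozenset([node.label])
                return
            for c in node.children:
                down(c)
            cost[id(node)] = [
                sum(
                    min(
                        cost[id(c)][ti] + (0.0 if ti == si else 1.0)
                        for ti in range(3)
                    )
                    for c in node.children
                )
                for si in range(3)
            ]
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))

        down(tree.root)
        root_cost = cost[id(tree.root)]
        fix_root = bool(outgroup) and all(
            pm.state(t, gene) == "intact" for t in outgroup if t in leaves
        ) and bool(outgroup & set(leaves))
        if fix_root and math.isfinite(root_cost[0]):
            root_state_i = 0
            total = root_cost[0]
        else:
            total = min(root_cost)
            root_state_i = root_cost.index(total)
        min_changes[gene] = int(total)
        n_ambiguous = 1 if sum(1 for c in root_cost if c == total) > 1 and not fix_root else 0

        def up(node: Node, state_i: int) -> None:
            nonlocal n_ambiguous
            for c in node.children:
                vals = [
                    cost[id(c)][ti] + (0.0 if ti == state_i else 1.0)
                    for ti in range(3)
                ]
                best = min(vals)
                optimal = [ti for ti in range(3) if vals[ti] == best]
                if len(optimal) > 1:
                    n_ambiguous += 1
                child_i = state_i if state_i in optimal else optimal[0]
                if child_i != state_i:
                    events.append(
                        Event(
                            branch=below[id(c)],
                            gene=gene,
                            from_state=STATES[state_i],
                            to_state=STATES[child_i],
                        )
                    )
                up(c, child_i)

        up(tree.root, root_state_i)
        ambiguous[gene] = n_ambiguous

    return EventMapping(events, min_changes, ambiguous)


# ---------------------------------------------------------------------------
# Inverted repeat detection


@dataclass
class IRStructure:
    """Quadripartite spans, 0-based half-open on the circle.

    ``end`` may exceed the genome length to denote wrap-around; all
    coordinates refer to the ORIGINAL sequence. ``rotation_offset`` is the
    LSC start, i.e. the rotation that brings the genome to the conventional
    LSC-first presentation.
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int

    @property
    def ir_length(self) -> int:
        return self.irb[1] - self.irb[0]

    @property
    def rotation_offset(self) -> int:
        return self.lsc[0] % self.genome_length

    def spans(self) -> dict[str, tuple[int, int]]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}

    def extract(self, seq: str, span_name: str) -> str:
        s, e = self.spans()[span_name]
        n = self.genome_length
        s %= n
        length = e - self.spans()[span_name][0]
        doubled = seq + seq
        return doubled[s : s + length]

    def write_tsv(self, path: str | Path) -> None:
        n = self.genome_length
        with Path(path).open("w") as fh:
            fh.write("span\tstart\tend\tlength\n")
            for name, (s, e) in self.spans().items():
                fh.write(f"{name}\t{s % n}\t{e % n}\t{e - s}\n")


def _prefix_hashes(s: str, base: int, mod: int) -> tuple[list[int], list[int]]:
    n = len(s)
    h = [0] * (n + 1)
    p = [1] * (n + 1)
    for i, ch in enumerate(s):
        h[i + 1] = (h[i] * base + ord(ch)) % mod
        p[i + 1] = (p[i] * base) % mod
    return h, p


def _window_hash(h, p, mod, i, L) -> int:
    return (h[i + L] - h[i] * p[L]) % mod


def _circ_disjoint(i: int, p: int, L: int, n: int) -> bool:
    return ((p - i) % n) >= L and ((i - p) % n) >= L


def find_ir(seq: SequenceRecord | str, min_len: int = 1000) -> IRStructure:
    """Locate the IR pair and label the four plastome regions.

    Finds the longest pair of disjoint, maximal, exactly
    reverse-complementary repeats of length >= ``min_len`` on the circle;
    the shorter arc between the two copies is SSC, the longer LSC, and IRb
    is the copy following the LSC in the plus direction.
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else seq.upper()
    n = len(s)
    if min_len < 1:
        raise GeneContentError("min_len must be positive")
    if n < 2 * min_len:
        raise GeneContentError("no IR detected")
    r = reverse_complement(s)
    s2, r2 = s + s, r + r
    mod = (1 << 61) - 1
    base = 131
    hs, ps = _prefix_hashes(s2, base, mod)
    hr, _ = _prefix_hashes(r2, base, mod)

    def feasible(L: int):
        """Smallest-(i,p) disjoint revcomp repeat pair of length L, or None."""
        table: dict[int, list[int]] = {}
        for j in range(n):
            table.setdefault(_window_hash(hr, ps, mod, j, L), []).append(j)
        best = None
        for i in range(n):
            hits = table.get(_window_hash(hs, ps, mod, i, L))
            if not hits:
                continue
            for j in hits:
                if s2[i : i + L] != r2[j : j + L]:
                    continue
                p = (n - j - L) % n
                if not _circ_disjoint(i, p, L, n):
                    continue
                if best is None or (i, p) < best:
                    best = (i, p)
            if best is not None and best[0] == i:
                return best
        return best

    lo, hi = min_len, n // 2
    if feasible(lo) is None:
        raise GeneContentError("no IR detected")
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if feasible(mid) is not None:
            lo = mid
        else:
            hi = mid - 1
    L = lo
    i, p = feasible(L)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    # maximal extension (defensive; L is already globally maximal)
    while (
        _circ_disjoint((i - 1) % n, p, L + 1, n)
        and comp.get(s[(i - 1) % n]) == s[(p + L) % n]
    ):
        i = (i - 1) % n
        L += 1
    while (
        _circ_disjoint(i, (p - 1) % n, L + 1, n)
        and comp.get(s[(p - 1) % n]) == s[(i + L) % n]
    ):
        p = (p - 1) % n
        L += 1

    gap_ab = (p - (i + L)) % n  # arc from copy-at-i end to copy-at-p start
    gap_ba = (i - (p + L)) % n
    if gap_ab >= gap_ba:
        lsc = (((i + L) % n), ((i + L) % n) + gap_ab)
        irb = (p % n, p % n + L)
        ssc = (((p + L) % n), ((p + L) % n) + gap_ba)
        ira = (i % n, i % n + L)
    else:
        lsc = (((p + L) % n), ((p + L) % n) + gap_ba)
        irb = (i % n, i % n + L)
        ssc = (((i + L) % n), ((i + L) % n) + gap_ab)
        ira = (p % n, p % n + L)
    return IRStructure(lsc=lsc, irb=irb, ssc=ssc, ira=ira, genome_length=n)


# ---------------------------------------------------------------------------
# Junction genes


@dataclass
class JunctionHit:
    junction: str
    position: int
    feature: str
    kind: str
    offset: int  # bases from the feature's genomic start to the junction


def junction_genes(
    plastome: AnnotatedPlastome, ir: IRStructure
) -> dict[str, list[JunctionHit]]:
    """Features whose span strictly contains each of the four junctions.

    Junction coordinates are the starts of IRb, SSC, IRa and LSC (i.e. the
    points where one region hands over to the next). Features split across
    the origin (stored as ordered parts) are handled circularly; the offset
    is measured within the joined feature.
    """
    from .regions import _feature_copies

    n = ir.genome_length
    junctions = {
        "LSC/IRb": ir.irb[0] % n,
        "IRb/SSC": ir.ssc[0] % n,
        "SSC/IRa": ir.ira[0] % n,
        "IRa/LSC": ir.lsc[0] % n,
    }
    out: dict[str, list[JunctionHit]] = {name: [] for name in junctions}
    for name in plastome.feature_names():
        for copy in _feature_copies(plastome, name):
            total = sum(f.end - f.start for f in copy)
            acc = 0
            for f in copy:
                for jname, c in junctions.items():
                    delta = (c - f.start) % n
                    # interior to the joined feature, not at its very ends
                    if delta < (f.end - f.start) and 0 < acc + delta < total:
                        out[jname].append(
                            JunctionHit(
                                junction=jname,
                                position=c,
                                feature=f.name,
                                kind=f.kind,
                                offset=acc + delta,
                            )
                        )
                acc += f.end - f.start
    return out


def write_junction_report(
    hits: dict[str, list[JunctionHit]], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("junction\tposition\tfeature\tkind\toffset\n")
        for jname, items in hits.items():
            if not items:
                fh.write(f"{jname}\t\t\t\t\n")
            for h in items:
                fh.write(
                    f"{h.junction}\t{h.position}\t{h.feature}\t{h.kind}\t{h.offset}\n"
                )
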