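"""Simulation of plastome sets with known truth.

Sequences evolve site-independently down a tree with branch lengths in
expected substitutions/site under the two-parameter (Kimura) model, so the
K2P distance estimator is consistent for true path lengths and every
downstream statistic has a closed-form expectation. Genomes are assembled
with the quadripartite LSC/IRb/SSC/IRa architecture and optional planted
gene-loss/pseudogenization events.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .genecontent import IRStructure, PresenceMatrix
from .seqio import (
    AnnotatedPlastome,
    Alignment,
    Feature,
    SequenceRecord,
    reverse_complement,
    write_alignment,
    write_fasta,
    write_genbank,
)
from .trees import Node, Tree, read_newick, write_newick, write_newick_file

_BASES = "ACGT"


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Two-parameter substitution model


def rate_matrix(kappa: float) -> np.ndarray:
    """K2P rate matrix (order ACGT), normalized to 1 substitution/site."""
    if kappa <= 0:
        raise SimulationError("kappa must be positive")
    alpha = kappa / (kappa + 2.0)
    beta = 1.0 / (kappa + 2.0)
    Q = np.full((4, 4), beta)
    Q[0, 2] = Q[2, 0] = alpha  # A <-> G
    Q[1, 3] = Q[3, 1] = alpha  # C <-> T
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_probabilities(t: float, kappa: float) -> np.ndarray:
    if t < 0:
        raise SimulationError("branch length must be non-negative")
    return expm(rate_matrix(kappa) * t)


def expected_p_distance(t: float, kappa: float) -> float:
    """Expected proportion of differing sites at path length t."""
    P = transition_probabilities(t, kappa)
    return float(1.0 - np.diag(P).mean())


def expected_transition_fraction(t: float, kappa: float) -> float:
    """Expected transition differences per site at path length t."""
    P = transition_probabilities(t, kappa)
    return float((P[0, 2] + P[1, 3]) / 2.0)


# ---------------------------------------------------------------------------
# Sequence evolution


def _check_lengths(node: Node) -> None:
    for c in node.children:
        if c.length is None:
            where = c.label if c.is_leaf() else "internal node"
            raise SimulationError(f"missing branch length above {where!r}")
        _check_lengths(c)


def simulate_alignment(
    tree: Tree,
    length: int,
    kappa: float = 2.0,
    rate_mult: float = 1.0,
    seed: int | np.random.SeedSequence | None = None,
) -> Alignment:
    """Evolve ``length`` sites down ``tree``; returns leaves in preorder.

    The root sequence is uniform over {A,C,G,T}; each branch applies the
    two-parameter transition matrix for (branch length x rate_mult)
    expected substitutions/site. Deterministic given the seed.
    """
    if rate_mult < 0:
        raise SimulationError("rate_mult must be non-negative")
    if seed is None:
        raise SimulationError("a seed is mandatory for reproducibility")
    _check_lengths(tree.root)
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=length)
    taxa: list[str] = []
    rows: list[str] = []

    def walk(node: Node, seq: np.ndarray) -> None:
        if node.is_leaf():
            taxa.append(node.label)
            rows.append("".join(_BASES[b] for b in seq))
            return
        for c in node.children:
            P = transition_probabilities(c.length * rate_mult, kappa)
            cum = P.cumsum(axis=1)
            u = rng.random(length)
            child_seq = (u[:, None] > cum[seq]).sum(axis=1)
            walk(c, child_seq)

    walk(tree.root, root_seq)
    return Alignment(taxa, rows)


def inject_gap_blocks(
    aln: Alignment, n_blocks: int, block_len: int, seed: int
) -> Alignment:
    """Replace uniformly placed blocks with gaps (exercises gap handling)."""
    rng = np.random.default_rng(seed)
    rows = [list(r) for r in aln.rows]
    for _ in range(n_blocks):
        i = int(rng.integers(0, aln.n_taxa))
        s = int(rng.integers(0, max(aln.length - block_len, 1)))
        for j in range(s, min(s + block_len, aln.length)):
            rows[i][j] = "-"
    return Alignment(list(aln.taxa), ["".join(r) for r in rows])


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class RegionSimSpec:
    name: str
    kind: str  # PCG | rRNA | tRNA | IGS
    length: int
    rate_mult: float = 1.0
    placement: str = "LSC"  # LSC | SSC
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.kind not in ("PCG", "rRNA", "tRNA", "IGS"):
            raise SimulationError(f"region {self.name!r}: bad kind {self.kind!r}")
        if self.length <= 0 or self.rate_mult < 0:
            raise SimulationError(f"region {self.name!r}: bad length/rate")
        if self.placement not in ("LSC", "SSC"):
            raise SimulationError(f"region {self.name!r}: bad placement")


@dataclass
class LossEvent:
    clade: tuple[str, ...]  # descendant leaf set of the branch's child node
    gene: str
    state: str  # absent | pseudogene

    def __post_init__(self) -> None:
        self.clade = tuple(self.clade)
        if self.state not in ("absent", "pseudogene"):
            raise SimulationError(f"bad loss state {self.state!r}")


@dataclass
class SimConfig:
    tree_newick: str
    regions: list[RegionSimSpec]
    seed: int
    clades: dict[str, list[str]] = field(default_factory=dict)
    outgroup: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)
    kappa: float = 2.0
    ir_template_length: int = 1200
    ir_rate_mult: float = 0.3
    losses: list[LossEvent] = field(default_factory=list)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        data = json.loads(Path(path).read_text())
        return cls(
            tree_newick=data["tree_newick"],
            regions=[RegionSimSpec(**r) for r in data["regions"]],
            seed=int(data["seed"]),
            clades=data.get("clades", {}),
            outgroup=data.get("outgroup", []),
            excluded=data.get("excluded", []),
            kappa=data.get("kappa", 2.0),
            ir_template_length=data.get("ir_template_length", 1200),
            ir_rate_mult=data.get("ir_rate_mult", 0.3),
            losses=[LossEvent(**e) for e in data.get("losses", [])],
        )

    def to_json(self, path: str | Path) -> None:
        data = {
            "tree_newick": self.tree_newick,
            "regions": [vars(r) for r in self.regions],
            "seed": self.seed,
            "clades": self.clades,
            "outgroup": self.outgroup,
            "excluded": self.excluded,
            "kappa": self.kappa,
            "ir_template_length": self.ir_template_length,
            "ir_rate_mult": self.ir_rate_mult,
            "losses": [
                {"clade": list(e.clade), "gene": e.gene, "state": e.state}
                for e in self.losses
            ],
        }
        Path(path).write_text(json.dumps(data, indent=1) + "\n")


@dataclass
class SimTruth:
    tree: Tree
    region_alignments: dict[str, Alignment]
    ir_alignment: Alignment | None
    ir_spans: dict[str, IRStructure]
    presence: PresenceMatrix
    events: list[LossEvent]
    path_lengths: pd.DataFrame  # true pairwise path lengths (subs/site)


# ---------------------------------------------------------------------------
# Plastome assembly

_PAD = "AA"  # constant junction pad; blocks chance IR boundary extension


def _clade_taxa_of_branches(tree: Tree) -> set[frozenset[str]]:
    out: set[frozenset[str]] = set()

    def walk(n: Node) -> frozenset[str]:
        s = (
            frozenset([n.label])
            if n.is_leaf()
            else frozenset().union(*(walk(c) for c in n.children))
        )
        out.add(s)
        return s

    walk(tree.root)
    return out


def _path_length_matrix(tree: Tree) -> pd.DataFrame:
    """True pairwise path lengths (sum of branch lengths) between leaves."""
    taxa = sorted(tree.leaf_labels())
    paths: dict[str, list] = {}

    # a leaf's path is the list of (edge id, length) from the root down
    def walk(n: Node, anc: list) -> None:
        if n.is_leaf():
            paths[n.label] = list(anc)
        for c in n.children:
            walk(c, anc + [(id(c), c.length or 0.0)])

    walk(tree.root, [])
    mat = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for i, a in enumerate(taxa):
        pa = dict(paths[a])
        for b in taxa[i + 1 :]:
            pb = dict(paths[b])
            shared = set(pa) & set(pb)
            d = (
                sum(pa.values())
                + sum(pb.values())
                - 2 * sum(pa[k] for k in shared)
            )
            mat.loc[a, b] = mat.loc[b, a] = d
    return mat


def simulate_plastome_set(
    cfg: SimConfig,
) -> tuple[list[AnnotatedPlastome], SimTruth]:
    """Simulate annotated genomes plus the full truth record.

    Genome layout per taxon: pad + LSC regions (in spec order) + pad + IRb +
    pad + SSC regions + pad + IRa (exact reverse complement of IRb). Loss
    events delete (absent) or re-flag (pseudogene) the gene on every taxon
    descending from the named branch.
    """
    tree = read_newick(cfg.tree_newick)
    taxa = tree.leaf_labels()
    branch_sets = _clade_taxa_of_branches(tree)
    loss_by_taxon: dict[str, dict[str, str]] = {t: {} for t in taxa}
    for ev in cfg.losses:
        cl = frozenset(ev.clade)
        if cl not in branch_sets:
            raise SimulationError(
                f"loss event on unknown branch {sorted(cl)} (no edge has this "
                "descendant leaf set)"
            )
        gene_names = {r.name for r in cfg.regions if r.kind != "IGS"}
        if ev.gene not in gene_names:
            raise SimulationError(f"loss event for unknown gene {ev.gene!r}")
        for t in cl:
            loss_by_taxon[t][ev.gene] = ev.state

    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = ss.spawn(len(cfg.regions) + 1)
    region_alignments: dict[str, Alignment] = {}
    for spec, child in zip(cfg.regions, child_seeds[:-1]):
        region_alignments[spec.name] = simulate_alignment(
            tree, spec.length, cfg.kappa, spec.rate_mult, seed=child
        )
    ir_alignment = None
    if cfg.ir_template_length:
        ir_alignment = simulate_alignment(
            tree, cfg.ir_template_length, cfg.kappa, cfg.ir_rate_mult,
            seed=child_seeds[-1],
        )

    plastomes: list[AnnotatedPlastome] = []
    ir_spans: dict[str, IRStructure] = {}
    presence_rows: dict[str, dict[str, str]] = {}
    for taxon in taxa:
        parts: list[str] = []
        features: list[Feature] = []
        presence_rows[taxon] = {}

        def add_section(placement: str) -> None:
            for spec in cfg.regions:
                if spec.placement != placement:
                    continue
                seq = region_alignments[spec.name].row(taxon)
                if spec.kind == "IGS":
                    parts.append(seq)
                    continue
                state = loss_by_taxon[taxon].get(spec.name, "intact")
                presence_rows[taxon][spec.name] = state
                if state == "absent":
                    continue
                pos = sum(len(p) for p in parts)
                genomic = seq if spec.strand == "+" else reverse_complement(seq)
                parts.append(genomic)
                kind = "pseudogene" if state == "pseudogene" else spec.kind
                if kind == "IGS":  # pragma: no cover - excluded above
                    kind = "other"
                features.append(
                    Feature(spec.name, kind, pos, pos + len(seq), spec.strand)
                )

        parts.append(_PAD)
        add_section("LSC")
        parts.append(_PAD)
        irb_seq = ir_alignment.row(taxon) if ir_alignment else ""
        irb_start = sum(len(p) for p in parts)
        parts.append(irb_seq)
        parts.append(_PAD)
        ssc_start = sum(len(p) for p in parts)
        add_section("SSC")
        parts.append(_PAD)
        ira_start = sum(len(p) for p in parts)
        parts.append(reverse_complement(irb_seq))
        genome = "".join(parts)
        n = len(genome)
        record = SequenceRecord(taxon, genome, circular=True)
        plastomes.append(AnnotatedPlastome(record, features))
        if irb_seq:
            L = len(irb_seq)
            # IRa runs to the genome end, so the LSC arc starts at the origin
            ir_spans[taxon] = IRStructure(
                lsc=(0, irb_start),
                irb=(irb_start, irb_start + L),
                ssc=(irb_start + L, ira_start),
                ira=(ira_start, ira_start + n - ira_start),
                genome_length=n,
            )

    presence = PresenceMatrix(
        pd.DataFrame.from_dict(presence_rows, orient="index").reindex(index=taxa)
    )
    truth = SimTruth(
        tree=tree,
        region_alignments=region_alignments,
        ir_alignment=ir_alignment,
        ir_spans=ir_spans,
        presence=presence,
        events=list(cfg.losses),
        path_lengths=_path_length_matrix(tree),
    )
    return plastomes, truth


# ---------------------------------------------------------------------------
# Default benchmark fixture (32 taxa, mixed IGS/PCG region panel)


def _ladder(labels: list[str], tip: float, internal: float) -> str:
    """Pectinate subtree newick over labels with fixed edge lengths."""
    out = f"{labels[0]}:{tip:.6g}"
    for i, lab in enumerate(labels[1:], start=1):
        t = tip + 0.00008 * (i % 3)  # mild, deterministic tip-length variation
        out = f"({out},{lab}:{t:.6g}):{internal:.6g}"
    return out


def default_tree_newick() -> str:
    """Fixed 32-taxon species tree: five ingroup clades, sister genus, outgroup."""
    I = _ladder([f"T{i:02d}" for i in range(1, 10)], 0.0006, 0.0004)
    II = _ladder([f"T{i:02d}" for i in range(10, 19)], 0.0006, 0.0004)
    III = _ladder([f"T{i:02d}" for i in range(19, 23)], 0.0005, 0.0004)
    IV = _ladder([f"T{i:02d}" for i in range(23, 27)], 0.0006, 0.0004)
    V = _ladder([f"T{i:02d}" for i in range(27, 29)], 0.0004, 0.0003)
    SC = _ladder(["S01", "S02", "S03"], 0.0008, 0.0006)
    ingroup = (
        f"(((({I}:0.0009,{II}:0.0009):0.00055,{III}:0.0009):0.00055,"
        f"{IV}:0.0009):0.00055,{V}:0.0009):0.0016"
    )
    return f"(({ingroup},{SC}:0.0008):0.002,OUT1:0.004);"


def default_clades() -> dict:
    return {
        "clades": {
            "I": [f"T{i:02d}" for i in range(1, 10)],
            "II": [f"T{i:02d}" for i in range(10, 19)],
            "III": [f"T{i:02d}" for i in range(19, 23)],
            "IV": [f"T{i:02d}" for i in range(23, 27)],
            "Scurrula": ["S01", "S02", "S03"],
        },
        "outgroup": ["OUT1"],
        "excluded": [f"T{i:02d}" for i in range(27, 29)],
    }


def default_config(seed: int) -> SimConfig:
    """Benchmark config: a realistic mixed panel of spacers and coding genes.

    IGS regions run several-fold faster than coding regions; one region is
    long and fast ("clean"), one short and hypervariable.
    """
    cd = default_clades()
    regions = [
        RegionSimSpec("rpl14", "PCG", 400, 1.0),
        RegionSimSpec("rpl14-rps3", "IGS", 1660, 5.0),
        RegionSimSpec("rps3", "PCG", 650, 1.0),
        RegionSimSpec("trnL", "tRNA", 80, 0.8),
        RegionSimSpec("trnL-trnF", "IGS", 638, 4.0),
        RegionSimSpec("trnF", "tRNA", 80, 0.8),
        RegionSimSpec("trnH", "tRNA", 75, 0.8),
        RegionSimSpec("trnH-psbA", "IGS", 300, 8.0),
        RegionSimSpec("psbA", "PCG", 1062, 0.7, strand="-"),
        RegionSimSpec("rbcL", "PCG", 1428, 0.5),
        RegionSimSpec("accD", "PCG", 1500, 1.5),
        RegionSimSpec("matK", "PCG", 1581, 1.0),
        RegionSimSpec("infA", "PCG", 234, 1.0),
        RegionSimSpec("trnA", "tRNA", 75, 0.8),
        RegionSimSpec("rrn16", "rRNA", 1490, 0.3),
        RegionSimSpec("ccsA", "PCG", 960, 1.2, placement="SSC"),
        RegionSimSpec("ccsA-psaC", "IGS", 339, 6.0, placement="SSC"),
        RegionSimSpec("psaC", "PCG", 246, 0.8, placement="SSC", strand="-"),
    ]
    losses = [
        LossEvent(tuple(cd["clades"]["Scurrula"]), "infA", "absent"),
        LossEvent(("T05",), "infA", "absent"),
        LossEvent(tuple(cd["excluded"]), "infA", "absent"),
        LossEvent(("T23",), "trnA", "pseudogene"),
    ]
    return SimConfig(
        tree_newick=default_tree_newick(),
        regions=regions,
        seed=seed,
        clades=cd["clades"],
        outgroup=cd["outgroup"],
        excluded=cd["excluded"],
        kappa=2.0,
        ir_template_length=1200,
        ir_rate_mult=0.3,
        losses=losses,
    )


#: Candidate regions evaluated by the benchmark; "+"-joined names are
#: concatenations of member alignments.
BENCHMARK_CANDIDATES = (
    "rpl14-rps3",
    "trnL-trnF",
    "trnH-psbA",
    "ccsA-psaC",
    "rbcL",
    "accD",
    "matK",
    "rbcL+accD",
)


@dataclass
class BenchmarkFixture:
    config: SimConfig
    plastomes: list[AnnotatedPlastome]
    truth: SimTruth
    candidate_alignments: dict[str, Alignment]

    def clade_definition(self):
        from .trees import CladeDefinition

        return CladeDefinition(
            clades={k: frozenset(v) for k, v in self.config.clades.items()},
            outgroup=frozenset(self.config.outgroup),
            excluded=frozenset(self.config.excluded),
        )


def make_benchmark(
    cfg: SimConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> BenchmarkFixture:
    """Build the end-to-end fixture; optionally write it to a directory.

    The directory layout (regions/*.fasta, reference.nwk, clades.json,
    genomes/*.gb|fasta, truth JSON/TSVs) is consumed unchanged by the CLI
    subcommands.
    """
    from .regions import concatenate

    cfg = cfg or default_config(seed)
    plastomes, truth = simulate_plastome_set(cfg)
    candidates: dict[str, Alignment] = {}
    for name in BENCHMARK_CANDIDATES:
        if "+" in name:
            members = name.split("+")
            aln, _ = concatenate([truth.region_alignments[m] for m in members])
        else:
            aln = truth.region_alignments[name]
        candidates[name] = aln
    fixture = BenchmarkFixture(cfg, plastomes, truth, candidates)
    if out_dir is not None:
        write_fixture(fixture, out_dir)
    return fixture


def write_fixture(fixture: BenchmarkFixture, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    (out_dir / "regions").mkdir(parents=True, exist_ok=True)
    (out_dir / "genomes").mkdir(exist_ok=True)
    fixture.config.to_json(out_dir / "config.json")
    write_newick_file(fixture.truth.tree, out_dir / "reference.nwk")
    cd = fixture.clade_definition()
    cd.to_json(out_dir / "clades.json")
    for name, aln in fixture.candidate_alignments.items():
        write_alignment(aln, out_dir / "regions" / f"{name.replace('+', '_')}.fasta")
    for p in fixture.plastomes:
        write_genbank(p, out_dir / "genomes" / f"{p.id}.gb")
        write_fasta([p.record], out_dir / "genomes" / f"{p.id}.fasta")
    fixture.truth.presence.to_tsv(out_dir / "presence.tsv")
    truth_meta = {
        "tree": write_newick(fixture.truth.tree),
        "ir_spans": {
            t: {k: list(v) for k, v in ir.spans().items()}
            for t, ir in fixture.truth.ir_spans.items()
        },
        "events": [
            {"clade": list(e.clade), "gene": e.gene, "state": e.state}
            for e in fixture.truth.events
        ],
    }
    (out_dir / "truth.json").write_text(json.dumps(truth_meta, indent=1) + "\n")


def score_benchmark(fixture: BenchmarkFixture):
    """NJ + K2P + utility scoring of every candidate region in the fixture."""
    from .diversity import region_stats
    from .trees import nj_tree_from_alignment
    from .utility import rank_regions, score_region

    clades = fixture.clade_definition()
    reference = fixture.truth.tree
    scores = []
    for name, aln in fixture.candidate_alignments.items():
        stats = region_stats(name, aln)
        candidate = nj_tree_from_alignment(aln)
        scores.append(
            score_region(
                candidate,
                reference,
                clades,
                region=name,
                alignment_length=stats.alignment_length,
                prop_pi=stats.prop_pi,
            )
        )
    return rank_regions(scores)
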