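"""Extraction of genes and intergenic spacers from annotated plastomes.

A "region" is either a named feature (gene/rRNA/tRNA), the spacer strictly
between two named features walking the plus strand of the circle, or a
concatenation of other regions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import (
    AnnotatedPlastome,
    Alignment,
    Feature,
    SequenceRecord,
    reverse_complement,
)


class RegionError(ValueError):
    pass


@dataclass
class RegionSpec:
    """What to extract: a gene, an IGS between two genes, or a concat."""

    name: str
    mode: str  # gene | igs | concat
    parts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("gene", "igs", "concat"):
            raise RegionError(f"region {self.name!r}: unknown mode {self.mode!r}")
        self.parts = tuple(self.parts)
        if self.mode == "igs" and len(self.parts) != 2:
            raise RegionError(
                f"igs region {self.name!r} needs exactly two flanking names"
            )
        if self.mode == "concat" and len(self.parts) < 2:
            raise RegionError(f"concat region {self.name!r} needs >=2 members")


def read_region_specs(path: str | Path) -> list[RegionSpec]:
    """Load region specs from JSON (list of {name, mode, parts}) or TSV."""
    path = Path(path)
    text = path.read_text()
    specs: list[RegionSpec] = []
    if path.suffix.lower() == ".json" or text.lstrip().startswith("["):
        for entry in json.loads(text):
            specs.append(
                RegionSpec(entry["name"], entry["mode"], tuple(entry.get("parts", ())))
            )
    else:
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            cols = line.split("\t")
            name, mode = cols[0], cols[1]
            parts = tuple(cols[2].split(",")) if len(cols) > 2 and cols[2] else ()
            specs.append(RegionSpec(name, mode, parts))
    return specs


def _feature_copies(plastome: AnnotatedPlastome, name: str) -> list[list[Feature]]:
    """Group same-named features into copies (multi-exon parts stay together)."""
    feats = [f for f in plastome.features if f.name == name]
    copies: list[list[Feature]] = []
    for f in sorted(feats, key=lambda f: (f.start, f.part or 0)):
        if (
            copies
            and f.part is not None
            and copies[-1][-1].part is not None
            and f.part == copies[-1][-1].part + 1
        ):
            copies[-1].append(f)
        else:
            copies.append([f])
    # a join() crossing the origin appears as a trailing run of parts at the
    # genome end continued by the leading run at position 0 — merge them
    n = len(plastome.record.seq)
    if (
        len(copies) > 1
        and copies[0][0].start == 0
        and copies[-1][-1].end == n
        and copies[0][0].part is not None
        and copies[-1][-1].part is not None
        and copies[0][0].part == copies[-1][-1].part + 1
    ):
        copies[-1].extend(copies.pop(0))
    # Exon order within a copy follows the recorded part index.
    for copy in copies:
        copy.sort(key=lambda f: (f.part if f.part is not None else 0))
    return copies


def extract_gene(
    plastome: AnnotatedPlastome,
    name: str,
    ir_policy: str = "first",
    ir=None,
) -> SequenceRecord:
    """Extract a named feature's sequence (coding orientation).

    Minus-strand features are reverse-complemented; multi-exon features are
    concatenated in exon order. When the gene occurs more than once (IR
    duplication), ``ir_policy`` selects the copy: "first" takes the first in
    feature order; "lsc-copy" requires an ``IRStructure`` (``ir=``) and takes
    the copy lying outside both IRs.
    """
    copies = _feature_copies(plastome, name)
    if not copies:
        available = ", ".join(plastome.feature_names()) or "<none>"
        raise RegionError(
            f"{plastome.id}: no feature named {name!r}; available: {available}"
        )
    if len(copies) == 1 or ir_policy == "first":
        copy = copies[0]
    elif ir_policy == "lsc-copy":
        if ir is None:
            raise RegionError("ir_policy='lsc-copy' requires an IRStructure (ir=)")
        in_single_copy = [
            c
            for c in copies
            if not any(
                _spans_overlap(c[0].start, c[-1].end, s, e, len(plastome.record.seq))
                for s, e in (ir.irb, ir.ira)
            )
        ]
        if not in_single_copy:
            raise RegionError(f"{plastome.id}: no single-copy instance of {name!r}")
        copy = in_single_copy[0]
    else:
        raise RegionError(f"unknown ir_policy {ir_policy!r}")
    if copy[0].kind == "pseudogene":
        warnings.warn(
            f"{plastome.id}: {name!r} is annotated as a pseudogene", stacklevel=2
        )
    seq = plastome.record.seq
    # minus-strand joins carry exons in translation order; genomic slices are
    # reverse-complemented individually then concatenated.
    pieces = []
    for f in copy:
        piece = seq[f.start : f.end]
        if f.strand == "-":
            piece = reverse_complement(piece)
        pieces.append(piece)
    return SequenceRecord(plastome.id, "".join(pieces))


def _spans_overlap(s1: int, e1: int, s2: int, e2: int, n: int) -> bool:
    return s1 < e2 and s2 < e1


def _copy_extent(copy: list[Feature]) -> tuple[int, int]:
    return min(f.start for f in copy), max(f.end for f in copy)


def extract_igs(
    plastome: AnnotatedPlastome, left: str, right: str
) -> SequenceRecord:
    """Extract the spacer strictly between ``left``'s end and ``right``'s start.

    The walk is on the plus strand of the circle, wrapping through the origin
    when needed. A zero-length spacer is returned as an empty record.
    """
    lcopies = _feature_copies(plastome, left)
    rcopies = _feature_copies(plastome, right)
    for name, copies in ((left, lcopies), (right, rcopies)):
        if not copies:
            available = ", ".join(plastome.feature_names()) or "<none>"
            raise RegionError(
                f"{plastome.id}: no feature named {name!r}; available: {available}"
            )
    n = len(plastome.record.seq)
    ls, le = _copy_extent(lcopies[0])
    rs, re_ = _copy_extent(rcopies[0])
    if _spans_overlap(ls, le, rs, re_, n):
        raise RegionError(
            f"{plastome.id}: features {left!r} [{ls},{le}) and {right!r} "
            f"[{rs},{re_}) overlap; no spacer exists"
        )
    seq = plastome.record.seq
    if rs >= le:
        spacer = seq[le:rs]
    else:
        if not plastome.record.circular:
            raise RegionError(
                f"{plastome.id}: {right!r} precedes {left!r} on a linear sequence"
            )
        spacer = seq[le:] + seq[:rs]
    return SequenceRecord(plastome.id, spacer)


@dataclass
class Provenance:
    plastome_id: str
    start: int
    end: int
    strand: str


@dataclass
class RegionSet:
    """Per-taxon extracted sequences for the regions shared by all taxa."""

    regions: dict[str, dict[str, SequenceRecord]] = field(default_factory=dict)
    dropped: list[tuple[str, str, str]] = field(default_factory=list)  # region, taxon, reason

    def shared_names(self) -> list[str]:
        return list(self.regions)

    def write(self, out_dir: str | Path) -> None:
        from .seqio import write_fasta

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, per_taxon in self.regions.items():
            safe = name.replace("/", "_")
            write_fasta(per_taxon.values(), out_dir / f"{safe}.fasta")
        with (out_dir / "dropped_regions.tsv").open("w") as fh:
            fh.write("region\ttaxon\treason\n")
            for region, taxon, reason in self.dropped:
                fh.write(f"{region}\t{taxon}\t{reason}\n")


def build_region_set(
    plastomes: Sequence[AnnotatedPlastome],
    specs: Sequence[RegionSpec],
    ir_policy: str = "first",
) -> RegionSet:
    """Extract every spec from every plastome, keeping only shared regions.

    Absences are not fatal: the region is dropped from the shared set and the
    (region, taxon, reason) triple recorded.
    """
    if len(plastomes) < 2:
        raise RegionError("need at least two plastomes to build a shared set")
    rs = RegionSet()
    gene_like = [s for s in specs if s.mode in ("gene", "igs")]
    for spec in gene_like:
        per_taxon: dict[str, SequenceRecord] = {}
        failures: list[tuple[str, str]] = []
        for p in plastomes:
            try:
                if spec.mode == "gene":
                    rec = extract_gene(p, spec.parts[0] if spec.parts else spec.name,
                                       ir_policy=ir_policy)
                else:
                    rec = extract_igs(p, spec.parts[0], spec.parts[1])
            except RegionError as exc:
                failures.append((p.id, str(exc)))
                continue
            per_taxon[p.id] = rec
        if failures:
            for taxon, reason in failures:
                rs.dropped.append((spec.name, taxon, reason))
        else:
            rs.regions[spec.name] = per_taxon
    return rs


def concatenate(alignments: Sequence[Alignment]) -> tuple[Alignment, list[int]]:
    """Concatenate alignments over an identical taxon set.

    Returns the combined alignment and the partition boundaries (cumulative
    column offsets where each subsequent member begins). An empty input list
    is an error; zero-length members are identity elements.
    """
    alignments = [a for a in alignments]
    if not alignments:
        raise RegionError("nothing to concatenate")
    base = alignments[0]
    taxa = list(base.taxa)
    for a in alignments[1:]:
        if set(a.taxa) != set(taxa):
            missing = set(taxa) ^ set(a.taxa)
            raise RegionError(
                f"taxon set mismatch in concatenation: {sorted(missing)}"
            )
    boundaries: list[int] = []
    offset = 0
    rows = {t: [] for t in taxa}
    for a in alignments:
        boundaries.append(offset)
        for t in taxa:
            rows[t].append(a.row(t))
        offset += a.length
    return Alignment(taxa, ["".join(rows[t]) for t in taxa]), boundaries


def records_to_alignment(records: Iterable[SequenceRecord]) -> Alignment:
    """Treat equal-length extracted records as an alignment (no-indel case)."""
    records = list(records)
    return Alignment([r.id for r in records], [r.seq for r in records])
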