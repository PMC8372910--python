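"""Sequence containers and FASTA/GenBank I/O.

Internal coordinates are 0-based half-open on the plus strand; GenBank's
1-based inclusive convention is converted at the I/O boundary only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: DNA alphabet: canonical bases, IUPAC ambiguity codes, N, and the gap.
DNA_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-"
)

FEATURE_KINDS = ("PCG", "tRNA", "rRNA", "pseudogene", "other")


class SeqIOError(ValueError):
    """Raised for malformed sequence input."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_seq(seq: str, label: str) -> str:
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise SeqIOError(
            f"record {label!r}: illegal characters {sorted(bad)!r} in sequence"
        )
    return seq


@dataclass
class SequenceRecord:
    """A named DNA sequence; ``circular`` marks plastome-style topology.

    Empty sequences are permitted (a zero-length intergenic spacer is a
    legitimate extraction result); file readers reject them at the boundary.
    """

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence id must be nonempty")
        self.seq = _validate_seq(self.seq, self.id)

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, reverse_complement(self.seq), self.circular)


@dataclass
class Feature:
    """A stranded annotation interval (0-based half-open, plus strand).

    ``part`` orders the exon pieces of a join()-style multi-part feature;
    single-part features leave it ``None``.
    """

    name: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    part: int | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise SeqIOError("feature name must be nonempty")
        if self.kind not in FEATURE_KINDS:
            raise SeqIOError(f"feature {self.name!r}: unknown kind {self.kind!r}")
        if self.strand not in "+-":
            raise SeqIOError(f"feature {self.name!r}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise SeqIOError(
                f"feature {self.name!r}: invalid span [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedPlastome:
    """A (by default circular) genome plus its ordered feature table."""

    record: SequenceRecord
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.record.seq)
        for f in self.features:
            if f.end > n:
                raise SeqIOError(
                    f"feature {f.name!r} end {f.end} beyond sequence length {n}"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    @property
    def id(self) -> str:
        return self.record.id

    def feature_names(self) -> list[str]:
        seen: list[str] = []
        for f in self.features:
            if f.name not in seen:
                seen.append(f.name)
        return seen


@dataclass
class Alignment:
    """Rectangular gapped matrix of taxa x columns."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise SeqIOError("taxa and rows must have equal length")
        if len(self.taxa) < 2:
            raise SeqIOError("an alignment needs at least 2 taxa")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise SeqIOError(f"duplicate taxa in alignment: {dupes}")
        self.rows = [_validate_seq(r, t) for t, r in zip(self.taxa, self.rows)]
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            detail = ", ".join(
                f"{t}={len(r)}" for t, r in zip(self.taxa, self.rows)
            )
            raise SeqIOError(f"alignment rows have unequal lengths: {detail}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def subset_columns(self, start: int, end: int) -> "Alignment":
        return Alignment(list(self.taxa), [r[start:end] for r in self.rows])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-FASTA file, preserving record order.

    Duplicate ids and empty files/records are errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).replace(" ", "")
        if not seq:
            raise SeqIOError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise SeqIOError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA (equal-length gapped rows)."""
    records = read_fasta(path)
    return Alignment([r.id for r in records], [r.seq for r in records])


def write_alignment(aln: Alignment, path: str | Path, width: int = 70) -> None:
    write_fasta(
        (SequenceRecord(t, r) for t, r in zip(aln.taxa, aln.rows)), path, width
    )


# ---------------------------------------------------------------------------
# GenBank

_KIND_TO_GB = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "other": "misc_feature"}
_GB_TO_KIND = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "misc_feature": "other"}


def _feature_name(biofeat: SeqFeature) -> str | None:
    for key in ("gene", "product", "note", "locus_tag"):
        if key in biofeat.qualifiers:
            return str(biofeat.qualifiers[key][0])
    return None


def read_genbank(path: str | Path) -> AnnotatedPlastome:
    """Read one GenBank record into an :class:`AnnotatedPlastome`.

    1-based inclusive locations become 0-based half-open; each part of a
    ``join()`` becomes a separate :class:`Feature` sharing the name, with
    ``part`` numbering the exon order.
    """
    path = Path(path)
    rec = SeqIO.read(str(path), "genbank")
    circular = rec.annotations.get("topology", "circular") == "circular"
    features: list[Feature] = []
    for biofeat in rec.features:
        if biofeat.type in ("source", "gene") and "pseudo" not in biofeat.qualifiers:
            continue
        name = _feature_name(biofeat)
        if name is None:
            continue
        if "pseudo" in biofeat.qualifiers:
            kind = "pseudogene"
        else:
            kind = _GB_TO_KIND.get(biofeat.type)
            if kind is None:
                continue
        try:
            parts = list(biofeat.location.parts)
        except AttributeError as exc:  # pragma: no cover - defensive
            raise SeqIOError(f"{path}: malformed location for feature {name!r}") from exc
        multi = len(parts) > 1
        # join() part order is biological (exon order); for minus-strand joins
        # Biopython already lists parts in translation order.
        for i, loc in enumerate(parts):
            start, end = int(loc.start), int(loc.end)
            if start >= end:
                raise SeqIOError(
                    f"{path}: malformed location for feature {name!r}: {loc}"
                )
            features.append(
                Feature(
                    name=name,
                    kind=kind,
                    start=start,
                    end=end,
                    strand="-" if loc.strand == -1 else "+",
                    part=i if multi else None,
                )
            )
    record = SequenceRecord(rec.id or rec.name, str(rec.seq), circular=circular)
    return AnnotatedPlastome(record, features)


def write_genbank(plastome: AnnotatedPlastome, path: str | Path) -> None:
    """Minimal GenBank writer (simulator output; round-trips read_genbank)."""
    path = Path(path)
    rec = _BioSeqRecord(
        Seq(plastome.record.seq),
        id=plastome.record.id,
        name=re.sub(r"[^A-Za-z0-9_]", "_", plastome.record.id)[:16],
        description="synthetic plastome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if plastome.record.circular else "linear",
        },
    )
    # Group multi-part features back into one join() per (name, copy).
    grouped: dict[tuple[str, int], list[Feature]] = {}
    copy_counter: dict[str, int] = {}
    prev: Feature | None = None
    for f in plastome.features:
        if (
            prev is not None
            and f.name == prev.name
            and f.part is not None
            and prev.part is not None
            and f.part == prev.part + 1
        ):
            key = (f.name, copy_counter[f.name])
        else:
            copy_counter[f.name] = copy_counter.get(f.name, -1) + 1
            key = (f.name, copy_counter[f.name])
        grouped.setdefault(key, []).append(f)
        prev = f
    for (name, _copy), parts in grouped.items():
        parts = sorted(parts, key=lambda f: (f.part if f.part is not None else 0))
        strand = -1 if parts[0].strand == "-" else 1
        locs = [FeatureLocation(f.start, f.end, strand=strand) for f in parts]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        kind = parts[0].kind
        qualifiers = {"gene": [name]}
        if kind == "pseudogene":
            qualifiers["pseudo"] = [""]
            gb_type = "gene"
        else:
            gb_type = _KIND_TO_GB[kind]
        rec.features.append(SeqFeature(location, type=gb_type, qualifiers=qualifiers))
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# Label sanitation (Newick-safe taxon names)


def sanitize_labels(labels: Sequence[str]) -> dict[str, str]:
    """Map labels to Newick-safe forms (spaces -> underscores), uniquely."""
    mapping: dict[str, str] = {}
    used: set[str] = set()
    for label in labels:
        safe = re.sub(r"[\s]+", "_", label).replace("(", "_").replace(")", "_")
        safe = safe.replace(",", "_").replace(";", "_").replace(":", "_")
        candidate, i = safe, 1
        while candidate in used:
            i += 1
            candidate = f"{safe}_{i}"
        used.add(candidate)
        mapping[label] = candidate
    return mapping


def write_label_map(mapping: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("original\tsanitized\n")
        for orig, safe in mapping.items():
            fh.write(f"{orig}\t{safe}\n")


def read_label_map(path: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with Path(path).open() as fh:
        header = fh.readline()
        if header.strip() != "original\tsanitized":
            raise SeqIOError(f"{path}: not a label-map TSV")
        for line in fh:
            orig, safe = line.rstrip("\n").split("\t")
            mapping[orig] = safe
    return mapping
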