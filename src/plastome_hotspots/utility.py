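"""Monophyly-based phylogenetic utility scoring of candidate regions.

A candidate region's tree earns one point for each defined clade it recovers
as monophyletic, one point for a monophyletic outgroup-adjacent group when
one is defined among the clades, and one point for matching the reference
backbone after collapsing clades — with the canonical five-set definition
(four ingroup clades plus the sister genus) the maximum total is six.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .trees import (
    CladeDefinition,
    Tree,
    backbone_match,
    is_monophyletic,
    prepare_for_scoring,
)


class UtilityError(ValueError):
    pass


@dataclass
class UtilityScore:
    region: str
    clade_scores: dict[str, int]  # one 0/1 indicator per defined clade
    topology: int
    alignment_length: int | None = None
    prop_pi: float | None = None

    def __post_init__(self) -> None:
        for name, v in self.clade_scores.items():
            if v not in (0, 1):
                raise UtilityError(f"indicator for {name!r} must be 0/1")
        if self.topology not in (0, 1):
            raise UtilityError("topology indicator must be 0/1")

    @property
    def total(self) -> int:
        return sum(self.clade_scores.values()) + self.topology

    @property
    def max_total(self) -> int:
        return len(self.clade_scores) + 1


def score_region(
    candidate: Tree,
    reference: Tree,
    clades: CladeDefinition,
    region: str = "",
    alignment_length: int | None = None,
    prop_pi: float | None = None,
) -> UtilityScore:
    """Score one candidate tree against the reference topology.

    Excluded taxa are pruned and the candidate rooted with the outgroup
    before any monophyly check; the topology point comes from
    :func:`~plastome_hotspots.trees.backbone_match`.
    """
    missing = clades.all_scored_taxa() - clades.excluded - candidate.leaf_set()
    if missing:
        raise UtilityError(
            f"candidate tree for {region or '<region>'} is missing taxa: "
            f"{sorted(missing)}"
        )
    rooted = prepare_for_scoring(candidate, clades)
    indicators = {
        name: int(is_monophyletic(rooted, taxa))
        for name, taxa in clades.clades.items()
    }
    topo = int(backbone_match(candidate, reference, clades))
    return UtilityScore(
        region=region,
        clade_scores=indicators,
        topology=topo,
        alignment_length=alignment_length,
        prop_pi=prop_pi,
    )


@dataclass
class RankedTable:
    scores: list[UtilityScore] = field(default_factory=list)

    def write_tsv(self, path: str | Path) -> None:
        if not self.scores:
            raise UtilityError("nothing to write")
        clade_names = list(self.scores[0].clade_scores)
        with Path(path).open("w") as fh:
            header = (
                ["region", "alignment_length", "prop_pi"]
                + clade_names
                + ["topology", "total"]
            )
            fh.write("\t".join(header) + "\n")
            for s in self.scores:
                row = [
                    s.region,
                    "" if s.alignment_length is None else str(s.alignment_length),
                    "" if s.prop_pi is None else f"{s.prop_pi:.2f}",
                ]
                row += [str(s.clade_scores[c]) for c in clade_names]
                row += [str(s.topology), str(s.total)]
                fh.write("\t".join(row) + "\n")


def rank_regions(scores: list[UtilityScore]) -> RankedTable:
    """Sort by total desc, then prop_pi desc, then region name."""
    if not scores:
        raise UtilityError("no scores to rank")
    names = [s.region for s in scores]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise UtilityError(f"duplicate region names: {dupes}")
    ordered = sorted(
        scores,
        key=lambda s: (-s.total, -(s.prop_pi if s.prop_pi is not None else -1.0), s.region),
    )
    return RankedTable(ordered)
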