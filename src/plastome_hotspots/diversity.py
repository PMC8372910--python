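"""Alignment variability statistics.

Nucleotide diversity (pi) is the mean over unordered taxon pairs of
(pairwise differences / pairwise comparable sites). Gaps and IUPAC ambiguity
codes are missing data: under the default pairwise-deletion mode each pair is
compared only at columns where both rows carry an unambiguous base; under
complete deletion only columns unambiguous in every row are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import Alignment

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i


class DiversityError(ValueError):
    pass


def encode(aln: Alignment) -> np.ndarray:
    """uint8 matrix: A,C,G,T -> 0..3; gap/ambiguity -> 255."""
    flat = np.frombuffer(
        "".join(aln.rows).encode("ascii"), dtype=np.uint8
    ).reshape(aln.n_taxa, aln.length)
    return _CODE[flat]


@dataclass
class WindowConfig:
    window_length: int = 500
    step: int = 100

    def __post_init__(self) -> None:
        if not (self.window_length >= self.step >= 1):
            raise DiversityError(
                f"need window_length >= step >= 1, got "
                f"{self.window_length}/{self.step}"
            )


@dataclass
class DiversityProfile:
    """Per-window pi values; coordinates are 0-based half-open alignment columns."""

    starts: list[int]
    ends: list[int]
    pi: list[float]

    def max_window(self) -> tuple[int, int, float]:
        i = int(np.argmax(self.pi))
        return self.starts[i], self.ends[i], self.pi[i]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("window_start\twindow_end\tpi\n")
            for s, e, p in zip(self.starts, self.ends, self.pi):
                fh.write(f"{s}\t{e}\t{p:.6f}\n")


def _pair_arrays(mat: np.ndarray, gap_mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair boolean (diff, comparable) arrays, stacked over pairs."""
    n = mat.shape[0]
    good = mat < 4
    if gap_mode == "complete":
        all_good = good.all(axis=0)
        good = good & all_good[None, :]
    elif gap_mode != "pairwise":
        raise DiversityError(f"unknown gap_mode {gap_mode!r}")
    idx = [(i, j) for i in range(n) for j in range(i + 1, n)]
    comp = np.stack([good[i] & good[j] for i, j in idx])
    diff = np.stack([(mat[i] != mat[j]) for i, j in idx]) & comp
    return diff, comp


def nucleotide_diversity(
    aln: Alignment,
    columns: tuple[int, int] | None = None,
    gap_mode: str = "pairwise",
) -> float:
    """Average pairwise proportion of differing sites.

    Pairs with zero comparable sites contribute nothing and reduce the pair
    count; if no pair is comparable at all, that is an error.
    """
    mat = encode(aln)
    if columns is not None:
        mat = mat[:, columns[0] : columns[1]]
    diff, comp = _pair_arrays(mat, gap_mode)
    nc = comp.sum(axis=1)
    usable = nc > 0
    if not usable.any():
        raise DiversityError("no comparable sites in any taxon pair")
    per_pair = diff.sum(axis=1)[usable] / nc[usable]
    return float(per_pair.mean())


def sliding_window_pi(
    aln: Alignment, cfg: WindowConfig | None = None, gap_mode: str = "pairwise"
) -> DiversityProfile:
    """Windows start at 0, step, 2*step, ...; only full windows are emitted."""
    cfg = cfg or WindowConfig()
    L = aln.length
    if L < cfg.window_length:
        raise DiversityError(
            f"alignment length {L} shorter than one window ({cfg.window_length})"
        )
    mat = encode(aln)
    diff, comp = _pair_arrays(mat, gap_mode)
    # cumulative sums let every window be O(#pairs)
    dcum = np.cumsum(diff, axis=1, dtype=np.int64)
    ccum = np.cumsum(comp, axis=1, dtype=np.int64)
    dcum = np.hstack([np.zeros((dcum.shape[0], 1), dtype=np.int64), dcum])
    ccum = np.hstack([np.zeros((ccum.shape[0], 1), dtype=np.int64), ccum])
    starts, ends, pis = [], [], []
    for s in range(0, L - cfg.window_length + 1, cfg.step):
        e = s + cfg.window_length
        d = dcum[:, e] - dcum[:, s]
        c = ccum[:, e] - ccum[:, s]
        usable = c > 0
        if not usable.any():
            pi = 0.0
        else:
            pi = float((d[usable] / c[usable]).mean())
        starts.append(s)
        ends.append(e)
        pis.append(pi)
    return DiversityProfile(starts, ends, pis)


@dataclass
class SiteClassCounts:
    invariant: int = 0
    variable: int = 0  # includes parsimony-informative columns
    parsimony_informative: int = 0
    gap_or_ambiguous_only: int = 0

    @property
    def total(self) -> int:
        return self.invariant + self.variable + self.gap_or_ambiguous_only


def site_classes(aln: Alignment) -> SiteClassCounts:
    """Classify columns; gaps/ambiguities never count as states.

    variable: >=2 distinct unambiguous bases present.
    parsimony-informative: >=2 distinct unambiguous bases each in >=2 taxa.
    """
    mat = encode(aln)
    counts = SiteClassCounts()
    # per-column base occupancy counts, vectorized over the 4 bases
    occ = np.stack([(mat == b).sum(axis=0) for b in range(4)])  # 4 x L
    n_states = (occ > 0).sum(axis=0)
    n_deep = (occ >= 2).sum(axis=0)
    counts.gap_or_ambiguous_only = int((n_states == 0).sum())
    counts.invariant = int((n_states == 1).sum())
    counts.variable = int((n_states >= 2).sum())
    counts.parsimony_informative = int(((n_states >= 2) & (n_deep >= 2)).sum())
    return counts


@dataclass
class RegionStats:
    name: str
    alignment_length: int
    prop_variable: float
    prop_pi: float
    n_taxa: int
    counts: SiteClassCounts = field(repr=False, default_factory=SiteClassCounts)


def region_stats(name: str, aln: Alignment) -> RegionStats:
    """Length and variable/PI-site proportions for one region alignment."""
    counts = site_classes(aln)
    L = aln.length
    return RegionStats(
        name=name,
        alignment_length=L,
        prop_variable=counts.variable / L if L else 0.0,
        prop_pi=counts.parsimony_informative / L if L else 0.0,
        n_taxa=aln.n_taxa,
        counts=counts,
    )


def stats_table(stats: list[RegionStats], path) -> None:
    with open(path, "w") as fh:
        fh.write("region\talignment_length\tprop_variable\tprop_pi\tn_taxa\n")
        for s in stats:
            fh.write(
                f"{s.name}\t{s.alignment_length}\t{s.prop_variable:.4f}\t"
                f"{s.prop_pi:.4f}\t{s.n_taxa}\n"
            )


def plot_profile(profile: DiversityProfile, path, top_k: int = 6) -> None:
    """Render the sliding-window profile with the top-k peaks labeled."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mids = [(s + e) / 2 for s, e in zip(profile.starts, profile.ends)]
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(mids, profile.pi, lw=0.8)
    order = np.argsort(profile.pi)[::-1][:top_k]
    for i in order:
        ax.annotate(
            f"{profile.pi[i]:.3f}",
            (mids[i], profile.pi[i]),
            fontsize=7,
            ha="center",
            va="bottom",
        )
    ax.set_xlabel("alignment position (bp)")
    ax.set_ylabel("nucleotide diversity (pi)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
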