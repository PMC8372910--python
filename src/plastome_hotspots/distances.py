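"""Pairwise genetic distances: Kimura 2-parameter and p-distance.

K2P counts transition (P) and transversion (Q) proportions over columns where
both rows carry an unambiguous base and applies
d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q). Saturated pairs (either log
argument <= 0) are flagged undefined (NaN), never clamped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import encode
from .seqio import Alignment

MODELS = ("K2P", "p")


class DistanceError(ValueError):
    pass


class SaturationWarning(UserWarning):
    pass


def _counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(comparable sites, transitions, transversions) for two coded rows."""
    both = (a < 4) & (b < 4)
    n = int(both.sum())
    diff = both & (a != b)
    # coding A=0 C=1 G=2 T=3: transitions (A<->G, C<->T) differ by xor 2
    ts = int((diff & ((a ^ b) == 2)).sum())
    tv = int(diff.sum()) - ts
    return n, ts, tv


def _k2p_from_counts(n: int, ts: int, tv: int) -> float:
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        warnings.warn(
            f"K2P undefined (saturation): P={P:.4f}, Q={Q:.4f}", SaturationWarning,
            stacklevel=3,
        )
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p(a: str, b: str) -> float:
    """K2P distance between two aligned (equal-length) gapped sequences."""
    if len(a) != len(b):
        raise DistanceError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    aln = Alignment(["a", "b"], [a, b])
    mat = encode(aln)
    n, ts, tv = _counts(mat[0], mat[1])
    if n == 0:
        raise DistanceError("no comparable sites between the two sequences")
    return _k2p_from_counts(n, ts, tv)


def p_distance(a: str, b: str) -> float:
    if len(a) != len(b):
        raise DistanceError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    aln = Alignment(["a", "b"], [a, b])
    mat = encode(aln)
    n, ts, tv = _counts(mat[0], mat[1])
    if n == 0:
        raise DistanceError("no comparable sites between the two sequences")
    return (ts + tv) / n


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray  # square, symmetric; NaN marks undefined (saturated) pairs
    model: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise DistanceError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if self.model not in MODELS:
            raise DistanceError(f"unknown model {self.model!r}")
        if not np.allclose(np.diag(self.d), 0.0):
            raise DistanceError("diagonal must be zero")
        off = ~np.eye(n, dtype=bool)
        finite = np.isfinite(self.d)
        if not np.array_equal(finite, finite.T):
            raise DistanceError("undefined entries must be symmetric")
        if not np.allclose(
            self.d[off & finite], self.d.T[off & finite], atol=1e-12
        ):
            raise DistanceError("matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def has_undefined(self) -> bool:
        return bool(np.isnan(self.d).any())

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])

    def summary(self) -> dict:
        """Min/max off-diagonal distances with their taxon pairs."""
        n = self.n
        best = (math.inf, None)
        worst = (-math.inf, None)
        for i in range(n):
            for j in range(i + 1, n):
                v = self.d[i, j]
                if math.isnan(v):
                    continue
                if v < best[0]:
                    best = (v, (self.taxa[i], self.taxa[j]))
                if v > worst[0]:
                    worst = (v, (self.taxa[i], self.taxa[j]))
        return {
            "min": best[0],
            "min_pair": best[1],
            "max": worst[0],
            "max_pair": worst[1],
            "n_undefined": int(np.isnan(self.d).sum() // 2),
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.taxa, columns=self.taxa)

    def write_tsv(self, path) -> None:
        df = self.to_dataframe().round(4)
        df.to_csv(path, sep="\t", float_format="%.4f")

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, t in enumerate(self.taxa):
                row = " ".join(f"{v:.6f}" for v in self.d[i])
                fh.write(f"{t:<12s}{row}\n")


def distance_matrix(
    aln: Alignment, model: str = "K2P", deletion: str = "pairwise"
) -> DistanceMatrix:
    """All-pairs distance matrix under K2P or p-distance.

    ``deletion`` chooses pairwise deletion (default) or complete deletion
    (columns unambiguous in every row).
    """
    if model not in MODELS:
        raise DistanceError(f"unknown model {model!r}")
    mat = encode(aln)
    if deletion == "complete":
        keep = (mat < 4).all(axis=0)
        mat = mat[:, keep]
    elif deletion != "pairwise":
        raise DistanceError(f"unknown deletion mode {deletion!r}")
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            nc, ts, tv = _counts(mat[i], mat[j])
            if nc == 0:
                raise DistanceError(
                    f"no comparable sites between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
                )
            if model == "K2P":
                v = _k2p_from_counts(nc, ts, tv)
            else:
                v = (ts + tv) / nc
            d[i, j] = d[j, i] = v
    return DistanceMatrix(list(aln.taxa), d, model)


def combined_matrix_table(
    lower: DistanceMatrix, upper: DistanceMatrix
) -> pd.DataFrame:
    """Two-triangle table: lower triangle from ``lower``, upper from ``upper``.

    The diagonal is left empty (NaN). Taxon sets and order must match.
    """
    if lower.taxa != upper.taxa:
        raise DistanceError(
            "taxon sets/order differ between the two matrices: "
            f"{lower.taxa} vs {upper.taxa}"
        )
    n = lower.n
    out = np.full((n, n), np.nan)
    il = np.tril_indices(n, k=-1)
    iu = np.triu_indices(n, k=1)
    out[il] = lower.d[il]
    out[iu] = upper.d[iu]
    return pd.DataFrame(out, index=lower.taxa, columns=lower.taxa)


def read_combined_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_combined_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.4f")


def plot_heatmap(df: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.35 * len(df) + 2, 0.35 * len(df) + 1.5))
    im = ax.imshow(df.values, cmap="viridis")
    ax.set_xticks(range(len(df)), df.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(df)), df.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="distance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
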