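"""Kimura two-parameter distances with pairwise deletion, and the
rank-level distance summaries used to profile a barcode library.

For an aligned pair, sites where either row carries a gap or an
ambiguity code are excluded ("pairwise deletion").  With P the
transition proportion and Q the transversion proportion over the
remaining sites,

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

The distance is undefined (masked, never clamped) when no sites remain
or when either logarithm argument is non-positive (saturation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .annotate import encode
from .msa import Alignment
from .records import TaxonomyTable

RANKS = ("species", "genus", "family")


def k2p_from_pq(p: float, q: float) -> float:
    """K2P distance from transition / transversion proportions.

    Returns ``nan`` outside the defined domain.
    """
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1 * math.sqrt(w2)) + 0.0  # +0.0 folds -0.0 into 0.0


@dataclass(frozen=True)
class K2PResult:
    distance: float  # nan when undefined
    p: float
    q: float
    n_sites: int
    reason: str | None = None  # None when defined: "no_sites" | "saturated"

    @property
    def defined(self) -> bool:
        return self.reason is None


def k2p(row_i: str, row_j: str) -> K2PResult:
    """K2P distance between two aligned rows under pairwise deletion."""
    if len(row_i) != len(row_j):
        raise ValueError("aligned rows must have equal length")
    a, b = encode(row_i), encode(row_j)
    valid = (a < 4) & (b < 4)
    n = int(valid.sum())
    if n == 0:
        return K2PResult(math.nan, math.nan, math.nan, 0, "no_sites")
    diff = valid & (a != b)
    pur_a = (a == 0) | (a == 2)
    pur_b = (b == 0) | (b == 2)
    ts = int((diff & (pur_a == pur_b)).sum())  # A<->G or C<->T
    tv = int(diff.sum()) - ts
    p, q = ts / n, tv / n
    d = k2p_from_pq(p, q)
    if math.isnan(d):
        return K2PResult(math.nan, p, q, n, "saturated")
    return K2PResult(d, p, q, n, None)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distances with an undefined-entry mask.

    ``distance`` holds nan for undefined pairs; ``reasons`` maps an
    (i, j) index pair (i < j) to why it is undefined.
    """

    ids: list[str]
    distance: np.ndarray  # (n, n) float, nan = undefined
    p: np.ndarray
    q: np.ndarray
    n_sites: np.ndarray  # (n, n) int
    reasons: dict[tuple[int, int], str]

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.distance)

    @property
    def n_undefined_pairs(self) -> int:
        return len(self.reasons)

    def get(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.distance[i, j])

    def submatrix(self, keep_ids: Iterable[str]) -> "DistanceMatrix":
        keep = list(keep_ids)
        idx = np.array([self.ids.index(s) for s in keep])
        sub = lambda m: m[np.ix_(idx, idx)]
        pos = {int(v): k for k, v in enumerate(idx)}
        reasons = {
            (min(pos[i], pos[j]), max(pos[i], pos[j])): r
            for (i, j), r in self.reasons.items()
            if i in pos and j in pos
        }
        return DistanceMatrix(
            keep, sub(self.distance), sub(self.p), sub(self.q), sub(self.n_sites), reasons
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.distance, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.6f")

    def write_phylip(self, path: str | Path) -> None:
        """Lower-triangle PHYLIP-style text ('NA' marks undefined pairs)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, name in enumerate(self.ids):
                cells = [
                    "NA" if math.isnan(self.distance[i, j]) else f"{self.distance[i, j]:.6f}"
                    for j in range(i)
                ]
                fh.write("\t".join([name] + cells) + "\n")


def distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """All-pairs K2P under pairwise deletion; symmetric by construction."""
    enc = alignment.encoded()
    n = enc.shape[0]
    valid = enc < 4
    purine = (enc == 0) | (enc == 2)
    dist = np.zeros((n, n))
    p = np.zeros((n, n))
    q = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(sites, valid.sum(axis=1))
    reasons: dict[tuple[int, int], str] = {}
    for i in range(n - 1):
        v = valid[i] & valid[i + 1 :]
        diff = (enc[i] != enc[i + 1 :]) & v
        ts = (diff & (purine[i] == purine[i + 1 :])).sum(axis=1)
        nv = v.sum(axis=1)
        tot = diff.sum(axis=1)
        tv = tot - ts
        with np.errstate(divide="ignore", invalid="ignore"):
            pi = np.where(nv > 0, ts / np.maximum(nv, 1), np.nan)
            qi = np.where(nv > 0, tv / np.maximum(nv, 1), np.nan)
            w1 = 1.0 - 2.0 * pi - qi
            w2 = 1.0 - 2.0 * qi
            di = (
                np.where(
                    (w1 > 0) & (w2 > 0), -0.5 * np.log(w1 * np.sqrt(np.abs(w2))), np.nan
                )
                + 0.0  # fold -0.0 into 0.0
            )
        for off in range(di.size):
            j = i + 1 + off
            dist[i, j] = dist[j, i] = di[off]
            p[i, j] = p[j, i] = pi[off]
            q[i, j] = q[j, i] = qi[off]
            sites[i, j] = sites[j, i] = nv[off]
            if nv[off] == 0:
                reasons[(i, j)] = "no_sites"
            elif math.isnan(di[off]):
                reasons[(i, j)] = "saturated"
    return DistanceMatrix(list(alignment.ids), dist, p, q, sites, reasons)


# ---------------------------------------------------------------------------
# rank summaries
# ---------------------------------------------------------------------------

@dataclass
class RankSummary:
    """Pooled within-taxon distances at one rank, reported in percent.

    Comparisons at a rank are the pairs whose *most recent shared rank*
    is that rank: within-species pairs; same genus but different
    species; same family but different genus.
    """

    rank: str
    n_taxa: int
    n_comparisons: int
    min_pct: float
    max_pct: float
    mean_pct: float
    n_masked: int

    def to_row(self) -> dict:
        return {
            "rank": self.rank,
            "taxa": self.n_taxa,
            "comparisons": self.n_comparisons,
            "min_pct": self.min_pct,
            "max_pct": self.max_pct,
            "mean_pct": self.mean_pct,
            "masked": self.n_masked,
        }


def _pair_selector(
    dm: DistanceMatrix, taxonomy: TaxonomyTable, rank: str
) -> tuple[np.ndarray, np.ndarray]:
    """(pair mask, shared-taxon labels) for the rank's comparison set."""
    species = np.array([taxonomy.species_of(s) for s in dm.ids])
    genus = np.array([taxonomy.genus_of(s) for s in dm.ids])
    family = np.array([taxonomy.family_of(s) for s in dm.ids])
    same_sp = species[:, None] == species[None, :]
    same_ge = genus[:, None] == genus[None, :]
    same_fa = family[:, None] == family[None, :]
    if rank == "species":
        mask, labels = same_sp, species
    elif rank == "genus":
        mask, labels = same_ge & ~same_sp, genus
    elif rank == "family":
        mask, labels = same_fa & ~same_ge, family
    else:
        raise ValueError(f"unknown rank: {rank}")
    mask = np.triu(mask, k=1)
    return mask, labels


def summarize_rank(
    dm: DistanceMatrix, taxonomy: TaxonomyTable, rank: str
) -> RankSummary:
    """Pool within-taxon pairwise distances at a rank (percent scale).

    Masked (undefined) distances are excluded and counted separately; a
    rank with no multi-member taxa yields an empty (zero-comparison)
    summary.
    """
    mask, labels = _pair_selector(dm, taxonomy, rank)
    ii, jj = np.nonzero(mask)
    vals = dm.distance[ii, jj]
    ok = ~np.isnan(vals)
    n_masked = int((~ok).sum())
    vals = vals[ok]
    if vals.size == 0:
        return RankSummary(rank, 0, 0, math.nan, math.nan, math.nan, n_masked)
    taxa = np.unique(labels[ii[ok]])
    pct = vals * 100.0
    return RankSummary(
        rank,
        int(taxa.size),
        int(vals.size),
        float(pct.min()),
        float(pct.max()),
        float(pct.mean()),
        n_masked,
    )


def summarize_all_ranks(dm: DistanceMatrix, taxonomy: TaxonomyTable) -> pd.DataFrame:
    """Species/genus/family distance-summary table (percent)."""
    return pd.DataFrame(
        [summarize_rank(dm, taxonomy, rank).to_row() for rank in RANKS]
    )
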