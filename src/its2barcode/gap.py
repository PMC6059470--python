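"""Barcoding-gap analysis.

For every species with at least two sequences, compare its maximum
intraspecific K2P distance against the minimum distance from any of its
sequences to any sequence of another species (the nearest neighbor).  A
species *violates the gap* when the former strictly exceeds the latter:
its internal variation reaches past its closest heterospecific, so
distance-based identification cannot separate them.  Singletons carry no
intraspecific distance and are excluded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .records import TaxonomyTable


@dataclass
class GapRecord:
    species: str
    n_specimens: int
    max_intra_pct: float
    nn_species: str
    min_inter_pct: float
    violation: bool
    tie: bool  # max_intra == min_inter exactly; reported, not a violation


def gap_table(
    dm: DistanceMatrix, taxonomy: TaxonomyTable
) -> tuple[list[GapRecord], pd.DataFrame]:
    """Per-species gap records plus a table of excluded species.

    Undefined distances never enter the min/max; nearest-neighbor ties
    resolve to the lexicographically first species.  Excluded species
    (with reason ``singleton`` or ``intra_undefined``) are returned in
    the second table.
    """
    species = np.array([taxonomy.species_of(s) for s in dm.ids])
    order = sorted(set(species))
    records: list[GapRecord] = []
    excluded: list[tuple[str, str]] = []
    for sp in order:
        members = np.nonzero(species == sp)[0]
        if members.size < 2:
            excluded.append((sp, "singleton"))
            continue
        intra = dm.distance[np.ix_(members, members)][
            np.triu_indices(members.size, k=1)
        ]
        intra = intra[~np.isnan(intra)]
        if intra.size == 0:
            excluded.append((sp, "intra_undefined"))
            continue
        max_intra = float(intra.max())

        others = np.nonzero(species != sp)[0]
        inter = dm.distance[np.ix_(members, others)]
        finite = ~np.isnan(inter)
        if not finite.any():
            excluded.append((sp, "inter_undefined"))
            continue
        min_inter = float(inter[finite].min())
        # nearest neighbor: species achieving the minimum; ties -> first name
        at_min = np.isclose(inter, min_inter, rtol=0.0, atol=0.0) & finite
        nn_candidates = sorted(set(species[others[at_min.any(axis=0)]]))
        nn = nn_candidates[0]
        records.append(
            GapRecord(
                species=sp,
                n_specimens=int(members.size),
                max_intra_pct=max_intra * 100.0,
                nn_species=nn,
                min_inter_pct=min_inter * 100.0,
                violation=max_intra > min_inter,
                tie=max_intra == min_inter,
            )
        )
    if not records:
        warnings.warn("no species with >= 2 specimens; gap table is empty")
    excluded_df = pd.DataFrame(excluded, columns=["species", "reason"])
    return records, excluded_df


def gap_frame(records: list[GapRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "n": r.n_specimens,
                "max_intra_pct": r.max_intra_pct,
                "nn_species": r.nn_species,
                "min_inter_pct": r.min_inter_pct,
                "violation": r.violation,
                "tie": r.tie,
            }
            for r in records
        ]
    )


def write_gap_outputs(
    records: list[GapRecord], out_tsv: str | Path, scatter_tsv: str | Path | None = None
) -> None:
    """TSV of gap records plus scatter data (x = max intra, y = min inter)."""
    frame = gap_frame(records)
    frame.to_csv(out_tsv, sep="\t", index=False)
    if scatter_tsv is not None:
        frame[["species", "max_intra_pct", "min_inter_pct"]].to_csv(
            scatter_tsv, sep="\t", index=False
        )


def n_violations(records: list[GapRecord]) -> int:
    return sum(r.violation for r in records)
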