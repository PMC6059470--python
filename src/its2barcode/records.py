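"""Core containers: sequence records and the specimen taxonomy table.

A reference barcode library is a set of specimen sequences plus a
four-column taxonomy (specimen_id, species, genus, family).  Both are
kept deliberately thin: sequences as plain strings, the taxonomy as a
pandas DataFrame wrapped with lookup helpers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

TAXONOMY_COLUMNS = ("specimen_id", "species", "genus", "family")


@dataclass(frozen=True)
class SequenceRecord:
    """One specimen's nucleotide sequence."""

    specimen_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


class TaxonomyTable:
    """Specimen → species → genus → family mapping.

    Wraps a DataFrame with columns ``specimen_id, species, genus,
    family`` (one row per specimen, specimen ids unique).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in TAXONOMY_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"taxonomy table missing columns: {missing}")
        if frame["specimen_id"].duplicated().any():
            dups = frame.loc[frame["specimen_id"].duplicated(), "specimen_id"]
            raise ValueError(f"duplicate specimen ids: {sorted(set(dups))[:5]}")
        self.frame = frame.loc[:, list(TAXONOMY_COLUMNS)].reset_index(drop=True)
        self._species = dict(zip(self.frame["specimen_id"], self.frame["species"]))
        self._genus = dict(zip(self.frame["specimen_id"], self.frame["genus"]))
        self._family = dict(zip(self.frame["specimen_id"], self.frame["family"]))

    # -- lookups ---------------------------------------------------------
    def species_of(self, specimen_id: str) -> str:
        return self._species[specimen_id]

    def genus_of(self, specimen_id: str) -> str:
        return self._genus[specimen_id]

    def family_of(self, specimen_id: str) -> str:
        return self._family[specimen_id]

    def genus_of_species(self, species: str) -> str:
        sub = self.frame.loc[self.frame["species"] == species, "genus"]
        return sub.iloc[0]

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.frame["specimen_id"])

    @property
    def species(self) -> list[str]:
        return sorted(self.frame["species"].unique())

    def specimens_of_species(self, species: str) -> list[str]:
        sel = self.frame["species"] == species
        return list(self.frame.loc[sel, "specimen_id"])

    def species_counts(self) -> pd.Series:
        return self.frame.groupby("species").size()

    def singleton_species(self) -> list[str]:
        counts = self.species_counts()
        return sorted(counts.index[counts == 1])

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, specimen_id: str) -> bool:
        return specimen_id in self._species

    # -- I/O -------------------------------------------------------------
    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TaxonomyTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into sequence records (uppercased)."""
    return [
        SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = (
        _BioSeqRecord(Seq(r.sequence), id=r.specimen_id, description="")
        for r in records
    )
    SeqIO.write(bio, str(path), "fasta")


def records_by_id(records: Iterable[SequenceRecord]) -> dict[str, SequenceRecord]:
    out: dict[str, SequenceRecord] = {}
    for r in records:
        if r.specimen_id in out:
            raise ValueError(f"duplicate sequence id: {r.specimen_id}")
        out[r.specimen_id] = r
    return out
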