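"""Similarity-based species identification against a reference library.

Every query is globally aligned (free end gaps; match +1, mismatch −1,
gap open −2, extend −0.5) against every library sequence.  The best-hit
set is every hit tying the top identity; identification is *correct*
when all best hits are conspecific with the query, *ambiguous* when they
mix conspecific and heterospecific labels, and *incorrect* when none is
conspecific.  The same rule applied to genus labels, at a more permissive
identity cutoff, gives the genus-level call.  Conspecific queries whose
best-match species disagree flag possible cryptic diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .records import SequenceRecord, TaxonomyTable

DEFAULT_MIN_IDENTITY = 0.97  # species level
DEFAULT_GENUS_MIN_IDENTITY = 0.95
DEFAULT_MIN_COVERAGE = 0.95
TIE_TOLERANCE = 1e-9


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    # free end gaps: identity mimics a local hit over full-length barcodes
    if hasattr(aligner, "open_end_insertion_score"):
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    else:  # older Biopython attribute names
        aligner.target_end_open_gap_score = 0.0
        aligner.target_end_extend_gap_score = 0.0
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


@dataclass(frozen=True)
class Hit:
    subject_id: str
    subject_species: str
    identity: float  # matches / aligned columns, end gaps excluded
    coverage: float  # fraction of query length inside the aligned core
    score: float


def alignment_identity(row_q: str, row_s: str) -> tuple[float, float]:
    """(identity, query coverage) of one gapped pair, excluding end gaps.

    The aligned core runs from the first to the last column where both
    rows carry a residue; identity counts matching columns over all core
    columns (internal gaps penalise identity), coverage counts query
    residues inside the core against the full query length.
    """
    q = np.frombuffer(row_q.encode(), dtype=np.uint8)
    s = np.frombuffer(row_s.encode(), dtype=np.uint8)
    gap = ord("-")
    both = (q != gap) & (s != gap)
    if not both.any():
        return 0.0, 0.0
    first, last = np.nonzero(both)[0][[0, -1]]
    core = slice(first, last + 1)
    n_cols = last - first + 1
    matches = int(((q == s) & both)[core].sum())
    q_len = int((q != gap).sum())
    q_in_core = int((q[core] != gap).sum())
    return matches / n_cols, q_in_core / q_len if q_len else 0.0


def best_match(
    query: SequenceRecord,
    library: Sequence[SequenceRecord],
    taxonomy: TaxonomyTable,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    leave_one_out: bool = False,
    aligner: Align.PairwiseAligner | None = None,
) -> list[Hit]:
    """All hits passing the identity/coverage filters, best first.

    ``leave_one_out`` removes the library entry with the query's own id.
    Ties are ordered by (−identity, subject_id) so output is
    deterministic.
    """
    if not library:
        raise ValueError("reference library is empty")
    if aligner is None:
        aligner = _make_aligner()
    hits = []
    for subject in library:
        if leave_one_out and subject.specimen_id == query.specimen_id:
            continue
        aln = aligner.align(query.sequence, subject.sequence)[0]
        identity, coverage = alignment_identity(str(aln[0]), str(aln[1]))
        if identity >= min_identity and coverage >= min_coverage:
            hits.append(
                Hit(
                    subject_id=subject.specimen_id,
                    subject_species=taxonomy.species_of(subject.specimen_id),
                    identity=identity,
                    coverage=coverage,
                    score=float(aln.score),
                )
            )
    hits.sort(key=lambda h: (-h.identity, h.subject_id))
    return hits


def best_hit_set(hits: Sequence[Hit], tolerance: float = TIE_TOLERANCE) -> list[Hit]:
    """Hits within ``tolerance`` of the top identity."""
    if not hits:
        return []
    top = max(h.identity for h in hits)
    return [h for h in hits if h.identity >= top - tolerance]


def classify_labels(true_label: str, best_labels: Sequence[str]) -> str:
    """Three-way call from the best-hit label multiset.

    correct: every best hit carries the true label; ambiguous: the true
    label is present alongside others; incorrect: the true label is
    absent.
    """
    labels = set(best_labels)
    if not labels:
        return "no_hit"
    if labels == {true_label}:
        return "correct"
    if true_label in labels:
        return "ambiguous"
    return "incorrect"


@dataclass
class IdentificationResult:
    query_id: str
    true_species: str | None
    best_hits: list[Hit] = field(default_factory=list)  # species-level best set
    species_call: str = "no_hit"
    genus_call: str = "no_hit"
    top_identity: float = float("nan")
    unsupervised: bool = False

    @property
    def best_species(self) -> list[str]:
        return sorted({h.subject_species for h in self.best_hits})


def identify_query(
    query: SequenceRecord,
    library: Sequence[SequenceRecord],
    taxonomy: TaxonomyTable,
    true_species: str | None = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    genus_min_identity: float = DEFAULT_GENUS_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    leave_one_out: bool = False,
    aligner: Align.PairwiseAligner | None = None,
) -> IdentificationResult:
    """Identify one query at the species and genus level.

    The genus-level call reuses the same three-way rule on genus labels
    of the best hits at the (lower) genus identity cutoff — this admits
    queries whose species is absent from the reference but whose genus
    is represented above ``genus_min_identity``.
    """
    floor = min(min_identity, genus_min_identity)
    hits = best_match(
        query,
        library,
        taxonomy,
        min_identity=floor,
        min_coverage=min_coverage,
        leave_one_out=leave_one_out,
        aligner=aligner,
    )
    species_hits = [h for h in hits if h.identity >= min_identity]
    sp_best = best_hit_set(species_hits)
    genus_best = best_hit_set(hits)

    result = IdentificationResult(
        query_id=query.specimen_id,
        true_species=true_species,
        best_hits=sp_best,
        top_identity=max((h.identity for h in hits), default=float("nan")),
    )
    if true_species is None:
        # no supervision: report the top label(s) without judging them
        result.unsupervised = True
        result.species_call = "unsupervised"
        result.genus_call = "unsupervised"
        return result
    result.species_call = classify_labels(
        true_species, [h.subject_species for h in sp_best]
    )
    true_genus = taxonomy.genus_of_species(true_species)
    result.genus_call = classify_labels(
        true_genus,
        [taxonomy.genus_of(h.subject_id) for h in genus_best],
    )
    return result


def leave_one_out_identification(
    records: Sequence[SequenceRecord],
    taxonomy: TaxonomyTable,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    genus_min_identity: float = DEFAULT_GENUS_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[IdentificationResult]:
    """Query every library member against the rest of the library."""
    aligner = _make_aligner()
    return [
        identify_query(
            rec,
            records,
            taxonomy,
            true_species=taxonomy.species_of(rec.specimen_id),
            min_identity=min_identity,
            genus_min_identity=genus_min_identity,
            min_coverage=min_coverage,
            leave_one_out=True,
            aligner=aligner,
        )
        for rec in records
    ]


def success_rates(
    results: Sequence[IdentificationResult], level: str = "species"
) -> dict:
    """Correct / ambiguous / incorrect percentages over classified queries.

    ``no_hit`` and unsupervised queries are excluded from the
    denominator but reported in the counts.
    """
    if not results:
        raise ValueError("no identification results")
    calls = [
        r.species_call if level == "species" else r.genus_call for r in results
    ]
    n_no_hit = calls.count("no_hit")
    n_unsup = calls.count("unsupervised")
    classified = [c for c in calls if c in ("correct", "ambiguous", "incorrect")]
    n = len(classified)
    if n == 0:
        raise ValueError("no classified queries (all no_hit/unsupervised)")
    pct = lambda c: 100.0 * classified.count(c) / n
    return {
        "level": level,
        "n_queries": len(calls),
        "n_classified": n,
        "n_no_hit": n_no_hit,
        "n_unsupervised": n_unsup,
        "correct_pct": pct("correct"),
        "ambiguous_pct": pct("ambiguous"),
        "incorrect_pct": pct("incorrect"),
    }


def conspecific_consistency(
    results: Sequence[IdentificationResult], taxonomy: TaxonomyTable
) -> pd.DataFrame:
    """Flag species whose conspecific queries disagree on the best match.

    Status per species (≥2 classified queries): ``consistent`` when all
    queries return the same best-match species set; ``cryptic_candidate``
    when two queries return disjoint sets (the paper's cryptic-diversity
    signal); ``inconsistent_ambiguous`` when sets differ but overlap.
    """
    per_species: dict[str, list[frozenset[str]]] = {}
    for r in results:
        if r.true_species is None or not r.best_hits:
            continue
        per_species.setdefault(r.true_species, []).append(
            frozenset(r.best_species)
        )
    rows = []
    for sp, sets in sorted(per_species.items()):
        if len(sets) < 2:
            continue
        if all(s == sets[0] for s in sets):
            status = "consistent"
        elif any(
            not (sets[i] & sets[j])
            for i in range(len(sets))
            for j in range(i + 1, len(sets))
        ):
            status = "cryptic_candidate"
        else:
            status = "inconsistent_ambiguous"
        rows.append(
            {
                "species": sp,
                "n_queries": len(sets),
                "status": status,
                "best_match_sets": ";".join(
                    sorted("|".join(sorted(s)) for s in set(sets))
                ),
            }
        )
    return pd.DataFrame(rows, columns=["species", "n_queries", "status", "best_match_sets"])


def results_frame(results: Sequence[IdentificationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_id": r.query_id,
                "true_species": r.true_species,
                "species_call": r.species_call,
                "genus_call": r.genus_call,
                "best_species": "|".join(r.best_species),
                "top_identity": r.top_identity,
            }
            for r in results
        ]
    )
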