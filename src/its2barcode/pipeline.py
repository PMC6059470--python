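"""End-to-end evaluation pipeline for a barcode reference library.

Stages: simulate (or load) → annotate → align → distance → gap → tree →
identify.  Every stage writes plain-text artifacts (FASTA / TSV /
newick) into the output directory plus a consolidated JSON summary, so
any stage's output can be re-loaded to resume downstream work.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotate import MotifProfile, annotate_records, group_summary, seq_stats
from .distance import distance_matrix, summarize_all_ranks
from .gap import gap_table, n_violations, write_gap_outputs
from .identify import (
    conspecific_consistency,
    leave_one_out_identification,
    results_frame,
    success_rates,
)
from .msa import Alignment, progressive_align
from .njtree import bootstrap_support, nj_tree, species_clusters, write_newick
from .records import TaxonomyTable, read_fasta, write_fasta
from .simulate import LibraryConfig, simulate_library

log = logging.getLogger("its2barcode")

ALL_STAGES = ("annotate", "align", "distance", "gap", "tree", "identify")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass
class RunConfig:
    """Pipeline configuration: either a simulation config or an input
    library (FASTA + taxonomy TSV), plus stage toggles and thresholds."""

    out_dir: Path
    simulate: LibraryConfig | None = None
    input_fasta: Path | None = None
    input_taxonomy: Path | None = None
    already_aligned: bool = False
    already_trimmed: bool = False
    stages: tuple[str, ...] = ALL_STAGES
    profile_5p: Path | None = None  # column-frequency files; default: built from
    profile_3p: Path | None = None  # the simulation config's flank motifs
    min_identity: float = 0.97
    genus_min_identity: float = 0.95
    min_coverage: float = 0.95
    bootstrap: int = 0
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.simulate is None and (
            self.input_fasta is None or self.input_taxonomy is None
        ):
            raise ValueError(
                "either a simulation config or input FASTA + taxonomy is required"
            )
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _profiles(config: RunConfig) -> tuple[MotifProfile, MotifProfile]:
    if config.profile_5p and config.profile_3p:
        return MotifProfile.read(config.profile_5p), MotifProfile.read(config.profile_3p)
    sim = config.simulate or LibraryConfig()
    return (
        MotifProfile.from_sequences([sim.flank_5p]),
        MotifProfile.from_sequences([sim.flank_3p]),
    )


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the JSON summary."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=logging.DEBUG if config.verbose else logging.INFO,
        format="%(levelname)s %(message)s",
        stream=sys.stderr,
    )
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "python": sys.version.split()[0],
        "config": {
            "stages": list(config.stages),
            "min_identity": config.min_identity,
            "genus_min_identity": config.genus_min_identity,
            "min_coverage": config.min_coverage,
            "bootstrap": config.bootstrap,
        },
    }

    # ---- load or simulate ------------------------------------------------
    stage = "simulate" if config.simulate else "load"
    try:
        if config.simulate is not None:
            records, taxonomy, truth = simulate_library(config.simulate)
            write_fasta(records, out / "library.fasta")
            taxonomy.write_tsv(out / "taxonomy.tsv")
            with open(out / "true_spans.tsv", "w") as fh:
                fh.write("specimen_id\tstart\tend\n")
                for sid, (a, b) in sorted(truth.its2_spans.items()):
                    fh.write(f"{sid}\t{a}\t{b}\n")
            truth.tree.write(path=str(out / "true_tree.nwk"), schema="newick")
        else:
            records = read_fasta(config.input_fasta)
            taxonomy = TaxonomyTable.read_tsv(config.input_taxonomy)
        summary["library"] = {
            "n_sequences": len(records),
            "n_species": len(taxonomy.species),
            "n_singleton_species": len(taxonomy.singleton_species()),
        }
        log.info("%s: %d sequences, %d species", stage, len(records), len(taxonomy.species))
    except Exception as exc:  # noqa: BLE001 - stage contract: halt, name stage
        raise StageError(stage, exc) from exc

    # ---- annotate --------------------------------------------------------
    if "annotate" in config.stages and not config.already_trimmed:
        try:
            p5, p3 = _profiles(config)
            barcodes, report = annotate_records(records, p5, p3)
            report.to_csv(out / "annotation_report.tsv", sep="\t", index=False)
            write_fasta(barcodes, out / "its2.fasta")
            summary["annotation"] = {
                "n_input": len(records),
                "n_annotated": len(barcodes),
                "n_failed": int((report["status"] != "ok").sum()),
            }
            records = barcodes
        except Exception as exc:  # noqa: BLE001
            raise StageError("annotate", exc) from exc

    stats = seq_stats(records)
    stats.to_csv(out / "seq_stats.tsv", sep="\t", index=False)
    fam_labels = {
        s: taxonomy.family_of(s) for s in stats["specimen_id"] if s in taxonomy
    }
    for value in ("length", "gc"):
        group_summary(stats, fam_labels, value=value).to_csv(
            out / f"{value}_by_family.tsv", sep="\t", index=False
        )
    summary["stats"] = {
        "median_length_bp": float(stats["length"].median()),
        "min_length_bp": int(stats["length"].min()),
        "max_length_bp": int(stats["length"].max()),
        "mean_gc_pct": float(stats["gc"].mean() * 100.0),
    }

    # ---- align -----------------------------------------------------------
    alignment: Alignment | None = None
    if "align" in config.stages:
        try:
            if config.already_aligned:
                alignment = Alignment(
                    [r.specimen_id for r in records], [r.sequence for r in records]
                )
            else:
                alignment = progressive_align(records)
            alignment.write_fasta(out / "aligned.fasta")
            summary["alignment"] = {
                "n_rows": alignment.n_rows,
                "n_cols": alignment.n_cols,
            }
            log.info("align: %d x %d", alignment.n_rows, alignment.n_cols)
        except Exception as exc:  # noqa: BLE001
            raise StageError("align", exc) from exc

    # ---- distances -------------------------------------------------------
    dm = None
    if "distance" in config.stages and alignment is not None:
        try:
            dm = distance_matrix(alignment)
            dm.write_tsv(out / "k2p_matrix.tsv")
            dm.write_phylip(out / "k2p_matrix.phy")
            rank_summary = summarize_all_ranks(dm, taxonomy)
            rank_summary.to_csv(out / "distance_summary.tsv", sep="\t", index=False)
            summary["distance"] = {
                "n_undefined_pairs": dm.n_undefined_pairs,
                "ranks": rank_summary.to_dict(orient="records"),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("distance", exc) from exc

    # ---- barcoding gap ---------------------------------------------------
    if "gap" in config.stages and dm is not None:
        try:
            records_gap, excluded = gap_table(dm, taxonomy)
            write_gap_outputs(records_gap, out / "gap_table.tsv", out / "gap_scatter.tsv")
            excluded.to_csv(out / "gap_excluded.tsv", sep="\t", index=False)
            summary["gap"] = {
                "n_species": len(records_gap),
                "n_violations": n_violations(records_gap),
                "n_excluded": len(excluded),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("gap", exc) from exc

    # ---- NJ tree + discrimination ---------------------------------------
    if "tree" in config.stages and dm is not None and alignment is not None:
        try:
            singles = set(taxonomy.singleton_species())
            keep = [
                s for s in dm.ids if taxonomy.species_of(s) not in singles
            ]
            if len(keep) < 3:
                summary["tree"] = {"skipped": "fewer than 3 non-singleton sequences"}
            else:
                dm_tree = dm.submatrix(keep)
                if config.bootstrap > 0:
                    tree, _support = bootstrap_support(
                        alignment.subset(keep), config.bootstrap, seed=config.seed
                    )
                else:
                    tree = nj_tree(dm_tree)
                write_newick(tree, out / "nj_tree.nwk")
                report, status = species_clusters(tree, taxonomy)
                status.to_csv(out / "species_status.tsv", sep="\t", index=False)
                summary["tree"] = {
                    "n_clusters": report.n_clusters,
                    "n_single_species_clusters": report.n_single_species_clusters,
                    "n_mixed_clusters": report.n_mixed_clusters,
                    "n_species_identified": report.n_species_identified,
                    "n_species_unidentified": report.n_species_unidentified,
                    "n_singletons_excluded_from_rate": report.n_singletons_excluded
                    + len(singles),
                    "discrimination_rate": report.discrimination_rate,
                }
                log.info(
                    "tree: %d/%d species identified",
                    report.n_species_identified,
                    report.n_species_identified + report.n_species_unidentified,
                )
        except Exception as exc:  # noqa: BLE001
            raise StageError("tree", exc) from exc

    # ---- identification --------------------------------------------------
    if "identify" in config.stages:
        try:
            results = leave_one_out_identification(
                records,
                taxonomy,
                min_identity=config.min_identity,
                genus_min_identity=config.genus_min_identity,
                min_coverage=config.min_coverage,
            )
            results_frame(results).to_csv(
                out / "identification.tsv", sep="\t", index=False
            )
            consistency = conspecific_consistency(results, taxonomy)
            consistency.to_csv(out / "consistency.tsv", sep="\t", index=False)
            summary["identify"] = {
                "species": success_rates(results, "species"),
                "genus": success_rates(results, "genus"),
                "n_cryptic_candidates": int(
                    (consistency["status"] == "cryptic_candidate").sum()
                ),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("identify", exc) from exc

    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
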