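"""Shared paths and the library configuration for the analysis scripts.

All scripts run from the repository root (``python analysis/01_simulate.py``).
Small summary tables land in ``results/``; bulky intermediates (FASTA,
distance matrices, trees) are kept under ``scratch/`` and regenerated on
demand.
"""

from pathlib import Path

from its2barcode import LibraryConfig

RESULTS = Path("results")
SCRATCH = Path("scratch/analysis")

SEED = 2026


def library_config() -> LibraryConfig:
    """The analysis library: 10 families x 2 genera x 3 species with 1-5
    specimens per species (ranges create singleton species on purpose),
    ITS2-like lengths and GC, divergence scales at the magnitudes typical
    of plant ITS2 libraries (~0.6% / ~12% / ~37%)."""
    return LibraryConfig(
        n_families=10,
        genera_per_family=2,
        species_per_genus=3,
        specimens_per_species=(1, 5),
        seed=SEED,
    )


def ensure_dirs() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
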