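import numpy as np
import pandas as pd
import pytest

from its2barcode import LibraryConfig, TaxonomyTable, simulate_library


@pytest.fixture(scope="session")
def small_config() -> LibraryConfig:
    """3 families x 2 genera x 2 species x 3 specimens, fixed lengths."""
    return LibraryConfig(
        n_families=3,
        genera_per_family=2,
        species_per_genus=2,
        specimens_per_species=3,
        its2_length=(220, 260),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_library(small_config):
    """(amplicons, taxonomy, ground truth) for a 36-specimen library."""
    return simulate_library(small_config)


def taxonomy_from_pairs(pairs: list[tuple[str, str]]) -> TaxonomyTable:
    """Build a flat taxonomy (one genus/family per species initial) from
    (specimen_id, species) pairs — convenience for constructed examples."""
    frame = pd.DataFrame(
        [(sid, sp, f"G_{sp[0]}", f"F_{sp[0]}") for sid, sp in pairs],
        columns=["specimen_id", "species", "genus", "family"],
    )
    return TaxonomyTable(frame)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
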