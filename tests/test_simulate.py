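"""Synthetic-library generator: taxonomy shape, substitution process,
flank handling and determinism."""

import math

import numpy as np
import pytest

from its2barcode import LibraryConfig, SequenceRecord, add_flanks, simulate_library
from its2barcode.simulate import (
    ConfigError,
    _evolve_branch,
    _random_root,
    generate_taxonomy,
    k2p_event_probabilities,
)


def test_taxonomy_counts_are_product_of_config():
    cfg = LibraryConfig(
        n_families=2, genera_per_family=2, species_per_genus=2,
        specimens_per_species=2, seed=0,
    )
    tax = generate_taxonomy(cfg)
    assert len(tax) == 16
    assert len(tax.species) == 8
    assert (tax.species_counts() == 2).all()


def test_taxonomy_with_ranges_is_seed_deterministic():
    cfg = LibraryConfig(specimens_per_species=(1, 3), seed=11)
    a = generate_taxonomy(cfg)
    b = generate_taxonomy(cfg)
    assert a.frame.equals(b.frame)
    # ranges actually vary the counts
    assert a.species_counts().nunique() > 1


@pytest.mark.parametrize(
    "kwargs",
    [
        {"species_per_genus": 0},
        {"n_families": 0},
        {"its2_length": (300, 200)},
        {"d_intra": 0.2, "d_species": 0.1},  # violates rank ordering
        {"kappa": -1.0},
        {"flank_5p": ""},
        {"gc_target": 1.5},
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ConfigError):
        LibraryConfig(**kwargs)


def test_zero_intra_divergence_gives_identical_conspecifics():
    cfg = LibraryConfig(
        n_families=2, genera_per_family=1, species_per_genus=2,
        specimens_per_species=3, d_intra=0.0, indel_rate=0.0,
        its2_length=(200, 200), seed=5,
    )
    records, tax, _ = simulate_library(cfg, with_flanks=False)
    by_id = {r.specimen_id: r.sequence for r in records}
    for sp in tax.species:
        seqs = {by_id[s] for s in tax.specimens_of_species(sp)}
        assert len(seqs) == 1


def test_transition_transversion_proportions_match_closed_form(rng):
    # one branch of length 0.1 at kappa=2 on a 10 kb sequence: realized
    # ts/tv counts should match the finite-time K2P event probabilities,
    # written out independently here from the rate-matrix solution.
    t, kappa, L = 0.1, 2.0, 50_000
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    p_tv_each = 0.25 - 0.25 * math.exp(-4 * beta * t)
    p_ts = 0.25 + 0.25 * math.exp(-4 * beta * t) - 0.5 * math.exp(-2 * (alpha + beta) * t)
    assert k2p_event_probabilities(t, kappa) == pytest.approx((p_ts, p_tv_each))

    cfg = LibraryConfig(kappa=kappa, seed=0)
    root = _random_root(L, 0.63, rng)
    leaf = _evolve_branch(root, t, cfg, rng)
    purine = np.isin(root, (0, 2))
    purine_leaf = np.isin(leaf, (0, 2))
    diff = root != leaf
    n_ts = int((diff & (purine == purine_leaf)).sum())
    n_tv = int(diff.sum()) - n_ts
    # expected count ratio ~ kappa/2 at small t; compare to the exact
    # finite-time expectation with Monte-Carlo slack (3 sigma ~ 0.08)
    expected_ratio = p_ts / (2 * p_tv_each)
    assert n_ts / n_tv == pytest.approx(expected_ratio, rel=0.12)
    assert expected_ratio == pytest.approx(kappa / 2, rel=0.05)


def test_same_seed_gives_byte_identical_library(tmp_path, small_config):
    from its2barcode import write_fasta

    for run in ("a", "b"):
        records, _, _ = simulate_library(small_config)
        write_fasta(records, tmp_path / f"{run}.fasta")
    assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()


def test_root_gc_matches_target():
    # at near-zero divergence the leaves are the family roots, so their
    # composition probes the root GC directly (the symmetric substitution
    # process later relaxes GC toward 0.5 along deep branches)
    cfg = LibraryConfig(
        n_families=5, genera_per_family=1, species_per_genus=1,
        specimens_per_species=2, its2_length=(300, 300),
        d_intra=1e-6, d_species=1e-5, d_genus=1e-4, d_family=1e-3, seed=2,
    )
    _, _, truth = simulate_library(cfg, with_flanks=False)
    gcs = [
        (s.count("G") + s.count("C")) / len(s)
        for s in truth.its2_sequences.values()
    ]
    assert abs(np.mean(gcs) - 0.63) < 0.05


def test_realized_rank_distances_are_ordered():
    # scales separated >= 3x: realized mean divergence must respect
    # species < genus < family
    cfg = LibraryConfig(
        n_families=3, genera_per_family=2, species_per_genus=2,
        specimens_per_species=3, its2_length=(300, 300),
        d_intra=0.01, d_species=0.05, d_genus=0.2, d_family=0.6, seed=3,
    )
    records, tax, _ = simulate_library(cfg, with_flanks=False)
    by_id = {r.specimen_id: r.sequence for r in records}

    def mean_pdist(pairs):
        vals = []
        for a, b in pairs:
            sa, sb = by_id[a], by_id[b]
            vals.append(sum(x != y for x, y in zip(sa, sb)) / len(sa))
        return float(np.mean(vals))

    ids = tax.specimen_ids
    same_sp, same_ge, same_fa = [], [], []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if tax.species_of(a) == tax.species_of(b):
                same_sp.append((a, b))
            elif tax.genus_of(a) == tax.genus_of(b):
                same_ge.append((a, b))
            elif tax.family_of(a) == tax.family_of(b):
                same_fa.append((a, b))
    assert mean_pdist(same_sp) < mean_pdist(same_ge) < mean_pdist(same_fa)


def test_add_flanks_concatenation_and_span():
    cfg = LibraryConfig(flank_5p="AAAA", flank_3p="TTTT")
    out = add_flanks([SequenceRecord("x", "GCGC")], cfg)
    assert out[0].sequence == "AAAAGCGCTTTT"


def test_add_flanks_records_true_span(small_library):
    records, _, truth = small_library
    w5 = len(truth.config.flank_5p)
    for rec in records:
        start, end = truth.its2_spans[rec.specimen_id]
        assert start == w5
        assert rec.sequence[start:end] == truth.its2_sequences[rec.specimen_id]


def test_add_flanks_rejects_zero_length_its2():
    cfg = LibraryConfig()
    with pytest.raises(ConfigError):
        add_flanks([SequenceRecord("x", "")], cfg)


def test_write_library_round_trips(tmp_path, small_library):
    from its2barcode import TaxonomyTable, read_fasta
    from its2barcode.simulate import write_library

    records, tax, _ = small_library
    fasta, tsv = write_library(records, tax, tmp_path)
    back = read_fasta(fasta)
    assert [(r.specimen_id, r.sequence) for r in back] == [
        (r.specimen_id, r.sequence) for r in records
    ]
    assert TaxonomyTable.read_tsv(tsv).frame.equals(tax.frame)


def test_indel_rate_changes_lengths_within_species():
    cfg = LibraryConfig(
        n_families=1, genera_per_family=1, species_per_genus=2,
        specimens_per_species=5, its2_length=(300, 300),
        indel_rate=0.2, d_intra=0.05, d_species=0.12, seed=9,
    )
    records, _, _ = simulate_library(cfg, with_flanks=False)
    assert len({len(r.sequence) for r in records}) > 1
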