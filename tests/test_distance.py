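"""K2P distances under pairwise deletion and rank summaries."""

import math
import subprocess

import numpy as np
import pandas as pd
import pytest

from its2barcode import SequenceRecord, k2p, k2p_from_pq
from its2barcode.distance import distance_matrix, summarize_all_ranks, summarize_rank
from its2barcode.msa import Alignment
from its2barcode.records import TaxonomyTable

from conftest import taxonomy_from_pairs

# hand evaluation of d = -1/2 ln[(1-2P-Q) sqrt(1-2Q)] at P=0.1, Q=0.05
K2P_EXAMPLE = 0.1701811651403471


def _random_gapped_pair(rng, length=120, gap_frac=0.1):
    chars = np.array(list("ACGT-N"))
    p = [0.225, 0.225, 0.225, 0.225, gap_frac * 0.7, gap_frac * 0.3]
    p = np.array(p) / np.sum(p)
    a = "".join(rng.choice(chars, size=length, p=p))
    b = "".join(rng.choice(chars, size=length, p=p))
    return a, b


def _brute_force_counts(a: str, b: str):
    """Site counting by direct iteration (independent of the vector path)."""
    purines = {"A", "G"}
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x != y:
            if (x in purines) == (y in purines):
                ts += 1
            else:
                tv += 1
    return n, ts, tv


def test_identical_rows_give_zero_distance():
    res = k2p("ACGTACGT", "ACGTACGT")
    assert res.distance == 0.0
    assert res.p == res.q == 0.0
    assert math.copysign(1.0, res.distance) == 1.0  # exactly +0.0


def test_closed_form_example():
    assert k2p_from_pq(0.1, 0.05) == pytest.approx(K2P_EXAMPLE, abs=1e-9)
    # rows realizing P=0.1, Q=0.05 on 100 sites: 10 transitions + 5 transversions
    a = "A" * 100
    b = "G" * 10 + "C" * 5 + "A" * 85
    res = k2p(a, b)
    assert (res.p, res.q, res.n_sites) == (0.1, 0.05, 100)
    assert res.distance == pytest.approx(K2P_EXAMPLE, abs=1e-9)


def test_pairwise_deletion_example():
    res = k2p("A-GT", "AC-T")
    assert res.n_sites == 2  # only the A/A and T/T columns survive
    assert res.distance == 0.0


def test_length_mismatch_raises():
    with pytest.raises(ValueError):
        k2p("ACGT", "ACG")


def test_saturated_pair_is_masked_not_clamped():
    # all transitions: P = 1 -> 1-2P-Q < 0
    res = k2p("A" * 50, "G" * 50)
    assert not res.defined
    assert res.reason == "saturated"
    assert math.isnan(res.distance)


def test_site_counts_match_brute_force_on_random_pairs(rng):
    for _ in range(200):
        a, b = _random_gapped_pair(rng)
        res = k2p(a, b)
        n, ts, tv = _brute_force_counts(a, b)
        assert res.n_sites == n
        if n:
            assert res.p == pytest.approx(ts / n)
            assert res.q == pytest.approx(tv / n)


def test_correction_never_below_raw_proportion(rng):
    for _ in range(200):
        a, b = _random_gapped_pair(rng, gap_frac=0.05)
        res = k2p(a, b)
        if res.defined and res.n_sites:
            raw = res.p + res.q
            assert res.distance >= raw - 1e-12


def test_distance_increases_with_p_at_fixed_q():
    q = 0.05
    ds = [k2p_from_pq(p, q) for p in np.linspace(0.0, 0.4, 20)]
    ds = [d for d in ds if not math.isnan(d)]
    assert all(x < y for x, y in zip(ds, ds[1:]))


def test_matrix_equals_per_pair_k2p(rng):
    rows = []
    for i in range(8):
        a, _ = _random_gapped_pair(rng, length=90, gap_frac=0.08)
        rows.append(a)
    aln = Alignment([f"s{i}" for i in range(8)], rows)
    dm = distance_matrix(aln)
    assert np.allclose(dm.distance, dm.distance.T, equal_nan=True)
    assert np.all(np.diag(dm.distance) == 0.0)
    for i in range(8):
        for j in range(i + 1, 8):
            ref = k2p(rows[i], rows[j])
            if ref.defined:
                assert dm.distance[i, j] == pytest.approx(ref.distance, abs=1e-12)
            else:
                assert (i, j) in dm.reasons and dm.reasons[(i, j)] == ref.reason
            assert dm.n_sites[i, j] == ref.n_sites


def test_matrix_agrees_with_ape_reference_implementation(tmp_path, rng):
    """Independent oracle: ape::dist.dna(model='K80', pairwise.deletion=TRUE)."""
    rows = []
    for _ in range(6):
        a, _ = _random_gapped_pair(rng, length=80, gap_frac=0.05)
        rows.append(a.replace("N", "-"))
    aln = Alignment([f"t{i}" for i in range(6)], rows)
    fasta = tmp_path / "aln.fasta"
    aln.write_fasta(fasta)
    out_csv = tmp_path / "ape.csv"
    script = (
        f"a <- ape::read.dna('{fasta}', format='fasta');"
        "d <- ape::dist.dna(a, model='K80', pairwise.deletion=TRUE);"
        f"write.csv(as.matrix(d), '{out_csv}')"
    )
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    ref = pd.read_csv(out_csv, index_col=0).to_numpy()
    ours = distance_matrix(aln).distance
    mask = ~np.isnan(ours) & np.isfinite(ref)
    assert mask.sum() > 10
    assert np.allclose(ours[mask], ref[mask], atol=1e-6)


def test_summary_counts_and_zero_distance_species():
    # species with specimen counts {3, 2, 1} -> 3 + 1 + 0 = 4 comparisons
    pairs = [
        ("a1", "A"), ("a2", "A"), ("a3", "A"),
        ("b1", "B"), ("b2", "B"),
        ("c1", "C"),
    ]
    tax = taxonomy_from_pairs(pairs)
    aln = Alignment([p[0] for p in pairs], ["ACGTACGT"] * 6)
    dm = distance_matrix(aln)
    s = summarize_rank(dm, tax, "species")
    assert s.n_comparisons == 4
    assert s.n_taxa == 2  # singleton C contributes no pair
    assert s.min_pct == s.max_pct == s.mean_pct == 0.0


def test_summary_rank_definitions_are_disjoint(small_library):
    _, tax, truth = small_library
    its2 = sorted(truth.its2_sequences.items())
    # equal-length per family is not guaranteed across the library; align first
    from its2barcode import progressive_align

    aln = progressive_align([SequenceRecord(k, v) for k, v in its2])
    dm = distance_matrix(aln)
    table = summarize_all_ranks(dm, tax)
    n = dm.n
    total_pairs = n * (n - 1) // 2
    # species+genus+family comparisons can never exceed all pairs
    assert table["comparisons"].sum() <= total_pairs
    means = table.set_index("rank")["mean_pct"]
    assert means["species"] < means["genus"] < means["family"]


def test_rank_with_no_multimember_taxa_is_empty():
    pairs = [("a1", "A"), ("b1", "B")]
    tax = taxonomy_from_pairs(pairs)
    aln = Alignment(["a1", "b1"], ["ACGT", "ACGG"])
    dm = distance_matrix(aln)
    s = summarize_rank(dm, tax, "species")
    assert s.n_comparisons == 0 and s.n_taxa == 0
    assert math.isnan(s.mean_pct)


def test_masked_entries_excluded_and_counted():
    pairs = [("a1", "A"), ("a2", "A"), ("a3", "A")]
    tax = taxonomy_from_pairs(pairs)
    # a1-a2 fine; a3 shares no sites with a1/a2 -> masked
    aln = Alignment(
        ["a1", "a2", "a3"],
        ["ACGT----", "ACGG----", "----ACGT"],
    )
    dm = distance_matrix(aln)
    assert dm.n_undefined_pairs == 2
    s = summarize_rank(dm, tax, "species")
    assert s.n_comparisons == 1
    assert s.n_masked == 2


def test_phylip_and_tsv_outputs(tmp_path):
    aln = Alignment(["a", "b", "c"], ["ACGT", "ACGG", "AAGG"])
    dm = distance_matrix(aln)
    dm.write_tsv(tmp_path / "m.tsv")
    dm.write_phylip(tmp_path / "m.phy")
    loaded = pd.read_csv(tmp_path / "m.tsv", sep="\t", index_col=0)
    assert np.allclose(loaded.to_numpy(), dm.distance, atol=1e-6, equal_nan=True)
    assert (tmp_path / "m.phy").read_text().splitlines()[0] == "3"
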