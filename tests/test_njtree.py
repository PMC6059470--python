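"""Neighbor joining, bootstrap support, and species discrimination."""

import dendropy
import numpy as np
import pytest

from its2barcode import bootstrap_support, nj_tree, species_clusters
from its2barcode.distance import DistanceMatrix, distance_matrix
from its2barcode.msa import Alignment
from its2barcode.njtree import UndefinedDistanceError, tree_bipartitions

from conftest import taxonomy_from_pairs


def _dm(ids, matrix):
    m = np.asarray(matrix, dtype=float)
    reasons = {
        (i, j): "saturated"
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if np.isnan(m[i, j])
    }
    zeros = np.zeros_like(m)
    return DistanceMatrix(list(ids), m, zeros, zeros, zeros.astype(int), reasons)


def _random_additive(n, rng):
    """Random binary tree with uniform branch lengths; returns its exact
    leaf-to-leaf path-length matrix (the oracle for NJ consistency)."""
    clusters = [({i}, {i: 0.0}) for i in range(n)]
    D = np.zeros((n, n))
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (la, da), (lb, db) = clusters[i], clusters[j]
        ea, eb = rng.uniform(0.05, 1.0, size=2)
        for x in la:
            for y in lb:
                D[x, y] = D[y, x] = da[x] + ea + db[y] + eb
        merged = {x: d + ea for x, d in da.items()}
        merged.update({y: d + eb for y, d in db.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((la | lb, merged))
    return D


def _tree_path_lengths(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.distance(taxa[a], taxa[b])


def test_three_taxon_branch_lengths_by_hand():
    dm = _dm(["A", "B", "C"], [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
    tree = nj_tree(dm)
    lengths = {
        leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
    }
    assert lengths["A"] == pytest.approx(0.05)
    assert lengths["B"] == pytest.approx(0.15)
    assert lengths["C"] == pytest.approx(0.25)


def test_additive_four_taxon_matrix_reproduced_exactly():
    # tree ((A:0.1,B:0.2):0.3,(C:0.4,D:0.5)) -> path-length matrix by hand
    ids = ["A", "B", "C", "D"]
    m = [
        [0.0, 0.3, 0.8, 0.9],
        [0.3, 0.0, 0.9, 1.0],
        [0.8, 0.9, 0.0, 0.9],
        [0.9, 1.0, 0.9, 0.0],
    ]
    tree = nj_tree(_dm(ids, m))
    dist = _tree_path_lengths(tree)
    for i, a in enumerate(ids):
        for j in range(i + 1, 4):
            assert dist(a, ids[j]) == pytest.approx(m[i][j], abs=1e-12)
    # four-point condition: the two larger sums are equal
    sums = sorted([m[0][1] + m[2][3], m[0][2] + m[1][3], m[0][3] + m[1][2]])
    assert sums[1] == pytest.approx(sums[2])


def test_random_additive_matrices_recovered(rng):
    for _ in range(10):
        n = int(rng.integers(4, 13))
        D = _random_additive(n, rng)
        ids = [f"t{k}" for k in range(n)]
        tree = nj_tree(_dm(ids, D))
        dist = _tree_path_lengths(tree)
        for i in range(n):
            for j in range(i + 1, n):
                assert dist(f"t{i}", f"t{j}") == pytest.approx(D[i, j], abs=1e-9)


def test_zero_matrix_gives_all_zero_branch_lengths():
    ids = list("ABCDE")
    tree = nj_tree(_dm(ids, np.zeros((5, 5))))
    assert all((e.length or 0.0) == 0.0 for e in tree.edges())


def test_undefined_entries_rejected_with_pair_listing():
    m = [[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]]
    with pytest.raises(UndefinedDistanceError) as err:
        nj_tree(_dm(["A", "B", "C"], m))
    assert ("A", "C") in err.value.pairs


def test_topology_agrees_with_skbio_reference(rng):
    """Independent cross-check: scikit-bio's NJ on the same additive matrix."""
    import skbio

    n = 8
    D = _random_additive(n, rng)
    ids = [f"t{k}" for k in range(n)]
    ours = tree_bipartitions(nj_tree(_dm(ids, D)))
    sk_tree = skbio.tree.nj(skbio.DistanceMatrix(D, ids))
    all_leaves = frozenset(ids)
    theirs = set()
    for node in sk_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= n - 2:
            other = all_leaves - side
            if len(other) < len(side) or (
                len(other) == len(side) and sorted(other) < sorted(side)
            ):
                side = other
            theirs.add(side)
    assert ours == theirs


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _two_clade_alignment():
    base1 = "ACGTAC" * 10
    # second clade: every 3rd site transverted (~33% divergence, unsaturated)
    comp = str.maketrans("ACGT", "CATG")
    base2 = "".join(
        ch.translate(comp) if i % 3 == 0 else ch for i, ch in enumerate(base1)
    )
    rows, ids = [], []
    for i in range(4):
        s = list(base1)
        s[i] = "T" if s[i] != "T" else "G"
        rows.append("".join(s))
        ids.append(f"x{i}")
    for i in range(4):
        s = list(base2)
        s[i + 10] = "A" if s[i + 10] != "A" else "C"
        rows.append("".join(s))
        ids.append(f"y{i}")
    return Alignment(ids, rows)


def test_bootstrap_saturates_on_clear_signal():
    aln = _two_clade_alignment()
    tree, support = bootstrap_support(aln, B=50, seed=0)
    key = frozenset({"x0", "x1", "x2", "x3"})
    assert support[key] == 100.0
    assert all(0.0 <= v <= 100.0 for v in support.values())


def test_single_replicate_supports_are_binary():
    aln = _two_clade_alignment()
    _, support = bootstrap_support(aln, B=1, seed=3)
    assert set(support.values()) <= {0.0, 100.0}


def test_bootstrap_is_seed_deterministic_and_topology_stable():
    aln = _two_clade_alignment()
    t1, s1 = bootstrap_support(aln, B=20, seed=7)
    t2, s2 = bootstrap_support(aln, B=20, seed=7)
    assert s1 == s2
    assert tree_bipartitions(t1) == tree_bipartitions(t2)
    # the full-data tree topology equals the no-bootstrap tree
    plain = nj_tree(distance_matrix(aln))
    assert tree_bipartitions(t1) == tree_bipartitions(plain)


def test_bootstrap_rejects_bad_replicate_count():
    with pytest.raises(ValueError):
        bootstrap_support(_two_clade_alignment(), B=0)


# ---------------------------------------------------------------------------
# species discrimination
# ---------------------------------------------------------------------------

def _tree_from_newick(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


def test_two_clean_species_both_identified():
    tree = _tree_from_newick("((a1,a2),(b1,b2));")
    tax = taxonomy_from_pairs([("a1", "A"), ("a2", "A"), ("b1", "B"), ("b2", "B")])
    report, status = species_clusters(tree, tax)
    assert report.n_species_identified == 2
    assert report.discrimination_rate == 1.0
    assert report.n_clusters == 2
    assert set(status["status"]) == {"identified"}


def test_interleaved_species_form_one_mixed_cluster():
    tree = _tree_from_newick("((a1,b1),(a2,b2));")
    tax = taxonomy_from_pairs([("a1", "A"), ("a2", "A"), ("b1", "B"), ("b2", "B")])
    report, _ = species_clusters(tree, tax)
    assert report.n_species_identified == 0
    assert report.n_mixed_clusters == 1
    assert report.n_clusters == 1
    assert report.discrimination_rate == 0.0


def test_singletons_excluded_from_denominator():
    tree = _tree_from_newick("(((a1,a2),c1),(b1,b2));")
    tax = taxonomy_from_pairs(
        [("a1", "A"), ("a2", "A"), ("b1", "B"), ("b2", "B"), ("c1", "C")]
    )
    report, status = species_clusters(tree, tax)
    assert report.n_singletons_excluded == 1
    assert report.discrimination_rate == 1.0
    assert (
        status.loc[status.species == "C", "status"].item() == "singleton_excluded"
    )


def test_monophyly_matches_mrca_oracle(rng):
    """Exclusivity on the unrooted tree must agree with a rooted-MRCA
    check after rerooting at a heterospecific leaf (DendroPy oracle)."""
    from its2barcode import LibraryConfig, simulate_library

    cfg = LibraryConfig(
        n_families=2, genera_per_family=2, species_per_genus=3,
        specimens_per_species=(2, 4), its2_length=(150, 150),
        d_intra=0.05, d_species=0.12, d_genus=0.3, d_family=0.45, seed=33,
    )
    records, tax, _ = simulate_library(cfg, with_flanks=False)
    aln = Alignment([r.specimen_id for r in records], [r.sequence for r in records])
    tree = nj_tree(distance_matrix(aln))
    _, status = species_clusters(tree, tax)
    judged = dict(zip(status["species"], status["status"]))

    for sp in tax.species:
        members = set(tax.specimens_of_species(sp))
        if len(members) < 2:
            continue
        out_label = next(s for s in tax.specimen_ids if s not in members)
        t2 = dendropy.Tree(tree)  # deep copy
        out_leaf = t2.find_node_with_taxon_label(out_label)
        t2.reroot_at_edge(out_leaf.edge)
        mrca = t2.mrca(taxa=[l.taxon for l in t2.leaf_node_iter()
                             if l.taxon.label in members])
        mono = {l.taxon.label for l in mrca.leaf_iter()} == members
        assert (judged[sp] == "identified") == mono, sp
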