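"""Neighbor-joining trees, bootstrap support, and tree-based species
discrimination.

A species is *identified* by the tree when its sequences form an
exclusive cluster: some edge of the unrooted topology separates exactly
that species' leaves from everything else (monophyly).  The
discrimination rate is the fraction of non-singleton species identified
this way; sequences of unidentified species are grouped into mixed
clusters via the smallest clades containing them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .distance import DistanceMatrix, distance_matrix
from .msa import Alignment
from .records import TaxonomyTable


class UndefinedDistanceError(ValueError):
    """The matrix contains undefined entries; prune those taxa first."""

    def __init__(self, pairs: list[tuple[str, str]]):
        self.pairs = pairs
        shown = ", ".join(f"{a}~{b}" for a, b in pairs[:5])
        more = "" if len(pairs) <= 5 else f" (+{len(pairs) - 5} more)"
        super().__init__(
            f"distance matrix has {len(pairs)} undefined pair(s): {shown}{more}; "
            "prune affected taxa or realign"
        )


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; deterministic, unrooted.

    Iteratively joins the pair minimizing Q = (n−2)·d(i,j) − r_i − r_j
    (ties → lowest (row, col) index), with the standard two-point branch
    length formulas; negative branch lengths are clamped to zero.  The
    final three lineages are joined by the three-point formulas.
    """
    if dm.n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if dm.reasons:
        pairs = [(dm.ids[i], dm.ids[j]) for (i, j) in sorted(dm.reasons)]
        raise UndefinedDistanceError(pairs)

    taxon_ns = dendropy.TaxonNamespace()
    nodes = [
        dendropy.Node(taxon=taxon_ns.new_taxon(label=name)) for name in dm.ids
    ]
    D = dm.distance.astype(float).copy()

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)  # first = lowest pair
        d_ij = D[i, j]
        vi = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (n - 2))
        vj = d_ij - vi
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = max(vi, 0.0)
        parent.add_child(nodes[j])
        nodes[j].edge.length = max(vj, 0.0)
        d_new = 0.5 * (D[i, :] + D[j, :] - d_ij)
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.pad(D[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        D[-1, :-1] = D[:-1, -1] = d_new[keep]
        nodes = [nodes[k] for k in keep] + [parent]

    # three-point formulas for the last trifurcation
    d_ab, d_ac, d_bc = D[0, 1], D[0, 2], D[1, 2]
    lengths = (
        (d_ab + d_ac - d_bc) / 2.0,
        (d_ab + d_bc - d_ac) / 2.0,
        (d_ac + d_bc - d_ab) / 2.0,
    )
    center = dendropy.Node()
    for node, length in zip(nodes, lengths):
        center.add_child(node)
        node.edge.length = max(float(length), 0.0)

    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions and bootstrap
# ---------------------------------------------------------------------------

def _leafsets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    sets: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset([node.taxon.label])
        else:
            acc: frozenset[str] = frozenset()
            for child in node.child_nodes():
                acc = acc | sets[child]
            sets[node] = acc
    return sets


def _normalize(side: frozenset[str], all_leaves: frozenset[str]) -> frozenset[str]:
    other = all_leaves - side
    # canonical side of an unrooted bipartition: smaller set, ties by sorted order
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return side if sorted(side) <= sorted(other) else other


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions (as canonical leaf sets) of a tree."""
    sets = _leafsets(tree)
    all_leaves = sets[tree.seed_node]
    out = set()
    for node, side in sets.items():
        if node is tree.seed_node:
            continue
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(_normalize(side, all_leaves))
    return out


def _fill_undefined(dm: DistanceMatrix) -> DistanceMatrix:
    """Replace undefined entries with 1.2 x the largest defined distance
    (bootstrap replicates only; the full-data tree never uses this)."""
    if not dm.reasons:
        return dm
    d = dm.distance.copy()
    fill = np.nanmax(d) * 1.2 if np.isfinite(np.nanmax(d)) else 1.0
    d[np.isnan(d)] = fill
    return DistanceMatrix(dm.ids, d, dm.p, dm.q, dm.n_sites, {})


def bootstrap_support(
    alignment: Alignment, B: int, seed: int = 0
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """NJ tree from the full alignment plus per-edge bootstrap support.

    Columns are resampled with replacement ``B`` times; each replicate's
    K2P/NJ tree votes for the bipartitions it contains.  Support is the
    percentage of replicates containing the same leaf bipartition, and
    is written onto the internal node labels of the returned tree.
    Replicates occasionally lose a defined distance to resampling; such
    entries are filled conservatively rather than discarding the
    replicate.
    """
    if B < 1:
        raise ValueError("bootstrap replicate count must be >= 1")
    full_dm = distance_matrix(alignment)
    tree = nj_tree(full_dm)
    target = tree_bipartitions(tree)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(B):
        rep = alignment.resample_columns(rng)
        rep_dm = _fill_undefined(distance_matrix(rep))
        rep_bps = tree_bipartitions(nj_tree(rep_dm))
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    support = {bp: 100.0 * c / B for bp, c in counts.items()}

    sets = _leafsets(tree)
    all_leaves = sets[tree.seed_node]
    for node, side in sets.items():
        if node is tree.seed_node or node.is_leaf():
            continue
        key = _normalize(side, all_leaves)
        if key in support:
            node.label = f"{support[key]:.0f}"
    return tree, support


# ---------------------------------------------------------------------------
# species discrimination
# ---------------------------------------------------------------------------

@dataclass
class ClusterReport:
    n_clusters: int
    n_single_species_clusters: int
    n_mixed_clusters: int
    n_species_identified: int
    n_species_unidentified: int
    n_singletons_excluded: int
    discrimination_rate: float  # identified / (identified + unidentified)


def species_clusters(
    tree: dendropy.Tree, taxonomy: TaxonomyTable
) -> tuple[ClusterReport, pd.DataFrame]:
    """Judge species monophyly on the tree and group failures.

    A species is identified iff some edge's bipartition isolates exactly
    its leaves (checked on the unrooted tree: the species' leaf set, or
    its complement, equals the leaf set under some node).  Singleton
    species are excluded from the denominator.  Unidentified species are
    grouped into mixed clusters: the smallest clade containing each
    unidentified species is computed, and overlapping clades are merged.
    """
    sets = _leafsets(tree)
    all_leaves = sets[tree.seed_node]
    clades = {side for node, side in sets.items() if node is not tree.seed_node}

    by_species: dict[str, frozenset[str]] = {}
    for leaf in all_leaves:
        sp = taxonomy.species_of(leaf)
        by_species[sp] = by_species.get(sp, frozenset()) | {leaf}

    identified, unidentified, singletons = [], [], []
    for sp, leaves in sorted(by_species.items()):
        if len(leaves) < 2:
            singletons.append(sp)
        elif (
            leaves == all_leaves
            or leaves in clades
            or (all_leaves - leaves) in clades
        ):
            identified.append(sp)
        else:
            unidentified.append(sp)

    # mixed clusters: merge overlapping smallest-containing-clades
    mrca_sets = []
    for sp in unidentified:
        leaves = by_species[sp]
        best = all_leaves
        for side in clades:
            if leaves <= side and len(side) < len(best):
                best = side
        mrca_sets.append(set(best))
    mixed: list[set[str]] = []
    for s in mrca_sets:
        merged = set(s)
        keep = []
        for existing in mixed:
            if existing & merged:
                merged |= existing
            else:
                keep.append(existing)
        keep.append(merged)
        mixed = keep

    n_id, n_un = len(identified), len(unidentified)
    rate = n_id / (n_id + n_un) if (n_id + n_un) else math.nan
    report = ClusterReport(
        n_clusters=n_id + len(mixed),
        n_single_species_clusters=n_id,
        n_mixed_clusters=len(mixed),
        n_species_identified=n_id,
        n_species_unidentified=n_un,
        n_singletons_excluded=len(singletons),
        discrimination_rate=rate,
    )
    status = pd.DataFrame(
        [(sp, len(by_species[sp]), "identified") for sp in identified]
        + [(sp, len(by_species[sp]), "unidentified") for sp in unidentified]
        + [(sp, 1, "singleton_excluded") for sp in singletons],
        columns=["species", "n_specimens", "status"],
    ).sort_values("species").reset_index(drop=True)
    return report, status


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
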