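"""Synthetic ITS2 reference-library generator with known ground truth.

The generator emulates the structure of a herbal-medicine barcode
reference library: a taxonomic hierarchy (families ⊃ genera ⊃ species ⊃
specimens) over ITS2-like sequences — short (158–348 bp), GC-rich
(~63%), with small within-species divergence and progressively larger
divergence between species, genera and families — flanked by the
conserved 5.8S tail and 28S head motifs that annotation relies on.

Sequences evolve down a star-like rank tree under the Kimura
two-parameter substitution process: transitions (A↔G, C↔T) occur at a
rate κ-fold higher than each of the two transversion alternatives.
Branch lengths are expressed in expected substitutions per site and are
chosen so the *expected pairwise* distance at each rank matches the
configured scale: two lineages that diverged from a common ancestor each
accumulate half the pairwise expectation, so a rank with pairwise scale
``d`` uses per-branch length ``d/2`` (the within-species branch) or
``(d - d_lower)/2`` for the increment above the next rank down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .records import SequenceRecord, TaxonomyTable, write_fasta

# Conserved rDNA segments bracketing ITS2: the 3' end of 5.8S and the
# 5' start of 28S (these contain the universal S2F / S3R primer sites).
DEFAULT_FLANK_5P = "ATGCGATACTTGGTGTGAAT"
DEFAULT_FLANK_3P = "ATTGTAGTCTGGAGAAGCGTC"

_ALPHABET = np.array(list("ACGT"))
# transition partner (A<->G, C<->T) and the two transversion targets
_TS = np.array([2, 3, 0, 1], dtype=np.int8)
_TV1 = np.array([1, 0, 1, 0], dtype=np.int8)
_TV2 = np.array([3, 2, 3, 2], dtype=np.int8)


class ConfigError(ValueError):
    """Invalid library configuration."""


CountLike = int | tuple[int, int]


def _as_range(value: CountLike, name: str, min_allowed: int = 1) -> tuple[int, int]:
    if isinstance(value, int):
        lo = hi = value
    else:
        lo, hi = int(value[0]), int(value[1])
    if lo > hi:
        raise ConfigError(f"{name}: empty range ({lo}, {hi})")
    if lo < min_allowed:
        raise ConfigError(f"{name}: must be >= {min_allowed}, got {lo}")
    return lo, hi


@dataclass
class LibraryConfig:
    """Parameters of a synthetic reference library.

    Divergence scales are expected *pairwise* K2P distances
    (substitutions/site) between lineages whose most recent common
    ancestor sits at the given rank; they must be strictly ordered
    ``d_intra < d_species < d_genus < d_family``.
    """

    n_families: int = 10
    genera_per_family: CountLike = 2
    species_per_genus: CountLike = 3
    specimens_per_species: CountLike = 3
    its2_length: tuple[int, int] = (158, 348)
    gc_target: float = 0.63
    d_intra: float = 0.0063
    d_species: float = 0.1177
    d_genus: float = 0.3698
    d_family: float = 0.55
    kappa: float = 2.0
    indel_rate: float = 0.0
    flank_5p: str = DEFAULT_FLANK_5P
    flank_3p: str = DEFAULT_FLANK_3P
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")
        _as_range(self.genera_per_family, "genera_per_family")
        _as_range(self.species_per_genus, "species_per_genus")
        _as_range(self.specimens_per_species, "specimens_per_species")
        lo, hi = _as_range(self.its2_length, "its2_length")
        if lo < 1:
            raise ConfigError("its2_length must be positive")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ConfigError("gc_target must be a fraction in [0, 1]")
        scales = (self.d_intra, self.d_species, self.d_genus, self.d_family)
        if any(d < 0 for d in scales):
            raise ConfigError("divergence scales must be >= 0")
        if not (self.d_intra < self.d_species < self.d_genus < self.d_family):
            raise ConfigError(
                "divergence scales must satisfy d_intra < d_species < d_genus < d_family"
            )
        if self.kappa < 0:
            raise ConfigError("kappa must be >= 0")
        if self.indel_rate < 0:
            raise ConfigError("indel_rate must be >= 0")
        if not self.flank_5p or not self.flank_3p:
            raise ConfigError("flank motifs must be non-empty")

    # per-branch lengths (pairwise expectation = 2 x branch length)
    @property
    def branch_specimen(self) -> float:
        return self.d_intra / 2.0

    @property
    def branch_species(self) -> float:
        return (self.d_species - self.d_intra) / 2.0

    @property
    def branch_genus(self) -> float:
        return (self.d_genus - self.d_species) / 2.0

    @property
    def branch_family(self) -> float:
        return (self.d_family - self.d_genus) / 2.0


@dataclass
class GroundTruth:
    """What the simulator knows that the pipeline must recover."""

    taxonomy: TaxonomyTable
    tree: dendropy.Tree
    config: LibraryConfig
    its2_sequences: dict[str, str] = field(default_factory=dict)
    its2_spans: dict[str, tuple[int, int]] = field(default_factory=dict)

    def expected_distance(self, id_a: str, id_b: str) -> float:
        """Expected pairwise divergence implied by the rank tree."""
        tax = self.taxonomy
        if id_a == id_b:
            return 0.0
        if tax.species_of(id_a) == tax.species_of(id_b):
            return self.config.d_intra
        if tax.genus_of(id_a) == tax.genus_of(id_b):
            return self.config.d_species
        if tax.family_of(id_a) == tax.family_of(id_b):
            return self.config.d_genus
        return self.config.d_family


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def generate_taxonomy(
    config: LibraryConfig, rng: np.random.Generator | None = None
) -> TaxonomyTable:
    """Draw a hierarchical specimen taxonomy from the configured counts."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g_lo, g_hi = _as_range(config.genera_per_family, "genera_per_family")
    s_lo, s_hi = _as_range(config.species_per_genus, "species_per_genus")
    n_lo, n_hi = _as_range(config.specimens_per_species, "specimens_per_species")

    rows = []
    for f in range(config.n_families):
        family = f"F{f + 1:02d}"
        n_genera = int(rng.integers(g_lo, g_hi + 1))
        for g in range(n_genera):
            genus = f"{family}G{g + 1:02d}"
            n_species = int(rng.integers(s_lo, s_hi + 1))
            for s in range(n_species):
                species = f"{genus}S{s + 1:02d}"
                n_spec = int(rng.integers(n_lo, n_hi + 1))
                for m in range(n_spec):
                    rows.append((f"{species}i{m + 1:02d}", species, genus, family))
    frame = pd.DataFrame(rows, columns=["specimen_id", "species", "genus", "family"])
    return TaxonomyTable(frame)


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def k2p_event_probabilities(t: float, kappa: float) -> tuple[float, float]:
    """Per-site substitution probabilities after branch length ``t``.

    Returns ``(p_transition, p_each_transversion)`` for the K2P process
    normalised so that ``t`` is the expected number of substitutions per
    site (rates alpha = kappa/(kappa+2) for the transition, beta =
    1/(kappa+2) for each transversion; alpha + 2*beta = 1).
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_tv_each = 0.25 - 0.25 * e1
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    return p_ts, p_tv_each


def _random_root(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.int8)


def _evolve_branch(
    seq: np.ndarray, t: float, config: LibraryConfig, rng: np.random.Generator
) -> np.ndarray:
    """Evolve an encoded sequence along one branch (substitutions, then indels)."""
    if t == 0:
        return seq.copy()
    p_ts, p_tv = k2p_event_probabilities(t, config.kappa)
    u = rng.random(seq.size)
    out = seq.copy()
    out[u < p_ts] = _TS[seq[u < p_ts]]
    m1 = (u >= p_ts) & (u < p_ts + p_tv)
    out[m1] = _TV1[seq[m1]]
    m2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[m2] = _TV2[seq[m2]]
    if config.indel_rate > 0:
        out = _apply_indels(out, config.indel_rate * t, config.gc_target, rng)
    return out


def _apply_indels(
    seq: np.ndarray, rate: float, gc: float, rng: np.random.Generator
) -> np.ndarray:
    # deletions and insertions each at rate/2 per site; never empties the sequence
    keep = rng.random(seq.size) >= rate / 2.0
    if not keep.any():
        keep[rng.integers(seq.size)] = True
    seq = seq[keep]
    n_ins = rng.binomial(seq.size, rate / 2.0)
    if n_ins:
        pos = np.sort(rng.integers(0, seq.size + 1, size=n_ins))
        bases = _random_root(n_ins, gc, rng)
        seq = np.insert(seq, pos, bases)
    return seq


def _resize(
    seq: np.ndarray, target: int, gc: float, rng: np.random.Generator
) -> np.ndarray:
    """Adjust sequence length by random indels (models length turnover
    between families)."""
    if seq.size > target:
        drop = rng.choice(seq.size, size=seq.size - target, replace=False)
        return np.delete(seq, drop)
    if seq.size < target:
        n = target - seq.size
        pos = np.sort(rng.integers(0, seq.size + 1, size=n))
        return np.insert(seq, pos, _random_root(n, gc, rng))
    return seq


def _decode(seq: np.ndarray) -> str:
    return "".join(_ALPHABET[seq])


def evolve_library(
    taxonomy: TaxonomyTable,
    config: LibraryConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SequenceRecord], GroundTruth]:
    """Evolve ITS2 sequences down the rank tree for every specimen.

    One global root at the target GC composition; family roots diverge
    from it, genus/species ancestors and finally specimens diverge in
    turn, each rank contributing the branch-length increment that makes
    the expected pairwise distance at that rank match the config.
    """
    if len(taxonomy) == 0:
        raise ConfigError("taxonomy is empty")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    lo, hi = config.its2_length
    root_len = (lo + hi) // 2
    root = _random_root(root_len, config.gc_target, rng)

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.is_rooted = True

    records: list[SequenceRecord] = []
    truth = GroundTruth(taxonomy=taxonomy, tree=tree, config=config)

    frame = taxonomy.frame
    for family in sorted(frame["family"].unique()):
        fam_target = int(rng.integers(lo, hi + 1))
        fam_seq = _evolve_branch(root, config.branch_family, config, rng)
        fam_seq = _resize(fam_seq, fam_target, config.gc_target, rng)
        fam_node = dendropy.Node(label=family)
        fam_node.edge.length = config.branch_family
        tree.seed_node.add_child(fam_node)
        fam_rows = frame[frame["family"] == family]
        for genus in sorted(fam_rows["genus"].unique()):
            gen_seq = _evolve_branch(fam_seq, config.branch_genus, config, rng)
            gen_node = dendropy.Node(label=genus)
            gen_node.edge.length = config.branch_genus
            fam_node.add_child(gen_node)
            gen_rows = fam_rows[fam_rows["genus"] == genus]
            for species in sorted(gen_rows["species"].unique()):
                sp_seq = _evolve_branch(gen_seq, config.branch_species, config, rng)
                sp_node = dendropy.Node(label=species)
                sp_node.edge.length = config.branch_species
                gen_node.add_child(sp_node)
                ids = gen_rows.loc[gen_rows["species"] == species, "specimen_id"]
                for specimen_id in ids:
                    leaf_seq = _evolve_branch(
                        sp_seq, config.branch_specimen, config, rng
                    )
                    seq_str = _decode(leaf_seq)
                    records.append(SequenceRecord(specimen_id, seq_str))
                    truth.its2_sequences[specimen_id] = seq_str
                    leaf = dendropy.Node(
                        taxon=taxon_ns.new_taxon(specimen_id), label=specimen_id
                    )
                    leaf.edge.length = config.branch_specimen
                    sp_node.add_child(leaf)
    return records, truth


# ---------------------------------------------------------------------------
# flanks and output
# ---------------------------------------------------------------------------

def add_flanks(
    records: Sequence[SequenceRecord],
    config: LibraryConfig,
    ground_truth: GroundTruth | None = None,
) -> list[SequenceRecord]:
    """Wrap each ITS2 in the conserved 5.8S / 28S flanking motifs.

    The resulting amplicon is ``flank_5p + its2 + flank_3p``; the true
    ITS2 span (0-based, half-open, in amplicon coordinates) is recorded
    in the ground truth when one is supplied.
    """
    if not config.flank_5p or not config.flank_3p:
        raise ConfigError("flank motifs must be non-empty")
    out = []
    w5 = len(config.flank_5p)
    for rec in records:
        if len(rec.sequence) == 0:
            raise ConfigError(f"zero-length ITS2 for {rec.specimen_id}")
        amplicon = config.flank_5p + rec.sequence + config.flank_3p
        out.append(SequenceRecord(rec.specimen_id, amplicon))
        if ground_truth is not None:
            ground_truth.its2_spans[rec.specimen_id] = (w5, w5 + len(rec.sequence))
    return out


def write_library(
    records: Sequence[SequenceRecord],
    taxonomy: TaxonomyTable,
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write the library FASTA and the 4-column taxonomy TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "library.fasta"
    tsv = out_dir / "taxonomy.tsv"
    write_fasta(records, fasta)
    taxonomy.write_tsv(tsv)
    return fasta, tsv


def simulate_library(
    config: LibraryConfig, with_flanks: bool = True
) -> tuple[list[SequenceRecord], TaxonomyTable, GroundTruth]:
    """Generate taxonomy and sequences from a single seeded random stream."""
    rng = np.random.default_rng(config.seed)
    taxonomy = generate_taxonomy(config, rng)
    records, truth = evolve_library(taxonomy, config, rng)
    if with_flanks:
        records = add_flanks(records, config, truth)
    return records, taxonomy, truth
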