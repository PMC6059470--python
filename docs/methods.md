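# Methods

## The evaluation model

A barcode reference library is judged by three complementary criteria,
all computed here from one alignment of the library:

* **Barcoding gap** — for species *s* with ≥2 sequences, let
  `max_intra(s)` be the largest K2P distance between two of its
  sequences and `min_inter(s)` the smallest distance from any of its
  sequences to any heterospecific sequence (the *nearest neighbor* is
  the species attaining that minimum; ties resolve to the
  lexicographically first name). The gap is violated when
  `max_intra(s) > min_inter(s)` strictly; an exact tie is reported
  separately, not counted as a violation. Sequence-level minima/maxima
  are used (not species means). Singletons have no intraspecific
  distance and are excluded.
* **Tree discrimination** — a species is identified by the
  neighbor-joining tree iff some edge of the unrooted topology
  bipartitions its leaves exactly (exclusivity/monophyly). The
  discrimination rate is identified ÷ non-singleton species. Support
  values are reported but do not gate identification, since cluster
  counting conventions in the literature do not apply a support
  threshold. Sequences of unidentified species are grouped into mixed
  clusters by merging the smallest clades containing each such species;
  the resulting cluster count is one consistent convention among
  several and is reported as context only.
* **Best-match identification** — each query is aligned globally (free
  end gaps) against every reference sequence; hits passing identity and
  coverage cutoffs are ranked by identity, and all hits within 1e−9 of
  the top identity form the best-hit set. The species call is *correct*
  if the set's species labels are exactly {true species}, *ambiguous*
  if the true species is present with others, *incorrect* if absent.
  The genus call applies the same rule to genus labels at the more
  permissive genus-level identity cutoff, which also admits queries
  whose species is missing from the reference. A species whose
  conspecific queries return disjoint best-match sets is a cryptic
  candidate; overlapping-but-unequal sets are flagged
  "inconsistent-ambiguous".

## Distances

K2P with pairwise deletion: per pair, sites where either row has a gap
or a non-ACGT symbol are discarded; P and Q are the transition and
transversion proportions over the remaining n sites and
`d = −½·ln[(1−2P−Q)·√(1−2Q)]`. The distance is *undefined* when n = 0
or either log argument is ≤ 0 (saturation); undefined entries are
masked with a reason and excluded from every summary (with the excluded
count reported) — clamping them would bias rank means downward
silently. IUPAC ambiguity codes are treated as missing, not resolved
probabilistically. Distances are fractions internally and percent in
all reported tables.

Rank summaries pool pairs by their most recent shared rank: species =
within-species pairs; genus = same genus, different species; family =
same family, different genus — the disjoint-levels convention of
standard barcode "distance summary" tools.

## Alignment

The built-in aligner is deliberately simple and fully deterministic: a
guide tree from k-mer sharing distances (k = 6, distance = 1 − shared
distinct k-mers ÷ smaller set), average-linkage merge order, then
profile–profile global Needleman–Wunsch with affine gaps (match +1,
mismatch −1, open −2, extend −0.5; column score = expected pair score
with gap residues contributing 0; ties prefer the diagonal state). The
DP core is JIT-compiled. Because distance results depend on the MSA,
externally computed alignments are accepted everywhere
(`--aligned`), which is also the route for reproducing any published
library exactly. The identification search uses the same scoring via
Biopython's pairwise aligner with free end gaps; identity = matching
columns ÷ all columns between the first and last position where both
rows carry a residue (so internal indels penalise identity, overhangs
do not), coverage = query residues inside that core ÷ query length.

## Neighbor joining

Standard Saitou–Nei agglomeration: join the pair minimising
`Q = (n−2)·d(i,j) − r_i − r_j`, branch lengths by the two-point
formulas, final trifurcation by the three-point formulas; negative
branch estimates are clamped to zero for output. Ties break to the
lowest (row, column) index so results are reproducible. Undefined
distances are rejected with the offending pairs listed (prune or
realign) rather than imputed — except inside bootstrap replicates,
where an entry that loses all its sites to column resampling is filled
with 1.2× the replicate's largest defined distance so the replicate
still votes; the full-data tree never uses this fallback. Bootstrap
support is the percentage of column-resampled replicates whose NJ tree
contains the same leaf bipartition.

## The simulator

The generator emulates the structure of a plant ITS2 reference library,
not its phylogenetic realism: a hierarchical taxonomy (families ⊇
genera ⊇ species ⊇ specimens, counts fixed or drawn from ranges —
ranges deliberately produce singleton species), sequences of 158–348 bp
at GC ≈ 0.63 evolved down a star-like rank tree under the K2P process
(transition rate κ-fold each transversion alternative, κ default 2),
flanked by the conserved 5.8S-tail / 28S-head motifs that annotation
cuts at (defaults are the universal primer-site segments of those
genes).

Branch lengths are in expected substitutions per site. Two lineages
diverging at a rank each accumulate half of that rank's expected
*pairwise* distance, so per-branch lengths are `d_intra/2`,
`(d_species−d_intra)/2`, `(d_genus−d_species)/2`, `(d_family−d_genus)/2`
down the hierarchy (the pairwise expectation at a rank is 2× the
per-branch increment). Family roots descend from a single global root
at the target GC: fully independent family roots would put
between-family pairs at random-sequence divergence, where the K2P log
argument is non-positive and the whole between-family block becomes
undefined — making full-library tree building impossible by
construction. Default scales (`d_intra` 0.0063, `d_species` 0.1177,
`d_genus` 0.3698, `d_family` 0.55) sit at the magnitudes typical of
published plant ITS2 rank summaries while keeping all pairs below
saturation.

Substitutions are drawn per site from the exact finite-time K2P event
probabilities (so multiple hits are modelled, and the estimated K2P
distance is consistent for the branch length). Per-family target
lengths are drawn from the length range and applied by random indels at
the family-root stage, giving between-family length variation; the
optional per-branch indel process (`indel_rate`, default 0 — within a
library indel turnover is much slower than substitution at these
scales, and a zero default keeps conspecific alignments exact) adds
within-family length variation. Indels never touch the flank motifs,
keeping annotation ground truth exact. One seeded random stream drives
taxonomy and evolution, so a config+seed pair reproduces the library
byte-for-byte.

What the simulator does *not* model — site-rate heterogeneity,
coalescent within-species genealogies, concerted-evolution paralogy,
chimeras, sequencing error — bounds what green tests mean: they show
the pipeline's logic is correct and recovers known truth under the
stated generative model, not that any particular real library will
reach the same rates.

## Annotation

Flank motifs are position weight matrices (pseudocount 0.5 per cell)
scored as summed log-odds against a uniform background; non-ACGT
symbols score 0. The best placement is the maximum-scoring offset
(ties → smallest offset). A hit must reach `min_score`, default 60% of
the profile's maximum attainable score — permissive enough to tolerate
a few flank substitutions, strict enough that random 160–350 bp
sequence essentially never passes. The ITS2 is the subsequence strictly
between the 5' hit's end and the 3' hit's start; failures carry reason
codes (`flank5_not_found`, `flank3_not_found`, `flanks_out_of_order`,
`empty_its2`). Coordinates are 0-based half-open throughout. A profile
HMM with insert/delete states would tolerate indel-riddled flanks, but
the 5.8S/28S ends are nearly gap-free in practice, so the PWM scan
recovers the same boundaries deterministically and with no extra
machinery.

GC content is (G+C)/(A+C+G+T) with ambiguity codes excluded from the
denominator; length counts non-gap characters; group summaries use
median and quartiles with linear interpolation (the standard box-plot
convention).

## Problem sizes and numerical choices

The reference study (`its2barcode.study`, also what
`scripts/acceptance.py` runs) uses 50 species × 5 specimens at 300 bp
with `d_intra` 0.006 / `d_species` 0.12 — comfortably separated scales
where the expected outcome is unambiguous: ~0.6% species-level mean,
zero gap violations, full discrimination, 100% correct leave-one-out
identification. The degradation sweep uses 10 species × 3 specimens
over 10 seeds per `d_intra` level, enough to make the expected
monotone trends (violations up, discrimination down) stable. Identity
ties in best-match sets use an absolute 1e−9 window; identification
defaults (0.97 species / 0.95 genus identity, 0.95 coverage) follow the
cutoffs customarily reported for ITS2 best-match studies.

## Known limitations

* The progressive aligner is adequate for barcode-scale libraries but
  is not a substitute for a production MSA tool on large or
  indel-heavy data; use `--aligned` with an external alignment there.
* Mixed-cluster counting is convention-dependent; only the
  identified-species count and discrimination rate are comparable
  across tools.
* The identification search is exhaustive (no heuristic seeding or
  E-values) and scales quadratically in library size; it is meant for
  library self-evaluation, not database-scale search.
* Genus-level calls require the taxonomy table to cover every
  reference sequence; queries themselves may be unknown.
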