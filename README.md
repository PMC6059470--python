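# its2barcode

Evaluation toolkit for ITS2 DNA-barcode reference libraries.

DNA barcoding identifies species from a short standardized marker; for
plants and herbal products the ITS2 spacer (the nuclear rDNA region
between the 5.8S and 28S genes, ~160–350 bp, GC-rich) is a workhorse
marker for quality control of medicinal material, where adulterants can
be a public-health hazard. Building a *reference library* of vouchered
ITS2 barcodes is only half the job — the library must then be shown to
actually discriminate its species. This package implements that
evaluation as a reusable pipeline:

1. **Annotation** — trim raw amplicons to the complete ITS2 by locating
   the conserved 5.8S-tail and 28S-head motifs (position-weight-matrix
   log-odds scan), plus length / GC / composition summaries.
2. **Distances** — progressive alignment and Kimura two-parameter
   distances under pairwise deletion,
   `d = −½·ln[(1−2P−Q)·√(1−2Q)]`, with P and Q the transition and
   transversion proportions; distance summaries pooled within species,
   within genus (between species) and within family (between genera).
3. **Barcoding gap** — per species, maximum intraspecific distance vs
   minimum distance to the nearest-neighbor species; a species violates
   the gap when the former strictly exceeds the latter.
4. **NJ discrimination** — Saitou–Nei neighbor joining (with optional
   column-bootstrap support); a species is identified when its
   sequences form an exclusive cluster (monophyly on the unrooted
   tree); singletons are excluded from the denominator.
5. **Identification** — leave-one-out best-match search (global
   alignment, free end gaps, ≥97% identity / ≥95% coverage defaults)
   with the three-way call: *correct* when all top hits are
   conspecific, *ambiguous* when top hits mix conspecific and
   heterospecific labels, *incorrect* otherwise; genus-level rollup at
   ≥95% identity; conspecific-consistency flags for cryptic diversity.
6. **Simulator** — a synthetic-library generator (hierarchical
   taxonomy, K2P substitution process with configurable κ and rank
   divergence scales, conserved flanks, optional indels) that gives
   every stage known ground truth.

## Worked example

```python
from its2barcode import (LibraryConfig, simulate_library, MotifProfile,
                         progressive_align, distance_matrix)
from its2barcode.annotate import annotate_records
from its2barcode.distance import summarize_all_ranks

cfg = LibraryConfig(n_families=5, genera_per_family=2, species_per_genus=5,
                    specimens_per_species=5, its2_length=(300, 300),
                    d_intra=0.006, d_species=0.12, d_genus=0.37, seed=1)
amplicons, taxonomy, truth = simulate_library(cfg)
p5 = MotifProfile.from_sequences([cfg.flank_5p])
p3 = MotifProfile.from_sequences([cfg.flank_3p])
barcodes, report = annotate_records(amplicons, p5, p3)
dm = distance_matrix(progressive_align(barcodes))
print(summarize_all_ranks(dm, taxonomy))
```

prints (seed 1):

```
      rank  taxa  comparisons    min_pct    max_pct   mean_pct  masked
0  species    50          500   0.000000   2.382238   0.634046       0
1    genus    10         2500   5.535134  18.480685  12.122128       0
2   family     5         3125  28.620333  45.679018  36.875162       0
```

i.e. the pipeline recovers the generating divergence hierarchy: mean
within-species distance 0.63% (configured 0.6%), congeneric 12.1%
(configured 12%), confamilial 36.9% (configured 37%). On this
well-separated library the gap analysis reports zero violations, the NJ
tree discriminates all 50 species, and leave-one-out identification is
100% correct.

The same pipeline runs on real data
(`its2barcode all --fasta library.fasta --taxonomy taxonomy.tsv`);
pre-aligned or pre-trimmed input is accepted with `--aligned` /
`--trimmed`.

## Analysis scripts

`analysis/01_simulate.py` … `07_degradation_sweep.py` run the full
evaluation story on a 60-species synthetic library (including singleton
species to exercise the exclusion rules) and a sweep showing how gap
violations rise and tree discrimination collapses as within-species
divergence approaches the between-species scale. Summary tables land in
`results/`; bulky intermediates in `scratch/`.

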