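"""Per-species barcoding-gap analysis.

Plots-ready scatter data (max intraspecific vs min distance to the
nearest neighbor) and the violation table go to results/.
"""

from common import SCRATCH, ensure_dirs
from its2barcode import TaxonomyTable, gap_table
from its2barcode.distance import distance_matrix
from its2barcode.gap import n_violations, write_gap_outputs
from its2barcode.msa import Alignment

ensure_dirs()
alignment = Alignment.read_fasta(SCRATCH / "aligned.fasta")
taxonomy = TaxonomyTable.read_tsv(SCRATCH / "taxonomy.tsv")
dm = distance_matrix(alignment)

records, excluded = gap_table(dm, taxonomy)
write_gap_outputs(records, "results/gap_table.tsv", "results/gap_scatter.tsv")
excluded.to_csv("results/gap_excluded.tsv", sep="\t", index=False)

print(f"{len(records)} species analysed, {len(excluded)} excluded "
      f"({', '.join(excluded.reason.unique()) or 'none'})")
print(f"gap violations (max intra > min inter): {n_violations(records)}")
worst = max(records, key=lambda r: r.max_intra_pct - r.min_inter_pct)
print(f"tightest species: {worst.species} "
      f"(max intra {worst.max_intra_pct:.2f}% vs min inter "
      f"{worst.min_inter_pct:.2f}% to {worst.nn_species})")
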