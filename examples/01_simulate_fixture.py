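"""Generate a small synthetic single-cell bisulfite fixture on disk.

Builds a 2-Mb annotated toy genome (four 500-kb tiles planted with
slow/intermediate/fast methylation-acquisition classes, genes, promoters,
CpG islands, ATAC peaks, repeats, imprinted DMRs and a lambda spike-in),
simulates 30 single-cell methylomes spread across developmental progression,
and writes the fixture (FASTA, BED6 tracks, per-cell cytosine reports,
sample sheet, expression matrix, truth tables, checksum manifest).
"""

from pathlib import Path

import scbskit as sk

out = Path("scratch/example_fixture")
genome = sk.build_genome(seed=1)
model = sk.KineticModel(somatic_fraction=0.05)
cohort = sk.simulate_cells(genome, model, n_cells=30, seed=2)
manifest = sk.emit_fixture(cohort, out)

print(f"fixture written to {out}/ ({len(manifest)} files)")
print(f"  CpG dyads in reference : {genome.cpg_dyad_count():,}")
print("  planted tile classes   :", ", ".join(genome.tile_truth["kinetic_class"]))
print("  cells:", len(cohort.methylomes),
      "| somatic planted:", int((cohort.specs['cell_type'] == 'somatic').sum()))
print("Each call file is a Bismark-style cytosine report; truth_*.tsv hold the")
print("planted progression, tile classes and gene classes for recovery checks.")
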