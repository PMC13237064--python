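"""Tile-level methylation-acquisition kinetics and annotation enrichment.

Per 500-kb tile and G-group, computes mean CpG methylation, then the kinetic
score S = (G3 - G1) - (G7 - G5): positive S means the tile gained most of
its methylation early (fast), negative S means it was still climbing late
(slow). Tiles are classified by ascending-S tertiles and each annotation
category is tested for enrichment across classes (chi-squared on bp overlap).
"""

import scbskit as sk
from scbskit import cellgroups, kinetics, qcfilter

genome = sk.build_genome(seed=1)
model = sk.KineticModel(somatic_fraction=0.05)
cohort = sk.simulate_cells(genome, model, n_cells=60, seed=2)

sheet = cohort.sample_sheet()
qcs = qcfilter.qc_cells(cohort.methylomes, sheet, genome.cpg_dyad_count(),
                        genome.annotations["imprint_dmr"])
table = qcfilter.apply_exclusions(sheet, qcs)
cells = {c: cohort.methylomes[c] for c in table.loc[table["included"], "cell_id"]}
scheme = cellgroups.assign_groups(
    {c: cellgroups.global_cpg_methylation(m) for c, m in cells.items()}, "marmoset"
)

tk = kinetics.tile_group_means(
    cells, scheme, {c: genome.chrom_sizes[c] for c in genome.main_chroms}
)
tk = kinetics.kinetic_score_and_classify(tk, ("G1", "G3"), ("G5", "G7"))
print("tile kinetic scores (planted classes in brackets):")
for (_, t), planted in zip(tk.tiles.iterrows(), genome.tile_truth["kinetic_class"]):
    print(f"  {t.Chromosome}:{t.Start:>9,}-{t.End:<9,}  S={t.score:+.3f}"
          f"  -> {t['class']:<13} [planted: {planted}]")

ann = genome.annotation_set()
enr = kinetics.annotation_enrichment(tk, ann, categories=["gene", "intergenic", "line"])
print("\nenrichment ratio by class (ratio > 1 = over-represented; * p < 0.05):")
for cat, sub in enr.groupby("category"):
    cells_ = "  ".join(
        f"{r['class']}={r['enrichment_ratio']:.2f}{'*' if r['significant'] else ''}"
        for _, r in sub.iterrows()
    )
    print(f"  {cat:<11} {cells_}")
print("Genic sequence concentrates in fast tiles; LINE repeats in slow tiles.")
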