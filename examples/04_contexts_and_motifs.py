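"""Context profiles, active-region masking and non-CG motif analysis.

Shows (1) mean methylation per annotation category and group, (2) the
genome-wide mean after masking active regions (promoters with CpG islands,
CpG islands, ATAC peaks, each +/- 2 kb around its midpoint) — active regions
stay unmethylated, so masking raises the mean — and (3) the fraction of
methylated calls at CG vs CH cytosines with the CH trinucleotide breakdown
(CAC/CAG are the DNMT3A/DNMT3B preferences).
"""

import scbskit as sk
from scbskit import cellgroups, contexts, qcfilter

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
ann = genome.annotation_set()

profile = contexts.context_methylation_profile(
    cells, scheme, ann, categories=["exon", "intron", "intergenic", "cgi", "atac_peak"]
)
g7 = profile[profile.group == "G7"].set_index("category")["mean"]
print("G7 (final group) mean methylation by context:")
for cat, val in g7.items():
    print(f"  {cat:<12} {100 * val:5.1f}%")

kept = contexts.filter_low_cpg_promoters(ann.frames["promoter"], genome.sequences)
ann_f = sk.AnnotationSet({**ann.frames, "promoter": kept})
masked = contexts.mask_active_regions(cells, scheme, ann_f)
row = masked[masked.group == "G7"].iloc[0]
print(f"\nG7 genome-wide mean: {100 * row['unmasked_mean']:.1f}%  ->"
      f" {100 * row['masked_mean']:.1f}% after masking active regions"
      f" (delta +{100 * row['delta']:.1f} points)")

mp = contexts.noncg_motif_profile(cells, scheme)
print("\nmethylated-call fraction per group (CG vs CH):")
for _, r in mp.summary.iterrows():
    print(f"  {r['group']}: CG {100 * r['cg_fraction']:5.1f}%   CH {100 * r['ch_fraction']:.2f}%")
top = mp.ch_tri_shares.loc["G7"].sort_values(ascending=False).head(3)
print("top CH motifs among methylated calls in G7:",
      ", ".join(f"{t} {100 * v:.0f}%" for t, v in top.items()))
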