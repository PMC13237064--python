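# Methods

This note documents the models, estimators and numerical choices behind
`scbskit`, and what the synthetic-data generator does and does not emulate.

## The measurement model

scBS-seq reports, per cell and per cytosine, a count of methylated and
unmethylated calls. Typical single-cell libraries observe a minority of all
CpGs at roughly single-molecule depth, so every estimator here is designed
for sparse, depth-1-ish data:

* **Strand merging.** A CpG dyad has a cytosine on each strand; both report
  the same methylation state. CG-context calls are merged by dyad (keyed by
  the plus-strand C), summing counts. Dyads covered on only one strand are
  kept with that strand's counts. CH calls are never merged (they are not
  palindromic) and are analysed per strand.
* **Site-mean levels.** A cell's global CpG methylation is the unweighted
  mean over covered dyads of the per-dyad rate n_meth/(n_meth+n_unmeth) —
  each site counts once regardless of depth, which keeps deeply covered
  sites from dominating. The spike-in contig is excluded everywhere.
* **Conversion.** Bisulfite conversion failure makes an unmethylated C look
  methylated. The conversion rate is estimated from an unmethylated
  lambda-phage spike-in as unmethylated calls / all calls, pooled over all
  lambda cytosines in all contexts. It is reported per cell but is not an
  exclusion criterion by default (a floor can be enabled); methylation
  levels are reported raw, not conversion-corrected.

## QC and exclusion

Two rules, applied independently per cell:

1. **Coverage** — covered CpG dyads / reference dyads < 1% (default)
   excludes the cell. Low mapping rate is reported but acts only through
   its coverage consequence. Whether "coverage" counts dyads or individual
   cytosines is a convention; dyads are used here (configurable).
2. **Somatic contamination** — maternally methylated imprinted DMRs are
   ~50% methylated in somatic cells and essentially unmethylated in male
   germ cells. Per DMR with at least `min_sites` (default 5) covered dyads,
   the mean dyad rate is computed; a cell is flagged somatic when the mean
   over qualifying DMRs is ≥ 0.25 (default). The 0.25 threshold separates
   ~0.5 from ~0 with margin on both sides at low depth; no published
   numeric threshold exists for this rule, so it is a package default.
   A cell with no qualifying DMR is *indeterminate*: retained, with a
   logged warning, never silently passed.

## Grouping

Cells are binned by global CpG methylation into ordered groups used as a
pseudo-developmental axis. Bins are half-open [lo, hi) with the top bin
closed — published group labels such as "0–10% / 10–20%" do not state edge
inclusivity, so one convention is fixed and tested. Species presets ship
the marmoset (7 bins, 0–80%), human (7 bins) and cynomolgus (5 bins)
schemes; the cynomolgus grouping was data-driven and its published group
*ranges* have gaps, so the preset places contiguous edges at the midpoints
between adjacent ranges. Arbitrary edges are accepted.

Expression summaries use log1p(count / library size × 10⁴) normalization.
The mitotic index is the mean normalized expression of an S/G2/M gene set
minus that of a size-matched random control set (fixed seed); score > 0
calls S/G2/M. This is deliberately simple — it is meant for cohorts where
cycling cells express the cycle program strongly.

## Tile kinetics

The genome (spike-in excluded) is cut into fixed tiles (500 kb default,
last tile truncated). Per tile and group, the mean is taken over all
covered dyad-cell observations pooled with equal weight (an
equal-cell-weight mode exists; at near-uniform coverage they coincide).
Tile/group cells with fewer than `min_sites` (default 50) observations are
undefined, and a tile is scored only when all four scoring groups are
defined. The kinetic score is the difference of differences

    S = (m[early_hi] − m[early_lo]) − (m[late_hi] − m[late_lo]),

with species presets (G1,G3)/(G5,G7) for the 7-group schemes and
(G1,G2)/(G3,G5) for the 5-group scheme. S is invariant to adding a constant
to all four means, so it measures timing, not final level. Classification
is by ascending-S tertiles (sizes differ by ≤ 1, stable tie-break), which
reproduces a three-way fast/intermediate/slow split without inventing a
numeric cutoff; a fixed-threshold mode is available. Tertile labels are
invariant under any strictly monotone transform of S.

Annotation enrichment builds, per category, a 2 × k contingency table of
(bp overlapping, bp not overlapping) × class over classified tiles and
applies Pearson's chi-squared test without continuity correction
(bp overlap rather than element counts: robust to annotation
fragmentation). If any expected cell falls below 5 the p-value switches to
a seeded Monte-Carlo permutation of the same statistic, recorded in the
output's `method` column. The enrichment ratio is the class overlap
fraction over the all-classified overlap fraction.

Gene-body kinetics applies the same score per gene body (default
`min_sites` 20, reflecting the smaller intervals), classifies genes by
tertile, and quantifies promoter accessibility as ATAC-peak bp overlapping
the promoter, signal-weighted when the peak file carries a score column.

## Contexts, masking, tertiles, motifs

* **Context profiles** pool dyad observations inside each category's merged
  footprint; a dyad under overlapping categories counts in each. Undefined
  (zero-coverage) category/group cells are reported as NaN, never dropped
  silently.
* **Active-region masking** removes every dyad within an active element or
  within ±2 kb of the element's midpoint (union of both), where active =
  promoters excluding low-CpG promoters, CpG islands, ATAC peaks. Low-CpG
  promoters are those with observed/expected CpG < 0.4 over the promoter
  interval (o/e = (#CG/L)/((#C/L)·(#G/L)); the threshold is a package
  default, configurable). Reported per group: unmasked mean, masked mean,
  delta. Masking a near-unmethylated subset can only raise the mean, and
  the delta is checked in the tests against a two-component mixture closed
  form computed from the generator's planted truth.
* **Expression tertiles.** Genes are ranked by mean normalized expression
  across the cohort and split into equal high/mid/low tertiles (stable
  gene-id tie-break; sizes differ by ≤ 1). Per group and tertile pair, a
  two-sided Wilcoxon rank-sum test compares per-gene gene-body methylation;
  all reported p-values are Benjamini–Hochberg adjusted together. Fewer
  than two testable tertiles skips the analysis with a notice.
* **Non-CG motifs.** Per group, the fraction of methylated calls among CG
  calls and among CH calls (CHG and CHH pooled to match the dinucleotide
  framing; the finer split remains in the call tables), and the breakdown
  of methylated CHN calls into the 12 CH trinucleotides (rolled up to
  CAN/CCN/CTN) and of methylated CGN calls into CGA/CGC/CGG/CGT. The
  default mode pools calls (each sequenced call counts once); a
  site-binarized mode exists, and at depth ~1 the two coincide. Calls with
  ambiguous bases and the spike-in contig are excluded.

## The synthetic-data generator

`simgen` is the package's study-condition definition, not a test stub.
Defaults: one 2-Mb chromosome (four 500-kb tiles planted
slow/slow/intermediate/fast — the ascending-tertile split sizes for four
tiles), a 48.5-kb lambda contig, 20 genes, 60 cells, 20% CpG coverage per
cell at depth 1. Its components:

* **Sequence.** Background bases at 42% GC with all CpGs removed, then CpG
  dyads planted at 0.008/bp genome-wide and 0.10/bp inside CpG islands and
  imprinted DMRs — so CGI CpG density strictly exceeds background by
  construction, and the reference dyad count is known exactly.
* **Trajectories.** Each cell has a latent progression τ ~ U(0, 1)
  (development within a testis is unsynchronized, so τ — not donor age —
  drives state; age labels are derived by binning τ). A dyad's true level
  follows its structural class: piecewise-linear in τ with a breakpoint at
  τ = 0.5 — fast gains 1.2/τ-unit early and 0.2 late (ceiling 0.85),
  slow is the mirror (0.35/1.15, ceiling 0.78), intermediate is linear
  (0.72/0.72, ceiling 0.80), all over a basal 0.04. These rates were chosen
  once to span the observed global range (~5% to ~70%) and to separate the
  class scores (S ≈ +0.2 / ≈0 / −0.25); they are not fitted quantities.
  Gene bodies carry their own planted class (near-equal thirds), genes are
  *placed* preferentially in fast tiles (so genic bp is enriched there),
  active regions sit at 0.01 regardless of τ, imprinted DMRs at 0 in germ
  cells and 0.5 in somatic cells, and somatic cells are 0.75 elsewhere.
* **Observation.** A covered dyad is reported on one random strand (both
  with probability 0.15). A call is methylated with probability
  m + (1 − m)(1 − c), c = 0.993 by default — conversion error is one-sided
  (failure to convert an unmethylated C), matching how conversion is
  estimated from an unmethylated spike-in; over-conversion of 5mC is
  ignored. Depth is 1 call/site by default with optional Poisson
  overdispersion — per-site single-cell depth is not a published quantity,
  so single-molecule depth is the default.
* **CH methylation.** True CH level ramps as 0.001 + 0.004τ; per
  trinucleotide t the level is scaled by w_t/f_t (w = configured motif
  weights, CAC/CAG elevated; f = genomic trinucleotide frequency), which
  makes truly methylated CH calls follow w exactly while preserving the
  pooled level. Observed CH fractions additionally contain conversion-error
  calls distributed by f; with the defaults the observed fraction spans
  ~0.8–1.2% across groups, deliberately in the regime where conversion
  error is a large share of apparent CH methylation. Motif-recovery tests
  therefore check either the analytic observed mixture, or the pure weights
  at c = 1.
* **Expression and cycle.** Gene expression tier follows kinetic class
  (fast high, slow low; Poisson counts with lognormal library sizes);
  promoter ATAC peaks have class-ordered probability and signal; ~12% of
  germ cells are mitotic and exclusively express a DNMT1-like maintenance
  marker plus an S/G2/M gene set. Methylation is maintained through
  division by default; a switch halves mitotic cells' CpG levels for
  contrast experiments with maintenance disabled.
* **Emission.** `emit_fixture` writes FASTA, BED6 tracks, per-cell
  cytosine reports, sample sheet, expression matrix and truth tables, plus
  a sha256 manifest; re-emission is byte-identical for a fixed seed and
  `validate_manifest` names any missing or modified file.

**What the generator does not emulate:** read-level artifacts (PCR bias,
duplicates, chimeras), mappability structure, copy-number variation,
correlated methylation along the genome beyond the planted classes,
cell-type mixtures beyond one somatic type, and biological noise in the
class trajectories. Passing recovery tests therefore demonstrates that the
estimators are correct under the stated sampling model — not that they are
robust to every artifact of real libraries.

## Problem sizes and determinism

The shipped tests and examples run the full pipeline on the default 2-Mb /
60-cell cohort (seconds per stage on one core) and use smaller 400-kb
genomes for I/O, CLI and roster checks; these sizes were chosen as the
smallest at which every group is populated and every planted signal is
recoverable with comfortable statistical margin. All randomness flows
through `numpy.random.default_rng` seeds carried in configs and function
arguments; property-based tests are derandomized. Degenerate inputs
(empty call files, zero-coverage categories, indeterminate imprint status,
masks covering everything, unclassifiable tile sets) are either defined
results, warnings, or loud errors — never silent NaN propagation.

## Known limitations

* Tertile classification needs at least three classified tiles/genes and is
  only as meaningful as the number of scored units; with four tiles the
  split is 2/1/1.
* The chi-squared enrichment treats base pairs as independent observations;
  on real data its p-values are anti-conservative and should be read as
  ranking evidence, as is conventional for genome-tiling enrichments.
* The mitotic index assumes the cycle gene set is essentially off outside
  S/G2/M; for real scRNA-seq a dedicated cell-cycle scorer is preferable.
* The coverage-dialect reader requires the genome FASTA; it will not guess
  contexts.
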