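"""Synthetic annotated genome and single-cell methylome cohorts.

The generator emulates the statistical structure of a postnatal male-germline
de novo methylation time course as seen by single-cell bisulfite sequencing:

* a latent developmental progression ``tau`` in [0, 1] per cell, with global
  CpG methylation rising from near-zero to ~70%;
* region-specific acquisition kinetics — each 500-kb tile (and each gene
  body) carries a planted ``fast`` / ``intermediate`` / ``slow`` class whose
  trajectory differs in early vs. late gain;
* active regulatory elements (CpG-island promoters, CpG islands, ATAC peaks)
  that stay essentially unmethylated throughout;
* maternally methylated imprinted DMRs: ~0 in germ cells, ~50% in somatic
  contaminants, which is what imprint-based QC exploits;
* an unmethylated lambda-phage spike-in contig read through an imperfect
  bisulfite conversion step (one-sided: a conversion failure shows an
  unmethylated C as methylated);
* low-level CH (non-CpG) methylation with configurable trinucleotide motif
  weights (CAC/CAG elevated by default);
* per-cell expression counts whose planted tiers follow gene kinetic class
  (fast > intermediate > slow), cell-cycle marker genes expressed only in
  mitotic cells, and promoter ATAC accessibility ordered by class.

Every planted quantity is stored as ground truth so downstream recovery is
assertable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import intervals, methio

CLASS_NAMES = ("fast", "intermediate", "slow")

# per-dyad structural codes, in precedence order (imprint wins over active,
# active over gene class, gene class over tile class)
CODE_ACTIVE, CODE_IMPRINT, CODE_FAST, CODE_INTERMEDIATE, CODE_SLOW = range(5)
_CLASS_TO_CODE = {"fast": CODE_FAST, "intermediate": CODE_INTERMEDIATE, "slow": CODE_SLOW}

CH_TRINUCLEOTIDES = tuple(
    f"C{h}{n}" for h in "ACT" for n in "ACGT"
)

CYCLE_GENES = ("CCNB1", "CDK1", "MKI67", "TOP2A", "AURKA")
MAINTENANCE_MARKER = "DNMT1"


class CapacityError(ValueError):
    """Requested annotation placements do not fit on the chromosome."""


class ManifestError(ValueError):
    """An emitted fixture no longer matches its manifest."""


def _default_motif_weights() -> dict[str, float]:
    w = {t: 0.055 for t in CH_TRINUCLEOTIDES}
    w["CAC"] = 0.25
    w["CAG"] = 0.20
    return w


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GenomeConfig:
    """Layout of the toy genome. Defaults give 1 chromosome x 2 Mb with four
    500-kb tiles planted slow/slow/intermediate/fast (the ascending-tertile
    split sizes for four tiles), plus a 48.5-kb lambda spike-in contig."""

    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 2_000_000})
    lambda_name: str = "lambda"
    lambda_size: int = 48_502
    tile_size: int = 500_000
    shuffle_tiles: bool = False
    n_genes: int = 20
    gene_length: tuple[int, int] = (12_000, 26_000)
    promoter_size: int = 1_000
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (150, 600)
    cgi_promoter_fraction: float = 0.7
    n_orphan_cgi: int = 4
    cgi_length: int = 1_000
    atac_width: int = 600
    atac_peak_prob: dict[str, float] = field(
        default_factory=lambda: {"fast": 1.0, "intermediate": 0.8, "slow": 0.3}
    )
    atac_score: dict[str, float] = field(
        default_factory=lambda: {"fast": 10.0, "intermediate": 5.0, "slow": 2.0}
    )
    n_intergenic_atac: int = 2
    n_line: int = 24
    line_length: int = 3_000
    n_ltr: int = 16
    ltr_length: int = 800
    repeat_class_weights: dict[str, float] = field(
        default_factory=lambda: {"fast": 0.1, "intermediate": 0.2, "slow": 0.7}
    )
    n_imprint_dmr: int = 3
    imprint_names: tuple[str, ...] = ("MEST", "RB1", "PLAGL1")
    imprint_length: int = 2_000
    gene_tile_weights: dict[str, float] = field(
        default_factory=lambda: {"fast": 0.60, "intermediate": 0.22, "slow": 0.09}
    )
    cpg_density: float = 0.008
    cgi_cpg_density: float = 0.10
    gc_content: float = 0.42
    flank_size: int = 2_000


@dataclass
class KineticModel:
    """Forward model of gradual methylation acquisition.

    CpG trajectories are piecewise linear in progression ``tau`` with a
    breakpoint at ``breakpoint``: level = base + early*min(tau, b) +
    late*max(tau - b, 0), clipped to the class ceiling. ``fast`` gains early
    and saturates; ``slow`` is the mirror image; ``intermediate`` is close to
    linear. Observed calls add one-sided bisulfite conversion error: a site
    with true level m yields a methylated call with probability
    m + (1 - m) * (1 - conversion_rate).
    """

    class_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "fast": (1.20, 0.20),
            "intermediate": (0.72, 0.72),
            "slow": (0.35, 1.15),
        }
    )
    ceilings: dict[str, float] = field(
        default_factory=lambda: {"fast": 0.85, "intermediate": 0.80, "slow": 0.78}
    )
    base_level: float = 0.04
    breakpoint: float = 0.5
    active_region_level: float = 0.01
    imprint_germ_level: float = 0.0
    imprint_somatic_level: float = 0.5
    somatic_level: float = 0.75
    ch_base: float = 0.001
    ch_gain: float = 0.004
    ch_somatic_level: float = 0.001
    ch_motif_weights: dict[str, float] = field(default_factory=_default_motif_weights)
    conversion_rate: float = 0.993
    somatic_fraction: float = 0.0
    mitotic_fraction: float = 0.12
    maintain_on_division: bool = True

    def validate(self) -> None:
        for cls, (e, l) in self.class_rates.items():
            if e < 0 or l < 0:
                raise ValueError(f"negative rate for class {cls}")
        for cls, c in self.ceilings.items():
            if not 0 <= c <= 1:
                raise ValueError(f"ceiling for {cls} outside [0, 1]")
        if not self.class_rates["fast"][0] > self.class_rates["slow"][0]:
            raise ValueError("fast early gain must exceed slow early gain")
        if not 0 < self.conversion_rate <= 1:
            raise ValueError("conversion_rate must be in (0, 1]")
        total = sum(self.ch_motif_weights.get(t, 0.0) for t in CH_TRINUCLEOTIDES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("CH motif weights must sum to 1 over CAN+CCN+CTN")

    def cg_level(self, kinetic_class: str, tau) -> np.ndarray:
        """True CpG methylation level of a class at progression tau."""
        e, l = self.class_rates[kinetic_class]
        tau = np.asarray(tau, dtype=float)
        m = self.base_level + e * np.minimum(tau, self.breakpoint) + l * np.maximum(
            tau - self.breakpoint, 0.0
        )
        return np.clip(m, 0.0, self.ceilings[kinetic_class])

    def ch_level(self, tau) -> np.ndarray:
        return self.ch_base + self.ch_gain * np.asarray(tau, dtype=float)

    def observed(self, m) -> np.ndarray:
        """Expected methylated-call probability after conversion error."""
        m = np.asarray(m, dtype=float)
        return m + (1.0 - m) * (1.0 - self.conversion_rate)

    def code_levels(self, cell_type: str, tau: float, mitotic: bool = False) -> np.ndarray:
        """True level per structural code (ACTIVE..SLOW) for one cell."""
        if cell_type == "somatic":
            lv = np.array(
                [
                    self.active_region_level,
                    self.imprint_somatic_level,
                    self.somatic_level,
                    self.somatic_level,
                    self.somatic_level,
                ]
            )
        else:
            lv = np.array(
                [
                    self.active_region_level,
                    self.imprint_germ_level,
                    float(self.cg_level("fast", tau)),
                    float(self.cg_level("intermediate", tau)),
                    float(self.cg_level("slow", tau)),
                ]
            )
            if mitotic and not self.maintain_on_division:
                lv = lv * 0.5  # passive dilution when maintenance is switched off
        return lv


# ---------------------------------------------------------------------------
# genome assembly


@dataclass
class SyntheticGenome:
    config: GenomeConfig
    chrom_sizes: dict[str, int]          # includes the lambda contig
    sequences: dict[str, str]
    annotations: dict[str, pd.DataFrame]
    gene_models: pd.DataFrame
    tile_truth: pd.DataFrame
    active_footprint: pd.DataFrame       # realized unmethylated footprint (truth)
    dyads: dict[str, np.ndarray]         # 0-based plus-strand C of each CpG dyad
    dyad_class: dict[str, np.ndarray]    # structural code per dyad
    dyad_tri_plus: dict[str, np.ndarray]
    dyad_tri_minus: dict[str, np.ndarray]
    ch_sites: dict[str, pd.DataFrame]    # pos, strand, tri, context, motif factor
    lambda_sites: pd.DataFrame

    @property
    def lambda_name(self) -> str:
        return self.config.lambda_name

    @property
    def main_chroms(self) -> list[str]:
        return [c for c in self.chrom_sizes if c != self.config.lambda_name]

    def cpg_dyad_count(self) -> int:
        return int(sum(self.dyads[c].size for c in self.main_chroms))

    def annotation_set(self) -> methio.AnnotationSet:
        ann = methio.AnnotationSet(self.annotations)
        ann.derive(
            {c: self.chrom_sizes[c] for c in self.main_chroms},
            flank_size=self.config.flank_size,
        )
        return ann


_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)


def _strip_cpg(b: np.ndarray, rng: np.random.Generator) -> None:
    """Destroy every CG dinucleotide by mutating its G (in place)."""
    hits = np.flatnonzero((b[:-1] == ord("C")) & (b[1:] == ord("G")))
    if hits.size:
        b[hits + 1] = rng.choice(np.frombuffer(b"AT", dtype=np.uint8), size=hits.size)


def _plant_cpgs(b: np.ndarray, density: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Plant non-adjacent CG dyads at per-position Bernoulli rates."""
    L = b.size
    cand = np.flatnonzero(rng.random(L - 2) < density[: L - 2])
    keep, last = [], -2
    for p in cand:
        if p > last + 1:
            keep.append(p)
            last = p
    pos = np.asarray(keep, dtype=np.int64)
    b[pos] = ord("C")
    b[pos + 1] = ord("G")
    return pos


def _tri_strings(cols: list[np.ndarray]) -> np.ndarray:
    arr = np.ascontiguousarray(np.stack(cols, axis=1))
    return np.frombuffer(arr.tobytes(), dtype="S3").astype("U3")


def _ch_inventory(b: np.ndarray) -> pd.DataFrame:
    """All non-CpG cytosines of a sequence (both strands) with contexts."""
    pos_p = np.flatnonzero(b[:-2] == ord("C"))
    pos_p = pos_p[b[pos_p + 1] != ord("G")]
    tri_p = _tri_strings([b[pos_p], b[pos_p + 1], b[pos_p + 2]])
    pos_m = np.flatnonzero(b[2:] == ord("G")) + 2
    pos_m = pos_m[b[pos_m - 1] != ord("C")]
    tri_m = _tri_strings([_COMP[b[pos_m]], _COMP[b[pos_m - 1]], _COMP[b[pos_m - 2]]])
    df = pd.DataFrame(
        {
            "pos": np.concatenate([pos_p, pos_m]),
            "strand": np.concatenate([np.full(pos_p.size, "+"), np.full(pos_m.size, "-")]),
            "tri": np.concatenate([tri_p, tri_m]),
        }
    ).sort_values("pos", kind="stable", ignore_index=True)
    df["context"] = np.where(df["tri"].str[2] == "G", "CHG", "CHH")
    return df


def _place_free(
    occupied: list[tuple[int, int]], lo: int, hi: int, length: int, rng, tries: int = 200
):
    """Random non-overlapping placement of ``length`` bp in [lo, hi)."""
    if hi - lo < length:
        return None
    for _ in range(tries):
        s = int(rng.integers(lo, hi - length))
        e = s + length
        if all(e <= a or s >= b for a, b in occupied):
            occupied.append((s, e))
            return s
    return None


def _tile_plan(n_tiles: int, rng, shuffle: bool) -> list[str]:
    """Planted classes per tile: ascending-tertile split sizes, slow first."""
    parts = np.array_split(np.arange(n_tiles), 3)
    plan = (
        ["slow"] * len(parts[0]) + ["intermediate"] * len(parts[1]) + ["fast"] * len(parts[2])
    )
    if shuffle:
        plan = list(rng.permutation(plan))
    return plan


def build_genome(config: GenomeConfig | None = None, seed: int = 0) -> SyntheticGenome:
    """Assemble sequence, annotations and planted truth for a toy genome.

    Deterministic for a fixed seed. Raises :class:`CapacityError` when the
    requested genes (bodies plus promoters and spacing) cannot fit in the
    tiles they were allocated to.
    """
    config = config or GenomeConfig()
    rng = np.random.default_rng(seed)
    for chrom, size in config.chrom_sizes.items():
        if size < 2 * config.tile_size:
            raise ValueError(f"{chrom}: chromosome shorter than two tiles")

    tiles_rows, gene_rows = [], []
    ann: dict[str, list] = {
        k: [] for k in ("gene", "exon", "intron", "promoter", "cgi", "atac_peak",
                        "line", "ltr", "imprint_dmr")
    }
    occupied_by_chrom: dict[str, list[tuple[int, int]]] = {}
    cgi_density_ivals: dict[str, list[tuple[int, int]]] = {}
    gidx = 0

    for chrom, size in config.chrom_sizes.items():
        starts = np.arange(0, size, config.tile_size)
        tile_bounds = [(int(s), int(min(s + config.tile_size, size))) for s in starts]
        plan = _tile_plan(len(tile_bounds), rng, config.shuffle_tiles)
        for (s, e), cls in zip(tile_bounds, plan):
            tiles_rows.append((chrom, s, e, cls))
        occupied = occupied_by_chrom.setdefault(chrom, [])
        cgi_density_ivals.setdefault(chrom, [])

        # allocate genes to tiles by class weight (largest-remainder rounding,
        # deterministic), then lay out within tiles
        w = np.array([config.gene_tile_weights[c] for c in plan], dtype=float)
        ideal = config.n_genes * w / w.sum()
        alloc = np.floor(ideal).astype(int)
        short = config.n_genes - alloc.sum()
        for i in np.argsort(-(ideal - alloc), kind="stable")[:short]:
            alloc[i] += 1
        margin = config.promoter_size + 1_000
        for (tstart, tend), n_here in zip(tile_bounds, alloc):
            if n_here == 0:
                continue
            seg = (tend - tstart) // n_here
            if seg < config.gene_length[1] + 2 * margin:
                raise CapacityError(
                    f"{chrom}:{tstart}-{tend}: {n_here} genes of up to "
                    f"{config.gene_length[1]} bp (+promoters) exceed tile capacity"
                )
            for j in range(n_here):
                body_len = int(rng.integers(*config.gene_length))
                lo = tstart + j * seg + margin
                hi = tstart + (j + 1) * seg - margin
                bstart = int(rng.integers(lo, hi - body_len))
                bend = bstart + body_len
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "+":
                    pstart, pend = bstart - config.promoter_size, bstart
                    tss = bstart
                else:
                    pstart, pend = bend, bend + config.promoter_size
                    tss = bend
                occupied.append((min(pstart, bstart), max(pend, bend)))
                gene_rows.append(
                    dict(
                        gene_id=f"G{gidx:04d}",
                        Chromosome=chrom,
                        Start=bstart,
                        End=bend,
                        strand=strand,
                        prom_start=pstart,
                        prom_end=pend,
                        tss=tss,
                    )
                )
                ann["gene"].append((chrom, bstart, bend, f"G{gidx:04d}", 0))
                ann["promoter"].append((chrom, pstart, pend, f"G{gidx:04d}", 0))
                # exons: one per equal chunk of the body, random offset
                n_ex = int(rng.integers(*config.exons_per_gene))
                chunk = body_len // n_ex
                prev_end = bstart
                for k in range(n_ex):
                    el = int(rng.integers(*config.exon_length))
                    el = min(el, chunk - 10)
                    off = int(rng.integers(0, chunk - el))
                    es = bstart + k * chunk + off
                    ann["exon"].append((chrom, es, es + el, f"G{gidx:04d}", 0))
                    if es > prev_end:
                        ann["intron"].append((chrom, prev_end, es, f"G{gidx:04d}", 0))
                    prev_end = es + el
                if bend > prev_end:
                    ann["intron"].append((chrom, prev_end, bend, f"G{gidx:04d}", 0))
                # promoter CGI (class-independent), kept upstream of the TSS
                # so the gene body's planted trajectory stays unmixed
                if rng.random() < config.cgi_promoter_fraction:
                    cs = tss - config.cgi_length if strand == "+" else tss
                    ann["cgi"].append((chrom, cs, cs + config.cgi_length, f"G{gidx:04d}", 0))
                    cgi_density_ivals[chrom].append((cs, cs + config.cgi_length))
                gidx += 1

        # orphan CGIs, imprinted DMRs, repeats and intergenic ATAC peaks
        for k in range(config.n_orphan_cgi):
            s = _place_free(occupied, 0, size, config.cgi_length, rng)
            if s is not None:
                ann["cgi"].append((chrom, s, s + config.cgi_length, f"orphan_{chrom}_{k}", 0))
                cgi_density_ivals[chrom].append((s, s + config.cgi_length))
        for k in range(config.n_intergenic_atac):
            s = _place_free(occupied, 0, size, config.atac_width, rng)
            if s is not None:
                ann["atac_peak"].append((chrom, s, s + config.atac_width, f"ig_{chrom}_{k}", 3.0))

    # planted gene-body classes: near-equal thirds, independent of the tile a
    # gene landed in, permuted deterministically; expression tier and promoter
    # ATAC accessibility follow the class (fast > intermediate > slow)
    parts = np.array_split(np.arange(len(gene_rows)), 3)
    class_pool = np.array(
        ["slow"] * len(parts[0]) + ["intermediate"] * len(parts[1]) + ["fast"] * len(parts[2]),
        dtype=object,
    )
    gene_classes = rng.permutation(class_pool)
    for row, cls in zip(gene_rows, gene_classes):
        row["kinetic_class"] = str(cls)
        row["expr_tier"] = {"fast": "high", "intermediate": "mid", "slow": "low"}[str(cls)]
        if rng.random() < config.atac_peak_prob[str(cls)]:
            asz = config.atac_width
            score = max(0.1, rng.normal(config.atac_score[str(cls)], 0.5))
            ps = row["tss"] - asz if row["strand"] == "+" else row["tss"]
            ann["atac_peak"].append(
                (row["Chromosome"], ps, ps + asz, row["gene_id"], round(score, 3))
            )

    # imprinted DMRs only on the first chromosome (CpG-dense, named loci)
    first = next(iter(config.chrom_sizes))
    for k in range(config.n_imprint_dmr):
        name = config.imprint_names[k % len(config.imprint_names)]
        s = _place_free(
            occupied_by_chrom[first], 0, config.chrom_sizes[first], config.imprint_length, rng
        )
        if s is None:
            raise CapacityError("no free space for imprinted DMRs")
        ann["imprint_dmr"].append((first, s, s + config.imprint_length, name, 0))
        cgi_density_ivals[first].append((s, s + config.imprint_length))

    # repeats, biased toward slow tiles
    tile_df = pd.DataFrame(tiles_rows, columns=["Chromosome", "Start", "End", "kinetic_class"])
    rep_w = tile_df["kinetic_class"].map(config.repeat_class_weights).to_numpy(float)
    rep_w /= rep_w.sum()
    for cat, n, length in (("line", config.n_line, config.line_length),
                           ("ltr", config.n_ltr, config.ltr_length)):
        for k in range(n):
            t = tile_df.iloc[int(rng.choice(len(tile_df), p=rep_w))]
            s = _place_free(
                occupied_by_chrom[t["Chromosome"]], int(t["Start"]), int(t["End"]), length, rng
            )
            if s is not None:
                ann[cat].append((t["Chromosome"], s, s + length, f"{cat}_{k}", 0))

    annotations = {
        cat: pd.DataFrame(rows, columns=["Chromosome", "Start", "End", "Name", "Score"])
        for cat, rows in ann.items()
    }
    gene_models = pd.DataFrame(gene_rows)

    # sequence: CpG-free background, then planted dyads at the target densities
    sequences: dict[str, str] = {}
    dyads, dyad_class, tri_plus, tri_minus, ch_sites = {}, {}, {}, {}, {}
    for chrom, size in config.chrom_sizes.items():
        b = _random_bases(size, config.gc_content, rng)
        _strip_cpg(b, rng)
        dens = np.full(size, config.cpg_density)
        for s, e in cgi_density_ivals[chrom]:
            dens[max(s, 0) : min(e, size)] = config.cgi_cpg_density
        _plant_cpgs(b, dens, rng)
        sequences[chrom] = b.tobytes().decode("ascii")

    # lambda spike-in: plain random sequence, no annotations
    lam = config.lambda_name
    b = _random_bases(config.lambda_size, 0.50, rng)
    sequences[lam] = b.tobytes().decode("ascii")
    chrom_sizes = dict(config.chrom_sizes)
    chrom_sizes[lam] = config.lambda_size

    # active footprint truth: cgi + atac + promoters that carry a cgi
    act_parts = [annotations["cgi"], annotations["atac_peak"]]
    prom = intervals.as_pyranges(annotations["promoter"][intervals.BED_COLS])
    cgi = intervals.as_pyranges(annotations["cgi"][intervals.BED_COLS])
    if len(prom) and len(cgi):
        hit = prom.overlap(cgi)
        if len(hit):
            act_parts.append(hit.df)
    active_df = (
        intervals.as_pyranges(
            pd.concat([p[intervals.BED_COLS] for p in act_parts], ignore_index=True)
        )
        .merge()
        .df
    )

    active_m = intervals.merged_arrays(intervals.as_pyranges(active_df))
    imprint_m = intervals.merged_arrays(
        intervals.as_pyranges(annotations["imprint_dmr"][intervals.BED_COLS])
    )
    tile_lookup = {
        (r.Chromosome, int(r.Start) // config.tile_size): r.kinetic_class
        for r in tile_df.itertuples()
    }

    ch_counts: dict[str, int] = {t: 0 for t in CH_TRINUCLEOTIDES}
    raw_ch: dict[str, pd.DataFrame] = {}
    for chrom in config.chrom_sizes:
        b = np.frombuffer(sequences[chrom].encode(), dtype=np.uint8)
        dy = np.flatnonzero((b[:-1] == ord("C")) & (b[1:] == ord("G")))
        dy = dy[(dy >= 1) & (dy <= b.size - 3)]
        dyads[chrom] = dy
        tri_plus[chrom] = _tri_strings([b[dy], b[dy + 1], b[dy + 2]])
        tri_minus[chrom] = _tri_strings([_COMP[b[dy + 1]], _COMP[b[dy]], _COMP[b[dy - 1]]])

        codes = np.empty(dy.size, dtype=np.int8)
        tile_cls = np.array(
            [_CLASS_TO_CODE[tile_lookup[(chrom, int(p) // config.tile_size)]] for p in dy],
            dtype=np.int8,
        )
        codes[:] = tile_cls
        gsub = gene_models[gene_models["Chromosome"] == chrom] if len(gene_models) else gene_models
        for grow in gsub.itertuples():
            lo, hi = np.searchsorted(dy, [grow.Start, grow.End])
            codes[lo:hi] = _CLASS_TO_CODE[grow.kinetic_class]
        codes[intervals.positions_in(active_m, chrom, dy)] = CODE_ACTIVE
        codes[intervals.positions_in(imprint_m, chrom, dy)] = CODE_IMPRINT
        dyad_class[chrom] = codes

        df = _ch_inventory(b)
        raw_ch[chrom] = df
        vc = df["tri"].value_counts()
        for t in CH_TRINUCLEOTIDES:
            ch_counts[t] += int(vc.get(t, 0))

    # motif factor g_t = w_t / f_t so that methylated CH calls follow the
    # configured weights while the pooled CH level stays at ch_level(tau)
    total_ch = sum(ch_counts.values())
    freq = {t: (ch_counts[t] / total_ch if total_ch else 0.0) for t in CH_TRINUCLEOTIDES}
    for chrom, df in raw_ch.items():
        if chrom == lam:
            continue
        df["freq"] = df["tri"].map(freq).fillna(0.0)
        ch_sites[chrom] = df

    blam = np.frombuffer(sequences[lam].encode(), dtype=np.uint8)
    lam_df = _ch_inventory(blam)
    dy_l = np.flatnonzero((blam[:-1] == ord("C")) & (blam[1:] == ord("G")))
    dy_l = dy_l[(dy_l >= 1) & (dy_l <= blam.size - 3)]
    cg_rows = pd.DataFrame(
        {
            "pos": np.concatenate([dy_l, dy_l + 1]),
            "strand": np.concatenate([np.full(dy_l.size, "+"), np.full(dy_l.size, "-")]),
            "tri": np.concatenate(
                [
                    _tri_strings([blam[dy_l], blam[dy_l + 1], blam[dy_l + 2]]),
                    _tri_strings([_COMP[blam[dy_l + 1]], _COMP[blam[dy_l]], _COMP[blam[dy_l - 1]]]),
                ]
            ),
        }
    )
    cg_rows["context"] = "CG"
    lambda_sites = (
        pd.concat([lam_df[["pos", "strand", "tri", "context"]], cg_rows], ignore_index=True)
        .sort_values("pos", kind="stable", ignore_index=True)
    )

    return SyntheticGenome(
        config=config,
        chrom_sizes=chrom_sizes,
        sequences=sequences,
        annotations=annotations,
        gene_models=gene_models,
        tile_truth=tile_df,
        active_footprint=active_df,
        dyads=dyads,
        dyad_class=dyad_class,
        dyad_tri_plus=tri_plus,
        dyad_tri_minus=tri_minus,
        ch_sites=ch_sites,
        lambda_sites=lambda_sites,
    )


# ---------------------------------------------------------------------------
# analytic expectations (used as oracles by the test suite)


def class_code_counts(genome: SyntheticGenome, selector=None) -> np.ndarray:
    """Dyad counts per structural code; ``selector`` maps chrom -> bool mask."""
    counts = np.zeros(5, dtype=np.int64)
    for chrom in genome.main_chroms:
        codes = genome.dyad_class[chrom]
        if selector is not None:
            codes = codes[selector[chrom]]
        counts += np.bincount(codes, minlength=5)
    return counts


def expected_global_level(
    genome: SyntheticGenome,
    model: KineticModel,
    tau: float,
    cell_type: str = "germ",
    observed: bool = True,
    selector=None,
) -> float:
    """Expected site-mean CpG methylation of one cell (optionally restricted
    to a dyad subset and/or adjusted for conversion error)."""
    counts = class_code_counts(genome, selector)
    levels = model.code_levels(cell_type, tau)
    if observed:
        levels = model.observed(levels)
    return float(np.average(levels, weights=counts)) if counts.sum() else float("nan")


def expected_ch_motif_shares(
    genome: SyntheticGenome, model: KineticModel, tau: float
) -> dict[str, float]:
    """Expected share of each CH trinucleotide among methylated CH calls,
    including conversion-error calls (which follow genomic composition)."""
    lvl = float(model.ch_level(tau))
    shares = {}
    for t in CH_TRINUCLEOTIDES:
        f = _genome_ch_freq(genome)[t]
        w = model.ch_motif_weights.get(t, 0.0)
        m = min(lvl * (w / f) if f > 0 else 0.0, 0.6)
        shares[t] = f * (m + (1 - m) * (1 - model.conversion_rate))
    z = sum(shares.values())
    return {t: v / z for t, v in shares.items()} if z else shares


def _genome_ch_freq(genome: SyntheticGenome) -> dict[str, float]:
    counts: dict[str, float] = {t: 0 for t in CH_TRINUCLEOTIDES}
    total = 0
    for chrom in genome.main_chroms:
        vc = genome.ch_sites[chrom]["tri"].value_counts()
        for t in CH_TRINUCLEOTIDES:
            counts[t] += int(vc.get(t, 0))
            total += int(vc.get(t, 0))
    return {t: c / total for t, c in counts.items()}


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CellSpec:
    cell_id: str
    tau: float
    cell_type: str = "germ"           # germ | somatic
    cycle: str = "G0"                 # G0 | S/G2/M
    coverage_fraction: float | None = None
    mapping_rate: float | None = None


@dataclass
class SyntheticCohort:
    genome: SyntheticGenome
    model: KineticModel
    specs: pd.DataFrame
    methylomes: dict[str, methio.CellMethylome]
    expression: pd.DataFrame            # genes x cells, raw counts
    truth_cells: pd.DataFrame
    truth_tiles: pd.DataFrame
    truth_genes: pd.DataFrame

    def sample_sheet(self, call_dir: str = "calls") -> pd.DataFrame:
        df = self.specs[["cell_id", "stage", "age_months", "mapping_rate"]].copy()
        df["call_file"] = [f"{call_dir}/{c}.CX_report.txt" for c in df["cell_id"]]
        return df


_STAGE_AGES = (0.03, 1.1, 2.5, 3.4, 5.0, 6.4, 8.5, 12.5)


def _stage_of(tau: float) -> tuple[str, float]:
    idx = min(int(tau * len(_STAGE_AGES)), len(_STAGE_AGES) - 1)
    return f"stage{idx + 1:02d}", _STAGE_AGES[idx]


def simulate_cells(
    genome: SyntheticGenome,
    model: KineticModel,
    n_cells: int = 60,
    depth: float = 1.0,
    coverage_fraction: float = 0.2,
    ch_coverage_fraction: float = 0.02,
    lambda_coverage_fraction: float = 0.5,
    both_strand_fraction: float = 0.15,
    seed: int = 0,
    cell_specs: list[CellSpec] | None = None,
) -> SyntheticCohort:
    """Draw a cohort of synthetic single-cell methylomes plus expression.

    Each cell observes a Bernoulli subsample of CpG dyads (and CH and lambda
    cytosines) at roughly ``depth`` calls per covered site; a covered dyad is
    reported on one strand, or on both with probability
    ``both_strand_fraction``. Methylated-call probabilities follow the
    kinetic model through the one-sided conversion-error channel.
    """
    model.validate()
    if cell_specs is None and n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0 < coverage_fraction <= 1:
        raise ValueError("coverage_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)

    if cell_specs is None:
        specs = []
        for i in range(n_cells):
            tau = float(rng.random())
            somatic = rng.random() < model.somatic_fraction
            mitotic = (not somatic) and rng.random() < model.mitotic_fraction
            specs.append(
                CellSpec(
                    cell_id=f"cell{i:03d}",
                    tau=tau,
                    cell_type="somatic" if somatic else "germ",
                    cycle="S/G2/M" if mitotic else "G0",
                )
            )
    else:
        specs = cell_specs

    # per-site motif factors for this model's weights
    freq = _genome_ch_freq(genome)
    factor = {
        t: (model.ch_motif_weights.get(t, 0.0) / freq[t] if freq[t] > 0 else 0.0)
        for t in CH_TRINUCLEOTIDES
    }

    methylomes: dict[str, methio.CellMethylome] = {}
    sheet_rows = []
    for spec in specs:
        cov = spec.coverage_fraction if spec.coverage_fraction is not None else coverage_fraction
        mrate = (
            spec.mapping_rate
            if spec.mapping_rate is not None
            else float(np.round(rng.uniform(0.5, 0.85), 3))
        )
        frames = []
        lv = model.code_levels(spec.cell_type, spec.tau, mitotic=spec.cycle != "G0")
        for chrom in genome.main_chroms:
            dy = genome.dyads[chrom]
            keep = rng.random(dy.size) < cov
            pos = dy[keep]
            m = lv[genome.dyad_class[chrom][keep]]
            u = rng.random(pos.size)
            both = u < both_strand_fraction
            plus_only = (~both) & (u < both_strand_fraction + (1 - both_strand_fraction) / 2)
            for strand, mask, tri_arr, offset in (
                ("+", both | plus_only, genome.dyad_tri_plus[chrom], 0),
                ("-", both | ~(both | plus_only), genome.dyad_tri_minus[chrom], 1),
            ):
                if not mask.any():
                    continue
                frames.append(
                    _draw_calls(
                        rng, chrom, pos[mask] + offset, strand,
                        tri_arr[keep][mask], "CG", m[mask], model, depth,
                    )
                )
            ch = genome.ch_sites[chrom]
            keep_ch = rng.random(len(ch)) < ch_coverage_fraction
            sub = ch[keep_ch]
            if spec.cell_type == "somatic":
                mch = np.full(len(sub), model.ch_somatic_level)
            else:
                base = float(model.ch_level(spec.tau))
                mch = np.clip(base * sub["tri"].map(factor).to_numpy(float), 0.0, 0.6)
            frames.append(
                _draw_calls(
                    rng, chrom, sub["pos"].to_numpy(), sub["strand"].to_numpy(),
                    sub["tri"].to_numpy(), sub["context"].to_numpy(), mch, model, depth,
                )
            )
        lam = genome.lambda_sites
        keep_l = rng.random(len(lam)) < lambda_coverage_fraction
        sub = lam[keep_l]
        frames.append(
            _draw_calls(
                rng, genome.lambda_name, sub["pos"].to_numpy(), sub["strand"].to_numpy(),
                sub["tri"].to_numpy(), sub["context"].to_numpy(),
                np.zeros(len(sub)), model, depth,
            )
        )
        calls = (
            pd.concat(frames, ignore_index=True)
            .sort_values(["chrom", "pos", "strand"], kind="stable", ignore_index=True)
        )
        methylomes[spec.cell_id] = methio.CellMethylome(spec.cell_id, calls)
        stage, age = _stage_of(spec.tau)
        sheet_rows.append(
            dict(
                cell_id=spec.cell_id, tau=spec.tau, cell_type=spec.cell_type,
                cycle=spec.cycle, stage=stage, age_months=age, mapping_rate=mrate,
            )
        )
    specs_df = pd.DataFrame(sheet_rows)

    expression = _simulate_expression(genome, specs_df, rng)

    truth_cells = specs_df[["cell_id", "tau", "cell_type", "cycle"]].copy()
    truth_cells["expected_global"] = [
        expected_global_level(genome, model, r.tau, r.cell_type)
        for r in truth_cells.itertuples()
    ]
    truth_genes = genome.gene_models[
        ["gene_id", "Chromosome", "Start", "End", "kinetic_class", "expr_tier"]
    ].copy()
    return SyntheticCohort(
        genome=genome, model=model, specs=specs_df, methylomes=methylomes,
        expression=expression, truth_cells=truth_cells,
        truth_tiles=genome.tile_truth.copy(), truth_genes=truth_genes,
    )


def _draw_calls(rng, chrom, pos, strand, tri, context, m, model: KineticModel, depth: float):
    n = pos.shape[0] if hasattr(pos, "shape") else len(pos)
    if depth <= 1.0:
        n_calls = np.ones(n, dtype=np.int64)
    else:
        n_calls = 1 + rng.poisson(depth - 1.0, size=n)
    p = model.observed(m)
    n_meth = rng.binomial(n_calls, p)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(pos, dtype=np.int64),
            "strand": strand,
            "n_meth": n_meth,
            "n_unmeth": n_calls - n_meth,
            "context": context,
            "tri": tri,
        }
    )


_TIER_MEANS = {"high": 60.0, "mid": 15.0, "low": 3.0}


def _simulate_expression(genome, specs_df: pd.DataFrame, rng) -> pd.DataFrame:
    genes = list(genome.gene_models["gene_id"])
    tiers = dict(zip(genome.gene_models["gene_id"], genome.gene_models["expr_tier"]))
    special = [MAINTENANCE_MARKER, *CYCLE_GENES]
    background = [f"BG{i:02d}" for i in range(1, 21)]
    all_genes = genes + special + background
    mat = np.zeros((len(all_genes), len(specs_df)), dtype=np.int64)
    lib = np.exp(rng.normal(0.0, 0.3, size=len(specs_df)))
    for j, row in enumerate(specs_df.itertuples()):
        mitotic = row.cycle != "G0"
        means = []
        for g in genes:
            means.append(_TIER_MEANS[tiers[g]])
        means.append(50.0 if mitotic else 0.5)        # DNMT1-like marker
        means.extend([40.0 if mitotic else 0.2] * len(CYCLE_GENES))
        means.extend([10.0] * len(background))
        mat[:, j] = rng.poisson(np.asarray(means) * lib[j])
    return pd.DataFrame(mat, index=all_genes, columns=list(specs_df["cell_id"]))


# ---------------------------------------------------------------------------
# fixture emission


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def emit_fixture(cohort: SyntheticCohort, out_dir) -> pd.DataFrame:
    """Write the cohort to disk (FASTA, BEDs, call files, sheets, truth) and
    return a manifest of every file with its sha256 checksum."""
    out = Path(out_dir)
    (out / "calls").mkdir(parents=True, exist_ok=True)
    write_fasta(cohort.genome.sequences, out / "genome.fa")
    ann = methio.AnnotationSet(cohort.genome.annotations)
    ann.write_beds(out / "beds")
    for cid, cm in cohort.methylomes.items():
        methio.write_cytosine_report(cm.calls, out / "calls" / f"{cid}.CX_report.txt")
    methio.write_sample_sheet(cohort.sample_sheet(), out / "sample_sheet.tsv")
    cohort.expression.rename_axis("gene_id").to_csv(out / "expression.tsv", sep="\t")
    cohort.truth_cells.to_csv(out / "truth_cells.tsv", sep="\t", index=False, float_format="%.6g")
    cohort.truth_tiles.to_csv(out / "truth_tiles.tsv", sep="\t", index=False)
    cohort.truth_genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)

    rows = []
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.tsv":
            rows.append((str(p.relative_to(out)), _sha256(p)))
    manifest = pd.DataFrame(rows, columns=["path", "sha256"])
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_manifest(out_dir) -> bool:
    """Re-checksum an emitted fixture; raises :class:`ManifestError` naming
    every missing or modified file."""
    out = Path(out_dir)
    manifest = pd.read_csv(out / "manifest.tsv", sep="\t")
    bad = []
    for row in manifest.itertuples():
        p = out / row.path
        if not p.is_file():
            bad.append(f"missing: {row.path}")
        elif _sha256(p) != row.sha256:
            bad.append(f"modified: {row.path}")
    if bad:
        raise ManifestError("; ".join(bad))
    return True
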