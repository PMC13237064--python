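"""End-to-end pipeline over an emitted fixture directory.

Wires the stages together for the CLI: load call files and annotations,
QC-filter the cells, group them by global methylation, and run the tile
kinetic, context and non-CG motif analyses, writing one TSV per result.
All stage parameters come from a YAML config; every stage can also be used
directly from Python through the underlying module functions.
"""

from __future__ import annotations

import logging
import sys
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cellgroups, contexts, kinetics, methio, qcfilter, simgen

log = logging.getLogger("scbskit")

DEFAULTS = {
    "scheme": "marmoset",
    "species": "marmoset",
    "lambda_contig": "lambda",
    "tile_size": 500_000,
    "min_sites": 50,
    "gene_min_sites": 20,
    "coverage_min": 0.01,
    "somatic_threshold": 0.25,
    "min_dmr_sites": 5,
    "mask_halfwidth": 2000,
    "low_cpg_oe": 0.4,
    "seed": 0,
}

BED_CATEGORIES = (
    "gene", "exon", "intron", "promoter", "cgi", "atac_peak",
    "line", "ltr", "imprint_dmr",
)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    merged = dict(DEFAULTS)
    merged.update(cfg)
    return merged


def _setup_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    log.setLevel(logging.INFO)
    for h in list(log.handlers):
        log.removeHandler(h)
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(out_dir / "run.log")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


class Pipeline:
    """Lazy stage runner over one fixture directory."""

    def __init__(self, config: dict):
        self.cfg = config
        self.fixture = Path(config["fixture_dir"])
        self.out = Path(config.get("out_dir", self.fixture / "results"))
        _setup_logging(self.out)
        log.info(
            "scbskit %s | seed=%s | scheme=%s | fixture=%s",
            _safe_version(), config.get("seed"), config.get("scheme"), self.fixture,
        )
        self._cells = None
        self._sheet = None
        self._annotations = None
        self._sequences = None
        self._qc = None
        self._scheme = None

    # ---------------- loading

    @property
    def sheet(self) -> pd.DataFrame:
        if self._sheet is None:
            self._sheet = methio.read_sample_sheet(self.fixture / "sample_sheet.tsv")
        return self._sheet

    @property
    def cells(self) -> dict[str, methio.CellMethylome]:
        if self._cells is None:
            self._cells = {}
            for row in self.sheet.itertuples():
                path = self.fixture / row.call_file
                self._cells[row.cell_id] = methio.read_cytosine_report(
                    path, dialect="cytosine_report", cell_id=row.cell_id
                )
            log.info("loaded %d call files", len(self._cells))
        return self._cells

    @property
    def sequences(self) -> dict[str, str]:
        if self._sequences is None:
            import pyfaidx

            fa = pyfaidx.Fasta(str(self.fixture / "genome.fa"))
            self._sequences = {name: str(fa[name][:]) for name in fa.keys()}
        return self._sequences

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def annotations(self) -> methio.AnnotationSet:
        if self._annotations is None:
            paths = {
                cat: self.fixture / "beds" / f"{cat}.bed"
                for cat in BED_CATEGORIES
                if (self.fixture / "beds" / f"{cat}.bed").exists()
            }
            ann = methio.AnnotationSet.from_bed_files(paths)
            main = {
                c: n for c, n in self.chrom_sizes.items()
                if c != self.cfg["lambda_contig"]
            }
            ann.derive(main, flank_size=self.cfg.get("flank_size", 2000))
            self._annotations = ann
        return self._annotations

    @property
    def gene_models(self) -> pd.DataFrame:
        genes = self.annotations.frames["gene"].rename(columns={"Name": "gene_id"})
        prom = self.annotations.frames["promoter"].rename(columns={"Name": "gene_id"})
        prom = prom[["gene_id", "Start", "End"]].rename(
            columns={"Start": "prom_start", "End": "prom_end"}
        )
        return genes.merge(prom, on="gene_id", how="left")

    @property
    def expression(self) -> pd.DataFrame | None:
        p = self.fixture / "expression.tsv"
        if not p.exists():
            return None
        return pd.read_csv(p, sep="\t", index_col=0)

    def genome_cpg_count(self) -> int:
        return sum(
            seq.count("CG")
            for name, seq in self.sequences.items()
            if name != self.cfg["lambda_contig"]
        )

    # ---------------- stages

    def run_qc(self) -> pd.DataFrame:
        if self._qc is None:
            dmrs = self.annotations.frames["imprint_dmr"]
            qcs = qcfilter.qc_cells(
                self.cells, self.sheet, self.genome_cpg_count(), dmrs,
                lambda_contig=self.cfg["lambda_contig"],
                somatic_threshold=self.cfg["somatic_threshold"],
                min_dmr_sites=self.cfg["min_dmr_sites"],
            )
            table = qcfilter.apply_exclusions(self.sheet, qcs, self.cfg["coverage_min"])
            table.to_csv(self.out / "qc_cells.tsv", sep="\t", index=False)
            log.info("QC: %d/%d cells retained", int(table["included"].sum()), len(table))
            self._qc = table
        return self._qc

    def included_cells(self) -> dict[str, methio.CellMethylome]:
        qc = self.run_qc()
        keep = set(qc.loc[qc["included"], "cell_id"])
        return {c: m for c, m in self.cells.items() if c in keep}

    def run_group(self) -> cellgroups.MethylGroupScheme:
        if self._scheme is None:
            cells = self.included_cells()
            levels = {
                c: cellgroups.global_cpg_methylation(m, self.cfg["lambda_contig"])
                for c, m in cells.items()
            }
            scheme = cellgroups.assign_groups(levels, self.cfg["scheme"])
            pd.DataFrame(
                {
                    "cell_id": list(levels),
                    "level": [levels[c] for c in levels],
                    "group": [scheme.assignment[c] for c in levels],
                }
            ).to_csv(self.out / "cell_levels.tsv", sep="\t", index=False)
            pd.Series(scheme.counts(), name="n_cells").rename_axis("group").to_csv(
                self.out / "group_counts.tsv", sep="\t"
            )
            expr = self.expression
            if expr is not None:
                expr = expr[[c for c in expr.columns if c in scheme.assignment]]
                summary, missing = cellgroups.summarize_expression_by_group(expr, scheme)
                summary.rename_axis("gene_id").to_csv(self.out / "expr_by_group.tsv", sep="\t")
                if missing:
                    log.warning("expression summary: %d genes missing", len(missing))
                cyc = [g for g in self.cfg.get("cycle_genes", simgen.CYCLE_GENES)]
                try:
                    calls = cellgroups.mitotic_index(expr, cyc, seed=self.cfg["seed"])
                    calls.to_csv(self.out / "cycle_calls.tsv", sep="\t", index=False)
                except ValueError as exc:
                    log.warning("mitotic index skipped: %s", exc)
            self._scheme = scheme
        return self._scheme

    def scoring_pairs(self):
        sp = kinetics.SCORING_PAIRS[self.cfg["species"]]
        return sp[0], sp[1]

    def run_kinetics(self) -> kinetics.TileKinetics:
        scheme = self.run_group()
        cells = self.included_cells()
        early, late = self.scoring_pairs()
        main = {c: n for c, n in self.chrom_sizes.items() if c != self.cfg["lambda_contig"]}
        tk = kinetics.tile_group_means(
            cells, scheme, main, self.cfg["tile_size"], self.cfg["min_sites"],
            exclude=(self.cfg["lambda_contig"],),
        )
        tk = kinetics.kinetic_score_and_classify(tk, early, late)
        tk.tiles.to_csv(self.out / "tile_means.tsv", sep="\t", index=False, float_format="%.6g")
        bed = tk.classified()
        pd.DataFrame(
            {
                "chrom": bed["Chromosome"], "start": bed["Start"], "end": bed["End"],
                "name": bed["class"],
                "score": (bed["score"] * 1000).round().astype(int),
                "strand": ".",
            }
        ).to_csv(self.out / "tile_kinetics.bed", sep="\t", header=False, index=False)
        try:
            enr = kinetics.annotation_enrichment(
                tk, self.annotations, seed=self.cfg["seed"],
                categories=[c for c in self.annotations.categories() if c != "imprint_dmr"],
            )
        except ValueError as exc:
            log.warning("annotation enrichment skipped: %s", exc)
            enr = pd.DataFrame(
                columns=["category", "class", "observed_bp", "expected_bp",
                         "class_fraction", "enrichment_ratio", "chi2", "df", "p",
                         "significant", "method"]
            )
        enr.to_csv(self.out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        gk = kinetics.gene_body_kinetics(
            cells, scheme, self.gene_models, self.annotations.frames.get("atac_peak"),
            early, late, min_sites=self.cfg["gene_min_sites"],
            exclude=(self.cfg["lambda_contig"],),
        )
        gk.to_csv(self.out / "gene_kinetics.tsv", sep="\t", index=False, float_format="%.6g")
        return tk

    def run_contexts(self) -> None:
        scheme = self.run_group()
        cells = self.included_cells()
        excl = (self.cfg["lambda_contig"],)
        profile = contexts.context_methylation_profile(
            cells, scheme, self.annotations, exclude=excl
        )
        profile.to_csv(self.out / "context_profile.tsv", sep="\t", index=False, float_format="%.6g")
        ann = self.annotations
        kept = contexts.filter_low_cpg_promoters(
            ann.frames["promoter"], self.sequences, self.cfg["low_cpg_oe"]
        )
        masked_ann = methio.AnnotationSet(
            {**{k: v for k, v in ann.frames.items()}, "promoter": kept}
        )
        masked = contexts.mask_active_regions(
            cells, scheme, masked_ann, halfwidth=self.cfg["mask_halfwidth"], exclude=excl
        )
        masked.to_csv(self.out / "masked_means.tsv", sep="\t", index=False, float_format="%.6g")
        expr = self.expression
        if expr is not None:
            tc = contexts.expression_tertile_analysis(
                expr, cells, scheme, self.gene_models, exclude=excl,
                min_genes=self.cfg.get("tertile_min_genes", 3),
            )
            tests = tc.tests if tc is not None else pd.DataFrame(
                columns=["group", "pair", "n1", "n2", "median1", "median2", "p", "q"]
            )
            tests.to_csv(self.out / "tertile_tests.tsv", sep="\t", index=False, float_format="%.6g")

    def run_noncg(self) -> None:
        scheme = self.run_group()
        cells = self.included_cells()
        mp = contexts.noncg_motif_profile(cells, scheme, self.cfg["lambda_contig"])
        mp.summary.to_csv(self.out / "motif_profile.tsv", sep="\t", index=False, float_format="%.6g")
        mp.ch_tri_shares.to_csv(self.out / "motif_ch_tri.tsv", sep="\t", float_format="%.6g")
        mp.ch_dinuc_shares.to_csv(self.out / "motif_ch_dinuc.tsv", sep="\t", float_format="%.6g")
        mp.cg_tri_shares.to_csv(self.out / "motif_cg_tri.tsv", sep="\t", float_format="%.6g")

    def run_all(self) -> None:
        self.run_qc()
        self.run_group()
        self.run_kinetics()
        self.run_contexts()
        self.run_noncg()


def simulate_from_config(config: dict) -> Path:
    """Run the generator per the config's ``simulate`` block and emit a fixture."""
    sim = dict(config.get("simulate") or {})
    seed = int(sim.pop("seed", config.get("seed", 0)))
    gc_keys = {f.name for f in simgen.GenomeConfig.__dataclass_fields__.values()}
    km_keys = {f.name for f in simgen.KineticModel.__dataclass_fields__.values()}
    genome_cfg = simgen.GenomeConfig(**{k: v for k, v in sim.items() if k in gc_keys})
    model = simgen.KineticModel(**{k: v for k, v in sim.items() if k in km_keys})
    sim_kwargs = {
        k: sim[k]
        for k in ("n_cells", "depth", "coverage_fraction", "ch_coverage_fraction",
                  "lambda_coverage_fraction", "both_strand_fraction")
        if k in sim
    }
    genome = simgen.build_genome(genome_cfg, seed=seed)
    cohort = simgen.simulate_cells(genome, model, seed=seed + 1, **sim_kwargs)
    out = Path(config["fixture_dir"])
    simgen.emit_fixture(cohort, out)
    log.info("fixture emitted to %s", out)
    return out


def _safe_version() -> str:
    try:
        return _pkg_version("scbskit")
    except Exception:
        return "dev"
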