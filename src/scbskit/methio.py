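"""On-disk formats and the central per-cell methylation call table.

Single-cell bisulfite pipelines leave one cytosine-level call file per cell
(Bismark ``coverage2cytosine`` report or the simpler ``coverage`` dialect).
This module reads and writes those files, merges CpG calls across the two DNA
strands into dyads, and loads the genome annotation BEDs that every
downstream stage queries.

Coordinate conventions: cytosine reports are 1-based (Bismark), BED is
0-based half-open. Everything in memory is 0-based half-open; conversion
happens only at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pyranges as pr

from . import intervals

log = logging.getLogger("scbskit")

#: column order of a Bismark-style cytosine report (no header on disk)
REPORT_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "tri"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Malformed row in an on-disk table; carries the 1-based line number."""


class MissingReferenceError(ValueError):
    """An operation needed a genome FASTA that was not supplied."""


def context_from_tri(tri: str) -> str:
    if tri[1] == "G":
        return "CG"
    return "CHG" if tri[2] == "G" else "CHH"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# per-cell call tables


def merge_cpg_strands(calls: pd.DataFrame) -> pd.DataFrame:
    """Merge CG-context calls from both strands into CpG dyads.

    A dyad is keyed by the 0-based position of its plus-strand C; the minus
    strand C sits one bp downstream. Counts from the two strands are summed;
    dyads covered on only one strand keep that strand's counts.
    """
    cg = calls[calls["context"] == "CG"]
    if cg.empty:
        return pd.DataFrame(columns=["chrom", "start", "n_meth", "n_unmeth"])
    start = np.where(cg["strand"].to_numpy() == "+", cg["pos"], cg["pos"] - 1)
    merged = (
        pd.DataFrame(
            {
                "chrom": cg["chrom"].to_numpy(),
                "start": start,
                "n_meth": cg["n_meth"].to_numpy(),
                "n_unmeth": cg["n_unmeth"].to_numpy(),
            }
        )
        .groupby(["chrom", "start"], as_index=False, sort=True)
        .sum()
    )
    return merged


@dataclass
class CellMethylome:
    """All cytosine calls of one cell plus the strand-merged CpG table."""

    cell_id: str
    calls: pd.DataFrame  # REPORT_COLUMNS with 0-based ``pos``
    _cpg: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def cpg_merged(self) -> pd.DataFrame:
        if self._cpg is None:
            self._cpg = merge_cpg_strands(self.calls)
        return self._cpg

    def cpg_on(self, chrom_whitelist=None, exclude=()) -> pd.DataFrame:
        df = self.cpg_merged
        if chrom_whitelist is not None:
            df = df[df["chrom"].isin(chrom_whitelist)]
        if exclude:
            df = df[~df["chrom"].isin(exclude)]
        return df


def validate_calls(df: pd.DataFrame, path: str = "<memory>") -> None:
    if df.empty:
        return
    bad = (df["n_meth"] < 0) | (df["n_unmeth"] < 0)
    bad |= ~df["strand"].isin(["+", "-"])
    bad |= df["tri"].str.len() != 3
    bad |= ~df["tri"].str.startswith("C") & ~df["tri"].str.contains("N")
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ParseError(f"{path}: malformed call at line {line}")


def read_cytosine_report(
    path,
    dialect: str = "cytosine_report",
    genome_fasta=None,
    cell_id: str | None = None,
) -> CellMethylome:
    """Read one cell's calls from a Bismark-style file.

    ``cytosine_report`` files carry strand/context/trinucleotide columns;
    ``coverage`` files do not, so that dialect needs ``genome_fasta`` (a path
    or a :class:`pyfaidx.Fasta`) to look the context up.
    """
    path = Path(path)
    cid = cell_id or path.stem.split(".")[0]
    if dialect == "cytosine_report":
        try:
            df = pd.read_csv(
                path,
                sep="\t",
                header=None,
                names=REPORT_COLUMNS,
                dtype={
                    "chrom": str,
                    "pos": np.int64,
                    "strand": str,
                    "n_meth": np.int64,
                    "n_unmeth": np.int64,
                    "context": str,
                    "tri": str,
                },
            )
        except pd.errors.EmptyDataError:
            log.warning("%s: empty call file, returning empty methylome", path)
            return CellMethylome(cid, pd.DataFrame(columns=REPORT_COLUMNS))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        if df.empty:
            log.warning("%s: empty call file, returning empty methylome", path)
        df["pos"] = df["pos"] - 1  # to 0-based
        validate_calls(df, str(path))
        return CellMethylome(cid, df)
    if dialect == "coverage":
        if genome_fasta is None:
            raise MissingReferenceError(
                "coverage dialect has no strand/context columns; pass genome_fasta"
            )
        try:
            cov = pd.read_csv(
                path,
                sep="\t",
                header=None,
                names=["chrom", "start", "end", "pct", "n_meth", "n_unmeth"],
                dtype={"chrom": str},
            )
        except pd.errors.EmptyDataError:
            log.warning("%s: empty call file, returning empty methylome", path)
            return CellMethylome(cid, pd.DataFrame(columns=REPORT_COLUMNS))
        fasta = _open_fasta(genome_fasta)
        rows = _annotate_coverage_rows(cov, fasta, str(path))
        validate_calls(rows, str(path))
        return CellMethylome(cid, rows)
    raise ValueError(f"unknown dialect {dialect!r}")


def _open_fasta(genome_fasta):
    import pyfaidx

    if isinstance(genome_fasta, (str, Path)):
        return pyfaidx.Fasta(str(genome_fasta))
    return genome_fasta


def _annotate_coverage_rows(cov: pd.DataFrame, fasta, path: str) -> pd.DataFrame:
    strands, tris, ctxs = [], [], []
    for i, row in enumerate(cov.itertuples(index=False)):
        p = int(row.start) - 1  # coverage files are 1-based
        seq = str(fasta[row.chrom][max(p - 2, 0) : p + 3]).upper()
        off = p - max(p - 2, 0)
        base = seq[off] if off < len(seq) else "N"
        if base == "C":
            tri = (seq[off : off + 3] + "NN")[:3]
            strand = "+"
        elif base == "G":
            tri = revcomp(("NN" + seq)[off : off + 3] if off < 2 else seq[off - 2 : off + 1])
            strand = "-"
        else:
            raise ParseError(f"{path}: line {i + 1} reference base {base!r} is not a cytosine")
        strands.append(strand)
        tris.append(tri)
        ctxs.append(context_from_tri(tri))
    return pd.DataFrame(
        {
            "chrom": cov["chrom"],
            "pos": cov["start"].to_numpy(np.int64) - 1,
            "strand": strands,
            "n_meth": cov["n_meth"].to_numpy(np.int64),
            "n_unmeth": cov["n_unmeth"].to_numpy(np.int64),
            "context": ctxs,
            "tri": tris,
        }
    )


def write_cytosine_report(calls: pd.DataFrame, path) -> None:
    """Write calls (0-based in memory) as a 1-based headerless Bismark report."""
    out = calls[REPORT_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# sample sheet

SHEET_COLUMNS = ["cell_id", "stage", "age_months", "mapping_rate", "call_file"]


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "stage": str})
    missing = set(SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ParseError(f"{path}: duplicate cell_id {dup!r}")
    if ((df["mapping_rate"] < 0) | (df["mapping_rate"] > 1)).any():
        raise ParseError(f"{path}: mapping_rate outside [0, 1]")
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df[SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotations


class AnnotationSet:
    """Per-category genomic interval store with overlap/membership queries.

    Categories mirror the annotation tracks used in this analysis: exon,
    intron, gene, promoter, cgi, atac_peak, line, ltr, imprint_dmr, plus the
    derived ``flanking`` (gene bodies +/- N kb) and ``intergenic``
    (complement of gene bodies and flanks) when not supplied explicitly.
    """

    def __init__(self, frames: dict[str, pd.DataFrame]):
        self.frames: dict[str, pd.DataFrame] = {}
        self._merged_cache: dict[str, dict] = {}
        for cat, df in frames.items():
            df = df.copy().reset_index(drop=True)
            df["Chromosome"] = df["Chromosome"].astype(str)
            intervals.as_pyranges(df[intervals.BED_COLS])  # bounds validation
            self.frames[cat] = df

    @classmethod
    def from_bed_files(cls, paths: dict[str, str]) -> "AnnotationSet":
        frames = {}
        for cat, p in paths.items():
            gr = pr.read_bed(str(p))
            frames[cat] = gr.df
        return cls(frames)

    def categories(self) -> list[str]:
        return list(self.frames)

    def ranges(self, category: str) -> pr.PyRanges:
        return intervals.as_pyranges(self.frames[category][intervals.BED_COLS])

    def merged(self, category: str):
        if category not in self._merged_cache:
            self._merged_cache[category] = intervals.merged_arrays(self.ranges(category))
        return self._merged_cache[category]

    def mask(self, category: str, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Membership of 0-based positions in a category's merged footprint."""
        return intervals.positions_in(self.merged(category), chrom, pos)

    def footprint_bp(self, category: str) -> int:
        return intervals.footprint_bp(self.ranges(category))

    def derive(
        self,
        chrom_sizes: dict[str, int],
        flank_size: int = 2000,
        exclude_chroms: tuple[str, ...] = (),
    ) -> None:
        """Fill in ``flanking`` and ``intergenic`` from gene bodies if absent."""
        if "gene" not in self.frames:
            raise ValueError("deriving flanking/intergenic requires a 'gene' category")
        genes = self.ranges("gene")
        if "flanking" not in self.frames:
            fl = intervals.flanks(genes, flank_size, chrom_sizes)
            self.frames["flanking"] = fl.df if len(fl) else pd.DataFrame(columns=intervals.BED_COLS)
        if "intergenic" not in self.frames:
            footprint_df = pd.concat(
                [self.frames["gene"][intervals.BED_COLS], self.frames["flanking"][intervals.BED_COLS]],
                ignore_index=True,
            )
            if footprint_df.empty:
                inter = intervals.complement(
                    pr.PyRanges(pd.DataFrame(columns=intervals.BED_COLS)), chrom_sizes, exclude_chroms
                )
            else:
                inter = intervals.complement(
                    intervals.as_pyranges(footprint_df), chrom_sizes, exclude_chroms
                )
            self.frames["intergenic"] = (
                inter.df if len(inter) else pd.DataFrame(columns=intervals.BED_COLS)
            )
        self._merged_cache.clear()

    def write_beds(self, out_dir) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = {}
        for cat, df in self.frames.items():
            p = out_dir / f"{cat}.bed"
            bed = df.copy()
            if "Name" not in bed.columns:
                bed["Name"] = cat
            if "Score" not in bed.columns:
                bed["Score"] = 0
            if "Strand" not in bed.columns:
                bed["Strand"] = "+"
            bed = bed.sort_values(["Chromosome", "Start"])
            bed[["Chromosome", "Start", "End", "Name", "Score", "Strand"]].to_csv(
                p, sep="\t", header=False, index=False
            )
            written[cat] = p
        return written
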