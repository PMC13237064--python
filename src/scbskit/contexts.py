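"""Context-resolved methylation profiles, active-region masking, expression
tertiles and non-CG motif analysis.

"Active regions" are the regulatory elements that stay unmethylated while
the rest of the genome gains methylation: promoters (excluding low-CpG
promoters), CpG islands and ATAC peaks. Masking them — each element plus a
window of +/- 2 kb around its midpoint — shows how much they pull the
genome-wide average down. Non-CG (CH) methylation is profiled per group as
the fraction of methylated calls among CH cytosines, with the methylated
calls broken down by trinucleotide motif (CAC/CAG are the DNMT3A/DNMT3B
preferences).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import intervals, methio
from .cellgroups import MethylGroupScheme, normalize_expression
from .kinetics import dyad_observations

log = logging.getLogger("scbskit")

ACTIVE_CATEGORIES = ("promoter", "cgi", "atac_peak")
CH_DINUCLEOTIDES = ("CA", "CC", "CT")
CGN_TRIS = ("CGA", "CGC", "CGG", "CGT")


# ---------------------------------------------------------------------------
# context profiles


def context_methylation_profile(
    cells: dict[str, methio.CellMethylome],
    scheme: MethylGroupScheme,
    annotations: methio.AnnotationSet,
    categories: list[str] | None = None,
    exclude: tuple[str, ...] = ("lambda",),
) -> pd.DataFrame:
    """Mean methylation per annotation category per group.

    Every covered dyad observation inside a category's merged footprint
    contributes once to that category (a dyad under overlapping categories
    counts in each). A ``genome_wide`` meta-category is always included.
    Categories with zero covered sites in a group are reported with NaN.
    """
    obs = dyad_observations(cells, scheme, exclude=exclude)
    cats = categories or annotations.categories()
    rows = []
    gw = obs.groupby("group")["rate"].agg(["mean", "size"])
    for g in scheme.groups:
        rows.append(
            dict(
                category="genome_wide", group=g,
                mean=float(gw.loc[g, "mean"]) if g in gw.index else np.nan,
                n_sites=int(gw.loc[g, "size"]) if g in gw.index else 0,
            )
        )
    for cat in cats:
        merged = annotations.merged(cat)
        mask = np.zeros(len(obs), dtype=bool)
        for chrom, sub in obs.groupby("chrom"):
            mask[sub.index] = intervals.positions_in(merged, str(chrom), sub["start"].to_numpy())
        stats_ = obs[mask].groupby("group")["rate"].agg(["mean", "size"])
        for g in scheme.groups:
            rows.append(
                dict(
                    category=cat, group=g,
                    mean=float(stats_.loc[g, "mean"]) if g in stats_.index else np.nan,
                    n_sites=int(stats_.loc[g, "size"]) if g in stats_.index else 0,
                )
            )
    return pd.DataFrame(rows)


def filter_low_cpg_promoters(
    promoters: pd.DataFrame, sequences: dict[str, str], min_oe: float = 0.4
) -> pd.DataFrame:
    """Drop promoters whose observed/expected CpG ratio falls below ``min_oe``.

    o/e = (#CG / L) / ((#C / L) * (#G / L)) over the promoter interval;
    ``sequences`` maps chromosome name to its sequence string (a pyfaidx
    Fasta works too).
    """
    keep = []
    for i, row in enumerate(promoters.itertuples()):
        seq = str(sequences[row.Chromosome][row.Start : row.End]).upper()
        L = len(seq)
        if L == 0:
            keep.append(False)
            continue
        n_c, n_g = seq.count("C"), seq.count("G")
        n_cg = seq.count("CG")
        expected = n_c * n_g / L
        keep.append(expected > 0 and (n_cg / expected) >= min_oe)
    return promoters[np.asarray(keep, dtype=bool)]


def active_mask_intervals(
    annotations: methio.AnnotationSet,
    active: tuple[str, ...] = ACTIVE_CATEGORIES,
    halfwidth: int = 2000,
) -> dict:
    """Merged mask: each active element unioned with midpoint +/- halfwidth."""
    frames = []
    for cat in active:
        if cat not in annotations.frames:
            continue
        df = annotations.frames[cat][intervals.BED_COLS]
        if df.empty:
            continue
        frames.append(df)
        frames.append(intervals.midpoint_windows(df, halfwidth))
    if not frames:
        return {}
    return intervals.merged_arrays(
        intervals.as_pyranges(pd.concat(frames, ignore_index=True))
    )


def mask_active_regions(
    cells: dict[str, methio.CellMethylome],
    scheme: MethylGroupScheme,
    annotations: methio.AnnotationSet,
    active: tuple[str, ...] = ACTIVE_CATEGORIES,
    halfwidth: int = 2000,
    exclude: tuple[str, ...] = ("lambda",),
) -> pd.DataFrame:
    """Genome-wide means per group before and after removing active regions.

    The mask is the union of every active element with a +/- ``halfwidth``
    window around its midpoint. Returns one row per group with unmasked
    mean, masked mean, and delta = masked - unmasked. To apply the low-CpG
    promoter exclusion, filter the annotation set's promoter frame first
    (see :func:`filter_low_cpg_promoters`).
    """
    obs = dyad_observations(cells, scheme, exclude=exclude)
    merged = active_mask_intervals(annotations, active, halfwidth)
    inmask = np.zeros(len(obs), dtype=bool)
    for chrom, sub in obs.groupby("chrom"):
        inmask[sub.index] = intervals.positions_in(merged, str(chrom), sub["start"].to_numpy())
    if inmask.all():
        raise ValueError("active-region mask covers every covered dyad")
    unmasked = obs.groupby("group")["rate"].agg(["mean", "size"])
    masked = obs[~inmask].groupby("group")["rate"].agg(["mean", "size"])
    rows = []
    for g in scheme.groups:
        u = float(unmasked.loc[g, "mean"]) if g in unmasked.index else np.nan
        m = float(masked.loc[g, "mean"]) if g in masked.index else np.nan
        rows.append(
            dict(
                group=g, unmasked_mean=u, masked_mean=m, delta=m - u,
                n_total=int(unmasked.loc[g, "size"]) if g in unmasked.index else 0,
                n_masked_out=int(unmasked.loc[g, "size"] - masked.loc[g, "size"])
                if g in unmasked.index and g in masked.index
                else 0,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression tertiles


@dataclass
class TertileComparison:
    tertiles: dict[str, list[str]]       # high/mid/low -> gene ids
    methylation: pd.DataFrame            # gene x group gene-body methylation
    tests: pd.DataFrame                  # group, pair, n, medians, p, q


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted q-values (monotone, q >= p elementwise)."""
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def expression_tertile_analysis(
    expr: pd.DataFrame,
    cells: dict[str, methio.CellMethylome],
    scheme: MethylGroupScheme,
    gene_models: pd.DataFrame,
    min_sites: int = 10,
    min_genes: int = 3,
    exclude: tuple[str, ...] = ("lambda",),
) -> TertileComparison | None:
    """Gene-body methylation compared across expression tertiles, per group.

    Genes are ranked by mean normalized expression over the scheme's cells
    and split into equal high/mid/low tertiles (ties broken by stable gene
    order). Within each group, every tertile pair is compared by a
    two-sided rank-sum test on per-gene gene-body methylation; p-values are
    BH-adjusted across all reported tests. Returns None (with a notice)
    when fewer than two tertiles are testable.
    """
    cohort_cells = [c for c in scheme.assignment if c in expr.columns]
    genes = [g for g in gene_models["gene_id"] if g in expr.index]
    if not genes or not cohort_cells:
        log.warning("tertile analysis skipped: no overlapping genes/cells")
        return None
    norm = normalize_expression(expr[cohort_cells])
    mean_expr = norm.loc[genes].mean(axis=1)

    # per-gene per-group gene-body methylation
    obs = dyad_observations(cells, scheme, exclude=exclude)
    by_chrom = {c: sub.sort_values("start", kind="stable") for c, sub in obs.groupby("chrom")}
    meth = {}
    gm = gene_models.set_index("gene_id")
    for g in genes:
        row = gm.loc[g]
        sub = by_chrom.get(row["Chromosome"])
        rec = {}
        if sub is not None:
            starts = sub["start"].to_numpy()
            lo, hi = np.searchsorted(starts, [row["Start"], row["End"]])
            window = sub.iloc[lo:hi].groupby("group")["rate"].agg(["mean", "size"])
            for grp in scheme.groups:
                if grp in window.index and window.loc[grp, "size"] >= min_sites:
                    rec[grp] = float(window.loc[grp, "mean"])
        meth[g] = rec
    meth_df = pd.DataFrame.from_dict(meth, orient="index").reindex(columns=scheme.groups)

    covered = [g for g in genes if not meth_df.loc[g].isna().all()]
    # descending expression; stable gene-id order breaks ties
    order = sorted(covered, key=lambda g: (-mean_expr[g], g))
    parts = np.array_split(np.asarray(order, dtype=object), 3)
    tertiles = {"high": list(parts[0]), "mid": list(parts[1]), "low": list(parts[2])}
    if sum(len(v) >= min_genes for v in tertiles.values()) < 2:
        log.warning("tertile analysis skipped: fewer than two testable tertiles")
        return None

    pairs = [("high", "mid"), ("high", "low"), ("mid", "low")]
    rows = []
    for grp in scheme.groups:
        for a, b in pairs:
            x = meth_df.loc[tertiles[a], grp].dropna()
            y = meth_df.loc[tertiles[b], grp].dropna()
            if len(x) < min_genes or len(y) < min_genes:
                continue
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            rows.append(
                dict(
                    group=grp, pair=f"{a}_vs_{b}", n1=len(x), n2=len(y),
                    median1=float(x.median()), median2=float(y.median()),
                    p=float(res.pvalue),
                )
            )
    tests = pd.DataFrame(rows)
    if len(tests):
        tests["q"] = benjamini_hochberg(tests["p"])
    return TertileComparison(tertiles=tertiles, methylation=meth_df, tests=tests)


# ---------------------------------------------------------------------------
# non-CG motifs


@dataclass
class MotifProfile:
    summary: pd.DataFrame      # group, cg_fraction, ch_fraction, n_cg_calls, n_ch_calls
    ch_tri_shares: pd.DataFrame    # group x CH trinucleotide (rows sum to 1)
    ch_dinuc_shares: pd.DataFrame  # group x {CAN, CCN, CTN}
    cg_tri_shares: pd.DataFrame    # group x {CGA, CGC, CGG, CGT}


def noncg_motif_profile(
    cells: dict[str, methio.CellMethylome],
    scheme: MethylGroupScheme,
    lambda_contig: str = "lambda",
    mode: str = "calls",
) -> MotifProfile:
    """Methylated-call fractions at CG and CH per group, with motif breakdowns.

    ``mode='calls'`` pools every sequenced call (each call counts once);
    ``mode='sites'`` binarizes per covered cytosine (a site counts as
    methylated when it carries at least one methylated call). CH pools the
    CHG and CHH contexts (per-strand, unmerged); calls whose trinucleotide
    contains an ambiguous base are dropped, as is the spike-in contig.
    """
    if mode not in ("calls", "sites"):
        raise ValueError("mode must be 'calls' or 'sites'")
    summary_rows, ch_share_rows, cg_share_rows = [], [], []
    for g in scheme.groups:
        frames = [
            cells[c].calls for c in scheme.members(g) if c in cells
        ]
        if frames:
            calls = pd.concat(frames, ignore_index=True)
            calls = calls[(calls["chrom"] != lambda_contig) & ~calls["tri"].str.contains("N")]
        else:
            calls = pd.DataFrame(columns=methio.REPORT_COLUMNS)
        is_cg = calls["context"] == "CG"
        cg, ch = calls[is_cg], calls[~is_cg]
        if mode == "calls":
            cg_meth, cg_tot = int(cg["n_meth"].sum()), int((cg["n_meth"] + cg["n_unmeth"]).sum())
            ch_meth, ch_tot = int(ch["n_meth"].sum()), int((ch["n_meth"] + ch["n_unmeth"]).sum())
            ch_by_tri = ch.groupby("tri")["n_meth"].sum()
            cg_by_tri = cg.groupby("tri")["n_meth"].sum()
        else:
            cg_meth, cg_tot = int((cg["n_meth"] > 0).sum()), len(cg)
            ch_meth, ch_tot = int((ch["n_meth"] > 0).sum()), len(ch)
            ch_by_tri = ch[ch["n_meth"] > 0].groupby("tri").size()
            cg_by_tri = cg[cg["n_meth"] > 0].groupby("tri").size()
        summary_rows.append(
            dict(
                group=g,
                cg_fraction=cg_meth / cg_tot if cg_tot else np.nan,
                ch_fraction=ch_meth / ch_tot if ch_tot else np.nan,
                n_cg_calls=cg_tot, n_ch_calls=ch_tot,
            )
        )
        ch_share_rows.append(_shares(ch_by_tri, g))
        cg_share_rows.append(_shares(cg_by_tri.reindex(CGN_TRIS).dropna(), g))
    summary = pd.DataFrame(summary_rows)
    ch_tri = pd.DataFrame(ch_share_rows).set_index("group").fillna(0.0)
    cg_tri = pd.DataFrame(cg_share_rows).set_index("group").fillna(0.0)
    dinuc = pd.DataFrame(
        {
            f"{d}N": ch_tri[[c for c in ch_tri.columns if c.startswith(d)]].sum(axis=1)
            for d in CH_DINUCLEOTIDES
        }
    )
    return MotifProfile(
        summary=summary, ch_tri_shares=ch_tri, ch_dinuc_shares=dinuc, cg_tri_shares=cg_tri
    )


def _shares(counts: pd.Series, group: str) -> dict:
    total = counts.sum()
    row = {"group": group}
    for tri, n in counts.items():
        row[tri] = n / total if total else np.nan
    return row
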