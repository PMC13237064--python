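"""Genome tiling, methylation-acquisition kinetics and annotation enrichment.

The genome is divided into fixed-size tiles (500 kb by default) and, for
each tile, the mean CpG methylation of every cell group is computed. The
kinetic score per tile is a difference of differences,

    S = (m[early_hi] - m[early_lo]) - (m[late_hi] - m[late_lo]),

e.g. (G3 - G1) - (G7 - G5): regions that gain most of their methylation
early score positive ("fast"), regions still climbing at the end score
negative ("slow"). Tiles are split into fast/intermediate/slow classes by
ascending-score tertiles (or a fixed threshold), and each annotation
category is tested for enrichment across the classes with a chi-squared
test on base-pair overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals, methio
from .cellgroups import MethylGroupScheme

#: species presets for the (early, late) scoring group pairs
SCORING_PAIRS = {
    "marmoset": (("G1", "G3"), ("G5", "G7")),
    "human": (("G1", "G3"), ("G5", "G7")),
    "cynomolgus": (("G1", "G2"), ("G3", "G5")),
}

CLASS_ORDER = ("slow", "intermediate", "fast")


def make_tiles(
    chrom_sizes: dict[str, int], tile_size: int = 500_000, exclude: tuple[str, ...] = ()
) -> pd.DataFrame:
    """Ordered fixed-size tiles covering each chromosome; last tile truncated."""
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        if chrom in exclude:
            continue
        for s in range(0, size, tile_size):
            rows.append((chrom, s, min(s + tile_size, size)))
    return pd.DataFrame(rows, columns=["Chromosome", "Start", "End"])


def dyad_observations(
    cells: dict[str, methio.CellMethylome],
    scheme: MethylGroupScheme,
    exclude: tuple[str, ...] = ("lambda",),
) -> pd.DataFrame:
    """Long table of per-cell covered-dyad rates with the cell's group label.

    One row per (cell, dyad): chrom, start, rate, group, cell_id. This is the
    pooled observation set every regional mean is computed from.
    """
    frames = []
    for cid, grp in scheme.assignment.items():
        if cid not in cells:
            continue
        cpg = cells[cid].cpg_on(exclude=exclude)
        if cpg.empty:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "chrom": cpg["chrom"].to_numpy(),
                    "start": cpg["start"].to_numpy(),
                    "rate": (cpg["n_meth"] / (cpg["n_meth"] + cpg["n_unmeth"])).to_numpy(),
                    "group": grp,
                    "cell_id": cid,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "rate", "group", "cell_id"])
    return pd.concat(frames, ignore_index=True)


@dataclass
class TileKinetics:
    """Per-tile group means/counts, kinetic scores and class labels."""

    tiles: pd.DataFrame          # Chromosome/Start/End + mean_<G>/n_<G> [+ score, class]
    groups: list[str]
    tile_size: int
    min_sites: int

    def classified(self) -> pd.DataFrame:
        return self.tiles[self.tiles["class"].notna() & (self.tiles["class"] != "unclassified")]


def tile_group_means(
    cells: dict[str, methio.CellMethylome],
    scheme: MethylGroupScheme,
    chrom_sizes: dict[str, int],
    tile_size: int = 500_000,
    min_sites: int = 50,
    weighting: str = "observation",
    exclude: tuple[str, ...] = ("lambda",),
) -> TileKinetics:
    """Group-mean methylation per tile.

    ``weighting='observation'`` pools every covered dyad-cell observation
    with equal weight; ``'cell'`` averages per-cell tile means instead.
    Tile/group combinations with fewer than ``min_sites`` observations are
    left undefined (NaN mean).
    """
    nonempty = [g for g in scheme.groups if scheme.members(g)]
    if len(nonempty) < 2:
        raise ValueError("need at least two nonempty groups")
    obs = dyad_observations(cells, scheme, exclude=exclude)
    tiles = make_tiles(chrom_sizes, tile_size, exclude=exclude)
    obs["tile"] = obs["start"] // tile_size
    key = obs["chrom"].astype(str) + ":" + obs["tile"].astype(str)
    tiles_key = tiles["Chromosome"].astype(str) + ":" + (tiles["Start"] // tile_size).astype(str)

    if weighting == "observation":
        agg = obs.groupby([key, obs["group"]])["rate"].agg(["mean", "size"])
    elif weighting == "cell":
        per_cell = obs.groupby([key, obs["group"], obs["cell_id"]])["rate"].agg(["mean", "size"])
        agg = per_cell.groupby(level=[0, 1]).agg(mean=("mean", "mean"), size=("size", "sum"))
    else:
        raise ValueError("weighting must be 'observation' or 'cell'")

    out = tiles.copy()
    for g in scheme.groups:
        means = pd.Series(np.nan, index=tiles_key)
        ns = pd.Series(0, index=tiles_key, dtype=np.int64)
        if g in agg.index.get_level_values(1):
            sub = agg.xs(g, level=1)
            means.loc[means.index.intersection(sub.index)] = sub["mean"]
            ns.loc[ns.index.intersection(sub.index)] = sub["size"]
        defined = ns >= min_sites
        out[f"mean_{g}"] = np.where(defined, means, np.nan)
        out[f"n_{g}"] = ns.to_numpy()
    return TileKinetics(tiles=out, groups=list(scheme.groups), tile_size=tile_size, min_sites=min_sites)


def _score_frame(
    df: pd.DataFrame,
    early_pair: tuple[str, str],
    late_pair: tuple[str, str],
    min_sites: int,
) -> pd.DataFrame:
    e_lo, e_hi = early_pair
    l_lo, l_hi = late_pair
    if {e_lo, e_hi} & {l_lo, l_hi}:
        raise ValueError("early and late scoring pairs must not overlap")
    needed = [e_lo, e_hi, l_lo, l_hi]
    for g in needed:
        if f"mean_{g}" not in df.columns:
            raise ValueError(f"group {g} missing from tile means")
    defined = np.ones(len(df), dtype=bool)
    for g in needed:
        defined &= df[f"mean_{g}"].notna().to_numpy() & (df[f"n_{g}"].to_numpy() >= min_sites)
    out = df.copy()
    out["early_diff"] = out[f"mean_{e_hi}"] - out[f"mean_{e_lo}"]
    out["late_diff"] = out[f"mean_{l_hi}"] - out[f"mean_{l_lo}"]
    out["score"] = np.where(defined, out["early_diff"] - out["late_diff"], np.nan)
    out.loc[~defined, ["early_diff", "late_diff"]] = np.nan
    return out


def tertile_labels(scores: np.ndarray) -> np.ndarray:
    """Split defined scores into slow/intermediate/fast thirds (ascending),
    sizes differing by at most one; ties broken by stable input order."""
    labels = np.full(scores.shape, None, dtype=object)
    idx = np.flatnonzero(~np.isnan(scores))
    order = idx[np.argsort(scores[idx], kind="stable")]
    parts = np.array_split(order, 3)
    for part, name in zip(parts, CLASS_ORDER):
        labels[part] = name
    return labels


def kinetic_score_and_classify(
    tk: TileKinetics,
    early_pair: tuple[str, str] = ("G1", "G3"),
    late_pair: tuple[str, str] = ("G5", "G7"),
    rule: str = "tertile",
    threshold: float = 0.05,
) -> TileKinetics:
    """Score every tile and attach fast/intermediate/slow class labels."""
    df = _score_frame(tk.tiles, early_pair, late_pair, tk.min_sites)
    s = df["score"].to_numpy()
    if rule == "tertile":
        df["class"] = tertile_labels(s)
    elif rule == "threshold":
        cls = np.where(s > threshold, "fast", np.where(s < -threshold, "slow", "intermediate"))
        df["class"] = np.where(np.isnan(s), None, cls)
    else:
        raise ValueError("rule must be 'tertile' or 'threshold'")
    df["class"] = df["class"].where(df["class"].notna(), None)
    return TileKinetics(tiles=df, groups=tk.groups, tile_size=tk.tile_size, min_sites=tk.min_sites)


def chi2_independence(table) -> tuple[float, float, int, np.ndarray]:
    """Pearson chi-squared test of independence, no continuity correction.

    Returns (statistic, p, dof, expected counts); the statistic equals the
    textbook sum of (observed - expected)^2 / expected over all cells.
    """
    chi2, p, dof, expected = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p), int(dof), expected


def _overlap_bp(merged, chrom, start, end) -> int:
    if chrom not in merged:
        return 0
    s, e = merged[chrom]
    return int(np.maximum(np.clip(e, start, end) - np.clip(s, start, end), 0).sum())


def annotation_enrichment(
    tk: TileKinetics,
    annotations: methio.AnnotationSet,
    categories: list[str] | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    n_mc: int = 10_000,
) -> pd.DataFrame:
    """Chi-squared enrichment of annotation bp across kinetic classes.

    For each category, classified tiles contribute a 2 x k contingency table
    of (bp overlapping, bp not overlapping) x class. Enrichment ratio per
    class is its overlap fraction over the all-classified overlap fraction.
    If any expected count falls below 5 the test switches to a seeded
    Monte-Carlo permutation of the same statistic, recorded in ``method``.
    """
    classed = tk.classified()
    present = [c for c in CLASS_ORDER if (classed["class"] == c).any()]
    if len(present) < 2:
        raise ValueError("need at least two nonempty classes for enrichment")
    rng = np.random.default_rng(seed)
    cats = categories or annotations.categories()
    rows = []
    class_bp = {
        c: int((classed.loc[classed["class"] == c, "End"] - classed.loc[classed["class"] == c, "Start"]).sum())
        for c in present
    }
    for cat in cats:
        merged = annotations.merged(cat)
        ovl = {c: 0 for c in present}
        for chrom, start, end, cls in classed[["Chromosome", "Start", "End", "class"]].itertuples(
            index=False, name=None
        ):
            ovl[cls] += _overlap_bp(merged, chrom, start, end)
        table = np.array([[ovl[c] for c in present], [class_bp[c] - ovl[c] for c in present]])
        total_frac = table[0].sum() / table.sum() if table.sum() else 0.0
        if table[0].sum() == 0 or table[1].sum() == 0:
            chi2, p, dof, method = 0.0, 1.0, len(present) - 1, "degenerate"
        else:
            chi2, p, dof, expected = chi2_independence(table)
            method = "chi2"
            if (expected < 5).any():
                p = _mc_chi2_pvalue(table, chi2, rng, n_mc)
                method = "mc_exact"
        for j, c in enumerate(present):
            frac = table[0, j] / class_bp[c] if class_bp[c] else np.nan
            rows.append(
                dict(
                    category=cat, **{"class": c},
                    observed_bp=int(table[0, j]),
                    expected_bp=float(class_bp[c] * total_frac),
                    class_fraction=frac,
                    enrichment_ratio=(frac / total_frac) if total_frac else np.nan,
                    chi2=float(chi2), df=int(dof), p=float(p),
                    significant=bool(p < alpha), method=method,
                )
            )
    return pd.DataFrame(rows)


def _mc_chi2_pvalue(table: np.ndarray, observed_stat: float, rng, n_mc: int) -> float:
    """Monte-Carlo chi-squared p-value under fixed margins (multinomial)."""
    n = table.sum()
    p_row = table.sum(axis=1) / n
    p_col = table.sum(axis=0) / n
    probs = np.outer(p_row, p_col).ravel()
    sims = rng.multinomial(n, probs, size=n_mc).reshape(n_mc, *table.shape)
    expected = probs.reshape(table.shape) * n
    stat = ((sims - expected) ** 2 / np.maximum(expected, 1e-12)).sum(axis=(1, 2))
    return float((np.count_nonzero(stat >= observed_stat - 1e-9) + 1) / (n_mc + 1))


def gene_body_kinetics(
    cells: dict[str, methio.CellMethylome],
    scheme: MethylGroupScheme,
    gene_models: pd.DataFrame,
    atac_peaks: pd.DataFrame | None = None,
    early_pair: tuple[str, str] = ("G1", "G3"),
    late_pair: tuple[str, str] = ("G5", "G7"),
    min_sites: int = 20,
    signal_weighted: bool = True,
    exclude: tuple[str, ...] = ("lambda",),
) -> pd.DataFrame:
    """Kinetic score/class per gene body plus promoter ATAC accessibility.

    Accessibility is the total ATAC-peak bp overlapping the promoter,
    multiplied by peak signal when a Score column is present.
    """
    if (gene_models["End"] <= gene_models["Start"]).any():
        bad = gene_models[gene_models["End"] <= gene_models["Start"]].iloc[0]
        raise ValueError(f"gene {bad['gene_id']}: zero-length body")
    obs = dyad_observations(cells, scheme, exclude=exclude)
    by_chrom = {
        chrom: sub.sort_values("start", kind="stable")
        for chrom, sub in obs.groupby("chrom")
    }
    rows = []
    for g in gene_models.itertuples():
        sub = by_chrom.get(g.Chromosome)
        rec = dict(gene_id=g.gene_id, Chromosome=g.Chromosome, Start=g.Start, End=g.End)
        if sub is not None:
            starts = sub["start"].to_numpy()
            lo, hi = np.searchsorted(starts, [g.Start, g.End])
            window = sub.iloc[lo:hi]
            stats_ = window.groupby("group")["rate"].agg(["mean", "size"])
            for grp in scheme.groups:
                if grp in stats_.index and stats_.loc[grp, "size"] >= min_sites:
                    rec[f"mean_{grp}"] = float(stats_.loc[grp, "mean"])
                    rec[f"n_{grp}"] = int(stats_.loc[grp, "size"])
                else:
                    rec[f"mean_{grp}"] = np.nan
                    rec[f"n_{grp}"] = int(stats_.loc[grp, "size"]) if grp in stats_.index else 0
        else:
            for grp in scheme.groups:
                rec[f"mean_{grp}"], rec[f"n_{grp}"] = np.nan, 0
        rec["accessibility"] = _promoter_accessibility(g, atac_peaks, signal_weighted)
        rows.append(rec)
    df = pd.DataFrame(rows)
    df = _score_frame(df, early_pair, late_pair, min_sites)
    df["class"] = tertile_labels(df["score"].to_numpy())
    return df


def _promoter_accessibility(gene, atac_peaks: pd.DataFrame | None, signal_weighted: bool) -> float:
    if atac_peaks is None or len(atac_peaks) == 0:
        return 0.0
    pstart, pend = getattr(gene, "prom_start", None), getattr(gene, "prom_end", None)
    if pstart is None:
        return 0.0
    sub = atac_peaks[atac_peaks["Chromosome"] == gene.Chromosome]
    ovl = np.maximum(
        np.minimum(sub["End"], pend) - np.maximum(sub["Start"], pstart), 0
    ).to_numpy(float)
    if signal_weighted and "Score" in sub.columns:
        ovl = ovl * sub["Score"].to_numpy(float)
    return float(ovl.sum())
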