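"""Thin helpers over :mod:`pyranges` for the interval queries the pipeline needs.

pyranges supplies the set algebra (merge, subtract, overlap); what it lacks in
the classic API is a vectorised "are these points inside the footprint"
query, so membership tests go through sorted merged start/end arrays and
``numpy.searchsorted``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pyranges as pr

BED_COLS = ["Chromosome", "Start", "End"]


def as_pyranges(df: pd.DataFrame) -> pr.PyRanges:
    """Wrap a Chromosome/Start/End frame as a PyRanges, validating bounds."""
    if not set(BED_COLS) <= set(df.columns):
        raise ValueError(f"interval frame needs columns {BED_COLS}")
    if len(df) and (df["Start"] >= df["End"]).any():
        bad = df[df["Start"] >= df["End"]].iloc[0]
        raise ValueError(
            f"invalid interval {bad['Chromosome']}:{bad['Start']}-{bad['End']} (start >= end)"
        )
    return pr.PyRanges(df.reset_index(drop=True))


def merged_arrays(gr: pr.PyRanges) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merged footprint as per-chromosome sorted (starts, ends) arrays."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if len(gr) == 0:
        return out
    m = gr.merge().df.sort_values(["Chromosome", "Start"])
    for chrom, sub in m.groupby("Chromosome", observed=True):
        out[str(chrom)] = (
            sub["Start"].to_numpy(np.int64),
            sub["End"].to_numpy(np.int64),
        )
    return out


def positions_in(
    merged: dict[str, tuple[np.ndarray, np.ndarray]], chrom: str, pos: np.ndarray
) -> np.ndarray:
    """Boolean mask: which 0-based positions fall inside the merged footprint."""
    pos = np.asarray(pos, dtype=np.int64)
    mask = np.zeros(pos.shape, dtype=bool)
    if chrom not in merged or pos.size == 0:
        return mask
    starts, ends = merged[chrom]
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    mask[ok] = pos[ok] < ends[idx[ok]]
    return mask


def footprint_bp(gr: pr.PyRanges) -> int:
    if len(gr) == 0:
        return 0
    m = gr.merge().df
    return int((m["End"] - m["Start"]).sum())


def overlap_bp(gr: pr.PyRanges, chrom: str, start: int, end: int) -> int:
    """Base pairs of the merged footprint overlapping [start, end)."""
    merged = merged_arrays(gr)
    if chrom not in merged:
        return 0
    s, e = merged[chrom]
    lo = np.clip(s, start, end)
    hi = np.clip(e, start, end)
    return int(np.maximum(hi - lo, 0).sum())


def complement(
    gr: pr.PyRanges, chrom_sizes: dict[str, int], exclude: tuple[str, ...] = ()
) -> pr.PyRanges:
    """Genome complement of the merged footprint over the given chromosomes."""
    merged = merged_arrays(gr)
    rows = []
    for chrom, size in chrom_sizes.items():
        if chrom in exclude:
            continue
        if chrom not in merged:
            rows.append((chrom, 0, size))
            continue
        s, e = merged[chrom]
        gaps_start = np.concatenate([[0], e])
        gaps_end = np.concatenate([s, [size]])
        for a, b in zip(gaps_start, gaps_end):
            if b > a:
                rows.append((chrom, int(a), int(b)))
    return pr.PyRanges(pd.DataFrame(rows, columns=BED_COLS))


def flanks(
    gr: pr.PyRanges, size: int, chrom_sizes: dict[str, int]
) -> pr.PyRanges:
    """(footprint +/- ``size`` bp) minus the footprint itself, clipped to bounds."""
    if len(gr) == 0:
        return pr.PyRanges(pd.DataFrame(columns=BED_COLS))
    m = gr.merge().df
    rows = []
    for _, r in m.iterrows():
        limit = chrom_sizes.get(str(r["Chromosome"]))
        lo = max(0, int(r["Start"]) - size)
        hi = int(r["End"]) + size
        if limit is not None:
            hi = min(hi, limit)
        if lo < r["Start"]:
            rows.append((r["Chromosome"], lo, int(r["Start"])))
        if hi > r["End"]:
            rows.append((r["Chromosome"], int(r["End"]), hi))
    fl = pr.PyRanges(pd.DataFrame(rows, columns=BED_COLS))
    return fl.subtract(gr)


def midpoint_windows(df: pd.DataFrame, halfwidth: int) -> pd.DataFrame:
    """Window of +/- ``halfwidth`` bp around each interval midpoint."""
    mid = (df["Start"] + df["End"]) // 2
    out = df[["Chromosome"]].copy()
    out["Start"] = np.maximum(mid - halfwidth, 0)
    out["End"] = mid + halfwidth
    return out
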