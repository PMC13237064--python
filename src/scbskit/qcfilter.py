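"""Per-cell quality control for single-cell bisulfite data.

Three quantities feed the inclusion decision: the bisulfite conversion rate
estimated from the unmethylated lambda spike-in, the fraction of reference
CpG dyads covered, and the mean methylation at maternally methylated
imprinted DMRs. Male germ cells are unmethylated at maternal DMRs while
somatic cells sit near 50%, so elevated DMR methylation flags somatic
contamination. Cells are excluded when coverage falls below a floor
(default 1% of dyads) or when the somatic flag fires; conversion rate is
reported but, by default, not an exclusion criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals, methio

log = logging.getLogger("scbskit")


class UndefinedRateError(ValueError):
    """A rate was requested from zero observations (distinct from rate 0)."""


@dataclass
class CellQC:
    cell_id: str
    conversion_rate: float | None
    coverage_rate: float
    mapping_rate: float | None
    imprint_means: dict[str, float]
    somatic_flag: bool | None          # None = indeterminate (no covered DMR)
    included: bool = True
    reasons: list[str] = field(default_factory=list)


def estimate_conversion_rate(cell: methio.CellMethylome, lambda_contig: str = "lambda") -> float:
    """Pooled conversion rate over every lambda cytosine (all contexts):
    unmethylated calls / total calls."""
    lam = cell.calls[cell.calls["chrom"] == lambda_contig]
    total = int(lam["n_meth"].sum() + lam["n_unmeth"].sum())
    if total == 0:
        raise UndefinedRateError(
            f"{cell.cell_id}: no calls on spike-in contig {lambda_contig!r}"
        )
    return float(lam["n_unmeth"].sum() / total)


def compute_coverage_rate(
    cell: methio.CellMethylome, genome_cpg_count: int, lambda_contig: str = "lambda"
) -> float:
    """Covered CpG dyads / reference dyad count (spike-in excluded)."""
    if genome_cpg_count <= 0:
        raise ValueError("genome_cpg_count must be positive")
    covered = len(cell.cpg_on(exclude=(lambda_contig,)))
    return covered / genome_cpg_count


def flag_somatic_by_imprints(
    cell: methio.CellMethylome,
    dmrs: pd.DataFrame,
    threshold: float = 0.25,
    min_sites: int = 5,
) -> tuple[bool | None, dict[str, float]]:
    """Flag a cell as somatic from maternal imprinted-DMR methylation.

    ``dmrs`` is a BED-like frame (Chromosome/Start/End/Name). Per DMR, the
    mean of covered dyad rates is computed; DMRs with fewer than
    ``min_sites`` covered dyads do not qualify. The flag is True when the
    mean across qualifying DMRs is at or above ``threshold``, and None
    (indeterminate, with a warning) when no DMR qualifies.
    """
    cpg = cell.cpg_merged
    means: dict[str, float] = {}
    qualifying = []
    for row in dmrs.itertuples():
        name = getattr(row, "Name", f"{row.Chromosome}:{row.Start}")
        sub = cpg[
            (cpg["chrom"] == row.Chromosome)
            & (cpg["start"] >= row.Start)
            & (cpg["start"] < row.End)
        ]
        if len(sub) == 0:
            continue
        rate = (sub["n_meth"] / (sub["n_meth"] + sub["n_unmeth"])).mean()
        means[name] = float(rate)
        if len(sub) >= min_sites:
            qualifying.append(float(rate))
    if not qualifying:
        log.warning(
            "%s: no imprinted DMR with >= %d covered dyads; somatic status indeterminate",
            cell.cell_id,
            min_sites,
        )
        return None, means
    return bool(np.mean(qualifying) >= threshold), means


def qc_cells(
    cells: dict[str, methio.CellMethylome],
    sheet: pd.DataFrame,
    genome_cpg_count: int,
    dmrs: pd.DataFrame,
    lambda_contig: str = "lambda",
    somatic_threshold: float = 0.25,
    min_dmr_sites: int = 5,
) -> list[CellQC]:
    """Compute the full QC record for every cell on the sample sheet."""
    mapping = dict(zip(sheet["cell_id"], sheet["mapping_rate"]))
    out = []
    for cid, cm in cells.items():
        try:
            conv = estimate_conversion_rate(cm, lambda_contig)
        except UndefinedRateError:
            conv = None
        flag, means = flag_somatic_by_imprints(
            cm, dmrs, threshold=somatic_threshold, min_sites=min_dmr_sites
        )
        out.append(
            CellQC(
                cell_id=cid,
                conversion_rate=conv,
                coverage_rate=compute_coverage_rate(cm, genome_cpg_count, lambda_contig),
                mapping_rate=mapping.get(cid),
                imprint_means=means,
                somatic_flag=flag,
            )
        )
    return out


def apply_exclusions(
    sheet: pd.DataFrame,
    qcs: list[CellQC],
    coverage_min: float = 0.01,
    conversion_min: float | None = None,
) -> pd.DataFrame:
    """Apply the two exclusion rules and record the reasons.

    A cell is excluded iff its CpG-dyad coverage rate is below
    ``coverage_min`` or its somatic flag is set. Mapping rate is carried
    through for reporting; a low-mapping cell is excluded through its
    coverage consequence rather than by a separate rule. An optional
    conversion-rate floor can be enforced via ``conversion_min``.
    """
    if sheet["cell_id"].duplicated().any():
        dup = sheet.loc[sheet["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicate cell_id {dup!r} in sample sheet")
    by_id = {q.cell_id: q for q in qcs}
    missing = [c for c in sheet["cell_id"] if c not in by_id]
    if missing:
        raise ValueError(f"no QC record for cells: {missing}")
    rows = []
    for cid in sheet["cell_id"]:
        q = by_id[cid]
        reasons = []
        if q.coverage_rate < coverage_min:
            reasons.append(f"coverage_rate {q.coverage_rate:.4f} < {coverage_min}")
        if q.somatic_flag:
            reasons.append("somatic contamination (imprinted-DMR methylation)")
        if conversion_min is not None and q.conversion_rate is not None:
            if q.conversion_rate < conversion_min:
                reasons.append(f"conversion_rate {q.conversion_rate:.4f} < {conversion_min}")
        rows.append(
            dict(
                cell_id=cid,
                conversion_rate=q.conversion_rate,
                coverage_rate=q.coverage_rate,
                mapping_rate=q.mapping_rate,
                somatic_flag=q.somatic_flag,
                included=not reasons,
                reasons="; ".join(reasons),
            )
        )
        q.included = not reasons
        q.reasons = reasons
    return pd.DataFrame(rows)
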