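"""Shared fixtures: one session-scoped synthetic cohort at the default study
scale (1 chromosome x 2 Mb, 60 cells) plus smaller purpose-built cohorts.
Everything is generated at test time from fixed seeds."""

from __future__ import annotations

import numpy as np
import pytest

import scbskit as sk
from scbskit import cellgroups, kinetics, qcfilter

GENOME_SEED = 1
COHORT_SEED = 2


@pytest.fixture(scope="session")
def genome():
    return sk.build_genome(seed=GENOME_SEED)


@pytest.fixture(scope="session")
def model():
    return sk.KineticModel(somatic_fraction=0.05)


@pytest.fixture(scope="session")
def cohort(genome, model):
    """60-cell cohort with ~5% planted somatic cells and ~12% mitotic cells."""
    return sk.simulate_cells(genome, model, n_cells=60, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def fixture_dir(cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    sk.emit_fixture(cohort, out)
    return out


@pytest.fixture(scope="session")
def annotations(genome):
    return genome.annotation_set()


@pytest.fixture(scope="session")
def qc_table(cohort, genome):
    sheet = cohort.sample_sheet()
    qcs = qcfilter.qc_cells(
        cohort.methylomes, sheet, genome.cpg_dyad_count(),
        genome.annotations["imprint_dmr"],
    )
    return qcfilter.apply_exclusions(sheet, qcs)


@pytest.fixture(scope="session")
def included_cells(cohort, qc_table):
    keep = set(qc_table.loc[qc_table["included"], "cell_id"])
    return {c: m for c, m in cohort.methylomes.items() if c in keep}


@pytest.fixture(scope="session")
def levels(included_cells):
    return {c: cellgroups.global_cpg_methylation(m) for c, m in included_cells.items()}


@pytest.fixture(scope="session")
def scheme(levels):
    return cellgroups.assign_groups(levels, "marmoset")


@pytest.fixture(scope="session")
def tile_kinetics(included_cells, scheme, genome):
    tk = kinetics.tile_group_means(
        included_cells, scheme,
        {c: genome.chrom_sizes[c] for c in genome.main_chroms},
        tile_size=genome.config.tile_size,
    )
    return kinetics.kinetic_score_and_classify(tk, ("G1", "G3"), ("G5", "G7"))


# --- smaller purpose-built cohorts -----------------------------------------


@pytest.fixture(scope="session")
def small_genome():
    cfg = sk.GenomeConfig(
        chrom_sizes={"chr1": 400_000}, tile_size=100_000, lambda_size=20_000,
        n_genes=6, gene_length=(8_000, 15_000),
        n_line=4, n_ltr=3, n_orphan_cgi=2, n_intergenic_atac=1,
        n_imprint_dmr=3,
    )
    return sk.build_genome(cfg, seed=21)


@pytest.fixture(scope="session")
def perfect_conversion_cohort(small_genome):
    """c = 1, no basal or active methylation: isolates the motif machinery.

    Motif weights follow a strongly skewed CAC/CAG preference so recovered
    shares are informative.
    """
    weights = {t: 0.03 for t in sk.simgen.CH_TRINUCLEOTIDES}
    weights["CAC"], weights["CAG"] = 0.4, 0.3
    model = sk.KineticModel(
        conversion_rate=1.0, base_level=0.0, active_region_level=0.0,
        ch_base=0.01, ch_gain=0.0, ch_motif_weights=weights,
    )
    specs = [sk.CellSpec(f"pc{i:02d}", tau=0.9) for i in range(10)]
    return sk.simulate_cells(
        small_genome, model, cell_specs=specs, ch_coverage_fraction=0.05, seed=31
    )


@pytest.fixture(scope="session")
def deep_cells(genome, model):
    """Three germ cells covering ~60% of dyads (>10k observed dyads each)."""
    specs = [
        sk.CellSpec("deep0", tau=0.15, coverage_fraction=0.6),
        sk.CellSpec("deep1", tau=0.5, coverage_fraction=0.6),
        sk.CellSpec("deep2", tau=0.85, coverage_fraction=0.6),
    ]
    return sk.simulate_cells(genome, model, cell_specs=specs, seed=41)


def make_roster_cohort(genome, seed: int) -> sk.SyntheticCohort:
    """103-cell roster: 100 clean germ cells, two low-mapping cells whose
    coverage falls below the 1% floor, and one somatic contaminant."""
    rng = np.random.default_rng(seed)
    specs = [
        sk.CellSpec(f"c{i:03d}", tau=float(rng.uniform(0.02, 0.98)))
        for i in range(100)
    ]
    specs.append(sk.CellSpec("c100", tau=0.3, coverage_fraction=0.005, mapping_rate=0.01))
    specs.append(sk.CellSpec("c101", tau=0.6, coverage_fraction=0.0025, mapping_rate=0.005))
    specs.append(sk.CellSpec("c102", tau=0.5, cell_type="somatic"))
    model = sk.KineticModel()
    return sk.simulate_cells(
        genome, model, cell_specs=specs, seed=seed + 1,
        ch_coverage_fraction=0.005, lambda_coverage_fraction=0.05,
    )
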