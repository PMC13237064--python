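"""Tile kinetics: group means, the difference-of-differences score, class
recovery, and chi-squared annotation enrichment."""

import numpy as np
import pandas as pd
import pytest

from scbskit import intervals, kinetics, methio, simgen
from scbskit.cellgroups import assign_groups


def _tk_from_means(rows, groups=("G1", "G3", "G5", "G7"), n=1000):
    """TileKinetics with hand-set group means (counts saturated)."""
    recs = []
    for i, means in enumerate(rows):
        rec = {"Chromosome": "chr1", "Start": i * 1000, "End": (i + 1) * 1000}
        for g, m in zip(groups, means):
            rec[f"mean_{g}"] = m
            rec[f"n_{g}"] = n
        recs.append(rec)
    return kinetics.TileKinetics(
        tiles=pd.DataFrame(recs), groups=list(groups), tile_size=1000, min_sites=1
    )


class TestTiles:
    def test_truncated_final_tile(self):
        tiles = kinetics.make_tiles({"chr1": 1_234_567}, 500_000)
        assert len(tiles) == 3
        assert tiles.iloc[-1]["End"] - tiles.iloc[-1]["Start"] == 234_567

    def test_tile_size_must_be_positive(self):
        with pytest.raises(ValueError):
            kinetics.make_tiles({"chr1": 100}, 0)

    def test_two_cells_opposite_rates_average_to_half(self):
        rows_a = [("chr1", 10, "+", 1, 0, "CG", "CGA")]
        rows_b = [("chr1", 20, "+", 0, 1, "CG", "CGA")]
        rows_c = [("chr1", 30, "+", 1, 0, "CG", "CGA")]
        cells = {
            "a": methio.CellMethylome("a", pd.DataFrame(rows_a, columns=methio.REPORT_COLUMNS)),
            "b": methio.CellMethylome("b", pd.DataFrame(rows_b, columns=methio.REPORT_COLUMNS)),
            "c": methio.CellMethylome("c", pd.DataFrame(rows_c, columns=methio.REPORT_COLUMNS)),
        }
        scheme = assign_groups({"a": 0.05, "b": 0.05, "c": 0.7}, "marmoset")
        tk = kinetics.tile_group_means(cells, scheme, {"chr1": 1000}, 1000, min_sites=1)
        assert tk.tiles.loc[0, "mean_G1"] == pytest.approx(0.5)

    def test_tile_means_match_analytic_expectation(
        self, tile_kinetics, genome, model, cohort, scheme
    ):
        """Closed-form oracle: per tile x group, the expected observed level
        from planted dyad classes and member-cell progressions, within 0.03."""
        taus = cohort.specs.set_index("cell_id")["tau"]
        checked = 0
        for t_idx, tile in tile_kinetics.tiles.iterrows():
            chrom = tile["Chromosome"]
            dy = genome.dyads[chrom]
            sel = (dy >= tile["Start"]) & (dy < tile["End"])
            counts = np.bincount(genome.dyad_class[chrom][sel], minlength=5)
            for g in ["G1", "G3", "G5", "G7"]:
                got = tile[f"mean_{g}"]
                if np.isnan(got):
                    continue
                members = [c for c in scheme.members(g) if c in taus.index]
                exp = np.mean(
                    [
                        np.average(model.observed(model.code_levels("germ", taus[c])), weights=counts)
                        for c in members
                    ]
                )
                assert got == pytest.approx(exp, abs=0.03)
                checked += 1
        assert checked >= 8

    def test_nonempty_group_precondition(self, cohort):
        scheme = assign_groups({}, "marmoset")
        with pytest.raises(ValueError):
            kinetics.tile_group_means(cohort.methylomes, scheme, {"chr1": 1000}, 1000)


class TestScoreAndClassify:
    def test_score_arithmetic(self):
        tk = _tk_from_means([[0.05, 0.25, 0.45, 0.50], [0.02, 0.08, 0.30, 0.60]])
        out = kinetics.kinetic_score_and_classify(tk, ("G1", "G3"), ("G5", "G7"))
        assert out.tiles["score"].tolist() == pytest.approx([0.15, -0.24])

    def test_overlapping_pairs_rejected(self):
        tk = _tk_from_means([[0.1, 0.2, 0.3, 0.4]])
        with pytest.raises(ValueError):
            kinetics.kinetic_score_and_classify(tk, ("G1", "G3"), ("G3", "G7"))

    def test_score_invariant_to_constant_shift(self):
        base = [[0.05, 0.25, 0.45, 0.50], [0.02, 0.08, 0.30, 0.60]]
        shifted = [[m + 0.1 for m in row] for row in base]
        s1 = kinetics.kinetic_score_and_classify(_tk_from_means(base)).tiles["score"]
        s2 = kinetics.kinetic_score_and_classify(_tk_from_means(shifted)).tiles["score"]
        assert np.allclose(s1, s2)

    def test_tertiles_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=30)
        s[rng.choice(30, 5, replace=False)] = np.nan
        a = kinetics.tertile_labels(s)
        b = kinetics.tertile_labels(np.where(np.isnan(s), np.nan, 2 * np.exp(s) + 1))
        assert list(a) == list(b)

    def test_classified_tiles_partition_defined_scores(self, tile_kinetics):
        df = tile_kinetics.tiles
        defined = df["score"].notna().sum()
        assert len(tile_kinetics.classified()) == defined
        sizes = tile_kinetics.classified()["class"].value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_recovers_planted_tile_classes(self, tile_kinetics, cohort):
        truth = cohort.truth_tiles.set_index(["Chromosome", "Start"])["kinetic_class"]
        got = tile_kinetics.classified().set_index(["Chromosome", "Start"])["class"]
        agree = (truth.loc[got.index] == got).mean()
        assert agree >= 0.9

    def test_threshold_rule(self):
        tk = _tk_from_means([[0.0, 0.3, 0.5, 0.55], [0.0, 0.05, 0.3, 0.6], [0.1, 0.2, 0.3, 0.4]])
        out = kinetics.kinetic_score_and_classify(tk, rule="threshold", threshold=0.1)
        assert list(out.tiles["class"]) == ["fast", "slow", "intermediate"]


class TestEnrichment:
    def _ann(self, frames):
        return methio.AnnotationSet(frames)

    def test_identical_overlap_fractions_give_null_result(self):
        tk = _tk_from_means([[0.0, 0.3, 0.5, 0.55], [0.0, 0.05, 0.3, 0.6], [0.1, 0.2, 0.3, 0.4]])
        tk = kinetics.kinetic_score_and_classify(tk)
        # category covering exactly half of every tile
        cat = pd.DataFrame(
            {"Chromosome": "chr1", "Start": [0, 1000, 2000], "End": [500, 1500, 2500]}
        )
        out = kinetics.annotation_enrichment(tk, self._ann({"half": cat}))
        assert out["chi2"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)
        assert np.allclose(out["enrichment_ratio"], 1.0)

    def test_chi2_matches_textbook_two_by_two(self):
        stat, p, dof, _ = kinetics.chi2_independence([[10, 90], [30, 70]])
        assert stat == pytest.approx(12.5)
        assert dof == 1

    def test_chi2_equals_brute_force_on_random_tables(self):
        """Property check: statistic equals sum (o-e)^2/e with margins-based
        expected counts, on 100 random small tables."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            table = rng.integers(5, 60, size=(2, rng.integers(2, 4)))
            stat, _, dof, _ = kinetics.chi2_independence(table)
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            brute = ((table - expected) ** 2 / expected).sum()
            assert stat == pytest.approx(brute)
            assert dof == (table.shape[0] - 1) * (table.shape[1] - 1)

    def test_low_expected_counts_use_exact_fallback(self):
        tk = _tk_from_means([[0.0, 0.3, 0.5, 0.55], [0.0, 0.05, 0.3, 0.6], [0.1, 0.2, 0.3, 0.4]])
        tk = kinetics.kinetic_score_and_classify(tk)
        tiny = pd.DataFrame({"Chromosome": ["chr1"], "Start": [0], "End": [4]})
        out = kinetics.annotation_enrichment(tk, self._ann({"tiny": tiny}))
        assert (out["method"] == "mc_exact").all()
        assert ((out["p"] >= 0) & (out["p"] <= 1)).all()

    def test_genic_enrichment_in_fast_class(self, tile_kinetics, annotations):
        out = kinetics.annotation_enrichment(tile_kinetics, annotations, categories=["gene"])
        fast = out[out["class"] == "fast"].iloc[0]
        assert fast["enrichment_ratio"] > 1
        assert fast["p"] < 0.05
        slow = out[out["class"] == "slow"].iloc[0]
        assert slow["enrichment_ratio"] < 1

    def test_enrichment_expected_totals_match_observed_totals(self, tile_kinetics, annotations):
        out = kinetics.annotation_enrichment(tile_kinetics, annotations)
        for cat, sub in out.groupby("category"):
            assert sub["expected_bp"].sum() == pytest.approx(sub["observed_bp"].sum())


class TestGeneKinetics:
    def test_gene_spanning_a_tile_matches_tile_score(
        self, included_cells, scheme, tile_kinetics, genome
    ):
        whole_tile = pd.DataFrame(
            {
                "gene_id": ["T1"], "Chromosome": ["chr1"],
                "Start": [0], "End": [genome.config.tile_size],
            }
        )
        gk = kinetics.gene_body_kinetics(
            included_cells, scheme, whole_tile, None, min_sites=tile_kinetics.min_sites
        )
        assert gk.loc[0, "score"] == pytest.approx(tile_kinetics.tiles.loc[0, "score"])

    def test_zero_length_body_rejected(self, included_cells, scheme):
        bad = pd.DataFrame({"gene_id": ["z"], "Chromosome": ["chr1"], "Start": [5], "End": [5]})
        with pytest.raises(ValueError, match="zero-length"):
            kinetics.gene_body_kinetics(included_cells, scheme, bad, None)

    def test_promoter_without_peak_has_zero_accessibility(self, included_cells, scheme):
        gene = pd.DataFrame(
            {
                "gene_id": ["g"], "Chromosome": ["chr1"], "Start": [1000], "End": [2000],
                "prom_start": [500], "prom_end": [1000],
            }
        )
        peaks = pd.DataFrame(
            {"Chromosome": ["chr1"], "Start": [5000], "End": [5600], "Score": [9.0]}
        )
        gk = kinetics.gene_body_kinetics(included_cells, scheme, gene, peaks, min_sites=1)
        assert gk.loc[0, "accessibility"] == 0.0

    def test_accessibility_ordered_by_recovered_class(
        self, included_cells, scheme, genome
    ):
        gk = kinetics.gene_body_kinetics(
            included_cells, scheme, genome.gene_models,
            genome.annotations["atac_peak"],
        )
        med = gk.groupby("class")["accessibility"].median()
        assert med["fast"] > med["intermediate"] > med["slow"]
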