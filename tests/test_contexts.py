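"""Context profiles, active-region masking, expression tertiles, BH
adjustment, and non-CG motif analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scbskit import contexts, intervals, methio, simgen
from scbskit.cellgroups import assign_groups


def _cell(rows, cell_id="c"):
    return methio.CellMethylome(cell_id, pd.DataFrame(rows, columns=methio.REPORT_COLUMNS))


def _one_group(cells):
    return assign_groups({c: 0.05 for c in cells}, "marmoset")


class TestContextProfile:
    def test_exon_covering_everything_equals_genome_wide(self):
        rows = [("chr1", 2 * i, "+", i % 2, 1 - i % 2, "CG", "CGA") for i in range(10)]
        cells = {"c": _cell(rows)}
        ann = methio.AnnotationSet(
            {"exon": pd.DataFrame({"Chromosome": ["chr1"], "Start": [0], "End": [100]})}
        )
        out = contexts.context_methylation_profile(cells, _one_group(cells), ann)
        gw = out[(out.category == "genome_wide") & (out.group == "G1")]["mean"].iloc[0]
        ex = out[(out.category == "exon") & (out.group == "G1")]["mean"].iloc[0]
        assert ex == gw == pytest.approx(0.5)

    def test_fully_methylated_category_is_one(self):
        rows = [("chr1", 2 * i, "+", 1, 0, "CG", "CGA") for i in range(5)]
        cells = {"c": _cell(rows)}
        ann = methio.AnnotationSet(
            {"cgi": pd.DataFrame({"Chromosome": ["chr1"], "Start": [0], "End": [100]})}
        )
        out = contexts.context_methylation_profile(cells, _one_group(cells), ann)
        assert out[(out.category == "cgi") & (out.group == "G1")]["mean"].iloc[0] == 1.0

    def test_zero_coverage_category_reported_as_undefined(self):
        rows = [("chr1", 0, "+", 1, 0, "CG", "CGA")]
        cells = {"c": _cell(rows)}
        ann = methio.AnnotationSet(
            {"ltr": pd.DataFrame({"Chromosome": ["chr1"], "Start": [500], "End": [600]})}
        )
        out = contexts.context_methylation_profile(cells, _one_group(cells), ann)
        row = out[(out.category == "ltr") & (out.group == "G1")].iloc[0]
        assert np.isnan(row["mean"]) and row["n_sites"] == 0

    def test_recovers_planted_context_ordering(
        self, included_cells, scheme, annotations, genome, model, cohort
    ):
        """In the final group, exon/intron means exceed intergenic, and each
        matches the planted-class analytic expectation within 0.03."""
        out = contexts.context_methylation_profile(
            included_cells, scheme, annotations, categories=["exon", "intron", "intergenic"]
        )
        taus = cohort.specs.set_index("cell_id")["tau"]
        g7 = {r["category"]: r["mean"] for _, r in out[out.group == "G7"].iterrows()}
        assert g7["exon"] > g7["intergenic"]
        for cat in ("exon", "intron", "intergenic"):
            merged = annotations.merged(cat)
            sel = {
                c: intervals.positions_in(merged, c, genome.dyads[c])
                for c in genome.main_chroms
            }
            exp = np.mean(
                [
                    simgen.expected_global_level(genome, model, taus[c], selector=sel)
                    for c in scheme.members("G7")
                ]
            )
            assert g7[cat] == pytest.approx(exp, abs=0.03)


class TestMasking:
    def test_masking_arithmetic(self):
        # 4 dyads at rate 0 inside the element, 6 at 0.8 (4/5 calls) outside
        rows = [("chr1", 2 * i, "+", 0, 1, "CG", "CGA") for i in range(4)]
        rows += [("chr1", 100 + 2 * i, "+", 4, 1, "CG", "CGA") for i in range(6)]
        cells = {"c": _cell(rows)}
        ann = methio.AnnotationSet(
            {"cgi": pd.DataFrame({"Chromosome": ["chr1"], "Start": [0], "End": [8]})}
        )
        out = contexts.mask_active_regions(
            cells, _one_group(cells), ann, active=("cgi",), halfwidth=10
        )
        row = out[out.group == "G1"].iloc[0]
        assert row["unmasked_mean"] == pytest.approx(0.48)
        assert row["masked_mean"] == pytest.approx(0.8)
        assert row["delta"] == pytest.approx(0.32)

    def test_no_active_elements_no_delta(self):
        rows = [("chr1", 2 * i, "+", 1, 0, "CG", "CGA") for i in range(5)]
        cells = {"c": _cell(rows)}
        ann = methio.AnnotationSet({})
        out = contexts.mask_active_regions(cells, _one_group(cells), ann, active=("cgi",))
        assert out[out.group == "G1"]["delta"].iloc[0] == pytest.approx(0.0)

    def test_mask_covering_everything_is_an_error(self):
        rows = [("chr1", 2 * i, "+", 1, 0, "CG", "CGA") for i in range(5)]
        cells = {"c": _cell(rows)}
        ann = methio.AnnotationSet(
            {"cgi": pd.DataFrame({"Chromosome": ["chr1"], "Start": [0], "End": [100]})}
        )
        with pytest.raises(ValueError, match="mask"):
            contexts.mask_active_regions(cells, _one_group(cells), ann, active=("cgi",))

    def test_delta_matches_mixture_closed_form(
        self, included_cells, scheme, annotations, genome, model, cohort
    ):
        """Two-component mixture oracle: expected masked and unmasked means
        from planted dyad classes agree with the measured ones within 0.02."""
        kept = contexts.filter_low_cpg_promoters(
            annotations.frames["promoter"], genome.sequences
        )
        ann2 = methio.AnnotationSet({**annotations.frames, "promoter": kept})
        out = contexts.mask_active_regions(included_cells, scheme, ann2)
        merged = contexts.active_mask_intervals(ann2)
        taus = cohort.specs.set_index("cell_id")["tau"]
        sel_out = {
            c: ~intervals.positions_in(merged, c, genome.dyads[c])
            for c in genome.main_chroms
        }
        for g in ("G3", "G7"):
            members = scheme.members(g)
            if not members:
                continue
            exp_unmasked = np.mean(
                [simgen.expected_global_level(genome, model, taus[c]) for c in members]
            )
            exp_masked = np.mean(
                [
                    simgen.expected_global_level(genome, model, taus[c], selector=sel_out)
                    for c in members
                ]
            )
            row = out[out.group == g].iloc[0]
            assert row["unmasked_mean"] == pytest.approx(exp_unmasked, abs=0.02)
            assert row["masked_mean"] == pytest.approx(exp_masked, abs=0.02)
            assert row["delta"] == pytest.approx(exp_masked - exp_unmasked, abs=0.02)

    def test_removing_hypomethylated_subset_never_decreases_mean(
        self, included_cells, scheme, annotations
    ):
        out = contexts.mask_active_regions(included_cells, scheme, annotations)
        assert (out["n_masked_out"] > 0).any()
        assert (out["delta"] >= 0).all()

    def test_low_cpg_promoter_filter_separates_cgi_promoters(self, genome, annotations):
        prom = annotations.frames["promoter"]
        kept = contexts.filter_low_cpg_promoters(prom, genome.sequences)
        cgi = intervals.as_pyranges(annotations.frames["cgi"][intervals.BED_COLS])
        with_cgi = intervals.as_pyranges(prom[intervals.BED_COLS]).overlap(cgi)
        # kept promoters are exactly those sharing footprint with a CGI
        assert len(kept) == len(with_cgi.df.drop_duplicates())


class TestTertiles:
    def test_bh_worked_example(self):
        q = contexts.benjamini_hochberg([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
    def test_bh_matches_step_up_brute_force(self, pvals):
        got = contexts.benjamini_hochberg(pvals)
        p = np.asarray(pvals)
        m = p.size
        order = np.argsort(p, kind="stable")
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            brute[i] = running
        assert np.allclose(got, brute)
        assert (got >= p - 1e-12).all()

    def test_planted_expression_methylation_coupling(
        self, cohort, included_cells, scheme, genome
    ):
        tc = contexts.expression_tertile_analysis(
            cohort.expression, included_cells, scheme, genome.gene_models
        )
        sizes = sorted(len(v) for v in tc.tertiles.values())
        assert sizes[-1] - sizes[0] <= 1
        all_genes = sorted(g for v in tc.tertiles.values() for g in v)
        assert len(all_genes) == len(set(all_genes))
        assert (tc.tests["q"] >= tc.tests["p"] - 1e-12).all()
        mid = tc.tests[(tc.tests.group.isin(["G3", "G4", "G5"])) & (tc.tests.pair == "high_vs_low")]
        assert (mid["median1"] > mid["median2"]).all()
        assert (mid["q"] < 0.05).all()

    def test_skips_when_too_few_genes(self, included_cells, scheme):
        expr = pd.DataFrame(
            {c: [1] for c in scheme.assignment}, index=["G0000"]
        )
        gm = pd.DataFrame(
            {"gene_id": ["G0000"], "Chromosome": ["chr1"], "Start": [0], "End": [1000]}
        )
        assert (
            contexts.expression_tertile_analysis(expr, included_cells, scheme, gm) is None
        )


class TestNonCgMotifs:
    def test_ch_fraction_definition(self):
        rows = [("chr1", i, "+", 0, 1, "CHH", "CTA") for i in range(990)]
        rows += [("chr1", 5000 + i, "+", 1, 0, "CHH", "CAC") for i in range(10)]
        cells = {"c": _cell(rows)}
        mp = contexts.noncg_motif_profile(cells, _one_group(cells))
        assert mp.summary["ch_fraction"].iloc[0] == pytest.approx(0.01)

    def test_all_methylated_ch_in_cac(self):
        rows = [("chr1", i, "+", 1, 0, "CHH", "CAC") for i in range(10)]
        rows += [("chr1", 100 + i, "+", 0, 1, "CHH", "CTA") for i in range(10)]
        cells = {"c": _cell(rows)}
        mp = contexts.noncg_motif_profile(cells, _one_group(cells))
        assert mp.ch_dinuc_shares.loc["G1", "CAN"] == pytest.approx(1.0)
        assert mp.ch_tri_shares.loc["G1", "CAC"] == pytest.approx(1.0)

    def test_shares_sum_to_one_per_group(self, included_cells, scheme):
        mp = contexts.noncg_motif_profile(included_cells, scheme)
        for df in (mp.ch_tri_shares, mp.ch_dinuc_shares, mp.cg_tri_shares):
            sums = df.sum(axis=1)
            assert np.allclose(sums[sums > 0], 1.0, atol=1e-9)

    def test_ch_fraction_range_matches_observed_mixture(self, included_cells, scheme, model):
        """Observed CH fraction = true CH level + conversion error; across
        groups it spans roughly the 0.7-1.1% window of the study system."""
        mp = contexts.noncg_motif_profile(included_cells, scheme)
        fr = mp.summary.set_index("group")["ch_fraction"]
        assert 0.005 < fr["G1"] < 0.010
        assert fr["G7"] > fr["G1"]
        assert fr["G7"] < 0.015

    def test_motif_shares_match_analytic_expectation(
        self, included_cells, scheme, genome, model, cohort
    ):
        """Multinomial oracle including the conversion-error channel."""
        mp = contexts.noncg_motif_profile(included_cells, scheme)
        taus = cohort.specs.set_index("cell_id")["tau"]
        for g in ("G2", "G6"):
            members = scheme.members(g)
            if not members:
                continue
            tau = float(np.mean([taus[c] for c in members]))
            exp = simgen.expected_ch_motif_shares(genome, model, tau)
            n_meth = mp.summary.set_index("group").loc[g]
            n_meth = n_meth["ch_fraction"] * n_meth["n_ch_calls"]
            for tri in ("CAC", "CAG", "CTA"):
                w = exp[tri]
                tol = 3 * np.sqrt(w * (1 - w) / n_meth) + 0.01
                assert mp.ch_tri_shares.loc[g, tri] == pytest.approx(w, abs=tol)

    def test_site_mode_equivalent_at_depth_one(self, included_cells, scheme):
        sub = {k: included_cells[k] for k in list(included_cells)[:3]}
        sub_scheme = assign_groups(
            {k: 0.05 for k in sub}, "marmoset"
        )
        calls_mode = contexts.noncg_motif_profile(sub, sub_scheme, mode="calls")
        sites_mode = contexts.noncg_motif_profile(sub, sub_scheme, mode="sites")
        a = calls_mode.summary.set_index("group").loc["G1", "ch_fraction"]
        b = sites_mode.summary.set_index("group").loc["G1", "ch_fraction"]
        assert a == pytest.approx(b, abs=1e-3)
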