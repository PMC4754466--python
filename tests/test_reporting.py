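"""Tract summaries, hemisphere pooling, trajectories, reference tables."""

import numpy as np
import pandas as pd
import pytest

import tractmat as tm
from tractmat.reporting import round_half_away


@pytest.fixture(scope="module")
def vertex_results(sheet):
    from tractmat.synthetic import Region

    half = sheet.n_vertices // 2
    regs = [
        Region("fast", np.arange(half), t=(3.0, 3.0)),
        Region("slow", np.arange(half, sheet.n_vertices), t=(8.0, 8.0)),
    ]
    growth = tm.gen_growth_field(sheet, regs, seed=6, smooth_fwhm=0.0)
    subjects = tm.gen_cohort(n=180, seed=7)
    measures = tm.gen_vertex_measures(sheet, growth, subjects, seed=8)
    measures = tm.smooth_measures(sheet, measures, fwhm=8.0)
    fits = tm.fit_vertexwise(measures, subjects, measure="fa")
    return tm.analyze_vertices(fits, sheet, fwhm=8.0)


class TestTractSummary:
    def test_percentages_and_t_plateau_identity(self, vertex_results):
        for s in tm.tract_summary(vertex_results):
            assert 0.0 <= s.p_exp + s.p_lin <= 100.0
            if not np.isnan(s.mean_t):
                assert s.mean_T == pytest.approx(6.0 + np.log(10) * s.mean_t)

    def test_fast_slow_patch_ordering(self, vertex_results, sheet):
        # the t=8 patch is close to linear over ages 6-30, so AIC assigns many
        # of its vertices to the linear model; the exponential subset must
        # still order the two patches correctly by mean plateau age
        half = sheet.n_vertices // 2
        fast = vertex_results[vertex_results["vertex_id"] < half]
        slow = vertex_results[vertex_results["vertex_id"] >= half]
        for sub in (fast, slow):
            assert (sub["model"] != "none").mean() > 0.3
        t_fast = tm.tract_summary(fast)[0].mean_T
        t_slow = tm.tract_summary(slow)[0].mean_T
        assert t_fast < t_slow

    def test_permutation_invariance(self, vertex_results):
        shuffled = vertex_results.sample(frac=1.0, random_state=0)
        a = tm.tract_summary(vertex_results)[0]
        b = tm.tract_summary(shuffled)[0]
        assert a.p_exp == pytest.approx(b.p_exp)
        assert a.mean_T == pytest.approx(b.mean_T, nan_ok=True)

    def test_single_vertex_percentages_binary(self, vertex_results):
        one = vertex_results[(vertex_results["vertex_id"] == 0)]
        for s in tm.tract_summary(one):
            assert s.p_exp in (0.0, 100.0) and s.p_lin in (0.0, 100.0)

    def test_empty_results_flagged(self):
        empty = pd.DataFrame(
            columns=["sex", "measure", "model", "lin_p", "exp_p", "exp_r", "lin_r",
                     "exp_t", "exp_se_t", "rate", "lin_a"]
        )
        empty.loc[0] = ["F", "fa", "none", np.nan, np.nan, np.nan, np.nan,
                        np.nan, np.nan, np.nan, np.nan]
        out = tm.tract_summary(empty)
        assert out[0].empty


class TestCombineHemispheres:
    def test_identical_sides_summary_unchanged(self, vertex_results):
        combined = tm.combine_hemispheres(vertex_results, vertex_results)
        a = tm.tract_summary(vertex_results)[0]
        b = tm.tract_summary(combined)[0]
        assert b.p_exp == pytest.approx(a.p_exp)
        assert b.mean_T == pytest.approx(a.mean_T, nan_ok=True)
        assert b.n_vertices == 2 * a.n_vertices

    def test_one_empty_side(self, vertex_results):
        empty = vertex_results.iloc[:0]
        out = tm.combine_hemispheres(vertex_results, empty)
        pd.testing.assert_frame_equal(out, vertex_results)

    def test_pooled_mean_is_count_weighted(self, vertex_results, sheet):
        half = sheet.n_vertices // 2
        left = vertex_results[vertex_results["vertex_id"] < half].reset_index(drop=True)
        right = vertex_results[vertex_results["vertex_id"] >= half].reset_index(drop=True)
        combined = tm.combine_hemispheres(left, right)
        sl, sr = tm.tract_summary(left)[0], tm.tract_summary(right)[0]
        sc = tm.tract_summary(combined)[0]
        nl = (left.loc[left["model"] == "exponential"]).shape[0] and \
            ((left["model"] == "exponential") & (left["sex"] == sl.sex)).sum()
        nr = ((right["model"] == "exponential") & (right["sex"] == sl.sex)).sum()
        expected = (sl.mean_t * nl + sr.mean_t * nr) / (nl + nr)
        assert sc.mean_t == pytest.approx(expected)

    def test_mismatched_groups_rejected(self, vertex_results):
        other = vertex_results.copy()
        other["measure"] = "md"
        with pytest.raises(ValueError, match="mismatched"):
            tm.combine_hemispheres(vertex_results, other)


class TestMeanTrajectory:
    def test_noiseless_subject_means_on_curve(self, sheet):
        from tractmat.synthetic import Region

        reg = Region("all", np.arange(sheet.n_vertices),
                     C=(0.55, 0.55), A=(-0.2, -0.2), t=(4.0, 4.0))
        growth = tm.gen_growth_field(sheet, [reg], seed=0, smooth_fwhm=0.0, noise_sd=0.0)
        subjects = tm.gen_cohort(n=30, seed=1)
        measures = tm.gen_vertex_measures(sheet, growth, subjects, seed=0)
        series = tm.mean_trajectory(measures, np.ones(sheet.n_vertices, bool), subjects)
        expected = 0.55 - 0.2 * np.exp(-series["age"] / 4.0)
        assert np.allclose(series["mean_value"], expected, atol=1e-12)
        for fit in series.attrs["fits"].values():
            assert fit.t == pytest.approx(4.0, abs=1e-4)

    def test_group_fit_recovers_common_t(self, sheet):
        from tractmat.synthetic import Region

        reg = Region("all", np.arange(sheet.n_vertices),
                     C=(0.55, 0.55), A=(-0.35, -0.35), t=(4.0, 4.0))
        growth = tm.gen_growth_field(sheet, [reg], seed=0, smooth_fwhm=0.0, noise_sd=0.03)
        subjects = tm.gen_cohort(n=178, seed=2)
        measures = tm.gen_vertex_measures(sheet, growth, subjects, seed=3)
        series = tm.mean_trajectory(measures, np.ones(sheet.n_vertices, bool), subjects)
        for fit in series.attrs["fits"].values():
            assert fit.t == pytest.approx(4.0, rel=0.15)

    def test_constant_shift_moves_asymptote_only(self, sheet, rng):
        from tractmat.synthetic import Region

        reg = Region("all", np.arange(sheet.n_vertices),
                     C=(0.5, 0.5), A=(-0.3, -0.3), t=(4.0, 4.0))
        growth = tm.gen_growth_field(sheet, [reg], seed=0, smooth_fwhm=0.0, noise_sd=0.02)
        subjects = tm.gen_cohort(n=90, seed=4)
        measures = tm.gen_vertex_measures(sheet, growth, subjects, seed=5, clip_fa=False)
        mask = np.ones(sheet.n_vertices, bool)
        base = tm.mean_trajectory(measures, mask, subjects)
        shifted_ms = tm.VertexMeasureSet(
            measures.subject_ids, measures.fa + 0.1, measures.md + 0.1
        )
        shifted = tm.mean_trajectory(shifted_ms, mask, subjects)
        for sex in ("F", "M"):
            f0, f1 = base.attrs["fits"][sex], shifted.attrs["fits"][sex]
            assert f1.C - f0.C == pytest.approx(0.1, abs=1e-6)
            assert f1.t == pytest.approx(f0.t, rel=1e-4)

    def test_empty_mask_rejected(self, sheet):
        ms = tm.VertexMeasureSet(["a"], np.zeros((1, sheet.n_vertices)),
                                 np.zeros((1, sheet.n_vertices)))
        with pytest.raises(ValueError, match="empty"):
            tm.mean_trajectory(ms, np.zeros(sheet.n_vertices, bool),
                               pd.DataFrame({"id": ["a"], "age": [10.0], "sex": ["F"]}))


class TestReferenceTables:
    def test_percent_summaries_match_published_text(self):
        ref = tm.load_reference_fits()
        fa = ref[ref["measure"] == "fa"]
        md = ref[ref["measure"] == "md"]
        assert round_half_away(fa["p_exp"].mean()) == 27
        assert round_half_away(fa["p_lin"].mean()) == 14
        assert round_half_away(md["p_exp"].mean()) == 51
        assert round_half_away((fa["p_exp"] + fa["p_lin"]).mean()) == 41

    def test_female_minus_male_md_exponential_gap(self):
        md = tm.load_reference_fits().query("measure == 'md'")
        piv = md.pivot(index="tract", columns="sex", values="p_exp")
        assert round_half_away((piv["F"] - piv["M"]).mean()) == 12

    def test_mean_plateau_ages_by_sex(self):
        ref = tm.load_reference_fits()
        assert round_half_away(ref.query("sex == 'F'")["T"].mean()) == 15
        assert round_half_away(ref.query("sex == 'M'")["T"].mean()) == 21

    def test_sex_significant_tract_sets(self):
        ref = tm.load_reference_fits()
        assert tm.sex_significant_tracts(ref, "fa") == {"CST", "SLF"}
        assert tm.sex_significant_tracts(ref, "md") == {"CST", "SLF", "IFO", "ILF"}
        # and they agree with the published flags row by row
        for _, grp in ref.groupby(["measure", "tract"]):
            f = grp[grp["sex"] == "F"].iloc[0]
            m = grp[grp["sex"] == "M"].iloc[0]
            sig, _ = tm.sex_overlap_test(f["T"], f["se_T"], m["T"], m["se_T"])
            assert sig == bool(f["sex_sig"])


def test_round_half_away_from_zero():
    assert round_half_away(0.5) == 1.0
    assert round_half_away(-0.5) == -1.0
    assert round_half_away(2.5) == 3.0
    assert round_half_away(12.45, 1) == 12.5
    assert np.array_equal(round_half_away(np.array([1.5, 2.5]), 0), [2.0, 3.0])
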