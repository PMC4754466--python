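"""Synthetic cohort, growth field, and embedded volume generators."""

import numpy as np
import pandas as pd
import pytest

import tractmat as tm
from tractmat.inference import LN10
from tractmat.synthetic import Region


class TestGenSurface:
    def test_grid_combinatorics(self):
        surf = tm.gen_surface("flat_sheet", 20, 10, (40.0, 20.0))
        assert surf.n_vertices == 200
        assert surf.n_triangles == 2 * 19 * 9

    def test_constant_radius_sheet_satisfies_invariants(self, sheet):
        assert np.all(sheet.radius > 0)
        assert np.allclose(np.linalg.norm(sheet.vertex_normals, axis=1), 1.0)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            tm.gen_surface("flat_sheet", 10, 5, (20.0, 10.0),
                           radius_spec={"kind": "linear", "r0": 1.0, "slope": -0.2})

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            tm.gen_surface("sphere", 5, 5, (10.0, 10.0))


class TestGenCohort:
    def test_study_sex_split(self):
        cohort = tm.gen_cohort(n=178, female_fraction=95 / 178, seed=0)
        assert (cohort["sex"] == "M").sum() == 83
        assert (cohort["sex"] == "F").sum() == 95

    def test_deterministic_under_seed(self):
        a = tm.gen_cohort(n=40, seed=7)
        b = tm.gen_cohort(n=40, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_uniform_age_moments(self):
        cohort = tm.gen_cohort(n=10_000, age_min=6, age_max=30, seed=3)
        se = (30 - 6) / np.sqrt(12) / np.sqrt(10_000)
        assert abs(cohort["age"].mean() - 18.0) < 3 * se

    def test_empirical_age_preset_matches_study_moments(self):
        cohort = tm.gen_cohort(n=20_000, seed=4, age_distribution="empirical")
        for sex, (mu, sd) in tm.synthetic.STUDY_AGE_MOMENTS.items():
            ages = cohort.loc[cohort["sex"] == sex, "age"]
            assert abs(ages.mean() - mu) < 0.35  # truncation shifts the mean slightly
            assert ages.between(6, 30).all()

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            tm.gen_cohort(n=5, age_min=30, age_max=6)


class TestGrowthField:
    def test_single_region_fixed_parameters_constant_maps(self, sheet):
        reg = Region("all", np.arange(sheet.n_vertices),
                     C=(0.5, 0.5), A=(-0.3, -0.3), t=(4.0, 4.0))
        growth = tm.gen_growth_field(sheet, [reg], seed=0, smooth_fwhm=0.0)
        assert np.allclose(growth.C, 0.5)
        assert np.allclose(growth.A, -0.3)
        assert np.allclose(growth.t, 4.0)

    def test_two_regions_bimodal_t_before_smoothing(self, sheet):
        half = sheet.n_vertices // 2
        regs = [
            Region("fast", np.arange(half), t=(3.0, 3.0)),
            Region("slow", np.arange(half, sheet.n_vertices), t=(8.0, 8.0)),
        ]
        growth = tm.gen_growth_field(sheet, regs, seed=0, smooth_fwhm=0.0)
        assert set(np.round(growth.t, 6)) == {3.0, 8.0}

    def test_sex_effect_plateau_offset(self, sheet):
        growth = tm.gen_growth_field(
            sheet, [Region("all", np.arange(sheet.n_vertices))], seed=1,
            sex_effect={"t_scale": 1.8},
        )
        diff = growth.plateau_ages("M") - growth.plateau_ages("F")
        assert np.allclose(diff, LN10 * 0.8 * growth.t)

    def test_regions_must_partition(self, sheet):
        with pytest.raises(ValueError, match="partition"):
            tm.gen_growth_field(sheet, [Region("half", np.arange(10))], seed=0)
        with pytest.raises(ValueError, match="empty"):
            tm.gen_growth_field(sheet, [Region("none", np.array([], dtype=int))], seed=0)

    def test_ground_truth_plateau_identity(self, sheet):
        growth = tm.gen_growth_field(sheet, [Region("all", np.arange(sheet.n_vertices))], seed=2)
        assert np.allclose(growth.plateau_ages("F"), 6.0 + growth.t * LN10)


class TestGenVertexMeasures:
    def test_noiseless_evaluation_exact(self, sheet):
        reg = Region("all", np.arange(sheet.n_vertices),
                     C=(0.55, 0.55), A=(-0.2, -0.2), t=(4.0, 4.0))
        growth = tm.gen_growth_field(sheet, [reg], seed=0, smooth_fwhm=0.0, noise_sd=0.0)
        subjects = pd.DataFrame({"id": ["s0"], "age": [6.0], "sex": ["F"]})
        out = tm.gen_vertex_measures(sheet, growth, subjects, seed=0)
        assert np.allclose(out.fa[0], 0.55 - 0.2 * np.exp(-1.5), atol=1e-12)

    def test_noise_sd_calibrated(self, sheet):
        reg = Region("all", np.arange(sheet.n_vertices),
                     C=(0.5, 0.5), A=(-0.3, -0.3), t=(4.0, 4.0))
        growth = tm.gen_growth_field(sheet, [reg], seed=0, smooth_fwhm=0.0, noise_sd=0.03)
        subjects = tm.gen_cohort(n=50, seed=5)
        out = tm.gen_vertex_measures(sheet, growth, subjects, seed=5)
        truth = np.vstack(
            [growth.curve(np.array([r["age"]]), r["sex"])[0] for _, r in subjects.iterrows()]
        )
        resid = (out.fa - truth).ravel()  # n = 50 * 200 = 10,000 draws
        assert abs(resid.std() - 0.03) / 0.03 < 0.05

    def test_null_vertices_have_no_age_trend(self, sheet):
        from tractmat.fitting import fit_linear

        reg = Region("all", np.arange(sheet.n_vertices), model="none",
                     intercept=(0.4, 0.4))
        growth = tm.gen_growth_field(sheet, [reg], seed=0, smooth_fwhm=0.0, noise_sd=0.03)
        covered = 0
        n_seeds = 20
        for seed in range(n_seeds):
            subjects = tm.gen_cohort(n=60, seed=100 + seed)
            out = tm.gen_vertex_measures(sheet, growth, subjects, seed=200 + seed)
            fit = fit_linear(subjects["age"].to_numpy(), out.fa[:, seed])
            covered += abs(fit.a) <= 1.96 * fit.se_a
        assert covered / n_seeds >= 0.9

    def test_reproducible_and_missingness(self, sheet):
        growth = tm.gen_growth_field(sheet, [Region("all", np.arange(sheet.n_vertices))], seed=0)
        subjects = tm.gen_cohort(n=10, seed=1)
        a = tm.gen_vertex_measures(sheet, growth, subjects, seed=3, missing_rate=0.2)
        b = tm.gen_vertex_measures(sheet, growth, subjects, seed=3, missing_rate=0.2)
        assert np.array_equal(a.fa, b.fa, equal_nan=True)
        frac = np.isnan(a.fa).mean()
        assert 0.15 < frac < 0.25


class TestGenTensorVolume:
    def test_background_only_volume_all_missing(self, sheet):
        reg = Region("all", np.arange(sheet.n_vertices))
        growth = tm.gen_growth_field(sheet, [reg], seed=0)
        subj = pd.Series({"id": "s0", "age": 20.0, "sex": "F"})
        vol = tm.gen_tensor_volume(sheet, growth, subj)
        bg = tm.DiffusionTensorVolume(
            np.tile(0.9e-3 * np.eye(3), vol.grid_shape + (1, 1)), vol.affine
        )
        fa, _ = tm.sample_max_fa(sheet, tm.build_spokes(sheet), bg)
        assert np.all(np.isnan(fa))

    def test_round_trip_fa_md(self, sheet):
        regs = [Region("all", np.arange(sheet.n_vertices))]
        growth = tm.gen_growth_field(sheet, regs, seed=4)
        md_field = tm.gen_growth_field(
            sheet, [Region.md("all", np.arange(sheet.n_vertices))], seed=5,
            noise_sd=tm.synthetic.NOISE_SD_MD,
        )
        subj = pd.Series({"id": "s0", "age": 14.0, "sex": "M"})
        vol = tm.gen_tensor_volume(sheet, growth, subj, md_field=md_field)
        fa, md = tm.sample_max_fa(sheet, tm.build_spokes(sheet), vol)
        fa_true = growth.curve(np.array([14.0]), "M")[0]
        md_true = md_field.curve(np.array([14.0]), "M")[0]
        ok = ~np.isnan(fa)
        assert ok.mean() > 0.95
        assert np.max(np.abs(fa[ok] - fa_true[ok])) < 0.02
        assert np.max(np.abs(md[ok] - md_true[ok]) / md_true[ok]) < 0.02

    def test_finer_voxels_reduce_round_trip_error(self):
        surf = tm.gen_surface("flat_sheet", 12, 6, (22.0, 10.0))
        growth = tm.gen_growth_field(surf, [Region("all", np.arange(surf.n_vertices))], seed=6)
        subj = pd.Series({"id": "s0", "age": 25.0, "sex": "F"})
        spokes = tm.build_spokes(surf)
        errs = []
        truth = growth.curve(np.array([25.0]), "F")[0]
        for voxel in (2.0, 1.0):
            vol = tm.gen_tensor_volume(surf, growth, subj, voxel_size=voxel)
            fa, _ = tm.sample_max_fa(surf, spokes, vol)
            ok = ~np.isnan(fa)
            errs.append(np.mean(np.abs(fa[ok] - truth[ok])))
        assert errs[1] <= errs[0]
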