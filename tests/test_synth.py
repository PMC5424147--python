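import numpy as np
import pandas as pd
import pytest

from netresp import synth
from netresp.stats import pearson_ci


class TestCohort:
    def test_shape_and_columns(self):
        c = synth.make_cohort(synth.CohortSpec(n_subjects=20, seed=1))
        assert len(c) == 20
        for col in ("subject", "age", "education", "handedness", "gender",
                    "latent_g"):
            assert col in c.columns

    def test_deterministic(self):
        a = synth.make_cohort(synth.CohortSpec(n_subjects=10, seed=5))
        b = synth.make_cohort(synth.CohortSpec(n_subjects=10, seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_age_range_respected(self):
        c = synth.make_cohort(synth.CohortSpec(n_subjects=200, seed=0))
        assert c["age"].between(23, 87).all()

    def test_too_small_cohort_rejected(self):
        with pytest.raises(synth.InvalidSpecError):
            synth.CohortSpec(n_subjects=2)

    def test_zscore_age_uniform_moments(self):
        ages = np.random.default_rng(0).uniform(23, 87, 100000)
        z = synth.zscore_age(ages)
        assert abs(z.mean()) < 0.02
        assert abs(z.std() - 1.0) < 0.02


class TestSpatialStructure:
    def test_default_scenario_maps_separable(self, default_scenario_fi):
        maps = synth.component_maps(default_scenario_fi)
        k = maps.shape[0]
        C = np.abs(np.corrcoef(maps))
        np.fill_diagonal(C, 0.0)
        assert C.max() < 0.3

    def test_tissue_masks_partition_grid(self, default_scenario_fi):
        masks = synth.tissue_masks(default_scenario_fi.grid_shape)
        total = (masks["gm"].astype(int) + masks["wm"].astype(int)
                 + masks["csf"].astype(int))
        assert np.all(total == 1)

    def test_dm_templates_inside_grid(self, default_scenario_fi):
        tpl = synth.dm_template_masks(default_scenario_fi.grid_shape)
        assert set(dict(synth.DM_REGION_CENTERS)) == set(tpl)
        for m in tpl.values():
            assert m.any()

    def test_nonneural_components_outside_gm(self, default_scenario_fi):
        masks = synth.tissue_masks(default_scenario_fi.grid_shape)
        maps = synth.component_maps(default_scenario_fi)
        kinds = default_scenario_fi.component_kinds()
        for m, kind in zip(maps, kinds):
            grid = m.reshape(default_scenario_fi.grid_shape)
            frac_gm = grid[masks["gm"]].sum() / grid.sum()
            if kind in ("vascular", "noise"):
                assert frac_gm < 0.5
            else:
                assert frac_gm > 0.8


class TestTimecourses:
    def test_deterministic(self, small_cohort, small_scenario):
        a = synth.simulate_component_timecourses(small_cohort,
                                                 small_scenario, seed=3)
        b = synth.simulate_component_timecourses(small_cohort,
                                                 small_scenario, seed=3)
        for task in a:
            assert np.array_equal(a[task], b[task])

    def test_noiseless_matches_design(self, small_cohort, small_scenario):
        tcs = synth.simulate_component_timecourses(
            small_cohort, small_scenario, seed=0, noiseless=True)
        task = small_scenario.tasks[0]
        amps = synth.subject_condition_amplitudes(
            small_cohort, small_scenario, task, seed=0)
        expected = np.einsum("sck,tk->sct", amps,
                             task.design().regressors)
        assert np.allclose(tcs[task.name], expected)

    def test_vascular_baseline_is_high_frequency(self, default_scenario_fi):
        from scipy.signal import welch
        cohort = synth.make_cohort(synth.CohortSpec(n_subjects=4, seed=0))
        tcs = synth.simulate_component_timecourses(
            cohort, default_scenario_fi, seed=0)["FI"]
        kinds = default_scenario_fi.component_kinds()
        task = default_scenario_fi.task("FI")
        vi = int(np.where(kinds == "vascular")[0][0])
        ni = int(np.where(kinds == "neural")[0][0])
        f, p_v = welch(tcs[0, vi], fs=1 / task.tr, nperseg=128)
        _, p_n = welch(tcs[0, ni], fs=1 / task.tr, nperseg=128)
        hi = (f >= 0.15) & (f <= 0.25)
        lo = (f >= 0.01) & (f <= 0.10)
        assert p_v[hi].mean() > p_v[lo].mean()
        assert p_n[lo].mean() > p_n[hi].mean()

    def test_planted_responsivity_age_gradient(self, default_scenario_fi):
        cohort = synth.make_cohort(synth.CohortSpec(n_subjects=400, seed=2))
        truth = synth.true_responsivity(cohort, default_scenario_fi,
                                        default_scenario_fi.task("FI"),
                                        seed=2)
        kinds = default_scenario_fi.component_kinds()
        ages = cohort["age"].to_numpy()
        for ci in np.where(kinds == "neural")[0][:4]:
            r = pearson_ci(truth[:, ci], ages)
            if default_scenario_fi.components[ci].amplitudes["FI"].age_slope \
                    < 0:
                assert r.r < -0.2

    def test_dm_suppression_planted(self, default_scenario_fi):
        cohort = synth.make_cohort(synth.CohortSpec(n_subjects=200, seed=1))
        truth = synth.true_responsivity(cohort, default_scenario_fi,
                                        default_scenario_fi.task("FI"),
                                        seed=1)
        kinds = default_scenario_fi.component_kinds()
        dm_mean = truth[:, kinds == "dm"].mean()
        assert dm_mean < 0


class TestBold:
    def test_image_shapes(self, small_sim, small_cohort, small_scenario):
        task = small_scenario.tasks[0]
        img = small_sim["images"][(small_cohort["subject"][0], task.name)]
        assert img.shape == small_scenario.grid_shape + (task.n_volumes,)

    def test_noiseless_bold_is_exact_mixture(self, small_cohort,
                                             small_scenario):
        sim = synth.simulate_task_bold(small_cohort, small_scenario,
                                       seed=0, noiseless=True)
        task = small_scenario.tasks[0].name
        maps = sim["maps"]
        s0 = small_cohort["subject"][0]
        img = sim["images"][(s0, task)]
        expected = (maps.T @ sim["timecourses"][task][0]).reshape(img.shape)
        assert np.allclose(img, expected, atol=1e-5)

    def test_events_tables_sorted(self, small_sim):
        for ev in small_sim["events"].values():
            assert (ev["onset"].diff().dropna() >= 0).all()

    def test_motion_shapes(self, small_sim, small_scenario):
        task = small_scenario.tasks[0]
        for mot in small_sim["motion"].values():
            assert mot.shape == (task.n_volumes, 6)


class TestBehaviour:
    def test_planted_age_effect(self, default_scenario_fi):
        cohort = synth.make_cohort(synth.CohortSpec(n_subjects=400, seed=0))
        beh = synth.make_behavior(cohort, default_scenario_fi, seed=0)
        fi = beh[beh["task"] == "FI"]
        r = pearson_ci(fi["score"], cohort["age"])
        assert r.r < -0.5

    def test_deterministic(self, small_cohort, small_scenario):
        a = synth.make_behavior(small_cohort, small_scenario, seed=9)
        b = synth.make_behavior(small_cohort, small_scenario, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestTrivariate:
    def test_recovers_requested_correlations(self):
        C = ((1.0, -0.72, -0.68), (-0.72, 1.0, 0.708), (-0.68, 0.708, 1.0))
        df = synth.sample_trivariate(synth.TrivariateSpec(C, 200000, seed=0))
        got = np.corrcoef(df.to_numpy().T)
        assert np.allclose(got, np.asarray(C), atol=0.01)

    def test_invalid_matrix_rejected(self):
        bad = ((1.0, 0.9, -0.9), (0.9, 1.0, 0.9), (-0.9, 0.9, 1.0))
        with pytest.raises(synth.InvalidSpecError):
            synth.sample_trivariate(synth.TrivariateSpec(bad, 100))

    def test_asymmetric_matrix_rejected(self):
        bad = ((1.0, 0.5, 0.2), (0.4, 1.0, 0.1), (0.2, 0.1, 1.0))
        with pytest.raises(synth.InvalidSpecError):
            synth.TrivariateSpec(bad, 100).matrix()
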