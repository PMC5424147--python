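import numpy as np
import pandas as pd
import pytest

from netresp import classify as cls
from netresp import synth
from netresp.preprocess import GridError


class TestThresholdMapMixture:
    def test_planted_mixture_recovered(self, rng):
        null = rng.normal(0, 1, 3000)
        signal = rng.normal(6, 1, 300)
        x = np.concatenate([null, signal])
        truth = np.concatenate([np.zeros(3000, bool), np.ones(300, bool)])
        thr = cls.threshold_map_mixture(x)
        agreement = (thr.retained == truth).mean()
        assert agreement >= 0.95

    def test_constant_map_returns_empty(self):
        thr = cls.threshold_map_mixture(np.full(200, 1.5))
        assert thr.n_retained == 0

    def test_retained_loadings_zero_outside(self, rng):
        x = np.concatenate([rng.normal(0, 1, 2000), rng.normal(5, 1, 200)])
        thr = cls.threshold_map_mixture(x)
        assert np.all(thr.loadings[~thr.retained] == 0)
        assert np.all(thr.loadings[thr.retained] == x[thr.retained])

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError):
            cls.threshold_map_mixture(np.zeros(50))

    def test_equal_variance_crossing_closed_form(self):
        # equal priors: crossing at the midpoint of the means
        assert cls.equal_variance_crossing(0.0, 4.0, 1.0) \
            == pytest.approx(2.0)
        # unequal priors shift toward the rarer class
        assert cls.equal_variance_crossing(0.0, 4.0, 1.0, pi0=0.9) > 2.0


class TestTissueOverlap:
    def test_full_overlap(self, rng):
        x = np.concatenate([rng.normal(0, 1, 2000), rng.normal(6, 1, 200)])
        thr = cls.threshold_map_mixture(x)
        mask = np.ones(2200, dtype=bool)
        assert cls.tissue_overlap(thr, mask) == pytest.approx(1.0)

    def test_weighted_fraction(self):
        thr = cls.ThresholdedMap(
            retained=np.array([True, True, False]),
            loadings=np.array([3.0, 1.0, 0.0]),
            threshold=1.0, converged=True)
        mask = np.array([True, False, False])
        assert cls.tissue_overlap(thr, mask) == pytest.approx(0.75)

    def test_empty_retained_gives_nan(self):
        thr = cls.ThresholdedMap(retained=np.zeros(3, bool),
                                 loadings=np.zeros(3),
                                 threshold=np.inf, converged=False)
        assert np.isnan(cls.tissue_overlap(thr, np.ones(3, bool)))

    def test_grid_mismatch(self):
        thr = cls.ThresholdedMap(retained=np.ones(3, bool),
                                 loadings=np.ones(3),
                                 threshold=0.0, converged=True)
        with pytest.raises(GridError):
            cls.tissue_overlap(thr, np.ones(4, bool))


class TestSpectralMetrics:
    def test_low_frequency_signal_high_ratio(self):
        tr = 1.97
        t = np.arange(256) * tr
        x = np.sin(2 * np.pi * 0.03 * t)
        ratio, drange = cls.spectral_metrics(x, tr)
        assert ratio > 10
        assert drange > cls.DYNAMIC_RANGE_THRESHOLD

    def test_high_frequency_signal_low_ratio(self):
        tr = 1.97
        t = np.arange(256) * tr
        x = np.sin(2 * np.pi * 0.2 * t)
        ratio, _ = cls.spectral_metrics(x, tr)
        assert ratio < cls.RATIO_THRESHOLD

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(200)
        a = cls.spectral_metrics(x, 2.0)
        b = cls.spectral_metrics(1000.0 * x, 2.0)
        assert np.allclose(a, b)

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError):
            cls.spectral_metrics(rng.standard_normal(40), 2.0)


class TestClassifyComponents:
    def _metrics(self, ratio, drange, gm):
        return pd.DataFrame([{"component": 0, "low_high_ratio": ratio,
                              "dynamic_range": drange, "gm_overlap": gm,
                              "wm_overlap": 0.0, "csf_overlap": 0.0,
                              "n_retained": 10}])

    def test_boundary_ratio_rule(self):
        # just below the ratio threshold -> non-neural
        out = cls.classify_components(self._metrics(0.64, 0.05, 0.9))
        assert not out["neural"].iloc[0]
        out = cls.classify_components(self._metrics(0.65, 0.05, 0.9))
        assert out["neural"].iloc[0]

    def test_dynamic_range_rule(self):
        out = cls.classify_components(self._metrics(2.0, 0.017, 0.9))
        assert not out["neural"].iloc[0]

    def test_gm_overlap_rule(self):
        out = cls.classify_components(self._metrics(2.0, 0.05, 0.74))
        assert not out["neural"].iloc[0]

    def test_nan_overlap_excluded(self):
        out = cls.classify_components(self._metrics(2.0, 0.05, np.nan))
        assert not out["neural"].iloc[0]

    def test_motor_exclusion_keeps_neural_flag(self):
        out = cls.classify_components(self._metrics(2.0, 0.05, 0.9),
                                      motor_exclude=(0,))
        assert out["neural"].iloc[0]
        assert out["motor_excluded"].iloc[0]
        assert not out["included"].iloc[0]

    def test_planted_nonneural_flagged_exactly(self, default_scenario_fi):
        # on the default scenario the planted vascular and noise components
        # (and only those) must be flagged non-neural
        import warnings
        sc = default_scenario_fi
        cohort = synth.make_cohort(synth.CohortSpec(n_subjects=6, seed=11))
        tcs = synth.simulate_component_timecourses(cohort, sc, seed=11)["FI"]
        d = {s: tcs[s].T for s in range(tcs.shape[0])}
        masks = synth.tissue_masks(sc.grid_shape)
        maps = synth.component_maps(sc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            met = cls.component_metrics(d, maps, masks, tr=1.97)
        flags = cls.classify_components(met)
        pred = set(flags.loc[~flags["neural"], "component"])
        kinds = sc.component_kinds()
        truth = set(np.where(np.isin(kinds, ["vascular", "noise"]))[0]
                    .tolist())
        assert pred == truth


class TestIdentifyDM:
    def test_planted_dm_components_found(self, default_scenario_fi):
        sc = default_scenario_fi
        maps = synth.component_maps(sc)
        templates = synth.dm_template_masks(sc.grid_shape)
        kinds = sc.component_kinds()
        out = cls.identify_dm(maps, templates)
        pred = set(out.loc[out["dm_member"], "component"])
        truth = set(np.where(kinds == "dm")[0].tolist())
        assert pred == truth

    def test_medial_subset_excludes_lateral_parietal(self,
                                                     default_scenario_fi):
        sc = default_scenario_fi
        maps = synth.component_maps(sc)
        templates = synth.dm_template_masks(sc.grid_shape)
        out = cls.identify_dm(maps, templates)
        lateral = out["best_region"].isin(["ipl_left", "ipl_right"])
        assert not (out["dm_medial"] & lateral).any()
        assert out.loc[out["dm_medial"], "dm_member"].all()

    def test_no_member_warns(self, rng):
        maps = rng.standard_normal((2, 400))
        templates = {"pcc": np.zeros(400, dtype=bool)}
        templates["pcc"][:5] = True
        with pytest.warns(UserWarning):
            cls.identify_dm(maps, templates)
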