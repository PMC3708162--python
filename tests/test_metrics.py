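"""Slope metrics: medians, outlier pruning, correlation points, OLS fits."""

import numpy as np
import pandas as pd
import pytest

from phonconv import bark, metrics
from phonconv.acoustics import measurements_from_simulation
from phonconv.design import ExperimentDesign
from phonconv.simulate import make_profiles, simulate_experiment

ZW = bark.ZWICKER_STANDARD


def tiny_tables(bark_values, n_total=None, variant=bark.AS_PRINTED):
    """One subject, one baseline sub-block of /i/ trials with the given bark
    F0 values (F1 mirrors F0); omitted trials fill up to ``n_total``."""
    n_total = n_total or len(bark_values)
    trials, meas = [], []
    for i in range(n_total):
        spoken = i < len(bark_values)
        trials.append(
            {
                "experiment": "production", "subject_id": "P01",
                "subject_gender": "female", "persona_id": "P01",
                "speaker_set": "female", "congruency": "same",
                "block_index": 1, "speaker_id": "", "sub_block_role": "baseline_ortho",
                "trial_index": i + 1, "cue": "orthographic", "vowel": "i",
                "response_kind": "spoken" if spoken else "omission",
                "audio_path": "", "sim_f0_hz": np.nan, "sim_f1_hz": np.nan,
            }
        )
        hz = bark.bark_to_hz(bark_values[i], variant) if spoken else np.nan
        meas.append(
            {
                "experiment": "production", "subject_id": "P01", "trial_index": i + 1,
                "seg_start": np.nan, "seg_end": np.nan, "peak_time": np.nan,
                "f0_hz": hz, "f1_hz": hz, "valid": spoken,
                "invalid_reason": "none" if spoken else "omission",
            }
        )
    return pd.DataFrame(meas), pd.DataFrame(trials)


class TestMedians:
    def test_odd_count_median(self):
        meas, trials = tiny_tables([2.0, 2.1, 2.2, 2.3, 2.4])
        med = metrics.compute_subblock_medians(meas, trials)
        f0 = med[(med.measure == "f0")]
        assert f0["median_bark"].iloc[0] == pytest.approx(2.2, abs=1e-9)

    def test_even_count_median_is_midpoint(self):
        meas, trials = tiny_tables([2.0, 2.0, 3.0, 3.0])
        med = metrics.compute_subblock_medians(meas, trials)
        assert med["median_bark"].iloc[0] == pytest.approx(2.5, abs=1e-9)

    def test_all_omissions_undefined_with_reason(self):
        meas, trials = tiny_tables([], n_total=5)
        med = metrics.compute_subblock_medians(meas, trials)
        assert med["median_bark"].isna().all()
        assert (med["undefined_reason"] == "too_few_valid_trials").all()

    def test_below_min_valid_undefined(self):
        meas, trials = tiny_tables([2.0], n_total=5)
        med = metrics.compute_subblock_medians(meas, trials, min_valid=2)
        assert med["median_bark"].isna().all()

    def test_shared_subblock_serves_two_roles(self):
        """A post-exposure sub-block of block k reappears as the baseline of
        block k+1 with the identical median."""
        design = ExperimentDesign("production", n_subjects=4, error_rate=0.0)
        profs = make_profiles(design, np.random.SeedSequence(3),
                              noise_sd=(0.0, 0.0), error_rate=0.0)
        res = simulate_experiment([design], {"production": profs}, seed=3)
        meas = measurements_from_simulation(res.trials)
        med = metrics.compute_subblock_medians(meas, res.trials)
        one = med[(med.subject_id == "P01") & (med.measure == "f0") & (med.vowel == "i")]
        post1 = one[(one.block_index == 1) & (one.role == "post")]["median_bark"].iloc[0]
        base2 = one[(one.block_index == 2) & (one.role == "baseline")]["median_bark"].iloc[0]
        assert post1 == base2
        # 3 baselines + 3 acoustic + 3 post rows per vowel/measure
        assert len(one) == 9


def median_frame(values):
    n = len(values)
    return pd.DataFrame(
        {
            "experiment": "production", "subject_id": [f"P{i:02d}" for i in range(n)],
            "block_index": 1, "role": "baseline", "vowel": "i", "measure": "f0",
            "median_bark": values, "n_valid_trials": 5, "outlier": False,
            "undefined_reason": "",
        }
    )


class TestMedianOutliers:
    def test_identical_values_flag_nothing(self):
        out = metrics.flag_median_outliers(median_frame([2.0] * 24))
        assert not out["outlier"].any()

    def test_single_extreme_value_flagged(self):
        vals = [2.0] * 23 + [9.0]
        out = metrics.flag_median_outliers(median_frame(vals))
        # oracle: direct mean/SD computation
        arr = np.array(vals)
        expected = np.abs(arr - arr.mean()) > 2 * arr.std(ddof=1)
        assert list(out["outlier"]) == list(expected)
        assert out["outlier"].sum() == 1

    def test_unreachable_bound_flags_nothing(self):
        rng = np.random.default_rng(0)
        out = metrics.flag_median_outliers(median_frame(rng.normal(2, 0.1, 24)), k=1000)
        assert not out["outlier"].any()

    def test_small_cell_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            metrics.flag_median_outliers(median_frame([2.0, 2.1]))


@pytest.fixture(scope="module")
def clean_single_task():
    """4 production subjects, no noise, no errors, with fixed gains."""
    def build(gain_c, gain_a=0.0, variant=bark.AS_PRINTED, seed=5):
        design = ExperimentDesign("production", n_subjects=4, error_rate=0.0)
        profs = make_profiles(
            design, np.random.SeedSequence(seed),
            gain_means={"converge": gain_c, "after": gain_a},
            gain_sds={"converge": 0.0, "after": 0.0},
            noise_sd=(0.0, 0.0), error_rate=0.0,
        )
        res = simulate_experiment([design], {"production": profs}, seed=seed,
                                  variant=variant)
        meas = measurements_from_simulation(res.trials)
        med = metrics.compute_subblock_medians(meas, res.trials, variant=variant)
        return res, med
    return build


class TestCorrelationPoints:
    def test_nine_points_per_subject_and_measure(self, clean_single_task):
        res, med = clean_single_task(0.3)
        pts = metrics.build_correlation_points(med, res.trials, "convergence")
        counts = pts.groupby(["subject_id", "measure"]).size()
        assert (counts == 9).all()

    def test_unit_gain_points_lie_on_diagonal(self, clean_single_task):
        res, med = clean_single_task(1.0)
        pts = metrics.build_correlation_points(med, res.trials, "convergence")
        assert np.allclose(pts["y"], pts["x"], atol=1e-9)

    def test_zero_gain_points_lie_on_zero(self, clean_single_task):
        res, med = clean_single_task(0.0)
        pts = metrics.build_correlation_points(med, res.trials, "convergence")
        assert np.allclose(pts["y"], 0.0, atol=1e-9)

    def test_flagged_medians_drop_points_pairwise(self, clean_single_task):
        res, med = clean_single_task(0.3)
        mask = (
            (med.subject_id == "P01") & (med.measure == "f0")
            & (med.block_index == 2) & (med.role == "baseline") & (med.vowel == "i")
        )
        med = med.copy()
        med.loc[mask, "outlier"] = True
        pts = metrics.build_correlation_points(med, res.trials, "convergence")
        counts = pts.groupby(["subject_id", "measure"]).size()
        assert counts[("P01", "f0")] == 8  # only that block x vowel lost
        assert counts[("P01", "f1")] == 9

    def test_unknown_contrast_rejected(self, clean_single_task):
        res, med = clean_single_task(0.3)
        with pytest.raises(ValueError, match="contrast"):
            metrics.build_correlation_points(med, res.trials, "sideways")


class TestSlopeFit:
    def test_exact_line(self):
        est = metrics.fit_subject_slope([(0, 0), (1, 1), (2, 2)])
        assert est.slope == pytest.approx(1.0, abs=1e-12)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_flat_line(self):
        est = metrics.fit_subject_slope([(0, 1), (1, 1), (2, 1)])
        assert est.slope == pytest.approx(0.0, abs=1e-12)
        assert est.intercept == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="2 points"):
            metrics.fit_subject_slope([(0, 0)])
        with pytest.raises(ValueError, match="identical"):
            metrics.fit_subject_slope([(1, 0), (1, 2)])

    def test_noiseless_generator_recovers_gain(self, clean_single_task):
        res, med = clean_single_task(0.48, gain_a=0.1)
        pts = metrics.build_correlation_points(med, res.trials, "convergence")
        slopes = metrics.fit_all_slopes(pts, res.trials)
        assert np.allclose(slopes["slope"], 0.48, atol=1e-6)

    def test_after_effect_gain_recovered(self, clean_single_task):
        res, med = clean_single_task(0.48, gain_a=0.21)
        pts = metrics.build_correlation_points(med, res.trials, "after_effect")
        slopes = metrics.fit_all_slopes(pts, res.trials)
        assert np.allclose(slopes["slope"], 0.21, atol=1e-6)

    @pytest.mark.parametrize("variant", [bark.AS_PRINTED, ZW])
    def test_variant_consistency(self, clean_single_task, variant):
        """Gain is defined in the analysis space: recovery is exact under
        either bark variant applied uniformly."""
        res, med = clean_single_task(0.37, gain_a=0.15, variant=variant)
        pts = metrics.build_correlation_points(med, res.trials, "convergence",
                                               variant=variant)
        slopes = metrics.fit_all_slopes(pts, res.trials)
        assert np.allclose(slopes["slope"], 0.37, atol=1e-6)


def slope_frame(values):
    n = len(values)
    return pd.DataFrame(
        {
            "experiment": "production", "subject_id": [f"P{i:02d}" for i in range(n)],
            "measure": "f0", "contrast": "convergence", "slope": values,
            "intercept": 0.0, "n_points": 9, "outlier": False,
        }
    )


class TestSlopeOutliers:
    def test_identical_slopes_flag_nothing(self):
        out = metrics.flag_slope_outliers(slope_frame([0.1] * 24))
        assert not out["outlier"].any()

    def test_extreme_slope_flagged(self):
        rng = np.random.default_rng(1)
        vals = list(rng.normal(0.1, 0.01, 23)) + [5.0]
        out = metrics.flag_slope_outliers(slope_frame(vals))
        arr = np.array(vals)
        expected = np.abs(arr - arr.mean()) > 2 * arr.std(ddof=1)
        assert list(out["outlier"]) == list(expected)
        assert out["outlier"].iloc[-1]

    def test_group_of_two_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            metrics.flag_slope_outliers(slope_frame([0.1, 0.2]))


def test_utterance_accounting(full_trials_clean):
    trials = full_trials_clean.trials
    assert metrics.count_contrast_utterances(trials, "convergence") == 6480
    assert metrics.count_contrast_utterances(trials, "after_effect") == 4320


def test_point_count_conservation(clean_single_task):
    res, med = clean_single_task(0.3, gain_a=0.1)
    pts = pd.concat(
        [metrics.build_correlation_points(med, res.trials, c) for c in metrics.CONTRASTS],
        ignore_index=True,
    )
    acct = metrics.points_accounting(pts, n_subjects=4, n_contrasts=2)
    assert acct["expected_if_unpruned"] == 9 * 4 * 2 * 2
    assert acct["present"] == acct["expected_if_unpruned"]
    assert acct["lost"] == 0
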