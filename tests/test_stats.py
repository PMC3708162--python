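"""Group statistics against independent textbook-formula oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phonconv.stats import (
    anova_task_by_congruency,
    pearson,
    run_full_inference,
    t_test_vs_zero_one_tailed,
)


# ---------------------------------------------------------------- oracles
def anova_2x2_balanced_oracle(cells):
    """Textbook balanced two-way ANOVA from a dict (a, b) -> values."""
    n = len(next(iter(cells.values())))
    all_vals = np.concatenate(list(cells.values()))
    grand = all_vals.mean()
    a_levels = sorted({k[0] for k in cells})
    b_levels = sorted({k[1] for k in cells})
    mean_a = {a: np.mean([v for (x, _), vs in cells.items() for v in vs if x == a])
              for a in a_levels}
    mean_b = {b: np.mean([v for (_, y), vs in cells.items() for v in vs if y == b])
              for b in b_levels}
    ss_a = n * len(b_levels) * sum((mean_a[a] - grand) ** 2 for a in a_levels)
    ss_b = n * len(a_levels) * sum((mean_b[b] - grand) ** 2 for b in b_levels)
    ss_cells = n * sum((np.mean(vs) - grand) ** 2 for vs in cells.values())
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(((np.asarray(vs) - np.mean(vs)) ** 2).sum() for vs in cells.values())
    df_a, df_b = len(a_levels) - 1, len(b_levels) - 1
    df_ab = df_a * df_b
    df_err = len(all_vals) - len(cells)
    ms_err = ss_err / df_err
    return {
        "task": ss_a / df_a / ms_err,
        "congruency": ss_b / df_b / ms_err,
        "interaction": ss_ab / df_ab / ms_err,
        "df_err": df_err,
    }


def t_oracle(values):
    arr = np.asarray(values, float)
    se = arr.std(ddof=1) / np.sqrt(len(arr))
    t = arr.mean() / se
    return t, sps.t.sf(t, len(arr) - 1)


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    r = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
    n = len(x)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * sps.t.sf(abs(t), n - 2)
    slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    return r, p, slope


def cells_to_frame(cells):
    rows = []
    for (a, b), vs in cells.items():
        for i, v in enumerate(vs):
            rows.append({"experiment": a, "congruency": b, "slope": v,
                         "subject_id": f"{a}{b}{i}", "outlier": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- ANOVA
def test_anova_matches_oracle_on_many_random_datasets():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(3, 9))
        cells = {
            (a, b): rng.normal(rng.normal(0, 1), 1.0, n)
            for a in ("production", "imitation") for b in ("same", "different")
        }
        table = anova_task_by_congruency(cells_to_frame(cells))
        oracle = anova_2x2_balanced_oracle(cells)
        assert table.task.F == pytest.approx(oracle["task"], abs=1e-8, rel=1e-8)
        assert table.congruency.F == pytest.approx(oracle["congruency"], abs=1e-8, rel=1e-8)
        assert table.interaction.F == pytest.approx(oracle["interaction"], abs=1e-8, rel=1e-8)
        assert table.task.df_den == oracle["df_err"]


def test_anova_df_bookkeeping_for_46_retained_subjects():
    """46 retained subjects in a 2 x 2 leave 42 denominator df."""
    rng = np.random.default_rng(0)
    cells = {
        ("production", "same"): rng.normal(0, 1, 12),
        ("production", "different"): rng.normal(0, 1, 11),
        ("imitation", "same"): rng.normal(0, 1, 12),
        ("imitation", "different"): rng.normal(0, 1, 11),
    }
    table = anova_task_by_congruency(cells_to_frame(cells))
    assert table.n_retained == 46
    assert table.task.df_den == 42


def test_anova_empty_cell_error_names_cell():
    rng = np.random.default_rng(0)
    cells = {
        ("production", "same"): rng.normal(0, 1, 5),
        ("production", "different"): rng.normal(0, 1, 5),
        ("imitation", "same"): rng.normal(0, 1, 5),
    }
    with pytest.raises(ValueError, match="imitation.*different"):
        anova_task_by_congruency(cells_to_frame(cells))


def test_anova_type3_close_to_type2_when_balanced():
    rng = np.random.default_rng(3)
    cells = {
        (a, b): rng.normal(0, 1, 6)
        for a in ("production", "imitation") for b in ("same", "different")
    }
    t2 = anova_task_by_congruency(cells_to_frame(cells), ss_type=2)
    t3 = anova_task_by_congruency(cells_to_frame(cells), ss_type=3)
    assert t2.task.F == pytest.approx(t3.task.F, rel=1e-8)


def test_anova_null_rejection_rate_near_alpha():
    rng = np.random.default_rng(7)
    rejections = 0
    n_sets = 100
    for _ in range(n_sets):
        cells = {
            (a, b): rng.normal(0.2, 1.0, 8)
            for a in ("production", "imitation") for b in ("same", "different")
        }
        table = anova_task_by_congruency(cells_to_frame(cells))
        rejections += table.task.p < 0.05
    assert 0 <= rejections / n_sets <= 0.13


# ---------------------------------------------------------------- t-test
def test_t_matches_oracle_on_many_random_samples():
    rng = np.random.default_rng(1)
    for _ in range(100):
        vals = rng.normal(rng.normal(0, 0.3), 1.0, int(rng.integers(3, 30)))
        res = t_test_vs_zero_one_tailed(vals)
        t, p = t_oracle(vals)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.p_one_tailed == pytest.approx(p, abs=1e-10)
        assert res.df == len(vals) - 1


def test_t_symmetric_sample_is_midpoint():
    res = t_test_vs_zero_one_tailed([-0.2, -0.1, 0.1, 0.2])
    assert res.t == pytest.approx(0.0, abs=1e-12)
    assert res.p_one_tailed == pytest.approx(0.5, abs=1e-12)


def test_t_hand_computed_example():
    """{0.1, 0.2, 0.3}: mean 0.2, SD 0.1 -> t = 2 sqrt(3), df 2."""
    res = t_test_vs_zero_one_tailed([0.1, 0.2, 0.3])
    assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-10)
    assert res.df == 2
    assert res.n == 3


def test_t_df_for_23_retained_values():
    rng = np.random.default_rng(2)
    res = t_test_vs_zero_one_tailed(rng.normal(0.1, 0.05, 23))
    assert res.df == 22


def test_t_degenerate_variance_rejected():
    with pytest.raises(ValueError, match="variance"):
        t_test_vs_zero_one_tailed([0.3, 0.3, 0.3])


# ---------------------------------------------------------------- Pearson
def test_pearson_matches_oracle_on_many_random_pairs():
    rng = np.random.default_rng(5)
    for _ in range(100):
        n = int(rng.integers(4, 25))
        x = rng.normal(0, 1, n)
        y = 0.5 * x + rng.normal(0, 1, n)
        res = pearson(x, y)
        r, p, slope = pearson_oracle(x, y)
        assert res.r == pytest.approx(r, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-8)
        assert res.fitted_slope == pytest.approx(slope, abs=1e-10)


def test_pearson_perfect_linearity():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    res = pearson(x, 2 * x)
    assert res.r == pytest.approx(1.0, abs=1e-12)
    assert res.fitted_slope == pytest.approx(2.0, abs=1e-12)


def test_pearson_orthogonal_by_construction():
    res = pearson([-1.0, 0.0, 1.0], [1.0, -2.0, 1.0])
    assert res.r == pytest.approx(0.0, abs=1e-12)


def test_pearson_input_errors():
    with pytest.raises(ValueError, match="three"):
        pearson([0.0, 1.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="variance"):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------- invariance
def test_shift_invariance_of_interaction_and_correlation():
    rng = np.random.default_rng(9)
    cells = {
        (a, b): rng.normal(0, 1, 6)
        for a in ("production", "imitation") for b in ("same", "different")
    }
    base = anova_task_by_congruency(cells_to_frame(cells))
    shifted_cells = {k: v + 3.7 for k, v in cells.items()}
    shifted = anova_task_by_congruency(cells_to_frame(shifted_cells))
    assert shifted.interaction.F == pytest.approx(base.interaction.F, rel=1e-9)

    x, y = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
    assert pearson(x + 3.7, y + 3.7).r == pytest.approx(pearson(x, y).r, abs=1e-12)


# ---------------------------------------------------------------- full battery
@pytest.fixture(scope="module")
def study_slopes(full_trials_clean):
    from phonconv import metrics
    from phonconv.acoustics import measurements_from_simulation

    trials = full_trials_clean.trials
    meas = measurements_from_simulation(trials)
    med = metrics.compute_subblock_medians(meas, trials)
    med = metrics.flag_median_outliers(med)
    pts = pd.concat(
        [metrics.build_correlation_points(med, trials, c) for c in metrics.CONTRASTS],
        ignore_index=True,
    )
    slopes = metrics.fit_all_slopes(pts, trials)
    return metrics.flag_slope_outliers(slopes)


def test_full_inference_structure_and_task_effect(study_slopes):
    report = run_full_inference(study_slopes)
    assert "convergence/f0" in report["anova"]
    assert "after_effect/f0" in report["anova"]
    # the generative gains differ strongly by task (0.08 vs 0.48 for F0)
    assert report["anova"]["convergence/f0"]["effects"]["task"]["p"] < 0.01
    # categorization subjects produce no convergence slopes
    assert set(report["t_tests"]["convergence/f0"]) == {"production", "imitation"}
    assert "production_x_imitation/f0" in report["correlations"]
    for entry in report["correlations"].values():
        assert entry["n"] >= 3
        assert abs(entry["r"]) <= 1


def test_full_inference_requires_labels(study_slopes):
    with pytest.raises(ValueError, match="missing columns"):
        run_full_inference(study_slopes.drop(columns=["congruency"]))
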