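"""Group-level inference on slope coefficients.

Three test families summarize a study:

* between-subjects factorial ANOVA of the slopes on task and acoustic-space
  congruency (same vs. different gender of subject and model speakers);
* one-sample t-tests of each task's mean slope against zero (one-tailed,
  "greater", since convergence predicts positive slopes);
* Pearson correlations between paired slope sets (F0 vs F1, convergence vs
  after-effect, and the production/imitation overlap subgroup).

Outlier-flagged slopes are excluded before each analysis; correlations
additionally re-apply the +/- 2 SD rule within the analysis pair, mirroring
per-analysis pruning.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .design import IMITATION, PRODUCTION
from .metrics import AFTER_EFFECT, CONVERGENCE, MEASURES, OUTLIER_K


@dataclass(frozen=True)
class EffectResult:
    name: str
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass(frozen=True)
class AnovaTable:
    task: EffectResult
    congruency: EffectResult
    interaction: EffectResult
    n_retained: int

    def to_dict(self) -> dict:
        return {
            "n_retained": self.n_retained,
            "effects": {
                e.name: asdict(e) for e in (self.task, self.congruency, self.interaction)
            },
        }


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_one_tailed: float
    mean: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    fitted_slope: float
    p: float
    n: int


def anova_task_by_congruency(
    slopes: pd.DataFrame,
    value: str = "slope",
    factors: tuple[str, str] = ("experiment", "congruency"),
    ss_type: int = 2,
) -> AnovaTable:
    """Between-subjects factorial ANOVA on retained slope values.

    Mild unbalance from outlier pruning is handled by Type-II sums of squares
    (default); Type-III with sum-to-zero contrast coding is available via
    ``ss_type=3``.  Every factor-level cell must be non-empty.
    """
    df = slopes.copy()
    fa, fb = factors
    for (a, b), grp in df.groupby([fa, fb]):
        if len(grp) == 0:  # pragma: no cover - groupby drops empty anyway
            raise ValueError(f"empty cell {fa}={a}, {fb}={b}")
    counts = df.groupby([fa, fb]).size()
    levels_a = df[fa].nunique()
    levels_b = df[fb].nunique()
    if len(counts) < levels_a * levels_b:
        present = set(counts.index)
        missing = [
            (a, b)
            for a in df[fa].unique()
            for b in df[fb].unique()
            if (a, b) not in present
        ]
        raise ValueError(f"empty design cell(s): {missing}")
    if levels_a < 2 or levels_b < 2:
        raise ValueError("each factor needs at least two levels")

    coding = "Sum" if ss_type == 3 else "Treatment"
    formula = f"{value} ~ C({fa}, {coding}) * C({fb}, {coding})"
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=ss_type)

    def effect(row_label: str, name: str) -> EffectResult:
        row = table.loc[row_label]
        return EffectResult(
            name=name,
            F=float(row["F"]),
            df_num=int(row["df"]),
            df_den=int(model.df_resid),
            p=float(row["PR(>F)"]),
        )

    la = f"C({fa}, {coding})"
    lb = f"C({fb}, {coding})"
    return AnovaTable(
        task=effect(la, "task"),
        congruency=effect(lb, "congruency"),
        interaction=effect(f"{la}:{lb}", "task_x_congruency"),
        n_retained=len(df),
    )


def t_test_vs_zero_one_tailed(values, alternative: str = "greater") -> TTestResult:
    """One-sample t-test of the mean slope against zero.

    One-tailed ("greater") by default: convergence predicts positive slopes.
    """
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        raise ValueError("need at least two values")
    if np.std(arr, ddof=1) == 0:
        raise ValueError("degenerate (zero-variance) sample")
    res = sps.ttest_1samp(arr, 0.0, alternative=alternative)
    return TTestResult(
        t=float(res.statistic),
        df=len(arr) - 1,
        p_one_tailed=float(res.pvalue),
        mean=float(arr.mean()),
        n=len(arr),
    )


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation between paired slope sets, plus the fitted slope
    of the OLS regression of y on x and the two-tailed p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 3:
        raise ValueError("need at least three complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    fitted = float(np.polyfit(x, y, 1)[0])
    return CorrelationResult(r=float(r), fitted_slope=fitted, p=float(p), n=len(x))


def _retained(slopes: pd.DataFrame, **filters) -> pd.DataFrame:
    df = slopes[~slopes["outlier"]]
    for col, val in filters.items():
        df = df[df[col].isin(val)] if isinstance(val, (list, tuple, set)) else df[df[col] == val]
    return df


def _prune_pairs(x: np.ndarray, y: np.ndarray, k: float = OUTLIER_K) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-analysis +/- k SD pruning: drop a pair when either member exceeds
    the bound within its own set.  Returns pruned x, y and count removed."""
    keep = np.ones(len(x), dtype=bool)
    for v in (x, y):
        m, sd = v.mean(), v.std(ddof=1)
        if sd > 0:
            keep &= np.abs(v - m) <= k * sd
    return x[keep], y[keep], int((~keep).sum())


def _paired_by_subject(
    slopes: pd.DataFrame, sel_x: dict, sel_y: dict, key: str = "subject_id"
) -> tuple[np.ndarray, np.ndarray]:
    a = _retained(slopes, **sel_x).set_index(key)["slope"]
    b = _retained(slopes, **sel_y).set_index(key)["slope"]
    common = a.index.intersection(b.index)
    return a.loc[common].to_numpy(), b.loc[common].to_numpy()


def run_full_inference(slopes: pd.DataFrame, alpha: float = 0.05) -> dict:
    """The full inference battery over a study's slope table.

    Expects columns experiment, subject_id, persona_id, congruency, measure,
    contrast, slope, outlier.  Returns a JSON-serializable nested report:
    per contrast and measure, the task x congruency ANOVA, per-task t-tests
    against zero, F0 x F1 correlations, convergence x after-effect
    correlations, and the production/imitation overlap-subgroup correlation.
    """
    required = {"experiment", "subject_id", "congruency", "measure", "contrast",
                "slope", "outlier"}
    missing = required - set(slopes.columns)
    if missing:
        raise ValueError(f"slope table missing columns: {sorted(missing)}")

    report: dict = {"alpha": alpha, "anova": {}, "t_tests": {}, "correlations": {}}

    for contrast in sorted(slopes["contrast"].unique()):
        tasks = (
            [PRODUCTION, IMITATION] if contrast == CONVERGENCE
            else sorted(slopes.loc[slopes["contrast"] == contrast, "experiment"].unique())
        )
        for measure in MEASURES:
            sel = _retained(slopes, contrast=contrast, measure=measure,
                            experiment=tasks)
            key = f"{contrast}/{measure}"
            if sel["experiment"].nunique() >= 2 and sel["congruency"].nunique() >= 2:
                report["anova"][key] = anova_task_by_congruency(sel).to_dict()
            t_entry = {}
            for task in tasks:
                vals = sel.loc[sel["experiment"] == task, "slope"]
                if len(vals) >= 2 and vals.std(ddof=1) > 0:
                    t_entry[task] = asdict(t_test_vs_zero_one_tailed(vals))
            report["t_tests"][key] = t_entry

    # F0 x F1 correlations per experiment and contrast (re-pruned pairwise)
    corr: dict = {}
    for contrast in sorted(slopes["contrast"].unique()):
        for task in sorted(slopes.loc[slopes["contrast"] == contrast, "experiment"].unique()):
            x, y = _paired_by_subject(
                slopes,
                {"contrast": contrast, "measure": "f0", "experiment": task},
                {"contrast": contrast, "measure": "f1", "experiment": task},
            )
            entry = _safe_corr(x, y)
            if entry:
                corr[f"f0_x_f1/{contrast}/{task}"] = entry
    # convergence x after-effect per task and measure
    for task in (PRODUCTION, IMITATION):
        for measure in MEASURES:
            x, y = _paired_by_subject(
                slopes,
                {"contrast": CONVERGENCE, "measure": measure, "experiment": task},
                {"contrast": AFTER_EFFECT, "measure": measure, "experiment": task},
            )
            entry = _safe_corr(x, y)
            if entry:
                corr[f"convergence_x_after/{task}/{measure}"] = entry
    # production x imitation overlap subgroup (paired by persona)
    if "persona_id" in slopes.columns:
        for measure in MEASURES:
            x, y = _paired_by_subject(
                slopes,
                {"contrast": CONVERGENCE, "measure": measure, "experiment": PRODUCTION},
                {"contrast": CONVERGENCE, "measure": measure, "experiment": IMITATION},
                key="persona_id",
            )
            entry = _safe_corr(x, y)
            if entry:
                corr[f"production_x_imitation/{measure}"] = entry
    report["correlations"] = corr
    return report


def _safe_corr(x: np.ndarray, y: np.ndarray) -> dict | None:
    if len(x) < 3:
        return None
    x, y, removed = _prune_pairs(x, y)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return None
    res = pearson(x, y)
    out = asdict(res)
    out["n_pruned"] = removed
    return out
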