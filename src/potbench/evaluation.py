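"""Performance metrics, method comparison, difficult-class analysis, baselines.

Metrics per activity class are MAE, MedAE, MSE (all in pKi units) and the
Pearson correlation r between observed and predicted potency.  Two methods
are compared class-by-class: one counts as superior on a class when its error
is at least 0.1 pKi units smaller (or its correlation at least 0.1 higher),
and the comparison is summarized as percentages of classes where either side
wins or neither does.  "Difficult" classes are those whose error e satisfies
e >= mu + 2*sigma over the class-error distribution.  A one-sided Wilcoxon
rank-sum test compares error-difference distributions between class groups.
Mean-potency baselines (per task or global) provide the no-learning control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetricSet",
    "compute_metrics",
    "per_class_metrics",
    "ComparisonRow",
    "compare_methods",
    "ClassErrorSummary",
    "flag_difficult_classes",
    "wilcoxon_one_sided",
    "mean_potency_baseline",
    "aggregate_global",
]


@dataclass(frozen=True)
class MetricSet:
    """Error metrics (pKi scale) and correlation for one prediction set.

    ``r`` is NaN with ``r_defined=False`` when either the observed or the
    predicted values have zero variance (or n < 2): the correlation is
    undefined there, not zero.
    """

    mae: float
    medae: float
    mse: float
    r: float
    n: int
    r_defined: bool = True


def compute_metrics(y: np.ndarray, y_hat: np.ndarray) -> MetricSet:
    """MAE, MedAE, MSE and Pearson r of predictions against observations."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have the same shape")
    n = y.size
    if n == 0:
        raise ValueError("empty prediction set")
    resid = y - y_hat
    mae = float(np.mean(np.abs(resid)))
    medae = float(np.median(np.abs(resid)))
    mse = float(np.mean(resid**2))
    if n >= 2 and np.std(y) > 0 and np.std(y_hat) > 0:
        r = float(stats.pearsonr(y, y_hat).statistic)
        return MetricSet(mae, medae, mse, r, n, True)
    return MetricSet(mae, medae, mse, float("nan"), n, False)


def per_class_metrics(predictions: pd.DataFrame) -> pd.DataFrame:
    """Metrics per activity class from a (compound_id, target_id, y, y_hat) table."""
    rows = []
    for t, grp in predictions.groupby("target_id", sort=True):
        m = compute_metrics(grp["y"].to_numpy(), grp["y_hat"].to_numpy())
        rows.append((t, m.mae, m.medae, m.mse, m.r, m.n))
    return pd.DataFrame(rows, columns=["target_id", "mae", "medae", "mse", "r", "n"]).set_index(
        "target_id"
    )


@dataclass(frozen=True)
class ComparisonRow:
    """Percentages of classes where A wins, B wins, or neither does."""

    pct_a_better: float
    pct_b_better: float
    pct_indistinguishable: float

    def __post_init__(self) -> None:
        total = self.pct_a_better + self.pct_b_better + self.pct_indistinguishable
        if abs(total - 100.0) > 0.1:
            raise ValueError(f"percentages sum to {total}, not 100")


def compare_methods(
    per_class_a: Mapping[str, float],
    per_class_b: Mapping[str, float],
    kind: str = "error",
    threshold: float = 0.1,
    inclusive: bool = True,
) -> ComparisonRow:
    """Class-wise superiority comparison of two methods on one metric.

    For ``kind="error"`` method A is superior on a class iff
    ``e_A <= e_B - threshold`` (strict ``<`` when ``inclusive=False``); for
    ``kind="correlation"`` iff ``r_A >= r_B + threshold``.  Both methods must
    report the same classes.  The inclusive boundary is evaluated with a
    1e-12 float tolerance so that a difference of exactly 0.1 counts as
    superior regardless of binary representation.
    """
    if set(per_class_a) != set(per_class_b):
        raise ValueError("mismatched class sets")
    if not per_class_a:
        raise ValueError("empty class set")
    n_a = n_b = 0
    for cls in per_class_a:
        a, b = per_class_a[cls], per_class_b[cls]
        if kind == "error":
            diff_a, diff_b = b - a, a - b  # positive when the method is better
        elif kind == "correlation":
            diff_a, diff_b = a - b, b - a
        else:
            raise ValueError("kind must be 'error' or 'correlation'")
        win = (
            (lambda d: d >= threshold - 1e-12)
            if inclusive
            else (lambda d: d > threshold + 1e-12)
        )
        if win(diff_a):
            n_a += 1
        elif win(diff_b):
            n_b += 1
    n = len(per_class_a)
    return ComparisonRow(
        100.0 * n_a / n, 100.0 * n_b / n, 100.0 * (n - n_a - n_b) / n
    )


@dataclass(frozen=True)
class ClassErrorSummary:
    """One class's error against the population mu + 2*sigma threshold."""

    class_id: str
    error: float
    mu: float
    sigma: float
    threshold: float
    difficult: bool


def flag_difficult_classes(
    errors: Mapping[str, float],
    n_sigmas: float = 2.0,
    ddof: int = 1,
    sigma_zero_all_suitable: bool = True,
) -> list[ClassErrorSummary]:
    """Flag classes whose error e satisfies e >= mu + 2*sigma (inclusive).

    ``mu`` and ``sigma`` are computed over all class errors; ``ddof``
    selects the sigma convention (1 = sample standard deviation, default;
    0 = population).  When all errors are identical (sigma = 0, every class
    exactly at the boundary) all classes are flagged suitable by default.
    Requires at least 3 classes.
    """
    if len(errors) < 3:
        raise ValueError("need at least 3 classes")
    values = np.array([errors[c] for c in sorted(errors)], dtype=float)
    mu = float(np.mean(values))
    sigma = float(np.std(values, ddof=ddof))
    threshold = mu + n_sigmas * sigma
    out = []
    for cls in sorted(errors):
        e = float(errors[cls])
        if sigma == 0.0 and sigma_zero_all_suitable:
            difficult = False
        else:
            difficult = e >= threshold
        out.append(ClassErrorSummary(cls, e, mu, sigma, threshold, difficult))
    return out


def wilcoxon_one_sided(
    group1: Sequence[float], group2: Sequence[float], alternative: str = "less"
) -> float:
    """One-sided Wilcoxon rank-sum p-value (group1 stochastically smaller).

    Exact null distribution when the combined sample size is <= 25 and there
    are no ties; normal approximation with tie correction otherwise.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([g1, g2])
    no_ties = len(np.unique(combined)) == combined.size
    method = "exact" if (combined.size <= 25 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(g1, g2, alternative=alternative, method=method)
    return float(res.pvalue)


def mean_potency_baseline(
    train_labels: Mapping[str, Sequence[float]],
    test_records: pd.DataFrame,
    mode: str = "per_task",
) -> pd.DataFrame:
    """No-learning control: predict the mean training pKi for every test pair.

    ``mode="per_task"`` uses each target's own training mean;
    ``mode="global"`` uses the mean over all tasks' training labels.  Test
    records for a task with no training labels are skipped with a warning in
    per-task mode.  Returns a prediction table in the standard
    (compound_id, target_id, y, y_hat) shape.
    """
    if mode not in ("per_task", "global"):
        raise ValueError("mode must be 'per_task' or 'global'")
    all_labels = [v for vals in train_labels.values() for v in vals]
    if not all_labels:
        raise ValueError("no training labels at all")
    global_mean = float(np.mean(all_labels))
    rows = []
    for rec in test_records.itertuples():
        t = rec.target_id
        if mode == "per_task":
            vals = train_labels.get(t, ())
            if len(vals) == 0:
                warnings.warn(f"task {t!r} has no training labels; skipped")
                continue
            y_hat = float(np.mean(vals))
        else:
            y_hat = global_mean
        rows.append((rec.compound_id, t, float(rec.y), y_hat))
    return pd.DataFrame(rows, columns=["compound_id", "target_id", "y", "y_hat"])


def flag_limited_training(model_error: float, baseline_error: float) -> bool:
    """A model shows "limited training success" when it fails to beat the
    mean-potency baseline (test error >= baseline error)."""
    return model_error >= baseline_error


def aggregate_global(per_class: Mapping[str, float] | Sequence[float]) -> tuple[float, float]:
    """Unweighted mean and sample standard deviation across classes."""
    values = np.asarray(
        [per_class[c] for c in per_class] if isinstance(per_class, Mapping) else per_class,
        dtype=float,
    )
    if values.size < 2:
        raise ValueError("need at least 2 classes")
    return float(np.mean(values)), float(np.std(values, ddof=1))
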