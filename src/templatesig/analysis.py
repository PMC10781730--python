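"""Comparison layer: reconstruction accuracy, structure-plausibility tests,
multiple-comparison-corrected coefficient contrasts, and case-study percent
differences."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .library import LibraryMatrix


def r_squared(predicted_acc: np.ndarray, measured_acc: np.ndarray
              ) -> tuple[np.ndarray, float]:
    """Coefficient of determination between predicted and measured CoM
    accelerations, per direction (AP, vertical, ML) and averaged.

    A zero-variance direction is omitted from the average with a warning.
    """
    predicted_acc = np.atleast_2d(predicted_acc)
    measured_acc = np.atleast_2d(measured_acc)
    if predicted_acc.shape != measured_acc.shape:
        raise ValueError("prediction and measurement shapes differ")
    r2 = np.full(measured_acc.shape[0], np.nan)
    for d in range(measured_acc.shape[0]):
        y = measured_acc[d]
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            warnings.warn(f"direction {d} has zero variance; omitted from r^2")
            continue
        ss_res = float(np.sum((y - predicted_acc[d]) ** 2))
        r2[d] = 1.0 - ss_res / ss_tot
    if np.all(np.isnan(r2)):
        raise ValueError("all directions have zero variance")
    return r2, float(np.nanmean(r2))


def r_squared_signature(xi: np.ndarray, library: LibraryMatrix
                        ) -> tuple[np.ndarray, float]:
    """r^2 of a coefficient vector's acceleration reconstruction over the
    samples in a library matrix."""
    return r_squared(library.predict_acceleration(xi),
                     library.measured_acceleration())


def structure_plausibility_test(delta_aicc_samples, threshold: float = 3.0,
                                alpha: float = 0.05):
    """One-sample right-tailed t-test of H0: mean(delta AICc) <= threshold.

    Used to test whether a reference condition's signature structure is less
    plausible than condition-specific structures across subjects.  Returns
    (t, p, reject).  With zero variance the mean is compared exactly.
    """
    x = np.asarray(delta_aicc_samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 subjects")
    if np.ptp(x) == 0:
        if x[0] == threshold:
            return 0.0, 0.5, False
        exceeds = x[0] > threshold
        return (np.inf if exceeds else -np.inf,
                0.0 if exceeds else 1.0, bool(exceeds))
    t, p = stats.ttest_1samp(x, popmean=threshold, alternative="greater")
    return float(t), float(p), bool(p < alpha)


def holm_sidak(p_values, alpha: float = 0.05) -> pd.DataFrame:
    """Holm–Šidák step-down multiple-comparison correction.

    For f tests sorted ascending, the rank-i critical level is
    1 - (1 - alpha)^(1/(f - i + 1)); testing stops at the first failure and
    all later hypotheses are retained.  Returns a frame in the original
    order with columns p, rank, critical_alpha, reject.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    f = p.size
    order = np.argsort(p, kind="stable")
    # mathematically <= alpha for every rank; clamp the float round-off
    crit = np.minimum(1.0 - (1.0 - alpha) ** (1.0 / (f - np.arange(f))),
                      alpha)
    reject_sorted = np.zeros(f, dtype=bool)
    for i in range(f):
        if p[order[i]] < crit[i]:
            reject_sorted[i] = True
        else:
            break  # step-down: first failure retains all the rest
    reject = np.zeros(f, dtype=bool)
    reject[order] = reject_sorted
    critical = np.zeros(f)
    critical[order] = crit
    rank = np.zeros(f, dtype=int)
    rank[order] = np.arange(1, f + 1)
    return pd.DataFrame({"p": p, "rank": rank, "critical_alpha": critical,
                         "reject": reject})


def percent_difference(a: float, b: float) -> float:
    """100 * (a - b) / |b|, with b the explicit reference value."""
    if b == 0:
        warnings.warn("reference value is zero; percent difference undefined")
        return np.nan
    return 100.0 * (a - b) / abs(b)


@dataclass
class PairedComparison:
    coefficient: str
    gait_phase: str
    mean_a: float
    mean_b: float
    t: float
    p: float


def paired_coefficient_tests(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    alpha: float = 0.05,
    by=("coefficient", "gait_phase"),
    subject_col: str = "subject",
) -> pd.DataFrame:
    """Paired t-tests of per-subject coefficient values between two
    conditions, Holm–Šidák corrected over the whole comparison family.

    Input tables are tidy frames with columns ``subject``, ``coefficient``,
    ``gait_phase``, ``value`` (legs pooled by the caller as appropriate).
    The family size is the number of (coefficient, gait phase) cells tested
    and is recorded in the output.
    """
    by = list(by)
    results = []
    for keys, grp_a in table_a.groupby(by):
        grp_b = table_b.set_index(subject_col).loc[
            grp_a[subject_col], :
        ].reset_index()
        grp_b = grp_b[np.logical_and.reduce(
            [grp_b[c] == k for c, k in zip(by, np.atleast_1d(keys))])]
        merged = grp_a.merge(grp_b, on=subject_col, suffixes=("_a", "_b"))
        if len(merged) < 2:
            continue
        diff = merged["value_a"].to_numpy() - merged["value_b"].to_numpy()
        if np.ptp(diff) == 0:
            t, p = (0.0, 1.0) if diff[0] == 0 else (np.inf, 0.0)
        else:
            t, p = stats.ttest_rel(merged["value_a"], merged["value_b"])
        rec = dict(zip(by, np.atleast_1d(keys)))
        rec.update(mean_a=float(merged["value_a"].mean()),
                   mean_b=float(merged["value_b"].mean()),
                   t=float(t), p=float(p))
        results.append(rec)
    if not results:
        raise ValueError("no testable (coefficient, gait phase) cells")
    frame = pd.DataFrame(results)
    corr = holm_sidak(frame["p"].to_numpy(), alpha=alpha)
    frame["rank"] = corr["rank"]
    frame["critical_alpha"] = corr["critical_alpha"]
    frame["reject"] = corr["reject"]
    frame.attrs["family_size"] = len(frame)
    frame.attrs["alpha"] = alpha
    return frame
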