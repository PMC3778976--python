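"""Lateralized series and the time-resolved factor regression.

The lateralization index is simply left-group minus right-group
relative-change power for homologous sensor groups (or ROI pairs).  At
every output time point the 8 response-required condition values of one
subject are regressed on the ±1-coded factors:

    ΔP̄(c) = b0 + b1·A(c) + b2·T(c) + b3·R(c) + ε

Because the design is balanced and orthogonal, b1 is half the difference
between the A=+1 and A=−1 condition means (likewise b2, b3) and b0 is the
grand mean.  Group inference is a second-level one-sample t test across
subjects per coefficient and time point, Bonferroni-corrected over the
evaluated time points, with maximal significant runs reported as windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

COEF_NAMES = ("b0", "b1_hand", "b2_target", "b3_response")


def lateralize(left: np.ndarray, right: np.ndarray,
               times_left=None, times_right=None) -> np.ndarray:
    """Left-minus-right series; validates matching shapes/time axes."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError(f"shape mismatch: {left.shape} vs {right.shape}")
    if times_left is not None and times_right is not None:
        if not np.array_equal(np.asarray(times_left), np.asarray(times_right)):
            raise ValueError("left/right time axes differ")
    return left - right


def fit_timepoint_regression(values: np.ndarray, coding: np.ndarray) -> np.ndarray:
    """OLS coefficients (b0, b1, b2, b3) for one subject.

    ``values`` is (8,) or (8, n_times): the 8 response-required condition
    values; ``coding`` is (8, 3) with the ±1 (A, T, R) codes.  Returns
    (4,) or (4, n_times).
    """
    values = np.asarray(values, dtype=float)
    coding = np.asarray(coding, dtype=float)
    if coding.shape != (8, 3):
        raise ValueError(f"coding must be (8, 3), got {coding.shape}")
    if values.shape[0] != 8:
        raise ValueError("expected 8 condition values (response-required set)")
    X = np.column_stack([np.ones(8), coding])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("rank-deficient factor coding: design not full rank")
    b, *_ = np.linalg.lstsq(X, values, rcond=None)
    return b


@dataclass
class RegressionTrack:
    """Group-level time-resolved regression results.

    Arrays are (n_coefficients, n_times) on ``times_ms``; ``windows`` maps
    coefficient name to a list of (onset_ms, offset_ms) maximal significant
    runs.  ``per_test_alpha`` is the Bonferroni-corrected threshold.
    """

    times_ms: np.ndarray
    coef_mean: np.ndarray
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    per_test_alpha: float
    n_subjects: int
    coef_names: tuple[str, ...] = COEF_NAMES
    windows: dict[str, list[tuple[float, float]]] = field(default_factory=dict)


def significant_runs(times_ms: np.ndarray, flags: np.ndarray) -> list[tuple[float, float]]:
    """Maximal runs of flagged time points as (onset, offset) pairs."""
    out = []
    flags = np.asarray(flags, dtype=bool)
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    for s, e in zip(starts, ends):
        out.append((float(times_ms[s]), float(times_ms[e])))
    return out


def group_coefficient_track(
    coefs: np.ndarray,
    times_ms: np.ndarray,
    alpha: float = 0.05,
    window: tuple[float, float] = (-500.0, 1650.0),
    bonferroni_divisor: int | None = None,
    coef_names: tuple[str, ...] = COEF_NAMES,
) -> RegressionTrack:
    """Across-subject one-sample t tests with Bonferroni correction.

    ``coefs`` is (n_subjects, n_coefficients, n_times).  Only time points
    inside ``window`` are evaluated; the per-test threshold is
    ``alpha / divisor`` where the divisor defaults to the number of
    evaluated time points (108 on the default −500..1650 ms, 20 ms grid).
    """
    coefs = np.asarray(coefs, dtype=float)
    n_sub, n_coef, _ = coefs.shape
    if n_sub < 3:
        raise ValueError("need at least 3 subjects for group inference")
    times_ms = np.asarray(times_ms, dtype=float)
    in_win = (times_ms >= window[0]) & (times_ms <= window[1])
    t_sel = times_ms[in_win]
    n_tests = int(bonferroni_divisor or in_win.sum())
    per_test_alpha = alpha / n_tests

    x = coefs[:, :, in_win]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n_sub))
    zero_var = sd == 0
    if np.any(zero_var & (mean != 0)):
        warnings.warn("zero between-subject variance with nonzero mean: "
                      "t infinite, flagged significant", stacklevel=2)
        t[zero_var & (mean != 0)] = np.inf
    t[zero_var & (mean == 0)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df=n_sub - 1)
    sig = p < per_test_alpha

    windows = {name: significant_runs(t_sel, sig[i])
               for i, name in enumerate(coef_names)}
    return RegressionTrack(times_ms=t_sel, coef_mean=mean, t=t, p=p,
                           significant=sig, per_test_alpha=per_test_alpha,
                           n_subjects=n_sub, coef_names=coef_names,
                           windows=windows)


def subject_regression_tracks(
    series: np.ndarray,
    coding: np.ndarray,
) -> np.ndarray:
    """Per-subject coefficient tracks.

    ``series`` is (n_subjects, 8, n_times): each subject's 8 condition
    series; ``coding`` is (8, 3).  Returns (n_subjects, 4, n_times).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 3 or series.shape[1] != 8:
        raise ValueError("series must be (n_subjects, 8, n_times)")
    return np.stack([fit_timepoint_regression(s, coding) for s in series])
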