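"""Factorial trial design and synthetic behavior.

The task crosses three two-level (plus one null level) factors per trial:

* ``A`` — the actor's moving hand, −1 (left) or +1 (right),
* ``T`` — the endpoint target location from the observer's perspective,
  −1 (left) or +1 (right),
* ``R`` — the cued response hand, −1 (left), +1 (right), or 0 (no response
  required).

This yields 12 experimental conditions, 8 of which require a response.
Because the actor faces the observer, a pointing movement whose hand and
target labels differ (``A != T``) stays within one visual hemifield and is
called *straight*; ``A == T`` movements cross the midline (*crossed*).
Response congruency compares the cued response hand with the endpoint
target side: congruent iff ``T == R`` (defined only when ``R != 0``).

Reaction times are generated from an additive model
``RT = subject_base + congruency_effect·1[incongruent]
+ stimulus_type_effect·1[straight] + coupling·beta_bias + skewed noise``
truncated to a configurable support, emulating the published summary
statistics (grand mean 451 ms, congruent − incongruent = −18 ms,
crossed − straight = −7 ms, medians within 300–610 ms).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: All 12 (A, T, R) factor combinations, in canonical order.
CONDITIONS: tuple[tuple[int, int, int], ...] = tuple(
    (a, t, r) for a in (-1, 1) for t in (-1, 1) for r in (-1, 1, 0)
)

DESIGN_COLUMNS = [
    "subject", "block", "trial", "A", "T", "R",
    "stimulus_type", "congruency", "rt_ms",
]


def stimulus_type_label(a: int, t: int) -> str:
    """Straight iff hand and target labels differ (actor faces the observer)."""
    return "straight" if a != t else "crossed"


def congruency_label(t: int, r: int) -> str:
    if r == 0:
        return "none"
    return "congruent" if t == r else "incongruent"


def generate_design(
    n_subjects: int = 12,
    n_blocks: int = 8,
    reps_per_condition: int = 10,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Generate a balanced randomized factorial design.

    Each block contains every one of the 12 conditions exactly
    ``reps_per_condition`` times, in randomized order (120 trials per block
    at the default 10 repetitions).  Returns a tidy DataFrame with one row
    per trial; ``rt_ms`` is NaN until :func:`generate_rts` fills it in.
    """
    if n_subjects < 1 or n_blocks < 1 or reps_per_condition < 1:
        raise ValueError(
            "n_subjects, n_blocks and reps_per_condition must all be >= 1"
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    base = np.repeat(np.arange(len(CONDITIONS)), reps_per_condition)
    rows = []
    for subject in range(1, n_subjects + 1):
        for block in range(1, n_blocks + 1):
            order = rng.permutation(base)
            for trial, ci in enumerate(order, start=1):
                a, t, r = CONDITIONS[ci]
                rows.append((subject, block, trial, a, t, r,
                             stimulus_type_label(a, t),
                             congruency_label(t, r), np.nan))
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


@dataclass
class RTGenParams:
    """Parameters of the reaction-time generator (all times in ms).

    Defaults reproduce the published group summaries: grand mean 451 ms,
    an 18 ms congruency advantage, a 7 ms advantage for crossed movements,
    and medians confined to 300–610 ms.  ``subject_sd`` is set so the
    between-subject SEM of mean RT is ≈10 ms at n = 12.
    """

    grand_mean: float = 451.0
    congruency_effect: float = 18.0     # added to incongruent trials
    stimulus_type_effect: float = 7.0   # added to straight trials
    subject_sd: float = 34.6
    noise_scale: float = 100.0          # scale of the shifted lognormal noise
    noise_sigma: float = 0.35           # lognormal shape parameter
    coupling: float = 0.0               # ms of RT per unit of beta bias
    support: tuple[float, float] = (300.0, 610.0)
    miss_rate: float = 0.0              # fraction of response trials with no RT


def _trial_noise(rng: np.random.Generator, n: int, params: RTGenParams) -> np.ndarray:
    """Zero-mean right-skewed trial noise: shifted lognormal."""
    s = params.noise_sigma
    ln = rng.lognormal(mean=0.0, sigma=s, size=n)
    return params.noise_scale * (ln - np.exp(s * s / 2.0))


def generate_rts(
    design: pd.DataFrame,
    params: RTGenParams | None = None,
    beta_bias: np.ndarray | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Fill in per-trial reaction times for all response-required trials.

    ``beta_bias`` is an optional per-trial covariate (aligned to the rows of
    ``design``) representing the trial's pre-cue motor lateralization bias;
    it enters the RT model scaled by ``params.coupling``.  The grand mean is
    preserved by centering each additive effect.  Trials with ``R == 0``
    keep ``rt_ms`` NaN.
    """
    params = params or RTGenParams()
    n = len(design)
    if beta_bias is None:
        beta_bias = np.zeros(n)
    beta_bias = np.asarray(beta_bias, dtype=float)
    if beta_bias.shape != (n,):
        raise ValueError(
            f"beta_bias has shape {beta_bias.shape}, expected ({n},) "
            "aligned to the design rows"
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    out = design.copy()
    subjects = out["subject"].to_numpy()
    uniq = np.unique(subjects)
    base_by_subject = dict(zip(
        uniq,
        params.grand_mean
        - params.congruency_effect / 2.0
        - params.stimulus_type_effect / 2.0
        + params.subject_sd * rng.standard_normal(len(uniq)),
    ))
    base = np.array([base_by_subject[s] for s in subjects])

    rt = (
        base
        + params.congruency_effect * (out["congruency"] == "incongruent").to_numpy()
        + params.stimulus_type_effect * (out["stimulus_type"] == "straight").to_numpy()
        + params.coupling * beta_bias
        + _trial_noise(rng, n, params)
    )
    rt = np.clip(rt, *params.support)

    answered = out["R"].to_numpy() != 0
    if params.miss_rate > 0:
        answered &= rng.random(n) >= params.miss_rate
    rt[~answered] = np.nan
    out["rt_ms"] = rt
    return out


def median_rt(design: pd.DataFrame) -> pd.DataFrame:
    """Per-subject median RT for each response-required (A, T, R) condition.

    Uses the arithmetic-midpoint convention for even counts (numpy median).
    Empty cells yield NaN with a logged warning.
    """
    resp = design[design["R"] != 0]
    table = (
        resp.groupby(["subject", "A", "T", "R"])["rt_ms"]
        .median()
        .unstack(["A", "T", "R"])
    )
    # groupby drops all-NaN cells silently only in some paths; make missing explicit
    n_cells = table.size
    n_missing = int(table.isna().sum().sum())
    if n_missing:
        logger.warning("median_rt: %d of %d subject x condition cells are empty",
                       n_missing, n_cells)
        warnings.warn(f"median_rt: {n_missing} empty subject x condition cells",
                      stacklevel=2)
    return table


def rm_effect_test(
    cell_medians: pd.DataFrame,
    contrast: dict[tuple[int, int, int], float] | pd.Series,
) -> tuple[float, float, float]:
    """One-degree-of-freedom repeated-measures effect test.

    ``cell_medians`` is the subject × condition table from :func:`median_rt`
    (columns are (A, T, R) tuples); ``contrast`` maps conditions to weights
    summing to zero.  Each subject's contrast score is the weighted sum of
    their condition medians; the test is the squared paired t on those
    scores, reported as F(1, n−1) with its p value.

    Returns ``(effect, F, p)`` where ``effect`` is the mean contrast score
    in ms.
    """
    contrast = pd.Series(dict(contrast)) if not isinstance(contrast, pd.Series) else contrast
    w = contrast.reindex(cell_medians.columns)
    if w.isna().any():
        missing = [c for c in cell_medians.columns if c not in contrast.index]
        raise ValueError(f"contrast missing weights for conditions {missing}")
    if abs(w.sum()) > 1e-12:
        raise ValueError(f"contrast weights must sum to 0, got {w.sum():g}")
    if cell_medians.isna().any().any():
        raise ValueError("cell_medians table is incomplete (contains NaN)")
    n = len(cell_medians)
    if n < 2:
        raise ValueError("need at least 2 subjects")

    scores = cell_medians.to_numpy() @ w.to_numpy()
    mean = scores.mean()
    sd = scores.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return 0.0, 0.0, 1.0
        warnings.warn("zero-variance contrast scores with nonzero mean: F infinite",
                      stacklevel=2)
        return float(mean), np.inf, 0.0
    t = mean / (sd / np.sqrt(n))
    f = t * t
    p = float(stats.f.sf(f, 1, n - 1))
    return float(mean), float(f), p


# Canonical 1-df contrasts on the 8 response-required conditions -----------

def _response_conditions() -> list[tuple[int, int, int]]:
    return [c for c in CONDITIONS if c[2] != 0]


def factor_contrast(which: str) -> dict[tuple[int, int, int], float]:
    """Weights for the standard contrasts over the 8 response conditions.

    ``which`` is one of ``"A"``, ``"T"``, ``"R"`` (main effects),
    ``"congruency"`` (incongruent − congruent) or ``"stimulus_type"``
    (straight − crossed).  Weights are ±1/4 so the contrast score is a
    difference of condition-mean medians in ms.
    """
    conds = _response_conditions()
    signs = {}
    for a, t, r in conds:
        if which == "A":
            s = a
        elif which == "T":
            s = t
        elif which == "R":
            s = r
        elif which == "congruency":
            s = 1 if congruency_label(t, r) == "incongruent" else -1
        elif which == "stimulus_type":
            s = 1 if stimulus_type_label(a, t) == "straight" else -1
        else:
            raise ValueError(f"unknown contrast {which!r}")
        signs[(a, t, r)] = s / 4.0
    return signs


@dataclass
class RTSummary:
    """Behavioral summary: condition medians plus 1-df effect tests."""

    medians: pd.DataFrame
    effects: pd.DataFrame = field(default_factory=pd.DataFrame)


def summarize_behavior(design: pd.DataFrame) -> RTSummary:
    """Medians table plus the standard main-effect and combined contrasts."""
    table = median_rt(design)
    rows = []
    for name in ("A", "T", "R", "congruency", "stimulus_type"):
        eff, f, p = rm_effect_test(table, factor_contrast(name))
        rows.append((name, eff, f, p))
    effects = pd.DataFrame(rows, columns=["contrast", "effect_ms", "F", "p"])
    return RTSummary(medians=table, effects=effects)
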