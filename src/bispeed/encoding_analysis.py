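"""Component response weights for bi-speed stimuli.

A neuron's response R to two simultaneously presented speeds is modeled as
a weighted average of its responses to the components presented alone,
R = w_s * R_s + w_f * R_f with w_s + w_f = 1.  Per-neuron weights follow
from w_f = (R - R_s) / (R_f - R_s), but the population-level estimator is
the ordinary least-squares regression of (R - R_s) on (R_f - R_s) across
neurons, whose slope approximates w_f when the intercept is near zero.
Two controls guard against the shared R_s term inducing spurious slopes:
a random-weight simulation (per-neuron a ~ Uniform(0,1)) and a split-trial
regression in which R_s on the two axes comes from disjoint trial halves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "BiSpeedCondition",
    "WeightRegressionResult",
    "UndefinedWeightError",
    "log_mean_speed",
    "component_weights",
    "estimate_weights_regression",
    "random_weight_control",
    "bootstrap_compare",
    "split_trial_regression",
]

#: per-neuron weights are undefined when |R_f - R_s| falls below this (spikes/s)
DEGENERATE_DENOMINATOR = 1e-9


class UndefinedWeightError(ValueError):
    """Raised when R_f == R_s, so the weighted-average weights are undefined."""


def log_mean_speed(v1: float, v2: float) -> float:
    """Geometric mean exp((ln v1 + ln v2)/2) = sqrt(v1 * v2), in deg/s."""
    if v1 <= 0 or v2 <= 0:
        raise ValueError("speeds must be positive")
    return math.sqrt(v1 * v2)


@dataclass(frozen=True)
class BiSpeedCondition:
    """An ordered speed pair, v_s < v_f, in deg/s."""

    v_s: float
    v_f: float

    def __post_init__(self):
        if not 0 < self.v_s < self.v_f:
            raise ValueError("need 0 < v_s < v_f")

    @property
    def separation_factor(self) -> float:
        return self.v_f / self.v_s

    @property
    def log_mean_speed(self) -> float:
        return log_mean_speed(self.v_s, self.v_f)

    @property
    def condition_id(self) -> str:
        return f"bi_{self.v_s:g}_{self.v_f:g}"


@dataclass(frozen=True)
class WeightRegressionResult:
    slope: float  # estimate of w_f
    intercept: float  # spikes/s
    r_squared: float
    ci95_slope: float  # +/- half-width (t-based)
    n_neurons: int


def component_weights(r: float, r_s: float, r_f: float) -> tuple[float, float]:
    """Per-neuron (w_s, w_f) under the sum-to-one constraint.

    w_s = (R_f - R)/(R_f - R_s), w_f = (R - R_s)/(R_f - R_s); the pair sums
    to one exactly.  Raises :class:`UndefinedWeightError` when R_f == R_s
    (such neurons are excluded from per-neuron analyses, not silently kept).
    """
    denom = r_f - r_s
    if abs(denom) < DEGENERATE_DENOMINATOR:
        raise UndefinedWeightError(
            f"R_f - R_s = {denom:g} spikes/s: weights undefined"
        )
    w_f = (r - r_s) / denom
    return 1.0 - w_f, w_f


def _as_arrays(records) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        return (
            records["R"].to_numpy(float),
            records["R_s"].to_numpy(float),
            records["R_f"].to_numpy(float),
        )
    r = np.array([rec[0] for rec in records], dtype=float)
    r_s = np.array([rec[1] for rec in records], dtype=float)
    r_f = np.array([rec[2] for rec in records], dtype=float)
    return r, r_s, r_f


def estimate_weights_regression(records) -> WeightRegressionResult:
    """OLS of (R - R_s) on (R_f - R_s) with intercept, across neurons.

    ``records`` is a DataFrame with columns R, R_s, R_f or an iterable of
    (R, R_s, R_f) triples.  The slope estimates the faster-component
    weight w_f; the 95% CI half-width is the t-based OLS interval.
    """
    r, r_s, r_f = _as_arrays(records)
    if r.size < 3:
        raise ValueError("need at least 3 neurons for the regression")
    x = r_f - r_s
    y = r - r_s
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all R_f - R_s equal")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return WeightRegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        ci95_slope=float((ci[1, 1] - ci[1, 0]) / 2.0),
        n_neurons=int(r.size),
    )


def _slope_r2(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form OLS slope and R^2; y may be (reps, n)."""
    xc = x - x.mean()
    yc = y - y.mean(axis=-1, keepdims=True)
    sxx = (xc**2).sum()
    sxy = yc @ xc
    slope = sxy / sxx
    syy = (yc**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(syy > 0, sxy**2 / (sxx * syy), 0.0)
    return slope, r2


def random_weight_control(records, n_reps: int = 1000, seed: int = 0):
    """Regression slopes when bi-speed responses are randomly weighted averages.

    Per repetition each neuron gets an independent a ~ Uniform(0,1) and a
    simulated response R_e = a*R_f + (1-a)*R_s; the slope of the regression
    of (R_e - R_s) on (R_f - R_s) is recorded.  Returns a dict with mean
    slope/R^2, percentile (2.5/97.5) CIs, and the raw distributions.  The
    expected mean slope is E[a] = 0.5.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    _, r_s, r_f = _as_arrays(records)
    x = r_f - r_s
    if x.size < 3 or np.ptp(x) == 0:
        raise ValueError("records unsuitable for regression")
    rng = np.random.default_rng(seed)
    a = rng.uniform(size=(n_reps, x.size))
    y = a * x  # (R_e - R_s) = a * (R_f - R_s)
    slopes, r2s = _slope_r2(x, y)
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    lo2, hi2 = np.percentile(r2s, [2.5, 97.5])
    return {
        "mean_slope": float(slopes.mean()),
        "ci95_slope": (float(lo), float(hi)),
        "mean_r2": float(r2s.mean()),
        "ci95_r2": (float(lo2), float(hi2)),
        "slopes": slopes,
        "r2s": r2s,
    }


def bootstrap_compare(measured_slope: float, simulated_slopes) -> float:
    """One-sided bootstrap p-value that the measured slope exceeds simulation.

    p = (#{simulated >= measured} + 1) / (n + 1); the +1 smoothing keeps
    p > 0 when the measured value exceeds every simulated one.
    """
    sims = np.asarray(simulated_slopes, dtype=float)
    if sims.size == 0:
        raise ValueError("empty simulation set")
    return float((np.sum(sims >= measured_slope) + 1) / (sims.size + 1))


def split_trial_regression(
    trials: pd.DataFrame,
    bi_condition: str,
    slow_condition: str,
    fast_condition: str,
    n_repeats: int = 50,
    seed: int = 0,
):
    """Regression slope with R_s estimated from disjoint trial halves.

    Per repeat, each neuron's slower-component trials are randomly halved
    into means R_s1 and R_s2; the regressions of (R - R_s1) on (R_f - R_s2)
    and of (R - R_s2) on (R_f - R_s1) are both computed with the shared
    split, and slopes are averaged over both orientations and all repeats.
    Neurons with fewer than 2 slower-component trials are excluded.

    ``trials`` is a trial table (neuron_id, condition_id, trial_index,
    spike_count, duration) containing the three named conditions.
    """
    rates = trials.assign(rate=trials["spike_count"] / trials["duration"])
    by = {
        cond: rates[rates["condition_id"] == cond]
        for cond in (bi_condition, slow_condition, fast_condition)
    }
    for cond, df in by.items():
        if df.empty:
            raise ValueError(f"no trials for condition {cond!r}")
    slow_counts = by[slow_condition].groupby("neuron_id").size()
    keep = set(slow_counts[slow_counts >= 2].index)
    dropped = set(slow_counts.index) - keep
    if dropped:
        import warnings

        warnings.warn(
            f"excluding {len(dropped)} neuron(s) with <2 slower-component trials"
        )
    neuron_ids = sorted(
        keep
        & set(by[bi_condition]["neuron_id"])
        & set(by[fast_condition]["neuron_id"])
    )
    if len(neuron_ids) < 3:
        raise ValueError("fewer than 3 usable neurons")
    r = by[bi_condition].groupby("neuron_id")["rate"].mean().loc[neuron_ids].to_numpy()
    r_f = by[fast_condition].groupby("neuron_id")["rate"].mean().loc[neuron_ids].to_numpy()
    slow_by_neuron = [
        by[slow_condition].loc[by[slow_condition]["neuron_id"] == nid, "rate"].to_numpy()
        for nid in neuron_ids
    ]

    rng = np.random.default_rng(seed)
    slopes, r2s = [], []
    for _ in range(n_repeats):
        r_s1 = np.empty(len(neuron_ids))
        r_s2 = np.empty(len(neuron_ids))
        for i, vals in enumerate(slow_by_neuron):
            perm = rng.permutation(vals.size)
            half = vals.size // 2
            r_s1[i] = vals[perm[:half]].mean()
            r_s2[i] = vals[perm[half:]].mean()
        for ra, rb in ((r_s1, r_s2), (r_s2, r_s1)):
            slope, r2 = _slope_r2(r_f - rb, (r - ra)[None, :])
            slopes.append(float(slope[0]))
            r2s.append(float(r2[0]))
    return {
        "mean_slope": float(np.mean(slopes)),
        "sd_slope": float(np.std(slopes, ddof=1)),
        "mean_r2": float(np.mean(r2s)),
        "n_neurons": len(neuron_ids),
    }


def regression_table(results: dict[str, WeightRegressionResult]) -> pd.DataFrame:
    """Summarize per-condition regressions as one row per speed pair."""
    rows = []
    for cond, res in results.items():
        rows.append(
            {
                "condition": cond,
                "slope_wf": res.slope,
                "ci95_slope": res.ci95_slope,
                "intercept": res.intercept,
                "r_squared": res.r_squared,
                "n_neurons": res.n_neurons,
            }
        )
    return pd.DataFrame(rows)
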