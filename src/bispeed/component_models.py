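"""Models of direction-tuning responses to two-speed, two-direction stimuli.

Two models of the bi-component direction tuning curve R_bi measured while
two overlapping dot fields move at different speeds in directions 90 deg
apart:

- linear weighted sum (LWS):
      R_bi(theta1, theta2) = w_s * R_s(theta1) + w_f * R_f(theta2) + c,
  with free weights (no sum-to-one constraint) and offset c in [0, 100]
  spikes/s;
- weighting-pool divisive normalization:
      R_bi = S_s^n / (S_s^n + alpha*S_f^n + sigma) * R_s
           + S_f^n / (S_s^n + alpha*S_f^n + sigma) * R_f + c,
  where S_s, S_f are the summed responses of a weighting pool (a broadly
  speed-tuned population) to the slower and faster component alone, and
  n in [0.01, 100], sigma in [0, 500], alpha in [0.01, 100], c in [0, 100].
  Because the population speed tuning rises up to ~20 deg/s, S_f > S_s for
  slow speed pairs, and raising either speed component's pool response
  raises its implied weight -- the model's account of the faster-speed bias.

Fit quality is percent variance explained, PV = 100 * (1 - SSE/SST).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import lsq_linear, minimize

__all__ = [
    "DirectionTuningSet",
    "LWSFit",
    "NormalizationFit",
    "WeightingPool",
    "align_direction_tuning",
    "fit_lws",
    "fit_normalization",
    "percent_variance",
]

#: pool responses (spikes/s) to 2.5 and 10 deg/s from the population-averaged
#: speed tuning of 100 recorded MT neurons
DEFAULT_POOL_S_S = 36.7
DEFAULT_POOL_S_F = 62.5

_NORM_BOUNDS = {"n": (0.01, 100.0), "sigma": (0.0, 500.0),
                "alpha": (0.01, 100.0), "c": (0.0, 100.0)}


@dataclass(frozen=True)
class WeightingPool:
    """Summed pool responses to the slower and faster component speed."""

    S_s: float = DEFAULT_POOL_S_S
    S_f: float = DEFAULT_POOL_S_F

    def __post_init__(self):
        if self.S_s <= 0 or self.S_f <= 0:
            raise ValueError("pool responses must be positive")


@dataclass(frozen=True)
class DirectionTuningSet:
    """Component and bi-component tuning sampled on a common VA-direction grid."""

    va_directions: np.ndarray
    r_slower: np.ndarray
    r_faster: np.ndarray
    r_bi: np.ndarray
    direction_offset: float = 90.0

    def __post_init__(self):
        for name in ("va_directions", "r_slower", "r_faster", "r_bi"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        n = self.va_directions.size
        if any(getattr(self, k).size != n for k in ("r_slower", "r_faster", "r_bi")):
            raise ValueError("all curves must share the VA-direction grid")
        if n < 3:
            raise ValueError("need at least 3 VA directions")


@dataclass(frozen=True)
class LWSFit:
    w_s: float
    w_f: float
    c: float
    pv: float


@dataclass(frozen=True)
class NormalizationFit:
    n: float
    sigma: float
    alpha: float
    c: float
    implied_w_s: float
    implied_w_f: float
    pv: float


def percent_variance(model_curve, data_curve) -> float:
    """PV = 100 * (1 - SSE/SST), SST about the data mean."""
    model = np.asarray(model_curve, float)
    data = np.asarray(data_curve, float)
    if model.shape != data.shape:
        raise ValueError("curves must have equal length")
    sst = float(np.sum((data - data.mean()) ** 2))
    if sst == 0:
        raise ValueError("data has zero variance; PV undefined")
    sse = float(np.sum((model - data) ** 2))
    return 100.0 * (1.0 - sse / sst)


def align_direction_tuning(directions, responses, preferred_direction: float):
    """Circularly shift a tuning curve so ``preferred_direction`` maps to 0 deg.

    ``directions`` must uniformly cover 360 deg (e.g. 0, 15, ..., 345).  The
    curve is interpolated with a periodic cubic spline and re-sampled on the
    same grid shifted by the preferred direction; an on-grid shift reduces
    to an exact cyclic permutation.
    """
    directions = np.asarray(directions, float)
    responses = np.asarray(responses, float)
    step = np.diff(directions)
    if directions.size < 3 or not np.allclose(step, step[0]):
        raise ValueError("directions must form a uniform grid")
    if not np.isclose(directions.size * step[0], 360.0):
        raise ValueError("directions must cover 360 degrees")
    # close the period for the spline
    xs = np.append(directions, directions[0] + 360.0)
    ys = np.append(responses, responses[0])
    spline = CubicSpline(xs, ys, bc_type="periodic")
    shifted = np.mod(directions + preferred_direction - directions[0], 360.0) + directions[0]
    return spline(shifted)


def fit_lws(data: DirectionTuningSet) -> LWSFit:
    """Least-squares LWS fit; weights free, offset c bounded to [0, 100].

    The model is linear in (w_s, w_f, c), so the bounded linear
    least-squares solution is exact (no restarts needed).
    """
    a = np.column_stack([data.r_slower, data.r_faster, np.ones(data.r_bi.size)])
    if np.linalg.matrix_rank(a) < 3:
        raise ValueError("component curves are collinear; LWS weights unidentifiable")
    # unconstrained solution first: exact when c already satisfies its bounds
    x, *_ = np.linalg.lstsq(a, data.r_bi, rcond=None)
    if not 0.0 <= x[2] <= 100.0:
        res = lsq_linear(
            a,
            data.r_bi,
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, 100.0]),
            tol=1e-14,
        )
        if not res.success:
            raise RuntimeError(f"LWS fit failed to converge: {res.message}")
        x = res.x
    w_s, w_f, c = x
    pv = percent_variance(a @ x, data.r_bi)
    return LWSFit(w_s=float(w_s), w_f=float(w_f), c=float(c), pv=float(pv))


def normalization_weights(n: float, sigma: float, alpha: float, pool: WeightingPool):
    """Implied (w_s, w_f) of the weighting-pool normalization equation."""
    ss = pool.S_s**n
    sf = pool.S_f**n
    denom = ss + alpha * sf + sigma
    return ss / denom, sf / denom


def _norm_predict(params, data: DirectionTuningSet, pool: WeightingPool):
    n, sigma, alpha, c = params
    w_s, w_f = normalization_weights(n, sigma, alpha, pool)
    return w_s * data.r_slower + w_f * data.r_faster + c


def fit_normalization(
    data: DirectionTuningSet,
    pool: WeightingPool | None = None,
    n_restarts: int = 20,
    seed: int = 0,
) -> NormalizationFit:
    """Bounded SSE minimization of the normalization model.

    n and alpha are optimized on a log10 scale (their bounds span four
    decades); sigma and c stay linear.  ``n_restarts`` random interior
    starts (seeded) are run through L-BFGS-B and the best SSE is kept.
    """
    pool = pool or WeightingPool()

    def unpack(z):
        return (10.0 ** z[0], z[1], 10.0 ** z[2], z[3])

    def sse(z):
        resid = _norm_predict(unpack(z), data, pool) - data.r_bi
        return float(resid @ resid)

    zbounds = [(-2.0, 2.0), _NORM_BOUNDS["sigma"], (-2.0, 2.0), _NORM_BOUNDS["c"]]
    rng = np.random.default_rng(seed)
    starts = [np.array([0.3, 50.0, 0.0, 1.0])]
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in zbounds]))

    best = None
    for z0 in starts:
        res = minimize(sse, z0, method="L-BFGS-B", bounds=zbounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("normalization fit failed from all restarts")
    n, sigma, alpha, c = unpack(best.x)
    w_s, w_f = normalization_weights(n, sigma, alpha, pool)
    pv = percent_variance(_norm_predict((n, sigma, alpha, c), data, pool), data.r_bi)
    return NormalizationFit(
        n=float(n),
        sigma=float(sigma),
        alpha=float(alpha),
        c=float(c),
        implied_w_s=float(w_s),
        implied_w_f=float(w_f),
        pv=float(pv),
    )
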