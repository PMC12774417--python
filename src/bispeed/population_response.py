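"""Pseudo-population responses indexed by preferred speed.

Neurons recorded in separate sessions, each with the stimulus centered on
its receptive field, are pooled into a pseudo-population: each neuron's
trial-averaged response to a stimulus is normalized by the maximum of its
spline-fitted single-speed tuning curve and plotted against the neuron's
preferred speed (the argmax of that spline) on a natural-log axis.  A
smoothing spline (p = 0.93) over ln preferred speed, evaluated on a fixed
121-point ln-uniform grid from 1.25 to 80 deg/s, gives the population
response curve used by the classifier and the decoder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .splines import aggregate_duplicate_sites, smoothing_spline

__all__ = [
    "SpeedGrid",
    "SpeedTuningCurve",
    "PopulationResponse",
    "build_speed_grid",
    "fit_tuning_spline",
    "preferred_speed",
    "build_pseudopopulation",
]

SPEED_MIN = 1.25
SPEED_MAX = 80.0
GRID_SIZE = 121
DEFAULT_SMOOTHING = 0.93
#: dense ln-uniform grid resolution for preferred-speed extraction
ARGMAX_GRID_SIZE = 1201


@dataclass(frozen=True)
class SpeedGrid:
    """Ln-uniform speed grid; default 121 points from 1.25 to 80 deg/s."""

    speeds: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "speeds", np.asarray(self.speeds, float))

    @property
    def ln_speeds(self) -> np.ndarray:
        return np.log(self.speeds)

    @property
    def log_step(self) -> float:
        return float(np.log(self.speeds[-1] / self.speeds[0]) / (self.speeds.size - 1))

    def __len__(self) -> int:
        return self.speeds.size


def build_speed_grid(n_points: int = GRID_SIZE) -> SpeedGrid:
    """Grid of ``n_points`` speeds, ln-uniform, endpoints exactly 1.25 and 80."""
    ln = np.linspace(np.log(SPEED_MIN), np.log(SPEED_MAX), n_points)
    speeds = np.exp(ln)
    speeds[0] = SPEED_MIN
    speeds[-1] = SPEED_MAX
    return SpeedGrid(speeds=speeds)


def fit_tuning_spline(speeds, rates, smoothing: float = DEFAULT_SMOOTHING):
    """Cubic smoothing spline of rate vs ln speed; returns a callable of ln v.

    ``smoothing`` follows the fidelity convention: 1 interpolates, 0 is the
    least-squares line in ln speed.
    """
    speeds = np.asarray(speeds, float)
    rates = np.asarray(rates, float)
    if np.unique(speeds).size < 4:
        raise ValueError("need at least 4 distinct speeds")
    if not np.all(np.isfinite(rates)):
        raise ValueError("rates must be finite")
    order = np.argsort(speeds)
    return smoothing_spline(np.log(speeds[order]), rates[order], p=smoothing)


class SpeedTuningCurve:
    """A neuron's single-speed tuning curve with its smoothing-spline fit.

    Attributes
    ----------
    spline : callable of ln speed.
    preferred_speed : argmax of the spline in [1.25, 80] deg/s; ties broken
        to the slowest maximizer, flat splines flagged via ``tie_flag``.
    max_rate : spline value at the preferred speed.
    """

    def __init__(self, speeds, rates, smoothing: float = DEFAULT_SMOOTHING,
                 neuron_id: str | None = None):
        self.neuron_id = neuron_id
        self.speeds = np.asarray(speeds, float)
        self.rates = np.asarray(rates, float)
        self.smoothing = smoothing
        self.spline = fit_tuning_spline(self.speeds, self.rates, smoothing)
        dense_ln = np.linspace(np.log(SPEED_MIN), np.log(SPEED_MAX), ARGMAX_GRID_SIZE)
        values = np.asarray(self.spline(dense_ln), float)
        vmax = values.max()
        self.tie_flag = bool(vmax - values.min() < 1e-12)
        self.preferred_speed = float(np.exp(dense_ln[int(np.argmax(values >= vmax - 1e-12))]))
        self.max_rate = float(vmax)

    def __call__(self, speed):
        """Spline-fitted rate at ``speed`` (deg/s)."""
        return self.spline(np.log(np.asarray(speed, float)))


def preferred_speed(curve: SpeedTuningCurve) -> float:
    """Speed (deg/s) at which the spline-fitted tuning curve peaks."""
    return curve.preferred_speed


@dataclass(frozen=True)
class PopulationResponse:
    """Normalized responses of N neurons indexed by ln preferred speed."""

    neuron_ids: list[str]
    ln_preferred_speeds: np.ndarray
    normalized_responses: np.ndarray
    max_rates: np.ndarray
    grid: SpeedGrid
    spline_values: np.ndarray
    condition_id: str | None = None
    smoothing: float = DEFAULT_SMOOTHING

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": self.neuron_ids,
                "ln_pref_speed": self.ln_preferred_speeds,
                "normalized_response": self.normalized_responses,
            }
        )


def population_spline_values(
    ln_prefs: np.ndarray,
    normalized: np.ndarray,
    grid: SpeedGrid,
    smoothing: float = DEFAULT_SMOOTHING,
) -> np.ndarray:
    """Smoothing-spline fit over ln preferred speed, evaluated on the grid.

    Duplicate preferred speeds are averaged with multiplicity weights, so
    the fit equals one that weights every neuron once.
    """
    xu, yu, counts = aggregate_duplicate_sites(ln_prefs, normalized, tol=1e-12)
    spline = smoothing_spline(xu, yu, p=smoothing, weights=counts)
    return np.asarray(spline(grid.ln_speeds), float)


def build_pseudopopulation(
    tuning_curves: dict[str, SpeedTuningCurve],
    responses: dict[str, float],
    condition_id: str | None = None,
    grid: SpeedGrid | None = None,
    smoothing: float = DEFAULT_SMOOTHING,
) -> PopulationResponse:
    """Pool per-neuron responses into a normalized population response.

    ``responses`` maps neuron id to the trial-averaged rate (spikes/s) for
    one stimulus condition.  Each rate is divided by the neuron's
    ``max_rate``; neurons missing the condition are excluded with a
    warning, and neurons whose spline maximum is <= 0 are excluded.
    """
    grid = grid or build_speed_grid()
    missing = [nid for nid in tuning_curves if nid not in responses]
    if missing:
        warnings.warn(f"excluding {len(missing)} neuron(s) missing the condition")
    rows = []
    for nid, curve in tuning_curves.items():
        if nid not in responses:
            continue
        if curve.max_rate <= 0:
            warnings.warn(f"excluding neuron {nid}: nonpositive spline maximum")
            continue
        rows.append((nid, np.log(curve.preferred_speed),
                     responses[nid] / curve.max_rate, curve.max_rate))
    if len(rows) < 4:
        raise ValueError("need at least 4 usable neurons")
    rows.sort(key=lambda t: t[1])
    ids = [t[0] for t in rows]
    ln_prefs = np.array([t[1] for t in rows])
    normalized = np.array([t[2] for t in rows])
    max_rates = np.array([t[3] for t in rows])
    values = population_spline_values(ln_prefs, normalized, grid, smoothing)
    return PopulationResponse(
        neuron_ids=ids,
        ln_preferred_speeds=ln_prefs,
        normalized_responses=normalized,
        max_rates=max_rates,
        grid=grid,
        spline_values=values,
        condition_id=condition_id,
        smoothing=smoothing,
    )
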