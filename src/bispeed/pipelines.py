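"""Convenience pipelines wiring the synthetic generator to the analyses.

These helpers reproduce the study conditions end to end on synthetic
populations: tuning curves sampled at the seven single speeds, pseudo-
population construction for a bi-speed condition and its log-mean
single-speed comparison, and decoder construction.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .encoding_analysis import BiSpeedCondition
from .population_response import (
    PopulationResponse,
    SpeedGrid,
    SpeedTuningCurve,
    build_pseudopopulation,
    build_speed_grid,
)
from .speed_decoder import PopulationDecoder
from .synthetic_data import EncodingRule, NeuronSpec, make_bispeed_responses, tuning_response

#: single speeds (deg/s) of the experimental design
SINGLE_SPEEDS = (1.25, 2.5, 5.0, 10.0, 20.0, 40.0, 80.0)

#: bi-speed pairs at 4x and 2x separation
PAIRS_4X = ((1.25, 5.0), (2.5, 10.0), (5.0, 20.0), (10.0, 40.0), (20.0, 80.0))
PAIRS_2X = ((1.25, 2.5), (2.5, 5.0), (5.0, 10.0), (10.0, 20.0), (20.0, 40.0))


def tuning_curves_from_population(
    population: Sequence[NeuronSpec],
    speeds: Sequence[float] = SINGLE_SPEEDS,
    smoothing: float = 0.93,
) -> dict[str, SpeedTuningCurve]:
    """Spline-fitted tuning curves from noise-free single-speed responses."""
    speeds = np.asarray(speeds, float)
    return {
        nrn.id: SpeedTuningCurve(
            speeds, tuning_response(nrn, speeds), smoothing=smoothing, neuron_id=nrn.id
        )
        for nrn in population
    }


def condition_populations(
    population: Sequence[NeuronSpec],
    condition: BiSpeedCondition,
    rule: EncodingRule,
    curves: dict[str, SpeedTuningCurve] | None = None,
    grid: SpeedGrid | None = None,
    seed: int | None = None,
) -> tuple[PopulationResponse, PopulationResponse]:
    """Pseudo-populations for a bi-speed condition and its log-mean single speed.

    The bi-speed response follows the encoding rule; the single-speed
    comparison is each neuron's tuning response at the log-mean speed (for
    2x separations this corresponds to spline interpolation of the tuning
    curve, which coincides with the generative tuning response here).
    """
    curves = curves or tuning_curves_from_population(population)
    grid = grid or build_speed_grid()
    bi = make_bispeed_responses(population, condition, rule, seed=seed)
    bi_rates = dict(zip(bi["neuron_id"], bi["R"]))
    vm = condition.log_mean_speed
    single_rates = {nrn.id: float(tuning_response(nrn, vm)) for nrn in population}
    pop_bi = build_pseudopopulation(curves, bi_rates, condition.condition_id, grid)
    pop_single = build_pseudopopulation(curves, single_rates, f"single_{vm:.4g}", grid)
    return pop_bi, pop_single


def decoder_for_population(
    population: Sequence[NeuronSpec],
    curves: dict[str, SpeedTuningCurve] | None = None,
    grid: SpeedGrid | None = None,
) -> PopulationDecoder:
    curves = curves or tuning_curves_from_population(population)
    return PopulationDecoder(curves, grid=grid)


def normalized_responses_for(
    pop: PopulationResponse, decoder: PopulationDecoder
) -> np.ndarray:
    """Normalized mean responses reordered to the decoder's neuron order."""
    lookup = dict(zip(pop.neuron_ids, pop.normalized_responses))
    return np.array([lookup[nid] for nid in decoder.neuron_ids])
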