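"""Constrained two-speed distribution decoding."""

import itertools

import numpy as np
import pytest

from bispeed.pipelines import decoder_for_population, tuning_curves_from_population
from bispeed.population_response import build_speed_grid
from bispeed.speed_decoder import (
    DecodeResult,
    PopulationDecoder,
    SearchConfig,
    SpeedDistribution,
    classify_readout,
    discriminate_from_decodes,
    estimate_component_response,
    objective,
)
from bispeed.synthetic_data import make_population


class TestSpeedDistribution:
    def test_validation(self):
        SpeedDistribution((3,), (1.0,))
        SpeedDistribution((3, 10), (0.25, 0.75))
        with pytest.raises(ValueError):
            SpeedDistribution((3, 10), (0.4, 0.4))
        with pytest.raises(ValueError):
            SpeedDistribution((1, 2, 3), (0.3, 0.3, 0.4))


class TestEstimateComponentResponse:
    f = np.linspace(0.0, 1.2, 121)

    def test_point_mass(self):
        dist = SpeedDistribution((7,), (1.0,))
        assert estimate_component_response(self.f, dist) == pytest.approx(self.f[7])

    def test_equal_mixture(self):
        dist = SpeedDistribution((10, 30), (0.5, 0.5))
        expected = (self.f[10] + self.f[30]) / 2
        assert estimate_component_response(self.f, dist) == pytest.approx(expected)

    def test_weighted_mixture(self):
        dist = SpeedDistribution((20, 60), (0.8, 0.2))
        expected = 0.8 * self.f[20] + 0.2 * self.f[60]
        assert estimate_component_response(self.f, dist) == pytest.approx(expected)

    def test_off_grid_index_rejected(self):
        with pytest.raises(IndexError):
            estimate_component_response(self.f, SpeedDistribution((200,), (1.0,)))


class TestObjective:
    def test_perfect_match_and_offset(self, rng):
        r = rng.normal(size=121)
        assert objective(r, r) == 0.0
        assert objective(r + 0.1, r) == pytest.approx(-121 * 0.01)

    def test_matches_brute_force_sum(self, rng):
        a, b = rng.normal(size=(2, 121))
        assert objective(a, b) == pytest.approx(-sum((x - y) ** 2 for x, y in zip(a, b)))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            objective(np.zeros(121), np.zeros(13))


class TestClassifyReadout:
    @pytest.mark.parametrize(
        "weights,expected",
        [((0.5, 0.5), "two"), ((0.9, 0.1), "single"), ((0.85, 0.15), "two"),
         ((1.0,), "single"), ((0.14, 0.86), "single")],
    )
    def test_gap_rule(self, weights, expected):
        assert classify_readout(weights) == expected

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            classify_readout((0.5, 0.4))


class TestDecode:
    def test_single_speed_recovery_noise_free(self, decoder):
        y = decoder.tuning_matrix[:, 60]  # single speed 10 deg/s
        res = decoder.decode(decoder.population_curve(y))
        assert res.objective >= -1e-9
        dominant = res.readout_speeds[int(np.argmax(res.weights))]
        assert abs(np.log(dominant / 10.0)) <= decoder.grid.log_step + 1e-9
        assert classify_readout(res.weights) == res.readout_class == "single"

    def test_two_speed_recovery_noise_free(self, decoder):
        y = 0.5 * decoder.tuning_matrix[:, 40] + 0.5 * decoder.tuning_matrix[:, 80]
        res = decoder.decode(decoder.population_curve(y))
        assert res.objective >= -1e-9
        assert res.readout_class == "two"
        assert abs(np.log(res.readout_speeds[0] / 5.0)) <= decoder.grid.log_step + 1e-9
        assert abs(np.log(res.readout_speeds[1] / 20.0)) <= decoder.grid.log_step + 1e-9
        assert not any(res.boundary_flags)

    def test_self_consistency_on_admissible_distributions(self, decoder, rng):
        """Decoding the forward model of any admissible distribution gives OF=0."""
        for _ in range(5):
            j1 = int(rng.integers(0, 60))
            j2 = j1 + 2 * int(rng.integers(1, 30))
            w = round(float(rng.integers(0, 101)) / 100.0, 2)
            dist = SpeedDistribution((j1, j2), (1.0 - w, w))
            sp_ep = decoder.estimate_population(dist)
            res = decoder.decode(sp_ep)
            assert res.objective >= -1e-9
            assert np.allclose(res.estimated_population, sp_ep, atol=1e-6)

    def test_weights_sum_to_one(self, decoder, rng):
        n_neurons = decoder.tuning_matrix.shape[0]
        for _ in range(3):
            y = decoder.tuning_matrix[:, 30] + rng.normal(0, 0.05, n_neurons)
            res = decoder.decode(decoder.population_curve(y))
            assert sum(res.weights) == pytest.approx(1.0, abs=1e-12)

    def test_flat_curve_tie_flag(self, decoder):
        res = decoder.decode(np.full(121, 0.5))
        assert res.tie

    def test_exhaustive_oracle_on_reduced_grid(self, population100, tuning_curves):
        """Hill-climbing equals brute-force enumeration on a small grid."""
        grid = build_speed_grid(13)
        dec = PopulationDecoder(tuning_curves, grid=grid)
        cfg = SearchConfig(
            separation_min_steps=1, separation_max_steps=12, separation_step=1,
            probability_step=0.1, continuation_intervals=12,
        )
        rng = np.random.default_rng(0)
        for trial in range(3):
            y = dec.tuning_matrix[:, 4] + rng.normal(0, 0.1, dec.tuning_matrix.shape[0])
            sp_rp = dec.population_curve(y)
            res = dec.decode(sp_rp, cfg)
            # brute force over all admissible distributions on the lattice
            best = max(
                objective(dec.estimate_population(SpeedDistribution((j,), (1.0,))), sp_rp)
                for j in range(13)
            )
            ws = np.round(np.linspace(0, 1, 11), 10)
            for j1, j2 in itertools.combinations(range(13), 2):
                for w in ws:
                    dist = SpeedDistribution((j1, j2), (1.0 - w, w))
                    best = max(best, objective(dec.estimate_population(dist), sp_rp))
            assert res.objective == pytest.approx(best, abs=1e-9)


class TestDiscriminateFromDecodes:
    @staticmethod
    def result(speeds, weights, cls):
        return DecodeResult(
            readout_speeds=speeds, weights=weights, objective=-1.0,
            readout_class=cls, boundary_flags=(False,) * len(speeds),
            estimated_population=np.zeros(121), support_indices=(0,) * len(speeds),
        )

    def test_perfect_separation(self):
        bi = [self.result((5.0, 20.0), (0.5, 0.5), "two")] * 10
        single = [self.result((10.0,), (1.0,), "single")] * 10
        out = discriminate_from_decodes(bi, single)
        assert out["hit_rate"] == 1.0 and out["false_alarm_rate"] == 0.0
        assert out["d_prime"] == pytest.approx(4.6675, abs=0.001)

    def test_identical_distributions_give_zero(self):
        same = [self.result((5.0, 20.0), (0.5, 0.5), "two")] * 10
        assert discriminate_from_decodes(same, same)["d_prime"] == pytest.approx(0.0)

    def test_single_class_counts_as_zero_separation(self):
        # two-speed readout classified 'single' by the gap rule is no hit
        bi = [self.result((5.0, 20.0), (0.95, 0.05), "single")] * 10
        single = [self.result((10.0,), (1.0,), "single")] * 10
        out = discriminate_from_decodes(bi, single)
        assert out["hit_rate"] == 0.0

    def test_threshold_range_qualitatively_stable(self):
        # single-speed decodes with a small spurious separation (ln ~ 0.04,
        # below even the 1.1x threshold of ln 1.1 ~ 0.095)
        bi = [self.result((5.0, 20.0), (0.5, 0.5), "two")] * 20
        single = [self.result((9.8, 10.2), (0.5, 0.5), "two")] * 20
        for thr in (1.1, 1.3, 1.7):
            out = discriminate_from_decodes(bi, single, threshold_ratio=thr)
            assert out["d_prime"] > 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            discriminate_from_decodes([], [])
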