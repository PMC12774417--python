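"""Signal-detection utilities: d' for 2AFC and the 3AFC no-two-speeds split.

d' is the difference of normal quantiles of the hit and false-alarm rates.
When a rate sits exactly at 0 or 1 the quantile diverges, so a modified
formula maps rates through ``(100 * rate + 1) / 102`` before taking the
quantile, keeping d' finite (maximum 2 * Phi^-1(101/102) ~ 4.65).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm

__all__ = ["PsychometricResult", "dprime", "dprime_3afc"]


@dataclass(frozen=True)
class PsychometricResult:
    hit_rate: float
    false_alarm_rate: float
    d_prime: float
    n_trials: int
    ntc_rate: float | None = None


def _check_rate(rate: float, name: str) -> float:
    rate = float(rate)
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {rate}")
    return rate


def dprime(hit: float, fa: float, mode: str = "extremes") -> float:
    """Discriminability index from hit and false-alarm rates.

    Parameters
    ----------
    hit, fa : probabilities in [0, 1].
    mode : ``"extremes"`` applies the finite-d' correction only when a rate
        is exactly 0 or 1; ``"always"`` applies it to every rate.
    """
    hit = _check_rate(hit, "hit rate")
    fa = _check_rate(fa, "false alarm rate")
    if mode not in ("extremes", "always"):
        raise ValueError("mode must be 'extremes' or 'always'")

    # the correction applies to both rates whenever either one is extreme;
    # correcting one rate only would let hit=1, fa=0.01 exceed hit=1, fa=0
    modify = mode == "always" or hit in (0.0, 1.0) or fa in (0.0, 1.0)

    def quantile(rate: float) -> float:
        if modify:
            rate = (100.0 * rate + 1.0) / 102.0
        return float(norm.ppf(rate))

    return quantile(hit) - quantile(fa)


def dprime_3afc(
    hits: float,
    false_alarms: float,
    ntc: float,
    n_bi_trials: int,
    n_single_trials: int,
    mode: str = "extremes",
) -> PsychometricResult:
    """d' for the three-alternative task with a "no two speeds" (NTC) option.

    NTC reports do not contribute to successful discrimination: half of the
    NTC count is added to the hit tally and half to the false-alarm tally
    before rates are formed, so a session of pure NTC responses gives
    hit = fa = 0.5 and d' = 0.  Odd NTC counts contribute fractional halves.
    """
    for name, v in (("hits", hits), ("false_alarms", false_alarms), ("ntc", ntc)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    if n_bi_trials <= 0 or n_single_trials <= 0:
        raise ValueError("trial totals must be positive")
    hit_tally = hits + ntc / 2.0
    fa_tally = false_alarms + ntc / 2.0
    if hit_tally > n_bi_trials or fa_tally > n_single_trials:
        raise ValueError("counts inconsistent with trial totals")
    hit_rate = hit_tally / n_bi_trials
    fa_rate = fa_tally / n_single_trials
    d = dprime(hit_rate, fa_rate, mode=mode)
    return PsychometricResult(
        hit_rate=hit_rate,
        false_alarm_rate=fa_rate,
        d_prime=d,
        n_trials=n_bi_trials + n_single_trials,
        ntc_rate=ntc / (n_bi_trials),
    )
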