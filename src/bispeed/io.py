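"""CSV/JSON interfaces for rate tables, trial tables and results."""

from __future__ import annotations

import json
from dataclasses import asdict

import pandas as pd

RATE_COLUMNS = ["neuron_id", "condition_id", "rate"]
TRIAL_COLUMNS = ["neuron_id", "condition_id", "trial_index", "spike_count", "duration"]


def write_rates(df: pd.DataFrame, path) -> None:
    df[RATE_COLUMNS].to_csv(path, index=False)


def read_rates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"rate table missing columns: {sorted(missing)}")
    return df


def write_trial_table(df: pd.DataFrame, path) -> None:
    df[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if (df["spike_count"] < 0).any() or (df["duration"] <= 0).any():
        raise ValueError("invalid trial table: negative counts or nonpositive durations")
    return df


def trial_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Trial-averaged rates (spikes/s) per neuron and condition."""
    rates = trials.assign(rate=trials["spike_count"] / trials["duration"])
    return (
        rates.groupby(["neuron_id", "condition_id"], as_index=False)["rate"].mean()
    )


def write_result_json(result, path) -> None:
    """Serialize a dataclass result (tuples/arrays coerced to lists)."""
    def default(o):
        try:
            return o.tolist()
        except AttributeError:
            return str(o)

    with open(path, "w") as fh:
        json.dump(asdict(result), fh, indent=1, default=default)
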