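"""Linear-classifier discrimination of bi-speed vs single-speed responses.

For one speed condition pair, Poisson trial responses are generated for
each class with means set to the trial-averaged (normalized) population
responses, and a linear classifier (logistic loss, L1 penalty, SGD) is
trained and tested with k-fold cross-validation (default k = 40, 200
trials per class).  Hits are bi-speed trials classified as bi-speed;
false alarms are single-speed trials classified as bi-speed; performance
is summarized as d'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import StratifiedKFold

from .population_response import PopulationResponse
from .psychometrics import dprime

__all__ = ["ClassifierProtocol", "DiscriminationResult", "run_discrimination"]

MOTION_DURATION = 0.5  # seconds used to convert rates to spike counts


@dataclass(frozen=True)
class ClassifierProtocol:
    n_trials_per_class: int = 200
    n_folds: int = 40
    regularization_strength: float | None = None  # None -> 1/n_train
    seed: int = 0

    def __post_init__(self):
        if self.n_trials_per_class % self.n_folds != 0:
            raise ValueError("n_trials_per_class must be divisible by n_folds")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass(frozen=True)
class DiscriminationResult:
    hit_rate: float
    false_alarm_rate: float
    d_prime: float
    per_fold_accuracy: np.ndarray


def poisson_normalized_trials(
    pop: PopulationResponse,
    n_trials: int,
    seed: int,
    duration: float = MOTION_DURATION,
) -> np.ndarray:
    """(n_trials, n_neurons) normalized responses with Poisson trial noise.

    Normalized means are converted to expected spike counts through each
    neuron's maximum rate and the motion-period duration, sampled as
    Poisson counts, and rescaled back to normalized units.
    """
    rng = np.random.default_rng(seed)
    lam = np.clip(pop.normalized_responses * pop.max_rates * duration, 0.0, None)
    counts = rng.poisson(lam, size=(n_trials, lam.size))
    return counts / (pop.max_rates * duration)


def run_discrimination(
    pop_bi: PopulationResponse,
    pop_single: PopulationResponse,
    protocol: ClassifierProtocol | None = None,
) -> DiscriminationResult:
    """Cross-validated discrimination of two population-response classes.

    Both populations must contain the same neurons.  Each generated trial
    is used for testing exactly once; train and test folds never overlap.
    The contract validated on synthetic data is the ordering of d' across
    conditions, not its absolute magnitude, which depends on the
    regularization strength.
    """
    protocol = protocol or ClassifierProtocol()
    if pop_bi.neuron_ids != pop_single.neuron_ids:
        raise ValueError("populations must share the same neuron set")

    n = protocol.n_trials_per_class
    x_bi = poisson_normalized_trials(pop_bi, n, seed=protocol.seed)
    x_single = poisson_normalized_trials(pop_single, n, seed=protocol.seed + 1)
    x = np.vstack([x_bi, x_single])
    y = np.concatenate([np.ones(n, dtype=int), np.zeros(n, dtype=int)])

    n_train = 2 * n - 2 * n // protocol.n_folds
    alpha = protocol.regularization_strength
    if alpha is None:
        alpha = 1.0 / n_train

    skf = StratifiedKFold(
        n_splits=protocol.n_folds, shuffle=True, random_state=protocol.seed
    )
    predicted = np.empty_like(y)
    seen = np.zeros(y.size, dtype=int)
    fold_acc = []
    for i, (train, test) in enumerate(skf.split(x, y)):
        clf = SGDClassifier(
            loss="log_loss",
            penalty="l1",
            alpha=alpha,
            max_iter=1000,
            tol=1e-4,
            random_state=protocol.seed + i,
        )
        clf.fit(x[train], y[train])
        pred = clf.predict(x[test])
        predicted[test] = pred
        seen[test] += 1
        fold_acc.append(float(np.mean(pred == y[test])))
    assert np.all(seen == 1), "each trial must be tested exactly once"

    hit_rate = float(np.mean(predicted[y == 1] == 1))
    fa_rate = float(np.mean(predicted[y == 0] == 1))
    # rates routinely sit at or near ceiling here; the 'always' variant of
    # the finite-d' correction keeps d' monotone in (hit, fa) across ceiling
    return DiscriminationResult(
        hit_rate=hit_rate,
        false_alarm_rate=fa_rate,
        d_prime=dprime(hit_rate, fa_rate, mode="always"),
        per_fold_accuracy=np.array(fold_acc),
    )
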