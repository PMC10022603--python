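"""Runnable scenarios: melody surprise and serial dependence.

The melody demo plays the four-tone progression and measures, before each
incoming tone, the one-step predictive belief and the surprisal of what
actually arrives.  Completing the melody is anticipated; an abrupt end after
the third tone violates the protention and carries high (in the noiseless
limit, infinite) surprisal.

The serial-dependence demo simulates a circular stimulus space observed
through a noisy likelihood, with the posterior of each trial carried into
the next through a smoothing transition kernel.  Retained information then
biases the current estimate toward the previous stimulus -- the attractive
serial dependence reported in perception experiments.  The simulation design
(circular space, carried-posterior prior, circular-mean readout) is this
package's minimal operationalization of that phenomenon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest

from .belief_updating import (BeliefLattice, UpdateConfig, gradient_sweep,
                              softmax, surprisal, _log)
from .generative_model import (GenerativeModel, MELODY_OUTCOMES,
                               make_melody_model)

__all__ = [
    "MelodyResult",
    "SerialDependenceResult",
    "run_melody_demo",
    "run_serial_dependence_demo",
    "make_circular_model",
]

MELODY_CONDITIONS = ("completed", "truncated")


@dataclass(frozen=True)
class MelodyResult:
    """Per-step predictive beliefs and surprisals for one melody condition."""

    condition: str
    outcomes: tuple[int, ...]
    outcome_labels: tuple[str, ...]
    predictive_beliefs: tuple[np.ndarray, ...]   # state beliefs, pre-update
    surprisals: tuple[float, ...]                # nats, +inf sentinel allowed
    progression_fidelity: float
    tone_noise: float

    def __post_init__(self) -> None:
        for s in self.surprisals:
            if not (s >= 0.0 or s == float("inf")):
                raise ValueError(f"surprisal must be >= 0 or inf, got {s}")


@dataclass(frozen=True)
class SerialDependenceResult:
    """Trial table and attraction statistic of the serial-dependence run."""

    true_stimuli: np.ndarray
    observed: np.ndarray
    estimates: np.ndarray           # fractional circular index
    signed_errors: np.ndarray       # estimate - truth, wrapped
    attraction_per_trial: np.ndarray  # error projected toward previous stimulus
    attraction_statistic: float
    standard_error: float
    sign_test_pvalue: float
    n_trials: int
    seed: int
    degenerate: bool = False        # identity kernel + noiseless likelihood


def run_melody_demo(fidelity: float = 0.9,
                    noise: float = 0.05,
                    condition: str = "completed",
                    seed: int = 0,
                    config: UpdateConfig | None = None) -> MelodyResult:
    """Play the melody and score each tone's surprisal against anticipation.

    ``completed`` presents A, B, C, D; ``truncated`` replaces the final tone
    with silence (the abrupt end).  Before each tone, the beliefs over the
    already-heard prefix are relaxed to their fixed point by
    :func:`gradient_sweep` and pushed one step through the transition kernel
    to form the predictive state belief.  Inference is deterministic; the
    seed is recorded for interface uniformity with the other demo.
    """
    if condition not in MELODY_CONDITIONS:
        raise ValueError(f"condition must be one of {MELODY_CONDITIONS}, "
                         f"got {condition!r}")
    model = make_melody_model(fidelity, noise)
    silence_outcome = len(MELODY_OUTCOMES) - 1
    seq = (0, 1, 2, 3) if condition == "completed" else (0, 1, 2, silence_outcome)
    config = config or UpdateConfig()

    predictives: list[np.ndarray] = []
    surprisals: list[float] = []
    for step, incoming in enumerate(seq):
        if step == 0:
            predictive = model.D.copy()
        else:
            lattice = BeliefLattice.from_observations(model, list(seq[:step]))
            lattice, _ = gradient_sweep(lattice, config)
            predictive = model.transition(step - 1) @ lattice.beliefs[-1]
        predictives.append(predictive)
        surprisals.append(surprisal(model, predictive, incoming))
    return MelodyResult(
        condition=condition,
        outcomes=tuple(seq),
        outcome_labels=tuple(MELODY_OUTCOMES[o] for o in seq),
        predictive_beliefs=tuple(predictives),
        surprisals=tuple(surprisals),
        progression_fidelity=float(fidelity),
        tone_noise=float(noise),
    )


# --------------------------------------------------------------------------
# serial dependence
# --------------------------------------------------------------------------

def _circular_kernel(n: int, concentration: float) -> np.ndarray:
    """Column-stochastic von-Mises-like kernel on n circular positions."""
    angles = 2.0 * np.pi * np.arange(n) / n
    col = np.exp(concentration * np.cos(angles))
    matrix = np.empty((n, n))
    for j in range(n):
        matrix[:, j] = np.roll(col, j)
    return matrix / matrix.sum(axis=0, keepdims=True)


def make_circular_model(n_states: int,
                        kernel_concentration: float,
                        likelihood_concentration: float) -> GenerativeModel:
    """Circular stimulus space: smoothing transitions, von-Mises likelihood.

    ``kernel_concentration`` sets how sharply the carried belief persists
    across trials (0 gives a uniform kernel: nothing is retained);
    ``likelihood_concentration`` sets observation precision (``inf`` gives a
    noiseless identity likelihood).
    """
    if n_states < 8:
        raise ValueError(f"n_states must be >= 8, got {n_states}")
    if np.isinf(likelihood_concentration):
        a = np.eye(n_states)
    else:
        a = _circular_kernel(n_states, likelihood_concentration)
    b = np.eye(n_states) if np.isinf(kernel_concentration) \
        else _circular_kernel(n_states, kernel_concentration)
    d = np.full(n_states, 1.0 / n_states)
    return GenerativeModel(A=a, B=(b,), D=d)


def _circular_mean_index(belief: np.ndarray) -> float:
    n = len(belief)
    angles = 2.0 * np.pi * np.arange(n) / n
    mean_angle = np.arctan2(belief @ np.sin(angles), belief @ np.cos(angles))
    return float((mean_angle * n / (2.0 * np.pi)) % n)


def _wrap(delta: np.ndarray | float, n: int) -> np.ndarray | float:
    return (np.asarray(delta) + n / 2.0) % n - n / 2.0


def run_serial_dependence_demo(n_states: int = 12,
                               kernel_concentration: float = 2.0,
                               likelihood_concentration: float = 2.0,
                               n_trials: int = 1000,
                               seed: int = 0) -> SerialDependenceResult:
    """Simulate attractive bias of current estimates toward recent stimuli.

    Stimuli are i.i.d. uniform on the circle; each is observed through the
    noisy likelihood; the previous trial's posterior, diffused through the
    smoothing kernel, serves as the prior of the current trial.  The readout
    is the posterior circular mean (a MAP readout would quantize away the
    graded bias).  ``attraction_statistic`` is the mean signed error
    projected onto the direction of the previous observation: positive means
    attraction toward the recent past.
    """
    if n_trials < 100:
        raise ValueError(f"n_trials must be >= 100, got {n_trials}")
    model = make_circular_model(n_states, kernel_concentration,
                                likelihood_concentration)
    degenerate = bool(np.isinf(likelihood_concentration)
                      and np.allclose(model.B[0], np.eye(n_states)))
    rng = np.random.default_rng(seed)
    n = n_states
    truths = rng.integers(0, n, size=n_trials)
    observed = np.empty(n_trials, dtype=np.int64)
    estimates = np.empty(n_trials)
    floor = 1e-16
    kernel = model.B[0]
    ln_a = _log(model.A, floor)
    belief = model.D.copy()
    for i in range(n_trials):
        observed[i] = rng.choice(n, p=model.A[:, truths[i]])
        prior = kernel @ belief
        posterior = softmax(_log(prior, floor) + ln_a[observed[i], :])
        estimates[i] = _circular_mean_index(posterior)
        belief = posterior

    errors = _wrap(estimates - truths, n)
    # project each error onto the direction of the previous observation
    prev_delta = _wrap(observed[:-1] - truths[1:], n)
    proj = np.sign(prev_delta) * errors[1:]
    usable = prev_delta != 0
    attraction = proj[usable]
    stat = float(attraction.mean()) if attraction.size else 0.0
    se = float(attraction.std(ddof=1) / np.sqrt(attraction.size)) \
        if attraction.size > 1 else float("nan")
    positives = int((attraction > 0).sum())
    negatives = int((attraction < 0).sum())
    if positives + negatives > 0:
        pvalue = float(binomtest(positives, positives + negatives,
                                 alternative="greater").pvalue)
    else:
        pvalue = 1.0
    return SerialDependenceResult(
        true_stimuli=truths,
        observed=observed,
        estimates=estimates,
        signed_errors=errors,
        attraction_per_trial=attraction,
        attraction_statistic=stat,
        standard_error=se,
        sign_test_pvalue=pvalue,
        n_trials=n_trials,
        seed=seed,
        degenerate=degenerate,
    )
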