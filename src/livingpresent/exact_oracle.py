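"""Ground-truth inference for validation.

With action taken out, the temporal generative model is an ordinary hidden
Markov model, so exact smoothed marginals and the exact log evidence are
available from the scaled forward-backward recursion; a brute-force sum over
all state paths provides a second, independent route for tiny instances.
Both are used as oracles against the approximate message-passing beliefs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .generative_model import GenerativeModel, _require_valid
from .temporal_graph import TimeIndex

__all__ = ["ExactPosterior", "forward_backward", "brute_force_enumeration"]

_ENUMERATION_GUARD = 10 ** 6


@dataclass(frozen=True)
class ExactPosterior:
    """Smoothed marginals p(s_p | o_{0:T-1}) keyed by (t, tau), plus the
    log evidence ln p(o_{0:T-1}).  ``impossible`` flags a sequence with
    zero probability, for which marginals are a uniform sentinel and the
    log evidence is -inf."""

    marginals: dict[TimeIndex, np.ndarray]
    log_evidence: float
    impossible: bool = False

    def as_array(self) -> np.ndarray:
        keys = sorted(self.marginals)
        return np.stack([self.marginals[k] for k in keys])


def _outcome_factor(model: GenerativeModel, o: int | None) -> np.ndarray:
    if o is None:
        return np.ones(model.n_states)
    if not 0 <= o < model.n_outcomes:
        raise ValueError(f"outcome {o} outside [0, {model.n_outcomes})")
    return model.A[o, :]


def _keys(T: int, objective_time: int) -> list[TimeIndex]:
    return [TimeIndex(objective_time, p) for p in range(T)]


def forward_backward(model: GenerativeModel,
                     observations: "list[int | None]",
                     objective_time: int = 0) -> ExactPosterior:
    """Exact smoothing by the scaled forward-backward recursion.

    Forward messages are normalized per step; the log evidence is the sum of
    the log scale factors.  ``None`` entries denote unobserved steps.
    """
    _require_valid(model)
    obs = list(observations)
    T = len(obs)
    if T == 0:
        raise ValueError("need at least one observation slot")
    n = model.n_states
    keys = _keys(T, objective_time)

    alpha = np.zeros((T, n))
    scales = np.zeros(T)
    prev = model.D * _outcome_factor(model, obs[0])
    for p in range(T):
        if p > 0:
            prev = (model.transition(p - 1) @ alpha[p - 1]) \
                * _outcome_factor(model, obs[p])
        c = prev.sum()
        if c == 0.0:
            uniform = np.full(n, 1.0 / n)
            return ExactPosterior({k: uniform.copy() for k in keys},
                                  float("-inf"), impossible=True)
        scales[p] = c
        alpha[p] = prev / c

    beta = np.ones((T, n))
    for p in range(T - 2, -1, -1):
        b = model.transition(p)
        vec = b.T @ (beta[p + 1] * _outcome_factor(model, obs[p + 1]))
        s = vec.sum()
        beta[p] = vec / s if s > 0 else vec

    marginals = {}
    for p in range(T):
        g = alpha[p] * beta[p]
        marginals[keys[p]] = g / g.sum()
    return ExactPosterior(marginals, float(np.log(scales).sum()))


def brute_force_enumeration(model: GenerativeModel,
                            observations: "list[int | None]",
                            objective_time: int = 0) -> ExactPosterior:
    """Exact smoothing by summing the joint over every state path."""
    _require_valid(model)
    obs = list(observations)
    T = len(obs)
    if T == 0:
        raise ValueError("need at least one observation slot")
    n = model.n_states
    if n ** T > _ENUMERATION_GUARD:
        raise ValueError(
            f"instance too large to enumerate: {n}^{T} > {_ENUMERATION_GUARD}")
    keys = _keys(T, objective_time)
    factors = [_outcome_factor(model, o) for o in obs]

    accum = np.zeros((T, n))
    evidence = 0.0
    for path in itertools.product(range(n), repeat=T):
        w = model.D[path[0]] * factors[0][path[0]]
        for p in range(1, T):
            w *= model.transition(p - 1)[path[p], path[p - 1]] \
                * factors[p][path[p]]
            if w == 0.0:
                break
        if w == 0.0:
            continue
        evidence += w
        for p, s in enumerate(path):
            accum[p, s] += w

    if evidence == 0.0:
        uniform = np.full(n, 1.0 / n)
        return ExactPosterior({k: uniform.copy() for k in keys},
                              float("-inf"), impossible=True)
    marginals = {keys[p]: accum[p] / evidence for p in range(T)}
    return ExactPosterior(marginals, float(np.log(evidence)))
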