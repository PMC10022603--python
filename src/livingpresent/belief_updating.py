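"""Belief updating over a temporal lattice by softmax message passing.

The posterior belief about the hidden state at one moment is the softmax of
three log-domain messages:

* a *forward* message from the preceding belief through the transition
  kernel (the prior, or under the integrated-continuity labelling the
  "prior protention" carried over from the previous objective step);
* a *backward* message from the following belief through the transposed
  kernel (the prediction, or "predicted primal impression");
* a *likelihood* message from the observation at that moment (the "likely
  retention": the just-past event, now observed).

The same fixed point

    s_p = softmax( ln(B_{p-1}) s_{p-1} + ln(B_p)^T s_{p+1} + ln(A)^T o_p )

is reached either by direct fixed-point iteration or by an explicit-Euler
gradient flow ``v <- ln s + dt * (messages - ln s)`` on the log-potential,
which is gradient descent on the mean-field variational free energy of the
chain.  Two index conventions label the same chain positions: ``stationary``
keeps a single objective time and walks the subjective index, while
``integrated`` reads the neighbours at (t-1, tau+1), (t, tau+1) and the
observation at (t, tau-1), interleaving objective and subjective coordinates
(chain position p = 2 t + tau).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy.special import xlogy

from .generative_model import GenerativeModel, Observation
from .temporal_graph import TimeIndex

__all__ = [
    "UpdateConfig",
    "BeliefState",
    "BeliefLattice",
    "ConvergenceRecord",
    "FreeEnergy",
    "FreeEnergyTerm",
    "softmax",
    "present_moment_inference",
    "message_sum",
    "consumed_indices",
    "stationary_update",
    "lattice_residual",
    "gradient_sweep",
    "solve_stationary",
    "free_energy",
    "surprisal",
    "lattice_to_frame",
]

_CONVENTIONS = ("stationary", "integrated")


@dataclass(frozen=True)
class UpdateConfig:
    """Numerical knobs of the belief-update dynamics.

    ``step_size`` is the Euler step dt on the log-potential (1.0 collapses
    the flow to direct fixed-point iteration; values above 1 overshoot and
    are allowed only to study divergence).  ``log_floor`` clips probabilities
    before any logarithm so deterministic models are first-class.
    ``index_convention`` selects how neighbour coordinates are labelled;
    ``log_of_product`` switches the forward/backward messages from
    (elementwise-log B) @ s to log(B @ s) for sensitivity checks.
    """

    step_size: float = 0.1
    max_iterations: int = 10_000
    tolerance: float = 1e-8
    log_floor: float = 1e-16
    index_convention: str = "stationary"
    log_of_product: bool = False

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.step_size > 1:
            warnings.warn(
                f"step_size {self.step_size} > 1 overshoots the fixed point; "
                "convergence is not guaranteed", RuntimeWarning, stacklevel=2)
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.index_convention not in _CONVENTIONS:
            raise ValueError(
                f"index_convention must be one of {_CONVENTIONS}, "
                f"got {self.index_convention!r}")


@dataclass(frozen=True)
class BeliefState:
    """A normalized probability vector over hidden states at one moment."""

    probabilities: np.ndarray
    index: TimeIndex

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.ndim != 1:
            raise ValueError("belief must be a vector")
        if np.any(p < 0):
            raise ValueError("belief entries must be non-negative")
        if abs(p.sum() - 1.0) > 1e-10:
            raise ValueError(f"belief must sum to 1, got {p.sum():.12g}")


def softmax(potential: np.ndarray) -> np.ndarray:
    """Exponentiate-and-normalize; invariant to adding a constant."""
    v = np.asarray(potential, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("softmax requires finite inputs")
    e = np.exp(v - v.max())
    return e / e.sum()


def _log(p: np.ndarray, floor: float) -> np.ndarray:
    return np.log(np.maximum(p, floor))


# --------------------------------------------------------------------------
# the lattice
# --------------------------------------------------------------------------

class BeliefLattice:
    """Beliefs over a chain of moments, addressable by (t, tau) coordinates.

    Internally the lattice is a chain of positions 0..T-1 with one belief
    vector and an optional observed outcome each.  The two index conventions
    are alternative coordinate charts on that chain: under ``stationary`` a
    hidden position p is (objective_time, p); under ``integrated`` position
    p is any (t, tau) with 2t + tau = p for hidden nodes and
    2t + tau + 1 = p for observation nodes, so each chain position is
    revisited from successive objective presents.
    """

    def __init__(self, model: GenerativeModel,
                 outcomes: Sequence[int | None],
                 convention: str = "stationary",
                 objective_time: int = 0,
                 beliefs: np.ndarray | None = None):
        if convention not in _CONVENTIONS:
            raise ValueError(f"unknown convention {convention!r}")
        self.model = model
        self.convention = convention
        self.objective_time = objective_time
        self.outcomes: list[int | None] = list(outcomes)
        for o in self.outcomes:
            if o is not None and not 0 <= o < model.n_outcomes:
                raise ValueError(f"outcome {o} outside [0, {model.n_outcomes})")
        n, T = model.n_states, len(self.outcomes)
        if T == 0:
            raise ValueError("lattice needs at least one position")
        if beliefs is None:
            beliefs = np.full((T, n), 1.0 / n)
        beliefs = np.asarray(beliefs, dtype=float)
        if beliefs.shape != (T, n):
            raise ValueError(f"beliefs must have shape ({T}, {n})")
        self.beliefs = beliefs

    @classmethod
    def from_observations(cls, model: GenerativeModel,
                          outcomes: Sequence[int | None],
                          convention: str = "stationary",
                          objective_time: int = 0) -> "BeliefLattice":
        return cls(model, outcomes, convention, objective_time)

    def copy(self) -> "BeliefLattice":
        return BeliefLattice(self.model, list(self.outcomes), self.convention,
                             self.objective_time, self.beliefs.copy())

    def __len__(self) -> int:
        return len(self.outcomes)

    # ---------------------------------------------------------- coordinates
    def hidden_position(self, index: TimeIndex) -> int:
        p = self._try_hidden_position(index)
        if p is None:
            raise KeyError(f"no hidden node at {index} under "
                           f"{self.convention!r} labelling")
        return p

    def _try_hidden_position(self, index: TimeIndex) -> int | None:
        if self.convention == "stationary":
            if index.objective != self.objective_time:
                return None
            p = index.subjective
        else:
            p = 2 * index.objective + index.subjective
        return p if 0 <= p < len(self) else None

    def _try_observation_position(self, index: TimeIndex) -> int | None:
        if self.convention == "stationary":
            if index.objective != self.objective_time:
                return None
            p = index.subjective
        else:
            p = 2 * index.objective + index.subjective + 1
        return p if 0 <= p < len(self) else None

    def hidden_index(self, position: int) -> TimeIndex:
        """Canonical (t, tau) chart for a chain position."""
        if not 0 <= position < len(self):
            raise IndexError(f"position {position} outside chain")
        if self.convention == "stationary":
            return TimeIndex(self.objective_time, position)
        return TimeIndex(position // 2, position % 2)

    def observation_index(self, position: int) -> TimeIndex:
        if not 0 <= position < len(self):
            raise IndexError(f"position {position} outside chain")
        if self.convention == "stationary":
            return TimeIndex(self.objective_time, position)
        # obs (t, u) labels chain position 2t + u + 1
        return (TimeIndex(position // 2, -1) if position % 2 == 0
                else TimeIndex((position - 1) // 2, 0))

    # --------------------------------------------------------------- views
    def belief(self, index: TimeIndex) -> BeliefState:
        return BeliefState(self.beliefs[self.hidden_position(index)], index)

    def belief_items(self) -> Iterator[tuple[TimeIndex, BeliefState]]:
        for p in range(len(self)):
            idx = self.hidden_index(p)
            yield idx, BeliefState(self.beliefs[p], idx)

    def observation_items(self) -> Iterator[tuple[TimeIndex, Observation]]:
        for p, o in enumerate(self.outcomes):
            if o is not None:
                idx = self.observation_index(p)
                yield idx, Observation(idx, o)


@dataclass
class ConvergenceRecord:
    converged: bool
    iterations: int
    free_energy_trace: list[float] = field(default_factory=list)
    max_change_trace: list[float] = field(default_factory=list)
    final_residual: float = float("nan")


@dataclass(frozen=True)
class FreeEnergyTerm:
    index: TimeIndex
    entropy: float                 # E_q[ln q]  (negative entropy, in fact)
    expected_transition: float     # -E_q[ln p(s_p | s_{p-1})]
    expected_likelihood: float     # -E_q[ln p(o_p | s_p)]

    @property
    def total(self) -> float:
        return self.entropy + self.expected_transition + self.expected_likelihood


@dataclass(frozen=True)
class FreeEnergy:
    value: float
    decomposition: tuple[FreeEnergyTerm, ...]


# --------------------------------------------------------------------------
# message passing
# --------------------------------------------------------------------------

def _neighbor_map(convention: str, target: TimeIndex) -> dict[str, TimeIndex]:
    t, u = target.objective, target.subjective
    if convention == "stationary":
        return {"forward": TimeIndex(t, u - 1),
                "backward": TimeIndex(t, u + 1),
                "observation": TimeIndex(t, u)}
    return {"forward": TimeIndex(t - 1, u + 1),
            "backward": TimeIndex(t, u + 1),
            "observation": TimeIndex(t, u - 1)}


def consumed_indices(lattice: BeliefLattice, target: TimeIndex,
                     convention: str | None = None) -> dict[str, TimeIndex]:
    """The neighbour coordinates an update of ``target`` actually reads.

    Only neighbours that exist on the finite lattice (and, for the
    observation slot, are observed) appear in the result.
    """
    convention = convention or lattice.convention
    lattice.hidden_position(target)
    nb = _neighbor_map(convention, target)
    out: dict[str, TimeIndex] = {}
    if lattice._try_hidden_position(nb["forward"]) is not None:
        out["forward"] = nb["forward"]
    if lattice._try_hidden_position(nb["backward"]) is not None:
        out["backward"] = nb["backward"]
    q = lattice._try_observation_position(nb["observation"])
    if q is not None and lattice.outcomes[q] is not None:
        out["observation"] = nb["observation"]
    return out


def message_sum(lattice: BeliefLattice, target: TimeIndex,
                config: UpdateConfig | None = None) -> np.ndarray:
    """Sum of the forward, backward and likelihood log-messages at ``target``.

    A missing forward neighbour (chain start) falls back to the initial
    prior; missing backward or observation terms are simply omitted
    (boundary rule for the truncated lattice).
    """
    config = config or UpdateConfig(index_convention=lattice.convention)
    if config.index_convention != lattice.convention:
        raise ValueError(
            f"config index_convention {config.index_convention!r} does not "
            f"match lattice convention {lattice.convention!r}")
    floor = config.log_floor
    model = lattice.model
    p = lattice.hidden_position(target)
    nb = _neighbor_map(config.index_convention, target)
    m = np.zeros(model.n_states)

    q = lattice._try_hidden_position(nb["forward"])
    if q is None:
        m += _log(model.D, floor)
    else:
        b = model.transition(q)
        s_prev = lattice.beliefs[q]
        m += _log(b @ s_prev, floor) if config.log_of_product \
            else _log(b, floor) @ s_prev
    q = lattice._try_hidden_position(nb["backward"])
    if q is not None:
        b = model.transition(p)
        s_next = lattice.beliefs[q]
        m += _log(b.T @ s_next, floor) if config.log_of_product \
            else _log(b, floor).T @ s_next
    q = lattice._try_observation_position(nb["observation"])
    if q is not None and lattice.outcomes[q] is not None:
        m += _log(model.A, floor)[lattice.outcomes[q], :]
    return m


def stationary_update(lattice: BeliefLattice, target: TimeIndex,
                      config: UpdateConfig | None = None) -> BeliefState:
    """Softmax of the three messages at ``target``: the fixed-point map."""
    config = config or UpdateConfig(index_convention=lattice.convention)
    return BeliefState(softmax(message_sum(lattice, target, config)), target)


def present_moment_inference(protention: BeliefState,
                             primal: BeliefState,
                             retention: Observation,
                             model: GenerativeModel,
                             log_floor: float = 1e-16) -> BeliefState:
    """Infer the present from its three constituting messages.

    The present belief is the softmax of the log-protention (the previous
    step's anticipation), the log-primal-impression (the current predicted
    state) and the likelihood message of the retained observation.
    """
    n = model.n_states
    for name, vec in (("protention", protention.probabilities),
                      ("primal", primal.probabilities)):
        if vec.shape != (n,):
            raise ValueError(f"{name} has {vec.shape[0]} states, model has {n}")
    if not 0 <= retention.outcome < model.n_outcomes:
        raise ValueError(f"retained outcome {retention.outcome} outside "
                         f"[0, {model.n_outcomes})")
    v = (_log(protention.probabilities, log_floor)
         + _log(primal.probabilities, log_floor)
         + _log(model.A, log_floor)[retention.outcome, :])
    index = TimeIndex(primal.index.objective, primal.index.subjective - 1)
    return BeliefState(softmax(v), index)


def lattice_residual(lattice: BeliefLattice,
                     config: UpdateConfig | None = None) -> float:
    """L-infinity distance of the lattice from the stationary fixed point."""
    config = config or UpdateConfig(index_convention=lattice.convention)
    worst = 0.0
    for p in range(len(lattice)):
        target = lattice.hidden_index(p)
        s_star = softmax(message_sum(lattice, target, config))
        worst = max(worst, float(np.abs(s_star - lattice.beliefs[p]).max()))
    return worst


def gradient_sweep(lattice: BeliefLattice,
                   config: UpdateConfig | None = None,
                   ) -> tuple[BeliefLattice, ConvergenceRecord]:
    """Relax all beliefs by Euler descent on the variational free energy.

    Each sweep updates every position in chain order (deterministic
    Gauss-Seidel schedule) via ``v <- ln s + dt (messages - ln s)`` followed
    by softmax renormalization.  Iteration stops when the largest belief
    change in a sweep drops below ``config.tolerance``; hitting
    ``max_iterations`` first is flagged in the record, not raised.
    """
    config = config or UpdateConfig(index_convention=lattice.convention)
    lat = lattice.copy()
    floor, dt = config.log_floor, config.step_size
    fe_trace = [free_energy(lat, log_floor=floor).value]
    change_trace: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        max_change = 0.0
        for p in range(len(lat)):
            target = lat.hidden_index(p)
            v = _log(lat.beliefs[p], floor)
            m = message_sum(lat, target, config)
            s_new = softmax(v + dt * (m - v))
            max_change = max(max_change,
                             float(np.abs(s_new - lat.beliefs[p]).max()))
            lat.beliefs[p] = s_new
        fe_trace.append(free_energy(lat, log_floor=floor).value)
        change_trace.append(max_change)
        if max_change < config.tolerance:
            converged = True
            break
    record = ConvergenceRecord(
        converged=converged,
        iterations=iterations,
        free_energy_trace=fe_trace,
        max_change_trace=change_trace,
        final_residual=lattice_residual(lat, config),
    )
    return lat, record


def solve_stationary(lattice: BeliefLattice,
                     config: UpdateConfig | None = None,
                     ) -> tuple[BeliefLattice, ConvergenceRecord]:
    """Direct fixed-point iteration (the dt = 1 limit of the gradient flow)."""
    config = config or UpdateConfig(index_convention=lattice.convention)
    return gradient_sweep(lattice, replace(config, step_size=1.0))


# --------------------------------------------------------------------------
# free energy and surprisal
# --------------------------------------------------------------------------

def free_energy(lattice: BeliefLattice, log_floor: float = 1e-16) -> FreeEnergy:
    """Mean-field variational free energy of the chain, term by term.

    F = sum_p E_q[ln q(s_p)] - E_q[ln p(s_p | s_{p-1})] - E_q[ln p(o_p | s_p)]
    with the first position using the initial prior.  Expectations use the
    factorized beliefs; exact zeros in a belief annihilate the floored
    logarithms, so deterministic models evaluate exactly.
    """
    model = lattice.model
    terms = []
    for p in range(len(lattice)):
        s = lattice.beliefs[p]
        entropy = float(xlogy(s, s).sum())
        if p == 0:
            cross = float(s @ _log(model.D, log_floor))
        else:
            b = model.transition(p - 1)
            cross = float(s @ (_log(b, log_floor) @ lattice.beliefs[p - 1]))
        o = lattice.outcomes[p]
        like = 0.0 if o is None else float(
            s @ _log(model.A, log_floor)[o, :])
        terms.append(FreeEnergyTerm(
            index=lattice.hidden_index(p),
            entropy=entropy,
            expected_transition=-cross,
            expected_likelihood=-like,
        ))
    return FreeEnergy(value=sum(t.total for t in terms),
                      decomposition=tuple(terms))


def surprisal(model: GenerativeModel,
              predictive: BeliefState | np.ndarray,
              outcome: Observation | int) -> float:
    """Negative log probability of an outcome under a predictive belief.

    Returns ``inf`` when the predictive outcome probability is exactly zero
    (the sentinel for a fully unanticipated event), never raises.
    """
    q = predictive.probabilities if isinstance(predictive, BeliefState) \
        else np.asarray(predictive, dtype=float)
    if q.shape != (model.n_states,):
        raise ValueError(f"predictive has shape {q.shape}, "
                         f"model has {model.n_states} states")
    o = outcome.outcome if isinstance(outcome, Observation) else int(outcome)
    if not 0 <= o < model.n_outcomes:
        raise ValueError(f"outcome {o} outside [0, {model.n_outcomes})")
    p = float(model.A[o, :] @ q)
    if p <= 0.0:
        return float("inf")
    return -float(np.log(p))


def lattice_to_frame(lattice: BeliefLattice) -> "pd.DataFrame":
    """Belief trajectories as tidy rows (objective_t, subjective_tau, state,
    probability)."""
    import pandas as pd

    labels = lattice.model.state_labels or tuple(
        f"s{i}" for i in range(lattice.model.n_states))
    rows = []
    for p in range(len(lattice)):
        idx = lattice.hidden_index(p)
        for i, prob in enumerate(lattice.beliefs[p]):
            rows.append({
                "objective_t": idx.objective,
                "subjective_tau": idx.subjective,
                "state_label": labels[i],
                "probability": float(prob),
            })
    return pd.DataFrame(rows)
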