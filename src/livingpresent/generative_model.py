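"""Discrete generative models: likelihood A, transitions B, initial prior D.

Conventions
-----------
All probability matrices are *column*-stochastic: columns index the
conditioning variable, rows the conditioned one.  ``A`` (n_outcomes x
n_states) maps hidden states to outcome distributions, ``B`` (n_states x
n_states) maps the current state to a distribution over the next state, so
both act by a left matrix-vector product.  ``B`` is stored as an ordered
list of matrices to allow per-step transition kernels; a homogeneous model
stores a single shared matrix.

The module also samples synthetic generative processes (the world side of
the model) and builds the melody scenario used by the demos: a five-state
progression toneA -> toneB -> toneC -> toneD that may fall silent at any
step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .temporal_graph import TimeIndex

__all__ = [
    "STOCHASTIC_ATOL",
    "Violation",
    "ModelValidationError",
    "Observation",
    "GenerativeModel",
    "validate_model",
    "sample_process",
    "make_melody_model",
    "load_model",
    "save_model",
    "samples_to_frame",
    "MELODY_STATES",
    "MELODY_OUTCOMES",
]

STOCHASTIC_ATOL = 1e-12

MELODY_STATES = ("toneA", "toneB", "toneC", "toneD", "silence")
MELODY_OUTCOMES = ("A", "B", "C", "D", "silence")


@dataclass(frozen=True)
class Violation:
    """One broken invariant of a generative model (data, not an exception)."""

    component: str          # "A", "B[2]", "D", ...
    where: tuple | None     # offending index, or None for shape problems
    kind: str               # "column_sum" | "out_of_range" | "shape"
    residual: float
    message: str


class ModelValidationError(ValueError):
    def __init__(self, violations: list[Violation]):
        self.violations = violations
        detail = "; ".join(v.message for v in violations[:5])
        super().__init__(f"invalid generative model: {detail}")


@dataclass(frozen=True)
class Observation:
    """A discrete outcome anchored at a (t, tau) coordinate."""

    index: TimeIndex
    outcome: int

    def __post_init__(self) -> None:
        if self.outcome < 0:
            raise ValueError(f"outcome must be non-negative, got {self.outcome}")


@dataclass(frozen=True)
class GenerativeModel:
    """Likelihood ``A``, transition list ``B``, initial prior ``D``."""

    A: np.ndarray
    B: tuple[np.ndarray, ...]
    D: np.ndarray
    state_labels: tuple[str, ...] | None = None
    outcome_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "A", np.asarray(self.A, dtype=float))
        bs = self.B
        if isinstance(bs, np.ndarray) and bs.ndim == 2:
            bs = (bs,)
        object.__setattr__(
            self, "B", tuple(np.asarray(b, dtype=float) for b in bs))
        object.__setattr__(self, "D", np.asarray(self.D, dtype=float))
        if self.state_labels is not None:
            object.__setattr__(self, "state_labels", tuple(self.state_labels))
        if self.outcome_labels is not None:
            object.__setattr__(self, "outcome_labels", tuple(self.outcome_labels))

    @property
    def n_states(self) -> int:
        return self.A.shape[1]

    @property
    def n_outcomes(self) -> int:
        return self.A.shape[0]

    @property
    def homogeneous(self) -> bool:
        return len(self.B) == 1

    def transition(self, step: int) -> np.ndarray:
        """Transition matrix applying between steps ``step`` and ``step+1``."""
        if self.homogeneous:
            return self.B[0]
        if not 0 <= step < len(self.B):
            raise IndexError(
                f"no transition matrix for step {step} "
                f"(model defines {len(self.B)})")
        return self.B[step]


def _check_stochastic(name: str, matrix: np.ndarray,
                      violations: list[Violation]) -> None:
    if matrix.ndim != 2:
        violations.append(Violation(name, None, "shape", 0.0,
                                    f"{name} must be a matrix"))
        return
    bad = (matrix < 0) | (matrix > 1)
    for i, j in zip(*np.nonzero(bad)):
        violations.append(Violation(
            name, (int(i), int(j)), "out_of_range", float(matrix[i, j]),
            f"{name}[{i},{j}] = {matrix[i, j]:g} outside [0, 1]"))
    sums = matrix.sum(axis=0)
    for j, s in enumerate(sums):
        if abs(s - 1.0) > STOCHASTIC_ATOL:
            violations.append(Violation(
                name, (int(j),), "column_sum", float(s - 1.0),
                f"column {j} of {name} sums to {s:.12g}, residual {s - 1.0:.3g}"))


def validate_model(model: GenerativeModel) -> list[Violation]:
    """Check stochasticity and dimensional consistency; return violations."""
    violations: list[Violation] = []
    _check_stochastic("A", model.A, violations)
    n = model.A.shape[1] if model.A.ndim == 2 else None
    for k, b in enumerate(model.B):
        name = f"B[{k}]"
        _check_stochastic(name, b, violations)
        if b.ndim == 2 and n is not None and b.shape != (n, n):
            violations.append(Violation(
                name, None, "shape", 0.0,
                f"{name} has shape {b.shape}, expected ({n}, {n})"))
    d = model.D
    if d.ndim != 1 or (n is not None and d.shape[0] != n):
        violations.append(Violation(
            "D", None, "shape", 0.0,
            f"D has shape {d.shape}, expected ({n},)"))
    else:
        bad = (d < 0) | (d > 1)
        for i in np.nonzero(bad)[0]:
            violations.append(Violation(
                "D", (int(i),), "out_of_range", float(d[i]),
                f"D[{i}] = {d[i]:g} outside [0, 1]"))
        s = d.sum()
        if abs(s - 1.0) > STOCHASTIC_ATOL:
            violations.append(Violation(
                "D", None, "column_sum", float(s - 1.0),
                f"D sums to {s:.12g}, residual {s - 1.0:.3g}"))
    return violations


def _require_valid(model: GenerativeModel) -> None:
    violations = validate_model(model)
    if violations:
        raise ModelValidationError(violations)


def sample_process(model: GenerativeModel, n_steps: int,
                   seed: int | np.random.Generator,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Sample a state/observation path from the generative process.

    The first state is drawn from ``D``; each subsequent state from the
    applicable transition matrix; each observation from the likelihood
    conditioned on the state.  Fully reproducible given ``seed``.
    """
    _require_valid(model)
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    rng = np.random.default_rng(seed)
    states = np.empty(n_steps, dtype=np.int64)
    outcomes = np.empty(n_steps, dtype=np.int64)
    n = model.n_states
    for k in range(n_steps):
        if k == 0:
            p = model.D
        else:
            b = model.B[0] if model.homogeneous else model.transition(k - 1)
            p = b[:, states[k - 1]]
        states[k] = rng.choice(n, p=p / p.sum())
        q = model.A[:, states[k]]
        outcomes[k] = rng.choice(model.n_outcomes, p=q / q.sum())
    return states, outcomes


def make_melody_model(progression_fidelity: float = 0.9,
                      tone_noise: float = 0.05) -> GenerativeModel:
    """Build the four-tone melody model with a silent absorbing state.

    Hidden states are toneA..toneD plus silence.  The progression advances
    A -> B -> C -> D with probability ``progression_fidelity`` and otherwise
    falls silent; toneD always resolves into silence, and silence is
    absorbing.  The likelihood reports each tone's own outcome with
    probability ``1 - tone_noise`` and spreads ``tone_noise`` uniformly over
    the other outcomes.  The initial prior is certain on toneA.
    """
    p, q = float(progression_fidelity), float(tone_noise)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"progression_fidelity must be in [0, 1], got {p}")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"tone_noise must be in [0, 1], got {q}")
    n = 5
    silence = 4
    b = np.zeros((n, n))
    for tone in range(3):               # toneA..toneC advance or fall silent
        b[tone + 1, tone] = p
        b[silence, tone] = 1.0 - p
    b[silence, 3] = 1.0                  # toneD resolves into silence
    b[silence, silence] = 1.0            # silence is absorbing
    a = np.full((n, n), q / (n - 1))
    np.fill_diagonal(a, 1.0 - q)
    d = np.zeros(n)
    d[0] = 1.0
    return GenerativeModel(A=a, B=(b,), D=d,
                           state_labels=MELODY_STATES,
                           outcome_labels=MELODY_OUTCOMES)


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

_MODEL_KEYS = {"A", "B", "D", "labels"}


def _model_payload(model: GenerativeModel) -> dict:
    payload: dict = {
        "A": model.A.tolist(),
        "B": [b.tolist() for b in model.B],
        "D": model.D.tolist(),
    }
    labels = {}
    if model.state_labels is not None:
        labels["states"] = list(model.state_labels)
    if model.outcome_labels is not None:
        labels["outcomes"] = list(model.outcome_labels)
    if labels:
        payload["labels"] = labels
    return payload


def save_model(model: GenerativeModel, path: str | Path) -> None:
    """Write a model to YAML (or JSON when the suffix is .json)."""
    path = Path(path)
    payload = _model_payload(model)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_model(path: str | Path) -> GenerativeModel:
    """Load and validate a model from a YAML/JSON file.

    Unknown top-level keys and invariant violations are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ValueError(f"model file {path} does not contain a mapping")
    unknown = set(payload) - _MODEL_KEYS
    if unknown:
        raise ValueError(f"unknown keys in model file {path}: {sorted(unknown)}")
    missing = {"A", "B", "D"} - set(payload)
    if missing:
        raise ValueError(f"model file {path} is missing keys: {sorted(missing)}")
    b_raw = payload["B"]
    b_arr = np.asarray(b_raw, dtype=float)
    b_list = (b_arr,) if b_arr.ndim == 2 else tuple(np.asarray(m, float) for m in b_raw)
    labels = payload.get("labels", {}) or {}
    model = GenerativeModel(
        A=np.asarray(payload["A"], dtype=float),
        B=b_list,
        D=np.asarray(payload["D"], dtype=float),
        state_labels=tuple(labels["states"]) if "states" in labels else None,
        outcome_labels=tuple(labels["outcomes"]) if "outcomes" in labels else None,
    )
    _require_valid(model)
    return model


def samples_to_frame(states: np.ndarray, outcomes: np.ndarray,
                     model: GenerativeModel | None = None) -> pd.DataFrame:
    """Tabulate a sampled path as (step, state, observation) rows."""
    frame = pd.DataFrame({
        "step": np.arange(len(states)),
        "state": states,
        "observation": outcomes,
    })
    if model is not None and model.state_labels is not None:
        frame["state_label"] = [model.state_labels[s] for s in states]
    if model is not None and model.outcome_labels is not None:
        frame["observation_label"] = [model.outcome_labels[o] for o in outcomes]
    return frame
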