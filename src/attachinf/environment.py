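"""The true generative process: a stochastic caregiver.

The environment samples hidden caregiver-infant states and emits
observations in response to the infant's actions.  It is a fixed
stochastic process, not an agent: the caregiver Attends with
probability ``q`` (the responsiveness) whenever the infant acts,
independently of history.  Matrix orientation matches the agent's
convention: columns = current state, rows = next state / outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .engine import _draw_index, assert_categorical

__all__ = [
    "GenerativeProcess",
    "sample_initial_state",
    "sample_transition",
    "sample_observation",
]


@dataclass
class GenerativeProcess:
    """True environment dynamics for one caregiver configuration.

    ``transitions`` is ``(L, J, J)`` with column-stochastic kernels (one
    per infant action), ``initial`` the distribution over the J hidden
    states at the start of an episode, ``emission`` the ``(W, J)``
    column-stochastic outcome distribution.  ``params`` records the
    caregiver parameters the matrices were built from.
    """

    transitions: np.ndarray
    initial: np.ndarray
    emission: np.ndarray
    params: dict = field(default_factory=dict)
    state_labels: Optional[Sequence[str]] = None
    outcome_labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        for kernel in self.transitions:
            assert_categorical(kernel)
        assert_categorical(self.initial)
        assert_categorical(self.emission)
        J = self.initial.shape[0]
        if self.transitions.shape[1:] != (J, J) or self.emission.shape[1] != J:
            raise ValueError("inconsistent process shapes")

    @property
    def num_states(self) -> int:
        return self.initial.shape[0]

    @property
    def num_outcomes(self) -> int:
        return self.emission.shape[0]

    @property
    def num_actions(self) -> int:
        return self.transitions.shape[0]


def sample_initial_state(process: GenerativeProcess, rng: np.random.Generator) -> int:
    """Draw the hidden state at the start of an episode."""
    return _draw_index(process.initial, rng)


def sample_transition(
    process: GenerativeProcess, state: int, action: int, rng: np.random.Generator
) -> int:
    """Draw the next hidden state given the current state and the
    infant's action."""
    if not 0 <= state < process.num_states:
        raise IndexError(f"state {state} out of range")
    if not 0 <= action < process.num_actions:
        raise IndexError(f"action {action} out of range")
    return _draw_index(process.transitions[action][:, state], rng)


def sample_observation(
    process: GenerativeProcess, state: int, rng: np.random.Generator
) -> int:
    """Draw the outcome emitted by the current hidden state."""
    if not 0 <= state < process.num_states:
        raise IndexError(f"state {state} out of range")
    return _draw_index(process.emission[:, state], rng)
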