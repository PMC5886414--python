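"""Builders for attachment processes and infant generative models.

Two families of environment are provided.

*Interoceptive* (6 hidden states): states are all combinations of the
infant's control state (Seek, GuardedSeek, Avoid) with the caregiver's
regulatory stance (Attend, Ignore).  The infant observes only
interoceptive outcomes I1..I5 reflecting its stress change: I1 = g
(Seek attended), I2 = h (GuardedSeek attended), I3 = -m (Seek
ignored), I4 = -n (GuardedSeek ignored), I5 = 0 (Avoid).  Observations
are deterministic given the state, and the caregiver Attends with
probability q on every exchange.

*Exteroceptive* (12 hidden states): the caregiving component becomes a
pair (current behaviour, subsequent behaviour), and alongside the
interoceptive outcome the caregiver emits an affective cue about its
subsequent behaviour -- an attend-cue (accurate before Attend with
probability a), no cue (accurate before Ignore with probability b) or
an ambiguous cue (rate c).  Misleading and ambiguous cues model the
affective-communication errors of the AMBIANCE scale.  An avoiding
infant always observes no cue.

Infant models encode beliefs as Dirichlet concentrations: a confident
belief places delta times the true probability on possible events and
the floor epsilon on impossible ones; uninformative transition priors
place unit mass on both caregiving responses, equivalent to an
uncertain expectation of a q = 0.5 caregiver.

Index conventions (0-based): states are control-major; interoceptive
outcomes are control-major over I1..I5; exteroceptive outcomes are
control-major, then interoceptive, then cue (attend-cue, no-cue,
ambiguous).  Caregiving pairs are ordered (A,A), (A,I), (I,A), (I,I).
"""

from __future__ import annotations

import numpy as np

from .config import AttachmentConfig
from .engine import DirichletFamily, GenerativeModel
from .environment import GenerativeProcess

__all__ = [
    "SEEK",
    "GUARDED_SEEK",
    "AVOID",
    "ACTION_LABELS",
    "ATTEND",
    "IGNORE",
    "CUE_ATTEND",
    "CUE_NONE",
    "CUE_AMBIGUOUS",
    "build_interoceptive_process",
    "build_preference_dist",
    "build_perfect_model",
    "build_uninformative_model",
    "build_exteroceptive_process",
    "build_exteroceptive_model",
]

SEEK, GUARDED_SEEK, AVOID = 0, 1, 2
ACTION_LABELS = ("Seek", "GuardedSeek", "Avoid")
ATTEND, IGNORE = 0, 1
CARE_LABELS = ("Attend", "Ignore")
CUE_ATTEND, CUE_NONE, CUE_AMBIGUOUS = 0, 1, 2
CUE_LABELS = ("AttendCue", "NoCue", "AmbiguousCue")
PAIR_LABELS = ("AA", "AI", "IA", "II")

#: interoceptive outcome (I index, 0-based) for (control, caregiving)
_INTERO_OUTCOME = {
    (SEEK, ATTEND): 0,  # I1: payoff g
    (SEEK, IGNORE): 2,  # I3: payoff -m
    (GUARDED_SEEK, ATTEND): 1,  # I2: payoff h
    (GUARDED_SEEK, IGNORE): 3,  # I4: payoff -n
    (AVOID, ATTEND): 4,  # I5: payoff 0
    (AVOID, IGNORE): 4,
}


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(np.asarray(x, dtype=float) - np.max(x))
    return e / e.sum()


def _confident_concentrations(
    probs: np.ndarray, delta: float, epsilon: float
) -> np.ndarray:
    """delta * p where p > 0, the floor epsilon elsewhere."""
    return np.where(probs > 0, delta * probs, epsilon)


# ---------------------------------------------------------------------------
# interoceptive (6-state) environment
# ---------------------------------------------------------------------------


def build_interoceptive_process(config: AttachmentConfig) -> GenerativeProcess:
    """The 6-state caregiver environment with interoceptive outcomes.

    Every action U_w leads to state (U_w, Attend) with probability q and
    (U_w, Ignore) with probability 1-q, from any current state.  The
    episode starts in the Avoid states (the infant begins each
    interaction at a distance), Attend vs Ignore weighted q : 1-q.
    Emissions are deterministic: the control component is observed
    directly and the caregiving stance fixes the interoceptive outcome.
    """
    q = config.q
    J, W, L = 6, 15, 3
    transitions = np.zeros((L, J, J))
    for w in range(L):
        transitions[w, 2 * w, :] = q
        transitions[w, 2 * w + 1, :] = 1.0 - q
    initial = np.zeros(J)
    initial[2 * AVOID] = q
    initial[2 * AVOID + 1] = 1.0 - q
    emission = np.zeros((W, J))
    for w in range(L):
        for x in (ATTEND, IGNORE):
            emission[5 * w + _INTERO_OUTCOME[(w, x)], 2 * w + x] = 1.0
    state_labels = [f"{ACTION_LABELS[w]}|{CARE_LABELS[x]}" for w in range(L) for x in (0, 1)]
    outcome_labels = [f"{ACTION_LABELS[w]}|I{i + 1}" for w in range(L) for i in range(5)]
    return GenerativeProcess(
        transitions=transitions,
        initial=initial,
        emission=emission,
        params={"q": q},
        state_labels=state_labels,
        outcome_labels=outcome_labels,
    )


def build_preference_dist(
    config: AttachmentConfig, num_control_blocks: int = 3, num_cues: int = 1
) -> np.ndarray:
    """Outcome preferences: the softmax of the payoff vector (g, h, -m,
    -n, 0) tiled over control blocks (the infant is indifferent to
    control outcomes) and, in the exteroceptive model, over cues."""
    payoffs = np.asarray(config.payoffs, dtype=float)
    tiled = np.tile(np.repeat(payoffs, num_cues), num_control_blocks)
    return _softmax(tiled)


def _model_from_process_probs(
    likelihood_probs: np.ndarray,
    transition_probs: np.ndarray,
    initial_probs: np.ndarray,
    preferences: np.ndarray,
    config: AttachmentConfig,
    transition_conc: np.ndarray | None = None,
    initial_conc: np.ndarray | None = None,
) -> GenerativeModel:
    d, e = config.delta, config.epsilon
    priors = DirichletFamily(
        likelihood=_confident_concentrations(likelihood_probs, d, e),
        transitions=(
            transition_conc
            if transition_conc is not None
            else _confident_concentrations(transition_probs, d, e)
        ),
        initial=(
            initial_conc
            if initial_conc is not None
            else _confident_concentrations(initial_probs, d, e)
        ),
    )
    return GenerativeModel(
        priors=priors,
        preferences=preferences,
        precision_shape=config.alpha,
        precision_rate=config.beta,
        horizon=config.horizon,
        variational_iters=config.variational_iters,
        decisions_per_episode=config.decisions_per_episode,
        learn_likelihood=False,
        learn_transitions=True,
        learn_initial=True,
    )


def build_perfect_model(
    process: GenerativeProcess, config: AttachmentConfig
) -> GenerativeModel:
    """An infant whose working model matches the true process: every
    concentration is delta times the true probability where positive,
    epsilon otherwise, for likelihood, transitions and initial state."""
    n_blocks = process.num_actions
    n_cues = process.num_outcomes // (5 * n_blocks)
    return _model_from_process_probs(
        process.emission,
        process.transitions,
        process.initial,
        build_preference_dist(config, n_blocks, n_cues),
        config,
    )


def build_uninformative_model(config: AttachmentConfig) -> GenerativeModel:
    """An infant with no knowledge of caregiver responsiveness.

    Transition priors place unit concentration on both caregiving
    responses to each action (rows 2w, 2w+1 for action U_w) and the
    floor elsewhere; the initial-state prior is all ones.  The
    likelihood is accurate (confident), and is not learned.
    """
    process = build_interoceptive_process(config)
    J, L, e = 6, 3, config.epsilon
    trans_conc = np.full((L, J, J), e)
    for w in range(L):
        trans_conc[w, 2 * w, :] = 1.0
        trans_conc[w, 2 * w + 1, :] = 1.0
    return _model_from_process_probs(
        process.emission,
        process.transitions,
        process.initial,
        build_preference_dist(config, L, 1),
        config,
        transition_conc=trans_conc,
        initial_conc=np.ones(J),
    )


# ---------------------------------------------------------------------------
# exteroceptive (12-state) environment
# ---------------------------------------------------------------------------


def _pair_kernel(q: float) -> np.ndarray:
    """4x4 caregiving-pair kernel: the new pair's first element is the
    old pair's second, and the new second element is Attend w.p. q."""
    P = np.zeros((4, 4))
    for col, (_, x2) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
        P[2 * x2 + ATTEND, col] = q
        P[2 * x2 + IGNORE, col] = 1.0 - q
    return P


def _control_mask(x: float, w: int, L: int = 3) -> np.ndarray:
    """L x L matrix with ones in row w and x elsewhere."""
    M = np.full((L, L), x)
    M[w, :] = 1.0
    return M


def _cue_dist(config: AttachmentConfig, control: int, subsequent: int) -> np.ndarray:
    """True cue-emission probabilities (attend-cue, no-cue, ambiguous)."""
    a, b, c = config.a, config.b, config.c
    cue = np.zeros(3)
    if control == AVOID:
        cue[CUE_NONE] = 1.0
    elif subsequent == ATTEND:
        cue[CUE_ATTEND] = a
        cue[CUE_AMBIGUOUS] = c
        cue[CUE_NONE] = 1.0 - a - c
    else:
        cue[CUE_NONE] = b
        cue[CUE_AMBIGUOUS] = c
        cue[CUE_ATTEND] = 1.0 - b - c
    return cue


def _extero_emission(config: AttachmentConfig, model_beliefs: bool) -> np.ndarray:
    """(45, 12) emission: interoceptive outcome fixed by control and the
    pair's current element; cue distributed by the pair's subsequent
    element.  With ``model_beliefs`` the cue component follows the
    infant's prior associations instead of the true rates."""
    W, L = 45, 3
    emission = np.zeros((W, 12))
    s = config.cue_model_split
    for w in range(L):
        for y, (x1, x2) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
            state = 4 * w + y
            intero = _INTERO_OUTCOME[(w, x1)]
            if model_beliefs:
                cue = np.zeros(3)
                if w == AVOID:
                    cue[CUE_NONE] = 1.0
                elif x2 == ATTEND:
                    cue[CUE_ATTEND] = 1.0 - s
                    cue[CUE_AMBIGUOUS] = s
                else:
                    cue[CUE_NONE] = 1.0 - s
                    cue[CUE_AMBIGUOUS] = s
            else:
                cue = _cue_dist(config, w, x2)
            for k in range(3):
                emission[15 * w + 3 * intero + k, state] = cue[k]
    return emission


def build_exteroceptive_process(config: AttachmentConfig) -> GenerativeProcess:
    """The 12-state environment with caregiving pairs and affective cues."""
    q = config.q
    P4 = _pair_kernel(q)
    transitions = np.stack(
        [np.kron(_control_mask(0.0, w), P4) for w in range(3)]
    )
    # infant starts avoiding; pair elements independently Attend w.p. q
    initial = np.zeros(12)
    initial[4 * AVOID:] = [q * q, q * (1 - q), (1 - q) * q, (1 - q) * (1 - q)]
    emission = _extero_emission(config, model_beliefs=False)
    state_labels = [
        f"{ACTION_LABELS[w]}|{PAIR_LABELS[y]}" for w in range(3) for y in range(4)
    ]
    outcome_labels = [
        f"{ACTION_LABELS[w]}|I{i + 1}|{CUE_LABELS[k]}"
        for w in range(3)
        for i in range(5)
        for k in range(3)
    ]
    return GenerativeProcess(
        transitions=transitions,
        initial=initial,
        emission=emission,
        params={"q": q, "a": config.a, "b": config.b, "c": config.c},
        state_labels=state_labels,
        outcome_labels=outcome_labels,
    )


def build_exteroceptive_model(config: AttachmentConfig) -> GenerativeModel:
    """The infant model for the 12-state environment.

    Transition priors are uninformative over caregiving pairs within
    the selected control block (unit concentration) and floored outside
    it; the initial prior is flat.  The likelihood is fixed (not
    learned): the interoceptive component is accurate, and the cue
    component encodes the infant's prior cue associations -- the
    attend-cue before Attend, no cue before Ignore, with the ambiguous
    cue expected under both (split ``cue_model_split``).
    """
    e = config.epsilon
    trans_conc = np.stack(
        [np.kron(_control_mask(e, w), np.ones((4, 4))) for w in range(3)]
    )
    # kron multiplies the epsilon blocks by 1; restore the exact floor
    trans_conc = np.maximum(trans_conc, e)
    model_emission = _extero_emission(config, model_beliefs=True)
    process = build_exteroceptive_process(config)
    return _model_from_process_probs(
        model_emission,
        process.transitions,
        process.initial,
        build_preference_dist(config, 3, 3),
        config,
        transition_conc=trans_conc,
        initial_conc=np.ones(12),
    )
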