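"""Discrete-state active inference engine.

Implements a partially observed Markov decision process agent that
perceives, acts and learns by (expected) free-energy minimisation:

* state inference -- a softmax over expected log-likelihood plus
  expected log-prior (or propagated previous belief),
* policy evaluation -- the expected free energy of every remaining
  action sequence, decomposed into an extrinsic (preference-seeking)
  and an epistemic (uncertainty-resolving) part,
* precision -- a Gamma-posterior expectation of the inverse temperature
  applied to policy values,
* action selection -- the policy posterior marginalised over first
  actions and sampled,
* learning -- Dirichlet concentration updates accumulated after each
  episode, with implicit learning rates set by prior experience.

All categorical parameters are held as Dirichlet concentrations; their
expected log values are obtained through the digamma function.  Matrix
orientation throughout: columns index the conditioning state, rows the
outcome / next state.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import digamma

__all__ = [
    "CONCENTRATION_FLOOR",
    "LOG_FLOOR",
    "InvalidConcentrationError",
    "PrecisionDivergenceError",
    "EmptyPolicyError",
    "DirichletFamily",
    "GenerativeModel",
    "PolicySet",
    "BeliefState",
    "EpisodeRecord",
    "ModelExpectations",
    "assert_categorical",
    "expected_log_params",
    "compute_expectations",
    "infer_states",
    "enumerate_policies",
    "predict_beliefs",
    "policy_quality",
    "update_policy_posterior",
    "update_precision",
    "variational_step",
    "action_posterior",
    "sample_action",
    "run_episode",
    "learn_from_episode",
    "run_learning",
]

#: smallest admissible Dirichlet concentration
CONCENTRATION_FLOOR = 1e-10
#: floor applied to log-probabilities inside value sums (0*log 0 := 0)
LOG_FLOOR = float(np.log(1e-16))


class InvalidConcentrationError(ValueError):
    """A Dirichlet concentration parameter was zero or negative."""


class PrecisionDivergenceError(ArithmeticError):
    """The precision-update denominator was non-positive.

    Signals pathologically large positive expected policy value; with
    non-positive extrinsic value dominating at the scales used here this
    does not occur in the shipped configurations.
    """


class EmptyPolicyError(ValueError):
    """Policies were requested past the last decision step."""


def assert_categorical(p: np.ndarray, tol: float = 1e-9) -> None:
    """Raise if ``p`` is not a probability vector (axis 0 for matrices)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < -tol):
        raise ValueError("negative probability entry")
    s = p.sum(axis=0)
    if np.any(np.abs(s - 1.0) > tol):
        raise ValueError(f"probabilities sum to {s}, expected 1")


def _softmax(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    e = np.exp(x - x.max())
    return e / e.sum()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DirichletFamily:
    """Dirichlet concentrations for likelihood, transition and initial-state
    distributions.

    ``likelihood`` is a ``(W, J)`` array (outcomes x states),
    ``transitions`` a ``(L, J, J)`` array (one column-stochastic-shaped
    kernel per action, rows = next state) and ``initial`` a ``(J,)``
    vector.  All entries must exceed :data:`CONCENTRATION_FLOOR` (up to
    equality).
    """

    likelihood: np.ndarray
    transitions: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        for name, arr in (
            ("likelihood", self.likelihood),
            ("transitions", self.transitions),
            ("initial", self.initial),
        ):
            if np.any(arr < CONCENTRATION_FLOOR * (1 - 1e-12)):
                raise InvalidConcentrationError(
                    f"{name} concentrations must be >= {CONCENTRATION_FLOOR}"
                )
        W, J = self.likelihood.shape
        if self.transitions.shape[1:] != (J, J) or self.initial.shape != (J,):
            raise ValueError("inconsistent Dirichlet family shapes")

    @property
    def num_states(self) -> int:
        return self.likelihood.shape[1]

    @property
    def num_outcomes(self) -> int:
        return self.likelihood.shape[0]

    @property
    def num_actions(self) -> int:
        return self.transitions.shape[0]

    def copy(self) -> "DirichletFamily":
        return DirichletFamily(
            self.likelihood.copy(), self.transitions.copy(), self.initial.copy()
        )


@dataclass
class GenerativeModel:
    """The agent's internal working model of its environment.

    ``priors`` hold the concentrations the agent starts from; the
    ``posteriors`` (initialised equal to the priors) accumulate
    experience through :func:`learn_from_episode`.  ``preferences`` is a
    strictly positive probability vector over outcomes (the softmax of
    the payoff structure); its log enters the extrinsic part of expected
    free energy.  ``precision_shape``/``precision_rate`` are the Gamma
    prior (alpha, beta) on policy precision.
    """

    priors: DirichletFamily
    preferences: np.ndarray
    precision_shape: float = 250.0
    precision_rate: float = 1.0
    horizon: int = 4
    variational_iters: int = 4
    learn_likelihood: bool = False
    learn_transitions: bool = True
    learn_initial: bool = True
    decisions_per_episode: Optional[int] = None
    posteriors: Optional[DirichletFamily] = None

    def __post_init__(self) -> None:
        self.preferences = np.asarray(self.preferences, dtype=float)
        assert_categorical(self.preferences)
        if np.any(self.preferences <= 0):
            raise ValueError("preferences must be strictly positive")
        if self.precision_shape <= 0 or self.precision_rate <= 0:
            raise ValueError("precision prior parameters must be positive")
        if self.horizon < 2:
            raise ValueError("horizon must be at least 2")
        if self.decisions_per_episode is None:
            self.decisions_per_episode = self.horizon
        if self.decisions_per_episode not in (self.horizon - 1, self.horizon):
            raise ValueError("decisions_per_episode must be T-1 or T")
        if self.posteriors is None:
            self.posteriors = self.priors.copy()
        if self.preferences.shape[0] != self.priors.num_outcomes:
            raise ValueError("preference dimension does not match outcomes")

    @property
    def num_states(self) -> int:
        return self.priors.num_states

    @property
    def num_outcomes(self) -> int:
        return self.priors.num_outcomes

    @property
    def num_actions(self) -> int:
        return self.priors.num_actions

    def copy(self) -> "GenerativeModel":
        m = copy.copy(self)
        m.priors = self.priors.copy()
        m.posteriors = self.posteriors.copy()
        m.preferences = self.preferences.copy()
        return m


@dataclass
class PolicySet:
    """All remaining action sequences at a decision step, in lexicographic
    order (first action varies slowest)."""

    policies: np.ndarray  # (K, R) int array
    num_actions: int

    @property
    def count(self) -> int:
        return self.policies.shape[0]

    @property
    def depth(self) -> int:
        return self.policies.shape[1]


@dataclass
class BeliefState:
    """Posterior expectations at one point within an episode."""

    state_beliefs: list = field(default_factory=list)
    policy_beliefs: Optional[np.ndarray] = None
    precision: float = 1.0
    quality: Optional[np.ndarray] = None
    extrinsic: Optional[np.ndarray] = None
    epistemic: Optional[np.ndarray] = None

    def snapshot(self) -> "BeliefState":
        return BeliefState(
            state_beliefs=list(self.state_beliefs),
            policy_beliefs=None if self.policy_beliefs is None else self.policy_beliefs,
            precision=self.precision,
            quality=self.quality,
            extrinsic=self.extrinsic,
            epistemic=self.epistemic,
        )


@dataclass
class EpisodeRecord:
    """One dyadic exchange: everything observed, believed and done."""

    observations: np.ndarray  # (T,) outcome index per time step
    actions: np.ndarray  # (D,) action index per decision step
    true_states: np.ndarray  # (T,) environment state (diagnostics only)
    state_beliefs: np.ndarray  # (T, J) final state expectation per step
    belief_trajectory: list  # BeliefState snapshot per time step
    precisions: np.ndarray  # (D,) precision after each decision step
    final_efe: np.ndarray  # (L, 3) per-action (quality, extrinsic, epistemic)

    def to_frame(self):
        """Flatten to one row per time step (for CSV export)."""
        import pandas as pd

        T = len(self.observations)
        rows = []
        for t in range(T):
            decided = t < len(self.actions)
            rows.append(
                {
                    "step": t + 1,
                    "observation": int(self.observations[t]),
                    "true_state": int(self.true_states[t]),
                    "action": int(self.actions[t]) if decided else -1,
                    "precision": float(self.precisions[t]) if decided else np.nan,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class ModelExpectations:
    """Expected-log parameters of a model's posterior Dirichlet family,
    plus their normalised (probability-scale) counterparts used for
    prediction.  Recomputed once per episode."""

    log_likelihood: np.ndarray  # (W, J)
    log_transitions: np.ndarray  # (L, J, J)
    log_initial: np.ndarray  # (J,)
    likelihood: np.ndarray  # (W, J) column-stochastic
    transitions: np.ndarray  # (L, J, J) column-stochastic
    log_preferences: np.ndarray  # (W,) floored at LOG_FLOOR


# ---------------------------------------------------------------------------
# expected parameters
# ---------------------------------------------------------------------------


def expected_log_params(concentration_column: Sequence[float]) -> np.ndarray:
    """Expected log-probabilities of a Dirichlet-distributed categorical.

    Returns ``psi(c_i) - psi(sum_i c_i)`` per entry, ``psi`` the digamma
    function.  Raises :class:`InvalidConcentrationError` on non-positive
    entries.
    """
    c = np.asarray(concentration_column, dtype=float)
    if np.any(c <= 0):
        raise InvalidConcentrationError("concentration entries must be positive")
    return digamma(c) - digamma(c.sum())


def _expected_log_columns(conc: np.ndarray) -> np.ndarray:
    """Column-wise expected log for a (rows=outcome, cols=condition) array."""
    if np.any(conc <= 0):
        raise InvalidConcentrationError("concentration entries must be positive")
    return digamma(conc) - digamma(conc.sum(axis=0, keepdims=True))


def _normalised_exp(log_cols: np.ndarray) -> np.ndarray:
    """exp of expected-log parameters, column-renormalised.

    exp(psi(c_i) - psi(sum c)) is sub-stochastic; renormalisation gives
    the probability-scale matrix used for forward prediction.
    """
    e = np.exp(log_cols - log_cols.max(axis=0, keepdims=True))
    return e / e.sum(axis=0, keepdims=True)


def compute_expectations(model: GenerativeModel) -> ModelExpectations:
    """Digest a model's posterior concentrations into the expected-log and
    normalised matrices used by inference and policy evaluation."""
    post = model.posteriors
    logA = _expected_log_columns(post.likelihood)
    logB = np.stack([_expected_log_columns(B) for B in post.transitions])
    logD = expected_log_params(post.initial)
    return ModelExpectations(
        log_likelihood=logA,
        log_transitions=logB,
        log_initial=logD,
        likelihood=_normalised_exp(logA),
        transitions=np.stack([_normalised_exp(B) for B in logB]),
        log_preferences=np.maximum(np.log(model.preferences), LOG_FLOOR),
    )


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def infer_states(
    model: GenerativeModel,
    observation: int,
    step: int,
    prev_belief: Optional[np.ndarray] = None,
    prev_action: Optional[int] = None,
    expectations: Optional[ModelExpectations] = None,
) -> np.ndarray:
    """Posterior state expectation after observing ``observation`` at
    ``step`` (1-based).

    At step 1 the prior is the expected log initial distribution; later
    steps propagate the previous belief through the expected log
    transition matrix of the previous action.
    """
    exps = expectations if expectations is not None else compute_expectations(model)
    W, J = exps.log_likelihood.shape
    if not 0 <= observation < W:
        raise IndexError(f"observation {observation} out of range [0, {W})")
    if step == 1:
        log_post = exps.log_likelihood[observation] + exps.log_initial
    else:
        if prev_belief is None or prev_action is None:
            raise ValueError("prev_belief and prev_action required for step > 1")
        if not 0 <= prev_action < exps.log_transitions.shape[0]:
            raise IndexError(f"action {prev_action} out of range")
        log_post = exps.log_likelihood[observation] + (
            exps.log_transitions[prev_action] @ np.asarray(prev_belief, dtype=float)
        )
    return _softmax(log_post)


def enumerate_policies(
    num_controls: int,
    current_step: int,
    horizon: int,
    decisions_per_episode: Optional[int] = None,
) -> PolicySet:
    """All action sequences covering the remaining decision steps.

    Decision steps run 1..D where by default D = horizon (one action per
    time step; the final policy's predictions extend one step past the
    last observation).  The set at step t holds
    ``num_controls ** (D - t + 1)`` sequences, enumerated
    lexicographically (first action varies slowest).
    """
    D = horizon if decisions_per_episode is None else decisions_per_episode
    remaining = D - current_step + 1
    if remaining < 1:
        raise EmptyPolicyError(
            f"step {current_step} is past the last decision step {D}"
        )
    grids = np.meshgrid(*([np.arange(num_controls)] * remaining), indexing="ij")
    policies = np.stack([g.ravel() for g in grids], axis=1)
    return PolicySet(policies=policies, num_actions=num_controls)


# ---------------------------------------------------------------------------
# policy evaluation (expected free energy)
# ---------------------------------------------------------------------------


def _step_values(exps: ModelExpectations, s_pred: np.ndarray) -> tuple[float, float]:
    """Extrinsic and epistemic value of one predicted step.

    Extrinsic: expected log preference of the predicted outcome.
    Epistemic: expected KL from the predictive state belief to the
    state posterior after the (counterfactual) outcome -- the mutual
    information between predicted outcome and state.  Zero-probability
    branches contribute zero.
    """
    o_pred = exps.likelihood @ s_pred
    ext = float(o_pred @ exps.log_preferences)
    joint = exps.likelihood * s_pred  # (W, J): Q(o, s | pi)
    denom = np.outer(o_pred, s_pred)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / denom)
    epi = float(np.nansum(terms))
    return ext, epi


def _evaluate_policy_tree(
    exps: ModelExpectations, belief: np.ndarray, num_actions: int, depth: int
) -> tuple[np.ndarray, np.ndarray]:
    """Extrinsic/epistemic sums for all ``num_actions ** depth`` policies
    in lexicographic order, sharing prefix computations."""
    L = num_actions
    block = L ** (depth - 1)
    ext = np.empty(L * block)
    epi = np.empty(L * block)
    for u in range(L):
        s_next = exps.transitions[u] @ belief
        e0, k0 = _step_values(exps, s_next)
        sl = slice(u * block, (u + 1) * block)
        if depth == 1:
            ext[sl] = e0
            epi[sl] = k0
        else:
            sub_e, sub_k = _evaluate_policy_tree(exps, s_next, L, depth - 1)
            ext[sl] = e0 + sub_e
            epi[sl] = k0 + sub_k
    return ext, epi


def predict_beliefs(
    model: GenerativeModel,
    current_belief: np.ndarray,
    policy: Sequence[int],
    expectations: Optional[ModelExpectations] = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Posterior predictive (state, outcome) distributions along a policy."""
    if len(policy) == 0:
        raise ValueError("policy must be non-empty")
    exps = expectations if expectations is not None else compute_expectations(model)
    s = np.asarray(current_belief, dtype=float)
    out = []
    for u in policy:
        s = exps.transitions[u] @ s
        out.append((s, exps.likelihood @ s))
    return out


def policy_quality(
    model: GenerativeModel,
    current_belief: np.ndarray,
    policy: Sequence[int],
    expectations: Optional[ModelExpectations] = None,
) -> tuple[float, float, float]:
    """Expected negative free energy of one policy, decomposed.

    Returns ``(quality, extrinsic, epistemic)`` with
    ``quality = extrinsic + epistemic``, ``extrinsic <= 0`` and
    ``epistemic >= 0``.
    """
    exps = expectations if expectations is not None else compute_expectations(model)
    s = np.asarray(current_belief, dtype=float)
    ext = epi = 0.0
    for u in policy:
        s = exps.transitions[u] @ s
        e, k = _step_values(exps, s)
        ext += e
        epi += k
    return ext + epi, ext, epi


def update_policy_posterior(quality: np.ndarray, precision: float) -> np.ndarray:
    """Softmax of precision-weighted policy values."""
    if precision <= 0:
        raise ValueError("precision must be positive")
    return _softmax(precision * np.asarray(quality, dtype=float))


def update_precision(
    shape: float, rate: float, quality: np.ndarray, policy_beliefs: np.ndarray
) -> float:
    """Gamma-posterior expected precision: alpha / (beta - Q . pi)."""
    denom = rate - float(np.dot(quality, policy_beliefs))
    if denom <= 0:
        raise PrecisionDivergenceError(
            f"precision denominator {denom} <= 0 (expected quality too large)"
        )
    return shape / denom


def variational_step(
    model: GenerativeModel,
    observation: int,
    step: int,
    belief: BeliefState,
    policies: Optional[PolicySet] = None,
    prev_action: Optional[int] = None,
    expectations: Optional[ModelExpectations] = None,
) -> BeliefState:
    """One sweep of the inference updates: state belief, then policy
    values and posterior, then precision.  The caller repeats this N
    times per observation.

    The quality vector is recomputed from the refreshed state belief;
    when the state belief is already at its fixed point (its update has
    fixed inputs, so one sweep suffices) the previous quality vector is
    reused unchanged.
    """
    exps = expectations if expectations is not None else compute_expectations(model)
    prev_belief = belief.state_beliefs[step - 2] if step > 1 else None
    s = infer_states(
        model, observation, step, prev_belief, prev_action, expectations=exps
    )
    refreshed = True
    if len(belief.state_beliefs) >= step:
        refreshed = bool(np.max(np.abs(s - belief.state_beliefs[step - 1])) > 1e-14)
        belief.state_beliefs[step - 1] = s
    else:
        belief.state_beliefs.append(s)

    if policies is None:
        policies = enumerate_policies(
            model.num_actions, step, model.horizon, model.decisions_per_episode
        )
    if refreshed or belief.quality is None or len(belief.quality) != policies.count:
        ext, epi = _evaluate_policy_tree(exps, s, policies.num_actions, policies.depth)
        belief.extrinsic = ext
        belief.epistemic = epi
        belief.quality = ext + epi
    belief.policy_beliefs = update_policy_posterior(belief.quality, belief.precision)
    belief.precision = update_precision(
        model.precision_shape, model.precision_rate, belief.quality, belief.policy_beliefs
    )
    return belief


# ---------------------------------------------------------------------------
# action
# ---------------------------------------------------------------------------


def action_posterior(policy_beliefs: np.ndarray, policies: PolicySet) -> np.ndarray:
    """Marginal probability of each first action under the policy posterior."""
    pi = np.asarray(policy_beliefs, dtype=float)
    if pi.shape[0] != policies.count:
        raise ValueError("policy posterior does not match policy set")
    post = np.bincount(
        policies.policies[:, 0], weights=pi, minlength=policies.num_actions
    )
    return post / post.sum()


def _draw_index(p: np.ndarray, rng: np.random.Generator) -> int:
    cum = np.cumsum(p)
    return int(min(np.searchsorted(cum, rng.random() * cum[-1], side="right"),
                   len(p) - 1))


def sample_action(action_post: np.ndarray, rng: np.random.Generator) -> int:
    """Draw an action index from its posterior distribution."""
    return _draw_index(np.asarray(action_post, dtype=float), rng)


# ---------------------------------------------------------------------------
# episodes and learning
# ---------------------------------------------------------------------------


def run_episode(
    model: GenerativeModel,
    process,
    rng: np.random.Generator,
    expectations: Optional[ModelExpectations] = None,
) -> EpisodeRecord:
    """Play out one episode of the perception-action loop.

    Alternates environment observation, N variational sweeps, action
    sampling and environment transition over the episode's time steps.
    The model is not mutated; learning is a separate call.
    """
    from . import environment as env

    exps = expectations if expectations is not None else compute_expectations(model)
    T = model.horizon
    D = model.decisions_per_episode
    L = model.num_actions
    N = model.variational_iters

    state = env.sample_initial_state(process, rng)
    belief = BeliefState(precision=model.precision_shape / model.precision_rate)
    observations = np.empty(T, dtype=np.int64)
    true_states = np.empty(T, dtype=np.int64)
    actions = np.empty(D, dtype=np.int64)
    precisions = np.empty(D, dtype=float)
    trajectory = []
    final_efe = None

    for t in range(1, T + 1):
        obs = env.sample_observation(process, state, rng)
        observations[t - 1] = obs
        true_states[t - 1] = state
        prev_action = int(actions[t - 2]) if t > 1 else None
        if t <= D:
            policies = enumerate_policies(L, t, T, D)
            for _ in range(N):
                variational_step(
                    model, obs, t, belief,
                    policies=policies, prev_action=prev_action, expectations=exps,
                )
            a = sample_action(action_posterior(belief.policy_beliefs, policies), rng)
            actions[t - 1] = a
            precisions[t - 1] = belief.precision
            if t == D:
                # singleton policies: per-action EFE decomposition
                final_efe = np.column_stack(
                    (belief.quality, belief.extrinsic, belief.epistemic)
                )
            if t < T:
                state = env.sample_transition(process, state, a, rng)
        else:
            s = infer_states(
                model, obs, t,
                prev_belief=belief.state_beliefs[-1], prev_action=prev_action,
                expectations=exps,
            )
            belief.state_beliefs.append(s)
        trajectory.append(belief.snapshot())

    return EpisodeRecord(
        observations=observations,
        actions=actions,
        true_states=true_states,
        state_beliefs=np.vstack(belief.state_beliefs),
        belief_trajectory=trajectory,
        precisions=precisions,
        final_efe=final_efe,
    )


def learn_from_episode(
    model: GenerativeModel, record: EpisodeRecord, inplace: bool = False
) -> GenerativeModel:
    """Dirichlet concentration updates after one episode.

    Likelihood: add the outer product of each observed outcome (one-hot)
    with the state belief at that step.  Transitions: for each step
    t >= 2, add the outer product of consecutive state beliefs to the
    kernel of the action taken between them.  Initial state: add the
    first state belief.  Disabled flags leave arrays untouched.
    """
    m = model if inplace else model.copy()
    S = record.state_beliefs
    T = S.shape[0]
    if T != m.horizon or S.shape[1] != m.num_states:
        raise ValueError("episode record does not match model dimensions")
    if m.learn_likelihood:
        for t in range(T):
            m.posteriors.likelihood[record.observations[t]] += S[t]
    if m.learn_transitions:
        for t in range(1, T):
            u = int(record.actions[t - 1])
            m.posteriors.transitions[u] += np.outer(S[t], S[t - 1])
    if m.learn_initial:
        m.posteriors.initial += S[0]
    return m


def run_learning(
    model: GenerativeModel,
    process,
    iterations: int,
    rng: np.random.Generator,
    keep_records: bool = True,
) -> tuple[list[EpisodeRecord], GenerativeModel]:
    """Interleave episodes and Dirichlet learning for ``iterations``
    episodes, starting from a copy of ``model``."""
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    work = model.copy()
    records: list[EpisodeRecord] = []
    for _ in range(iterations):
        exps = compute_expectations(work)
        rec = run_episode(work, process, rng, expectations=exps)
        learn_from_episode(work, rec, inplace=True)
        if keep_records:
            records.append(rec)
    return records, work
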