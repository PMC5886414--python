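"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from attachinf import AttachmentConfig, builders, engine


@pytest.fixture
def config() -> AttachmentConfig:
    """Reference parameterisation."""
    return AttachmentConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_small_model(
    rng: np.random.Generator,
    max_states: int = 4,
    max_outcomes: int = 4,
    max_actions: int = 3,
    horizon: int = 3,
) -> engine.GenerativeModel:
    """A random well-posed model with small dimensions."""
    J = int(rng.integers(2, max_states + 1))
    W = int(rng.integers(2, max_outcomes + 1))
    L = int(rng.integers(1, max_actions + 1))
    fam = engine.DirichletFamily(
        likelihood=rng.gamma(2.0, 1.0, size=(W, J)) + 0.05,
        transitions=rng.gamma(2.0, 1.0, size=(L, J, J)) + 0.05,
        initial=rng.gamma(2.0, 1.0, size=J) + 0.05,
    )
    prefs = rng.dirichlet(np.ones(W) * 2.0)
    prefs = np.maximum(prefs, 1e-6)
    prefs /= prefs.sum()
    return engine.GenerativeModel(
        priors=fam,
        preferences=prefs,
        precision_shape=8.0,
        precision_rate=1.0,
        horizon=horizon,
        variational_iters=4,
    )


def brute_force_policy_value(
    exps: engine.ModelExpectations, belief: np.ndarray, policy
) -> float:
    """Direct evaluation of a policy's expected negative free energy as
    the expected log joint preference-weighted probability plus the
    entropy of the predictive state belief, summed over future steps.

    Independent of the extrinsic/epistemic decomposition used by the
    implementation: works from the predictive joint by explicit
    element-wise enumeration.
    """
    s = np.asarray(belief, dtype=float)
    lnC = exps.log_preferences
    total = 0.0
    for u in policy:
        s = exps.transitions[int(u)] @ s
        A = exps.likelihood
        W, J = A.shape
        joint = A * s  # Q(o, s | pi)
        o_pred = joint.sum(axis=1)
        expected_log_joint = 0.0
        for o in range(W):
            for j in range(J):
                if joint[o, j] > 0:
                    # ln P(o, s) with P(o, s) = C(o) Q(s | o)
                    expected_log_joint += joint[o, j] * (
                        lnC[o] + np.log(joint[o, j] / o_pred[o])
                    )
        entropy = -sum(p * np.log(p) for p in s if p > 0)
        total += expected_log_joint + entropy
    return total


@pytest.fixture
def perfect_intero(config):
    """Perfect-model infant in the 6-state environment at q = 0.9."""
    process = builders.build_interoceptive_process(config)
    model = builders.build_perfect_model(process, config)
    return process, model
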