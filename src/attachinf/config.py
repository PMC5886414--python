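"""Attachment simulation configuration.

One flat record collects every tunable of the dyadic simulations:
caregiver responsiveness ``q``; the payoff structure ``g, h, m, n``
(stress-change units entering the infant's outcome preferences); the
affective-cue parameters ``a, b, c`` of the exteroceptive model; the
concentration scales ``delta`` / ``epsilon`` used to encode (near-)
deterministic beliefs; the precision prior ``alpha, beta``; and loop
and experiment counts.  Defaults are the reference parameterisation
used throughout the simulations (g=2, h=0.75, m=2, n=0.9, alpha=250,
beta=1, N=4, T=4, delta=1e3, epsilon=1e-10).

Configs round-trip through a flat YAML key-value file; unknown keys
are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["AttachmentConfig", "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    """A configuration file or value failed validation."""


@dataclass
class AttachmentConfig:
    # caregiver
    q: float = 0.9  # responsiveness: P(Attend) on each exchange
    # payoffs (stress changes; encoded as log-preferences by softmax)
    g: float = 2.0  # Seek + Attend: stress reduction
    h: float = 0.75  # GuardedSeek + Attend: smaller reduction (0 < h < g)
    m: float = 2.0  # Seek + Ignore: stress increase
    n: float = 0.9  # GuardedSeek + Ignore: smaller increase (0 < n < m)
    # affective-communication cue parameters (exteroceptive model)
    a: float = 1.0  # accurate attend-cue rate before Attend
    b: float = 1.0  # accurate no-cue rate before Ignore
    c: float = 0.0  # ambiguous-cue rate
    # model fidelity
    delta: float = 1e3  # large concentration encoding confident beliefs
    epsilon: float = 1e-10  # concentration floor for impossible events
    cue_model_split: float = 0.1  # infant's prior weight on the ambiguous cue
    # precision prior
    alpha: float = 250.0
    beta: float = 1.0
    # loop counts
    variational_iters: int = 4  # N: inference sweeps per observation
    horizon: int = 4  # T: time steps per episode
    decisions_per_episode: Optional[int] = None  # T (default) or T-1
    # experiment counts
    repetitions: int = 100
    iterations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ConfigError(f"q={self.q} outside [0, 1]")
        if not 0.0 < self.h < self.g:
            raise ConfigError(f"require 0 < h < g, got h={self.h}, g={self.g}")
        if not 0.0 < self.n < self.m:
            raise ConfigError(f"require 0 < n < m, got n={self.n}, m={self.m}")
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"cue parameter {name}={v} outside [0, 1]")
        if self.a + self.c > 1.0 + 1e-12:
            raise ConfigError(f"a + c = {self.a + self.c} > 1")
        if self.b + self.c > 1.0 + 1e-12:
            raise ConfigError(f"b + c = {self.b + self.c} > 1")
        if not 0.0 < self.cue_model_split < 1.0:
            raise ConfigError("cue_model_split must lie strictly in (0, 1)")
        if not self.delta > self.epsilon > 0:
            raise ConfigError("require delta > epsilon > 0")
        if self.alpha <= 0 or self.beta <= 0:
            raise ConfigError("alpha and beta must be positive")
        if self.variational_iters < 1:
            raise ConfigError("variational_iters must be >= 1")
        if self.horizon < 2:
            raise ConfigError("horizon must be >= 2")
        if self.decisions_per_episode is not None and self.decisions_per_episode not in (
            self.horizon - 1,
            self.horizon,
        ):
            raise ConfigError("decisions_per_episode must be T-1 or T")
        if self.repetitions < 1 or self.iterations < 1:
            raise ConfigError("repetitions and iterations must be >= 1")

    @property
    def payoffs(self) -> tuple[float, float, float, float, float]:
        """Payoff per interoceptive outcome I1..I5."""
        return (self.g, self.h, -self.m, -self.n, 0.0)

    def replace(self, **changes) -> "AttachmentConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> AttachmentConfig:
    """Read a flat YAML key-value file into an :class:`AttachmentConfig`.

    Absent keys take the reference defaults; unknown keys raise
    :class:`ConfigError`.  An empty file yields the full default config.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(AttachmentConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    try:
        return AttachmentConfig(**data)
    except ConfigError as err:
        raise ConfigError(f"{path}: {err}") from err


def save_config(config: AttachmentConfig, path) -> None:
    """Write a config as a canonical flat YAML file (keys in field order)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
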