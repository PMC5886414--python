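"""Dyadic simulation protocols and behavioural summaries.

Experiments run many seeded repetitions of caregiver-infant episodes
and summarise behaviour as: per-iteration action-selection
proportions; the number of distinct actions chosen per episode (an
organisation measure -- consistent strategies score near 1, mixed
behaviour higher); final-step expected precision; and the per-action
expected-free-energy decomposition at the last decision step.  A
simple threshold classifier maps trailing-window summaries to
attachment labels.

Repetition r of a run seeded with s draws from its own counter-based
stream (entropy (s, r)), so any repetition can be reproduced in
isolation and distinct master seeds share no streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import builders, engine
from .config import AttachmentConfig

__all__ = [
    "LearningTrace",
    "trace_from_records",
    "mean_trace",
    "repetition_rng",
    "run_attachment_learning",
    "run_perfect_episodes",
    "make_sweep_grid",
    "run_parameter_sweep",
    "distinct_actions_per_iteration",
    "efe_decomposition_trace",
    "classify_attachment",
]

NUM_ACTIONS = 3


def repetition_rng(seed: int, repetition: int) -> np.random.Generator:
    """The independent random stream of one repetition of a seeded run."""
    return np.random.default_rng(np.random.SeedSequence((seed, repetition)))

#: trailing-window defaults used when summarising a learning run
TRAILING_WINDOW = {"interoceptive": 100, "exteroceptive": 10}


@dataclass
class LearningTrace:
    """Per-iteration behavioural summaries of one learning run."""

    action_props: np.ndarray  # (iters, 3) proportion of decisions per action
    distinct_actions: np.ndarray  # (iters,) unique actions within the episode
    precision: np.ndarray  # (iters,) final-decision-step expected precision
    efe: np.ndarray  # (iters, 3, 3) per-action (quality, extrinsic, epistemic)
    repetition: Optional[int] = None
    config: Optional[AttachmentConfig] = None

    @property
    def iterations(self) -> int:
        return self.action_props.shape[0]


def trace_from_records(
    records: Sequence[engine.EpisodeRecord],
    repetition: Optional[int] = None,
    config: Optional[AttachmentConfig] = None,
) -> LearningTrace:
    """Summarise a sequence of episode records into a LearningTrace."""
    if not records:
        raise ValueError("no episode records supplied")
    n = len(records)
    props = np.empty((n, NUM_ACTIONS))
    distinct = np.empty(n)
    precision = np.empty(n)
    efe = np.empty((n, NUM_ACTIONS, 3))
    for i, rec in enumerate(records):
        counts = np.bincount(rec.actions, minlength=NUM_ACTIONS)
        props[i] = counts / counts.sum()
        distinct[i] = np.count_nonzero(counts)
        precision[i] = rec.precisions[-1]
        efe[i] = rec.final_efe
    return LearningTrace(props, distinct, precision, efe, repetition, config)


def mean_trace(traces: Sequence[LearningTrace]) -> LearningTrace:
    """Element-wise mean of traces across repetitions."""
    return LearningTrace(
        action_props=np.mean([t.action_props for t in traces], axis=0),
        distinct_actions=np.mean([t.distinct_actions for t in traces], axis=0),
        precision=np.mean([t.precision for t in traces], axis=0),
        efe=np.mean([t.efe for t in traces], axis=0),
        repetition=None,
        config=traces[0].config,
    )


def _build_pair(config: AttachmentConfig, model_kind: str):
    if model_kind == "interoceptive":
        process = builders.build_interoceptive_process(config)
        model = builders.build_uninformative_model(config)
    elif model_kind == "exteroceptive":
        process = builders.build_exteroceptive_process(config)
        model = builders.build_exteroceptive_model(config)
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    return process, model


def run_attachment_learning(
    config: AttachmentConfig,
    model_kind: str = "interoceptive",
    repetitions: Optional[int] = None,
    iterations: Optional[int] = None,
    seed: Optional[int] = None,
) -> tuple[list[LearningTrace], LearningTrace]:
    """Learning protocol: fresh uninformative priors per repetition,
    ``iterations`` episodes of interleaved inference and Dirichlet
    learning each.  Returns the per-repetition traces and their mean."""
    reps = config.repetitions if repetitions is None else repetitions
    iters = config.iterations if iterations is None else iterations
    base_seed = config.seed if seed is None else seed
    process, model = _build_pair(config, model_kind)
    traces = []
    for r in range(reps):
        rng = repetition_rng(base_seed, r)
        records, _ = engine.run_learning(model, process, iters, rng)
        traces.append(trace_from_records(records, repetition=r, config=config))
    return traces, mean_trace(traces)


def run_perfect_episodes(
    config: AttachmentConfig,
    repetitions: int = 100,
    seed: Optional[int] = None,
    model_kind: str = "interoceptive",
) -> np.ndarray:
    """Per-action selection proportions for a perfect-model infant
    (no learning), pooled over ``repetitions`` independent episodes."""
    base_seed = config.seed if seed is None else seed
    if model_kind == "interoceptive":
        process = builders.build_interoceptive_process(config)
    else:
        process = builders.build_exteroceptive_process(config)
    model = builders.build_perfect_model(process, config)
    exps = engine.compute_expectations(model)
    counts = np.zeros(NUM_ACTIONS)
    for r in range(repetitions):
        rng = repetition_rng(base_seed, r)
        rec = engine.run_episode(model, process, rng, expectations=exps)
        counts += np.bincount(rec.actions, minlength=NUM_ACTIONS)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# parameter sweep
# ---------------------------------------------------------------------------


def make_sweep_grid() -> list[tuple[float, float, float, float]]:
    """The 405-cell (q, h, m, n) grid of the perfect-model sweep.

    q runs over nine equally spaced responsiveness values; h over five
    comfort levels below g = 2; the nine (m, n) pairs have m increasing
    by 0.4 from 0.1 and n chosen so g*n/m increases by 0.2 from 0.1.
    """
    qs = [round(0.1 * i, 10) for i in range(1, 10)]
    hs = [0.05, 0.5, 1.0, 1.5, 1.95]
    g = 2.0
    mn = []
    for i in range(9):
        m = 0.1 + 0.4 * i
        ratio = 0.1 + 0.2 * i  # target g*n/m
        mn.append((round(m, 10), round(m * ratio / g, 10)))
    return [(q, h, m, n) for q in qs for h in hs for (m, n) in mn]


def run_parameter_sweep(
    repetitions: int = 100,
    seed: int = 0,
    base_config: Optional[AttachmentConfig] = None,
    grid: Optional[Sequence[tuple[float, float, float, float]]] = None,
) -> pd.DataFrame:
    """Perfect-model action proportions over the (q, h, m, n) grid.

    Returns a tidy frame with one row per cell: grid coordinates,
    per-action selection proportions and the repetition count.
    """
    base = base_config or AttachmentConfig()
    cells = list(grid) if grid is not None else make_sweep_grid()
    rows = []
    for idx, (q, h, m, n) in enumerate(cells):
        cfg = base.replace(q=q, h=h, m=m, n=n)
        props = run_perfect_episodes(
            cfg, repetitions=repetitions, seed=seed + 1000 * idx
        )
        rows.append(
            {
                "q": q,
                "h": h,
                "m": m,
                "n": n,
                "p_seek": props[builders.SEEK],
                "p_guarded_seek": props[builders.GUARDED_SEEK],
                "p_avoid": props[builders.AVOID],
                "repetitions": repetitions,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def distinct_actions_per_iteration(
    trace, window: Optional[int] = None
) -> tuple[np.ndarray, float]:
    """Distinct-action series of a trace (or episode records) and its
    mean over an optional trailing window."""
    if isinstance(trace, LearningTrace):
        series = trace.distinct_actions
    else:
        series = trace_from_records(list(trace)).distinct_actions
    if series.size == 0:
        raise ValueError("empty trace")
    if window is not None:
        if not 1 <= window <= series.size:
            raise ValueError(f"window {window} outside [1, {series.size}]")
        return series, float(series[-window:].mean())
    return series, float(series.mean())


def efe_decomposition_trace(traces) -> dict[str, np.ndarray]:
    """Per-action quality/extrinsic/epistemic series, averaged over
    repetitions when a list of traces is given."""
    if isinstance(traces, LearningTrace):
        efe = traces.efe
    else:
        efe = mean_trace(list(traces)).efe
    return {
        "quality": efe[:, :, 0],
        "extrinsic": efe[:, :, 1],
        "epistemic": efe[:, :, 2],
    }


def classify_attachment(
    trace: LearningTrace,
    window: int = 100,
    dominance_threshold: float = 0.6,
    disorg_threshold: float = 1.8,
) -> str:
    """Label a (mean) learning trace by its trailing-window behaviour.

    A single action dominating the window maps to the organised types
    (Seek -> secure, GuardedSeek -> ambivalent, Avoid -> avoidant);
    otherwise persistently mixed behaviour (high mean distinct-actions)
    is disorganised.  Thresholds are reporting conventions, not model
    quantities.
    """
    if not 0 < dominance_threshold <= 1:
        raise ValueError("dominance_threshold must lie in (0, 1]")
    if disorg_threshold < 1:
        raise ValueError("disorg_threshold must be >= 1")
    if not 1 <= window <= trace.iterations:
        raise ValueError(f"window {window} outside [1, {trace.iterations}]")
    props = trace.action_props[-window:].mean(axis=0)
    distinct = float(trace.distinct_actions[-window:].mean())
    top = int(np.argmax(props))
    if props[top] >= dominance_threshold:
        return {
            builders.SEEK: "secure",
            builders.GUARDED_SEEK: "ambivalent",
            builders.AVOID: "avoidant",
        }[top]
    if distinct >= disorg_threshold:
        return "disorganised"
    return "unclassified"


def traces_to_frame(traces: Sequence[LearningTrace]) -> pd.DataFrame:
    """Tidy per-repetition, per-iteration table of all recorded metrics."""
    frames = []
    for t in traces:
        n = t.iterations
        frames.append(
            pd.DataFrame(
                {
                    "repetition": t.repetition if t.repetition is not None else -1,
                    "iteration": np.arange(1, n + 1),
                    "p_seek": t.action_props[:, builders.SEEK],
                    "p_guarded_seek": t.action_props[:, builders.GUARDED_SEEK],
                    "p_avoid": t.action_props[:, builders.AVOID],
                    "distinct_actions": t.distinct_actions,
                    "precision": t.precision,
                    "q_seek": t.efe[:, builders.SEEK, 0],
                    "q_guard": t.efe[:, builders.GUARDED_SEEK, 0],
                    "q_avoid": t.efe[:, builders.AVOID, 0],
                    "ext_seek": t.efe[:, builders.SEEK, 1],
                    "ext_guard": t.efe[:, builders.GUARDED_SEEK, 1],
                    "ext_avoid": t.efe[:, builders.AVOID, 1],
                    "epi_seek": t.efe[:, builders.SEEK, 2],
                    "epi_guard": t.efe[:, builders.GUARDED_SEEK, 2],
                    "epi_avoid": t.efe[:, builders.AVOID, 2],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
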