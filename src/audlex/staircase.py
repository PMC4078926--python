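"""Transformed up-down (1-up/n-down) adaptive staircase engine.

Implements the three auditory discrimination continua of the battery
(frequency-modulation depth, amplitude rise time, intensity increment), a
virtual observer with a logistic psychometric function, and the adaptive
track itself: step one continuum level harder after ``n_down`` consecutive
correct responses, one level easier after every incorrect response, stop
after a fixed number of reversals, and take the threshold as the arithmetic
mean of the stimulus levels at the last few reversals.  The 1-up/2-down rule
targets the stimulus level where the probability of a correct response is
(1/2)^(1/2) = 70.7% (Levitt's transformed up-down framework).

Tasks are three-alternative forced-choice "odd one out", so the chance
(guess) rate is 1/3.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "StimulusContinuum",
    "StaircaseConfig",
    "VirtualObserver",
    "ScriptedObserver",
    "TrackResult",
    "build_fm_continuum",
    "build_rt_continuum",
    "build_id_continuum",
    "build_fine_continuum",
    "respond",
    "run_track",
    "best_of_runs",
    "convergence_probability",
]


# --------------------------------------------------------------------------
# Continua
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusContinuum:
    """Ordered difficulty levels for one task.

    ``levels[0]`` is the easiest stimulus (largest difference from the
    reference); levels are strictly decreasing on the native scale.
    """

    task: str
    levels: tuple[float, ...]

    def __post_init__(self):
        if len(self.levels) < 2:
            raise ConfigurationError("continuum needs at least 2 levels")
        diffs = np.diff(self.levels)
        if not np.all(diffs < 0):
            raise ConfigurationError("levels must be strictly decreasing (easiest first)")
        if min(self.levels) <= 0:
            raise ConfigurationError("levels must be positive on the native scale")

    def __len__(self) -> int:
        return len(self.levels)


def build_fm_continuum() -> StimulusContinuum:
    """FM-depth continuum: geometric by a factor 1.2 from 100 Hz down to the
    11 Hz region, then arithmetic 1 Hz steps down to a 1 Hz floor.

    100/1.2^k never lands exactly on 11 Hz; the geometric region ends at the
    last value above 11 Hz (~11.22 Hz) and the arithmetic region runs
    11, 10, ..., 1 Hz.
    """
    levels = [100.0]
    while levels[-1] / 1.2 > 11.0:
        levels.append(levels[-1] / 1.2)
    levels.extend(float(v) for v in range(11, 0, -1))
    return StimulusContinuum(task="FM", levels=tuple(levels))


def build_rt_continuum() -> StimulusContinuum:
    """Rise-time continuum: 41 log-spaced rise times from 15 to 500 ms;
    levels are the discrimination differences from the 15 ms reference, so
    the easiest level is 485 ms and the reference itself (difference 0) is
    excluded, leaving 40 levels."""
    rise = np.geomspace(15.0, 500.0, 41)
    diffs = rise[1:] - 15.0
    return StimulusContinuum(task="RT", levels=tuple(diffs[::-1]))


def build_id_continuum() -> StimulusContinuum:
    """Intensity-increment continuum: 40 increments of 0.25 dB above the
    70 dB SPL reference, from 10.0 dB (easiest) down to 0.25 dB."""
    incs = np.arange(40, 0, -1) * 0.25
    return StimulusContinuum(task="ID", levels=tuple(incs))


def build_fine_continuum(task: str, lo: float, hi: float, n: int = 201) -> StimulusContinuum:
    """A fine geometric continuum for simulation studies (easiest first)."""
    return StimulusContinuum(task=task, levels=tuple(np.geomspace(hi, lo, n)))


# --------------------------------------------------------------------------
# Observers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VirtualObserver:
    """Psychometric response model for a forced-choice task.

    P(correct | level) = guess + (1 - guess - lapse) * F(level), with
    F a logistic sigmoid in log stimulus level, F(threshold) = 1/2.
    ``slope`` is the logistic steepness on the log-level axis.
    """

    threshold: float
    slope: float = 4.0
    guess: float = 1.0 / 3.0
    lapse: float = 0.0
    task: str | None = None

    def __post_init__(self):
        if not (0.0 < self.guess < 1.0):
            raise ConfigurationError("guess rate must be in (0, 1)")
        if not (0.0 <= self.lapse <= 0.1):
            raise ConfigurationError("lapse rate must be in [0, 0.1]")
        if self.slope <= 0:
            raise ConfigurationError("slope must be positive")
        if self.threshold <= 0:
            raise ConfigurationError("threshold must be positive")

    def p_correct(self, level: float) -> float:
        if level < 0:
            raise ValueError("stimulus level must be non-negative")
        if level == 0:
            f = 0.0
        else:
            f = 1.0 / (1.0 + math.exp(-self.slope * math.log(level / self.threshold)))
        return self.guess + (1.0 - self.guess - self.lapse) * f

    def respond(self, level: float, rng: np.random.Generator) -> bool:
        return bool(rng.random() < self.p_correct(level))


class ScriptedObserver:
    """Deterministic observer replaying a fixed correct/incorrect script.

    Used to validate the staircase bookkeeping against hand enumeration.
    """

    def __init__(self, script: Sequence[bool]):
        self._script = list(script)
        self._i = 0

    def respond(self, level: float, rng=None) -> bool:  # noqa: ARG002 - level unused
        if self._i >= len(self._script):
            raise IndexError("scripted responses exhausted")
        out = self._script[self._i]
        self._i += 1
        return bool(out)


def respond(observer, level: float, rng: np.random.Generator) -> bool:
    """Simulate one trial; True means a correct response."""
    if level < 0:
        raise ValueError("stimulus level must be non-negative")
    return observer.respond(level, rng)


# --------------------------------------------------------------------------
# Track
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StaircaseConfig:
    """Up-down rule parameters.

    Defaults are the battery's procedure: 1-up/2-down, terminate after 10
    reversals, threshold = mean of the last 4 reversal levels, two runs per
    task.  ``target_p`` is the implied asymptote (1/2)^(1/n_down).
    """

    n_down: int = 2
    n_up: int = 1
    stop_reversals: int = 10
    threshold_last: int = 4
    runs_per_task: int = 2
    max_trials: int = 1000

    def __post_init__(self):
        if self.n_down < 1 or self.n_up < 1:
            raise ConfigurationError("n_down and n_up must be >= 1")
        if self.threshold_last > self.stop_reversals:
            raise ConfigurationError("threshold_last cannot exceed stop_reversals")

    @property
    def target_p(self) -> float:
        return 0.5 ** (1.0 / self.n_down)


@dataclass(frozen=True)
class TrackResult:
    task: str
    presented_levels: tuple[float, ...]
    responses: tuple[bool, ...]
    reversal_indices: tuple[int, ...]
    reversal_levels: tuple[float, ...]
    threshold: float
    terminated_normally: bool
    config: StaircaseConfig = field(repr=False, default=StaircaseConfig())

    def to_rows(self) -> list[dict]:
        rev = set(self.reversal_indices)
        return [
            {
                "trial": i,
                "level": lvl,
                "response": int(r),
                "is_reversal": int(i in rev),
            }
            for i, (lvl, r) in enumerate(zip(self.presented_levels, self.responses))
        ]

    def to_csv(self, path) -> None:
        rows = self.to_rows()
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["trial", "level", "response", "is_reversal"])
            w.writeheader()
            w.writerows(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "task": self.task,
                "threshold": self.threshold,
                "terminated_normally": self.terminated_normally,
                "reversal_indices": list(self.reversal_indices),
                "trials": self.to_rows(),
            }
        )


def run_track(
    continuum: StimulusContinuum,
    config: StaircaseConfig,
    observer,
    rng: np.random.Generator | None = None,
) -> TrackResult:
    """Run one adaptive track.

    Index bookkeeping: level index increases toward harder stimuli (smaller
    differences).  After ``n_down`` consecutive correct responses the track
    steps harder; after ``n_up`` consecutive incorrect responses it steps
    easier.  Both counters reset whenever a step is taken.  A reversal is a
    change in the intended direction of movement; direction changes forced
    while clamped at a continuum boundary count as reversals.  The track
    starts at the easiest level and stops at ``stop_reversals`` reversals or
    at the ``max_trials`` safety cap (``terminated_normally`` False).
    """
    if len(continuum) < 2:
        raise ConfigurationError("continuum needs at least 2 levels")
    levels = continuum.levels
    idx = 0
    n_correct = 0
    n_wrong = 0
    last_dir = 0
    presented: list[float] = []
    responses: list[bool] = []
    rev_idx: list[int] = []
    rev_lvl: list[float] = []

    while len(rev_idx) < config.stop_reversals and len(presented) < config.max_trials:
        level = levels[idx]
        correct = respond(observer, level, rng)
        presented.append(level)
        responses.append(correct)

        move = 0
        if correct:
            n_correct += 1
            n_wrong = 0
            if n_correct >= config.n_down:
                move = +1  # harder
        else:
            n_wrong += 1
            n_correct = 0
            if n_wrong >= config.n_up:
                move = -1  # easier
        if move != 0:
            n_correct = 0
            n_wrong = 0
            if last_dir != 0 and move != last_dir:
                rev_idx.append(len(presented) - 1)
                rev_lvl.append(level)
            last_dir = move
            idx = min(max(idx + move, 0), len(levels) - 1)

    normal = len(rev_idx) >= config.stop_reversals
    k = config.threshold_last
    if len(rev_lvl) >= k:
        threshold = float(np.mean(rev_lvl[-k:]))
    elif rev_lvl:
        threshold = float(np.mean(rev_lvl))
    else:
        threshold = float("nan")
    return TrackResult(
        task=continuum.task,
        presented_levels=tuple(presented),
        responses=tuple(responses),
        reversal_indices=tuple(rev_idx),
        reversal_levels=tuple(rev_lvl),
        threshold=threshold,
        terminated_normally=normal,
        config=config,
    )


def best_of_runs(run1: TrackResult, run2: TrackResult) -> float:
    """Best (smallest native-scale) threshold of two runs of the same task.

    The two runs are deliberately not averaged: the battery treats the best
    run as the estimate of sensory capability.
    """
    if run1.task != run2.task:
        raise ConfigurationError(
            f"cannot compare runs of different tasks: {run1.task!r} vs {run2.task!r}"
        )
    return min(run1.threshold, run2.threshold)


# --------------------------------------------------------------------------
# Convergence diagnostics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvergenceResult:
    p_at_mean_level: float
    mean_converged_level: float
    per_track_p: tuple[float, ...]
    threshold_outside_continuum: bool


def convergence_probability(
    observer: VirtualObserver,
    config: StaircaseConfig,
    continuum: StimulusContinuum,
    n_tracks: int,
    rng: np.random.Generator,
    eq_reversals: int = 60,
    eq_last: int = 40,
) -> ConvergenceResult:
    """Estimate the long-run proportion correct at the staircase's
    convergence point.

    Runs ``n_tracks`` independent tracks with the rule of ``config`` but
    extended to ``eq_reversals`` reversals (the clinical 10-reversal stop
    rule targets the 70.7% level asymptotically; measuring the asymptote
    itself needs tracks long enough to leave the initial descent behind).
    Each track's converged level is the mean of its last ``eq_last``
    reversal levels; the observer's psychometric function is evaluated at
    the mean converged level.  For a 1-up/2-down rule the result
    approaches (1/2)^(1/2) = 70.7% on a sufficiently fine continuum.
    """
    from dataclasses import replace as _replace

    lo, hi = min(continuum.levels), max(continuum.levels)
    outside = not (lo <= observer.threshold <= hi)
    eq_config = _replace(
        config,
        stop_reversals=eq_reversals,
        threshold_last=eq_last,
        max_trials=max(config.max_trials, 40 * eq_reversals),
    )
    ps = []
    thr = []
    for _ in range(n_tracks):
        res = run_track(continuum, eq_config, observer, rng)
        thr.append(res.threshold)
        ps.append(observer.p_correct(res.threshold))
    mean_level = float(np.mean(thr))
    return ConvergenceResult(
        p_at_mean_level=float(observer.p_correct(mean_level)),
        mean_converged_level=mean_level,
        per_track_p=tuple(ps),
        threshold_outside_continuum=outside,
    )
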