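"""Transformed up-down staircase engine and per-task measure estimators.

Tracked tasks adjust the stimulus level trial by trial: one-up/one-down for
the first ``switch_trial`` trials (fast initial descent), two-up/one-down
thereafter, which converges on the level where the probability of a correct
response is 2^(-1/2) ~ 70.7%.  Thresholds are the mean of the levels
presented on the final five trials; a convergence score counts the correct
responses among those same five trials.

Reaction-time tasks record per-trial response times (median and, after
robust outlier screening, their standard deviation).  The dynamic detection
task ramps the stimulus from zero at a fixed rate and records the amplitude
at the moment of the button press, uncorrected for reaction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from statistics import median
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, InsufficientDataError
from .battery import TaskSpec
from .observers import ObserverParams, psychometric_correct_prob, trial_response
from .reliability import mad_outliers

__all__ = [
    "StaircaseState",
    "TrialRecord",
    "TaskResult",
    "update_staircase",
    "run_task",
    "estimate_threshold",
    "estimate_rt",
    "estimate_isv",
    "estimate_ddt",
    "convergence_score",
    "truncate_long",
]

SITES = ("LD2", "LD3")


@dataclass(frozen=True)
class StaircaseState:
    """Tracking state; ``level`` is the level to present on trial ``trial_index``."""

    level: float
    step: float
    floor: float
    trial_index: int = 1          # 1-based index of the next trial to present
    phase: str = "1u1d"
    consecutive_correct: int = 0  # counts toward the 2-down rule; 0 or 1
    switch_trial: int = 10

    def __post_init__(self) -> None:
        if self.level < self.floor:
            raise ValueError("level must be >= floor")
        if self.consecutive_correct not in (0, 1):
            raise ValueError("consecutive_correct must be 0 or 1")
        expected = "1u1d" if self.trial_index <= self.switch_trial else "2u1d"
        if self.phase != expected:
            raise ValueError(
                f"phase {self.phase!r} inconsistent with trial_index {self.trial_index}"
            )

    @classmethod
    def from_spec(cls, spec: TaskSpec) -> "StaircaseState":
        return cls(
            level=spec.initial_level,
            step=spec.step_size,
            floor=spec.floor_level,
            switch_trial=spec.switch_trial,
        )


def update_staircase(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the staircase after the response to trial ``state.trial_index``.

    One-up/one-down phase: every correct response lowers the level one step,
    every incorrect response raises it.  Two-up/one-down phase: an incorrect
    response raises the level and resets the correct counter; a first correct
    response only arms the counter; a second consecutive correct response
    lowers the level.  The level never drops below the floor.
    """
    level, counter = state.level, state.consecutive_correct
    if state.phase == "1u1d":
        level += -state.step if correct else state.step
        counter = 0
    else:
        if not correct:
            level += state.step
            counter = 0
        elif counter == 0:
            counter = 1
        else:
            level -= state.step
            counter = 0
    next_index = state.trial_index + 1
    return replace(
        state,
        level=max(level, state.floor),
        consecutive_correct=counter,
        trial_index=next_index,
        phase="1u1d" if next_index <= state.switch_trial else "2u1d",
    )


@dataclass(frozen=True)
class TrialRecord:
    """One presented trial."""

    trial_index: int
    target_site: str
    response_site: str
    correct: bool
    presented_level: Optional[float] = None   # tracked units; None for RT tasks
    response_time_ms: Optional[float] = None  # RT and dDT tasks
    amplitude_at_press_um: Optional[float] = None  # dDT only

    def __post_init__(self) -> None:
        if self.amplitude_at_press_um is not None and self.amplitude_at_press_um < 0:
            raise ValueError("amplitude_at_press_um must be >= 0")


@dataclass(frozen=True)
class TaskResult:
    """All trials of one task run plus its derived measures."""

    task_id: str
    version: str
    trials: tuple[TrialRecord, ...]
    measures: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        """Trial table with the documented trials-CSV columns."""
        def _f(vals):
            return np.array([np.nan if v is None else v for v in vals], dtype=float)

        return pd.DataFrame(
            {
                "task": self.task_id,
                "version": self.version,
                "trial": [t.trial_index for t in self.trials],
                "level": _f(t.presented_level for t in self.trials),
                "target_site": [t.target_site for t in self.trials],
                "response_site": [t.response_site for t in self.trials],
                "correct": [t.correct for t in self.trials],
                "rt_ms": _f(t.response_time_ms for t in self.trials),
                "amp_at_press_um": _f(t.amplitude_at_press_um for t in self.trials),
            }
        )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def estimate_threshold(trials: Sequence[TrialRecord]) -> float:
    """Mean of the levels presented on the final five trials."""
    if len(trials) < 5:
        raise InsufficientDataError("threshold estimation needs >= 5 trials")
    return float(np.mean([t.presented_level for t in trials[-5:]]))


def estimate_rt(trials: Sequence[TrialRecord], correct_only: bool = False) -> float:
    """Median response time, optionally over correct trials only (choice RT)."""
    rts = [t.response_time_ms for t in trials if (t.correct or not correct_only)]
    if not rts:
        raise InsufficientDataError("no qualifying trials for the RT median")
    return float(median(rts))


def estimate_isv(trials: Sequence[TrialRecord]) -> float:
    """Intrasubject variability: SD of trial RTs after MAD outlier screening."""
    rts = np.asarray([t.response_time_ms for t in trials], float)
    if rts.size < 3:
        raise InsufficientDataError("ISV needs >= 3 trials")
    kept = rts[~mad_outliers(rts, threshold=2.5)]
    if kept.size < 3:
        raise InsufficientDataError("ISV needs >= 3 trials after outlier removal")
    return float(np.std(kept, ddof=1))


def estimate_ddt(trials: Sequence[TrialRecord]) -> float:
    """Mean amplitude at button press over correct trials (no RT correction)."""
    amps = [t.amplitude_at_press_um for t in trials if t.correct]
    if not amps:
        raise InsufficientDataError("dynamic threshold needs >= 1 correct trial")
    return float(np.mean(amps))


def convergence_score(trials: Sequence[TrialRecord]) -> int:
    """Number of correct responses among the final five trials (0-5)."""
    if len(trials) < 5:
        raise InsufficientDataError("convergence score needs >= 5 trials")
    return int(sum(t.correct for t in trials[-5:]))


def _compute_measures(spec_id: str, trials: Sequence[TrialRecord]) -> dict[str, float]:
    if spec_id in ("sRT", "cRT"):
        return {
            "rt_median": estimate_rt(trials, correct_only=(spec_id == "cRT")),
            "rt_isv": estimate_isv(trials),
        }
    if spec_id == "dDT":
        return {"threshold": estimate_ddt(trials)}
    return {
        "threshold": estimate_threshold(trials),
        "convergence": float(convergence_score(trials)),
    }


# ---------------------------------------------------------------------------
# trial loop
# ---------------------------------------------------------------------------

def _other_site(site: str) -> str:
    return SITES[1] if site == SITES[0] else SITES[0]


def _respond(spec, level, observer, rng):
    """Dispatch to a scripted observer's respond() or the parametric model."""
    if hasattr(observer, "respond"):
        return observer.respond(spec, level, rng)
    return trial_response(spec, level, observer, rng)


def run_task(spec: TaskSpec, observer, rng: np.random.Generator) -> TaskResult:
    """Run one task for one observer and compute its measures.

    Target sites are drawn uniformly per trial.  Tracked tasks follow the
    transformed up-down rule of :func:`update_staircase`; reaction-time tasks
    just sample responses; the dynamic detection task draws a pre-ramp delay
    uniformly, ramps the amplitude at ``ramp_rate_um_s`` and records the
    amplitude at the press (threshold crossing plus motor delay).

    ``observer`` is either :class:`~vibropsych.observers.ObserverParams` or
    any object with a ``respond(spec, level, rng) -> (correct, rt_ms)``
    method (scripted observers for worked examples).
    """
    records: list[TrialRecord] = []

    if spec.task_id == "dDT":
        if not isinstance(observer, ObserverParams):
            raise ConfigurationError(
                "the dynamic detection task needs a parametric ObserverParams observer"
            )
        for t in range(1, spec.n_trials + 1):
            target = SITES[rng.integers(2)]
            rng.uniform(*spec.pre_ramp_delay_ms)  # pre-ramp delay; no modelled consequence
            theta = max(observer.theta_ddt_um + rng.normal(0.0, observer.ddt_trial_sd_um), 0.1)
            amp = theta + spec.ramp_rate_um_s * observer.motor_delay_s
            rt_ms = (theta / spec.ramp_rate_um_s + observer.motor_delay_s) * 1000.0
            p_loc = psychometric_correct_prob(
                amp, observer.theta_sdt_um, observer.slope, observer.lapse, observer.psychometric
            )
            correct = bool(rng.random() < p_loc)
            records.append(
                TrialRecord(
                    trial_index=t,
                    target_site=target,
                    response_site=target if correct else _other_site(target),
                    correct=correct,
                    response_time_ms=rt_ms,
                    amplitude_at_press_um=amp,
                )
            )
    elif spec.is_tracking:
        state = StaircaseState.from_spec(spec)
        for t in range(1, spec.n_trials + 1):
            target = SITES[rng.integers(2)]
            correct, _ = _respond(spec, state.level, observer, rng)
            records.append(
                TrialRecord(
                    trial_index=t,
                    target_site=target,
                    response_site=target if correct else _other_site(target),
                    correct=bool(correct),
                    presented_level=state.level,
                )
            )
            state = update_staircase(state, correct)
    else:  # sRT / cRT
        for t in range(1, spec.n_trials + 1):
            target = SITES[rng.integers(2)]
            correct, rt = _respond(spec, None, observer, rng)
            response = "any" if spec.task_id == "sRT" else (target if correct else _other_site(target))
            records.append(
                TrialRecord(
                    trial_index=t,
                    target_site=target,
                    response_site=response,
                    correct=bool(correct),
                    response_time_ms=rt,
                )
            )

    trials = tuple(records)
    return TaskResult(spec.task_id, spec.version, trials, _compute_measures(spec.task_id, trials))


def truncate_long(result: TaskResult, n_short: int) -> TaskResult:
    """Keep the first ``n_short`` trials and recompute every measure.

    This realizes the secondary "Short(3)" analysis: a long run cut back to
    the short version's trial count, thresholds re-estimated from the last
    five retained trials.
    """
    if n_short > len(result.trials):
        raise ValueError(
            f"cannot truncate {len(result.trials)} trials to {n_short}"
        )
    trials = result.trials[:n_short]
    return TaskResult(result.task_id, result.version, trials,
                      _compute_measures(result.task_id, trials))
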