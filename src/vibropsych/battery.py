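"""Canonical parameterization of the 11-paradigm vibrotactile battery.

The battery probes flutter-range (25-50 Hz) tactile function on two digit
sites (LD2/LD3): simple and choice reaction time (sRT, cRT), static and
dynamic detection thresholds (sDT, dDT), amplitude discrimination without
and with dual-/single-site adaptation (nAD, dAD, sAD), sequential and
simultaneous frequency discrimination (sqFD, smFD), and temporal order
judgement without and with a carrier stimulus (TOJs, TOJc).

Each task exists in a ``short`` version and a ``long`` version with twice
the number of trials.  Tracked tasks run a transformed up-down staircase:
one-up/one-down for the first ``switch_trial`` trials, two-up/one-down
thereafter.  Amplitude- and frequency-discrimination tasks track the
comparison-minus-standard *difference*; reported thresholds are on that
difference scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "TASK_IDS",
    "VERSIONS",
    "SESSION_VERSIONS",
    "TRACKED_QUANTITIES",
    "StimulusSpec",
    "TaskSpec",
    "BatterySchedule",
    "default_battery",
    "make_schedule",
    "battery_to_config",
    "battery_from_config",
    "save_battery_config",
    "load_battery_config",
]

TASK_IDS = ("sRT", "cRT", "sDT", "dDT", "nAD", "dAD", "sAD", "sqFD", "smFD", "TOJs", "TOJc")
VERSIONS = ("short", "long")
#: Version labels a subject sees across the three sessions (each exactly once).
SESSION_VERSIONS = ("Short1", "Short2", "Long")

TRACKED_QUANTITIES = (
    "amplitude_um",            # absolute test amplitude (sDT)
    "amplitude_difference_um", # comparison - standard amplitude (AD tasks)
    "frequency_difference_hz", # comparison - standard frequency (FD tasks)
    "isi_ms",                  # inter-pulse interval (TOJ tasks)
    "none",                    # RT tasks and the ramping dDT task
)


@dataclass(frozen=True)
class StimulusSpec:
    """One sinusoidal vibrotactile stimulus."""

    frequency_hz: float
    amplitude_um: float
    duration_ms: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"StimulusSpec.{f.name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class TaskSpec:
    """Complete parameterization of one paradigm in one version."""

    task_id: str
    version: str
    n_trials: int
    iti_s: float
    tracked: str = "none"
    initial_level: Optional[float] = None     # tracked units
    standard_value: Optional[float] = None    # 100 um (AD) / 30 Hz (FD)
    step_size: Optional[float] = None         # tracked units
    switch_trial: int = 10                    # 1u1d -> 2u1d change point
    floor_level: Optional[float] = None       # tracked units
    stimulus: Optional[StimulusSpec] = None
    adaptor: Optional[StimulusSpec] = None    # dAD / sAD conditioning stimulus
    carrier: Optional[StimulusSpec] = None    # TOJc concurrent stimulus
    isi_ms: Optional[float] = None            # sqFD inter-stimulus interval
    ramp_rate_um_s: Optional[float] = None    # dDT only
    pre_ramp_delay_ms: Optional[tuple[float, float]] = None  # dDT only

    def __post_init__(self) -> None:
        if self.task_id not in TASK_IDS:
            raise ValueError(f"unknown task_id {self.task_id!r}")
        if self.version not in VERSIONS:
            raise ValueError(f"unknown version {self.version!r}")
        if self.tracked not in TRACKED_QUANTITIES:
            raise ValueError(f"unknown tracked quantity {self.tracked!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.iti_s <= 0:
            raise ValueError("iti_s must be positive")
        if self.is_tracking:
            if self.initial_level is None or self.step_size is None or self.floor_level is None:
                raise ValueError(f"{self.task_id}: tracking tasks need initial/step/floor")
            if not (self.initial_level > self.floor_level > 0):
                raise ValueError(
                    f"{self.task_id}: need initial_level > floor_level > 0, got "
                    f"{self.initial_level} / {self.floor_level}"
                )
            if self.step_size <= 0:
                raise ValueError("step_size must be positive")
        if self.task_id in ("sRT", "cRT", "dDT") and self.tracked != "none":
            raise ValueError(f"{self.task_id} does not track a stimulus quantity")

    @property
    def is_tracking(self) -> bool:
        return self.tracked != "none"


@dataclass(frozen=True)
class BatterySchedule:
    """Session plan for one subject: fixed task order, per-session versions."""

    subject_id: int
    session_versions: tuple[str, str, str]
    task_order: tuple[str, ...] = TASK_IDS

    def __post_init__(self) -> None:
        if sorted(self.session_versions) != sorted(SESSION_VERSIONS):
            raise ValueError(
                "each subject must receive Short1, Short2 and Long exactly once, "
                f"got {self.session_versions}"
            )


def _n(version: str, short_n: int) -> int:
    return short_n if version == "short" else 2 * short_n


def default_battery(version: str, overrides: Optional[dict] = None) -> list[TaskSpec]:
    """Return the 11 canonical TaskSpecs for ``version`` ('short' or 'long').

    Trial counts in the long version are double those of the short version.
    ``overrides`` maps ``task_id -> {field: value}`` and is applied on top of
    the canonical constants (this is how the long-nAD starting-difference
    anomaly could be undone, or step sizes changed).

    Step sizes are not part of the published task constants; the defaults are
    10% of the initial tracked value (sDT 2 um; AD 10 um, 20 um for the long
    nAD; FD 1 Hz; TOJ 15 ms), and the floor is one step.
    """
    if version not in VERSIONS:
        raise ValueError(f"unknown version {version!r}; expected one of {VERSIONS}")

    rt_stim = StimulusSpec(frequency_hz=25, amplitude_um=300, duration_ms=40)
    ad_stim = StimulusSpec(frequency_hz=25, amplitude_um=100, duration_ms=500)
    ad_adaptor = StimulusSpec(frequency_hz=25, amplitude_um=100, duration_ms=1000)
    fd_stim = StimulusSpec(frequency_hz=30, amplitude_um=200, duration_ms=500)
    toj_pulse = StimulusSpec(frequency_hz=25, amplitude_um=200, duration_ms=40)
    toj_carrier = StimulusSpec(frequency_hz=25, amplitude_um=20, duration_ms=1000)

    # Long nAD: the comparison inadvertently started at 300 um instead of
    # 200 um, i.e. an initial difference of 200 um from the 100-um standard.
    nad_initial = 100.0 if version == "short" else 200.0
    nad_step = 10.0 if version == "short" else 20.0

    specs = [
        TaskSpec("sRT", version, _n(version, 20), iti_s=3, stimulus=rt_stim),
        TaskSpec("cRT", version, _n(version, 20), iti_s=3, stimulus=rt_stim),
        TaskSpec(
            "sDT", version, _n(version, 24), iti_s=5, tracked="amplitude_um",
            initial_level=20.0, step_size=2.0, floor_level=2.0,
            stimulus=StimulusSpec(frequency_hz=25, amplitude_um=20, duration_ms=500),
        ),
        TaskSpec(
            "dDT", version, _n(version, 7), iti_s=10,
            ramp_rate_um_s=2.0, pre_ramp_delay_ms=(0.0, 2500.0),
        ),
        TaskSpec(
            "nAD", version, _n(version, 20), iti_s=5, tracked="amplitude_difference_um",
            initial_level=nad_initial, standard_value=100.0,
            step_size=nad_step, floor_level=nad_step, stimulus=ad_stim,
        ),
        TaskSpec(
            "dAD", version, _n(version, 20), iti_s=5, tracked="amplitude_difference_um",
            initial_level=100.0, standard_value=100.0,
            step_size=10.0, floor_level=10.0, stimulus=ad_stim, adaptor=ad_adaptor,
        ),
        TaskSpec(
            "sAD", version, _n(version, 20), iti_s=5, tracked="amplitude_difference_um",
            initial_level=100.0, standard_value=100.0,
            step_size=10.0, floor_level=10.0, stimulus=ad_stim, adaptor=ad_adaptor,
        ),
        TaskSpec(
            "sqFD", version, _n(version, 20), iti_s=5, tracked="frequency_difference_hz",
            initial_level=10.0, standard_value=30.0,
            step_size=1.0, floor_level=1.0, stimulus=fd_stim, isi_ms=500.0,
        ),
        TaskSpec(
            "smFD", version, _n(version, 20), iti_s=5, tracked="frequency_difference_hz",
            initial_level=10.0, standard_value=30.0,
            step_size=1.0, floor_level=1.0, stimulus=fd_stim,
        ),
        TaskSpec(
            "TOJs", version, _n(version, 20), iti_s=5, tracked="isi_ms",
            initial_level=150.0, step_size=15.0, floor_level=15.0, stimulus=toj_pulse,
        ),
        TaskSpec(
            "TOJc", version, _n(version, 20), iti_s=5, tracked="isi_ms",
            initial_level=150.0, step_size=15.0, floor_level=15.0,
            stimulus=toj_pulse, carrier=toj_carrier,
        ),
    ]

    if overrides:
        unknown = set(overrides) - set(TASK_IDS)
        if unknown:
            raise ValueError(f"battery overrides for unknown tasks: {sorted(unknown)}")
        specs = [
            replace(s, **overrides.get(s.task_id, {})) if s.task_id in overrides else s
            for s in specs
        ]
    return specs


def make_schedule(n_subjects: int, rng: np.random.Generator) -> list[BatterySchedule]:
    """Draw one session plan per subject.

    Session order (which session carries Short1 / Short2 / Long) is a uniform
    draw over the 6 permutations, independently per subject; the task order
    within a session is fixed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    orders = list(itertools.permutations(SESSION_VERSIONS))
    picks = rng.integers(0, len(orders), size=n_subjects)
    return [
        BatterySchedule(subject_id=i + 1, session_versions=orders[p])
        for i, p in enumerate(picks)
    ]


# ---------------------------------------------------------------------------
# plain-text (YAML) battery configuration
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = (
    "n_trials", "iti_s", "tracked", "initial_level", "standard_value",
    "step_size", "switch_trial", "floor_level", "isi_ms",
    "ramp_rate_um_s", "pre_ramp_delay_ms",
)


def battery_to_config(specs: list[TaskSpec]) -> dict:
    """Export battery constants as a key-value mapping, one section per task."""
    cfg: dict = {}
    for s in specs:
        sec = {}
        for name in _CONFIG_FIELDS:
            v = getattr(s, name)
            if v is not None:
                sec[name] = list(v) if isinstance(v, tuple) else v
        for name in ("stimulus", "adaptor", "carrier"):
            stim = getattr(s, name)
            if stim is not None:
                sec[name] = {
                    "frequency_hz": stim.frequency_hz,
                    "amplitude_um": stim.amplitude_um,
                    "duration_ms": stim.duration_ms,
                }
        cfg[s.task_id] = sec
    return cfg


def battery_from_config(cfg: dict, version: str) -> list[TaskSpec]:
    """Build a battery from a config mapping (sections override the defaults)."""
    overrides: dict = {}
    for task_id, sec in (cfg or {}).items():
        ov = dict(sec)
        for name in ("stimulus", "adaptor", "carrier"):
            if name in ov and isinstance(ov[name], dict):
                ov[name] = StimulusSpec(**ov[name])
        if "pre_ramp_delay_ms" in ov and ov["pre_ramp_delay_ms"] is not None:
            ov["pre_ramp_delay_ms"] = tuple(ov["pre_ramp_delay_ms"])
        overrides[task_id] = ov
    return default_battery(version, overrides=overrides)


def save_battery_config(path, version: str = "short") -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(battery_to_config(default_battery(version)), fh, sort_keys=False)


def load_battery_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
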