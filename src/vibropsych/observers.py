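"""Simulated observers and measure-level synthetic data generation.

Two levels of synthesis are supported:

* **Trial level** — :class:`ObserverParams` describes a subject's latent
  thresholds, psychometric shape and reaction-time distribution; together
  with :func:`trial_response` it answers individual staircase trials so the
  full battery can be run in silico.

* **Measure level** — :class:`MeasureSpec` / :func:`sample_measures` emit
  subject-by-session threshold matrices with explicit between-subject,
  between-session and residual variance components.  This is the statistical
  structure the reliability analysis (CVs, ICC) assumes, so closed-form
  expectations are available for validation.

Observer performance on a two-alternative task follows a Weibull-family
psychometric function calibrated so that the probability of a correct
response at the latent threshold is exactly 2^(-1/2) ~ 0.707 — the
asymptotic convergence point of a two-up/one-down staircase — for any lapse
rate.  A two-up/one-down track against such an observer therefore converges
to the latent threshold by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

import numpy as np

from ._exceptions import ConfigurationError

__all__ = [
    "ObserverParams",
    "ConstantObserver",
    "PopulationSpec",
    "MeasureSpec",
    "TABLE1_MEASURES",
    "psychometric_correct_prob",
    "effective_difficulty",
    "trial_response",
    "sample_population",
    "jitter_observer",
    "sample_measures",
    "default_population",
]

_SQRT_HALF = 2.0 ** -0.5
_CHANCE = 0.5  # two-alternative forced choice


def psychometric_correct_prob(
    difference: float,
    theta: float,
    beta: float = 2.5,
    lapse: float = 0.02,
    family: str = "weibull",
) -> float:
    """P(correct) on a 2AFC trial at stimulus ``difference``.

    The function rises from 0.5 at zero difference to ``1 - lapse`` at large
    differences and is calibrated so that it passes through 2^(-1/2) exactly
    at ``difference == theta`` regardless of ``lapse``.

    Parameters
    ----------
    difference : stimulus difference (or absolute level for detection), >= 0,
        in the tracked units of the task.
    theta : latent threshold in the same units (> 0).
    beta : slope of the underlying Weibull / log-logistic core.
    lapse : stimulus-independent error rate, in [0, 0.1].
    family : 'weibull' (default) or 'logistic' (log-logistic in difference).
    """
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    if not 0.0 <= lapse <= 0.1:
        raise ValueError(f"lapse must be in [0, 0.1], got {lapse}")
    d = float(difference)
    if d < 0:
        raise ValueError("difference must be >= 0")
    span = _CHANCE - lapse  # (1 - lapse) - 0.5
    q = (_SQRT_HALF - _CHANCE) / span  # required core value at threshold
    if family == "weibull":
        c = 1.0 - q
        core = 1.0 - c ** ((d / theta) ** beta)
    elif family == "logistic":
        if d == 0.0:
            core = 0.0
        else:
            a = math.log(1.0 / q - 1.0)
            core = 1.0 / (1.0 + math.exp(a - beta * math.log(d / theta)))
    else:
        raise ValueError(f"unknown psychometric family {family!r}")
    return _CHANCE + span * core


@dataclass(frozen=True)
class ObserverParams:
    """Latent parameters of one simulated subject.

    Thresholds are on the scale the corresponding task tracks (sDT: absolute
    amplitude; AD: amplitude difference from the 100-um standard; FD:
    frequency difference from the 30-Hz standard; TOJ: inter-pulse ISI).
    Task-variant gains multiply the effective stimulus difference: dual-site
    adaptation sharpens discrimination (``g_dual > 1``, lowering measured
    thresholds), single-site adaptation impairs it (``g_single < 1``), a TOJ
    carrier impairs order judgement (``g_carrier < 1``), and simultaneous
    frequency delivery is slightly harder than sequential
    (``g_simultaneous < 1``).

    The defaults are the calibrated population means used by
    :func:`default_population`, chosen to land group means near the
    commonly reported adult values (sDT ~5 um, dDT ~8.3 um, nAD ~34 um,
    sRT median ~215 ms, TOJ ~24 ms) and to reproduce the canonical task
    orderings dDT > sDT, sAD > nAD > dAD and TOJc > TOJs.
    """

    theta_sdt_um: float = 5.1
    theta_ddt_um: float = 7.9          # amplitude actually felt; button press adds ramp x motor delay
    theta_ad_um: float = 34.0
    g_single: float = 0.68
    g_dual: float = 1.55
    theta_fd_hz: float = 6.9
    g_simultaneous: float = 0.88
    theta_toj_ms: float = 24.0
    g_carrier: float = 0.69
    slope: float = 2.5
    lapse: float = 0.02
    rt_log_loc: float = math.log(215.0)  # ln ms
    rt_log_scale: float = 0.22           # ln ms
    crt_increment_ms: float = 212.0      # added decision time in choice RT
    motor_delay_s: float = 0.20
    ddt_trial_sd_um: float = 1.0         # trial-to-trial noise on the dynamic threshold
    psychometric: str = "weibull"

    def __post_init__(self) -> None:
        for name in ("theta_sdt_um", "theta_ddt_um", "theta_ad_um", "theta_fd_hz", "theta_toj_ms"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must be in [0, 0.1]")
        if not self.g_single < 1.0 < self.g_dual:
            raise ValueError("need g_single < 1 < g_dual")


@dataclass(frozen=True)
class ConstantObserver:
    """Deterministic observer answering every trial the same way.

    Used for worked examples and degenerate-case checks (e.g. an error-free
    or always-wrong staircase run).
    """

    correct: bool = True
    rt_ms: float = 250.0

    def respond(self, spec, level, rng) -> tuple[bool, Optional[float]]:
        rt = self.rt_ms if spec.task_id in ("sRT", "cRT") else None
        return self.correct, rt


def effective_difficulty(spec, level: float, obs: ObserverParams) -> tuple[float, float]:
    """Map a presented tracked level to (effective difference, threshold)."""
    tid = spec.task_id
    if tid == "sDT":
        return level, obs.theta_sdt_um
    if tid == "nAD":
        return level, obs.theta_ad_um
    if tid == "dAD":
        return obs.g_dual * level, obs.theta_ad_um
    if tid == "sAD":
        return obs.g_single * level, obs.theta_ad_um
    if tid == "sqFD":
        return level, obs.theta_fd_hz
    if tid == "smFD":
        return obs.g_simultaneous * level, obs.theta_fd_hz
    if tid == "TOJs":
        return level, obs.theta_toj_ms
    if tid == "TOJc":
        return obs.g_carrier * level, obs.theta_toj_ms
    raise ConfigurationError(f"observer has no difficulty mapping for task {tid!r}")


def _sample_rt(obs: ObserverParams, rng: np.random.Generator, choice: bool) -> float:
    rt = math.exp(rng.normal(obs.rt_log_loc, obs.rt_log_scale))
    if choice:
        rt += obs.crt_increment_ms
    return rt


def trial_response(spec, level, obs: ObserverParams, rng: np.random.Generator):
    """Simulate one trial: returns ``(correct, rt_ms)``.

    ``level`` is the tracked quantity presented on this trial (ignored for
    the RT tasks).  Reaction times are log-normal, with a fixed decision
    increment for choice RT; tracked tasks return ``rt_ms = None``.
    """
    tid = spec.task_id
    if tid == "sRT":
        return True, _sample_rt(obs, rng, choice=False)
    if tid == "cRT":
        p = psychometric_correct_prob(
            spec.stimulus.amplitude_um, obs.theta_sdt_um, obs.slope, obs.lapse, obs.psychometric
        )
        return bool(rng.random() < p), _sample_rt(obs, rng, choice=True)
    diff, theta = effective_difficulty(spec, level, obs)
    p = psychometric_correct_prob(diff, theta, obs.slope, obs.lapse, obs.psychometric)
    return bool(rng.random() < p), None


# ---------------------------------------------------------------------------
# population-level sampling
# ---------------------------------------------------------------------------

# admissible ranges per parameter; draws outside are rejected and redrawn
_FIELD_BOUNDS = {
    "g_single": (1e-6, 1.0),
    "g_dual": (1.0, math.inf),
    "g_simultaneous": (1e-6, math.inf),
    "g_carrier": (1e-6, math.inf),
    "lapse": (0.0, 0.1),
    "slope": (0.5, math.inf),
    "rt_log_loc": (-math.inf, math.inf),
    "ddt_trial_sd_um": (0.0, math.inf),
}
_DEFAULT_BOUNDS = (1e-9, math.inf)


@dataclass(frozen=True)
class PopulationSpec:
    """Population distribution of observer parameters.

    ``means``/``sds`` map :class:`ObserverParams` field names to truncated-
    normal population moments (fields absent from ``means`` keep the
    dataclass default and do not vary).  ``session_jitter_cv`` gives, per
    parameter, the within-subject between-session coefficient of variation of
    the latent value: before each session the subject's thresholds are
    multiplied by a positive factor with that CV (``rt_log_loc`` is jittered
    additively on the log scale, which is the same thing for a log-normal
    median).  This is the day-to-day "state" component of within-subject
    variance; the staircase itself adds estimation noise on top.
    """

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    session_jitter_cv: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = {f.name for f in fields(ObserverParams) if f.name != "psychometric"}
        for d, label in ((self.means, "means"), (self.sds, "sds"), (self.session_jitter_cv, "session_jitter_cv")):
            unknown = set(d) - valid
            if unknown:
                raise ConfigurationError(f"{label} for unknown observer fields: {sorted(unknown)}")
        if any(v < 0 for v in self.sds.values()):
            raise ConfigurationError("population SDs must be >= 0")
        if any(v < 0 for v in self.session_jitter_cv.values()):
            raise ConfigurationError("session jitter CVs must be >= 0")


def default_population() -> PopulationSpec:
    """Calibrated default population for the in-silico study.

    Means sit at the :class:`ObserverParams` defaults; between-subject SDs
    and session jitter CVs are chosen to put group-level between- and
    within-subject CVs in the ranges commonly reported for these measures
    (RT ~10% within / ~23% between; detection and discrimination thresholds
    ~15-35% within / 20-60% between).
    """
    d = ObserverParams()
    means = {
        "theta_sdt_um": d.theta_sdt_um,
        "theta_ddt_um": d.theta_ddt_um,
        "theta_ad_um": d.theta_ad_um,
        "g_single": d.g_single,
        "g_dual": d.g_dual,
        "theta_fd_hz": d.theta_fd_hz,
        "g_simultaneous": d.g_simultaneous,
        "theta_toj_ms": d.theta_toj_ms,
        "g_carrier": d.g_carrier,
        "slope": d.slope,
        "lapse": d.lapse,
        "rt_log_loc": d.rt_log_loc,
        "rt_log_scale": d.rt_log_scale,
        "crt_increment_ms": d.crt_increment_ms,
        "motor_delay_s": d.motor_delay_s,
        "ddt_trial_sd_um": d.ddt_trial_sd_um,
    }
    sds = {
        "theta_sdt_um": 1.5,
        "theta_ddt_um": 1.5,
        "theta_ad_um": 14.0,
        "g_single": 0.12,
        "g_dual": 0.25,
        "theta_fd_hz": 2.4,
        "g_simultaneous": 0.12,
        "theta_toj_ms": 9.0,
        "g_carrier": 0.15,
        "slope": 0.5,
        "lapse": 0.01,
        "rt_log_loc": 0.22,
        "rt_log_scale": 0.05,
        "crt_increment_ms": 60.0,
        "motor_delay_s": 0.04,
        "ddt_trial_sd_um": 0.3,
    }
    jitter = {
        "theta_sdt_um": 0.22,
        "theta_ddt_um": 0.10,
        "theta_ad_um": 0.25,
        "theta_fd_hz": 0.28,
        "theta_toj_ms": 0.28,
        "rt_log_loc": 0.09,
        "crt_increment_ms": 0.09,
    }
    return PopulationSpec(means=means, sds=sds, session_jitter_cv=jitter)


def _draw_truncated(mean: float, sd: float, bounds: tuple[float, float],
                    rng: np.random.Generator, max_tries: int = 1000) -> float:
    lo, hi = bounds
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(max_tries):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    raise ConfigurationError(
        f"could not draw a value in [{lo}, {hi}] from N({mean}, {sd}^2); check the population spec"
    )


def sample_population(pop: PopulationSpec, n: int, rng: np.random.Generator) -> list[ObserverParams]:
    """Draw ``n`` observers from a population spec (truncated-normal fields)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    for _ in range(n):
        kwargs = {}
        for name, mean in pop.means.items():
            sd = pop.sds.get(name, 0.0)
            bounds = _FIELD_BOUNDS.get(name, _DEFAULT_BOUNDS)
            kwargs[name] = _draw_truncated(mean, sd, bounds, rng)
        out.append(ObserverParams(**kwargs))
    return out


def jitter_observer(obs: ObserverParams, jitter_cv: dict[str, float],
                    rng: np.random.Generator) -> ObserverParams:
    """Return a per-session copy of ``obs`` with latent values jittered.

    Multiplicative jitter with the given CV (truncated to stay positive);
    ``rt_log_loc`` is jittered additively on the log scale.
    """
    kwargs = {}
    for name, cv in jitter_cv.items():
        if cv == 0:
            continue
        base = getattr(obs, name)
        if name == "rt_log_loc":
            kwargs[name] = base + rng.normal(0.0, cv)
        else:
            factor = _draw_truncated(1.0, cv, (1e-6, math.inf), rng)
            kwargs[name] = base * factor
    return replace(obs, **kwargs) if kwargs else obs


# ---------------------------------------------------------------------------
# measure-level generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasureSpec:
    """Per-session moments of one measure, as printed in a descriptive table.

    ``session_means``/``session_sds`` are the per-session group mean and SD
    (in measure units); ``cv_ws`` is the within-subject coefficient of
    variation in percent.  The generator decomposes these into additive
    subject, session and residual components.
    """

    name: str
    session_means: tuple[float, ...]
    session_sds: tuple[float, ...]
    cv_ws: float
    units: str = ""

    def __post_init__(self) -> None:
        if len(self.session_means) != len(self.session_sds):
            raise ValueError("session_means and session_sds must have equal length")
        if any(s < 0 for s in self.session_sds) or self.cv_ws < 0:
            raise ValueError("SDs and CV_ws must be >= 0")

    def variance_components(self, n_sess: Optional[int] = None) -> dict[str, float]:
        """Implied (sigma_b^2, sigma_w^2, session effects) decomposition."""
        k = n_sess or len(self.session_means)
        mu = np.asarray(self.session_means[:k], float)
        s = np.asarray(self.session_sds[:k], float)
        grand = float(mu.mean())
        sigma_w = self.cv_ws / 100.0 * grand
        var_b = float((s ** 2).mean()) - sigma_w ** 2
        clamped = var_b < 0
        return {
            "grand_mean": grand,
            "sigma_w2": sigma_w ** 2,
            "sigma_b2": max(var_b, 0.0),
            "session_effects": tuple(mu - grand),
            "clamped": clamped,
        }


def sample_measures(m: MeasureSpec, n_subj: int, n_sess: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw a ``(n_subj, n_sess)`` measure matrix with the spec's components.

    entry(i, j) = grand mean + b_i + c_j + e_ij with b_i ~ N(0, sigma_b^2),
    c_j the fixed session offsets (session mean minus grand mean) and
    e_ij ~ N(0, sigma_w^2) where sigma_w = CV_ws/100 x grand mean.  The
    subject variance is the mean per-session variance minus sigma_w^2
    (clamped at zero with a warning if the spec is internally inconsistent).
    Values are clamped to be strictly positive.
    """
    if n_sess > len(m.session_means):
        raise ValueError(
            f"{m.name}: {n_sess} sessions requested but only "
            f"{len(m.session_means)} session means provided"
        )
    comp = m.variance_components(n_sess)
    if comp["clamped"]:
        warnings.warn(
            f"{m.name}: within-subject variance exceeds mean per-session variance; "
            "subject-effect variance clamped to 0",
            stacklevel=2,
        )
    b = rng.normal(0.0, math.sqrt(comp["sigma_b2"]), size=n_subj)
    c = np.asarray(comp["session_effects"], float)
    e = rng.normal(0.0, math.sqrt(comp["sigma_w2"]), size=(n_subj, n_sess))
    vals = comp["grand_mean"] + b[:, None] + c[None, :] + e
    return np.maximum(vals, 1e-9)


#: Published per-session descriptive statistics (mean, SD per version column
#: Short1/Short2/Long, plus within-subject CV %) for the 13 battery measures.
#: These printed moments are the calibration inputs for the measure-level
#: generator and the `fixtures` CLI command.
TABLE1_MEASURES: dict[str, MeasureSpec] = {
    "sRT": MeasureSpec("sRT", (217.75, 212.46, 216.10), (51.34, 49.09, 56.05), 10.85, "ms"),
    "sRT (ISV)": MeasureSpec("sRT (ISV)", (50.42, 47.67, 46.06), (19.07, 18.52, 17.57), 23.41, "ms"),
    "cRT": MeasureSpec("cRT", (434.83, 430.87, 417.10), (112.31, 93.13, 78.64), 9.50, "ms"),
    "cRT (ISV)": MeasureSpec("cRT (ISV)", (78.55, 67.71, 73.61), (30.51, 23.70, 31.01), 26.53, "ms"),
    "sDT": MeasureSpec("sDT", (5.51, 5.17, 4.61), (2.10, 1.45, 2.70), 30.85, "um"),
    "dDT": MeasureSpec("dDT", (7.94, 9.03, 7.93), (1.90, 2.16, 1.38), 13.48, "um"),
    "nAD": MeasureSpec("nAD", (38.13, 37.87, 25.23), (21.74, 18.01, 13.63), 40.45, "um"),
    "dAD": MeasureSpec("dAD", (19.86, 23.29, 22.71), (11.83, 11.65, 15.00), 45.71, "um"),
    "sAD": MeasureSpec("sAD", (50.27, 52.27, 46.67), (29.29, 22.46, 23.12), 31.44, "um"),
    "sqFD": MeasureSpec("sqFD", (7.03, 7.15, 6.40), (2.50, 2.59, 4.04), 41.72, "Hz"),
    "smFD": MeasureSpec("smFD", (7.37, 8.97, 7.12), (2.59, 3.87, 4.15), 36.96, "Hz"),
    "TOJs": MeasureSpec("TOJs", (27.79, 26.52, 18.12), (12.79, 13.06, 11.08), 45.94, "ms"),
    "TOJc": MeasureSpec("TOJc", (30.65, 44.63, 29.51), (14.33, 19.59, 22.07), 35.93, "ms"),
}
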