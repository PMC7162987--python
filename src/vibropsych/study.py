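"""End-to-end in-silico study: simulate the battery, analyze reliability.

`run_study` simulates the default design — 15 subjects x 3 sessions x 11
tasks, with the short battery administered twice (Short1, Short2) and the
double-length battery once (Long), session order randomized per subject —
and returns a tidy :class:`StudyDataset`.  `analyze_study` applies the full
reproducibility pipeline: MAD outlier screening, descriptive reliability
rows (per-version mean +/- SD, CV_bs, CV_ws, ICC(A,k)), the truncated-long
re-analysis, Bland-Altman agreement tables, and the random-intercept
mixed-model comparisons (version, training/time and within-domain task
effects with likelihood-ratio tests and Holm-corrected post-hoc contrasts).

Determinism: the master seed fully determines every artifact.  Child random
streams are derived from (seed, subject, session, task index), so adding or
removing one task never perturbs another task's stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, InsufficientDataError
from .battery import SESSION_VERSIONS, TASK_IDS, default_battery, make_schedule
from .effects import RandomInterceptModel, fit_lmm, lrt, effect_size, tukey_posthoc
from .observers import (
    MeasureSpec,
    PopulationSpec,
    TABLE1_MEASURES,
    default_population,
    jitter_observer,
    sample_measures,
    sample_population,
)
from .reliability import ReliabilityAnalysis, reliability_table
from .staircase import TaskResult, TrialRecord, run_task, truncate_long

__all__ = [
    "StudyConfig",
    "StudyDataset",
    "run_study",
    "analyze_study",
    "read_dataset",
    "write_dataset",
    "write_report",
]

MEASURES_COLUMNS = ("subject_id", "session_index", "version", "task", "measure", "value", "units")
TRIALS_COLUMNS = ("subject_id", "session_index", "version", "task", "trial", "level",
                  "target_site", "response_site", "correct", "rt_ms", "amp_at_press_um")

_UNITS = {
    "sRT": "ms", "cRT": "ms", "sDT": "um", "dDT": "um",
    "nAD": "um", "dAD": "um", "sAD": "um",
    "sqFD": "Hz", "smFD": "Hz", "TOJs": "ms", "TOJc": "ms",
}


def _units_for(task: str, measure: str) -> str:
    if measure == "convergence":
        return "count"
    if measure in ("rt_median", "rt_isv"):
        return "ms"
    return _UNITS[task]


#: printed-table row name -> (task, measure) used by the measure-level mode
_MEASURE_ROW_MAP = {
    "sRT": ("sRT", "rt_median"), "sRT (ISV)": ("sRT", "rt_isv"),
    "cRT": ("cRT", "rt_median"), "cRT (ISV)": ("cRT", "rt_isv"),
    **{t: (t, "threshold") for t in ("sDT", "dDT", "nAD", "dAD", "sAD",
                                     "sqFD", "smFD", "TOJs", "TOJc")},
}


@dataclass
class StudyConfig:
    """Configuration of one in-silico study."""

    n_subjects: int = 15
    n_sessions: int = 3
    seed: int = 0
    mode: str = "trial"  # 'trial' (simulated observers) or 'measure' (variance components)
    population: Optional[PopulationSpec] = None
    measures: Optional[dict[str, MeasureSpec]] = None  # measure mode; defaults to TABLE1_MEASURES
    battery_overrides: Optional[dict] = None
    keep_trials: bool = True
    # analysis options
    mad_threshold: float = 2.5
    icc_sessions: Optional[tuple[str, ...]] = None
    icc_by: str = "version"
    truncate: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("a reliability study needs >= 2 subjects")
        if self.mode not in ("trial", "measure"):
            raise ConfigurationError("mode must be 'trial' or 'measure'")
        if self.mode == "trial" and self.n_sessions != 3:
            raise ConfigurationError("the trial-level design has exactly 3 sessions")
        if self.seed is None:
            raise ConfigurationError("a master seed is required")


@dataclass
class StudyDataset:
    """Tidy per-(subject, session, task, measure) records, plus raw trials."""

    measures: pd.DataFrame
    trials: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        missing = set(MEASURES_COLUMNS) - set(self.measures.columns)
        if missing:
            raise ValueError(f"measures table missing columns: {sorted(missing)}")
        dup = self.measures.duplicated(["subject_id", "session_index", "task", "measure"])
        if dup.any():
            raise ValueError(
                f"duplicate (subject, session, task, measure) records: "
                f"{self.measures[dup].head().to_dict('records')}"
            )


def run_study(cfg: StudyConfig) -> StudyDataset:
    """Simulate the full study described by ``cfg``.

    In ``trial`` mode, observers are sampled from the population spec, their
    latent parameters jittered per session, and every task of every session
    run through the staircase engine.  In ``measure`` mode, subject-by-
    session matrices are drawn directly from per-measure variance components
    (no trial level exists).
    """
    if cfg.mode == "measure":
        return _run_measure_study(cfg)

    pop = cfg.population or default_population()
    obs_rng = np.random.default_rng([cfg.seed, 1])
    sched_rng = np.random.default_rng([cfg.seed, 2])
    observers = sample_population(pop, cfg.n_subjects, obs_rng)
    schedules = make_schedule(cfg.n_subjects, sched_rng)
    batteries = {v: default_battery(v, cfg.battery_overrides) for v in ("short", "long")}

    m_rows: list[dict] = []
    t_rows: list[pd.DataFrame] = []
    for subj, (obs, sched) in enumerate(zip(observers, schedules), start=1):
        for sess in range(1, cfg.n_sessions + 1):
            label = sched.session_versions[sess - 1]
            kind = "long" if label == "Long" else "short"
            sess_obs = jitter_observer(
                obs, pop.session_jitter_cv, np.random.default_rng([cfg.seed, 3, subj, sess])
            )
            for ti, spec in enumerate(batteries[kind]):
                rng = np.random.default_rng([cfg.seed, 4, subj, sess, ti])
                result = run_task(spec, sess_obs, rng)
                for measure, value in result.measures.items():
                    m_rows.append({
                        "subject_id": subj, "session_index": sess, "version": label,
                        "task": spec.task_id, "measure": measure, "value": value,
                        "units": _units_for(spec.task_id, measure),
                    })
                if cfg.keep_trials:
                    tf = result.to_frame()
                    tf.insert(0, "subject_id", subj)
                    tf.insert(1, "session_index", sess)
                    tf["version"] = label
                    t_rows.append(tf)

    measures = pd.DataFrame(m_rows, columns=list(MEASURES_COLUMNS))
    trials = None
    if cfg.keep_trials:
        trials = pd.concat(t_rows, ignore_index=True)[list(TRIALS_COLUMNS)]
    return StudyDataset(measures=measures, trials=trials)


def _run_measure_study(cfg: StudyConfig) -> StudyDataset:
    specs = cfg.measures or TABLE1_MEASURES
    rng = np.random.default_rng([cfg.seed, 5])
    rows: list[dict] = []
    for name, spec in specs.items():
        task, measure = _MEASURE_ROW_MAP.get(name, (name, "threshold"))
        mat = sample_measures(spec, cfg.n_subjects, cfg.n_sessions, rng)
        for i in range(cfg.n_subjects):
            for j in range(cfg.n_sessions):
                label = SESSION_VERSIONS[j] if j < 3 else f"Session{j + 1}"
                rows.append({
                    "subject_id": i + 1, "session_index": j + 1, "version": label,
                    "task": task, "measure": measure, "value": float(mat[i, j]),
                    "units": spec.units,
                })
    return StudyDataset(measures=pd.DataFrame(rows, columns=list(MEASURES_COLUMNS)))


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

_DOMAINS = (
    ("RT", "rt_median", ("sRT", "cRT")),
    ("RT ISV", "rt_isv", ("sRT", "cRT")),
    ("DT", "threshold", ("sDT", "dDT")),
    ("AD", "threshold", ("nAD", "dAD", "sAD")),
    ("FD", "threshold", ("sqFD", "smFD")),
    ("TOJ", "threshold", ("TOJs", "TOJc")),
)


def _prep(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["is_long"] = (out["version"] == "Long").astype(float)
    out["session"] = out["session_index"].astype(float)
    return out


def _fit_pair(data, full_cols, reduced_cols):
    X_full = data[full_cols]
    X_red = data[reduced_cols]
    full = fit_lmm(data["value"], X_full, data["subject_id"])
    red = fit_lmm(data["value"], X_red, data["subject_id"])
    chi2, df, p = lrt(full, red)
    return chi2, df, p, effect_size(full, red)


def _with_design(data: pd.DataFrame, task_factor: bool = False,
                 interaction: Optional[str] = None) -> tuple[pd.DataFrame, list[str]]:
    d = data.copy()
    d["Intercept"] = 1.0
    cols = ["Intercept"]
    if task_factor:
        levels = sorted(d["task"].unique())
        for lev in levels[1:]:
            name = f"task[{lev}]"
            d[name] = (d["task"] == lev).astype(float)
            cols.append(name)
        if interaction is not None:
            for lev in levels[1:]:
                name = f"task[{lev}]:{interaction}"
                d[name] = d[f"task[{lev}]"] * d[interaction]
    return d, cols


def version_time_effects(measures: pd.DataFrame) -> pd.DataFrame:
    """Per-(task, measure) LRTs for battery-version and training (time) effects.

    Short1 and Short2 are collapsed into one 'short' level for the version
    contrast; the time effect uses the linear chronological session index.
    """
    rows = []
    data = _prep(measures[measures["measure"] != "convergence"])
    for (task, measure), grp in data.groupby(["task", "measure"], sort=False):
        grp = grp.dropna(subset=["value"]).copy()
        grp["Intercept"] = 1.0
        for effect, col in (("version", "is_long"), ("time", "session")):
            try:
                chi2, df, p, es = _fit_pair(grp, ["Intercept", col], ["Intercept"])
            except (ValueError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"{task}/{measure} {effect} effect skipped: {exc}", stacklevel=2)
                continue
            rows.append({"scope": f"{task}/{measure}", "effect": effect,
                         "chi2": chi2, "df": df, "p": p, "effect_size": es})
    return pd.DataFrame(rows)


def domain_task_effects(measures: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-domain task comparisons, version-adjusted.

    For each domain the full model carries the task factor plus the version
    covariate; the reduced model keeps the covariate only, so the LRT df is
    the number of task levels minus one.  The three-level amplitude-
    discrimination domain additionally gets Holm-corrected pairwise z
    contrasts.
    """
    test_rows, contrast_rows = [], []
    data = _prep(measures)
    for name, measure, tasks in _DOMAINS:
        grp = data[(data["measure"] == measure) & (data["task"].isin(tasks))].dropna(subset=["value"])
        if grp["task"].nunique() < 2:
            continue
        d, cols = _with_design(grp, task_factor=True)
        try:
            chi2, df, p, es = _fit_pair(d, cols + ["is_long"], ["Intercept", "is_long"])
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"domain {name} skipped: {exc}", stacklevel=2)
            continue
        test_rows.append({"scope": name, "effect": "task", "chi2": chi2, "df": df,
                          "p": p, "effect_size": es})
        if len(tasks) >= 3:
            for c in tukey_posthoc(grp, "value", "task", "subject_id", covariates=["is_long"]):
                contrast_rows.append({"scope": name, "pair": f"{c.pair[0]} - {c.pair[1]}",
                                      "estimate": c.estimate, "z": c.z,
                                      "p_raw": c.p_raw, "p_holm": c.p_holm})
    return pd.DataFrame(test_rows), pd.DataFrame(contrast_rows)


def convergence_effects(measures: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mixed-model comparisons of staircase convergence scores.

    Task, version, time, task x version and task x time effects on the count
    of correct responses in the final five trials, across the eight
    staircase-tracked paradigms; pairwise task contrasts are Holm-corrected.
    """
    grp = _prep(measures[measures["measure"] == "convergence"]).dropna(subset=["value"])
    if grp.empty:
        return pd.DataFrame(), pd.DataFrame()
    d, task_cols = _with_design(grp, task_factor=True)
    rows = []

    def emit(effect, full_cols, red_cols, frame=None):
        try:
            chi2, df, p, es = _fit_pair(frame if frame is not None else d, full_cols, red_cols)
            rows.append({"scope": "convergence", "effect": effect, "chi2": chi2,
                         "df": df, "p": p, "effect_size": es})
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"convergence {effect} effect skipped: {exc}", stacklevel=2)

    base = task_cols + ["is_long"]
    emit("task", base, ["Intercept", "is_long"])
    emit("version", base, task_cols)
    emit("time", task_cols + ["session"], task_cols)
    di, _ = _with_design(grp, task_factor=True, interaction="is_long")
    inter_cols = [c for c in di.columns if c.endswith(":is_long")]
    emit("task x version", base + inter_cols, base, frame=di)
    dt, _ = _with_design(grp.assign(), task_factor=True, interaction="session")
    t_inter = [c for c in dt.columns if c.endswith(":session")]
    emit("task x time", task_cols + ["session"] + t_inter, task_cols + ["session"], frame=dt)

    contrasts = [
        {"scope": "convergence", "pair": f"{c.pair[0]} - {c.pair[1]}",
         "estimate": c.estimate, "z": c.z, "p_raw": c.p_raw, "p_holm": c.p_holm}
        for c in tukey_posthoc(grp, "value", "task", "subject_id", covariates=["is_long"])
    ]
    return pd.DataFrame(rows), pd.DataFrame(contrasts)


def _truncated_measures(ds: StudyDataset) -> pd.DataFrame:
    """Recompute long-version measures after truncation to the short trial count."""
    if ds.trials is None:
        raise InsufficientDataError("truncation analysis needs trial-level data")
    n_short = {s.task_id: s.n_trials for s in default_battery("short")}
    replacement_rows = []
    long_trials = ds.trials[ds.trials["version"] == "Long"]
    for (subj, sess, task), grp in long_trials.groupby(["subject_id", "session_index", "task"]):
        grp = grp.sort_values("trial")
        records = tuple(
            TrialRecord(
                trial_index=int(r.trial),
                target_site=r.target_site,
                response_site=r.response_site,
                correct=bool(r.correct),
                presented_level=None if pd.isna(r.level) else float(r.level),
                response_time_ms=None if pd.isna(r.rt_ms) else float(r.rt_ms),
                amplitude_at_press_um=None if pd.isna(r.amp_at_press_um) else float(r.amp_at_press_um),
            )
            for r in grp.itertuples()
        )
        result = TaskResult(task, "long", records, {})
        trunc = truncate_long(result, n_short[task])
        for measure, value in trunc.measures.items():
            replacement_rows.append({
                "subject_id": subj, "session_index": sess, "version": "Long",
                "task": task, "measure": measure, "value": value,
                "units": _units_for(task, measure),
            })
    short_rows = ds.measures[ds.measures["version"] != "Long"]
    return pd.concat([short_rows, pd.DataFrame(replacement_rows)], ignore_index=True)


def bland_altman_table(measures: pd.DataFrame, mad_threshold: float = 2.5) -> pd.DataFrame:
    """Tabulated Bland-Altman quantities for every version pair and measure."""
    res = ReliabilityAnalysis(measures, mad_threshold=mad_threshold).fit()
    rows = []
    for (task, measure), _ in measures[measures["measure"] != "convergence"].groupby(
            ["task", "measure"], sort=False):
        for pair in (("Short1", "Short2"), ("Short1", "Long"), ("Short2", "Long")):
            try:
                ba = res.bland_altman(task, measure, pair)
            except (KeyError, ValueError):
                continue
            ba = ba.assign(task=task, measure=measure, pair=f"{pair[0]} vs {pair[1]}")
            rows.append(ba)
    if not rows:
        return pd.DataFrame(columns=["task", "measure", "pair", "subject_id", "mean", "pct_diff"])
    out = pd.concat(rows, ignore_index=True)
    return out[["task", "measure", "pair", "subject_id", "mean", "pct_diff"]]


def analyze_study(ds: StudyDataset, cfg: Optional[StudyConfig] = None) -> dict:
    """Run the complete reproducibility analysis; returns a report bundle.

    Keys: ``table1`` (descriptive reliability rows), ``table2`` (same after
    truncating the long version; present only when trial data exist and
    truncation is enabled), ``bland_altman``, ``effects`` (LRT table),
    ``contrasts`` (Holm-corrected pairwise comparisons) and ``summary``
    (plain text).
    """
    cfg = cfg or StudyConfig(seed=0)
    bundle: dict = {}
    analysis = ReliabilityAnalysis(
        ds.measures, by=cfg.icc_by, icc_sessions=cfg.icc_sessions,
        mad_threshold=cfg.mad_threshold,
    )
    res1 = analysis.fit()
    bundle["table1"] = res1.table

    if cfg.truncate and ds.trials is not None:
        truncated = _truncated_measures(ds)
        bundle["table2"] = ReliabilityAnalysis(
            truncated, by=cfg.icc_by, icc_sessions=cfg.icc_sessions,
            mad_threshold=cfg.mad_threshold,
        ).fit().table

    bundle["bland_altman"] = bland_altman_table(ds.measures, cfg.mad_threshold)

    vt = version_time_effects(ds.measures)
    dom, dom_contrasts = domain_task_effects(ds.measures)
    conv, conv_contrasts = convergence_effects(ds.measures)
    bundle["effects"] = pd.concat([vt, dom, conv], ignore_index=True)
    bundle["contrasts"] = pd.concat([dom_contrasts, conv_contrasts], ignore_index=True)

    lines = [res1.summary(), "", "Mixed-model effects (LRT)", "-" * 72]
    for _, r in bundle["effects"].iterrows():
        lines.append(
            f"{r['scope']:24s} {r['effect']:14s} chi2({r['df']})={r['chi2']:8.2f}  "
            f"p={r['p']:.4g}  effect size={r['effect_size']:.2f}"
        )
    if len(bundle["contrasts"]):
        lines += ["", "Post-hoc contrasts (Holm-corrected z)", "-" * 72]
        for _, r in bundle["contrasts"].iterrows():
            lines.append(
                f"{r['scope']:14s} {r['pair']:16s} z={r['z']:7.2f}  p_Holm={r['p_holm']:.4g}"
            )
    bundle["summary"] = "\n".join(lines)
    return bundle


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_dataset(ds: StudyDataset, path, trials_path=None) -> None:
    """Write the tidy measures CSV (and optionally the trials CSV)."""
    ds.measures.to_csv(path, index=False)
    if trials_path is not None and ds.trials is not None:
        ds.trials.to_csv(trials_path, index=False)


def read_dataset(path, trials_path=None) -> StudyDataset:
    """Read a tidy measures CSV (and optionally a trials CSV) back.

    Enforces the documented header and the uniqueness of the
    (subject, session, task, measure) key; an empty file yields an empty
    dataset with a warning.
    """
    try:
        measures = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty file; returning an empty dataset", stacklevel=2)
        measures = pd.DataFrame(columns=list(MEASURES_COLUMNS))
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    missing = set(MEASURES_COLUMNS) - set(measures.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    trials = None
    if trials_path is not None:
        trials = pd.read_csv(trials_path)
        missing = set(TRIALS_COLUMNS) - set(trials.columns)
        if missing:
            raise ValueError(f"{trials_path}: missing columns {sorted(missing)}")
    return StudyDataset(measures=measures, trials=trials)


def write_report(bundle: dict, outdir) -> None:
    """Write the report bundle as CSVs plus a plain-text summary."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for key, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{key}.csv", index=False)
    if "summary" in bundle:
        (out / "summary.txt").write_text(bundle["summary"] + "\n")
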