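"""Test-retest reliability statistics for repeated psychophysical measures.

Implements the reproducibility pipeline for a subjects x sessions measure
matrix: robust outlier screening (median absolute deviation, threshold 2.5,
sessions collapsed), between- and within-subject coefficients of variation,
the two-way absolute-agreement average-measures intraclass correlation
ICC(A,k), and Bland-Altman agreement quantities.  The high-level entry point
is :class:`ReliabilityAnalysis`, whose :meth:`~ReliabilityAnalysis.fit`
returns a :class:`ReliabilityResults` with one descriptive row per
(task, measure).

The ICC used throughout is the McGraw & Wong ICC(A,k) computed from the
two-way ANOVA mean squares (rows = subjects, columns = sessions or
versions)::

    ICC(A,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n)

which estimates sigma_b^2 / (sigma_b^2 + (sigma_c^2 + sigma_e^2)/k): the
share of the variance of a k-session average attributable to stable
between-subject differences, with session bias penalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._exceptions import InsufficientDataError

__all__ = [
    "mad_outliers",
    "cv_between",
    "cv_within",
    "icc_avg_absolute",
    "bland_altman",
    "reliability_table",
    "ReliabilityAnalysis",
    "ReliabilityResults",
]

#: consistency constant making the MAD a normal-SD estimate
MAD_SCALE = 1.4826


def mad_outliers(x, threshold: float = 2.5) -> np.ndarray:
    """Flag outliers by the median-absolute-deviation rule.

    An observation is flagged when its absolute deviation from the median
    exceeds ``threshold`` times the scaled MAD (1.4826 x MAD).  A zero MAD
    (more than half the data identical) flags nothing and warns.

    Returns a boolean mask, True = outlier.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("MAD screening needs >= 3 observations")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        warnings.warn("MAD is zero; no outliers flagged", stacklevel=2)
        return np.zeros(x.shape, dtype=bool)
    return np.abs(x - med) / (MAD_SCALE * mad) > threshold


def cv_between(values) -> float:
    """Between-subject coefficient of variation, 100 x SD / mean (sample SD)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise InsufficientDataError("CV needs >= 2 values")
    m = v.mean()
    if m == 0:
        raise ZeroDivisionError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / m)


def cv_within(matrix) -> float:
    """Within-subject CV: mean over subjects of 100 x (across-session SD / mean).

    Rows are subjects, columns sessions; rows with fewer than two non-missing
    sessions are skipped.
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a subjects x sessions matrix")
    cvs = []
    for row in a:
        row = row[~np.isnan(row)]
        if row.size < 2:
            continue
        m = row.mean()
        if m == 0:
            raise ZeroDivisionError("within-subject CV undefined for zero subject mean")
        cvs.append(100.0 * row.std(ddof=1) / m)
    if not cvs:
        raise InsufficientDataError("no subject has >= 2 sessions")
    return float(np.mean(cvs))


def icc_avg_absolute(matrix) -> float:
    """ICC(A,k): two-way absolute-agreement, average-measures intraclass correlation.

    Subjects with any missing session are dropped.  Returns the *raw*
    estimate (may be negative; clamp to [0, 1] for reporting).  Returns NaN
    with a warning when the matrix has no variance at all.
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a subjects x sessions matrix")
    a = a[~np.isnan(a).any(axis=1)]
    n, k = a.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("ICC needs a complete matrix of at least 2 x 2")
    grand = a.mean()
    row_means = a.mean(axis=1)
    col_means = a.mean(axis=0)
    ss_total = float(((a - grand) ** 2).sum())
    if ss_total == 0:
        warnings.warn("zero total variance; ICC undefined", stacklevel=2)
        return float("nan")
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return float((ms_r - ms_e) / (ms_r + (ms_c - ms_e) / n))


def bland_altman(a, b) -> pd.DataFrame:
    """Pairwise agreement: per-pair mean and percentage difference.

    For each pair, returns ``mean = (a_i + b_i)/2`` and
    ``pct_diff = 100 (a_i - b_i) / mean``.  Pairs with a zero mean get NaN
    with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("inputs must have equal length")
    m = (a + b) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (a - b) / m
    zero = (m == 0) & ~np.isnan(m)
    if zero.any():
        warnings.warn(f"{int(zero.sum())} pair(s) with zero mean; difference undefined",
                      stacklevel=2)
        pct = np.where(zero, np.nan, pct)
    return pd.DataFrame({"mean": m, "pct_diff": pct})


# ---------------------------------------------------------------------------
# table-level analysis
# ---------------------------------------------------------------------------

_TIDY_COLUMNS = ("subject_id", "session_index", "version", "task", "measure", "value")

#: measure label appended to the task name in report rows
_MEASURE_SUFFIX = {"rt_median": "", "threshold": "", "rt_isv": " (ISV)",
                   "convergence": " (convergence)"}


def _row_label(task: str, measure: str) -> str:
    return task + _MEASURE_SUFFIX.get(measure, f" ({measure})")


def _screen_outliers(values: pd.Series, threshold: float) -> pd.Series:
    """Return the series with MAD-flagged measurements removed (sessions collapsed)."""
    if values.notna().sum() < 3:
        return values
    mask = np.zeros(len(values), dtype=bool)
    ok = values.notna().to_numpy()
    mask[ok] = mad_outliers(values.to_numpy(dtype=float)[ok], threshold=threshold)
    return values.where(~mask)


def reliability_table(
    data: pd.DataFrame,
    by: str = "version",
    icc_sessions: Optional[Sequence[str]] = None,
    mad_threshold: float = 2.5,
    measures: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Descriptive reliability summary, one row per (task, measure).

    ``data`` is a tidy table with columns subject_id, session_index, version,
    task, measure, value.  Columns of the reliability matrix are chosen by
    ``by`` ('version' -> Short1/Short2/Long, 'session' -> chronological
    session index).  Outliers are removed per (task, measure) with sessions
    collapsed; CVs use all remaining data while the ICC drops subjects with
    a removed or missing measurement.  ``icc_sessions`` restricts the ICC to
    a column subset (e.g. ('Short1', 'Short2'), giving k = 2).
    """
    missing = set(_TIDY_COLUMNS) - set(data.columns)
    if missing:
        raise ValueError(f"tidy dataset is missing columns: {sorted(missing)}")
    if by not in ("version", "session"):
        raise ValueError("by must be 'version' or 'session'")
    col = "version" if by == "version" else "session_index"
    if measures is None:
        measures = [m for m in data["measure"].unique() if m != "convergence"]

    rows = []
    for (task, measure), grp in data.groupby(["task", "measure"], sort=False):
        if measure not in measures:
            continue
        if grp.empty or grp["value"].notna().sum() == 0:
            warnings.warn(f"no data for {task}/{measure}; skipped", stacklevel=2)
            continue
        grp = grp.copy()
        grp["value"] = _screen_outliers(grp["value"], mad_threshold)
        n_removed = int(grp["value"].isna().sum())

        pivot = grp.pivot_table(index="subject_id", columns=col, values="value",
                                aggfunc="first", dropna=False)
        if by == "version":
            order = [c for c in ("Short1", "Short2", "Long") if c in pivot.columns]
            pivot = pivot[order]

        row: dict = {
            "row": _row_label(task, measure),
            "task": task,
            "measure": measure,
        }
        for c in pivot.columns:
            vals = pivot[c].dropna()
            row[f"mean_{c}"] = vals.mean()
            row[f"sd_{c}"] = vals.std(ddof=1)
            row[f"cv_bs_{c}"] = cv_between(vals) if len(vals) >= 2 else np.nan
        pooled = grp["value"].dropna()
        row["mean_all"] = pooled.mean()
        row["sd_all"] = pooled.std(ddof=1)
        row["cv_bs_all"] = cv_between(pooled) if len(pooled) >= 2 else np.nan
        try:
            row["cv_ws"] = cv_within(pivot.to_numpy())
        except InsufficientDataError:
            row["cv_ws"] = np.nan

        icc_mat = pivot[list(icc_sessions)] if icc_sessions else pivot
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                raw = icc_avg_absolute(icc_mat.to_numpy())
        except InsufficientDataError:
            raw = np.nan
        row["icc_raw"] = raw
        row["icc"] = np.nan if np.isnan(raw) else min(max(raw, 0.0), 1.0)
        row["n_subjects_icc"] = int((~np.isnan(icc_mat.to_numpy()).any(axis=1)).sum())
        row["n_removed"] = n_removed
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ReliabilityAnalysis:
    """Reliability model of a tidy study dataset.

    Parameters
    ----------
    data : tidy measures table (subject_id, session_index, version, task,
        measure, value[, units]).
    by : whether matrix columns are battery versions or chronological
        sessions; the printed tables use versions.
    icc_sessions : optional column subset for the ICC (e.g. the two short
        administrations only).
    mad_threshold : MAD outlier-screening threshold.
    """

    data: pd.DataFrame
    by: str = "version"
    icc_sessions: Optional[tuple[str, ...]] = None
    mad_threshold: float = 2.5

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "ReliabilityAnalysis":
        return cls(data=data, **kwargs)

    def fit(self) -> "ReliabilityResults":
        table = reliability_table(
            self.data, by=self.by, icc_sessions=self.icc_sessions,
            mad_threshold=self.mad_threshold,
        )
        return ReliabilityResults(model=self, table=table)


@dataclass
class ReliabilityResults:
    """Fitted reliability summary with agreement diagnostics."""

    model: ReliabilityAnalysis
    table: pd.DataFrame

    def _pivot(self, task: str, measure: str) -> pd.DataFrame:
        d = self.model.data
        grp = d[(d["task"] == task) & (d["measure"] == measure)].copy()
        if grp.empty:
            raise KeyError(f"no data for {task}/{measure}")
        grp["value"] = _screen_outliers(grp["value"], self.model.mad_threshold)
        col = "version" if self.model.by == "version" else "session_index"
        return grp.pivot_table(index="subject_id", columns=col, values="value",
                               aggfunc="first", dropna=False)

    def bland_altman(self, task: str, measure: str = "threshold",
                     pair: tuple = ("Short1", "Short2")) -> pd.DataFrame:
        """Agreement between two administrations of one measure."""
        pivot = self._pivot(task, measure)
        a, b = pivot[pair[0]], pivot[pair[1]]
        keep = a.notna() & b.notna()
        out = bland_altman(a[keep].to_numpy(), b[keep].to_numpy())
        out.insert(0, "subject_id", pivot.index[keep])
        return out

    def plot_bland_altman(self, task: str, measure: str = "threshold", ax=None):
        """Scatter of pairwise means vs percentage differences for all version pairs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for pair, color in ((("Short1", "Short2"), "grey"),
                            (("Short1", "Long"), "tab:orange"),
                            (("Short2", "Long"), "tab:blue")):
            ba = self.bland_altman(task, measure, pair)
            ax.scatter(ba["mean"], ba["pct_diff"], label=f"{pair[0]} vs {pair[1]}",
                       color=color, alpha=0.7)
        ax.axhline(0, lw=0.8, color="k")
        ax.set_xlabel("pair mean")
        ax.set_ylabel("% difference")
        ax.set_title(_row_label(task, measure))
        ax.legend(fontsize="small")
        return ax

    def summary(self) -> str:
        """Plain-text descriptive table in the style of a reliability report."""
        lines = ["Test-retest reliability summary", "=" * 72]
        cols = [c for c in self.table.columns if c.startswith("mean_") and c != "mean_all"]
        sess = [c[len("mean_"):] for c in cols]
        for _, r in self.table.iterrows():
            lines.append(f"{r['row']}:")
            for s in sess:
                m, sd, cv = r.get(f"mean_{s}"), r.get(f"sd_{s}"), r.get(f"cv_bs_{s}")
                if pd.notna(m):
                    lines.append(f"  {s:8s} {m:10.2f} +/- {sd:8.2f}   CV_bs {cv:6.2f}%")
            lines.append(
                f"  {'All':8s} {r['mean_all']:10.2f} +/- {r['sd_all']:8.2f}   "
                f"CV_bs {r['cv_bs_all']:6.2f}%   CV_ws {r['cv_ws']:6.2f}%   "
                f"ICC {r['icc']:.2f} (n={r['n_subjects_icc']})"
            )
        return "\n".join(lines)
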