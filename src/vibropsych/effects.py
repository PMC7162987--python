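"""Random-intercept mixed models for version, training and task effects.

The model is the standard repeated-measures random-intercept LMM

    y_ij = beta_0 + s_j + beta_1 x_ij + eps_ij,
    s_j ~ N(0, sigma_s^2),  eps_ij ~ N(0, sigma_eps^2),

fitted by maximum likelihood (not REML), where y_ij is a measure for
subject j in session i and x_ij encodes the fixed effect of interest
(battery version, session index, or task within a domain).  Effects are
tested with likelihood-ratio tests against the nested model without the
effect; the effect size is the proportional reduction in residual variance.
Post-hoc pairwise comparisons use z statistics on the fitted level contrasts
with Holm-Bonferroni correction.

The numerical fit is delegated to statsmodels ``MixedLM`` (ML); this module
owns the modelling surface, the LRT/effect-size/contrast machinery and the
Holm step-down.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "LMMFit",
    "ContrastResult",
    "fit_lmm",
    "lrt",
    "effect_size",
    "tukey_posthoc",
    "holm_adjust",
    "RandomInterceptModel",
    "RandomInterceptResults",
]


@dataclass(frozen=True)
class LMMFit:
    """Maximum-likelihood fit of the random-intercept model."""

    params: pd.Series          # fixed effects, named
    cov_params: pd.DataFrame   # covariance of the fixed effects
    sigma_subject2: float      # random-intercept variance
    sigma_resid2: float        # residual variance
    llf: float                 # maximized log-likelihood (ML)
    n_params: int              # fixed effects + 2 variance components
    nobs: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.llf):
            raise ValueError("log-likelihood must be finite")
        if self.sigma_subject2 < 0 or self.sigma_resid2 < 0:
            raise ValueError("variances must be >= 0")


def fit_lmm(y, X, groups) -> LMMFit:
    """Fit y = X beta + random subject intercept + residual, by ML.

    ``X`` should include the intercept column.  Accepts arrays or a pandas
    DataFrame (column names are kept for contrasts).
    """
    X_df = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if len(y) != len(X_df) or len(y) != len(groups):
        raise ValueError("y, X and groups must have equal length")
    if np.unique(groups).size < 2:
        raise ValueError("need >= 2 subjects")
    Xa = X_df.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        raise np.linalg.LinAlgError("fixed-effect design is rank deficient")
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, Xa, groups=groups)
        # boundary variance estimates can make one optimizer's Hessian
        # singular; fall through a short ladder of methods
        for method in (None, "powell", "nm"):
            try:
                kwargs = {} if method is None else {"method": method}
                res = model.fit(reml=False, maxiter=500, **kwargs)
                if np.isfinite(res.llf):
                    break
            except np.linalg.LinAlgError:
                continue
    if res is None or not np.isfinite(res.llf):
        raise np.linalg.LinAlgError("mixed-model fit failed to converge")
    k = Xa.shape[1]
    names = [str(c) for c in X_df.columns]
    fe = pd.Series(np.asarray(res.fe_params, dtype=float), index=names)
    cov = pd.DataFrame(np.asarray(res.cov_params())[:k, :k], index=names, columns=names)
    return LMMFit(
        params=fe,
        cov_params=cov,
        sigma_subject2=float(np.asarray(res.cov_re)[0, 0]),
        sigma_resid2=float(res.scale),
        llf=float(res.llf),
        n_params=k + 2,
        nobs=int(len(y)),
    )


def lrt(full: LMMFit, reduced: LMMFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested reduced model against the full model.

    Returns (chi-square statistic, degrees of freedom, p value).  The
    statistic is clamped at zero (boundary/optimizer noise).
    """
    if full.nobs != reduced.nobs:
        raise ValueError("models must be fitted on the same data")
    df = full.n_params - reduced.n_params
    if df <= 0:
        raise ValueError("reduced model must have fewer parameters than the full model")
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    return chi2, df, float(stats.chi2.sf(chi2, df))


def effect_size(full: LMMFit, reduced: LMMFit) -> float:
    """Proportional reduction in residual variance from reduced to full model."""
    if full.nobs != reduced.nobs:
        raise ValueError("models must be fitted on the same data")
    if reduced.sigma_resid2 <= 0:
        raise ZeroDivisionError("reduced model has zero residual variance")
    prop = (reduced.sigma_resid2 - full.sigma_resid2) / reduced.sigma_resid2
    return float(min(max(prop, 0.0), 1.0))


def holm_adjust(p: Sequence[float]) -> list[float]:
    """Holm-Bonferroni step-down adjustment, returned in input order."""
    p = list(map(float, p))
    if any(not 0.0 <= v <= 1.0 for v in p):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise comparison of factor-level means."""

    pair: tuple[str, str]
    estimate: float
    se: float
    z: float
    p_raw: float
    p_holm: float


def _dummy_design(data: pd.DataFrame, factor: str, covariates: Sequence[str] = ()) -> tuple[pd.DataFrame, list[str]]:
    levels = sorted(data[factor].astype(str).unique())
    X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    for lev in levels[1:]:  # treatment coding, first level as reference
        X[f"{factor}[{lev}]"] = (data[factor].astype(str) == lev).astype(float)
    for cov in covariates:
        X[cov] = np.asarray(data[cov], dtype=float)
    return X, levels


def tukey_posthoc(
    data: pd.DataFrame,
    response: str,
    factor: str,
    group: str,
    covariates: Sequence[str] = (),
) -> list[ContrastResult]:
    """All pairwise post-hoc comparisons of a >= 3-level factor in the LMM.

    Fits the random-intercept model with treatment-coded factor dummies
    (plus any covariates), forms every pairwise contrast of the level means
    with pooled standard errors from the fit, and reports two-tailed z tests
    with Holm-adjusted p values.
    """
    X, levels = _dummy_design(data, factor, covariates)
    if len(levels) < 3:
        raise ValueError("post-hoc comparisons need a factor with >= 3 levels; use lrt")
    fit = fit_lmm(data[response], X, data[group])

    def coef_vec(level: str) -> np.ndarray:
        v = np.zeros(len(fit.params))
        name = f"{factor}[{level}]"
        if name in fit.params.index:
            v[fit.params.index.get_loc(name)] = 1.0
        return v

    results = []
    for a, b in itertools.combinations(levels, 2):
        c = coef_vec(a) - coef_vec(b)
        est = float(c @ fit.params.to_numpy())
        var = float(c @ fit.cov_params.to_numpy() @ c)
        se = np.sqrt(var)
        z = est / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        results.append((a, b, est, se, z, p))
    adj = holm_adjust([r[5] for r in results])
    return [
        ContrastResult(pair=(a, b), estimate=est, se=se, z=z, p_raw=p, p_holm=ph)
        for (a, b, est, se, z, p), ph in zip(results, adj)
    ]


# ---------------------------------------------------------------------------
# model / results presentation
# ---------------------------------------------------------------------------

class RandomInterceptModel:
    """Random-intercept LMM for one effect of interest.

    Examples
    --------
    >>> m = RandomInterceptModel.from_dataframe(
    ...     df, response="value", fixed="version", group="subject_id",
    ...     categorical=True)
    >>> res = m.fit()
    >>> chi2, df, p = res.compare_null()
    """

    def __init__(self, endog, exog, groups, exog_names: Optional[Sequence[str]] = None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = pd.DataFrame(exog)
        if exog_names is not None:
            self.exog.columns = list(exog_names)
        self.groups = np.asarray(groups)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        fixed: Optional[str] = None,
        group: str = "subject_id",
        categorical: bool = False,
        covariates: Sequence[str] = (),
    ) -> "RandomInterceptModel":
        """Build the design from a tidy table.

        ``fixed`` is the predictor of interest (``None`` for the intercept-only
        null model); ``categorical`` switches between a linear slope and
        treatment-coded dummies.
        """
        if fixed is None:
            X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
            for cov in covariates:
                X[cov] = np.asarray(data[cov], dtype=float)
        elif categorical:
            X, _ = _dummy_design(data, fixed, covariates)
        else:
            X = pd.DataFrame({"Intercept": np.ones(len(data)),
                              fixed: np.asarray(data[fixed], dtype=float)},
                             index=data.index)
            for cov in covariates:
                X[cov] = np.asarray(data[cov], dtype=float)
        return cls(data[response], X, data[group])

    def fit(self) -> "RandomInterceptResults":
        return RandomInterceptResults(self, fit_lmm(self.endog, self.exog, self.groups))


@dataclass
class RandomInterceptResults:
    """Results wrapper carrying estimates, variances and model comparisons."""

    model: RandomInterceptModel
    fit_: LMMFit

    def __getattr__(self, name):
        return getattr(self.fit_, name)

    def compare(self, other: "RandomInterceptResults") -> dict:
        """LRT and effect size of this (full) fit against a nested fit."""
        chi2, df, p = lrt(self.fit_, other.fit_)
        return {"chi2": chi2, "df": df, "p": p,
                "effect_size": effect_size(self.fit_, other.fit_)}

    def compare_null(self) -> dict:
        """Compare against the intercept-only model on the same data."""
        null = RandomInterceptModel(
            self.model.endog,
            pd.DataFrame({"Intercept": np.ones(len(self.model.endog))}),
            self.model.groups,
        ).fit()
        return self.compare(null)

    def summary(self) -> str:
        f = self.fit_
        lines = [
            "Random-intercept linear mixed model (ML)",
            "=" * 48,
            f"n obs: {f.nobs}    n params: {f.n_params}    logLik: {f.llf:.3f}",
            f"sigma^2 subject: {f.sigma_subject2:.4f}    sigma^2 residual: {f.sigma_resid2:.4f}",
            "-" * 48,
            f"{'coef':24s} {'estimate':>10s} {'se':>8s}",
        ]
        se = np.sqrt(np.diag(f.cov_params))
        for name, est, s in zip(f.params.index, f.params, se):
            lines.append(f"{name:24s} {est:10.4f} {s:8.4f}")
        return "\n".join(lines)
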