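"""Longitudinal clinical-evaluation statistics.

Percent change from baseline, paired t-tests, marker correlations, and
random-intercept linear mixed-effects models with fully standardized
coefficients and conditional R^2 (variance-partition form: fixed-effect
variance plus random-intercept variance over the total).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import DegenerateTestError, InvalidParameterError

DEFAULT_COVARIATES = ("age", "sex", "relative_daytime", "scan_focus")
MARKERS = ("egfr", "creatinine", "urea")


@dataclass
class LMEFitResult:
    """Standardized fixed effects with Wald 95% CIs, plus variance components."""

    terms: dict[str, dict]  # name -> {beta, ci: (lo, hi), p}
    random_intercept_sd: float
    conditional_r2: float
    n_obs: int
    n_patients: int
    converged: bool = True

    def beta(self, term: str) -> float:
        return self.terms[term]["beta"]

    def ci(self, term: str) -> tuple[float, float]:
        return self.terms[term]["ci"]


def percent_change(baseline: float, followup: float) -> float:
    """100 * (followup - baseline) / baseline."""
    if baseline == 0:
        raise InvalidParameterError("baseline value must be nonzero")
    return 100.0 * (followup - baseline) / baseline


def cohort_percent_change(
    table: pd.DataFrame, value_col: str, week: float, baseline_week: float = 0
) -> dict:
    """Per-patient percent change summarized as mean, SD, median.

    The cohort summary is the mean of per-patient percent changes, not the
    percent change of cohort means.
    """
    base = table[table["visit_week"] == baseline_week].set_index("patient")[value_col]
    fup = table[table["visit_week"] == week].set_index("patient")[value_col]
    common = base.index.intersection(fup.index)
    if len(common) == 0:
        raise InvalidParameterError("no patients with both baseline and follow-up")
    pc = np.array([percent_change(base[p], fup[p]) for p in common])
    return {
        "mean": float(np.mean(pc)),
        "sd": float(np.std(pc, ddof=1)) if len(pc) > 1 else 0.0,
        "median": float(np.median(pc)),
        "n": int(len(pc)),
        "per_patient": pd.Series(pc, index=common),
    }


def paired_t_test(a, b) -> tuple[float, float]:
    """Student's t-test for dependent, paired samples; two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidParameterError("paired samples must have equal length")
    n = len(a)
    if n < 2:
        raise InvalidParameterError("need at least 2 pairs")
    d = b - a
    sd = np.std(d, ddof=1)
    if sd == 0:
        if np.mean(d) == 0:
            return 0.0, 1.0
        raise DegenerateTestError("zero-variance nonzero differences")
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return t, p


def marker_correlations(
    table: pd.DataFrame,
    choroid_vars=("auto_ca", "auto_ct", "manual_ct"),
    markers=MARKERS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Complete-case Pearson r and two-sided p per (choroid measure, marker).

    Returns (r, p) DataFrames indexed by choroid measure with marker columns.
    """
    r = pd.DataFrame(index=list(choroid_vars), columns=list(markers), dtype=float)
    p = r.copy()
    for cv in choroid_vars:
        for mk in markers:
            sub = table[[cv, mk]].dropna()
            if len(sub) < 3:
                raise InvalidParameterError(f"fewer than 3 complete pairs for ({cv}, {mk})")
            x, y = sub[cv].to_numpy(), sub[mk].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                raise DegenerateTestError(f"zero variance in ({cv}, {mk})")
            rr, pp = stats.pearsonr(x, y)
            r.loc[cv, mk] = rr
            p.loc[cv, mk] = pp
    return r, p


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = np.std(v, ddof=1)
    return (v - np.mean(v)) / sd if sd > 0 else np.zeros_like(v)


def fit_lme(
    table: pd.DataFrame,
    response: str,
    choroid_var: str,
    covariates=DEFAULT_COVARIATES,
    group_col: str = "patient",
) -> LMEFitResult:
    """Random-intercept LME with standardized response and predictors.

    The response and continuous covariates are z-scored on the complete-case
    analysis subset; binary sex is contrast-coded (0/1, centered). The model
    is fit by restricted maximum likelihood with a per-patient random
    intercept. CIs are Wald intervals on the standardized scale, using a
    Student-t quantile with (patients - 1) degrees of freedom as a
    small-sample correction for the limited number of clusters. Conditional
    R^2 is (fixed-effect variance + random-intercept variance) / (those +
    residual variance). A noise-free response (zero residual variance) is
    detected up front and returned as an exact least-squares fit with
    conditional R^2 of 1.
    """
    import statsmodels.api as sm

    cols = [response, choroid_var, *covariates, group_col]
    data = table.dropna(subset=[c for c in cols if c in table.columns]).copy()
    n_patients = data[group_col].nunique()
    if len(data) < 4 or n_patients < 2:
        raise InvalidParameterError("need >= 2 patients with >= 2 visits")

    design = {}
    for cov in (*covariates, choroid_var):
        v = data[cov]
        if v.dtype == object or str(v.dtype) == "category":
            mapping = {lvl: i for i, lvl in enumerate(sorted(v.unique()))}  # stable 0/1 coding
            x = v.map(mapping).astype(float).to_numpy()
            design[cov] = x - x.mean()
        else:
            design[cov] = _zscore(v.to_numpy(dtype=float))
    y = _zscore(data[response].to_numpy(dtype=float))

    names = list(design)
    X = np.column_stack([np.ones(len(y))] + [design[n] for n in names])
    term_names = ["intercept"] + names

    # zero-noise guard: an exact linear fit makes REML degenerate
    beta_ls, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ls
    if np.var(resid) < 1e-12:
        terms = {
            nm: {
                "beta": float(b),
                "ci": (float(b), float(b)),
                "p": 0.0 if abs(b) > 1e-9 else 1.0,
            }
            for nm, b in zip(term_names, beta_ls)
        }
        return LMEFitResult(
            terms=terms, random_intercept_sd=0.0, conditional_r2=1.0,
            n_obs=len(y), n_patients=n_patients,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=data[group_col].to_numpy())
        fit = model.fit(reml=True)

    dof = max(n_patients - 1, 1)
    crit = stats.t.ppf(0.975, df=dof)
    terms = {}
    for i, nm in enumerate(term_names):
        b = float(fit.fe_params[i])
        se = float(fit.bse_fe[i])
        terms[nm] = {
            "beta": b,
            "ci": (b - crit * se, b + crit * se),
            "p": float(2.0 * stats.t.sf(abs(b / se), df=dof)) if se > 0 else np.nan,
        }
    var_re = float(np.asarray(fit.cov_re)[0, 0])
    var_resid = float(fit.scale)
    var_fixed = float(np.var(X @ fit.fe_params))
    r2c = (var_fixed + var_re) / (var_fixed + var_re + var_resid)
    return LMEFitResult(
        terms=terms,
        random_intercept_sd=float(np.sqrt(max(var_re, 0.0))),
        conditional_r2=float(r2c),
        n_obs=len(y),
        n_patients=n_patients,
        converged=bool(fit.converged),
    )


def significance_by_ci(fit: LMEFitResult, term: str) -> bool:
    """True iff the term's 95% CI strictly excludes 0."""
    if term not in fit.terms:
        raise InvalidParameterError(f"unknown term {term!r}")
    lo, hi = fit.terms[term]["ci"]
    return bool(lo > 0 or hi < 0)
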