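"""The statistical chain: Cox proportional hazards, normality-gated group
comparisons, chi-square, Pearson R^2, and descriptives.

The Cox model is fitted by Newton-Raphson maximization of the partial
likelihood with either the Breslow (default) or Efron correction for tied
event times.  Standard errors come from the observed information at the
optimum; confidence intervals and p-values are Wald-based, all two-sided.

The remaining procedures follow a fixed protocol: Shapiro-Wilk at 0.05
gates t-test (mean +/- SD summaries) versus Mann-Whitney U (median [IQR]);
2x2 categorical comparisons use Pearson chi-square without continuity
correction; no multiple-testing adjustment is applied anywhere.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class CoxModelFit:
    """A fitted proportional-hazards model."""

    names: list
    coef: np.ndarray            # log-hazard per unit covariate
    se: np.ndarray
    hazard_ratios: np.ndarray   # exp(coef)
    ci95: np.ndarray            # (p, 2) exp(coef -/+ 1.96 se)
    p_values: np.ndarray        # two-sided Wald
    log_partial_likelihood: float
    ties_method: str
    n: int
    n_events: int
    score_max: float            # max |gradient| at the optimum
    n_iter: int
    converged: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef, "se": self.se, "hr": self.hazard_ratios,
            "ci_lo": self.ci95[:, 0], "ci_hi": self.ci95[:, 1],
            "p": self.p_values}, index=self.names)


@dataclass
class TestResult:
    """A two-group comparison with its normality-gated summaries."""

    test: str                  # "t-test" | "mann-whitney" | "chi-square"
    statistic: float
    p_value: float
    summaries: list = field(default_factory=list)
    warning: Optional[str] = None


def _cox_quantities(beta, time, event, X, ties):
    """Log partial likelihood, score, and observed information at beta."""
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    # suffix sums over the risk set {j : t_j >= t_i} on time-sorted data
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    ev_idx = np.flatnonzero(event == 1)
    if ev_idx.size == 0:
        return ll, score, info
    ev_times = time[ev_idx]
    # group tied event times; risk set starts at the first subject with t >= t_k
    uniq, starts = np.unique(ev_times, return_index=True)
    for k, t in enumerate(uniq):
        D = ev_idx[ev_times == t]
        d = D.size
        i0 = np.searchsorted(time, t, side="left")
        ll += eta[D].sum()
        if ties == "breslow":
            ll -= d * np.log(s0[i0])
            score += X[D].sum(axis=0) - d * s1[i0] / s0[i0]
            m = s1[i0] / s0[i0]
            info += d * (s2[i0] / s0[i0] - np.outer(m, m))
        else:  # efron
            wd0 = w[D].sum()
            wd1 = wx[D].sum(axis=0)
            wd2 = wxx[D].sum(axis=0)
            score += X[D].sum(axis=0)
            for l in range(d):
                f = l / d
                a0 = s0[i0] - f * wd0
                a1 = s1[i0] - f * wd1
                a2 = s2[i0] - f * wd2
                ll -= np.log(a0)
                m = a1 / a0
                score -= m
                info += a2 / a0 - np.outer(m, m)
    return ll, score, info


def cox_fit(time, event, covariates, names: Optional[Sequence[str]] = None,
            ties: str = "breslow", max_iter: int = 50,
            tol: float = 1e-9) -> CoxModelFit:
    """Fit a Cox proportional-hazards model.

    Parameters
    ----------
    time, event
        Follow-up times and binary event indicators.
    covariates
        (n, p) matrix (a vector is treated as a single covariate).
    ties
        "breslow" (default) or "efron" correction for tied event times.

    Newton-Raphson with step-halving; convergence when the score (gradient
    of the log partial likelihood) satisfies max |component| < ``tol`` or
    after ``max_iter`` iterations.  A monotone likelihood (perfect
    separation) is flagged as non-convergence rather than raised.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)
    if len(names) != p:
        raise ValueError("names length does not match covariate count")
    if time.shape[0] != n or event.shape[0] != n:
        raise ValueError("time, event, covariates lengths differ")
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    if np.any(X.std(axis=0) == 0):
        bad = [names[j] for j in range(p) if X[:, j].std() == 0]
        raise ValueError(f"constant covariate(s): {bad}")
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")

    order = np.argsort(time, kind="stable")
    time, event, X = time[order], event[order], X[order]
    center = X.mean(axis=0)
    Xc = X - center  # partial likelihood is shift-invariant; this is for
    # numerical stability of exp(eta) only

    beta = np.zeros(p)
    ll, score, info = _cox_quantities(beta, time, event, Xc, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step-halving to guarantee ascent; the tolerance is relative to
        # |ll| so float-level noise near the optimum cannot stall the step
        for _ in range(30):
            cand = beta + step
            ll_new, score_new, info_new = _cox_quantities(
                cand, time, event, Xc, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-9 * (1.0 + abs(ll)):
                break
            step = step / 2.0
        beta, ll, score, info = cand, ll_new, score_new, info_new
    else:
        it = max_iter
    if np.max(np.abs(score)) < tol:
        converged = True
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    # monotone likelihood: the score can vanish numerically while the
    # coefficient drifts out with an exploding standard error
    if (not np.all(np.isfinite(se)) or np.max(np.abs(beta)) > 50
            or np.any(np.abs(beta) * se > 1e3)):
        converged = False
    if not converged:
        warnings.warn("Cox fit did not converge (possible monotone "
                      "likelihood / perfect separation)", RuntimeWarning)

    z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    half = 1.959963984540054 * se
    ci = np.exp(np.clip(np.column_stack([beta - half, beta + half]),
                        -700.0, 700.0))
    return CoxModelFit(
        names=names, coef=beta, se=se, hazard_ratios=np.exp(beta),
        ci95=ci, p_values=pvals, log_partial_likelihood=float(ll),
        ties_method=ties, n=n, n_events=int(event.sum()),
        score_max=float(np.max(np.abs(score))), n_iter=it,
        converged=converged)


def univariate_screen(df: pd.DataFrame, candidates: Sequence[str],
                      time_col: str = "followup_months",
                      event_col: str = "event", age_col: str = "age_years",
                      threshold: float = 0.1,
                      ties: str = "breslow") -> dict:
    """Univariate Cox fits with the p < threshold screen to age-adjusted fits.

    Each candidate is fitted alone; candidates whose univariate Wald p is
    below ``threshold`` are refitted in a two-covariate model together with
    age.  Rows missing the candidate are dropped per fit.  Returns a dict
    per candidate with ``univariate`` and ``bivariate`` (None when not
    advanced or identical to age itself) fit objects.
    """
    out = {}
    for var in candidates:
        cols = [time_col, event_col, var]
        sub = df[cols].dropna()
        try:
            uni = cox_fit(sub[time_col], sub[event_col], sub[var].to_numpy(),
                          names=[var], ties=ties)
        except ValueError as exc:
            out[var] = {"univariate": None, "bivariate": None,
                        "error": str(exc)}
            continue
        biv = None
        if uni.p_values[0] < threshold and var != age_col:
            sub2 = df[[time_col, event_col, var, age_col]].dropna()
            biv = cox_fit(sub2[time_col], sub2[event_col],
                          sub2[[var, age_col]].to_numpy(),
                          names=[var, age_col], ties=ties)
        out[var] = {"univariate": uni, "bivariate": biv}
    return out


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    stat, p, _, _ = sps.chi2_contingency(tab, correction=False)
    return float(stat), float(p)


def _summary(values: np.ndarray, normal: bool) -> dict:
    if normal:
        return {"style": "mean_sd", "mean": float(np.mean(values)),
                "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
                "n": int(len(values))}
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return {"style": "median_iqr", "median": float(med),
            "iqr_width": float(q3 - q1), "n": int(len(values))}


def compare_groups(group_a, group_b, kind: str = "continuous") -> TestResult:
    """Two-group comparison under the normality-gated protocol.

    Continuous: Shapiro-Wilk on each group at 0.05; if both pass, an
    independent-samples t-test with mean +/- SD summaries, otherwise a
    two-sided Mann-Whitney U with median [IQR].  Groups too small for
    Shapiro-Wilk (< 3) fall back to Mann-Whitney with a warning.
    Categorical: the inputs are binary vectors; Pearson chi-square without
    continuity correction on the 2x2 table.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if kind == "categorical":
        tab = np.array([[np.sum(a == 0), np.sum(a == 1)],
                        [np.sum(b == 0), np.sum(b == 1)]], dtype=float)
        stat, p = chi_square_2x2(tab)
        summaries = [{"style": "count", "n": int(len(g)),
                      "positive": int(np.sum(g == 1))} for g in (a, b)]
        return TestResult("chi-square", stat, p, summaries)
    if kind != "continuous":
        raise ValueError("kind must be 'continuous' or 'categorical'")

    warning = None
    if len(a) < 3 or len(b) < 3:
        normal = False
        warning = "group too small for Shapiro-Wilk; using Mann-Whitney"
    else:
        normal = (sps.shapiro(a).pvalue >= 0.05
                  and sps.shapiro(b).pvalue >= 0.05)
    if normal:
        res = sps.ttest_ind(a, b)
        name = "t-test"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann-whitney"
    summaries = [_summary(g, normal) for g in (a, b)]
    out = TestResult(name, float(res.statistic), float(res.pvalue), summaries)
    out.warning = warning
    return out


def pearson_r2(x, y) -> dict:
    """Coefficient of determination R^2 from the Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input")
    r, p = sps.pearsonr(x, y)
    return {"r2": float(r * r), "r": float(r), "p": float(p),
            "n": int(len(x))}


def describe(values) -> dict:
    """Normality-gated descriptive summary of one variable.

    Shapiro-Wilk at 0.05 selects mean +/- SD versus median [IQR]; the IQR
    is reported as a single width (quartiles by linear interpolation).
    Vectors too short for the test (n < 3) are summarized as median [IQR]
    with dispersion flagged undefined at n = 1.
    """
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("empty input")
    if len(v) == 1:
        return {"style": "median_iqr", "median": float(v[0]),
                "iqr_width": None, "n": 1, "normal": None}
    if len(v) < 3 or np.std(v) == 0:
        normal = bool(np.std(v) == 0)  # constant vectors: mean +/- 0
    else:
        normal = bool(sps.shapiro(v).pvalue >= 0.05)
    out = _summary(v, normal)
    out["normal"] = normal
    return out
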