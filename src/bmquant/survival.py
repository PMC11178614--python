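"""Survival and correlation statistics.

The statistical stage downstream of quantification: Spearman rank correlation
between imaging markers and marrow infiltration, Kaplan–Meier estimation with
median survival (median follow-up by the inverse-KM trick of swapping event
and censoring roles), log-rank comparison of median-dichotomized markers,
uni-/multivariable Cox proportional-hazards regression, ROC analysis of
2-year outcome with the Youden-optimal cut point, and ISS / R-ISS staging.

Established backends do the model fitting: lifelines for KM, log-rank and
Efron-ties Cox; statsmodels PHReg for Breslow ties. The ROC/Youden routine
with its DeLong confidence interval is implemented here. p-values are
two-sided throughout; no multiple-testing correction is applied (the
analyses are exploratory by design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times
from scipy import stats

__all__ = [
    "CoxFitResult",
    "KMResult",
    "RocResult",
    "spearman_corr",
    "km_estimate",
    "median_followup_inverse_km",
    "log_rank_test",
    "dichotomize_at_median",
    "cox_fit",
    "binary_outcome_at_horizon",
    "roc_youden",
    "roc_at_horizon",
    "iss_stage",
    "r_iss_stage",
]


# ---------------------------------------------------------------------------
# correlation


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties; two-sided p.

    A constant input leaves the rank correlation undefined: (nan, nan) is
    returned with a warning rather than an arbitrary value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1D vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Kaplan–Meier


@dataclass(frozen=True)
class KMResult:
    """Product-limit estimate: step curve, median and its 95% CI.

    ``median_months`` is ``inf`` when the curve never drops to 0.5 — the
    "median not reached" case.
    """

    times: np.ndarray
    survival: np.ndarray
    median_months: float
    median_ci: tuple[float, float]
    n: int
    n_events: int

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median_months)


def _check_records(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if len(time) == 0:
        raise ValueError("at least one record is required")
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("times must be finite and strictly positive")
    return time, event


def km_estimate(time, event) -> KMResult:
    """Kaplan–Meier survival estimate with median and 95% CI."""
    time, event = _check_records(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return KMResult(
        times=kmf.survival_function_.index.to_numpy(dtype=float),
        survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
        median_months=float(kmf.median_survival_time_),
        median_ci=(lo, hi),
        n=len(time),
        n_events=int(event.sum()),
    )


def median_followup_inverse_km(time, event) -> float:
    """Median follow-up by inverse Kaplan–Meier (event and censoring roles
    swapped). With no censored subject the follow-up distribution is never
    observed: ``inf`` is returned with a warning."""
    time, event = _check_records(time, event)
    if event.all():
        warnings.warn("no censored observations: median follow-up not estimable",
                      stacklevel=2)
        return float("inf")
    return km_estimate(time, ~event).median_months


# ---------------------------------------------------------------------------
# group comparison


def dichotomize_at_median(values) -> np.ndarray:
    """High/low split at the median; values strictly above the median are
    'high' (1), ties at the median go 'low' (0)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two values to dichotomize")
    labels = (values > np.median(values)).astype(int)
    if labels.sum() == 0:
        warnings.warn("median split produced an empty high group", stacklevel=2)
    return labels


def log_rank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test (1 df, two-sided)."""
    time, event = _check_records(time, event)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(levels)}")
    a = group == levels[0]
    res = _ll_logrank(time[a], time[~a], event_observed_A=event[a],
                      event_observed_B=event[~a])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox regression


@dataclass(frozen=True)
class CoxFitResult:
    """Per-covariate hazard ratios with Wald 95% CIs and p-values."""

    covariates: tuple[str, ...]
    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    p_values: dict[str, float]
    log_likelihood: float
    n: int
    n_events: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "hr": self.hazard_ratios, "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper, "p": self.p_values,
        })


def cox_fit(df: pd.DataFrame, covariates: list[str],
            time_col: str = "time_months", event_col: str = "event",
            ties: str = "efron") -> CoxFitResult:
    """Cox proportional-hazards fit by partial likelihood.

    Efron's tie handling (default) runs through lifelines; ``ties='breslow'``
    runs through statsmodels PHReg. Requires at least two events and
    non-constant covariates.
    """
    data = df[[time_col, event_col] + list(covariates)].copy()
    time, event = _check_records(data[time_col], data[event_col])
    if event.sum() < 2:
        raise ValueError("Cox regression requires at least two events")
    for c in covariates:
        if np.ptp(np.asarray(data[c], dtype=float)) == 0:
            raise ValueError(f"covariate {c!r} is constant")

    if ties == "efron":
        cph = CoxPHFitter()
        cph.fit(data, duration_col=time_col, event_col=event_col)
        summ = cph.summary
        return CoxFitResult(
            covariates=tuple(covariates),
            hazard_ratios={c: float(summ.loc[c, "exp(coef)"]) for c in covariates},
            ci_lower={c: float(np.exp(summ.loc[c, "coef lower 95%"])) for c in covariates},
            ci_upper={c: float(np.exp(summ.loc[c, "coef upper 95%"])) for c in covariates},
            p_values={c: float(summ.loc[c, "p"]) for c in covariates},
            log_likelihood=float(cph.log_likelihood_),
            n=len(data), n_events=int(event.sum()),
        )
    if ties == "breslow":
        from statsmodels.duration.hazard_regression import PHReg
        model = PHReg(np.asarray(data[time_col], float),
                      np.asarray(data[covariates], float),
                      status=np.asarray(data[event_col], int), ties="breslow")
        res = model.fit(disp=False)
        se = np.asarray(res.bse)
        coef = np.asarray(res.params)
        z = coef / se
        p = 2 * stats.norm.sf(np.abs(z))
        return CoxFitResult(
            covariates=tuple(covariates),
            hazard_ratios={c: float(np.exp(b)) for c, b in zip(covariates, coef)},
            ci_lower={c: float(np.exp(b - 1.959963984540054 * s))
                      for c, b, s in zip(covariates, coef, se)},
            ci_upper={c: float(np.exp(b + 1.959963984540054 * s))
                      for c, b, s in zip(covariates, coef, se)},
            p_values={c: float(pv) for c, pv in zip(covariates, p)},
            log_likelihood=float(res.llf),
            n=len(data), n_events=int(event.sum()),
        )
    raise ValueError(f"unknown tie method {ties!r} (use 'efron' or 'breslow')")


# ---------------------------------------------------------------------------
# 2-year outcome and ROC


def binary_outcome_at_horizon(time, event, horizon_months: float = 24.0
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Binary outcome at a fixed horizon.

    Positive: event at or before the horizon. Negative: followed beyond the
    horizon (with or without a later event). Subjects censored event-free at
    or before the horizon are not classifiable and are flagged non-evaluable.
    Returns (labels, evaluable) aligned with the input; labels of
    non-evaluable subjects are set to -1.
    """
    if horizon_months <= 0:
        raise ValueError("horizon must be positive")
    time, event = _check_records(time, event)
    positive = event & (time <= horizon_months)
    negative = time > horizon_months
    evaluable = positive | negative
    if not evaluable.any():
        raise ValueError("no subject is evaluable at the requested horizon")
    labels = np.where(positive, 1, np.where(negative, 0, -1))
    return labels, evaluable


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC summary: AUC with DeLong 95% CI and p for AUC = 0.5,
    plus the Youden-optimal cut with its sensitivity and specificity."""

    auc: float
    auc_ci: tuple[float, float]
    p_value: float
    cut_point: float
    sensitivity: float
    specificity: float
    n_positive: int
    n_negative: int


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from the structural-component formulation."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    tz = _midrank(all_scores)
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n          # placement of each positive among negatives
    v01 = 1.0 - (tz[m:] - ty) / m    # placement of each negative among positives
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    return float(auc), float(var)


def roc_youden(marker, labels) -> RocResult:
    """Empirical ROC of a continuous marker against a binary outcome.

    The optimal cut maximizes the Youden index (sensitivity + specificity
    - 1) over midpoints between consecutive distinct marker values (plus the
    all-positive and all-negative extremes); ties are broken toward the lower
    cut value. A subject is called positive when the marker is at or above
    the cut. The AUC CI and the p-value for AUC = 0.5 use DeLong's variance.
    """
    marker = np.asarray(marker, dtype=float)
    labels = np.asarray(labels).astype(int)
    if marker.shape != labels.shape:
        raise ValueError("marker and labels must align")
    pos = marker[labels == 1]
    neg = marker[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present for ROC analysis")

    auc, var = _delong_auc_variance(pos, neg)
    se = np.sqrt(var)
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2 * stats.norm.sf(abs(z)))
        ci = (max(0.0, auc - 1.959963984540054 * se),
              min(1.0, auc + 1.959963984540054 * se))
    else:  # degenerate: perfect or constant separation
        p = 0.0 if auc != 0.5 else 1.0
        ci = (auc, auc)

    uniq = np.unique(marker)
    cuts = [uniq[0] - 0.5]                       # everything positive
    cuts += list((uniq[:-1] + uniq[1:]) / 2.0)   # between observed values
    cuts += [uniq[-1] + 0.5]                     # nothing positive
    best = None
    for cut in cuts:  # ascending, so argmax-by-first-win prefers the lower cut
        sens = float((pos >= cut).mean())
        spec = float((neg < cut).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, cut, sens, spec)
    _, cut, sens, spec = best
    return RocResult(auc=float(auc), auc_ci=ci, p_value=p, cut_point=float(cut),
                     sensitivity=sens, specificity=spec,
                     n_positive=len(pos), n_negative=len(neg))


def roc_at_horizon(df: pd.DataFrame, marker_col: str, horizon_months: float = 24.0,
                   time_col: str = "time_months", event_col: str = "event",
                   method: str = "binary") -> RocResult:
    """ROC of a marker for the outcome "event within the horizon".

    ``method='binary'`` (default) excludes subjects censored before the
    horizon and runs the plain empirical ROC. ``method='ipcw'`` keeps all
    subjects and weights cases/controls by inverse probability of censoring
    (KM of the censoring distribution); its cut point comes from weighted
    sensitivity/specificity, and no DeLong CI applies (the CI degenerates to
    the point estimate and the p-value is reported as nan).
    """
    time = np.asarray(df[time_col], dtype=float)
    event = np.asarray(df[event_col]).astype(bool)
    marker = np.asarray(df[marker_col], dtype=float)
    if method == "binary":
        labels, evaluable = binary_outcome_at_horizon(time, event, horizon_months)
        return roc_youden(marker[evaluable], labels[evaluable])
    if method != "ipcw":
        raise ValueError(f"unknown ROC method {method!r}")

    # IPCW: weight cases by 1/G(T-), controls by 1/G(horizon)
    cens_km = km_estimate(time, ~event)

    def g_at(t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(cens_km.times, t, side="right") - 1
        return np.where(idx >= 0, cens_km.survival[np.clip(idx, 0, None)], 1.0)

    case = event & (time <= horizon_months)
    control = time > horizon_months
    w_case = np.where(case, 1.0 / np.clip(g_at(time - 1e-9), 1e-12, None), 0.0)
    w_ctrl = np.where(control, 1.0 / np.clip(g_at(np.full_like(time, horizon_months)),
                                             1e-12, None), 0.0)
    wc, mc = w_case[case], marker[case]
    wn, mn = w_ctrl[control], marker[control]
    if len(mc) == 0 or len(mn) == 0:
        raise ValueError("both cases and controls are required at the horizon")
    # weighted Mann-Whitney AUC
    order = np.argsort(mn, kind="mergesort")
    mn_s, wn_s = mn[order], wn[order]
    cw = np.concatenate([[0.0], np.cumsum(wn_s)])
    lo = np.searchsorted(mn_s, mc, side="left")
    hi = np.searchsorted(mn_s, mc, side="right")
    below = cw[lo]
    ties_w = cw[hi] - cw[lo]
    auc = float(np.sum(wc * (below + 0.5 * ties_w)) / (wc.sum() * wn.sum()))

    uniq = np.unique(marker)
    cuts = np.concatenate([[uniq[0] - 0.5], (uniq[:-1] + uniq[1:]) / 2.0,
                           [uniq[-1] + 0.5]])
    best = None
    for cut in cuts:
        sens = float(np.sum(wc[mc >= cut]) / wc.sum())
        spec = float(np.sum(wn[mn < cut]) / wn.sum())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(cut), sens, spec)
    _, cut, sens, spec = best
    return RocResult(auc=auc, auc_ci=(auc, auc), p_value=float("nan"),
                     cut_point=cut, sensitivity=sens, specificity=spec,
                     n_positive=int(case.sum()), n_negative=int(control.sum()))


# ---------------------------------------------------------------------------
# staging


def iss_stage(b2m_mg_l: float, albumin_g_dl: float) -> int:
    """International Staging System: I if beta2-microglobulin < 3.5 mg/L and
    albumin >= 3.5 g/dL; III if beta2-microglobulin > 5.5 mg/L; II otherwise."""
    if b2m_mg_l < 0 or albumin_g_dl < 0:
        raise ValueError("staging inputs must be non-negative")
    if b2m_mg_l > 5.5:
        return 3
    if b2m_mg_l < 3.5 and albumin_g_dl >= 3.5:
        return 1
    return 2


def r_iss_stage(iss: int, high_risk_cyto: bool, ldh_high: bool) -> int:
    """Revised ISS: I requires ISS I with no high-risk cytogenetics and normal
    LDH; III requires ISS III with high-risk cytogenetics or elevated LDH;
    every other combination is II."""
    if iss not in (1, 2, 3):
        raise ValueError("iss must be 1, 2 or 3")
    if iss == 1 and not high_risk_cyto and not ldh_high:
        return 1
    if iss == 3 and (high_risk_cyto or ldh_high):
        return 3
    return 2
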