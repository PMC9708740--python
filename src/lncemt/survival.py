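"""Survival analysis: Kaplan-Meier, log-rank, univariate Cox, risk score.

The risk model is the prognostic signature sum(beta_i * exp_i): per-feature
coefficients from *univariate* Cox fits (deliberately not a joint fit)
applied to expression, with samples split into high/low risk at a cutoff
(cohort median by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ClinicalTable, ExpressionMatrix

logger = logging.getLogger("lncemt")


@dataclass
class SurvivalCurve:
    """Product-limit estimate: event times, at-risk counts, S(t)."""

    times: np.ndarray  # distinct event times, increasing
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time

    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5; inf when never reached."""
        below = self.survival <= 0.5
        return float(self.times[below][0]) if below.any() else float("inf")

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimator; ties handled by simultaneous multiplication."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival time")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    at_risk = np.array([(times >= t).sum() for t in event_times])
    n_events = np.array([((times == t) & (events == 1)).sum() for t in event_times])
    if len(event_times):
        surv = np.cumprod(1.0 - n_events / at_risk)
    else:
        surv = np.array([])
    return SurvivalCurve(
        times=event_times, at_risk=at_risk, n_events=n_events, survival=surv
    )


def restricted_mean_survival(curve: SurvivalCurve, horizon: float) -> float:
    """Area under the KM curve up to ``horizon``."""
    ts = np.concatenate([[0.0], curve.times, [horizon]])
    ss = np.concatenate([[1.0], curve.survival, [curve.survival_at(horizon)]])
    ts = np.clip(ts, 0, horizon)
    # step function: S is constant on [t_i, t_{i+1})
    return float(np.sum(ss[:-1] * np.diff(ts)))


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic and p (chi2, 1 df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    if (groups == labels[0]).sum() == 0 or (groups == labels[1]).sum() == 0:
        raise ValueError("a group is empty")
    if events.sum() == 0:
        raise ValueError("no events observed")
    g1 = groups == labels[0]
    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class CoxFit:
    """Univariate Cox fit: log hazard ratio beta, SE, Wald p, HR."""

    feature: str
    beta: float
    se: float
    p: float
    converged: bool

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))


def _cox_derivatives(beta, times, events, x, ties):
    """Log partial likelihood derivatives (score, information)."""
    order = np.argsort(-times, kind="stable")  # decreasing time
    t_s, e_s, x_s = times[order], events[order], x[order]
    eta = beta * x_s
    w = np.exp(eta)
    # running risk-set sums (samples with time >= t enter before t is reached)
    cw = np.cumsum(w)
    cwx = np.cumsum(w * x_s)
    cwx2 = np.cumsum(w * x_s**2)
    score = 0.0
    info = 0.0
    loglik = 0.0
    i = 0
    n = len(t_s)
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        # block [i, j) shares a time; risk set = all samples up to index j-1
        d_idx = [k for k in range(i, j) if e_s[k] == 1]
        d = len(d_idx)
        if d:
            s0, s1, s2 = cw[j - 1], cwx[j - 1], cwx2[j - 1]
            sx = sum(x_s[k] for k in d_idx)
            if ties == "breslow":
                loglik += beta * sx - d * np.log(s0)
                score += sx - d * s1 / s0
                info += d * (s2 / s0 - (s1 / s0) ** 2)
            elif ties == "efron":
                dw = sum(w[k] for k in d_idx)
                dwx = sum(w[k] * x_s[k] for k in d_idx)
                dwx2 = sum(w[k] * x_s[k] ** 2 for k in d_idx)
                loglik += beta * sx
                score_blk = sx
                info_blk = 0.0
                for r in range(d):
                    f = r / d
                    z0 = s0 - f * dw
                    z1 = s1 - f * dwx
                    z2 = s2 - f * dwx2
                    loglik -= np.log(z0)
                    score_blk -= z1 / z0
                    info_blk += z2 / z0 - (z1 / z0) ** 2
                score += score_blk
                info += info_blk
            else:
                raise ValueError(f"unknown tie method {ties!r}")
        i = j
    return loglik, score, info


def cox_univariate(
    times,
    events,
    x,
    feature: str = "x",
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Maximize the univariate Cox partial likelihood by Newton iteration.

    Convergence when |score| < 1e-8. Monotone likelihood (perfect
    separation) is flagged as a non-converged fit with beta capped at +/-10.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    if np.std(x) == 0:
        raise ValueError("constant covariate")
    if events.sum() < 2:
        raise ValueError("need at least 2 events")
    beta = 0.0
    converged = False
    for _ in range(max_iter):
        _, score, info = _cox_derivatives(beta, times, events, x, ties)
        if abs(score) < tol:
            converged = True
            break
        if info <= 0:
            break
        step = score / info
        beta += np.clip(step, -5.0, 5.0)
        if abs(beta) > 10.0:
            beta = float(np.sign(beta) * 10.0)
            logger.warning(
                "cox fit for %s: monotone likelihood, beta capped at %s", feature, beta
            )
            break
    _, score, info = _cox_derivatives(beta, times, events, x, ties)
    converged = converged and abs(beta) < 10.0
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CoxFit(feature=feature, beta=float(beta), se=se, p=p, converged=converged)


@dataclass
class RiskModel:
    """Prognostic score sum(beta_i * expression_i) with a high/low split."""

    coefficients: pd.Series  # beta per feature
    scores: pd.Series  # per-sample risk score
    cutoff: float
    groups: pd.Series  # "high" / "low"


def risk_model(
    expr: ExpressionMatrix,
    fits: list[CoxFit],
    cutoff: str | float = "median",
) -> RiskModel:
    """Build the risk score from univariate Cox coefficients.

    ``cutoff`` is "median", "mean" or a numeric value; samples with score
    strictly above the cutoff are "high" risk.
    """
    missing = [f.feature for f in fits if f.feature not in expr.feature_ids]
    if missing:
        raise KeyError(f"risk-model features absent from expression: {missing}")
    betas = pd.Series({f.feature: f.beta for f in fits}, name="beta")
    sub = expr.values.loc[betas.index]
    scores = pd.Series(betas.to_numpy() @ sub.to_numpy(), index=expr.sample_ids, name="risk")
    if cutoff == "median":
        cut = float(scores.median())
    elif cutoff == "mean":
        cut = float(scores.mean())
    else:
        cut = float(cutoff)
    groups = pd.Series(
        np.where(scores.to_numpy() > cut, "high", "low"),
        index=scores.index,
        name="risk_group",
    )
    return RiskModel(coefficients=betas, scores=scores, cutoff=cut, groups=groups)


def fit_risk_features(
    expr: ExpressionMatrix, clinical: ClinicalTable, features, ties: str = "breslow"
) -> list[CoxFit]:
    """Univariate Cox fit per feature against the clinical table."""
    clin = clinical.table.loc[expr.sample_ids]
    fits = []
    for f in features:
        fits.append(
            cox_univariate(
                clin["os_time"].to_numpy(),
                clin["os_event"].to_numpy(),
                expr.values.loc[f].to_numpy(),
                feature=f,
                ties=ties,
            )
        )
    return fits
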