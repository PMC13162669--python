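"""Survival analysis: median dichotomization, Kaplan–Meier, log-rank, and
univariate → multivariate Cox screening.

The Kaplan–Meier estimator and the two-group log-rank test are delegated to
``lifelines``.  Cox proportional-hazards fitting is implemented here as a
Newton–Raphson maximizer of the partial likelihood with both Efron (default)
and Breslow tie handling behind a single code path, so the two conventions
coincide to machine precision on tie-free data.  Inference is Wald-based:
95% confidence intervals are ``exp(coef ± 1.96·SE)`` and p-values come from
the normal approximation, matching the convention of clinical survival
software.  Harrell's concordance index of the fitted linear predictor is
reported with every model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index
from scipy import stats

logger = logging.getLogger(__name__)

_Z975 = float(stats.norm.ppf(0.975))


class CoxConvergenceError(RuntimeError):
    """The partial likelihood has no finite maximizer (monotone likelihood)."""


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate evaluated at the observed event times."""

    times: np.ndarray       # distinct observed times, ascending
    survival: np.ndarray    # S(t) immediately after each time
    at_risk: np.ndarray     # subjects at risk just before each time


@dataclass(frozen=True)
class SurvivalModelResult:
    summary: pd.DataFrame   # coef, hr, ci_low, ci_high, se, z, p per covariate
    cindex: float
    n: int
    n_events: int
    log_likelihood: float
    ties: str

    def coef(self, name: str) -> float:
        return float(self.summary.loc[name, "coef"])

    def hazard_ratio(self, name: str) -> float:
        return float(self.summary.loc[name, "hr"])


@dataclass(frozen=True)
class ScreeningReport:
    """Univariate p-values, the covariates passing the gate, and the
    multivariate model over them (None when nothing passes)."""

    univariate: pd.DataFrame     # coef, hr, ci, p (or error note) per candidate
    selected: list[str]
    multivariate: SurvivalModelResult | None
    alpha: float


def dichotomize_at_median(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Split scores at their median into ``low`` / ``high`` group labels.

    ``high`` means value >= median (so the median observation itself joins
    the high group — 23 distinct values split 11 low / 12 high); the median
    is the midpoint convention over defined values.  Missing values get a
    ``None`` label.  All-equal input puts everyone in ``high`` with a warning.
    """
    v = np.asarray(values, dtype=float)
    defined = ~np.isnan(v)
    if defined.sum() < 2:
        raise ValueError("need at least 2 defined values to dichotomize")
    med = float(np.median(v[defined]))
    if np.ptp(v[defined]) == 0:
        warnings.warn("all values equal; every subject labelled 'high'",
                      stacklevel=2)
    labels = np.where(v >= med, "high", "low").astype(object)
    labels[~defined] = None
    return labels


def km_estimate(
    times: Sequence[float] | np.ndarray, events: Sequence[int] | np.ndarray
) -> KMEstimate:
    """Kaplan–Meier product-limit estimate.

    A subject censored at an event time remains at risk for that event
    (events processed first at tied times), the standard convention.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty input")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    tab = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index \
        else kmf.event_table
    grid = tab.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    at_risk = tab["at_risk"].to_numpy(dtype=int)
    return KMEstimate(times=grid, survival=surv, at_risk=at_risk)


def logrank_test(
    group_labels: Sequence,
    times: Sequence[float] | np.ndarray,
    events: Sequence[int] | np.ndarray,
) -> tuple[float, float]:
    """Two-group log-rank test (hypergeometric variance, 1-df chi-square).

    Returns ``(chi_square, p_value)``.  With no events in either group the
    statistic is 0 and p = 1 (flagged in the log).
    """
    g = np.asarray(group_labels, dtype=object)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(labels)}")
    m0, m1 = (g == labels[0]), (g == labels[1])
    if m0.sum() == 0 or m1.sum() == 0:
        raise ValueError("each group needs at least one subject")
    if e.sum() == 0:
        logger.warning("no events in either group; log-rank statistic is 0")
        return 0.0, 1.0
    res = _ll_logrank(t[m0], t[m1], event_observed_A=e[m0], event_observed_B=e[m1])
    return float(res.test_statistic), float(res.p_value)


def _cox_nll_grad_hess(
    beta: np.ndarray,
    X: np.ndarray,
    order_groups: list[tuple[np.ndarray, np.ndarray]],
    ties: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Negative log partial likelihood with gradient and Hessian.

    ``order_groups`` holds, per distinct event time (descending), the indices
    of the risk-set increment and of the events at that time, so cumulative
    sums over the risk set can be built incrementally.
    """
    p = X.shape[1]
    eta = X @ beta
    eta -= eta.max()  # guards exp overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = w[:, None, None] * (X[:, :, None] * X[:, None, :])

    nll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S0, S1, S2 = 0.0, np.zeros(p), np.zeros((p, p))
    for risk_idx, event_idx in order_groups:
        S0 += float(w[risk_idx].sum())
        S1 += wx[risk_idx].sum(axis=0)
        S2 += wxx[risk_idx].sum(axis=0)
        d = event_idx.size
        if d == 0:
            continue
        nll -= float(eta[event_idx].sum())
        if ties == "breslow":
            fracs = np.zeros(d)
        else:  # efron
            fracs = np.arange(d) / d
        D0 = float(w[event_idx].sum())
        D1 = wx[event_idx].sum(axis=0)
        D2 = wxx[event_idx].sum(axis=0)
        for f in fracs:
            s0 = S0 - f * D0
            s1 = S1 - f * D1
            s2 = S2 - f * D2
            nll += np.log(s0)
            grad += s1 / s0
            hess += s2 / s0 - np.outer(s1, s1) / s0**2
    grad -= X[np.concatenate([g[1] for g in order_groups if g[1].size])].sum(axis=0)
    return nll, grad, hess


def _prepare_groups(t: np.ndarray, e: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    order = np.argsort(-t, kind="stable")
    ts = t[order]
    groups = []
    start = 0
    n = ts.size
    while start < n:
        stop = start
        while stop < n and ts[stop] == ts[start]:
            stop += 1
        idx = order[start:stop]
        groups.append((idx, idx[e[idx] == 1]))
        start = stop
    return groups


def cox_fit(
    times: Sequence[float] | np.ndarray,
    events: Sequence[int] | np.ndarray,
    covariates: pd.DataFrame,
    ties: Literal["efron", "breslow"] = "efron",
    max_iter: int = 100,
    tol: float = 1e-10,
) -> SurvivalModelResult:
    """Cox proportional-hazards fit by Newton–Raphson.

    Raises :class:`CoxConvergenceError`, naming the worst covariate, when a
    coefficient diverges (monotone partial likelihood, e.g. a covariate that
    perfectly orders the events); zero events is an error.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie handling: {ties!r}")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    X = covariates.to_numpy(dtype=float)
    names = list(covariates.columns)
    n, p = X.shape
    if t.shape[0] != n or e.shape[0] != n:
        raise ValueError("times, events and covariates must align")
    if e.sum() == 0:
        raise ValueError("no events; Cox model is not estimable")

    # center covariates for conditioning; coefficients are unaffected
    mu = X.mean(axis=0)
    Xc = X - mu
    groups = _prepare_groups(t, e)

    beta = np.zeros(p)
    nll, grad, hess = _cox_nll_grad_hess(beta, Xc, groups, ties)
    for _ in range(max_iter):
        try:
            delta = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxConvergenceError(f"singular information matrix: {exc}")
        step = 1.0
        for _ in range(30):
            cand = beta - step * delta
            nll_new, grad_new, hess_new = _cox_nll_grad_hess(cand, Xc, groups, ties)
            if nll_new <= nll + 1e-14:
                break
            step /= 2
        beta, nll, grad, hess = cand, nll_new, grad_new, hess_new
        if np.max(np.abs(beta)) > 20:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise CoxConvergenceError(
                f"coefficient for {worst!r} diverged (monotone likelihood)"
            )
        if np.max(np.abs(step * delta)) < tol:
            break
    else:
        raise CoxConvergenceError("Newton iteration did not converge")
    if np.max(np.abs(grad)) > 1e-4:
        worst = names[int(np.argmax(np.abs(grad)))]
        raise CoxConvergenceError(
            f"no stationary point for {worst!r} (monotone likelihood)"
        )

    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):  # huge SE -> inf CI bound, reported as such
        summary = pd.DataFrame({
            "coef": beta,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - _Z975 * se),
            "ci_high": np.exp(beta + _Z975 * se),
            "se": se,
            "z": z,
            "p": pvals,
        }, index=pd.Index(names, name="covariate"))
    lp = Xc @ beta
    cindex = float(concordance_index(t, -lp, e)) if p > 0 else float("nan")
    return SurvivalModelResult(
        summary=summary, cindex=cindex, n=n, n_events=int(e.sum()),
        log_likelihood=-nll, ties=ties,
    )


def screen_univariate_multivariate(
    times: Sequence[float] | np.ndarray,
    events: Sequence[int] | np.ndarray,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    ties: Literal["efron", "breslow"] = "efron",
) -> ScreeningReport:
    """Univariate Cox screen followed by one multivariate model.

    Every candidate is fit alone; those with Wald p < ``alpha`` enter a joint
    model.  A candidate whose univariate fit fails is recorded with the error
    note and excluded, never fatal.  An empty selection yields a report with
    ``multivariate=None`` (flagged in the log).
    """
    if candidates.shape[1] < 2:
        raise ValueError("need at least 2 candidate covariates")
    rows = []
    selected: list[str] = []
    for name in candidates.columns:
        try:
            res = cox_fit(times, events, candidates[[name]], ties=ties)
            r = res.summary.loc[name]
            rows.append({"covariate": name, "coef": r["coef"], "hr": r["hr"],
                         "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                         "p": r["p"], "error": ""})
            if r["p"] < alpha:
                selected.append(name)
        except (CoxConvergenceError, ValueError) as exc:
            logger.warning("univariate fit failed for %s: %s", name, exc)
            rows.append({"covariate": name, "coef": np.nan, "hr": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                         "error": str(exc)})
    univariate = pd.DataFrame(rows).set_index("covariate")
    multivariate = None
    if selected:
        try:
            multivariate = cox_fit(times, events, candidates[selected], ties=ties)
        except CoxConvergenceError as exc:
            logger.warning("multivariate fit failed: %s", exc)
    else:
        logger.info("no candidate passed the univariate gate at alpha=%g", alpha)
    return ScreeningReport(univariate=univariate, selected=selected,
                           multivariate=multivariate, alpha=alpha)
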