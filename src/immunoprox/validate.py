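"""ROC discrimination, Youden cutoff selection, and bootstrap optimism
correction of AUC and Harrell's C-index.

The internal-validation scheme is Harrell's: refit the model on each
bootstrap resample (patients drawn with replacement), evaluate the metric on
the resample and on the original data, and subtract the mean difference
(the optimism) from the apparent metric.  For 1-year progression prediction
the model is a single-covariate logistic regression; for survival it is the
Cox model of :mod:`immunoprox.survival`.  Patients censored before the
horizon have unknown 1-year status and are excluded from the binary label
(their number is logged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score, roc_curve

from .survival import CoxConvergenceError, concordance_index, cox_fit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray      # descending; rule: positive if score >= threshold
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    positive_label: int = 1


@dataclass(frozen=True)
class CutoffResult:
    threshold: float
    youden_j: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class ValidationResult:
    apparent: float
    optimism: float
    corrected: float
    n_boot: int
    seed: int | None
    n_redrawn: int = 0


def binary_outcome_at_horizon(
    times: Sequence[float] | np.ndarray,
    events: Sequence[int] | np.ndarray,
    horizon: float = 365.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Label survival past a horizon (e.g. PFS > 1 year) as the positive class.

    Returns ``(labels, usable_mask)``: subjects still event-free past the
    horizon are 1, subjects with an event at or before it are 0, and subjects
    censored before the horizon are excluded (mask False) because their
    status is unknown; the excluded count is logged.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    labels = np.where(t > horizon, 1, 0)
    usable = (t > horizon) | (e == 1)
    n_excl = int((~usable).sum())
    if n_excl:
        logger.info("%d subject(s) censored before the %g-day horizon excluded",
                    n_excl, horizon)
    return labels, usable


def roc_auc(
    scores: Sequence[float] | np.ndarray, labels: Sequence[int] | np.ndarray
) -> RocResult:
    """Empirical ROC curve and trapezoid AUC.

    The AUC equals the Mann–Whitney concordance probability, with tied
    scores contributing 1/2.  Both classes must be present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) != 2:
        raise ValueError("both outcome classes must be present")
    fpr, tpr, thr = roc_curve(y, s)
    return RocResult(
        thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr,
        auc=float(roc_auc_score(y, s)),
    )


def youden_cutoff(roc: RocResult) -> CutoffResult:
    """Threshold maximizing Youden's J = sensitivity + specificity − 1.

    Ties on J resolve to the lowest threshold (the most sensitive operating
    point), deterministically.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.flatnonzero(j == j.max())[-1]  # thresholds descend: last = lowest
    thr = float(roc.thresholds[best])
    return CutoffResult(
        threshold=thr, youden_j=float(j[best]),
        sensitivity=float(roc.sensitivity[best]),
        specificity=float(roc.specificity[best]),
    )


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficients (intercept first) of an unpenalized logistic MLE.

    Falls back to a sign-only separating direction on the first column when
    the likelihood is monotone (perfect separation) — the ranking, hence the
    AUC, of the limiting model is all that downstream code consumes.
    """
    Xd = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation warnings are expected in small resamples; the
            # non-finite check below handles the pathological outcome
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
        if np.all(np.isfinite(fit.params)):
            return np.asarray(fit.params, dtype=float)
    except Exception:  # pragma: no cover - separation path
        pass
    beta = np.zeros(Xd.shape[1])
    sign = 1.0 if X[y == 1, 0].mean() >= X[y == 0, 0].mean() else -1.0
    beta[1] = sign * 1e3
    return beta


def bootstrap_optimism_auc(
    scores,
    labels: Sequence[int] | np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ValidationResult:
    """Optimism-corrected AUC of a logistic model.

    ``scores`` is a single marker (1-d array) — the primary use, a
    one-covariate model in the interaction variable — or a feature matrix /
    DataFrame for a multi-covariate model.  Per resample: refit the logistic
    model, take its AUC on the resample and on the original sample; optimism
    is the mean difference; corrected = apparent − optimism.  Single-class
    resamples are redrawn (counted in ``n_redrawn``).  Fixing ``seed`` fixes
    the output bit-exactly.

    Note that a one-covariate model cannot overfit a rank metric (the AUC of
    its predictions equals the AUC of the marker whenever the fitted slope is
    positive), so its estimated optimism is bootstrap noise around zero;
    appreciable optimism requires a model with more than one covariate.
    """
    if isinstance(scores, pd.DataFrame):
        S = scores.to_numpy(dtype=float)
    else:
        S = np.asarray(scores, dtype=float)
        if S.ndim == 1:
            S = S[:, None]
    y = np.asarray(labels, dtype=int)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if any(np.ptp(S[:, j]) == 0 for j in range(S.shape[1])):
        raise ValueError("constant score column; model is degenerate")
    if len(np.unique(y)) != 2:
        raise ValueError("both outcome classes must be present")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = S.shape[0]

    beta = _fit_logistic(S, y)
    apparent = roc_auc(beta[0] + S @ beta[1:], y).auc

    optimisms = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
            n_redrawn += 1
        bb = _fit_logistic(S[idx], y[idx])
        auc_boot = roc_auc(bb[0] + S[idx] @ bb[1:], y[idx]).auc
        auc_orig = roc_auc(bb[0] + S @ bb[1:], y).auc
        optimisms[b] = auc_boot - auc_orig
    if n_redrawn:
        logger.info("%d single-class resample(s) redrawn", n_redrawn)
    optimism = float(optimisms.mean())
    return ValidationResult(
        apparent=float(apparent), optimism=optimism,
        corrected=float(apparent - optimism), n_boot=n_boot, seed=seed,
        n_redrawn=n_redrawn,
    )


def harrell_cindex(
    times: Sequence[float] | np.ndarray,
    events: Sequence[int] | np.ndarray,
    risk: Sequence[float] | np.ndarray,
) -> float:
    """Harrell's C: concordance over usable pairs, ties counted one-half.

    ``risk`` is a risk score — higher risk should fail earlier.
    """
    return float(concordance_index(
        np.asarray(times, dtype=float),
        -np.asarray(risk, dtype=float),
        np.asarray(events, dtype=int),
    ))


def bootstrap_optimism_cindex(
    times: Sequence[float] | np.ndarray,
    events: Sequence[int] | np.ndarray,
    covariates: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_redraws: int = 50,
) -> ValidationResult:
    """Optimism-corrected Harrell C-index of a Cox model.

    Same schema as :func:`bootstrap_optimism_auc` with ``cox_fit`` as the
    model.  Resamples with zero events (or a failed fit) are redrawn, at most
    ``max_redraws`` times per iteration before raising.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    X = covariates.reset_index(drop=True)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if e.sum() == 0:
        raise ValueError("no events; C-index validation is not possible")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = t.size

    model = cox_fit(t, e, X)
    lp = (X.to_numpy(dtype=float) - X.to_numpy(dtype=float).mean(axis=0)) \
        @ model.summary["coef"].to_numpy()
    apparent = harrell_cindex(t, e, lp)

    Xmat = X.to_numpy(dtype=float)
    optimisms = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        for attempt in range(max_redraws + 1):
            idx = rng.integers(n, size=n)
            if e[idx].sum() == 0:
                n_redrawn += 1
                continue
            try:
                bm = cox_fit(t[idx], e[idx], X.iloc[idx])
            except CoxConvergenceError:
                n_redrawn += 1
                continue
            break
        else:
            raise RuntimeError(
                f"bootstrap iteration {b}: exceeded {max_redraws} redraws"
            )
        beta = bm.summary["coef"].to_numpy()
        mu = Xmat[idx].mean(axis=0)
        c_boot = harrell_cindex(t[idx], e[idx], (Xmat[idx] - mu) @ beta)
        c_orig = harrell_cindex(t, e, (Xmat - mu) @ beta)
        optimisms[b] = c_boot - c_orig
    if n_redrawn:
        logger.info("%d degenerate resample(s) redrawn", n_redrawn)
    optimism = float(optimisms.mean())
    return ValidationResult(
        apparent=float(apparent), optimism=optimism,
        corrected=float(apparent - optimism), n_boot=n_boot, seed=seed,
        n_redrawn=n_redrawn,
    )
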