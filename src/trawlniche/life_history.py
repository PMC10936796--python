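"""Maturity ogives and allometric length-weight fits.

Two estimators in the scikit-learn idiom:

:class:`MaturityOgive`
    Binomial logistic regression of maturity (0/1) on total length,
    maximized in-package by Newton-Raphson/IRLS with step-halving.  The
    length at 50% maturity is ``L50 = −β0/β1`` and the length at 95%
    maturity ``L95 = (ln 19 − β0)/β1``; the coefficient covariance is the
    inverse observed information at the optimum.  Quasi-separated data
    (diverging slope) are flagged, never silently reported.

:class:`LengthWeightModel`
    The allometric power law ``W = a·TL^b`` fitted as ordinary least
    squares of ``ln W`` on ``ln TL``; ``log_a`` is the natural-log
    intercept, ``b`` the allometric exponent, and r² is reported on the
    log-log scale.

Module-level functions (``fit_maturity_ogive``, ``fit_length_weight``,
``predict_maturity``, ``l50_ci_bootstrap``, ``binarize_maturity``) are
thin wrappers for pipeline use.

Maturity stages follow the 7-point elasmobranch scale: stage 1 immature,
2 developing, 3-4 maturing/fertilized, 5-6 pregnant, 7 spent.  The
default binarization counts stages 3-7 as mature; the cut is a named,
overridable parameter because usage varies between studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    ConfigError,
    DegenerateDataError,
    InsufficientDataError,
    InvalidFitError,
    UnstableFitError,
)

#: named maturity binarization schemes: stage → mature?
MATURITY_SCHEMES = {
    "stage3plus": lambda stage: stage >= 3,  # stages 3-7 mature
    "stage4plus": lambda stage: stage >= 4,  # conservative: fertilized onward
}
DEFAULT_SCHEME = "stage3plus"


def binarize_maturity(stage: int, scheme: str = DEFAULT_SCHEME) -> bool:
    """Map a 1-7 maturity stage to binary mature/immature."""
    if scheme not in MATURITY_SCHEMES:
        raise ConfigError(f"unknown maturity scheme {scheme!r}")
    stage = int(stage)
    if not 1 <= stage <= 7:
        raise ValueError(f"maturity stage {stage} outside 1-7")
    return bool(MATURITY_SCHEMES[scheme](stage))


@dataclass
class MaturityRecord:
    total_length: float  # cm
    mature: bool


@dataclass
class OgiveFit:
    """Functional-API view of a fitted maturity ogive."""

    beta0: float
    beta1: float
    l50: float
    l95: float
    cov: np.ndarray  # 2×2 coefficient covariance
    converged: bool
    separation: bool
    n_used: int
    n_mature: int

    def predict(self, length):
        return predict_maturity(self, length)

    def as_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "l50": self.l50,
            "l95": self.l95,
            "cov": np.asarray(self.cov).tolist(),
            "converged": self.converged,
            "separation": self.separation,
            "n_used": self.n_used,
            "n_mature": self.n_mature,
        }


class MaturityOgive(BaseEstimator):
    """Logistic maturity-at-length ogive (Bernoulli GLM, logit link).

    Parameters
    ----------
    tol : float
        Convergence threshold on the score (gradient) norm.
    max_iter : int
        Newton iteration cap.

    Attributes
    ----------
    intercept_ : float
        β0 on the logit scale.
    coef_ : float
        β1, logit units per cm.
    l50_, l95_ : float
        Lengths at 50% and 95% maturity (cm); ``l50_ = −β0/β1``.
    cov_ : ndarray, shape (2, 2)
        Inverse observed information at the optimum.
    converged_, separation_ : bool
    n_iter_, n_used_, n_mature_ : int
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        """Fit to lengths ``X`` (1-d or (n, 1)) and binary maturity ``y``."""
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise ValueError("X must be a length vector or a single-column matrix")
        y = np.asarray(y, dtype=float)
        if y.shape != x.shape:
            raise ValueError("X and y must have the same length")
        if np.any((y != 0) & (y != 1)):
            raise ValueError("y must be binary (0/1)")
        n1 = int(y.sum())
        if n1 < 2 or (len(y) - n1) < 2:
            raise DegenerateDataError(
                "need at least 2 mature and 2 immature records to fit an ogive"
            )
        if np.ptp(x) == 0:
            raise DegenerateDataError("all lengths identical")

        design = np.column_stack([np.ones_like(x), x])
        pbar = y.mean()
        beta = np.array([np.log(pbar / (1.0 - pbar)), 0.0])
        loglik = self._loglik(design, y, beta)
        converged = False
        separation = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            eta = design @ beta
            mu = expit(eta)
            grad = design.T @ (y - mu)
            w = mu * (1.0 - mu)
            info = design.T @ (design * w[:, None])
            if np.linalg.norm(grad) < self.tol:
                converged = True
                break
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                separation = True
                break
            # step-halving: never accept a likelihood decrease
            scale = 1.0
            for _ in range(30):
                candidate = beta + scale * step
                ll = self._loglik(design, y, candidate)
                if ll >= loglik - 1e-12:
                    beta, loglik = candidate, ll
                    break
                scale *= 0.5
            else:
                break
            if np.abs(beta).max() > 1e4:
                separation = True
                break
        else:
            eta = design @ beta
            mu = expit(eta)
            grad = design.T @ (y - mu)
            converged = bool(np.linalg.norm(grad) < self.tol)

        # quasi-separation: fitted probabilities pinned at 0/1 everywhere
        mu = expit(design @ beta)
        if not separation and np.all((mu < 1e-8) | (mu > 1 - 1e-8)):
            separation = True
        if separation:
            converged = False

        mu = expit(design @ beta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        info = design.T @ (design * w[:, None])
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)

        self.intercept_ = float(beta[0])
        self.coef_ = float(beta[1])
        self.cov_ = cov
        self.converged_ = converged
        self.separation_ = separation
        self.n_iter_ = n_iter
        self.n_used_ = int(len(y))
        self.n_mature_ = n1
        if self.coef_ != 0:
            self.l50_ = -self.intercept_ / self.coef_
            self.l95_ = (np.log(0.95 / 0.05) - self.intercept_) / self.coef_
        else:
            self.l50_ = np.nan
            self.l95_ = np.nan
        return self

    @staticmethod
    def _loglik(design, y, beta) -> float:
        eta = design @ beta
        # numerically safe Bernoulli log-likelihood: y·η − log(1+e^η)
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    def predict(self, X):
        """Proportion mature at the given lengths."""
        if not getattr(self, "converged_", False):
            raise InvalidFitError("ogive did not converge; predictions unavailable")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        return expit(self.intercept_ + self.coef_ * x)

    def to_fit(self) -> OgiveFit:
        return OgiveFit(
            beta0=self.intercept_,
            beta1=self.coef_,
            l50=float(self.l50_),
            l95=float(self.l95_),
            cov=self.cov_,
            converged=self.converged_,
            separation=self.separation_,
            n_used=self.n_used_,
            n_mature=self.n_mature_,
        )


def fit_maturity_ogive(records: Sequence[MaturityRecord]) -> OgiveFit:
    """Fit the logistic ogive to (length, mature) records."""
    records = list(records)
    lengths = np.array([r.total_length for r in records], dtype=float)
    mature = np.array([r.mature for r in records], dtype=float)
    return MaturityOgive().fit(lengths, mature).to_fit()


def predict_maturity(fit: OgiveFit, length):
    """Proportion mature at ``length`` under a converged ogive fit."""
    if not fit.converged:
        raise InvalidFitError("ogive did not converge; predictions unavailable")
    out = expit(fit.beta0 + fit.beta1 * np.asarray(length, dtype=float))
    return float(out) if np.ndim(length) == 0 else out


def l50_ci_bootstrap(
    records: Sequence[MaturityRecord],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Nonparametric percentile bootstrap interval for L50.

    Records are resampled with replacement; resamples whose refit fails
    (degenerate class composition, separation, non-convergence) are
    dropped and counted — more than 50% failures aborts with an error.
    Deterministic for a fixed seed.
    """
    if n_boot <= 0:
        raise ConfigError("n_boot must be positive")
    if not 0.0 < level < 1.0:
        raise ConfigError("level must lie in (0, 1)")
    records = list(records)
    point = fit_maturity_ogive(records)
    if not point.converged:
        raise InvalidFitError("full-data ogive did not converge")
    lengths = np.array([r.total_length for r in records], dtype=float)
    mature = np.array([r.mature for r in records], dtype=float)
    n = len(records)
    rng = np.random.default_rng(seed)
    est = MaturityOgive()
    draws = []
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = mature[idx]
        s = yb.sum()
        if s < 2 or n - s < 2 or np.ptp(lengths[idx]) == 0:
            failed += 1
            continue
        est.fit(lengths[idx], yb)
        if est.converged_ and est.coef_ > 0:
            draws.append(est.l50_)
        else:
            failed += 1
    if failed > n_boot / 2:
        raise UnstableFitError(f"{failed}/{n_boot} bootstrap refits failed")
    alpha = 1.0 - level
    lo, hi = np.quantile(np.asarray(draws), [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def l50_ci_delta(fit: OgiveFit, level: float = 0.95) -> tuple[float, float]:
    """Delta-method interval for L50 = −β0/β1, a cross-check utility."""
    from scipy.stats import norm

    if not fit.converged:
        raise InvalidFitError("ogive did not converge")
    g = np.array([-1.0 / fit.beta1, fit.beta0 / fit.beta1**2])
    se = float(np.sqrt(g @ np.asarray(fit.cov) @ g))
    z = norm.ppf(1 - (1 - level) / 2)
    return fit.l50 - z * se, fit.l50 + z * se


# ---------------------------------------------------------------------------
# allometric length-weight

@dataclass
class LWFit:
    """Fitted allometric power law ``W = exp(log_a)·TL^b``."""

    log_a: float  # natural-log intercept, ln(g)
    b: float  # allometric exponent
    r2: float  # on the log-log scale
    resid_sd: float
    n_used: int

    def predict(self, length):
        out = np.exp(self.log_a + self.b * np.log(np.asarray(length, dtype=float)))
        return float(out) if np.ndim(length) == 0 else out

    def as_dict(self) -> dict:
        return {
            "log_a": self.log_a,
            "b": self.b,
            "r2": self.r2,
            "resid_sd": self.resid_sd,
            "n_used": self.n_used,
        }


class LengthWeightModel(BaseEstimator, RegressorMixin):
    """Allometric length-weight regression, ``ln W = log_a + b·ln TL``.

    Fitted by OLS on the log-log scale; ``predict`` returns weight in
    grams via ``exp(log_a_ + b_·ln TL)``.
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        w = np.asarray(y, dtype=float)
        if x.shape != w.shape or x.ndim != 1:
            raise ValueError("lengths and weights must be 1-d of equal length")
        if np.any(x <= 0) or np.any(w <= 0):
            raise ValueError("lengths and weights must be strictly positive")
        if x.size < 3:
            raise InsufficientDataError("need at least 3 (length, weight) pairs")
        lx, lw = np.log(x), np.log(w)
        design = np.column_stack([np.ones_like(lx), lx])
        coef, *_ = np.linalg.lstsq(design, lw, rcond=None)
        resid = lw - design @ coef
        sst = float(np.sum((lw - lw.mean()) ** 2))
        sse = float(resid @ resid)
        self.log_a_ = float(coef[0])
        self.b_ = float(coef[1])
        self.r2_ = 1.0 if sst == 0 else max(0.0, 1.0 - sse / sst)
        dof = x.size - 2
        self.resid_sd_ = float(np.sqrt(sse / dof)) if dof > 0 else 0.0
        self.n_used_ = int(x.size)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        return np.exp(self.log_a_ + self.b_ * np.log(x))

    def to_fit(self) -> LWFit:
        return LWFit(
            log_a=self.log_a_, b=self.b_, r2=self.r2_,
            resid_sd=self.resid_sd_, n_used=self.n_used_,
        )


def fit_length_weight(lengths, weights) -> LWFit:
    """OLS fit of ``ln W`` on ``ln TL``; see :class:`LengthWeightModel`."""
    return LengthWeightModel().fit(np.asarray(lengths), np.asarray(weights)).to_fit()
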