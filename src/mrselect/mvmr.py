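"""Multivariable MR estimation, conditional instrument strength, adjusted Q.

The MVMR estimator regresses the instrument-outcome associations ``Gamma``
on the K columns of the instrument-exposure matrix ``gamma`` by weighted
least squares without an intercept, weights 1/se(Gamma)^2, giving direct
effects of each exposure conditional on the others.

Instrument strength for exposure k *conditional on* the co-included
exposures is measured by a conditional F-statistic: regress gamma[:, k] on
the remaining columns with weights reflecting the sampling variance of the
residualized associations, and scale the weighted residual sum of squares
Q_k by L - K + 1. Weak conditional instruments (F below ~10) make direct
effects unreliable even when every univariable F is large — the situation
the forward-selection algorithm in :mod:`mrselect.selection` is built to
avoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    CollinearExposuresError,
    ConvergenceError,
    EstimationError,
    InsufficientInstrumentsError,
)
from .summary_data import HarmonizedSet

_Z95 = 1.959963984540054


@dataclass
class MVMREstimate:
    """Direct (conditional) effects of K exposures from one MVMR fit."""

    exposure_names: list[str]
    betas: np.ndarray
    ses: np.ndarray
    ci_lows: np.ndarray
    ci_highs: np.ndarray
    pvalues: np.ndarray
    odds_ratios: np.ndarray
    n_snps: int

    def __getitem__(self, name: str) -> dict[str, float]:
        k = self.exposure_names.index(name)
        return {
            "beta": float(self.betas[k]),
            "se": float(self.ses[k]),
            "ci_low": float(self.ci_lows[k]),
            "ci_high": float(self.ci_highs[k]),
            "pvalue": float(self.pvalues[k]),
            "odds_ratio": float(self.odds_ratios[k]),
        }


@dataclass
class ConditionalStrength:
    """Per-exposure conditional F-statistics for one MVMR model."""

    exposure_names: list[str]
    conditional_f: np.ndarray
    threshold: float = 10.0
    all_pass: bool = field(init=False)

    def __post_init__(self) -> None:
        self.conditional_f = np.asarray(self.conditional_f, dtype=float)
        self.all_pass = bool(np.min(self.conditional_f) >= self.threshold)

    def __getitem__(self, name: str) -> float:
        return float(self.conditional_f[self.exposure_names.index(name)])


@dataclass
class AdjustedQ:
    """MVMR analogue of Cochran's Q testing residual pleiotropy."""

    Q_a: float
    df: int
    pvalue: float


def _check_dims(hset: HarmonizedSet, min_extra: int = 1) -> tuple[int, int]:
    L, K = hset.gamma.shape
    if L < K + min_extra:
        raise InsufficientInstrumentsError(
            f"need at least K+{min_extra}={K + min_extra} instruments, have {L}"
        )
    return L, K


def mvmr_ivw(hset: HarmonizedSet) -> MVMREstimate:
    """Weighted least squares of Gamma on the gamma columns (no intercept).

    Weights are 1/se(Gamma)^2; standard errors come from the WLS
    covariance (fixed-effect). With K=1 this reduces exactly to the
    univariable IVW estimate.
    """
    L, K = _check_dims(hset)
    w = 1.0 / hset.Gamma_se**2
    X = hset.gamma
    WX = X * w[:, None]
    xtwx = X.T @ WX
    if np.linalg.matrix_rank(xtwx) < K:
        corr = np.corrcoef(X, rowvar=False)
        offenders = [
            f"{hset.exposure_names[i]}~{hset.exposure_names[j]}"
            for i in range(K) for j in range(i + 1, K)
            if abs(corr[i, j]) > 1 - 1e-8
        ] or hset.exposure_names
        raise CollinearExposuresError(
            f"collinear exposure associations: {offenders}", offenders
        )
    cov = np.linalg.inv(xtwx)
    betas = cov @ (WX.T @ hset.Gamma)
    ses = np.sqrt(np.diag(cov))
    z = betas / ses
    return MVMREstimate(
        exposure_names=list(hset.exposure_names),
        betas=betas,
        ses=ses,
        ci_lows=betas - _Z95 * ses,
        ci_highs=betas + _Z95 * ses,
        pvalues=2.0 * stats.norm.sf(np.abs(z)),
        odds_ratios=np.exp(betas),
        n_snps=L,
    )


def _conditional_f_one(
    hset: HarmonizedSet,
    k: int,
    pairwise_cov: np.ndarray | None,
    tol: float,
    max_iter: int,
) -> float:
    """Conditional F for exposure k via iterated weighted residualization.

    Weights for instrument j are the inverse sampling variance of the
    residual gamma_jk - sum_m delta_m gamma_jm, i.e.
    se_jk^2 + sum_m delta_m^2 se_jm^2 minus cross-covariance terms when a
    between-trait covariance structure is supplied. delta and the weights
    are mutually dependent, so they are iterated to a fixed point.
    """
    L, K = hset.gamma.shape
    y = hset.gamma[:, k]
    others = [m for m in range(K) if m != k]
    X = hset.gamma[:, others]
    se_y = hset.gamma_se[:, k]
    se_X = hset.gamma_se[:, others]

    def solve_wls(wts: np.ndarray) -> np.ndarray:
        WX = X * wts[:, None]
        delta, *_ = np.linalg.lstsq(X.T @ WX, WX.T @ y, rcond=None)
        return delta

    def weights(delta: np.ndarray) -> np.ndarray:
        var = se_y**2 + (se_X**2) @ delta**2
        if pairwise_cov is not None:
            rho = np.asarray(pairwise_cov, dtype=float)
            # cross terms: -2 delta_m cov(k,m) + delta_m delta_m' cov(m,m')
            for a, m in enumerate(others):
                var -= 2.0 * delta[a] * rho[k, m] * se_y * se_X[:, a]
                for b, mp in enumerate(others):
                    if b != a:
                        var += delta[a] * delta[b] * rho[m, mp] * se_X[:, a] * se_X[:, b]
        if np.any(var <= 0):
            raise EstimationError("non-positive residual variance in conditional F")
        return 1.0 / var

    delta = solve_wls(np.ones(L))
    for _ in range(max_iter):
        w = weights(delta)
        new = solve_wls(w)
        if np.max(np.abs(new - delta)) < tol:
            delta = new
            break
        delta = new
    else:
        raise ConvergenceError(
            f"conditional F for {hset.exposure_names[k]!r} did not converge "
            f"within {max_iter} iterations",
            last_iterate=delta,
        )
    w = weights(delta)
    resid = y - X @ delta
    q_tilde = float(np.sum(w * resid**2))
    return q_tilde / (L - K + 1)


def conditional_f(
    hset: HarmonizedSet,
    pairwise_cov: np.ndarray | None = None,
    threshold: float = 10.0,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> ConditionalStrength:
    """Conditional F-statistic for every exposure in an MVMR model.

    ``pairwise_cov`` is an optional K x K between-trait correlation used to
    scale cross-covariance terms with the per-variant SEs; with summary data
    it is usually unavailable and defaults to zero.
    """
    L, K = _check_dims(hset)
    if K < 2:
        raise EstimationError("conditional F requires at least 2 exposures")
    fs = np.array([
        _conditional_f_one(hset, k, pairwise_cov, tol, max_iter)
        for k in range(K)
    ])
    return ConditionalStrength(list(hset.exposure_names), fs, threshold)


def adjusted_q(hset: HarmonizedSet, estimate: MVMREstimate) -> AdjustedQ:
    """Adjusted Q-statistic for residual heterogeneity after an MVMR fit.

    Q_a sums weighted squared residuals Gamma_j - sum_k beta_k gamma_jk with
    weights 1/(se(Gamma_j)^2 + sum_k beta_k^2 se(gamma_jk)^2); under no
    residual pleiotropy Q_a ~ chi-square(L - K).
    """
    L, K = hset.gamma.shape
    if L <= K:
        raise EstimationError(f"adjusted Q needs L > K (L={L}, K={K})")
    if list(estimate.exposure_names) != list(hset.exposure_names):
        raise EstimationError("estimate does not match the harmonized set")
    betas = np.asarray(estimate.betas, dtype=float)
    resid = hset.Gamma - hset.gamma @ betas
    var = hset.Gamma_se**2 + (hset.gamma_se**2) @ betas**2
    Q_a = float(np.sum(resid**2 / var))
    df = L - K
    return AdjustedQ(Q_a, df, float(stats.chi2.sf(Q_a, df)))
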