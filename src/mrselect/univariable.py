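"""Univariable two-sample MR estimators and heterogeneity diagnostics.

Implements the Wald ratio, inverse-variance weighted (IVW) meta-analysis,
MR-Egger regression, the weighted median, and the weighted mode (ZEMPA)
estimator, together with the mean instrument F-statistic, Cochran's Q and a
Bonferroni-corrected single-pass heterogeneity outlier filter.

Notation: for instrument j, ``gamma_j`` is the variant-exposure association
(SD units of a z-standardized exposure) with standard error ``se(gamma_j)``,
and ``Gamma_j`` the variant-outcome association (log-odds for binary
outcomes) with standard error ``se(Gamma_j)``. The per-variant Wald ratio is
``theta_j = Gamma_j / gamma_j`` with first-order (delta-method) standard
error ``se(Gamma_j)/|gamma_j|``; inverse-variance weights are then
``w_j = gamma_j^2 / se(Gamma_j)^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateInstrumentError,
    EstimationError,
    InsufficientInstrumentsError,
)
from .summary_data import HarmonizedSet

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class RatioEstimate:
    """Single-instrument Wald ratio with first-order SE and IVW weight."""

    variant_id: str
    theta_j: float
    se_j: float
    weight_j: float


@dataclass
class MREstimate:
    """A causal-effect estimate on the beta (log-odds) and odds-ratio scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    n_snps: int
    status: str = "ok"
    message: str = ""

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snps: int) -> "MREstimate":
        lo, hi = beta - _Z95 * se, beta + _Z95 * se
        p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
        return cls(
            method=method,
            beta=float(beta),
            se=float(se),
            ci_low=float(lo),
            ci_high=float(hi),
            pvalue=float(p),
            odds_ratio=float(np.exp(beta)),
            or_ci_low=float(np.exp(lo)),
            or_ci_high=float(np.exp(hi)),
            n_snps=int(n_snps),
        )

    @classmethod
    def unavailable(cls, method: str, message: str) -> "MREstimate":
        nan = float("nan")
        return cls(method, nan, nan, nan, nan, nan, nan, nan, nan, 0,
                   status="insufficient_instruments", message=message)


@dataclass
class HeterogeneityResult:
    """Cochran's Q with per-variant contributions and flagged outliers."""

    Q: float
    df: int
    pvalue: float
    per_snp_q: np.ndarray = field(repr=False)
    outlier_ids: list[str] = field(default_factory=list)


def _check_k1(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if hset.n_exposures != 1:
        raise EstimationError("univariable estimators require a K=1 harmonized set")
    return (
        hset.gamma[:, 0],
        hset.gamma_se[:, 0],
        hset.Gamma,
        hset.Gamma_se,
    )


def wald_ratio(
    gamma: float, gamma_se: float, Gamma: float, Gamma_se: float,
    variant_id: str = "",
) -> RatioEstimate:
    """Per-variant causal estimate Gamma/gamma with first-order SE.

    The delta-method SE ignores the uncertainty of ``gamma`` (standard
    summary-MR practice for strong instruments).
    """
    if gamma == 0:
        raise DegenerateInstrumentError("variant-exposure association is zero")
    theta = Gamma / gamma
    se = Gamma_se / abs(gamma)
    return RatioEstimate(variant_id, float(theta), float(se), float(1.0 / se**2))


def _ratios(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g, _, G, Gse = _check_k1(hset)
    if np.any(g == 0):
        raise DegenerateInstrumentError("zero variant-exposure association in set")
    theta = G / g
    se = Gse / np.abs(g)
    return theta, se, 1.0 / se**2


def ivw(
    hset: HarmonizedSet,
    model: Literal["fixed", "multiplicative_random"] = "fixed",
) -> MREstimate:
    """Inverse-variance weighted average of the per-variant Wald ratios.

    Equivalent to weighted least squares of Gamma on gamma through the
    origin with weights 1/se(Gamma)^2. The multiplicative random-effects
    model scales the fixed-effect SE by max(1, sqrt(Q/(L-1))).
    """
    theta, _, w = _ratios(hset)
    L = len(theta)
    if L < 2:
        raise InsufficientInstrumentsError("IVW requires at least 2 instruments")
    beta = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    if model == "multiplicative_random":
        Q = float(np.sum(w * (theta - beta) ** 2))
        se *= max(1.0, np.sqrt(Q / (L - 1)))
    elif model != "fixed":
        raise ConfigurationError(f"unknown IVW model {model!r}")
    return MREstimate.from_beta_se("ivw", beta, se, L)


def mr_egger(hset: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: IVW regression with a pleiotropy intercept.

    Instrument orientation is fixed so that all gamma_j >= 0 (rows with
    negative gamma have both gamma and Gamma sign-flipped), making the
    intercept interpretable as average directional pleiotropy. Returns
    ``(slope, intercept)`` estimates. Standard errors come from the WLS
    covariance scaled by max(1, residual sigma).
    """
    g, _, G, Gse = _check_k1(hset)
    L = len(g)
    if L < 3:
        raise InsufficientInstrumentsError("MR-Egger requires at least 3 instruments")
    sign = np.where(g < 0, -1.0, 1.0)
    x = g * sign
    y = G * sign
    w = 1.0 / Gse**2
    if np.allclose(x, x[0]):
        raise EstimationError("all oriented gamma equal; Egger design is collinear")
    X = np.column_stack([np.ones(L), x])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ y)
    resid = y - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (L - 2)) if L > 2 else 0.0
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    slope = MREstimate.from_beta_se("egger_slope", coef[1], np.sqrt(cov[1, 1]), L)
    intercept = MREstimate.from_beta_se("egger_intercept", coef[0], np.sqrt(cov[0, 0]), L)
    return slope, intercept


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median of theta under weights w."""
    order = np.argsort(theta, kind="stable")
    t = theta[order]
    p = w[order] / np.sum(w)
    s = np.cumsum(p) - 0.5 * p
    if 0.5 <= s[0]:
        return float(t[0])
    if 0.5 >= s[-1]:
        return float(t[-1])
    k = np.searchsorted(s, 0.5) - 1
    return float(t[k] + (t[k + 1] - t[k]) * (0.5 - s[k]) / (s[k + 1] - s[k]))


def _parametric_boot(
    hset: HarmonizedSet,
    n_boot: int,
    seed: int,
    point_fn,
) -> float:
    """Bootstrap SE: resample (gamma*, Gamma*) from their sampling normals."""
    g, gse, G, Gse = _check_k1(hset)
    rng = np.random.default_rng(seed)
    L = len(g)
    gstar = rng.normal(g, gse, size=(n_boot, L))
    Gstar = rng.normal(G, Gse, size=(n_boot, L))
    gstar = np.where(gstar == 0, np.finfo(float).tiny, gstar)
    thetas = Gstar / gstar
    ws = (gstar / Gse) ** 2
    ests = np.array([point_fn(thetas[b], ws[b]) for b in range(n_boot)])
    return float(np.std(ests, ddof=1)) if n_boot > 1 else float("nan")


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of the Wald ratios (valid if >50% of weight is valid).

    The estimate interpolates the ordered ratios at standardized cumulative
    weight 0.5; the SE comes from a seeded parametric bootstrap.
    """
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")
    theta, _, w = _ratios(hset)
    if len(theta) < 3:
        raise InsufficientInstrumentsError("weighted median requires >= 3 instruments")
    beta = _weighted_median_point(theta, w)
    se = _parametric_boot(hset, n_boot, seed, _weighted_median_point)
    return MREstimate.from_beta_se("weighted_median", beta, se, len(theta))


def modified_silverman_bandwidth(theta: np.ndarray) -> float:
    """0.9 * min(sd, IQR/1.34) * L^(-1/5); falls back to sd if IQR is zero."""
    sd = float(np.std(theta, ddof=1))
    iqr = float(np.subtract(*np.percentile(theta, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * len(theta) ** -0.2


def _weighted_mode_point(
    theta: np.ndarray, w: np.ndarray, bandwidth_multiplier: float, grid_size: int
) -> float:
    h = bandwidth_multiplier * modified_silverman_bandwidth(theta)
    if h == 0:
        if np.ptp(theta) == 0:  # exact consensus
            return float(theta[0])
        raise EstimationError("zero kernel bandwidth with dispersed ratios")
    lo, hi = theta.min() - 3 * h, theta.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    z = (grid[:, None] - theta[None, :]) / h
    dens = np.exp(-0.5 * z**2) @ w
    return float(grid[int(np.argmax(dens))])


def weighted_mode(
    hset: HarmonizedSet,
    bandwidth_multiplier: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    grid_size: int = 1024,
) -> MREstimate:
    """Weighted modal ratio estimate (ZEMPA: the largest cluster is valid).

    A normal-kernel weighted density over the ratios is maximized on a fine
    grid; the bandwidth is ``bandwidth_multiplier`` times the modified
    Silverman rule. SE via seeded parametric bootstrap.
    """
    if bandwidth_multiplier <= 0:
        raise ConfigurationError("bandwidth_multiplier must be positive")
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")
    theta, _, w = _ratios(hset)
    if len(theta) < 3:
        raise InsufficientInstrumentsError("weighted mode requires >= 3 instruments")
    beta = _weighted_mode_point(theta, w, bandwidth_multiplier, grid_size)
    se = _parametric_boot(
        hset, n_boot, seed,
        lambda t, ww: _weighted_mode_point(t, ww, bandwidth_multiplier, grid_size),
    )
    return MREstimate.from_beta_se("weighted_mode", beta, se, len(theta))


def mean_instrument_f(table) -> float:
    """Mean per-variant F-statistic, (beta/se)^2 averaged over variants.

    Accepts an :class:`AssociationTable` or a K=1 :class:`HarmonizedSet`.
    """
    if isinstance(table, HarmonizedSet):
        g, gse, _, _ = _check_k1(table)
        return float(np.mean((g / gse) ** 2))
    if len(table.df) == 0:
        raise EstimationError("empty association table")
    z = table.df["beta"].to_numpy() / table.df["se"].to_numpy()
    return float(np.mean(z**2))


def cochran_q(hset: HarmonizedSet) -> HeterogeneityResult:
    """Cochran's Q heterogeneity of the Wald ratios around the IVW estimate."""
    theta, _, w = _ratios(hset)
    L = len(theta)
    if L < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >= 2 instruments")
    beta = float(np.sum(w * theta) / np.sum(w))
    per = w * (theta - beta) ** 2
    Q = float(np.sum(per))
    df = L - 1
    return HeterogeneityResult(Q, df, float(stats.chi2.sf(Q, df)), per)


def remove_outliers(
    hset: HarmonizedSet, alpha: float = 0.05
) -> tuple[HarmonizedSet, HeterogeneityResult]:
    """Single-pass heterogeneity outlier filter.

    Variant j is flagged when the upper-tail chi-square(1) p-value of its Q
    contribution falls below the Bonferroni-corrected threshold alpha/L.
    Returns the filtered set and the diagnostic with ``outlier_ids`` filled.
    """
    if hset.n_variants < 3:
        raise InsufficientInstrumentsError("outlier removal requires >= 3 instruments")
    het = cochran_q(hset)
    L = hset.n_variants
    pvals = stats.chi2.sf(het.per_snp_q, 1)
    flagged = pvals < bonferroni_threshold(alpha, L)
    het.outlier_ids = [str(v) for v in hset.variant_ids[flagged]]
    if flagged.all():
        raise EstimationError(
            "every instrument flagged as a heterogeneity outlier; refusing to "
            "return an empty set"
        )
    return hset.subset(~flagged), het


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected significance threshold alpha/m."""
    if not (0 < alpha < 1):
        raise ConfigurationError("alpha must lie in (0, 1)")
    if m < 1:
        raise ConfigurationError("m must be a positive integer")
    return alpha / m


@dataclass
class UnivariableConfig:
    """Configuration for the combined univariable analysis."""

    methods: Sequence[str] = ("ivw", "egger", "median", "mode")
    ivw_model: str = "fixed"
    n_boot: int = 1000
    seed: int = 0
    bandwidth_multiplier: float = 1.0
    remove_outliers: bool = False
    outliers_before_sensitivity: bool = True
    outlier_alpha: float = 0.05


@dataclass
class UnivariableResult:
    """Estimates, heterogeneity and mean instrument strength for one pair."""

    exposure: str
    outcome: str
    estimates: list[MREstimate]
    heterogeneity: HeterogeneityResult
    mean_f: float
    n_outliers_removed: int = 0


def run_univariable_suite(
    hset: HarmonizedSet, config: UnivariableConfig | None = None
) -> UnivariableResult:
    """Run IVW, MR-Egger, weighted median and weighted mode on one exposure.

    With ``remove_outliers`` set, the heterogeneity filter runs either
    before all estimators (default) or after IVW only, re-fitting the
    sensitivity estimators on the filtered set.
    """
    config = config or UnivariableConfig()
    working = hset
    removed = 0
    het = cochran_q(hset)
    if config.remove_outliers and config.outliers_before_sensitivity and hset.n_variants >= 3:
        working, het = remove_outliers(hset, config.outlier_alpha)
        removed = hset.n_variants - working.n_variants

    estimates: list[MREstimate] = []
    for method in config.methods:
        try:
            if method == "ivw":
                estimates.append(ivw(working, model=config.ivw_model))
            elif method == "egger":
                slope, intercept = mr_egger(working)
                estimates.extend([slope, intercept])
            elif method == "median":
                estimates.append(
                    weighted_median(working, config.n_boot, config.seed)
                )
            elif method == "mode":
                estimates.append(
                    weighted_mode(
                        working, config.bandwidth_multiplier,
                        config.n_boot, config.seed,
                    )
                )
            else:
                raise ConfigurationError(f"unknown method {method!r}")
        except InsufficientInstrumentsError as exc:
            estimates.append(MREstimate.unavailable(method, str(exc)))

    if config.remove_outliers and not config.outliers_before_sensitivity and hset.n_variants >= 3:
        working2, het = remove_outliers(hset, config.outlier_alpha)
        removed = hset.n_variants - working2.n_variants
        if removed:
            refit = run_univariable_suite(
                working2,
                UnivariableConfig(
                    methods=config.methods, ivw_model=config.ivw_model,
                    n_boot=config.n_boot, seed=config.seed,
                    bandwidth_multiplier=config.bandwidth_multiplier,
                ),
            )
            estimates = refit.estimates

    return UnivariableResult(
        exposure=hset.exposure_names[0],
        outcome=hset.outcome_name,
        estimates=estimates,
        heterogeneity=het,
        mean_f=mean_instrument_f(hset),
        n_outliers_removed=removed,
    )
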