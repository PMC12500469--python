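"""Synthetic two-sample GWAS summary data with known causal truth.

The generator draws independent biallelic variants under Hardy-Weinberg
equilibrium, builds correlated z-standardized exposures from per-allele
effects, a shared confounder and optional exposure-to-exposure (mediation)
paths, and produces a binary outcome from a liability that combines the
exposures' causal effects, direct variant effects (horizontal pleiotropy)
and the confounder. Exposure and outcome samples are disjoint cohorts (a
two-sample design), and the outcome GWAS is run on an incident-style
case-control subsample with a configurable case:control ratio.

A prevalent-case mechanism is included: each case is retained with a
probability that depends on its exposure values (survival-dependent
recruitment), which induces selection bias in downstream MR estimates even
for exposures with no causal effect.

Because the outcome is binary, per-variant log-odds associations are
attenuated relative to liability-scale coefficients (non-collapsibility of
the odds ratio). The truth record therefore also carries the implied
*marginal log-odds* per-variant effects, which are the estimands of any
summary-data analysis run on the generated outcome associations.

All randomness flows from one integer seed through named substreams, so
identical configurations reproduce byte-identical tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy import stats

from .errors import ConfigurationError, InputError
from .summary_data import COLUMNS, AssociationTable

FIXTURES = ("null", "valid_instruments", "pleiotropic", "mediator_13", "selection_bias")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG stream of a base seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())])
    )


@dataclass
class SelectionModel:
    """Survival-dependent case retention: logit(P(observed | case)) = a + X s."""

    survival_coefficients: np.ndarray
    retention_target: float = 0.5

    def __post_init__(self) -> None:
        self.survival_coefficients = np.asarray(self.survival_coefficients, float)
        if not (0 < self.retention_target < 1):
            raise ConfigurationError("retention_target must lie in (0, 1)")


@dataclass
class SimulationConfig:
    """Full specification of one synthetic two-sample MR study."""

    n_variants: int
    n_exposures: int
    n_exposure_sample: int
    n_outcome_sample: int
    effect_matrix: np.ndarray  # J x K per-allele effects on (raw) exposures
    maf_range: tuple[float, float] = (0.1, 0.4)
    confounder_effects: np.ndarray | None = None  # length K+1, last entry: outcome
    causal_effects: np.ndarray | None = None  # length K, per-SD effects on liability
    pleiotropy: np.ndarray | None = None  # length J, direct variant->liability
    mediation_map: Mapping[int, Mapping[int, float]] | None = None  # target -> {source: coef}
    outcome_model: str = "logistic"  # or "liability_threshold"
    baseline_prevalence: float = 0.08
    selection: SelectionModel | None = None
    case_control_ratio: float = 10.0
    seed: int = 0
    exposure_names: list[str] | None = None
    outcome_name: str = "outcome"

    def __post_init__(self) -> None:
        J, K = self.n_variants, self.n_exposures
        self.effect_matrix = np.asarray(self.effect_matrix, float)
        if self.effect_matrix.shape != (J, K):
            raise ConfigurationError(f"effect_matrix must be {J}x{K}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.confounder_effects is None:
            self.confounder_effects = np.zeros(K + 1)
        self.confounder_effects = np.asarray(self.confounder_effects, float)
        if self.confounder_effects.shape != (K + 1,):
            raise ConfigurationError("confounder_effects must have length K+1")
        if self.causal_effects is None:
            self.causal_effects = np.zeros(K)
        self.causal_effects = np.asarray(self.causal_effects, float)
        if self.pleiotropy is None:
            self.pleiotropy = np.zeros(J)
        self.pleiotropy = np.asarray(self.pleiotropy, float)
        if not (0 < self.baseline_prevalence < 1):
            raise ConfigurationError("baseline_prevalence must lie in (0, 1)")
        if self.outcome_model not in ("logistic", "liability_threshold"):
            raise ConfigurationError(f"unknown outcome_model {self.outcome_model!r}")
        if self.mediation_map:
            for tgt, srcs in self.mediation_map.items():
                for src in srcs:
                    if src >= tgt:
                        raise ConfigurationError(
                            "mediation_map must be acyclic: source index < target index"
                        )
        if self.exposure_names is None:
            self.exposure_names = [f"exposure_{k}" for k in range(K)]


@dataclass
class Cohort:
    """Individual-level draw: genotypes, standardized exposures, outcome."""

    genotypes: np.ndarray  # n x J dosages 0/1/2
    exposures: np.ndarray  # n x K, z-standardized
    confounder: np.ndarray
    liability: np.ndarray
    outcome: np.ndarray  # 0/1
    exposure_scales: np.ndarray  # raw SD of each exposure before standardization


@dataclass
class SimulatedStudy:
    """Two-sample summary data plus the generating truth."""

    exposure_tables: list[AssociationTable]
    outcome_table: AssociationTable
    truth: dict
    realized: dict
    companion_tables: dict = field(default_factory=dict)


def variant_frame(J: int) -> pd.DataFrame:
    """Deterministic variant metadata: ids, positions spaced beyond any
    pruning window (2e7 bp, cycling 22 chromosomes), fixed A/G alleles."""
    chrom = (np.arange(J) % 22 + 1).astype(str)
    pos = (np.arange(J) // 22 + 1) * 20_000_000
    return pd.DataFrame(
        {
            "variant_id": [f"snp_{j + 1:04d}" for j in range(J)],
            "chromosome": chrom,
            "position": pos,
            "effect_allele": "A",
            "other_allele": "G",
        }
    )


def simulate_genotypes(
    J: int, n: int, maf_range: tuple[float, float], seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """HWE dosages: per-variant maf ~ U(maf_range), dosage ~ Binomial(2, maf).

    Returns ``(genotypes, mafs)``. Pass a Generator to reuse a stream (the
    study generator draws mafs once and shares them across cohorts).
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ConfigurationError("maf_range must lie within (0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "genotypes")
    mafs = rng.uniform(lo, hi, J)
    G = rng.binomial(2, mafs, size=(n, J)).astype(float)
    return G, mafs


def _build_exposures(cfg: SimulationConfig, G: np.ndarray, U: np.ndarray,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = len(U)
    K = cfg.n_exposures
    X = np.empty((n, K))
    scales = np.empty(K)
    for k in range(K):
        raw = G @ cfg.effect_matrix[:, k] + cfg.confounder_effects[k] * U
        if cfg.mediation_map and k in cfg.mediation_map:
            for src, coef in cfg.mediation_map[k].items():
                raw = raw + coef * X[:, src]
        raw = raw + rng.standard_normal(n)
        sd = raw.std()
        if sd == 0:
            raise InputError(f"degenerate exposure {k}: zero variance")
        X[:, k] = (raw - raw.mean()) / sd
        scales[k] = sd
    return X, scales


def simulate_cohort(
    cfg: SimulationConfig,
    sample: str = "exposure",
    mafs: np.ndarray | None = None,
) -> Cohort:
    """Draw one individual-level cohort (exposure or outcome sample).

    The two samples use distinct substreams of the configured seed, so the
    cohorts are disjoint by construction (a two-sample design). Exposures
    are z-standardized; the binary outcome is calibrated so the population
    case fraction matches ``baseline_prevalence``.
    """
    if sample not in ("exposure", "outcome"):
        raise ConfigurationError("sample must be 'exposure' or 'outcome'")
    n = cfg.n_exposure_sample if sample == "exposure" else cfg.n_outcome_sample
    rng = substream(cfg.seed, f"cohort_{sample}")
    if mafs is None:
        _, mafs = simulate_genotypes(cfg.n_variants, 1, cfg.maf_range, substream(cfg.seed, "mafs"))
    G = rng.binomial(2, mafs, size=(n, cfg.n_variants)).astype(float)
    U = rng.standard_normal(n)
    X, scales = _build_exposures(cfg, G, U, rng)
    eta = X @ cfg.causal_effects + G @ cfg.pleiotropy + cfg.confounder_effects[-1] * U
    if not np.all(np.isfinite(eta)):
        raise InputError("non-finite outcome liability")
    if cfg.outcome_model == "logistic":
        alpha0 = _solve_logistic_intercept(eta, cfg.baseline_prevalence)
        Y = (rng.random(n) < expit(alpha0 + eta)).astype(float)
    else:
        liab = eta + rng.standard_normal(n)
        thr = np.quantile(liab, 1.0 - cfg.baseline_prevalence)
        Y = (liab > thr).astype(float)
    return Cohort(G, X, U, eta, Y, scales)


def _solve_logistic_intercept(eta: np.ndarray, prevalence: float) -> float:
    lo, hi = -40.0, 40.0
    f = lambda a: expit(a + eta).mean() - prevalence
    return brentq(f, lo, hi, xtol=1e-10)


# ---------------------------------------------------------------------------
# per-variant GWAS scans

def _ols_scan(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-variant simple linear regression (beta, se, pvalue)."""
    n = len(y)
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", Gc, Gc)
    mono = sxx <= 0
    sxx_safe = np.where(mono, np.nan, sxx)
    sxy = Gc.T @ yc
    beta = sxy / sxx_safe
    rss = np.maximum(np.sum(yc**2) - beta * sxy, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx_safe)
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return beta, se, p


def _logistic_scan(
    G: np.ndarray, y: np.ndarray, max_iter: int = 40, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-variant simple logistic regression via Newton-Raphson.

    Fits logit P(y=1) = a_j + b_j g_j independently for every variant j;
    identical to column-by-column IRLS but a few hundred times faster.
    """
    n, J = G.shape
    ybar = y.mean()
    a = np.full(J, np.log(ybar / (1 - ybar)))
    b = np.zeros(J)
    yv = y[:, None]
    for _ in range(max_iter):
        mu = expit(a + G * b)
        w = mu * (1.0 - mu)
        r = yv - mu
        s_a = r.sum(axis=0)
        s_b = np.einsum("ij,ij->j", G, r)
        i_aa = w.sum(axis=0)
        i_ab = np.einsum("ij,ij->j", w, G)
        i_bb = np.einsum("ij,ij->j", w, G * G)
        det = i_aa * i_bb - i_ab**2
        with np.errstate(divide="ignore", invalid="ignore"):
            da = (i_bb * s_a - i_ab * s_b) / det
            db = (i_aa * s_b - i_ab * s_a) / det
        da = np.nan_to_num(da)
        db = np.nan_to_num(db)
        a += da
        b += db
        if max(np.max(np.abs(da)), np.max(np.abs(db))) < tol:
            break
    mu = expit(a + G * b)
    w = mu * (1.0 - mu)
    i_aa = w.sum(axis=0)
    i_ab = np.einsum("ij,ij->j", w, G)
    i_bb = np.einsum("ij,ij->j", w, G * G)
    det = i_aa * i_bb - i_ab**2
    mono = G.std(axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(det > 0, i_aa / det, np.nan))
    beta = np.where(mono, np.nan, b)
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return beta, se, p


def compute_summary_stats(
    genotypes: np.ndarray,
    trait: np.ndarray,
    trait_type: str,
    variants: pd.DataFrame | None = None,
    trait_name: str = "trait",
) -> AssociationTable:
    """Per-variant GWAS of one trait: OLS for continuous, logistic for binary.

    Monomorphic variants (zero dosage variance) are dropped with their
    count recorded nowhere but the table length. Effect-allele frequencies
    are the sample frequencies of the counted allele.
    """
    n, J = genotypes.shape
    if variants is None:
        variants = variant_frame(J)
    if trait_type == "continuous":
        beta, se, p = _ols_scan(genotypes, trait)
    elif trait_type == "binary":
        beta, se, p = _logistic_scan(genotypes, trait)
    else:
        raise ConfigurationError(f"unknown trait_type {trait_type!r}")
    eaf = genotypes.mean(axis=0) / 2.0
    df = variants.copy()
    df["eaf"] = eaf
    df["beta"] = beta
    df["se"] = se
    df["pvalue"] = np.clip(p, np.finfo(float).tiny, 1.0)
    df["n"] = n
    keep = np.isfinite(beta) & np.isfinite(se) & (se > 0)
    df = df[keep].reset_index(drop=True)
    if df.empty:
        raise InputError(f"{trait_name}: all variants monomorphic or degenerate")
    return AssociationTable(trait_name, trait_type, df[COLUMNS])


def linear_to_logodds(
    beta: np.ndarray | float, se: np.ndarray | float, case_fraction: float
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Rescale linear-model associations with a binary trait to log-odds.

    Divides beta and se by mu(1-mu) where mu is the case fraction — the
    first-order conversion used when a binary outcome is analyzed with a
    linear mixed model and interpreted on the odds-ratio scale.
    """
    if not (0 < case_fraction < 1):
        raise ConfigurationError("case_fraction must lie strictly in (0, 1)")
    scale = 1.0 / (case_fraction * (1.0 - case_fraction))
    return beta * scale, se * scale


@dataclass
class CaseControlSample:
    """Row indices of a case-control subsample plus design metadata."""

    indices: np.ndarray
    n_cases: int
    n_controls: int
    design: str  # "incident" | "prevalent"


def apply_case_selection(
    cohort: Cohort,
    survival_coefficients: np.ndarray | None,
    ratio: float,
    seed: int | np.random.Generator,
    retention_target: float = 0.5,
) -> CaseControlSample:
    """Construct a case-control subsample, optionally with survival bias.

    With nonzero ``survival_coefficients`` each case is retained with
    probability inverse-logit(a + X s), the intercept a solved so the mean
    retention equals ``retention_target`` (prevalent design). Controls are
    drawn uniformly from non-cases at ``ratio`` controls per retained case,
    capped at the available pool. With zero coefficients the design is the
    unbiased incident analogue.
    """
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "selection")
    cases = np.flatnonzero(cohort.outcome == 1)
    noncases = np.flatnonzero(cohort.outcome == 0)
    if len(cases) == 0:
        raise InputError("cohort contains no cases")
    design = "incident"
    if survival_coefficients is not None and np.any(np.asarray(survival_coefficients) != 0):
        design = "prevalent"
        s = np.asarray(survival_coefficients, float)
        r = cohort.exposures[cases] @ s
        a = brentq(lambda a0: expit(a0 + r).mean() - retention_target, -40, 40)
        cases = cases[rng.random(len(cases)) < expit(a + r)]
        if len(cases) == 0:
            raise InputError("no cases retained under the selection model")
    n_controls = min(int(round(ratio * len(cases))), len(noncases))
    controls = rng.choice(noncases, size=n_controls, replace=False)
    idx = np.concatenate([cases, controls])
    return CaseControlSample(idx, len(cases), n_controls, design)


def marginal_logodds_effects(
    cohort: Cohort, cfg: SimulationConfig, direct_only: bool = False
) -> np.ndarray:
    """True per-variant marginal log-odds slopes implied by the generator.

    For variant j with total per-allele liability effect d_j (direct
    pleiotropy plus exposure-mediated paths), the marginal log-odds slope
    solves the population logistic score equations over g in {0,1,2} with
    HWE genotype weights, integrating the remaining liability empirically.
    With ``direct_only`` the exposure-mediated component is excluded,
    giving the marginal-scale horizontal-pleiotropy effect.
    """
    if cfg.outcome_model != "logistic":
        raise ConfigurationError("marginal effects implemented for the logistic model")
    mediated = np.zeros(cfg.n_variants) if direct_only else (
        (cfg.effect_matrix / cohort.exposure_scales[None, :]) @ cfg.causal_effects
    )
    d = cfg.pleiotropy + mediated
    alpha0 = _solve_logistic_intercept(cohort.liability, cfg.baseline_prevalence)
    mafs = cohort.genotypes.mean(axis=0) / 2.0
    out = np.empty(cfg.n_variants)
    gvals = np.array([0.0, 1.0, 2.0])
    for j in range(cfg.n_variants):
        eta_minus = cohort.liability - d[j] * cohort.genotypes[:, j]
        P = np.array([
            expit(alpha0 + eta_minus + d[j] * g).mean() for g in gvals
        ])
        q = np.array([
            (1 - mafs[j]) ** 2, 2 * mafs[j] * (1 - mafs[j]), mafs[j] ** 2
        ])
        # solve logistic score equations sum_g q_g (P_g - expit(a+bg)) (1,g)' = 0
        a, b = np.log(P[1] / (1 - P[1])), 0.0
        for _ in range(50):
            mu = expit(a + b * gvals)
            w = q * mu * (1 - mu)
            r = q * (P - mu)
            s = np.array([r.sum(), (r * gvals).sum()])
            info = np.array([
                [w.sum(), (w * gvals).sum()],
                [(w * gvals).sum(), (w * gvals**2).sum()],
            ])
            step = np.linalg.solve(info, s)
            a += step[0]
            b += step[1]
            if np.max(np.abs(step)) < 1e-12:
                break
        out[j] = b
    return out


# ---------------------------------------------------------------------------
# study assembly and canonical fixtures

def simulate_study(cfg: SimulationConfig, compute_marginal_truth: bool = False) -> SimulatedStudy:
    """Generate a full two-sample study: K exposure GWAS + outcome GWAS.

    Exposure associations come from OLS on the exposure cohort; outcome
    associations from per-variant logistic regression on a case-control
    subsample of the disjoint outcome cohort (the configured selection
    model, if any, defines the primary outcome table; an unbiased incident
    companion table is always provided when a selection model is present).
    """
    _, mafs = simulate_genotypes(cfg.n_variants, 1, cfg.maf_range, substream(cfg.seed, "mafs"))
    variants = variant_frame(cfg.n_variants)

    exp_cohort = simulate_cohort(cfg, "exposure", mafs)
    tables = [
        compute_summary_stats(
            exp_cohort.genotypes, exp_cohort.exposures[:, k], "continuous",
            variants, cfg.exposure_names[k],
        )
        for k in range(cfg.n_exposures)
    ]

    out_cohort = simulate_cohort(cfg, "outcome", mafs)
    rng_sel = substream(cfg.seed, "selection")

    def outcome_table(sample: CaseControlSample, name: str) -> AssociationTable:
        idx = sample.indices
        return compute_summary_stats(
            out_cohort.genotypes[idx], out_cohort.outcome[idx], "binary",
            variants, name,
        )

    companion: dict[str, AssociationTable] = {}
    if cfg.selection is not None:
        prevalent = apply_case_selection(
            out_cohort, cfg.selection.survival_coefficients,
            cfg.case_control_ratio, rng_sel, cfg.selection.retention_target,
        )
        incident = apply_case_selection(
            out_cohort, None, cfg.case_control_ratio, rng_sel
        )
        main = outcome_table(prevalent, cfg.outcome_name)
        companion["incident"] = outcome_table(incident, cfg.outcome_name + "_incident")
        realized = {
            "n_cases": prevalent.n_cases,
            "n_controls": prevalent.n_controls,
            "design": "prevalent",
            "n_cases_incident": incident.n_cases,
            "n_controls_incident": incident.n_controls,
        }
    else:
        incident = apply_case_selection(out_cohort, None, cfg.case_control_ratio, rng_sel)
        main = outcome_table(incident, cfg.outcome_name)
        realized = {
            "n_cases": incident.n_cases,
            "n_controls": incident.n_controls,
            "design": "incident",
        }

    truth = {
        "config": cfg,
        "mafs": mafs,
        "causal_effects": cfg.causal_effects.copy(),
        "pleiotropy": cfg.pleiotropy.copy(),
        "effect_matrix": cfg.effect_matrix.copy(),
    }
    if compute_marginal_truth and cfg.outcome_model == "logistic":
        truth["marginal_logodds"] = marginal_logodds_effects(out_cohort, cfg)
        truth["marginal_pleiotropy"] = marginal_logodds_effects(
            out_cohort, cfg, direct_only=True
        )
    return SimulatedStudy(tables, main, truth, realized, companion)


def _null_config(seed: int, **over) -> SimulationConfig:
    J = over.pop("n_variants", 30)
    rng = substream(seed, "design")
    b = rng.uniform(0.15, 0.30, J)
    return SimulationConfig(
        n_variants=J, n_exposures=1,
        n_exposure_sample=over.pop("n_exposure_sample", 10_000),
        n_outcome_sample=over.pop("n_outcome_sample", 10_000),
        effect_matrix=b[:, None],
        confounder_effects=np.array([0.2, 0.2]),
        causal_effects=np.array([0.0]),
        seed=seed, **over,
    )


def _valid_config(seed: int, **over) -> SimulationConfig:
    J = over.pop("n_variants", 50)
    rng = substream(seed, "design")
    # bimodal per-allele effects: a weak and a strong cluster, giving the
    # gamma spread MR-Egger needs while keeping total genetic variance sane
    b = np.where(np.arange(J) % 2 == 0, 0.08, 0.26) + rng.uniform(-0.01, 0.01, J)
    return SimulationConfig(
        n_variants=J, n_exposures=1,
        n_exposure_sample=over.pop("n_exposure_sample", 20_000),
        n_outcome_sample=over.pop("n_outcome_sample", 20_000),
        effect_matrix=b[:, None],
        maf_range=(0.1, 0.3),
        confounder_effects=np.array([0.15, 0.15]),
        causal_effects=np.array([over.pop("theta", 0.2)]),
        seed=seed, **over,
    )


def _pleiotropic_config(seed: int, **over) -> SimulationConfig:
    cfg = _valid_config(
        seed, theta=0.0,
        n_outcome_sample=over.pop("n_outcome_sample", 40_000), **over,
    )
    rng = substream(seed, "pleiotropy_design")
    J = cfg.n_variants
    chosen = rng.choice(J, size=int(round(0.3 * J)), replace=False)
    pleio = np.zeros(J)
    pleio[chosen] = 0.25  # directional: all positive
    cfg.pleiotropy = pleio
    return cfg


def _selection_config(seed: int, **over) -> SimulationConfig:
    J = over.pop("n_variants", 30)
    rng = substream(seed, "design")
    b = rng.uniform(0.15, 0.30, J)
    return SimulationConfig(
        n_variants=J, n_exposures=1,
        n_exposure_sample=over.pop("n_exposure_sample", 10_000),
        n_outcome_sample=over.pop("n_outcome_sample", 40_000),
        effect_matrix=b[:, None],
        confounder_effects=np.array([0.2, 0.2]),
        causal_effects=np.array([0.0]),  # null exposure: any signal is bias
        selection=SelectionModel(np.array([-0.6]), retention_target=0.5),
        seed=seed, **over,
    )


#: mediator_13 layout: four "core" exposures with disjoint strong instrument
#: blocks, nine downstream exposures each loading strongly on one core and
#: weakly on another. Staggered strong loadings keep every mediator-involving
#: pair far from balanced, so forward selection recovers exactly the cores.
_CORES = ["hdl", "triglycerides", "ldl", "sbp"]
#: per-variant effect size of each core's instrument block; the two lipid
#: cores and the two remaining cores form balanced pairs (equal strength),
#: which is what lets a core pair win the seed step reliably
_CORE_B = [0.21, 0.21, 0.16, 0.16]
_MEDIATORS = {
    # name: (strong core index, strong loading, weak core index)
    # strong loadings are tiered per core so no two mediators from
    # different groups ever form a balanced (similar-F) pair
    "apoa1": (0, 0.62, 2),
    "hdl2_cholesterol": (0, 0.63, 3),
    "vldl": (1, 0.52, 2),
    "remnant_cholesterol": (1, 0.51, 0),
    "apob": (2, 0.55, 1),
    "non_hdl_cholesterol": (2, 0.56, 3),
    "dbp": (3, 0.45, 0),
    "pulse_pressure": (3, 0.46, 1),
    "map_pressure": (3, 0.44, 2),
}


def _mediator13_config(seed: int, **over) -> SimulationConfig:
    J = over.pop("n_variants", 60)
    rng = substream(seed, "design")
    block = np.arange(J) % 4  # variant j instruments core (j mod 4)
    K = 4 + len(_MEDIATORS)
    B = np.zeros((J, K))
    for c in range(4):
        rows = block == c
        B[rows, c] = _CORE_B[c] + rng.uniform(-0.005, 0.005, rows.sum())
    mediation: dict[int, dict[int, float]] = {}
    for m, (name, (core, lam, weak)) in enumerate(_MEDIATORS.items(), start=4):
        mediation[m] = {core: lam, weak: 0.2}
    conf = np.full(K + 1, 0.2)
    theta = np.zeros(K)
    theta[:4] = [-0.25, 0.20, 0.25, 0.20]
    return SimulationConfig(
        n_variants=J, n_exposures=K,
        n_exposure_sample=over.pop("n_exposure_sample", 20_000),
        n_outcome_sample=over.pop("n_outcome_sample", 20_000),
        effect_matrix=B,
        maf_range=(0.25, 0.35),
        confounder_effects=conf,
        causal_effects=theta,
        mediation_map=mediation,
        exposure_names=_CORES + list(_MEDIATORS),
        outcome_name="chd",
        seed=seed, **over,
    )


def make_fixture(name: str, seed: int, **overrides) -> SimulatedStudy:
    """Build one of the canonical seeded study fixtures.

    - ``null``: one valid-instrument exposure with zero causal effect.
    - ``valid_instruments``: one exposure, true effect 0.2 per SD, J=50,
      n=20,000 per sample.
    - ``pleiotropic``: as above but null effect and 30% of variants given a
      directional (all-positive) direct effect of 0.25 on the liability.
    - ``mediator_13``: 13 correlated exposures, four with disjoint strong
      instruments (the designated MVMR model) and nine mediated ones.
    - ``selection_bias``: one null exposure; prevalent outcome table with
      survival-dependent case retention plus an unbiased incident companion.
    """
    builders = {
        "null": _null_config,
        "valid_instruments": _valid_config,
        "pleiotropic": _pleiotropic_config,
        "mediator_13": _mediator13_config,
        "selection_bias": _selection_config,
    }
    if name not in builders:
        raise ConfigurationError(f"unknown fixture {name!r}; choose from {FIXTURES}")
    marginal = overrides.pop("compute_marginal_truth", name == "pleiotropic")
    cfg = builders[name](seed, **overrides)
    study = simulate_study(cfg, compute_marginal_truth=marginal)
    if name == "mediator_13":
        study.truth["designated_model"] = list(_CORES)
        study.truth["designated_mediator"] = "apoa1"
    return study
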