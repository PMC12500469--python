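import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mrselect import AssociationTable, HarmonizedSet

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_table(
    trait_name,
    betas,
    ses,
    pvalues=None,
    eafs=None,
    positions=None,
    chromosomes=None,
    effect_alleles=None,
    other_alleles=None,
    trait_type="continuous",
    variant_ids=None,
    n=10_000,
):
    """Hand-rolled association table for small deterministic examples."""
    J = len(betas)
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    if pvalues is None:
        from scipy import stats

        pvalues = 2 * stats.norm.sf(np.abs(betas / ses))
    df = pd.DataFrame(
        {
            "variant_id": variant_ids or [f"rs{i + 1}" for i in range(J)],
            "chromosome": chromosomes or ["1"] * J,
            "position": positions or (np.arange(J) + 1) * 20_000_000,
            "effect_allele": effect_alleles or ["A"] * J,
            "other_allele": other_alleles or ["G"] * J,
            "eaf": eafs if eafs is not None else [0.3] * J,
            "beta": betas,
            "se": ses,
            "pvalue": np.clip(pvalues, 1e-300, 1.0),
            "n": n,
        }
    )
    return AssociationTable(trait_name, trait_type, df)


def make_hset(gamma, gamma_se, Gamma, Gamma_se, exposure_names=None):
    """HarmonizedSet straight from arrays (bypasses file plumbing)."""
    gamma = np.atleast_2d(np.asarray(gamma, float))
    if gamma.shape[0] == 1:
        gamma = gamma.T
    gamma_se = np.atleast_2d(np.asarray(gamma_se, float))
    if gamma_se.shape[0] == 1:
        gamma_se = gamma_se.T
    L, K = gamma.shape
    names = exposure_names or [f"x{k}" for k in range(K)]
    return HarmonizedSet(
        outcome_name="y",
        exposure_names=list(names),
        variant_ids=np.array([f"rs{i + 1}" for i in range(L)], dtype=object),
        gamma=gamma,
        gamma_se=gamma_se,
        Gamma=np.asarray(Gamma, float),
        Gamma_se=np.asarray(Gamma_se, float),
        provenance=pd.DataFrame(columns=["variant_id", "flag", "detail"]),
    )


@pytest.fixture
def toy_hset():
    """5 instruments, consensus ratio 0.5 plus mild noise."""
    rng = np.random.default_rng(42)
    g = rng.uniform(0.1, 0.3, 5)
    G = 0.5 * g + rng.normal(0, 0.005, 5)
    return make_hset(g, np.full(5, 0.01), G, np.full(5, 0.02))
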