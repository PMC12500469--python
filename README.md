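# mrselect

Two-sample Mendelian randomization (MR) from GWAS summary statistics, with
a conditional-F-maximizing forward-selection algorithm for choosing which
exposures a multivariable MR (MVMR) model can actually support.

## The problem

MR uses genetic variants as instrumental variables: because alleles are
assigned at conception, a variant robustly associated with an exposure can
estimate that exposure's causal effect on a disease outcome free of the
usual confounding — given only per-variant association summaries
(beta, SE) from two non-overlapping GWAS. For variant *j* with
variant–exposure association γ̂ⱼ and variant–outcome association Γ̂ⱼ, the
Wald ratio is θ̂ⱼ = Γ̂ⱼ/γ̂ⱼ, and the inverse-variance weighted (IVW)
estimate pools the ratios with weights wⱼ = γ̂ⱼ²/se(Γ̂ⱼ)². MR-Egger,
weighted-median and weighted-mode estimators relax the exclusion
restriction in different ways; Cochran's Q flags heterogeneity.

With many correlated risk factors (lipid fractions, blood pressures,
adiposity…) the interesting quantity is each exposure's *direct* effect,
from MVMR. But MVMR needs each exposure to remain strongly instrumented
*conditional on* the others — measured by the conditional F-statistic with
the conventional threshold of 10 — and fitting all candidate exposures at
once usually collapses conditional strength. `mrselect` implements a
forward-selection algorithm for this model-choice problem: score all
exposure pairs by their mean conditional F penalized by within-pair
imbalance, seed with the best feasible pair, then repeatedly add the
exposure that maximizes the minimum conditional F of the augmented model,
stopping when any addition would push a conditional F below threshold.
The result is the largest defensible MVMR model plus an audited trace of
every accepted and rejected candidate.

A synthetic GWAS generator with known causal truth (correlated exposures,
horizontal/vertical pleiotropy, confounding, binary outcomes, and a
prevalent-case survival-selection mechanism) makes the entire workflow
testable without any external data.

## Worked example

```python
import mrselect as mr

study = mr.make_fixture("valid_instruments", seed=7)   # true effect: 0.2/SD
hset = mr.assemble_mvmr_set(study.exposure_tables, study.outcome_table)
result = mr.run_univariable_suite(hset, mr.UnivariableConfig(n_boot=500, seed=7))
```

Running `python examples/01_univariable_mr.py` prints:

```
instruments after selection + harmonization: 38
mean instrument F-statistic: 191.7
Cochran's Q = 35.0 (df=37, p=0.564)

method                beta      se      OR            95% CI
ivw                  0.194   0.044   1.214   [1.113, 1.324]
egger_slope          0.112   0.113   1.119   [0.896, 1.396]
egger_intercept      0.015   0.019   1.015   [0.978, 1.054]
weighted_median      0.152   0.066   1.164   [1.022, 1.325]
weighted_mode        0.117   0.101   1.124   [0.923, 1.370]
```

Every estimator's interval covers the true odds ratio exp(0.2) ≈ 1.22; the
non-significant Q and near-zero Egger intercept are consistent with the
all-valid instruments this fixture generates.

The other examples show the core capabilities in the same style:
`02_conditional_f_attenuation.py` (a mediated trait's F collapsing from 72
to 0.8 once its upstream exposure is co-modelled),
`03_forward_selection.py` (13 candidate exposures reduced to the
four-exposure model the data support, with the full audit trace), and
`04_selection_bias.py` (a null exposure acquiring OR 0.71, p ≈ 4e-15 under
survival-dependent case recruitment while the incident design stays at the
null).

There is also a thin CLI mirroring the stages:

```bash
mrselect simulate --fixture mediator_13 --seed 7 --out data/
mrselect pipeline --exposures data/hdl.tsv,data/ldl.tsv,... \
                  --outcome data/chd.tsv --seed 7 --out run/
```

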