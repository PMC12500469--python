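"""Prevalent-case ascertainment bias, demonstrated on a null exposure.

The outcome cohort's cases are retained with probability depending
negatively on the exposure (survivors are enriched for low exposure).
The exposure has no causal effect, so any signal in the prevalent design
is pure selection bias; the incident design on the same cohort is clean.
"""

import mrselect as mr

study = mr.make_fixture("selection_bias", seed=7)

prevalent = mr.ivw(mr.assemble_mvmr_set(study.exposure_tables, study.outcome_table))
incident = mr.ivw(
    mr.assemble_mvmr_set(study.exposure_tables, study.companion_tables["incident"])
)

print(f"true causal effect: 0 (null exposure)")
print(f"survival coefficient on exposure: -0.6 (low-exposure cases survive)")
print(f"prevalent design: beta = {prevalent.beta:+.3f} "
      f"(OR {prevalent.odds_ratio:.3f}, p = {prevalent.pvalue:.2g})")
print(f"incident design:  beta = {incident.beta:+.3f} "
      f"(OR {incident.odds_ratio:.3f}, p = {incident.pvalue:.2g})")
print()
print("The prevalent design manufactures a 'protective' association out of")
print("nothing but survival-dependent recruitment; the incident design,")
print("which samples cases before selection can act, stays at the null.")
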