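"""Why univariable F-statistics are not enough for multivariable MR.

A mediated trait (apoa1-like, generated downstream of the hdl-like core
exposure's instruments) looks strongly instrumented on its own, but its
conditional F collapses once the core exposure enters the same model —
the instruments' strength belongs to the shared pathway.
"""

import mrselect as mr

study = mr.make_fixture("mediator_13", seed=7)
tables = {t.trait_name: t for t in study.exposure_tables}
core = study.truth["designated_model"][0]          # "hdl"
mediator = study.truth["designated_mediator"]      # "apoa1"

uni_f = mr.mean_instrument_f(mr.select_instruments(tables[mediator]))
hset = mr.assemble_mvmr_set(
    [tables[core], tables[mediator]], study.outcome_table
)
strength = mr.conditional_f(hset)

print(f"univariable mean F of {mediator}: {uni_f:.1f}")
print(f"conditional F in the ({core}, {mediator}) MVMR model:")
for name, f in zip(strength.exposure_names, strength.conditional_f):
    print(f"  {name:<12} {f:8.2f}")
print()
print(f"{mediator} drops from F={uni_f:.0f} to F="
      f"{strength[mediator]:.1f} (< 10): its apparent instrument strength")
print(f"was borrowed from {core}; estimating both direct effects jointly")
print("from these instruments is not feasible.")
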