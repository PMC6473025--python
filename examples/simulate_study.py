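"""Simulate a full intervention study and run the MLS analysis on it.

The default design mirrors the reference study: 20 control and 56
experimental mice, intervention at 15 months, six injections with a 6%
embolic risk each, five animals sacrificed at 21 months, and a milder
post-intervention mortality law for the treated arm.  The analysis applies
the inclusion policy (sacrifices dropped, embolic deaths counted as
natural), then compares top-decile mean lifespans between arms.
"""

from maxlifespan import (
    Event,
    StudyDesign,
    apply_mortality_policy,
    estimate_chimerism,
    extension_percent,
    mls_direct,
    simulate_study,
)

design = StudyDesign(seed=1)
cohort, chimerism_samples = simulate_study(design)

n_embolic = sum(r.event == Event.EMBOLIC for r in cohort.records)
n_sac = sum(r.event == Event.SACRIFICED for r in cohort.records)
print(f"simulated {len(cohort)} animals: {n_embolic} embolic deaths, {n_sac} sacrificed")

analysed = apply_mortality_policy(cohort)
exp = analysed.subset("experimental")
ctl = analysed.subset("control")
mls_exp = mls_direct(exp.death_ages(), n_cohort=len(exp))
mls_ctl = mls_direct(ctl.death_ages(), n_cohort=len(ctl))

print(f"experimental MLS (top decile of n={len(exp)}): {mls_exp.value:.2f} months")
print(f"control      MLS (top decile of n={len(ctl)}): {mls_ctl.value:.2f} months")
print(f"extension: {extension_percent(mls_exp.value, mls_ctl.value):.1f}%")

chim = [estimate_chimerism(s) for s in chimerism_samples]
print(f"chimerism across {len(chim)} sampled animals: "
      + ", ".join(f"{c:.3f}" for c in chim)
      + f"  (design truth {design.chimerism_truth})")
print()
print("a positive extension is expected here because the design gives the")
print("treated arm a lower post-intervention baseline hazard.")
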