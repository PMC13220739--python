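"""Estimate adjusted hazard ratios for the three illness-death transitions.

Builds person-time split at waves and 1-year attained ages, then fits the
Poisson-Gompertz proportional-hazards model per sex and transition with the
pre-specified baseline adjustment set (age, household composition,
education, physical activity, diet score, smoking + cigarettes/day,
alcohol, COPD) and cluster-robust standard errors at the individual level.
"""

import warnings

import heartspan as hs

warnings.simplefilter("ignore")

cohort = hs.generate_cohort(hs.SyntheticCohortConfig(), seed=20260917)
cohort.waves = hs.add_phenotypes(cohort.waves, cohort.participants.set_index("id")["sex"])
eligible, _ = hs.apply_eligibility(cohort)
pt = hs.build_person_time(eligible, exposure_kind="composite")

print(f"person-time segments: {len(pt):,}")
for transition in hs.TRANSITIONS:
    print(f"\n=== {transition}, men (adjusted HRs, 95% robust Wald CI) ===")
    hset = hs.estimate_hrs(pt, transition, "men")
    print(hset.table.round(2).to_string())

print(
    "\nThe reference category (low adiposity) has HR 1 by construction; an\n"
    "HR above 1 means that category experiences the transition at a\n"
    "proportionally higher rate at every age.  With the default generator\n"
    "the true values are the published adjusted estimates, so at cohort\n"
    "scale (~2,300 people) the fits recover them within sampling error."
)
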