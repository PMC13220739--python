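"""Parametric-bootstrap percentile confidence intervals for life expectancy.

Parameter vectors (Gompertz intercept/slope, log hazard ratios) are redrawn
from their cluster-robust asymptotic distributions and prevalence vectors
from Dirichlet distributions with observed person-years as concentrations;
each draw is propagated through rate calibration and the life tables.
B = 200 here for a quick run (the reference design uses 1,000 iterations).
"""

import warnings

import heartspan as hs
from heartspan.uncertainty import LifetableInputs, bootstrap_le

warnings.simplefilter("ignore")

cohort = hs.generate_cohort(hs.SyntheticCohortConfig(), seed=20260917)
cohort.waves = hs.add_phenotypes(cohort.waves, cohort.participants.set_index("id")["sex"])
eligible, _ = hs.apply_eligibility(cohort)
pt = hs.build_person_time(eligible)

overall, hrs = hs.models.fit_all_transitions(pt)
prev = hs.estimate_prevalences(pt)
inputs = LifetableInputs(overall, hrs, prev, hs.estimate_initial_cvd(pt))

res = bootstrap_le(inputs, B=200, seed=42)
s = res.summary
diffs = s[(s["kind"] == "difference_vs_ref") & (s["category"] == "very_high")]
print("very-high vs low adiposity, LE differences at age 50 (95% percentile CI):")
print(diffs[["sex", "measure", "estimate", "lo", "hi"]].round(2).to_string(index=False))
print(
    "\nEach row reads: people in the very-high category are expected to live\n"
    "'estimate' more (positive) or fewer (negative) years in that state\n"
    "between ages 50 and 80 than the low category; the CI propagates the\n"
    "sampling uncertainty of every fitted ingredient.  Identical seeds give\n"
    "bit-identical intervals."
)
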