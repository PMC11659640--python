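"""Simulate a longitudinal twin cohort and check its correlation structure.

Draws a three-stage cohort (104 MZ + 124 DZ pairs, with attrition to 170
pairs by the permanent dentition) from the bivariate-normal twin model and
prints the per-zygosity intraclass correlations of posterior palatal depth.
Under the generating components A = 0.89, E = 0.11 the population values
are r_MZ = 0.89 and r_DZ = 0.445; sample ICCs scatter around them with
~1/sqrt(n) error.
"""

from palatwin.synthetic_data import default_stage_specs, simulate_longitudinal_cohort
from palatwin.twin_stats import zygosity_icc

specs = default_stage_specs(
    {"primary": (104, 124), "mixed": (103, 122), "permanent": (78, 92)}
)
cohort = simulate_longitudinal_cohort(specs, seed=42)
print(cohort.groupby("stage").size().rename("records per stage"))
print()
for stage in ("primary", "mixed", "permanent"):
    icc = zygosity_icc(cohort, "posterior_depth", stage)
    print(f"{stage:10s} posterior_depth ICC  "
          f"MZ={icc['MZ'].icc:.3f} (n={icc['MZ'].n_pairs})  "
          f"DZ={icc['DZ'].icc:.3f} (n={icc['DZ'].n_pairs})")
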