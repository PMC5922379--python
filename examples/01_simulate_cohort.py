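"""Simulate a survival cohort with planted prognostic genes.

Builds a 200-patient, 30-gene expression matrix in which two genes carry a
real effect on overall survival (log hazard ratio log 3, acting as a step
at the median expression), then summarizes the cohort.
"""

import numpy as np

import episcore as ep

spec = ep.SyntheticCohortSpec(
    n_patients=200,
    n_genes=30,
    planted_genes=(
        ep.PlantedGene(gene_index=0, beta=float(np.log(3)), cut_quantile=0.5),
        ep.PlantedGene(gene_index=5, beta=float(np.log(3)), cut_quantile=0.5),
    ),
    baseline_rate=0.02,     # events per month in the all-low group
    censor_horizon=120.0,   # 10 years of uniform accrual censoring
    seed=1,
)
expr, clin, truth = ep.generate_cohort(spec)

print(f"expression matrix: {expr.shape[0]} probes x {expr.shape[1]} patients")
print(f"observed events:   {int(clin['os_event'].sum())} / {len(clin)} "
      f"({clin['os_event'].mean():.0%})")
curve = ep.kaplan_meier(clin["os_months"].to_numpy(), clin["os_event"].to_numpy())
median = ("not reached" if not curve.median_reached
          else f"{curve.median_survival:.1f} months")
print(f"median OS:         {median}")
for t in truth:
    print(f"planted {t['probe_id']}: beta={t['beta']:.3f}, "
          f"hidden cutpoint={t['cutpoint']:.1f} (expression units, "
          f"{t['cut_quantile']:.0%} quantile)")

# The event fraction reflects the exponential hazard + uniform censoring;
# the hidden cutpoints are what the screening stage must recover from the
# expression and survival data alone.
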