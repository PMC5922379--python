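"""Find survival-optimal expression cutpoints and screen genes in two cohorts.

A maximally selected rank statistic scans every candidate cutpoint of a
continuous marker and reports the best split with a p-value adjusted for
having optimized the cutpoint.  Screening runs this per gene in a training
and a validation cohort, adjusts with Benjamini-Hochberg within each
cohort, and keeps genes significant in both.
"""

import numpy as np

import episcore as ep

spec = ep.SyntheticCohortSpec(
    n_patients=300,
    n_genes=40,
    planted_genes=(ep.PlantedGene(2, float(np.log(2.5)), 0.5),
                   ep.PlantedGene(17, float(np.log(2.5)), 0.35)),
    seed=4,
)
train, valid, truth = ep.generate_cohort_pair(spec)

# single-gene scan on the first planted gene
x = train.expression.loc["probe_0002"].to_numpy()
res = ep.maxstat_cutpoint(x, train.times, train.events)
print("single-gene scan of probe_0002:")
print(f"  cutpoint {res.cutpoint:.1f} "
      f"({(x <= res.cutpoint).mean():.0%} of patients below)")
print(f"  standardized max statistic b = {res.statistic:.2f}, "
      f"selection-adjusted p = {res.p_approx:.2e}")
print(f"  direction: {'high' if res.direction == 1 else 'low'} expression "
      "is the high-risk side")

screening = ep.screen_prognostic_genes(train, valid, alpha=0.05, minprop=0.1)
selected = screening[screening["selected"]]
print(f"\nscreened {len(screening)} genes; "
      f"{len(selected)} pass adjusted p < 0.05 in BOTH cohorts:")
print(selected[["cutpoint_train", "b_train", "padj_train", "padj_valid"]]
      .round(4).to_string())
print("planted genes were:", sorted(t["probe_id"] for t in truth))

# The adjusted p penalizes the optimized cutpoint, and the two-cohort rule
# with per-cohort FDR control is what keeps the 38 null genes out.
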