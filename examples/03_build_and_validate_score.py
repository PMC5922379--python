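"""Build a frozen risk score from screened genes and validate it.

Pipeline: screen genes in two cohorts -> prune to independently prognostic
genes by multivariate Cox -> attach per-gene betas -> stratify the training
cohort by the count of high-risk genes, merging adjacent groups whose
survival does not differ -> freeze the model -> apply it unchanged to the
validation cohort.
"""

import numpy as np

import episcore as ep

spec = ep.SyntheticCohortSpec(
    n_patients=400,
    n_genes=100,
    planted_genes=tuple(
        ep.PlantedGene(i, float(np.log(2.5)), 0.5) for i in (3, 41, 77)
    ),
    seed=11,
)
train, valid, truth = ep.generate_cohort_pair(spec)

screening = ep.screen_prognostic_genes(train, valid)
rules = ep.selected_gene_rules(screening)
print(f"screening selected {len(rules)} of {len(screening)} genes")

retained, fit = ep.prune_multivariate(rules, train, alpha=0.05)
print(f"multivariate pruning retained {len(retained)}: "
      f"{[g.probe_id for g in retained]}")

retained = ep.fit_gene_betas(retained, train, source="univariate")
model, groups = ep.build_model(retained, train, merge_alpha=0.05)
print(f"risk groups (count of high-risk genes -> merged group): "
      f"{model.merge_map}")
shares = groups["group"].value_counts(normalize=True).sort_index()
print("training group shares:",
      {int(g): f"{s:.1%}" for g, s in shares.items()})

assignment, logrank = ep.apply_model(model, valid)
print(f"\nvalidation cohort (n={valid.n_patients}): "
      f"log-rank across {model.n_groups} groups "
      f"chi2={logrank.chi_square:.1f}, p={logrank.p_value:.2e}")
for g in sorted(assignment["group"].unique()):
    mask = (assignment["group"] == g).to_numpy()
    curve = ep.kaplan_meier(valid.times[mask], valid.events[mask])
    med = ("not reached" if not curve.median_reached
           else f"{curve.median_survival:.1f} mo")
    print(f"  group {g}: n={mask.sum():3d}, median OS {med}")

# Higher groups carry more high-risk genes and die sooner; the frozen model
# reuses the training cutoffs, betas and merge map with no re-estimation.
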