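# Methods

## The statistic and its selection-adjusted p-value

For survival data (t_i, δ_i), i = 1..N, the per-patient log-rank score is
a_i = δ_i − Λ̂(t_i), where Λ̂ is the Nelson–Aalen estimator
Λ̂(t) = Σ_{s ≤ t} d_s/n_s over distinct times s with d_s events and n_s at
risk. Patients tied at one observed time all receive the hazard
accumulated *through* that time, with events counted before censorings;
under this convention Σ a_i = 0 exactly.

A candidate cutpoint μ splits the cohort into a low group
L(μ) = {i : x_i ≤ μ} of size m. The linear rank statistic
T(μ) = Σ_{L(μ)} a_i has permutation moments E = m·ā and
V = m(N−m)/(N(N−1)) · Σ(a_i − ā)², giving Z(μ) = (T−E)/√V. Candidates are
the midpoints between consecutive distinct marker values whose midpoint
lies between the `minprop` and `1−minprop` quantiles of x (default
minprop 0.1, the conventional window for this statistic). The maximally
selected statistic is b = max |Z(μ)|; ties in |Z| resolve to the smallest
μ, and the reported direction is +1 when the above-cutpoint side carries
the excess hazard (Z(μ*) < 0). Both b and the cutpoint's quantile position
are invariant under strictly monotone transforms of x, so no expression
scale/log decision affects screening (it does affect β magnitudes; the
readers therefore never transform implicitly, and the CLI exposes
`--log2`).

Because b is a maximum over many correlated statistics, its p-value uses
the Brownian-bridge crossing bound

    p(b) = min(1, 4φ(b)/b + φ(b)(b − 1/b)·ln[ q2(1−q1) / (q1(1−q2)) ]),

for b > 1 (p = 1 otherwise), where (q1, q2) is the quantile window the
candidates actually span and φ the standard normal density. This is an
improved-Bonferroni *upper bound* on the limiting crossing probability: it
is deliberately conservative, increasingly so at small N where the
discrete scan has fewer effective candidates than the continuous bridge.
Empirically (n = 2000, 10,000 permutations, b = 3) the bound sits within
about 0.005 of the permutation tail probability and never below it; at
n = 100–200 the permutation p runs roughly 20% smaller. A Monte-Carlo
permutation p-value (`pmethod="permutation"`) is available whenever
exactness matters more than speed; it permutes the marker/score pairing,
holding the candidate set fixed, and is vectorized over permutations.

## Screening and pruning

Each gene is scanned in a training and an independent validation cohort.
Benjamini–Hochberg step-up adjustment is applied within each cohort across
the tested genes, and a gene is selected only when adjusted p < α
(default 0.05) in *both* cohorts — the two-cohort intersection is what
makes the screen robust to cohort-specific artifacts. The training
cohort's cutpoints and directions are the ones frozen downstream; a
selected gene whose above-cutpoint group is protective has its direction
flipped so that "high" always denotes the worse-prognosis side.

Selected genes, dichotomized at their training cutpoints in the risk
direction (a value exactly at the cutoff always falls on the low side),
enter one multivariate Cox model; genes with multivariate Wald p < α are
retained. The betas stored in the score default to each retained gene's
*univariate* Cox coefficient on its dichotomy (`beta_source="univariate"`),
with the multivariate coefficients available as an option: group
assignment depends only on counts, so the choice affects the continuous
score but never the risk groups.

## Risk groups and merging

Raw groups are the counts 0..K of genes on the high-risk side. Empty
counts are first absorbed into the nearest non-empty neighbor (ties toward
the higher count). Then, iteratively, the two-sample log-rank test is run
on every adjacent pair of groups; while the *largest* adjacent p-value is
at or above `merge_alpha` (default 0.05), that least-separated pair is
merged and all pairs recomputed. This is the minimal deterministic
completion of "merge consecutive groups that do not differ": merging the
weakest separation first makes the outcome independent of scan order.
Note the decision inherits the log-rank test's sampling noise — two groups
drawn from one survival law still stay apart in ~5% of replicates at
merge_alpha = 0.05, and genuinely different groups can merge when power is
low. The final count→group map is frozen; `apply_model` reuses cutoffs,
betas, directions and the merge map verbatim, so
serialize → deserialize → apply reproduces assignments bit-exactly.

In Cox comparisons against competing covariates the merged group enters as
a single ordinal term (0, 1, 2, …), matching the convention of reporting
one hazard ratio per risk-group step; pairwise mode fits one bivariate
model per competitor, joint mode fits all terms at once, both
complete-case per fit.

## Survival estimators

Kaplan–Meier, log-rank and Cox fits are delegated to lifelines behind this
package's interfaces, with the conventions pinned and tested here: events
precede censorings at tied times; median survival is the smallest t with
S(t) ≤ 0.5, infinite when never reached; the k-sample log-rank uses the
hypergeometric variance with k−1 degrees of freedom; Cox fits use the
Efron tie correction and report per-covariate Wald z and p. Constant
covariates are rejected before fitting, and convergence failures (e.g.
collinear covariates in joint comparisons) surface as explicit errors.

The exact 2×2 test uses the two-sided sum-of-small-probabilities rule
(sum of hypergeometric probabilities of all margin-consistent tables no
more probable than the observed one) — this variant, not the
conditional-MLE one, reproduces the reference table p-values to 4 decimal
places. The paired Wilcoxon drops zero differences and uses the exact null
distribution up to 25 non-zero pairs (normal approximation with continuity
correction beyond, or when rank ties preclude the exact distribution).
The t test defaults to the pooled-variance Student form, Welch behind a
flag.

## The synthetic generator

`generate_cohort` emulates what the pipeline consumes, not how microarray
data are made: gene signals are i.i.d. log2-normal (location 7, scale 1 on
the log2 scale), giving positive MAS5-like intensities spanning roughly
two orders of magnitude; planted genes act on the hazard through a step at
a hidden quantile cutpoint, λ_j = λ0·exp(Σ β_g·1[x_gj > c_g]); event times
are exponential at that rate and censoring is independent
Uniform(0, horizon). Defaults — λ0 = 0.02 events/month and a 120-month
horizon — give a ~60% event fraction and a short median survival typical
of an aggressive-lymphoma cohort. A `linear` effect mode exists for
robustness checks, and `generate_grouped_cohort` builds cohorts whose
count-based group structure and per-group hazards are exact by
construction, for exercising the merging rule in isolation.
`generate_contingency_cohort` draws 2×2 tables from the Plackett joint
distribution with prescribed margins and odds ratio. A single seed drives
everything through spawned per-component streams, so identical
specifications are bit-identical.

Deliberately not emulated: probe-level array artifacts, normalization,
batch effects, correlated co-expression programs (each gene is
independent), non-proportional hazards, and informative censoring.
Passing tests therefore demonstrate that the *pipeline logic* recovers
planted structure under its own model assumptions — not that the score
would transfer across real cohorts with batch or platform differences.

## Problem sizes and checks

The test suite and `scripts/acceptance.py` use desk-scale simulations
chosen to make the checks sharp while staying fast: 400 patients per
cohort and 100 genes (3 planted at log HR = log 2.5) for pipeline
recovery; 150 patients per raw group for the merging scenarios (500 per
group for the no-merge case); 1000 replicates of n = 200 for log-rank
type-I error; 10,000 permutations at n = 2000 for the p-value oracle; 31
patients for the IHC-scale cutpoint recovery. At 400 patients the
per-gene dichotomized Cox β̂ has a standard error near 0.12, so parameter
recovery is asserted on the mean of the planted genes' estimates; the
recovered cutpoint's quantile position typically lands within a few
percentile points of the planted median but has a heavy-tailed selection
error (occasional 20–30 point misses at this effect size are sampling
behavior, not failure to detect the gene).

## Known limitations

* The analytic p-value is a bound, not an exact tail probability; for
  small cohorts (tens of patients) the permutation method should be
  preferred.
* The merge procedure tests adjacent pairs only and does not adjust for
  the sequential testing; `merge_alpha` is a tuning knob, not a
  false-merge rate guarantee.
* One probe = one gene: collapsing multiple probes per gene is left to
  the caller.
* No handling of competing risks, time-varying effects, or stratified
  baselines.
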