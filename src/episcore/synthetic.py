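"""Synthetic expression/survival cohorts with known prognostic structure.

The generator emulates the kind of data the score pipeline consumes: a
patients-by-genes matrix of positive, MAS5-like microarray signals and a
right-censored overall-survival endpoint.  A small set of *planted* genes
acts on the hazard through a step function: patient ``j``'s hazard is

    lambda_j = lambda0 * exp( sum_g beta_g * 1[x_gj > c_g] )

where ``c_g`` is the hidden cutpoint, realized as the ``cut_quantile``
quantile of gene ``g``'s simulated expression.  Event times are exponential
with that rate; censoring is independent Uniform(0, horizon).  This plants
exactly the dichotomized prognostic structure the downstream cutpoint
selection, pruning and grouping stages are supposed to recover, so every
stage can be tested against ground truth.

A single integer seed drives everything; per-component streams are spawned
deterministically from it, so identical specs give bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import Cohort

__all__ = [
    "PlantedGene",
    "SyntheticCohortSpec",
    "generate_cohort",
    "generate_contingency_cohort",
]


class InvalidSpecError(ValueError):
    """The cohort specification is internally inconsistent."""


@dataclass(frozen=True)
class PlantedGene:
    """A gene given a real effect on survival.

    beta is the log hazard ratio of the above-cutpoint group; cut_quantile
    places the hidden cutpoint as a quantile of the gene's expression.
    """

    gene_index: int
    beta: float
    cut_quantile: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.cut_quantile < 1.0:
            raise InvalidSpecError("cut_quantile must lie strictly in (0, 1)")
        if not math.isfinite(self.beta):
            raise InvalidSpecError("beta must be finite")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of one simulated cohort.

    Defaults emulate a lymphoma microarray cohort followed for ten years:
    an exponential baseline hazard of 0.02 events/month (median untreated
    survival ~35 months) with uniform accrual censoring over 120 months,
    and log-normal expression with location 7 and scale 1 on the log2
    scale, i.e. positive signals spanning roughly two orders of magnitude.
    """

    n_patients: int
    n_genes: int
    planted_genes: tuple[PlantedGene, ...] = ()
    baseline_rate: float = 0.02          # events per month
    censor_horizon: float = 120.0        # months
    expression_distribution: tuple[str, float, float] = ("lognormal", 7.0, 1.0)
    effect_mode: Literal["step", "linear"] = "step"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_genes <= 0:
            raise InvalidSpecError("n_patients and n_genes must be positive")
        if self.baseline_rate <= 0:
            raise InvalidSpecError("baseline_rate must be positive")
        if self.censor_horizon <= 0:
            raise InvalidSpecError("censor_horizon must be positive")
        if len(self.planted_genes) > self.n_genes:
            raise InvalidSpecError("more planted genes than genes")
        idx = [g.gene_index for g in self.planted_genes]
        if len(set(idx)) != len(idx):
            raise InvalidSpecError("duplicate planted gene indices")
        if any(i < 0 or i >= self.n_genes for i in idx):
            raise InvalidSpecError("planted gene index out of range")
        kind = self.expression_distribution[0]
        if kind not in ("lognormal", "normal"):
            raise InvalidSpecError(f"unknown expression distribution {kind!r}")
        object.__setattr__(self, "planted_genes", tuple(self.planted_genes))


def _expression(spec: SyntheticCohortSpec, rng: np.random.Generator) -> np.ndarray:
    kind, loc, scale = spec.expression_distribution
    z = rng.normal(loc, scale, size=(spec.n_genes, spec.n_patients))
    if kind == "lognormal":
        return np.exp2(z)  # log2-normal positive signal, MAS5-like
    return z


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Simulate one cohort.

    Returns ``(expression, clinical, truth)`` where expression is a
    probes-x-patients DataFrame, clinical has columns
    ``patient_id, os_months, os_event``, and truth records each planted
    gene with its realized expression cutpoint.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_expr, rng_event, rng_censor = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    x = _expression(spec, rng_expr)
    log_hazard = np.full(spec.n_patients, math.log(spec.baseline_rate))
    truth: list[dict] = []
    for g in spec.planted_genes:
        xg = x[g.gene_index]
        cut = float(np.quantile(xg, g.cut_quantile))
        if spec.effect_mode == "step":
            log_hazard = log_hazard + g.beta * (xg > cut)
        else:
            # linear robustness mode: same beta per SD of expression
            log_hazard = log_hazard + g.beta * (xg - xg.mean()) / xg.std()
        truth.append(
            {
                "gene_index": g.gene_index,
                "beta": g.beta,
                "cut_quantile": g.cut_quantile,
                "cutpoint": cut,
            }
        )

    rate = np.exp(log_hazard)
    event_time = rng_event.exponential(1.0 / rate)
    censor_time = rng_censor.uniform(0.0, spec.censor_horizon, spec.n_patients)
    os_months = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    probe_ids = [f"probe_{i:04d}" for i in range(spec.n_genes)]
    patient_ids = [f"PT{j:04d}" for j in range(spec.n_patients)]
    expr = pd.DataFrame(x, index=probe_ids, columns=patient_ids)
    clin = pd.DataFrame(
        {"patient_id": patient_ids, "os_months": os_months, "os_event": os_event}
    )
    for t in truth:
        t["probe_id"] = probe_ids[t["gene_index"]]
    return expr, clin, truth


def generate_cohort_pair(
    spec: SyntheticCohortSpec,
) -> tuple[Cohort, Cohort, list[dict]]:
    """Training and validation cohorts from the same generative law.

    The validation cohort reuses the planted effect structure but draws
    fresh expression and survival with an independent stream; its ground
    truth (training-scale cutpoints) is the training cohort's.
    """
    expr_t, clin_t, truth = generate_cohort(spec)
    valid_spec = replace(spec, seed=int(np.random.SeedSequence(spec.seed).spawn(4)[3].generate_state(1)[0] % (2**31)))
    expr_v, clin_v, _ = generate_cohort(valid_spec)
    return (
        Cohort(expression=expr_t, clinical=clin_t),
        Cohort(expression=expr_v, clinical=clin_v),
        truth,
    )


def generate_grouped_cohort(
    group_hazards: Sequence[float],
    n_per_group: int | Sequence[int],
    censor_horizon: float = 120.0,
    seed: int = 0,
) -> tuple[Cohort, list]:
    """A cohort whose risk-group structure is exact by construction.

    With K+1 hazard rates (one per count of high-risk genes 0..K), K
    pseudo-genes are created with cutpoint 0; a patient in group c has the
    first c genes at +1 (high side) and the rest at -1, plus small noise,
    so the count-based grouping recovers c exactly.  Survival is
    exponential at the group's hazard with Uniform(0, horizon) censoring.
    Intended for exercising the group-merging rule with known group laws.

    Returns the cohort and the gene rules (beta 1.0, direction +1).
    """
    from .io import GeneRule  # local import to avoid cycle at module load

    hazards = np.asarray(group_hazards, dtype=float)
    if hazards.ndim != 1 or hazards.size < 2 or (hazards <= 0).any():
        raise InvalidSpecError("need >=2 positive group hazards")
    k = hazards.size - 1
    if np.isscalar(n_per_group) or isinstance(n_per_group, (int, np.integer)):
        sizes = np.full(k + 1, int(n_per_group))
    else:
        sizes = np.asarray(n_per_group, dtype=int)
        if sizes.size != k + 1:
            raise InvalidSpecError("one group size per hazard required")
    if (sizes < 0).any() or sizes.sum() < 2:
        raise InvalidSpecError("invalid group sizes")

    rng = np.random.default_rng(seed)
    counts = np.repeat(np.arange(k + 1), sizes)
    n = counts.size
    x = np.where(np.arange(k)[:, None] < counts[None, :], 1.0, -1.0)
    x = x + rng.normal(0.0, 0.05, size=x.shape)
    event_time = rng.exponential(1.0 / hazards[counts])
    censor_time = rng.uniform(0.0, censor_horizon, n)
    os_months = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    probe_ids = [f"gene_{i}" for i in range(k)]
    patient_ids = [f"PT{j:04d}" for j in range(n)]
    expr = pd.DataFrame(x, index=probe_ids, columns=patient_ids)
    clin = pd.DataFrame(
        {"patient_id": patient_ids, "os_months": os_months, "os_event": os_event}
    )
    rules = [GeneRule(p, cutoff=0.0, beta=1.0, direction=1) for p in probe_ids]
    return Cohort(expression=expr, clinical=clin), rules


def generate_contingency_cohort(
    n: int,
    marginals: Sequence[float],
    log_odds: float,
    seed: int,
) -> np.ndarray:
    """Draw a 2x2 count table with given margins and population log odds ratio.

    The joint cell probabilities follow the Plackett construction: the
    unique 2x2 distribution with row margin ``p_r``, column margin ``p_c``
    and odds ratio exp(log_odds).  Counts are one multinomial draw of size
    ``n``, so the *expected* log odds ratio equals ``log_odds`` while the
    sample table fluctuates.
    """
    if n < 4:
        raise InvalidSpecError("n must be at least 4")
    p_r, p_c = marginals
    if not (0.0 < p_r < 1.0 and 0.0 < p_c < 1.0):
        raise InvalidSpecError("marginal fractions must lie strictly in (0, 1)")
    if not math.isfinite(log_odds):
        raise InvalidSpecError("log_odds must be finite")
    psi = math.exp(log_odds)
    if psi == 1.0:
        p11 = p_r * p_c
    else:
        s = 1.0 + (p_r + p_c) * (psi - 1.0)
        p11 = (s - math.sqrt(s * s - 4.0 * psi * (psi - 1.0) * p_r * p_c)) / (
            2.0 * (psi - 1.0)
        )
    probs = np.array(
        [p11, p_r - p11, p_c - p11, 1.0 - p_r - p_c + p11], dtype=float
    )
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, probs)
    return counts.reshape(2, 2)
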