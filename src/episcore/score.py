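"""Building, freezing and applying the dichotomized risk score.

The score for a patient is the sum over the K retained genes of the gene's
Cox beta weighted +1 or -1 according to whether the patient's expression
falls on the gene's high-risk side of its cutpoint.  Because group
membership only depends on *how many* genes are on the risk side, patients
are first stratified into K+1 raw groups by that count; adjacent groups
whose survival does not differ (two-sample log-rank) are then merged
iteratively — least-separated pair first — until every remaining adjacent
pair differs at the merge threshold.  The resulting count-to-group map is
frozen into the model together with each gene's cutoff, beta and
direction, and reapplied to validation cohorts without any re-estimation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import Cohort, EpiScoreModel, GeneRule
from .survival import CoxFit, LogrankResult, cox_fit, logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "fit_gene_betas",
    "prune_multivariate",
    "build_model",
    "apply_model",
    "compare_covariates",
]


def _risk_matrix(rules: Sequence[GeneRule], cohort: Cohort) -> pd.DataFrame:
    """Patients x genes 0/1 matrix of high-risk-side indicators."""
    missing = [g.probe_id for g in rules if g.probe_id not in cohort.expression.index]
    if missing:
        raise KeyError(f"model probes absent from cohort: {missing}")
    data = {
        g.probe_id: g.risk_indicator(cohort.expression.loc[g.probe_id].to_numpy())
        for g in rules
    }
    return pd.DataFrame(data, index=cohort.expression.columns)


def fit_gene_betas(
    rules: Sequence[GeneRule],
    cohort: Cohort,
    source: Literal["univariate", "multivariate"] = "univariate",
) -> list[GeneRule]:
    """Attach a Cox log-hazard-ratio to each gene's dichotomy.

    ``univariate`` (default) fits one Cox model per gene on its risk
    indicator; ``multivariate`` takes the coefficients of the joint fit.
    """
    ind = _risk_matrix(rules, cohort)
    t, e = cohort.times, cohort.events
    if source == "multivariate":
        fit = cox_fit(ind, t, e)
        betas = [fit.beta(g.probe_id) for g in rules]
    elif source == "univariate":
        betas = [
            cox_fit(ind[[g.probe_id]], t, e).beta(g.probe_id) for g in rules
        ]
    else:
        raise ValueError(f"unknown beta source {source!r}")
    return [replace(g, beta=float(b)) for g, b in zip(rules, betas)]


def prune_multivariate(
    rules: Sequence[GeneRule],
    cohort: Cohort,
    alpha: float = 0.05,
) -> tuple[list[GeneRule], CoxFit]:
    """Retain the genes that stay independently prognostic.

    Fits one multivariate Cox model on all dichotomized genes and keeps
    those with Wald p < alpha; the returned rules carry the multivariate
    betas of the retained genes (the score's betas may be refit separately
    via :func:`fit_gene_betas`).
    """
    if not rules:
        raise ValueError("no genes to prune")
    ind = _risk_matrix(rules, cohort)
    fit = cox_fit(ind, cohort.times, cohort.events)
    retained = [
        replace(g, beta=fit.beta(g.probe_id))
        for g in rules
        if fit.p_value(g.probe_id) < alpha
    ]
    return retained, fit


def _merge_counts(
    counts: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    k: int,
    merge_alpha: float,
) -> dict[int, int]:
    """Iteratively merge adjacent count-based groups with indistinct survival.

    Blocks start as the single counts 0..k; empty counts are first absorbed
    into the nearest non-empty neighbor (preferring the higher count).
    Then, while the least-separated adjacent pair of blocks has a
    two-sample log-rank p >= merge_alpha, that pair is merged and all
    adjacent p-values recomputed.  Returns count -> final group index.
    """
    occupancy = np.bincount(counts, minlength=k + 1)
    nonempty = [c for c in range(k + 1) if occupancy[c] > 0]
    if len(nonempty) < 2:
        warnings.warn("fewer than 2 non-empty raw groups; single-group model")
        return {c: 0 for c in range(k + 1)}

    # blocks of counts, ordered; empty counts join the nearest non-empty
    # neighbor, ties and all-below cases resolving toward the higher count
    owner = {}
    for c in range(k + 1):
        if occupancy[c] > 0:
            owner[c] = c
        else:
            higher = [x for x in nonempty if x > c]
            lower = [x for x in nonempty if x < c]
            if higher and (not lower or higher[0] - c <= c - lower[-1]):
                owner[c] = higher[0]
            else:
                owner[c] = lower[-1]
    blocks: list[list[int]] = [
        [c for c in range(k + 1) if owner[c] == b] for b in nonempty
    ]

    def block_mask(block: list[int]) -> np.ndarray:
        return np.isin(counts, block)

    while len(blocks) > 1:
        pvals = []
        for left, right in zip(blocks, blocks[1:]):
            mask = block_mask(left) | block_mask(right)
            lab = block_mask(right)[mask]
            pvals.append(
                logrank_test(times[mask], events[mask], lab.astype(int)).p_value
            )
        worst = int(np.argmax(pvals))
        if pvals[worst] < merge_alpha:
            break
        blocks[worst] = blocks[worst] + blocks.pop(worst + 1)
    return {c: i for i, block in enumerate(blocks) for c in block}


def _assignment(
    rules: Sequence[GeneRule], cohort: Cohort, merge_map: dict[int, int]
) -> pd.DataFrame:
    ind = _risk_matrix(rules, cohort)
    side = 2 * ind.to_numpy() - 1  # +1 risk side, -1 otherwise
    betas = np.array([g.beta for g in rules])
    score = side @ betas
    high_count = ind.to_numpy().sum(axis=1)
    return pd.DataFrame(
        {
            "patient_id": cohort.expression.columns,
            "score": score,
            "high_count": high_count,
            "group": [merge_map[int(c)] for c in high_count],
        }
    )


def build_model(
    rules: Sequence[GeneRule],
    cohort: Cohort,
    merge_alpha: float = 0.05,
    metadata: dict | None = None,
) -> tuple[EpiScoreModel, pd.DataFrame]:
    """Freeze a risk-score model on the training cohort.

    ``rules`` must carry fitted betas (see :func:`fit_gene_betas`).
    Returns the frozen model and the training-cohort assignment table
    (columns ``patient_id, score, high_count, group``).
    """
    rules = list(rules)
    if not rules:
        raise ValueError("model needs at least one gene")
    ind = _risk_matrix(rules, cohort)
    counts = ind.to_numpy().sum(axis=1)
    merge_map = _merge_counts(
        counts, cohort.times, cohort.events, len(rules), merge_alpha
    )
    model = EpiScoreModel(
        genes=rules,
        merge_map=merge_map,
        metadata={"merge_alpha": merge_alpha, **(metadata or {})},
    )
    return model, _assignment(rules, cohort, merge_map)


def apply_model(
    model: EpiScoreModel, cohort: Cohort
) -> tuple[pd.DataFrame, LogrankResult | None]:
    """Score a cohort with a frozen model; no re-estimation of any kind.

    Returns the assignment table and the log-rank test across the merged
    groups (None, with a warning, when only one group is populated).
    """
    assignment = _assignment(model.genes, cohort, model.merge_map)
    groups = assignment["group"].to_numpy()
    if np.unique(groups).size < 2:
        warnings.warn("all patients fall in a single risk group; "
                      "log-rank across groups is undefined")
        return assignment, None
    res = logrank_test(cohort.times, cohort.events, groups)
    return assignment, res


def compare_covariates(
    assignment: pd.DataFrame,
    cohort: Cohort,
    covariates: Sequence[str],
    mode: Literal["pairwise", "joint"] = "pairwise",
    score_col: str = "group",
) -> pd.DataFrame:
    """Cox comparisons of the risk score against competing covariates.

    The score enters as the ordinal merged-group code.  ``pairwise`` fits
    one bivariate Cox per competing covariate (complete-case per fit);
    ``joint`` fits all terms simultaneously.  Constant covariates are
    excluded with a warning.  Returns one row per (model, term) with
    beta, HR and Wald p.
    """
    clin = cohort.clinical.set_index("patient_id")
    base = clin.loc[assignment["patient_id"]].reset_index()
    base["episcore"] = assignment[score_col].to_numpy(dtype=float)

    usable = []
    for cov in covariates:
        if cov not in base.columns:
            raise KeyError(f"covariate {cov!r} absent from clinical table")
        if base[cov].nunique(dropna=True) <= 1:
            warnings.warn(f"covariate {cov!r} is degenerate; excluded")
            continue
        usable.append(cov)

    rows = []

    def fit_terms(cols: list[str], label: str) -> None:
        sub = base[["os_months", "os_event", *cols]].dropna()
        fit = cox_fit(sub[cols], sub["os_months"].to_numpy(),
                      sub["os_event"].to_numpy(dtype=int))
        for term in cols:
            rows.append(
                {
                    "model": label,
                    "term": term,
                    "beta": fit.beta(term),
                    "hazard_ratio": fit.hazard_ratio(term),
                    "p": fit.p_value(term),
                    "n": len(sub),
                }
            )

    fit_terms(["episcore"], "univariate")
    if mode == "pairwise":
        for cov in usable:
            fit_terms(["episcore", cov], f"episcore+{cov}")
    elif mode == "joint":
        fit_terms(["episcore", *usable], "joint")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows)
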