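"""Readers, writers and validation for expression matrices, clinical tables
and frozen score models.

Expression matrices are plain TSV: first column the probe id, remaining
columns one per patient, values in MAS5-like arbitrary units.  Clinical
tables are CSV with at least ``patient_id``, ``os_months`` (months of
follow-up) and ``os_event`` (1 = death observed, 0 = censored); any further
columns are carried along as covariates.  A trained score model is frozen
to JSON and reapplied without re-estimation.

Times are in months throughout; no unit conversion is ever applied.
Expression values are used as stored — no implicit log transform.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_CLINICAL_COLUMNS = ("patient_id", "os_months", "os_event")


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


class SchemaError(ValueError):
    """A frozen model violated its schema."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check an expression matrix (probes x patients): unique ids, finite values."""
    if expr.index.duplicated().any():
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate probe ids: {dupes}")
    if expr.columns.duplicated().any():
        dupes = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate patient ids: {dupes}")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = expr.columns[
            [not np.issubdtype(d, np.number) for d in expr.dtypes]
        ].tolist()
        raise FormatError(f"non-numeric expression columns: {bad}")
    if not np.isfinite(values).all():
        rows = expr.index[~np.isfinite(values).all(axis=1)].tolist()
        raise FormatError(f"non-finite expression values in probes: {rows}")
    return expr


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a probes-x-patients expression TSV into a DataFrame.

    Raises :class:`FormatError` on duplicate ids, non-numeric cells or
    ragged rows, naming the offending line where pandas reports one.
    """
    try:
        expr = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: malformed expression TSV: {exc}") from exc
    for col in expr.columns:
        if not np.issubdtype(expr[col].dtype, np.number):
            bad = expr.index[pd.to_numeric(expr[col], errors="coerce").isna()]
            raise FormatError(
                f"{path}: non-numeric value for patient {col!r}"
                f" at probe(s) {bad.tolist()[:5]}"
            )
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    expr.index.name = None  # round-trip identity with in-memory matrices
    return validate_expression(expr)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    validate_expression(expr).to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

def validate_clinical(clin: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_CLINICAL_COLUMNS:
        if col not in clin.columns:
            raise FormatError(f"clinical table missing required column {col!r}")
    if clin["patient_id"].duplicated().any():
        dupes = clin.loc[clin["patient_id"].duplicated(), "patient_id"].tolist()
        raise FormatError(f"duplicate patient ids: {dupes}")
    times = clin["os_months"].to_numpy(dtype=float)
    if not np.isfinite(times).all() or (times < 0).any():
        raise FormatError("os_months must be finite and non-negative")
    events = clin["os_event"].to_numpy()
    if not np.isin(events, (0, 1)).all():
        raise FormatError("os_event must be 0 or 1")
    return clin


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the per-patient clinical CSV.  Missing covariate values stay NaN
    and are handled per-model by complete-case analysis downstream."""
    try:
        clin = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: malformed clinical CSV: {exc}") from exc
    clin["patient_id"] = clin["patient_id"].astype(str)
    return validate_clinical(clin)


def write_clinical(clin: pd.DataFrame, path: str | Path) -> None:
    validate_clinical(clin).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# aligned cohort
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """An expression matrix and a clinical table restricted to the same
    patients in the same order."""

    expression: pd.DataFrame  # probes x patients
    clinical: pd.DataFrame    # one row per patient, same order as columns

    @property
    def n_patients(self) -> int:
        return self.expression.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.clinical["os_months"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.clinical["os_event"].to_numpy(dtype=int)


def align_cohort(expr: pd.DataFrame, clin: pd.DataFrame) -> Cohort:
    """Restrict expression and clinical data to their shared patients.

    Patient order follows the expression matrix.  Dropped ids are counted
    and logged; fewer than 2 shared patients is an error.
    """
    validate_expression(expr)
    validate_clinical(clin)
    clin_ids = set(clin["patient_id"])
    shared = [p for p in expr.columns if p in clin_ids]
    if len(shared) < 2:
        raise ValueError(
            f"only {len(shared)} patient(s) shared between expression and clinical data"
        )
    n_dropped = (len(expr.columns) - len(shared)) + (len(clin_ids) - len(shared))
    if n_dropped:
        logger.warning("align_cohort: dropped %d unmatched patient id(s)", n_dropped)
    expr_a = expr.loc[:, shared]
    clin_a = (
        clin.set_index("patient_id").loc[shared].reset_index()
    )
    return Cohort(expression=expr_a, clinical=clin_a)


# ---------------------------------------------------------------------------
# frozen score models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRule:
    """One gene of a frozen risk score.

    ``direction`` is +1 when expression strictly above ``cutoff`` marks the
    high-risk side, -1 when at-or-below the cutoff does.  A value exactly
    equal to the cutoff always falls on the "below" side.
    """

    probe_id: str
    cutoff: float
    beta: float
    direction: int

    def risk_indicator(self, x: np.ndarray) -> np.ndarray:
        """1 where the patient lies on the gene's high-risk side."""
        above = np.asarray(x, dtype=float) > self.cutoff  # ties go low
        return (above if self.direction > 0 else ~above).astype(int)


@dataclass
class EpiScoreModel:
    """A frozen ±beta-weighted dichotomized risk score.

    ``merge_map`` sends the raw count of high-risk genes (0..K) to the
    merged risk-group label (0..G-1, order preserving).
    """

    genes: list[GeneRule]
    merge_map: dict[int, int]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.genes)
        for g in self.genes:
            if not math.isfinite(g.cutoff):
                raise SchemaError(f"non-finite cutoff for probe {g.probe_id!r}")
            if not math.isfinite(g.beta):
                raise SchemaError(f"non-finite beta for probe {g.probe_id!r}")
            if g.direction not in (-1, 1):
                raise SchemaError(f"direction must be ±1 for probe {g.probe_id!r}")
        expected = list(range(k + 1))
        if sorted(self.merge_map) != expected:
            raise SchemaError(
                f"merge map must cover counts 0..{k}, got {sorted(self.merge_map)}"
            )
        labels = [self.merge_map[c] for c in expected]
        if any(b < a for a, b in zip(labels, labels[1:])):
            raise SchemaError("merged labels must be non-decreasing in count")
        if sorted(set(labels)) != list(range(max(labels) + 1)):
            raise SchemaError("merged labels must be consecutive from 0")

    @property
    def n_groups(self) -> int:
        return max(self.merge_map.values()) + 1


def write_model(model: EpiScoreModel, path: str | Path) -> None:
    payload = {
        "genes": [dataclasses.asdict(g) for g in model.genes],
        "merge_map": {str(k): v for k, v in model.merge_map.items()},
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_model(path: str | Path) -> EpiScoreModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON: {exc}") from exc
    try:
        genes = [GeneRule(**g) for g in payload["genes"]]
        merge_map = {int(k): int(v) for k, v in payload["merge_map"].items()}
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: missing or malformed field: {exc}") from exc
    return EpiScoreModel(genes=genes, merge_map=merge_map,
                         metadata=payload.get("metadata", {}))
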