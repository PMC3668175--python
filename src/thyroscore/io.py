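"""Cohort CSV reading, validation and writing.

Schema (header required, feature codes case-insensitive, UTF-8, comma
separated)::

    id,G,L,O,C1,V,E,M,H,C2,D,dim1_mm,dim2_mm,dim3_mm,exam_date,
    prior_dim1_mm,prior_dim2_mm,prior_dim3_mm,prior_exam_date,
    tbsrtc,malignant

Only ``id`` and the feature columns that are actually used must be present.
Booleans are accepted as 1/0, true/false, yes/no (any case); dates are
ISO-8601; lengths are millimetres.  Two features can be derived when their
column is missing or blank:

* ``D`` (diameter > 30 mm) from ``dim*_mm`` when present;
* ``G`` (rapid growth) from the prior and current dated measurements.

Any feature still unresolved is handled by ``missing_policy``: ``"reject"``
(default) fails the record with its line number; ``"false"`` treats the
feature as absent and logs a warning — a deliberate, visible imputation,
never a silent one.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .config import DEFAULT_CONFIG, ScoringConfig
from .features import FEATURE_CODES, NoduleMeasurement, USFeatureProfile
from .management import TBSRTCCategory
from .scoring import detect_rapid_growth, diameter_criterion

log = logging.getLogger("thyroscore")

__all__ = ["CohortRecord", "CohortValidationError", "read_cohort", "write_cohort", "COLUMNS"]

_DIM_COLS = ("dim1_mm", "dim2_mm", "dim3_mm")
_PRIOR_DIM_COLS = ("prior_dim1_mm", "prior_dim2_mm", "prior_dim3_mm")
COLUMNS: tuple[str, ...] = (
    "id",
    *FEATURE_CODES,
    *_DIM_COLS,
    "exam_date",
    *_PRIOR_DIM_COLS,
    "prior_exam_date",
    "tbsrtc",
    "malignant",
)

_TRUE = {"1", "true", "yes", "t", "y"}
_FALSE = {"0", "false", "no", "f", "n"}


class CohortValidationError(ValueError):
    """A cohort file or record failed validation; message carries line numbers."""


@dataclass(frozen=True)
class CohortRecord:
    """One validated nodule record with a fully resolved feature profile."""

    record_id: str
    profile: USFeatureProfile
    measurement: Optional[NoduleMeasurement] = None
    prior_measurement: Optional[NoduleMeasurement] = None
    tbsrtc: Optional[TBSRTCCategory] = None
    malignant: Optional[bool] = None


def _parse_bool(raw: object, where: str) -> Optional[bool]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    text = str(raw).strip().lower()
    if text == "":
        return None
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise CohortValidationError(f"{where}: cannot parse boolean value {raw!r}")


def _parse_measurement(
    row: pd.Series, dim_cols: tuple[str, ...], date_col: str, where: str
) -> Optional[NoduleMeasurement]:
    raw_dims = [row.get(c) for c in dim_cols]
    raw_date = row.get(date_col)
    present = [v for v in raw_dims if v not in (None, "") and not pd.isna(v)]
    has_date = raw_date not in (None, "") and not pd.isna(raw_date)
    if not present and not has_date:
        return None
    if len(present) != 3 or not has_date:
        raise CohortValidationError(
            f"{where}: a measurement needs all three of {dim_cols} and {date_col}"
        )
    try:
        dims = tuple(float(v) for v in raw_dims)
        date = datetime.date.fromisoformat(str(raw_date).strip())
        return NoduleMeasurement(dims_mm=dims, date=date)
    except (TypeError, ValueError) as exc:
        raise CohortValidationError(f"{where}: invalid measurement: {exc}") from exc


def _resolve_record(
    row: pd.Series,
    line: int,
    missing_policy: str,
    config: ScoringConfig,
) -> CohortRecord:
    where = f"line {line}"
    record_id = str(row.get("id", "")).strip()
    if not record_id:
        raise CohortValidationError(f"{where}: missing record id")

    features: dict[str, Optional[bool]] = {
        code: _parse_bool(row.get(code), f"{where}, column {code}") for code in FEATURE_CODES
    }
    measurement = _parse_measurement(row, _DIM_COLS, "exam_date", where)
    prior = _parse_measurement(row, _PRIOR_DIM_COLS, "prior_exam_date", where)

    if features["D"] is None and measurement is not None:
        features["D"] = diameter_criterion(measurement.dims_mm, config)
    if features["G"] is None and measurement is not None and prior is not None:
        try:
            features["G"] = detect_rapid_growth(prior, measurement, config=config)
        except ValueError as exc:
            raise CohortValidationError(f"{where}: cannot derive G: {exc}") from exc

    unresolved = [c for c, v in features.items() if v is None]
    if unresolved:
        if missing_policy == "reject":
            raise CohortValidationError(
                f"{where}: missing feature value(s) {unresolved} (missing_policy='reject')"
            )
        log.warning("%s: treating missing feature(s) %s as false", where, unresolved)
        for c in unresolved:
            features[c] = False

    raw_tbsrtc = row.get("tbsrtc")
    tbsrtc = None
    if raw_tbsrtc not in (None, "") and not pd.isna(raw_tbsrtc):
        try:
            tbsrtc = TBSRTCCategory.parse(raw_tbsrtc)
        except ValueError as exc:
            raise CohortValidationError(f"{where}: {exc}") from exc

    return CohortRecord(
        record_id=record_id,
        profile=USFeatureProfile.from_codes({c: bool(v) for c, v in features.items()}),
        measurement=measurement,
        prior_measurement=prior,
        tbsrtc=tbsrtc,
        malignant=_parse_bool(row.get("malignant"), f"{where}, column malignant"),
    )


def read_cohort(
    path: str | Path,
    missing_policy: str = "reject",
    config: ScoringConfig | None = None,
) -> list[CohortRecord]:
    """Read and validate a cohort CSV; see the module docstring for the schema."""
    if missing_policy not in ("reject", "false"):
        raise ValueError(f"missing_policy must be 'reject' or 'false', got {missing_policy!r}")
    config = config or DEFAULT_CONFIG.scoring
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    # header codes are case-insensitive; canonicalise
    canon = {c.lower(): c for c in COLUMNS}
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in canon:
            rename[col] = canon[key]
        else:
            raise CohortValidationError(f"unknown column {col!r} in {path.name}")
    df = df.rename(columns=rename)
    if "id" not in df.columns:
        raise CohortValidationError(f"{path.name}: required column 'id' missing")

    records = []
    errors = []
    for i, (_, row) in enumerate(df.iterrows()):
        line = i + 2  # header is line 1
        try:
            records.append(_resolve_record(row, line, missing_policy, config))
        except CohortValidationError as exc:
            errors.append(str(exc))
    if errors:
        raise CohortValidationError(
            f"{path.name}: {len(errors)} invalid record(s):\n" + "\n".join(errors)
        )
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise CohortValidationError(f"{path.name}: duplicate record id(s): {dupes}")
    log.info("read %d valid record(s) from %s", len(records), path)
    return records


def _fmt_bool(v: Optional[bool]) -> str:
    return "" if v is None else str(v).lower()


def write_cohort(records: list[CohortRecord], path: str | Path) -> None:
    """Write records in the standard cohort CSV schema (round-trips with read)."""
    rows = []
    for r in records:
        row: dict[str, object] = {"id": r.record_id}
        row.update({c: _fmt_bool(v) for c, v in r.profile.code_values().items()})
        for meas, dim_cols, date_col in (
            (r.measurement, _DIM_COLS, "exam_date"),
            (r.prior_measurement, _PRIOR_DIM_COLS, "prior_exam_date"),
        ):
            if meas is not None:
                row.update(dict(zip(dim_cols, (f"{d:g}" for d in meas.dims_mm))))
                row[date_col] = meas.date.isoformat()
            else:
                row.update({c: "" for c in dim_cols})
                row[date_col] = ""
        row["tbsrtc"] = r.tbsrtc.value if r.tbsrtc is not None else ""
        row["malignant"] = _fmt_bool(r.malignant)
        rows.append(row)
    pd.DataFrame(rows, columns=list(COLUMNS)).to_csv(path, index=False)
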