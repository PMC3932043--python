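"""Readers and writers for the delimited-file schemas shared by all stages.

Files are comma-delimited UTF-8 with ISO-8601 dates (``YYYY-MM`` for months,
``YYYY-MM-DD`` for days); ordered diagnosis-code lists are serialized as a
pipe-separated string.  Booleans are written ``true``/``false``.  Unknown
columns are preserved as opaque string payload and written back verbatim, so
write -> read -> write round-trips are lossless.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .datamodel import Claim, EnrollmentSpan, RegistryRecord
from .errors import RowParseError, SchemaError

logger = logging.getLogger(__name__)

REGISTRY_COLUMNS = (
    "patient_id",
    "dx_month",
    "ajcc_m",
    "age_at_dx",
    "sex",
    "race",
    "prior_cancer_within_5y",
    "comorbidity_class",
)
CLAIM_COLUMNS = (
    "patient_id",
    "setting",
    "service_date",
    "dx_codes",
    "service_category",
    "is_physician_em",
)
ENROLLMENT_COLUMNS = ("patient_id", "month", "part_a", "part_b", "hmo")

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(value, row: int) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise RowParseError(f"cannot parse boolean {value!r}", row=row)


def _fmt_bool(value: bool) -> str:
    return "true" if value else "false"


def _load_frame(path: str | Path, mandatory: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [col for col in mandatory if col not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {', '.join(missing)}")
    return frame


def _extras(frame: pd.DataFrame, known: Sequence[str]) -> list[str]:
    return [col for col in frame.columns if col not in known]


def read_registry(path: str | Path) -> list[RegistryRecord]:
    frame = _load_frame(path, REGISTRY_COLUMNS)
    extra_cols = _extras(frame, REGISTRY_COLUMNS)
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            records.append(
                RegistryRecord(
                    patient_id=row["patient_id"],
                    dx_month=row["dx_month"],
                    ajcc_m=row["ajcc_m"],
                    age_at_dx=int(row["age_at_dx"]),
                    sex=row["sex"],
                    race=row["race"],
                    prior_cancer_within_5y=_parse_bool(row["prior_cancer_within_5y"], i),
                    comorbidity_class=row["comorbidity_class"],
                    extra={c: row[c] for c in extra_cols},
                )
            )
        except (RowParseError, ValueError) as exc:
            raise RowParseError(str(exc), row=i) from exc
    logger.info("read %d registry records from %s", len(records), path)
    return records


def read_claims(path: str | Path) -> list[Claim]:
    frame = _load_frame(path, CLAIM_COLUMNS)
    extra_cols = _extras(frame, CLAIM_COLUMNS)
    claims = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            claims.append(
                Claim(
                    patient_id=row["patient_id"],
                    setting=row["setting"],
                    service_date=row["service_date"],
                    dx_codes=tuple(c for c in row["dx_codes"].split("|") if c),
                    service_category=row["service_category"],
                    is_physician_em=_parse_bool(row["is_physician_em"], i),
                    extra={c: row[c] for c in extra_cols},
                )
            )
        except (RowParseError, ValueError) as exc:
            raise RowParseError(str(exc), row=i) from exc
    logger.info("read %d claims from %s", len(claims), path)
    return claims


def read_enrollment(path: str | Path) -> list[EnrollmentSpan]:
    frame = _load_frame(path, ENROLLMENT_COLUMNS)
    extra_cols = _extras(frame, ENROLLMENT_COLUMNS)
    spans = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            spans.append(
                EnrollmentSpan(
                    patient_id=row["patient_id"],
                    month=row["month"],
                    part_a=_parse_bool(row["part_a"], i),
                    part_b=_parse_bool(row["part_b"], i),
                    hmo=_parse_bool(row["hmo"], i),
                    extra={c: row[c] for c in extra_cols},
                )
            )
        except (RowParseError, ValueError) as exc:
            raise RowParseError(str(exc), row=i) from exc
    logger.info("read %d enrollment spans from %s", len(spans), path)
    return spans


def read_tables(
    directory: str | Path,
) -> tuple[list[RegistryRecord], list[Claim], list[EnrollmentSpan]]:
    """Read ``registry.csv``, ``claims.csv`` and ``enrollment.csv`` from a directory."""
    directory = Path(directory)
    return (
        read_registry(directory / "registry.csv"),
        read_claims(directory / "claims.csv"),
        read_enrollment(directory / "enrollment.csv"),
    )


def _record_frame(records: Iterable, base_row) -> pd.DataFrame:
    rows = []
    extra_cols: list[str] = []
    for rec in records:
        row = base_row(rec)
        for key, value in rec.extra.items():
            if key not in extra_cols:
                extra_cols.append(key)
            row[key] = value
        rows.append(row)
    return pd.DataFrame(rows)


def write_registry(records: Iterable[RegistryRecord], path: str | Path) -> None:
    frame = _record_frame(
        records,
        lambda r: {
            "patient_id": r.patient_id,
            "dx_month": str(r.dx_month),
            "ajcc_m": r.ajcc_m,
            "age_at_dx": r.age_at_dx,
            "sex": r.sex,
            "race": r.race,
            "prior_cancer_within_5y": _fmt_bool(r.prior_cancer_within_5y),
            "comorbidity_class": r.comorbidity_class,
        },
    )
    if frame.empty:
        frame = pd.DataFrame(columns=REGISTRY_COLUMNS)
    frame.to_csv(path, index=False)


def write_claims(claims: Iterable[Claim], path: str | Path) -> None:
    frame = _record_frame(
        claims,
        lambda c: {
            "patient_id": c.patient_id,
            "setting": c.setting,
            "service_date": c.service_date.isoformat(),
            "dx_codes": "|".join(c.dx_codes),
            "service_category": c.service_category,
            "is_physician_em": _fmt_bool(c.is_physician_em),
        },
    )
    if frame.empty:
        frame = pd.DataFrame(columns=CLAIM_COLUMNS)
    frame.to_csv(path, index=False)


def write_enrollment(spans: Iterable[EnrollmentSpan], path: str | Path) -> None:
    frame = _record_frame(
        spans,
        lambda s: {
            "patient_id": s.patient_id,
            "month": str(s.month),
            "part_a": _fmt_bool(s.part_a),
            "part_b": _fmt_bool(s.part_b),
            "hmo": _fmt_bool(s.hmo),
        },
    )
    if frame.empty:
        frame = pd.DataFrame(columns=ENROLLMENT_COLUMNS)
    frame.to_csv(path, index=False)


def write_tables(
    registry: Iterable[RegistryRecord],
    claims: Iterable[Claim],
    enrollment: Iterable[EnrollmentSpan],
    directory: str | Path,
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_registry(registry, directory / "registry.csv")
    write_claims(claims, directory / "claims.csv")
    write_enrollment(enrollment, directory / "enrollment.csv")


def claims_by_patient(claims: Iterable[Claim]) -> dict[str, list[Claim]]:
    """Group claims by patient id, preserving input order."""
    grouped: dict[str, list[Claim]] = {}
    for claim in claims:
        grouped.setdefault(claim.patient_id, []).append(claim)
    return grouped
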