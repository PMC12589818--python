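"""PSQA record model, CSV I/O and validation.

One :class:`PSQARecord` is one patient-specific QA verification measurement:
a pseudonymous patient key, the stratification metadata (facility, machine,
QA device, disease site), the QA and plan-approval dates, the gamma passing
rate (%) per gamma criterion, and the signed absolute-dose difference (%)
between measurement and calculation.

The exchange format is flat RFC-4180 CSV (UTF-8), one column per gamma
criterion named ``gamma_<dose>_<dta>`` (``gamma_3_3`` for 3%/3 mm), dates in
ISO-8601.  Ingest applies range checks to numeric fields and controlled
vocabularies to categorical fields; rows that violate an error-severity rule
are rejected and reported, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import vocab
from .vocab import UNMAPPED, normalize_site

__all__ = [
    "GammaCriterion",
    "PSQARecord",
    "ValidationIssue",
    "ValidationReport",
    "DOSE_DIFF",
    "read_records",
    "write_records",
    "records_to_frame",
    "filter_records",
    "normalize_site",
]

#: Channel name for the absolute dose-difference channel (a signed percent
#: with process target 0, unlike the gamma channels whose target is 100).
DOSE_DIFF = "dose_diff_pct"

_MANDATORY_COLUMNS = (
    "patient_key",
    "facility",
    "machine",
    "qa_device",
    "site",
    "qa_date",
    "gamma_3_3",
)
_OPTIONAL_COLUMNS = ("approval_date", "gamma_2_2", DOSE_DIFF)


@dataclass(frozen=True, order=True)
class GammaCriterion:
    """A dose-difference / distance-to-agreement pair naming a passing-rate
    channel, e.g. ``GammaCriterion(3, 3)`` for the 3%/3 mm gamma test."""

    dose_pct: float
    dta_mm: float

    def __post_init__(self) -> None:
        if not (self.dose_pct > 0 and self.dta_mm > 0):
            raise ValueError(
                f"gamma criterion requires positive tolerances, got "
                f"{self.dose_pct}%/{self.dta_mm}mm"
            )

    @property
    def label(self) -> str:
        """Canonical rendering, e.g. ``"3%/3mm"``."""
        return f"{_fmt_num(self.dose_pct)}%/{_fmt_num(self.dta_mm)}mm"

    @property
    def column(self) -> str:
        """CSV column name, e.g. ``"gamma_3_3"``."""
        return f"gamma_{_fmt_num(self.dose_pct)}_{_fmt_num(self.dta_mm)}"

    @classmethod
    def parse(cls, text: "str | GammaCriterion") -> "GammaCriterion":
        """Parse ``"3/3"``, ``"3%/3mm"``, ``"gamma_3_3"`` or ``"2%/2 mm"``."""
        if isinstance(text, GammaCriterion):
            return text
        m = re.fullmatch(
            r"(?:gamma[_ ])?(\d+(?:\.\d+)?)\s*%?\s*[/_]\s*(\d+(?:\.\d+)?)\s*(?:mm)?",
            str(text).strip(),
        )
        if m is None:
            raise ValueError(f"cannot parse gamma criterion from {text!r}")
        return cls(float(m.group(1)), float(m.group(2)))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


CRITERION_3_3 = GammaCriterion(3, 3)
CRITERION_2_2 = GammaCriterion(2, 2)


@dataclass
class PSQARecord:
    """One QA verification measurement with its stratification metadata."""

    patient_key: str
    facility: str
    machine: str
    qa_device: str
    site: str
    qa_date: _dt.date
    gamma_pass: dict[GammaCriterion, float]
    approval_date: _dt.date | None = None
    dose_diff_pct: float | None = None

    def channel_value(self, channel: "GammaCriterion | str") -> float | None:
        """Value of a measurement channel: a gamma criterion or ``dose_diff_pct``."""
        if isinstance(channel, str) and channel == DOSE_DIFF:
            return self.dose_diff_pct
        return self.gamma_pass.get(GammaCriterion.parse(channel))


@dataclass(frozen=True)
class ValidationIssue:
    row: int  # 0-based data-row index in the input file
    field: str
    rule: str
    severity: str  # "error" | "warning"
    message: str = ""


@dataclass
class ValidationReport:
    """Outcome of validating an input file: every row is counted exactly once
    as accepted or rejected, and every rejected row carries at least one
    error-severity issue."""

    accepted: int = 0
    rejected: int = 0
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "accepted": self.accepted,
            "rejected": self.rejected,
            "issues": [dataclasses.asdict(i) for i in self.issues],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Reading and validation


def _parse_date(text: str) -> _dt.date:
    return _dt.date.fromisoformat(text.strip())


def _gamma_columns(columns: Iterable[str]) -> dict[str, GammaCriterion]:
    out: dict[str, GammaCriterion] = {}
    for col in columns:
        if col.startswith("gamma_"):
            out[col] = GammaCriterion.parse(col)
    return out


def read_records(
    path: str | Path,
    *,
    delimiter: str = ",",
    dose_diff_window: tuple[float, float] = (-10.0, 10.0),
    site_synonyms: dict[str, str] | None = None,
) -> tuple[list[PSQARecord], ValidationReport]:
    """Read and validate a PSQA CSV file.

    Rows that pass all error-severity rules become :class:`PSQARecord`
    objects; the rest are rejected and itemized in the returned
    :class:`ValidationReport`.  Severity policy: missing mandatory field,
    out-of-range numeric value (gamma outside [0, 100], dose difference
    outside ``dose_diff_window``), unparseable date and unmapped disease
    site are **errors** (row rejected); a machine, device or facility label
    outside the controlled vocabulary is a **warning** (row kept).

    Raises
    ------
    ValueError
        If a mandatory column is absent (named in the message) or the file
        cannot be parsed as delimited text.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed file is a hard failure
        raise ValueError(f"cannot parse {path} as delimited text: {exc}") from exc

    missing = [c for c in _MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")

    gamma_cols = _gamma_columns(frame.columns)
    records: list[PSQARecord] = []
    report = ValidationReport()
    lo, hi = dose_diff_window

    for idx, row in enumerate(frame.itertuples(index=False)):
        row_map = dict(zip(frame.columns, row))
        issues: list[ValidationIssue] = []

        def err(fieldname: str, rule: str, msg: str = "") -> None:
            issues.append(ValidationIssue(idx, fieldname, rule, "error", msg))

        def warn(fieldname: str, rule: str, msg: str = "") -> None:
            issues.append(ValidationIssue(idx, fieldname, rule, "warning", msg))

        for col in _MANDATORY_COLUMNS:
            if not str(row_map.get(col, "")).strip():
                err(col, "missing_mandatory", f"{col} is mandatory")

        qa_date: _dt.date | None = None
        if str(row_map.get("qa_date", "")).strip():
            try:
                qa_date = _parse_date(row_map["qa_date"])
            except ValueError:
                err("qa_date", "unparseable_date", row_map["qa_date"])
        approval_date: _dt.date | None = None
        if str(row_map.get("approval_date", "")).strip():
            try:
                approval_date = _parse_date(row_map["approval_date"])
            except ValueError:
                err("approval_date", "unparseable_date", row_map["approval_date"])

        site = normalize_site(row_map.get("site", ""), site_synonyms)
        if str(row_map.get("site", "")).strip() and site == UNMAPPED:
            err("site", "unmapped_site", row_map["site"])

        gamma_pass: dict[GammaCriterion, float] = {}
        for col, crit in gamma_cols.items():
            raw = str(row_map.get(col, "")).strip()
            if not raw:
                continue
            try:
                value = float(raw)
            except ValueError:
                err(col, "not_numeric", raw)
                continue
            if not (0.0 <= value <= 100.0):
                err(col, "out_of_range", f"{value} outside [0, 100]")
                continue
            gamma_pass[crit] = value

        dose_diff: float | None = None
        raw_dd = str(row_map.get(DOSE_DIFF, "")).strip()
        if raw_dd:
            try:
                dose_diff = float(raw_dd)
            except ValueError:
                err(DOSE_DIFF, "not_numeric", raw_dd)
            else:
                if not (lo <= dose_diff <= hi) or not math.isfinite(dose_diff):
                    err(DOSE_DIFF, "out_of_range", f"{dose_diff} outside [{lo}, {hi}]")
                    dose_diff = None

        facility = str(row_map.get("facility", "")).strip()
        if facility and facility not in vocab.known_facilities():
            warn("facility", "unknown_vocabulary", facility)
        machine = str(row_map.get("machine", "")).strip()
        if machine and machine not in vocab.known_machines():
            warn("machine", "unknown_vocabulary", machine)
        device = str(row_map.get("qa_device", "")).strip()
        if device and device not in vocab.known_devices():
            warn("qa_device", "unknown_vocabulary", device)

        report.issues.extend(issues)
        if any(i.severity == "error" for i in issues):
            report.rejected += 1
            continue
        report.accepted += 1
        records.append(
            PSQARecord(
                patient_key=str(row_map["patient_key"]).strip(),
                facility=facility,
                machine=machine,
                qa_device=device,
                site=site,
                qa_date=qa_date,  # type: ignore[arg-type]  # error'd above if None
                approval_date=approval_date,
                gamma_pass=gamma_pass,
                dose_diff_pct=dose_diff,
            )
        )
    return records, report


# ---------------------------------------------------------------------------
# Writing


def records_to_frame(records: Sequence[PSQARecord]) -> pd.DataFrame:
    """Tabular view of records; missing optional values become empty cells."""
    criteria = sorted({c for r in records for c in r.gamma_pass})
    if not criteria:
        criteria = [CRITERION_3_3]
    columns = list(_MANDATORY_COLUMNS[:6]) + ["approval_date"]
    columns += [c.column for c in criteria] + [DOSE_DIFF]
    rows = []
    for r in records:
        row: dict[str, object] = {
            "patient_key": r.patient_key,
            "facility": r.facility,
            "machine": r.machine,
            "qa_device": r.qa_device,
            "site": r.site,
            "qa_date": r.qa_date.isoformat(),
            "approval_date": r.approval_date.isoformat() if r.approval_date else "",
        }
        for c in criteria:
            v = r.gamma_pass.get(c)
            row[c.column] = "" if v is None else repr(float(v))
        row[DOSE_DIFF] = "" if r.dose_diff_pct is None else repr(float(r.dose_diff_pct))
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)


def write_records(records: Sequence[PSQARecord], path: str | Path) -> None:
    """Write records as CSV; ``read_records`` of the output reproduces them
    field-for-field (floats serialized with ``repr`` for losslessness)."""
    frame = records_to_frame(records)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Filtering


def filter_records(
    records: Sequence[PSQARecord],
    *,
    site: str | None = None,
    facility: str | None = None,
    criterion: "GammaCriterion | str | None" = None,
    date_from: _dt.date | str | None = None,
    date_to: _dt.date | str | None = None,
) -> list[PSQARecord]:
    """Subset records by stratum and inclusive date window, preserving order.

    ``criterion`` keeps only records that carry a passing rate for that gamma
    channel.  Unknown ``site`` or ``facility`` values raise ``ValueError``
    rather than silently matching nothing.
    """
    if site is not None and site not in vocab.SITES:
        raise ValueError(f"unknown site {site!r}; expected one of {vocab.SITES}")
    if facility is not None and facility not in vocab.known_facilities():
        raise ValueError(
            f"unknown facility {facility!r}; expected one of {vocab.known_facilities()}"
        )
    crit = GammaCriterion.parse(criterion) if criterion is not None else None
    lo = _dt.date.fromisoformat(date_from) if isinstance(date_from, str) else date_from
    hi = _dt.date.fromisoformat(date_to) if isinstance(date_to, str) else date_to

    out = []
    for r in records:
        if site is not None and r.site != site:
            continue
        if facility is not None and r.facility != facility:
            continue
        if crit is not None and crit not in r.gamma_pass:
            continue
        if lo is not None and r.qa_date < lo:
            continue
        if hi is not None and r.qa_date > hi:
            continue
        out.append(r)
    return out
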