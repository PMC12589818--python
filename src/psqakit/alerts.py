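"""IQR outlier flagging and action/tolerance-limit breach alerting.

Two alerting layers run over a cohort:

* **Limit breaches** — a passing rate strictly below its stratum's tolerance
  limit raises a ``TL_breach``; strictly below the action limit raises the
  more severe ``AL_breach`` (which notes that the TL is also crossed).
  Boundary equality is not a breach: the limits are lower bounds for
  acceptable results.  Dose-difference channels breach on either side of the
  two-sided limits.

* **Statistical outliers** — Tukey fences at the quartiles ± k·IQR
  (default k = 1.5), quartiles by linear interpolation between order
  statistics, evaluated within each stratum.  Values strictly outside the
  fences are flagged.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .limits import LimitSet, stratum_label
from .records import DOSE_DIFF, GammaCriterion, PSQARecord

__all__ = ["DEFAULT_FENCE_K", "OutlierReport", "Alert", "iqr_outliers", "evaluate_alerts"]

DEFAULT_FENCE_K = 1.5

AL_BREACH = "AL_breach"
TL_BREACH = "TL_breach"
OUTLIER = "outlier"


@dataclass
class OutlierReport:
    """Tukey-fence outlier scan of one value series."""

    q1: float
    q3: float
    iqr: float
    k: float
    lower_fence: float
    upper_fence: float
    flagged: list[tuple[int, float]] = field(default_factory=list)

    @property
    def flagged_indices(self) -> list[int]:
        return [i for i, _ in self.flagged]


@dataclass
class Alert:
    """One triggered alert: which record, which channel, what was crossed."""

    patient_key: str
    qa_date: _dt.date
    stratum: dict[str, str]
    channel: str
    level: str  # AL_breach | TL_breach | outlier
    threshold: float
    value: float
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "patient_key": self.patient_key,
            "qa_date": self.qa_date.isoformat(),
            "stratum": dict(self.stratum),
            "channel": self.channel,
            "level": self.level,
            "threshold": self.threshold,
            "value": self.value,
            "note": self.note,
        }


def iqr_outliers(values: Sequence[float], k: float = DEFAULT_FENCE_K) -> OutlierReport:
    """Flag values strictly outside the Tukey fences ``[Q1 − k·IQR, Q3 + k·IQR]``.

    Quartiles use linear interpolation between order statistics.  Requires at
    least four values: quartiles of shorter series are dominated by the
    interpolation convention rather than the data.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError("IQR outlier detection requires at least 4 values")
    if k < 0:
        raise ValueError(f"fence multiplier must be non-negative, got {k}")
    q1, q3 = np.percentile(arr, [25, 75])  # linear interpolation
    iqr = q3 - q1
    lo = q1 - k * iqr
    hi = q3 + k * iqr
    flagged = [
        (int(i), float(arr[i])) for i in np.nonzero((arr < lo) | (arr > hi))[0]
    ]
    return OutlierReport(
        q1=float(q1), q3=float(q3), iqr=float(iqr), k=float(k),
        lower_fence=float(lo), upper_fence=float(hi), flagged=flagged,
    )


def _record_stratum(record: PSQARecord, template: Mapping[str, str]) -> dict[str, str]:
    # project the record onto the stratum fields the LimitSets were built with
    out: dict[str, str] = {}
    for key in template:
        if key == "site":
            out[key] = record.site
        elif key == "facility":
            out[key] = record.facility
        else:  # pragma: no cover - defensive
            raise ValueError(f"unknown stratum field {key!r}")
    return out


def evaluate_alerts(
    records: Sequence[PSQARecord],
    limits: Mapping[str, LimitSet],
    k: float = DEFAULT_FENCE_K,
) -> list[Alert]:
    """Batch-evaluate limit breaches and IQR outliers over a cohort.

    ``limits`` maps stratum labels (as produced by ``limits_by_stratum``) to
    their :class:`LimitSet`; every record whose stratum carries a value on
    the limit channel must have one, else ``KeyError`` lists the missing
    strata.  Breach comparisons are strict; a value below both TL and AL
    yields a single ``AL_breach`` alert annotated that the TL is also
    crossed.  Outliers are scanned within stratum (skipped for strata with
    fewer than four values).  Alerts are returned sorted by QA date.
    """
    if not limits:
        return []
    template = next(iter(limits.values())).stratum
    channel_name = next(iter(limits.values())).channel
    channel: "GammaCriterion | str" = (
        DOSE_DIFF if channel_name == DOSE_DIFF else GammaCriterion.parse(channel_name)
    )

    by_stratum: dict[str, list[PSQARecord]] = {}
    missing: set[str] = set()
    for r in records:
        if r.channel_value(channel) is None:
            continue
        key = stratum_label(_record_stratum(r, template))
        if key not in limits:
            missing.add(key)
            continue
        by_stratum.setdefault(key, []).append(r)
    if missing:
        raise KeyError(f"no LimitSet for strata: {sorted(missing)}")

    alerts: list[Alert] = []
    for key, recs in by_stratum.items():
        ls = limits[key]
        values = [float(r.channel_value(channel)) for r in recs]  # type: ignore[arg-type]

        for r, v in zip(recs, values):
            breach = _breach_level(v, ls)
            if breach is not None:
                level, threshold, note = breach
                alerts.append(
                    Alert(
                        patient_key=r.patient_key,
                        qa_date=r.qa_date,
                        stratum=dict(ls.stratum),
                        channel=ls.channel,
                        level=level,
                        threshold=threshold,
                        value=v,
                        note=note,
                    )
                )

        if len(values) >= 4:
            report = iqr_outliers(values, k)
            for idx, v in report.flagged:
                r = recs[idx]
                fence = (
                    report.lower_fence if v < report.lower_fence else report.upper_fence
                )
                alerts.append(
                    Alert(
                        patient_key=r.patient_key,
                        qa_date=r.qa_date,
                        stratum=dict(ls.stratum),
                        channel=ls.channel,
                        level=OUTLIER,
                        threshold=float(fence),
                        value=v,
                        note=f"outside Tukey fences (k={report.k:g})",
                    )
                )

    alerts.sort(key=lambda a: (a.qa_date, a.patient_key, a.level))
    return alerts


def _breach_level(value: float, ls: LimitSet) -> "tuple[str, float, str] | None":
    if ls.al_upper is None:  # one-sided passing-rate channel
        if value < ls.al:
            note = "TL also breached" if value < ls.tl else ""
            return AL_BREACH, ls.al, note
        if value < ls.tl:
            return TL_BREACH, ls.tl, ""
        return None
    # two-sided dose-difference channel
    if value < ls.al or value > ls.al_upper:
        thr = ls.al if value < ls.al else ls.al_upper
        note = (
            "TL also breached"
            if (value < ls.tl or (ls.tl_upper is not None and value > ls.tl_upper))
            else ""
        )
        return AL_BREACH, float(thr), note
    if value < ls.tl:
        return TL_BREACH, ls.tl, ""
    if ls.tl_upper is not None and value > ls.tl_upper:
        return TL_BREACH, ls.tl_upper, ""
    return None
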