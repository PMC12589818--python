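"""End-to-end cohort analysis: counts, pooled moments, stratified limits,
control charts, alerts, and structured reporting.

``run_analysis`` composes the pipeline stages — filter → summarize → limits →
charts → alerts — into a single :class:`CohortReport` that mirrors what a
multi-institution QA review needs: how many verifications per disease site,
the pooled passing-rate moments per gamma criterion, action/tolerance limits
per stratum, per-stratum control-chart summaries, and the triggered alerts.
The report embeds a content digest of its input records plus the full
configuration, so an audit can verify which data produced which limits.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import spc
from .alerts import Alert, evaluate_alerts
from .config import AnalysisConfig
from .limits import LimitSet, limits_by_stratum
from .records import DOSE_DIFF, GammaCriterion, PSQARecord, records_to_frame
from . import vocab

__all__ = ["CohortReport", "run_analysis", "facility_comparison", "write_report"]

logger = logging.getLogger(__name__)

_GROUPINGS = ("site", "facility", "both")


def _channel_label(channel: str) -> str:
    return channel if channel == DOSE_DIFF else GammaCriterion.parse(channel).label


@dataclass
class CohortReport:
    """Structured result of one cohort analysis run."""

    total: int
    site_counts: dict[str, int]
    pooled: dict[str, dict]  # channel label -> {n, mean, sd}
    limits: dict[str, dict[str, dict[str, LimitSet]]]  # grouping -> channel -> stratum
    charts: dict[str, dict]  # stratum label -> chart summary (alert channel)
    alerts: list[Alert]
    config: dict
    provenance: dict

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "total": self.total,
            "site_counts": self.site_counts,
            "pooled": self.pooled,
            "limits": {
                g: {ch: {k: ls.to_dict() for k, ls in strata.items()}
                    for ch, strata in by_ch.items()}
                for g, by_ch in self.limits.items()
            },
            "charts": self.charts,
            "alerts": [a.to_dict() for a in self.alerts],
            "config": self.config,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "CohortReport":
        p = Path(str(text_or_path))
        raw = json.loads(p.read_text() if p.is_file() else str(text_or_path))
        limits = {
            g: {ch: {k: LimitSet(**d) for k, d in strata.items()}
                for ch, strata in by_ch.items()}
            for g, by_ch in raw["limits"].items()
        }
        alerts = [
            Alert(
                patient_key=a["patient_key"],
                qa_date=_dt.date.fromisoformat(a["qa_date"]),
                stratum=a["stratum"],
                channel=a["channel"],
                level=a["level"],
                threshold=a["threshold"],
                value=a["value"],
                note=a.get("note", ""),
            )
            for a in raw["alerts"]
        ]
        return cls(
            total=raw["total"],
            site_counts=raw["site_counts"],
            pooled=raw["pooled"],
            limits=limits,
            charts=raw["charts"],
            alerts=alerts,
            config=raw["config"],
            provenance=raw["provenance"],
        )


def _input_digest(records: Sequence[PSQARecord]) -> str:
    if not records:
        return hashlib.sha256(b"").hexdigest()
    csv_bytes = records_to_frame(records).to_csv(index=False).encode()
    return hashlib.sha256(csv_bytes).hexdigest()


def run_analysis(
    records: Sequence[PSQARecord],
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> CohortReport:
    """Run the full analysis pipeline over validated records.

    Deterministic: identical ``(records, config)`` yield a byte-identical
    report JSON.  ``seed`` is recorded in provenance when the cohort is
    synthetic; it does not influence the analysis itself.
    """
    config = (config or AnalysisConfig()).validate()
    logger.info("analysis start: %d records", len(records))

    site_counts = {site: 0 for site in vocab.SITES}
    for r in records:
        site_counts.setdefault(r.site, 0)
        site_counts[r.site] += 1
    site_counts = {s: c for s, c in site_counts.items() if c or s in vocab.SITES}

    pooled: dict[str, dict] = {}
    for channel in config.channels:
        label = _channel_label(channel)
        ch = DOSE_DIFF if channel == DOSE_DIFF else GammaCriterion.parse(channel)
        values = [v for r in records if (v := r.channel_value(ch)) is not None]
        if len(values) >= 2:
            s = pd.Series(values, dtype=float)
            pooled[label] = {
                "n": int(s.size),
                "mean": float(s.mean()),
                "sd": float(s.std(ddof=1)),
            }
        else:
            pooled[label] = {"n": len(values), "mean": None, "sd": None}

    limits: dict[str, dict[str, dict[str, LimitSet]]] = {}
    for grouping in _GROUPINGS:
        by_channel: dict[str, dict[str, LimitSet]] = {}
        for channel in config.channels:
            ch = DOSE_DIFF if channel == DOSE_DIFF else GammaCriterion.parse(channel)
            by_channel[_channel_label(channel)] = limits_by_stratum(
                records, grouping=grouping, channel=ch,
                beta=config.beta, min_n=config.min_n,
            )
        limits[grouping] = by_channel
    for grouping, by_channel in limits.items():
        for label, strata in by_channel.items():
            logger.info("limits[%s][%s]: %d strata", grouping, label, len(strata))

    alert_label = _channel_label(config.alert_channel)
    primary_limits = limits[config.grouping][alert_label]

    charts: dict[str, dict] = {}
    alert_ch = (
        DOSE_DIFF if config.alert_channel == DOSE_DIFF
        else GammaCriterion.parse(config.alert_channel)
    )
    grouped: dict[str, list[PSQARecord]] = {}
    for key, ls in primary_limits.items():
        grouped[key] = []
    for r in records:
        key_fields = {
            "site": {"site": r.site},
            "facility": {"facility": r.facility},
            "both": {"facility": r.facility, "site": r.site},
        }[config.grouping]
        key = ",".join(f"{k}={key_fields[k]}" for k in sorted(key_fields))
        if key in grouped and r.channel_value(alert_ch) is not None:
            grouped[key].append(r)
    for key in sorted(grouped):
        recs = sorted(grouped[key], key=lambda r: r.qa_date)
        values = [r.channel_value(alert_ch) for r in recs]
        if len(values) < 2:
            continue
        chart = spc.build_chart(values)
        charts[key] = {
            "n": chart.n,
            "centerline": chart.centerline,
            "mr_bar": chart.mr_bar,
            "ucl": chart.ucl,
            "lcl": chart.lcl,
            "n_flagged": chart.n_flagged,
            "flagged_indices": chart.flagged_indices(),
        }

    alert_list = evaluate_alerts(records, primary_limits, k=config.fence_k)
    logger.info("alerts: %d", len(alert_list))

    provenance = {
        "input_digest": _input_digest(records),
        "n_input": len(records),
        "config": config.to_dict(),
        "seed": seed,
    }
    return CohortReport(
        total=len(records),
        site_counts=site_counts,
        pooled=pooled,
        limits=limits,
        charts=charts,
        alerts=alert_list,
        config=config.to_dict(),
        provenance=provenance,
    )


def facility_comparison(
    report: CohortReport, site: str, channel: str = "3/3"
) -> pd.DataFrame:
    """Per-facility AL/TL comparison table for one disease site and channel.

    One row per facility (sorted by facility label) with columns
    ``facility, al, tl, n, mean, sd, flags`` — the shape of a cross-facility
    benchmark table for a single treatment site.
    """
    label = _channel_label(channel)
    strata = report.limits.get("both", {}).get(label)
    if strata is None:
        raise ValueError(f"report has no per-(facility,site) limits for channel {label}")
    rows = []
    for ls in strata.values():
        if ls.stratum.get("site") != site:
            continue
        rows.append(
            {
                "facility": ls.stratum["facility"],
                "al": ls.al,
                "tl": ls.tl,
                "n": ls.n_used,
                "mean": ls.mean,
                "sd": ls.sd,
                "flags": ";".join(ls.flags),
            }
        )
    if not rows:
        raise ValueError(f"no strata for site {site!r} on channel {label}")
    return pd.DataFrame(rows).sort_values("facility").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Report writing


def _limits_frame(report: CohortReport) -> pd.DataFrame:
    rows = []
    for grouping, by_ch in report.limits.items():
        for label, strata in by_ch.items():
            for key, ls in strata.items():
                rows.append(
                    {
                        "grouping": grouping,
                        "channel": label,
                        "stratum": key,
                        "n": ls.n_used,
                        "mean": ls.mean,
                        "sd": ls.sd,
                        "delta_a": ls.delta_a,
                        "al": ls.al,
                        "tl": ls.tl,
                        "al_upper": ls.al_upper,
                        "tl_upper": ls.tl_upper,
                        "flags": ";".join(ls.flags),
                    }
                )
    return pd.DataFrame(rows)


def write_report(report: CohortReport, path: str | Path, format: str = "json") -> list[Path]:
    """Write a report as ``json`` (single lossless file), ``csv-bundle``
    (limits.csv, charts.csv, alerts.csv under a directory) or ``text``
    (human-readable summary).  Returns the written paths."""
    path = Path(path)
    if format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        report.to_json(path)
        return [path]
    if format == "csv-bundle":
        path.mkdir(parents=True, exist_ok=True)
        limits_path = path / "limits.csv"
        charts_path = path / "charts.csv"
        alerts_path = path / "alerts.csv"
        _limits_frame(report).to_csv(limits_path, index=False)
        chart_rows = [
            {"stratum": k, **{kk: vv for kk, vv in v.items() if kk != "flagged_indices"},
             "flagged_indices": ";".join(map(str, v["flagged_indices"]))}
            for k, v in report.charts.items()
        ]
        pd.DataFrame(chart_rows).to_csv(charts_path, index=False)
        pd.DataFrame([a.to_dict() for a in report.alerts]).to_csv(alerts_path, index=False)
        return [limits_path, charts_path, alerts_path]
    if format == "text":
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(render_text(report))
        return [path]
    raise ValueError(f"unknown report format {format!r}; expected json|csv-bundle|text")


def render_text(report: CohortReport) -> str:
    lines = [
        f"PSQA cohort report — {report.total} records",
        "",
        "Records per disease site:",
    ]
    for site, n in report.site_counts.items():
        lines.append(f"  {site:10s} {n:5d}")
    lines.append(f"  {'total':10s} {report.total:5d}")
    lines.append("")
    lines.append("Pooled channel moments:")
    for label, m in report.pooled.items():
        if m["mean"] is None:
            lines.append(f"  {label:15s} n={m['n']} (insufficient data)")
        else:
            lines.append(
                f"  {label:15s} n={m['n']:4d}  mean={m['mean']:7.2f}  sd={m['sd']:5.2f}"
            )
    lines.append("")
    grouping = report.config.get("grouping", "both")
    for label, strata in report.limits.get(grouping, {}).items():
        lines.append(f"Limits by {grouping} — channel {label}:")
        for key, ls in strata.items():
            flags = f"  [{';'.join(ls.flags)}]" if ls.flags else ""
            lines.append(
                f"  {key:45s} n={ls.n_used:4d}  AL={ls.al:7.2f}  TL={ls.tl:7.2f}{flags}"
            )
        lines.append("")
    lines.append(f"Alerts: {len(report.alerts)}")
    for a in report.alerts[:20]:
        lines.append(
            f"  {a.qa_date} {a.patient_key} {a.channel} {a.level}: "
            f"value={a.value:.2f} vs threshold={a.threshold:.2f}"
        )
    if len(report.alerts) > 20:
        lines.append(f"  ... and {len(report.alerts) - 20} more")
    lines.append("")
    return "\n".join(lines)
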