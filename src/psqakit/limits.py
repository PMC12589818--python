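"""TG-218-style action and tolerance limits for PSQA processes.

The tolerance width of a QA process with mean ``x̄``, sample standard
deviation ``σ`` and target ``T`` is

    ΔA = β · sqrt(σ² + (x̄ − T)²)

with β a dimensionless width constant (default 6, the conventional
six-sigma-style choice).  For passing-rate channels (target 100%) the
action limit — the lower threshold of acceptable QA results — is

    AL = 100 − ΔA / 2

and is one-sided: only low passing rates are actionable.  For the
dose-difference channel (target 0) the action limits are the symmetric
pair ±ΔA/2 about zero.

The tolerance limit (TL) is a process-behaviour boundary computed from the
individuals control chart over the chronologically ordered series: the lower
control limit, centerline − 2.660·mR̄ (and for two-sided channels also the
upper).  TL warns that the process has left its historical behaviour before
the AL — acceptability — is breached.  Because AL is moment-based and TL is
moving-range-based, TL < AL is possible for an unstable process; such strata
are flagged, not rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import spc
from .records import DOSE_DIFF, GammaCriterion, PSQARecord

__all__ = [
    "DEFAULT_BETA",
    "DEFAULT_MIN_N",
    "ProcessSummary",
    "LimitSet",
    "summarize",
    "tolerance_width",
    "action_limit",
    "tolerance_limit",
    "limits_by_stratum",
    "channel_target",
]

DEFAULT_BETA = 6.0
#: Strata with fewer records than this carry a "provisional" advisory flag.
DEFAULT_MIN_N = 20


def channel_target(channel: "GammaCriterion | str") -> float:
    """Process target: 100% for passing-rate channels, 0% for dose difference."""
    return 0.0 if _is_dose_diff(channel) else 100.0


def _is_dose_diff(channel: "GammaCriterion | str") -> bool:
    return isinstance(channel, str) and channel == DOSE_DIFF


@dataclass(frozen=True)
class ProcessSummary:
    """Moments of one QA process stratum: count, mean, sample SD (n−1
    denominator) and the process target."""

    n: int
    mean: float
    sd: float
    target: float


@dataclass
class LimitSet:
    """Derived limits for one stratum and channel.

    ``al``/``tl`` are the lower (actionable) limits; ``al_upper``/``tl_upper``
    are populated only for two-sided channels (dose difference).  ``flags``
    carries advisories such as ``"provisional"`` (n below the minimum) or
    ``"TL<AL"`` (chart-based TL below the moment-based AL).
    """

    channel: str
    stratum: dict[str, str]
    n_used: int
    mean: float
    sd: float
    target: float
    beta: float
    delta_a: float
    al: float
    tl: float
    al_upper: float | None = None
    tl_upper: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "stratum": dict(self.stratum),
            "n_used": self.n_used,
            "mean": self.mean,
            "sd": self.sd,
            "target": self.target,
            "beta": self.beta,
            "delta_a": self.delta_a,
            "al": self.al,
            "tl": self.tl,
            "al_upper": self.al_upper,
            "tl_upper": self.tl_upper,
            "flags": list(self.flags),
        }


def summarize(values: Sequence[float], target: float) -> ProcessSummary:
    """Process moments: mean and sample SD (n−1 denominator) plus target.

    Raises ``ValueError`` for fewer than two values — the SD is undefined.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("process summary requires at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("process summary requires finite values")
    return ProcessSummary(
        n=int(arr.size),
        mean=float(np.mean(arr)),
        sd=float(np.std(arr, ddof=1)),
        target=float(target),
    )


def tolerance_width(summary: ProcessSummary, beta: float = DEFAULT_BETA) -> float:
    """ΔA = β·sqrt(σ² + (x̄ − T)²), the width between the upper and lower
    intervention thresholds."""
    if not beta > 0:
        raise ValueError(f"beta must be positive, got {beta}")
    return beta * math.sqrt(summary.sd**2 + (summary.mean - summary.target) ** 2)


def action_limit(
    delta_a: float, channel: "GammaCriterion | str" = "3/3"
) -> "float | tuple[float, float]":
    """Action limit(s) from a tolerance width.

    Passing-rate channels return the one-sided lower limit ``100 − ΔA/2``;
    the dose-difference channel returns the symmetric pair ``(−ΔA/2, +ΔA/2)``
    about its zero target.
    """
    if delta_a < 0:
        raise ValueError(f"tolerance width must be non-negative, got {delta_a}")
    if _is_dose_diff(channel):
        return (-delta_a / 2.0, delta_a / 2.0)
    return 100.0 - delta_a / 2.0


def tolerance_limit(values: Sequence[float]) -> float:
    """Lower tolerance limit of a chronologically ordered series: the
    individuals-chart LCL, centerline − 2.660·mR̄.

    Order-sensitive by construction (the moving range is); callers must pass
    values in chronological order.
    """
    chart = spc.build_chart(values)
    return chart.lcl


# ---------------------------------------------------------------------------
# Stratified limits over record collections


def _stratum_key(record: PSQARecord, grouping: str) -> dict[str, str]:
    if grouping == "site":
        return {"site": record.site}
    if grouping == "facility":
        return {"facility": record.facility}
    if grouping == "both":
        return {"facility": record.facility, "site": record.site}
    raise ValueError(f"unknown grouping {grouping!r}; expected site|facility|both")


def stratum_label(stratum: Mapping[str, str]) -> str:
    """Stable printable key, e.g. ``"facility=Fujigaoka,site=Pelvis"``."""
    return ",".join(f"{k}={stratum[k]}" for k in sorted(stratum))


def _chronological(records: Sequence[PSQARecord]) -> list[PSQARecord]:
    # stable sort: ties on qa_date keep input order
    return sorted(records, key=lambda r: r.qa_date)


def limits_for_values(
    values: Sequence[float],
    channel: "GammaCriterion | str",
    *,
    stratum: Mapping[str, str] | None = None,
    beta: float = DEFAULT_BETA,
    min_n: int = DEFAULT_MIN_N,
) -> LimitSet:
    """Build a :class:`LimitSet` from a chronologically ordered value series."""
    target = channel_target(channel)
    summary = summarize(values, target)
    width = tolerance_width(summary, beta)
    chart = spc.build_chart(values)
    channel_name = channel if _is_dose_diff(channel) else GammaCriterion.parse(channel).label
    flags: list[str] = []
    if summary.n < min_n:
        flags.append("provisional")
    if _is_dose_diff(channel):
        al_lo, al_hi = action_limit(width, channel)
        ls = LimitSet(
            channel=channel_name,
            stratum=dict(stratum or {}),
            n_used=summary.n,
            mean=summary.mean,
            sd=summary.sd,
            target=target,
            beta=beta,
            delta_a=width,
            al=al_lo,
            tl=chart.lcl,
            al_upper=al_hi,
            tl_upper=chart.ucl,
            flags=flags,
        )
        if chart.lcl < al_lo or chart.ucl > al_hi:
            flags.append("TL_outside_AL")
    else:
        al = action_limit(width, channel)
        ls = LimitSet(
            channel=channel_name,
            stratum=dict(stratum or {}),
            n_used=summary.n,
            mean=summary.mean,
            sd=summary.sd,
            target=target,
            beta=beta,
            delta_a=width,
            al=float(al),
            tl=chart.lcl,
            flags=flags,
        )
        if ls.tl < ls.al:
            flags.append("TL<AL")
    return ls


def limits_by_stratum(
    records: Sequence[PSQARecord],
    grouping: str = "site",
    channel: "GammaCriterion | str" = "3/3",
    beta: float = DEFAULT_BETA,
    min_n: int = DEFAULT_MIN_N,
) -> dict[str, LimitSet]:
    """Compute one :class:`LimitSet` per stratum of the cohort.

    ``grouping`` is ``"site"``, ``"facility"`` or ``"both"``.  Records
    without a value on ``channel`` are skipped; strata left with fewer than
    two values are omitted (no SD exists).  Strata below ``min_n`` are kept
    and flagged ``"provisional"``.  Keys are :func:`stratum_label` strings.
    """
    groups: dict[str, tuple[dict[str, str], list[PSQARecord]]] = {}
    for r in records:
        stratum = _stratum_key(r, grouping)
        key = stratum_label(stratum)
        groups.setdefault(key, (stratum, []))[1].append(r)

    out: dict[str, LimitSet] = {}
    for key in sorted(groups):
        stratum, recs = groups[key]
        ordered = _chronological(recs)
        values = [
            v for r in ordered if (v := r.channel_value(channel)) is not None
        ]
        if len(values) < 2:
            continue
        out[key] = limits_for_values(
            values, channel, stratum=stratum, beta=beta, min_n=min_n
        )
    return out
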