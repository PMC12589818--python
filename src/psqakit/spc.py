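"""Individuals / moving-range statistical process control.

Longitudinal QA monitoring treats each verification measurement as a single
observation in time order.  The individuals chart places control limits at

    UCL = centerline + 2.660 * mRbar
    LCL = centerline - 2.660 * mRbar

where the centerline is the arithmetic mean of the series and mRbar is the
average moving range, the mean of |x_i - x_{i-1}|.  The constant 2.660 is
3/d2 for moving ranges of span two (d2 = 1.128), so the limits approximate
three-sigma bounds for an in-control process without requiring replicate
measurements at each time point.

Rule 1 (a point beyond the control limits) is always evaluated; the run
rules (eight consecutive points on one side of the centerline; six
monotonically increasing or decreasing points) are off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MR_CONSTANT", "ControlChart", "moving_ranges", "build_chart", "flag_points"]

#: Individuals-chart control-limit constant, 3/d2 for subgroups of size 2.
MR_CONSTANT = 2.660

RULE_BEYOND_LIMITS = "beyond_limits"
RULE_RUN_OF_8 = "run_of_8"
RULE_TREND_OF_6 = "trend_of_6"
DEFAULT_RULES = (RULE_BEYOND_LIMITS,)


@dataclass
class ControlChart:
    """An individuals chart over a chronologically ordered series.

    ``point_flags[i]`` lists the rules point ``i`` triggers (empty when in
    control).  Limits are reported unclamped: the UCL of a passing-rate
    series may exceed 100, which is a statement about process spread, not an
    achievable measurement.
    """

    values: np.ndarray
    centerline: float
    mr_bar: float
    ucl: float
    lcl: float
    point_flags: list[list[str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(len(self.values))

    @property
    def n_flagged(self) -> int:
        return sum(1 for f in self.point_flags if f)

    def flagged_indices(self, rule: str | None = None) -> list[int]:
        return [
            i
            for i, flags in enumerate(self.point_flags)
            if (flags if rule is None else rule in flags)
        ]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "centerline": self.centerline,
            "mr_bar": self.mr_bar,
            "ucl": self.ucl,
            "lcl": self.lcl,
            "values": [float(v) for v in self.values],
            "point_flags": self.point_flags,
        }


def moving_ranges(values) -> np.ndarray:
    """Absolute differences of consecutive observations, length ``n - 1``.

    Raises ``ValueError`` for fewer than two values — a single observation
    has no moving range.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("moving ranges require at least 2 values in a 1-d series")
    return np.abs(np.diff(arr))


def build_chart(values, rules: tuple[str, ...] = DEFAULT_RULES) -> ControlChart:
    """Build an individuals chart from a chronologically ordered series.

    The caller is responsible for chronological ordering: the average moving
    range, hence the control limits, depend on it.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("a control chart requires at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("control chart values must be finite")
    centerline = float(np.mean(arr))
    mr_bar = float(np.mean(moving_ranges(arr)))
    chart = ControlChart(
        values=arr,
        centerline=centerline,
        mr_bar=mr_bar,
        ucl=centerline + MR_CONSTANT * mr_bar,
        lcl=centerline - MR_CONSTANT * mr_bar,
    )
    chart.point_flags = flag_points(chart, rules)
    return chart


def flag_points(chart: ControlChart, rules: tuple[str, ...] = DEFAULT_RULES) -> list[list[str]]:
    """Evaluate out-of-control rules per point.

    Rule 1 (``beyond_limits``) is always evaluated even if omitted from
    ``rules``; the optional run rules flag the point completing the run.
    """
    arr = np.asarray(chart.values, dtype=float)
    n = arr.size
    flags: list[list[str]] = [[] for _ in range(n)]

    for i in np.nonzero((arr > chart.ucl) | (arr < chart.lcl))[0]:
        flags[int(i)].append(RULE_BEYOND_LIMITS)

    if RULE_RUN_OF_8 in rules:
        side = np.sign(arr - chart.centerline)
        run = 0
        prev = 0.0
        for i in range(n):
            if side[i] != 0 and side[i] == prev:
                run += 1
            else:
                run = 1 if side[i] != 0 else 0
            prev = side[i]
            if run >= 8:
                flags[i].append(RULE_RUN_OF_8)

    if RULE_TREND_OF_6 in rules:
        diffs = np.sign(np.diff(arr))
        run = 0
        prev = 0.0
        for i, d in enumerate(diffs):
            if d != 0 and d == prev:
                run += 1
            else:
                run = 1 if d != 0 else 0
            prev = d
            # run of k equal-signed steps spans k+1 points; flag at 6 points
            if run >= 5:
                flags[i + 1].append(RULE_TREND_OF_6)

    return flags
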