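"""Growth-rate metrics and derived 2D formulas.

Absolute growth rate is the analytic derivative of a fitted mean curve
(units/week). Relative growth rate (RGR) between two timepoints is the
log-difference convention

    RGR = 100 · (ln V2 − ln V1) / (GA2 − GA1)   [%/week]

which is the average of the instantaneous rate 100·V'(g)/V(g) over the
interval. Growth tables report both: a per-row instantaneous relative rate
and an endpoint-span summary RGR, since summary conventions differ between
published cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .centiles import CentileModel
from .errors import DomainError


def round2(x: float) -> float:
    """Round to 2 decimal places, half away from zero (growth-table style)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def relative_growth_rate(v1: float, v2: float, ga1: float, ga2: float) -> float:
    """Percent growth per week between (ga1, v1) and (ga2, v2)."""
    if v1 <= 0 or v2 <= 0:
        raise DomainError("volumes must be strictly positive")
    if ga2 <= ga1:
        raise DomainError("ga2 must exceed ga1")
    return 100.0 * (math.log(v2) - math.log(v1)) / (ga2 - ga1)


def absolute_growth_rate(model: CentileModel, ga: float) -> float:
    """Analytic derivative of the model mean at ``ga``, units per week."""
    return float(model.mean_derivative(ga))


@dataclass
class GrowthTable:
    """Per-GA growth summary for one measurement (printed-table shape).

    ``rows`` holds (ga, average_value, absolute_rate, relative_rate_row)
    where relative_rate_row = 100·mean'(g)/mean(g) is the instantaneous
    percent rate. ``summary_relative_rate`` is the endpoint-span RGR, or
    None for a single-row table.
    """

    measurement_name: str
    rows: list[tuple[float, float, float, float]]
    summary_relative_rate: float | None

    def to_records(self) -> list[dict]:
        return [
            {
                "ga_weeks": g,
                "average_value": v,
                "absolute_rate": a,
                "relative_rate_row": r,
            }
            for g, v, a, r in self.rows
        ]


def growth_table(model: CentileModel, ga_list) -> GrowthTable:
    """Tabulate mean, absolute and relative growth rates on a GA grid."""
    ga = np.asarray(ga_list, dtype=float)
    if ga.ndim != 1 or len(ga) == 0:
        raise DomainError("ga_list must be a non-empty 1-D sequence")
    if np.any(np.diff(ga) <= 0):
        raise DomainError("ga_list must be strictly increasing")
    means = np.atleast_1d(model.mean(ga))
    rates = np.atleast_1d(model.mean_derivative(ga))
    rows = []
    for g, v, a in zip(ga, means, rates):
        rel = 100.0 * a / v if v > 0 else float("nan")
        rows.append((float(g), float(v), float(a), float(rel)))
    summary = None
    if len(ga) >= 2 and means[0] > 0 and means[-1] > 0:
        summary = relative_growth_rate(means[0], means[-1], ga[0], ga[-1])
    return GrowthTable(model.measurement_name, rows, summary)


def allometric_exponent(x_volumes, y_volumes) -> tuple[float, float]:
    """OLS slope and intercept of ln(y) on ln(x): the scaling exponent."""
    x = np.asarray(x_volumes, dtype=float)
    y = np.asarray(y_volumes, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be paired 1-D arrays")
    if len(x) < 3:
        raise DomainError("need at least 3 pairs")
    if np.any(x <= 0) or np.any(y <= 0):
        raise DomainError("volumes must be strictly positive")
    slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
    return float(slope), float(intercept)


def head_circumference(skull_bpd: float, skull_ofd: float) -> float:
    """HC in mm from the two skull diameters: 1.62 × (BPD + OFD)."""
    if skull_bpd <= 0 or skull_ofd <= 0:
        raise DomainError("skull diameters must be strictly positive")
    return 1.62 * (skull_bpd + skull_ofd)


def ecsf_linear(skull_bpd: float, brain_bpd: float) -> tuple[float, bool]:
    """Linear extra-cerebral CSF estimate: skull BPD − brain BPD (mm).

    A negative difference is physically implausible (brain wider than
    skull) but allowed; it is returned with ``flagged=True``.
    """
    diff = skull_bpd - brain_bpd
    return diff, diff < 0


def asymmetry_percent(left: float, right: float) -> float:
    """Left-right asymmetry as percent of the bilateral mean.

    100·(L − R)/((L + R)/2): symmetric-denominator convention, antisymmetric
    under swapping sides.
    """
    if left <= 0 or right <= 0:
        raise DomainError("volumes must be strictly positive")
    return 100.0 * (left - right) / ((left + right) / 2.0)
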