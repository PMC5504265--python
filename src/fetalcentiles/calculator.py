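"""Centile calculator: dates to GA, measurements to centiles, chart data.

Re-implements the clinical calculator workflow: the user supplies the
expected date of delivery (EDD, from a first-trimester dating ultrasound)
and the scan date — or a gestational age directly — plus any set of
measurements; the calculator returns each measurement's exact centile and
z-score against the serialized reference models, together with 5th/50th/
95th centile chart series for plotting. Obstetric dating convention:
GA = 40 weeks exactly at the EDD, in decimal weeks (days/7, 2 dp).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from .centiles import CentileModel, centile_curve, value_to_centile
from .errors import ValidationError

DEFAULT_CHART_CENTILES = (5, 50, 95)


def ga_at_scan(edd: date, scan_date: date) -> float:
    """Decimal gestational weeks at scan from the EDD (GA 40.0 at EDD)."""
    if scan_date > edd + timedelta(weeks=4):
        raise ValidationError("scan date is more than 4 weeks after the EDD")
    ga = 40.0 - (edd - scan_date).days / 7.0
    ga = round(ga, 2)
    if not 15.0 <= ga <= 43.0:
        raise ValidationError(f"implausible GA at scan: {ga:.2f} weeks")
    return ga


@dataclass
class CalculatorRequest:
    """Either (edd, scan_date) or ga_weeks, plus a measurement map."""

    measurements: dict[str, float]
    edd: date | None = None
    scan_date: date | None = None
    ga_weeks: float | None = None

    def resolve_ga(self) -> float:
        by_dates = self.edd is not None and self.scan_date is not None
        if by_dates == (self.ga_weeks is not None):
            raise ValidationError("supply exactly one of (edd + scan_date) or ga_weeks")
        if by_dates:
            return ga_at_scan(self.edd, self.scan_date)
        return round(float(self.ga_weeks), 2)


@dataclass
class CentileReport:
    ga_weeks: float
    results: dict[str, dict] = field(default_factory=dict)  # value/centile/z/extrapolated
    skipped: list[str] = field(default_factory=list)
    charts: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ga_weeks": self.ga_weeks,
            "results": self.results,
            "skipped": self.skipped,
            "charts": self.charts,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def chart_data(
    model: CentileModel,
    ga_grid,
    centiles=DEFAULT_CHART_CENTILES,
) -> dict:
    """Centile curve series on a GA grid: one column per requested centile.

    Grid points outside the model's fitted GA domain are flagged, not
    dropped.
    """
    ga_grid = np.asarray(ga_grid, dtype=float)
    series = {f"p{c:g}": centile_curve(model, c / 100.0, ga_grid).tolist() for c in centiles}
    return {
        "ga": ga_grid.tolist(),
        "centiles": list(centiles),
        "series": series,
        "extrapolated": (~model.in_domain(ga_grid)).tolist(),
    }


def evaluate(
    request: CalculatorRequest,
    models: dict[str, CentileModel],
    chart_points: int = 50,
) -> CentileReport:
    """Place every requested measurement on its reference model.

    Measurements without a model are reported under ``skipped``, never
    silently dropped. Chart series span each model's own GA domain.
    """
    ga = request.resolve_ga()
    report = CentileReport(ga_weeks=ga)
    for name in sorted(request.measurements):
        value = request.measurements[name]
        model = models.get(name)
        if model is None:
            report.skipped.append(name)
            continue
        res = value_to_centile(model, ga, value)
        report.results[name] = {
            "value": float(value),
            "centile": res.percentile,
            "z_score": res.z_score,
            "extrapolated": res.extrapolated,
        }
        lo, hi = model.ga_domain
        grid = np.round(np.linspace(lo, hi, chart_points), 4)
        chart = chart_data(model, grid)
        chart["subject_point"] = {"ga": ga, "value": float(value)}
        report.charts[name] = chart
    return report


def load_models(model_dir: str | Path) -> dict[str, CentileModel]:
    """Load every ``*.json`` reference model in a directory, keyed by name."""
    models = {}
    for path in sorted(Path(model_dir).glob("*.json")):
        model = CentileModel.from_json(path)
        models[model.measurement_name] = model
    return models
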