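"""Cohort-level fitting helpers shared by the analysis drivers.

Wraps the per-measurement centile fit with the registry's default model
families and an explicit, logged SD-family adequacy fallback: if the
preferred SD polynomial is non-positive somewhere inside the observed GA
domain (which the fitter refuses), the next simpler family is tried. This
mirrors how the SD family is chosen in practice — the simplest curve that
adequately represents the residual spread.
"""

from __future__ import annotations

import numpy as np

from .centiles import CentileModel, fit_centile_model
from .cohort import ScanRecord
from .errors import DegenerateSDError
from .registry import MEASUREMENTS

_SD_FALLBACK = {"quadratic": "linear", "linear": None}


def fit_measurement(
    scans: list[ScanRecord],
    measurement: str,
    mean_family: str | None = None,
    sd_family: str | None = None,
) -> tuple[CentileModel, str | None]:
    """Fit one measurement from scan records; returns (model, note).

    ``note`` is None for a clean fit, otherwise a human-readable record of
    the SD-family fallback that was applied.
    """
    info = MEASUREMENTS.get(measurement)
    mean_family = mean_family or (info.mean_family if info else "quadratic")
    sd_family = sd_family or (info.sd_family if info else "linear")
    pairs = [(s.ga_weeks, s.measurements[measurement]) for s in scans
             if measurement in s.measurements]
    ga = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])

    tried = []
    family: str | None = sd_family
    while family is not None:
        try:
            model = fit_centile_model(ga, y, mean_family, family, measurement)
            note = None
            if tried:
                note = (
                    f"{measurement}: SD family fell back {' -> '.join(tried + [family])} "
                    "(higher-order SD curve non-positive inside the GA domain)"
                )
            return model, note
        except DegenerateSDError:
            tried.append(family)
            family = _SD_FALLBACK.get(family)
    raise DegenerateSDError(
        f"no SD family yields a positive SD curve for {measurement!r} (tried {tried})"
    )
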