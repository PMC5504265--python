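"""Measurement registry: canonical names, units and model families.

3D structures are segmented volumes in cm^3; 2D measurements are linear
distances in mm (vermis area in mm^2). Every structure is modelled with a
quadratic-in-GA mean and GA-linear SD except the cortical volume, whose
mean grows exponentially and whose SD is quadratic in GA.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MeasurementInfo:
    name: str
    units: str  # cm3 | mm | mm2
    mean_family: str  # quadratic | exponential
    sd_family: str  # linear | quadratic
    dimensionality: str  # 2D | 3D


_Q = "quadratic"
_L = "linear"

MEASUREMENTS: dict[str, MeasurementInfo] = {
    m.name: m
    for m in [
        # 3D volumes
        MeasurementInfo("supratentorial", "cm3", _Q, _L, "3D"),
        MeasurementInfo("ventricles_total", "cm3", _Q, _L, "3D"),
        MeasurementInfo("ventricle_left", "cm3", _Q, _L, "3D"),
        MeasurementInfo("ventricle_right", "cm3", _Q, _L, "3D"),
        MeasurementInfo("cortex", "cm3", "exponential", _Q, "3D"),
        MeasurementInfo("cerebellum", "cm3", _Q, _L, "3D"),
        MeasurementInfo("ecsf", "cm3", _Q, _L, "3D"),
        # 2D linear measurements
        MeasurementInfo("brain_bpd", "mm", _Q, _L, "2D"),
        MeasurementInfo("fronto_occipital_length", "mm", _Q, _L, "2D"),
        MeasurementInfo("skull_bpd", "mm", _Q, _L, "2D"),
        MeasurementInfo("skull_ofd", "mm", _Q, _L, "2D"),
        MeasurementInfo("head_circumference", "mm", _Q, _L, "2D"),
        MeasurementInfo("tcd", "mm", _Q, _L, "2D"),
        MeasurementInfo("ecsf_linear", "mm", _Q, _L, "2D"),
        MeasurementInfo("atrial_diameter", "mm", _Q, _L, "2D"),
        MeasurementInfo("vermis_height", "mm", _Q, _L, "2D"),
        MeasurementInfo("vermis_width", "mm", _Q, _L, "2D"),
        MeasurementInfo("vermis_area", "mm2", _Q, _L, "2D"),
    ]
}

#: The five volumetric structures carried by the printed growth table.
TABLE_STRUCTURES = ["supratentorial", "ventricles_total", "cortex", "cerebellum", "ecsf"]


def info(name: str) -> MeasurementInfo:
    try:
        return MEASUREMENTS[name]
    except KeyError:
        raise KeyError(f"unknown measurement {name!r}") from None
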