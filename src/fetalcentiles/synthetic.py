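"""Seeded synthetic cohorts with the statistical structure of the study.

No individual-level data are deposited for this cohort, so every
downstream stage (filtering, centile fitting, growth tables, calculator)
is exercised on simulated cohorts that emulate the study's published
statistical structure:

* 108 fetuses / 127 scans (17 scanned twice, 1 three times), 57 male /
  51 female, GA 21.29-38.86 weeks with a unimodal distribution peaking
  near 29-30 weeks;
* quadratic-in-GA mean growth with GA-linear SD for every volumetric
  structure except the cortex, which grows exponentially;
* left > right lateral-ventricle volumes, with a shared subject-level
  random effect between the two sides, and larger ventricles in males;
* labelled exclusion subjects at the published per-reason frequencies.

Mean curves are anchored to the published average volumes at 22-38 weeks
(see :func:`table2_truth`). The published record carries no per-structure
SD magnitudes, so truth SD curves are a synthetic convention: GA-linear
(quadratic for the exponential-mean cortex), anchored to a coefficient of
variation of ~8% of the mean at 21 weeks rising to ~12% at 39 weeks to
mimic the reported widening of the volume range from ~30 weeks.
Measurement noise is additive Gaussian; negative draws are resampled (at
most 100 tries) to keep the Gaussian model rather than truncating it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cohort import ScanRecord, SubjectRecord
from .errors import ConfigurationError

# Published growth-table anchors: average volumes (cm^3) at 22..38 weeks.
TABLE2_GA = (22.0, 26.0, 30.0, 34.0, 38.0)
TABLE2_VOLUMES: dict[str, tuple[float, ...]] = {
    "supratentorial": (43.26, 92.26, 153.31, 226.39, 311.52),
    "ventricles_total": (2.51, 3.29, 3.99, 4.60, 5.14),
    "cortex": (10.19, 17.38, 29.63, 50.51, 86.12),
    "cerebellum": (1.57, 3.77, 7.38, 12.38, 18.78),
    "ecsf": (26.90, 60.85, 84.43, 97.63, 100.45),
}

# Per-reason exclusion frequencies reported for the 128 evaluated fetuses.
STUDY_EXCLUSION_FREQUENCIES: dict[str, int] = {
    "motion": 1,
    "infection": 9,
    "delivery_complications": 2,
    "chromosomal_abnormality": 1,
    "developmental_delay": 2,
    "iugr": 1,
    "seizures": 1,
    "no_contact": 3,
}

STUDY_GA_RANGE = (21.29, 38.86)
GA_MODE = 29.5
STUDY_GROUP_COUNTS = (83, 15, 5, 5)  # healthy, sibling, us_query, non_cns
_GROUPS = ("healthy_volunteer", "sibling_with_disability", "us_query_cns", "non_cns_mild")

# Ventricle side decomposition: left/right share a subject-level effect of
# variance a^2 and carry independent noise of variance b^2 (in units of the
# half-total SD); 4a^2 + 2b^2 = 4 keeps the SD of (L+R) equal to the truth
# SD of the total.
_SIDE_SHARED_SD = math.sqrt(0.5)
_SIDE_NOISE_SD = 1.0


@dataclass
class GrowthTruth:
    """Generating curves for one structure: mean(GA) and SD(GA) on raw GA.

    ``mean_coeffs`` are (a, b, c) for a + b·GA + c·GA² when quadratic, or
    (A, k) for A·exp(k·GA) when exponential. SD curves here are synthetic
    conventions, not published values (``sd_synthetic``).
    """

    structure_name: str
    mean_family: str
    mean_coeffs: list[float]
    sd_family: str
    sd_coeffs: list[float]
    units: str = "cm3"
    sd_synthetic: bool = True

    def mean(self, ga):
        ga = np.asarray(ga, dtype=float)
        c = self.mean_coeffs
        if self.mean_family == "quadratic":
            return c[0] + c[1] * ga + c[2] * ga * ga
        return c[0] * np.exp(c[1] * ga)

    def sd(self, ga):
        ga = np.asarray(ga, dtype=float)
        c = self.sd_coeffs
        out = c[0] + c[1] * ga
        if self.sd_family == "quadratic":
            out = out + c[2] * ga * ga
        return out


#: CV anchors for the synthetic SD convention: ~8% of the mean at the young
#: edge of the GA domain rising to ~12% at the old edge.
_SD_DOMAIN = (21.0, 39.0)
_SD_CV = (0.08, 0.12)


def _linear_sd_coeffs(mean_fn) -> list[float]:
    # anchored at the domain edges so the line stays positive on [21, 39]
    (g_lo, g_hi), (cv_lo, cv_hi) = _SD_DOMAIN, _SD_CV
    s_lo, s_hi = cv_lo * float(mean_fn(g_lo)), cv_hi * float(mean_fn(g_hi))
    slope = (s_hi - s_lo) / (g_hi - g_lo)
    return [s_lo - g_lo * slope, slope]


def _quadratic_sd_coeffs(mean_fn) -> list[float]:
    # tracks the CV anchors at both edges and mid-domain; used for the
    # exponential-mean cortex, whose CV would balloon mid-gestation under a
    # straight SD line
    (g_lo, g_hi), (cv_lo, cv_hi) = _SD_DOMAIN, _SD_CV
    g_mid = (g_lo + g_hi) / 2.0
    gs = np.array([g_lo, g_mid, g_hi])
    cvs = np.array([cv_lo, (cv_lo + cv_hi) / 2.0, cv_hi])
    c2, c1, c0 = np.polyfit(gs, cvs * np.array([float(mean_fn(g)) for g in gs]), 2)
    return [float(c0), float(c1), float(c2)]


def table2_truth() -> dict[str, GrowthTruth]:
    """Generating truth anchored to the published average volumes.

    Mean curves are least-squares fits through the five printed anchors
    (quadratic for all structures, exponential for the cortex); printed
    volumes are themselves near-exactly quadratic/exponential, so the
    curves interpolate them to ~0.01 cm^3.
    """
    ga = np.asarray(TABLE2_GA)
    out: dict[str, GrowthTruth] = {}
    for name, vols in TABLE2_VOLUMES.items():
        v = np.asarray(vols)
        if name == "cortex":
            k, lna = np.polyfit(ga, np.log(v), 1)
            mean_coeffs = [float(np.exp(lna)), float(k)]
            family = "exponential"
        else:
            c2, c1, c0 = np.polyfit(ga, v, 2)
            mean_coeffs = [float(c0), float(c1), float(c2)]
            family = "quadratic"
        partial = GrowthTruth(
            structure_name=name, mean_family=family, mean_coeffs=mean_coeffs,
            sd_family="linear", sd_coeffs=[0.0, 0.0],
        )
        if family == "exponential":
            partial.sd_family = "quadratic"
            partial.sd_coeffs = _quadratic_sd_coeffs(partial.mean)
        else:
            partial.sd_coeffs = _linear_sd_coeffs(partial.mean)
        out[name] = partial
    return out


@dataclass
class CohortConfig:
    """Simulation parameters; defaults are the study's published structure."""

    n_subjects: int = 108
    n_twice_scanned: int = 17
    n_thrice_scanned: int = 1
    ga_range: tuple[float, float] = STUDY_GA_RANGE
    sex_counts: tuple[int, int] = (57, 51)  # (male, female)
    ventricle_left_excess: float = 0.1791  # L-R asymmetry fraction of side mean
    male_ventricle_excess: float = 0.10  # male total-ventricle mean multiplier - 1
    group_counts: tuple[int, int, int, int] | None = None
    exclusion_frequencies: dict[str, int] = field(default_factory=dict)
    n_followup: int | None = None  # default: 75% of n_subjects
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ConfigurationError("n_subjects must be non-negative")
        if self.n_twice_scanned < 0 or self.n_thrice_scanned < 0:
            raise ConfigurationError("repeat-scan counts must be non-negative")
        if self.n_twice_scanned + self.n_thrice_scanned > self.n_subjects:
            raise ConfigurationError(
                "n_twice_scanned + n_thrice_scanned exceeds n_subjects"
            )
        lo, hi = self.ga_range
        if not (20.0 <= lo < hi <= 40.0):
            raise ConfigurationError("ga_range must be an increasing pair within [20, 40]")
        if any(c < 0 for c in self.sex_counts):
            raise ConfigurationError("sex_counts must be non-negative")
        if sum(self.sex_counts) != self.n_subjects:
            raise ConfigurationError("sex_counts must sum to n_subjects")
        if self.group_counts is not None and sum(self.group_counts) != self.n_subjects:
            raise ConfigurationError("group_counts must sum to n_subjects")
        if any(c < 0 for c in self.exclusion_frequencies.values()):
            raise ConfigurationError("exclusion_frequencies counts must be non-negative")
        unknown = set(self.exclusion_frequencies) - set(STUDY_EXCLUSION_FREQUENCIES)
        if unknown:
            raise ConfigurationError(f"unknown exclusion reasons: {sorted(unknown)}")
        if self.n_followup is not None and not 0 <= self.n_followup <= self.n_subjects:
            raise ConfigurationError("n_followup must lie in [0, n_subjects]")


def study_config(seed: int = 0) -> CohortConfig:
    """The full published cohort structure: 128 evaluated, 20 flagged for
    exclusion, 108 retained with 127 scans and 81 followed up."""
    return CohortConfig(
        group_counts=STUDY_GROUP_COUNTS,
        exclusion_frequencies=dict(STUDY_EXCLUSION_FREQUENCIES),
        n_followup=81,
        seed=seed,
    )


def _triangular(rng: np.random.Generator, lo: float, hi: float, n: int = 1) -> np.ndarray:
    mode = min(max(GA_MODE, lo), hi)
    return rng.triangular(lo, mode, hi, size=n)


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    raise RuntimeError(f"could not draw a positive value from N({mean:.3g}, {sd:.3g})")


def _scaled_group_counts(n: int) -> list[int]:
    # largest-remainder apportionment of the published group proportions
    total = sum(STUDY_GROUP_COUNTS)
    quotas = [n * c / total for c in STUDY_GROUP_COUNTS]
    counts = [int(q) for q in quotas]
    rem = n - sum(counts)
    order = sorted(range(4), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _draw_measurements(
    rng: np.random.Generator,
    ga: float,
    truth: dict[str, GrowthTruth],
    ventricle_side_mult: float,
    left_excess: float,
    subject_effect: float,
) -> dict[str, float]:
    meas: dict[str, float] = {}
    for name, t in truth.items():
        if name == "ventricles_total":
            continue
        meas[name] = _positive_normal(rng, float(t.mean(ga)), float(t.sd(ga)))
    vt = truth.get("ventricles_total")
    if vt is not None:
        half_mean = float(vt.mean(ga)) / 2.0 * ventricle_side_mult
        half_sd = float(vt.sd(ga)) / 2.0
        u = subject_effect * half_sd * _SIDE_SHARED_SD
        left = _positive_normal(
            rng, half_mean * (1.0 + left_excess / 2.0) + u, half_sd * _SIDE_NOISE_SD
        )
        right = _positive_normal(
            rng, half_mean * (1.0 - left_excess / 2.0) + u, half_sd * _SIDE_NOISE_SD
        )
        meas["ventricle_left"] = left
        meas["ventricle_right"] = right
        meas["ventricles_total"] = left + right
    return meas


_EXCLUSION_ANNOTATORS = {
    "motion": lambda s: None,  # handled via scan quality
    "infection": lambda s: s.flags.add("infection_positive"),
    "delivery_complications": lambda s: s.flags.add("delivery_complication"),
    "chromosomal_abnormality": lambda s: s.flags.add("chromosomal_abnormality"),
    "developmental_delay": lambda s: s.followup_scores.__setitem__(
        "bayley_composite_language", 80.0
    ),
    "iugr": lambda s: s.flags.add("iugr"),
    "seizures": lambda s: s.flags.add("seizures"),
    "no_contact": lambda s: s.flags.update({"no_followup_contact", "no_delivery_summary"}),
}


def make_cohort(
    config: CohortConfig, truth: dict[str, GrowthTruth]
) -> tuple[list[SubjectRecord], list[ScanRecord]]:
    """Simulate a cohort: records for retained-eligible subjects plus one
    singly-scanned, annotated subject per configured exclusion.

    Deterministic given ``config.seed``: the same config yields an
    identical cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.ga_range

    n = config.n_subjects
    sexes = np.array(["male"] * config.sex_counts[0] + ["female"] * config.sex_counts[1])
    sexes = rng.permutation(sexes)
    group_counts = (
        list(config.group_counts) if config.group_counts is not None else _scaled_group_counts(n)
    )
    groups = np.array([g for g, c in zip(_GROUPS, group_counts) for _ in range(c)])
    groups = rng.permutation(groups)

    n_followup = (
        config.n_followup if config.n_followup is not None else int(round(0.75 * n))
    )
    followup_ids = set(rng.choice(n, size=n_followup, replace=False).tolist()) if n else set()

    subjects: list[SubjectRecord] = []
    scans: list[ScanRecord] = []
    for i in range(n):
        sid = f"S{i + 1:03d}"
        subject = SubjectRecord(subject_id=sid, sex=str(sexes[i]), recruitment_group=str(groups[i]))
        if i in followup_ids:
            subject.followup_scores["gmds_dq"] = float(np.round(rng.uniform(90.0, 112.0), 1))
        subjects.append(subject)

        n_scans = 3 if i < config.n_thrice_scanned else (
            2 if i < config.n_thrice_scanned + config.n_twice_scanned else 1
        )
        # repeat visits are >= 2 weeks apart, all within ga_range
        max_first = hi - 2.0 * (n_scans - 1)
        ga1 = float(_triangular(rng, lo, min(hi, max_first))[0]) if n_scans > 1 else float(
            _triangular(rng, lo, hi)[0]
        )
        gas = [ga1]
        for _ in range(n_scans - 1):
            prev = gas[-1]
            upper = hi - 2.0 * (n_scans - 1 - len(gas))
            gas.append(float(rng.uniform(prev + 2.0, upper)))
        side_mult = 1.0 + (config.male_ventricle_excess if subject.sex == "male" else 0.0)
        subject_effect = float(rng.standard_normal())
        for ga in gas:
            scans.append(
                ScanRecord(
                    subject_id=sid,
                    ga_weeks=round(ga, 2),
                    measurements=_draw_measurements(
                        rng, ga, truth, side_mult, config.ventricle_left_excess, subject_effect
                    ),
                )
            )

    # annotated exclusion subjects, one scan each
    idx = 0
    for reason in STUDY_EXCLUSION_FREQUENCIES:  # fixed declaration order
        for _ in range(config.exclusion_frequencies.get(reason, 0)):
            idx += 1
            sid = f"X{idx:03d}"
            subject = SubjectRecord(
                subject_id=sid,
                sex="male" if rng.random() < 0.5 else "female",
                recruitment_group="healthy_volunteer",
            )
            _EXCLUSION_ANNOTATORS[reason](subject)
            subjects.append(subject)
            ga = float(_triangular(rng, lo, hi)[0])
            scans.append(
                ScanRecord(
                    subject_id=sid,
                    ga_weeks=round(ga, 2),
                    image_quality="motion_corrupted" if reason == "motion" else "ok",
                    measurements=_draw_measurements(
                        rng, ga, truth, 1.0, config.ventricle_left_excess,
                        float(rng.standard_normal()),
                    ),
                )
            )
    return subjects, scans


def write_truth_json(path: str | Path, truth: dict[str, GrowthTruth]) -> None:
    Path(path).write_text(
        json.dumps({k: asdict(v) for k, v in truth.items()}, indent=2) + "\n"
    )


def read_truth_json(path: str | Path) -> dict[str, GrowthTruth]:
    raw = json.loads(Path(path).read_text())
    return {k: GrowthTruth(**v) for k, v in raw.items()}
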