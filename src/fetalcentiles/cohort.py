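"""Cohort records, inclusion/exclusion rules and the filtering pipeline.

The analysis cohort is assembled from fetuses with a normal brain
appearance on MRI; subjects are then excluded for perinatal or follow-up
findings that cast doubt on "normal": maternal infection, delivery
complications, chromosomal abnormality, developmental delay on formal
assessment, intrauterine growth restriction, postnatal seizures, or loss
to all contact. Image quality operates at scan level: a motion-corrupted
scan is dropped, and the subject is excluded only if no usable scan
remains.

Exclusion attribution is first-match in rule declaration order, so each
excluded subject carries exactly one reason and per-reason counts sum to
the excluded total.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from .errors import IntegrityError

RECRUITMENT_GROUPS = (
    "healthy_volunteer",
    "sibling_with_disability",
    "us_query_cns",
    "non_cns_mild",
)

# Developmental-assessment thresholds: scores strictly below these mark delay.
GMDS_DQ_MIN = 88
GMDS_SQ_MIN = 84
BAYLEY_SCALED_MIN = 7
BAYLEY_COMPOSITE_MIN = 85
ASQ_Z_MIN = -2.0


@dataclass
class SubjectRecord:
    """One fetus: identity, sex, recruitment group and outcome annotations."""

    subject_id: str
    sex: str  # male | female
    recruitment_group: str = "healthy_volunteer"
    edd: date | None = None
    flags: set[str] = field(default_factory=set)
    followup_scores: dict[str, float] = field(default_factory=dict)


@dataclass
class ScanRecord:
    """One MR scan: subject link, GA, image quality and measurements."""

    subject_id: str
    ga_weeks: float
    image_quality: str = "ok"  # ok | motion_corrupted
    measurements: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ExclusionRule:
    """A named subject-level exclusion predicate, evaluated in declaration order."""

    name: str
    predicate: Callable[[SubjectRecord], bool]


@dataclass
class CohortSummary:
    n_evaluated: int
    n_excluded: int
    n_included_subjects: int
    n_scans: int
    per_reason: dict[str, int]
    per_group: dict[str, int]
    scans_per_subject: dict[int, int]
    n_followup: int
    followup_rate_percent: float

    def to_dict(self) -> dict:
        return {
            "n_evaluated": self.n_evaluated,
            "n_excluded": self.n_excluded,
            "n_included_subjects": self.n_included_subjects,
            "n_scans": self.n_scans,
            "per_reason": dict(self.per_reason),
            "per_group": dict(self.per_group),
            "scans_per_subject": {str(k): v for k, v in sorted(self.scans_per_subject.items())},
            "n_followup": self.n_followup,
            "followup_rate_percent": self.followup_rate_percent,
        }


def _developmental_delay(subject: SubjectRecord) -> bool:
    for key, score in subject.followup_scores.items():
        if key.startswith("gmds_dq") and score < GMDS_DQ_MIN:
            return True
        if key.startswith("gmds_sq") and score < GMDS_SQ_MIN:
            return True
        if key.startswith("bayley_scaled") and score < BAYLEY_SCALED_MIN:
            return True
        if key.startswith("bayley_composite") and score < BAYLEY_COMPOSITE_MIN:
            return True
        if key.startswith("asq_z") and score < ASQ_Z_MIN:
            return True
    return False


def default_rules() -> list[ExclusionRule]:
    """The study's subject-level exclusion rules, in attribution order.

    Image quality is not listed here because it is handled at scan level
    by :func:`apply_exclusions` (reason ``inadequate_image_quality`` when
    a subject loses every scan to motion).

    Missing follow-up alone never excludes; only the combination of no
    postnatal contact AND no delivery summary does.
    """
    return [
        ExclusionRule("infection", lambda s: "infection_positive" in s.flags),
        ExclusionRule("delivery_complications", lambda s: "delivery_complication" in s.flags),
        ExclusionRule("chromosomal_abnormality", lambda s: "chromosomal_abnormality" in s.flags),
        ExclusionRule("developmental_delay", _developmental_delay),
        ExclusionRule("iugr", lambda s: "iugr" in s.flags),
        ExclusionRule("seizures", lambda s: "seizures" in s.flags),
        ExclusionRule(
            "no_contact",
            lambda s: "no_followup_contact" in s.flags and "no_delivery_summary" in s.flags,
        ),
    ]


def apply_exclusions(
    subjects: Sequence[SubjectRecord],
    scans: Sequence[ScanRecord],
    rules: Sequence[ExclusionRule] | None = None,
    drop_subject_on_any_motion: bool = False,
) -> tuple[list[SubjectRecord], list[ScanRecord], list[tuple[str, str]], CohortSummary]:
    """Partition a cohort into included and excluded, with a full audit.

    Returns (included subjects, included scans, exclusion log, summary).
    The log lists (subject_id, reason) in deterministic input order.
    Excluding a subject removes all of that subject's scans.

    ``drop_subject_on_any_motion=True`` switches to subject-level image
    quality exclusion (one corrupted scan loses the subject).
    """
    if rules is None:
        rules = default_rules()
    names = [r.name for r in rules]
    if len(set(names)) != len(names):
        raise ValueError("exclusion rule names must be unique")

    by_subject: dict[str, list[ScanRecord]] = {s.subject_id: [] for s in subjects}
    for scan in scans:
        if scan.subject_id not in by_subject:
            raise IntegrityError(f"scan references unknown subject {scan.subject_id!r}")
        by_subject[scan.subject_id].append(scan)

    log: list[tuple[str, str]] = []
    included_subjects: list[SubjectRecord] = []
    included_scans: list[ScanRecord] = []

    for subject in subjects:
        usable = [s for s in by_subject[subject.subject_id] if s.image_quality == "ok"]
        dropped = len(by_subject[subject.subject_id]) - len(usable)
        if dropped and (drop_subject_on_any_motion or not usable):
            log.append((subject.subject_id, "inadequate_image_quality"))
            continue
        reason = next((r.name for r in rules if r.predicate(subject)), None)
        if reason is not None:
            log.append((subject.subject_id, reason))
            continue
        included_subjects.append(subject)
        included_scans.extend(usable)

    hist, total = scan_accounting(included_scans)
    n_followup = sum(1 for s in included_subjects if s.followup_scores)
    n_inc = len(included_subjects)
    summary = CohortSummary(
        n_evaluated=len(subjects),
        n_excluded=len(log),
        n_included_subjects=n_inc,
        n_scans=total,
        per_reason=dict(Counter(reason for _, reason in log)),
        per_group=dict(Counter(s.recruitment_group for s in included_subjects)),
        scans_per_subject=hist,
        n_followup=n_followup,
        followup_rate_percent=100.0 * n_followup / n_inc if n_inc else 0.0,
    )
    return included_subjects, included_scans, log, summary


def scan_accounting(scans: Sequence[ScanRecord]) -> tuple[dict[int, int], int]:
    """Histogram of scans per subject and the total scan count."""
    per_subject = Counter(s.subject_id for s in scans)
    hist = dict(Counter(per_subject.values()))
    total = sum(k * v for k, v in hist.items())
    return hist, total


# ---------------------------------------------------------------------------
# CSV schema: one row per scan. Subject-level fields repeat across a
# subject's rows; flags are 0/1 columns "flag_<name>", follow-up scores
# "score_<name>", measurements one column each (blank = not measured).
# ---------------------------------------------------------------------------


def cohort_to_frame(subjects: Sequence[SubjectRecord], scans: Sequence[ScanRecord]) -> pd.DataFrame:
    subj = {s.subject_id: s for s in subjects}
    flag_names = sorted({f for s in subjects for f in s.flags})
    score_names = sorted({k for s in subjects for k in s.followup_scores})
    meas_names = sorted({m for sc in scans for m in sc.measurements})
    rows = []
    for sc in scans:
        s = subj[sc.subject_id]
        row: dict = {
            "subject_id": s.subject_id,
            "sex": s.sex,
            "group": s.recruitment_group,
            "edd": s.edd.isoformat() if s.edd else "",
            "ga_weeks": sc.ga_weeks,
            "image_quality": sc.image_quality,
        }
        for f in flag_names:
            row[f"flag_{f}"] = int(f in s.flags)
        for k in score_names:
            row[f"score_{k}"] = s.followup_scores.get(k, "")
        for m in meas_names:
            row[m] = sc.measurements.get(m, "")
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(path: str | Path, subjects, scans) -> None:
    cohort_to_frame(subjects, scans).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> tuple[list[SubjectRecord], list[ScanRecord]]:
    df = pd.read_csv(path, dtype={"subject_id": str}, keep_default_na=False)
    flag_cols = [c for c in df.columns if c.startswith("flag_")]
    score_cols = [c for c in df.columns if c.startswith("score_")]
    core = {"subject_id", "sex", "group", "edd", "ga_weeks", "image_quality"}
    meas_cols = [c for c in df.columns if c not in core and not c.startswith(("flag_", "score_"))]
    subjects: dict[str, SubjectRecord] = {}
    scans: list[ScanRecord] = []
    for _, row in df.iterrows():
        sid = row["subject_id"]
        if sid not in subjects:
            subjects[sid] = SubjectRecord(
                subject_id=sid,
                sex=row["sex"],
                recruitment_group=row["group"],
                edd=date.fromisoformat(row["edd"]) if row.get("edd") else None,
                flags={c[len("flag_"):] for c in flag_cols if int(row[c] or 0)},
                followup_scores={
                    c[len("score_"):]: float(row[c]) for c in score_cols if row[c] != ""
                },
            )
        scans.append(
            ScanRecord(
                subject_id=sid,
                ga_weeks=float(row["ga_weeks"]),
                image_quality=row["image_quality"],
                measurements={m: float(row[m]) for m in meas_cols if row[m] != ""},
            )
        )
    return list(subjects.values()), scans


def write_exclusion_log(path: str | Path, log: list[tuple[str, str]]) -> None:
    pd.DataFrame(log, columns=["subject_id", "reason"]).to_csv(path, index=False)


def write_summary_json(path: str | Path, summary: CohortSummary) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
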