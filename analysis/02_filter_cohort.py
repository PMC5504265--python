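"""Apply the inclusion/exclusion rules and audit the cohort.

Reads the simulated evaluated cohort, applies the default exclusion rules
(first-match attribution; motion handled at scan level), and writes the
included-scan CSV, the per-subject exclusion log, and the summary JSON
with scan accounting and the follow-up rate.
"""

from pathlib import Path

from fetalcentiles import apply_exclusions, read_cohort_csv, write_cohort_csv
from fetalcentiles.cohort import write_exclusion_log, write_summary_json

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    subjects, scans = read_cohort_csv(RESULTS / "cohort_full.csv")
    included_subjects, included_scans, log, summary = apply_exclusions(subjects, scans)
    write_cohort_csv(RESULTS / "cohort_included.csv", included_subjects, included_scans)
    write_exclusion_log(RESULTS / "exclusion_log.csv", log)
    write_summary_json(RESULTS / "cohort_summary.json", summary)
    print(f"{summary.n_evaluated} evaluated -> {summary.n_excluded} excluded "
          f"({dict(sorted(summary.per_reason.items()))})")
    print(f"included: {summary.n_included_subjects} fetuses / {summary.n_scans} scans "
          f"(scans-per-subject {dict(sorted(summary.scans_per_subject.items()))})")
    print(f"follow-up: {summary.n_followup}/{summary.n_included_subjects} "
          f"({summary.followup_rate_percent:.0f}%)")


if __name__ == "__main__":
    main()
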