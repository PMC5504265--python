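"""Fit the reference centile models for the volumetric structures.

For each structure the mean curve is fitted by least squares (quadratic
in GA; exponential for cortex) and the SD curve by regression of scaled
absolute residuals (linear; quadratic preferred for cortex, falling back
to linear when the quadratic is non-positive inside the GA domain).
Serialized models go to results/models/.
"""

from pathlib import Path

from fetalcentiles import read_cohort_csv
from fetalcentiles.errors import DegenerateSDError
from fetalcentiles.fitting import fit_measurement
from fetalcentiles.registry import TABLE_STRUCTURES

RESULTS = Path(__file__).resolve().parents[1] / "results"
STRUCTURES = TABLE_STRUCTURES + ["ventricle_left", "ventricle_right"]


def main() -> None:
    _, scans = read_cohort_csv(RESULTS / "cohort_included.csv")
    model_dir = RESULTS / "models"
    model_dir.mkdir(exist_ok=True)
    for name in STRUCTURES:
        try:
            model, note = fit_measurement(scans, name)
        except DegenerateSDError as err:
            # a reference model with non-positive SD is unusable: refuse
            # loudly and move on rather than flooring the curve
            print(f"{name}: no reference model emitted ({err})")
            continue
        model.to_json(model_dir / f"{name}.json")
        lo, hi = model.ga_domain
        print(f"{name}: n={model.n_scans}, GA [{lo:.2f}, {hi:.2f}], "
              f"mean({30.0:.0f})={float(model.mean(30)):.2f}, "
              f"SD(30)={float(model.sd(30)):.2f} "
              f"[{model.mean_family} mean, {model.sd_family} SD]")
        if note:
            print(f"  note: {note}")


if __name__ == "__main__":
    main()
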