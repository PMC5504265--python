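"""Centile-calculator walkthrough.

Dates a scan from the expected date of delivery, places a set of
volumetric measurements on the fitted reference models, and writes the
full report (centiles, z-scores, 5th/50th/95th chart series) to
results/centile_report.json.
"""

from datetime import date
from pathlib import Path

from fetalcentiles import CalculatorRequest, evaluate
from fetalcentiles.calculator import load_models

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    models = load_models(RESULTS / "models")
    request = CalculatorRequest(
        edd=date(2020, 3, 15),
        scan_date=date(2020, 1, 2),
        measurements={"cerebellum": 9.1, "supratentorial": 170.0, "ventricles_total": 4.2},
    )
    report = evaluate(request, models)
    report.to_json(RESULTS / "centile_report.json")
    print(f"GA at scan: {report.ga_weeks:.2f} weeks")
    for name, res in report.results.items():
        flag = " (extrapolated)" if res["extrapolated"] else ""
        print(f"  {name}: {res['value']:g} cm^3 -> centile {res['centile']:.1f} "
              f"(z = {res['z_score']:+.2f}){flag}")


if __name__ == "__main__":
    main()
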