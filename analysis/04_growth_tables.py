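"""Growth-rate analysis: printed-table-style summaries and scaling laws.

Tabulates average volume, absolute growth rate (cm^3/week) and relative
growth rate (%/week) at 22/26/30/34/38 weeks from the fitted models, and
computes the allometric scaling exponents of cortex, cerebellum and
extra-cerebral CSF against supratentorial brain tissue together with the
left-right ventricular asymmetry of the cohort.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from fetalcentiles import (
    CentileModel,
    allometric_exponent,
    asymmetry_percent,
    growth_table,
    read_cohort_csv,
)
from fetalcentiles.registry import TABLE_STRUCTURES

RESULTS = Path(__file__).resolve().parents[1] / "results"
GA_GRID = [22.0, 26.0, 30.0, 34.0, 38.0]


def main() -> None:
    frames = []
    endpoint_rgr = {}
    for name in TABLE_STRUCTURES:
        path = RESULTS / "models" / f"{name}.json"
        if not path.exists():
            print(f"{name}: skipped (no reference model was fitted)")
            continue
        model = CentileModel.from_json(path)
        table = growth_table(model, GA_GRID)
        df = pd.DataFrame(table.to_records())
        df.insert(0, "structure", name)
        frames.append(df)
        endpoint_rgr[name] = table.summary_relative_rate
        print(f"{name}: endpoint relative growth rate "
              f"{table.summary_relative_rate:.2f} %/week; absolute rate at 30 GW "
              f"{df.loc[df.ga_weeks == 30.0, 'absolute_rate'].iloc[0]:.2f} cm^3/week")
    pd.concat(frames).to_csv(RESULTS / "growth_tables.csv", index=False)

    _, scans = read_cohort_csv(RESULTS / "cohort_included.csv")
    supra = np.array([s.measurements["supratentorial"] for s in scans])
    scaling = {}
    for name in ("cortex", "cerebellum", "ecsf"):
        y = np.array([s.measurements[name] for s in scans])
        exponent, _ = allometric_exponent(supra, y)
        scaling[name] = exponent
        print(f"{name} ~ supratentorial^{exponent:.2f} (allometric exponent)")

    asym = [asymmetry_percent(s.measurements["ventricle_left"], s.measurements["ventricle_right"])
            for s in scans]
    print(f"mean left-right ventricular asymmetry: {np.mean(asym):.2f}%")

    (RESULTS / "growth_summary.json").write_text(json.dumps({
        "endpoint_relative_growth_rate_pct_per_week": endpoint_rgr,
        "allometric_exponent_vs_supratentorial": scaling,
        "mean_ventricular_asymmetry_percent": float(np.mean(asym)),
    }, indent=2) + "\n")


if __name__ == "__main__":
    main()
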