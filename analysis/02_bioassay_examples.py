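"""Worked examples of the assay arithmetic feeding the activity table.

Shows the DPPH scavenging equation, a FRAP calibration round trip, the
NO-inhibition rate at the measured stimulated/baseline levels, and IC50
estimation on a logistic dose-response, then stores the numbers in
results/bioassay_examples.json.
"""

import json
from pathlib import Path

import numpy as np

from phytomarker.bioassay import (DPPHMeasurement, _four_pl, dpph_scavenging,
                                  estimate_ic50, fit_frap_calibration,
                                  frap_value, inhibition_rate)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    dpph = dpph_scavenging(DPPHMeasurement(A0=0.05, A1=0.80, A2=0.45))
    print(f"DPPH: A0=0.05, A1=0.80, A2=0.45 -> scavenging {dpph:.1%}")

    conc = np.array([100.0, 250, 500, 750, 1000])  # µmol/L Fe(II) standards
    cal = fit_frap_calibration(conc, 0.0008 * conc + 0.04)
    value, _ = frap_value(0.44, cal, mass_g=0.5, dilution=0.02)
    print(f"FRAP: abs 0.44 on calibration (slope {cal.slope:.4g}, "
          f"r²={cal.r_squared:.4f}) -> {value:.1f} µmol Fe(II)/g")

    rate, _ = inhibition_rate(treated=22.2, stimulated=43.72, unstimulated=0.67)
    print(f"NO inhibition: 43.72 µM stimulated, 0.67 µM baseline, "
          f"22.2 µM treated -> {rate:.1%}")

    doses = np.array([12.5, 25, 50, 100, 200, 400])  # µg/mL
    resp = _four_pl(doses, 0.0, 1.0, 1.2, 90.0)
    est = estimate_ic50(doses, resp)
    print(f"IC50 on logistic curve (true 90): {est.label} µg/mL")

    censored = estimate_ic50(doses, np.minimum(resp, 0.42))
    print(f"weak compound never reaching 50%: {censored.label} µg/mL")

    OUT.mkdir(parents=True, exist_ok=True)
    with open(OUT / "bioassay_examples.json", "w") as fh:
        json.dump({
            "dpph_scavenging_percent": round(100 * dpph, 3),
            "frap_umol_fe_per_g": round(value, 3),
            "no_inhibition_percent": round(100 * rate, 3),
            "ic50_recovered": round(est.ic50, 3),
            "ic50_censored_label": censored.label,
        }, fh, indent=2, sort_keys=True)
        fh.write("\n")


if __name__ == "__main__":
    main()
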