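"""Drug-likeness admission of the screened candidates.

Takes the candidate peaks from 04_pls_screening.py, computes descriptors
for the study compounds those peaks correspond to (RDKit, structures
without stereochemistry), evaluates the five rule sets and the
GI-absorption ellipse, and applies the admission rule with the > 20-fold
content override. Writes results/admission.csv.
"""

import json
from pathlib import Path

import pandas as pd

from phytomarker import read_peak_table
from phytomarker.descriptors import descriptors_from_smiles
from phytomarker.druglikeness import AdmissionConfig, admit_marker

ROOT = Path(__file__).resolve().parents[1] / "results"

# peak number -> (compound, SMILES); flat structures for the study compounds
PEAK_COMPOUNDS = {
    "1": ("caftaric acid",
          "O=C(O)C(O)C(OC(=O)/C=C/c1ccc(O)c(O)c1)C(=O)O"),
    "3": ("5-O-caffeoylquinic acid",
          "O=C(O)C1(O)CC(O)C(O)C(OC(=O)/C=C/c2ccc(O)c(O)c2)C1"),
    "5": ("caffeic acid", "O=C(O)/C=C/c1ccc(O)c(O)c1"),
    "7": ("cichoric acid",
          "O=C(O)C(OC(=O)/C=C/c1ccc(O)c(O)c1)"
          "C(OC(=O)/C=C/c1ccc(O)c(O)c1)C(=O)O"),
    "8": ("p-coumaric acid", "O=C(O)/C=C/c1ccc(O)cc1"),
    "9": ("luteolin-7-O-gentiobioside",
          "O=c1cc(-c2ccc(O)c(O)c2)oc2cc(OC3OC(COC4OC(CO)C(O)C(O)C4O)"
          "C(O)C(O)C3O)cc(O)c12"),
    "13": ("luteolin-7-O-glucoside",
           "O=c1cc(-c2ccc(O)c(O)c2)oc2cc(OC3OC(CO)C(O)C(O)C3O)cc(O)c12"),
    "17": ("isorhamnetin-3-O-glucoside",
           "COc1cc(-c2oc3cc(O)cc(O)c3c(=O)c2OC2OC(CO)C(O)C(O)C2O)ccc1O"),
    "18": ("luteolin", "O=c1cc(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12"),
    "19": ("kaempferol", "O=c1c(O)c(-c2ccc(O)cc2)oc2cc(O)cc(O)c12"),
    "20": ("apigenin", "O=c1cc(-c2ccc(O)cc2)oc2cc(O)cc(O)c12"),
    # eupalitin: 3,5,4'-trihydroxy-6,7-dimethoxyflavone
    "21": ("eupalitin", "COc1cc2oc(-c3ccc(O)cc3)c(O)c(=O)c2c(O)c1OC"),
}


def main() -> None:
    summary = json.loads((ROOT / "screening" / "summary.json").read_text())
    candidates = sorted(set().union(*summary["per_group"].values()), key=int)
    peaks = read_peak_table(ROOT / "cohort" / "peaks.csv")
    mean_area = peaks.data.mean(axis=0)
    rows = []
    admitted = []
    for cid in candidates:
        if cid not in PEAK_COMPOUNDS:
            rows.append({"peak": cid, "compound": "unidentified",
                         "status": "no_structure"})
            continue
        name, smiles = PEAK_COMPOUNDS[cid]
        record, _ = descriptors_from_smiles(smiles, cid)
        ratio_base = float(mean_area.drop(cid).median())
        rep = admit_marker(record, float(mean_area[cid]), ratio_base,
                           AdmissionConfig())
        if rep.admissible:
            admitted.append(f"{cid} ({name})")
        rows.append({
            "peak": cid, "compound": name, "status": "evaluated",
            "ga_class": rep.ga_class, "rules_passed": rep.rules_passed,
            "content_ratio": round(rep.content_ratio, 2),
            "admissible": rep.admissible,
            "override_applied": rep.override_applied,
        })
        route = ("high-content override" if rep.override_applied
                 else "GA + drug-likeness" if rep.admissible else "rejected")
        print(f"peak {cid:>2} {name:32s} GA={rep.ga_class:4s} "
              f"rules={rep.rules_passed}/5 ratio={rep.content_ratio:6.1f} "
              f"-> {route}")
    pd.DataFrame(rows).to_csv(ROOT / "admission.csv", index=False)
    print(f"\nadmitted quality markers: {admitted}")
    print("wrote results/admission.csv")


if __name__ == "__main__":
    main()
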