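"""Run the pre-specified 18-marker logistic LRT screen on the simulated
trial: association with pCR in the experimental arm, in the control arm,
marker-by-treatment interaction (raw and HR-adjusted), and receptor-subset
analyses.  Pending outcomes are coded non-pCR per protocol.

Writes results/biomarkers/marker_screen.csv (Fig-4-style table).
"""

from dataclasses import replace
from pathlib import Path

from platformtrial.biomarker_screen import results_frame, screen_markers
from platformtrial.synthetic_trial import scenario_presets
from platformtrial.trial_data import evaluability_filter, read_patients

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    scenario = scenario_presets()["ganetespib_like"]
    patients = read_patients(ROOT / "trial" / "patients.csv", scenario.arms)
    evaluable, _ = evaluability_filter(patients)
    coded = [replace(p, pcr=0) if p.pcr is None else p for p in evaluable]
    results = screen_markers(coded, "ganetespib")
    out = ROOT / "biomarkers"
    out.mkdir(parents=True, exist_ok=True)
    table = results_frame(results)
    table.to_csv(out / "marker_screen.csv", index=False)
    qual = table[table.qualifies]
    print(f"screened {len(table)} markers on {len(coded)} patients; "
          f"{len(qual)} qualify as arm-specific predictors")
    if len(qual):
        print(qual[["marker", "p_arm", "p_control", "p_interaction"]]
              .to_string(index=False))
    print("(the generator plants no marker effects in this scenario, so "
          "qualifiers reflect the screen's joint type-I rate)")


if __name__ == "__main__":
    main()
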