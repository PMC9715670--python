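"""Apply the platform's decision rules to the fitted arm: per-signature
probability of superiority, predictive probability of success in a
300-patient 1:1 phase 3 trial, and the graduate / futile / continue /
max-accrual action.

Reads the trial from results/trial/, refits (the posterior file stores draws,
not the rate pairing used here), and writes results/decisions/.
"""

from pathlib import Path

from platformtrial.decision_engine import DecisionConfig, build_decision_report
from platformtrial.pcr_model import ModelConfig, sample_posterior
from platformtrial.synthetic_trial import scenario_presets
from platformtrial.trial_data import (
    default_signature_catalogue,
    evaluability_filter,
    read_patients,
    signature_members,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
ANALYSIS_DAY = 540


def main(seed: int = 1) -> None:
    scenario = scenario_presets()["ganetespib_like"]
    patients = read_patients(ROOT / "trial" / "patients.csv", scenario.arms)
    evaluable, _ = evaluability_filter(patients)
    signatures = default_signature_catalogue()
    draws = sample_posterior(
        evaluable, scenario.arms, ANALYSIS_DAY,
        model_cfg=ModelConfig(n_warmup=500, n_draws=1500), seed=seed,
    )
    arm = next(a for a in scenario.arms if not a.is_control)
    enrolled = [p for p in evaluable if p.arm_id == arm.arm_id]
    enrollment = {s.name: len(signature_members(s, enrolled)) for s in signatures}
    enrollment["__arm_total__"] = len(enrolled)
    report = build_decision_report(draws, arm, signatures, enrollment,
                                   DecisionConfig())
    out = ROOT / "decisions"
    out.mkdir(parents=True, exist_ok=True)
    frame = report.to_frame()
    frame.to_csv(out / "decision_report.csv", index=False)
    cols = ["signature", "prob_superiority", "pred_prob_phase3", "n_enrolled"]
    print(frame[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"action for arm {arm.arm_id!r}: {report.action} "
          f"{report.graduated_signatures or ''}")


if __name__ == "__main__":
    main()
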