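"""YAML/JSON configuration: one document with sections per module.

Example::

    scenario: ganetespib_like          # preset name, or an inline mapping
    time_machine: {bin_width: 90}
    model: {n_warmup: 500, n_draws: 1000}
    decision: {graduation_threshold: 0.85}
    signatures:                        # optional override of the catalogue
      - {name: "HER2-", hr: null, her2: false, mp2: null}

Inline scenario mappings use subtype keys like ``"HR+/HER2-/MP2"`` and arm
effect keys like ``"ganetespib|HR-/HER2-/MP1"``.
"""

from __future__ import annotations

from typing import Optional

import yaml

from .decision_engine import DecisionConfig
from .pcr_model import ModelConfig
from .synthetic_trial import FtvModel, MarkerSpec, ScenarioConfig, scenario_presets
from .time_machine import TimeMachineConfig
from .trial_data import ALL_SUBTYPES, ArmSpec, Signature, Subtype


class ConfigError(ValueError):
    pass


def parse_subtype(label: str) -> Subtype:
    try:
        hr_s, her2_s, mp_s = label.split("/")
        return Subtype("+" in hr_s, "+" in her2_s, mp_s.strip().upper() == "MP2")
    except Exception:
        raise ConfigError(f"bad subtype label {label!r} (want e.g. 'HR+/HER2-/MP2')")


def _build(cls, section: dict, name: str):
    try:
        return cls(**(section or {}))
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{name}: {e}") from None


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("top-level config must be a mapping")
    return doc


def scenario_from_config(doc: dict, seed: Optional[int] = None) -> ScenarioConfig:
    sc = doc.get("scenario", "null")
    if isinstance(sc, str):
        presets = scenario_presets()
        if sc not in presets:
            raise ConfigError(
                f"unknown scenario preset {sc!r}; have {sorted(presets)}")
        cfg = presets[sc]
    elif isinstance(sc, dict):
        cfg = _scenario_from_dict(sc)
    else:
        raise ConfigError("scenario must be a preset name or a mapping")
    if seed is not None:
        cfg.seed = seed
    cfg.validate()
    return cfg


def _scenario_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    if "subtype_prevalence" in d:
        d["subtype_prevalence"] = {
            parse_subtype(k): float(v) for k, v in d["subtype_prevalence"].items()
        }
    if "true_control_pcr" in d:
        d["true_control_pcr"] = {
            parse_subtype(k): float(v) for k, v in d["true_control_pcr"].items()
        }
    if "arm_effects" in d:
        eff = {}
        for k, v in d["arm_effects"].items():
            arm, _, sub = k.partition("|")
            if not sub:
                raise ConfigError(f"arm_effects key {k!r} must be 'arm|subtype'")
            eff[(arm, parse_subtype(sub))] = float(v)
        d["arm_effects"] = eff
    if "arms" in d:
        arms = []
        for a in d["arms"]:
            a = dict(a)
            if "eligible_subtypes" in a:
                a["eligible_subtypes"] = frozenset(
                    parse_subtype(s) for s in a["eligible_subtypes"])
            arms.append(_build(ArmSpec, a, "arms"))
        d["arms"] = arms
    if "drift_knots_her2neg" in d:
        d["drift_knots_her2neg"] = tuple(tuple(k) for k in d["drift_knots_her2neg"])
    if "drift_knots_her2pos" in d:
        d["drift_knots_her2pos"] = tuple(tuple(k) for k in d["drift_knots_her2pos"])
    if "ftv_model" in d:
        d["ftv_model"] = _build(FtvModel, d["ftv_model"], "ftv_model")
    if "marker_model" in d:
        d["marker_model"] = {
            m: MarkerSpec(
                mean=float(s.get("mean", 0.0)),
                sd=float(s.get("sd", 1.0)),
                effects=tuple((a, float(v)) for a, v in (s.get("effects") or {}).items()),
            )
            for m, s in d["marker_model"].items()
        }
    return _build(ScenarioConfig, d, "scenario")


def tm_config_from_config(doc: dict) -> TimeMachineConfig:
    return _build(TimeMachineConfig, doc.get("time_machine", {}), "time_machine")


def model_config_from_config(doc: dict) -> ModelConfig:
    return _build(ModelConfig, doc.get("model", {}), "model")


def decision_config_from_config(doc: dict) -> DecisionConfig:
    return _build(DecisionConfig, doc.get("decision", {}), "decision")


def signatures_from_config(doc: dict) -> Optional[list[Signature]]:
    """Signature catalogue override: each entry filters on hr/her2/mp2
    (null = unrestricted)."""
    if "signatures" not in doc:
        return None
    sigs = []
    for entry in doc["signatures"]:
        name = entry.get("name")
        if not name:
            raise ConfigError("each signature needs a name")
        members = frozenset(
            s for s in ALL_SUBTYPES
            if all(
                entry.get(k) is None or getattr(s, k) == bool(entry[k])
                for k in ("hr", "her2", "mp2")
            )
        )
        sigs.append(Signature(name, members))
    return sigs
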