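"""Configuration and file-format round-tripping.

Protocols are stored as YAML documents with ``subject``, ``infusions``
and ``meals`` blocks (times in hours from label start, masses in grams;
per-kg dose fields are expanded via the subject's weight).  Run
configurations are validated against a flat schema; unknown keys are
rejected with a message naming them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tracer_simulator import (InfusionSegment, MealEvent, Protocol, Subject,
                               Trajectory)

__all__ = ["ConfigError", "load_protocol", "dump_protocol",
           "load_run_config", "trajectory_frame", "DEFAULT_RUN_CONFIG"]


class ConfigError(ValueError):
    """Invalid configuration document."""


_SUBJECT_KEYS = {"weight", "height", "sex", "age"}
_INFUSION_KEYS = {"start", "stop", "rate", "prime",
                  "rate_mg_per_kg_min", "prime_mg_per_kg"}
_MEAL_KEYS = {"time", "cho", "energy", "volume", "fraction_solid", "duration"}


def _check_keys(block: dict, allowed: set, what: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown {what} keys: {sorted(unknown)}")


def load_protocol(path: str | Path) -> Protocol:
    """Read a protocol YAML document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "subject" not in doc:
        raise ConfigError("protocol document must contain a 'subject' block")
    _check_keys(doc, {"subject", "infusions", "meals", "horizon"}, "protocol")
    sub = doc["subject"]
    _check_keys(sub, _SUBJECT_KEYS, "subject")
    if "weight" not in sub:
        raise ConfigError("subject block missing required key: 'weight'")
    subject = Subject(**sub)
    infusions = []
    for block in doc.get("infusions") or []:
        _check_keys(block, _INFUSION_KEYS, "infusion")
        block = dict(block)
        if "rate_mg_per_kg_min" in block:
            block["rate"] = block.pop("rate_mg_per_kg_min") \
                * subject.weight * 60.0 / 1000.0
        if "prime_mg_per_kg" in block:
            block["prime"] = block.pop("prime_mg_per_kg") \
                * subject.weight / 1000.0
        infusions.append(InfusionSegment(**block))
    meals = []
    for block in doc.get("meals") or []:
        _check_keys(block, _MEAL_KEYS, "meal")
        meals.append(MealEvent(**block))
    horizon = doc.get("horizon")
    if horizon is None:
        last = [seg.stop for seg in infusions] + \
            [m.time + m.duration for m in meals]
        horizon = (max(last) if last else 0.0) + 5.0
    return Protocol(subject=subject, infusions=tuple(infusions),
                    meals=tuple(meals), horizon=float(horizon))


def dump_protocol(protocol: Protocol, path: str | Path) -> None:
    doc = {
        "subject": {"weight": protocol.subject.weight,
                    "height": protocol.subject.height,
                    "sex": protocol.subject.sex},
        "infusions": [{"start": s.start, "stop": s.stop, "rate": s.rate,
                       "prime": s.prime} for s in protocol.infusions],
        "meals": [{"time": m.time, "cho": m.cho, "energy": m.energy,
                   "duration": m.duration} for m in protocol.meals],
        "horizon": protocol.horizon,
    }
    if protocol.subject.age is not None:
        doc["subject"]["age"] = protocol.subject.age
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


DEFAULT_RUN_CONFIG = {
    "template": "oneday",
    "n_subjects": 8,
    "seed": 42,
    "grid_step_h": 0.05,
    "n_starts": 200,
    "plasma_cv": 0.05,
    "dna_cv": 0.10,
    "p_bounds": [0.0, 1.0],
    "d_star_bounds": [0.0, 10.0],
    "auc_bounds": [1e-6, 100.0],
    "b": 0.65,
    "lag_day": 0.5,
    "round_increase_to_int": True,
}


def load_run_config(path: str | Path | None) -> dict:
    """Load a run configuration, applying defaults and rejecting unknown keys."""
    cfg = dict(DEFAULT_RUN_CONFIG)
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError("run config must be a mapping")
        unknown = set(doc) - set(DEFAULT_RUN_CONFIG)
        if unknown:
            raise ConfigError(f"unknown run config keys: {sorted(unknown)}")
        cfg.update(doc)
    return cfg


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Trajectory as a tidy frame (enrichment in percent)."""
    return pd.DataFrame({
        "time_h": traj.t,
        "enrichment_pct": 100.0 * traj.enrichment.u,
        "G_u_g": [s.G_u for s in traj.states],
        "G_l_g": [s.G_l for s in traj.states],
        "gut_u_g": [s.Gut_u for s in traj.states],
        "gut_l_g": [s.Gut_l for s in traj.states],
        "insulin_norm": [s.I for s in traj.states],
        "y_gly": [s.y_gly for s in traj.states],
    })
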