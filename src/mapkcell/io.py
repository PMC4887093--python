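"""Config file serialisation (YAML/JSON) and time-series CSV helpers.

Configs round-trip losslessly: ``config_from_dict(config_to_dict(cfg))``
reproduces the original :class:`~mapkcell.engine.SimulationConfig`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .agents import PopulationConfig
from .clusters import ClusterConfig
from .engine import SimulationConfig
from .radp import FixedTimeTrigger, Phase, PlateauTrigger, RadpConfig, RadpSchedule


def _trigger_to_dict(trigger):
    if trigger is None:
        return None
    if isinstance(trigger, FixedTimeTrigger):
        return {"type": "fixed_time", "at_min": trigger.at_min}
    if isinstance(trigger, PlateauTrigger):
        return {
            "type": "plateau",
            "species": trigger.species,
            "window_min": trigger.window_min,
            "rel_tol": trigger.rel_tol,
        }
    raise TypeError(f"unknown trigger type {type(trigger)!r}")


def _trigger_from_dict(d):
    if d is None:
        return None
    kind = d["type"]
    if kind == "fixed_time":
        return FixedTimeTrigger(at_min=float(d["at_min"]))
    if kind == "plateau":
        return PlateauTrigger(
            species=d.get("species", "pMAPK"),
            window_min=float(d.get("window_min", 5.0)),
            rel_tol=float(d.get("rel_tol", 0.01)),
        )
    raise ValueError(f"unknown trigger type {kind!r}")


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["schedule"] = {
        "phases": [
            {
                "radp": dataclasses.asdict(ph.radp),
                "trigger": _trigger_to_dict(ph.trigger),
            }
            for ph in cfg.schedule.phases
        ]
    }
    d["clusters"] = None if cfg.clusters is None else dataclasses.asdict(cfg.clusters)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    pop = PopulationConfig(**d.pop("population"))
    sched = RadpSchedule(
        phases=[
            Phase(
                radp=RadpConfig(**ph["radp"]),
                trigger=_trigger_from_dict(ph.get("trigger")),
            )
            for ph in d.pop("schedule")["phases"]
        ]
    )
    clusters_d = d.pop("clusters", None)
    clusters = None if clusters_d is None else ClusterConfig(**clusters_d)
    return SimulationConfig(population=pop, schedule=sched, clusters=clusters, **d)


def save_config(cfg: SimulationConfig, path) -> None:
    path = Path(path)
    d = config_to_dict(cfg)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_config(path) -> SimulationConfig:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return config_from_dict(d)
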