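"""Declarative session configuration (YAML).

One document describes a whole run: the arena (geometry, reference
point, ROIs, screen wall, fps), the simulator kinematics, the protocol
(name plus its parameters) and output options.  Every default is
overridable; :func:`default_config` writes a complete, commented-free
starting point.
"""

from __future__ import annotations

import copy

import yaml

from .arena import ROI, ArenaSpec
from .engine import (
    ConditioningProtocol,
    HeadDirectionProtocol,
    PreferenceProtocol,
    Protocol,
    SecondOrderProtocol,
    YokedProtocol,
)
from .synthetic import KinematicsParams
from .triggers import HeadDirectionWindow

__all__ = [
    "load_config",
    "dump_config",
    "default_config",
    "arena_from_config",
    "kinematics_from_config",
    "protocol_from_config",
]


def default_config() -> dict:
    """A complete head-direction-session configuration."""
    return {
        "arena": {
            "shape": "circle",
            "size": 200.0,
            "center": [424.0, 240.0],
            "reference_point": [724.0, 240.0],
            "cue_arc": [150.0, 170.0],
            "rois": [],
            "screen_wall": None,
            "fps": 30.0,
        },
        "kinematics": {
            "step_sd": 3.0,
            "heading_sd": 5.0,
            "nose_offset": 15.0,
            "tail_offset": 30.0,
            "bias_episodes": [],
            "seed": 0,
            "start_position": None,
            "start_heading": 0.0,
        },
        "protocol": {
            "name": "head_direction_optogenetics",
            "window_width": 60.0,
            "min_stim": 1.0,
            "max_stim": 5.0,
            "inter_stimulus": 15.0,
            "max_duration": 1800.0,
            "actuator_delay": 0,
            "seed": 0,
        },
        "output": {"directory": ".", "table": "session.csv"},
    }


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    merged = default_config()
    for section, values in cfg.items():
        if section in merged and isinstance(values, dict):
            base = dict(merged[section])
            base.update(values)
            merged[section] = base
        else:
            merged[section] = values
    return merged


def dump_config(cfg: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def arena_from_config(cfg: dict) -> ArenaSpec:
    return ArenaSpec.from_dict(cfg["arena"])


def kinematics_from_config(cfg: dict, seed: int | None = None) -> KinematicsParams:
    d = dict(cfg["kinematics"])
    if seed is not None:
        d["seed"] = seed
    return KinematicsParams.from_dict(d)


def protocol_from_config(cfg: dict, arena: ArenaSpec | None = None,
                         seed: int | None = None) -> Protocol:
    """Instantiate the protocol a config names."""
    arena = arena if arena is not None else arena_from_config(cfg)
    p = copy.deepcopy(cfg["protocol"])
    name = p.pop("name")
    if seed is not None:
        p["seed"] = seed
    p.setdefault("fps", arena.fps)
    if name == "head_direction_optogenetics":
        window = HeadDirectionWindow(
            reference_point=tuple(arena.reference_point),
            width=float(p.pop("window_width", 60.0)),
        )
        return HeadDirectionProtocol(window, **p)
    if name == "conditioning":
        roi_cfg = p.pop("reward_roi")
        roi = ROI("reward", tuple(roi_cfg["center"]), float(roi_cfg["radius"]))
        toward = p.pop("toward_screen_deg", None)
        if toward is None:
            inward = arena.wall_inward_normal_deg()
            toward = inward + 180.0
        return ConditioningProtocol(float(toward), roi, **p)
    if name in ("second_order", "preference"):
        rois = {
            o: ROI(o, tuple(r["center"]), float(r["radius"]))
            for o, r in p.pop("odor_rois").items()
        }
        if name == "second_order":
            stim_map = p.pop("stimulus_map", {o: o for o in rois})
            return SecondOrderProtocol(rois, stim_map, **p)
        return PreferenceProtocol(rois, **p)
    if name == "yoked":
        timeline = [tuple(e) for e in p.pop("timeline")]
        return YokedProtocol(timeline, **p)
    raise ValueError(f"unknown protocol name {name!r}")
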