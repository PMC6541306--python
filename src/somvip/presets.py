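"""Named experiment presets shipped as YAML configuration files.

Each preset bundles a circuit parameterization and an experiment pipeline
(`somvip.experiments`).  Presets can be loaded, overridden via dotted keys
and turned into a :class:`~somvip.circuit.CircuitSpec`.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import replace

import yaml

from .circuit import (
    AdaptationParams,
    CircuitSpec,
    ConnectivityParams,
    PCParams,
    PopulationLayout,
    STFParams,
)

__all__ = ["list_presets", "load_preset", "spec_from_config", "apply_overrides"]


def _preset_dir():
    return resources.files("somvip") / "presets"


def list_presets() -> list[str]:
    return sorted(p.name[:-5] for p in _preset_dir().iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> dict:
    path = _preset_dir() / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(list_presets())}")
    cfg = yaml.safe_load(text)
    cfg.setdefault("name", name)
    return cfg


def apply_overrides(cfg: dict, overrides: dict) -> dict:
    """Apply dotted-key overrides (e.g. ``circuit.adaptation.b = 0.5``) to a
    nested config dictionary."""
    import copy

    cfg = copy.deepcopy(cfg)
    for key, value in overrides.items():
        node = cfg
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
    return cfg


def spec_from_config(circuit_cfg: dict) -> CircuitSpec:
    """Build a :class:`CircuitSpec` from the ``circuit`` section of a
    preset config."""
    cfg = dict(circuit_cfg)
    conn = ConnectivityParams()
    mi = cfg.pop("mutual_inhibition", None)
    if mi is not None:
        if isinstance(mi, dict):
            conn = conn.with_mutual_inhibition(float(mi["sv"]), float(mi["vs"]))
        else:
            conn = conn.with_mutual_inhibition(float(mi))
    wr = cfg.pop("recurrence", None)
    if wr is not None:
        conn = conn.with_recurrence(float(wr))
    totals = cfg.pop("totals", None)
    if totals:
        t = dict(conn.total)
        for pair, val in totals.items():
            post, pre = pair.split("<-")
            t[(post, pre)] = float(val)
        conn = replace(conn, total=t)
    probs = cfg.pop("probabilities", None)
    if probs:
        p = dict(conn.prob)
        for pair, val in probs.items():
            post, pre = pair.split("<-")
            p[(post, pre)] = float(val)
        conn = replace(conn, prob=p)
    kwargs = {"connectivity": conn}
    if "layout" in cfg:
        kwargs["layout"] = PopulationLayout(**cfg.pop("layout"))
    if "adaptation" in cfg:
        a = cfg.pop("adaptation")
        if "b" in a:
            kwargs["adaptation"] = AdaptationParams.symmetric(
                float(a["b"]), float(a.get("tau_a", 0.1)))
        else:
            kwargs["adaptation"] = AdaptationParams(**a)
    if "stf" in cfg:
        kwargs["stf"] = STFParams(**cfg.pop("stf"))
    if "pc" in cfg:
        kwargs["pc"] = PCParams(**cfg.pop("pc"))
    for key in ("variant", "include_pc", "background", "interneuron_tau", "r0"):
        if key in cfg:
            kwargs[key] = cfg.pop(key)
    if cfg:
        raise KeyError(f"unknown circuit config keys: {sorted(cfg)}")
    return CircuitSpec(**kwargs)
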