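"""Pipeline configuration: defaults, YAML loading, strict key checking.

Configuration is a nested mapping with one section per pipeline stage;
every key has a default so an empty config is valid, and unknown keys are
rejected rather than silently ignored (a misspelled threshold must not run
with its default). Precedence: explicit overrides > config file > defaults.
"""

from __future__ import annotations

import copy
from dataclasses import fields

import yaml

from .detect import DetectParams
from .errors import ParameterError
from .synthetic import SeizureTemplate, SimConfig, abrupt_onset_template, ramping_template

__all__ = ["default_config", "load_config", "resolve_config", "sim_config_from_dict"]


def _detect_defaults() -> dict:
    return {f.name: f.default for f in fields(DetectParams)}


def default_config() -> dict:
    return {
        "preprocess": {"presets": []},
        "detect": _detect_defaults(),
        "jitter": {"pairing": "signed", "max_shift": None},
        "dynamics": {
            "window_s": 3600.0,
            "step_s": 600.0,
            "k_sd": 2.0,
            "bin_s": 300.0,
        },
        "calcium": {
            "lam": 1e5,
            "p": 0.01,
            "n_iter": 10,
            "frac": 0.02,
            "sustain_s": 60.0,
        },
    }


def _merge(base: dict, update: dict, path: str = "") -> dict:
    for key, value in update.items():
        here = f"{path}{key}"
        if key not in base:
            raise ParameterError(f"unknown config key {here!r}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            _merge(base[key], value, here + ".")
        else:
            base[key] = value
    return base


def load_config(path) -> dict:
    """Read a YAML config file and merge it over the defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParameterError("config file must contain a mapping")
    return _merge(default_config(), data)


def resolve_config(config: dict | None = None, **section_overrides) -> dict:
    """Merge (already-loaded) config and per-section override dicts."""
    cfg = copy.deepcopy(config) if config else default_config()
    overrides = {k: v for k, v in section_overrides.items() if v}
    return _merge(cfg, overrides)


def detect_params_from(cfg: dict) -> DetectParams:
    return DetectParams(**cfg["detect"])


_TEMPLATE_BUILDERS = {
    "abrupt_onset": abrupt_onset_template,
    "ramping": ramping_template,
}


def _template_from_dict(spec: dict) -> SeizureTemplate:
    spec = dict(spec)
    kind = spec.pop("kind", "abrupt_onset")
    if "spike_offsets_s" in spec:
        return SeizureTemplate(
            kind,
            tuple(spec["spike_offsets_s"]),
            tuple(spec["spike_amps_v"]),
        )
    if kind not in _TEMPLATE_BUILDERS:
        raise ParameterError(f"unknown template kind {kind!r}")
    return _TEMPLATE_BUILDERS[kind](**spec)


def sim_config_from_dict(data: dict) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML-friendly mapping.

    Templates may be given either explicitly (``spike_offsets_s`` +
    ``spike_amps_v``) or as builder parameters
    (``{kind: abrupt_onset, duration_s: 20, ...}``).
    """
    data = dict(data)
    if "templates" in data:
        data["templates"] = [_template_from_dict(t) for t in data["templates"]]
    if "state_schedule" in data:
        data["state_schedule"] = [tuple(x) for x in data["state_schedule"]]
    if "noise_schedule" in data and data["noise_schedule"] is not None:
        data["noise_schedule"] = [tuple(x) for x in data["noise_schedule"]]
    known = {f.name for f in fields(SimConfig)}
    unknown = set(data) - known
    if unknown:
        raise ParameterError(f"unknown simulation keys {sorted(unknown)}")
    return SimConfig(**data)
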