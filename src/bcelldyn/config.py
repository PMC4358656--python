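"""Configuration file handling.

A configuration is a YAML mapping of flat key paths onto the calibrated
defaults, e.g.::

    sim.n_agents: 250
    sim.horizon: 144
    model.K_myc: 3.0e4
    input.ikk_decay: 0.03
    noise.partition_cv: 0.072
    noise.cv.tr_myc: 0.25

Sections: ``sim.*`` (engine settings), ``model.*`` (mean parameter values,
including the ``input.*`` aliases for the IKK forcing), ``noise.*``
(partition/init CVs and per-parameter ``noise.cv.<param>``).  Unknown keys
are errors.
"""

from __future__ import annotations

import yaml

from .engine import SimulationConfig
from .model_core import ConfigurationError, PARAM_INDEX, default_model
from .noise import DEFAULT_NOISE_TABLE, default_noise_spec

__all__ = ["load_config", "build_config"]

_SIM_KEYS = {
    "n_agents": int, "horizon": float, "equilibration_min": float,
    "equilibration_max": float, "seed": int, "grid_step": float, "dt": float,
    "volume_scale": float, "debounce": float,
}
_NOISE_FIELDS = {"partition_cv", "init_mass_cv", "init_gm_cv"}
_INPUT_ALIASES = {"ikk_basal", "ikk_amp", "ikk_decay"}


def build_config(overrides: dict | None = None, **kwargs) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from flat key-path overrides."""
    overrides = dict(overrides or {})
    param_updates: dict = {}
    sim_updates: dict = dict(kwargs)
    noise_fields: dict = {}
    cv_overrides: dict = {}

    for key, value in overrides.items():
        section, _, rest = key.partition(".")
        if section == "model":
            if rest not in PARAM_INDEX:
                raise ConfigurationError(f"unknown config key {key!r}")
            param_updates[rest] = float(value)
        elif section == "input":
            name = f"ikk_{rest}" if not rest.startswith("ikk_") else rest
            if name not in _INPUT_ALIASES:
                raise ConfigurationError(f"unknown config key {key!r}")
            param_updates[name] = float(value)
        elif section == "sim":
            if rest not in _SIM_KEYS:
                raise ConfigurationError(f"unknown config key {key!r}")
            sim_updates[rest] = _SIM_KEYS[rest](value)
        elif section == "noise":
            if rest in _NOISE_FIELDS:
                noise_fields[rest] = float(value)
            elif rest.startswith("cv."):
                param = rest[3:]
                if param not in DEFAULT_NOISE_TABLE:
                    raise ConfigurationError(
                        f"unknown noise parameter in config key {key!r}"
                    )
                cv_overrides[param] = float(value)
            else:
                raise ConfigurationError(f"unknown config key {key!r}")
        else:
            raise ConfigurationError(f"unknown config key {key!r}")

    model = default_model(**param_updates)
    noise = default_noise_spec(model.params, cv_overrides=cv_overrides,
                               **noise_fields)
    return SimulationConfig(model=model, noise=noise, **sim_updates)


def load_config(path, **kwargs) -> SimulationConfig:
    """Load a YAML configuration file of flat key paths."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} must be a mapping")
    return build_config(data, **kwargs)
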