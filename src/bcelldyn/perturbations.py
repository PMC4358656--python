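"""Named perturbation presets.

Each preset is a reproducible transformation of a baseline configuration
implementing one experimental condition:

* ``wild_type`` — identity.
* ``low_dose`` — low-dose CpG stimulation, modeled as a faster decay of the
  active IKK species (default multiplier 2.0 on the decay rate).
* ``crel_ko`` — cRel knockout: the cRel translation rate is set to exactly 0.
* ``rapamycin`` — global translation inhibition: every translation/synthesis
  rate mean is multiplied by 0.7.
* ``noise_scan:<group>:<mean|cv>`` — the protein-group mean/CV manipulations
  (rates ×1.1, fixed totals ×1.5, or CV ×2) on one of the groups
  ``nfkb_negative``, ``nfkb_positive``, ``other`` or ``all``.

Presets apply to a baseline configuration only (one-at-a-time design);
stacking a second mean-shifting preset is rejected, while re-applying an
idempotent preset (``crel_ko``, ``wild_type``) is allowed.
"""

from __future__ import annotations

from dataclasses import replace

from .engine import SimulationConfig
from .model_core import ConfigurationError, TRANSLATION_PARAMS
from .noise import apply_group_scaling, default_noise_spec, GROUPS

__all__ = ["PRESETS", "apply_preset", "list_presets", "LOW_DOSE_DECAY_FACTOR"]

#: Fitted IKK-decay multiplier for low-dose stimulation (calibration knob,
#: recorded in the run manifest through the preset name).
LOW_DOSE_DECAY_FACTOR = 2.0

PRESETS = {
    "wild_type": "baseline calibrated configuration (identity)",
    "low_dose": f"low-dose stimulation: active-IKK decay x{LOW_DOSE_DECAY_FACTOR}",
    "crel_ko": "cRel knockout: cRel translation rate = 0",
    "rapamycin": "global translation inhibition: all synthesis rate means x0.7",
    "noise_scan:<group>:<mean|cv>": (
        "protein-group scan: rate means x1.1 / fixed totals x1.5, or CV x2; "
        f"groups: {', '.join(GROUPS + ('all',))}"
    ),
}


def list_presets() -> dict:
    return dict(PRESETS)


def _rebuild_noise(config: SimulationConfig, model) -> object:
    """Rebuild noise entries so their means follow the (possibly rescaled)
    model parameter means, preserving CVs and partition/init settings."""
    cvs = {e.param: e.cv for e in config.noise.entries}
    return default_noise_spec(
        model.params, cv_overrides=cvs,
        partition_cv=config.noise.partition_cv,
        init_mass_cv=config.noise.init_mass_cv,
        init_gm_cv=config.noise.init_gm_cv,
    )


def apply_preset(config: SimulationConfig, preset: str) -> SimulationConfig:
    """Return a new configuration with ``preset`` applied."""
    name = preset.strip()
    if name == "wild_type":
        return replace(config, preset="wild_type")

    if name in config.presets_applied and name != "crel_ko":
        raise ConfigurationError(
            f"preset {name!r} already applied; presets do not stack"
        )

    if name == "low_dose":
        model = config.model.with_params(
            ikk_decay=config.model.params["ikk_decay"] * LOW_DOSE_DECAY_FACTOR
        )
        return replace(config, model=model, preset=name,
                       presets_applied=config.presets_applied + (name,))

    if name == "crel_ko":
        model = config.model.with_params(tr_crel=0.0, crel_ind=0.0)
        noise = _rebuild_noise(config, model)
        applied = config.presets_applied
        if name not in applied:
            applied = applied + (name,)
        return replace(config, model=model, noise=noise, preset=name,
                       presets_applied=applied)

    if name == "rapamycin":
        updates = {p: 0.7 * config.model.params[p] for p in TRANSLATION_PARAMS}
        model = config.model.with_params(**updates)
        noise = _rebuild_noise(config, model)
        return replace(config, model=model, noise=noise, preset=name,
                       presets_applied=config.presets_applied + (name,))

    if name.startswith("noise_scan:"):
        parts = name.split(":")
        if len(parts) != 3 or parts[2] not in ("mean", "cv"):
            raise ConfigurationError(
                "noise_scan preset must be 'noise_scan:<group>:<mean|cv>'"
            )
        _, group, mode = parts
        noise = apply_group_scaling(
            config.noise, group,
            mean_mode="scale" if mode == "mean" else "none",
            cv_mode="x2" if mode == "cv" else "none",
        )
        return replace(config, noise=noise, preset=name,
                       presets_applied=config.presets_applied + (name,))

    raise ConfigurationError(
        f"unknown preset {preset!r}; available presets: {sorted(PRESETS)}"
    )
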