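"""Extrinsic cell-to-cell parameter variability.

Each agent carries a private draw of a small set of noise-eligible model
parameters, fixed at birth (extrinsic noise; the ODEs themselves are
deterministic).  Two distribution families are used, following how each
quantity enters the model:

* ``fixed_total`` — quantities that are conserved totals (total RelA,
  the per-cell IKK scale, the division size): lognormal, moment-matched so
  the *arithmetic* mean and CV equal the spec entry.
* ``rate`` — synthesis/degradation-style rates (translation multipliers,
  caspase activation): normal, truncated at zero by resampling.

At division each daughter's parameter is remixed as the average of the
mother's value and a fresh independent population draw, so kin correlations
decay geometrically with generation distance.

The three protein groups used by the noise-scan experiments are the negative
regulators of NF-κB activation (the IκBs), the positive regulators (IKK and
the NF-κB monomers), and all other (cell-cycle/apoptosis) proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .model_core import PARAM_INDEX, ConfigurationError

__all__ = [
    "NoiseEntry",
    "NoiseSpec",
    "ExtrinsicParams",
    "sample_extrinsic",
    "remix_daughter",
    "apply_group_scaling",
    "default_noise_spec",
    "GROUPS",
]

GROUPS = ("nfkb_negative", "nfkb_positive", "other")
KINDS = ("rate", "fixed_total")


@dataclass(frozen=True)
class NoiseEntry:
    """One noise-eligible parameter: distribution family, moments, group."""

    param: str
    kind: str
    mean: float
    cv: float
    group: str

    def __post_init__(self):
        if self.param not in PARAM_INDEX:
            raise ConfigurationError(f"unknown noise parameter {self.param!r}")
        if self.kind not in KINDS:
            raise ConfigurationError(f"noise kind must be one of {KINDS}, got {self.kind!r}")
        if self.group not in GROUPS:
            raise ConfigurationError(f"noise group must be one of {GROUPS}, got {self.group!r}")
        if self.cv < 0:
            raise ConfigurationError(f"CV must be >= 0 for {self.param!r}")
        if self.mean < 0:
            raise ConfigurationError(f"mean must be >= 0 for {self.param!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Population-level noise description.

    ``partition_cv`` is the CV of the mass split between daughters at
    mitosis; ``init_mass_cv`` / ``init_gm_cv`` are normal CVs applied to the
    founders' initial mass and general machinery.
    """

    entries: tuple
    partition_cv: float = 0.022
    init_mass_cv: float = 0.15
    init_gm_cv: float = 0.15

    def __post_init__(self):
        seen = set()
        for e in self.entries:
            if e.param in seen:
                raise ConfigurationError(
                    f"parameter {e.param!r} appears in more than one noise entry"
                )
            seen.add(e.param)
        for name in ("partition_cv", "init_mass_cv", "init_gm_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    def entry(self, param: str) -> NoiseEntry:
        for e in self.entries:
            if e.param == param:
                return e
        raise KeyError(param)


@dataclass(frozen=True)
class ExtrinsicParams:
    """One agent's private parameter draw.

    ``values`` maps parameter name to the sampled value; ``provenance`` maps
    parameter name to the generation at which the value was last remixed.
    """

    values: dict
    provenance: dict = field(default_factory=dict)


def _draw_one(entry: NoiseEntry, rng: np.random.Generator) -> float:
    if entry.cv == 0.0 or entry.mean == 0.0:
        return entry.mean
    if entry.kind == "fixed_total":
        # lognormal with arithmetic mean m and CV c:
        # sigma^2 = ln(1+c^2), mu = ln m - sigma^2/2
        s2 = math.log1p(entry.cv**2)
        mu = math.log(entry.mean) - 0.5 * s2
        return float(rng.lognormal(mu, math.sqrt(s2)))
    # rate: truncated normal by resampling
    sd = entry.cv * entry.mean
    for _ in range(1000):
        v = float(rng.normal(entry.mean, sd))
        if v >= 0.0:
            return v
    raise ConfigurationError(
        f"normal draw for {entry.param!r} (mean {entry.mean}, CV {entry.cv}) "
        "rejected at rate > 99%; CV too large"
    )


def sample_extrinsic(spec: NoiseSpec, rng: np.random.Generator,
                     generation: int = 0) -> ExtrinsicParams:
    """Draw a fresh extrinsic parameter set from the population distribution."""
    values = {e.param: _draw_one(e, rng) for e in spec.entries}
    return ExtrinsicParams(values=values,
                           provenance={k: generation for k in values})


def remix_daughter(inherited: ExtrinsicParams, spec: NoiseSpec,
                   rng: np.random.Generator, generation: int = 0) -> ExtrinsicParams:
    """Daughter parameter set: the average of the mother's value and a fresh
    independent population draw, per parameter.

    Call once per daughter with that daughter's own RNG stream so the two
    daughters of a mother receive independent fresh draws.
    """
    values = {}
    for e in spec.entries:
        fresh = _draw_one(e, rng)
        values[e.param] = 0.5 * (inherited.values[e.param] + fresh)
    return ExtrinsicParams(values=values,
                           provenance={k: generation for k in values})


def apply_group_scaling(spec: NoiseSpec, groups, mean_mode: str = "none",
                        cv_mode: str = "none") -> NoiseSpec:
    """Return a new spec with the noise-scan manipulation applied.

    ``mean_mode``: ``"scale"`` multiplies rate-kind means by 1.1 and
    fixed-total means by 1.5 in the selected groups; ``cv_mode``: ``"x2"``
    doubles the CV of selected entries.  The two manipulations are applied
    one at a time, matching the one-factor experimental design.
    """
    if mean_mode not in ("none", "scale"):
        raise ConfigurationError(f"mean_mode must be 'none' or 'scale', got {mean_mode!r}")
    if cv_mode not in ("none", "x2"):
        raise ConfigurationError(f"cv_mode must be 'none' or 'x2', got {cv_mode!r}")
    if mean_mode != "none" and cv_mode != "none":
        raise ConfigurationError(
            "mean and CV manipulations are applied one at a time, not together"
        )
    if isinstance(groups, str):
        groups = (groups,)
    groups = tuple(groups)
    if not groups:
        raise ConfigurationError("group selection must be nonempty")
    if "all" in groups:
        selected = set(GROUPS)
    else:
        for g in groups:
            if g not in GROUPS:
                raise ConfigurationError(
                    f"unknown group {g!r}; valid groups: {GROUPS + ('all',)}"
                )
        selected = set(groups)

    new_entries = []
    for e in spec.entries:
        if e.group in selected:
            mean = e.mean
            cv = e.cv
            if mean_mode == "scale":
                mean *= 1.1 if e.kind == "rate" else 1.5
            if cv_mode == "x2":
                cv *= 2.0
            e = replace(e, mean=mean, cv=cv)
        new_entries.append(e)
    return replace(spec, entries=tuple(new_entries))


#: (kind, group, default CV) for each noise-eligible parameter.  Means are
#: taken from the model's current parameter values so that presets which
#: rescale a mean (e.g. global translation inhibition) stay consistent.
DEFAULT_NOISE_TABLE = {
    "tr_ikb": ("rate", "nfkb_negative", 0.15),
    "rela_total": ("fixed_total", "nfkb_positive", 0.14),
    "ikk_scale": ("fixed_total", "nfkb_positive", 0.14),
    "tr_crel": ("rate", "nfkb_positive", 0.65),
    "tr_myc": ("rate", "other", 0.04),
    "tr_cycd": ("rate", "other", 0.04),
    "tr_bcl": ("rate", "other", 0.15),
    "ka_casp": ("rate", "other", 0.35),
    "gm_myc_max": ("rate", "other", 0.05),
    "mass_div": ("fixed_total", "other", 0.045),
}


def default_noise_spec(params: dict | None = None, cv_overrides: dict | None = None,
                       **field_overrides) -> NoiseSpec:
    """Default wild-type noise specification.

    Entry means are read from ``params`` (defaulting to the model's default
    parameter values); ``cv_overrides`` maps parameter name to CV.  The
    default CVs and the partition CV are calibration knobs exposed through
    the configuration layer.
    """
    from .model_core import DEFAULT_PARAMS

    params = dict(DEFAULT_PARAMS) if params is None else params
    cv_overrides = cv_overrides or {}
    entries = tuple(
        NoiseEntry(name, kind, params[name], cv_overrides.get(name, cv), group)
        for name, (kind, group, cv) in DEFAULT_NOISE_TABLE.items()
    )
    spec = NoiseSpec(entries=entries)
    if field_overrides:
        spec = replace(spec, **field_overrides)
    return spec
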