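"""Integrated per-cell ODE model of B-lymphocyte fate control.

A single cellular agent is described by three coupled submodules sharing one
state vector:

* **NF-κB signaling** — an IKK-driven nuclear translocation cycle for the two
  transcription-activating dimers RelA:p50 and cRel:p50, with an
  NF-κB-inducible IκB pool providing negative feedback.  Active IKK is an
  external forcing profile (basal level plus an exponentially decaying
  stimulated amplitude).
* **Apoptosis** — a caspase cascade driven by a constant post-stimulation
  death signal, inhibited by the anti-apoptotic protein Bcl-XL, and read out
  by cleaved PARP (cPARP).  A cell dies when cPARP rises through
  25,000 molecules/cell.
* **Cell cycle / growth** — dimensionless cell mass grows in proportion to a
  lumped "general machinery" (GM) species whose production depends on the
  current mass and on Myc; cell-cycle commitment is read out by a switch
  species (``cdh1_readout``) that fires upward through 0.2 when Cyclin D is
  high and the mass approaches the division size.

The modules are coupled by cooperative Hill activation of the Cyclin D, Myc
and Bcl-XL promoters by nuclear NF-κB (Bcl-XL weighted toward cRel:p50), and
by the Myc/mass dependence of GM production.

The submodules here are reduced surrogates (12 species in total) that expose
exactly the interface species used by the agent engine and the analytics:
nuclear RelA:p50 and cRel:p50, the IκB pool, cPARP, the mitosis readout,
mass, GM, Myc, CycD and Bcl-XL.  The right-hand side is registered through
:attr:`IntegratedModel.rhs_builder`, so a different (e.g. fully mechanistic)
module set with the same interface species can be dropped in without touching
the agent engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SPECIES",
    "SPECIES_INDEX",
    "SPECIES_SCALE",
    "PARAM_NAMES",
    "TRANSLATION_PARAMS",
    "ConfigurationError",
    "ModuleSpec",
    "CouplingSpec",
    "IkkProfile",
    "IntegratedModel",
    "hill",
    "gm_growth_rate",
    "ikk_input",
    "assemble_rhs",
    "default_model",
    "DEATH_THRESHOLD",
    "DIVISION_THRESHOLD",
]


class ConfigurationError(ValueError):
    """Raised for invalid model/engine configuration (unknown names, bad values)."""


# ---------------------------------------------------------------------------
# State vector layout
# ---------------------------------------------------------------------------

#: Ordered species names: (name, owning module, compartment, unit).
SPECIES = [
    ("ikb", "nfkb", "cytoplasmic", "molecules/cell"),
    ("nfkb_rela_nuc", "nfkb", "nuclear", "molecules/cell"),
    ("crel_total", "nfkb", "none", "molecules/cell"),
    ("nfkb_crel_nuc", "nfkb", "nuclear", "molecules/cell"),
    ("myc", "cellcycle", "none", "molecules/cell"),
    ("cycd", "cellcycle", "none", "molecules/cell"),
    ("bcl_xl", "apoptosis", "none", "molecules/cell"),
    ("caspase", "apoptosis", "none", "molecules/cell"),
    ("cparp", "apoptosis", "none", "molecules/cell"),
    ("mass", "cellcycle", "none", "model units"),
    ("gm", "cellcycle", "none", "model units"),
    ("cdh1_readout", "cellcycle", "none", "model units"),
]

SPECIES_INDEX = {name: i for i, (name, _, _, _) in enumerate(SPECIES)}
N_SPECIES = len(SPECIES)

IKB, NRELA, CRELT, NCREL, MYC, CYCD, BCLXL, CASP, CPARP, MASS, GM, CDH1 = range(12)

#: Typical magnitude per species; used for solver tolerances, equilibration
#: convergence tests and negativity guards.
SPECIES_SCALE = np.array(
    [2e4, 2e4, 5e4, 2e4, 1e3, 1e3, 1e3, 1e3, 2.5e4, 1.0, 0.5, 0.2]
)

#: Death fires when cPARP rises through this level (molecules/cell).
DEATH_THRESHOLD = 25_000.0
#: Division fires when the mitosis readout rises through this level.
DIVISION_THRESHOLD = 0.2

# ---------------------------------------------------------------------------
# Parameter vector layout
# ---------------------------------------------------------------------------

#: Packed parameter order shared by the Python and compiled right-hand sides.
PARAM_NAMES = [
    # input forcing
    "ikk_basal", "ikk_amp", "ikk_decay", "ikk_scale", "death_sig",
    # NF-kB module
    "rela_total", "ka_rela", "ka_crel", "ke0", "ke_ikb",
    "tr_ikb", "ikb_syn_basal", "ikb_syn_ind", "K_ikb", "h_ikb",
    "dg_ikb", "dg_ikb_ikk",
    "tr_crel", "crel_ind", "K_crel", "dg_crel",
    # coupling: NF-kB-driven promoters
    "tr_myc", "myc_basal", "K_myc", "h_myc", "dg_myc",
    "tr_cycd", "cycd_basal", "K_cycd", "h_cycd", "dg_cycd",
    "tr_bcl", "bcl_basal", "K_bcl", "h_bcl", "dg_bcl",
    "w_crel_bcl", "w_rela_bcl",
    # apoptosis module
    "ka_casp", "K_bclinh", "h_inh", "dg_casp", "k_parp", "dg_parp",
    # growth / cell-cycle module
    "gm_basal", "gm_myc_max", "K_gm_myc", "h_gm", "dg_gm", "k_mass",
    "mass_div", "K_cycd_sw", "h_sw", "h_mass", "k_sw",
    # dimer weighting of the growth/cycle drive
    "w_crel_g",
    # late ramp of the death signal (activation-induced death pressure)
    "ds_ramp",
]
PARAM_INDEX = {n: i for i, n in enumerate(PARAM_NAMES)}
N_PARAMS = len(PARAM_NAMES)

#: Parameters representing protein translation/synthesis rates; these are the
#: knobs a global translation inhibitor (rapamycin preset) scales down.
TRANSLATION_PARAMS = ("tr_ikb", "tr_crel", "tr_myc", "tr_cycd", "tr_bcl",
                      "gm_myc_max", "ka_casp", "death_sig")

#: Default mean parameter values (hours, molecules/cell, model mass units).
DEFAULT_PARAMS = {
    # input
    "ikk_basal": 100.0,      # molecules/cell, pre-stimulation IKK activity
    "ikk_amp": 1.0e4,        # stimulated active-IKK amplitude
    "ikk_decay": 0.009,       # 1/h decay of the stimulated IKK species
    "ikk_scale": 1.0,        # per-cell total-IKK multiplier (lognormal noise)
    "death_sig": 1.0,        # post-stimulation death-signal amplitude
    # NF-kB
    "rela_total": 1.0e5,
    "ka_rela": 2.0e-5,       # per molecule IKK per h nuclear import
    "ka_crel": 2.0e-5,
    "ke0": 0.1,              # 1/h baseline nuclear export
    "ke_ikb": 1.0e-4,        # export per IkB molecule per h (sequestration)
    "tr_ikb": 1.0,           # IkB translation multiplier
    "ikb_syn_basal": 4.0e3,  # molecules/h
    "ikb_syn_ind": 4.0e4,    # molecules/h max NF-kB-induced synthesis
    "K_ikb": 3.0e4,
    "h_ikb": 2.0,
    "dg_ikb": 0.2,           # 1/h
    "dg_ikb_ikk": 5.0e-4,    # per molecule IKK per h IKK-driven degradation
    "tr_crel": 2.0e3,        # molecules/h cRel translation
    "crel_ind": 4.0,         # fold NF-kB-induced cRel synthesis
    "K_crel": 2.0e4,
    "dg_crel": 0.025,
    # coupling
    "tr_myc": 150.0,
    "myc_basal": 0.003,
    "K_myc": 2.2e4,
    "h_myc": 3.0,
    "dg_myc": 0.15,
    "tr_cycd": 200.0,
    "cycd_basal": 0.01,
    "K_cycd": 2.2e4,
    "h_cycd": 2.0,
    "dg_cycd": 0.2,
    "tr_bcl": 100.0,
    "bcl_basal": 0.1,
    "K_bcl": 1.65e5,
    "h_bcl": 4.0,
    "dg_bcl": 0.1,
    "w_crel_bcl": 2.0,       # cRel:p50 contributes ~2/3 of Bcl-XL drive
    "w_rela_bcl": 1.0,
    # apoptosis
    "ka_casp": 360.0,
    "K_bclinh": 110.0,
    "h_inh": 4.0,
    "dg_casp": 0.3,
    "k_parp": 4.0,
    "dg_parp": 0.04,
    # growth / cycle
    "gm_basal": 0.0,
    "gm_myc_max": 0.115,      # max Myc-driven GM production per unit mass per h
    "K_gm_myc": 280.0,
    "h_gm": 2.0,
    "dg_gm": 0.05,
    "k_mass": 0.1,           # mass accretion per unit GM per h
    "mass_div": 5.7,         # division size in mass units
    "K_cycd_sw": 80.0,
    "h_sw": 4.0,
    "h_mass": 8.0,
    "k_sw": 2.0,             # 1/h relaxation of the mitosis readout
    "w_crel_g": 0.1,         # cRel:p50 weight in the Myc/CycD drive (RelA-dominant,
                             # so growth is largely cRel-independent)
    "ds_ramp": 0.0,         # 1/h linear ramp of the death signal after stimulation
}

#: Names readable by other modules and the event detector.
READOUT_SPECIES = {
    "nfkb": ["nfkb_rela_nuc", "nfkb_crel_nuc", "ikb"],
    "apoptosis": ["cparp", "bcl_xl"],
    "cellcycle": ["cdh1_readout", "mass", "gm", "myc", "cycd"],
}


# ---------------------------------------------------------------------------
# Elementary rate laws
# ---------------------------------------------------------------------------

def hill(x: float, K: float, h: float) -> float:
    """Cooperative Hill activation ``x^h / (K^h + x^h)``.

    Parameters
    ----------
    x : nonnegative activator concentration
    K : half-maximal concentration (> 0)
    h : cooperativity (>= 1)
    """
    if K <= 0:
        raise ConfigurationError(f"Hill K must be positive, got {K}")
    if h < 1:
        raise ConfigurationError(f"Hill cooperativity must be >= 1, got {h}")
    if x < 0:
        raise ValueError(f"Hill activator concentration must be >= 0, got {x}")
    if x == 0.0:
        return 0.0
    r = (x / K) ** h
    return r / (1.0 + r)


def gm_growth_rate(mass: float, myc: float, params: dict | None = None) -> float:
    """Production rate of general machinery given current mass and Myc.

    The rate is proportional to mass (biosynthesis scales with cell size) and
    saturably activated by Myc; with Myc -> 0 it falls to the basal term, so
    quiescent cells barely grow.
    """
    p = DEFAULT_PARAMS if params is None else params
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    if myc < 0:
        raise ValueError(f"myc must be >= 0, got {myc}")
    return mass * (p["gm_basal"] + p["gm_myc_max"] * hill(myc, p["K_gm_myc"], p["h_gm"]))


@dataclass(frozen=True)
class IkkProfile:
    """Active-IKK forcing: basal level plus a decaying stimulated amplitude.

    ``scale`` is the per-cell total-IKK multiplier (extrinsic noise); the
    low-dose stimulation preset increases ``decay``.
    """

    basal: float = DEFAULT_PARAMS["ikk_basal"]
    amp: float = DEFAULT_PARAMS["ikk_amp"]
    decay: float = DEFAULT_PARAMS["ikk_decay"]
    t_on: float = 0.0
    scale: float = 1.0

    def __post_init__(self):
        if self.decay < 0:
            raise ConfigurationError(f"IKK decay rate must be >= 0, got {self.decay}")
        if self.basal < 0 or self.amp < 0 or self.scale < 0:
            raise ConfigurationError("IKK profile levels must be >= 0")


def ikk_input(t: float, profile: IkkProfile) -> float:
    """Active IKK (molecules/cell) at time ``t`` hours."""
    if t < profile.t_on:
        return profile.scale * profile.basal
    return profile.scale * (
        profile.basal + profile.amp * math.exp(-profile.decay * (t - profile.t_on))
    )


# ---------------------------------------------------------------------------
# Module / model specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModuleSpec:
    """One submodule: its species (with compartment/unit), parameters and
    the readout species it exposes to the other modules and the event
    detector."""

    name: str
    species: tuple  # of (name, compartment, unit)
    parameters: dict
    readout_species: tuple

    def __post_init__(self):
        if self.name not in {"nfkb", "apoptosis", "cellcycle"}:
            raise ConfigurationError(f"unknown module name {self.name!r}")
        names = {s[0] for s in self.species}
        for r in self.readout_species:
            if r not in names:
                raise ConfigurationError(
                    f"readout species {r!r} is not a species of module {self.name!r}"
                )
        for sname, compartment, _unit in self.species:
            if compartment == "nuclear" and self.name != "nfkb":
                raise ConfigurationError(
                    f"species {sname!r}: only NF-κB/IκB species may carry the "
                    "'nuclear' compartment tag (they alone are redistributed at mitosis)"
                )
        for pname, value in self.parameters.items():
            if not np.isfinite(value) or value < 0:
                raise ConfigurationError(
                    f"parameter {pname!r} of module {self.name!r} must be finite "
                    f"and >= 0, got {value}"
                )


@dataclass(frozen=True)
class CouplingSpec:
    """NF-κB-driven synthesis of CycD, Myc and Bcl-XL plus the GM growth law.

    ``targets`` maps each target to Hill parameters (K, h, max rate) and the
    weights of the contributing dimers (cRel:p50 vs RelA:p50).
    """

    targets: dict
    gm_growth: dict

    def __post_init__(self):
        for tname, t in self.targets.items():
            if t["K"] <= 0:
                raise ConfigurationError(f"coupling target {tname!r}: K must be > 0")
            if t["h"] < 1:
                raise ConfigurationError(f"coupling target {tname!r}: h must be >= 1")
            if t["w_crel"] < 0 or t["w_rela"] < 0:
                raise ConfigurationError(f"coupling target {tname!r}: weights must be >= 0")


@dataclass(frozen=True)
class IntegratedModel:
    """The assembled three-module model plus coupling and IKK input."""

    modules: tuple  # (nfkb, apoptosis, cellcycle) ModuleSpecs
    coupling: CouplingSpec
    input: IkkProfile
    params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))

    def __post_init__(self):
        owners = {}
        for m in self.modules:
            for sname, _, _ in m.species:
                if sname in owners:
                    raise ConfigurationError(
                        f"species {sname!r} owned by both {owners[sname]!r} and {m.name!r}"
                    )
                owners[sname] = m.name
        if set(owners) != set(SPECIES_INDEX):
            missing = set(SPECIES_INDEX) - set(owners)
            extra = set(owners) - set(SPECIES_INDEX)
            raise ConfigurationError(
                f"model species mismatch (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        for pname in self.params:
            if pname not in PARAM_INDEX:
                raise ConfigurationError(f"unknown model parameter {pname!r}")

    # -- parameter packing ---------------------------------------------------

    def pack_params(
        self,
        overrides: dict | None = None,
        *,
        stimulated: bool = True,
    ) -> np.ndarray:
        """Pack parameters (with per-cell extrinsic overrides) into the flat
        vector consumed by the right-hand side.

        With ``stimulated=False`` the stimulated IKK amplitude and the death
        signal are zeroed (equilibration conditions).
        """
        merged = dict(self.params)
        merged["ikk_basal"] = self.input.basal
        merged["ikk_amp"] = self.input.amp
        merged["ikk_decay"] = self.input.decay
        if overrides:
            for name, value in overrides.items():
                if name not in PARAM_INDEX:
                    raise ConfigurationError(f"unknown extrinsic parameter {name!r}")
                merged[name] = value
        if not stimulated:
            merged["ikk_amp"] = 0.0
            merged["death_sig"] = 0.0
        p = np.empty(N_PARAMS)
        for name, i in PARAM_INDEX.items():
            p[i] = merged[name]
        return p

    def with_params(self, **updates) -> "IntegratedModel":
        """Return a copy with updated mean parameter values."""
        params = dict(self.params)
        for name, value in updates.items():
            if name not in PARAM_INDEX:
                raise ConfigurationError(f"unknown model parameter {name!r}")
            params[name] = value
        new_input = self.input
        for key in ("ikk_basal", "ikk_amp", "ikk_decay"):
            if key in updates:
                new_input = replace(
                    new_input, **{key.replace("ikk_", "") if key != "ikk_decay" else "decay":
                                  updates[key]}
                )
        return replace(self, params=params, input=new_input)


def default_model(**param_overrides) -> IntegratedModel:
    """Construct the default integrated model (optionally overriding mean
    parameter values by name)."""
    params = dict(DEFAULT_PARAMS)
    for name, value in param_overrides.items():
        if name not in PARAM_INDEX:
            raise ConfigurationError(f"unknown model parameter {name!r}")
        params[name] = value
    modules = tuple(
        ModuleSpec(
            name=mod,
            species=tuple(
                (s, comp, unit) for s, owner, comp, unit in SPECIES if owner == mod
            ),
            parameters={
                k: v for k, v in params.items() if k in _MODULE_PARAMS[mod]
            },
            readout_species=tuple(READOUT_SPECIES[mod]),
        )
        for mod in ("nfkb", "apoptosis", "cellcycle")
    )
    coupling = CouplingSpec(
        targets={
            "myc": {"K": params["K_myc"], "h": params["h_myc"],
                    "max_rate": params["tr_myc"], "w_crel": 1.0, "w_rela": 1.0},
            "cycd": {"K": params["K_cycd"], "h": params["h_cycd"],
                     "max_rate": params["tr_cycd"], "w_crel": 1.0, "w_rela": 1.0},
            "bcl_xl": {"K": params["K_bcl"], "h": params["h_bcl"],
                       "max_rate": params["tr_bcl"],
                       "w_crel": params["w_crel_bcl"], "w_rela": params["w_rela_bcl"]},
        },
        gm_growth={k: params[k] for k in ("gm_basal", "gm_myc_max", "K_gm_myc", "h_gm")},
    )
    profile = IkkProfile(
        basal=params["ikk_basal"], amp=params["ikk_amp"], decay=params["ikk_decay"]
    )
    return IntegratedModel(modules=modules, coupling=coupling, input=profile, params=params)


_MODULE_PARAMS = {
    "nfkb": {
        "rela_total", "ka_rela", "ka_crel", "ke0", "ke_ikb", "tr_ikb",
        "ikb_syn_basal", "ikb_syn_ind", "K_ikb", "h_ikb", "dg_ikb",
        "dg_ikb_ikk", "tr_crel", "crel_ind", "K_crel", "dg_crel",
    },
    "apoptosis": {
        "ka_casp", "K_bclinh", "h_inh", "dg_casp", "k_parp", "dg_parp", "ds_ramp",
        "tr_bcl", "bcl_basal", "K_bcl", "h_bcl", "dg_bcl",
        "w_crel_bcl", "w_rela_bcl",
    },
    "cellcycle": {
        "tr_myc", "myc_basal", "K_myc", "h_myc", "dg_myc",
        "tr_cycd", "cycd_basal", "K_cycd", "h_cycd", "dg_cycd",
        "gm_basal", "gm_myc_max", "K_gm_myc", "h_gm", "dg_gm", "k_mass",
        "mass_div", "K_cycd_sw", "h_sw", "h_mass", "k_sw", "w_crel_g",
    },
}


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def rhs(t: float, y: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Time-derivative of the integrated state vector.

    Autonomous except for the exponentially decaying IKK forcing.  Species
    values are clamped at zero on input so the derivative stays continuous
    and trajectories cannot be driven by small negative solver excursions.
    """
    out = np.empty(N_SPECIES)
    _rhs_core(t, y, p, out)
    return out


def _rhs_core(t, y, p, out):  # pragma: no cover - exercised via wrappers
    ikb = max(y[0], 0.0)
    nrela = max(y[1], 0.0)
    crelt = max(y[2], 0.0)
    ncrel = max(y[3], 0.0)
    myc = max(y[4], 0.0)
    cycd = max(y[5], 0.0)
    bcl = max(y[6], 0.0)
    casp = max(y[7], 0.0)
    cparp = max(y[8], 0.0)
    mass = max(y[9], 1e-9)
    gm = max(y[10], 0.0)
    cdh1 = y[11]

    # input forcing
    tt = t if t > 0.0 else 0.0
    ikk = p[3] * (p[0] + p[1] * math.exp(-p[2] * tt))

    # NF-kB module
    free_rela = p[5] - nrela
    if free_rela < 0.0:
        free_rela = 0.0
    free_crel = crelt - ncrel
    if free_crel < 0.0:
        free_crel = 0.0
    ke = p[8] + p[9] * ikb
    out[1] = p[6] * ikk * free_rela - ke * nrela
    out[3] = p[7] * ikk * free_crel - ke * ncrel - p[20] * ncrel
    act_crel_syn = nrela / (p[19] + nrela) if nrela > 0.0 else 0.0
    out[2] = p[17] * (1.0 + p[18] * act_crel_syn) - p[20] * crelt
    act = nrela + ncrel
    h_act = _hill(act, p[13], p[14])
    out[0] = p[10] * (p[11] + p[12] * h_act) - (p[15] + p[16] * ikk) * ikb

    # NF-kB-driven promoters; the growth/cycle drive is RelA-dominant
    act_g = nrela + p[55] * ncrel
    out[4] = p[21] * (p[22] + _hill(act_g, p[23], p[24])) - p[25] * myc
    out[5] = p[26] * (p[27] + _hill(act_g, p[28], p[29])) - p[30] * cycd
    act_b = p[36] * ncrel + p[37] * nrela
    out[6] = p[31] * (p[32] + _hill(act_b, p[33], p[34])) - p[35] * bcl

    # apoptosis; death pressure ramps slowly after stimulation
    inh = 1.0 + (bcl / p[39]) ** p[40]
    ds = p[4] * (1.0 + p[56] * tt)
    out[7] = p[38] * ds / inh - p[41] * casp
    out[8] = p[42] * casp - p[43] * cparp

    # growth / cycle
    gm_rate = mass * (p[44] + p[45] * _hill(myc, p[46], p[47]))
    out[10] = gm_rate - p[48] * gm
    out[9] = p[49] * gm
    x_sw = _hill(cycd, p[51], p[52]) * _hill(mass, p[50], p[53])
    out[11] = p[54] * (x_sw - cdh1)


def _hill(x, K, h):  # pragma: no cover - exercised via wrappers
    if x <= 0.0:
        return 0.0
    r = (x / K) ** h
    return r / (1.0 + r)


# Compile the core with numba when available; the pure-Python path is kept as
# a functional fallback and as the reference for the compiled one.
try:  # pragma: no cover
    from numba import njit as _njit

    _hill = _njit(cache=False)(_hill)
    _rhs_core = _njit(cache=False)(_rhs_core)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


def assemble_rhs(model: IntegratedModel, extrinsic=None, *, stimulated: bool = True):
    """Build the derivative function ``f(t, y) -> dy/dt`` for one agent.

    ``extrinsic`` may be an :class:`~bcelldyn.noise.ExtrinsicParams` or a
    plain mapping of parameter overrides; unknown names raise
    :class:`ConfigurationError`.
    """
    overrides = None
    if extrinsic is not None:
        overrides = extrinsic if isinstance(extrinsic, dict) else extrinsic.values
    p = model.pack_params(overrides, stimulated=stimulated)

    def f(t, y):
        return rhs(t, y, p)

    f.packed_params = p
    return f
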