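"""Agent-based population engine.

Runs a population of independent integrated-model agents generation by
generation: per-founder equilibration under basal signaling, stimulated
integration until the first fate event (division, death) or the horizon,
division bookkeeping (mass/GM partitioning, nuclear redistribution,
extrinsic-parameter remixing), and lineage-tree construction.

Randomness is organized as one root seed with a dedicated substream per
agent keyed by its lineage path, so agents can be solved in any order (and
analytics can draw random numbers) without perturbing simulation draws.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .lineage import LineageTree, TrackRecord
from .model_core import (
    CDH1, CPARP, CASP, CRELT, GM, IKB, MASS, MYC, BCLXL, CYCD, NCREL, NRELA,
    DEATH_THRESHOLD, DIVISION_THRESHOLD, N_SPECIES, SPECIES_SCALE,
    ConfigurationError, IntegratedModel, default_model,
)
from .noise import NoiseSpec, ExtrinsicParams, default_noise_spec, remix_daughter, sample_extrinsic

__all__ = ["SimulationConfig", "FateEvent", "AgentState", "equilibrate",
           "integrate_until_event", "divide", "run_population", "default_config"]

_FATE_NAMES = {_kernels.CENSORED: "censored", _kernels.DIVIDED: "divided",
               _kernels.DIED: "died"}


@dataclass(frozen=True)
class FateEvent:
    """Terminal event of one agent: kind and absolute time (hours)."""

    kind: str  # division | death | censored_at_horizon
    time: float


@dataclass
class AgentState:
    """One live agent: identity, birth time, ODE state and private noise draw."""

    path: tuple            # lineage path, e.g. (12,), (12, 0), (12, 0, 1)
    parent_path: tuple | None
    generation: int
    t_birth: float
    state: np.ndarray      # length-N_SPECIES vector
    extrinsic: ExtrinsicParams

    @property
    def lineage_id(self) -> str:
        return "c" + ".".join(str(k) for k in self.path)

    @property
    def mass(self) -> float:
        return float(self.state[MASS])

    @property
    def gm(self) -> float:
        return float(self.state[GM])


@dataclass(frozen=True)
class SimulationConfig:
    """Full simulation configuration.

    Defaults reflect the wild-type study conditions: 250 founder agents,
    144-h horizon, at least 24 h of basal-signaling equilibration, volume
    output every 0.2 h, and 300 μm³ per model mass unit so mean initial
    volume matches a resting B cell.
    """

    model: IntegratedModel
    noise: NoiseSpec
    n_agents: int = 250
    horizon: float = 144.0
    equilibration_min: float = 24.0
    equilibration_max: float = 96.0
    seed: int = 0
    preset: str = "wild_type"
    grid_step: float = 0.2
    dt: float = 0.005
    volume_scale: float = 300.0   # μm³ per mass unit
    debounce: float = 1.0         # h the mitosis readout must stay below 0.2
    tie_tol: float = 1e-3         # h; closer death/division ties resolve to death
    presets_applied: tuple = ()

    def __post_init__(self):
        if self.horizon <= 0:
            raise ConfigurationError("horizon must be > 0")
        if self.n_agents < 1:
            raise ConfigurationError("n_agents must be >= 1")
        if self.equilibration_min < 24.0:
            raise ConfigurationError("equilibration_min must be >= 24 h")

    def config_hash(self) -> str:
        payload = {
            "params": self.model.params,
            "noise": [(e.param, e.kind, e.mean, e.cv, e.group) for e in self.noise.entries],
            "partition_cv": self.noise.partition_cv,
            "init_mass_cv": self.noise.init_mass_cv,
            "init_gm_cv": self.noise.init_gm_cv,
            "n_agents": self.n_agents, "horizon": self.horizon,
            "equilibration_min": self.equilibration_min, "seed": self.seed,
            "preset": self.preset, "grid_step": self.grid_step, "dt": self.dt,
            "volume_scale": self.volume_scale,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=float).encode()
        ).hexdigest()[:16]


def default_config(**overrides) -> SimulationConfig:
    """Calibrated wild-type configuration."""
    model = default_model()
    noise = default_noise_spec(model.params)
    return SimulationConfig(model=model, noise=noise, **overrides)


# ---------------------------------------------------------------------------
# Per-agent operations
# ---------------------------------------------------------------------------

def _agent_rng(seed: int, path: tuple) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(path)))


def _quiescent_guess(p: np.ndarray, mass0: float, gm0: float | None) -> np.ndarray:
    """Analytic approximation of the basal steady state used to start
    equilibration."""
    from .model_core import PARAM_INDEX as PI

    def g(name):
        return p[PI[name]]

    ikk = g("ikk_scale") * g("ikk_basal")
    ikb = g("tr_ikb") * g("ikb_syn_basal") / (g("dg_ikb") + g("dg_ikb_ikk") * ikk)
    ke = g("ke0") + g("ke_ikb") * ikb
    nrela = g("rela_total") * g("ka_rela") * ikk / (g("ka_rela") * ikk + ke)
    crelt = g("tr_crel") * (1 + g("crel_ind") * nrela / (g("K_crel") + nrela)) / max(g("dg_crel"), 1e-12) \
        if g("dg_crel") > 0 else 0.0
    ncrel = crelt * g("ka_crel") * ikk / (g("ka_crel") * ikk + ke + g("dg_crel"))
    act = nrela + ncrel

    def hill(x, K, h):
        return 0.0 if x <= 0 else (x / K) ** h / (1 + (x / K) ** h)

    myc = g("tr_myc") * (g("myc_basal") + hill(act, g("K_myc"), g("h_myc"))) / g("dg_myc")
    cycd = g("tr_cycd") * (g("cycd_basal") + hill(act, g("K_cycd"), g("h_cycd"))) / g("dg_cycd")
    act_b = g("w_crel_bcl") * ncrel + g("w_rela_bcl") * nrela
    bcl = g("tr_bcl") * (g("bcl_basal") + hill(act_b, g("K_bcl"), g("h_bcl"))) / g("dg_bcl")
    if gm0 is None:
        gm0 = mass0 * (g("gm_basal") + g("gm_myc_max") * hill(myc, g("K_gm_myc"), g("h_gm"))) / g("dg_gm")
    y = np.zeros(N_SPECIES)
    y[IKB], y[NRELA], y[CRELT], y[NCREL] = ikb, nrela, crelt, ncrel
    y[MYC], y[CYCD], y[BCLXL] = myc, cycd, bcl
    y[CASP] = 0.0
    y[CPARP] = 0.0
    y[MASS], y[GM], y[CDH1] = mass0, gm0, 0.0
    return y


def equilibrate(y0: np.ndarray, model: IntegratedModel, extrinsic: ExtrinsicParams,
                *, min_hours: float = 24.0, max_hours: float = 96.0,
                dt: float = 0.005, tol: float = 1e-4):
    """Settle an agent to its quiescent state under basal IKK and no death
    signaling.

    Runs at least ``min_hours`` and until the maximum relative species change
    over a 1-h window falls below ``tol`` (capped at ``max_hours`` with a
    warning flag).  A cell-cycle entry during equilibration means the
    parameter draw is not quiescent and raises :class:`ConfigurationError`.

    Returns ``(state, info)`` with ``info = {'hours', 'converged'}``.
    """
    overrides = extrinsic if isinstance(extrinsic, dict) else extrinsic.values
    p_eq = model.pack_params(overrides, stimulated=False)
    y, hours, converged, cycled = _kernels.equilibrate_kernel(
        np.asarray(y0, float), p_eq, dt, min_hours, max_hours, tol,
        SPECIES_SCALE, DIVISION_THRESHOLD,
    )
    if cycled:
        raise ConfigurationError(
            "division readout crossed threshold during equilibration: "
            "parameters are not quiescent"
        )
    return y, {"hours": float(hours), "converged": bool(converged)}


def integrate_until_event(agent: AgentState, model: IntegratedModel, t_end: float,
                          *, dt: float = 0.005, grid_step: float = 0.2,
                          debounce: float = 1.0, tie_tol: float = 1e-3):
    """Integrate one agent until its first fate event or ``t_end``.

    Returns ``(grid_times, grid_mass, event, y_final)`` where the grid holds
    mass samples on the output grid (birth and event time included).
    """
    p = model.pack_params(agent.extrinsic.values, stimulated=True)
    status, t_fin, y_fin, grid_t, grid_m, n = _kernels.simulate_lifetime(
        agent.state, p, agent.t_birth, t_end, dt, grid_step, debounce,
        DEATH_THRESHOLD, DIVISION_THRESHOLD, tie_tol,
    )
    kind = {_kernels.CENSORED: "censored_at_horizon",
            _kernels.DIVIDED: "division", _kernels.DIED: "death"}[status]
    return grid_t[:n].copy(), grid_m[:n].copy(), FateEvent(kind, float(t_fin)), y_fin


def divide(mother: AgentState, t_div: float, y_div: np.ndarray,
           noise_spec: NoiseSpec, rng: np.random.Generator, seed: int):
    """Create the two daughters of a dividing mother.

    Mass and general machinery are partitioned conservatively: the daughter-A
    share is ``r_a/2`` with ``r_a ~ N(1, CV_partition)`` truncated to (0, 2),
    so ``mass_A + mass_B = mass_mother`` exactly and both quantities use the
    same split.  Nuclear NF-κB dimers are redistributed evenly between
    nucleus and cytoplasm (nuclear amount halved, total dimer conserved), all
    other concentrations are copied unchanged, the mitosis readout restarts
    at its quiescent value, and each daughter's extrinsic parameters are
    remixed with an independent fresh draw.
    """
    cv = noise_spec.partition_cv
    r_a = 1.0
    if cv > 0:
        for attempt in range(100):
            r_a = float(rng.normal(1.0, cv))
            if 0.0 < r_a < 2.0:
                break
        else:
            raise ConfigurationError(
                f"partition draw outside (0, 2) after 100 resamples (CV={cv})"
            )
    frac_a = r_a / 2.0

    base = np.asarray(y_div, float).copy()
    # nuclear envelope breakdown: nuclear dimers spread evenly over the cell
    base[NRELA] *= 0.5
    base[NCREL] *= 0.5
    base[CDH1] = 0.0

    daughters = []
    for k, frac in ((0, frac_a), (1, 1.0 - frac_a)):
        y = base.copy()
        y[MASS] = frac * y_div[MASS]
        y[GM] = frac * y_div[GM]
        path = mother.path + (k,)
        d_rng = _agent_rng(seed, path)
        extr = remix_daughter(mother.extrinsic, noise_spec, d_rng,
                              generation=mother.generation + 1)
        daughters.append(AgentState(
            path=path, parent_path=mother.path, generation=mother.generation + 1,
            t_birth=t_div, state=y, extrinsic=extr,
        ))
    return daughters[0], daughters[1]


# ---------------------------------------------------------------------------
# Population driver
# ---------------------------------------------------------------------------

def run_population(config: SimulationConfig):
    """Run the full agent-based simulation.

    Agents are solved breadth-first by generation; division adds two new
    agents, death removes the agent, and agents alive at the horizon are
    censored.  Returns ``(tree, manifest)`` where ``tree`` is the
    :class:`~bcelldyn.lineage.LineageTree` with volume trajectories and
    ``manifest`` records the config hash, seed, solver statistics and
    excluded-agent count.
    """
    model = config.model
    # align the integration step with the output grid
    dt = config.grid_step / max(1, round(config.grid_step / config.dt))

    records: list[TrackRecord] = []
    cell_meta: dict = {}
    n_warn_equil = 0
    n_excluded = 0
    n_div = 0
    n_die = 0

    founders = []
    for i in range(config.n_agents):
        rng = _agent_rng(config.seed, (i,))
        extr = sample_extrinsic(config.noise, rng, generation=0)
        mass0 = -1.0
        while mass0 <= 0.2:
            mass0 = float(rng.normal(1.0, config.noise.init_mass_cv))
        p_eq = model.pack_params(extr.values, stimulated=False)
        y_guess = _quiescent_guess(p_eq, mass0, None)
        if config.noise.init_gm_cv > 0 and y_guess[GM] > 0:
            y_guess[GM] = abs(float(rng.normal(y_guess[GM],
                                               config.noise.init_gm_cv * y_guess[GM])))
        y_eq, info = equilibrate(
            y_guess, model, extr, min_hours=config.equilibration_min,
            max_hours=config.equilibration_max, dt=dt,
        )
        if not info["converged"]:
            n_warn_equil += 1
        founders.append(AgentState(path=(i,), parent_path=None, generation=0,
                                   t_birth=0.0, state=y_eq, extrinsic=extr))

    current = founders
    generation = 0
    while current:
        next_gen = []
        for agent in current:
            grid_t, grid_m, event, y_fin = integrate_until_event(
                agent, model, config.horizon, dt=dt, grid_step=config.grid_step,
                debounce=config.debounce, tie_tol=config.tie_tol,
            )
            if not np.all(np.isfinite(y_fin)):
                n_excluded += 1
                continue
            fate = {"division": "divided", "death": "died",
                    "censored_at_horizon": "censored"}[event.kind]
            parent_id = None if agent.parent_path is None else \
                "c" + ".".join(str(k) for k in agent.parent_path)
            records.append(TrackRecord(
                cell_id=agent.lineage_id, parent_id=parent_id,
                generation=agent.generation, t_birth=agent.t_birth,
                t_end=event.time, fate=fate,
                times=grid_t, volumes=grid_m * config.volume_scale,
            ))
            cell_meta[agent.lineage_id] = {
                "extrinsic": dict(agent.extrinsic.values),
                "birth_state": agent.state.copy(),
            }
            if fate == "divided":
                n_div += 1
                if config.horizon - event.time > 1e-6:
                    # partition draw comes from a dedicated substream so it
                    # cannot collide with the agent's own sampling draws
                    mother_rng = _agent_rng(config.seed, agent.path + (2,))
                    da, db = divide(agent, event.time, y_fin, config.noise,
                                    mother_rng, config.seed)
                    next_gen.extend([da, db])
            elif fate == "died":
                n_die += 1
        current = next_gen
        generation += 1
        if generation > 64:  # safety against runaway trees
            raise RuntimeError("generation depth exceeded 64")

    tree = LineageTree.from_records(records)
    tree.meta = cell_meta
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "preset": config.preset,
        "n_agents": config.n_agents,
        "horizon_h": config.horizon,
        "dt_h": dt,
        "n_cells_tracked": len(records),
        "n_divisions": n_div,
        "n_deaths": n_die,
        "n_excluded": n_excluded,
        "n_equilibration_warnings": n_warn_equil,
    }
    return tree, manifest
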