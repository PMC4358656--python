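"""Parametric synthetic-lineage generator (no ODEs).

Produces lineage trees with known ground truth — per-generation response
fractions, long-tailed lognormal fate timings, a tunable sister-correlation
mixing weight, and piecewise growth-curve volumes — so every analytics
operation can be tested quickly against the parameters that generated the
data, and the command line has demo inputs.

Timing model: in generation g a cell divides with probability ``F[g]``
(drawing an interdivision time) and otherwise dies (drawing a death time);
log-times of the two daughters of one mother share a mother-level latent
factor with weight ``w``, so the sister log-time correlation is ``w`` by
construction.  Everything is censored at ``censor_time``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .lineage import LineageTree, TrackRecord

__all__ = ["FixtureParams", "generate_lineages"]


@dataclass(frozen=True)
class FixtureParams:
    """Ground-truth parameters of the synthetic branching process.

    ``fractions`` are per-generation division probabilities F_0..F_max
    (cells beyond the last listed generation never divide).  Timing
    distributions are lognormal, given as (median hours, log-sd shape).
    ``sister_weight`` is the shared-latent mixing weight w in [0, 1].
    """

    fractions: tuple = (0.4, 0.85, 0.7, 0.5, 0.3, 0.15, 0.09)
    tdiv0: tuple = (32.0, 0.25)
    tdiv1: tuple = (11.0, 0.25)
    tdie0: tuple = (28.0, 0.45)
    tdie1: tuple = (16.0, 0.45)
    tgro0: tuple = (12.0, 0.35)
    sister_weight: float = 0.7
    v0_mean: float = 300.0
    v0_cv: float = 0.12
    k_mean: float = 0.10
    k_cv: float = 0.15
    volume_noise_cv: float = 0.02
    sample_step: float = 0.5
    censor_time: float = 144.0

    def __post_init__(self):
        for fr in self.fractions:
            if not 0.0 <= fr <= 1.0:
                raise ValueError(f"response fraction {fr} outside [0, 1]")
        if not 0.0 <= self.sister_weight <= 1.0:
            raise ValueError("sister_weight must be in [0, 1]")
        for name in ("tdiv0", "tdiv1", "tdie0", "tdie1", "tgro0"):
            med, shape = getattr(self, name)
            if med <= 0 or shape <= 0:
                raise ValueError(f"{name}: median and shape must be > 0")


def _lognormal(rng, median, shape, z_shared=None, w=0.0):
    """Lognormal draw; if ``z_shared`` is given, the log-draw mixes the
    shared standard-normal latent (weight sqrt(w)) with an independent
    remainder so corr(log T_a, log T_b) = w for a shared latent."""
    eps = rng.standard_normal()
    if z_shared is None:
        z = eps
    else:
        z = math.sqrt(w) * z_shared + math.sqrt(1.0 - w) * eps
    return float(median * math.exp(shape * z))


def _volume_track(rng, params: FixtureParams, t_birth, t_end, grower, tgro):
    n = max(int((t_end - t_birth) / params.sample_step) + 1, 2)
    times = t_birth + np.arange(n) * params.sample_step
    times[-1] = min(times[-1], t_end)
    if times[-1] <= times[-2]:
        times = times[:-1]
    v0 = max(rng.normal(params.v0_mean, params.v0_cv * params.v0_mean), 50.0)
    tau = times - t_birth
    if grower:
        k = max(rng.normal(params.k_mean, params.k_cv * params.k_mean), 0.01)
        v = np.where(tau < tgro, v0, v0 * np.exp(k * (tau - tgro)))
    else:
        v = np.full_like(tau, v0)
    noise = rng.normal(1.0, params.volume_noise_cv, size=v.shape)
    return times, np.maximum(v * noise, 10.0)


def generate_lineages(params: FixtureParams, n_founders: int,
                      seed: int = 0) -> tuple[LineageTree, "np.ndarray"]:
    """Generate a synthetic lineage forest.

    Returns ``(tree, truth)`` where ``truth`` is a pandas-ready record array
    of the per-cell latent decisions (generation, divided?, drawn time) for
    parameter-recovery tests.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    records = []
    truth_rows = []

    # (path, parent_id, generation, t_birth, shared_latent or None)
    queue = [((i,), None, 0, 0.0, None) for i in range(n_founders)]
    while queue:
        path, parent_id, gen, t_birth, z_shared = queue.pop(0)
        cid = "c" + ".".join(str(k) for k in path)
        f = params.fractions[gen] if gen < len(params.fractions) else 0.0
        divides = bool(rng.random() < f)
        med_div, sh_div = params.tdiv0 if gen == 0 else params.tdiv1
        med_die, sh_die = params.tdie0 if gen == 0 else params.tdie1
        w = params.sister_weight
        if divides:
            dt = _lognormal(rng, med_div, sh_div, z_shared, w)
        else:
            dt = _lognormal(rng, med_die, sh_die, z_shared, w)
        t_event = t_birth + dt
        truth_rows.append((cid, gen, divides, dt))

        if t_event >= params.censor_time:
            fate, t_end = "censored", params.censor_time
        elif divides:
            fate, t_end = "divided", t_event
        else:
            fate, t_end = "died", t_event

        grower = divides if gen > 0 else (divides or rng.random() < 0.1)
        tgro = _lognormal(rng, *params.tgro0) if gen == 0 else 0.0
        times, vols = _volume_track(rng, params, t_birth, t_end, grower, tgro)
        records.append(TrackRecord(
            cell_id=cid, parent_id=parent_id, generation=gen,
            t_birth=t_birth, t_end=t_end, fate=fate,
            times=times, volumes=vols,
        ))
        if fate == "divided":
            z_next = rng.standard_normal()  # mother-level latent for daughters
            for k in (0, 1):
                queue.append((path + (k,), cid, gen + 1, t_end, z_next))

    tree = LineageTree.from_records(records)
    truth = pd.DataFrame(truth_rows, columns=["cell_id", "generation",
                                              "divided", "draw_time"])
    return tree, truth
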