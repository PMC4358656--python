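"""Lineage analytics.

Implements the statistics computed on lineage-track data, whether the tracks
come from microscopy-style files, the agent engine, or the synthetic-lineage
generator: growth classification (350/800 μm³ rules), piecewise growth-curve
fitting (flat baseline followed by exponential growth, the inflection being
the growth-onset time Tgro), generation-structured fate fractions inside
24-h observation windows, kin (sister/cousin) correlations, the
race-model lower bound on dying growers, and population summaries.

Simulated and experimental-style tracks are treated identically: Tgro always
comes from the fitted inflection, never from the simulator's internals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .lineage import LineageTree, TrackRecord

__all__ = [
    "GrowthFit", "GenerationStats", "PopulationResult", "RaceBound",
    "classify_growth", "classify_all", "fit_growth", "fate_fractions",
    "race_lower_bound", "kin_correlations", "population_summaries",
    "average_growth_curves",
]

#: Default grower thresholds (μm³): minimum volume gain, minimum final size.
DELTA_THRESH = 350.0
FINAL_THRESH = 800.0

#: Fate windows (hours): generation 0 measured from stimulation, later
#: generations from birth.
DEFAULT_WINDOWS = {"gen0": (12.0, 36.0), "gen1plus": (0.0, 24.0)}


# ---------------------------------------------------------------------------
# Growth classification and fitting
# ---------------------------------------------------------------------------

def classify_growth(track: TrackRecord, delta_thresh: float = DELTA_THRESH,
                    final_thresh: float = FINAL_THRESH, trailing: int = 5) -> str:
    """Classify a track as ``"grower"`` or ``"non_grower"``.

    A cell is a grower iff its mean ending volume exceeds its mean starting
    volume by at least ``delta_thresh`` or its ending volume reaches
    ``final_thresh``.  Start/end volumes are trailing means of up to
    ``trailing`` samples, so a cell that grew and then shrank back below the
    criteria is a non-grower.  Thresholds may be rescaled for sensitivity
    reruns.
    """
    if track.volumes is None or len(track.volumes) < 2:
        raise ValueError(
            f"cell {track.cell_id}: growth class undetermined (<2 volume samples)"
        )
    v = np.asarray(track.volumes, float)
    k = min(trailing, len(v))
    v_start = float(np.mean(v[:k]))
    v_end = float(np.mean(v[-k:]))
    if (v_end - v_start >= delta_thresh) or (v_end >= final_thresh):
        return "grower"
    return "non_grower"


def classify_all(tree: LineageTree, threshold_scale: float = 1.0,
                 trailing: int = 5):
    """Classify every cell with a volume trajectory.

    Returns ``(classes, n_excluded)`` where ``classes`` maps cell_id to
    class and ``n_excluded`` counts cells with too few samples.
    ``threshold_scale`` rescales both thresholds (±25% sensitivity reruns).
    """
    classes = {}
    n_excluded = 0
    for rec in tree.records():
        if rec.volumes is None:
            continue
        try:
            classes[rec.cell_id] = classify_growth(
                rec, DELTA_THRESH * threshold_scale, FINAL_THRESH * threshold_scale,
                trailing,
            )
        except ValueError:
            n_excluded += 1
    return classes, n_excluded


@dataclass(frozen=True)
class GrowthFit:
    """Piecewise growth fit: V(t) = v0 for t < t_gro, v0·exp(k(t−t_gro))
    afterwards (t relative to birth)."""

    v0: float
    t_gro: float
    k: float
    rmsd: float

    def predict(self, tau: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau, float)
        return np.where(tau < self.t_gro, self.v0,
                        self.v0 * np.exp(self.k * (tau - self.t_gro)))


def _piecewise_sse(tau, v, tg, k):
    w = np.where(tau < tg, 1.0, np.exp(np.minimum(k * (tau - tg), 50.0)))
    denom = float(w @ w)
    v0 = float(v @ w) / denom if denom > 0 else float(np.mean(v))
    resid = v - v0 * w
    return float(resid @ resid), v0


def _best_k(tau, v, tg, k_max):
    res = minimize_scalar(lambda k: _piecewise_sse(tau, v, tg, k)[0],
                          bounds=(0.0, k_max), method="bounded",
                          options={"xatol": 1e-6})
    k = float(res.x)
    sse, v0 = _piecewise_sse(tau, v, tg, k)
    return sse, v0, k


def fit_growth(track: TrackRecord, k_max: float = 2.0) -> GrowthFit:
    """Least-squares piecewise growth fit.

    The inflection ``t_gro`` is searched on the sampling grid (coarsened to
    at most 64 candidates for long tracks, then refined at full sampling
    resolution around the best candidate); for each candidate the rate is
    optimized in 1-D and the baseline has a closed form.  Deterministic.
    """
    if track.volumes is None or len(track.volumes) < 5:
        raise ValueError(f"cell {track.cell_id}: growth fit needs >= 5 samples")
    tau = np.asarray(track.times, float) - track.times[0]
    v = np.asarray(track.volumes, float)

    if np.allclose(v, v[0]):
        return GrowthFit(v0=float(v[0]), t_gro=float(tau[-1]), k=0.0, rmsd=0.0)

    def evaluate(tg):
        if tg >= tau[-1]:
            v0 = float(np.mean(v))
            resid = v - v0
            return float(resid @ resid), v0, 0.0
        return _best_k(tau, v, tg, k_max)

    candidates = np.unique(np.append(tau, tau[-1]))
    if len(candidates) > 64:
        coarse = candidates[np.linspace(0, len(candidates) - 1, 64).astype(int)]
    else:
        coarse = candidates
    scored = [(evaluate(tg), tg) for tg in coarse]
    (best_sse, best_v0, best_k), best_tg = min(scored, key=lambda s: s[0][0])

    if len(candidates) > 64:
        i = int(np.searchsorted(coarse, best_tg))
        lo = coarse[max(i - 1, 0)]
        hi = coarse[min(i + 1, len(coarse) - 1)]
        fine = candidates[(candidates >= lo) & (candidates <= hi)]
        for tg in fine:
            (sse, v0, k) = evaluate(tg)
            if sse < best_sse:
                best_sse, best_v0, best_k, best_tg = sse, v0, k, tg

    rmsd = math.sqrt(best_sse / len(v))
    return GrowthFit(v0=best_v0, t_gro=float(best_tg), k=best_k, rmsd=rmsd)


# ---------------------------------------------------------------------------
# Generation-structured fate statistics
# ---------------------------------------------------------------------------

@dataclass
class GenerationStats:
    """Per-generation fate fractions (within the observation windows) and
    timing samples.  ``table`` columns: generation, n_cells, n_eligible,
    fraction_divided, fraction_died, err (the 1/n error-bar convention);
    ``timings[g]`` holds arrays ``tdiv`` and ``tdie`` (hours)."""

    table: pd.DataFrame
    timings: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)


def fate_fractions(tree: LineageTree, windows: dict | None = None) -> GenerationStats:
    """Fraction of cells dividing/dying inside the generation's observation
    window.

    Generation 0 uses a window measured from stimulation (default 12–36 h);
    generations 1+ use a window from birth (default 0–24 h).  Cells censored
    before their window's end are excluded from the denominator.
    """
    windows = windows or DEFAULT_WINDOWS
    rows = []
    timings = {}
    notes = []
    t = tree.tracks
    for g, grp in t.groupby("generation"):
        if g == 0:
            w_lo, w_hi = windows["gen0"]
            event_t = grp["t_end_h"].to_numpy()
            win_end = np.full(len(grp), w_hi)
        else:
            w_lo, w_hi = windows["gen1plus"]
            event_t = (grp["t_end_h"] - grp["t_birth_h"]).to_numpy()
            win_end = grp["t_birth_h"].to_numpy() + w_hi
        fate = grp["fate"].to_numpy()
        censored_early = (fate == "censored") & (grp["t_end_h"].to_numpy() < win_end)
        eligible = ~censored_early
        n_eligible = int(eligible.sum())
        if n_eligible == 0:
            notes.append(f"generation {g}: no eligible cells (all censored early)")
            continue
        in_window = (event_t >= w_lo) & (event_t <= w_hi)
        frac_div = float(((fate == "divided") & in_window & eligible).sum() / n_eligible)
        frac_die = float(((fate == "died") & in_window & eligible).sum() / n_eligible)
        rows.append((int(g), len(grp), n_eligible, frac_div, frac_die,
                     1.0 / n_eligible))
        life = (grp["t_end_h"] - grp["t_birth_h"]).to_numpy() if g > 0 \
            else grp["t_end_h"].to_numpy()
        timings[int(g)] = {
            "tdiv": life[fate == "divided"],
            "tdie": life[fate == "died"],
        }
    table = pd.DataFrame(rows, columns=[
        "generation", "n_cells", "n_eligible", "fraction_divided",
        "fraction_died", "err",
    ])
    return GenerationStats(table=table, timings=timings, notes=notes)


def raw_division_fractions(tree: LineageTree) -> pd.Series:
    """Fraction of cells of each generation whose fate is 'divided'
    (no observation window; censored cells count in the denominator)."""
    t = tree.tracks
    return t.groupby("generation").apply(
        lambda g: (g["fate"] == "divided").mean(), include_groups=False
    )


# ---------------------------------------------------------------------------
# Race-vs-decision lower bound
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RaceBound:
    """Lower bound on P(grew then died) under the race hypothesis, together
    with the decision-model expectation (exactly 0: under a decision model a
    cell committed to death never starts growing)."""

    p_race: float
    p_decision: float = 0.0


def race_lower_bound(tgro_samples, tdie_samples, f_resp: float) -> RaceBound:
    """Race-model lower bound on the fraction of cells that start growing
    and then die.

    Under independent growth-onset and death clocks, a cell dying at time
    ``Tdie`` would already have started growing with probability
    ``F̂_gro(Tdie)`` (the empirical CDF of the growth-onset times), so the
    bound is ``f_resp · mean_j F̂_gro(Tdie_j)`` with ``f_resp`` the observed
    responding (dividing) fraction.
    """
    tgro = np.sort(np.asarray(tgro_samples, float))
    tdie = np.asarray(tdie_samples, float)
    if tgro.size == 0:
        raise ValueError("race_lower_bound: empty growth-onset sample")
    if tdie.size == 0:
        raise ValueError("race_lower_bound: empty death-time sample")
    if not 0.0 <= f_resp <= 1.0:
        raise ValueError(f"f_resp must be in [0, 1], got {f_resp}")
    cdf_at_death = np.searchsorted(tgro, tdie, side="right") / tgro.size
    return RaceBound(p_race=float(f_resp * cdf_at_death.mean()))


# ---------------------------------------------------------------------------
# Kin correlations
# ---------------------------------------------------------------------------

def _paired_r2(pairs):
    """Squared symmetrized Pearson correlation over unordered pairs (each
    pair enters in both orders)."""
    if len(pairs) < 3:
        return None
    a = np.array([p[0] for p in pairs], float)
    b = np.array([p[1] for p in pairs], float)
    x = np.concatenate([a, b])
    y = np.concatenate([b, a])
    if np.std(x) == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def kin_correlations(tree: LineageTree, tgro: dict | None = None,
                     dtgro_window: float = 4.0) -> dict:
    """Sister and cousin concordance/correlation statistics.

    Returns ``{"sister": {...}, "cousin": {...}}`` with keys
    ``same_fate_prob`` (both fates observed), ``pr_dtgro_le_4h`` (growth
    onsets within 4 h, needs fitted Tgro values), ``r2_interdivision``
    (both divided) and ``r2_lifespan`` (both fates observed).  A statistic
    with no eligible pairs is ``None``.  ``n_pairs`` reports the pair count
    used for ``r2_interdivision``.
    """
    if tgro is None:
        tgro = {}
        classes, _ = classify_all(tree)
        for rec in tree.records():
            if classes.get(rec.cell_id) == "grower" and rec.volumes is not None \
                    and len(rec.volumes) >= 5:
                tgro[rec.cell_id] = fit_growth(rec).t_gro

    def stats_for(pairs):
        fate_pairs, tdiv_pairs, life_pairs, tgro_pairs = [], [], [], []
        for a, b in pairs:
            fa, fb = a.fate, b.fate
            la = a.t_end_h - a.t_birth_h
            lb = b.t_end_h - b.t_birth_h
            if fa in ("divided", "died") and fb in ("divided", "died"):
                fate_pairs.append(fa == fb)
                life_pairs.append((la, lb))
            if fa == "divided" and fb == "divided":
                tdiv_pairs.append((la, lb))
            ga, gb = tgro.get(a.cell_id), tgro.get(b.cell_id)
            if ga is not None and gb is not None:
                tgro_pairs.append(abs(ga - gb) <= dtgro_window)
        return {
            "same_fate_prob": float(np.mean(fate_pairs)) if fate_pairs else None,
            "pr_dtgro_le_4h": float(np.mean(tgro_pairs)) if tgro_pairs else None,
            "r2_interdivision": _paired_r2(tdiv_pairs),
            "r2_lifespan": _paired_r2(life_pairs),
            "n_pairs": len(tdiv_pairs),
        }

    sisters = [(a, b) for a, b in tree.sister_pairs()]
    cousins = [(a, b) for a, b in tree.cousin_pairs()]
    if not sisters:
        raise ValueError("kin_correlations requires at least one sister pair")
    return {"sister": stats_for(sisters), "cousin": stats_for(cousins)}


# ---------------------------------------------------------------------------
# Population summaries
# ---------------------------------------------------------------------------

@dataclass
class PopulationResult:
    """Time-resolved normalized counts and scalar population summaries."""

    grid: np.ndarray
    counts_total: np.ndarray          # normalized to founder count
    counts_by_generation: pd.DataFrame
    max_relative_count: float
    expected_divisions: float
    mean_interdivision_gen1plus: float | None
    end_relative_count: float


def population_summaries(tree: LineageTree, grid: np.ndarray | None = None) -> PopulationResult:
    """Normalized cell counts over time plus the scalar summaries: maximum
    relative count, expected divisions per progenitor (from the
    per-generation division-fraction chain E = Σ_g Π_{i≤g} f_i), mean
    generation-1+ interdivision time, and the end-of-run relative count."""
    t = tree.tracks
    n0 = int((t["generation"] == 0).sum())
    if n0 == 0:
        raise ValueError("population_summaries: tree has no founders")
    if grid is None:
        grid = np.arange(0.0, float(t["t_end_h"].max()) + 1.0, 1.0)
    birth = t["t_birth_h"].to_numpy()
    end = t["t_end_h"].to_numpy()
    gen = t["generation"].to_numpy()
    alive = (birth[None, :] <= grid[:, None]) & (grid[:, None] < end[None, :])
    counts_total = alive.sum(axis=1) / n0
    by_gen = {}
    for g in np.unique(gen):
        by_gen[int(g)] = alive[:, gen == g].sum(axis=1) / n0
    counts_by_generation = pd.DataFrame(by_gen, index=grid)

    f = raw_division_fractions(tree)
    expected = 0.0
    chain = 1.0
    for g in sorted(f.index):
        chain *= float(f.loc[g])
        expected += chain

    div1 = t[(t["generation"] >= 1) & (t["fate"] == "divided")]
    mean_idt = float((div1["t_end_h"] - div1["t_birth_h"]).mean()) if len(div1) else None

    # survivors at the end of the run are the censored cells
    end_relative = float((t["fate"] == "censored").sum() / n0)

    return PopulationResult(
        grid=grid,
        counts_total=counts_total,
        counts_by_generation=counts_by_generation,
        max_relative_count=float(counts_total.max()),
        expected_divisions=float(expected),
        mean_interdivision_gen1plus=mean_idt,
        end_relative_count=end_relative,
    )


def average_growth_curves(tree: LineageTree, n_bins: int = 20,
                          threshold_scale: float = 1.0) -> pd.DataFrame:
    """Average volume trajectories per generation and growth class, with
    each cell's lifetime normalized to percent lifespan.

    Returns a DataFrame indexed by (generation, growth_class, pct_lifespan)
    with columns ``mean_volume`` and ``n_cells``.
    """
    classes, _ = classify_all(tree, threshold_scale)
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    acc = {}
    for rec in tree.records():
        cls = classes.get(rec.cell_id)
        if cls is None or rec.volumes is None or len(rec.volumes) < 2:
            continue
        tau = (np.asarray(rec.times) - rec.times[0])
        pct = 100.0 * tau / tau[-1]
        binned = np.interp(centers, pct, np.asarray(rec.volumes, float))
        key = (int(rec.generation), cls)
        if key not in acc:
            acc[key] = [np.zeros(n_bins), 0]
        acc[key][0] += binned
        acc[key][1] += 1
    rows = []
    for (g, cls), (total, n) in sorted(acc.items()):
        for c, v in zip(centers, total / n):
            rows.append((g, cls, c, v, n))
    return pd.DataFrame(rows, columns=[
        "generation", "growth_class", "pct_lifespan", "mean_volume", "n_cells",
    ]).set_index(["generation", "growth_class", "pct_lifespan"])
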