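"""Lineage-tree container for tracked or simulated cells.

A :class:`LineageTree` is a table of cell records (id, parent, generation,
birth/end time, fate in {divided, died, censored}) plus optional per-cell
volume trajectories in μm³.  It is the common currency between the agent
engine, the synthetic-lineage generator, the file I/O layer and the
analytics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FATES", "TrackRecord", "LineageTree"]

FATES = ("divided", "died", "censored")

TRACK_COLUMNS = ["cell_id", "parent_id", "generation", "t_birth_h", "t_end_h", "fate"]


@dataclass(frozen=True)
class TrackRecord:
    """One cell's track: identity, lifetime and (optionally) its volume
    samples on ``[t_birth, t_end]`` in hours / μm³."""

    cell_id: str
    parent_id: str | None
    generation: int
    t_birth: float
    t_end: float
    fate: str
    times: np.ndarray | None = None
    volumes: np.ndarray | None = None

    def __post_init__(self):
        if self.fate not in FATES:
            raise ValueError(f"fate must be one of {FATES}, got {self.fate!r}")
        if not self.t_end > self.t_birth:
            raise ValueError(
                f"cell {self.cell_id}: t_end ({self.t_end}) must exceed "
                f"t_birth ({self.t_birth})"
            )
        if self.times is not None:
            t = np.asarray(self.times, dtype=float)
            v = np.asarray(self.volumes, dtype=float)
            if t.shape != v.shape:
                raise ValueError(f"cell {self.cell_id}: times/volumes length mismatch")
            if t.size and np.any(np.diff(t) <= 0):
                raise ValueError(f"cell {self.cell_id}: times must be strictly increasing")
            if np.any(v <= 0):
                raise ValueError(f"cell {self.cell_id}: volumes must be positive")

    @property
    def lifespan(self) -> float:
        return self.t_end - self.t_birth


@dataclass
class LineageTree:
    """Forest of cell records with attached volume trajectories.

    ``tracks`` is a DataFrame with columns ``cell_id, parent_id, generation,
    t_birth_h, t_end_h, fate`` (parent_id is ``None``/NaN for founders);
    ``volumes`` maps cell_id to an ``(n, 2)`` array of (time_h, volume_um3).
    """

    tracks: pd.DataFrame
    volumes: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)  # optional per-cell metadata (e.g. extrinsic draws)

    @classmethod
    def from_records(cls, records) -> "LineageTree":
        rows = []
        volumes = {}
        for r in records:
            rows.append((r.cell_id, r.parent_id, r.generation,
                         r.t_birth, r.t_end, r.fate))
            if r.times is not None:
                volumes[r.cell_id] = np.column_stack(
                    [np.asarray(r.times, float), np.asarray(r.volumes, float)]
                )
        tracks = pd.DataFrame(rows, columns=TRACK_COLUMNS)
        tree = cls(tracks=tracks, volumes=volumes)
        tree.validate()
        return tree

    def validate(self) -> None:
        """Check structural invariants: unique ids, known parents, child
        generation = parent generation + 1, acyclicity, positive lifespans."""
        t = self.tracks
        if t["cell_id"].duplicated().any():
            dup = t.loc[t["cell_id"].duplicated(), "cell_id"].tolist()
            raise ValueError(f"duplicate cell ids: {dup}")
        ids = set(t["cell_id"])
        gen = dict(zip(t["cell_id"], t["generation"]))
        birth = dict(zip(t["cell_id"], t["t_birth_h"]))
        end = dict(zip(t["cell_id"], t["t_end_h"]))
        for cid, pid, g in zip(t["cell_id"], t["parent_id"], t["generation"]):
            if not end[cid] > birth[cid]:
                raise ValueError(f"cell {cid}: nonpositive lifespan")
            if pid is None or (isinstance(pid, float) and np.isnan(pid)) or pid == "":
                if g != 0:
                    raise ValueError(f"founder {cid} has generation {g} != 0")
                continue
            if pid not in ids:
                raise ValueError(f"cell {cid}: unknown parent {pid!r}")
            if gen[pid] + 1 != g:
                raise ValueError(
                    f"cell {cid}: generation {g} != parent generation {gen[pid]} + 1"
                )
        for cid in self.volumes:
            if cid not in ids:
                raise ValueError(f"volume trajectory for unknown cell {cid!r}")

    # -- convenience views ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.tracks)

    def record(self, cell_id: str) -> TrackRecord:
        row = self.tracks.loc[self.tracks["cell_id"] == cell_id]
        if row.empty:
            raise KeyError(cell_id)
        r = row.iloc[0]
        vol = self.volumes.get(cell_id)
        pid = r["parent_id"]
        if isinstance(pid, float) and np.isnan(pid):
            pid = None
        return TrackRecord(
            cell_id=r["cell_id"], parent_id=pid, generation=int(r["generation"]),
            t_birth=float(r["t_birth_h"]), t_end=float(r["t_end_h"]), fate=r["fate"],
            times=None if vol is None else vol[:, 0],
            volumes=None if vol is None else vol[:, 1],
        )

    def records(self):
        for cid in self.tracks["cell_id"]:
            yield self.record(cid)

    def founders(self) -> pd.DataFrame:
        return self.tracks[self.tracks["generation"] == 0]

    def sister_pairs(self):
        """Yield (row_a, row_b) for each pair of cells sharing a parent."""
        t = self.tracks
        has_parent = t["parent_id"].notna() & (t["parent_id"] != "")
        for _, grp in t[has_parent].groupby("parent_id"):
            if len(grp) == 2:
                yield grp.iloc[0], grp.iloc[1]

    def cousin_pairs(self):
        """Yield (row_a, row_b) for cells sharing a grandparent but not a
        parent."""
        t = self.tracks
        parent_of = dict(zip(t["cell_id"], t["parent_id"]))

        def grandparent(cid):
            p = parent_of.get(cid)
            if p is None or p == "" or (isinstance(p, float) and np.isnan(p)):
                return None
            return parent_of.get(p)

        gp = {cid: grandparent(cid) for cid in t["cell_id"]}
        t2 = t.assign(_gp=[gp[c] for c in t["cell_id"]])
        valid = t2["_gp"].notna() & (t2["_gp"] != "")
        for _, grp in t2[valid].groupby("_gp"):
            rows = list(grp.itertuples(index=False))
            for i in range(len(rows)):
                for j in range(i + 1, len(rows)):
                    if rows[i].parent_id != rows[j].parent_id:
                        yield rows[i], rows[j]
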