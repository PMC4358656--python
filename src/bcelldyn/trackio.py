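"""Tab-separated track and volume files.

Track file: one row per cell with columns ``cell_id, parent_id, generation,
t_birth_h, t_end_h, fate`` (parent_id empty for founders; parents precede
children; times in hours with at least 3 decimals).  Volume file: long
format ``cell_id, time_h, volume_um3``.  Comment lines start with ``#`` and
record units and provenance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lineage import FATES, LineageTree

__all__ = ["write_tracks", "read_tracks", "write_volumes", "read_volumes",
           "TrackFileError"]

TRACK_HEADER = ["cell_id", "parent_id", "generation", "t_birth_h", "t_end_h", "fate"]
VOLUME_HEADER = ["cell_id", "time_h", "volume_um3"]


class TrackFileError(ValueError):
    """Malformed track/volume file; message lists offending lines."""


def write_tracks(tree: LineageTree, path, comments: tuple = ()) -> None:
    t = tree.tracks.sort_values(["generation", "cell_id"], kind="stable")
    with open(path, "w") as fh:
        fh.write("# bcelldyn lineage tracks; times in hours\n")
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("\t".join(TRACK_HEADER) + "\n")
        for row in t.itertuples(index=False):
            pid = "" if row.parent_id is None or \
                (isinstance(row.parent_id, float) and np.isnan(row.parent_id)) \
                else row.parent_id
            fh.write(f"{row.cell_id}\t{pid}\t{row.generation}\t"
                     f"{row.t_birth_h:.4f}\t{row.t_end_h:.4f}\t{row.fate}\n")


def read_tracks(path) -> LineageTree:
    """Parse a track file into a (volume-less) :class:`LineageTree`.

    Raises :class:`TrackFileError` listing line numbers for malformed rows,
    orphan parents, or invalid times.
    """
    rows = []
    errors = []
    seen = set()
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header != TRACK_HEADER:
                    raise TrackFileError(
                        f"line {lineno}: header must be {TRACK_HEADER}, got {header}"
                    )
                continue
            parts = line.split("\t")
            if len(parts) != len(TRACK_HEADER):
                errors.append(f"line {lineno}: expected {len(TRACK_HEADER)} fields, "
                              f"got {len(parts)}")
                continue
            cid, pid, gen, tb, te, fate = parts
            try:
                gen = int(gen)
                tb = float(tb)
                te = float(te)
            except ValueError:
                errors.append(f"line {lineno}: non-numeric generation/time")
                continue
            if fate not in FATES:
                errors.append(f"line {lineno}: unknown fate {fate!r}")
                continue
            if te <= tb:
                errors.append(f"line {lineno}: t_end_h <= t_birth_h for {cid}")
                continue
            if cid in seen:
                errors.append(f"line {lineno}: duplicate cell_id {cid}")
                continue
            if pid and pid not in seen:
                errors.append(f"line {lineno}: parent {pid!r} of {cid} not seen "
                              "on an earlier row")
                continue
            seen.add(cid)
            rows.append((cid, pid or None, gen, tb, te, fate))
    if header is None:
        raise TrackFileError("empty file: missing header row")
    if errors:
        raise TrackFileError("malformed track file:\n  " + "\n  ".join(errors))
    tracks = pd.DataFrame(rows, columns=TRACK_HEADER)
    tree = LineageTree(tracks=tracks, volumes={})
    if len(tree):
        tree.validate()
    return tree


def write_volumes(tree: LineageTree, path, comments: tuple = ()) -> None:
    with open(path, "w") as fh:
        fh.write("# bcelldyn volume trajectories; time in hours, volume in um^3\n")
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("\t".join(VOLUME_HEADER) + "\n")
        order = tree.tracks.sort_values(["generation", "cell_id"], kind="stable")
        for cid in order["cell_id"]:
            tv = tree.volumes.get(cid)
            if tv is None:
                continue
            for t, v in tv:
                fh.write(f"{cid}\t{t:.4f}\t{v:.4f}\n")


def read_volumes(path, tree: LineageTree) -> LineageTree:
    """Attach volume trajectories from a volume file to ``tree`` (returned
    as a new object).  Rows referencing unknown cells, duplicate times, or
    non-increasing times raise :class:`TrackFileError`."""
    known = set(tree.tracks["cell_id"])
    errors = []
    data: dict[str, list] = {}
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header != VOLUME_HEADER:
                    raise TrackFileError(
                        f"line {lineno}: header must be {VOLUME_HEADER}, got {header}"
                    )
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                errors.append(f"line {lineno}: expected 3 fields, got {len(parts)}")
                continue
            cid, t, v = parts
            if cid not in known:
                errors.append(f"line {lineno}: volume row references unknown cell "
                              f"{cid!r}")
                continue
            try:
                t = float(t)
                v = float(v)
            except ValueError:
                errors.append(f"line {lineno}: non-numeric time/volume")
                continue
            bucket = data.setdefault(cid, [])
            if bucket and t <= bucket[-1][0]:
                errors.append(f"line {lineno}: time {t} not increasing for {cid}")
                continue
            bucket.append((t, v))
    if header is None:
        raise TrackFileError("empty file: missing header row")
    if errors:
        raise TrackFileError("malformed volume file:\n  " + "\n  ".join(errors))
    volumes = {cid: np.asarray(rows, float) for cid, rows in data.items()}
    return LineageTree(tracks=tree.tracks.copy(), volumes=volumes)
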