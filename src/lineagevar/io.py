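"""Reading and writing cell-tracking tables and lineage topologies.

Tracking-table dialect
----------------------
Tab-separated, UTF-8, one row per cell per frame.  Required columns::

    colony_id  cell_id  parent_id  frame  time_min  length_um  x_px  y_px

plus one or more ``fluor_<channel>`` intensity columns.  The founder's
``parent_id`` is ``-``; missing values are ``NA``.  An optional ``end_state``
column records each cell's fate (``divided``/``arrested``/``censored``);
without it, fates are inferred from the topology (two children -> divided,
otherwise censored).  Two metadata comment lines precede the header::

    # frame_interval_min<TAB><value>
    # induction_time_min<TAB><value or NA>

Birth and end times are reconstructed deterministically: a cell is born at
its first frame; a divided mother ends at her daughters' birth; a leaf's
record is taken to extend one frame interval past its last frame (the cell
was observed alive there).  Written and re-loaded trees round-trip to
identical bytes.
"""

from __future__ import annotations

import io as _stdio
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, StructuralError
from .lineage import CellRecord, LineageTree, SampleTable

REQUIRED_COLUMNS = [
    "colony_id", "cell_id", "parent_id", "frame", "time_min",
    "length_um", "x_px", "y_px",
]
_NA = "NA"
_FOUNDER = "-"


def _fmt(v: float) -> str:
    return _NA if (v is None or not math.isfinite(v)) else format(v, ".6g")


def write_tracking_table(tree: LineageTree, path, colony_id: str = "colony1") -> None:
    """Serialise a tree in the tracking-table dialect (deterministic bytes)."""
    channels = sorted({ch for r in tree.cells.values() for ch in r.samples.fluor})
    cols = REQUIRED_COLUMNS + ["end_state"] + [f"fluor_{ch}" for ch in channels]
    rows: list[tuple] = []
    for cid in sorted(tree.cells):
        rec = tree.cells[cid]
        pid = rec.parent_id if rec.parent_id is not None else _FOUNDER
        for j in range(rec.samples.n):
            t = rec.samples.time[j]
            frame = int(round(t / tree.frame_interval))
            fl = [rec.samples.fluor.get(ch, [math.nan] * rec.samples.n)[j]
                  for ch in channels]
            rows.append((frame, cid, pid, t, rec.samples.length[j],
                         rec.samples.x[j], rec.samples.y[j], rec.end_state, fl))
    rows.sort(key=lambda r: (r[0], r[1]))
    buf = _stdio.StringIO()
    buf.write(f"# frame_interval_min\t{_fmt(tree.frame_interval)}\n")
    ind = _fmt(tree.induction_time) if tree.induction_time is not None else _NA
    buf.write(f"# induction_time_min\t{ind}\n")
    buf.write("\t".join(cols) + "\n")
    for frame, cid, pid, t, ln, x, y, state, fl in rows:
        fields = [colony_id, cid, pid, str(frame), _fmt(t), _fmt(ln),
                  _fmt(x), _fmt(y), state] + [_fmt(v) for v in fl]
        buf.write("\t".join(fields) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def load_tracking_table(path) -> LineageTree:
    """Parse a tracking table into a validated :class:`LineageTree`."""
    text = Path(path).read_text(encoding="utf-8")
    frame_interval, induction_time = None, None
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            parts = line.lstrip("# ").split("\t")
            if len(parts) == 2:
                key, val = parts
                if key == "frame_interval_min":
                    frame_interval = float(val)
                elif key == "induction_time_min":
                    induction_time = None if val == _NA else float(val)
        elif line.strip():
            body_lines.append(line)
    if not body_lines:
        raise FormatError(f"{path}: no header line found")
    df = pd.read_csv(
        _stdio.StringIO("\n".join(body_lines)), sep="\t",
        dtype={"colony_id": str, "cell_id": str, "parent_id": str},
        na_values=[_NA], keep_default_na=False,
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise FormatError(f"{path}: header-only file, no cell rows")
    if df["colony_id"].nunique() > 1:
        raise FormatError(
            f"{path}: multiple colony_ids in one file; load them separately")
    fluor_cols = [c for c in df.columns if c.startswith("fluor_")]
    has_state = "end_state" in df.columns
    if frame_interval is None:
        times = np.sort(df["time_min"].unique())
        frame_interval = float(np.min(np.diff(times))) if len(times) > 1 else 1.5

    cells: dict[str, CellRecord] = {}
    parent_of: dict[str, str | None] = {}
    children: dict[str, list[str]] = {}
    for cid, grp in df.groupby("cell_id", sort=True):
        t = grp["time_min"].to_numpy(dtype=float)
        order = np.argsort(t, kind="stable")
        t = t[order]
        if np.any(np.diff(t) <= 0):
            raise FormatError(f"{path}: cell {cid} has non-monotone times")
        pid = grp["parent_id"].iloc[0]
        pid = None if pid == _FOUNDER else str(pid)
        parent_of[str(cid)] = pid
        if pid is not None:
            children.setdefault(pid, []).append(str(cid))
        samples = SampleTable(
            t,
            grp["length_um"].to_numpy(dtype=float)[order],
            grp["x_px"].to_numpy(dtype=float)[order],
            grp["y_px"].to_numpy(dtype=float)[order],
            {c.removeprefix("fluor_"): grp[c].to_numpy(dtype=float)[order]
             for c in fluor_cols},
        )
        state = str(grp["end_state"].iloc[0]) if has_state else ""
        cells[str(cid)] = CellRecord(str(cid), pid, float(t[0]), math.nan,
                                     state, samples)

    for cid, pid in parent_of.items():
        if pid is not None and pid not in cells:
            raise StructuralError(
                f"{path}: cell {cid} references absent parent {pid}")
    founders = [c for c, p in parent_of.items() if p is None]
    if len(founders) != 1:
        raise StructuralError(
            f"{path}: expected exactly 1 founder, found {len(founders)}")

    for cid, rec in cells.items():
        kids = children.get(cid, [])
        own_end = float(rec.samples.time[-1]) + frame_interval
        if kids:
            rec.end_time = max(min(cells[k].birth_time for k in kids), own_end)
            if not has_state:
                rec.end_state = "divided"
        else:
            rec.end_time = own_end
            if not has_state:
                rec.end_state = "censored"
    tree = LineageTree(cells, founders[0], induction_time, frame_interval)
    try:
        tree.validate()
    except StructuralError as exc:
        # lineage-switch randomized trees legitimately relax the
        # mother-end == daughter-birth identity; everything else is fatal
        if "parent" in str(exc) and "end_time" in str(exc):
            warnings.warn(f"{path}: division-time identity relaxed "
                          f"(randomized tree?)", stacklevel=2)
            tree.validate(strict_division_times=False)
        else:
            raise
    return tree


def to_newick(tree: LineageTree) -> str:
    """Topology as a Newick string.

    Labels are cell ids, branch lengths are lifetimes in minutes, and a
    trailing comment on each node carries the end state.
    """
    def node(cid: str) -> str:
        rec = tree.cells[cid]
        kids = tree.children_of(cid)
        inner = f"({','.join(node(k) for k in kids)})" if kids else ""
        life = rec.end_time - rec.birth_time
        return f"{inner}{cid}:{life:.6g}[&end_state={rec.end_state}]"

    return node(tree.founder_id) + ";"
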