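"""Lineage forest data model and per-cell derived quantities.

A micro-colony is represented as a :class:`LineageTree`: a founder cell and
its descendants, each a :class:`CellRecord` holding the per-frame
measurements produced by time-lapse segmentation (length, centroid,
fluorescence channels).  Times are minutes throughout; lengths are µm;
positions are pixels; fluorescence is in arbitrary units.

Conventions
-----------
* The division instant belongs to both the mother (her ``end_time``) and the
  daughters (their ``birth_time``).  For the purpose of "alive at t" queries
  a divided mother is alive on ``[birth_time, end_time)`` so that a colony
  census at the division instant counts the daughters, not the mother.
* Non-divided cells (growth-arrested or censored at the end of the record)
  are alive on ``[birth_time, end_time]``.
* Generation 0 is the founder; ``generation_of`` counts division edges.
  The *colony-stage* generation, used as the time axis of lineage
  autocorrelation curves, is ``floor(log2(colony size))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import AlignmentError, DomainError, EstimationError, StructuralError

END_STATES = ("divided", "arrested", "censored")


@dataclass
class SampleTable:
    """Per-frame measurements of one cell, as parallel numpy arrays."""

    time: np.ndarray          # minutes, strictly increasing
    length: np.ndarray        # µm, > 0
    x: np.ndarray             # px
    y: np.ndarray             # px
    fluor: dict[str, np.ndarray] = field(default_factory=dict)  # channel -> a.u.

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.length = np.asarray(self.length, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.fluor = {k: np.asarray(v, dtype=float) for k, v in self.fluor.items()}

    @property
    def n(self) -> int:
        return len(self.time)

    def nearest_index(self, t: float) -> int:
        """Index of the frame whose time is closest to ``t``."""
        return int(np.argmin(np.abs(self.time - t)))

    def copy(self) -> "SampleTable":
        return SampleTable(
            self.time.copy(), self.length.copy(), self.x.copy(), self.y.copy(),
            {k: v.copy() for k, v in self.fluor.items()},
        )


@dataclass
class CellRecord:
    """One cell from birth to division, arrest, or end of observation."""

    cell_id: str
    parent_id: str | None     # None for the founder
    birth_time: float         # minutes
    end_time: float           # minutes
    end_state: str            # 'divided' | 'arrested' | 'censored'
    samples: SampleTable

    def validate(self) -> None:
        if self.end_state not in END_STATES:
            raise StructuralError(
                f"cell {self.cell_id}: unknown end_state {self.end_state!r}")
        if not self.birth_time < self.end_time:
            raise StructuralError(
                f"cell {self.cell_id}: birth_time {self.birth_time} >= "
                f"end_time {self.end_time}")
        t = self.samples.time
        if len(t) == 0:
            raise StructuralError(f"cell {self.cell_id}: no samples")
        if np.any(np.diff(t) <= 0):
            raise StructuralError(
                f"cell {self.cell_id}: sample times not strictly increasing")
        if t[0] < self.birth_time - 1e-9 or t[-1] > self.end_time + 1e-9:
            raise StructuralError(
                f"cell {self.cell_id}: sample times outside "
                f"[{self.birth_time}, {self.end_time}]")
        if np.any(self.samples.length <= 0):
            raise StructuralError(f"cell {self.cell_id}: non-positive length")
        for ch, v in self.samples.fluor.items():
            if np.any(v[np.isfinite(v)] < 0):
                raise StructuralError(
                    f"cell {self.cell_id}: negative intensity in channel {ch}")

    def alive_at(self, t: float) -> bool:
        if self.end_state == "divided":
            return self.birth_time <= t < self.end_time
        return self.birth_time <= t <= self.end_time


@dataclass
class PhenotypeSeries:
    """A scalar phenotype of one cell along its frames.

    Values carry whichever unit the phenotype has: growth rate in min⁻¹,
    intensity in a.u., promoter activity in a.u.·min⁻¹.
    """

    cell_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise AlignmentError(
                f"cell {self.cell_id}: times/values length mismatch")

    def value_nearest(self, t: float) -> float:
        if len(self.times) == 0:
            return math.nan
        return float(self.values[int(np.argmin(np.abs(self.times - t)))])


class LineageTree:
    """A rooted lineage forest of one micro-colony."""

    def __init__(
        self,
        cells: dict[str, CellRecord],
        founder_id: str,
        induction_time: float | None = None,
        frame_interval: float = 1.5,
    ) -> None:
        self.cells = cells
        self.founder_id = founder_id
        self.induction_time = induction_time
        self.frame_interval = float(frame_interval)
        self._children: dict[str, list[str]] = {}
        self._rebuild_children()

    # -- structure ---------------------------------------------------------

    def _rebuild_children(self) -> None:
        self._children = {cid: [] for cid in self.cells}
        for cid, rec in self.cells.items():
            if rec.parent_id is not None:
                if rec.parent_id not in self.cells:
                    raise StructuralError(
                        f"cell {cid} references absent parent {rec.parent_id}")
                self._children[rec.parent_id].append(cid)
        for kids in self._children.values():
            kids.sort()

    def children_of(self, cell_id: str) -> list[str]:
        return self._children[cell_id]

    def validate(self, strict_division_times: bool = True) -> None:
        """Check all tree invariants.

        ``strict_division_times=False`` relaxes the requirement that a
        daughter's birth time equal her mother's end time; lineage-switch
        randomized trees (which re-parent subtrees between same-generation
        cells) satisfy every invariant except that one.
        """
        founders = [cid for cid, r in self.cells.items() if r.parent_id is None]
        if len(founders) != 1:
            raise StructuralError(f"expected exactly 1 founder, found {len(founders)}")
        if founders[0] != self.founder_id:
            raise StructuralError(
                f"founder_id {self.founder_id!r} does not match the parentless "
                f"cell {founders[0]!r}")
        for cid, rec in self.cells.items():
            rec.validate()
            kids = self._children[cid]
            if rec.end_state == "divided":
                if len(kids) != 2:
                    raise StructuralError(
                        f"divided cell {cid} has {len(kids)} children (need 2)")
                if strict_division_times:
                    for kid in kids:
                        if abs(self.cells[kid].birth_time - rec.end_time) > 1e-6:
                            raise StructuralError(
                                f"child {kid} birth_time != parent {cid} end_time")
            elif kids:
                raise StructuralError(
                    f"{rec.end_state} cell {cid} has children")
        # acyclicity / connectivity: every cell must reach the founder
        for cid in self.cells:
            seen = set()
            cur = cid
            while self.cells[cur].parent_id is not None:
                if cur in seen:
                    raise StructuralError(f"cycle through cell {cid}")
                seen.add(cur)
                cur = self.cells[cur].parent_id
            if cur != self.founder_id:
                raise StructuralError(f"cell {cid} not connected to founder")

    def copy(self) -> "LineageTree":
        cells = {
            cid: replace(rec, samples=rec.samples.copy())
            for cid, rec in self.cells.items()
        }
        return LineageTree(cells, self.founder_id, self.induction_time,
                           self.frame_interval)

    # -- census ------------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def span(self) -> tuple[float, float]:
        t0 = self.cells[self.founder_id].birth_time
        t1 = max(r.end_time for r in self.cells.values())
        return t0, t1

    def frame_times(self) -> np.ndarray:
        """The common frame grid (union of sample times, sorted)."""
        all_t = np.concatenate([r.samples.time for r in self.cells.values()])
        return np.unique(np.round(all_t, 9))

    def cells_alive_at(self, t: float) -> set[str]:
        return {cid for cid, r in self.cells.items() if r.alive_at(t)}

    def population_size(self, t: float) -> int:
        return len(self.cells_alive_at(t))

    def leaves(self) -> list[str]:
        return [cid for cid in sorted(self.cells) if not self._children[cid]]

    def subtree_ids(self, root_id: str) -> list[str]:
        out, stack = [], [root_id]
        while stack:
            cid = stack.pop()
            out.append(cid)
            stack.extend(self._children[cid])
        return out

    # -- genealogy ---------------------------------------------------------

    def generation_of(self, cell_id: str) -> int:
        """Number of division edges from the founder (founder = 0)."""
        g, cur = 0, cell_id
        while self.cells[cur].parent_id is not None:
            cur = self.cells[cur].parent_id
            g += 1
        return g

    def colony_stage_generation(self, t: float) -> int:
        """floor(log2 colony size): the population-based generation index."""
        n = self.population_size(t)
        if n < 1:
            raise DomainError(f"no cells alive at t={t}")
        return int(math.floor(math.log2(n)))

    def ancestor_at(self, cell_id: str, s: float) -> str:
        """The unique ancestor of ``cell_id`` (possibly itself) alive at time s.

        Raises :class:`DomainError` when ``s`` lies after the cell's death or
        before the founder's birth.  In randomized trees, where re-parenting
        may open small gaps between a mother's end and a daughter's birth, the
        latest ancestor born at or before ``s`` is returned.
        """
        rec = self.cells[cell_id]
        if s > rec.end_time:
            raise DomainError(
                f"time {s} is after the end of cell {cell_id}'s record")
        cur = rec
        while cur.birth_time > s:
            if cur.parent_id is None:
                raise DomainError(
                    f"time {s} precedes the founder's birth {cur.birth_time}")
            cur = self.cells[cur.parent_id]
        return cur.cell_id


# ---------------------------------------------------------------------------
# Derived per-cell quantities
# ---------------------------------------------------------------------------

def growth_rate_series(cell: CellRecord, window_frames: int = 5) -> PhenotypeSeries:
    """Instantaneous exponential growth rate along a cell's record.

    The rate at a frame is the least-squares slope of log(length) over a
    centered window of ``window_frames`` frames, in min⁻¹.  Windows that
    would straddle a division (i.e. reach beyond the cell's own record) are
    excluded, so only interior frames carry a rate.
    """
    if window_frames < 3 or window_frames % 2 == 0:
        raise ValueError("window_frames must be odd and >= 3")
    n = cell.samples.n
    if n < window_frames:
        raise EstimationError(
            f"cell {cell.cell_id}: {n} samples < window of {window_frames}")
    t = cell.samples.time
    y = np.log(cell.samples.length)
    tw = sliding_window_view(t, window_frames)
    yw = sliding_window_view(y, window_frames)
    tc = tw - tw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    slopes = (tc * yc).sum(axis=1) / (tc * tc).sum(axis=1)
    half = window_frames // 2
    return PhenotypeSeries(cell.cell_id, t[half:n - half], slopes)


def promoter_activity_series(
    fluor_series: PhenotypeSeries, growth_series: PhenotypeSeries
) -> PhenotypeSeries:
    """Dilution-corrected promoter activity, dF/dt + k·F, in a.u.·min⁻¹.

    ``F`` is a concentration-like intensity; subtracting nothing and adding
    ``k·F`` corrects for dilution by exponential growth at rate ``k``.  The
    derivative is a central finite difference on the common time grid of the
    two input series.
    """
    common, ia, ib = np.intersect1d(
        np.round(fluor_series.times, 9), np.round(growth_series.times, 9),
        return_indices=True)
    if len(common) < 3:
        raise AlignmentError("fewer than 3 shared time points between series")
    dt = np.diff(common)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise AlignmentError("shared time grid is not uniform")
    F = fluor_series.values[ia]
    k = growth_series.values[ib]
    dFdt = np.gradient(F, common)        # central differences, one-sided at ends
    act = dFdt[1:-1] + k[1:-1] * F[1:-1]
    return PhenotypeSeries(fluor_series.cell_id, common[1:-1], act)


def distance_to_border(tree: LineageTree, t: float) -> dict[str, float]:
    """Distance (px) from each cell's centroid to the micro-colony border.

    Border cells are those whose centroid lies on the convex hull of all
    centroids at the frame nearest ``t`` (hull vertices and any centroid on
    a hull edge); they get distance 0.  Interior cells get the minimum
    centroid-to-centroid distance to any border cell.  With fewer than 3
    cells (or a degenerate, collinear hull) every cell is on the border.
    """
    alive = sorted(tree.cells_alive_at(t))
    pts = np.array([
        [tree.cells[c].samples.x[tree.cells[c].samples.nearest_index(t)],
         tree.cells[c].samples.y[tree.cells[c].samples.nearest_index(t)]]
        for c in alive
    ])
    if len(alive) < 3:
        return {c: 0.0 for c in alive}
    from scipy.spatial import ConvexHull, QhullError
    try:
        hull = ConvexHull(pts)
    except QhullError:                    # collinear colony: everyone borders
        return {c: 0.0 for c in alive}
    scale = max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]), 1.0)
    # on-boundary test via the hull's facet equations a·x + b <= 0
    dist_to_facets = pts @ hull.equations[:, :2].T + hull.equations[:, 2]
    on_border = np.any(np.abs(dist_to_facets) < 1e-9 * scale, axis=1)
    bpts = pts[on_border]
    out: dict[str, float] = {}
    for i, c in enumerate(alive):
        if on_border[i]:
            out[c] = 0.0
        else:
            out[c] = float(np.min(np.linalg.norm(bpts - pts[i], axis=1)))
    return out


# ---------------------------------------------------------------------------
# Phenotype lookup across a tree
# ---------------------------------------------------------------------------

PHENOTYPES = ("fluorescence", "growth_rate", "promoter_activity")


class PhenotypeProvider:
    """Precomputed per-cell phenotype series with nearest-frame lookup.

    Centralises the mapping (cell, time) -> phenotype value used by the
    variation, predisposition and memory analyses.  Growth rates (and hence
    promoter activities) are only defined on interior frames; lookups snap to
    the nearest frame that carries a value, which may sit up to half a cell
    cycle away for cells born close to the query time.
    """

    def __init__(
        self,
        tree: LineageTree,
        phenotype: str = "fluorescence",
        channel: str | None = None,
        window_frames: int = 5,
    ) -> None:
        if phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {phenotype!r}")
        self.tree = tree
        self.phenotype = phenotype
        self.window_frames = window_frames
        if channel is None:
            channels = sorted(
                {ch for r in tree.cells.values() for ch in r.samples.fluor})
            # the stress reporter is the conventional default channel
            if "yfp" in channels:
                channel = "yfp"
            else:
                channel = channels[0] if channels else None
        self.channel = channel
        self._series: dict[str, PhenotypeSeries | None] = {}

    def series(self, cell_id: str) -> PhenotypeSeries | None:
        if cell_id in self._series:
            return self._series[cell_id]
        rec = self.tree.cells[cell_id]
        ser: PhenotypeSeries | None
        try:
            if self.phenotype == "fluorescence":
                if self.channel is None or self.channel not in rec.samples.fluor:
                    ser = None
                else:
                    ser = PhenotypeSeries(
                        cell_id, rec.samples.time, rec.samples.fluor[self.channel])
            elif self.phenotype == "growth_rate":
                ser = growth_rate_series(rec, self.window_frames)
            else:  # promoter_activity
                growth = growth_rate_series(rec, self.window_frames)
                fl = PhenotypeSeries(
                    cell_id, rec.samples.time, rec.samples.fluor[self.channel])
                ser = promoter_activity_series(fl, growth)
        except (EstimationError, AlignmentError, KeyError):
            ser = None
        self._series[cell_id] = ser
        return ser

    def at(self, cell_id: str, t: float) -> float:
        ser = self.series(cell_id)
        return math.nan if ser is None else ser.value_nearest(t)

    def values_at(self, t: float, cell_ids=None) -> dict[str, float]:
        """Phenotype value at the frame nearest ``t`` for each (alive) cell."""
        if cell_ids is None:
            cell_ids = sorted(self.tree.cells_alive_at(t))
        return {c: self.at(c, t) for c in cell_ids}


def first_time_at_size(tree: LineageTree, n: int) -> float:
    """Earliest frame time at which the colony counts >= n cells."""
    for t in tree.frame_times():
        if tree.population_size(t) >= n:
            return float(t)
    raise DomainError(f"colony never reaches {n} cells")
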