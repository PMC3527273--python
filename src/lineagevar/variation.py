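"""Differentiation statistics for micro-colony phenotypes.

Two coefficients of variation summarise a colony at time ``t``:

* **IDCV** — the coefficient of variation across all ``N_t`` individual
  cells, irrespective of ancestry: ``sd(x) / mean(x)`` with the unbiased
  (ddof=1) standard deviation.
* **SLCV** — the *sub-lineage* coefficient of variation for a start time
  ``s``: cells at ``t`` are grouped by their ancestor alive at ``s``
  (``N_s`` groups of sizes ``n_i``), and

  .. math::  \\mathrm{SLCV} = \\sqrt{\\sum_i n_i(\\bar x_i - \\bar x)^2
              / (N_s - 1)} \\; / \\; \\bar x

  i.e. the size-weighted between-group mean square normalised by the grand
  mean (the simple mean over all ``N_t`` cells).  Under no differentiation —
  values i.i.d. across the colony, however grouped — the between-group mean
  square is an unbiased estimate of the individual variance, so SLCV and
  IDCV have the same expectation; with ``s = t`` (every group a singleton)
  SLCV equals IDCV identically.  SLCV rising above IDCV therefore flags
  lineage differentiation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, EstimationError, TestError
from .lineage import LineageTree, PhenotypeProvider, first_time_at_size

__all__ = [
    "idcv", "slcv", "between_group_cv", "VariationCurve", "variation_curves",
    "curves_to_frame", "phenotype_growth_correlation", "FateCall",
    "classify_fate", "death_commitment_time", "gmm_threshold",
]


def idcv(values) -> float:
    """Coefficient of variation among individual cells (dimensionless)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise EstimationError(f"IDCV needs >= 2 values, got {len(x)}")
    m = x.mean()
    if m <= 0:
        raise DomainError(f"IDCV undefined for non-positive mean {m}")
    return float(x.std(ddof=1) / m)


def between_group_cv(values, labels, weighted: bool = True) -> float:
    """Between-group CV of ``values`` grouped by ``labels``.

    The core SLCV estimator: size-weighted between-group mean square with
    divisor (number of groups - 1), square-rooted and divided by the grand
    mean.  ``weighted=False`` gives the unweighted-group-mean variant
    (plain CV of the group means).
    """
    x = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = np.isfinite(x)
    x, labels = x[keep], labels[keep]
    groups = [x[labels == g] for g in np.unique(labels)]
    groups = [g for g in groups if len(g) > 0]
    n_groups = len(groups)
    if n_groups < 2:
        raise EstimationError(f"SLCV needs >= 2 groups, got {n_groups}")
    grand = x.mean()
    if grand <= 0:
        raise DomainError(f"SLCV undefined for non-positive grand mean {grand}")
    means = np.array([g.mean() for g in groups])
    if weighted:
        sizes = np.array([len(g) for g in groups])
        ms = float((sizes * (means - grand) ** 2).sum() / (n_groups - 1))
    else:
        ms = float(((means - means.mean()) ** 2).sum() / (n_groups - 1))
    return math.sqrt(ms) / grand


def _grouped_values(tree, s, t, provider):
    """(values, ancestor labels) for cells alive at t, grouped by ancestry at s."""
    alive = sorted(tree.cells_alive_at(t))
    vals, labels = [], []
    for cid in alive:
        v = provider.at(cid, t)
        if not math.isfinite(v):
            continue
        labels.append(tree.ancestor_at(cid, s))
        vals.append(v)
    return np.array(vals), np.array(labels)


def slcv(
    tree: LineageTree,
    s: float,
    t: float,
    phenotype: str = "fluorescence",
    channel: str | None = None,
    weighted: bool = True,
    provider: PhenotypeProvider | None = None,
) -> float:
    """Sub-lineage CV at time ``t`` for sub-lineages rooted at time ``s``.

    Extinct sub-lineages (ancestors at ``s`` with no descendant alive at
    ``t``) are dropped with a warning, reducing the effective group count.
    """
    if provider is None:
        provider = PhenotypeProvider(tree, phenotype, channel)
    vals, labels = _grouped_values(tree, s, t, provider)
    n_start = len(tree.cells_alive_at(s))
    n_groups = len(np.unique(labels))
    if n_groups < n_start:
        warnings.warn(
            f"{n_start - n_groups} sub-lineage(s) extinct or unmeasured "
            f"between s={s} and t={t}; groups reduced", stacklevel=2)
    return between_group_cv(vals, labels, weighted=weighted)


@dataclass
class VariationCurve:
    """SLCV/IDCV trajectory for one start size ``N_s``.

    ``points`` rows are (t, N_t, slcv, idcv); for curves averaged over
    several colonies, ``N_t`` is the mean population size.
    """

    phenotype: str
    start_size: int
    start_time: float
    points: np.ndarray  # shape (n, 4): t, N_t, slcv, idcv


def variation_curves(
    trees,
    start_sizes=(4, 8, 16, 32, 64),
    phenotype: str = "fluorescence",
    channel: str | None = None,
    weighted: bool = True,
) -> list[VariationCurve]:
    """SLCV/IDCV versus time for each start size, averaged over colonies.

    For each tree and each ``N_s`` the start point ``s`` is the first frame
    at which the colony counts ``N_s`` cells; the curve is evaluated at every
    subsequent frame.  With several trees the output is the per-timepoint
    mean of the per-colony curves (curves are averaged, not cells pooled);
    time points are matched on the shared frame grid.  A colony that never
    reaches ``N_s`` is omitted from that curve with a warning.
    """
    trees = list(trees)
    out: list[VariationCurve] = []
    for n_s in start_sizes:
        per_tree: list[dict[float, tuple[float, float, float]]] = []
        s_times = []
        for tree in trees:
            try:
                s = first_time_at_size(tree, n_s)
            except DomainError:
                warnings.warn(
                    f"a colony never reaches {n_s} cells; omitted", stacklevel=2)
                continue
            provider = PhenotypeProvider(tree, phenotype, channel)
            pts: dict[float, tuple[float, float, float]] = {}
            for t in tree.frame_times():
                if t < s:
                    continue
                vals, labels = _grouped_values(tree, s, t, provider)
                if len(vals) < 2 or len(np.unique(labels)) < 2:
                    continue
                try:
                    pts[round(float(t), 6)] = (
                        float(len(vals)),
                        between_group_cv(vals, labels, weighted=weighted),
                        idcv(vals),
                    )
                except (DomainError, EstimationError):
                    continue
            per_tree.append(pts)
            s_times.append(s)
        if not per_tree:
            continue
        common = sorted(set.intersection(*[set(p) for p in per_tree]))
        rows = [
            (t,) + tuple(np.mean([p[t][j] for p in per_tree]) for j in range(3))
            for t in common
        ]
        out.append(VariationCurve(
            phenotype, int(n_s), float(np.mean(s_times)),
            np.array(rows, dtype=float)))
    return out


def curves_to_frame(curves):
    """Tidy table (phenotype, N_s, t, N_t, slcv, idcv) from VariationCurves."""
    import pandas as pd

    rows = []
    for c in curves:
        for t, n_t, sl, idv in c.points:
            rows.append((c.phenotype, c.start_size, t, n_t, sl, idv))
    return pd.DataFrame(
        rows, columns=["phenotype", "N_s", "t", "N_t", "slcv", "idcv"])


def phenotype_growth_correlation(
    tree: LineageTree,
    t: float,
    channel: str | None = None,
    window_frames: int = 5,
):
    """Per-cell (growth rate, intensity) pairs at ``t`` with both correlations.

    Returns ``(pairs, pearson_r, spearman_rho)`` where ``pairs`` is an
    (n, 2) array of (growth rate min⁻¹, intensity a.u.) for cells alive at
    the frame nearest ``t``.
    """
    growth = PhenotypeProvider(tree, "growth_rate", window_frames=window_frames)
    fluor = PhenotypeProvider(tree, "fluorescence", channel)
    pairs = []
    for cid in sorted(tree.cells_alive_at(t)):
        g, f = growth.at(cid, t), fluor.at(cid, t)
        if math.isfinite(g) and math.isfinite(f):
            pairs.append((g, f))
    pairs = np.array(pairs)
    if len(pairs) < 3:
        raise EstimationError(f"only {len(pairs)} usable cells at t={t}")
    if np.ptp(pairs[:, 0]) == 0 or np.ptp(pairs[:, 1]) == 0:
        raise TestError("correlation undefined: a vector is constant")
    r = float(stats.pearsonr(pairs[:, 0], pairs[:, 1]).statistic)
    rho = float(stats.spearmanr(pairs[:, 0], pairs[:, 1]).statistic)
    return pairs, r, rho


# ---------------------------------------------------------------------------
# Fate classification from growth-rate bimodality
# ---------------------------------------------------------------------------

@dataclass
class FateCall:
    cell_id: str
    fate: str                      # 'live' | 'dead'
    threshold: float               # min⁻¹
    commitment_time: float | None = None


def gmm_threshold(rates, random_state: int = 0) -> float:
    """Equal-posterior split point of a 2-component Gaussian mixture.

    Raises :class:`TestError` when the fitted component means are closer
    than the pooled standard deviation (no usable bimodality) — callers
    should then supply a manual threshold.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(rates, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 4:
        raise EstimationError("too few rates for a mixture fit")
    gm = GaussianMixture(n_components=2, random_state=random_state, n_init=3)
    gm.fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    w = gm.weights_.ravel()
    lo, hi = np.argsort(means)
    pooled_sd = math.sqrt(float(w[lo] * sds[lo] ** 2 + w[hi] * sds[hi] ** 2))
    if abs(means[hi] - means[lo]) < pooled_sd:
        raise TestError(
            "growth rates look unimodal (component means closer than the "
            "pooled SD); supply method='manual' with an explicit threshold")

    def post_diff(v):
        return (w[lo] * stats.norm.pdf(v, means[lo], sds[lo])
                - w[hi] * stats.norm.pdf(v, means[hi], sds[hi]))

    grid = np.linspace(means[lo], means[hi], 512)
    d = post_diff(grid)
    sign_change = np.nonzero(np.diff(np.sign(d)) != 0)[0]
    if len(sign_change):
        from scipy.optimize import brentq
        i = sign_change[0]
        return float(brentq(post_diff, grid[i], grid[i + 1]))
    return float(grid[np.argmin(np.abs(d))])


def classify_fate(
    tree: LineageTree,
    t: float,
    method: str = "gmm",
    threshold: float | None = None,
    min_arrest_minutes: float = 60.0,
    window_frames: int = 5,
) -> list[FateCall]:
    """Call live/dead for every cell alive at ``t``.

    The threshold separating the slow (death-prone) from the fast mode is
    either fitted by a two-component Gaussian mixture on the growth rates at
    ``t`` (``method='gmm'``) or supplied (``method='manual'``).  A cell is
    called dead when it never divides again and its growth rate stays below
    the threshold for at least ``min_arrest_minutes`` at the end of its
    record (prolonged growth arrest).
    """
    provider = PhenotypeProvider(tree, "growth_rate", window_frames=window_frames)
    alive = sorted(tree.cells_alive_at(t))
    if method == "gmm":
        rates = [provider.at(c, t) for c in alive]
        thr = gmm_threshold(rates)
    elif method == "manual":
        if threshold is None:
            raise ValueError("method='manual' requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown method {method!r}")

    calls = []
    for cid in alive:
        fate = "live"
        if not tree.children_of(cid):
            ser = provider.series(cid)
            if ser is not None and len(ser.values):
                below = ser.values < thr
                if below[-1]:
                    i = len(below)
                    while i > 0 and below[i - 1]:
                        i -= 1
                    arrest_span = ser.times[-1] - ser.times[i]
                    # pad by the unrated tail of the record (rates stop half a
                    # window before the last frame)
                    arrest_span += tree.cells[cid].end_time - ser.times[-1]
                    if arrest_span >= min_arrest_minutes:
                        fate = "dead"
        calls.append(FateCall(cid, fate, thr))
    return calls


def death_commitment_time(tree: LineageTree, fate_calls) -> dict[str, float]:
    """Birth time of the root of each maximal all-dead subtree.

    The root of a maximal subtree whose terminal cells all die is the last
    common ancestor committed to death; its birth time bounds when the
    commitment happened.  Returns an empty map when no cell is dead.
    """
    dead = {fc.cell_id for fc in fate_calls if fc.fate == "dead"}
    if not dead:
        return {}
    doomed: dict[str, bool] = {}

    def is_doomed(cid: str) -> bool:
        if cid in doomed:
            return doomed[cid]
        kids = tree.children_of(cid)
        d = cid in dead if not kids else all(is_doomed(k) for k in kids)
        doomed[cid] = d
        return d

    out = {}
    for cid in sorted(tree.cells):
        if is_doomed(cid):
            pid = tree.cells[cid].parent_id
            if pid is None or not is_doomed(pid):
                out[cid] = tree.cells[cid].birth_time
    return out
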