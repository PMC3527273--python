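"""Within-lineage phenotype autocorrelation and epigenetic memory half-life.

The lineage autocorrelation function AF(g) correlates a cell's phenotype at
a start time ``s`` with its descendants' phenotype ``g`` colony generations
later, where the colony-stage generation is ``floor(log2(colony size))``.
For a stable gene product made at a constant rate and diluted by exponential
growth, the concentration decorrelates at the dilution rate ln2/T_d, so AF
decays as 2^(-g) — a half-life of one generation.  Positive feedback (or any
heritable slow variable) lengthens the half-life; the linear birth–dilution
model below makes the dependence explicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, EstimationError, FitError
from .lineage import LineageTree, PhenotypeProvider

__all__ = ["AFCurve", "lineage_af", "fit_halflife", "linear_model_halflife",
           "average_af_curves"]


@dataclass
class AFCurve:
    """Lineage autocorrelation versus generations elapsed from ``start_time``.

    ``points`` rows are (g, af, n_pairs); ``halflife`` (generations) is
    attached by :func:`fit_halflife`.
    """

    start_time: float
    phenotype: str
    points: np.ndarray               # shape (n, 3): g, af, n_pairs
    halflife: float | None = None
    stage_times: np.ndarray | None = None   # evaluation time of each point

    def stage_duration(self) -> float:
        """Mean minutes per colony-stage generation along this curve.

        A stage increments only when the last division of a wave
        completes, so it runs slightly longer than the single-cell
        doubling time; multiply the fitted half-life (generations) by this
        to get minutes.
        """
        if self.stage_times is None or len(self.stage_times) < 2:
            raise EstimationError("no stage times recorded on this curve")
        return float(np.mean(np.diff(self.stage_times)))


def lineage_af(
    tree: LineageTree,
    s: float,
    phenotype: str = "fluorescence",
    channel: str | None = None,
    min_pairs: int = 16,
    max_g: int | None = None,
    weighting: str = "descendant",
    provider: PhenotypeProvider | None = None,
) -> AFCurve:
    """Lineage autocorrelation function from start time ``s``.

    For each generation lag ``g`` the evaluation time ``t_g`` is the first
    frame at which the colony-stage generation has advanced by ``g`` from
    its value at ``s``.  Every cell ``d`` alive at ``t_g`` is paired with
    its unique ancestor ``a`` alive at ``s``; AF(g) is the Pearson
    correlation over pairs of (phenotype of ``a`` at ``s``, phenotype of
    ``d`` at ``t_g``).  Points with fewer than ``min_pairs`` pairs are
    omitted (small-sample truncation).

    ``weighting='descendant'`` (default) weights every pair equally, which
    repeats prolific ancestors; ``weighting='ancestor'`` first averages the
    descendants of each ancestor so each sub-lineage counts once.
    """
    if provider is None:
        provider = PhenotypeProvider(tree, phenotype, channel)
    if weighting not in ("descendant", "ancestor"):
        raise ValueError(f"unknown weighting {weighting!r}")
    g0 = tree.colony_stage_generation(s)
    frame_t = tree.frame_times()
    frame_t = frame_t[frame_t >= s - 1e-9]
    stages = np.array([tree.colony_stage_generation(t) for t in frame_t])

    anc_value: dict[str, float] = {
        cid: provider.at(cid, s) for cid in tree.cells_alive_at(s)}
    pts = []
    t_points = []
    g = 0
    while True:
        if max_g is not None and g > max_g:
            break
        idx = np.nonzero(stages >= g0 + g)[0]
        if len(idx) == 0:
            break
        t_g = float(frame_t[idx[0]])
        xs, ys, anc_ids = [], [], []
        for d in sorted(tree.cells_alive_at(t_g)):
            try:
                a = tree.ancestor_at(d, s)
            except DomainError:
                continue
            x, y = anc_value.get(a, math.nan), provider.at(d, t_g)
            if math.isfinite(x) and math.isfinite(y):
                xs.append(x)
                ys.append(y)
                anc_ids.append(a)
        n_pairs = len(xs)
        if n_pairs >= min_pairs:
            x = np.array(xs)
            y = np.array(ys)
            if weighting == "ancestor":
                uniq = sorted(set(anc_ids))
                lab = np.array([uniq.index(a) for a in anc_ids])
                x = np.array([x[lab == i].mean() for i in range(len(uniq))])
                y = np.array([y[lab == i].mean() for i in range(len(uniq))])
            if x.std() == 0 or y.std() == 0:
                raise EstimationError(
                    f"zero phenotype variance at g={g}; AF undefined")
            af = float(np.corrcoef(x, y)[0, 1])
            pts.append((g, af, n_pairs))
            t_points.append(t_g)
        g += 1
    return AFCurve(float(s), provider.phenotype,
                   np.array(pts, dtype=float).reshape(-1, 3),
                   stage_times=np.array(t_points))


def fit_halflife(af_curve: AFCurve, floor: float = 0.1,
                 skip_zero_lag: bool = False) -> float:
    """Exponential half-life of an AF curve, in generations.

    Least-squares slope of log2(AF) versus g over the points with
    AF > ``floor`` (log of near-zero or negative correlations is
    meaningless); half-life = -1/slope.  Multiply by the doubling time for
    minutes.  The fitted value is also stored on ``af_curve.halflife``.

    ``skip_zero_lag=True`` drops the g = 0 point before fitting.  Estimated
    correlations at g >= 1 share a roughly constant multiplicative
    attenuation (the finite number of ancestors clusters the pairs), which
    the fitted intercept absorbs — but only if the exact, unattenuated
    AF(0) = 1 does not anchor the line.  Use it when at least three g >= 1
    points are available.
    """
    pts = af_curve.points
    if skip_zero_lag:
        pts = pts[pts[:, 0] > 0]
    use = pts[pts[:, 1] > floor]
    if len(use) < 3:
        raise FitError(
            f"only {len(use)} AF points above floor {floor}; need >= 3")
    slope = np.polyfit(use[:, 0], np.log2(use[:, 1]), 1)[0]
    if slope >= 0:
        raise FitError(f"non-decaying AF (slope {slope:.3g}); no finite half-life")
    af_curve.halflife = float(-1.0 / slope)
    return af_curve.halflife


def average_af_curves(curves) -> AFCurve:
    """Pointwise mean of AF curves over colonies, matched on g.

    Only lags present in every curve are kept; n_pairs are summed.
    """
    curves = list(curves)
    if not curves:
        raise EstimationError("no AF curves to average")
    common = set(curves[0].points[:, 0])
    for c in curves[1:]:
        common &= set(c.points[:, 0])
    rows = []
    times = []
    for g in sorted(common):
        afs = [c.points[c.points[:, 0] == g, 1][0] for c in curves]
        ns = [c.points[c.points[:, 0] == g, 2][0] for c in curves]
        rows.append((g, float(np.mean(afs)), float(np.sum(ns))))
        per_curve_t = [
            c.stage_times[np.nonzero(c.points[:, 0] == g)[0][0]]
            for c in curves if c.stage_times is not None]
        if per_curve_t:
            times.append(float(np.mean(per_curve_t)))
    return AFCurve(
        float(np.mean([c.start_time for c in curves])),
        curves[0].phenotype, np.array(rows, dtype=float).reshape(-1, 3),
        stage_times=np.array(times) if len(times) == len(rows) else None)


def linear_model_halflife(
    doubling_time: float, extra_decay: float = 0.0, feedback_gain: float = 0.0
) -> float:
    """Autocorrelation half-life of the linear birth–dilution model, minutes.

    A gene product made at a constant rate, diluted by growth at
    ln2/T_d, degraded at ``extra_decay`` and self-promoted with linearised
    feedback gain ``feedback_gain`` relaxes at

        gamma = ln2/T_d + extra_decay - feedback_gain   [min^-1]

    and its autocorrelation decays as exp(-gamma·t), giving a half-life of
    ln2/gamma.  With no degradation and no feedback this is exactly the
    doubling time; feedback approaching the critical value gamma -> 0 makes
    the memory arbitrarily long.
    """
    if doubling_time <= 0:
        raise DomainError("doubling_time must be positive")
    gamma = math.log(2) / doubling_time + extra_decay - feedback_gain
    if gamma <= 0:
        raise DomainError(
            f"effective relaxation rate {gamma:.3g} <= 0: memory never decays")
    return math.log(2) / gamma
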