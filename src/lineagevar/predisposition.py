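"""Pre-disposition tests on lineage trees.

A *pre-disposition node* is a division that occurred before stress induction
whose two sister sub-lineages end up with significantly different phenotype
distributions — evidence that the sisters already differed when they were
born.  This module provides:

* the per-node Welch two-sample test on the sisters' descendant groups,
* a progeny re-assignment null (randomly re-splitting the pooled
  descendants into groups of the original sizes),
* the combinatorial probability of observing a tree with a given number of
  significant nodes,
* an exact binomial test for a direction bias (does the brighter sister
  produce the more stressed progeny?),
* the same-generation lineage-switch randomization that scrambles ancestry
  while preserving every measured value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, RandomizationError, TestError
from .lineage import LineageTree, PhenotypeProvider

__all__ = [
    "NodeTestResult", "node_progeny_test", "randomized_node_test",
    "tree_probability", "bias_binomial_test", "lineage_switch_randomization",
    "pre_induction_nodes",
]

BRIGHTER_MORE = "brighter_sister_more_stressed"
BRIGHTER_LESS = "brighter_sister_less_stressed"


@dataclass
class NodeTestResult:
    node_id: str
    t_stat: float
    p_value: float
    direction: str | None              # set only when p_value < alpha
    rand_sig_fraction: float | None = None


def pre_induction_nodes(tree: LineageTree) -> list[str]:
    """Ids of cells that divided before the induction time.

    Without a recorded induction time every divided cell qualifies.
    """
    t_ind = tree.induction_time
    return [
        cid for cid in sorted(tree.cells)
        if tree.cells[cid].end_state == "divided"
        and (t_ind is None or tree.cells[cid].end_time <= t_ind)
    ]


def _descendant_values(tree, root_id, t_end, provider):
    vals = [
        provider.at(cid, t_end)
        for cid in tree.subtree_ids(root_id)
        if tree.cells[cid].alive_at(t_end)
    ]
    return np.array([v for v in vals if math.isfinite(v)])


def _welch(a, b, equal_var=False):
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def node_progeny_test(
    tree: LineageTree,
    node_id: str,
    t_end: float,
    phenotype: str = "fluorescence",
    channel: str | None = None,
    alpha: float = 0.01,
    equal_var: bool = False,
    provider: PhenotypeProvider | None = None,
) -> NodeTestResult:
    """Welch T-test between the two sisters' descendant groups at ``t_end``.

    The node must have divided before induction (when an induction time is
    recorded) and each sister needs >= 2 measured descendants alive at
    ``t_end``.  The direction compares the sisters' own fluorescence at
    birth with which descendant group is more stressed (higher fluorescence,
    or lower growth rate when the phenotype is growth rate).
    """
    rec = tree.cells[node_id]
    if rec.end_state != "divided":
        raise TestError(f"node {node_id} did not divide")
    if tree.induction_time is not None and rec.end_time > tree.induction_time:
        raise DomainError(
            f"node {node_id} divided at {rec.end_time}, after induction "
            f"({tree.induction_time}); only pre-induction nodes are tested")
    if provider is None:
        provider = PhenotypeProvider(tree, phenotype, channel)
    s1, s2 = tree.children_of(node_id)
    g1 = _descendant_values(tree, s1, t_end, provider)
    g2 = _descendant_values(tree, s2, t_end, provider)
    if len(g1) < 2 or len(g2) < 2:
        raise TestError(
            f"node {node_id}: descendant groups of sizes {len(g1)}/{len(g2)} "
            f"(need >= 2 each)")
    if g1.var() == 0 and g2.var() == 0:
        if g1.mean() == g2.mean():
            return NodeTestResult(node_id, 0.0, 1.0, None)
        raise TestError(f"node {node_id}: both groups have zero variance")
    t_stat, p = _welch(g1, g2, equal_var=equal_var)

    direction = None
    if p < alpha:
        fluor = PhenotypeProvider(tree, "fluorescence", channel)
        # the sisters' own expression, averaged over their lives: at birth
        # the two are near-identical (contents split with volume), so the
        # informative signal is what each accumulates before dividing
        ser1, ser2 = fluor.series(s1), fluor.series(s2)
        b1 = float(np.nanmean(ser1.values)) if ser1 is not None else math.nan
        b2 = float(np.nanmean(ser2.values)) if ser2 is not None else math.nan
        brighter_is_1 = b1 >= b2
        if provider.phenotype == "growth_rate":
            stressed_is_1 = g1.mean() < g2.mean()   # slower = more stressed
        else:
            stressed_is_1 = g1.mean() > g2.mean()
        direction = BRIGHTER_MORE if brighter_is_1 == stressed_is_1 else BRIGHTER_LESS
    return NodeTestResult(node_id, t_stat, p, direction)


def randomized_node_test(
    tree: LineageTree,
    node_id: str,
    t_end: float,
    phenotype: str = "fluorescence",
    channel: str | None = None,
    n_rand: int = 500,
    alpha: float = 0.01,
    seed: int | np.random.Generator | None = None,
    provider: PhenotypeProvider | None = None,
) -> float:
    """Fraction of progeny re-assignments that reach Welch p < alpha.

    Pools both sisters' descendant values at ``t_end`` and, ``n_rand``
    times, re-splits them at random (without replacement) into groups of
    the original sizes.  Exchangeability makes the null true by
    construction, so the fraction estimates the per-node false-positive
    rate of the T-test on these data.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if provider is None:
        provider = PhenotypeProvider(tree, phenotype, channel)
    s1, s2 = tree.children_of(node_id)
    g1 = _descendant_values(tree, s1, t_end, provider)
    g2 = _descendant_values(tree, s2, t_end, provider)
    if len(g1) < 2 or len(g2) < 2:
        raise TestError(
            f"node {node_id}: descendant groups of sizes {len(g1)}/{len(g2)}")
    pooled = np.concatenate([g1, g2])
    n1, n = len(g1), len(pooled)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    order = np.argsort(rng.random((n_rand, n)), axis=1)
    shuffled = pooled[order]
    a, b = shuffled[:, :n1], shuffled[:, n1:]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2_1, se2_2 = v1 / n1, v2 / (n - n1)
    denom = np.sqrt(se2_1 + se2_2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
        df = (se2_1 + se2_2) ** 2 / (
            se2_1 ** 2 / (n1 - 1) + se2_2 ** 2 / (n - n1 - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[~np.isfinite(p)] = 1.0
    return float(np.mean(p < alpha))


def tree_probability(n_nodes: int, n_sig: int, p_node: float,
                     mode: str = "paper") -> float:
    """Chance probability of ``n_sig`` significant nodes out of ``n_nodes``.

    ``mode='paper'`` uses the bare product C(n, k)·p^k; the omitted
    (1-p)^(n-k) factor is negligible for small per-node rates (at p = 0.02
    it changes the result by a few percent).  ``mode='binomial_tail'`` is
    the exact upper tail P[X >= k] for X ~ Binomial(n, p).
    """
    if not (0 <= n_sig <= n_nodes):
        raise DomainError(f"need 0 <= n_sig ({n_sig}) <= n_nodes ({n_nodes})")
    if not (0.0 <= p_node <= 1.0):
        raise DomainError(f"p_node {p_node} outside [0, 1]")
    if mode == "paper":
        return float(math.comb(n_nodes, n_sig) * p_node ** n_sig)
    if mode == "binomial_tail":
        return float(stats.binom.sf(n_sig - 1, n_nodes, p_node))
    raise ValueError(f"unknown mode {mode!r}")


def bias_binomial_test(events, alternative: str = "greater") -> float:
    """Exact binomial p-value for a direction bias among significant nodes.

    ``events`` are direction strings; the test counts how often the brighter
    sister founded the more stressed sub-lineage against P = 1/2.  One-sided
    ('greater') by default, matching the directional hypothesis; pass
    ``alternative='two-sided'`` for the agnostic version.
    """
    events = list(events)
    if not events:
        raise TestError("no direction events to test")
    k = sum(e == BRIGHTER_MORE for e in events)
    return float(stats.binomtest(k, len(events), 0.5,
                                 alternative=alternative).pvalue)


def lineage_switch_randomization(
    tree: LineageTree,
    n_pairs: int,
    seed: int | np.random.Generator | None = None,
    mode: str = "subtree",
) -> LineageTree:
    """Scramble ancestry by swapping same-generation post-induction cells.

    ``n_pairs`` times, two distinct cells born after induction and of equal
    (division-count) generation are drawn and exchanged.  In ``mode=
    'subtree'`` the cells swap positions in the tree (each keeps its own
    descendants and measurements) by exchanging their parents; because
    same-generation cells are not born at exactly the same minute, the
    mother-end == daughter-birth identity is relaxed in the output
    (validated with ``strict_division_times=False``).  In ``mode='values'``
    the topology is untouched and the two cells exchange their fluorescence
    values at shared frame times instead.  Either way the multiset of
    per-frame measurements — hence IDCV at every time point — is untouched,
    while the lineage association of values (hence SLCV) is randomized.
    """
    if tree.induction_time is None:
        raise RandomizationError("tree has no induction time")
    if mode not in ("subtree", "values"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    new = tree.copy()
    by_gen: dict[int, list[str]] = {}
    for cid in sorted(new.cells):
        if new.cells[cid].birth_time > tree.induction_time:
            by_gen.setdefault(new.generation_of(cid), []).append(cid)
    eligible_gens = [g for g, cells in sorted(by_gen.items()) if len(cells) >= 2]
    if not eligible_gens:
        raise RandomizationError(
            "no generation holds >= 2 post-induction cells")
    weights = np.array([len(by_gen[g]) for g in eligible_gens], dtype=float)
    weights /= weights.sum()
    for _ in range(n_pairs):
        g = eligible_gens[rng.choice(len(eligible_gens), p=weights)]
        i, j = rng.choice(len(by_gen[g]), size=2, replace=False)
        a, b = by_gen[g][i], by_gen[g][j]
        ra, rb = new.cells[a], new.cells[b]
        if mode == "subtree":
            ra.parent_id, rb.parent_id = rb.parent_id, ra.parent_id
        else:
            ta = np.round(ra.samples.time, 9)
            tb = np.round(rb.samples.time, 9)
            _, ia, ib = np.intersect1d(ta, tb, return_indices=True)
            for ch in set(ra.samples.fluor) & set(rb.samples.fluor):
                va, vb = ra.samples.fluor[ch], rb.samples.fluor[ch]
                va[ia], vb[ib] = vb[ib].copy(), va[ia].copy()
    new._rebuild_children()
    new.validate(strict_division_times=mode == "values")
    return new
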