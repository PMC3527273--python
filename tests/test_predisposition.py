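import itertools
import math

import numpy as np
import pytest
from scipy import stats

from lineagevar import (
    bias_binomial_test,
    get_params,
    lineage_switch_randomization,
    node_progeny_test,
    pre_induction_nodes,
    randomized_node_test,
    simulate_tree,
    slcv,
    tree_probability,
    write_tracking_table,
)
from lineagevar import idcv, first_time_at_size
from lineagevar.errors import DomainError, RandomizationError
from lineagevar.errors import TestError as StatTestError
from lineagevar.lineage import PhenotypeProvider
from lineagevar.predisposition import BRIGHTER_MORE, BRIGHTER_LESS

from conftest import FRAME, make_cell
from lineagevar import LineageTree


def two_family_tree(values_b, values_c, fluor_b=80.0, fluor_c=120.0):
    """Founder A -> sisters B, C; each sister -> a fan of leaf grandchildren.

    ``values_b``/``values_c`` are the leaves' constant fluorescence values,
    the quantities compared by the node test at the final time.
    """
    cells = {"A": make_cell("A", None, 0.0, 10, "divided", end_time=15.0)}
    cells["B"] = make_cell("B", "A", 15.0, 10, "divided", end_time=30.0,
                           fluor=fluor_b)
    cells["C"] = make_cell("C", "A", 15.0, 10, "divided", end_time=30.0,
                           fluor=fluor_c)
    # chain-divide to hang len(values) leaves under each sister
    def fan(parent, prefix, values):
        n = len(values)
        for i, v in enumerate(values):
            if i < n - 1:
                inner = f"{prefix}i{i}"
                birth = 30.0 + 3.0 * i
                cells[inner] = make_cell(inner, parent, birth, 2, "divided",
                                         end_time=birth + 3.0, fluor=v)
                leaf_parent, leaf_birth = inner, birth + 3.0
                cells[f"{prefix}{i}"] = make_cell(
                    f"{prefix}{i}", inner, leaf_birth,
                    int((60.0 - leaf_birth) / FRAME) + 1, "censored", fluor=v)
                parent = inner
            else:
                birth = 30.0 + 3.0 * (n - 1)
                cells[f"{prefix}{i}"] = make_cell(
                    f"{prefix}{i}", parent, birth,
                    int((60.0 - birth) / FRAME) + 1, "censored", fluor=v)
    fan("B", "b", values_b)
    fan("C", "c", values_c)
    return LineageTree(cells, "A", induction_time=20.0, frame_interval=FRAME)


class TestNodeProgenyTest:
    def test_identical_groups_give_t0_p1(self):
        tree = two_family_tree([10, 10, 10], [10, 10, 10])
        res = node_progeny_test(tree, "A", 60.0)
        assert res.t_stat == 0.0
        assert res.p_value == 1.0
        assert res.direction is None

    def test_matches_textbook_welch_oracle(self):
        a, b = [10.0, 11.0, 10.0, 11.0], [30.0, 31.0, 30.0, 31.0]
        tree = two_family_tree(a, b)
        res = node_progeny_test(tree, "A", 60.0)
        # textbook Welch formulas, coded independently
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        t = (ma - mb) / math.sqrt(va / 4 + vb / 4)
        df = (va / 4 + vb / 4) ** 2 / (
            (va / 4) ** 2 / 3 + (vb / 4) ** 2 / 3)
        p = 2 * stats.t.sf(abs(t), df)
        assert res.t_stat == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert res.p_value < 0.01

    def test_direction_brighter_sister_more_stressed(self):
        # sister C is brighter at birth and its progeny are more fluorescent
        tree = two_family_tree([10, 11, 10, 11], [30, 31, 30, 31],
                               fluor_b=80.0, fluor_c=120.0)
        assert node_progeny_test(tree, "A", 60.0).direction == BRIGHTER_MORE
        # flip the sisters' own birth fluorescence: now the dimmer sister
        # has the more stressed progeny
        tree2 = two_family_tree([10, 11, 10, 11], [30, 31, 30, 31],
                                fluor_b=120.0, fluor_c=80.0)
        assert node_progeny_test(tree2, "A", 60.0).direction == BRIGHTER_LESS

    def test_post_induction_node_is_rejected(self):
        tree = two_family_tree([10, 11, 10, 11], [30, 31, 30, 31])
        with pytest.raises(DomainError, match="after induction"):
            node_progeny_test(tree, "B", 60.0)

    def test_degenerate_group_raises(self):
        tree = two_family_tree([10.0], [30, 31, 30])
        with pytest.raises(StatTestError, match="need >= 2"):
            node_progeny_test(tree, "A", 60.0)

    def test_stressed_trees_have_significant_preinduction_nodes(
            self, stressed_trees):
        n_sig = n_tot = 0
        for tree in stressed_trees:
            t_end = float(tree.frame_times()[-1])
            prov = PhenotypeProvider(tree, "fluorescence")
            for node in pre_induction_nodes(tree):
                try:
                    res = node_progeny_test(tree, node, t_end, provider=prov)
                except StatTestError:
                    continue
                n_tot += 1
                n_sig += res.p_value < 0.01
        assert n_tot >= 10
        assert n_sig > 0


class TestRandomizedNodeTest:
    def test_null_rate_approaches_alpha(self, null_tree):
        t_end = float(null_tree.frame_times()[-1])
        frac = randomized_node_test(null_tree, null_tree.founder_id, t_end,
                                    n_rand=4000, alpha=0.05, seed=0)
        se = math.sqrt(0.05 * 0.95 / 4000)
        # exchangeable null by construction; allow permutation-t slack
        assert abs(frac - 0.05) < 6 * se

    def test_reassignment_destroys_a_planted_effect(self):
        # effect size ~10 pooled SD between the sisters' progenies
        rng = np.random.default_rng(0)
        a = list(10.0 + rng.normal(0, 1, 8))
        b = list(40.0 + rng.normal(0, 1, 8))
        tree = two_family_tree(a, b)
        assert node_progeny_test(tree, "A", 60.0).p_value < 1e-6
        frac = randomized_node_test(tree, "A", 60.0, n_rand=2000,
                                    alpha=0.01, seed=1)
        assert frac < 0.05

    def test_n_rand_validation(self, null_tree):
        with pytest.raises(ValueError):
            randomized_node_test(null_tree, null_tree.founder_id, 100.0,
                                 n_rand=0)


class TestTreeProbability:
    def test_paper_formula_reproduces_printed_number(self):
        p = tree_probability(15, 12, 0.02, "paper")
        assert p == pytest.approx(455 * 0.02 ** 12, rel=1e-12)
        assert p == pytest.approx(1.86e-18, rel=0.01)
        # printed to one significant figure: 2E-18
        assert float(f"{p:.0e}") == 2e-18

    def test_certain_outcome_is_one(self):
        assert tree_probability(5, 5, 1.0, "paper") == 1.0
        assert tree_probability(5, 5, 1.0, "binomial_tail") == 1.0

    @pytest.mark.parametrize("n,k,p", [(4, 2, 0.3), (7, 5, 0.02),
                                       (12, 3, 0.5), (9, 0, 0.1)])
    def test_binomial_tail_matches_exhaustive_enumeration(self, n, k, p):
        total = 0.0
        for outcome in itertools.product((0, 1), repeat=n):
            s = sum(outcome)
            if s >= k:
                total += p ** s * (1 - p) ** (n - s)
        assert tree_probability(n, k, p, "binomial_tail") == pytest.approx(
            total, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            tree_probability(5, 6, 0.5)
        with pytest.raises(DomainError):
            tree_probability(5, 2, 1.5)


class TestBiasBinomialTest:
    def test_unanimous_ten_events_closed_form(self):
        p = bias_binomial_test([BRIGHTER_MORE] * 10)
        assert p == pytest.approx(2.0 ** -10, rel=1e-12)

    def test_nine_of_eleven_matches_enumeration(self):
        events = [BRIGHTER_MORE] * 9 + [BRIGHTER_LESS] * 2
        total = sum(1 for o in itertools.product((0, 1), repeat=11)
                    if sum(o) >= 9) / 2 ** 11
        assert bias_binomial_test(events) == pytest.approx(total, rel=1e-12)

    def test_empty_event_list_is_an_error(self):
        with pytest.raises(StatTestError):
            bias_binomial_test([])

    def test_stressed_trees_show_direction_bias(self, stressed_params,
                                                stressed_trees):
        # the bias is a per-node event; pool enough colonies to accumulate
        # a meaningful number of significant pre-induction nodes
        forest = list(stressed_trees) + [
            simulate_tree(stressed_params, seed=s) for s in range(9, 21)]
        events = []
        for tree in forest:
            t_end = float(tree.frame_times()[-1])
            prov = PhenotypeProvider(tree, "fluorescence")
            for node in pre_induction_nodes(tree):
                try:
                    res = node_progeny_test(tree, node, t_end, provider=prov)
                except StatTestError:
                    continue
                if res.direction is not None:
                    events.append(res.direction)
        assert len(events) >= 5
        assert bias_binomial_test(events) < 0.05


class TestLineageSwitchRandomization:
    def test_zero_pairs_is_identity(self, stressed_tree, tmp_path):
        rnd = lineage_switch_randomization(stressed_tree, 0, seed=0)
        f1, f2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_tracking_table(stressed_tree, f1)
        write_tracking_table(rnd, f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_preserves_generations_lifetimes_and_values(self, stressed_tree):
        rnd = lineage_switch_randomization(stressed_tree, 250, seed=3)
        gens0 = sorted(stressed_tree.generation_of(c)
                       for c in stressed_tree.cells)
        gens1 = sorted(rnd.generation_of(c) for c in rnd.cells)
        assert gens0 == gens1
        for cid in stressed_tree.cells:
            r0, r1 = stressed_tree.cells[cid], rnd.cells[cid]
            assert r0.end_time - r0.birth_time == pytest.approx(
                r1.end_time - r1.birth_time)
            assert np.array_equal(r0.samples.fluor["yfp"],
                                  r1.samples.fluor["yfp"])

    def test_idcv_invariant_and_slcv_collapses(self, stressed_trees):
        import warnings

        excess0, excess_r, spreads = [], [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for tree in stressed_trees:
                te = float(tree.frame_times()[-1])
                prov = PhenotypeProvider(tree, "fluorescence")
                s = first_time_at_size(tree, 8)
                sl0 = slcv(tree, s, te, provider=prov)
                idv = idcv([v for v in prov.values_at(te).values()
                            if math.isfinite(v)])
                n = tree.population_size(te)
                sls = []
                for k in range(4):
                    rnd = lineage_switch_randomization(tree, n, seed=k)
                    sls.append(slcv(rnd, s, te))
                    vals_r = [v for v in PhenotypeProvider(
                        rnd, "fluorescence").values_at(te).values()
                        if math.isfinite(v)]
                    assert idcv(vals_r) == pytest.approx(idv, rel=1e-12)
                excess0.append(sl0 - idv)
                excess_r.append(np.mean(sls) - idv)
                spreads.append(np.std(sls))
        # differentiated colonies before randomization...
        assert np.mean(excess0) > 0
        # ...and after switching the excess collapses: most of it disappears
        # and what remains is within the randomization sampling spread
        assert np.mean(excess_r) < 0.6 * np.mean(excess0)
        assert abs(np.mean(excess_r)) <= 2.0 * np.mean(spreads)

    def test_values_mode_also_preserves_idcv(self, stressed_tree):
        te = float(stressed_tree.frame_times()[-1])
        prov = PhenotypeProvider(stressed_tree, "fluorescence")
        idv = idcv([v for v in prov.values_at(te).values()
                    if math.isfinite(v)])
        rnd = lineage_switch_randomization(stressed_tree, 100, seed=1,
                                           mode="values")
        vals = [v for v in PhenotypeProvider(rnd, "fluorescence")
                .values_at(te).values() if math.isfinite(v)]
        assert idcv(vals) == pytest.approx(idv, rel=1e-12)

    def test_requires_induction_time(self, null_tree):
        with pytest.raises(RandomizationError):
            lineage_switch_randomization(null_tree, 10, seed=0)
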