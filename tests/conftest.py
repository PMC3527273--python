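import math

import numpy as np
import pytest

from lineagevar import LineageTree, SampleTable, get_params, simulate_tree
from lineagevar.lineage import CellRecord

FRAME = 1.5


def make_cell(cid, parent, birth, n_frames, end_state, *, rate=0.02,
              length0=1.75, fluor=100.0, end_time=None, x=0.0, y=0.0):
    """A cell with exponential length growth and constant fluorescence."""
    t = birth + FRAME * np.arange(n_frames)
    length = length0 * np.exp(rate * (t - birth))
    if end_time is None:
        end_time = t[-1] + FRAME
    return CellRecord(
        cid, parent, birth, end_time, end_state,
        SampleTable(t, length, np.full(n_frames, x), np.full(n_frames, y),
                    {"yfp": np.full(n_frames, float(fluor))}))


def three_generation_tree():
    """Founder A divides at 15 into B,C; B divides at 30 into D,E."""
    cells = {}
    cells["A"] = make_cell("A", None, 0.0, 10, "divided", end_time=15.0)
    cells["B"] = make_cell("B", "A", 15.0, 10, "divided", end_time=30.0,
                           fluor=80.0)
    cells["C"] = make_cell("C", "A", 15.0, 20, "censored", fluor=120.0)
    cells["D"] = make_cell("D", "B", 30.0, 10, "censored", fluor=70.0)
    cells["E"] = make_cell("E", "B", 30.0, 10, "censored", fluor=90.0)
    return LineageTree(cells, "A", induction_time=None, frame_interval=FRAME)


@pytest.fixture
def three_gen_tree():
    return three_generation_tree()


def caterpillar_tree(leaf_positions, t_final=30.0):
    """A caterpillar lineage whose leaves sit at the given (x, y) points.

    Internal cell i lives [3(i-1), 3i); leaf i is born at 3i and survives to
    t_final.  Geometry fixtures only — lengths/fluorescence are nominal.
    """
    n = len(leaf_positions)
    cells = {}
    for i in range(1, n):
        pid = None if i == 1 else f"i{i - 1}"
        cells[f"i{i}"] = make_cell(f"i{i}", pid, 3.0 * (i - 1), 2, "divided",
                                   end_time=3.0 * i)
    for i, (x, y) in enumerate(leaf_positions, start=1):
        birth = 3.0 * min(i, n - 1)
        nf = int((t_final - birth) / FRAME) + 1
        pid = f"i{i}" if i < n else f"i{n - 1}"
        cells[f"L{i}"] = make_cell(f"L{i}", pid, birth, nf, "censored",
                                   x=x, y=y)
    return LineageTree(cells, "i1", induction_time=None, frame_interval=FRAME)


@pytest.fixture(scope="session")
def null_params():
    return get_params("null")


@pytest.fixture(scope="session")
def null_tree(null_params):
    return simulate_tree(null_params, seed=11)


@pytest.fixture(scope="session")
def small_null_trees():
    p = get_params("null", max_colony_size=70, t_max=180.0)
    return [simulate_tree(p, seed=s) for s in range(101, 109)]


@pytest.fixture(scope="session")
def stressed_params():
    return get_params("stressed")


@pytest.fixture(scope="session")
def stressed_tree(stressed_params):
    return simulate_tree(stressed_params, seed=5)


@pytest.fixture(scope="session")
def stressed_trees(stressed_params):
    return [simulate_tree(stressed_params, seed=s) for s in range(1, 9)]
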