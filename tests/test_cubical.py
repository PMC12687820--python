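"""Topology oracle suite.

The independent reference is a brute-force threshold-labeling oracle:
at every distinct intensity t, Betti numbers of the sublevel set are
counted directly with scipy.ndimage component labeling (4-connected
components; holes as 8-connected superlevel components that avoid the
border).  Diagrams from boundary-matrix reduction, the union-find fast
paths, and this oracle must all agree.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import ndimage

from topobow import cubical
from topobow.phantoms import make_topology_fixture

S4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
S8 = np.ones((3, 3), dtype=int)


def betti_numbers_brute(grid: np.ndarray, t: float) -> tuple[int, int]:
    """(b0, b1) of the sublevel set at t, by direct component labeling."""
    sub = grid <= t
    b0 = ndimage.label(sub, structure=S4)[1] if sub.any() else 0
    lab, n = ndimage.label(~sub, structure=S8)
    border = set(np.unique(np.r_[lab[0], lab[-1], lab[:, 0], lab[:, -1]]))
    b1 = n - len(border - {0})
    return b0, b1


def betti_from_diagram(dgm: cubical.PersistenceDiagram, dim: int, t: float) -> int:
    pts = dgm.in_dim(dim)
    if len(pts) == 0:
        return 0
    return int(np.sum((pts[:, 0] <= t) & (t < pts[:, 1])))


small_grids = arrays(
    dtype=np.int64,
    shape=st.tuples(st.integers(2, 10), st.integers(2, 10)),
    elements=st.integers(0, 7),
)


class TestBuildComplex:
    def test_two_by_two_grid_has_nine_cells(self):
        cx = cubical.build_complex(np.array([[1, 2], [3, 4]]))
        assert cx.n_cells == 9
        dims = [cx.cell_dim(i, j) for i in range(3) for j in range(3)]
        assert dims.count(0) == 4 and dims.count(1) == 4 and dims.count(2) == 1

    def test_cell_count_formula(self, rng):
        for _ in range(5):
            r, c = rng.integers(2, 12, size=2)
            cx = cubical.build_complex(rng.integers(0, 9, size=(r, c)))
            assert cx.n_cells == (2 * r - 1) * (2 * c - 1)

    def test_constant_grid_constant_filtration(self):
        cx = cubical.build_complex(np.full((4, 5), 7.0))
        assert np.all(cx.values == 7.0)

    def test_monotone_filtration_random_grids(self, rng):
        """Every cell's value >= the values of all its facets."""
        for _ in range(100):
            cx = cubical.build_complex(rng.integers(0, 256, size=(8, 8)))
            n_i, n_j = cx.shape
            for i in range(n_i):
                for j in range(n_j):
                    for fi, fj in cx.boundary(i, j):
                        assert cx.values[i, j] >= cx.values[fi, fj]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            cubical.build_complex(np.empty((0, 3)))


class TestPersistenceReduction:
    def test_constant_image(self):
        dgm = cubical.persistence_reduction(
            cubical.build_complex(np.full((5, 5), 42.0)))
        assert np.array_equal(dgm.in_dim(0), [[42.0, np.inf]])
        assert len(dgm.in_dim(1)) == 0

    def test_three_disks_merge_structure(self):
        rec = make_topology_fixture("k_disks", k=3, size=48, low=50, high=200)
        dgm = cubical.persistence_reduction(
            cubical.build_complex(rec.channels["gray"]))
        pd0 = dgm.in_dim(0)
        births_at_low = pd0[pd0[:, 0] == 50]
        assert len(births_at_low) == 3
        assert np.sum(births_at_low[:, 1] == 200) == 2
        assert np.sum(np.isinf(births_at_low[:, 1])) == 1

    def test_matches_brute_force_on_random_grids(self, rng):
        """Betti curves of the reduced diagram equal direct counting."""
        for _ in range(60):
            r, c = rng.integers(3, 7, size=2)
            grid = rng.integers(0, 6, size=(r, c)).astype(float)
            dgm = cubical.persistence_reduction(cubical.build_complex(grid))
            for t in np.unique(grid):
                assert (betti_from_diagram(dgm, 0, t),
                        betti_from_diagram(dgm, 1, t)) == \
                    betti_numbers_brute(grid, t)


@pytest.fixture(scope="module")
def random_grids():
    rng = np.random.default_rng(20240901)
    grids = []
    for _ in range(220):
        r = rng.integers(6, 17)
        c = rng.integers(6, 17)
        levels = rng.integers(2, 12)
        grids.append(rng.integers(0, levels, size=(r, c)).astype(float))
    return grids


class TestOracleEquivalence:
    """All three diagram routes agree on >= 200 random grids 6x6-16x16."""

    def test_reduction_equals_fast_path_as_multisets(self, random_grids):
        for grid in random_grids:
            red = cubical.persistence_reduction(cubical.build_complex(grid))
            fast = cubical.sublevel_diagrams(grid)
            assert red.as_multiset() == fast.as_multiset()

    def test_union_find_h0_equals_reduction_dim0(self, random_grids):
        for grid in random_grids:
            red = cubical.persistence_reduction(cubical.build_complex(grid))
            uf = cubical.h0_union_find(grid)
            assert np.array_equal(red.in_dim(0), uf.in_dim(0))

    def test_fast_path_matches_threshold_oracle(self, random_grids):
        for grid in random_grids[:80]:
            dgm = cubical.sublevel_diagrams(grid)
            for t in np.unique(grid):
                assert (betti_from_diagram(dgm, 0, t),
                        betti_from_diagram(dgm, 1, t)) == \
                    betti_numbers_brute(grid, t)


class TestUnionFindH0:
    def test_two_pixel_elder_rule(self):
        dgm = cubical.h0_union_find(np.array([[10.0, 20.0]]))
        assert np.array_equal(dgm.in_dim(0), [[10.0, np.inf]])

    def test_two_disks_one_finite_point(self):
        rec = make_topology_fixture("k_disks", k=2, size=32, low=50, high=200)
        dgm = cubical.h0_union_find(rec.channels["gray"])
        pd0 = dgm.in_dim(0)
        finite = pd0[np.isfinite(pd0[:, 1])]
        assert len(finite) == 1
        assert tuple(finite[0]) == (50.0, 200.0)

    def test_exactly_one_essential_component(self, rng):
        for _ in range(20):
            grid = rng.integers(0, 30, size=(12, 12))
            pd0 = cubical.h0_union_find(grid).in_dim(0)
            assert np.sum(np.isinf(pd0[:, 1])) == 1


class TestProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(grid=small_grids)
    def test_diagram_routes_agree(self, grid):
        grid = grid.astype(float)
        red = cubical.persistence_reduction(cubical.build_complex(grid))
        fast = cubical.sublevel_diagrams(grid)
        assert red.as_multiset() == fast.as_multiset()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(grid=small_grids)
    def test_stability_under_unit_perturbation(self, grid):
        """Interleaving bound for a +/-1 pixel perturbation: since
        {f<=t-1} is contained in {g<=t} is contained in {f<=t+1}, every
        feature of f persisting across [t-1, t+1] must be alive in g at
        t, and symmetrically."""

        def n_persistent(dgm, dim, lo, hi):
            pts = dgm.in_dim(dim)
            if len(pts) == 0:
                return 0
            return int(np.sum((pts[:, 0] <= lo) & (pts[:, 1] > hi)))

        rng = np.random.default_rng(0)
        pert = (grid + rng.integers(-1, 2, size=grid.shape)).astype(float)
        d_f = cubical.sublevel_diagrams(grid.astype(float))
        d_g = cubical.sublevel_diagrams(pert)
        thresholds = np.union1d(np.unique(grid), np.unique(pert)).astype(float)
        for dim in (0, 1):
            for t in thresholds:
                assert (n_persistent(d_f, dim, t - 1, t + 1)
                        <= betti_from_diagram(d_g, dim, t))
                assert (n_persistent(d_g, dim, t - 1, t + 1)
                        <= betti_from_diagram(d_f, dim, t))

    def test_annulus_fixture_h1(self):
        for k in (1, 2, 3):
            rec = make_topology_fixture("k_annuli", k=k, size=64,
                                        low=50, high=200)
            pd1 = cubical.sublevel_diagrams(rec.channels["gray"]).in_dim(1)
            born_low = pd1[pd1[:, 0] == 50]
            assert len(born_low) == k

    def test_diagram_csv_roundtrip(self, tmp_path, rng):
        grid = rng.integers(0, 9, size=(8, 8))
        dgm = cubical.sublevel_diagrams(grid)
        path = tmp_path / "diagram.csv"
        dgm.to_csv(path)
        back = cubical.PersistenceDiagram.from_csv(path)
        assert dgm.as_multiset() == back.as_multiset()
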