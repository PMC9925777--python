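"""Cubical persistence: filtration construction, diagram correctness against
the brute-force Betti oracle, quadrant laws, and stability."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from microholes.persistence import (
    PersistenceDiagram,
    QuadrantLawError,
    build_filtration,
    compute_persistence,
    oracle_betti_curve,
    read_diagrams_csv,
    split_quadrants,
    write_diagrams_csv,
)
from microholes.sedt import SEDTField, signed_edt
from microholes.synthetic import HoleSpec, make_annulus_field, make_disk_field


def alive_counts(diag: PersistenceDiagram, delta: float) -> tuple[int, int]:
    """Number of diagram classes alive at threshold delta, per dimension."""
    a0 = int(((diag.h0[:, 0] <= delta) & (diag.h0[:, 1] > delta)).sum())
    if not diag.degenerate and diag.essential_birth <= delta:
        a0 += 1
    a1 = int(((diag.h1[:, 0] <= delta) & (diag.h1[:, 1] > delta)).sum())
    return a0, a1


class TestFiltration:
    def test_smallest_complex(self):
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        cells = build_filtration(vals)
        assert (cells["dim"].value_counts().sort_index() == [4, 4, 1]).all()
        assert cells.loc[cells["dim"] == 2, "value"].item() == 4.0

    def test_strip_has_no_squares(self):
        cells = build_filtration(np.arange(6, dtype=float).reshape(1, 6))
        counts = cells["dim"].value_counts()
        assert counts.get(0) == 6 and counts.get(1) == 5 and 2 not in counts

    def test_cell_order_matches_hand_enumeration(self, rng):
        vals = rng.permutation(9).astype(float).reshape(3, 3)
        cells = build_filtration(vals)
        assert len(cells) == 9 + 12 + 4
        # faces never precede their faces' vertices; order sorted by value
        assert (cells["value"].diff().dropna() >= 0).all()
        # every cell's value is attained at a vertex adjacent to its anchor
        for _, cell in cells.iterrows():
            i, j = int(cell["row"]), int(cell["col"])
            assert np.isclose(vals[i : i + 2, j : j + 2], cell["value"]).any()


class TestDiagramsSmall:
    def test_strip_union_find_by_hand(self):
        # values [2, 0, 3, 1]: two local minima; the union-find produces
        # n - 1 = 3 merges of which two are zero-persistence, leaving the
        # single hand-computed pair (1, 3) plus the essential class born at 0
        dg = compute_persistence(np.array([[2.0, 0.0, 3.0, 1.0]]))
        assert dg.h0.tolist() == [[1.0, 3.0]]
        assert dg.essential_birth == 0.0
        assert dg.essential_pixel == (0, 1)
        assert dg.h1.size == 0

    def test_monotone_strip_has_only_essential(self):
        dg = compute_persistence(np.array([[1.0, 2.0, 3.0, 4.0]]))
        assert dg.h0.size == 0 and dg.h1.size == 0
        assert dg.essential_birth == 1.0

    def test_annulus_gives_one_microhole_loop(self):
        patch = make_annulus_field((30, 30), outer=12, inner=6, canvas=60)
        dg = compute_persistence(signed_edt(patch))
        assert len(dg.h1) == 1
        b, d = dg.h1[0]
        assert b < 0 < d
        assert len(split_quadrants(dg)[("h1", "q2")]) == 1

    def test_ring_image_dominant_loop(self):
        # greyscale-style levelset field: a ring of low values around a
        # higher centre in a high background -> one long-lived H1 class
        vals = np.full((9, 9), 0.9)
        ii, jj = np.mgrid[0:9, 0:9]
        d = np.sqrt((ii - 4) ** 2 + (jj - 4) ** 2)
        vals[d < 2] = 0.5
        vals[(d >= 2) & (d <= 3.2)] = 0.1
        dg = compute_persistence(vals)
        pers = dg.h1[:, 1] - dg.h1[:, 0]
        assert pers.max() == pytest.approx(0.4)  # born 0.1, filled at 0.5
        assert (np.sort(pers)[:-1] < pers.max()).all()

    def test_degenerate_field_yields_flagged_empty_diagram(self):
        dg = compute_persistence(signed_edt(np.ones((5, 5), dtype=bool)))
        assert dg.degenerate
        assert dg.h0.size == 0 and dg.h1.size == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(30))
    def test_alive_counts_match_betti_numbers(self, seed):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(1, 16, size=2)
        if seed % 2:
            vals = rng.integers(-5, 6, size=(h, w)).astype(float)  # heavy ties
        else:
            vals = rng.normal(size=(h, w))
        dg = compute_persistence(vals)
        deltas = np.unique(vals)
        for delta, betti in zip(deltas, oracle_betti_curve(vals, deltas)):
            assert alive_counts(dg, delta) == betti

    def test_tie_order_does_not_change_diagram(self, rng):
        vals = rng.integers(-3, 4, size=(12, 12)).astype(float)
        dg_a = compute_persistence(vals)
        dg_b = compute_persistence(vals.T)  # transposition permutes tie order
        for pts_a, pts_b in ((dg_a.h0, dg_b.h0), (dg_a.h1, dg_b.h1)):
            a = np.sort(pts_a.view([("b", float), ("d", float)]).ravel())
            b = np.sort(pts_b.view([("b", float), ("d", float)]).ravel())
            assert np.array_equal(a, b)
        assert dg_a.essential_birth == dg_b.essential_birth


class TestQuadrants:
    def test_two_separated_disks(self):
        spec = HoleSpec(
            centers=np.array([[20.0, 20.0], [60.0, 60.0]]),
            radii=np.array([4.0, 6.0]),
            canvas=90,
        )
        patch, _ = make_disk_field(spec)
        quads = split_quadrants(compute_persistence(signed_edt(patch)))
        assert len(quads[("h0", "q2")]) == 1  # plus the essential class
        assert len(quads[("h0", "q3")]) == 0

    def test_dumbbell_hole_creates_quadrant3_point(self):
        # two overlapping disks: one connected hole with two SEDT minima
        spec = HoleSpec(
            centers=np.array([[30.0, 25.0], [30.0, 37.0]]),
            radii=np.array([7.0, 7.0]),
            canvas=60,
        )
        patch, _ = make_disk_field(spec)
        quads = split_quadrants(compute_persistence(signed_edt(patch)))
        assert len(quads[("h0", "q3")]) >= 1
        q3 = quads[("h0", "q3")]
        assert (q3[:, 1] <= 0).all()  # merged at or before delta = 0

    def test_four_close_disks_make_a_bone_loop(self):
        c = np.array([[25.0, 25.0], [25.0, 55.0], [55.0, 25.0], [55.0, 55.0]])
        spec = HoleSpec(centers=c, radii=np.full(4, 8.0), canvas=80)
        patch, _ = make_disk_field(spec)
        quads = split_quadrants(compute_persistence(signed_edt(patch)))
        assert len(quads[("h1", "q1")]) == 1

    def test_violation_raises(self):
        bad = PersistenceDiagram(
            h0=np.array([[0.5, 1.0]]),
            h1=np.zeros((0, 2)),
            h0_pixels=np.zeros((1, 2), dtype=int),
            h1_pixels=np.zeros((0, 2), dtype=int),
        )
        with pytest.raises(QuadrantLawError):
            split_quadrants(bad)


def bottleneck_upper_bound(a: np.ndarray, b: np.ndarray) -> float:
    """Max transport cost of a min-sum matching between two diagrams, with
    the diagonal available as a match target (upper-bounds the bottleneck)."""
    n, m = len(a), len(b)
    if n == 0 and m == 0:
        return 0.0
    big = 1e9
    size = n + m
    cost = np.full((size, size), 0.0)
    if n and m:
        cost[:n, :m] = np.abs(a[:, None, :] - b[None, :, :]).max(-1)
    diag_a = (a[:, 1] - a[:, 0]) / 2 if n else np.zeros(0)
    diag_b = (b[:, 1] - b[:, 0]) / 2 if m else np.zeros(0)
    cost[:n, m:] = big
    cost[:n, m:][np.arange(n), np.arange(n)] = diag_a
    cost[n:, :m] = big
    cost[n:, :m][np.arange(m), np.arange(m)] = diag_b
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].max())


def test_stability_under_small_field_perturbation(rng):
    vals = rng.normal(size=(15, 15))
    eps = 0.05
    noisy = vals + rng.uniform(-eps, eps, size=vals.shape)
    dg = compute_persistence(vals)
    dg_n = compute_persistence(noisy)
    assert bottleneck_upper_bound(dg.h0, dg_n.h0) <= eps + 1e-9
    assert bottleneck_upper_bound(dg.h1, dg_n.h1) <= eps + 1e-9
    assert abs(dg.essential_birth - dg_n.essential_birth) <= eps


def test_birth_pixels_point_at_hole_centres():
    spec = HoleSpec(
        centers=np.array([[20.0, 20.0], [60.0, 60.0]]), radii=np.array([4.0, 6.0]), canvas=90
    )
    patch, _ = make_disk_field(spec)
    dg = compute_persistence(signed_edt(patch))
    # the finite micro-hole's birth pixel sits at a planted centre
    assert np.linalg.norm(dg.h0_pixels[0] - spec.centers, axis=1).min() <= 1.0
    assert np.linalg.norm(np.array(dg.essential_pixel) - spec.centers, axis=1).min() <= 1.0


def test_diagram_csv_roundtrip(tmp_path, rng):
    vals = rng.normal(size=(10, 10))
    dg = compute_persistence(vals)
    path = tmp_path / "diagrams.csv"
    write_diagrams_csv([dg], path)
    back = read_diagrams_csv(path)[0]
    assert np.allclose(np.sort(back.h0, axis=0), np.sort(dg.h0, axis=0))
    assert np.allclose(np.sort(back.h1, axis=0), np.sort(dg.h1, axis=0))
    assert back.essential_birth == pytest.approx(dg.essential_birth)
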