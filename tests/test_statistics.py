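"""Persistence statistics: entropy formula, panel arithmetic, scale
restriction, patch scoring and ground-truth recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microholes.persistence import PersistenceDiagram, compute_persistence, split_quadrants
from microholes.sedt import signed_edt
from microholes.statistics import (
    PANEL28,
    STAT_COLUMNS,
    compute_panel,
    panel_table,
    persistent_entropy,
    restrict_scale,
    score_patches,
)
from microholes.synthetic import HoleSpec, make_disk_field


def make_diagram(h0=(), h1=(), essential_birth=-10.0):
    h0 = np.asarray(h0, dtype=float).reshape(-1, 2)
    h1 = np.asarray(h1, dtype=float).reshape(-1, 2)
    return PersistenceDiagram(
        h0=h0,
        h1=h1,
        h0_pixels=np.zeros((len(h0), 2), dtype=int),
        h1_pixels=np.zeros((len(h1), 2), dtype=int),
        essential_birth=essential_birth,
        essential_pixel=(0, 0),
    )


class TestEntropy:
    def test_single_point_is_zero(self):
        assert persistent_entropy([(-2.0, 1.0)]) == 0.0

    def test_uniform_lifetimes_give_log_n(self):
        pts = [(-1.0, 1.0), (-3.0, -1.0), (0.0, 2.0), (5.0, 7.0)]
        assert persistent_entropy(pts) == pytest.approx(np.log(4))

    def test_two_point_formula(self):
        # lifetimes {1, 3}: -(1/4 ln 1/4 + 3/4 ln 3/4)
        pts = [(0.0, 1.0), (0.0, 3.0)]
        expected = -(0.25 * np.log(0.25) + 0.75 * np.log(0.75))
        assert persistent_entropy(pts) == pytest.approx(expected)

    def test_empty_is_nan_not_zero(self):
        assert np.isnan(persistent_entropy(np.zeros((0, 2))))

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=20))
    def test_bounded_by_log_n(self, lifetimes):
        pts = np.column_stack([np.zeros(len(lifetimes)), lifetimes])
        h = persistent_entropy(pts)
        assert -1e-9 <= h <= np.log(len(lifetimes)) + 1e-9


class TestPanel:
    def test_two_point_hand_arithmetic(self):
        diag = make_diagram(h0=[(-5.0, 2.0), (-3.0, 4.0)])
        panel = compute_panel(diag)
        assert panel["h0q2_n_points"] == 2
        assert panel["h0q2_mean_birth"] == -4.0
        assert panel["h0q2_mean_death"] == 3.0
        assert panel["h0q2_total_persistence"] == 14.0
        assert panel["h0q2_iqr_birth"] == panel["h0q2_p75_birth"] - panel["h0q2_p25_birth"]
        assert panel["h0q2_n_radius_ge_2"] == 2
        assert panel["h0q2_n_radius_lt_2"] == 0

    def test_small_hole_counted_below_threshold(self):
        panel = compute_panel(make_diagram(h0=[(-1.5, 1.0)]))
        assert panel["h0q2_n_radius_lt_2"] == 1
        assert panel["h0q2_n_radius_ge_2"] == 0

    def test_radius_threshold_is_configurable(self):
        panel = compute_panel(make_diagram(h0=[(-1.5, 1.0)]), radius_threshold=1.0)
        assert panel["h0q2_n_radius_ge_2"] == 1

    def test_empty_quadrant_missing_markers(self):
        panel = compute_panel(make_diagram())
        assert panel["h0q2_n_points"] == 0
        assert np.isnan(panel["h0q2_mean_birth"])
        assert np.isnan(panel["h0q2_entropy"])
        assert panel["h0q2_total_persistence"] == 0.0

    def test_panel28_columns_exist_and_count(self):
        assert len(PANEL28) == 28
        panel = compute_panel(make_diagram(h0=[(-3.0, 1.0)], h1=[(1.0, 2.0)]))
        assert set(PANEL28) <= set(panel)
        assert set(panel) == set(STAT_COLUMNS)

    def test_order_invariance(self, rng):
        pts = np.column_stack([-rng.uniform(1, 5, 8), rng.uniform(0.5, 4, 8)])
        p1 = compute_panel(make_diagram(h0=pts))
        p2 = compute_panel(make_diagram(h0=pts[rng.permutation(8)]))
        for k in p1:
            np.testing.assert_allclose(p1[k], p2[k], err_msg=k)

    def test_adding_point_monotonicity(self):
        base = [(-4.0, 1.0), (-2.0, 2.0)]
        extra = (-3.0, 3.0)
        p1 = compute_panel(make_diagram(h0=base))
        p2 = compute_panel(make_diagram(h0=base + [extra]))
        assert p2["h0q2_n_points"] == p1["h0q2_n_points"] + 1
        assert p2["h0q2_total_persistence"] == pytest.approx(
            p1["h0q2_total_persistence"] + (extra[1] - extra[0])
        )

    def test_essential_point_excluded(self):
        # same finite points, different essential births -> identical panels
        p1 = compute_panel(make_diagram(h0=[(-3.0, 1.0)], essential_birth=-50.0))
        p2 = compute_panel(make_diagram(h0=[(-3.0, 1.0)], essential_birth=-5.0))
        assert p1 == p2


class TestRestrictScale:
    def test_unbounded_windows_identity(self, rng):
        dg = compute_persistence(rng.normal(size=(10, 10)))
        out = restrict_scale(dg)
        assert np.array_equal(out.h0, dg.h0) and np.array_equal(out.h1, dg.h1)

    def test_birth_window_matches_radius_count(self):
        spec = HoleSpec(
            centers=np.array([[20.0, 20.0], [60.0, 60.0], [20.0, 60.0]]),
            radii=np.array([1.5, 4.0, 6.0]),
            canvas=90,
            border=2,
        )
        patch, _ = make_disk_field(spec)
        dg = compute_persistence(signed_edt(patch))
        panel = compute_panel(dg)
        restricted = restrict_scale(dg, birth_window=(-np.inf, -2.0))
        n_large = len(split_quadrants(restricted)[("h0", "q2")])
        assert n_large == panel["h0q2_n_radius_ge_2"]

    def test_death_window_is_predicate_filter(self, rng):
        dg = compute_persistence(rng.normal(size=(12, 12)))
        out = restrict_scale(dg, death_window=(0.2, 0.8))
        expected = dg.h0[(dg.h0[:, 1] >= 0.2) & (dg.h0[:, 1] <= 0.8)]
        assert np.array_equal(out.h0, expected)


class TestScorePatches:
    def _panels(self, values, side=300):
        rows = []
        for (r, c), v in values.items():
            rows.append({"origin_row": r * side, "origin_col": c * side, "h0q2_n_points": v})
        return pd.DataFrame(rows)

    def test_constant_map(self):
        grid = score_patches(self._panels({(0, 0): 3, (0, 1): 3, (1, 0): 3}), "h0q2_n_points")
        assert (grid.compressed() == 3).all()

    def test_single_patch_map(self):
        grid = score_patches(self._panels({(0, 0): 7}), "h0q2_n_points")
        assert grid.shape == (1, 1) and grid[0, 0] == 7

    def test_missing_tiles_masked(self):
        grid = score_patches(self._panels({(0, 0): 1, (1, 1): 2}), "h0q2_n_points")
        assert grid.mask[0, 1] and grid.mask[1, 0]

    def test_hotspot_is_argmax(self):
        grid = score_patches(
            self._panels({(0, 0): 2, (0, 1): 9, (1, 0): 1, (1, 1): 3}), "h0q2_n_points"
        )
        assert np.unravel_index(np.ma.argmax(grid), grid.shape) == (0, 1)

    def test_unknown_statistic_lists_valid_names(self):
        with pytest.raises(ValueError, match="valid names"):
            score_patches(self._panels({(0, 0): 1}), "not_a_statistic")


def test_generator_recovery_counts_radii_crowding(small_contrast):
    """Planted hole count, radii and nearest-gap crowding are recovered by
    the pipeline to pixel accuracy on well-separated synthetic patches."""
    panel, specs = small_contrast["panel"], small_contrast["specs"]
    diagrams = small_contrast["diagrams"]
    for spec, dg, (_, row) in zip(specs, diagrams, panel.iterrows()):
        # the largest hole is the essential class; finite count is k - 1
        assert row["h0q2_n_points"] == spec.n_holes - 1
        births = np.sort(np.append(dg.h0[dg.h0[:, 1] > 0][:, 0], dg.essential_birth))
        assert np.allclose(np.sort(-births), np.sort(spec.radii), atol=1.0)


def test_panel_table_carries_provenance(small_contrast):
    panel = small_contrast["panel"]
    assert {"source", "origin_row", "origin_col", "genotype", "sex", "modality"} <= set(
        panel.columns
    )
    assert panel["genotype"].isin(["KO", "WT"]).all()
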