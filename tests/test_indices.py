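"""SMM and DMS: hand-computed examples, oracles, bounds, invariances."""

import numpy as np
import pytest

import palsymetry as pm
from palsymetry.errors import DegenerateGeometryError, SequenceTooShortError
from palsymetry.geometry import NormalizedSequence, to_midline_frame
from palsymetry.indices import (
    DisplacementSeries,
    IndexConfig,
    MouthRaster,
    _frame_asymmetry_fast,
)

from conftest import fold_area_ratio_oracle, random_simple_polygon


def norm_seq_from_corner_tracks(right_xy, left_xy, fps=30.0):
    """Minimal NormalizedSequence whose mouth corners follow given tracks."""
    n = len(right_xy)
    pts = np.zeros((n, 98, 2))
    pts[:, pm.WFLW_SCHEME.right_mouth_corner] = right_xy
    pts[:, pm.WFLW_SCHEME.left_mouth_corner] = left_xy
    return NormalizedSequence(points=pts, fps=fps, axes_per_frame=[])


class TestDisplacement:
    def test_static_landmarks_zero_magnitudes(self):
        seq = norm_seq_from_corner_tracks(np.ones((40, 2)), np.ones((40, 2)))
        disp = pm.displacement_magnitudes(seq)
        assert np.all(disp.d_right == 0) and np.all(disp.d_left == 0)

    def test_three_four_five_window(self):
        # corner jumps from (0,0) to (3,4) exactly T=15 frames apart
        track = np.zeros((16, 2))
        track[15] = (3, 4)
        seq = norm_seq_from_corner_tracks(track, track)
        disp = pm.displacement_magnitudes(seq)
        assert disp.T_frames == 15
        assert disp.d_right.shape == (1,)
        assert disp.d_right[0] == pytest.approx(5.0)

    def test_window_count_at_60fps(self):
        # 300 frames at 60 fps with a 0.5 s window: T = 30, 270 windows
        seq = norm_seq_from_corner_tracks(np.zeros((300, 2)), np.zeros((300, 2)), fps=60.0)
        disp = pm.displacement_magnitudes(seq)
        assert disp.T_frames == 30
        assert len(disp.d_right) == 270

    def test_too_short_sequence_raises(self):
        seq = norm_seq_from_corner_tracks(np.zeros((10, 2)), np.zeros((10, 2)))
        with pytest.raises(SequenceTooShortError, match="N=10"):
            pm.displacement_magnitudes(seq)


class TestSmm:
    @pytest.mark.parametrize(
        "right, left, expected",
        [
            ((1.0, 2.0, 3.0), (1.0, 2.0, 3.0), 1.0),  # identical
            ((1.0, 0.0), (0.0, 1.0), 0.0),  # orthogonal
            ((1.0, 2.0, 3.0), (3.0, 2.0, 1.0), 10.0 / 14.0),  # hand arithmetic
        ],
    )
    def test_hand_examples(self, right, left, expected):
        disp = DisplacementSeries(np.array(right), np.array(left), T_frames=1)
        assert pm.compute_smm(disp) == pytest.approx(expected)

    def test_symmetric_under_side_swap(self, rng):
        r, l = rng.uniform(0, 1, 50), rng.uniform(0, 1, 50)
        a = pm.compute_smm(DisplacementSeries(r, l, 1))
        b = pm.compute_smm(DisplacementSeries(l, r, 1))
        assert a == pytest.approx(b)

    def test_motionless_corner_is_undefined_not_zero(self):
        disp = DisplacementSeries(np.array([1.0, 2.0]), np.array([0.0, 0.0]), 1)
        assert pm.compute_smm(disp) is None

    def test_bounds_on_random_nonnegative_series(self, rng):
        for _ in range(500):
            r = rng.uniform(0, 10, 20)
            l = rng.uniform(0, 10, 20)
            v = pm.compute_smm(DisplacementSeries(r, l, 1))
            assert 0.0 <= v <= 1.0


class TestRasterize:
    def run(self, polygon_xy, cells=200):
        pts = np.zeros((98, 2))
        ring = np.asarray(pm.WFLW_SCHEME.outer_mouth_contour)
        poly12 = np.asarray(polygon_xy)
        assert poly12.shape[0] == len(ring)
        pts[ring] = poly12
        return pm.rasterize_mouth(pts, cfg=IndexConfig(grid_width_cells=cells))

    @staticmethod
    def rectangle(x0, x1, y0=0.0, y1=1.0):
        # 12 points walking the rectangle boundary (the mouth ring has 12)
        xs = np.linspace(x0, x1, 5)
        top = [(x, y0) for x in xs]  # 5 points left-to-right
        bottom = [(x, y1) for x in xs[::-1]]  # 5 points right-to-left
        sides = [(x1, (y0 + y1) / 2)], [(x0, (y0 + y1) / 2)]
        return np.array(top + sides[0] + bottom + sides[1])[:12]

    def test_one_sided_polygon_has_empty_left(self):
        ring = np.column_stack(
            [np.cos(np.linspace(0, 2 * np.pi, 12, endpoint=False)) * 0.3 - 1.0,
             np.sin(np.linspace(0, 2 * np.pi, 12, endpoint=False)) * 0.3]
        )  # circle centered at x = -1, entirely in the right half-plane
        raster = self.run(ring)
        assert len(raster.left_cells) == 0 and len(raster.right_cells) > 0

    def test_symmetric_rectangle_equal_sides(self):
        # rectangle spanning [-1, 1]: equal cell counts and zero asymmetry
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        ring = np.column_stack([np.cos(theta), 0.5 * np.sin(theta)])
        raster = self.run(ring)
        assert len(raster.right_cells) == len(raster.left_cells)
        assert pm.frame_asymmetry(raster) == pytest.approx(0.0, abs=0.02)

    def test_off_center_rectangle_area_ratio(self):
        # rectangle spanning [-1, 2]: a third of the area left of the fold
        # line ends up... |L|/|R| -> 1/2 as the grid refines
        ring = self.rectangle(-1.0, 2.0)
        raster = self.run(ring, cells=600)
        ratio = len(raster.right_cells) / len(raster.left_cells)
        assert ratio == pytest.approx(0.5, abs=0.01)

    def test_self_intersecting_contour_rejected(self):
        bowtie = np.array(
            [(-1, -1), (1, 1), (1, -1), (-1, 1)] * 3, dtype=float
        ) + np.linspace(0, 1e-3, 12)[:, None]
        with pytest.raises(DegenerateGeometryError):
            self.run(bowtie)

    def test_fold_is_exact_cell_bijection(self, rng):
        poly = random_simple_polygon(rng)
        raster = self.run(poly)
        folded = {(raster.n_cols - 1 - c, r) for c, r in raster.left_cells}
        # folded cells live on the right-side columns of the symmetric grid
        assert all(c < raster.n_cols / 2 for c, _ in folded)

    def test_disjoint_side_sets_enforced(self):
        with pytest.raises(ValueError):
            MouthRaster(0.1, frozenset({(1, 1)}), frozenset({(1, 1)}), n_cols=10)


class TestFrameAsymmetry:
    def test_brute_force_set_example(self):
        # right side 60 cells, folded left 40 cells, 30 overlapping:
        # XOR = 30 + 10, total = 100 -> 0.4
        n_cols = 20
        right = {(c, r) for c in range(10) for r in range(6)}  # 60 cells, cols 0..9
        # folded left: 30 cells inside right (rows 0..2) + 10 outside (row 6)
        folded_target = {(c, r) for c in range(10) for r in range(3)} | {
            (c, 6) for c in range(10)
        }
        overlap = right & folded_target
        assert len(overlap) == 30
        left = {(n_cols - 1 - c, r) for c, r in folded_target}
        raster = MouthRaster(0.1, frozenset(right), frozenset(left), n_cols=n_cols)
        assert pm.frame_asymmetry(raster) == pytest.approx(0.4)

    def test_mirror_symmetric_region_zero(self):
        right = {(c, r) for c in range(5) for r in range(3)}
        left = {(9 - c, r) for c, r in right}
        raster = MouthRaster(0.1, frozenset(right), frozenset(left), n_cols=10)
        assert pm.frame_asymmetry(raster) == 0.0

    def test_fully_one_sided_region_is_one(self):
        right = {(c, r) for c in range(5) for r in range(3)}
        raster = MouthRaster(0.1, frozenset(right), frozenset(), n_cols=10)
        assert pm.frame_asymmetry(raster) == 1.0

    def test_empty_region_raises(self):
        raster = MouthRaster(0.1, frozenset(), frozenset(), n_cols=10)
        with pytest.raises(DegenerateGeometryError):
            pm.frame_asymmetry(raster)

    def test_fast_path_matches_set_path(self, rng):
        for _ in range(20):
            poly = random_simple_polygon(rng)
            pts = np.zeros((98, 2))
            pts[np.asarray(pm.WFLW_SCHEME.outer_mouth_contour)] = poly
            cfg = IndexConfig(grid_width_cells=150)
            via_sets = pm.frame_asymmetry(pm.rasterize_mouth(pts, cfg=cfg))
            via_masks = _frame_asymmetry_fast(pts, pm.WFLW_SCHEME, cfg)
            assert via_sets == via_masks

    def test_grid_convergence_to_clipping_oracle(self, rng):
        for _ in range(25):
            poly = random_simple_polygon(rng)
            pts = np.zeros((98, 2))
            pts[np.asarray(pm.WFLW_SCHEME.outer_mouth_contour)] = poly
            grid = _frame_asymmetry_fast(
                pts, pm.WFLW_SCHEME, IndexConfig(grid_width_cells=400)
            )
            exact = fold_area_ratio_oracle(poly)
            assert grid == pytest.approx(exact, abs=0.01)


class TestDms:
    def test_mean_of_per_frame_asymmetries(self, symmetric_subject):
        norm = to_midline_frame(symmetric_subject.sequence)
        two = NormalizedSequence(norm.points[:2], norm.fps, norm.axes_per_frame[:2])
        per_frame = [
            _frame_asymmetry_fast(two.points[i], pm.WFLW_SCHEME, IndexConfig())
            for i in range(2)
        ]
        assert pm.compute_dms(two) == pytest.approx(np.mean(per_frame))

    def test_mirror_symmetric_clip_zero(self, symmetric_subject):
        norm = to_midline_frame(symmetric_subject.sequence)
        assert pm.compute_dms(norm) == 0.0


class TestComposition:
    def test_symmetric_show_teeth_motion(self, symmetric_subject):
        pair = pm.compute_indices(symmetric_subject.sequence)
        assert pair.smm >= 0.99
        assert pair.dms <= 0.02

    def test_frozen_corner_noise_free_flags_undefined(self):
        subj = pm.generate_subject(pm.SyntheticParams(movement_asymmetry=1.0))
        pair = pm.compute_indices(subj.sequence)
        assert pair.smm is None

    def test_palsy_lowers_smm_and_raises_dms(self):
        base = pm.compute_indices(
            pm.generate_subject(pm.SyntheticParams(landmark_noise_sd=0.3, seed=8)).sequence
        )
        palsied = pm.compute_indices(
            pm.generate_subject(
                pm.SyntheticParams(
                    movement_asymmetry=0.8, droop_offset=6.0,
                    landmark_noise_sd=0.3, seed=8,
                )
            ).sequence
        )
        assert palsied.smm < base.smm
        assert palsied.dms > base.dms

    def test_indices_invariant_under_similarity_transform(self, rng):
        from conftest import similarity_transform

        subj = pm.generate_subject(
            pm.SyntheticParams(movement_asymmetry=0.4, droop_offset=3.0,
                               landmark_noise_sd=0.3, seed=6)
        )
        pair = pm.compute_indices(subj.sequence)
        moved = similarity_transform(subj.sequence.points, rng)
        pair2 = pm.compute_indices(pm.LandmarkSequence(moved, subj.sequence.fps))
        assert abs(pair.smm - pair2.smm) < 1e-9
        assert abs(pair.dms - pair2.dms) < 1e-9
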