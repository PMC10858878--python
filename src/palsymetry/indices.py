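"""The two facial-palsy evaluation indices: SMM and DMS.

Symmetry of Mouth Movement (SMM)
    For each frame t, the displacement magnitude of each mouth corner over a
    sliding window of T frames (0.5 s) is

        d_{R,t} = || p_{t+T}(right corner) - p_t(right corner) ||,
        d_{L,t} = || p_{t+T}(left corner)  - p_t(left corner)  ||,

    and SMM is the uncentered correlation (cosine similarity) of the two
    nonnegative magnitude series over all N - T windows.  1 means the two
    corners move with identical magnitude profiles; values toward the low
    end of [0, 1] mean asymmetric movement.  If one corner never moves the
    denominator vanishes and SMM is undefined (returned as ``None``, never
    silently 0: a motionless corner is exactly the case the index cannot
    grade).

Difference in Mouth Shape (DMS)
    Per frame, the outer mouth contour polygon is rasterized onto a square
    grid whose columns are symmetric about the facial midline; the cells on
    the anatomical-right side (R) and left side (L) of the midline are
    collected, the left set is folded (reflected) across the midline, and
    the frame's asymmetry is |R xor L| / (|R| + |L|) — the fraction of the
    mouth area covered by exactly one side.  DMS is the mean over all N
    frames.  0 means mirror-symmetric mouth shape, 1 a fully one-sided one.

Both indices operate on a :class:`~palsymetry.geometry.NormalizedSequence`
and are therefore invariant under similarity transforms of the raw video
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .errors import DegenerateGeometryError, SequenceTooShortError
from .geometry import NormalizedSequence, PreprocessConfig, to_midline_frame
from .landmark_io import LandmarkScheme, LandmarkSequence, WFLW_SCHEME

__all__ = [
    "IndexConfig",
    "DisplacementSeries",
    "MouthRaster",
    "IndexPair",
    "displacement_magnitudes",
    "compute_smm",
    "rasterize_mouth",
    "frame_asymmetry",
    "compute_dms",
    "compute_indices",
]


@dataclass(frozen=True)
class IndexConfig:
    """Index parameters.

    window_seconds
        The displacement window T expressed in seconds (default 0.5 s; at
        60 fps this is T = 30 frames).
    grid_width_cells
        Number of square-grid columns across the symmetrized mouth bounding
        rectangle (default 200).
    """

    window_seconds: float = 0.5
    grid_width_cells: int = 200

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be > 0")
        if self.grid_width_cells < 2:
            raise ValueError("grid_width_cells must be >= 2")

    def window_frames(self, fps: float) -> int:
        return int(round(self.window_seconds * fps))


@dataclass(frozen=True)
class DisplacementSeries:
    """Mouth-corner displacement magnitudes over all N - T windows."""

    d_right: np.ndarray
    d_left: np.ndarray
    T_frames: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "d_right", np.asarray(self.d_right, dtype=float))
        object.__setattr__(self, "d_left", np.asarray(self.d_left, dtype=float))
        if self.d_right.shape != self.d_left.shape or self.d_right.ndim != 1:
            raise ValueError("d_right and d_left must be 1-D arrays of equal length")
        if self.d_right.size < 1:
            raise ValueError("displacement series must have length >= 1")
        if np.any(self.d_right < 0) or np.any(self.d_left < 0):
            raise ValueError("displacement magnitudes must be nonnegative")


@dataclass(frozen=True)
class MouthRaster:
    """Square-grid discretization of one frame's mouth region.

    Cells are identified by (column, row); columns are mirror-symmetric
    about the midline so the fold maps column j to column n_cols - 1 - j
    exactly.  ``right_cells``/``left_cells`` hold the in-mouth cells whose
    centers lie strictly on the respective side of the midline (centers
    exactly on the midline belong to neither).
    """

    cell_size: float
    right_cells: frozenset
    left_cells: frozenset
    n_cols: int
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.right_cells & self.left_cells:
            raise ValueError("a cell cannot belong to both sides")


@dataclass(frozen=True)
class IndexPair:
    """The two indices for one clip; ``smm`` is None when undefined
    (a motionless corner makes the cosine denominator vanish)."""

    smm: float | None
    dms: float
    n_frames_used: int

    def __post_init__(self) -> None:
        if self.smm is not None and not (0.0 <= self.smm <= 1.0 + 1e-12):
            raise ValueError(f"smm out of range: {self.smm}")
        if not (0.0 <= self.dms <= 1.0 + 1e-12):
            raise ValueError(f"dms out of range: {self.dms}")


# ---------------------------------------------------------------------------
# SMM


def displacement_magnitudes(
    seq: NormalizedSequence,
    scheme: LandmarkScheme = WFLW_SCHEME,
    cfg: IndexConfig = IndexConfig(),
) -> DisplacementSeries:
    """Sliding-window displacement magnitudes of both mouth corners
    (stride 1, all N - T windows)."""
    T = cfg.window_frames(seq.fps)
    n = len(seq)
    if n <= T:
        raise SequenceTooShortError(
            f"need more than T={T} frames for a {cfg.window_seconds} s window, got N={n}"
        )
    right = seq.points[:, scheme.right_mouth_corner]
    left = seq.points[:, scheme.left_mouth_corner]
    d_right = np.linalg.norm(right[T:] - right[:-T], axis=1)
    d_left = np.linalg.norm(left[T:] - left[:-T], axis=1)
    return DisplacementSeries(d_right=d_right, d_left=d_left, T_frames=T)


def compute_smm(disp: DisplacementSeries) -> float | None:
    """Uncentered correlation of the right and left displacement-magnitude
    series; None if either series is identically zero."""
    r, l = disp.d_right, disp.d_left
    nr = np.sqrt(np.sum(r * r))
    nl = np.sqrt(np.sum(l * l))
    if nr == 0.0 or nl == 0.0:
        return None
    value = float(np.sum(r * l) / (nr * nl))
    # nonnegative series => cosine in [0, 1]; clamp fp rounding only
    return min(max(value, 0.0), 1.0)


# ---------------------------------------------------------------------------
# DMS


def _mouth_polygon(points98: np.ndarray, scheme: LandmarkScheme) -> shapely.Polygon:
    ring = points98[np.asarray(scheme.outer_mouth_contour)]
    poly = shapely.Polygon(ring)
    if not poly.is_valid:
        raise DegenerateGeometryError("mouth contour polygon is self-intersecting")
    if poly.area == 0.0:
        raise DegenerateGeometryError("mouth contour polygon has zero area")
    return poly


def _raster_masks(
    pts: np.ndarray, scheme: LandmarkScheme, cfg: IndexConfig
) -> tuple[np.ndarray, np.ndarray, float]:
    """Shared rasterization core: (inside mask of shape (n_cols, n_rows),
    column centers xc, cell size)."""
    poly = _mouth_polygon(pts, scheme)
    ring = pts[np.asarray(scheme.outer_mouth_contour)]
    half = float(np.max(np.abs(ring[:, 0])))
    if half == 0.0:
        raise DegenerateGeometryError("mouth contour collapsed onto the midline")
    n_cols = cfg.grid_width_cells
    cell = 2.0 * half / n_cols
    ymin = float(ring[:, 1].min())
    ymax = float(ring[:, 1].max())
    n_rows = max(1, int(np.ceil((ymax - ymin) / cell)))
    xc = -half + (np.arange(n_cols) + 0.5) * cell
    yc = ymin + (np.arange(n_rows) + 0.5) * cell
    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    inside = shapely.intersects_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
    return inside, xc, cell


def rasterize_mouth(
    points98: np.ndarray,
    scheme: LandmarkScheme = WFLW_SCHEME,
    cfg: IndexConfig = IndexConfig(),
    frame_index: int = 0,
) -> MouthRaster:
    """Rasterize one frame's outer mouth contour onto a square grid.

    The bounding rectangle of the contour (axis-aligned in the midline
    frame) is widened to be symmetric about the midline, its width divided
    into ``grid_width_cells`` columns of square cells, and a cell belongs to
    the mouth region iff its center lies inside the closed contour polygon
    (boundary counts as inside).  Cells are split into right/left sets by
    the sign of the center's first coordinate.
    """
    pts = points98.points if hasattr(points98, "points") else np.asarray(points98, dtype=float)
    inside, xc, cell = _raster_masks(pts, scheme, cfg)
    cols, rows = np.nonzero(inside)
    x_centers = xc[cols]
    right = frozenset(zip(cols[x_centers < 0].tolist(), rows[x_centers < 0].tolist()))
    left = frozenset(zip(cols[x_centers > 0].tolist(), rows[x_centers > 0].tolist()))
    return MouthRaster(
        cell_size=cell, right_cells=right, left_cells=left, n_cols=cfg.grid_width_cells,
        frame_index=frame_index,
    )


def frame_asymmetry(raster: MouthRaster) -> float:
    """Fold the left cell set across the midline and return
    ``|R xor L| / (|R| + |L|)`` for one frame."""
    total = len(raster.right_cells) + len(raster.left_cells)
    if total == 0:
        raise DegenerateGeometryError(
            f"frame {raster.frame_index}: empty mouth region at this grid resolution"
        )
    folded = {(raster.n_cols - 1 - c, r) for c, r in raster.left_cells}
    xor = len(raster.right_cells.symmetric_difference(folded))
    return xor / total


def _frame_asymmetry_fast(
    pts: np.ndarray, scheme: LandmarkScheme, cfg: IndexConfig
) -> float:
    """Array-mask equivalent of rasterize_mouth + frame_asymmetry (same
    cells, same fold: column j maps to n_cols - 1 - j under reflection)."""
    inside, xc, _ = _raster_masks(pts, scheme, cfg)
    right = inside & (xc < 0)[:, None]
    left = inside & (xc > 0)[:, None]
    total = int(right.sum() + left.sum())
    if total == 0:
        raise DegenerateGeometryError("empty mouth region at this grid resolution")
    folded_left = left[::-1]
    xor = int((right ^ folded_left).sum())
    return xor / total


def compute_dms(
    seq: NormalizedSequence,
    scheme: LandmarkScheme = WFLW_SCHEME,
    cfg: IndexConfig = IndexConfig(),
) -> float:
    """Mean per-frame fold asymmetry over all N frames of the clip."""
    values = np.empty(len(seq))
    for i in range(len(seq)):
        try:
            values[i] = _frame_asymmetry_fast(seq.points[i], scheme, cfg)
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(f"frame {i}: {exc}") from exc
    return float(values.mean())


# ---------------------------------------------------------------------------
# Composition


def compute_indices(
    seq: LandmarkSequence,
    scheme: LandmarkScheme = WFLW_SCHEME,
    pre_cfg: PreprocessConfig = PreprocessConfig(),
    idx_cfg: IndexConfig = IndexConfig(),
) -> IndexPair:
    """Preprocess a raw landmark sequence and compute both indices."""
    norm = to_midline_frame(seq, scheme, pre_cfg)
    smm = compute_smm(displacement_magnitudes(norm, scheme, idx_cfg))
    dms = compute_dms(norm, scheme, idx_cfg)
    return IndexPair(smm=smm, dms=dms, n_frames_used=len(norm))
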