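"""Landmark preprocessing: smoothing, scale correction, facial midline.

The asymmetry indices are defined relative to the facial midline, the line
through the centroid of the five nose-bottom landmarks perpendicular to the
segment joining the centroids of the two eye-bottom landmark triples.  Eye
bottoms are used because the eye region is largely spared by central facial
palsy and the lower lid is less affected by ptosis than the upper; the nose
centroid anchors the midline near the mouth.

The full preprocessing pipeline (:func:`to_midline_frame`) is

    Gaussian temporal smoothing -> face-width scale correction ->
    per-frame midline -> change of basis into the midline frame,

which makes every downstream quantity invariant under translation, rotation
and uniform scaling of the raw pixel coordinates.  In the midline frame the
first coordinate runs along the inter-ocular (horizontal) axis from the
anatomical right toward the left, the second up the midline from nose toward
eyes, and all coordinates are in units of face width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import DegenerateGeometryError, ValidationError
from .landmark_io import LandmarkFrame, LandmarkScheme, LandmarkSequence, WFLW_SCHEME

__all__ = [
    "FacialAxes",
    "PreprocessConfig",
    "NormalizedSequence",
    "compute_facial_axes",
    "smooth_landmarks",
    "scale_normalize",
    "to_midline_frame",
]


@dataclass(frozen=True)
class FacialAxes:
    """Per-frame facial coordinate frame.

    ``origin`` is the nose-bottom centroid; ``horiz_dir`` the unit vector
    from the right eye-bottom centroid toward the left; ``midline_dir`` the
    unit vector perpendicular to it, oriented from the nose toward the eyes
    ("up the face").
    """

    origin: np.ndarray
    midline_dir: np.ndarray
    horiz_dir: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "midline_dir", "horiz_dir"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if abs(np.dot(self.midline_dir, self.horiz_dir)) > 1e-9:
            raise ValidationError("midline_dir and horiz_dir must be orthogonal")
        for name in ("midline_dir", "horiz_dir"):
            if abs(np.linalg.norm(getattr(self, name)) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must be unit length")


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing knobs.

    gaussian_sigma_seconds
        Temporal Gaussian smoothing bandwidth, in seconds (default 0.05 s,
        i.e. 1.5 frames at 30 fps): suppresses per-frame landmark jitter
        while leaving the 0.5 s displacement window intact.  0 disables.
    per_frame_midline
        Recompute the facial axes in every frame (default).  When False a
        single reference frame computed from the time-averaged landmarks is
        used, for sensitivity analysis.
    per_frame_scale
        Divide each frame by its own face width (default) or by the mean
        width over the clip.
    """

    gaussian_sigma_seconds: float = 0.05
    per_frame_midline: bool = True
    per_frame_scale: bool = True

    def __post_init__(self) -> None:
        if self.gaussian_sigma_seconds < 0:
            raise ValidationError("gaussian_sigma_seconds must be >= 0")


@dataclass
class NormalizedSequence:
    """Landmarks expressed in the midline frame, in face-width units.

    In every frame the nose-bottom centroid maps to (0, 0) and the two
    eye-bottom centroids share the same second-axis coordinate.
    """

    points: np.ndarray  # (N, 98, 2), dimensionless
    fps: float
    axes_per_frame: list[FacialAxes]
    subject_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def n_frames(self) -> int:
        return len(self)


def _centroid(points: np.ndarray, indices) -> np.ndarray:
    return points[np.asarray(indices)].mean(axis=0)


def compute_facial_axes(
    frame: LandmarkFrame | np.ndarray, scheme: LandmarkScheme = WFLW_SCHEME
) -> FacialAxes:
    """Construct the facial midline frame from one frame's landmarks.

    Raises :class:`DegenerateGeometryError` if the two eye-bottom centroids
    coincide.
    """
    pts = frame.points if isinstance(frame, LandmarkFrame) else np.asarray(frame, dtype=float)
    right_eye = _centroid(pts, scheme.right_eye_bottom)
    left_eye = _centroid(pts, scheme.left_eye_bottom)
    origin = _centroid(pts, scheme.nose_bottom)
    seg = left_eye - right_eye
    norm = np.linalg.norm(seg)
    if norm == 0.0:
        raise DegenerateGeometryError("eye-bottom centroids coincide; midline undefined")
    horiz = seg / norm
    midline = np.array([-horiz[1], horiz[0]])  # +90 degree rotation
    toward_eyes = 0.5 * (left_eye + right_eye) - origin
    if np.dot(midline, toward_eyes) < 0:
        midline = -midline
    return FacialAxes(origin=origin, midline_dir=midline, horiz_dir=horiz)


def smooth_landmarks(
    seq: LandmarkSequence, cfg: PreprocessConfig = PreprocessConfig()
) -> LandmarkSequence:
    """Temporal Gaussian smoothing of every landmark coordinate series.

    The kernel has sigma = ``gaussian_sigma_seconds * fps`` frames, is
    truncated at 4 sigma, and the series boundary is handled by
    nearest-value extension.  ``sigma == 0`` returns the input unchanged.
    """
    sigma_frames = cfg.gaussian_sigma_seconds * seq.fps
    if sigma_frames == 0.0:
        return seq
    smoothed = gaussian_filter1d(
        seq.points, sigma=sigma_frames, axis=0, mode="nearest", truncate=4.0
    )
    return LandmarkSequence(
        smoothed, seq.fps, seq.subject_id, seq.frame_indices, seq.metadata
    )


def _face_widths(seq: LandmarkSequence, scheme: LandmarkScheme) -> np.ndarray:
    a, b = scheme.face_width_pair
    return np.linalg.norm(seq.points[:, a] - seq.points[:, b], axis=1)


def scale_normalize(
    seq: LandmarkSequence,
    scheme: LandmarkScheme = WFLW_SCHEME,
    cfg: PreprocessConfig = PreprocessConfig(),
) -> LandmarkSequence:
    """Divide all coordinates by the face width (distance between the two
    facial-contour landmarks of ``scheme.face_width_pair``), per frame or by
    the clip mean, making face size dimensionless."""
    widths = _face_widths(seq, scheme)
    if np.any(widths == 0.0):
        bad = int(np.where(widths == 0.0)[0][0])
        raise DegenerateGeometryError(f"zero face width in frame {bad}")
    divisor = widths[:, None, None] if cfg.per_frame_scale else widths.mean()
    return LandmarkSequence(
        seq.points / divisor, seq.fps, seq.subject_id, seq.frame_indices, seq.metadata
    )


def to_midline_frame(
    seq: LandmarkSequence,
    scheme: LandmarkScheme = WFLW_SCHEME,
    cfg: PreprocessConfig = PreprocessConfig(),
) -> NormalizedSequence:
    """Full preprocessing pipeline: smooth, scale-correct, and express every
    frame in its facial midline frame."""
    seq = smooth_landmarks(seq, cfg)
    seq = scale_normalize(seq, scheme, cfg)
    pts = seq.points
    n = pts.shape[0]
    out = np.empty_like(pts)
    axes_list: list[FacialAxes] = []
    if cfg.per_frame_midline:
        frame_axes = (compute_facial_axes(pts[i], scheme) for i in range(n))
    else:
        fixed = compute_facial_axes(pts.mean(axis=0), scheme)
        frame_axes = (fixed for _ in range(n))
    for i, axes in enumerate(frame_axes):
        rel = pts[i] - axes.origin
        out[i, :, 0] = rel @ axes.horiz_dir
        out[i, :, 1] = rel @ axes.midline_dir
        axes_list.append(axes)
    return NormalizedSequence(
        points=out,
        fps=seq.fps,
        axes_per_frame=axes_list,
        subject_id=seq.subject_id,
        metadata=dict(seq.metadata),
    )
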