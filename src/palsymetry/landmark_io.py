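"""Landmark sequence containers and file I/O.

The package consumes per-frame 98-point facial landmarks in the WFLW
numbering (indices 0-97, image pixel coordinates with the origin at the
top-left and y increasing downward).  ``LandmarkScheme`` pins down which
indices play which anatomical role; everything downstream takes the scheme
as an argument so an alternative annotation convention only has to supply
a different scheme instance.

"Left" and "right" are anatomical sides as labelled by WFLW (landmark 76 is
the subject's right mouth corner, 82 the left), not image sides.

Two on-disk formats are supported:

* CSV — header comment ``# fps=<float> subject=<id>``, then one row per
  (frame, landmark) with columns ``frame,landmark,x,y``.
* JSON — ``{"subject_id": ..., "fps": ..., "frames": [{"frame_index": ...,
  "points": [[x, y] * 98]}]}``.

Coordinates round-trip at full ``repr`` precision in both formats.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "LandmarkScheme",
    "WFLW_SCHEME",
    "LandmarkFrame",
    "LandmarkSequence",
    "read_landmark_sequence",
    "write_landmark_sequence",
    "interpolate_gaps",
]


@dataclass(frozen=True)
class LandmarkScheme:
    """Anatomical roles of landmark indices within a 98-point annotation."""

    n_landmarks: int = 98
    right_mouth_corner: int = 76
    left_mouth_corner: int = 82
    right_eye_bottom: tuple[int, ...] = (65, 66, 67)
    left_eye_bottom: tuple[int, ...] = (73, 74, 75)
    nose_bottom: tuple[int, ...] = (55, 56, 57, 58, 59)
    face_width_pair: tuple[int, int] = (6, 26)
    outer_mouth_contour: tuple[int, ...] = tuple(range(76, 88))

    def __post_init__(self) -> None:
        groups = {
            "right_eye_bottom": set(self.right_eye_bottom),
            "left_eye_bottom": set(self.left_eye_bottom),
            "nose_bottom": set(self.nose_bottom),
        }
        all_indices = (
            [self.right_mouth_corner, self.left_mouth_corner]
            + list(self.right_eye_bottom)
            + list(self.left_eye_bottom)
            + list(self.nose_bottom)
            + list(self.face_width_pair)
            + list(self.outer_mouth_contour)
        )
        if any(i < 0 or i >= self.n_landmarks for i in all_indices):
            raise ValidationError("scheme indices must lie in [0, n_landmarks)")
        names = list(groups)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if groups[a] & groups[b]:
                    raise ValidationError(f"scheme role sets {a} and {b} overlap")
        if self.right_mouth_corner == self.left_mouth_corner:
            raise ValidationError("mouth corners must be distinct landmarks")
        ring = self.outer_mouth_contour
        if len(ring) != len(set(ring)) or len(ring) < 3:
            raise ValidationError("outer_mouth_contour must be a ring of >=3 distinct indices")


WFLW_SCHEME = LandmarkScheme()


@dataclass(frozen=True)
class LandmarkFrame:
    """One video frame: 98 (x, y) landmark positions in image pixels."""

    frame_index: int
    points: np.ndarray  # shape (98, 2), float64

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.shape != (WFLW_SCHEME.n_landmarks, 2):
            raise ValidationError(
                f"frame {self.frame_index}: expected (98, 2) points, got {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValidationError(f"frame {self.frame_index}: non-finite coordinate")


class LandmarkSequence:
    """An ordered landmark time series with its frame rate.

    Internally stores an ``(N, 98, 2)`` float array plus the per-frame
    ``frame_indices``; iteration yields :class:`LandmarkFrame` views.
    """

    def __init__(
        self,
        points: np.ndarray,
        fps: float,
        subject_id: str = "",
        frame_indices: np.ndarray | None = None,
        metadata: Mapping[str, str] | None = None,
    ) -> None:
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 3 or pts.shape[1:] != (WFLW_SCHEME.n_landmarks, 2):
            raise ValidationError(f"expected points of shape (N, 98, 2), got {pts.shape}")
        if pts.shape[0] < 2:
            raise ValidationError(f"a sequence needs at least 2 frames, got {pts.shape[0]}")
        if not np.all(np.isfinite(pts)):
            bad = int(np.where(~np.isfinite(pts).all(axis=(1, 2)))[0][0])
            raise ValidationError(f"non-finite coordinate in frame {bad}")
        if not (math.isfinite(fps) and fps > 0):
            raise ValidationError(f"fps must be positive and finite, got {fps}")
        if frame_indices is None:
            frame_indices = np.arange(pts.shape[0])
        idx = np.asarray(frame_indices, dtype=int)
        if idx.shape != (pts.shape[0],) or np.any(np.diff(idx) <= 0):
            raise ValidationError("frame_index must be strictly increasing, one per frame")
        self.points = pts
        self.fps = float(fps)
        self.subject_id = subject_id
        self.frame_indices = idx
        self.metadata: dict[str, str] = dict(metadata or {})

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return self.points.shape[0]

    def __iter__(self) -> Iterator[LandmarkFrame]:
        for i in range(len(self)):
            yield LandmarkFrame(int(self.frame_indices[i]), self.points[i])

    @property
    def n_frames(self) -> int:
        return len(self)

    @property
    def is_contiguous(self) -> bool:
        return bool(np.all(np.diff(self.frame_indices) == 1))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkSequence):
            return NotImplemented
        return (
            self.fps == other.fps
            and self.subject_id == other.subject_id
            and self.metadata == other.metadata
            and np.array_equal(self.frame_indices, other.frame_indices)
            and np.array_equal(self.points, other.points)
        )

    def __repr__(self) -> str:
        return (
            f"LandmarkSequence(subject_id={self.subject_id!r}, n_frames={len(self)}, "
            f"fps={self.fps})"
        )


# ---------------------------------------------------------------------------
# File I/O


def _format_float(x: float) -> str:
    return repr(float(x))


def write_landmark_sequence(seq: LandmarkSequence, path: str | Path, format: str = "csv") -> Path:
    """Write *seq* to *path*; readable back bit-identically by
    :func:`read_landmark_sequence`."""
    path = Path(path)
    if format == "csv":
        with open(path, "w") as fh:
            header = f"# fps={_format_float(seq.fps)} subject={seq.subject_id}"
            fh.write(header + "\n")
            if seq.metadata:
                fh.write("# meta=" + json.dumps(seq.metadata, sort_keys=True) + "\n")
            fh.write("frame,landmark,x,y\n")
            for i, fi in enumerate(seq.frame_indices):
                for lm in range(seq.points.shape[1]):
                    x, y = seq.points[i, lm]
                    fh.write(f"{fi},{lm},{_format_float(x)},{_format_float(y)}\n")
    elif format == "json":
        doc = {
            "subject_id": seq.subject_id,
            "fps": seq.fps,
            "metadata": seq.metadata,
            "frames": [
                {"frame_index": int(fi), "points": seq.points[i].tolist()}
                for i, fi in enumerate(seq.frame_indices)
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'json')")
    return path


def read_landmark_sequence(path: str | Path, format: str | None = None) -> LandmarkSequence:
    """Read a landmark sequence from *path* (format inferred from the suffix
    unless given)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        return _read_csv(path)
    if format == "json":
        return _read_json(path)
    raise ValueError(f"unknown format {format!r} (expected 'csv' or 'json')")


def _read_csv(path: Path) -> LandmarkSequence:
    fps: float | None = None
    subject_id = ""
    metadata: dict[str, str] = {}
    n_comment = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            body = line[1:].strip()
            if body.startswith("meta="):
                metadata = json.loads(body[len("meta=") :])
                continue
            for token in body.split():
                key, _, value = token.partition("=")
                if key == "fps":
                    fps = float(value)
                elif key == "subject":
                    subject_id = value
    if fps is None:
        raise SchemaError(f"{path}: missing '# fps=...' header comment")
    df = pd.read_csv(path, skiprows=n_comment, float_precision="round_trip")
    required = {"frame", "landmark", "x", "y"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    n_lm = WFLW_SCHEME.n_landmarks
    frames = []
    indices = []
    for fi, grp in df.groupby("frame", sort=True):
        lms = grp["landmark"].to_numpy()
        if len(grp) != n_lm or not np.array_equal(np.sort(lms), np.arange(n_lm)):
            missing = sorted(set(range(n_lm)) - set(int(v) for v in lms))
            raise SchemaError(
                f"{path}: frame {fi} has {len(grp)} landmark rows "
                f"(missing {missing[:5]}{'...' if len(missing) > 5 else ''})"
            )
        ordered = grp.sort_values("landmark")[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(ordered)):
            raise ValidationError(f"{path}: non-finite coordinate in frame {fi}")
        frames.append(ordered)
        indices.append(int(fi))
    if not frames:
        raise SchemaError(f"{path}: no landmark rows")
    return LandmarkSequence(
        np.stack(frames), fps, subject_id, np.asarray(indices), metadata
    )


def _read_json(path: Path) -> LandmarkSequence:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        fps = float(doc["fps"])
        frames = doc["frames"]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: missing required key {exc}") from exc
    pts, indices = [], []
    for rec in frames:
        try:
            indices.append(int(rec["frame_index"]))
            arr = np.asarray(rec["points"], dtype=float)
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: malformed frame record: {exc}") from exc
        if arr.shape != (WFLW_SCHEME.n_landmarks, 2):
            raise SchemaError(
                f"{path}: frame {rec.get('frame_index')} has points of shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError(
                f"{path}: non-finite coordinate in frame {rec.get('frame_index')}"
            )
        pts.append(arr)
    if not pts:
        raise SchemaError(f"{path}: no frames")
    return LandmarkSequence(
        np.stack(pts),
        fps,
        str(doc.get("subject_id", "")),
        np.asarray(indices),
        doc.get("metadata") or {},
    )


# ---------------------------------------------------------------------------
# Gap handling


def interpolate_gaps(seq: LandmarkSequence, max_gap: int | None = None) -> LandmarkSequence:
    """Fill missing frames (non-contiguous ``frame_index``) by per-landmark
    linear interpolation.

    ``max_gap`` is the largest number of consecutive missing frames that may
    be filled; longer gaps raise :class:`ValidationError` reporting the span.
    Defaults to ``fps / 6`` frames (about 0.17 s of missing detections).
    """
    if max_gap is None:
        max_gap = max(1, round(seq.fps / 6))
    if seq.is_contiguous:
        return seq
    idx = seq.frame_indices
    gaps = np.diff(idx) - 1
    too_long = np.where(gaps > max_gap)[0]
    if too_long.size:
        i = int(too_long[0])
        raise ValidationError(
            f"gap of {int(gaps[i])} missing frames between frame_index {int(idx[i])} "
            f"and {int(idx[i + 1])} exceeds max_gap={max_gap}"
        )
    full = np.arange(idx[0], idx[-1] + 1)
    flat = seq.points.reshape(len(seq), -1)
    filled = np.empty((full.size, flat.shape[1]))
    for j in range(flat.shape[1]):
        filled[:, j] = np.interp(full, idx, flat[:, j])
    return LandmarkSequence(
        filled.reshape(full.size, WFLW_SCHEME.n_landmarks, 2),
        seq.fps,
        seq.subject_id,
        full,
        seq.metadata,
    )
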