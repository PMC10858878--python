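"""Synthetic landmark-sequence generator.

Emulates the recording protocol behind the cohort data — the subject holds
a neutral expression, shows their teeth, then closes the mouth — as a 98
point WFLW-topology landmark clip, with palsy severity exposed as explicit
parameters:

* ``movement_asymmetry`` in [0, 1]: the affected mouth corner's smile
  excursion is scaled by (1 - asymmetry) and its onset lagged proportionally
  (0.3 * asymmetry seconds), mimicking the weakened, delayed movement of a
  paretic side.  1 freezes the corner entirely.
* ``droop_offset`` (pixels): static downward displacement of the affected
  outer-lip half, tapered linearly from the corner (full offset) to the lip
  midline (zero) so the contour stays a simple polygon.
* ``landmark_noise_sd`` (pixels): i.i.d. Gaussian jitter on every landmark
  in every frame, standing in for frame-to-frame landmark-localization
  error.
* optional slow rigid head drift (translation + rotation), exercising the
  similarity invariance of the preprocessing.

The template face is a fixed, exactly mirror-symmetric layout (every left
landmark is constructed as the reflection of its right counterpart), so
with asymmetry, droop and noise all zero the generated clip is perfectly
symmetric and yields SMM = 1 and DMS = 0 to machine precision.  The face is
about 220 px wide; the smile moves each corner about 18 px outward/upward
over a raised-cosine ramp (1 s up, 1 s hold, 1 s release by default).
All randomness flows from ``seed`` via ``numpy.random.default_rng``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import SubjectRecord
from .errors import ValidationError
from .indices import IndexConfig, compute_indices
from .geometry import PreprocessConfig
from .landmark_io import LandmarkSequence

__all__ = [
    "SyntheticParams",
    "SyntheticSubject",
    "template_face",
    "generate_subject",
    "generate_cohort",
]

# Template geometry constants (pixels, image convention: y down).
_CX, _CY = 320.0, 240.0
_MOUTH_Y = _CY + 75.0
_MOUTH_HALF_WIDTH = 28.0
_DROOP_FULL_SCALE = 10.0  # droop_offset giving severity_scalar 1.0


@dataclass(frozen=True)
class SyntheticParams:
    """Generator parameters; defaults are a healthy 30 fps, 5 s clip."""

    fps: float = 30.0
    duration_seconds: float = 5.0
    smile_amplitude: float = 18.0
    movement_asymmetry: float = 0.0
    droop_offset: float = 0.0
    affected_side: str = "left"
    landmark_noise_sd: float = 0.0
    head_motion: str = "none"  # "none" | "slow-drift"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        if self.duration_seconds < 2:
            raise ValidationError("duration must be at least 2 s")
        if not (0.0 <= self.movement_asymmetry <= 1.0):
            raise ValidationError("movement_asymmetry must lie in [0, 1]")
        if self.landmark_noise_sd < 0:
            raise ValidationError("landmark_noise_sd must be >= 0")
        if self.affected_side not in ("left", "right"):
            raise ValidationError("affected_side must be 'left' or 'right'")
        if self.head_motion not in ("none", "slow-drift"):
            raise ValidationError("head_motion must be 'none' or 'slow-drift'")

    @property
    def severity_scalar(self) -> float:
        return max(self.movement_asymmetry, self.droop_offset / _DROOP_FULL_SCALE)


@dataclass(frozen=True)
class SyntheticSubject:
    sequence: LandmarkSequence
    params: SyntheticParams
    truth: dict = field(default_factory=dict)  # {"is_palsy": bool, "severity_scalar": float}


def _mirror_pairs(out: np.ndarray, pairs: list[tuple[int, int]]) -> None:
    """Set each left landmark to the exact reflection of its right partner."""
    for right, left in pairs:
        out[left, 0] = 2.0 * _CX - out[right, 0]
        out[left, 1] = out[right, 1]


def template_face() -> np.ndarray:
    """The neutral 98-landmark template (WFLW topology), exactly symmetric
    about the vertical line x = 320."""
    p = np.zeros((98, 2))
    # Face contour 0-32: half-ellipse from right temple through the chin;
    # left half mirrored exactly from the right half.
    for i in range(17):  # 0..16, right temple to chin
        phi = math.pi * i / 32.0
        p[i] = (_CX - 110.0 * math.cos(phi), _CY - 40.0 + 180.0 * math.sin(phi))
    _mirror_pairs(p, [(i, 32 - i) for i in range(16)])
    # Right eyebrow 33-41 (arc above the eye), left 42-50 mirrored.
    for k in range(9):
        phi = math.pi * (1.0 - k / 8.0)
        p[33 + k] = (_CX - 45.0 + 22.0 * math.cos(phi), _CY - 62.0 - 7.0 * math.sin(phi))
    _mirror_pairs(p, [(33 + k, 42 + k) for k in range(9)])
    # Nose bridge 51-54 on the midline, bottom 55-59 in a shallow arc.
    for k in range(4):
        p[51 + k] = (_CX, _CY - 35.0 + 15.0 * k)
    p[55] = (_CX - 14.0, _CY + 18.0)
    p[56] = (_CX - 7.0, _CY + 22.0)
    p[57] = (_CX, _CY + 24.0)
    _mirror_pairs(p, [(56, 58), (55, 59)])
    # Right eye 60-67 (60 outer corner, 61-63 top, 64 inner, 65-67 bottom).
    ex, ey = _CX - 45.0, _CY - 35.0
    eye = [(-18, 0), (-11, -7), (0, -9), (11, -7), (18, 0), (11, 7), (0, 9), (-11, 7)]
    for k, (dx, dy) in enumerate(eye):
        p[60 + k] = (ex + dx, ey + dy)
    # Left eye 68-75 mirrored index-for-index, so bottoms 65-67 <-> 73-75.
    _mirror_pairs(p, [(60 + k, 68 + k) for k in range(8)])
    # Outer lip 76-87 (76 right corner, 79 top center, 82 left corner,
    # 85 bottom center) and inner lip 88-95.
    p[76] = (_CX - _MOUTH_HALF_WIDTH, _MOUTH_Y)
    p[77] = (_CX - 18.0, _MOUTH_Y - 9.0)
    p[78] = (_CX - 9.0, _MOUTH_Y - 12.0)
    p[79] = (_CX, _MOUTH_Y - 13.0)
    p[85] = (_CX, _MOUTH_Y + 15.0)
    p[86] = (_CX - 9.0, _MOUTH_Y + 14.0)  # right-bottom, mirrored to 84
    p[87] = (_CX - 18.0, _MOUTH_Y + 11.0)
    _mirror_pairs(p, [(78, 80), (77, 81), (76, 82), (87, 83), (86, 84)])
    p[88] = (_CX - 20.0, _MOUTH_Y)
    p[89] = (_CX - 10.0, _MOUTH_Y - 5.0)
    p[90] = (_CX, _MOUTH_Y - 6.0)
    p[94] = (_CX, _MOUTH_Y + 7.0)
    p[95] = (_CX - 10.0, _MOUTH_Y + 6.0)
    _mirror_pairs(p, [(89, 91), (88, 92), (95, 93)])
    # Pupils.
    p[96] = (ex, ey)
    _mirror_pairs(p, [(96, 97)])
    return p


def _envelope(times: np.ndarray, duration: float) -> tuple[np.ndarray, float]:
    """Raised-cosine neutral -> smile -> close envelope in [0, 1].

    Returns the envelope and the phase length (ramp = hold = release) so
    the affected-side lag can be expressed in the same units.  Short clips
    compress the three active phases proportionally.
    """
    active = min(3.0, max(duration - 0.5, duration / 2.0))
    phase = active / 3.0
    t0 = (duration - active) / 2.0
    e = np.zeros_like(times)
    rise = (times >= t0) & (times < t0 + phase)
    hold = (times >= t0 + phase) & (times < t0 + 2 * phase)
    fall = (times >= t0 + 2 * phase) & (times < t0 + 3 * phase)
    e[rise] = 0.5 * (1 - np.cos(math.pi * (times[rise] - t0) / phase))
    e[hold] = 1.0
    e[fall] = 0.5 * (1 + np.cos(math.pi * (times[fall] - t0 - 2 * phase) / phase))
    return e, phase


# Per-landmark smile displacement = amplitude * envelope * (0.85*s, -0.5*|s|)
# where s in [-1, 1] is the landmark's lateral position relative to the
# mouth corners (negative = anatomical right).  Mouth landmarks only.
_MOUTH_IDX = np.arange(76, 96)


def generate_subject(params: SyntheticParams) -> SyntheticSubject:
    """Generate one subject's landmark clip; deterministic given
    ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n = int(round(params.fps * params.duration_seconds))
    times = np.arange(n) / params.fps
    base = template_face()
    s = (base[_MOUTH_IDX, 0] - _CX) / _MOUTH_HALF_WIDTH  # lateral factor
    s = np.clip(s, -1.0, 1.0)
    affected = s < 0 if params.affected_side == "right" else s > 0
    gain = np.where(affected, 1.0 - params.movement_asymmetry, 1.0)

    env, _ = _envelope(times, params.duration_seconds)
    lag = 0.3 * params.movement_asymmetry
    env_lagged, _ = _envelope(times - lag, params.duration_seconds)
    env_per_lm = np.where(affected[None, :], env_lagged[:, None], env[:, None])

    dx = params.smile_amplitude * 0.85 * s[None, :] * gain[None, :] * env_per_lm
    dy = -params.smile_amplitude * 0.5 * np.abs(s)[None, :] * gain[None, :] * env_per_lm
    droop = params.droop_offset * np.abs(s) * affected  # static, tapered

    pts = np.broadcast_to(base, (n, 98, 2)).copy()
    pts[:, _MOUTH_IDX, 0] += dx
    pts[:, _MOUTH_IDX, 1] += dy + droop[None, :]

    if params.head_motion == "slow-drift":
        shift = np.column_stack(
            [3.0 * np.sin(2 * math.pi * 0.2 * times), 2.0 * np.cos(2 * math.pi * 0.15 * times)]
        )
        theta = 0.02 * np.sin(2 * math.pi * 0.1 * times)
        c, sn = np.cos(theta), np.sin(theta)
        rel = pts - np.array([_CX, _CY])
        rot = np.empty_like(rel)
        rot[..., 0] = c[:, None] * rel[..., 0] - sn[:, None] * rel[..., 1]
        rot[..., 1] = sn[:, None] * rel[..., 0] + c[:, None] * rel[..., 1]
        pts = rot + np.array([_CX, _CY]) + shift[:, None, :]

    if params.landmark_noise_sd > 0:
        pts = pts + rng.normal(0.0, params.landmark_noise_sd, size=pts.shape)

    seq = LandmarkSequence(pts, params.fps, subject_id=f"synthetic-{params.seed}")
    sev = params.severity_scalar
    return SyntheticSubject(
        sequence=seq, params=params, truth={"is_palsy": sev > 0.1, "severity_scalar": sev}
    )


def generate_cohort(
    n_healthy: int,
    n_palsy: int,
    severity_range: tuple[float, float] = (0.4, 1.0),
    seed: int = 0,
    fps: float = 30.0,
    duration_seconds: float = 5.0,
    noise_sd: float = 0.3,
    pre_cfg: PreprocessConfig = PreprocessConfig(),
    idx_cfg: IndexConfig = IndexConfig(),
) -> tuple[list[SyntheticSubject], list[SubjectRecord]]:
    """Generate a cohort, run the full index pipeline on every subject, and
    return (subjects, records) ready for the statistics/classifier stages.

    Healthy subjects get near-zero asymmetry and droop with small jitter;
    palsy subjects draw a severity scalar from ``severity_range`` mapped to
    asymmetry 0.85*s and droop 9*s px, split mild (s < 0.6) / severe.
    """
    if n_healthy < 1 or n_palsy < 1:
        raise ValidationError("need at least one subject per group")
    rng = np.random.default_rng(seed)
    subjects: list[SyntheticSubject] = []
    records: list[SubjectRecord] = []

    def _run(sid: str, group: str, params: SyntheticParams) -> None:
        subj = generate_subject(params)
        subj.sequence.subject_id = sid
        pair = compute_indices(subj.sequence, pre_cfg=pre_cfg, idx_cfg=idx_cfg)
        if pair.smm is None:
            raise ValidationError(f"{sid}: SMM undefined (motionless corner)")
        subjects.append(subj)
        records.append(SubjectRecord(sid, group, pair.smm, pair.dms))

    common = dict(fps=fps, duration_seconds=duration_seconds, landmark_noise_sd=noise_sd)
    for i in range(n_healthy):
        params = SyntheticParams(
            movement_asymmetry=min(abs(rng.normal(0.0, 0.02)), 1.0),
            droop_offset=abs(rng.normal(0.0, 0.3)),
            smile_amplitude=18.0 * (1.0 + rng.normal(0.0, 0.1)),
            seed=int(rng.integers(2**31)),
            **common,
        )
        _run(f"synthetic-healthy-{i + 1}", "healthy", params)
    lo, hi = severity_range
    for i in range(n_palsy):
        sev = float(rng.uniform(lo, hi))
        # baseline jitter matches the healthy draw so severity 0 is
        # distributionally identical to a healthy subject
        params = SyntheticParams(
            movement_asymmetry=min(
                0.85 * sev * (1.0 + rng.normal(0.0, 0.05)) + abs(rng.normal(0.0, 0.02)), 1.0
            ),
            droop_offset=9.0 * sev * max(1.0 + rng.normal(0.0, 0.1), 0.0)
            + abs(rng.normal(0.0, 0.3)),
            smile_amplitude=18.0 * (1.0 + rng.normal(0.0, 0.1)),
            affected_side="left" if rng.random() < 0.5 else "right",
            seed=int(rng.integers(2**31)),
            **common,
        )
        _run(f"synthetic-palsy-{i + 1}", "mild" if sev < 0.6 else "severe", params)
    return subjects, records
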