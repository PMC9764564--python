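"""Head-motion quality control: framewise displacement and relative RMS.

Two scalar motion summaries are computed from the T x 6 rigid-body
realignment parameters and carried into group statistics as nuisance
covariates:

* mean framewise displacement (FD, Power convention): per frame, the sum of
  absolute translation deltas plus the absolute rotation deltas converted to
  arc length on a 50 mm sphere;
* mean relative RMS: the root-mean-square of the frame-to-frame translation
  displacement norms.  (The matrix-based RMS of a full affine realignment
  needs transforms that plain parameter tables do not carry; the delta-norm
  definition is used and recorded in the run metadata.)

Both depend only on frame-to-frame deltas, so a constant offset of the whole
trace changes nothing.  A separate inclusion gate rejects subjects whose
cumulative motion exceeds 2.5 mm translation on any axis or 2.5 degrees
rotation (inclusive bounds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import MotionParams

__all__ = [
    "MotionSummary",
    "framewise_displacement",
    "relative_rms",
    "motion_gate",
    "summarize_motion",
]

DEFAULT_HEAD_RADIUS_MM = 50.0
GATE_TRANSLATION_MM = 2.5
GATE_ROTATION_DEG = 2.5


@dataclass(frozen=True)
class MotionSummary:
    """Per-subject motion scalars, all non-negative (mm / radians)."""

    subject_id: str
    mean_fd: float
    mean_rms: float
    max_abs_translation: float
    max_abs_rotation: float


def framewise_displacement(motion: MotionParams,
                           head_radius: float = DEFAULT_HEAD_RADIUS_MM
                           ) -> tuple[np.ndarray, float]:
    """Per-frame FD vector (first frame 0) and its mean over frames 2..T."""
    if motion.n_frames < 2:
        raise ValidationError(
            f"{motion.subject_id}: framewise displacement needs >= 2 frames"
        )
    deltas = np.abs(np.diff(motion.values, axis=0))
    fd = deltas[:, :3].sum(axis=1) + head_radius * deltas[:, 3:].sum(axis=1)
    per_frame = np.concatenate([[0.0], fd])
    return per_frame, float(fd.mean())


def relative_rms(motion: MotionParams) -> float:
    """RMS over frames of the Euclidean norm of translation deltas."""
    if motion.n_frames < 2:
        raise ValidationError(f"{motion.subject_id}: relative RMS needs >= 2 frames")
    deltas = np.diff(motion.translations, axis=0)
    norms_sq = (deltas ** 2).sum(axis=1)
    return float(np.sqrt(norms_sq.mean()))


def motion_gate(motion: MotionParams,
                max_translation: float = GATE_TRANSLATION_MM,
                max_rotation_deg: float = GATE_ROTATION_DEG
                ) -> tuple[bool, list[str]]:
    """Inclusion gate on cumulative motion; returns (passed, reasons).

    Bounds are inclusive: a rotation of exactly 2.5 degrees passes.
    """
    reasons: list[str] = []
    trans = motion.translations
    rot_deg = np.rad2deg(motion.rotations)
    for axis, label in enumerate(("x", "y", "z")):
        peak = float(np.abs(trans[:, axis]).max(initial=0.0))
        if peak > max_translation:
            reasons.append(
                f"translation {label}-axis reached {peak:.3g} mm "
                f"(limit {max_translation:g} mm)"
            )
    for axis, label in enumerate(("pitch", "roll", "yaw")):
        peak = float(np.abs(rot_deg[:, axis]).max(initial=0.0))
        if peak > max_rotation_deg:
            reasons.append(
                f"rotation {label} reached {peak:.3g} deg "
                f"(limit {max_rotation_deg:g} deg)"
            )
    return (not reasons), reasons


def summarize_motion(motion: MotionParams,
                     head_radius: float = DEFAULT_HEAD_RADIUS_MM) -> MotionSummary:
    _, mean_fd = framewise_displacement(motion, head_radius)
    return MotionSummary(
        subject_id=motion.subject_id,
        mean_fd=mean_fd,
        mean_rms=relative_rms(motion),
        max_abs_translation=float(np.abs(motion.translations).max(initial=0.0)),
        max_abs_rotation=float(np.abs(motion.rotations).max(initial=0.0)),
    )
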