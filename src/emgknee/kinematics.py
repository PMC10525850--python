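"""Knee-joint angle from three sagittal motion-capture markers.

The thigh and shank are modelled as a two-segment linkage through markers
A (thigh), B (knee rotation centre) and C (shank).  The knee angle is the
angle between the *extension line* of the thigh chain and the shank chain:

    theta = 180 deg - arccos( l1 . l2 / (|l1| |l2|) )

with l1 = A - B and l2 = C - B.  A straight leg (A, B, C collinear with C
opposite A) gives 0 deg; a right angle between the segments gives 90 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MarkerFrame", "knee_angle", "angle_series"]


@dataclass(frozen=True)
class MarkerFrame:
    """One synchronized triple of marker positions, in millimetres."""

    p_a: np.ndarray
    p_b: np.ndarray
    p_c: np.ndarray

    def __post_init__(self) -> None:
        for name in ("p_a", "p_b", "p_c"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
            if getattr(self, name).shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")


def knee_angle(frame: MarkerFrame) -> float:
    """Knee angle in degrees for one marker frame, confined to [0, 180].

    Raises ``ValueError`` if either limb vector has zero length.
    """
    l1 = frame.p_a - frame.p_b
    l2 = frame.p_c - frame.p_b
    n1 = np.linalg.norm(l1)
    n2 = np.linalg.norm(l2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("degenerate limb: marker coincides with the knee centre")
    # clamp against floating-point overshoot before arccos
    cosang = float(np.clip(np.dot(l1, l2) / (n1 * n2), -1.0, 1.0))
    return 180.0 - float(np.degrees(np.arccos(cosang)))


def angle_series(frames) -> np.ndarray:
    """Map :func:`knee_angle` over a sequence of frames.

    ``frames`` may be an iterable of :class:`MarkerFrame` or an
    ``(n, 3, 3)`` array with marker order A, B, C along the second axis.
    Per-frame failures are re-raised with the frame index attached.
    """
    if isinstance(frames, np.ndarray):
        if frames.ndim != 3 or frames.shape[1:] != (3, 3):
            raise ValueError("marker array must have shape (n, 3, 3)")
        frames = [MarkerFrame(f[0], f[1], f[2]) for f in frames]
    out = np.empty(len(frames), dtype=float)
    for i, frame in enumerate(frames):
        try:
            out[i] = knee_angle(frame)
        except ValueError as exc:
            raise ValueError(f"frame {i}: {exc}") from exc
    return out
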