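"""Rigid per-frame drift correction.

Stage drift over a 11-minute recording is dominated by in-plane translation,
so each frame is registered to a reference frame (the first, by default) by
phase correlation with sub-pixel refinement.  Rotation and scale are not
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .core_io import ImageStack

#: cross-correlation upsampling factor for sub-pixel refinement
UPSAMPLE_FACTOR = 10


@dataclass
class DriftTrack:
    """Per-frame (dy, dx) displacement relative to the reference frame.

    ``shifts[t]`` is the displacement OF frame t: the frame content sits at
    the reference position plus this vector.  ``flat_frames`` lists frames
    that were constant (zero variance) and therefore got shift (0, 0).
    """

    shifts: np.ndarray
    reference_frame: int = 0
    flat_frames: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must be a T x 2 array")
        if not np.all(np.isfinite(self.shifts)):
            raise ValueError("shifts contain non-finite values")
        if not np.allclose(self.shifts[self.reference_frame], 0.0):
            raise ValueError("shift of the reference frame must be (0, 0)")

    @property
    def n_frames(self) -> int:
        return self.shifts.shape[0]


def estimate_drift(stack: ImageStack, reference: int = 0) -> DriftTrack:
    """Estimate per-frame translation against a reference frame.

    Uses phase correlation with sub-pixel refinement (upsampling factor
    10).  A constant (zero-variance) frame cannot be registered; it gets
    shift (0, 0) and is recorded in ``flat_frames``.
    """
    frames = np.asarray(stack.frames, dtype=float)
    T = frames.shape[0]
    if T < 2:
        raise ValueError("drift estimation needs at least 2 frames")
    ref = frames[reference]
    ref_flat = np.ptp(ref) == 0
    shifts = np.zeros((T, 2))
    flat = []
    for t in range(T):
        if t == reference:
            continue
        if np.ptp(frames[t]) == 0 or ref_flat:
            flat.append(t)
            continue
        # phase_cross_correlation returns the shift that registers the
        # moving frame onto the reference; the frame's displacement is its
        # negation.
        reg_shift, _, _ = phase_cross_correlation(
            ref, frames[t], upsample_factor=UPSAMPLE_FACTOR, normalization=None
        )
        shifts[t] = -reg_shift
    return DriftTrack(shifts=shifts, reference_frame=reference, flat_frames=flat)


def apply_drift(stack: ImageStack, drift: DriftTrack) -> ImageStack:
    """Undo the measured drift by translating each frame by −shift.

    Translation uses cubic-spline interpolation; pixels exposed at the
    borders are filled with the frame's median so background statistics are
    minimally perturbed.  Output shape equals input shape.
    """
    frames = np.asarray(stack.frames, dtype=float)
    if drift.n_frames != frames.shape[0]:
        raise ValueError(
            f"drift track length {drift.n_frames} != stack length {frames.shape[0]}"
        )
    out = np.empty_like(frames)
    for t in range(frames.shape[0]):
        s = drift.shifts[t]
        if np.all(s == 0):
            out[t] = frames[t]
        else:
            out[t] = ndimage.shift(
                frames[t], -s, order=3, mode="constant",
                cval=float(np.median(frames[t])),
            )
    return ImageStack(
        frames=out,
        frame_interval_s=stack.frame_interval_s,
        stimulus_frame=stack.stimulus_frame,
        metadata={**stack.metadata, "drift_corrected": True},
    )
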