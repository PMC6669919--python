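"""Lateral stage-drift estimation and correction for time-lapses.

Drift is modeled as a rigid per-frame translation, estimated by phase
correlation of every frame against a single fixed reference (by default
a frame index; for FRAP movies the mean of the pre-bleach frames is a
good reference image) with subpixel refinement.  Correcting against one
fixed reference avoids accumulating error over long (120+ frame)
recordings, unlike sequential pairwise alignment.

Corrected frames are translated back with bilinear interpolation;
pixels whose source fell outside the field are marked NaN and excluded
from all downstream ROI statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

from .stack import ImageStack

__all__ = ["DriftTrajectory", "estimate_drift", "correct_drift", "prebleach_reference", "register_stack"]


@dataclass
class DriftTrajectory:
    """Per-frame content translation (dx, dy) in pixels relative to the reference.

    ``shifts[t] = (dx, dy)`` means the content of frame ``t`` is displaced
    by that vector with respect to the reference; correction translates
    the frame by the negative of it.
    """

    shifts: np.ndarray  # (T, 2) float, columns (dx, dy)
    reference_index: int | None

    def __post_init__(self) -> None:
        self.shifts = np.atleast_2d(np.asarray(self.shifts, dtype=np.float64))
        if self.shifts.shape[1] != 2:
            raise ValueError("shifts must be (T, 2)")

    @property
    def n_frames(self) -> int:
        return self.shifts.shape[0]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"frame": np.arange(self.n_frames), "dx": self.shifts[:, 0], "dy": self.shifts[:, 1]}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, reference_index: int | None = None) -> "DriftTrajectory":
        df = pd.read_csv(path)
        return cls(shifts=df[["dx", "dy"]].to_numpy(), reference_index=reference_index)


def _finite_filled(frame: np.ndarray) -> np.ndarray:
    """Replace NaN (invalid) pixels by the frame mean so FFTs stay finite."""
    if np.all(np.isfinite(frame)):
        return frame
    fill = np.nanmean(frame)
    if not np.isfinite(fill):
        raise ValueError("frame has no valid pixels")
    return np.where(np.isfinite(frame), frame, fill)


def estimate_drift(
    stack: ImageStack,
    reference: int = 0,
    reference_image: np.ndarray | None = None,
    upsample_factor: int = 50,
) -> DriftTrajectory:
    """Estimate per-frame translation against a fixed reference.

    Parameters
    ----------
    stack:
        Time-lapse with at least two frames.
    reference:
        Index of the reference frame (its shift is exactly (0, 0)).
    reference_image:
        Optional explicit reference (e.g. the mean of the pre-bleach
        frames, which has less noise than any single frame); overrides
        ``reference`` for the correlation.  The trajectory is then
        re-baselined so frame 0 has zero shift, keeping it in frame-0
        coordinates (where ROIs are defined).
    upsample_factor:
        Subpixel refinement factor of the phase correlation.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least two frames to estimate drift")
    if reference_image is None:
        ref = stack.data[reference]
        ref_index: int | None = int(reference)
    else:
        ref = np.asarray(reference_image, dtype=np.float64)
        ref_index = None
    ref = _finite_filled(ref)
    if np.ptp(ref) == 0:
        raise ValueError("reference frame has zero variance; shift undefined")

    shifts = np.zeros((stack.n_frames, 2), dtype=np.float64)
    for t in range(stack.n_frames):
        if ref_index is not None and t == ref_index:
            continue  # exactly (0, 0) by definition
        frame = _finite_filled(stack.data[t])
        if np.ptp(frame) == 0:
            raise ValueError(f"frame {t} has zero variance; shift undefined")
        # Returned value is the translation registering `frame` onto `ref`,
        # i.e. minus the content displacement.
        (sy, sx), _err, _phase = phase_cross_correlation(
            ref, frame, upsample_factor=upsample_factor, normalization=None
        )
        shifts[t] = (-sx, -sy)
    if ref_index is None:
        # express the trajectory relative to frame 0, where ROIs live
        shifts = shifts - shifts[0]
        ref_index = 0
    return DriftTrajectory(shifts=shifts, reference_index=ref_index)


def prebleach_reference(stack: ImageStack, n_prebleach: int, upsample_factor: int = 50) -> np.ndarray:
    """Low-noise reference image in frame-0 coordinates.

    The pre-bleach frames are first aligned to frame 0 (so their average
    is not smeared by the drift accumulated across them) and then
    averaged.  Averaging after alignment keeps the reference sharp while
    suppressing per-frame noise.
    """
    if not 1 <= n_prebleach <= stack.n_frames:
        raise ValueError("invalid pre-bleach frame count")
    if n_prebleach == 1:
        return stack.data[0].copy()
    sub = ImageStack(stack.data[:n_prebleach], stack.pixel_size_um, stack.frame_interval_s)
    traj = estimate_drift(sub, reference=0, upsample_factor=upsample_factor)
    aligned = correct_drift(sub, traj)
    return np.nanmean(aligned.data, axis=0)


def register_stack(
    stack: ImageStack, n_prebleach: int = 1, upsample_factor: int = 50
) -> tuple[ImageStack, DriftTrajectory]:
    """Estimate drift against the aligned pre-bleach mean and correct it."""
    ref = prebleach_reference(stack, n_prebleach, upsample_factor)
    traj = estimate_drift(stack, reference_image=ref, upsample_factor=upsample_factor)
    return correct_drift(stack, traj), traj


def correct_drift(stack: ImageStack, traj: DriftTrajectory) -> ImageStack:
    """Translate each frame by minus its drift (bilinear interpolation).

    Out-of-field pixels become NaN.  Frames with zero recorded shift are
    copied bit-identically.
    """
    if traj.n_frames != stack.n_frames:
        raise ValueError(
            f"trajectory length {traj.n_frames} does not match stack ({stack.n_frames} frames)"
        )
    out = np.empty_like(stack.data)
    for t in range(stack.n_frames):
        dx, dy = traj.shifts[t]
        if dx == 0.0 and dy == 0.0:
            out[t] = stack.data[t]
        else:
            out[t] = ndi.shift(
                stack.data[t], (-dy, -dx), order=1, mode="constant", cval=np.nan
            )
    return ImageStack(out, stack.pixel_size_um, stack.frame_interval_s)
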