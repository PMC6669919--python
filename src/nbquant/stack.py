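"""Calibrated image stacks, ROI sets and their sidecar I/O.

An :class:`ImageStack` is a ``(T, H, W)`` float array with physical
calibration (μm/px pixel size, seconds/frame interval).  Invalid pixels —
e.g. pixels that left the field of view during drift correction — are
marked ``NaN`` and excluded from all downstream ROI statistics.

ROIs are boolean masks over the frame; on disk they are stored as small
JSON sidecars built from geometric primitives (half-open pixel boxes and
disks) so that no binary data is needed.  Coordinates are 0-based pixel
indices, x to the right, y down.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "ROISet", "box_mask", "disk_mask"]


def box_mask(shape: tuple[int, int], x0: int, y0: int, x1: int, y1: int) -> np.ndarray:
    """Boolean mask for the half-open pixel box [y0:y1, x0:x1]."""
    if not (0 <= x0 < x1 <= shape[1] and 0 <= y0 < y1 <= shape[0]):
        raise ValueError(f"box ({x0},{y0})-({x1},{y1}) outside image of shape {shape}")
    m = np.zeros(shape, dtype=bool)
    m[y0:y1, x0:x1] = True
    return m


def disk_mask(shape: tuple[int, int], cx: float, cy: float, r: float) -> np.ndarray:
    """Boolean mask of pixels whose centers lie within radius r of (cx, cy)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def _mask_from_spec(spec: dict, shape: tuple[int, int]) -> np.ndarray:
    kind = spec["kind"]
    if kind == "box":
        return box_mask(shape, spec["x0"], spec["y0"], spec["x1"], spec["y1"])
    if kind == "disk":
        return disk_mask(shape, spec["cx"], spec["cy"], spec["r"])
    if kind == "mask":
        m = np.asarray(spec["data"], dtype=bool)
        if m.shape != shape:
            raise ValueError("mask ROI shape does not match image")
        return m
    raise ValueError(f"unknown ROI kind {kind!r}")


@dataclass
class ImageStack:
    """A 2D time-lapse with physical calibration.

    Parameters
    ----------
    data:
        ``(T, H, W)`` array; converted to float64.  ``NaN`` marks invalid
        pixels.
    pixel_size_um:
        Lateral pixel size in μm per pixel.
    frame_interval_s:
        Time between consecutive frames in seconds.
    """

    data: np.ndarray
    pixel_size_um: float = 1.0
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be (T, H, W)")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame, t=0 at frame 0."""
        return np.arange(self.n_frames) * self.frame_interval_s

    def save(self, path: str | Path) -> None:
        """Write a multi-page float32 TIFF plus a JSON metadata sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.data.astype(np.float32))
        meta = {
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ImageStack":
        path = Path(path)
        data = tifffile.imread(path)
        meta_path = path.with_suffix(".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            data=np.asarray(data, dtype=np.float64),
            pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
            frame_interval_s=float(meta.get("frame_interval_s", 1.0)),
        )


@dataclass
class ROISet:
    """Bleach / whole-structure / background regions for FRAP extraction.

    Invariants (checked by :meth:`validate`): the bleach ROI is contained
    in the total (whole-structure) ROI and the background ROI is disjoint
    from the total ROI.
    """

    bleach: np.ndarray
    total: np.ndarray
    background: np.ndarray
    specs: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.bleach = np.asarray(self.bleach, dtype=bool)
        self.total = np.asarray(self.total, dtype=bool)
        self.background = np.asarray(self.background, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if not (self.bleach.shape == self.total.shape == self.background.shape):
            raise ValueError("ROI masks must share one shape")
        for name, m in [("bleach", self.bleach), ("total", self.total), ("background", self.background)]:
            if not m.any():
                raise ValueError(f"{name} ROI is empty")
        if np.any(self.bleach & ~self.total):
            raise ValueError("bleach ROI must be contained in the total ROI")
        if np.any(self.background & self.total):
            raise ValueError("background ROI must be disjoint from the total ROI")

    def inset_bleach(self, px: int = 1) -> "ROISet":
        """Measurement ROI eroded ``px`` pixels inward from the bleach area.

        Boundary pixels of the bleached region are corrupted by subpixel
        resampling during drift correction (and, in real recordings, by
        diffusion during the bleach pulse); measuring in the interior
        avoids them.  The background and total ROIs are unchanged.
        """
        from scipy import ndimage as ndi

        eroded = ndi.binary_erosion(self.bleach, iterations=px)
        if not eroded.any():
            raise ValueError(f"inset of {px} px empties the bleach ROI")
        return ROISet(bleach=eroded, total=self.total, background=self.background)

    def to_json(self, path: str | Path) -> None:
        """Serialize; geometric specs are used when available, else raw masks."""
        if self.specs is not None:
            payload = self.specs
        else:
            payload = {
                name: {"kind": "mask", "data": getattr(self, name).astype(int).tolist()}
                for name in ("bleach", "total", "background")
            }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path, shape: tuple[int, int]) -> "ROISet":
        specs = json.loads(Path(path).read_text())
        return cls(
            bleach=_mask_from_spec(specs["bleach"], shape),
            total=_mask_from_spec(specs["total"], shape),
            background=_mask_from_spec(specs["background"], shape),
            specs=specs,
        )

    @classmethod
    def from_specs(cls, specs: dict, shape: tuple[int, int]) -> "ROISet":
        return cls(
            bleach=_mask_from_spec(specs["bleach"], shape),
            total=_mask_from_spec(specs["total"], shape),
            background=_mask_from_spec(specs["background"], shape),
            specs=specs,
        )
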