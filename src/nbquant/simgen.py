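"""Synthetic microscopy generator with known ground truth.

Two generators are provided:

* :func:`make_field` renders a single-timepoint multi-channel field of
  nuclei containing bright subnuclear bodies (condensates), with a cargo
  channel whose true inside/surround enrichment ratio is set exactly —
  the substrate for segmentation, enrichment and foci-counting analyses.
* :func:`make_frap_movie` renders a photobleaching time-lapse: a square
  region inside a nuclear body is bleached between the last pre-bleach
  and the first post-bleach frame, and recovers as a sum of a fast and a
  slow exponentially exchanging population plus an immobile remainder.

Both emulate camera offset, shot noise (Poisson on the scaled signal),
Gaussian read noise and, for movies, global acquisition photobleaching
and lateral stage drift.  Every output is fully determined by the seeds
in the parameter objects, and a serializable :class:`GroundTruth` records
everything a parameter-recovery test needs.

Recovery model
--------------
The noiseless bleach-ROI signal at post-bleach time t is

    offset + B(t) * I0 * [1 - depth * g(t)],
    g(t) = f_imm + f_fast * exp(-t/tau_fast) + f_slow * exp(-t/tau_slow),

with B(t) = exp(-acquisition_bleach_rate * frame_index) the global
acquisition-bleaching factor.  The structure is modeled as exchanging
with an effectively unlimited unbleached nucleoplasmic reservoir, so
pixels of the structure outside the bleach ROI stay at I0 * B(t) and the
whole-structure signal decays only by B(t) plus the current bleached
fluorophore deficit depth * S * g(t) (S = pre-bleach ROI flux).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .stack import ImageStack, ROISet, box_mask, disk_mask

__all__ = [
    "SimFieldParams",
    "FrapSimParams",
    "GroundTruth",
    "SimField",
    "FrapMovie",
    "make_field",
    "make_frap_movie",
    "frap_field_params",
]


@dataclass
class SimFieldParams:
    """Geometry, intensity and noise model of a synthetic field.

    Intensities are detector counts.  ``poisson_scale`` converts counts to
    photon-equivalents before Poisson sampling (variance = counts /
    poisson_scale); ``math.inf`` disables shot noise.  ``camera_offset``
    is a constant added to every pixel, the background term of the FRAP
    normalization equation.
    """

    field_size_px: tuple[int, int] = (512, 512)  # (height, width)
    pixel_size_um: float = 0.2
    n_nuclei: int = 8
    nucleus_radius_um: float = 4.0
    nucleus_radius_jitter: float = 0.1  # fractional radius jitter
    bodies_per_nucleus_mean: float = 5.0
    bodies_per_nucleus_dispersion: float = math.inf  # inf -> Poisson counts
    body_radius_um: float = 0.5
    body_peak_over_nucleoplasm: float = 5.0
    cargo_enrichment: float = 2.0
    nucleoplasm_intensity: float = 100.0
    camera_offset: float = 100.0
    gaussian_read_noise_sd: float = 5.0
    poisson_scale: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.field_size_px
        if h < 8 or w < 8:
            raise ValueError("field too small")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.nucleus_radius_um / self.pixel_size_um < 1:
            raise ValueError("nucleus radius below one pixel")
        if self.body_radius_um / self.pixel_size_um < 1:
            raise ValueError("body radius below one pixel")
        if not 0 <= self.nucleus_radius_jitter < 1:
            raise ValueError("jitter must be in [0, 1)")
        if self.bodies_per_nucleus_mean < 0:
            raise ValueError("bodies_per_nucleus_mean must be nonnegative")
        if self.body_peak_over_nucleoplasm <= 0 or self.cargo_enrichment <= 0:
            raise ValueError("enrichment factors must be positive")
        if self.camera_offset < 0 or self.gaussian_read_noise_sd < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.poisson_scale <= 0:
            raise ValueError("poisson_scale must be positive (inf disables shot noise)")
        # A body must fit inside the smallest jittered nucleus with a margin.
        r_nuc_min = self.nucleus_radius_um * (1 - self.nucleus_radius_jitter)
        r_body_px = self.body_radius_um / self.pixel_size_um
        if self.bodies_per_nucleus_mean > 0 and (
            r_body_px + 2 > r_nuc_min / self.pixel_size_um
        ):
            raise ValueError("geometry infeasible: bodies cannot fit inside nuclei")

    @property
    def nucleus_radius_px(self) -> float:
        return self.nucleus_radius_um / self.pixel_size_um

    @property
    def body_radius_px(self) -> float:
        return self.body_radius_um / self.pixel_size_um


@dataclass
class FrapSimParams:
    """Acquisition and kinetic parameters of a synthetic FRAP movie.

    The default acquisition matches a 120-point, 600 s recovery recording
    at 5 s per frame with a 2.02 × 2.02 μm bleach square.  Population
    fractions must sum to 1; the true mobile fraction is
    ``frac_fast + frac_slow``.  ``dead_time_s`` is the (instrument-
    dependent) delay between the bleach pulse and the first recovery
    frame, exposed as a parameter because it varies between setups.
    """

    n_prebleach_frames: int = 5
    n_postbleach_frames: int = 120
    frame_interval_s: float = 5.0
    bleach_depth: float = 0.7
    frac_fast: float = 0.5
    frac_slow: float = 0.3
    frac_immobile: float = 0.2
    tau_fast_s: float = 5.0
    tau_slow_s: float = 60.0
    acquisition_bleach_rate: float = 0.002  # per frame
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)  # (dx, dy)
    bleach_side_um: float = 2.02
    dead_time_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_prebleach_frames < 1:
            raise ValueError("need at least one pre-bleach frame")
        if self.n_postbleach_frames < 2:
            raise ValueError("need at least two post-bleach frames")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if not 0 <= self.bleach_depth <= 1:
            raise ValueError("bleach_depth must be in [0, 1]")
        fracs = (self.frac_fast, self.frac_slow, self.frac_immobile)
        if any(f < 0 for f in fracs):
            raise ValueError("population fractions must be nonnegative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("population fractions must sum to 1")
        if not 0 < self.tau_fast_s < self.tau_slow_s:
            raise ValueError("need 0 < tau_fast_s < tau_slow_s")
        if self.acquisition_bleach_rate < 0:
            raise ValueError("acquisition_bleach_rate must be nonnegative")
        if self.bleach_side_um <= 0:
            raise ValueError("bleach_side_um must be positive")
        if self.dead_time_s < 0:
            raise ValueError("dead_time_s must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.n_prebleach_frames + self.n_postbleach_frames

    @property
    def mobile_fraction(self) -> float:
        return self.frac_fast + self.frac_slow

    def unrecovered_fraction(self, t_s: np.ndarray | float) -> np.ndarray:
        """g(t): fraction of the bleach-ROI deficit still unrecovered at time t."""
        t = np.asarray(t_s, dtype=float)
        return (
            self.frac_immobile
            + self.frac_fast * np.exp(-t / self.tau_fast_s)
            + self.frac_slow * np.exp(-t / self.tau_slow_s)
        )


@dataclass
class NucleusTruth:
    nucleus_id: int
    cx: float
    cy: float
    radius_px: float
    n_bodies: int


@dataclass
class BodyTruth:
    body_id: int
    nucleus_id: int
    cx: float
    cy: float
    radius_px: float
    enrichment: float


@dataclass
class GroundTruth:
    """Everything the generator knows, for parameter-recovery oracles."""

    field_params: dict
    frap_params: dict | None
    nuclei: list
    bodies: list
    drift_px: list | None  # per-frame (dx, dy), frame-0 relative
    mobile_fraction: float | None
    bleach_roi_flux: float | None  # pre-bleach noiseless ROI flux, offset excluded
    total_flux: float | None  # pre-bleach noiseless whole-structure flux

    def to_dict(self) -> dict:
        d = asdict(self)
        return json.loads(json.dumps(d))  # normalize tuples -> lists

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["nuclei"] = [NucleusTruth(**n) for n in d["nuclei"]]
        d["bodies"] = [BodyTruth(**b) for b in d["bodies"]]
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SimField:
    """A rendered multi-channel field: noisy channels, clean channels, truth."""

    channels: dict  # name -> (H, W) noisy array
    clean: dict  # name -> (H, W) noiseless array (offset included)
    truth: GroundTruth
    pixel_size_um: float


@dataclass
class FrapMovie:
    """A rendered FRAP time-lapse with ROIs and ground truth."""

    stack: ImageStack  # noisy
    clean: np.ndarray  # (T, H, W) noiseless, offset included
    rois: ROISet
    truth: GroundTruth
    n_prebleach: int


def _apply_noise(clean_signal: np.ndarray, params: SimFieldParams, rng: np.random.Generator) -> np.ndarray:
    """Shot + read noise + offset on a noiseless, offset-free signal."""
    out = clean_signal
    if math.isfinite(params.poisson_scale):
        lam = np.clip(clean_signal, 0, None) * params.poisson_scale
        out = rng.poisson(lam).astype(np.float64) / params.poisson_scale
    out = out + params.camera_offset
    if params.gaussian_read_noise_sd > 0:
        out = out + rng.normal(0.0, params.gaussian_read_noise_sd, size=out.shape)
    return out


def _sample_body_count(params: SimFieldParams, rng: np.random.Generator) -> int:
    mean = params.bodies_per_nucleus_mean
    if mean == 0:
        return 0
    disp = params.bodies_per_nucleus_dispersion
    if math.isinf(disp):
        return int(rng.poisson(mean))
    # Negative binomial with variance mean + mean^2/dispersion.
    p = disp / (disp + mean)
    return int(rng.negative_binomial(disp, p))


def _place_nuclei(params: SimFieldParams, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    h, w = params.field_size_px
    placed: list[tuple[float, float, float]] = []
    tries = 0
    while len(placed) < params.n_nuclei:
        tries += 1
        if tries > 20000:
            raise ValueError(
                f"could not place {params.n_nuclei} non-overlapping nuclei in a "
                f"{h}x{w} field; reduce n_nuclei or nucleus radius"
            )
        r = params.nucleus_radius_px * (
            1 + params.nucleus_radius_jitter * rng.uniform(-1, 1)
        )
        margin = r + 2
        if 2 * margin >= min(h, w):
            raise ValueError("nucleus radius too large for field")
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        if all((cx - x) ** 2 + (cy - y) ** 2 > (r + rr + 2) ** 2 for x, y, rr in placed):
            placed.append((cx, cy, r))
    return placed


def _place_bodies(
    nucleus: tuple[float, float, float],
    n_bodies: int,
    r_body: float,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    cx, cy, r_nuc = nucleus
    limit = r_nuc - r_body - 2
    if n_bodies > 0 and limit <= 0:
        raise ValueError("geometry infeasible: bodies cannot fit inside nuclei")
    centers: list[tuple[float, float]] = []
    for _ in range(n_bodies):
        for _try in range(2000):
            rho = limit * math.sqrt(rng.uniform())
            phi = rng.uniform(0, 2 * math.pi)
            bx, by = cx + rho * math.cos(phi), cy + rho * math.sin(phi)
            if all((bx - x) ** 2 + (by - y) ** 2 > (2 * r_body + 2) ** 2 for x, y in centers):
                centers.append((bx, by))
                break
        # if the nucleus is too crowded we keep the bodies placed so far;
        # GroundTruth always records the rendered configuration
    return centers


def make_field(params: SimFieldParams) -> SimField:
    """Render a multi-channel field of nuclei with subnuclear bodies.

    Channels: ``nuclei`` (nuclear marker, uniform inside each nucleus),
    ``bodies`` (body marker, ``body_peak_over_nucleoplasm`` times brighter
    inside bodies) and ``cargo`` (the assayed protein, exactly
    ``cargo_enrichment`` times brighter inside bodies than in the
    surrounding nucleoplasm, before noise).
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.field_size_px
    shape = (h, w)
    base = params.nucleoplasm_intensity

    nuclei = _place_nuclei(params, rng)
    nucleus_mask = np.zeros(shape, dtype=bool)
    for cx, cy, r in nuclei:
        nucleus_mask |= disk_mask(shape, cx, cy, r)

    nuclei_truth, bodies_truth = [], []
    body_mask = np.zeros(shape, dtype=bool)
    r_body = params.body_radius_px
    body_id = 0
    for i, nuc in enumerate(nuclei, start=1):
        n_bodies = _sample_body_count(params, rng)
        centers = _place_bodies(nuc, n_bodies, r_body, rng)
        for bx, by in centers:
            body_id += 1
            body_mask |= disk_mask(shape, bx, by, r_body)
            bodies_truth.append(
                BodyTruth(
                    body_id=body_id,
                    nucleus_id=i,
                    cx=bx,
                    cy=by,
                    radius_px=r_body,
                    enrichment=params.cargo_enrichment,
                )
            )
        nuclei_truth.append(
            NucleusTruth(nucleus_id=i, cx=nuc[0], cy=nuc[1], radius_px=nuc[2], n_bodies=len(centers))
        )

    nuc_ch = np.where(nucleus_mask, base, 0.0)
    body_ch = np.where(nucleus_mask, base, 0.0)
    body_ch[body_mask] = base * params.body_peak_over_nucleoplasm
    cargo_ch = np.where(nucleus_mask, base, 0.0)
    cargo_ch[body_mask] = base * params.cargo_enrichment

    clean = {
        "nuclei": nuc_ch + params.camera_offset,
        "bodies": body_ch + params.camera_offset,
        "cargo": cargo_ch + params.camera_offset,
    }
    noisy = {
        "nuclei": _apply_noise(nuc_ch, params, rng),
        "bodies": _apply_noise(body_ch, params, rng),
        "cargo": _apply_noise(cargo_ch, params, rng),
    }
    truth = GroundTruth(
        field_params=asdict(params),
        frap_params=None,
        nuclei=nuclei_truth,
        bodies=bodies_truth,
        drift_px=None,
        mobile_fraction=None,
        bleach_roi_flux=None,
        total_flux=None,
    )
    return SimField(channels=noisy, clean=clean, truth=truth, pixel_size_um=params.pixel_size_um)


def frap_field_params(seed: int = 0, snr: float = 20.0, **overrides) -> SimFieldParams:
    """Field geometry/noise defaults for FRAP movies.

    One nucleus (the "entire cellular structure" of the normalization
    equation) containing one large body that accommodates the 2.02 μm
    bleach square.  SNR is defined as the pre-bleach bleach-ROI pixel
    signal above offset divided by the read-noise SD; shot noise is
    disabled so the stated SNR is exact.
    """
    peak = overrides.pop("body_peak_over_nucleoplasm", 2.0)
    base = overrides.pop("nucleoplasm_intensity", 100.0)
    kwargs = dict(
        field_size_px=(384, 384),
        pixel_size_um=0.1,
        n_nuclei=1,
        nucleus_radius_um=7.0,
        nucleus_radius_jitter=0.0,
        bodies_per_nucleus_mean=1.0,
        body_radius_um=1.5,
        body_peak_over_nucleoplasm=peak,
        nucleoplasm_intensity=base,
        camera_offset=100.0,
        gaussian_read_noise_sd=(base * peak / snr) if math.isfinite(snr) else 0.0,
        poisson_scale=math.inf,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimFieldParams(**kwargs)


def make_frap_movie(field_params: SimFieldParams, frap_params: FrapSimParams) -> FrapMovie:
    """Render a FRAP time-lapse of one nucleus with a bleached body.

    The nucleus (whole structure / total ROI) is centered in the field
    with a single body at its center; the bleach square is centered in
    the body and must fit inside it.  Returns the noisy stack, the
    noiseless stack, the ROI set in frame-0 coordinates and GroundTruth.
    """
    if field_params.n_nuclei != 1:
        raise ValueError("FRAP movies are rendered for a single nucleus (n_nuclei=1)")
    h, w = field_params.field_size_px
    shape = (h, w)
    fp = frap_params
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    r_nuc = field_params.nucleus_radius_px
    r_body = field_params.body_radius_px
    if r_nuc + 4 > min(h, w) / 2:
        raise ValueError("nucleus does not fit in the field")

    side_px = max(2, round(fp.bleach_side_um / field_params.pixel_size_um))
    half_diag = side_px * math.sqrt(2) / 2
    if half_diag > r_body:
        raise ValueError(
            f"bleach ROI ({fp.bleach_side_um} um, {side_px} px square) does not fit "
            f"inside the body (radius {r_body:.1f} px)"
        )

    nucleus_mask = disk_mask(shape, cx, cy, r_nuc)
    body_mask = disk_mask(shape, cx, cy, r_body)
    x0 = int(round(cx)) - side_px // 2
    y0 = int(round(cy)) - side_px // 2
    roi_specs = {
        "bleach": {"kind": "box", "x0": x0, "y0": y0, "x1": x0 + side_px, "y1": y0 + side_px},
        "total": {"kind": "disk", "cx": cx, "cy": cy, "r": r_nuc},
        "background": None,  # filled below
    }
    bleach_mask = box_mask(shape, x0, y0, x0 + side_px, y0 + side_px)

    # Background box: camera-offset-only region away from the nucleus and
    # far enough from the border to stay valid after drift correction.
    bg_side = 20
    bx0, by0 = w // 6, h // 6
    bg_mask = box_mask(shape, bx0, by0, bx0 + bg_side, by0 + bg_side)
    if np.any(bg_mask & nucleus_mask):
        raise ValueError("field too small to place a background ROI outside the nucleus")
    roi_specs["background"] = {"kind": "box", "x0": bx0, "y0": by0, "x1": bx0 + bg_side, "y1": by0 + bg_side}

    base = np.where(nucleus_mask, field_params.nucleoplasm_intensity, 0.0)
    base[body_mask] = field_params.nucleoplasm_intensity * field_params.body_peak_over_nucleoplasm

    n_frames = fp.n_frames
    dx, dy = fp.drift_px_per_frame
    rng = np.random.default_rng(fp.seed)
    clean = np.empty((n_frames, h, w), dtype=np.float64)
    noisy = np.empty_like(clean)
    drift = []
    for i in range(n_frames):
        frame = base.copy()
        if i >= fp.n_prebleach_frames:
            t = fp.dead_time_s + (i - fp.n_prebleach_frames) * fp.frame_interval_s
            g = float(fp.unrecovered_fraction(t))
            frame[bleach_mask] *= 1.0 - fp.bleach_depth * g
        frame *= math.exp(-fp.acquisition_bleach_rate * i)
        shift = (dy * i, dx * i)
        drift.append((dx * i, dy * i))
        if shift != (0.0, 0.0):
            frame = ndi.shift(frame, shift, order=1, mode="constant", cval=0.0)
        clean[i] = frame + field_params.camera_offset
        noisy[i] = _apply_noise(frame, field_params, rng)

    truth = GroundTruth(
        field_params=asdict(field_params),
        frap_params=asdict(fp),
        nuclei=[NucleusTruth(nucleus_id=1, cx=cx, cy=cy, radius_px=r_nuc, n_bodies=1)],
        bodies=[
            BodyTruth(
                body_id=1,
                nucleus_id=1,
                cx=cx,
                cy=cy,
                radius_px=r_body,
                enrichment=field_params.body_peak_over_nucleoplasm,
            )
        ],
        drift_px=drift,
        mobile_fraction=fp.mobile_fraction,
        bleach_roi_flux=float(base[bleach_mask].sum()),
        total_flux=float(base[nucleus_mask].sum()),
    )
    stack = ImageStack(noisy, field_params.pixel_size_um, fp.frame_interval_s)
    rois = ROISet(bleach=bleach_mask, total=nucleus_mask, background=bg_mask, specs=roi_specs)
    return FrapMovie(stack=stack, clean=clean, rois=rois, truth=truth, n_prebleach=fp.n_prebleach_frames)
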