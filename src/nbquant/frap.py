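"""FRAP trace extraction, double normalization, recovery fitting and
population decomposition.

The normalization is the classical double normalization

    N(t) = [(Ibleach(t) - Ibg(t)) / (Ibleach(t0) - Ibg(t0))]
         / [(Itotal(t)  - Ibg(t)) / (Itotal(t0)  - Ibg(t0))]

where Itotal is the mean intensity over the entire cellular structure,
Ibleach the mean over the bleach area, Ibg the camera-offset background,
and the t0 reference statistics are means over the pre-bleach frames.
Dividing the bleach-normalized term by the total-normalized term cancels
any global multiplicative decay such as acquisition photobleaching.

Recovery is fitted as an immobile floor plus up to two exchanging
populations,

    N(t) = floor + A_fast (1 - e^(-k_fast t)) + A_slow (1 - e^(-k_slow t)),

by bounded multi-start nonlinear least squares; the single- vs
double-exponential model is selected by AICc.  The mobile fraction is
normalized for bleach depth,

    mobile = (plateau - floor) / (1 - floor),

so that comparisons between experiments do not depend on how deeply the
spot was bleached.  The three reported populations are
``immobile = 1 - mobile`` and the mobile part split in proportion to the
fitted amplitudes: ``fast = mobile * A_fast / (A_fast + A_slow)`` and
analogously for ``slow``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .stack import ImageStack, ROISet

__all__ = [
    "FrapTrace",
    "NormalizedCurve",
    "RecoveryFit",
    "MeanCurve",
    "extract_traces",
    "double_normalize",
    "fit_recovery",
    "classify_populations",
    "aggregate_curves",
]

logger = logging.getLogger(__name__)

K_BOUNDS = (1e-4, 10.0)  # recovery rate bounds, 1/s


@dataclass
class FrapTrace:
    """Raw per-frame mean intensities of the three ROIs."""

    times_s: np.ndarray
    i_bleach: np.ndarray
    i_total: np.ndarray
    i_background: np.ndarray
    t0_index: int  # index of the last pre-bleach frame

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.i_bleach = np.asarray(self.i_bleach, dtype=np.float64)
        self.i_total = np.asarray(self.i_total, dtype=np.float64)
        self.i_background = np.asarray(self.i_background, dtype=np.float64)
        n = len(self.times_s)
        if not (len(self.i_bleach) == len(self.i_total) == len(self.i_background) == n):
            raise ValueError("trace arrays must have equal length")
        if not 0 <= self.t0_index < n - 1:
            raise ValueError("t0_index must leave at least one post-bleach frame")

    @property
    def n_prebleach(self) -> int:
        return self.t0_index + 1


@dataclass
class NormalizedCurve:
    """Double-normalized post-bleach recovery; t = 0 at the first
    post-bleach frame.  ``prebleach_value`` is the normalized t0
    statistic, equal to 1 by construction."""

    times_s: np.ndarray
    values: np.ndarray
    prebleach_value: float = 1.0

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.times_s) != len(self.values):
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized curve contains non-finite values")


@dataclass
class RecoveryFit:
    """Fitted recovery model and its derived population fractions."""

    model: str  # "single-exp" | "double-exp"
    floor: float
    a_fast: float
    a_slow: float
    k_fast: float
    k_slow: float  # NaN for single-exp
    mobile_fraction: float
    frac_fast: float
    frac_slow: float
    frac_immobile: float
    residual_sd: float
    aicc: float
    n_points: int

    @property
    def plateau(self) -> float:
        return self.floor + self.a_fast + self.a_slow

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        y = self.floor + self.a_fast * (1 - np.exp(-self.k_fast * t))
        if self.a_slow > 0 and np.isfinite(self.k_slow):
            y = y + self.a_slow * (1 - np.exp(-self.k_slow * t))
        return y


@dataclass
class MeanCurve:
    """Pointwise mean +/- SD over replicate recovery curves."""

    times_s: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int


def _roi_mean(frame: np.ndarray, mask: np.ndarray, frame_idx: int, name: str) -> float:
    vals = frame[mask]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError(
            f"{name} ROI has no valid pixels in frame {frame_idx} "
            "(fully cropped by drift correction)"
        )
    return float(vals[finite].mean())


def extract_traces(stack: ImageStack, rois: ROISet, t0_frames: int) -> FrapTrace:
    """Mean intensity per frame over each ROI's valid (finite) pixels.

    ``t0_frames`` is the number of pre-bleach frames; the last of them is
    the t0 index of the trace.
    """
    if rois.bleach.shape != stack.frame_shape:
        raise ValueError("ROI shape does not match stack frames")
    if not 1 <= t0_frames < stack.n_frames:
        raise ValueError("t0_frames must be >= 1 and leave post-bleach frames")
    n = stack.n_frames
    ib = np.empty(n)
    it = np.empty(n)
    ibg = np.empty(n)
    for t in range(n):
        frame = stack.data[t]
        ib[t] = _roi_mean(frame, rois.bleach, t, "bleach")
        it[t] = _roi_mean(frame, rois.total, t, "total")
        ibg[t] = _roi_mean(frame, rois.background, t, "background")
    return FrapTrace(
        times_s=stack.times_s,
        i_bleach=ib,
        i_total=it,
        i_background=ibg,
        t0_index=t0_frames - 1,
    )


def double_normalize(trace: FrapTrace) -> NormalizedCurve:
    """Apply the double-normalization equation to a raw trace.

    The t0 reference statistics are the means of the pre-bleach frames.
    Post-bleach frames with a nonpositive total denominator are excluded
    with a logged warning; nonpositive t0 denominators are an error.
    """
    pre = slice(0, trace.t0_index + 1)
    bg0 = trace.i_background[pre].mean()
    ib0 = trace.i_bleach[pre].mean() - bg0
    it0 = trace.i_total[pre].mean() - bg0
    if ib0 <= 0 or it0 <= 0:
        raise ValueError("nonpositive pre-bleach (t0) denominator; check ROIs/background")

    post = slice(trace.t0_index + 1, None)
    t_post = trace.times_s[post] - trace.times_s[trace.t0_index + 1]
    ib = trace.i_bleach[post] - trace.i_background[post]
    it = trace.i_total[post] - trace.i_background[post]
    valid = it > 0
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("excluding %d frame(s) with nonpositive total denominator", n_bad)
    values = (ib[valid] / ib0) / (it[valid] / it0)

    # normalized pre-bleach reference: equals 1 by construction
    pre_val = (trace.i_bleach[pre].mean() - bg0) / ib0 / (
        (trace.i_total[pre].mean() - bg0) / it0
    )
    return NormalizedCurve(times_s=t_post[valid], values=values, prebleach_value=float(pre_val))


def _model(t: np.ndarray, params: np.ndarray) -> np.ndarray:
    if len(params) == 3:
        floor, a, k = params
        return floor + a * (1 - np.exp(-k * t))
    floor, a1, k1, a2, k2 = params
    return floor + a1 * (1 - np.exp(-k1 * t)) + a2 * (1 - np.exp(-k2 * t))


def _aicc(rss: float, n: int, p: int) -> float:
    if n <= p + 1:
        return np.inf
    return n * np.log(max(rss, 1e-300) / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def _fit_one(t: np.ndarray, y: np.ndarray, n_exp: int) -> tuple[np.ndarray, float]:
    floor0 = float(np.clip(y[0], 0.0, 1.0))
    tail = float(np.clip(np.mean(y[max(1, int(0.9 * len(y))):]), floor0, 2.0))
    amp0 = max(tail - floor0, 1e-3)
    klo, khi = K_BOUNDS
    starts = []
    k_grid = [0.005, 0.02, 0.08, 0.3, 1.0]
    if n_exp == 1:
        for k0 in k_grid:
            starts.append([floor0, amp0, k0])
        lb, ub = [0.0, 0.0, klo], [1.5, 2.0, khi]
    else:
        for kf, ks in [(0.2, 1 / 60), (0.5, 0.02), (0.1, 0.01), (1.0, 0.05), (0.05, 0.005)]:
            starts.append([floor0, amp0 / 2, kf, amp0 / 2, ks])
        lb, ub = [0.0, 0.0, klo, 0.0, klo], [1.5, 2.0, khi, 2.0, khi]

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lb, ub)
        try:
            res = least_squares(
                lambda p: _model(t, p) - y, x0, bounds=(lb, ub), method="trf", xtol=1e-12, ftol=1e-12
            )
        except Exception:  # pragma: no cover - solver failure on one start
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("recovery fit failed to converge from any start")
    rss = float(2 * best.cost)
    return best.x, rss


def fit_recovery(curve: NormalizedCurve, model: str = "auto") -> RecoveryFit:
    """Fit the recovery model to a normalized curve.

    ``model`` is ``"single-exp"``, ``"double-exp"`` or ``"auto"`` (AICc
    selection between the two).
    """
    t, y = curve.times_s, curve.values
    if len(t) < 10:
        raise ValueError("need at least 10 post-bleach points to fit")
    if model not in ("auto", "single-exp", "double-exp"):
        raise ValueError(f"unknown model {model!r}")

    candidates = []
    if model in ("auto", "single-exp"):
        px, rss = _fit_one(t, y, 1)
        candidates.append(("single-exp", px, rss, _aicc(rss, len(t), 3)))
    if model in ("auto", "double-exp"):
        px, rss = _fit_one(t, y, 2)
        candidates.append(("double-exp", px, rss, _aicc(rss, len(t), 5)))
    # auto: lowest AICc; ties broken by lowest residual then fewest rates
    candidates.sort(key=lambda c: (round(c[3], 9), c[2], len(c[1])))
    tag, px, rss, aicc = candidates[0]

    if tag == "single-exp":
        floor, a_fast, k_fast = px
        a_slow, k_slow = 0.0, np.nan
    else:
        floor, a1, k1, a2, k2 = px
        if k1 >= k2:
            a_fast, k_fast, a_slow, k_slow = a1, k1, a2, k2
        else:
            a_fast, k_fast, a_slow, k_slow = a2, k2, a1, k1

    plateau = floor + a_fast + a_slow
    if plateau > 1.0 + 1e-9:
        warnings.warn(
            f"fitted plateau {plateau:.4f} > 1; clipped to 1 for the mobile fraction",
            RuntimeWarning,
            stacklevel=2,
        )
    plateau_eff = min(plateau, 1.0)
    floor_eff = min(floor, plateau_eff)
    denom = 1.0 - floor_eff
    mobile = (plateau_eff - floor_eff) / denom if denom > 1e-12 else 0.0
    mobile = float(np.clip(mobile, 0.0, 1.0))

    amp = a_fast + a_slow
    if amp > 0:
        frac_fast = mobile * a_fast / amp
        frac_slow = mobile * a_slow / amp
    else:
        frac_fast = frac_slow = 0.0
    resid = y - _model(t, px)
    return RecoveryFit(
        model=tag,
        floor=float(floor),
        a_fast=float(a_fast),
        a_slow=float(a_slow),
        k_fast=float(k_fast),
        k_slow=float(k_slow),
        mobile_fraction=mobile,
        frac_fast=float(frac_fast),
        frac_slow=float(frac_slow),
        frac_immobile=float(1.0 - mobile),
        residual_sd=float(np.sqrt(rss / len(t))),
        aicc=float(aicc),
        n_points=len(t),
    )


def classify_populations(fit: RecoveryFit) -> tuple[float, float, float]:
    """(fast, slow, immobile) population fractions; they sum to 1."""
    return fit.frac_fast, fit.frac_slow, fit.frac_immobile


def aggregate_curves(curves: list[NormalizedCurve]) -> MeanCurve:
    """Pointwise mean and SD over replicate curves.

    Curves on different time grids are resampled by linear interpolation
    onto the first curve's grid restricted to the common time span.
    """
    if not curves:
        raise ValueError("no curves to aggregate")
    t0 = curves[0].times_s
    if all(len(c.times_s) == len(t0) and np.allclose(c.times_s, t0) for c in curves):
        grid = t0
        stackv = np.vstack([c.values for c in curves])
    else:
        tmin = max(c.times_s.min() for c in curves)
        tmax = min(c.times_s.max() for c in curves)
        if tmax <= tmin:
            raise ValueError("curves share no common time span")
        grid = t0[(t0 >= tmin) & (t0 <= tmax)]
        stackv = np.vstack([np.interp(grid, c.times_s, c.values) for c in curves])
    return MeanCurve(
        times_s=grid,
        mean=stackv.mean(axis=0),
        sd=stackv.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros_like(grid),
        n=len(curves),
    )
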