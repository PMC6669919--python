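"""Nucleus and nuclear-body segmentation, enrichment scoring and
per-nucleus foci counting (the high-content assay).

Bodies are detected with a Laplacian-of-Gaussian blob filter followed by
hysteresis thresholding — the standard open realization of "edge
detection" for bright subnuclear puncta.  For each body, enrichment of a
protein channel is the mean intensity inside the body divided by the
mean in a surrounding nucleoplasmic annulus (a dilation ring of
configurable width that excludes every body pixel and anything outside
the parent nucleus).  A body is called enriched above a configurable
threshold, 1.5 by default.  Per-nucleus body counts are categorized into
configurable bins; the default bins are {0}, {1-2} and {>=3}.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, filters, measure, morphology, segmentation

__all__ = [
    "LabelMap",
    "EnrichmentRecord",
    "EnrichmentResult",
    "FociSummary",
    "segment_nuclei",
    "segment_bodies",
    "enrichment",
    "count_foci",
    "categorize_counts",
    "classify_positive_cells",
    "DEFAULT_BINS",
    "DEFAULT_ENRICHMENT_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: enrichment-ratio threshold above which a body is called enriched
DEFAULT_ENRICHMENT_THRESHOLD = 1.5

#: per-nucleus foci-count bins: 0, 1-2, >=3 (inclusive lo, inclusive hi, None = unbounded)
DEFAULT_BINS = ((0, 0), (1, 2), (3, None))


def _drop_small(mask: np.ndarray, min_area_px: int) -> np.ndarray:
    """Remove connected components with fewer than min_area_px pixels."""
    labels, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    small = sizes < min_area_px
    small[0] = False
    return mask & ~small[labels]


@dataclass
class LabelMap:
    """Integer label image (0 = background) with provenance.

    For body maps, ``parents`` maps each body label to the nucleus label
    that contains its centroid.
    """

    labels: np.ndarray
    kind: str  # "nuclei" | "bodies"
    parents: dict | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2D")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def areas_px(self) -> dict:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def centroids(self) -> dict:
        """label -> (cx, cy) in pixel coordinates (x right, y down)."""
        out = {}
        for p in measure.regionprops(self.labels):
            cy, cx = p.centroid
            out[p.label] = (cx, cy)
        return out


@dataclass
class EnrichmentRecord:
    body_id: int
    nucleus_id: int
    mean_inside: float
    mean_surround: float
    ratio: float
    enriched: bool
    valid: bool = True  # False when the annulus was empty (body at nucleus border)


@dataclass
class EnrichmentResult:
    records: list
    threshold: float
    fraction_enriched: float  # over valid records
    n_valid: int
    n_excluded: int
    annulus_px: int


@dataclass
class FociSummary:
    nucleus_id: int
    n_bodies: int
    n_enriched: int
    category: str


def segment_nuclei(
    nuclear_channel: np.ndarray,
    sigma: float = 2.0,
    min_area_px: int = 200,
    split_touching: bool = True,
    min_distance_px: int = 10,
) -> LabelMap:
    """Segment nuclei by Otsu thresholding of the smoothed nuclear marker.

    Holes are filled, objects below ``min_area_px`` removed, and touching
    nuclei split by a distance-transform watershed.  A blank (zero
    variance) image yields an empty map with a warning.
    """
    img = np.asarray(nuclear_channel, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a single 2D channel")
    if np.ptp(img[np.isfinite(img)]) == 0:
        warnings.warn("blank nuclear channel; returning empty label map", stacklevel=2)
        return LabelMap(labels=np.zeros(img.shape, dtype=np.int32), kind="nuclei")

    smooth = filters.gaussian(img, sigma=sigma, preserve_range=True)
    mask = smooth > filters.threshold_otsu(smooth)
    mask = ndi.binary_fill_holes(mask)
    mask = _drop_small(mask, min_area_px)
    if not mask.any():
        warnings.warn("no nuclei above threshold/min area", stacklevel=2)
        return LabelMap(labels=np.zeros(img.shape, dtype=np.int32), kind="nuclei")

    if split_touching:
        dist = ndi.distance_transform_edt(mask)
        peak_idx = feature.peak_local_max(
            dist, min_distance=min_distance_px, labels=mask, exclude_border=False
        )
        markers = np.zeros(img.shape, dtype=np.int32)
        markers[tuple(peak_idx.T)] = np.arange(1, len(peak_idx) + 1)
        markers, _ = ndi.label(ndi.binary_dilation(markers > 0, iterations=2))
        labels = segmentation.watershed(-dist, markers, mask=mask)
    else:
        labels, _ = ndi.label(mask)
    labels = measure.label(labels > 0) if labels.max() == 0 else labels
    # relabel contiguously 1..n
    labels = segmentation.relabel_sequential(labels)[0].astype(np.int32)
    return LabelMap(labels=labels, kind="nuclei")


def segment_bodies(
    body_channel: np.ndarray,
    nuclei: LabelMap,
    sigma_px: float = 2.0,
    low_sd: float = 3.0,
    high_sd: float = 6.0,
    min_area_px: int = 3,
    refine_half_max: bool = True,
) -> LabelMap:
    """Detect bright subnuclear bodies by LoG filtering with hysteresis.

    The negated Laplacian-of-Gaussian response (bright blobs positive) is
    hysteresis-thresholded at ``low_sd``/``high_sd`` robust standard
    deviations above the median response inside nuclei.  Because the LoG
    skirt extends past the true object boundary, each detected blob's
    extent is then refined to the pixels above the half-maximum between
    its interior median and the local nucleoplasm median
    (``refine_half_max``), giving masks that track the object edge.
    Detected bodies are restricted to nuclear masks and assigned to the
    nucleus containing their centroid; bodies whose centroid lies outside
    every nucleus are discarded.
    """
    img = np.asarray(body_channel, dtype=np.float64)
    if img.shape != nuclei.labels.shape:
        raise ValueError("channel and nucleus map shapes differ")
    nuc_mask = nuclei.labels > 0
    if not nuc_mask.any():
        return LabelMap(labels=np.zeros(img.shape, dtype=np.int32), kind="bodies", parents={})

    response = -ndi.gaussian_laplace(img, sigma=sigma_px)
    inside = response[nuc_mask]
    med = np.median(inside)
    mad_sd = 1.4826 * np.median(np.abs(inside - med))
    if mad_sd == 0:
        mad_sd = inside.std() or 1.0
    hyst = filters.apply_hysteresis_threshold(
        response, med + low_sd * mad_sd, med + high_sd * mad_sd
    )
    mask = hyst & nuc_mask
    mask = _drop_small(mask, min_area_px)
    labels, n_blobs = ndi.label(mask)

    if refine_half_max and n_blobs:
        nucleoplasm = nuc_mask & ~mask
        bg_med = np.median(img[nucleoplasm]) if nucleoplasm.any() else np.median(img[nuc_mask])
        refined = np.zeros_like(mask)
        for i, blob in enumerate(ndi.find_objects(labels), start=1):
            if blob is None:
                continue
            sub = labels[blob] == i
            vals = img[blob]
            thr = 0.5 * (bg_med + np.median(vals[sub]))
            keep = sub & (vals > thr)
            refined[blob] |= keep if keep.any() else sub
        mask = _drop_small(refined, min_area_px)
        labels, _ = ndi.label(mask)

    parents: dict[int, int] = {}
    keep = np.zeros(labels.max() + 1, dtype=np.int32)
    next_id = 0
    for p in measure.regionprops(labels):
        cy, cx = p.centroid
        parent = int(nuclei.labels[int(round(cy)), int(round(cx))])
        if parent == 0:
            continue  # centroid outside any nucleus: discard
        next_id += 1
        keep[p.label] = next_id
        parents[next_id] = parent
    return LabelMap(labels=keep[labels], kind="bodies", parents=parents)


def enrichment(
    bodies: LabelMap,
    nuclei: LabelMap,
    channel: np.ndarray,
    annulus_px: int = 3,
    threshold: float = DEFAULT_ENRICHMENT_THRESHOLD,
    camera_offset: float = 0.0,
    subtract_offset: bool = True,
    gap_px: int = 1,
) -> EnrichmentResult:
    """Inside/surrounding enrichment ratio for every body.

    The surround is a morphological dilation ring of width ``annulus_px``
    around the body, minus all body pixels, intersected with the parent
    nucleus.  A guard gap of ``gap_px`` separates the ring from every
    body mask so that rim pixels missed by the segmentation (which hugs
    the intensity half-maximum) cannot contaminate the surround.  Bodies with an empty annulus (touching the nucleus border)
    or touching the image border are flagged invalid and excluded from
    the enriched fraction, with a logged count.  When ``subtract_offset``
    is true the camera offset is removed from both means before the ratio
    (matching the background handling of the FRAP equation).
    """
    if annulus_px < 1:
        raise ValueError("annulus_px must be >= 1")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    img = np.asarray(channel, dtype=np.float64)
    if img.shape != bodies.labels.shape or img.shape != nuclei.labels.shape:
        raise ValueError("shape mismatch between channel and label maps")
    off = camera_offset if subtract_offset else 0.0

    all_bodies = bodies.labels > 0
    if gap_px:
        excluded = ndi.binary_dilation(all_bodies, structure=morphology.disk(gap_px))
    else:
        excluded = all_bodies
    selem = morphology.disk(annulus_px + gap_px)
    records: list[EnrichmentRecord] = []
    h, w = img.shape
    for bid in bodies.label_ids:
        bid = int(bid)
        bmask = bodies.labels == bid
        nucleus_id = (bodies.parents or {}).get(bid, 0)
        if nucleus_id == 0:
            nucleus_id = int(np.bincount(nuclei.labels[bmask]).argmax())
        ys, xs = np.nonzero(bmask)
        touches_border = ys.min() == 0 or xs.min() == 0 or ys.max() == h - 1 or xs.max() == w - 1
        ring = ndi.binary_dilation(bmask, structure=selem) & ~excluded
        ring &= nuclei.labels == nucleus_id
        mean_inside = float(img[bmask].mean()) - off
        if not ring.any() or touches_border:
            records.append(
                EnrichmentRecord(bid, nucleus_id, mean_inside + off, np.nan, np.nan, False, valid=False)
            )
            continue
        mean_surround = float(img[ring].mean()) - off
        ratio = mean_inside / mean_surround
        records.append(
            EnrichmentRecord(
                body_id=bid,
                nucleus_id=nucleus_id,
                mean_inside=mean_inside + off,
                mean_surround=mean_surround + off,
                ratio=ratio,
                enriched=bool(ratio > threshold),
                valid=True,
            )
        )
    valid = [r for r in records if r.valid]
    n_excluded = len(records) - len(valid)
    if n_excluded:
        logger.warning("%d body/bodies excluded from enrichment (empty annulus/border)", n_excluded)
    frac = float(np.mean([r.enriched for r in valid])) if valid else float("nan")
    return EnrichmentResult(
        records=records,
        threshold=threshold,
        fraction_enriched=frac,
        n_valid=len(valid),
        n_excluded=n_excluded,
        annulus_px=annulus_px,
    )


def count_foci(bodies: LabelMap, nuclei: LabelMap) -> dict:
    """Exact per-nucleus body counts (nucleus label -> count, zeros included)."""
    counts = {int(nid): 0 for nid in nuclei.label_ids}
    parents = bodies.parents
    if parents is None:
        parents = {}
        for p in measure.regionprops(bodies.labels):
            cy, cx = p.centroid
            parents[p.label] = int(nuclei.labels[int(round(cy)), int(round(cx))])
    for _bid, nid in parents.items():
        if nid in counts:
            counts[nid] += 1
    return counts


def _validate_bins(bins) -> list[tuple[int, int | None]]:
    norm = []
    for lo, hi in bins:
        if hi is not None and hi < lo:
            raise ValueError(f"bin ({lo}, {hi}) is empty")
        norm.append((int(lo), None if hi is None else int(hi)))
    norm.sort(key=lambda b: b[0])
    expect = 0
    for i, (lo, hi) in enumerate(norm):
        if lo != expect:
            raise ValueError("bins must partition the nonnegative integers (gap/overlap)")
        if hi is None:
            if i != len(norm) - 1:
                raise ValueError("only the last bin may be unbounded")
            return norm
        expect = hi + 1
    raise ValueError("last bin must be unbounded to cover all counts")


def bin_label(lo: int, hi: int | None) -> str:
    if hi is None:
        return f">={lo}"
    if lo == hi:
        return str(lo)
    return f"{lo}-{hi}"


def categorize_counts(counts, bins=DEFAULT_BINS) -> tuple[list, dict]:
    """Assign each count to its bin and report per-category percentages.

    Returns ``(labels, percentages)`` where ``labels[i]`` is the category
    of ``counts[i]`` and ``percentages`` maps every category label to its
    percentage of all nuclei (summing to 100).
    """
    norm = _validate_bins(bins)
    counts = np.asarray(list(counts), dtype=int)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    labels = []
    for c in counts:
        for lo, hi in norm:
            if c >= lo and (hi is None or c <= hi):
                labels.append(bin_label(lo, hi))
                break
    percentages = {bin_label(lo, hi): 0.0 for lo, hi in norm}
    if len(counts):
        for lab in labels:
            percentages[lab] += 100.0 / len(counts)
    return labels, percentages


def classify_positive_cells(
    channel: np.ndarray,
    regions: LabelMap,
    c: float = 3.0,
    background_mask: np.ndarray | None = None,
) -> tuple[dict, float, int]:
    """Call each region positive when its mean intensity exceeds
    background mean + c * background SD.

    ``background_mask`` defaults to all pixels outside every region.
    Returns (region -> bool, percentage positive, n regions).
    """
    img = np.asarray(channel, dtype=np.float64)
    ids = regions.label_ids
    if len(ids) == 0:
        raise ValueError("no regions to classify")
    if background_mask is None:
        background_mask = regions.labels == 0
    bg = img[background_mask & np.isfinite(img)]
    if bg.size == 0:
        raise ValueError("empty background")
    cut = bg.mean() + c * bg.std()
    calls = {int(i): bool(img[regions.labels == i].mean() > cut) for i in ids}
    pct = 100.0 * sum(calls.values()) / len(calls)
    return calls, pct, len(calls)
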