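"""Chromogenic (H-DAB) section quantification.

Two read-outs, both computed in optical-density space after stain
deconvolution:

* **CK20 positive area** — colonoid regions are segmented from the
  total chromogen density, cleaned by object-level exclusion rules
  (OD-sum, solidity, residual color), and the percentage of region area
  whose smoothed DAB density exceeds a threshold is reported.
* **Ki67 positive nuclei** — nuclei are detected on the hematoxylin
  channel (resample, background-subtract, smooth, threshold, watershed
  split, area gate), faint nuclei are excluded, and nuclei whose DAB
  mean exceeds a cut-off count as positive.

The region segmenter is a fixed-threshold classical stand-in for a
trained pixel classifier, and the nucleus detector a classical stand-in
for a positive-cell-detection plugin; both sit behind small functional
interfaces so learned detectors can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation, transform
from skimage.feature import peak_local_max

from .imgio import ODImage

__all__ = [
    "ColonoidAnnotation",
    "NucleusDetectionParams",
    "CellDetection",
    "segment_colonoid_regions",
    "filter_annotations",
    "ck20_positive_area",
    "detect_nuclei_brightfield",
    "classify_ki67",
]


@dataclass
class ColonoidAnnotation:
    """One segmented colonoid region with the measurements the
    exclusion rules consume."""

    id: int
    mask: np.ndarray  # boolean, full-frame
    area_um2: float
    od_sum_mean: float  # mean over the object of (hematoxylin + DAB) OD
    solidity: float
    residual_mean: float


@dataclass(frozen=True)
class NucleusDetectionParams:
    """Nucleus detection settings (all spatial units in µm)."""

    requested_pixel_size: float = 0.5
    background_radius: float = 8.0
    median_radius: float = 0.0
    sigma: float = 1.3
    min_area: float = 15.0
    max_area: float = 200.0
    detection_threshold: float = 0.1  # OD

    def __post_init__(self):
        if self.min_area >= self.max_area:
            raise ValueError("min_area must be < max_area")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class CellDetection:
    """One detected nucleus with per-stain OD means and its class."""

    id: int
    centroid: tuple[float, float]
    nucleus_area_um2: float
    hematoxylin_mean: float
    dab_mean: float
    cls: str = "unclassified"  # positive | negative | excluded | unclassified


def segment_colonoid_regions(
    od: ODImage, od_sum_threshold: float = 0.1, smoothing_sigma: float = 2.0
) -> list[ColonoidAnnotation]:
    """Segment colonoid structures from the total chromogen density.

    Gaussian-smoothed hematoxylin+DAB OD is thresholded, closed with a
    radius-2 disk, hole-filled, and 8-connected components become
    annotations carrying the mean OD-sum, solidity and residual-channel
    mean needed by :func:`filter_annotations`.
    """
    if od_sum_threshold <= 0:
        raise ValueError("od_sum_threshold must be > 0")
    total = od.od_sum()
    smoothed = ndimage.gaussian_filter(total, smoothing_sigma)
    fg = smoothed > od_sum_threshold
    fg = morphology.closing(fg, morphology.disk(2))
    fg = ndimage.binary_fill_holes(fg)
    labels, _ = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    annotations = []
    for prop in measure.regionprops(labels):
        mask = labels == prop.label
        annotations.append(
            ColonoidAnnotation(
                id=int(prop.label),
                mask=mask,
                area_um2=float(prop.area * od.calibration**2),
                od_sum_mean=float(total[mask].mean()),
                solidity=float(prop.solidity),
                residual_mean=float(od.residual[mask].mean()),
            )
        )
    return annotations


def filter_annotations(
    annotations: list[ColonoidAnnotation],
    od_sum_cutoff: float = 0.15,
    solidity_cutoff: float = 0.25,
    residual_cutoff: float = 0.0,
    residual_tolerance: float = 1e-3,
) -> list[ColonoidAnnotation]:
    """Apply the object-level exclusion rules, preserving order.

    An annotation is kept iff its mean OD-sum >= ``od_sum_cutoff``, its
    solidity >= ``solidity_cutoff`` and its residual-channel mean does
    not exceed ``residual_cutoff`` beyond a small numerical tolerance —
    a literal "> 0" residual test would reject everything under float
    noise, so the tolerance (1e-3 OD) defines "presence" of residual
    color.
    """
    kept = []
    for ann in annotations:
        for name in ("od_sum_mean", "solidity", "residual_mean"):
            if getattr(ann, name, None) is None:
                raise ValueError(f"annotation {ann.id} lacks measurement {name!r}")
        if ann.od_sum_mean < od_sum_cutoff:
            continue
        if ann.solidity < solidity_cutoff:
            continue
        if ann.residual_mean > residual_cutoff + residual_tolerance:
            continue
        kept.append(ann)
    return kept


def ck20_positive_area(
    annotations: list[ColonoidAnnotation],
    od: ODImage,
    dab_mean_threshold: float = 0.3,
    sigma: float = 2.5,
) -> float:
    """Percent of annotation area whose smoothed DAB OD exceeds the
    threshold — the CK20-positive area fraction of a section.

    The DAB channel is Gaussian-smoothed (sigma in px) before
    thresholding, mirroring a single-measurement pixel thresholder.
    """
    if not annotations:
        raise ValueError("no annotations; section has no segmented colonoid area")
    union = np.zeros(od.shape, dtype=bool)
    for ann in annotations:
        union |= ann.mask
    total_px = int(union.sum())
    if total_px == 0:
        raise ValueError("total annotation area is zero")
    smoothed = ndimage.gaussian_filter(od.dab, sigma)
    positive_px = int(((smoothed > dab_mean_threshold) & union).sum())
    return 100.0 * positive_px / total_px


def detect_nuclei_brightfield(
    od: ODImage, params: NucleusDetectionParams = NucleusDetectionParams()
) -> list[CellDetection]:
    """Detect nuclei on the hematoxylin channel.

    Pipeline: resample to ``requested_pixel_size``; subtract a
    morphological-opening background (structuring disk of
    ``background_radius``; a rolling-ball analog); optional median
    filter; Gaussian smooth at ``sigma``; threshold at
    ``detection_threshold``; split touching nuclei by distance-
    transform watershed; keep components within [min_area, max_area]
    µm². Per-nucleus hematoxylin and DAB means are measured on the
    resampled but *unsmoothed* channels.
    """
    if od.hematoxylin is None:
        raise ValueError("hematoxylin channel missing")
    px = params.requested_pixel_size
    factor = od.calibration / px
    hema = od.hematoxylin
    dab = od.dab
    if abs(factor - 1.0) > 1e-9:
        hema = transform.rescale(hema, factor, order=1, anti_aliasing=factor < 1)
        dab = transform.rescale(dab, factor, order=1, anti_aliasing=factor < 1)

    bg_r = max(int(round(params.background_radius / px)), 1)
    background = morphology.opening(hema, morphology.disk(bg_r))
    work = hema - background
    if params.median_radius > 0:
        med_r = max(int(round(params.median_radius / px)), 1)
        work = ndimage.median_filter(work, footprint=morphology.disk(med_r))
    work = ndimage.gaussian_filter(work, params.sigma / px)

    fg = work > params.detection_threshold
    fg = ndimage.binary_fill_holes(fg)
    if not fg.any():
        return []

    distance = ndimage.distance_transform_edt(fg)
    min_sep = max(int(round(np.sqrt(params.min_area / np.pi) / px)), 1)
    peaks = peak_local_max(distance, min_distance=min_sep, labels=fg, exclude_border=False)
    markers = np.zeros(fg.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels, _ = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    else:
        labels = segmentation.watershed(-distance, markers, mask=fg)

    detections = []
    for prop in measure.regionprops(labels):
        area_um2 = prop.area * px**2
        if not (params.min_area <= area_um2 <= params.max_area):
            continue
        rr, cc = prop.coords[:, 0], prop.coords[:, 1]
        detections.append(
            CellDetection(
                id=int(prop.label),
                centroid=tuple(float(v) * px / od.calibration for v in prop.centroid),
                nucleus_area_um2=float(area_um2),
                hematoxylin_mean=float(hema[rr, cc].mean()),
                dab_mean=float(dab[rr, cc].mean()),
            )
        )
    return detections


def classify_ki67(
    detections: list[CellDetection],
    hematoxylin_min: float = 0.11,
    dab_positive: float = 0.15,
) -> tuple[float, list[CellDetection]]:
    """Classify detections and return the Ki67 positivity percentage.

    Nuclei with hematoxylin mean *less than* ``hematoxylin_min`` are
    excluded (faint detections, typically debris); among the remainder
    a nucleus is positive iff its DAB mean is *greater than*
    ``dab_positive`` (strict inequalities in both rules). Percent
    positive = 100 × positives / (positives + negatives).
    """
    classified = []
    n_pos = n_neg = 0
    for det in detections:
        if det.hematoxylin_mean < hematoxylin_min:
            cls = "excluded"
        elif det.dab_mean > dab_positive:
            cls = "positive"
            n_pos += 1
        else:
            cls = "negative"
            n_neg += 1
        classified.append(
            CellDetection(
                id=det.id,
                centroid=det.centroid,
                nucleus_area_um2=det.nucleus_area_um2,
                hematoxylin_mean=det.hematoxylin_mean,
                dab_mean=det.dab_mean,
                cls=cls,
            )
        )
    if n_pos + n_neg == 0:
        raise ValueError("no non-excluded nuclei; percent positive undefined")
    return 100.0 * n_pos / (n_pos + n_neg), classified
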