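"""Fluorescence section quantification.

Covers the two confocal read-outs:

* **triple-marker compound classification** — nuclei detected on DAPI,
  filtered on area and DAPI signal, expanded into a simulated
  cytoplasm, then classified KI67+/− (nuclear mean) × CK20+/−
  (cytoplasmic mean); the headline statistic is the percentage of KI67+
  cells among CK20+ cells (proliferation within the differentiated
  compartment);
* **TUNEL area per cell** — apoptotic area is segmented from the green
  channel, converted to polygons, shape-simplified, re-rasterized, and
  reported as µm² of TUNEL-positive area per kept DAPI nucleus.

Nucleus detection is a deterministic classical detector (smoothing +
threshold + distance-transform watershed, with a normalized peak
response as the detection score) behind a pluggable interface mirroring
(image -> labeled nuclei + scores), so a learned star-convex detector
can be dropped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import draw, measure, segmentation, transform
from skimage.feature import peak_local_max

from .imgio import RasterImage

__all__ = [
    "FluoDetectionParams",
    "FluoCell",
    "TunelSectionResult",
    "detect_nuclei_fluor",
    "filter_nuclei",
    "expand_cytoplasm",
    "classify_compound",
    "tunel_area_metric",
    "CHANNEL_ALIASES",
]

#: Microscope channel names mapped to canonical markers.
CHANNEL_ALIASES = {"Ch1-T2": "DAPI"}


@dataclass(frozen=True)
class FluoDetectionParams:
    """Detection and filtering settings for fluorescence nuclei.

    ``dapi_min_mean`` differs by analysis mode (60 for the TUNEL
    read-out, 25 for the triple-marker read-out); areas are µm².
    """

    probability_threshold: float = 0.6
    dapi_channel: str = "DAPI"
    requested_pixel_size: float = 0.225
    area_min: float = 12.0
    area_max: float = 175.0
    dapi_min_mean: float = 60.0
    expansion_radius: float = 5.0  # µm
    intensity_threshold: float = 30.0  # DAPI units, foreground gate
    smoothing_sigma: float = 2.0  # px at working resolution

    def __post_init__(self):
        if not 0.0 <= self.probability_threshold <= 1.0:
            raise ValueError("probability_threshold must be in [0, 1]")
        if self.area_min >= self.area_max:
            raise ValueError("area_min must be < area_max")


@dataclass
class FluoCell:
    """One detected cell: nucleus pixel coordinates, optional cytoplasm
    coordinates, per-channel mean intensities and class labels."""

    id: int
    coords: np.ndarray  # (n, 2) nucleus pixel coordinates, native frame
    area_um2: float
    score: float
    nucleus_means: dict[str, float] = field(default_factory=dict)
    cyto_coords: np.ndarray | None = None
    cyto_means: dict[str, float] = field(default_factory=dict)
    labels: set[str] = field(default_factory=set)


@dataclass
class TunelSectionResult:
    """TUNEL-positive area normalized by DAPI cell count."""

    tunel_area_um2: float
    n_dapi_cells: int
    metric_um2_per_cell: float
    regions: list[dict] = field(default_factory=list)


def _resolve_channel(image: RasterImage, name: str) -> np.ndarray:
    if name not in image.channels and name in CHANNEL_ALIASES:
        name = CHANNEL_ALIASES[name]
    return image.channel(name)  # raises KeyError when truly missing


def _default_detector(
    dapi: np.ndarray, params: FluoDetectionParams
) -> tuple[np.ndarray, dict[int, float]]:
    """Classical nucleus detector: smooth, threshold, watershed split.

    Returns a label image and a per-label detection score in (0, 1),
    defined as the object's peak smoothed response / 256 — a bright,
    well-focused nucleus scores high, background clutter low.
    """
    smoothed = ndimage.gaussian_filter(dapi.astype(np.float64), params.smoothing_sigma)
    fg = smoothed > params.intensity_threshold
    fg = ndimage.binary_fill_holes(fg)
    if not fg.any():
        return np.zeros(dapi.shape, dtype=np.int32), {}
    distance = ndimage.distance_transform_edt(fg)
    min_sep = max(int(round(np.sqrt(params.area_min / np.pi) / params.requested_pixel_size)), 3)
    peaks = peak_local_max(distance, min_distance=min_sep, labels=fg, exclude_border=False)
    markers = np.zeros(fg.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels, _ = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    else:
        labels = segmentation.watershed(-distance, markers, mask=fg)
    scores = {}
    for prop in measure.regionprops(labels, intensity_image=smoothed):
        scores[int(prop.label)] = float(prop.intensity_max) / 256.0
    return labels.astype(np.int32), scores


def detect_nuclei_fluor(
    image: RasterImage,
    params: FluoDetectionParams = FluoDetectionParams(),
    detector: Callable[[np.ndarray, FluoDetectionParams], tuple[np.ndarray, dict[int, float]]]
    | None = None,
) -> list[FluoCell]:
    """Detect nuclei on the DAPI channel.

    The channel is resampled to ``requested_pixel_size``, the detector
    (default classical, pluggable) produces labeled nuclei with
    detection scores, objects scoring below ``probability_threshold``
    are dropped, and labels are mapped back to the native pixel grid
    where areas and per-channel nucleus means are measured.
    """
    dapi = _resolve_channel(image, params.dapi_channel)
    detector = detector or _default_detector
    factor = image.calibration / params.requested_pixel_size
    work = dapi
    if abs(factor - 1.0) > 1e-9:
        work = transform.rescale(dapi.astype(np.float64), factor, order=1, anti_aliasing=factor < 1)
    labels, scores = detector(np.asarray(work), params)
    if labels.shape != dapi.shape:
        labels = transform.resize(
            labels, dapi.shape, order=0, preserve_range=True, anti_aliasing=False
        ).astype(np.int32)

    cells = []
    for prop in measure.regionprops(labels):
        score = scores.get(int(prop.label), 0.0)
        if score < params.probability_threshold:
            continue
        coords = prop.coords
        means = {
            ch: float(image.channel(ch)[coords[:, 0], coords[:, 1]].mean())
            for ch in image.channels
        }
        cells.append(
            FluoCell(
                id=int(prop.label),
                coords=coords,
                area_um2=float(prop.area * image.calibration**2),
                score=score,
                nucleus_means=means,
            )
        )
    return cells


def filter_nuclei(cells: list[FluoCell], params: FluoDetectionParams) -> list[FluoCell]:
    """Keep nuclei with area in [area_min, area_max] µm² and DAPI mean
    >= ``dapi_min_mean``. Pure and order-preserving; may return []."""
    kept = []
    for cell in cells:
        if not params.area_min <= cell.area_um2 <= params.area_max:
            continue
        if cell.nucleus_means.get("DAPI", 0.0) < params.dapi_min_mean:
            continue
        kept.append(cell)
    return kept


def expand_cytoplasm(
    cells: list[FluoCell], radius_um: float, image: RasterImage
) -> list[FluoCell]:
    """Attach a simulated cytoplasm to each nucleus.

    Nuclei are dilated by ``radius_um``; where expansions would overlap,
    pixels go to the nearest nucleus (label expansion is a distance-
    limited Voronoi partition), so cytoplasm masks are pairwise
    disjoint and disjoint from all nuclei. Per-channel cytoplasmic
    means are measured and stored on the returned cells.
    """
    if radius_um < 0:
        raise ValueError("expansion radius must be >= 0")
    shape = image.shape
    labels = np.zeros(shape, dtype=np.int32)
    for cell in cells:
        labels[cell.coords[:, 0], cell.coords[:, 1]] = cell.id
    radius_px = radius_um / image.calibration
    expanded = segmentation.expand_labels(labels, distance=radius_px)
    out = []
    for cell in cells:
        cyto = (expanded == cell.id) & (labels != cell.id)
        cyto_coords = np.argwhere(cyto)
        cyto_means = {}
        if cyto_coords.size:
            cyto_means = {
                ch: float(image.channel(ch)[cyto_coords[:, 0], cyto_coords[:, 1]].mean())
                for ch in image.channels
            }
        out.append(
            FluoCell(
                id=cell.id,
                coords=cell.coords,
                area_um2=cell.area_um2,
                score=cell.score,
                nucleus_means=dict(cell.nucleus_means),
                cyto_coords=cyto_coords,
                cyto_means=cyto_means,
                labels=set(cell.labels),
            )
        )
    return out


def classify_compound(
    cells: list[FluoCell], ck20_cutoff: float = 15.0, ki67_cutoff: float = 25.0
) -> tuple[dict[str, int], float, list[FluoCell]]:
    """Compound KI67 × CK20 classification.

    A cell is CK20+ iff its cytoplasmic CK20 mean > ``ck20_cutoff`` and
    KI67+ iff its nuclear KI67 mean > ``ki67_cutoff``. Returns the 2×2
    class table, the percentage of KI67+ cells among CK20+ cells, and
    the labeled cells. Raises when no cell is CK20+ (the percentage is
    undefined).
    """
    counts = {"KI67+CK20+": 0, "KI67+CK20-": 0, "KI67-CK20+": 0, "KI67-CK20-": 0}
    labeled = []
    for cell in cells:
        if cell.cyto_coords is None:
            raise ValueError(f"cell {cell.id} has no cytoplasm mask; run expand_cytoplasm first")
        ck20 = cell.cyto_means.get("CK20", 0.0) > ck20_cutoff
        ki67 = cell.nucleus_means.get("KI67", 0.0) > ki67_cutoff
        cls = f"KI67{'+' if ki67 else '-'}CK20{'+' if ck20 else '-'}"
        counts[cls] += 1
        tags = set()
        if ki67:
            tags.add("KI67+")
        if ck20:
            tags.add("CK20+")
        labeled.append(
            FluoCell(
                id=cell.id,
                coords=cell.coords,
                area_um2=cell.area_um2,
                score=cell.score,
                nucleus_means=dict(cell.nucleus_means),
                cyto_coords=cell.cyto_coords,
                cyto_means=dict(cell.cyto_means),
                labels=tags,
            )
        )
    n_ck20 = counts["KI67+CK20+"] + counts["KI67-CK20+"]
    if n_ck20 == 0:
        raise ValueError("no CK20-positive cells; percent KI67+ of CK20+ is undefined")
    percent = 100.0 * counts["KI67+CK20+"] / n_ck20
    return counts, percent, labeled


def _region_polygon(mask: np.ndarray) -> Polygon | None:
    """Exterior polygon of a connected region via its 0.5-level contour."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return None
    exterior = max(contours, key=len)
    if len(exterior) < 4:
        return None
    poly = Polygon(exterior)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly if not poly.is_empty else None


def tunel_area_metric(
    image: RasterImage,
    kept_cells: list[FluoCell],
    green_threshold: float = 68.2,
    simplify_tolerance: float = 1.5,
    smoothing_sigma: float = 1.0,
    channel: str = "TUNEL",
) -> TunelSectionResult:
    """TUNEL-positive area per kept DAPI cell (µm²/cell).

    The green (TUNEL) channel is Gaussian-smoothed, thresholded at
    ``green_threshold``, connected regions are traced to polygons,
    simplified (Douglas-Peucker, ``simplify_tolerance`` px), re-
    rasterized and their union area summed. Per region the area before
    and after simplification and the perimeter are recorded so the
    simplification-induced area change can be bounded.
    """
    if not kept_cells:
        raise ValueError("no kept cells; µm²/cell metric undefined")
    green = _resolve_channel(image, channel).astype(np.float64)
    smoothed = ndimage.gaussian_filter(green, smoothing_sigma)
    fg = smoothed > green_threshold
    shape = fg.shape
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    final = np.zeros(shape, dtype=bool)
    regions = []
    for prop in measure.regionprops(labels):
        mask = labels == prop.label
        poly = _region_polygon(mask)
        if poly is None:
            final |= mask  # tiny region, below contour resolution
            regions.append(
                {"area_px_before": int(prop.area), "area_px_after": int(prop.area),
                 "perimeter_px": float(prop.perimeter)}
            )
            continue
        simplified = poly.simplify(simplify_tolerance, preserve_topology=True)
        remask = draw.polygon2mask(shape, np.asarray(simplified.exterior.coords))
        final |= remask
        regions.append(
            {
                "area_px_before": int(prop.area),
                "area_px_after": int(remask.sum()),
                "perimeter_px": float(prop.perimeter),
            }
        )
    area_um2 = float(final.sum() * image.calibration**2)
    return TunelSectionResult(
        tunel_area_um2=area_um2,
        n_dapi_cells=len(kept_cells),
        metric_um2_per_cell=area_um2 / len(kept_cells),
        regions=regions,
    )
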