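"""Calibrated raster I/O, bit-depth conversion, and stain deconvolution.

Shared infrastructure for all image stages. Conventions used throughout
the package:

* coordinates are (row, col), 0-based, pixel-center;
* areas in µm² are pixel counts × calibration²;
* optical density is ``OD = -log10((I + 1) / I0)`` in log base 10 with a
  +1 offset on intensity so that a zero pixel stays finite, clipped to a
  configurable maximum (default 3.0);
* chromogenic stains mix additively in OD space (Beer-Lambert), so a
  pixel's OD vector is ``M @ c`` where the columns of M are unit stain
  vectors and c the per-stain concentrations. Deconvolution inverts
  this linear system and clips negative concentrations to zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import imageio.v3 as iio

__all__ = [
    "RasterImage",
    "StainVectors",
    "ODImage",
    "read_image",
    "write_image",
    "to_8bit",
    "rgb_to_od",
    "deconvolve_stains",
]


@dataclass
class RasterImage:
    """A calibrated single- or multi-channel raster.

    ``pixels`` has shape (H, W) for a single channel or (H, W, C); all
    channels share the same shape and µm/pixel calibration.
    """

    pixels: np.ndarray
    channels: tuple[str, ...]
    calibration: float  # µm per pixel

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        self.channels = tuple(self.channels)
        if self.calibration <= 0:
            raise ValueError(f"calibration must be > 0 µm/px, got {self.calibration}")
        n = 1 if self.pixels.ndim == 2 else self.pixels.shape[2]
        if len(self.channels) != n:
            raise ValueError(
                f"{len(self.channels)} channel names for {n} channel(s) of pixel data"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 2-D array."""
        if name not in self.channels:
            raise KeyError(f"no channel {name!r}; have {self.channels}")
        if self.pixels.ndim == 2:
            return self.pixels
        return self.pixels[:, :, self.channels.index(name)]

    def pixel_area_um2(self) -> float:
        return self.calibration**2


# Standard published H-DAB stain vectors (unit norm); the residual axis
# is the normalized cross product so that the 3x3 matrix is invertible.
_HEMATOXYLIN = np.array([0.65, 0.70, 0.29])
_DAB = np.array([0.27, 0.57, 0.78])


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("stain vector must be non-zero")
    return v / n


@dataclass(frozen=True)
class StainVectors:
    """Unit OD-space absorption vectors for hematoxylin, DAB and residual."""

    hematoxylin: tuple = tuple(_unit(_HEMATOXYLIN))
    dab: tuple = tuple(_unit(_DAB))
    residual: tuple | None = None

    def matrix(self) -> np.ndarray:
        """3x3 matrix with stain vectors as columns (H, DAB, residual)."""
        h = _unit(self.hematoxylin)
        d = _unit(self.dab)
        if self.residual is None:
            r = np.cross(h, d)
            if np.linalg.norm(r) < 1e-8:
                raise ValueError(
                    "hematoxylin and DAB vectors are collinear; supply an explicit residual"
                )
            r = _unit(r)
        else:
            r = _unit(self.residual)
        m = np.column_stack([h, d, r])
        if np.linalg.matrix_rank(m) < 3:
            raise ValueError(
                f"stain matrix is singular for vectors H={h}, DAB={d}, residual={r}"
            )
        return m


@dataclass
class ODImage:
    """Per-stain optical-density concentrations after deconvolution."""

    hematoxylin: np.ndarray
    dab: np.ndarray
    residual: np.ndarray
    calibration: float

    def od_sum(self) -> np.ndarray:
        """Total chromogen density (hematoxylin + DAB) per pixel."""
        return self.hematoxylin + self.dab

    @property
    def shape(self) -> tuple[int, int]:
        return self.hematoxylin.shape


def write_image(image: RasterImage, path: str | Path) -> Path:
    """Write a RasterImage to TIFF (any dtype/channels) or PNG (8-bit RGB).

    TIFF carries channel names and the µm/px calibration in the image
    description as JSON, so a round trip is lossless and self-describing.
    """
    path = Path(path)
    meta = {"calibration_um_per_px": image.calibration, "channels": list(image.channels)}
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        data = image.pixels
        if data.ndim == 3:  # store channel-first for tifffile axes convention
            data = np.moveaxis(data, -1, 0)
        tifffile.imwrite(path, data, description=json.dumps(meta))
    elif suffix == ".png":
        if image.pixels.dtype != np.uint8:
            raise ValueError("PNG output requires 8-bit pixels; use to_8bit first")
        iio.imwrite(path, image.pixels)
    else:
        raise ValueError(f"unsupported image format {suffix!r} (use .tif/.tiff/.png)")
    return path


def read_image(path: str | Path, calibration: float | None = None) -> RasterImage:
    """Read a TIFF or PNG into a RasterImage.

    TIFFs written by :func:`write_image` carry calibration and channel
    names; for other files ``calibration`` must be supplied. PNG RGB
    channels are named R, G, B.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
        channels = None
        if desc:
            try:
                meta = json.loads(desc)
                calibration = calibration or meta.get("calibration_um_per_px")
                channels = meta.get("channels")
            except (json.JSONDecodeError, AttributeError):
                pass
        if data.ndim == 3:
            data = np.moveaxis(data, 0, -1)
            if channels is None:
                channels = [f"C{i}" for i in range(data.shape[2])]
        elif channels is None:
            channels = ["C0"]
    elif suffix == ".png":
        data = np.asarray(iio.imread(path))
        if data.ndim == 3 and data.shape[2] >= 3:
            data = data[:, :, :3]
            channels = ["R", "G", "B"]
        else:
            channels = ["C0"]
    else:
        raise ValueError(f"unsupported image format {suffix!r}")
    if calibration is None:
        raise ValueError(f"{path} carries no calibration; pass calibration=µm/px")
    return RasterImage(pixels=data, channels=tuple(channels), calibration=float(calibration))


def to_8bit(
    image: RasterImage,
    mode: str = "minmax",
    display_range: tuple[float, float] | None = None,
) -> RasterImage:
    """Convert a single-channel image to 8-bit.

    ``minmax`` maps [min, max] linearly onto [0, 255] (a constant image
    maps to 0 by convention); ``fixed-range`` uses the supplied
    ``display_range`` instead, clipping outside values. Rounding is
    numpy's round-half-even.
    """
    if image.n_channels != 1:
        raise ValueError("to_8bit expects a single-channel image")
    px = np.asarray(image.pixels, dtype=np.float64)
    if px.size == 0:
        raise ValueError("empty image")
    if mode == "minmax":
        lo, hi = float(px.min()), float(px.max())
        if hi == lo:
            out = np.zeros(px.shape, dtype=np.uint8)
            return RasterImage(out, image.channels, image.calibration)
    elif mode == "fixed-range":
        if display_range is None:
            raise ValueError("fixed-range mode requires display_range=(lo, hi)")
        lo, hi = map(float, display_range)
        if hi <= lo:
            raise ValueError("display_range must be increasing")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    scaled = np.clip((px - lo) / (hi - lo), 0.0, 1.0) * 255.0
    out = np.rint(scaled).astype(np.uint8)
    return RasterImage(out, image.channels, image.calibration)


def rgb_to_od(
    image: RasterImage, i0: float | tuple[float, float, float] = 255.0, od_max: float = 3.0
) -> np.ndarray:
    """Transform an RGB image to per-channel optical density.

    OD_c = -log10((I_c + 1) / I0_c), clipped to [0, od_max]. The +1
    offset keeps zero-intensity pixels finite; a pixel at the white
    level I0 - 1 maps exactly to OD 0.
    """
    if image.n_channels != 3:
        raise ValueError("rgb_to_od expects a 3-channel image")
    i0_arr = np.broadcast_to(np.asarray(i0, dtype=np.float64), (3,))
    if np.any(i0_arr <= 0):
        raise ValueError("white level I0 must be > 0")
    px = np.asarray(image.pixels, dtype=np.float64)
    od = -np.log10((px + 1.0) / i0_arr)
    return np.clip(od, 0.0, od_max)


def deconvolve_stains(
    od: np.ndarray, vectors: StainVectors | None = None, calibration: float = 1.0
) -> ODImage:
    """Unmix per-channel OD into per-stain concentrations.

    Solves M @ c = od per pixel, where the columns of M are the stain
    vectors; negative concentrations are clipped to 0. The inverse
    matrix is cached per StainVectors instance.
    """
    vectors = vectors or StainVectors()
    od = np.asarray(od, dtype=np.float64)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) OD array")
    inv = _cached_inverse(vectors)
    conc = od @ inv.T
    conc = np.clip(conc, 0.0, None)
    return ODImage(
        hematoxylin=conc[:, :, 0],
        dab=conc[:, :, 1],
        residual=conc[:, :, 2],
        calibration=calibration,
    )


_INVERSE_CACHE: dict[StainVectors, np.ndarray] = {}


def _cached_inverse(vectors: StainVectors) -> np.ndarray:
    inv = _INVERSE_CACHE.get(vectors)
    if inv is None:
        inv = np.linalg.inv(vectors.matrix())
        _INVERSE_CACHE[vectors] = inv
    return inv
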