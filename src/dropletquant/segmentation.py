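"""Particle segmentation and equivalent-sphere volume statistics.

Condensates formed by liquid-liquid phase separation appear in a
fluorescence micrograph as bright quasi-circular particles on a dark
background.  The analysis here mirrors the classical particle-analysis
workflow: an automatic global intensity threshold separates foreground
from background, connected components are extracted, components of four
pixels or fewer are discarded as noise artifacts, interior holes are
filled so that a droplet containing smaller internal droplets counts as
one entity, and each surviving particle's projected area is converted to
the volume of the sphere with the same great-circle area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters as _skfilters
from skimage import measure as _skmeasure

__all__ = [
    "Image2D",
    "ParticleRecord",
    "ImageStats",
    "DegenerateHistogramError",
    "auto_threshold",
    "label_particles",
    "particle_volume",
    "image_stats",
    "segment_image",
]

#: survivors must have strictly more than this many pixels
ARTIFACT_MAX_AREA_PX = 4


class DegenerateHistogramError(ValueError):
    """Raised when an image has no intensity contrast to threshold."""


@dataclass
class Image2D:
    """A single-channel micrograph with physical pixel size.

    Parameters
    ----------
    values : ndarray
        2-D array of non-negative intensities.
    pixel_size_nm : float
        Physical edge length of one pixel in nanometres (e.g. 325 for
        wide-field statistics images, 114.17 for dual-view TIRF).
    channel : str
        Channel label, conventionally ``"green"`` or ``"red"``.
    meta : dict
        Free-form acquisition/simulation metadata (e.g. clipping
        fraction of the 16-bit quantization).
    """

    values: np.ndarray
    pixel_size_nm: float
    channel: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("Image2D requires a 2-D array")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ParticleRecord:
    """One segmented droplet and its derived geometric measurements.

    ``centroid_nm`` and ``ellipse_center_nm`` use the convention
    x = (column + 0.5) * pixel_size, y = (row + 0.5) * pixel_size with
    the origin at the top-left pixel corner; all lengths in nm.
    """

    id: int
    area_px: int
    area_um2: float
    centroid_nm: tuple[float, float]
    equivalent_volume_um3: float
    circularity: float
    ellipse_center_nm: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)


@dataclass
class ImageStats:
    """Per-image particle count and mean equivalent-sphere volume.

    ``mean_volume_um3`` is ``None`` when the image holds no particles;
    the undefined mean is represented explicitly rather than as 0 or NaN
    so downstream statistics can exclude empty images deliberately.
    """

    particle_count: int
    mean_volume_um3: float | None
    volumes_um3: list[float]


def auto_threshold(image: Image2D | np.ndarray, method: str = "otsu") -> float:
    """Select a global intensity threshold automatically.

    Foreground is defined as pixels *strictly above* the returned
    threshold; ties go to background.

    Parameters
    ----------
    image : Image2D or ndarray
        Intensity image. Values are treated on the integer grid they
        occupy (16-bit camera counts).
    method : {"otsu", "isodata"}
        ``otsu`` maximizes the between-class variance over every integer
        threshold level in the image's range; ``isodata`` is the
        iterative intermeans algorithm (the historical ImageJ default
        family).

    Returns
    -------
    float
        Threshold within the image's intensity range.

    Raises
    ------
    DegenerateHistogramError
        If the image is constant (no contrast to split).
    """
    values = image.values if isinstance(image, Image2D) else np.asarray(image)
    if values.size == 0:
        raise ValueError("empty image")
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        raise DegenerateHistogramError(
            f"constant image (all pixels = {vmin}): no threshold exists"
        )
    if method == "otsu":
        return _otsu_integer_levels(values)
    if method == "isodata":
        return float(_skfilters.threshold_isodata(values.astype(np.float64)))
    raise ValueError(f"unknown threshold method: {method!r}")


def _otsu_integer_levels(values: np.ndarray) -> float:
    """Otsu's threshold over all integer levels, foreground = strictly above.

    Equivalent to scanning every candidate integer threshold t in
    [min, max) and maximizing the between-class variance
    w_bg * w_fg * (mu_bg - mu_fg)^2 for the split {v <= t} / {v > t};
    the first maximizer (lowest t) wins on ties.  Implemented with
    cumulative histogram sums, so the scan is exact but O(levels).
    """
    v = np.round(values).astype(np.int64)
    vmin = int(v.min())
    hist = np.bincount((v - vmin).ravel())
    levels = np.arange(hist.size, dtype=np.float64) + vmin
    w = np.cumsum(hist)  # pixels <= level
    m = np.cumsum(hist * levels)  # intensity sum <= level
    total_n, total_sum = w[-1], m[-1]
    # candidate thresholds: every level except the maximum (which would
    # leave an empty foreground class)
    w_bg = w[:-1].astype(np.float64)
    w_fg = total_n - w_bg
    mu_bg = m[:-1] / w_bg
    mu_fg = (total_sum - m[:-1]) / w_fg
    valid = (w_bg > 0) & (w_fg > 0)
    var_between = np.where(valid, w_bg * w_fg * (mu_bg - mu_fg) ** 2, -np.inf)
    return float(levels[int(np.argmax(var_between))])


def label_particles(
    mask: np.ndarray,
    pixel_size_nm: float,
    min_area_px: int = ARTIFACT_MAX_AREA_PX + 1,
    connectivity: int = 8,
) -> list[ParticleRecord]:
    """Extract particles from a binary mask.

    Interior holes are filled before any measurement, so a droplet with
    smaller droplets formed inside it is measured as a single big
    entity.  Components with area below ``min_area_px`` (default 5, i.e.
    particles of 4 or fewer pixels) are regarded as artifacts and
    dropped.

    Parameters
    ----------
    mask : ndarray of bool
        Binary foreground mask.
    pixel_size_nm : float
        Physical pixel size in nm.
    min_area_px : int
        Minimum surviving area in pixels (inclusive).
    connectivity : {4, 8}
        Pixel connectivity for component labelling.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel size must be positive")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return []
    filled = ndimage.binary_fill_holes(mask)
    labels = _skmeasure.label(filled, connectivity=1 if connectivity == 4 else 2)
    records: list[ParticleRecord] = []
    for rp in _skmeasure.regionprops(labels):
        if rp.area < min_area_px:
            continue
        area_px = int(rp.area)
        area_um2 = area_px * (pixel_size_nm / 1000.0) ** 2
        row, col = rp.centroid
        center = ((col + 0.5) * pixel_size_nm, (row + 0.5) * pixel_size_nm)
        perimeter = rp.perimeter
        circ = 4.0 * math.pi * area_px / perimeter**2 if perimeter > 0 else 1.0
        records.append(
            ParticleRecord(
                id=len(records),
                area_px=area_px,
                area_um2=area_um2,
                centroid_nm=center,
                equivalent_volume_um3=particle_volume(area_px, pixel_size_nm),
                circularity=circ,
                # moments-ellipse center coincides with the mask centroid
                ellipse_center_nm=center,
                bbox=tuple(rp.bbox),
            )
        )
    return records


def particle_volume(area_px: float, pixel_size_nm: float) -> float:
    """Equivalent-sphere volume (µm³) from projected area.

    Assuming a completely spherical condensate whose great-circle disk
    has the measured projected area A, the radius is r = sqrt(A / pi)
    and the volume (4/3) pi r^3.

    Parameters
    ----------
    area_px : float
        Particle area in pixels (> 0).
    pixel_size_nm : float
        Pixel size in nm (> 0).
    """
    if area_px <= 0:
        raise ValueError("area must be positive")
    if pixel_size_nm <= 0:
        raise ValueError("pixel size must be positive")
    area_um2 = area_px * (pixel_size_nm / 1000.0) ** 2
    r_um = math.sqrt(area_um2 / math.pi)
    return 4.0 / 3.0 * math.pi * r_um**3


def image_stats(particles: list[ParticleRecord]) -> ImageStats:
    """Summarize one image's particles: count and mean equivalent volume."""
    volumes = [p.equivalent_volume_um3 for p in particles]
    mean = float(np.mean(volumes)) if volumes else None
    return ImageStats(particle_count=len(volumes), mean_volume_um3=mean, volumes_um3=volumes)


def segment_image(
    image: Image2D,
    method: str = "otsu",
    min_area_px: int = ARTIFACT_MAX_AREA_PX + 1,
    connectivity: int = 8,
) -> list[ParticleRecord]:
    """Threshold an image and extract its particles in one call."""
    thr = auto_threshold(image, method=method)
    mask = image.values > thr
    return label_particles(mask, image.pixel_size_nm, min_area_px, connectivity)
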