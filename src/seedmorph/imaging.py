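"""Chroma-key seed segmentation.

Turns a calibrated RGB image of seeds on a uniformly coloured (blue)
background into labeled seed particles:

1. scale calibration from a tag of known physical length,
2. RGB channel separation,
3. threshold binarization (Otsu or fixed threshold),
4. connected-component labeling,
5. removal of noise particles far smaller than the seeds.

Coordinates are 0-based (row, col); bounding boxes are inclusive at both
ends. Images are H x W x 3 uint8 arrays in red/green/blue channel order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}

_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


class CalibrationError(RuntimeError):
    """The scale tag could not be located unambiguously."""


class DegenerateHistogramError(ValueError):
    """Otsu thresholding on a constant-valued channel."""


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel-to-millimetre conversion derived from the scale tag.

    ``tag_bbox`` is the inclusive (row_min, row_max, col_min, col_max)
    box of the detected tag, used to exclude it from particle analysis.
    """

    mm_per_px: float
    tag_length_mm: float
    tag_length_px: int
    tag_bbox: tuple[int, int, int, int] | None = None


@dataclass(frozen=True)
class Particle:
    """A connected foreground component.

    pixels: (N, 2) array of (row, col); bbox inclusive at both ends.
    """

    label: int
    pixels: np.ndarray
    area_px: int
    bbox: tuple[int, int, int, int]


def _check_rgb(image: np.ndarray) -> None:
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB image, got shape {image.shape}")


def calibrate_scale(
    image: np.ndarray,
    tag_color: tuple[int, int, int] = (255, 255, 255),
    tag_length_mm: float = 16.0,
    tolerance: int = 0,
) -> ScaleCalibration:
    """Locate the scale tag and derive mm per pixel.

    The tag is the unique connected region whose colour is within a
    Chebyshev distance ``tolerance`` of ``tag_color`` (exact match by
    default, suited to synthetic scenes). mm_per_px is tag_length_mm
    divided by the tag's horizontal pixel extent.
    """
    _check_rgb(image)
    if tag_length_mm <= 0:
        raise ValueError("tag_length_mm must be positive")
    diff = np.abs(image.astype(int) - np.asarray(tag_color, dtype=int)).max(axis=2)
    tag_mask = diff <= tolerance
    lab, n = ndimage.label(tag_mask, structure=_STRUCTURE_8)
    if n == 0:
        raise CalibrationError(f"no region matching tag color {tag_color}")
    if n > 1:
        raise CalibrationError(f"{n} regions match tag color {tag_color}; expected 1")
    rows, cols = np.nonzero(lab == 1)
    span_px = int(cols.max() - cols.min() + 1)
    bbox = (int(rows.min()), int(rows.max()), int(cols.min()), int(cols.max()))
    return ScaleCalibration(
        mm_per_px=tag_length_mm / span_px,
        tag_length_mm=tag_length_mm,
        tag_length_px=span_px,
        tag_bbox=bbox,
    )


def split_channels(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split an RGB image into (red, green, blue) single-channel rasters."""
    _check_rgb(image)
    return image[:, :, 0].copy(), image[:, :, 1].copy(), image[:, :, 2].copy()


def merge_channels(red: np.ndarray, green: np.ndarray, blue: np.ndarray) -> np.ndarray:
    """Inverse of :func:`split_channels`."""
    return np.stack([red, green, blue], axis=2)


def binarize(
    channel: np.ndarray,
    method: str = "otsu",
    polarity: str = "foreground_below",
    threshold: float | None = None,
) -> tuple[np.ndarray, float]:
    """Threshold a single-channel raster into a boolean foreground mask.

    method "otsu" picks the threshold maximizing between-class variance
    of the 256-bin histogram; method "fixed" uses ``threshold``.
    Polarity "foreground_below" marks pixels <= threshold as foreground
    (seeds dark in the blue channel against a bright blue background);
    "foreground_above" marks pixels > threshold.

    Returns (mask, threshold_used).
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("empty channel")
    if polarity not in ("foreground_below", "foreground_above"):
        raise ValueError(f"unknown polarity: {polarity!r}")
    if method == "otsu":
        if channel.min() == channel.max():
            raise DegenerateHistogramError(
                "constant-valued channel: Otsu threshold undefined"
            )
        t = float(threshold_otsu(channel, nbins=256))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method 'fixed' requires a threshold")
        t = float(threshold)
    else:
        raise ValueError(f"unknown threshold method: {method!r}")
    mask = channel <= t if polarity == "foreground_below" else channel > t
    return mask, t


def label_particles(mask: np.ndarray, connectivity: int = 8) -> list[Particle]:
    """Maximal connected components of a boolean mask.

    Labels run 1..n in raster-scan order of each component's first
    pixel. The pixel sets partition the foreground.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCTURE_4 if connectivity == 4 else _STRUCTURE_8
    lab, n = ndimage.label(np.asarray(mask, dtype=bool), structure=structure)
    if n == 0:
        return []
    coords = np.argwhere(lab > 0)
    labels = lab[coords[:, 0], coords[:, 1]]
    order = np.argsort(labels, kind="stable")
    coords = coords[order]
    counts = np.bincount(labels, minlength=n + 1)[1:]
    particles: list[Particle] = []
    offset = 0
    for i, cnt in enumerate(counts, start=1):
        pix = coords[offset : offset + cnt]
        offset += cnt
        bbox = (
            int(pix[:, 0].min()),
            int(pix[:, 0].max()),
            int(pix[:, 1].min()),
            int(pix[:, 1].max()),
        )
        particles.append(Particle(label=i, pixels=pix, area_px=int(cnt), bbox=bbox))
    return particles


def remove_noise(
    particles: list[Particle], size_ratio: float = 100.0
) -> tuple[list[Particle], list[Particle]]:
    """Drop particles far smaller than the typical seed.

    The size threshold is median(area_px) / size_ratio, estimated in a
    single pass over the input; particles with area >= threshold are
    kept. With the default ratio of 100 this removes specks two orders
    of magnitude smaller than the seeds while never removing anything
    when all particles are the same size.
    """
    if size_ratio <= 0:
        raise ValueError("size_ratio must be positive")
    if not particles:
        warnings.warn("remove_noise: empty particle list", stacklevel=2)
        return [], []
    threshold = float(np.median([p.area_px for p in particles])) / size_ratio
    kept = [p for p in particles if p.area_px >= threshold]
    removed = [p for p in particles if p.area_px < threshold]
    return kept, removed


def _bbox_overlap(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1] and a[2] <= b[3] and b[2] <= a[3]


def exclude_region(
    particles: list[Particle], bbox: tuple[int, int, int, int]
) -> list[Particle]:
    """Remove particles whose bounding box intersects ``bbox``.

    Used to exclude the scale tag (and, on real photographs, any colour
    tag) from seed measurement.
    """
    return [p for p in particles if not _bbox_overlap(p.bbox, bbox)]


@dataclass(frozen=True)
class SegmentationResult:
    calibration: ScaleCalibration
    particles: list[Particle]
    noise: list[Particle]
    threshold: float
    mask: np.ndarray


def segment_image(
    image: np.ndarray,
    channel: str = "blue",
    method: str = "otsu",
    polarity: str = "foreground_below",
    threshold: float | None = None,
    connectivity: int = 8,
    size_ratio: float = 100.0,
    tag_color: tuple[int, int, int] = (255, 255, 255),
    tag_length_mm: float = 16.0,
    tag_tolerance: int = 0,
) -> SegmentationResult:
    """Full segmentation pipeline on one chroma-key image.

    Calibrates the scale from the tag, thresholds the chosen channel,
    labels connected components, excludes the tag region and filters
    noise particles. Returns the kept particles along with the
    calibration, threshold and intermediate mask.
    """
    if channel not in CHANNEL_INDEX:
        raise ValueError(f"unknown channel: {channel!r}")
    cal = calibrate_scale(image, tag_color, tag_length_mm, tag_tolerance)
    chan = split_channels(image)[CHANNEL_INDEX[channel]]
    mask, t = binarize(chan, method=method, polarity=polarity, threshold=threshold)
    particles = label_particles(mask, connectivity=connectivity)
    if cal.tag_bbox is not None:
        particles = exclude_region(particles, cal.tag_bbox)
    kept, removed = remove_noise(particles, size_ratio) if particles else ([], [])
    return SegmentationResult(
        calibration=cal, particles=kept, noise=removed, threshold=t, mask=mask
    )
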