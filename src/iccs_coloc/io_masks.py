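"""Image input/output and nuclear mask derivation.

Multi-channel planes are stored as a list of 2D arrays sharing one shape
and one physical pixel size.  All correlation averaging downstream runs
over the boolean nuclear mask produced here.

Coordinate convention (shared package-wide): arrays are indexed
``(row, col) = (y, x)``, 0-based, pixel centers at integer coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .errors import DegenerateInputError, FormatError, SegmentationError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_SIZE_NM = 40.0


@dataclass
class MultiChannelImage:
    """Registered 2D intensity planes for two or more channels.

    Parameters
    ----------
    channels : list of ndarray
        2D intensity grids, identical ``(H, W)`` shape, finite and >= 0.
    pixel_size_nm : float
        Physical pixel pitch in nanometres (> 0).
    channel_labels : list of str
        One label per channel; auto-filled ``ch0, ch1, ...`` when omitted.
    """

    channels: list[np.ndarray]
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("at least one channel is required")
        self.channels = [np.asarray(c) for c in self.channels]
        shape = self.channels[0].shape
        for i, ch in enumerate(self.channels):
            if ch.ndim != 2:
                raise ValidationError(f"channel {i} is not 2D (shape {ch.shape})")
            if ch.shape != shape:
                raise ValidationError(
                    f"channel {i} shape {ch.shape} differs from channel 0 shape {shape}"
                )
            arr = np.asarray(ch, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"channel {i} contains non-finite values")
            if np.any(arr < 0):
                raise ValidationError(f"channel {i} contains negative intensities")
        if not self.pixel_size_nm > 0:
            raise ValidationError("pixel_size_nm must be > 0")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(len(self.channels))]
        if len(self.channel_labels) != len(self.channels):
            raise ValidationError("channel_labels length must match channels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass
class NuclearMask:
    """Boolean per-nucleus pixel mask over which correlations are averaged."""

    mask: np.ndarray
    area_px: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("mask must be 2D")
        n_true = int(self.mask.sum())
        if self.area_px == 0:
            self.area_px = n_true
        elif self.area_px != n_true:
            raise ValidationError(
                f"area_px={self.area_px} does not match true-pixel count {n_true}"
            )
        if self.area_px == 0:
            raise ValidationError("mask is empty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def read_image(
    path: str | Path,
    channel_indices: list[int] | None = None,
    pixel_size_nm: float | None = None,
) -> MultiChannelImage:
    """Read a single- or multi-page TIFF as a :class:`MultiChannelImage`.

    Pages are interpreted as channels.  Bit depth is preserved as stored
    (12-bit data in 16-bit containers is accepted unchanged).  When no
    pixel size is given and none can be recovered from the file metadata,
    the 40 nm default is used with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta_px = _pixel_size_from_tiff(tif)
    if data.ndim == 2:
        planes = [data]
    elif data.ndim == 3:
        planes = [data[k] for k in range(data.shape[0])]
    else:
        raise FormatError(f"expected 2D pages, got array of ndim {data.ndim} in {path}")
    if channel_indices is None:
        channel_indices = list(range(len(planes)))
    for idx in channel_indices:
        if not (0 <= idx < len(planes)):
            raise ValidationError(
                f"channel index {idx} out of range for {len(planes)}-page file {path}"
            )
    if pixel_size_nm is None:
        if meta_px is not None:
            pixel_size_nm = meta_px
        else:
            pixel_size_nm = DEFAULT_PIXEL_SIZE_NM
            logger.warning(
                "no pixel size in metadata of %s; defaulting to %.0f nm",
                path,
                DEFAULT_PIXEL_SIZE_NM,
            )
    return MultiChannelImage(
        channels=[planes[i] for i in channel_indices],
        pixel_size_nm=pixel_size_nm,
    )


def _pixel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    """Recover pixel pitch in nm from TIFF resolution tags, if present."""
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if xres is None:
            return None
        num, den = xres.value
        if num == 0:
            return None
        pixels_per_unit = num / den
        # unit 3 = centimetre, unit 2 = inch
        unit_nm = {2: 2.54e7, 3: 1e7}.get(getattr(unit, "value", None) and unit.value)
        if unit_nm is None:
            return None
        return unit_nm / pixels_per_unit
    except Exception:  # noqa: BLE001 - metadata recovery is best-effort
        return None


def write_image(path: str | Path, image: MultiChannelImage) -> None:
    """Write channels as a multi-page TIFF, preserving integer dtypes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack([np.asarray(c) for c in image.channels])
    tifffile.imwrite(str(path), stack)


def write_mask(path: str | Path, mask: NuclearMask) -> None:
    """Persist a mask as a single-page 8-bit TIFF with values 0/255."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), (mask.mask.astype(np.uint8) * 255))


def segment_nucleus(
    dna_channel: np.ndarray,
    smoothing_sigma_px: float = 2.0,
    min_area_px: int = 1000,
) -> NuclearMask:
    """Segment the nucleus from a DNA counterstain channel.

    Gaussian smooth, global Otsu threshold, fill holes, keep the largest
    8-connected component.
    """
    img = np.asarray(dna_channel, dtype=float)
    if img.ndim != 2:
        raise ValidationError("dna_channel must be 2D")
    if not np.all(np.isfinite(img)) or np.any(img < 0):
        raise ValidationError("dna_channel must be finite and non-negative")
    if smoothing_sigma_px < 0:
        raise ValidationError("smoothing_sigma_px must be >= 0")
    if min_area_px <= 0:
        raise ValidationError("min_area_px must be positive")
    if smoothing_sigma_px > 0:
        img = ndimage.gaussian_filter(img, sigma=smoothing_sigma_px)
    if np.ptp(img) == 0:
        raise DegenerateInputError("constant image: Otsu threshold undefined")
    thr = threshold_otsu(img)
    binary = img > thr
    binary = ndimage.binary_fill_holes(binary)
    labels = label(binary, connectivity=2)
    if labels.max() == 0:
        raise SegmentationError("no foreground component found")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    largest = int(sizes.argmax())
    area = int(sizes[largest])
    if area < min_area_px:
        raise SegmentationError(
            f"largest component has {area} px, below min_area_px={min_area_px}"
        )
    return NuclearMask(mask=labels == largest)


def segment_nuclei(
    dna_channel: np.ndarray,
    smoothing_sigma_px: float = 2.0,
    min_area_px: int = 1000,
    max_nuclei: int = 1,
) -> list[NuclearMask]:
    """Segment up to ``max_nuclei`` nuclei, largest components first."""
    img = np.asarray(dna_channel, dtype=float)
    if smoothing_sigma_px > 0:
        img = ndimage.gaussian_filter(img, sigma=smoothing_sigma_px)
    if np.ptp(img) == 0:
        raise DegenerateInputError("constant image: Otsu threshold undefined")
    thr = threshold_otsu(img)
    binary = ndimage.binary_fill_holes(img > thr)
    labels = label(binary, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    order = np.argsort(sizes)[::-1]
    masks = []
    for lab in order[:max_nuclei]:
        if sizes[lab] < min_area_px:
            break
        masks.append(NuclearMask(mask=labels == lab))
    if not masks:
        raise SegmentationError("no component meets min_area_px")
    return masks
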