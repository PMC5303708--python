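"""Raster I/O and the pixel-to-area calibration.

Images are treated as 8-bit sRGB, row-major with the origin at the top-left
pixel and 0-based indices.  Label masks use a fixed three-class palette
(soil/background, green tissue, dead tissue) and are written as indexed PNG
so that a saved mask reloads to the identical label array.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError


class Label(enum.IntEnum):
    """Per-pixel class of a segmented canopy image."""

    BACKGROUND = 0  # soil / anything that is not plant tissue
    GREEN = 1       # photosynthetically active (green) tissue
    DEAD = 2        # chlorotic or senescent ("dead") tissue


#: Palette used when masks are written to disk: label -> RGB color.
MASK_PALETTE: dict[Label, tuple[int, int, int]] = {
    Label.BACKGROUND: (60, 40, 25),   # dark brown
    Label.GREEN: (0, 180, 0),         # bright green
    Label.DEAD: (220, 190, 60),       # straw yellow
}


class ImageFormatError(ValueError):
    """Raised when a file does not decode to a supported raster."""


@dataclass
class RGBImage:
    """An 8-bit, three-channel raster holding one plant per frame.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` array of dtype ``uint8``.
    source_id
        Free-text identifier (typically the file name or plant id).
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ImageFormatError(
                f"expected an H x W x 3 array, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ImageFormatError("image must contain at least one pixel")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ImageFormatError("channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class AreaCalibration:
    """Ground sampling scale: physical edge length of one pixel.

    ``mm_per_pixel`` must be measured externally (ruler in the frame,
    camera geometry...); it cannot be inferred from the image alone.
    """

    mm_per_pixel: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.mm_per_pixel) or self.mm_per_pixel <= 0:
            raise ValueError(f"mm_per_pixel must be positive, got {self.mm_per_pixel}")


@dataclass
class LabelMask:
    """Per-pixel class map over {BACKGROUND, GREEN, DEAD}."""

    labels: np.ndarray
    image_source_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"labels must be 2-D, got shape {self.labels.shape}")
        if self.labels.size == 0:
            raise ValueError("mask has zero area")
        valid = {int(v) for v in Label}
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise ValueError(f"labels contain values outside {sorted(valid)}: {present}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]


def load_image(path: str | Path) -> RGBImage:
    """Read a JPEG/PNG raster as an :class:`RGBImage`.

    Intensities are preserved exactly as decoded; grayscale images are
    promoted by channel replication and an alpha channel is dropped.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode in ("1", "I", "I;16", "F"):
                raise ImageFormatError(f"{path}: unsupported {im.mode} sample depth")
            if mode == "P":
                im = im.convert("RGB")
            arr = np.asarray(im)
    except (UnidentifiedImageError, OSError) as exc:
        raise ImageFormatError(f"cannot decode image file {path}: {exc}") from exc

    if arr.ndim == 2:  # grayscale -> replicate
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(
            f"{path}: expected 1, 3 or 4 channels, got shape {arr.shape}"
        )
    return RGBImage(pixels=arr.astype(np.uint8), source_id=path.name)


def save_mask(mask: LabelMask, path: str | Path) -> Path:
    """Write a label mask as an indexed-color PNG (palette in MASK_PALETTE)."""
    path = Path(path)
    pal = np.zeros(768, dtype=np.uint8)
    for lab, rgb in MASK_PALETTE.items():
        pal[3 * int(lab): 3 * int(lab) + 3] = rgb
    im = Image.fromarray(mask.labels, mode="P")
    im.putpalette(pal.tolist())
    try:
        im.save(path, format="PNG")
    except OSError as exc:
        raise OSError(f"cannot write mask to {path}: {exc}") from exc
    return path


def load_mask(path: str | Path) -> LabelMask:
    """Reload a mask written by :func:`save_mask`; the inverse operation."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode != "P":
                raise ImageFormatError(f"{path} is not an indexed-color mask")
            labels = np.asarray(im)
    except (UnidentifiedImageError, OSError) as exc:
        raise ImageFormatError(f"cannot decode mask file {path}: {exc}") from exc
    return LabelMask(labels=labels, image_source_id=path.name)
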