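"""Pixel counting, percentages, physical-area conversion and record export.

Counts from a label mask are expressed two ways: as a share of the whole
frame and as a share of the plant silhouette (green + dead).  Pixel counts
convert to physical areas through the ground sampling scale (mm per pixel
edge); areas are held in mm^2 and reported in cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import AreaCalibration, Label, LabelMask

MM2_PER_CM2 = 100.0


@dataclass(frozen=True)
class ClassCounts:
    """Exact per-class pixel tallies of one mask."""

    pixels_green: int
    pixels_dead: int
    pixels_background: int

    def __post_init__(self) -> None:
        for name in ("pixels_green", "pixels_dead", "pixels_background"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total_pixels(self) -> int:
        return self.pixels_green + self.pixels_dead + self.pixels_background

    @property
    def plant_pixels(self) -> int:
        return self.pixels_green + self.pixels_dead


def count_pixels(mask: LabelMask) -> ClassCounts:
    """Tally the pixels of each class; counts always sum to H*W."""
    counts = np.bincount(mask.labels.ravel(), minlength=3)
    return ClassCounts(
        pixels_green=int(counts[int(Label.GREEN)]),
        pixels_dead=int(counts[int(Label.DEAD)]),
        pixels_background=int(counts[int(Label.BACKGROUND)]),
    )


@dataclass(frozen=True)
class ClassPercentages:
    """Per-class percentages of the frame and of the plant silhouette.

    Of-plant values are ``None`` (missing, not zero) when the mask contains
    no plant pixels.
    """

    of_image_green: float
    of_image_dead: float
    of_image_background: float
    of_plant_green: float | None
    of_plant_dead: float | None


def to_percentages(counts: ClassCounts) -> ClassPercentages:
    """Express counts as percentages of the image and of the plant area."""
    total = counts.total_pixels
    if total == 0:
        raise ValueError("total_pixels must be positive")
    plant = counts.plant_pixels
    return ClassPercentages(
        of_image_green=100.0 * counts.pixels_green / total,
        of_image_dead=100.0 * counts.pixels_dead / total,
        of_image_background=100.0 * counts.pixels_background / total,
        of_plant_green=(100.0 * counts.pixels_green / plant) if plant else None,
        of_plant_dead=(100.0 * counts.pixels_dead / plant) if plant else None,
    )


def pixels_to_area(count: int, cal: AreaCalibration) -> float:
    """Convert a pixel count to mm^2: count x (mm per pixel)^2."""
    if count < 0:
        raise ValueError(f"pixel count must be non-negative, got {count}")
    return float(count) * cal.mm_per_pixel ** 2


def mm2_to_cm2(area_mm2: float) -> float:
    return area_mm2 / MM2_PER_CM2


@dataclass(frozen=True)
class ProjectedAreas:
    """Projected green and dead canopy areas of one plant, in mm^2."""

    projected_green_mm2: float
    projected_dead_mm2: float

    def __post_init__(self) -> None:
        if self.projected_green_mm2 < 0 or self.projected_dead_mm2 < 0:
            raise ValueError("projected areas must be non-negative")

    @property
    def projected_green_cm2(self) -> float:
        return mm2_to_cm2(self.projected_green_mm2)

    @property
    def projected_dead_cm2(self) -> float:
        return mm2_to_cm2(self.projected_dead_mm2)

    @classmethod
    def from_counts(cls, counts: ClassCounts, cal: AreaCalibration) -> "ProjectedAreas":
        return cls(
            projected_green_mm2=pixels_to_area(counts.pixels_green, cal),
            projected_dead_mm2=pixels_to_area(counts.pixels_dead, cal),
        )


@dataclass
class SegmentationResult:
    """Mask plus derived quantities and provenance for one frame."""

    mask: LabelMask
    counts: ClassCounts
    percentages: ClassPercentages
    config_fingerprint: str
    seed: int
    warnings: list[str] = field(default_factory=list)


def summarize(mask: LabelMask, config_fingerprint: str, seed: int,
              warnings: list[str] | None = None) -> SegmentationResult:
    """Bundle a mask with its counts and percentages."""
    counts = count_pixels(mask)
    return SegmentationResult(
        mask=mask,
        counts=counts,
        percentages=to_percentages(counts),
        config_fingerprint=config_fingerprint,
        seed=seed,
        warnings=list(warnings or []),
    )


@dataclass
class PlantObservation:
    """One plant x time-point record of measured and image-derived traits.

    Any trait may be missing (``None``); missingness is preserved through
    CSV export as empty cells, never as zero.
    """

    plant_id: str
    genotype: str
    treatment: str                 # "control" or "waterlogged"
    replicate: int
    time_point: str                # "before" or "after"
    pixels_green: int | None = None
    pixels_dead: int | None = None
    pixels_background: int | None = None
    pct_image_green: float | None = None
    pct_image_dead: float | None = None
    pga_cm2: float | None = None   # projected green area
    pda_cm2: float | None = None   # projected dead area
    ndvi: float | None = None
    shb_g: float | None = None     # shoot biomass, g/plant
    glb_g: float | None = None     # green leaf biomass
    dlb_g: float | None = None     # dead leaf biomass
    height_cm: float | None = None
    iv: float | None = None        # initial vigor score, 1-5
    ve: float | None = None        # visual evaluation score, 1-5

    def __post_init__(self) -> None:
        if self.treatment not in ("control", "waterlogged"):
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.time_point not in ("before", "after"):
            raise ValueError(f"unknown time_point {self.time_point!r}")
        for name in ("iv", "ve"):
            v = getattr(self, name)
            if v is not None and not (1 <= v <= 5):
                raise ValueError(f"{name} must lie in [1, 5], got {v}")
        if self.ndvi is not None and not (-1 <= self.ndvi <= 1):
            raise ValueError(f"ndvi must lie in [-1, 1], got {self.ndvi}")
        for name in ("shb_g", "glb_g", "dlb_g", "height_cm", "pga_cm2", "pda_cm2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


#: Canonical column order of the record CSV (the column dictionary).
RECORD_COLUMNS = [
    "plant_id", "genotype", "treatment", "replicate", "time_point",
    "pixels_green", "pixels_dead", "pixels_background",
    "pct_image_green", "pct_image_dead",
    "pga_cm2", "pda_cm2", "ndvi",
    "shb_g", "glb_g", "dlb_g", "height_cm", "iv", "ve",
]

_INT_COLUMNS = {"pixels_green", "pixels_dead", "pixels_background"}


def records_to_frame(records: list[PlantObservation]) -> pd.DataFrame:
    """Records as a DataFrame with the canonical column order."""
    rows = [{c: getattr(r, c) for c in RECORD_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(records: list[PlantObservation], path: str | Path) -> Path:
    """Write per-plant records to CSV (UTF-8, header row, missing = empty)."""
    path = Path(path)
    df = records_to_frame(records)
    df.to_csv(path, index=False)
    return path


def read_records(path: str | Path) -> list[PlantObservation]:
    """Inverse of :func:`write_records`."""
    df = pd.read_csv(path, dtype={"plant_id": str, "genotype": str})
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for c in RECORD_COLUMNS:
            v = row[c]
            if pd.isna(v):
                v = None
            elif c in _INT_COLUMNS:
                v = int(v)
            elif c == "replicate":
                v = int(v)
            kwargs[c] = v
        records.append(PlantObservation(**kwargs))
    return records
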