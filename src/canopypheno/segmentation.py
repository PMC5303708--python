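"""Color-based segmentation of overhead canopy images.

The pipeline classifies every pixel of a single-plant frame as soil
(background), green tissue, or chlorotic/senescent ("dead") tissue in four
steps:

1. *Background removal* — a per-channel color box learned from labeled soil
   pixels; anything inside the box is soil.
2. *Color stretch* — a decorrelation stretch (covariance whitening followed
   by per-channel rescaling to the full 8-bit range) that exaggerates hue
   differences among the remaining plant pixels.  A percentile stretch is
   the fallback when the channel covariance is degenerate.
3. *K-means clustering* — seeded Lloyd iterations with k-means++
   initialization over the stretched foreground colors.
4. *Class assignment* — each cluster is mapped to the class of its nearest
   color prototype (Euclidean distance), turning the unsupervised clusters
   into the three classes of interest.

All randomness flows from one integer seed, so a given image and
configuration always reproduce the same mask.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from skimage import measure
from skimage.color import rgb2hsv

from . import quantification
from .image_io import Label, LabelMask, RGBImage

# Tie-break priority when a centroid is equidistant from two prototypes.
_LABEL_PRIORITY = (Label.GREEN, Label.DEAD, Label.BACKGROUND)

#: Channel ranges per working color space (used for bound validation and
#: the floor width of threshold tightening).
_SPACE_RANGES = {
    "rgb": np.array([[0.0, 255.0]] * 3),
    "hsv": np.array([[0.0, 1.0]] * 3),
}


class TrainingError(ValueError):
    """Raised when a threshold model cannot be learned from the given pixels."""


class ConfigurationError(ValueError):
    """Raised when a segmentation configuration is internally inconsistent."""


def _to_space(rgb_colors: np.ndarray, channel_space: str) -> np.ndarray:
    """Convert an (N, 3) or (H, W, 3) array of 8-bit RGB to the working space."""
    arr = np.asarray(rgb_colors, dtype=float)
    if channel_space == "rgb":
        return arr
    if channel_space == "hsv":
        return rgb2hsv(arr.reshape(-1, 1, 3) / 255.0).reshape(arr.shape)
    raise ValueError(f"unknown channel space {channel_space!r}")


@dataclass
class ColorThresholdModel:
    """Axis-aligned color volume enclosing soil/background pixels.

    A pixel whose color (in ``channel_space``) lies inside the closed box
    ``[lower, upper]`` on every channel is classified as background.

    Hue is circular: in HSV mode the hue channel is rotated by
    ``hue_offset`` (mod 1) before the bounds are applied, so a soil hue
    cluster straddling the 0/1 wrap point still forms one contiguous box.
    """

    channel_space: str
    lower: np.ndarray
    upper: np.ndarray
    hue_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.channel_space not in _SPACE_RANGES:
            raise ValueError(f"channel_space must be one of {sorted(_SPACE_RANGES)}")
        self.lower = np.asarray(self.lower, dtype=float).reshape(3)
        self.upper = np.asarray(self.upper, dtype=float).reshape(3)
        rng = _SPACE_RANGES[self.channel_space]
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound")
        if np.any(self.lower < rng[:, 0] - 1e-9) or np.any(self.upper > rng[:, 1] + 1e-9):
            raise ValueError("bounds outside the channel's representable range")

    def contains(self, rgb_colors: np.ndarray) -> np.ndarray:
        """Boolean array: True where the color lies inside the soil volume."""
        x = _to_space(rgb_colors, self.channel_space)
        if self.channel_space == "hsv" and self.hue_offset != 0.0:
            x = x.copy()
            x[..., 0] = (x[..., 0] + self.hue_offset) % 1.0
        inside = np.logical_and(x >= self.lower, x <= self.upper)
        return inside.all(axis=-1)


def learn_soil_threshold(
    colors: np.ndarray,
    is_soil: np.ndarray,
    channel_space: str = "hsv",
    trim_percentiles: tuple[float, float] = (0.0, 100.0),
    floor_fraction: float = 0.02,
) -> ColorThresholdModel:
    """Learn a per-channel soil color box from labeled training pixels.

    The box starts as the (optionally percentile-trimmed) envelope of the
    soil pixels and is then tightened greedily toward the soil median, one
    bound at a time, until no plant training pixel lies inside it or every
    bound has reached a floor width (``floor_fraction`` of the channel
    range on each side of the median).  Tightening maximizes retained soil
    pixels: at each step the bound move that excludes the most plant pixels
    at the least soil cost is applied.

    Parameters
    ----------
    colors
        (N, 3) 8-bit RGB training colors.
    is_soil
        (N,) boolean; True for soil-labeled pixels, False for plant.
    """
    colors = np.asarray(colors, dtype=float).reshape(-1, 3)
    is_soil = np.asarray(is_soil, dtype=bool).reshape(-1)
    if colors.shape[0] != is_soil.shape[0]:
        raise TrainingError("colors and labels disagree in length")
    soil = _to_space(colors[is_soil], channel_space)
    plant = _to_space(colors[~is_soil], channel_space)
    if soil.shape[0] == 0 or plant.shape[0] == 0:
        raise TrainingError(
            "need at least one soil-labeled and one plant-labeled training pixel"
        )

    hue_offset = 0.0
    if channel_space == "hsv":
        # recenter the circular hue axis on the soil cluster so a cluster
        # straddling the 0/1 wrap point forms one contiguous interval
        ang = 2 * np.pi * soil[:, 0]
        center = (np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
                  / (2 * np.pi)) % 1.0
        hue_offset = (0.5 - center) % 1.0
        soil = soil.copy()
        plant = plant.copy()
        soil[:, 0] = (soil[:, 0] + hue_offset) % 1.0
        plant[:, 0] = (plant[:, 0] + hue_offset) % 1.0

    lo_p, hi_p = trim_percentiles
    lower = np.percentile(soil, lo_p, axis=0)
    upper = np.percentile(soil, hi_p, axis=0)
    median = np.median(soil, axis=0)
    chan_range = _SPACE_RANGES[channel_space]
    floor = floor_fraction * (chan_range[:, 1] - chan_range[:, 0])
    eps = 1e-9 * (chan_range[:, 1] - chan_range[:, 0])

    def inside(points: np.ndarray) -> np.ndarray:
        return np.logical_and(points >= lower, points <= upper).all(axis=1)

    while True:
        plant_in = inside(plant)
        if not plant_in.any():
            break
        best = None  # (plant_excluded, -soil_excluded, channel, side, new_bound)
        soil_in = inside(soil)
        for c in range(3):
            # raise the lower bound toward the median
            limit = median[c] - floor[c]
            if lower[c] < limit:
                vals = plant[plant_in, c]
                reachable = vals[vals < limit]
                if reachable.size:
                    new_lo = min(reachable.max() + eps[c], limit)
                    n_plant = int((plant[plant_in, c] < new_lo).sum())
                    n_soil = int((soil[soil_in, c] < new_lo).sum())
                    cand = (n_plant, -n_soil, c, 0, new_lo)
                    best = max(best, cand) if best else cand
            # lower the upper bound toward the median
            limit = median[c] + floor[c]
            if upper[c] > limit:
                vals = plant[plant_in, c]
                reachable = vals[vals > limit]
                if reachable.size:
                    new_hi = max(reachable.min() - eps[c], limit)
                    n_plant = int((plant[plant_in, c] > new_hi).sum())
                    n_soil = int((soil[soil_in, c] > new_hi).sum())
                    cand = (n_plant, -n_soil, c, 1, new_hi)
                    best = max(best, cand) if best else cand
        if best is None or best[0] == 0:
            break  # floor reached on every channel; plant not separable
        _, _, c, side, bound = best
        if side == 0:
            lower[c] = bound
        else:
            upper[c] = bound

    return ColorThresholdModel(channel_space=channel_space, lower=lower,
                               upper=upper, hue_offset=hue_offset)


def remove_background(img: RGBImage, model: ColorThresholdModel) -> np.ndarray:
    """Return a boolean foreground mask (True = plant, False = soil)."""
    return ~model.contains(img.pixels)


@dataclass
class StretchParams:
    """Provenance of a color stretch: the method actually applied and its
    fitted parameters."""

    method: str                      # "decorrelation" or "percentile"
    requested_method: str
    fallback: bool = False
    mean: np.ndarray | None = None           # decorrelation: channel means
    whitening: np.ndarray | None = None      # decorrelation: 3x3 transform
    rescale_offset: np.ndarray | None = None
    rescale_gain: np.ndarray | None = None
    percentiles: tuple[float, float] | None = None
    channel_low: np.ndarray | None = None    # percentile: per-channel anchors
    channel_high: np.ndarray | None = None


def _percentile_stretch(fg: np.ndarray, percentiles: tuple[float, float]):
    lo_p, hi_p = percentiles
    lo = np.percentile(fg, lo_p, axis=0)
    hi = np.percentile(fg, hi_p, axis=0)
    out = np.empty_like(fg)
    for c in range(3):
        if hi[c] <= lo[c]:  # zero dynamic range -> defined midpoint
            out[:, c] = 128.0
        else:
            out[:, c] = np.clip(255.0 * (fg[:, c] - lo[c]) / (hi[c] - lo[c]), 0, 255)
    return out, lo, hi


def stretch_colors(
    img: RGBImage,
    foreground: np.ndarray,
    method: str = "decorrelation",
    percentiles: tuple[float, float] = (2.0, 98.0),
) -> tuple[RGBImage, StretchParams]:
    """Contrast-stretch the foreground colors; background passes through.

    Decorrelation stretch whitens the channel covariance of the foreground
    pixels (removing inter-channel correlation) and rescales each resulting
    channel to span [0, 255].  When the covariance is rank-deficient the
    percentile stretch is applied instead and the fallback is recorded.
    """
    if method not in ("decorrelation", "percentile"):
        raise ValueError(f"unknown stretch method {method!r}")
    foreground = np.asarray(foreground, dtype=bool)
    if foreground.shape != (img.height, img.width):
        raise ValueError("foreground mask shape does not match image")
    fg = img.pixels[foreground].astype(float)
    if fg.shape[0] == 0:
        raise ValueError("stretch requires at least one foreground pixel")

    params = StretchParams(method=method, requested_method=method,
                           percentiles=percentiles)
    stretched = None
    if method == "decorrelation":
        if fg.shape[0] < 2:
            params.fallback = True
        else:
            cov = np.cov(fg, rowvar=False)
            evals, evecs = np.linalg.eigh(cov)
            if evals[-1] <= 0 or evals[0] < 1e-8 * evals[-1]:
                params.fallback = True  # degenerate covariance
            else:
                mean = fg.mean(axis=0)
                whiten = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
                y = (fg - mean) @ whiten
                lo = y.min(axis=0)
                hi = y.max(axis=0)
                gain = np.where(hi > lo, 255.0 / np.where(hi > lo, hi - lo, 1.0), 0.0)
                stretched = np.where(hi > lo, (y - lo) * gain, 128.0)
                params.mean = mean
                params.whitening = whiten
                params.rescale_offset = lo
                params.rescale_gain = gain
        if params.fallback:
            params.method = "percentile"
    if stretched is None:
        stretched, lo, hi = _percentile_stretch(fg, percentiles)
        params.channel_low = lo
        params.channel_high = hi

    out = img.pixels.copy()
    out[foreground] = np.clip(np.rint(stretched), 0, 255).astype(np.uint8)
    return RGBImage(pixels=out, source_id=img.source_id), params


@dataclass
class KMeansResult:
    """Outcome of seeded Lloyd's k-means over pixel colors."""

    k: int
    centroids: np.ndarray          # (k, 3)
    assignment: np.ndarray         # (N,) cluster index per pixel
    sse: float                     # within-cluster sum of squared distances
    sse_history: list[float]       # SSE after each assignment step
    n_iter: int
    seed: int
    converged: bool


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: D^2-weighted sampling of initial centroids."""
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    idx = int(rng.integers(n))
    centroids[0] = X[idx]
    d2 = ((X - centroids[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a centroid
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centroids[j] = X[idx]
        d2 = np.minimum(d2, ((X - centroids[j]) ** 2).sum(axis=1))
    return centroids


def kmeans_cluster(
    pixel_colors: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> KMeansResult:
    """Cluster pixel colors with Lloyd's algorithm from a seeded k-means++
    start.

    Each point is assigned to its nearest centroid by Euclidean distance
    (ties broken toward the lowest centroid index).  An empty cluster is
    re-seeded to the point currently farthest from its assigned centroid.
    The result is deterministic given the data order and the seed.
    """
    X = np.asarray(pixel_colors, dtype=float)
    if X.ndim != 2:
        raise ValueError("pixel_colors must be an (N, C) matrix")
    if not np.isfinite(X).all():
        raise ValueError("pixel colors must be finite")
    n = X.shape[0]
    if k < 1 or n < k:
        raise ValueError(f"need N >= k >= 1, got N={n}, k={k}")

    rng = np.random.default_rng(seed)
    centroids = _kmeans_pp_init(X, k, rng)
    sse_history: list[float] = []
    converged = False
    it = 0
    assignment = np.zeros(n, dtype=np.intp)
    for it in range(1, max_iter + 1):
        d = cdist(X, centroids, metric="sqeuclidean")
        assignment = d.argmin(axis=1)
        # repair empty clusters: farthest point becomes the new centroid
        point_cost = d[np.arange(n), assignment]
        for j in range(k):
            if not (assignment == j).any():
                far = int(point_cost.argmax())
                centroids[j] = X[far]
                assignment[far] = j
                point_cost[far] = 0.0
        sse_history.append(float(
            ((X - centroids[assignment]) ** 2).sum()
        ))
        new_centroids = np.vstack([
            X[assignment == j].mean(axis=0) for j in range(k)
        ])
        movement = float(np.sqrt(((new_centroids - centroids) ** 2).sum(axis=1)).max())
        centroids = new_centroids
        if movement < tol:
            converged = True
            break

    # final exact assignment against the final centroids
    d = cdist(X, centroids, metric="sqeuclidean")
    assignment = d.argmin(axis=1)
    sse = float(d[np.arange(n), assignment].sum())
    sse_history.append(sse)
    return KMeansResult(k=k, centroids=centroids, assignment=assignment, sse=sse,
                        sse_history=sse_history, n_iter=it, seed=seed,
                        converged=converged)


@dataclass(frozen=True)
class ClassPrototype:
    """A reference color for one class, used to label k-means clusters."""

    label: Label
    centroid: tuple[float, float, float]


#: Default prototypes in RGB, matched to typical field scenes: green canopy,
#: straw-colored senescent tissue, and brown soil.
DEFAULT_PROTOTYPES: tuple[ClassPrototype, ...] = (
    ClassPrototype(Label.GREEN, (60.0, 120.0, 50.0)),
    ClassPrototype(Label.DEAD, (160.0, 140.0, 60.0)),
    ClassPrototype(Label.BACKGROUND, (110.0, 85.0, 65.0)),
)


def assign_classes(
    result: KMeansResult,
    prototypes: Sequence[ClassPrototype],
    foreground: np.ndarray,
    centroid_colors: np.ndarray | None = None,
) -> LabelMask:
    """Map k-means clusters to classes and build a full-image label mask.

    Each cluster centroid is labeled with its nearest prototype (Euclidean
    distance; ties resolved by the GREEN < DEAD < BACKGROUND priority).
    ``result.assignment`` must cover the foreground pixels in row-major
    order; everything outside the foreground is forced to BACKGROUND.

    ``centroid_colors`` optionally substitutes the coordinates used for the
    prototype comparison (e.g., mean original-RGB color per cluster when
    clustering ran in a stretched space).
    """
    labels_present = {p.label for p in prototypes}
    for req in (Label.GREEN, Label.DEAD, Label.BACKGROUND):
        if req not in labels_present:
            raise ConfigurationError(f"missing prototype for label {req.name}")
    foreground = np.asarray(foreground, dtype=bool)
    n_fg = int(foreground.sum())
    if result.assignment.shape[0] != n_fg:
        raise ConfigurationError(
            f"assignment covers {result.assignment.shape[0]} pixels, "
            f"foreground has {n_fg}"
        )
    coords = result.centroids if centroid_colors is None else np.asarray(centroid_colors, float)

    # order prototypes by priority so argmin tie-breaks correctly
    order = sorted(range(len(prototypes)),
                   key=lambda i: _LABEL_PRIORITY.index(prototypes[i].label))
    proto_mat = np.array([prototypes[i].centroid for i in order], dtype=float)
    proto_labels = np.array([int(prototypes[i].label) for i in order])
    d = cdist(coords, proto_mat)
    cluster_label = proto_labels[d.argmin(axis=1)]

    flat = np.full(foreground.size, int(Label.BACKGROUND), dtype=np.uint8)
    flat[foreground.ravel()] = cluster_label[result.assignment]
    return LabelMask(labels=flat.reshape(foreground.shape))


@dataclass
class SegmentationConfig:
    """All knobs of the segmentation pipeline, fixed up front for
    reproducibility.

    ``k`` defaults to 4 so that shadowed plant tissue and residual soil can
    occupy their own clusters before the prototype mapping collapses them
    onto the three classes of interest.
    """

    threshold_model: ColorThresholdModel
    stretch_method: str = "decorrelation"
    stretch_percentiles: tuple[float, float] = (2.0, 98.0)
    k: int = 4
    seed: int = 0
    max_iter: int = 50
    tol: float = 1e-3
    prototypes: tuple[ClassPrototype, ...] = DEFAULT_PROTOTYPES
    min_region_size: int = 0        # connected-component cleanup; 0 = off
    sample_cap: int = 200_000       # max pixels used to fit centroids

    def __post_init__(self) -> None:
        if self.k < len({p.label for p in self.prototypes}):
            raise ConfigurationError(
                "k must be at least the number of distinct prototype labels")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")
        if self.tol < 0:
            raise ConfigurationError("tol must be >= 0")
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.sample_cap < 1:
            raise ConfigurationError("sample_cap must be >= 1")

    def fingerprint(self) -> str:
        """Stable hash of the configuration, stored with every result."""
        parts = [
            self.threshold_model.channel_space,
            np.array2string(self.threshold_model.lower, precision=10),
            np.array2string(self.threshold_model.upper, precision=10),
            repr(self.threshold_model.hue_offset),
            self.stretch_method, str(self.stretch_percentiles), str(self.k),
            str(self.seed), str(self.max_iter), str(self.tol),
            str([(p.label.name, p.centroid) for p in self.prototypes]),
            str(self.min_region_size), str(self.sample_cap),
        ]
        return hashlib.sha1("|".join(parts).encode()).hexdigest()[:16]


def segment_plant(img: RGBImage, config: SegmentationConfig) -> "quantification.SegmentationResult":
    """Run the full pipeline on one frame and quantify the outcome.

    Composes background removal, color stretch, k-means clustering of the
    foreground colors, prototype class assignment and pixel counting.  A
    frame with no foreground after thresholding yields an all-background
    result flagged with a warning rather than an error.
    """
    warnings: list[str] = []
    foreground = remove_background(img, config.threshold_model)
    n_fg = int(foreground.sum())
    h, w = img.height, img.width

    if n_fg == 0:
        mask = LabelMask(labels=np.zeros((h, w), dtype=np.uint8),
                         image_source_id=img.source_id)
        warnings.append("zero-foreground: no plant pixels after background removal")
        return quantification.summarize(mask, config_fingerprint=config.fingerprint(),
                                        seed=config.seed, warnings=warnings)

    stretched, stretch_params = stretch_colors(
        img, foreground, method=config.stretch_method,
        percentiles=config.stretch_percentiles)
    if stretch_params.fallback:
        warnings.append("stretch: degenerate covariance, fell back to percentile")

    fg_cols = stretched.pixels[foreground].astype(float)
    orig_cols = img.pixels[foreground].astype(float)

    k = min(config.k, n_fg)
    if k < config.k:
        warnings.append(f"k reduced to {k}: only {n_fg} foreground pixels")

    if n_fg > config.sample_cap:
        rng = np.random.default_rng(config.seed)
        fit_idx = np.sort(rng.choice(n_fg, size=config.sample_cap, replace=False))
        fit_cols = fg_cols[fit_idx]
    else:
        fit_cols = fg_cols
    km = kmeans_cluster(fit_cols, k=k, seed=config.seed,
                        max_iter=config.max_iter, tol=config.tol)

    # exact assignment of every foreground pixel to the fitted centroids
    d = cdist(fg_cols, km.centroids, metric="sqeuclidean")
    full_assignment = d.argmin(axis=1)
    sse = float(d[np.arange(n_fg), full_assignment].sum())
    km_full = replace(km, assignment=full_assignment, sse=sse)

    # classify clusters by their mean ORIGINAL color (prototypes live in RGB)
    centroid_colors = np.vstack([
        orig_cols[full_assignment == j].mean(axis=0)
        if (full_assignment == j).any() else km.centroids[j]
        for j in range(k)
    ])
    mask = assign_classes(km_full, config.prototypes, foreground,
                          centroid_colors=centroid_colors)
    mask.image_source_id = img.source_id

    if config.min_region_size > 0:
        plant = mask.labels != int(Label.BACKGROUND)
        comp = measure.label(plant, connectivity=2)
        sizes = np.bincount(comp.ravel())
        small = sizes < config.min_region_size
        small[0] = False
        mask.labels[small[comp]] = int(Label.BACKGROUND)

    return quantification.summarize(mask, config_fingerprint=config.fingerprint(),
                                    seed=config.seed, warnings=warnings)
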