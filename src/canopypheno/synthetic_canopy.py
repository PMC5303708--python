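"""Seeded synthetic inputs: canopy scenes with pixel-exact ground truth, and
genotype x treatment trait cohorts with known generating parameters.

Scenes emulate an overhead view of a single plant on bare soil: a textured
soil background over which senescent ("dead") elliptical leaves are drawn
first and green leaves second, so green canopy occludes the senescing lower
leaves.  The truth mask records the final visible class of every pixel.

Cohorts emulate a waterlogging field trial: genotype effects on shoot
biomass, a multiplicative treatment reduction, per-genotype senescence
sensitivity splitting biomass into green and dead fractions, and projected
canopy areas tied to biomass by a linear link with configurable noise.

All randomness flows from a single integer seed through one generator per
call; identical specs and seeds reproduce identical outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from skimage.draw import ellipse as draw_ellipse

from .image_io import Label, LabelMask, RGBImage
from .quantification import ClassCounts, PlantObservation, count_pixels


@dataclass(frozen=True)
class EllipseStroke:
    """Provenance of one rendered leaf (all geometry in pixels/radians)."""

    label: Label
    row: float
    col: float
    r_radius: float
    c_radius: float
    rotation: float


@dataclass
class SceneSpec:
    """Parameters of one synthetic canopy scene.

    Default class colors — green (60, 120, 50), dead (160, 140, 60), soil
    (110, 85, 65) with sigma = 5 — are separable but not trivially so; they
    are fixture values, not measurements.
    """

    width: int = 512
    height: int = 512
    soil_color: tuple[float, float, float] = (110.0, 85.0, 65.0)
    soil_noise_sigma: float = 5.0
    n_green: int = 12
    green_axis_range: tuple[float, float] | None = None  # default: 3-12% of frame
    n_dead: int = 8
    dead_axis_range: tuple[float, float] | None = None   # default: 2.5-9% of frame
    green_color: tuple[float, float, float] = (60.0, 120.0, 50.0)
    dead_color: tuple[float, float, float] = (160.0, 140.0, 60.0)
    color_sigma: float = 5.0
    rotation_range: tuple[float, float] = (0.0, np.pi)
    illumination_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 32 or self.height < 32:
            raise ValueError("scene dimensions must be at least 32 pixels")
        if min(self.soil_noise_sigma, self.color_sigma) < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.n_green < 0 or self.n_dead < 0:
            raise ValueError("leaf counts must be non-negative")
        colors = [tuple(self.soil_color), tuple(self.green_color), tuple(self.dead_color)]
        if len(set(colors)) != 3:
            raise ValueError("class color means must be pairwise distinct")
        m = min(self.width, self.height)
        if self.green_axis_range is None:
            self.green_axis_range = (0.03 * m, 0.12 * m)
        if self.dead_axis_range is None:
            self.dead_axis_range = (0.025 * m, 0.09 * m)
        half = m / 2.0
        for name, rng_ in (("green", self.green_axis_range), ("dead", self.dead_axis_range)):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError(f"invalid {name} axis range {rng_}")
            if rng_[1] > half:
                raise ValueError(f"{name} leaves larger than the frame ({rng_[1]} > {half})")
        if not (0 <= self.illumination_amplitude < 1):
            raise ValueError("illumination amplitude must lie in [0, 1)")


@dataclass
class Scene:
    """A rendered scene with its pixel-exact ground truth."""

    image: RGBImage
    mask: LabelMask
    counts: ClassCounts
    ellipses: list[EllipseStroke]


def generate_scene(spec: SceneSpec) -> Scene:
    """Render a scene and its truth mask from a :class:`SceneSpec`.

    Dead leaves are composited first and green leaves second, so each pixel's
    truth label is the class of the last stroke covering it (soil where no
    leaf does).  The returned counts are an exact tally of the truth mask.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(spec.soil_color)
    if spec.soil_noise_sigma > 0:
        img += rng.normal(0.0, spec.soil_noise_sigma, size=img.shape)
    labels = np.full((h, w), int(Label.BACKGROUND), dtype=np.uint8)

    strokes: list[EllipseStroke] = []
    plan = [(Label.DEAD, spec.n_dead, spec.dead_axis_range, spec.dead_color),
            (Label.GREEN, spec.n_green, spec.green_axis_range, spec.green_color)]
    for label, n_leaves, axis_range, color in plan:
        for _ in range(n_leaves):
            r0 = rng.uniform(0, h - 1)
            c0 = rng.uniform(0, w - 1)
            a = rng.uniform(*axis_range)
            b = rng.uniform(*axis_range)
            theta = rng.uniform(*spec.rotation_range)
            rr, cc = draw_ellipse(r0, c0, a, b, shape=(h, w), rotation=theta)
            pix = np.asarray(color) + (
                rng.normal(0.0, spec.color_sigma, size=(rr.size, 3))
                if spec.color_sigma > 0 else 0.0
            )
            img[rr, cc] = pix
            labels[rr, cc] = int(label)
            strokes.append(EllipseStroke(label, r0, c0, a, b, theta))

    if spec.illumination_amplitude > 0:
        ramp = 1.0 + spec.illumination_amplitude * (
            2.0 * np.arange(w) / max(w - 1, 1) - 1.0)
        img *= ramp[None, :, None]

    image = RGBImage(pixels=np.clip(np.rint(img), 0, 255).astype(np.uint8),
                     source_id=f"synthetic-scene-seed{spec.seed}")
    mask = LabelMask(labels=labels, image_source_id=image.source_id)
    return Scene(image=image, mask=mask, counts=count_pixels(mask), ellipses=strokes)


@dataclass
class CohortSpec:
    """Parameters of a synthetic genotype x treatment trial.

    The defaults mirror a waterlogging screening trial: 22 genotypes, six
    replicates per treatment, control shoot biomass around 700 g/plant, and
    a 50% mean biomass reduction under waterlogging.
    """

    n_genotypes: int = 22
    replicates: int = 6
    base_biomass: float = 700.0          # g/plant under control
    genotype_sd: float = 0.25            # multiplicative genotype effect SD
    reduction: float = 0.5               # mean biomass loss under waterlogging
    replicate_cv: float = 0.15           # within-genotype replicate noise
    dead_sensitivity_range: tuple[float, float] = (0.1, 0.6)
    control_dead_fraction: float = 0.05
    area_coeff: float = 1.2              # cm^2 projected area per g biomass
    area_noise_sd: float = 0.0           # absolute noise on projected areas
    area_target_r: float | None = None   # if set, choose noise to plant this r
    height_intercept: float = 10.0       # cm
    height_slope: float = 0.04           # cm per g shoot biomass
    height_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.n_genotypes < 1:
            raise ValueError("need at least one genotype and one replicate")
        if not (0 <= self.reduction <= 1):
            raise ValueError("reduction fraction must lie in [0, 1]")
        if self.area_noise_sd < 0 or self.replicate_cv < 0 or self.height_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        lo, hi = self.dead_sensitivity_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("dead sensitivity range must lie within [0, 1]")
        if self.area_target_r is not None and not (0 < self.area_target_r <= 1):
            raise ValueError("area_target_r must lie in (0, 1]")


def noise_sd_for_target_r(coeff: float, signal_sd: float, target_r: float) -> float:
    """Noise SD that makes corr(coeff*x + e, x) equal ``target_r`` when
    sd(x) = ``signal_sd``."""
    if not (0 < target_r <= 1):
        raise ValueError("target_r must lie in (0, 1]")
    return abs(coeff) * signal_sd * np.sqrt(1.0 / target_r**2 - 1.0)


def generate_cohort(spec: CohortSpec) -> tuple[list[PlantObservation], dict]:
    """Draw a trial cohort; returns the observations and the generating
    parameters (for recovery tests).

    Per genotype g: control biomass mean = base x (1 + effect_g); the
    waterlogged mean is reduced by the treatment fraction; replicates add
    multiplicative noise.  Green/dead fractions follow the genotype's
    senescence sensitivity (applied under waterlogging only).  Projected
    areas are coeff x biomass fraction + Gaussian noise; height is linear in
    shoot biomass; NDVI tracks the green fraction.
    """
    rng = np.random.default_rng(spec.seed)
    nG, nR = spec.n_genotypes, spec.replicates
    effects = rng.normal(0.0, spec.genotype_sd, size=nG)
    geno_mean = np.maximum(spec.base_biomass * (1.0 + effects),
                           0.1 * spec.base_biomass)
    sens = rng.uniform(*spec.dead_sensitivity_range, size=nG)

    # draw biomass for every cell first so a target correlation can use the
    # realized green-biomass spread
    rows: list[dict] = []
    for gi in range(nG):
        for treatment in ("control", "waterlogged"):
            mu = geno_mean[gi] * (1.0 - (spec.reduction if treatment == "waterlogged" else 0.0))
            for rep in range(1, nR + 1):
                shb = max(mu * (1.0 + rng.normal(0.0, spec.replicate_cv)), 1e-6)
                d = sens[gi] if treatment == "waterlogged" else spec.control_dead_fraction
                rows.append(dict(genotype=f"G{gi + 1:02d}", treatment=treatment,
                                 replicate=rep, shb=shb, glb=shb * (1 - d),
                                 dlb=shb * d))

    glb = np.array([r["glb"] for r in rows])
    dlb = np.array([r["dlb"] for r in rows])
    shb = np.array([r["shb"] for r in rows])
    if spec.area_target_r is not None:
        area_sd = noise_sd_for_target_r(spec.area_coeff, float(glb.std()),
                                        spec.area_target_r)
    else:
        area_sd = spec.area_noise_sd
    pga = np.maximum(spec.area_coeff * glb + rng.normal(0, area_sd, glb.size)
                     if area_sd > 0 else spec.area_coeff * glb, 0.0)
    pda = np.maximum(spec.area_coeff * dlb + rng.normal(0, area_sd, dlb.size)
                     if area_sd > 0 else spec.area_coeff * dlb, 0.0)
    height = np.maximum(spec.height_intercept + spec.height_slope * shb +
                        (rng.normal(0, spec.height_noise_sd, shb.size)
                         if spec.height_noise_sd > 0 else 0.0), 1.0)

    # ordinal scores: vigor tracks control biomass rank, visual evaluation
    # tracks the green fraction
    iv_by_geno = 1 + np.floor(4.999 * (rankdata(geno_mean) - 0.5) / nG).astype(int)
    observations: list[PlantObservation] = []
    for i, row in enumerate(rows):
        gi = int(row["genotype"][1:]) - 1
        green_frac = row["glb"] / row["shb"]
        ndvi_val = float(np.clip(0.2 + 0.6 * green_frac, -1.0, 1.0))
        ve = float(np.clip(round(1 + 4 * green_frac), 1, 5))
        observations.append(PlantObservation(
            plant_id=f"{row['genotype']}-{row['treatment'][:1]}{row['replicate']}",
            genotype=row["genotype"], treatment=row["treatment"],
            replicate=row["replicate"], time_point="after",
            shb_g=float(row["shb"]), glb_g=float(row["glb"]),
            dlb_g=float(row["dlb"]), height_cm=float(height[i]),
            pga_cm2=float(pga[i]), pda_cm2=float(pda[i]), ndvi=ndvi_val,
            iv=float(min(5, max(1, iv_by_geno[gi]))), ve=ve,
        ))
    params = dict(genotype_effects=effects, genotype_means=geno_mean,
                  sensitivities=sens, area_noise_sd=area_sd,
                  reduction=spec.reduction, area_coeff=spec.area_coeff,
                  seed=spec.seed)
    return observations, params
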