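"""Waterlogging-tolerance indices and field-trial summary statistics.

The waterlogging tolerance coefficient (WTC) is the percentage of control
shoot biomass retained under waterlogging; its image-based analogue
(projected WTC) substitutes projected green canopy areas for harvested
biomass.  NDVI is the normalized difference of near-infrared and red
reflectance.  Trial statistics cover genotype means (arithmetic cell means,
which coincide with least-square means under a balanced design), the
coefficient of variation, Pearson correlation matrices with significance
stars, and Fisher's protected LSD with letter groupings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantification import PlantObservation, records_to_frame

#: Default significance thresholds for star annotations.
STAR_THRESHOLDS = (0.05, 0.01, 0.001)


class DegenerateDesignError(ValueError):
    """Raised when a statistical design cannot support the requested test."""


# ---------------------------------------------------------------------------
# Derived indices


def compute_wtc(shb_waterlogged: float, shb_control: float) -> float:
    """Waterlogging tolerance coefficient, %.

    WTC = 100 x (shoot biomass under waterlogging) / (shoot biomass under
    control), both in g/plant.  Scale-invariant: multiplying both inputs by
    the same positive factor leaves it unchanged.
    """
    if shb_control <= 0:
        raise ValueError(f"control shoot biomass must be positive, got {shb_control}")
    if shb_waterlogged < 0:
        raise ValueError("waterlogged shoot biomass must be non-negative")
    return 100.0 * shb_waterlogged / shb_control


def compute_projected_wtc(pga_waterlogged: float, pga_control: float) -> float:
    """Projected WTC, %: the WTC ratio computed from projected green areas
    (cm^2/plant) measured by overhead image analysis."""
    if pga_control <= 0:
        raise ValueError(f"control projected area must be positive, got {pga_control}")
    if pga_waterlogged < 0:
        raise ValueError("waterlogged projected area must be non-negative")
    return 100.0 * pga_waterlogged / pga_control


def ndvi(nir_reflectance: float, red_reflectance: float) -> float:
    """Normalized difference vegetation index: (NIR - Red)/(NIR + Red)."""
    if nir_reflectance < 0 or red_reflectance < 0:
        raise ValueError("reflectances must be non-negative")
    s = nir_reflectance + red_reflectance
    if s == 0:
        raise ValueError("NIR + Red must be positive")
    return (nir_reflectance - red_reflectance) / s


def percent_change(mean_control: float, mean_treated: float) -> float:
    """Percent decrease of a treated mean relative to its control mean."""
    if mean_control <= 0:
        raise ValueError(f"control mean must be positive, got {mean_control}")
    return 100.0 * (mean_control - mean_treated) / mean_control


# ---------------------------------------------------------------------------
# Genotype means and dispersion


@dataclass
class GenotypeMeans:
    """Per-genotype trait means for one treatment, with trial-level summary.

    ``grand_mean`` is the mean of genotype means; ``cv`` is 100 x pooled
    within-genotype SD / grand mean (NaN when no genotype has replication).
    """

    trait: str
    treatment: str
    means: pd.Series              # index: genotype
    n: pd.Series                  # non-missing observations per genotype
    grand_mean: float
    cv: float


def genotype_means(
    observations: Sequence[PlantObservation] | pd.DataFrame,
    trait: str,
    treatment: str,
) -> GenotypeMeans:
    """Arithmetic genotype means of one trait under one treatment.

    Under the balanced designs this package targets, arithmetic cell means
    equal least-square means.  Genotypes with no non-missing observation
    appear as NaN.
    """
    if isinstance(observations, pd.DataFrame):
        df = observations
    else:
        df = records_to_frame(list(observations))
    if trait not in df.columns:
        raise KeyError(f"unknown trait column {trait!r}")
    sub = df[df["treatment"] == treatment]
    if sub.empty:
        raise ValueError(f"no observations for treatment {treatment!r}")
    grouped = sub.groupby("genotype")[trait]
    means = grouped.mean()
    n = grouped.count()
    grand_mean = float(means.mean())

    # pooled within-genotype SD over genotypes with >= 2 observations
    ss, dof = 0.0, 0
    for _, vals in grouped:
        v = vals.dropna().to_numpy(dtype=float)
        if v.size >= 2:
            ss += float(((v - v.mean()) ** 2).sum())
            dof += v.size - 1
    if dof > 0 and grand_mean != 0:
        cv = 100.0 * np.sqrt(ss / dof) / grand_mean
    else:
        cv = float("nan")
    return GenotypeMeans(trait=trait, treatment=treatment, means=means, n=n,
                         grand_mean=grand_mean, cv=cv)


# ---------------------------------------------------------------------------
# Correlations


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Pearson r with a two-sided t-test p-value and the pair count used.

    Missing pairs are deleted pairwise.  Requires n >= 3 complete pairs and
    nonzero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: an input has zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), n


def star(p: float, thresholds: tuple[float, float, float] = STAR_THRESHOLDS) -> str:
    """Significance annotation: 'ns', '*', '**' or '***' (strictly nested)."""
    t1, t2, t3 = thresholds
    if not (t3 < t2 < t1):
        raise ValueError("star thresholds must be strictly decreasing")
    if p < t3:
        return "***"
    if p < t2:
        return "**"
    if p < t1:
        return "*"
    return "ns"


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations of a trait table."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    stars: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def correlation_matrix(
    table: pd.DataFrame,
    star_thresholds: tuple[float, float, float] = STAR_THRESHOLDS,
) -> CorrelationResult:
    """All-pairs Pearson correlations with star annotations.

    Rows are observational units (e.g., genotype means); columns are traits.
    Undefined cells (constant columns, too few pairs) become NaN with a
    warning instead of aborting the whole matrix.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 trait columns")
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    n = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    stars = pd.DataFrame("", index=cols, columns=cols)
    warnings: list[str] = []
    for i in range(k):
        n.iloc[i, i] = int(table[cols[i]].notna().sum())
        for j in range(i + 1, k):
            try:
                rij, pij, nij = pearson(table[cols[i]], table[cols[j]])
            except ValueError as exc:
                warnings.append(f"{cols[i]} vs {cols[j]}: {exc}")
                rij, pij, nij = np.nan, np.nan, 0
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
            n.iloc[i, j] = n.iloc[j, i] = nij
            s = star(pij, star_thresholds) if np.isfinite(pij) else ""
            stars.iloc[i, j] = stars.iloc[j, i] = s
    return CorrelationResult(r=r, p=p, n=n, stars=stars, warnings=warnings)


# ---------------------------------------------------------------------------
# Fisher's protected LSD


@dataclass
class LSDResult:
    """Fisher's protected LSD over >= 2 groups.

    Letters follow the standard convention: two groups that share no letter
    differ by more than the LSD.  When the overall F-test is not significant
    (the 'protected' step) every group shares one letter.
    """

    alpha: float
    f_statistic: float
    f_pvalue: float
    significant: bool
    df_error: int
    mse: float
    lsd: float
    means: pd.Series               # sorted descending
    letters: dict[str, str]


def _letter_groups(means: pd.Series, lsd: float) -> dict[str, str]:
    """Assign letters by the maximal-run sweep over descending means."""
    names = list(means.index)
    vals = means.to_numpy(dtype=float)
    k = len(names)
    runs: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and vals[i] - vals[j + 1] <= lsd:
            j += 1
        runs.append((i, j))
    # drop runs subsumed by an earlier, wider run
    kept: list[tuple[int, int]] = []
    for run in runs:
        if not any(a <= run[0] and run[1] <= b for a, b in kept):
            kept.append(run)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {name: "" for name in names}
    for idx, (a, b) in enumerate(kept):
        ch = alphabet[idx % len(alphabet)]
        for m in range(a, b + 1):
            letters[names[m]] += ch
    return letters


def fisher_lsd(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> LSDResult:
    """One-way ANOVA followed by Fisher's protected LSD mean separation.

    LSD = t(1 - alpha/2, df_error) x sqrt(2 x MSE / n), with n the common
    replicate count (harmonic mean when group sizes differ).  The LSD is
    applied only when the overall F-test is significant at ``alpha``;
    otherwise all groups share a single letter.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    clean = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if len(clean) < 2:
        raise DegenerateDesignError("need at least 2 groups")
    for g, v in clean.items():
        if v.size < 2:
            raise DegenerateDesignError(f"group {g!r} has fewer than 2 replicates")
        if not np.isfinite(v).all():
            raise ValueError(f"group {g!r} contains non-finite values")
    allvals = np.concatenate(list(clean.values()))
    if np.ptp(allvals) == 0:
        raise DegenerateDesignError("all values identical: no variance to test")

    k = len(clean)
    n_total = allvals.size
    grand = allvals.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in clean.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in clean.values())
    df_between = k - 1
    df_error = n_total - k
    ms_between = ss_between / df_between
    mse = ss_within / df_error
    if mse == 0:
        # separable with zero noise: F is infinite, every difference counts
        f_stat, f_p = float("inf"), 0.0
    else:
        f_stat = ms_between / mse
        f_p = float(sps.f.sf(f_stat, df_between, df_error))
    significant = f_p <= alpha

    n_harm = k / sum(1.0 / v.size for v in clean.values())
    lsd = float(sps.t.ppf(1 - alpha / 2, df_error) * np.sqrt(2 * mse / n_harm))

    means = pd.Series({g: v.mean() for g, v in clean.items()}).sort_values(
        ascending=False, kind="mergesort")
    if significant:
        letters = _letter_groups(means, lsd)
    else:
        letters = {g: "a" for g in means.index}
    return LSDResult(alpha=alpha, f_statistic=float(f_stat), f_pvalue=f_p,
                     significant=significant, df_error=df_error, mse=float(mse),
                     lsd=lsd, means=means, letters=letters)
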