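"""Variance-component statistics for replicated qPCR plate data.

Implements the measurement-error machinery for technical-replicate qPCR
experiments: severe-outlier removal by Tukey-style interquartile fences,
bias-corrected standard deviations (the Gaussian c4 correction), bootstrap
percentile confidence intervals for the SD, pooling of intra-plate SDs
across plates, inter-plate SDs adjusted for the intra-plate contribution,
geometric SDs for ratio-scale data, and the regression summaries relating
assay precision to heteroplasmy level and to Cq.

Two SD flavours run through everything:

* arithmetic, in percentage points, for mtDNA deletion heteroplasmy;
* geometric, on the natural-log scale, for MT-ND1/B2M copy-number ratios,
  reported alongside the multiplicative scale factor ``exp(GSD)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .exceptions import ConfigurationError

__all__ = [
    "OutlierResult",
    "VarianceComponents",
    "RegressionResult",
    "severe_outlier_filter",
    "c4",
    "bias_corrected_sd",
    "bootstrap_sd_ci",
    "plate_estimates",
    "pooled_intra_sd",
    "inter_plate_sd",
    "pooled_inter_plate_sd",
    "geometric_sd",
    "fit_sd_vs_level",
    "spearman_sd_vs_cq",
]

#: numpy quantile method implementing linear interpolation between order
#: statistics (the SAS/R "type 7" convention); configurable in the filter.
DEFAULT_QUARTILE_METHOD = "linear"


@dataclass(frozen=True)
class OutlierResult:
    """Outcome of the severe-outlier filter."""

    kept: np.ndarray
    removed: np.ndarray
    mask_removed: np.ndarray  # boolean over the input, True = removed
    lower_fence: float
    upper_fence: float

    @property
    def n_removed(self) -> int:
        return int(self.mask_removed.sum())


@dataclass(frozen=True)
class VarianceComponents:
    """Intra- and inter-plate variability estimates for one analysis group.

    ``flavor`` is ``"arithmetic"`` (percentage points) or ``"geometric"``
    (natural-log scale).  For the geometric flavour ``scale_factor`` carries
    ``exp(sigma_intra)``, the multiplicative one-SD band.
    """

    flavor: str
    sigma_intra: float
    sigma_inter: float
    k: int
    sigma_intra_ci: tuple[float, float] | None = None
    scale_factor: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.flavor not in ("arithmetic", "geometric"):
            raise ValueError(f"unknown flavor {self.flavor!r}")
        if self.sigma_intra < 0 or self.sigma_inter < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.sigma_intra_ci is not None:
            lo, hi = self.sigma_intra_ci
            if not (lo <= self.sigma_intra <= hi):
                raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class RegressionResult:
    """Linear (Pearson) or rank (Spearman) association summary."""

    slope: float | None
    intercept: float | None
    r: float
    n: int
    p_value: float
    kind: str = "pearson"  # or "spearman"

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must not exceed 1")


def severe_outlier_filter(
    values,
    multiplier: float = 3.0,
    quartile_method: str = DEFAULT_QUARTILE_METHOD,
) -> OutlierResult:
    """Remove severe outliers: points beyond ``multiplier`` times the IQR
    below the lower quartile or above the upper quartile.

    The filter is single-pass: fences are computed once from the input and
    never recomputed from the filtered data.  With fewer than 4 values the
    quartiles are meaningless, so the filter warns and keeps everything.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if multiplier <= 0:
        raise ConfigurationError("outlier multiplier must be positive")
    if values.size < 4:
        warnings.warn(
            "fewer than 4 values; severe-outlier filter skipped", stacklevel=2
        )
        mask = np.zeros(values.size, dtype=bool)
        return OutlierResult(values, values[:0], mask, -math.inf, math.inf)
    q1, q3 = np.quantile(values, [0.25, 0.75], method=quartile_method)
    iqr = q3 - q1
    lower = q1 - multiplier * iqr
    upper = q3 + multiplier * iqr
    mask = (values < lower) | (values > upper)
    return OutlierResult(values[~mask], values[mask], mask, float(lower), float(upper))


def c4(n: int) -> float:
    """Bias-correction factor for the Gaussian sample SD.

    ``E[s] = c4(n) * sigma`` for an i.i.d. normal sample of size ``n`` with
    the (n-1)-denominator sample SD ``s``; dividing by ``c4`` makes the SD
    estimate unbiased.  ``c4(n) = sqrt(2/(n-1)) * Gamma(n/2) / Gamma((n-1)/2)``,
    evaluated through log-gamma for numerical stability at large ``n``.
    """
    n = int(n)
    if n < 2:
        raise ValueError("c4 requires n >= 2")
    return math.sqrt(2.0 / (n - 1)) * math.exp(gammaln(n / 2) - gammaln((n - 1) / 2))


def bias_corrected_sd(values) -> float:
    """Sample SD (n-1 denominator) divided by ``c4(n)``.

    Unbiased for the population SD under Gaussian sampling; always at least
    as large as the raw sample SD since ``c4 < 1``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("bias_corrected_sd requires at least 2 values")
    return float(np.std(values, ddof=1)) / c4(values.size)


def bootstrap_sd_ci(
    values, B: int = 10_000, seed: int | np.random.Generator = 0,
    level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Bias-corrected SD with a bootstrap percentile confidence interval.

    ``B`` resamples with replacement; the interval is the empirical
    ``(1-level)/2`` and ``1-(1-level)/2`` percentiles of the resampled
    bias-corrected SDs.  Deterministic for a fixed ``seed``.  ``B`` below
    1000 is refused: percentile intervals are too granular below that.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 8:
        raise ValueError("bootstrap_sd_ci requires at least 8 values")
    if B < 1000:
        raise ConfigurationError("bootstrap resample count B must be >= 1000")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = values.size
    idx = rng.integers(0, n, size=(B, n))
    resamples = values[idx]
    sds = np.std(resamples, axis=1, ddof=1) / c4(n)
    alpha = 1.0 - level
    lo, hi = np.quantile(sds, [alpha / 2, 1 - alpha / 2])
    return bias_corrected_sd(values), (float(lo), float(hi))


def plate_estimates(
    df: pd.DataFrame,
    value_col: str = "value",
    plate_col: str = "plate_id",
) -> pd.DataFrame:
    """Per-plate means and bias-corrected intra-plate SDs.

    Returns one row per plate with columns ``plate_id`` (index), ``mean``,
    ``sd`` (bias-corrected) and ``k`` (wells on the plate).  Plates with
    fewer than 2 wells cannot contribute an SD and are dropped with a
    warning.
    """
    rows = {}
    for plate, grp in df.groupby(plate_col, sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        if vals.size < 2:
            warnings.warn(
                f"plate {plate!r} has fewer than 2 wells; excluded", stacklevel=2
            )
            continue
        rows[plate] = {
            "mean": float(vals.mean()),
            "sd": bias_corrected_sd(vals),
            "k": int(vals.size),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = plate_col
    return out


def pooled_intra_sd(plates: pd.DataFrame) -> float:
    """Pool per-plate bias-corrected SDs into one intra-plate SD.

    Degrees-of-freedom-weighted root mean square:
    ``sqrt(sum((k_i - 1) * sd_i^2) / sum(k_i - 1))``.
    """
    if plates.empty:
        raise ValueError("no plates to pool")
    df_w = plates["k"].to_numpy() - 1
    return float(np.sqrt(np.sum(df_w * plates["sd"].to_numpy() ** 2) / np.sum(df_w)))


def inter_plate_sd(
    plate_values,
    intra_sd: float,
    k: int,
) -> float:
    """Inter-plate SD adjusted for the intra-plate contribution.

    ``plate_values`` are the per-plate estimates (means) of the measure.
    Their bias-corrected SD ``s_between`` overstates the true between-plate
    dispersion because each plate mean carries sampling noise of variance
    ``intra_sd**2 / k``; that share is subtracted on the variance scale:

        sigma_inter = sqrt(max(0, s_between**2 - intra_sd**2 / k))

    A negative adjusted variance (possible by sampling noise) is clamped to
    zero with a warning.
    """
    plate_values = np.asarray(plate_values, dtype=float)
    if plate_values.size < 2:
        raise ValueError("inter_plate_sd requires at least 2 plates")
    if intra_sd < 0:
        raise ValueError("intra_sd must be non-negative")
    if k < 1:
        raise ValueError("k must be >= 1")
    s_between = bias_corrected_sd(plate_values)
    adjusted = s_between**2 - intra_sd**2 / k
    if adjusted < 0:
        warnings.warn(
            "adjusted inter-plate variance negative; clamped to 0", stacklevel=2
        )
        return 0.0
    return float(np.sqrt(adjusted))


def pooled_inter_plate_sd(
    plate_value_groups,
    intra_sd: float,
    k: int,
) -> float:
    """Inter-plate SD pooled over several analysis groups (samples).

    Each group supplies its per-plate estimates; between-plate variances
    are pooled across groups with degrees-of-freedom weights *before* bias
    correction, so the c4 factor is applied once at the pooled sample size
    (``c4(df + 1)``) instead of once per 3-plate group, where it would
    inflate the variance appreciably.  The intra-plate share is then
    subtracted as in :func:`inter_plate_sd`.
    """
    if intra_sd < 0:
        raise ValueError("intra_sd must be non-negative")
    if k < 1:
        raise ValueError("k must be >= 1")
    ss, df_total = 0.0, 0
    for vals in plate_value_groups:
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            continue
        ss += np.sum((vals - vals.mean()) ** 2)
        df_total += vals.size - 1
    if df_total < 1:
        raise ValueError("pooled inter-plate SD requires >= 2 plates in a group")
    s_between = math.sqrt(ss / df_total) / c4(df_total + 1)
    adjusted = s_between**2 - intra_sd**2 / k
    if adjusted < 0:
        warnings.warn(
            "adjusted inter-plate variance negative; clamped to 0", stacklevel=2
        )
        return 0.0
    return float(math.sqrt(adjusted))


def geometric_sd(values) -> tuple[float, float]:
    """Geometric SD of positive ratio data and its scale factor.

    The GSD is the bias-corrected SD of the natural logs; the scale factor
    ``exp(GSD)`` expresses the one-SD band as a multiplicative change
    (e.g. GSD 0.0686 -> scale factor 1.071, a 7.1% spread).
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("geometric_sd requires strictly positive values")
    gsd = bias_corrected_sd(np.log(values))
    return gsd, float(np.exp(gsd))


def fit_sd_vs_level(levels, sds) -> RegressionResult:
    """Ordinary least squares of intra-plate SD on heteroplasmy level.

    Captures the inverse linear precision/heteroplasmy relationship seen at
    high DNA concentration: SD falls as deletion level rises.
    """
    levels = np.asarray(levels, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if levels.size < 3:
        raise ValueError("regression requires n >= 3")
    if np.ptp(levels) == 0:
        raise ValueError("constant predictor: degenerate fit")
    res = stats.linregress(levels, sds)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n=int(levels.size),
        p_value=float(res.pvalue),
        kind="pearson",
    )


def spearman_sd_vs_cq(cqs, sds) -> RegressionResult:
    """Spearman rank correlation of intra-plate SD against mean Cq.

    Used where the precision/concentration relationship is monotone but not
    linear; ties get average ranks.
    """
    cqs = np.asarray(cqs, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if cqs.size < 4:
        raise ValueError("spearman correlation requires n >= 4")
    if np.ptp(cqs) == 0 or np.ptp(sds) == 0:
        raise ValueError("constant input: degenerate correlation")
    rho, p = stats.spearmanr(cqs, sds)
    return RegressionResult(
        slope=None,
        intercept=None,
        r=float(rho),
        n=int(cqs.size),
        p_value=float(p),
        kind="spearman",
    )
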