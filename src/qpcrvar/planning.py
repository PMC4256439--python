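"""Replicate planning for two-sample qPCR comparisons.

Given the intra- and inter-plate variance components of an assay, the unit
of replication for a comparison between two DNA samples is the *plate*:
each plate contributes one estimate per sample (the mean of its k wells),
with per-plate SD

    sigma_plate = sqrt(sigma_inter**2 + sigma_intra**2 / k).

The number of plates per group needed to detect a difference ``d`` with a
two-sided pooled-variance two-sample t-test is found by exact noncentral-t
power: with ``n`` plates per group, ``df = 2n - 2`` and noncentrality
``d / (sigma_plate * sqrt(2/n))``.  For deletion heteroplasmy, ``d`` and
the SDs are in percentage points; for copy-number ratios everything lives
on the natural-log scale and a "10% difference" means ``d = ln(1.10)``.

The grid builders regenerate full planning tables (detectable difference x
replicates-per-plate x deletion level or concentration level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PowerSpec",
    "PlanningCell",
    "combined_plate_sd",
    "intra_sd_from_combined",
    "power_two_sample_t",
    "min_plates",
    "build_deletion_table",
    "build_copynumber_table",
    "DELETION_SD_K3",
    "COPYNUMBER_GSD_INTRA",
    "DELETION_SIGMA_INTER",
    "COPYNUMBER_GSD_INTER",
]

# Characterised variance components of the two assays (high-concentration
# deletion SDs by heteroplasmy level; copy-number GSDs by concentration).
DELETION_SIGMA_INTER = 0.485  # percentage points, pooled across levels
DELETION_SD_K3 = {  # per-plate SD at k=3 wells, percentage points
    10: 1.83, 20: 1.64, 30: 1.45, 40: 1.27, 50: 1.09,
    60: 0.92, 70: 0.76, 80: 0.62, 90: 0.52,
}
COPYNUMBER_GSD_INTER = 0.0305  # natural-log scale
COPYNUMBER_GSD_INTRA = {"high": 0.0686, "moderate": 0.0834, "low": 0.181}

_MAX_PLATES = 10**6


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to a two-sample plate-replicate power calculation.

    ``d`` — detectable difference, in the units of ``sigma_plate``
    (percentage points for deletion; natural-log units for copy number,
    i.e. ``ln(1 + fractional_difference)``).
    ``sigma_plate`` — SD of one plate's estimate of the measure.
    ``k`` — wells per sample per plate (bookkeeping only; already folded
    into ``sigma_plate``).
    """

    d: float
    sigma_plate: float
    alpha: float = 0.05
    target_power: float = 0.80
    k: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")
        if self.d <= 0:
            raise ValueError("detectable difference d must be positive")
        if self.sigma_plate <= 0:
            raise ValueError("sigma_plate must be positive")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class PlanningCell:
    """One planning-table cell: minimum plates and the power achieved there."""

    d: float
    sigma_plate: float
    k: int
    n_plates: int
    power: float
    row_label: str = ""

    def __post_init__(self) -> None:
        if self.n_plates < 2:
            raise ValueError("a group needs at least 2 plates")


def combined_plate_sd(sigma_intra: float, sigma_inter: float, k: int) -> float:
    """SD of a per-plate estimate from k wells: between-plate variance plus
    the within-plate variance of a k-well mean."""
    if sigma_intra < 0 or sigma_inter < 0:
        raise ValueError("standard deviations must be non-negative")
    if k < 1:
        raise ValueError("k must be >= 1")
    return math.sqrt(sigma_inter**2 + sigma_intra**2 / k)


def intra_sd_from_combined(sigma_plate: float, sigma_inter: float, k: int) -> float:
    """Invert :func:`combined_plate_sd`: recover the intra-plate SD from a
    per-plate SD observed at k wells.  Clamps to 0 (with a warning via
    math) when ``sigma_plate < sigma_inter``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    var = k * (sigma_plate**2 - sigma_inter**2)
    if var < 0:
        import warnings

        warnings.warn(
            "sigma_plate below sigma_inter; intra-plate SD clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return math.sqrt(var)


def power_two_sample_t(spec: PowerSpec, n: int) -> float:
    """Exact power of the two-sided two-sample t-test with ``n`` plates per
    group.

    ``T`` follows a noncentral t with ``df = 2n - 2`` and noncentrality
    ``delta = d / (sigma_plate * sqrt(2/n))``; power is
    ``P(|T| > t_{1-alpha/2, df})``.  At extreme noncentrality the scipy
    noncentral-t CDF can lose precision (NaN); there power is
    indistinguishable from the normal-approximation value, which is used as
    a guarded fallback.
    """
    if n < 2:
        raise ValueError("n must be >= 2 (one plate gives no between-plate df)")
    df = 2 * n - 2
    ncp = spec.d / (spec.sigma_plate * math.sqrt(2.0 / n))
    tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
    power = stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    if not np.isfinite(power):
        # Normal approximation; only reached when power is essentially 1.
        power = stats.norm.sf(tcrit - ncp) + stats.norm.cdf(-tcrit - ncp)
    return float(min(max(power, 0.0), 1.0))


def min_plates(spec: PowerSpec) -> PlanningCell:
    """Smallest number of plates per group achieving the target power.

    Linear scan upward from n=2; power is strictly increasing in n, so the
    first hit is the minimum.  The floor of 2 reflects that a single plate
    per group leaves no between-plate degrees of freedom.
    """
    n = 2
    while n <= _MAX_PLATES:
        p = power_two_sample_t(spec, n)
        if p >= spec.target_power:
            return PlanningCell(
                d=spec.d,
                sigma_plate=spec.sigma_plate,
                k=spec.k,
                n_plates=n,
                power=p,
            )
        n += 1
    raise RuntimeError("target power unreachable within 10^6 plates")


def build_deletion_table(
    sd_k3: dict[int, float] | None = None,
    sigma_inter: float = DELETION_SIGMA_INTER,
    differences=(1.0, 2.0, 5.0, 10.0, 20.0),
    ks=(3, 6),
    alpha: float = 0.05,
    target_power: float = 0.80,
):
    """Planning grid for the deletion assay.

    ``sd_k3`` maps deletion level (percent) to the per-plate SD observed at
    k=3 wells (percentage points).  For other k the SD column is rebuilt by
    decomposing each k=3 SD into intra/inter components and recombining.
    Returns a pandas DataFrame with one row per (k, level) and, per
    difference, the minimum plates ``n`` and achieved power ``P``.
    """
    import pandas as pd

    if sd_k3 is None:
        sd_k3 = DELETION_SD_K3
    rows = []
    for k in ks:
        for level, sd3 in sorted(sd_k3.items()):
            sigma_intra = intra_sd_from_combined(sd3, sigma_inter, 3)
            sigma_plate = combined_plate_sd(sigma_intra, sigma_inter, k)
            row = {"k": k, "level_pct": level, "sd": sigma_plate}
            for d in differences:
                cell = min_plates(
                    PowerSpec(d=d, sigma_plate=sigma_plate, alpha=alpha,
                              target_power=target_power, k=k)
                )
                row[f"n_{d:g}pct"] = cell.n_plates
                row[f"P_{d:g}pct"] = cell.power
            rows.append(row)
    return pd.DataFrame(rows)


def build_copynumber_table(
    gsd_intra: dict[str, float] | None = None,
    gsd_inter: float = COPYNUMBER_GSD_INTER,
    differences_pct=(10.0, 20.0, 30.0, 40.0, 50.0),
    ks=(3, 6),
    alpha: float = 0.05,
    target_power: float = 0.80,
):
    """Planning grid for the copy-number assay.

    Differences are fractional changes in relative copy number; they act on
    the natural-log scale (a 10% difference is ``d = ln(1.10)``) because the
    assay's error is geometric.  One row per (k, concentration level).
    """
    import pandas as pd

    if gsd_intra is None:
        gsd_intra = COPYNUMBER_GSD_INTRA
    rows = []
    for k in ks:
        for level, sig_intra in gsd_intra.items():
            sigma_plate = combined_plate_sd(sig_intra, gsd_inter, k)
            row = {"k": k, "concentration": level, "sd_log": sigma_plate}
            for pct in differences_pct:
                d = math.log1p(pct / 100.0)
                cell = min_plates(
                    PowerSpec(d=d, sigma_plate=sigma_plate, alpha=alpha,
                              target_power=target_power, k=k)
                )
                row[f"n_{pct:g}pct"] = cell.n_plates
                row[f"P_{pct:g}pct"] = cell.power
            rows.append(row)
    return pd.DataFrame(rows)
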