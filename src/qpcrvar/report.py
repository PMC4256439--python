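"""Analysis orchestration and reporting.

Chains outlier filtering, per-plate estimates and variance components into
the delimited variance report the command line emits, plus the outlier log
and the human-readable bookkeeping lines ("removal of X values from the Y
total replicates (Z%)").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import variance
from .exceptions import SchemaError
from .quantify import relative_copy_number

__all__ = [
    "AnalysisResult",
    "format_removal_message",
    "filter_group_outliers",
    "analyze_deletion",
    "analyze_copynumber",
]

REPORT_COLUMNS = ["group", "component", "flavor", "estimate",
                  "ci_low", "ci_high", "scale_factor", "n_wells", "k", "n_plates"]


@dataclass
class AnalysisResult:
    """Variance report plus the outlier bookkeeping for one dataset."""

    report: pd.DataFrame
    outliers: pd.DataFrame  # removed rows with reason
    n_removed: int
    n_total: int

    @property
    def removal_message(self) -> str:
        return format_removal_message(self.n_removed, self.n_total)


def format_removal_message(n_removed: int, n_total: int) -> str:
    """Outlier bookkeeping line; percentage rounded to 1 decimal."""
    pct = 100.0 * n_removed / n_total if n_total else 0.0
    return (f"removal of {n_removed} values from the {n_total} "
            f"total replicates ({pct:.1f}%)")


def filter_group_outliers(
    df: pd.DataFrame,
    value_col: str,
    group_cols: list[str],
    multiplier: float = 3.0,
    quartile_method: str = variance.DEFAULT_QUARTILE_METHOD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the severe-outlier filter within every analysis group.

    Groups are sample x plate (x concentration where present): the fences
    must come from replicates of the same true value.  Returns the kept
    rows and a log of removed rows annotated with the violated fence.
    """
    kept_frames, removed_frames = [], []
    for key, grp in df.groupby(group_cols, sort=True, dropna=False):
        vals = grp[value_col].to_numpy(dtype=float)
        if vals.size < 4:
            kept_frames.append(grp)
            continue
        res = variance.severe_outlier_filter(
            vals, multiplier=multiplier, quartile_method=quartile_method
        )
        kept_frames.append(grp[~res.mask_removed])
        if res.n_removed:
            bad = grp[res.mask_removed].copy()
            bad["reason"] = [
                f"value {v:g} outside fences [{res.lower_fence:.4g}, "
                f"{res.upper_fence:.4g}]"
                for v in bad[value_col]
            ]
            removed_frames.append(bad)
    kept = pd.concat(kept_frames, ignore_index=True)
    removed = (pd.concat(removed_frames, ignore_index=True)
               if removed_frames else df.iloc[0:0].assign(reason=pd.NA))
    return kept, removed


def analyze_deletion(
    df: pd.DataFrame,
    bootstrap_B: int | None = 10_000,
    seed: int = 0,
    outlier_multiplier: float = 3.0,
) -> AnalysisResult:
    """Variance components of per-well deletion percentages.

    Per sample: severe-outlier filtering per plate, per-plate means and
    bias-corrected SDs, a pooled intra-plate SD with bootstrap CI (when a
    plate has >= 8 wells), and — when several plates are present — the
    inter-plate SD of plate means adjusted for the intra-plate share.
    ``bootstrap_B=None`` skips the (comparatively slow) bootstrap CIs.
    """
    if "value" not in df.columns:
        raise SchemaError("table is missing required column 'value'")
    kept, removed = filter_group_outliers(
        df, "value", ["sample_id", "plate_id"], multiplier=outlier_multiplier
    )
    rng = np.random.default_rng(seed)
    rows = []
    pooled_groups, pooled_cells = [], []
    for sample_id, grp in kept.groupby("sample_id", sort=True):
        plates = variance.plate_estimates(grp, "value", "plate_id")
        intra = variance.pooled_intra_sd(plates)
        k = int(round(plates["k"].mean()))
        ci = (None, None)
        vals = grp["value"].to_numpy(dtype=float)
        if bootstrap_B is not None and vals.size >= 8:
            _, ci = variance.bootstrap_sd_ci(vals - _plate_centered(grp),
                                             B=bootstrap_B, seed=rng)
        rows.append({
            "group": sample_id, "component": "intra", "flavor": "arithmetic",
            "estimate": intra, "ci_low": ci[0], "ci_high": ci[1],
            "scale_factor": None, "n_wells": int(vals.size), "k": k,
            "n_plates": len(plates),
        })
        if len(plates) >= 2:
            inter = variance.inter_plate_sd(plates["mean"].to_numpy(), intra, k)
            rows.append({
                "group": sample_id, "component": "inter", "flavor": "arithmetic",
                "estimate": inter, "ci_low": None, "ci_high": None,
                "scale_factor": None, "n_wells": int(vals.size), "k": k,
                "n_plates": len(plates),
            })
            pooled_groups.append(plates["mean"].to_numpy())
            pooled_cells.append(plates)
    if pooled_groups:
        # pooled across samples: bias-correct at the pooled df, not per group
        all_plates = pd.concat(pooled_cells, ignore_index=True)
        intra_all = variance.pooled_intra_sd(all_plates)
        k_all = int(round(all_plates["k"].mean()))
        inter_all = variance.pooled_inter_plate_sd(pooled_groups, intra_all, k_all)
        rows.append({
            "group": "pooled", "component": "inter", "flavor": "arithmetic",
            "estimate": inter_all, "ci_low": None, "ci_high": None,
            "scale_factor": None, "n_wells": int(len(kept)), "k": k_all,
            "n_plates": int(all_plates.shape[0]),
        })
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return AnalysisResult(report, removed, int(len(removed)), int(len(df)))


def _plate_centered(grp: pd.DataFrame) -> np.ndarray:
    """Per-plate means broadcast back to wells (for intra-plate residuals)."""
    return grp.groupby("plate_id")["value"].transform("mean").to_numpy(dtype=float)


def analyze_copynumber(
    df: pd.DataFrame,
    reference_sample: str = "S1",
    outlier_multiplier: float = 3.0,
) -> AnalysisResult:
    """Variance components of MT-ND1/B2M copy-number ratios (geometric).

    Ratios are filtered per sample x pair and intra-plate geometric SDs
    pooled across pairs.  The between-pair (inter-plate) geometric SD is
    estimated from each sample's per-pair mean log-ratio, adjusted for the
    intra-plate share, and pooled across samples.  Reference-normalised
    relative copy numbers (which would fold the reference sample's pair
    effect into every value) are reported for bookkeeping but not used for
    the variance decomposition.
    """
    if "value" not in df.columns:
        raise SchemaError("table is missing required column 'value'")
    kept, removed = filter_group_outliers(
        df, "value", ["sample_id", "pair_id"], multiplier=outlier_multiplier
    )
    rows = []
    # intra: pooled GSD over sample x pair cells
    cells = []
    for (sample_id, pair_id), grp in kept.groupby(["sample_id", "pair_id"]):
        vals = grp["value"].to_numpy(dtype=float)
        if vals.size < 2:
            continue
        gsd, _ = variance.geometric_sd(vals)
        cells.append({"sd": gsd, "k": vals.size})
    cells = pd.DataFrame(cells)
    intra = variance.pooled_intra_sd(cells)
    k = int(round(cells["k"].mean()))
    rows.append({
        "group": "all", "component": "intra", "flavor": "geometric",
        "estimate": intra, "ci_low": None, "ci_high": None,
        "scale_factor": float(np.exp(intra)), "n_wells": int(len(kept)),
        "k": k, "n_plates": kept["pair_id"].nunique(),
    })
    # inter: each sample's per-pair mean log ratio, pooled across samples
    ratios = kept.rename(columns={"value": "ratio"})[
        ["pair_id", "sample_id", "ratio"]
    ]
    rel = relative_copy_number(ratios, reference_sample)
    pair_means = (
        kept.assign(log_ratio=np.log(kept["value"].astype(float)))
        .groupby(["sample_id", "pair_id"])["log_ratio"].mean()
        .reset_index()
    )
    groups = [
        grp["log_ratio"].to_numpy()
        for _, grp in pair_means.groupby("sample_id")
        if len(grp) >= 2
    ]
    if groups:
        inter = variance.pooled_inter_plate_sd(groups, intra, k)
        rows.append({
            "group": "all", "component": "inter", "flavor": "geometric",
            "estimate": inter, "ci_low": None, "ci_high": None,
            "scale_factor": float(np.exp(inter)), "n_wells": int(len(rel)),
            "k": k, "n_plates": kept["pair_id"].nunique(),
        })
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return AnalysisResult(report, removed, int(len(removed)), int(len(df)))
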