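"""Cq-to-quantity calibration and derived qPCR measures.

Converts quantification cycles (Cq) to template quantities through linear
standard curves, and computes the two derived measures the pipeline
analyses:

* **deletion heteroplasmy** — percent of mtDNA molecules lacking the
  MT-ND4 region, ``p = (1 - Q_ND4 / Q_ND1) * 100`` where MT-ND1 counts all
  molecules and MT-ND4 only wild type;
* **relative copy number** — the MT-ND1/B2M quantity ratio per well,
  normalised against a reference sample per plate pair.

Wells live in long-format pandas DataFrames with the schema written by the
simulators (``plate_id, pair_id, well, sample_id, target, cq, quantity,
value, dna_conc_pg_per_ul``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    CalibrationError,
    NormalizationError,
    PairingError,
    QuantificationError,
    SchemaError,
)

__all__ = [
    "StandardCurve",
    "PERFECT_EFFICIENCY_SLOPE",
    "quantity_from_cq",
    "cq_from_quantity",
    "deletion_level",
    "deletion_table",
    "copy_ratio_pairs",
    "relative_copy_number",
    "read_wells",
    "write_wells",
    "read_standard_curves",
]

#: slope of a 100%-efficient standard curve: one 10-fold dilution costs
#: log2(10) = 3.3219 cycles.
PERFECT_EFFICIENCY_SLOPE = -math.log2(10)

WELL_COLUMNS = [
    "plate_id", "pair_id", "well", "sample_id", "target",
    "cq", "quantity", "value", "dna_conc_pg_per_ul",
]

VALID_TARGETS = frozenset({"MT-ND1", "MT-ND4", "B2M"})


@dataclass(frozen=True)
class StandardCurve:
    """Linear Cq vs log10-quantity calibration for one target.

    ``Cq = intercept + slope * log10(quantity)``; the slope must be
    negative (more template, earlier crossing).  Amplification efficiency
    follows as ``E = 10**(-1/slope) - 1`` (1.0 = perfect doubling).
    """

    target: str
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise CalibrationError(
                f"standard-curve slope must be negative, got {self.slope}"
            )
        if not 0 < self.efficiency <= 1.5:
            raise CalibrationError(
                f"implied efficiency {self.efficiency:.3f} outside (0, 1.5]"
            )

    @property
    def efficiency(self) -> float:
        return 10 ** (-1.0 / self.slope) - 1.0

    @classmethod
    def perfect(cls, target: str, intercept: float = 33.0) -> "StandardCurve":
        """A 100%-efficiency curve, the fallback when no curve was run."""
        return cls(target=target, slope=PERFECT_EFFICIENCY_SLOPE, intercept=intercept)


def quantity_from_cq(cq, curve: StandardCurve):
    """Invert the standard curve: ``Q = 10**((Cq - intercept) / slope)``.

    Strictly decreasing in Cq; always positive.  Accepts scalars or arrays.
    """
    return 10.0 ** ((np.asarray(cq, dtype=float) - curve.intercept) / curve.slope)


def cq_from_quantity(quantity, curve: StandardCurve):
    """Forward standard-curve relation (used by the Cq-level simulator)."""
    quantity = np.asarray(quantity, dtype=float)
    if np.any(quantity <= 0):
        raise QuantificationError("quantity must be positive")
    return curve.intercept + curve.slope * np.log10(quantity)


def deletion_level(q_nd4, q_nd1) -> tuple[float, bool]:
    """Percent deleted mtDNA from MT-ND4 (wild type) and MT-ND1 (total)
    quantities.

    ``p = (1 - q_nd4 / q_nd1) * 100`` clamped to [0, 100].  Measurement
    noise routinely pushes low-heteroplasmy wells slightly negative; those
    are clamped to 0 rather than dropped (dropping would bias SDs) and the
    clamp is reported in the second return value.
    """
    if q_nd4 <= 0 or q_nd1 <= 0:
        raise QuantificationError("quantities must be positive")
    raw = (1.0 - q_nd4 / q_nd1) * 100.0
    clamped = raw < 0.0 or raw > 100.0
    return float(min(max(raw, 0.0), 100.0)), clamped


def _require_columns(df: pd.DataFrame, cols) -> None:
    for col in cols:
        if col not in df.columns:
            raise SchemaError(f"table is missing required column {col!r}")


def deletion_table(
    wells: pd.DataFrame,
    curves: dict[str, StandardCurve] | None = None,
) -> pd.DataFrame:
    """Per-well deletion estimates from paired MT-ND1/MT-ND4 Cq rows.

    The multiplex assay reads both targets from the same physical well, so
    rows are matched on (plate_id, well, sample_id).  Without standard
    curves, 100% efficiency is assumed, which reduces the wild-type
    fraction to ``2**(Cq_ND4-relative delta)``.
    """
    _require_columns(wells, ["plate_id", "well", "sample_id", "target", "cq"])
    if curves is None:
        curves = {t: StandardCurve.perfect(t) for t in ("MT-ND1", "MT-ND4")}
    nd1 = wells[wells["target"] == "MT-ND1"]
    nd4 = wells[wells["target"] == "MT-ND4"]
    keys = ["plate_id", "well", "sample_id"]
    merged = nd1.merge(nd4, on=keys, suffixes=("_nd1", "_nd4"), how="outer",
                       indicator=True)
    unmatched = merged[merged["_merge"] != "both"]
    if len(unmatched):
        offenders = unmatched[keys].to_records(index=False).tolist()
        raise PairingError(f"unpaired MT-ND1/MT-ND4 wells: {offenders[:10]}")
    q_nd1 = quantity_from_cq(merged["cq_nd1"], curves["MT-ND1"])
    q_nd4 = quantity_from_cq(merged["cq_nd4"], curves["MT-ND4"])
    raw = (1.0 - q_nd4 / q_nd1) * 100.0
    out = merged[keys].copy()
    out["deletion_pct"] = np.clip(raw, 0.0, 100.0)
    out["clamped"] = (raw < 0.0) | (raw > 100.0)
    return out


def copy_ratio_pairs(
    nd1_wells: pd.DataFrame,
    b2m_wells: pd.DataFrame,
    curves: dict[str, StandardCurve] | None = None,
) -> pd.DataFrame:
    """MT-ND1/B2M quantity ratio for every matched well of a plate pair.

    The singleplex assays run on separate plates with samples in the same
    wells, so rows are matched on (pair_id, well, sample_id).  Unmatched
    wells raise a :class:`PairingError` naming the offenders rather than
    being silently dropped.
    """
    for df, name in ((nd1_wells, "MT-ND1"), (b2m_wells, "B2M")):
        _require_columns(df, ["pair_id", "well", "sample_id", "cq"])
    if curves is None:
        curves = {t: StandardCurve.perfect(t) for t in ("MT-ND1", "B2M")}
    keys = ["pair_id", "well", "sample_id"]
    merged = nd1_wells.merge(
        b2m_wells, on=keys, suffixes=("_nd1", "_b2m"), how="outer", indicator=True
    )
    unmatched = merged[merged["_merge"] != "both"]
    if len(unmatched):
        offenders = unmatched[["pair_id", "well"]].to_records(index=False).tolist()
        raise PairingError(f"unpaired MT-ND1/B2M wells: {offenders[:10]}")
    q_nd1 = quantity_from_cq(merged["cq_nd1"], curves["MT-ND1"])
    q_b2m = quantity_from_cq(merged["cq_b2m"], curves["B2M"])
    out = merged[keys].copy()
    out["ratio"] = q_nd1 / q_b2m
    return out


def relative_copy_number(
    ratios: pd.DataFrame,
    reference_sample: str,
) -> pd.DataFrame:
    """Relative copy number of every non-reference replicate versus the
    reference sample, per plate pair.

    Each non-reference ratio is divided by the geometric mean of the
    reference sample's replicate ratios on the same pair; pair-level
    multiplicative effects cancel.  With 4 comparison samples in 12
    replicates this yields 48 independent values per pair.
    """
    _require_columns(ratios, ["pair_id", "sample_id", "ratio"])
    out_frames = []
    for pair, grp in ratios.groupby("pair_id", sort=True):
        ref = grp[grp["sample_id"] == reference_sample]
        if ref.empty:
            raise NormalizationError(
                f"reference sample {reference_sample!r} missing on pair {pair!r}"
            )
        ref_gm = float(np.exp(np.mean(np.log(ref["ratio"].to_numpy(dtype=float)))))
        rest = grp[grp["sample_id"] != reference_sample].copy()
        rest["relative"] = rest["ratio"] / ref_gm
        out_frames.append(rest)
    return pd.concat(out_frames, ignore_index=True)


def read_wells(path) -> pd.DataFrame:
    """Read a long-format well table (CSV, header row, '.' decimal)."""
    df = pd.read_csv(path)
    _require_columns(df, ["plate_id", "well", "sample_id", "target"])
    return df


def write_wells(df: pd.DataFrame, path) -> None:
    """Write a well table in the canonical column order; missing fields empty."""
    out = df.copy()
    for col in WELL_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    out[WELL_COLUMNS].to_csv(path, index=False)


def read_standard_curves(path) -> dict[str, StandardCurve]:
    """Read per-target curves from a CSV with columns target, slope, intercept."""
    df = pd.read_csv(path)
    _require_columns(df, ["target", "slope", "intercept"])
    return {
        row.target: StandardCurve(row.target, float(row.slope), float(row.intercept))
        for row in df.itertuples()
    }
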