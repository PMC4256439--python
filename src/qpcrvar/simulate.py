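"""Synthetic plate-structured qPCR data with hierarchical error.

Real plate data for the two assays cannot be redistributed, so this module
generates datasets with the error structure the analysis assumes, at two
fidelity levels:

* **measurement level** (primary): per-well deletion percentages or
  MT-ND1/B2M ratios drawn from the hierarchical model

      value = truth + plate_effect + well_noise,

  with the plate effect (Gaussian, SD ``sigma_inter``) drawn once per
  sample per plate and shared by all of that sample's replicate wells on
  the plate — it models the plate-to-plate shift of a sample's measured
  level, which is what survives in between-sample differences — and well
  noise Gaussian with an SD that depends on the measurand: for deletion, a linear function of heteroplasmy inflated
  at low DNA concentration; for copy number, a per-concentration geometric
  SD acting on the natural log of the ratio.

* **Cq level**: raw quantification cycles generated by inverting the
  standard-curve relation, so the calibration stage can be exercised
  end-to-end and round-trips exactly at zero noise.

Determinism: a single root seed; per-plate RNG streams are spawned from it
so a plate's wells do not change when the plate count does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .quantify import StandardCurve, cq_from_quantity

__all__ = [
    "IntraSDModel",
    "SimulationDesign",
    "simulate_deletion_measurements",
    "simulate_copynumber_plate_pairs",
    "simulate_cq_wells",
    "inject_outliers",
    "deletion_intra_design",
    "deletion_interplate_design",
    "copynumber_design",
    "DELETION_MEAN_CQ",
    "COPYNUMBER_MEAN_CQ",
    "DELETION_SAMPLES",
    "MIXTURE_SAMPLES",
    "COPYNUMBER_SAMPLES",
]

# Mean MT-ND1 Cq per concentration level for the deletion assay; the assay
# is characterised in three Cq windows (<25, 25-30, >30 cycles).
DELETION_MEAN_CQ = {"high": 22.0, "moderate": 27.5, "low": 31.5}

# Copy-number assay mean Cq per target and concentration level (the B2M
# reaction runs an order of magnitude more concentrated to stay below 33).
COPYNUMBER_MEAN_CQ = {
    "high": {"MT-ND1": 19.0, "B2M": 27.0},
    "moderate": {"MT-ND1": 24.0, "B2M": 30.0},
    "low": {"MT-ND1": 25.5, "B2M": 33.0},
}

# Final PCR DNA concentration (pg/ul, MT-ND1 reaction) per level.
DELETION_DNA_CONC = {"high": 100.0, "moderate": 1.0, "low": 0.01}
COPYNUMBER_DNA_CONC = {"high": 20.0, "moderate": 0.6, "low": 0.3}

#: six single-deletion patient samples, percent deleted mtDNA
DELETION_SAMPLES = {"patient1": 84.0, "patient2": 69.0, "patient3": 48.0,
                    "patient4": 38.0, "patient5": 20.0, "patient6": 6.0}

#: six mixtures at low (20-25%) and high (70-80%) deletion level
MIXTURE_SAMPLES = {"A": 20.0, "B": 22.5, "C": 25.0,
                   "D": 70.0, "E": 75.0, "F": 80.0}

#: five copy-number mixtures, relative mtDNA level versus S1
COPYNUMBER_SAMPLES = {"S1": 1.0, "S2": 1.10, "S3": 1.25, "S4": 1.50, "S5": 1.9}

# Linear intra-plate SD model for the deletion assay at high concentration,
# sigma(p) = a + b * p (percentage points): the assay is least precise at
# low heteroplasmy.  Coefficients chosen to give sigma(10) = 3.06 and
# sigma(90) = 0.32, the characterised high-concentration values.
_DELETION_SD_INTERCEPT = 3.398
_DELETION_SD_SLOPE = -0.03415

_COPYNUMBER_GSD = {"high": 0.0686, "moderate": 0.0834, "low": 0.181}


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ParameterError(f"{fieldname}: {msg}")


@dataclass(frozen=True)
class IntraSDModel:
    """Within-plate noise model.

    ``mode="deletion"``: SD in percentage points is ``a + b * p`` (clamped
    at 0), multiplied by ``cq_inflation`` when the run's mean Cq exceeds
    ``cq_threshold`` — precision degrades sharply past ~30 cycles.

    ``mode="copynumber"``: geometric SD (natural-log scale) looked up per
    concentration level.
    """

    mode: str = "deletion"
    a: float = _DELETION_SD_INTERCEPT
    b: float = _DELETION_SD_SLOPE
    cq_threshold: float = 30.0
    cq_inflation: float = 3.0
    gsd_by_level: dict = field(default_factory=lambda: dict(_COPYNUMBER_GSD))

    def __post_init__(self) -> None:
        _check(self.mode in ("deletion", "copynumber"), "mode",
               "must be 'deletion' or 'copynumber'")
        _check(self.cq_inflation >= 1, "cq_inflation", "must be >= 1")
        _check(all(g >= 0 for g in self.gsd_by_level.values()),
               "gsd_by_level", "geometric SDs must be >= 0")

    def deletion_sd(self, p: float, mean_cq: float) -> float:
        sd = max(0.0, self.a + self.b * p)
        if mean_cq > self.cq_threshold:
            sd *= self.cq_inflation
        return sd

    def copynumber_gsd(self, level: str) -> float:
        try:
            return self.gsd_by_level[level]
        except KeyError:
            raise ParameterError(f"concentration: unknown level {level!r}") from None


@dataclass(frozen=True)
class SimulationDesign:
    """Full description of one simulated experiment.

    ``samples`` maps sample id to truth: percent deletion in [0, 100] for
    the deletion modes, or a positive relative copy number for the
    copy-number mode.  ``n_plates`` x ``k`` wells are generated per sample;
    for the copy-number mode a "plate" is an MT-ND1/B2M plate pair.
    """

    samples: dict
    n_plates: int = 3
    k: int = 24
    concentration: str = "high"
    intra_model: IntraSDModel = field(default_factory=IntraSDModel)
    sigma_inter: float = 0.485
    outlier_prob: float = 0.0
    outlier_magnitude: float = 12.0
    cq_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(len(self.samples) > 0, "samples", "at least one sample required")
        _check(self.n_plates >= 1, "n_plates", "must be >= 1")
        _check(self.k >= 1, "k", "must be >= 1")
        _check(self.concentration in ("high", "moderate", "low"),
               "concentration", "must be high, moderate or low")
        _check(self.sigma_inter >= 0, "sigma_inter", "must be >= 0")
        _check(0 <= self.outlier_prob < 1, "outlier_prob", "must be in [0, 1)")
        _check(self.cq_sd >= 0, "cq_sd", "must be >= 0")
        if self.intra_model.mode == "deletion":
            for sid, p in self.samples.items():
                _check(0 <= p <= 100, "samples",
                       f"deletion percent for {sid!r} must be in [0, 100]")
        else:
            for sid, r in self.samples.items():
                _check(r > 0, "samples",
                       f"relative copy number for {sid!r} must be positive")

    def plate_rngs(self) -> list[np.random.Generator]:
        """One independent RNG stream per plate, spawned from the root seed."""
        children = np.random.SeedSequence(self.seed).spawn(self.n_plates)
        return [np.random.default_rng(c) for c in children]


def _well_labels(k: int) -> list[str]:
    return [f"w{i + 1:03d}" for i in range(k)]


def simulate_deletion_measurements(design: SimulationDesign) -> pd.DataFrame:
    """Per-well deletion percentages under the hierarchical error model.

    For every (plate, sample) cell one Gaussian plate effect (SD
    ``sigma_inter``) is drawn and shared by all of that sample's wells on
    the plate; each well adds Gaussian noise with the heteroplasmy- and
    Cq-dependent intra-plate SD.  Values are clipped to [0, 100]; the clip
    bias is negligible away from the boundaries.
    """
    if design.intra_model.mode != "deletion":
        raise ParameterError("intra_model.mode: expected 'deletion'")
    mean_cq = DELETION_MEAN_CQ[design.concentration]
    conc = DELETION_DNA_CONC[design.concentration]
    frames = []
    for plate_idx, rng in enumerate(design.plate_rngs(), start=1):
        plate_id = f"P{plate_idx}"
        for sample_id, p_true in design.samples.items():
            plate_effect = (rng.normal(0.0, design.sigma_inter)
                            if design.sigma_inter else 0.0)
            sd = design.intra_model.deletion_sd(p_true, mean_cq)
            noise = rng.normal(0.0, sd, size=design.k) if sd else np.zeros(design.k)
            values = p_true + plate_effect + noise
            if design.outlier_prob:
                values, _ = inject_outliers(values, design.outlier_prob,
                                            design.outlier_magnitude, seed=rng)
            values = np.clip(values, 0.0, 100.0)
            frames.append(pd.DataFrame({
                "plate_id": plate_id,
                "pair_id": pd.NA,
                "well": _well_labels(design.k),
                "sample_id": sample_id,
                "target": pd.NA,
                "cq": mean_cq,
                "quantity": pd.NA,
                "value": values,
                "dna_conc_pg_per_ul": conc,
            }))
    return pd.concat(frames, ignore_index=True)


def simulate_copynumber_plate_pairs(design: SimulationDesign) -> pd.DataFrame:
    """Per-well MT-ND1/B2M copy-number ratios for replicate plate pairs.

    The model lives on the natural-log scale:
    ``ln(ratio) = ln(R_true) + pair_effect + well_noise`` with the pair
    effect (SD ``sigma_inter``, geometric) drawn per sample per pair and
    shared across that sample's wells, and well noise at the concentration
    level's geometric SD.  The ``value`` column holds the back-transformed
    ratio.
    """
    if design.intra_model.mode != "copynumber":
        raise ParameterError("intra_model.mode: expected 'copynumber'")
    gsd = design.intra_model.copynumber_gsd(design.concentration)
    conc = COPYNUMBER_DNA_CONC[design.concentration]
    mean_cq = COPYNUMBER_MEAN_CQ[design.concentration]["MT-ND1"]
    frames = []
    for pair_idx, rng in enumerate(design.plate_rngs(), start=1):
        pair_id = f"PP{pair_idx}"
        for sample_id, r_true in design.samples.items():
            pair_effect = (rng.normal(0.0, design.sigma_inter)
                           if design.sigma_inter else 0.0)
            noise = rng.normal(0.0, gsd, size=design.k) if gsd else np.zeros(design.k)
            log_ratios = np.log(r_true) + pair_effect + noise
            if design.outlier_prob:
                # contamination acts on the log scale, like the error model
                log_ratios, _ = inject_outliers(
                    log_ratios, design.outlier_prob,
                    design.outlier_magnitude, seed=rng)
            ratios = np.exp(log_ratios)
            frames.append(pd.DataFrame({
                "plate_id": pd.NA,
                "pair_id": pair_id,
                "well": _well_labels(design.k),
                "sample_id": sample_id,
                "target": pd.NA,
                "cq": mean_cq,
                "quantity": pd.NA,
                "value": ratios,
                "dna_conc_pg_per_ul": conc,
            }))
    return pd.concat(frames, ignore_index=True)


def simulate_cq_wells(
    design: SimulationDesign,
    curves: dict[str, StandardCurve],
) -> pd.DataFrame:
    """Raw Cq-level wells generated by inverting the standard curves.

    For the deletion mode each well carries an MT-ND1 row (total mtDNA, at
    the concentration level's base quantity) and an MT-ND4 row (wild type,
    scaled by ``1 - p/100``); for the copy-number mode an MT-ND1 row scaled
    by the true relative level and a B2M row at the nuclear base quantity.
    Gaussian noise of SD ``cq_sd`` (cycles) is added to every Cq.  With
    ``cq_sd = 0`` the calibration stage recovers the true quantities to
    machine precision.
    """
    for target in (("MT-ND1", "MT-ND4") if design.intra_model.mode == "deletion"
                   else ("MT-ND1", "B2M")):
        if target not in curves:
            raise ParameterError(f"curves: missing standard curve for {target!r}")

    deletion = design.intra_model.mode == "deletion"
    if deletion:
        mean_cq = {"MT-ND1": DELETION_MEAN_CQ[design.concentration]}
        mean_cq["MT-ND4"] = mean_cq["MT-ND1"]  # multiplex: same well, same input
        conc = DELETION_DNA_CONC[design.concentration]
    else:
        mean_cq = COPYNUMBER_MEAN_CQ[design.concentration]
        conc = COPYNUMBER_DNA_CONC[design.concentration]

    rows = []
    for plate_idx, rng in enumerate(design.plate_rngs(), start=1):
        plate_id = f"P{plate_idx}"
        pair_id = f"PP{plate_idx}"
        for sample_id, truth in design.samples.items():
            if deletion:
                q_nd1 = 10.0 ** ((mean_cq["MT-ND1"] - curves["MT-ND1"].intercept)
                                 / curves["MT-ND1"].slope)
                wt_frac = max(1.0 - truth / 100.0, 1e-9)
                quantities = {"MT-ND1": q_nd1, "MT-ND4": q_nd1 * wt_frac}
            else:
                q_base = {t: 10.0 ** ((mean_cq[t] - curves[t].intercept)
                                      / curves[t].slope)
                          for t in ("MT-ND1", "B2M")}
                quantities = {"MT-ND1": q_base["MT-ND1"] * truth,
                              "B2M": q_base["B2M"]}
            for target, q in quantities.items():
                cq_true = float(cq_from_quantity(q, curves[target]))
                noise = (rng.normal(0.0, design.cq_sd, size=design.k)
                         if design.cq_sd else np.zeros(design.k))
                for well, eps in zip(_well_labels(design.k), noise):
                    rows.append({
                        "plate_id": plate_id,
                        "pair_id": pair_id,
                        "well": well,
                        "sample_id": sample_id,
                        "target": target,
                        "cq": cq_true + float(eps),
                        "quantity": q,
                        "value": pd.NA,
                        "dna_conc_pg_per_ul": conc,
                    })
    return pd.DataFrame(rows)


def inject_outliers(
    values,
    probability: float,
    magnitude: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Contaminate a value vector with gross errors.

    Each value independently receives, with the given probability, a shift
    of ``+-magnitude`` (random sign) emulating operator error such as a
    mispipetted well.  Returns the contaminated copy and a boolean truth
    mask of injected positions, for validating outlier filters.
    """
    _check(0 <= probability < 1, "probability", "must be in [0, 1)")
    _check(magnitude > 0, "magnitude", "must be positive")
    values = np.asarray(values, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = rng.random(values.size) < probability
    signs = rng.choice([-1.0, 1.0], size=values.size)
    contaminated = values + mask * signs * magnitude
    return contaminated, mask


# --- study-design factories -------------------------------------------------

def deletion_intra_design(concentration: str = "high", seed: int = 0,
                          **overrides) -> SimulationDesign:
    """Six single-deletion samples (6-84%) in 84 replicates on one plate,
    per concentration level of a 10-fold dilution series."""
    kwargs = dict(samples=dict(DELETION_SAMPLES), n_plates=1, k=84,
                  concentration=concentration, sigma_inter=0.0, seed=seed)
    kwargs.update(overrides)
    return SimulationDesign(**kwargs)


def deletion_interplate_design(seed: int = 0, **overrides) -> SimulationDesign:
    """Six mixture samples (A-C low 20-25%, D-F high 70-80% deletion) in
    24 replicates on each of 3 plates, at high DNA concentration."""
    kwargs = dict(samples=dict(MIXTURE_SAMPLES), n_plates=3, k=24,
                  concentration="high", sigma_inter=0.485, seed=seed)
    kwargs.update(overrides)
    return SimulationDesign(**kwargs)


def copynumber_design(concentration: str = "high", seed: int = 0,
                      **overrides) -> SimulationDesign:
    """Five samples S1-S5 (relative levels 1 to 1.9) in 12 replicates per
    plate pair on 4 replicate pairs."""
    kwargs = dict(samples=dict(COPYNUMBER_SAMPLES), n_plates=4, k=12,
                  concentration=concentration,
                  intra_model=IntraSDModel(mode="copynumber"),
                  sigma_inter=0.0305, seed=seed)
    kwargs.update(overrides)
    return SimulationDesign(**kwargs)
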