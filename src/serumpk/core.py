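"""Quantitative bioanalysis and pharmacokinetics of an orally dosed small
molecule in serum.

The module covers the full computational workflow of a targeted LC-MS/MS
bioanalytical study, in the order a study runs:

1.  **Synthetic data** -- a one-compartment first-order-absorption simulator
    (with lag time, log-normal inter-individual variability, proportional
    assay noise and BLQ censoring) standing in for clinical serum samples,
    plus a calibration-batch generator whose response noise grows
    proportionally with concentration (the structure that justifies 1/x
    weighting).
2.  **Calibration & validation** -- weighted linear calibration
    (unweighted, 1/x, 1/x^2), back-calculation, S/N-based LOD/LOQ,
    QC precision/accuracy (RSD%, accuracy%), LOQ acceptance (80-120%
    accuracy, <=20% RSD) and stability assessment (+-15% deviation).
3.  **Noncompartmental analysis (NCA)** -- Cmax/Tmax, lag time, best-fit
    terminal-phase log-linear regression (lambda_z), linear-trapezoidal
    AUC(0-t) with Clast/lambda_z extrapolation to infinity, and the derived
    parameters t1/2 = ln2/lambda_z, CL/F = dose/AUC(0-inf),
    Vd/F = CL/F/lambda_z, summarized as population mean +- SD.
4.  **I/O and pipeline** -- CSV profile/runsheet round-tripping, YAML/JSON
    run configuration, and a reproducible `simulate -> calibrate ->
    validate -> nca` pipeline with seeded determinism.

Units throughout: dose in mg, time in h, concentration in ng/mL, AUC in
h*ng/mL, CL/F in L/h, Vd/F in L.  The single mg->ng (1e6) and mL->L (1e3)
conversion lives in :func:`derive_parameters`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("serumpk")

__all__ = [
    # constants
    "CALIBRATION_LEVELS", "REFERENCE_SLOPE", "REFERENCE_INTERCEPT",
    "LLOQ", "LOD", "DEFAULT_SCHEDULE", "DEFAULT_DOSE_MG", "QC_LEVELS",
    "ACCURACY_BOUNDS", "RSD_MAX_PCT", "STABILITY_TOL_PCT",
    # errors / warnings
    "SerumPKError", "ProfileError", "CalibrationError", "NCAError",
    "DataValidationWarning",
    # types
    "PKParameters", "PopulationConfig", "ConcentrationTimeProfile",
    "CalibrationBatch", "CalibrationFit", "QCEvaluation", "AcceptanceCheck",
    "StabilityResult", "NCAResult", "PopulationSummary", "RunConfig",
    # synthetic data
    "concentration_at", "analytic_tmax", "analytic_auc_inf",
    "simulate_profile", "simulate_population", "censor_blq",
    "simulate_calibration_batch", "prodrug_arm_config",
    # calibration
    "fit_weighted_line", "predict_response", "back_calculate",
    "back_calculate_flagged", "evaluate_qc", "check_loq_acceptance",
    "check_standard_acceptance", "lod_loq_from_sn", "assess_stability",
    # nca
    "cmax_tmax", "estimate_tlag", "select_terminal_phase", "fit_lambda_z",
    "auc_linear_trapezoid", "auc_0_inf", "derive_parameters", "run_nca",
    "summarize_population", "format_summary",
    # io / pipeline
    "read_profiles", "write_profiles", "read_runsheet", "write_batch",
    "run_pipeline",
]


# --------------------------------------------------------------------------
# Study constants and defaults
# --------------------------------------------------------------------------

#: Nominal calibration-standard concentrations (ng/mL), low to high.
CALIBRATION_LEVELS: tuple[float, ...] = (7.5, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0)

#: Reference calibration line (response = slope * conc + intercept) used as
#: generative truth for synthetic batches and for the full-pipeline
#: concentration -> response mapping.
REFERENCE_SLOPE: float = 0.8466
REFERENCE_INTERCEPT: float = 12.36

#: Limits of detection / quantification in serum (ng/mL); LLOQ anchors both
#: the lowest calibration standard and BLQ censoring.
LOD: float = 3.5
LLOQ: float = 7.5

#: Serial sampling schedule (h post dose), predose sample at 0.
DEFAULT_SCHEDULE: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 5.0, 8.0, 24.0)
DEFAULT_DOSE_MG: float = 100.0

#: QC sample concentrations (ng/mL) for precision/accuracy batches.
QC_LEVELS: tuple[float, ...] = (50.0, 250.0)

#: Acceptance rules: accuracy within [80, 120]% and RSD <= 20% at the LOQ
#: (closed bounds), back-calculated standards within +-15% (+-20% at LOQ),
#: stability deviation within +-15%.
ACCURACY_BOUNDS: tuple[float, float] = (80.0, 120.0)
RSD_MAX_PCT: float = 20.0
STANDARD_RESIDUAL_TOL_PCT: float = 15.0
LOQ_RESIDUAL_TOL_PCT: float = 20.0
STABILITY_TOL_PCT: float = 15.0

#: Extrapolated AUC fraction above which a quality flag is raised.
EXTRAPOLATION_WARN_PCT: float = 20.0

#: Adjusted-r^2 differences below this are ties in terminal-phase window
#: selection (more points wins) -- the conventional best-fit tolerance.
LAMBDA_Z_TIE_TOL: float = 1e-4

_WEIGHTING_SCHEMES = ("unweighted", "1/x", "1/x^2")
_NG_PER_MG = 1.0e6
_ML_PER_L = 1.0e3


class SerumPKError(Exception):
    """Base class for errors raised by this package."""


class ProfileError(SerumPKError):
    """A concentration-time profile is structurally invalid."""


class CalibrationError(SerumPKError):
    """A calibration batch, fit or QC evaluation is invalid."""


class NCAError(SerumPKError):
    """A profile cannot be analyzed noncompartmentally."""


class DataValidationWarning(UserWarning):
    """Non-fatal inconsistency found while reading input data."""


def _normalize_weighting(weighting: str) -> str:
    w = {"1/x2": "1/x^2", "1/x²": "1/x^2", "none": "unweighted"}.get(
        weighting, weighting)
    if w not in _WEIGHTING_SCHEMES:
        raise CalibrationError(
            f"unknown weighting {weighting!r}; expected one of {_WEIGHTING_SCHEMES}")
    return w


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PKParameters:
    """One-compartment oral-absorption parameters for a single subject.

    ka and kel are first-order absorption and elimination rate constants
    (1/h); vd_over_f is the apparent volume of distribution (L); tlag the
    absorption lag time (h); dose the administered amount (mg).
    """

    ka: float
    kel: float
    vd_over_f: float
    tlag: float = 0.0
    dose: float = DEFAULT_DOSE_MG

    def __post_init__(self) -> None:
        if not (self.ka > 0 and self.kel > 0 and self.vd_over_f > 0 and self.dose > 0):
            raise ValueError("ka, kel, vd_over_f and dose must be positive")
        if self.tlag < 0:
            raise ValueError("tlag must be nonnegative")
        if self.ka == self.kel:
            raise ValueError("ka == kel (degenerate flip-flop form not supported)")


def _default_iiv() -> dict[str, float]:
    return {"ka": 0.30, "kel": 0.45, "vd_over_f": 0.45}


@dataclass(frozen=True)
class PopulationConfig:
    """Generative model for a simulated study arm.

    iiv_cv gives per-parameter coefficients of variation of the log-normal
    inter-individual variability (a bare float applies the same CV to ka,
    kel and vd_over_f).  tlag varies uniformly on
    [max(0, tlag - tlag_halfwidth), tlag + tlag_halfwidth].  assay_cv is the
    proportional measurement-error CV; lloq the censoring limit (ng/mL).
    """

    typical: PKParameters = field(
        default_factory=lambda: PKParameters(
            ka=2.6, kel=math.log(2) / 3.93, vd_over_f=1500.0, tlag=0.15))
    iiv_cv: Mapping[str, float] | float = field(default_factory=_default_iiv)
    tlag_halfwidth: float = 0.15
    assay_cv: float = 0.05
    lloq: float = LLOQ
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    n_subjects: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "schedule", tuple(float(t) for t in self.schedule))
        if isinstance(self.iiv_cv, (int, float)):
            object.__setattr__(self, "iiv_cv",
                               {k: float(self.iiv_cv) for k in _default_iiv()})
        else:
            cvs = dict(_default_iiv(), **dict(self.iiv_cv))
            unknown = set(cvs) - set(_default_iiv())
            if unknown:
                raise ValueError(f"iiv_cv for unknown parameters: {sorted(unknown)}")
            object.__setattr__(self, "iiv_cv", cvs)
        if any(cv < 0 for cv in self.iiv_cv.values()) or self.assay_cv < 0:
            raise ValueError("coefficients of variation must be nonnegative")
        if self.tlag_halfwidth < 0:
            raise ValueError("tlag_halfwidth must be nonnegative")
        if self.lloq < 0:
            raise ValueError("lloq must be nonnegative")
        sched = np.asarray(self.schedule, float)
        if sched.size == 0 or sched[0] != 0.0 or np.any(np.diff(sched) <= 0):
            raise ValueError("schedule must start at 0 and be strictly increasing")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass(frozen=True, eq=False)
class ConcentrationTimeProfile:
    """One subject's dosed serum time course with BLQ censoring flags.

    ``concentrations`` holds NaN where a sample is censored (BLQ); the
    parallel ``blq_flags`` mark those samples (two censored samples compare
    equal).  Times are hours post dose, strictly increasing.
    """

    subject_id: str
    dose: float
    times: tuple[float, ...]
    concentrations: tuple[float, ...]
    blq_flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        c = np.asarray(self.concentrations, float)
        b = np.asarray(self.blq_flags, bool)
        if not (t.size == c.size == b.size):
            raise ProfileError(f"{self.subject_id}: times/concentrations/flags "
                               "must have equal length")
        if t.size == 0:
            raise ProfileError(f"{self.subject_id}: empty profile")
        if np.any(np.diff(t) <= 0):
            raise ProfileError(f"{self.subject_id}: times must be strictly increasing")
        if np.any(t < 0):
            raise ProfileError(f"{self.subject_id}: negative sampling time")
        if np.any(c[~np.isnan(c)] < 0):
            raise ProfileError(f"{self.subject_id}: negative concentration")
        if self.dose <= 0:
            raise ProfileError(f"{self.subject_id}: dose must be positive")
        object.__setattr__(self, "times", tuple(t.tolist()))
        object.__setattr__(self, "concentrations", tuple(c.tolist()))
        object.__setattr__(self, "blq_flags", tuple(bool(x) for x in b))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConcentrationTimeProfile):
            return NotImplemented
        return (self.subject_id == other.subject_id
                and self.dose == other.dose
                and self.times == other.times
                and self.blq_flags == other.blq_flags
                and np.array_equal(np.asarray(self.concentrations),
                                   np.asarray(other.concentrations),
                                   equal_nan=True))

    @property
    def n_blq(self) -> int:
        return int(sum(self.blq_flags))

    @property
    def n_quantifiable(self) -> int:
        return len(self.times) - self.n_blq

    def quantifiable(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and concentrations of the non-censored samples."""
        t = np.asarray(self.times)
        c = np.asarray(self.concentrations)
        mask = ~np.asarray(self.blq_flags) & ~np.isnan(c)
        return t[mask], c[mask]


@dataclass(frozen=True)
class CalibrationBatch:
    """Nominal standard levels with replicate instrument responses.

    Responses are analyte/internal-standard peak-area ratios
    (dimensionless); levels are ng/mL, strictly increasing, each with at
    least one replicate.
    """

    levels: tuple[float, ...]
    responses: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, float)
        if lv.size < 2 or np.any(np.diff(lv) <= 0):
            raise CalibrationError("need >=2 strictly increasing levels")
        if np.any(lv <= 0):
            raise CalibrationError("levels must be positive")
        if len(self.responses) != lv.size or any(len(r) < 1 for r in self.responses):
            raise CalibrationError("every level needs >=1 response")
        object.__setattr__(self, "levels", tuple(lv.tolist()))
        object.__setattr__(self, "responses",
                           tuple(tuple(float(y) for y in r) for r in self.responses))

    def points(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (concentration, response) pairs, one per replicate."""
        x = np.repeat(self.levels, [len(r) for r in self.responses])
        y = np.concatenate([np.asarray(r, float) for r in self.responses])
        return x, y

    def to_frame(self) -> pd.DataFrame:
        rows = [(lvl, i + 1, resp)
                for lvl, reps in zip(self.levels, self.responses)
                for i, resp in enumerate(reps)]
        return pd.DataFrame(rows, columns=["level_ng_ml", "replicate", "response"])


@dataclass(frozen=True)
class CalibrationFit:
    """Weighted linear calibration: response = slope * conc + intercept.

    r_squared is computed on the weighted regression (weighted residual and
    total sums of squares about the weighted mean); r_squared_unweighted is
    the ordinary r^2 of the same line, reported for transparency.
    residual_pct holds per-point back-calculation errors,
    100 * (back-calculated - nominal) / nominal.
    """

    slope: float
    intercept: float
    weighting: str
    r_squared: float
    r_squared_unweighted: float
    n_points: int
    x: tuple[float, ...]
    y: tuple[float, ...]
    residual_pct: tuple[float, ...]


@dataclass(frozen=True)
class QCEvaluation:
    """Per-level QC summary: detected mean, precision (RSD%) and accuracy (%)."""

    nominal: float
    detected_mean: float
    sd: float
    rsd_pct: float
    accuracy_pct: float
    n: int
    scope: str
    n_sub_blank: int = 0


@dataclass(frozen=True)
class AcceptanceCheck:
    """Outcome of an acceptance rule, with the reasons for any failure."""

    passed: bool
    reasons: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class StabilityResult:
    """Stability under a storage condition as signed % deviation from nominal."""

    condition: str
    nominal: float
    detected_mean: float
    deviation_pct: float
    passed: bool
    n: int


#: NCA parameter fields summarized across a population.
NCA_PARAMETERS = ("cmax", "tmax", "tlag", "lambda_z", "t_half",
                  "auc_0_t", "auc_0_inf", "pct_extrapolated",
                  "cl_over_f", "vd_over_f")

#: Row labels / units for the population summary table.
_SUMMARY_LAYOUT = (
    ("cmax", "Cmax (ng/mL)"),
    ("tmax", "Tmax (h)"),
    ("t_half", "t1/2 (h)"),
    ("auc_0_inf", "AUC (h*ng/mL)"),
    ("cl_over_f", "CL/F (L/h)"),
    ("vd_over_f", "Vd/F (L)"),
)


@dataclass(frozen=True)
class NCAResult:
    """Per-subject noncompartmental parameter set.

    ``error`` is set (and numeric fields are NaN) when the profile could not
    be analyzed; ``flags`` carries non-fatal quality warnings such as
    extrapolated AUC above 20%.
    """

    subject_id: str
    dose: float
    cmax: float = math.nan
    tmax: float = math.nan
    tlag: float = math.nan
    lambda_z: float = math.nan
    lambda_z_n_points: int = 0
    lambda_z_r2_adj: float = math.nan
    t_half: float = math.nan
    auc_0_t: float = math.nan
    auc_0_inf: float = math.nan
    pct_extrapolated: float = math.nan
    cl_over_f: float = math.nan
    vd_over_f: float = math.nan
    flags: tuple[str, ...] = ()
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass(frozen=True)
class PopulationSummary:
    """Mean +- sample SD (n-1 denominator) per NCA parameter.

    n counts successfully analyzed subjects; excluded lists subjects that
    produced error records and are not part of any statistic.
    """

    stats: Mapping[str, tuple[float, float]]  # parameter -> (mean, sd)
    n: int
    excluded: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = [(p, m, s, self.n) for p, (m, s) in self.stats.items()]
        return pd.DataFrame(rows, columns=["parameter", "mean", "sd", "n"])


# --------------------------------------------------------------------------
# Synthetic data: one-compartment oral model, population and batches
# --------------------------------------------------------------------------

def concentration_at(params: PKParameters, t: float | np.ndarray) -> np.ndarray:
    """Noise-free serum concentration (ng/mL) of the one-compartment oral model.

    C(t) = D*ka / (V*(ka - kel)) * (exp(-kel*(t-tlag)) - exp(-ka*(t-tlag)))
    for t > tlag, else 0, with dose in ng and volume in mL.
    """
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("negative time")
    te = np.maximum(t - params.tlag, 0.0)
    dose_ng = params.dose * _NG_PER_MG
    v_ml = params.vd_over_f * _ML_PER_L
    amp = dose_ng * params.ka / (v_ml * (params.ka - params.kel))
    return amp * (np.exp(-params.kel * te) - np.exp(-params.ka * te))


def analytic_tmax(params: PKParameters) -> float:
    """Closed-form time of maximum: ln(ka/kel)/(ka - kel) + tlag."""
    return math.log(params.ka / params.kel) / (params.ka - params.kel) + params.tlag


def analytic_auc_inf(params: PKParameters) -> float:
    """Closed-form AUC(0-inf) = dose / (Vd/F * kel), in h*ng/mL."""
    return params.dose * _NG_PER_MG / (params.vd_over_f * _ML_PER_L * params.kel)


def simulate_profile(params: PKParameters, schedule: Sequence[float],
                     subject_id: str = "S01") -> ConcentrationTimeProfile:
    """Noise-free, uncensored profile of one subject on a sampling schedule."""
    schedule = np.asarray(schedule, float)
    if schedule.size == 0:
        raise ValueError("empty schedule")
    conc = concentration_at(params, schedule)
    return ConcentrationTimeProfile(
        subject_id=subject_id, dose=params.dose,
        times=tuple(schedule.tolist()), concentrations=tuple(conc.tolist()),
        blq_flags=(False,) * schedule.size)


def censor_blq(profile: ConcentrationTimeProfile,
               lloq: float) -> ConcentrationTimeProfile:
    """Flag and mask samples below the quantification limit.

    Samples with concentration < lloq (and samples already censored) are
    flagged BLQ and their value replaced by NaN; others pass through
    unchanged.  Idempotent; raising lloq never un-flags a sample.  The flag
    count is available as ``profile.n_blq``.
    """
    if lloq <= 0:
        raise ValueError("lloq must be positive")
    c = np.asarray(profile.concentrations, float)
    flags = np.asarray(profile.blq_flags, bool) | np.isnan(c)
    with np.errstate(invalid="ignore"):
        flags |= c < lloq
    c = np.where(flags, np.nan, c)
    return dataclasses.replace(profile, concentrations=tuple(c.tolist()),
                               blq_flags=tuple(bool(f) for f in flags))


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative log-normal IIV with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_population(
        config: PopulationConfig,
        return_parameters: bool = False,
) -> list[ConcentrationTimeProfile] | tuple[list[ConcentrationTimeProfile],
                                            list[PKParameters]]:
    """Simulate a study arm: IIV, proportional assay noise, BLQ censoring.

    Per subject, ka/kel/Vd-over-F are drawn log-normally around the typical
    values with the configured CVs (unit-mean parameterization), tlag
    uniformly on its interval; observed concentrations are
    C_true * (1 + assay_cv * z), floored at zero, then censored at lloq.
    Identical config (including seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    typ = config.typical
    fac = {p: _lognormal_factor(rng, config.iiv_cv[p], n)
           for p in ("ka", "kel", "vd_over_f")}
    lo = max(0.0, typ.tlag - config.tlag_halfwidth)
    hi = typ.tlag + config.tlag_halfwidth
    tlags = rng.uniform(lo, hi, n) if hi > lo else np.full(n, typ.tlag)

    width = len(str(n))
    profiles, parameters = [], []
    for i in range(n):
        ka = typ.ka * fac["ka"][i]
        kel = typ.kel * fac["kel"][i]
        if ka == kel:  # measure-zero; nudge to keep the model defined
            ka *= 1.0 + 1e-9
        params = PKParameters(ka=ka, kel=kel,
                              vd_over_f=typ.vd_over_f * fac["vd_over_f"][i],
                              tlag=float(tlags[i]), dose=typ.dose)
        parameters.append(params)
        truth = concentration_at(params, np.asarray(config.schedule))
        if config.assay_cv > 0:
            obs = truth * (1.0 + config.assay_cv * rng.standard_normal(truth.size))
            obs = np.maximum(obs, 0.0)
        else:
            obs = truth
        prof = ConcentrationTimeProfile(
            subject_id=f"S{i + 1:0{width}d}", dose=typ.dose,
            times=config.schedule, concentrations=tuple(obs.tolist()),
            blq_flags=(False,) * len(config.schedule))
        if config.lloq > 0:
            prof = censor_blq(prof, config.lloq)
        profiles.append(prof)
    if return_parameters:
        return profiles, parameters
    return profiles


def simulate_calibration_batch(slope: float = REFERENCE_SLOPE,
                               intercept: float = REFERENCE_INTERCEPT,
                               levels: Sequence[float] = CALIBRATION_LEVELS,
                               replicates: int = 2,
                               noise_cv: float = 0.0,
                               seed: int | None = 0) -> CalibrationBatch:
    """Synthetic calibration batch with concentration-proportional noise.

    response = slope*x + intercept + eps, eps ~ N(0, (noise_cv*slope*x)^2),
    so the response SD grows linearly with concentration -- the
    heteroscedasticity that motivates 1/x weighting.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    responses = []
    for x in levels:
        mu = slope * x + intercept
        eps = (noise_cv * slope * x * rng.standard_normal(replicates)
               if noise_cv > 0 else np.zeros(replicates))
        responses.append(tuple((mu + eps).tolist()))
    return CalibrationBatch(levels=tuple(float(x) for x in levels),
                            responses=tuple(responses))


def prodrug_arm_config(base: PopulationConfig,
                       prodrug_dose: float = 90.0,
                       conversion_fraction: float = 0.1) -> PopulationConfig:
    """Configuration for the ester-prodrug arm of the two-arm scenario.

    Heuristic: the prodrug dose contributes an effective parent-compound
    dose of ``prodrug_dose * conversion_fraction`` (default one-tenth),
    leaving the kinetics unchanged -- most samples then fall below the LLOQ.
    """
    if not 0 < conversion_fraction <= 1:
        raise ValueError("conversion_fraction must be in (0, 1]")
    typical = dataclasses.replace(base.typical,
                                  dose=prodrug_dose * conversion_fraction)
    return dataclasses.replace(base, typical=typical)


# --------------------------------------------------------------------------
# Calibration, QC and validation
# --------------------------------------------------------------------------

def _weights(x: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "unweighted":
        return np.ones_like(x)
    if weighting == "1/x":
        return 1.0 / x
    return 1.0 / (x * x)


def fit_weighted_line(batch: CalibrationBatch,
                      weighting: str = "1/x") -> CalibrationFit:
    """Weighted least-squares calibration line through a standards batch.

    Minimizes sum w_i * (y_i - a*x_i - b)^2 with w_i per the scheme
    (unweighted, 1/x, 1/x^2; x = nominal concentration) via the weighted
    normal equations.  All replicate points enter individually (no
    averaging).
    """
    weighting = _normalize_weighting(weighting)
    x, y = batch.points()
    if np.unique(x).size < 2:
        raise CalibrationError("all levels identical: singular design")
    w = _weights(x, weighting)

    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar

    resid = y - (slope * x + intercept)
    ss_res = (w * resid ** 2).sum()
    ss_tot = (w * (y - ybar) ** 2).sum()
    r2_w = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    ybar_u = y.mean()
    ss_tot_u = ((y - ybar_u) ** 2).sum()
    r2_u = 1.0 - (resid ** 2).sum() / ss_tot_u if ss_tot_u > 0 else 1.0

    back = (y - intercept) / slope
    residual_pct = 100.0 * (back - x) / x
    return CalibrationFit(slope=float(slope), intercept=float(intercept),
                          weighting=weighting,
                          r_squared=float(r2_w), r_squared_unweighted=float(r2_u),
                          n_points=int(x.size),
                          x=tuple(x.tolist()), y=tuple(y.tolist()),
                          residual_pct=tuple(residual_pct.tolist()))


def predict_response(fit: CalibrationFit, conc):
    """Predicted instrument response at a concentration (inverse of back-calculation)."""
    return fit.slope * np.asarray(conc, float) + fit.intercept


def back_calculate(fit: CalibrationFit, response):
    """Concentration (ng/mL) from an instrument response: (y - b)/a.

    May be negative for sub-blank responses; values are never clipped so QC
    statistics stay unbiased.  Use :func:`back_calculate_flagged` to obtain
    the sub-blank mask.
    """
    if fit.slope == 0:
        raise CalibrationError("zero slope: back-calculation undefined")
    out = (np.asarray(response, float) - fit.intercept) / fit.slope
    return float(out) if out.ndim == 0 else out


def back_calculate_flagged(fit: CalibrationFit, response):
    """Back-calculated concentration plus a sub-blank (negative value) flag."""
    conc = back_calculate(fit, response)
    return conc, np.asarray(conc) < 0 if np.ndim(conc) else conc < 0


def evaluate_qc(fit: CalibrationFit, qc_responses: Sequence[float],
                nominal: float, scope: str = "intra-day") -> QCEvaluation:
    """Precision and accuracy of replicate QC samples at one nominal level.

    Detected concentrations come from back-calculation through the fit;
    rsd_pct = 100*SD/mean of detected (sample SD, n-1), accuracy_pct =
    100*mean/nominal.  Inter-day evaluation simply pools all days'
    replicates into ``qc_responses``.
    """
    resp = np.asarray(qc_responses, float)
    if resp.size < 2:
        raise CalibrationError("need >=2 QC replicates")
    if nominal <= 0:
        raise CalibrationError("nominal concentration must be positive")
    detected, sub_blank = back_calculate_flagged(fit, resp)
    mean = float(detected.mean())
    if mean <= 0:
        raise CalibrationError("mean detected concentration <= 0: RSD undefined")
    sd = float(detected.std(ddof=1))
    return QCEvaluation(nominal=float(nominal), detected_mean=mean, sd=sd,
                        rsd_pct=100.0 * sd / mean,
                        accuracy_pct=100.0 * mean / nominal,
                        n=int(resp.size), scope=scope,
                        n_sub_blank=int(sub_blank.sum()))


def check_loq_acceptance(evaluation: QCEvaluation,
                         accuracy_bounds: tuple[float, float] = ACCURACY_BOUNDS,
                         rsd_max: float = RSD_MAX_PCT) -> AcceptanceCheck:
    """LOQ acceptance: accuracy within 80-120% and RSD <= 20% (closed bounds).

    Warns (without failing) when fewer than seven replicates support the
    claim.
    """
    reasons = []
    lo, hi = accuracy_bounds
    if not lo <= evaluation.accuracy_pct <= hi:
        reasons.append(f"accuracy {evaluation.accuracy_pct:.1f}% outside "
                       f"[{lo:g}, {hi:g}]%")
    if not evaluation.rsd_pct <= rsd_max:
        reasons.append(f"RSD {evaluation.rsd_pct:.1f}% exceeds {rsd_max:g}%")
    warns = []
    if evaluation.n < 7:
        warns.append(f"only {evaluation.n} replicates (7 recommended for LOQ)")
    return AcceptanceCheck(passed=not reasons, reasons=tuple(reasons),
                           warnings=tuple(warns))


def check_standard_acceptance(fit: CalibrationFit,
                              lloq: float = LLOQ) -> AcceptanceCheck:
    """Back-calculation acceptance of calibration standards.

    Each point must back-calculate within +-15% of nominal (+-20% at the
    LOQ level); reasons list the offending points.
    """
    reasons = []
    for xi, ri in zip(fit.x, fit.residual_pct):
        tol = LOQ_RESIDUAL_TOL_PCT if xi <= lloq else STANDARD_RESIDUAL_TOL_PCT
        if abs(ri) > tol:
            reasons.append(f"standard {xi:g} ng/mL back-calculates "
                           f"{ri:+.1f}% (tolerance +-{tol:g}%)")
    return AcceptanceCheck(passed=not reasons, reasons=tuple(reasons))


def lod_loq_from_sn(reference_conc: float,
                    reference_sn: float) -> tuple[float, float]:
    """Limits of detection/quantification from a measured signal-to-noise ratio.

    With S/N proportional to concentration through the origin, the
    concentrations at S/N = 3 and 10 are lod = 3*c/sn and loq = 10*c/sn, so
    loq/lod = 10/3 always.
    """
    if reference_conc <= 0 or reference_sn <= 0:
        raise CalibrationError("reference concentration and S/N must be positive")
    return 3.0 * reference_conc / reference_sn, 10.0 * reference_conc / reference_sn


def assess_stability(measured: Sequence[float], nominal: float,
                     condition: str) -> StabilityResult:
    """Stability as signed % deviation of the mean detected concentration.

    deviation_pct = 100 * (mean(measured) - nominal)/nominal; passes when
    |deviation| <= 15% (closed bound).
    """
    meas = np.asarray(measured, float)
    if meas.size < 1:
        raise CalibrationError("need >=1 stability replicate")
    if nominal <= 0:
        raise CalibrationError("nominal concentration must be positive")
    mean = float(meas.mean())
    dev = 100.0 * (mean - nominal) / nominal
    return StabilityResult(condition=condition, nominal=float(nominal),
                           detected_mean=mean, deviation_pct=dev,
                           passed=abs(dev) <= STABILITY_TOL_PCT, n=int(meas.size))


# --------------------------------------------------------------------------
# Noncompartmental analysis
# --------------------------------------------------------------------------

def cmax_tmax(profile: ConcentrationTimeProfile) -> tuple[float, float]:
    """Observed maximum concentration and its time; ties break to the
    earliest time."""
    t, c = profile.quantifiable()
    if t.size == 0:
        raise NCAError(f"{profile.subject_id}: no quantifiable samples")
    i = int(np.argmax(c))  # argmax returns the first maximum
    return float(c[i]), float(t[i])


def estimate_tlag(profile: ConcentrationTimeProfile) -> float:
    """Absorption lag: time of the last BLQ/zero sample before the first
    quantifiable one (0 when absorption is already measurable at the first
    post-dose sample)."""
    t = np.asarray(profile.times)
    c = np.asarray(profile.concentrations)
    blq = np.asarray(profile.blq_flags)
    quant = ~blq & ~np.isnan(c) & (c > 0)
    if not quant.any():
        raise NCAError(f"{profile.subject_id}: no quantifiable samples")
    first = int(np.argmax(quant))
    return float(t[first - 1]) if first > 0 else 0.0


def _adjusted_r2_loglinear(t: np.ndarray, logc: np.ndarray) -> tuple[float, float]:
    """OLS of ln C on t; returns (slope, adjusted r^2)."""
    n = t.size
    slope, intercept = np.polyfit(t, logc, 1)
    fitted = slope * t + intercept
    ss_res = float(((logc - fitted) ** 2).sum())
    ss_tot = float(((logc - logc.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(slope), float(r2_adj)


def select_terminal_phase(profile: ConcentrationTimeProfile) -> tuple[int, ...]:
    """Best-fit terminal window: indices (into the profile) of the points
    used for the lambda_z regression.

    Candidate windows are the suffixes of the quantifiable samples strictly
    after Tmax (the Cmax point itself excluded) with at least three points;
    among windows with a positive lambda_z, the one maximizing the adjusted
    r^2 of the log-linear fit wins, with differences below 1e-4 treated as
    ties broken toward more points.
    """
    t = np.asarray(profile.times)
    c = np.asarray(profile.concentrations)
    blq = np.asarray(profile.blq_flags)
    quant = ~blq & ~np.isnan(c) & (c > 0)
    if not quant.any():
        raise NCAError(f"{profile.subject_id}: no quantifiable samples")
    _, tmax = cmax_tmax(profile)
    eligible = np.flatnonzero(quant & (t > tmax))
    if eligible.size < 3:
        raise NCAError(f"{profile.subject_id}: fewer than 3 quantifiable "
                       "points after Tmax; lambda_z not estimable")
    candidates: list[tuple[float, tuple[int, ...]]] = []
    for start in range(eligible.size - 2):
        idx = eligible[start:]
        slope, r2_adj = _adjusted_r2_loglinear(t[idx], np.log(c[idx]))
        if slope < 0:
            candidates.append((r2_adj, tuple(int(i) for i in idx)))
    if not candidates:
        raise NCAError(f"{profile.subject_id}: no terminal window with a "
                       "declining log-linear phase")
    best_r2 = max(r2 for r2, _ in candidates)
    tied = [idx for r2, idx in candidates if r2 >= best_r2 - LAMBDA_Z_TIE_TOL]
    return max(tied, key=len)


def fit_lambda_z(profile: ConcentrationTimeProfile,
                 indices: Sequence[int]) -> tuple[float, float]:
    """Terminal elimination rate constant from log-linear regression.

    Ordinary least squares of ln(concentration) on time over the selected
    window; lambda_z is the negated slope and must be positive.
    """
    idx = np.asarray(indices, int)
    if idx.size < 3:
        raise NCAError("lambda_z regression needs >=3 points")
    t = np.asarray(profile.times)[idx]
    c = np.asarray(profile.concentrations)[idx]
    if np.any(~(c > 0)):
        raise NCAError("nonpositive concentration in lambda_z window")
    slope, r2_adj = _adjusted_r2_loglinear(t, np.log(c))
    if slope >= 0:
        raise NCAError("terminal phase not declining (lambda_z <= 0)")
    return -slope, r2_adj


def _auc_series(profile: ConcentrationTimeProfile) -> tuple[np.ndarray, np.ndarray]:
    """Working series for trapezoidal AUC under the BLQ convention:
    BLQ samples at or before Tmax count as 0; BLQ samples after Tmax are
    dropped."""
    t = np.asarray(profile.times)
    c = np.asarray(profile.concentrations)
    blq = np.asarray(profile.blq_flags) | np.isnan(c)
    _, tmax = cmax_tmax(profile)
    keep = ~blq | (t <= tmax)
    tt, cc = t[keep], c[keep]
    cc = np.where(np.isnan(cc), 0.0, cc)
    return tt, cc


def auc_linear_trapezoid(profile: ConcentrationTimeProfile,
                         t_start: float | None = None,
                         t_end: float | None = None) -> float:
    """Linear-trapezoidal AUC between two sampling times (h*ng/mL).

    Defaults to the full usable range (first sample to last quantifiable
    sample).  Endpoints must coincide with sampling times of the
    BLQ-adjusted series.
    """
    tt, cc = _auc_series(profile)
    if tt.size < 2:
        raise NCAError(f"{profile.subject_id}: fewer than 2 usable points for AUC")
    t0 = float(tt[0]) if t_start is None else float(t_start)
    t1 = float(tt[-1]) if t_end is None else float(t_end)
    if not t0 < t1:
        raise NCAError("t_start must be < t_end")
    sel = (tt >= t0) & (tt <= t1)
    if sel.sum() < 2:
        raise NCAError("fewer than 2 points inside AUC range")
    if not (np.isclose(tt[sel][0], t0) and np.isclose(tt[sel][-1], t1)):
        raise NCAError("AUC endpoints must coincide with sampling times")
    return float(np.trapezoid(cc[sel], tt[sel]))


def auc_0_inf(auc_0_t: float, c_last: float,
              lambda_z: float) -> tuple[float, float]:
    """Extrapolate AUC to infinity with the tail term Clast/lambda_z.

    Returns (AUC(0-inf), % of it that is extrapolated).  Uses the observed
    last quantifiable concentration.
    """
    if lambda_z <= 0:
        raise NCAError("cannot extrapolate: lambda_z <= 0")
    if c_last <= 0:
        raise NCAError("cannot extrapolate: nonpositive Clast")
    tail = c_last / lambda_z
    total = auc_0_t + tail
    return float(total), float(100.0 * tail / total)


def derive_parameters(dose_mg: float, auc_0_inf_value: float,
                      lambda_z: float) -> tuple[float, float, float]:
    """Derived parameters (t_half h, CL/F L/h, Vd/F L).

    t_half = ln2/lambda_z; CL/F = dose/AUC(0-inf) with dose converted
    mg -> ng and the resulting mL/h converted to L/h (the only place the
    1e6 ng/mg and 1e3 mL/L factors appear); Vd/F = CL/F / lambda_z.
    """
    if dose_mg <= 0 or auc_0_inf_value <= 0 or lambda_z <= 0:
        raise NCAError("dose, AUC(0-inf) and lambda_z must be positive")
    t_half = math.log(2) / lambda_z
    cl_over_f = (dose_mg * _NG_PER_MG / auc_0_inf_value) / _ML_PER_L  # L/h
    vd_over_f = cl_over_f / lambda_z
    return t_half, cl_over_f, vd_over_f


def run_nca(profile: ConcentrationTimeProfile,
            dose: float | None = None,
            extrapolation_warn_pct: float = EXTRAPOLATION_WARN_PCT) -> NCAResult:
    """Full noncompartmental analysis of one subject.

    Any failure (all-BLQ profile, too few points, no declining terminal
    phase) yields an NCAResult carrying an ``error`` message instead of
    raising, so population runs never crash on a bad subject.
    """
    dose = profile.dose if dose is None else dose
    try:
        if profile.n_quantifiable < 3:
            raise NCAError(f"{profile.subject_id}: insufficient quantifiable "
                           f"data ({profile.n_quantifiable} samples)")
        cmax, tmax = cmax_tmax(profile)
        tlag = estimate_tlag(profile)
        indices = select_terminal_phase(profile)
        lambda_z, r2_adj = fit_lambda_z(profile, indices)
        tq, cq = profile.quantifiable()
        auc_t = auc_linear_trapezoid(profile)
        auc_inf, pct_extrap = auc_0_inf(auc_t, float(cq[-1]), lambda_z)
        t_half, cl_f, vd_f = derive_parameters(dose, auc_inf, lambda_z)
    except NCAError as exc:
        logger.info("nca subject=%s status=error message=%s",
                    profile.subject_id, exc)
        return NCAResult(subject_id=profile.subject_id, dose=dose,
                         error=str(exc))
    flags = []
    if pct_extrap > extrapolation_warn_pct:
        flags.append(f"extrapolated AUC {pct_extrap:.1f}% exceeds "
                     f"{extrapolation_warn_pct:g}%")
    logger.info("nca subject=%s status=ok lambda_z_window=%s flags=%s",
                profile.subject_id, list(indices), flags)
    return NCAResult(subject_id=profile.subject_id, dose=dose, cmax=cmax,
                     tmax=tmax, tlag=tlag, lambda_z=lambda_z,
                     lambda_z_n_points=len(indices), lambda_z_r2_adj=r2_adj,
                     t_half=t_half, auc_0_t=auc_t, auc_0_inf=auc_inf,
                     pct_extrapolated=pct_extrap, cl_over_f=cl_f,
                     vd_over_f=vd_f, flags=tuple(flags))


def summarize_population(results: Iterable[NCAResult]) -> PopulationSummary:
    """Arithmetic mean +- sample SD per parameter across successful subjects.

    Per-subject parameters are averaged directly (never ratios of averages);
    subjects with error records are excluded and listed.
    """
    results = list(results)
    ok = [r for r in results if r.ok]
    excluded = tuple(r.subject_id for r in results if not r.ok)
    if not ok:
        raise NCAError("no successfully analyzed subjects to summarize")
    stats = {}
    for p in NCA_PARAMETERS:
        vals = np.array([getattr(r, p) for r in ok], float)
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        stats[p] = (float(vals.mean()), sd)
    return PopulationSummary(stats=stats, n=len(ok), excluded=excluded)


def format_summary(summary: PopulationSummary) -> str:
    """Population summary as a mean +- SD text table (Cmax, Tmax, t1/2,
    AUC, CL/F, Vd/F rows)."""
    lines = [f"Pharmacokinetic parameters (n = {summary.n})"]
    if summary.excluded:
        lines.append(f"Excluded subjects: {', '.join(summary.excluded)}")
    for key, label in _SUMMARY_LAYOUT:
        mean, sd = summary.stats[key]
        lines.append(f"{label:<16} {mean:.2f} ± {sd:.2f}")
    return "\n".join(lines)


# --------------------------------------------------------------------------
# I/O, run configuration and pipeline
# --------------------------------------------------------------------------

PROFILE_COLUMNS = ("subject_id", "dose_mg", "time_h", "conc_ng_ml", "blq")
RUNSHEET_COLUMNS = ("level_ng_ml", "replicate", "response")


def write_profiles(profiles: Sequence[ConcentrationTimeProfile],
                   path: str | Path) -> None:
    """Write profiles as CSV with header subject_id,dose_mg,time_h,conc_ng_ml,blq
    (empty concentration field for censored samples)."""
    rows = []
    for p in profiles:
        for t, c, b in zip(p.times, p.concentrations, p.blq_flags):
            rows.append((p.subject_id, p.dose, t,
                         "" if (b or math.isnan(c)) else repr(float(c)),
                         str(bool(b)).lower()))
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)


def read_profiles(path: str | Path,
                  lloq: float | None = None) -> list[ConcentrationTimeProfile]:
    """Read and validate concentration-time profiles from CSV.

    Rows are sorted by time within subject.  Structural problems (missing
    columns, duplicate times, negative values) raise ProfileError with the
    offending CSV line numbers; a quantified value below ``lloq`` that is
    not flagged BLQ only warns (DataValidationWarning).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ProfileError(f"{path}: missing columns {sorted(missing)}")
    df = df.reset_index().rename(columns={"index": "_row"})
    df["_line"] = df["_row"] + 2  # header is line 1
    blq = df["blq"].map(lambda v: str(v).strip().lower() in ("true", "1", "yes"))
    conc = pd.to_numeric(df["conc_ng_ml"], errors="coerce")
    times = pd.to_numeric(df["time_h"], errors="coerce")
    bad = df.loc[times.isna() | (times < 0), "_line"].tolist()
    if bad:
        raise ProfileError(f"{path}: unparseable or negative time_h at "
                           f"lines {bad}")
    bad = df.loc[(conc < 0).fillna(False), "_line"].tolist()
    if bad:
        raise ProfileError(f"{path}: negative concentration at lines {bad}")
    if lloq is not None:
        susp = df.loc[(~blq) & (conc < lloq).fillna(False), "_line"].tolist()
        if susp:
            warnings.warn(
                f"{path}: quantified concentration below LLOQ {lloq:g} ng/mL "
                f"without BLQ flag at lines {susp}", DataValidationWarning,
                stacklevel=2)
    df["_t"], df["_c"], df["_b"] = times, conc, blq
    profiles = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("_t")
        if grp["_t"].duplicated().any():
            dup = grp.loc[grp["_t"].duplicated(), "_line"].tolist()
            raise ProfileError(f"{path}: duplicate times for subject {sid} "
                               f"at lines {dup}")
        doses = grp["dose_mg"].unique()
        if doses.size != 1:
            raise ProfileError(f"{path}: subject {sid} has multiple doses")
        profiles.append(ConcentrationTimeProfile(
            subject_id=str(sid), dose=float(doses[0]),
            times=tuple(grp["_t"].tolist()),
            concentrations=tuple(np.where(grp["_b"], np.nan,
                                          grp["_c"]).tolist()),
            blq_flags=tuple(bool(b) for b in grp["_b"])))
    return profiles


def write_batch(batch: CalibrationBatch, path: str | Path) -> None:
    """Write a calibration batch as a level_ng_ml,replicate,response runsheet."""
    batch.to_frame().to_csv(path, index=False)


def read_runsheet(path: str | Path) -> CalibrationBatch:
    """Read a calibration runsheet CSV into a batch (levels sorted ascending)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(RUNSHEET_COLUMNS) - set(df.columns)
    if missing:
        raise CalibrationError(f"{path}: missing columns {sorted(missing)}")
    levels = sorted(df["level_ng_ml"].unique())
    responses = [tuple(df.loc[df["level_ng_ml"] == lvl, "response"]
                       .astype(float).tolist()) for lvl in levels]
    return CalibrationBatch(levels=tuple(float(x) for x in levels),
                            responses=tuple(responses))


@dataclass(frozen=True)
class RunConfig:
    """Reproducible pipeline run: mode, paths, generative and analysis settings.

    mode is one of simulate, calibrate, validate, nca, full.  Every tunable
    defaults to the study conditions: seven standards 7.5-500 ng/mL,
    LLOQ 7.5 ng/mL, 100 mg dose on the 0-24 h schedule, 1/x weighting,
    80-120%/20% LOQ bounds and the +-15% stability rule.
    """

    mode: str = "full"
    input_path: str | None = None
    population: PopulationConfig = field(default_factory=PopulationConfig)
    calibration_levels: tuple[float, ...] = CALIBRATION_LEVELS
    calibration_replicates: int = 2
    calibration_noise_cv: float = 0.03
    qc_noise_cv: float = 0.01
    qc_replicates: int = 4
    qc_days: int = 3
    stability_noise_cv: float = 0.05
    stability_replicates: int = 4
    loq_replicates: int = 7
    loq_noise_cv: float = 0.05
    true_slope: float = REFERENCE_SLOPE
    true_intercept: float = REFERENCE_INTERCEPT
    weighting: str = "1/x"
    accuracy_bounds: tuple[float, float] = ACCURACY_BOUNDS
    rsd_max: float = RSD_MAX_PCT
    extrapolation_warn_pct: float = EXTRAPOLATION_WARN_PCT
    seed: int = 0

    _MODES = ("simulate", "calibrate", "validate", "nca", "full")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}")
        if self.mode == "nca" and not self.input_path:
            raise ValueError("nca mode requires input_path")
        _normalize_weighting(self.weighting)
        object.__setattr__(self, "calibration_levels",
                           tuple(float(x) for x in self.calibration_levels))
        object.__setattr__(self, "accuracy_bounds",
                           tuple(float(x) for x in self.accuracy_bounds))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["population"]["typical"] = dataclasses.asdict(self.population.typical)
        return _jsonable(d)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        pop = data.pop("population", None)
        if pop is not None:
            pop = dict(pop)
            typ = pop.pop("typical", None)
            if typ is not None:
                pop["typical"] = PKParameters(**typ)
            data["population"] = PopulationConfig(**pop)
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a YAML or JSON config (dispatch on extension)."""
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix.lower() == ".json"
                else yaml.safe_load(text))
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Stable hash of the full configuration, stamped into artifacts."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _derive_seed(seed: int, salt: str) -> int:
    """Independent, reproducible per-stage seed below 2^31."""
    h = hashlib.sha256(f"{seed}:{salt}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _results_frame(results: Sequence[NCAResult]) -> pd.DataFrame:
    cols = ["subject_id", "dose"] + list(NCA_PARAMETERS) + [
        "lambda_z_n_points", "lambda_z_r2_adj", "flags", "error"]
    rows = [{**{c: getattr(r, c) for c in cols if c not in ("flags", "error")},
             "flags": ";".join(r.flags), "error": r.error or ""}
            for r in results]
    return pd.DataFrame(rows, columns=cols)


def _stage_simulate(config: RunConfig, out: Path) -> list[ConcentrationTimeProfile]:
    pop = dataclasses.replace(config.population,
                              seed=_derive_seed(config.seed, "population"))
    profiles = simulate_population(pop)
    write_profiles(profiles, out / "profiles.csv")
    return profiles


def _stage_calibrate(config: RunConfig, out: Path) -> CalibrationFit:
    batch = simulate_calibration_batch(
        slope=config.true_slope, intercept=config.true_intercept,
        levels=config.calibration_levels,
        replicates=config.calibration_replicates,
        noise_cv=config.calibration_noise_cv,
        seed=_derive_seed(config.seed, "calibration"))
    write_batch(batch, out / "calibration_batch.csv")
    fit = fit_weighted_line(batch, config.weighting)
    std_check = check_standard_acceptance(fit, lloq=config.population.lloq)
    (out / "calibration_fit.json").write_text(json.dumps(_jsonable({
        "slope": fit.slope, "intercept": fit.intercept,
        "weighting": fit.weighting, "r_squared": fit.r_squared,
        "r_squared_unweighted": fit.r_squared_unweighted,
        "n_points": fit.n_points, "residual_pct": list(fit.residual_pct),
        "standards_accepted": std_check.passed,
        "standards_reasons": list(std_check.reasons),
    }), indent=2, sort_keys=True))
    logger.info("calibrate slope=%.6g intercept=%.6g r2=%.6f accepted=%s",
                fit.slope, fit.intercept, fit.r_squared, std_check.passed)
    return fit


def _stage_validate(config: RunConfig, fit: CalibrationFit,
                    out: Path) -> dict:
    """Synthetic validation batch: QC precision/accuracy per day plus pooled
    inter-day, LOQ acceptance, and stability -- reported in the layout of a
    validation table (detected conc., RSD%, accuracy% per level)."""
    rng = np.random.default_rng(_derive_seed(config.seed, "validation"))

    def _responses(nominal: float, cv: float, n: int) -> np.ndarray:
        # true measurement chain: responses off the true line, with noise
        # proportional to the analyte signal (SD = cv * slope * conc)
        mu = config.true_slope * nominal + config.true_intercept
        return mu + cv * config.true_slope * nominal * rng.standard_normal(n)

    rows, evaluations = [], {}
    for nominal in QC_LEVELS:
        per_day = []
        for day in range(1, config.qc_days + 1):
            resp = _responses(nominal, config.qc_noise_cv,
                              config.qc_replicates)
            per_day.append(resp)
            ev = evaluate_qc(fit, resp, nominal, scope=f"day-{day}")
            evaluations[(nominal, ev.scope)] = ev
            rows.append(ev)
        ev = evaluate_qc(fit, np.concatenate(per_day), nominal,
                         scope="inter-day")
        evaluations[(nominal, "inter-day")] = ev
        rows.append(ev)
    qc_df = pd.DataFrame([{
        "nominal_ng_ml": e.nominal, "scope": e.scope, "n": e.n,
        "detected_conc_ng_ml": e.detected_mean, "rsd_pct": e.rsd_pct,
        "accuracy_pct": e.accuracy_pct} for e in rows])
    qc_df.to_csv(out / "qc_report.csv", index=False)

    lloq = config.population.lloq
    loq_resp = _responses(lloq, config.loq_noise_cv, config.loq_replicates)
    loq_eval = evaluate_qc(fit, loq_resp, lloq, scope="loq")
    loq_check = check_loq_acceptance(loq_eval, config.accuracy_bounds,
                                     config.rsd_max)

    stab_results = []
    for nominal in QC_LEVELS:
        for condition in ("short-term", "post-treatment"):
            resp = _responses(nominal, config.stability_noise_cv,
                              config.stability_replicates)
            stab_results.append(assess_stability(
                back_calculate(fit, resp), nominal, condition))
    stab_df = pd.DataFrame([dataclasses.asdict(s) for s in stab_results])
    stab_df.to_csv(out / "stability_report.csv", index=False)

    lines = ["Validation report", "=" * 60,
             f"Calibration: slope {fit.slope:.4f}, intercept "
             f"{fit.intercept:.4f}, weighting {fit.weighting}, "
             f"r^2 {fit.r_squared:.5f}", "",
             "QC precision and accuracy",
             f"{'Nominal':>8} {'Scope':>10} {'n':>3} {'Dect.Conc.':>11} "
             f"{'RSD(%)':>7} {'Accu.(%)':>9}"]
    for e in rows:
        lines.append(f"{e.nominal:>8g} {e.scope:>10} {e.n:>3} "
                     f"{e.detected_mean:>11.2f} {e.rsd_pct:>7.2f} "
                     f"{e.accuracy_pct:>9.1f}")
    lines += ["", f"LOQ ({lloq:g} ng/mL, n={loq_eval.n}): accuracy "
              f"{loq_eval.accuracy_pct:.1f}%, RSD {loq_eval.rsd_pct:.1f}% "
              f"-> {'PASS' if loq_check.passed else 'FAIL'}"]
    lines += [f"  reason: {r}" for r in loq_check.reasons]
    lines += ["", "Stability (+-15% rule)"]
    for s in stab_results:
        lines.append(f"  {s.condition:>14} {s.nominal:>6g} ng/mL: "
                     f"{s.deviation_pct:+.1f}% -> "
                     f"{'PASS' if s.passed else 'FAIL'}")
    (out / "validation_report.txt").write_text("\n".join(lines) + "\n")
    return {"qc": evaluations, "loq_eval": loq_eval, "loq_check": loq_check,
            "stability": stab_results}


def _measure_through_assay(profiles: Sequence[ConcentrationTimeProfile],
                           true_slope: float, true_intercept: float,
                           fit: CalibrationFit,
                           lloq: float) -> list[ConcentrationTimeProfile]:
    """Map simulated true concentrations through the measurement chain:
    true line -> instrument response -> back-calculation through the fitted
    line -> re-censoring at the LLOQ."""
    measured = []
    for p in profiles:
        c = np.asarray(p.concentrations, float)
        quant = ~np.asarray(p.blq_flags) & ~np.isnan(c)
        resp = true_slope * c[quant] + true_intercept
        c_meas = c.copy()
        c_meas[quant] = np.maximum(back_calculate(fit, resp), 0.0)
        prof = dataclasses.replace(p, concentrations=tuple(c_meas.tolist()))
        measured.append(censor_blq(prof, lloq) if lloq > 0 else prof)
    return measured


def _stage_nca(config: RunConfig, profiles: Sequence[ConcentrationTimeProfile],
               out: Path) -> tuple[list[NCAResult], PopulationSummary]:
    results = [run_nca(p, extrapolation_warn_pct=config.extrapolation_warn_pct)
               for p in profiles]
    _results_frame(results).to_csv(out / "nca_results.csv", index=False)
    summary = summarize_population(results)
    summary.to_frame().to_csv(out / "population_summary.csv", index=False)
    (out / "population_summary.txt").write_text(format_summary(summary) + "\n")
    log = {"n_analyzed": summary.n,
           "excluded": list(summary.excluded),
           "subjects": [{"subject_id": r.subject_id,
                         "lambda_z_n_points": r.lambda_z_n_points,
                         "flags": list(r.flags), "error": r.error}
                        for r in results]}
    (out / "nca_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return results, summary


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute one reproducible run; returns a manifest of the artifacts.

    Mode ``full`` chains simulate -> calibrate (true concentrations mapped
    to responses and back through the fitted line) -> validate -> nca.
    Every run writes run_manifest.json stamped with the config hash and
    seed; identical configs give byte-identical artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"mode": config.mode, "seed": config.seed,
                      "config_hash": config.config_hash(), "artifacts": []}

    def _record(*names: str) -> None:
        manifest["artifacts"].extend(names)

    if config.mode == "simulate":
        _stage_simulate(config, out)
        _record("profiles.csv")
    elif config.mode == "calibrate":
        _stage_calibrate(config, out)
        _record("calibration_batch.csv", "calibration_fit.json")
    elif config.mode == "validate":
        fit = _stage_calibrate(config, out)
        _stage_validate(config, fit, out)
        _record("calibration_batch.csv", "calibration_fit.json",
                "qc_report.csv", "stability_report.csv",
                "validation_report.txt")
    elif config.mode == "nca":
        profiles = read_profiles(config.input_path, lloq=config.population.lloq)
        _, summary = _stage_nca(config, profiles, out)
        manifest["n_analyzed"] = summary.n
        manifest["excluded"] = list(summary.excluded)
        _record("nca_results.csv", "population_summary.csv",
                "population_summary.txt", "nca_log.json")
    else:  # full
        profiles = _stage_simulate(config, out)
        fit = _stage_calibrate(config, out)
        _stage_validate(config, fit, out)
        measured = _measure_through_assay(
            profiles, config.true_slope, config.true_intercept, fit,
            config.population.lloq)
        write_profiles(measured, out / "profiles_measured.csv")
        _, summary = _stage_nca(config, measured, out)
        manifest["n_analyzed"] = summary.n
        manifest["excluded"] = list(summary.excluded)
        _record("profiles.csv", "calibration_batch.csv",
                "calibration_fit.json", "qc_report.csv",
                "stability_report.csv", "validation_report.txt",
                "profiles_measured.csv", "nca_results.csv",
                "population_summary.csv", "population_summary.txt",
                "nca_log.json")

    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
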