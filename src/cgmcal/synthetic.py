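"""Synthetic CGM cohorts with a known sensor-error mechanism.

Emulates the structure of a small free-living type-1-diabetes study: a few
patients wearing a 5-minute-cadence CGM sensor plus a chest-band vitals
monitor, with sparse fingerstick references taken before meals and two hours
after.  The reference glucose trajectory is a mean-reverting random walk with
meal spikes; the sensor error is a configurable closed-form function of the
glucose range (per-cluster bias and gain), the seven wearable covariates, a
per-patient offset, and Gaussian noise — so every downstream stage can be
tested against recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .clustering import N_CLUSTERS, ClusterScheme, assign_cluster

COVARIATES = ["x2", "x3", "x4", "x5", "x6", "x7", "x8"]
COHORT_COLUMNS = ["patient_id", "timestamp", "g_m", "g_r"] + COVARIATES

#: start of the simulated wear period (arbitrary but fixed for determinism)
_EPOCH = pd.Timestamp("2023-01-01 00:00:00")
#: mean-reversion timescale of the glucose process, minutes
_GLUCOSE_TAU_MIN = 120.0
_GLUCOSE_LO, _GLUCOSE_HI = 40.0, 400.0
_G_M_FLOOR = 1.0


class CohortValidationError(ValueError):
    """A cohort config or readings table violates an invariant."""


class CohortParseError(ValueError):
    """A cohort CSV is malformed; carries the 1-based file line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


class CohortSchemaError(ValueError):
    """Required columns are missing from an input table."""

    def __init__(self, missing: Sequence[str]):
        self.missing = list(missing)
        super().__init__(f"missing required columns: {', '.join(self.missing)}")


@dataclass
class ErrorModelSpec:
    """Closed-form sensor-error mechanism.

    error = bias[c(g_r)] + slope[c(g_r)] * g_r + coeffs . (x2..x8)
            + patient_offset + noise

    where c(g_r) is the glucose cluster of the reference value.  All terms in
    mg/dL; slopes are dimensionless gains on reference glucose; coefficients
    are mg/dL per covariate unit.
    """

    per_cluster_bias: Sequence[float] = (12.0, 8.0, -7.0, 10.0, -12.0, -22.0)
    per_cluster_slope: Sequence[float] = (0.06, 0.04, 0.03, -0.04, 0.03, 0.05)
    covariate_coefficients: Sequence[float] = (1.0, 1.5, 0.03, 0.05, 0.2, 0.4, 0.005)
    noise_sd: float = 6.0
    patient_offset_sd: float = 5.0

    def __post_init__(self) -> None:
        if len(self.per_cluster_bias) != N_CLUSTERS:
            raise CohortValidationError("per_cluster_bias: expected 6 values")
        if len(self.per_cluster_slope) != N_CLUSTERS:
            raise CohortValidationError("per_cluster_slope: expected 6 values")
        if len(self.covariate_coefficients) != len(COVARIATES):
            raise CohortValidationError("covariate_coefficients: expected 7 values")
        if self.noise_sd < 0:
            raise CohortValidationError("noise_sd: must be >= 0")
        if self.patient_offset_sd < 0:
            raise CohortValidationError("patient_offset_sd: must be >= 0")

    def systematic_error(self, g_r, covariates, scheme: ClusterScheme | None = None):
        """Deterministic part of the error (no noise, no patient offset)."""
        g_r = np.asarray(g_r, dtype=float)
        cov = np.asarray(covariates, dtype=float)
        cluster = assign_cluster(g_r, scheme or ClusterScheme())
        bias = np.asarray(self.per_cluster_bias)[cluster]
        gain = np.asarray(self.per_cluster_slope)[cluster] * g_r
        covterm = cov @ np.asarray(self.covariate_coefficients)
        return bias + gain + covterm

    @classmethod
    def zero(cls) -> "ErrorModelSpec":
        """An error-free sensor: g_m == g_r everywhere."""
        return cls(
            per_cluster_bias=(0.0,) * 6,
            per_cluster_slope=(0.0,) * 6,
            covariate_coefficients=(0.0,) * 7,
            noise_sd=0.0,
            patient_offset_sd=0.0,
        )


@dataclass
class GlucoseProcess:
    """Reference-glucose trajectory parameters (mg/dL, minutes)."""

    mean: float = 150.0
    variability: float = 55.0
    spike_amplitude: float = 80.0
    spike_decay_minutes: float = 90.0

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise CohortValidationError("glucose_process.mean: must be > 0")
        if self.variability < 0:
            raise CohortValidationError("glucose_process.variability: must be >= 0")
        if self.spike_decay_minutes <= 0:
            raise CohortValidationError("glucose_process.spike_decay_minutes: must be > 0")


@dataclass
class CohortConfig:
    """Study-design knobs for a synthetic cohort."""

    n_patients: int = 9
    duration_days: int = 14
    cgm_interval: int = 5
    references_per_day: int = 6
    glucose_process: GlucoseProcess = field(default_factory=GlucoseProcess)
    error_model: ErrorModelSpec = field(default_factory=ErrorModelSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise CohortValidationError("n_patients: must be >= 1")
        if self.duration_days < 1:
            raise CohortValidationError("duration_days: must be >= 1")
        if self.cgm_interval <= 0:
            raise CohortValidationError("cgm_interval: must be > 0 minutes")
        if self.references_per_day < 1:
            raise CohortValidationError("references_per_day: must be >= 1")


class GeneratedCohort(NamedTuple):
    readings: pd.DataFrame  #: COHORT_COLUMNS
    truth: pd.DataFrame  #: per-reading error decomposition


class PairingResult(NamedTuple):
    readings: pd.DataFrame
    n_dropped: int


def _simulate_patient(cfg: CohortConfig, rng: np.random.Generator):
    """One patient's CGM grid: reference glucose + covariate series + meals."""
    n_steps = int(cfg.duration_days * 24 * 60 / cfg.cgm_interval)
    t_min = np.arange(n_steps) * float(cfg.cgm_interval)
    gp = cfg.glucose_process

    # OU baseline around the patient mean
    a = np.exp(-cfg.cgm_interval / _GLUCOSE_TAU_MIN)
    innov_sd = gp.variability * np.sqrt(max(1.0 - a * a, 0.0))
    base = np.empty(n_steps)
    base[0] = gp.mean + gp.variability * rng.standard_normal()
    shocks = rng.standard_normal(n_steps)
    for i in range(1, n_steps):
        base[i] = gp.mean + a * (base[i - 1] - gp.mean) + innov_sd * shocks[i]

    # meals: ~3/day at breakfast/lunch/dinner windows, jittered
    meal_anchor = np.array([8.0, 12.5, 19.0])  # hours
    meal_times = []
    meal_cal = []
    for day in range(cfg.duration_days):
        hours = meal_anchor + rng.uniform(-1.0, 1.0, size=3)
        for h in hours:
            meal_times.append((day * 24 + h) * 60.0)
            meal_cal.append(rng.uniform(200.0, 1200.0))
    meal_times = np.asarray(meal_times)
    meal_cal = np.asarray(meal_cal)

    spike = np.zeros(n_steps)
    for mt in meal_times:
        dt = t_min - mt
        mask = dt >= 0
        spike[mask] += gp.spike_amplitude * np.exp(-dt[mask] / gp.spike_decay_minutes)
    g_r = np.clip(base + spike, _GLUCOSE_LO, _GLUCOSE_HI)

    def ar1(lo, hi, tau_steps, n=n_steps):
        mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        rho = np.exp(-1.0 / tau_steps)
        x = np.empty(n)
        x[0] = rng.uniform(lo, hi)
        eps = rng.standard_normal(n) * half * 0.3 * np.sqrt(1 - rho * rho)
        for i in range(1, n):
            x[i] = mid + rho * (x[i - 1] - mid) + eps[i]
        return np.clip(x, lo, hi)

    cov = pd.DataFrame(
        {
            "x2": np.abs(ar1(-0.5, 2.0, 12.0)),  # physical activity, g
            "x3": np.abs(ar1(-0.5, 3.0, 6.0)),  # peak acceleration, g
            "x4": ar1(-90.0, 90.0, 24.0),  # posture, degrees
            "x5": ar1(50.0, 160.0, 36.0),  # heart rate, BPM
            "x6": ar1(8.0, 30.0, 36.0),  # breath rate, BPM
            "x7": ar1(30.0, 38.0, 72.0),  # skin temperature, degC
        }
    )
    # food intake: calories logged at the CGM step nearest each meal, else 0
    x8 = np.zeros(n_steps)
    meal_idx = np.clip(np.round(meal_times / cfg.cgm_interval).astype(int), 0, n_steps - 1)
    x8[meal_idx] += meal_cal
    cov["x8"] = x8
    # heart/breath rate must stay positive after clipping
    cov["x5"] = cov["x5"].clip(lower=40.0)
    cov["x6"] = cov["x6"].clip(lower=6.0)

    # fingerstick times: one before each meal and one 2 h after, snapped to
    # the CGM grid, truncated/padded to references_per_day per day
    ref_idx = []
    per_day = cfg.references_per_day
    steps_per_day = int(24 * 60 / cfg.cgm_interval)
    for day in range(cfg.duration_days):
        day_meals = meal_times[(meal_times >= day * 24 * 60) & (meal_times < (day + 1) * 24 * 60)]
        cand = np.concatenate([day_meals - 10.0, day_meals + 120.0])
        cand.sort()
        idx = np.clip(np.round(cand / cfg.cgm_interval).astype(int), 0, n_steps - 1)
        while len(idx) < per_day:  # dense sampling regimes: add random extras
            extra = day * steps_per_day + rng.integers(0, steps_per_day)
            idx = np.append(idx, min(int(extra), n_steps - 1))
        idx = np.unique(idx)[:per_day]
        ref_idx.extend(idx.tolist())
    ref_idx = np.unique(np.asarray(ref_idx, dtype=int))

    return t_min, g_r, cov, ref_idx


def generate_cohort(config: CohortConfig) -> GeneratedCohort:
    """Simulate a cohort of paired CGM/reference readings.

    Returns the readings table (``COHORT_COLUMNS``) together with a ``truth``
    table decomposing each reading's sensor error into its systematic,
    patient-offset and noise parts.  Identical config + seed yields a
    bit-identical cohort.
    """
    if not isinstance(config, CohortConfig):
        raise CohortValidationError("config: expected a CohortConfig")
    scheme = ClusterScheme()
    em = config.error_model
    rows = []
    truth_rows = []
    root = np.random.SeedSequence([int(config.seed), 0xC61])
    patient_seeds = root.spawn(config.n_patients)
    for p in range(config.n_patients):
        rng = np.random.default_rng(patient_seeds[p])
        patient_id = f"patient_{p + 1:03d}"
        t_min, g_r, cov, ref_idx = _simulate_patient(config, rng)
        offset = em.patient_offset_sd * rng.standard_normal()
        g_r_ref = g_r[ref_idx]
        cov_ref = cov.iloc[ref_idx].to_numpy()
        systematic = em.systematic_error(g_r_ref, cov_ref, scheme)
        noise = em.noise_sd * rng.standard_normal(len(ref_idx))
        g_m = g_r_ref + systematic + offset + noise
        g_m = np.maximum(g_m, _G_M_FLOOR)
        err = g_m - g_r_ref  # equals systematic+offset+noise unless floored
        ts = _EPOCH + pd.to_timedelta(t_min[ref_idx], unit="m")
        frame = pd.DataFrame(
            {
                "patient_id": patient_id,
                "timestamp": ts,
                "g_m": g_m,
                "g_r": g_r_ref,
            }
        )
        frame[COVARIATES] = cov.iloc[ref_idx].reset_index(drop=True)
        rows.append(frame)
        truth_rows.append(
            pd.DataFrame(
                {
                    "patient_id": patient_id,
                    "timestamp": ts,
                    "cluster": assign_cluster(g_r_ref, scheme),
                    "systematic_error": systematic,
                    "patient_offset": offset,
                    "noise": noise,
                    "true_error": err,
                }
            )
        )
    readings = pd.concat(rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    order = readings.sort_values(["patient_id", "timestamp"]).index
    readings = readings.loc[order].reset_index(drop=True)
    truth = truth.loc[order].reset_index(drop=True)
    validate_readings(readings)
    return GeneratedCohort(readings, truth)


def validate_readings(readings: pd.DataFrame) -> None:
    """Check the paired-readings invariants; raise naming the bad column."""
    missing = [c for c in COHORT_COLUMNS if c not in readings.columns]
    if missing:
        raise CohortSchemaError(missing)
    if len(readings) == 0:
        return
    for col in ["g_m", "g_r"]:
        vals = readings[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or not np.all(vals > 0):
            raise CohortValidationError(f"{col}: values must be finite and > 0")
    for col in COVARIATES:
        vals = readings[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise CohortValidationError(f"{col}: values must be finite")
    for col in ["x5", "x6"]:
        if not np.all(readings[col].to_numpy(dtype=float) > 0):
            raise CohortValidationError(f"{col}: values must be > 0")


def pair_and_merge(
    cgm_table: pd.DataFrame,
    reference_table: pd.DataFrame,
    covariate_table: pd.DataFrame,
    tolerance: float = 5.0,
) -> PairingResult:
    """Time-align sparse reference readings with CGM and covariate rows.

    Each reference reading is matched to the nearest CGM reading and nearest
    covariate row of the same patient within ``tolerance`` minutes;
    references without both matches are dropped and counted.  Output is
    sorted by patient then time, so the result is invariant to input row
    order.
    """
    if tolerance < 0:
        raise CohortValidationError("tolerance: must be >= 0 minutes")
    for table, req in (
        (cgm_table, ["patient_id", "timestamp", "g_m"]),
        (reference_table, ["patient_id", "timestamp", "g_r"]),
        (covariate_table, ["patient_id", "timestamp"] + COVARIATES),
    ):
        missing = [c for c in req if c not in table.columns]
        if missing:
            raise CohortSchemaError(missing)

    tol = pd.Timedelta(minutes=tolerance)

    def prep(df):
        out = df.copy()
        out["timestamp"] = pd.to_datetime(out["timestamp"])
        return out.sort_values("timestamp", kind="stable").reset_index(drop=True)

    refs = prep(reference_table)
    merged = pd.merge_asof(
        refs,
        prep(cgm_table)[["patient_id", "timestamp", "g_m"]],
        on="timestamp",
        by="patient_id",
        direction="nearest",
        tolerance=tol,
    )
    merged = pd.merge_asof(
        merged,
        prep(covariate_table)[["patient_id", "timestamp"] + COVARIATES],
        on="timestamp",
        by="patient_id",
        direction="nearest",
        tolerance=tol,
    )
    matched = merged.dropna(subset=["g_m"] + COVARIATES)
    n_dropped = len(merged) - len(matched)
    out = matched[COHORT_COLUMNS].sort_values(["patient_id", "timestamp"], kind="stable")
    return PairingResult(out.reset_index(drop=True), int(n_dropped))


def write_cohort(readings: pd.DataFrame, path) -> None:
    """Write a cohort CSV: fixed column order, ISO-8601 timestamps."""
    validate_readings(readings)
    out = readings[COHORT_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`.

    A header-only file yields an empty table.  Malformed numeric fields or
    invariant violations raise :class:`CohortParseError` citing the 1-based
    line number (header is line 1).  An optional ordinal ``food_quality``
    column (0/1/2) is tolerated and carried through.
    """
    try:
        raw = pd.read_csv(path, dtype=str, skip_blank_lines=False)
    except pd.errors.EmptyDataError:
        raise CohortParseError("file has no header row")
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortSchemaError(missing)
    if len(raw) == 0:
        empty = pd.DataFrame({c: pd.Series(dtype=float) for c in COHORT_COLUMNS})
        empty["patient_id"] = pd.Series(dtype=str)
        empty["timestamp"] = pd.Series(dtype="datetime64[ns]")
        return empty[COHORT_COLUMNS]

    out = pd.DataFrame({"patient_id": raw["patient_id"].astype(str)})
    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    if ts.isna().any():
        line = int(ts.index[ts.isna()][0]) + 2
        raise CohortParseError(f"unparseable timestamp {raw['timestamp'][line - 2]!r}", line)
    out["timestamp"] = ts
    numeric_cols = ["g_m", "g_r"] + COVARIATES
    if "food_quality" in raw.columns:
        numeric_cols = numeric_cols + ["food_quality"]
    for col in numeric_cols:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna()
        if bad.any() or vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 2
            raise CohortParseError(f"non-numeric value {raw[col][line - 2]!r} in column {col}", line)
        out[col] = vals.astype(float)
    try:
        validate_readings(out)
    except CohortValidationError as exc:
        raise CohortParseError(str(exc)) from exc
    return out


#: column-name fragments mapped to covariate slots for wearable summary files
_SUMMARY_MAP = [
    ("x5", ("heartrate", "hr")),
    ("x6", ("breathingrate", "breathrate", "br")),
    ("x7", ("temp",)),
    ("x4", ("posture",)),
    ("x2", ("activity",)),
    ("x3", ("peakaccel",)),
]


def read_summary_csv(path) -> pd.DataFrame:
    """Best-effort reader for a wearable ``Summary.csv`` covariate table.

    Maps, by case-insensitive column-name match, HeartRate→x5,
    BreathingRate→x6, Temp→x7, Posture→x4, Activity→x2, PeakAccel→x3.
    Missing channels are absent from the output; a Time/Timestamp column
    becomes ``timestamp``.
    """
    raw = pd.read_csv(path)
    norm = {c.lower().replace(" ", "").replace("_", ""): c for c in raw.columns}
    out = pd.DataFrame(index=raw.index)
    for tcol in ("timestamp", "time", "datetime"):
        if tcol in norm:
            out["timestamp"] = pd.to_datetime(raw[norm[tcol]])
            break
    for slot, keys in _SUMMARY_MAP:
        for key in keys:
            hit = next((norm[k] for k in norm if k == key or k.startswith(key)), None)
            if hit is not None:
                out[slot] = pd.to_numeric(raw[hit], errors="coerce")
                break
    return out
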