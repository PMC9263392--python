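"""Seeded synthetic EEG cohort generator with outcome-linked coupling.

The generator emulates the structure the prognostic analysis assumes rather
than any biophysical mechanism: every channel is a convex mixture of a
shared band-limited AR(2) latent source ``z`` (spectral peak in the alpha
band) and channel-private AR(2) noise,

    x_c(t) = w_c * z(t) + (1 - w_c) * eps_c(t),

with both components standardized, so ``w_c`` directly controls pairwise
synchrony.  All channels use the resting mixing weight ``coupling_base``
except the central and prefrontal channels of the unaffected hemisphere
(Cu, FPu) under pain stimulation of the unaffected side, whose weight is a
per-patient *knob*.  Because C-ApEn responds monotonically to the mixing
weight (established empirically by :func:`calibrate_knob`, not assumed),
the knob can be chosen through the calibrated inverse map so that a patient
realizes a prescribed target value of the pain-minus-rest difference
statistic D.  Recovery phenotypes differ only through their target-D
distribution; under closed eyes the two phenotypes are generatively
identical.

All randomness derives from integer seed lists fed to numpy's
``default_rng`` (``[seed, patient_index, condition_index]`` for signals,
``[seed, 10**6]`` for demographics, ``[seed, 10**6 + 1, grid_index, rep]``
for calibration), so any stage can be replayed in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .capen import CApEnParams, epoch_capen
from .errors import CalibrationError, ConfigError
from .montage import CANONICAL_LABELS, CONDITIONS, EEGRecording, MontageMap


def ar2_coeffs(peak_hz: float, rho: float, fs: float) -> tuple[float, float]:
    """AR(2) coefficients with complex poles at radius *rho* and frequency *peak_hz*."""
    theta = 2.0 * np.pi * peak_hz / fs
    return 2.0 * rho * np.cos(theta), -(rho**2)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Cohort sizes mirror the historical-control design (50 control, 35 tDCS);
    improvement rates per group mirror the observed 22.0% / 37.1%; target-D
    distributions straddle the 0.07 decision cutoff (recoverers 0.12 +/- 0.02,
    non-recoverers 0.00 +/- 0.02).  Signal-level settings (128 Hz, 64 s per
    condition, alpha-peaked AR(2) background) are generator choices, since no
    recording parameters are prescribed by the analysis itself.
    """

    n_control: int = 50
    n_tdcs: int = 35
    fs: float = 128.0
    duration_s: float = 64.0
    ar_peak_hz: float = 10.0
    latent_rho: float = 0.9
    noise_rho: float = 0.3
    coupling_base: float = 0.88
    knob_bounds: tuple[float, float] = (0.60, 0.97)
    d_targets: dict = field(
        default_factory=lambda: {
            "recoverer": (0.12, 0.02),
            "non_recoverer": (0.00, 0.02),
        }
    )
    improvement_rates: dict = field(
        default_factory=lambda: {"control": 0.22, "tDCS": 0.371}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling_base <= 1.0:
            raise ConfigError(f"coupling_base must be in [0,1], got {self.coupling_base}")
        lo, hi = self.knob_bounds
        if not 0.0 <= lo < hi <= 1.0:
            raise ConfigError(f"knob_bounds must satisfy 0 <= lo < hi <= 1, got {self.knob_bounds}")
        if self.duration_s * self.fs < 1024:
            raise ConfigError("duration_s * fs must cover at least one analysis epoch")
        rec_mean = self.d_targets["recoverer"][0]
        non_mean = self.d_targets["non_recoverer"][0]
        if not rec_mean > 0.07 > non_mean:
            raise ConfigError(
                f"d_targets must straddle the 0.07 cutoff (recoverer {rec_mean}, "
                f"non-recoverer {non_mean})"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


_COND_INDEX = {c: i for i, c in enumerate(CONDITIONS)}


def _ar2(rng: np.random.Generator, n: int, a1: float, a2: float, burn: int = 512) -> np.ndarray:
    white = rng.standard_normal(n + burn)
    x = sps.lfilter([1.0], [1.0, -a1, -a2], white)[burn:]
    return (x - x.mean()) / x.std()


def _mix(z: np.ndarray, eps: np.ndarray, w: float) -> np.ndarray:
    return w * z + (1.0 - w) * eps


def gen_recording(
    config: CohortConfig,
    condition: str,
    seed_key: tuple[int, ...],
    affected_side: str = "left",
    pain_knob: float | None = None,
    patient_id: str = "",
) -> EEGRecording:
    """Generate one condition's 16-channel recording.

    ``pain_knob`` replaces ``coupling_base`` on the Cu/FPu channels when
    ``condition == 'pain_unaffected'``; elsewhere (and for every other
    channel) the resting weight applies.  Deterministic given ``seed_key``.
    """
    if condition not in CONDITIONS:
        raise ConfigError(f"unknown condition {condition!r}")
    knob = config.coupling_base if pain_knob is None else float(pain_knob)
    if not 0.0 <= knob <= 1.0:
        raise ConfigError(f"mixing weight must be in [0,1], got {knob}")
    rng = np.random.default_rng(list(seed_key))
    n = config.n_samples
    za1, za2 = ar2_coeffs(config.ar_peak_hz, config.latent_rho, config.fs)
    ea1, ea2 = ar2_coeffs(config.ar_peak_hz, config.noise_rho, config.fs)
    z = _ar2(rng, n, za1, za2)
    montage = MontageMap(affected_side)
    special = {montage.physical("Cu"), montage.physical("FPu")}
    rows = np.empty((16, n))
    for i, lbl in enumerate(CANONICAL_LABELS):
        eps = _ar2(rng, n, ea1, ea2)
        w = knob if (condition == "pain_unaffected" and lbl in special) else config.coupling_base
        rows[i] = _mix(z, eps, w)
    return EEGRecording(
        signal=rows,
        fs=config.fs,
        channel_labels=CANONICAL_LABELS,
        condition=condition,
        patient_id=patient_id,
    )


def _pair_signals(
    config: CohortConfig, w: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two channels sharing the latent source with weight *w* (calibration helper)."""
    za1, za2 = ar2_coeffs(config.ar_peak_hz, config.latent_rho, config.fs)
    ea1, ea2 = ar2_coeffs(config.ar_peak_hz, config.noise_rho, config.fs)
    z = _ar2(rng, n, za1, za2)
    return _mix(z, _ar2(rng, n, ea1, ea2), w), _mix(z, _ar2(rng, n, ea1, ea2), w)


@dataclass(frozen=True)
class KnobCalibration:
    """Empirical monotone map between mixing weight and expected Cu-FPu C-ApEn."""

    knobs: np.ndarray
    capen_means: np.ndarray
    capen_sems: np.ndarray
    increasing: bool

    def capen_at(self, knob: float | np.ndarray) -> np.ndarray:
        return np.interp(knob, self.knobs, self.capen_means)

    def knob_at(self, capen_value: float | np.ndarray) -> np.ndarray:
        """Inverse map; raises :class:`ConfigError` outside the calibrated range."""
        y = self.capen_means if self.increasing else self.capen_means[::-1]
        x = self.knobs if self.increasing else self.knobs[::-1]
        v = np.atleast_1d(np.asarray(capen_value, dtype=float))
        lo, hi = y.min(), y.max()
        if np.any(v < lo - 1e-12) or np.any(v > hi + 1e-12):
            raise ConfigError(
                f"target C-ApEn outside calibrated range [{lo:.4f}, {hi:.4f}]"
            )
        out = np.interp(v, y, x)
        return out if np.ndim(capen_value) else float(out[0])


def calibrate_knob(
    config: CohortConfig,
    knob_grid: np.ndarray | None = None,
    n_reps: int = 16,
    params: CApEnParams = CApEnParams(),
    epochs_per_rep: int = 3,
) -> KnobCalibration:
    """Map the mixing knob to the expected Cu-FPu C-ApEn by simulation.

    For each grid value, ``n_reps`` independent two-channel pair recordings
    are generated and their epoch-mean C-ApEn averaged.  The empirical curve
    must be strictly monotone (in either direction); otherwise the grid or
    replication is insufficient and a :class:`CalibrationError` is raised.
    """
    if knob_grid is None:
        knob_grid = np.linspace(config.knob_bounds[0], config.knob_bounds[1], 9)
    knob_grid = np.asarray(knob_grid, dtype=float)
    if knob_grid.size < 5:
        raise ConfigError("knob grid needs at least 5 points")
    n = params.epoch_len * epochs_per_rep
    means = np.empty(knob_grid.size)
    sems = np.empty(knob_grid.size)
    for gi, w in enumerate(knob_grid):
        vals = []
        for rep in range(n_reps):
            rng = np.random.default_rng([config.seed, 10**6 + 1, gi, rep])
            u, v = _pair_signals(config, float(w), n, rng)
            vals.append(epoch_capen(u, v, params)[0])
        means[gi] = np.mean(vals)
        sems[gi] = np.std(vals, ddof=1) / np.sqrt(len(vals))
    diffs = np.diff(means)
    if np.all(diffs > 0):
        increasing = True
    elif np.all(diffs < 0):
        increasing = False
    else:
        raise CalibrationError(
            "empirical knob -> C-ApEn curve is not strictly monotone; "
            "increase n_reps or coarsen the grid "
            f"(means: {np.array2string(means, precision=4)})"
        )
    return KnobCalibration(knob_grid, means, sems, increasing)


def gen_cohort_table(config: CohortConfig, calibration: KnobCalibration) -> pd.DataFrame:
    """Assign phenotypes, demographics, target D and calibrated knobs.

    Per-group recoverer counts are the rounded Table-3-style improvement
    rates (11/50 and 13/35 at the defaults), so cohort-level rates are exact
    by construction.  Demographics are sampled to plausible marginals (age
    ~ N(47, 14) truncated to [17, 83]; 72% male; 68% traumatic brain injury;
    duration log-normal with median 121 days; CRS-R ~ N(7.7, 1.3) clipped to
    [3, 12]) — sanity scaffolding, not an analysis target.
    """
    rng = np.random.default_rng([config.seed, 10**6])
    rows = []
    d_lo = calibration.capen_means.min() - calibration.capen_at(config.coupling_base)
    d_hi = calibration.capen_means.max() - calibration.capen_at(config.coupling_base)
    idx = 0
    for group, n_group in (("control", config.n_control), ("tDCS", config.n_tdcs)):
        n_rec = int(round(config.improvement_rates[group] * n_group))
        phenotypes = np.array(["recoverer"] * n_rec + ["non_recoverer"] * (n_group - n_rec))
        rng.shuffle(phenotypes)
        for ph in phenotypes:
            mean, sd = config.d_targets[ph]
            d_target = float(np.clip(rng.normal(mean, sd), d_lo + 1e-6, d_hi - 1e-6))
            if not d_lo <= d_target <= d_hi:
                raise ConfigError(f"target D {d_target} outside calibrated range")
            age = float(np.clip(rng.normal(47.0, 14.0), 17.0, 83.0))
            duration = float(np.clip(np.exp(rng.normal(np.log(121.0), 0.45)), 60.0, 298.0))
            mgos = int(rng.integers(3, 7) if ph == "recoverer" else rng.integers(1, 3))
            rows.append(
                {
                    "patient_id": f"P{idx:03d}",
                    "age": round(age, 1),
                    "sex": "male" if rng.random() < 0.72 else "female",
                    "lesion": "TBI" if rng.random() < 0.68 else "hemorrhage",
                    "duration_days": round(duration, 0),
                    "crsr": int(np.clip(round(rng.normal(7.7, 1.3)), 3, 12)),
                    "group": group,
                    "mgos": mgos,
                    "affected_side": "left" if rng.random() < 0.5 else "right",
                    "phenotype": ph,
                    "d_target": d_target,
                    "pain_knob": float(
                        calibration.knob_at(calibration.capen_at(config.coupling_base) + d_target)
                    ),
                }
            )
            idx += 1
    df = pd.DataFrame(rows)
    df["improved"] = df["mgos"] >= 3
    return df


def gen_patient_recordings(
    config: CohortConfig, row: pd.Series | dict
) -> dict[str, EEGRecording]:
    """All three condition recordings for one cohort-table row."""
    pidx = int(str(row["patient_id"]).lstrip("P"))
    return {
        cond: gen_recording(
            config,
            cond,
            (config.seed, pidx, _COND_INDEX[cond]),
            affected_side=row["affected_side"],
            pain_knob=row["pain_knob"],
            patient_id=row["patient_id"],
        )
        for cond in CONDITIONS
    }


#: Ground-truth coefficients for the regression-recovery cohort, on the scale
#: of the outcome model (intercept plus eight C-ApEn cells and four clinical
#: covariates; the Cu-FPu cell carries the dominant positive weight).
REGRESSION_TRUTH: dict[str, float] = {
    "(Constant)": 2.302,
    "Ca-Fa@pain_affected": 3.551,
    "Ca-FPa@pain_affected": 8.332,
    "Ca-Oa@pain_affected": -4.366,
    "Cu-Fu@pain_unaffected": -4.872,
    "Cu-Pu@pain_unaffected": -5.318,
    "Cu-MTu@pain_unaffected": 3.735,
    "Cu-FPu@pain_unaffected": 11.492,
    "Cu-Ou@pain_unaffected": 3.925,
    "sex": 0.205,
    "age": -0.001,
    "duration": -0.003,
    "lesion": -0.084,
}


def gen_regression_cohort(
    n: int, seed: int, noise_sd: float = 0.3
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Design matrix from a known linear model, for parameter-recovery checks.

    C-ApEn predictors are correlated Gaussians (pairwise correlation 0.5,
    mean 1.2, SD 0.05 — the scale of epoch-mean C-ApEn values, which is what
    makes coefficients like 11.5 plausible); clinical covariates mimic the
    cohort marginals.  The outcome is the linear predictor under
    :data:`REGRESSION_TRUTH` plus N(0, ``noise_sd``) noise.

    Returns ``(design frame including 'mgos' outcome, truth dict)``.
    """
    rng = np.random.default_rng([seed, 10**6 + 2])
    capen_names = [k for k in REGRESSION_TRUTH if "@" in k]
    k = len(capen_names)
    cov = 0.0025 * (0.5 * np.ones((k, k)) + 0.5 * np.eye(k))
    capen_vals = rng.multivariate_normal(np.full(k, 1.2), cov, size=n)
    design = pd.DataFrame(capen_vals, columns=capen_names)
    design["sex"] = (rng.random(n) < 0.28).astype(float)
    design["age"] = np.clip(rng.normal(47.0, 14.0, n), 17, 83)
    design["duration"] = np.clip(np.exp(rng.normal(np.log(121.0), 0.45, n)), 60, 298)
    design["lesion"] = (rng.random(n) < 0.32).astype(float)
    eta = REGRESSION_TRUTH["(Constant)"] + sum(
        REGRESSION_TRUTH[c] * design[c] for c in design.columns
    )
    design["mgos"] = eta + rng.normal(0.0, noise_sd, n)
    return design, dict(REGRESSION_TRUTH)


def gen_cohort(
    config: CohortConfig, calibration: KnobCalibration | None = None
) -> tuple[pd.DataFrame, KnobCalibration]:
    """Calibrate (unless given) and build the cohort table.

    Recordings are intentionally not materialized here — they total hundreds
    of megabytes at the default sizes; use :func:`gen_patient_recordings`
    per patient, or the pipeline's simulate stage to put them on disk.
    """
    if calibration is None:
        calibration = calibrate_knob(config)
    return gen_cohort_table(config, calibration), calibration
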