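"""Synthetic cohorts: correlated constructs, regional kinetic truths, TACs.

The generator draws latent constructs (age, sex, BMI, striatal transporter
availability, astrocyte marker level, log lesion volume, general cognition)
from a multivariate normal with a calibrated correlation matrix, then maps
latents to per-region kinetic ground truths, log-normal lesion volumes and
cognitive test scores, and finally simulates framewise TACs for both
tracers so the whole estimation chain can be exercised without any data
download.

Regional truths are built as ``construct latent + sum-to-zero residuals``:
the equal-weight regional composite then recovers the construct latent
exactly while the inter-regional correlations match their calibration
targets. This keeps the measured-composite correlation structure equal to
the latent structure in the noise-free limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import FrameSchedule, TimeActivityCurve, ded_schedule, pe2i_schedule
from .kinetics import running_integral

__all__ = [
    "DegenerateShapeError",
    "ReferenceShape",
    "RegionalKineticTruth",
    "CognitiveTestSpec",
    "CohortSpec",
    "Cohort",
    "CONSTRUCTS",
    "DEFAULT_TEST_BATTERY",
    "DEFAULT_DOMAIN_MAP",
    "MAOB_PCA_REGIONS",
    "default_construct_correlations",
    "nearest_correlation",
    "make_reference_tac",
    "simulate_reversible_tac",
    "simulate_irreversible_tac",
    "add_frame_noise",
    "generate_cohort",
    "lognormal_params",
]


class DegenerateShapeError(ValueError):
    """Reference-curve rate constants coincide; the shape is degenerate."""


# --------------------------------------------------------------------------
# reference input curve
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceShape:
    """Two-exponential-difference reference curve, analytic integral.

    ``C(t) = amplitude * (exp(-lam1 t) - exp(-lam2 t))`` with
    ``lam2 > lam1 > 0`` (rates in 1/min); positive for t > 0 and peaking at
    ``ln(lam2/lam1)/(lam2 - lam1)``.
    """

    amplitude: float = 100.0
    lam1: float = 0.05
    lam2: float = 1.0

    def __post_init__(self) -> None:
        if self.lam1 <= 0 or self.lam2 <= 0:
            raise ValueError("rate constants must be positive")
        if math.isclose(self.lam1, self.lam2, rel_tol=1e-9, abs_tol=1e-12):
            raise DegenerateShapeError("rate constants must be distinct")
        if self.lam2 < self.lam1:
            raise ValueError("lam2 must exceed lam1 (fast wash-in)")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    def value(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        return self.amplitude * (np.exp(-self.lam1 * t) - np.exp(-self.lam2 * t))

    def integral(self, t_min) -> np.ndarray:
        """Closed-form running integral from 0 to t (kBq*min/ml)."""
        t = np.asarray(t_min, dtype=float)
        return self.amplitude * (
            (1.0 - np.exp(-self.lam1 * t)) / self.lam1
            - (1.0 - np.exp(-self.lam2 * t)) / self.lam2
        )

    @property
    def peak_time_min(self) -> float:
        return math.log(self.lam2 / self.lam1) / (self.lam2 - self.lam1)


def make_reference_tac(
    schedule: FrameSchedule, shape: ReferenceShape, region: str = "cerebellum"
) -> TimeActivityCurve:
    """Evaluate a reference shape at the schedule's frame midpoints."""
    return TimeActivityCurve(schedule, shape.value(schedule.midpoints_min), region)


# --------------------------------------------------------------------------
# kinetic truths and forward models
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionalKineticTruth:
    """Ground-truth simulator parameters for one region of one subject.

    Reversible-tracer fields: ``r1`` (delivery ratio), ``k2`` (reference
    efflux, 1/min), ``bp_nd`` (binding potential). Irreversible-tracer
    fields: ``ki`` (uptake rate, 1/min) and ``v0`` (distribution term).
    Unused fields may stay at None.
    """

    r1: float | None = None
    k2: float | None = None
    bp_nd: float | None = None
    ki: float | None = None
    v0: float | None = None

    def __post_init__(self) -> None:
        if self.k2 is not None and self.k2 <= 0:
            raise ValueError("k2 must be > 0")
        if self.bp_nd is not None and self.bp_nd < 0:
            raise ValueError("bp_nd must be >= 0")
        if self.ki is not None and self.ki < 0:
            raise ValueError("ki must be >= 0")


def _fine_grid(schedule: FrameSchedule, dt_min: float) -> np.ndarray:
    end = schedule.bounds_min[-1]
    n = int(round(end / dt_min))
    return np.linspace(0.0, end, n + 1)


def _interp_from_midpoints(tac: TimeActivityCurve, t_fine: np.ndarray) -> np.ndarray:
    # activity is zero at injection; extend flat beyond the last midpoint
    t = np.concatenate([[0.0], tac.times_min])
    c = np.concatenate([[0.0], tac.activity])
    return np.interp(t_fine, t, c)


def _frame_average(
    schedule: FrameSchedule, t_fine: np.ndarray, c_fine: np.ndarray
) -> np.ndarray:
    """Average a fine-grid curve within each frame via its running integral."""
    dt = t_fine[1] - t_fine[0]
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (c_fine[1:] + c_fine[:-1]) * dt)])
    bounds = schedule.bounds_min
    cum_at = np.interp(bounds, t_fine, cum)
    return np.diff(cum_at) / np.diff(bounds)


def simulate_reversible_tac(
    ref: TimeActivityCurve,
    truth: RegionalKineticTruth,
    schedule: FrameSchedule | None = None,
    *,
    shape: ReferenceShape | None = None,
    dt_min: float = 0.1,
    region: str = "",
) -> TimeActivityCurve:
    """Forward SRTM solution for a reversible ligand.

    ``C_T = R1*C_R + (k2 - R1*k2a) * (C_R conv exp(-k2a t))`` with
    ``k2a = k2/(1 + BP_ND)``, computed on a fine internal grid and averaged
    per frame. If ``shape`` is given the reference is evaluated
    analytically on the fine grid; otherwise it is interpolated from the
    framewise ``ref``.
    """
    if truth.bp_nd is None or truth.bp_nd < 0:
        raise ValueError("truth.bp_nd must be set and >= 0")
    if truth.r1 is None or truth.k2 is None:
        raise ValueError("truth.r1 and truth.k2 must be set")
    if schedule is None:
        schedule = ref.schedule
    elif schedule != ref.schedule:
        raise ValueError("reference TAC must be on the same schedule")
    k2a = truth.k2 / (1.0 + truth.bp_nd)
    t_fine = _fine_grid(schedule, dt_min)
    c_r = shape.value(t_fine) if shape is not None else _interp_from_midpoints(ref, t_fine)
    dt = t_fine[1] - t_fine[0]
    kernel = np.exp(-k2a * t_fine)
    conv = np.convolve(c_r, kernel)[: t_fine.size] * dt
    # trapezoid end-correction of the discrete convolution
    conv -= 0.5 * dt * (c_r * kernel[0] + c_r[0] * kernel)
    c_t = truth.r1 * c_r + (truth.k2 - truth.r1 * k2a) * conv
    return TimeActivityCurve(schedule, _frame_average(schedule, t_fine, c_t), region)


def simulate_irreversible_tac(
    ref_corrected: TimeActivityCurve,
    truth: RegionalKineticTruth,
    *,
    lambda_bar: float = 0.04,
    region: str = "",
) -> tuple[TimeActivityCurve, TimeActivityCurve]:
    """Forward Patlak model for an irreversible ligand.

    The target is ``Ki * int_0^t C_ref + V0 * C_ref(t)`` on the frame grid
    (same trapezoidal integral as the estimator). The emitted cerebellum
    curve is ``C_cer(t) = C_ref(t) * exp(+lambda_bar t)`` so that the
    estimator's exponential adjustment exactly inverts it.
    """
    if truth.ki is None or truth.ki < 0:
        raise ValueError("truth.ki must be set and >= 0")
    if truth.v0 is None:
        raise ValueError("truth.v0 must be set")
    c_ref = ref_corrected.activity
    if np.any(c_ref[1:] <= 0):
        raise ValueError("ref_corrected must be strictly positive after frame 1")
    int_ref = running_integral(ref_corrected)
    target = TimeActivityCurve(
        ref_corrected.schedule, truth.ki * int_ref + truth.v0 * c_ref, region
    )
    t = ref_corrected.times_min
    cer = TimeActivityCurve(
        ref_corrected.schedule, c_ref * np.exp(lambda_bar * t), "cerebellum"
    )
    return target, cer


def add_frame_noise(
    tac: TimeActivityCurve,
    noise_scale: float,
    seed: int | np.random.Generator | None = None,
) -> TimeActivityCurve:
    """Add frame-weighted Gaussian noise, SD_j = scale*sqrt(max(C_j, eps)/dur_j).

    Longer frames average more counts and are less noisy; this is the
    standard frame-duration-weighted approximation for decay-corrected PET
    activity. Reproducible under a fixed seed; ``noise_scale = 0`` returns
    the input activity unchanged.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    if noise_scale == 0:
        return tac.with_activity(tac.activity.copy())
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dur_min = tac.schedule.duration_s / 60.0
    sd = noise_scale * np.sqrt(np.maximum(tac.activity, 1e-6) / dur_min)
    return tac.with_activity(tac.activity + rng.normal(0.0, sd))


# --------------------------------------------------------------------------
# cohort specification
# --------------------------------------------------------------------------

CONSTRUCTS = ("age", "sex", "bmi", "dat", "maob", "log_lesion", "cognition")

#: regions whose Ki feeds the first-component factor score
MAOB_PCA_REGIONS = ("cortex", "hippocampus", "thalamus")


@dataclass(frozen=True)
class CognitiveTestSpec:
    """One cognitive test: domain membership, scoring and generator knobs."""

    name: str
    domain: str  # episodic | working | speed
    max_score: int | None = None
    reliability: float = 0.8
    gen_mean: float | None = None  # raw-score mean (accuracy tests)
    gen_sd: float | None = None

    def __post_init__(self) -> None:
        if self.domain not in ("episodic", "working", "speed"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.domain != "speed" and (self.max_score is None or self.max_score <= 0):
            raise ValueError("accuracy tests need max_score > 0")
        if not (0 < self.reliability <= 1):
            raise ValueError("reliability must be in (0, 1]")


DEFAULT_TEST_BATTERY = (
    CognitiveTestSpec("word_recall", "episodic", 32, 0.65, gen_mean=17.6, gen_sd=3.8),
    CognitiveTestSpec("number_word_recall", "episodic", 16, 0.58, gen_mean=5.6, gen_sd=1.9),
    CognitiveTestSpec("object_position_recall", "episodic", 24, 0.77, gen_mean=13.2, gen_sd=2.9),
    CognitiveTestSpec("letter_updating", "working", 48, 0.68, gen_mean=26.4, gen_sd=5.8),
    CognitiveTestSpec("number_3back", "working", 108, 0.91, gen_mean=59.4, gen_sd=13.0),
    CognitiveTestSpec("spatial_updating", "working", 30, 0.65, gen_mean=16.5, gen_sd=3.6),
    CognitiveTestSpec("letter_comparison", "speed", None, 0.96),
    CognitiveTestSpec("number_comparison", "speed", None, 0.95),
    CognitiveTestSpec("figure_comparison", "speed", None, 0.93),
)

DEFAULT_DOMAIN_MAP = {t.name: t.domain for t in DEFAULT_TEST_BATTERY}

#: (mean, sd) of BP_ND per striatal region
DEFAULT_BP_TRUTH = {"caudate": (2.24, 0.52), "putamen": (3.31, 0.59)}

#: (mean, sd) of Ki_ref per region; printed SDs of 0.00 widened to 0.004
DEFAULT_KI_TRUTH = {
    "cortex": (0.04, 0.004),
    "hippocampus": (0.05, 0.004),
    "thalamus": (0.06, 0.004),
    "caudate": (0.06, 0.010),
    "putamen": (0.07, 0.004),
}


def default_construct_correlations() -> pd.DataFrame:
    """Calibrated latent correlation matrix over the seven constructs.

    Off-diagonal values are chosen so the measured (composite-level)
    zero-order and age-adjusted partial correlations hit the calibration
    targets: age-maob 0.36, age-lesions 0.42, age-cognition -0.50,
    dat-maob|age 0.53, dat-lesions|age -0.39, maob-lesions|age -0.33,
    dat-cognition|age 0.42, plus BMI/sex associations.
    """

    def zero_order(partial, r_xa, r_ya):
        return partial * math.sqrt((1 - r_xa**2) * (1 - r_ya**2)) + r_xa * r_ya

    R = pd.DataFrame(
        np.eye(len(CONSTRUCTS)), index=CONSTRUCTS, columns=CONSTRUCTS, dtype=float
    )

    def setr(a, b, v):
        R.loc[a, b] = R.loc[b, a] = v

    setr("age", "dat", -0.20)
    setr("age", "maob", 0.36)
    setr("age", "log_lesion", 0.42)
    setr("age", "cognition", -0.50)
    setr("sex", "dat", 0.39)  # latent scale; men higher after thresholding
    setr("bmi", "dat", -0.53)
    setr("bmi", "maob", -0.43)
    setr("dat", "maob", zero_order(0.53, -0.20, 0.36))
    setr("dat", "log_lesion", zero_order(-0.39, -0.20, 0.42))
    setr("dat", "cognition", zero_order(0.42, -0.20, -0.50))
    setr("maob", "log_lesion", zero_order(-0.33, 0.36, 0.42))
    setr("maob", "cognition", zero_order(0.10, 0.36, -0.50))
    setr("log_lesion", "cognition", zero_order(-0.25, 0.42, -0.50))
    return R


def nearest_correlation(R: np.ndarray, max_shift: float = 0.05) -> np.ndarray:
    """Project a symmetric matrix to the nearest valid correlation matrix.

    Eigenvalues are floored at a small positive value and the diagonal
    rescaled to one. If any entry moves by more than ``max_shift`` the
    matrix is rejected rather than silently replaced.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    w, V = np.linalg.eigh((R + R.T) / 2.0)
    if w.min() >= 1e-10:
        return R
    w = np.maximum(w, 1e-8)
    A = (V * w) @ V.T
    d = np.sqrt(np.diag(A))
    out = A / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    if np.max(np.abs(out - R)) > max_shift:
        raise ValueError(
            "correlation matrix is too far from positive semi-definite "
            f"(max adjustment {np.max(np.abs(out - R)):.3f} > {max_shift})"
        )
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one synthetic cohort deterministically."""

    n_subjects: int = 55
    seed: int = 0
    age_mean: float = 67.4
    age_sd: float = 5.1
    age_range: tuple[float, float] = (60.0, 80.0)
    bmi_mean: float = 27.4
    bmi_sd: float = 5.5
    lesion_mean_ml: float = 2.0
    lesion_sd_ml: float = 2.9
    hypertension_rate: float = 0.55
    construct_correlations: pd.DataFrame | None = None  # None -> default
    bp_truth: dict = field(default_factory=lambda: dict(DEFAULT_BP_TRUTH))
    ki_truth: dict = field(default_factory=lambda: dict(DEFAULT_KI_TRUTH))
    striatal_cross_correlation: float = 0.78
    maob_cross_correlation: float = 0.67
    domain_cross_correlation: float = 0.50
    test_battery: tuple = DEFAULT_TEST_BATTERY
    bp_floor: float = 0.1
    ki_floor: float = 0.005
    r1: float = 0.9
    k2: float = 0.35
    v0: float = 1.0
    noise_scale: float = 0.5
    simulate_tacs: bool = True
    inject_lesion_outlier: bool = False
    pe2i_shape: ReferenceShape = ReferenceShape(30.0, 0.03, 0.5)
    ded_shape: ReferenceShape = ReferenceShape(100.0, 0.05, 1.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")

    def correlation_matrix(self) -> pd.DataFrame:
        R = (
            default_construct_correlations()
            if self.construct_correlations is None
            else self.construct_correlations
        )
        R = pd.DataFrame(R)
        if list(R.index) != list(CONSTRUCTS):
            R.index = CONSTRUCTS
            R.columns = CONSTRUCTS
        return pd.DataFrame(
            nearest_correlation(R.to_numpy()), index=CONSTRUCTS, columns=CONSTRUCTS
        )


@dataclass
class Cohort:
    """Generated cohort: one table row per subject plus optional TAC bundles."""

    table: pd.DataFrame
    spec: CohortSpec
    tacs: dict | None = None  # subject_id -> {"pe2i": {...}, "ded": {...}}


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _sum_zero_equicorrelated(
    rng: np.random.Generator, latent: np.ndarray, k: int, rho: float
) -> np.ndarray:
    """k unit-variance indicators of ``latent`` with pairwise correlation rho.

    Residuals are constrained to sum to zero across the k indicators, so
    the row mean recovers ``latent`` exactly (up to a constant scale).
    """
    n = latent.size
    tau2 = k * (1.0 - rho) / (1.0 + rho * (k - 1))
    raw = rng.normal(0.0, math.sqrt(tau2), size=(n, k))
    resid = raw - raw.mean(axis=1, keepdims=True)
    scale = math.sqrt(1.0 + tau2 * (k - 1) / k)
    return (latent[:, None] + resid) / scale


def _heteroscedastic_indicators(
    rng: np.random.Generator, latent: np.ndarray, reliabilities: np.ndarray
) -> np.ndarray:
    """Unit-variance test indicators with sum-to-zero, reliability-tuned noise."""
    n, k = latent.size, reliabilities.size
    tau2 = (1.0 - reliabilities) / reliabilities
    raw = rng.normal(0.0, 1.0, size=(n, k)) * np.sqrt(tau2)
    resid = raw - raw.mean(axis=1, keepdims=True)
    # exact residual variances after centering heteroscedastic draws
    var_resid = (1 - 1 / k) ** 2 * tau2 + (tau2.sum() - tau2) / k**2
    return (latent[:, None] + resid) / np.sqrt(1.0 + var_resid)


def _simulate_subject_tacs(
    spec: CohortSpec, row, rng: np.random.Generator
) -> dict:
    """Noise-free forward curves for one subject, then frame noise."""
    out: dict[str, dict[str, TimeActivityCurve]] = {"pe2i": {}, "ded": {}}

    sched_r = pe2i_schedule()
    ref_r = make_reference_tac(sched_r, spec.pe2i_shape)
    for region in spec.bp_truth:
        truth = RegionalKineticTruth(
            r1=spec.r1, k2=spec.k2, bp_nd=getattr(row, f"bp_nd_true_{region}")
        )
        tac = simulate_reversible_tac(
            ref_r, truth, shape=spec.pe2i_shape, region=region
        )
        out["pe2i"][region] = add_frame_noise(tac, spec.noise_scale, rng)
    out["pe2i"]["cerebellum"] = add_frame_noise(ref_r, spec.noise_scale, rng)

    sched_i = ded_schedule()
    ref_c = make_reference_tac(sched_i, spec.ded_shape, region="reference_corrected")
    cer = None
    for region in spec.ki_truth:
        truth = RegionalKineticTruth(ki=getattr(row, f"ki_true_{region}"), v0=spec.v0)
        tac, cer = simulate_irreversible_tac(ref_c, truth, region=region)
        out["ded"][region] = add_frame_noise(tac, spec.noise_scale, rng)
    out["ded"]["cerebellum"] = add_frame_noise(cer, spec.noise_scale, rng)
    return out


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a full synthetic cohort; deterministic for a fixed spec+seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    R = spec.correlation_matrix().to_numpy()
    L = rng.standard_normal((n, len(CONSTRUCTS))) @ np.linalg.cholesky(R).T
    lat = {name: L[:, i] for i, name in enumerate(CONSTRUCTS)}

    table = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "age": spec.age_mean + spec.age_sd * lat["age"],
            "sex": np.where(lat["sex"] > 0, "M", "F"),
            "bmi": spec.bmi_mean + spec.bmi_sd * lat["bmi"],
        }
    )

    # hypertension: loosely tied to age and BMI, thresholded at the target rate
    htn_score = 0.3 * lat["age"] + 0.3 * lat["bmi"] + rng.standard_normal(n)
    cut = np.quantile(htn_score, 1.0 - spec.hypertension_rate)
    table["hypertension"] = (htn_score > cut).astype(int)

    mu, sigma = lognormal_params(spec.lesion_mean_ml, spec.lesion_sd_ml)
    volumes = np.exp(mu + sigma * lat["log_lesion"])
    if spec.inject_lesion_outlier:
        volumes[int(np.argmax(volumes))] = 14.7
    table["lesion_volume_ml"] = volumes
    table["fazekas"] = np.digitize(volumes, [0.15, 2.0, 12.0])

    # regional kinetic truths (sum-to-zero residual construction)
    z_striat = _sum_zero_equicorrelated(
        rng, lat["dat"], len(spec.bp_truth), spec.striatal_cross_correlation
    )
    for j, (region, (m, s)) in enumerate(spec.bp_truth.items()):
        table[f"bp_nd_true_{region}"] = np.maximum(m + s * z_striat[:, j], spec.bp_floor)

    pca_regions = [r for r in spec.ki_truth if r in MAOB_PCA_REGIONS]
    other_regions = [r for r in spec.ki_truth if r not in MAOB_PCA_REGIONS]
    z_pca = _sum_zero_equicorrelated(
        rng, lat["maob"], len(pca_regions), spec.maob_cross_correlation
    )
    for j, region in enumerate(pca_regions):
        m, s = spec.ki_truth[region]
        table[f"ki_true_{region}"] = np.maximum(m + s * z_pca[:, j], spec.ki_floor)
    load = math.sqrt(spec.maob_cross_correlation)
    for region in other_regions:
        m, s = spec.ki_truth[region]
        z = load * lat["maob"] + math.sqrt(1 - load**2) * rng.standard_normal(n)
        table[f"ki_true_{region}"] = np.maximum(m + s * z, spec.ki_floor)

    # cognitive battery: cognition -> three domains -> tests
    domains = ("episodic", "working", "speed")
    z_dom = _sum_zero_equicorrelated(
        rng, lat["cognition"], len(domains), spec.domain_cross_correlation
    )
    for d_idx, domain in enumerate(domains):
        tests = [t for t in spec.test_battery if t.domain == domain]
        rel = np.array([t.reliability for t in tests])
        z_tests = _heteroscedastic_indicators(rng, z_dom[:, d_idx], rel)
        for t_idx, test in enumerate(tests):
            z = z_tests[:, t_idx]
            if domain == "speed":
                rate = np.maximum(30.0 + 6.0 * z, 1.0)  # correct responses / min
                rt = np.maximum(rng.normal(90_000.0, 5_000.0, n), 30_000.0)
                n_corr = np.maximum(np.rint(rate * rt / 60_000.0), 0.0)
                table[f"{test.name}_n_correct"] = n_corr.astype(int)
                table[f"{test.name}_total_rt_ms"] = rt
            else:
                raw = np.rint(test.gen_mean + test.gen_sd * z)
                table[test.name] = np.clip(raw, 0, test.max_score).astype(int)

    for name in ("dat", "maob", "cognition", "log_lesion"):
        table[f"latent_{name}"] = lat[name]

    tacs = None
    if spec.simulate_tacs:
        tacs = {
            row.subject_id: _simulate_subject_tacs(spec, row, rng)
            for row in table.itertuples()
        }
    return Cohort(table=table, spec=spec, tacs=tacs)
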