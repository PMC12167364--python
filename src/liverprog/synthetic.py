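"""Synthetic triphasic-CT cohort generator with known hazard structure.

Real multicenter HCC cohorts are not redistributable, so every downstream
stage of the pipeline is exercised on simulated patients for whom the data
generating process is known exactly:

* a miniature liver phantom per patient — a smooth ellipsoidal liver with
  Gaussian-textured parenchyma and one or more ellipsoidal tumors whose
  diameter and internal texture amplitude are latent covariates;
* three contrast phases (arterial / portal-venous / delayed) produced from
  the same geometry with phase-specific mean enhancement offsets, so the
  phases are co-registered by construction;
* clinical covariates partially derived from the image latents (tumor size,
  lesion count) and partially independent (AFP, PVTT, ECOG, Child-Pugh …),
  so the imaging and clinical channels carry overlapping plus complementary
  prognostic signal;
* right-censored Weibull survival times for OS and PFS whose hazard is
  proportional to ``exp(LP)`` with a known linear predictor
  ``LP = sum(beta_k * covariate_k)``.

The generator is deterministic given a seed: every patient draws from named
RNG substreams (clinical / image / survival) spawned from the run seed, so
adding a stage never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .datatypes import ClinicalRecord, SurvivalLabel, TriphasicScan, PHASES

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ConfigurationError",
    "GenerationError",
    "simulate_cohort",
    "simulate_scan",
    "simulate_survival",
    "default_config",
    "strong_image_signal_config",
    "null_signal_config",
    "complementary_signal_config",
    "clinical_only_signal_config",
]


class ConfigurationError(ValueError):
    """An invalid simulation-configuration field."""


class GenerationError(RuntimeError):
    """Geometrically impossible phantom (e.g. tumor larger than liver)."""


# Default log-hazard weights on the generative covariates.  Continuous
# covariates enter standardized (unit variance), binary flags as 0/1, so a
# weight is a log hazard ratio per SD / per flag.
DEFAULT_HAZARD_COEFFICIENTS = {
    "size_z": 0.70,       # standardized tumor diameter
    "eta_z": 0.55,        # standardized intra-tumor heterogeneity amplitude
    "extra_lesions": 0.30,  # lesion count - 1
    "afp_gt_400": 0.50,
    "pvtt": 0.50,
    "ecog1": 0.40,
    "child_b": 0.40,
}

#: Covariates realized in the image channel (drive the phantom's appearance).
IMAGE_COVARIATES = ("size_z", "eta_z", "extra_lesions")
#: Covariates realized only in the clinical table.
CLINICAL_COVARIATES = ("afp_gt_400", "pvtt", "ecog1", "child_b")

# Mean HU enhancement offsets per phase, (liver, tumor).  Arterial phase
# hyper-enhances the tumor; portal-venous enhances parenchyma most; the
# delayed phase shows washout.
DEFAULT_PHASE_ENHANCEMENT = {
    "A": (10.0, 40.0),
    "V": (50.0, 10.0),
    "D": (30.0, 5.0),
}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    ``baseline_scale`` is in months and set so the median OS at ``LP == 0``
    (scale * ln2^(1/shape) ≈ 0.783 * scale) matches the ~18.5-month median
    of the target population; the PFS baseline uses a larger hazard
    (``pfs_scale_factor`` < 1) giving a ~7.5-month median.
    """

    n_patients: int = 100
    volume_edge: int = 32           # 128 mirrors the clinical input cube
    voxel_spacing: tuple = (1.0, 1.0, 1.0)  # mm, (z, y, x)
    seed: int = 0
    hazard_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_HAZARD_COEFFICIENTS)
    )
    baseline_shape: float = 1.5     # Weibull shape; right-skewed, non-exponential
    baseline_scale: float = 23.6    # months
    pfs_scale_factor: float = 0.41
    censoring_rate: float = 0.35
    phase_enhancement: dict = field(
        default_factory=lambda: dict(DEFAULT_PHASE_ENHANCEMENT)
    )
    liver_hu: float = 60.0
    tumor_hu: float = 50.0
    background_hu: float = -80.0
    liver_texture_sd: float = 6.0   # HU, smooth parenchymal texture
    heterogeneity_scale: float = 4.0  # HU of tumor texture per unit eta
    noise_floor: float = 1.0        # HU; scanner noise sd = 0.6 * noise_floor
    lp_clip: float = 8.0
    render_images: bool = True      # False: tabular-only cohort (no phantoms)

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError(f"n_patients must be >= 0, got {self.n_patients}")
        if self.volume_edge < 8:
            raise ConfigurationError(f"volume_edge must be >= 8, got {self.volume_edge}")
        if not (0.0 <= self.censoring_rate <= 1.0):
            raise ConfigurationError(
                f"censoring_rate must be in [0, 1], got {self.censoring_rate}"
            )
        if any(s <= 0 for s in self.voxel_spacing):
            raise ConfigurationError(f"voxel_spacing must be positive, got {self.voxel_spacing}")
        if self.baseline_shape <= 0:
            raise ConfigurationError(f"baseline_shape must be > 0, got {self.baseline_shape}")
        if self.baseline_scale <= 0:
            raise ConfigurationError(f"baseline_scale must be > 0, got {self.baseline_scale}")
        if not (0 < self.pfs_scale_factor <= 1):
            raise ConfigurationError(
                f"pfs_scale_factor must be in (0, 1], got {self.pfs_scale_factor}"
            )
        unknown = set(self.hazard_coefficients) - set(DEFAULT_HAZARD_COEFFICIENTS)
        if unknown:
            raise ConfigurationError(f"hazard_coefficients has unknown keys {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Latent truth behind a simulated cohort.

    ``lp`` is exactly ``covariates[names] @ beta`` for the stored
    coefficient map, and ``true_os`` / ``true_pfs`` are the event times
    before censoring (so the observed time equals the true time whenever the
    event indicator is 1, and is smaller when it is 0).
    """

    covariates: pd.DataFrame           # one row per patient, generative scale
    coefficients: dict                 # name -> beta
    lp: np.ndarray
    true_os: np.ndarray
    true_pfs: np.ndarray
    censor_times: np.ndarray

    def image_lp(self) -> np.ndarray:
        """Part of the linear predictor carried by the image latents."""
        return sum(
            self.coefficients.get(k, 0.0) * self.covariates[k].to_numpy()
            for k in IMAGE_COVARIATES
        )

    def clinical_lp(self) -> np.ndarray:
        """Part of the linear predictor carried by clinical-only covariates."""
        return sum(
            self.coefficients.get(k, 0.0) * self.covariates[k].to_numpy()
            for k in CLINICAL_COVARIATES
        )


# ---------------------------------------------------------------------------
# preset study conditions


def default_config(**kw) -> SimulationConfig:
    return SimulationConfig(**kw)


def strong_image_signal_config(**kw) -> SimulationConfig:
    """All prognostic signal in the image latents (for network training tests)."""
    coeffs = {k: 0.0 for k in DEFAULT_HAZARD_COEFFICIENTS}
    coeffs.update(size_z=1.0, eta_z=0.8, extra_lesions=0.3)
    kw.setdefault("hazard_coefficients", coeffs)
    kw.setdefault("censoring_rate", 0.2)
    return SimulationConfig(**kw)


def null_signal_config(**kw) -> SimulationConfig:
    """No covariate affects the hazard (all beta = 0)."""
    kw.setdefault("hazard_coefficients", {k: 0.0 for k in DEFAULT_HAZARD_COEFFICIENTS})
    return SimulationConfig(**kw)


def complementary_signal_config(**kw) -> SimulationConfig:
    """Image and clinical channels carry comparable, independent signal."""
    coeffs = {k: 0.0 for k in DEFAULT_HAZARD_COEFFICIENTS}
    coeffs.update(size_z=0.6, eta_z=0.5, afp_gt_400=0.6, pvtt=0.6, ecog1=0.5)
    kw.setdefault("hazard_coefficients", coeffs)
    return SimulationConfig(**kw)


def clinical_only_signal_config(**kw) -> SimulationConfig:
    coeffs = {k: 0.0 for k in DEFAULT_HAZARD_COEFFICIENTS}
    coeffs.update(afp_gt_400=0.6, pvtt=0.6, ecog1=0.5, child_b=0.4)
    kw.setdefault("hazard_coefficients", coeffs)
    return SimulationConfig(**kw)


# ---------------------------------------------------------------------------
# RNG plumbing: one named substream per patient per purpose

_PURPOSES = {"clinical": 0, "image": 1, "survival": 2}


def _stream(seed: int, patient: int, purpose: str) -> np.random.Generator:
    ss = np.random.SeedSequence([int(seed), int(patient), _PURPOSES[purpose]])
    return np.random.Generator(np.random.PCG64(ss))


# ---------------------------------------------------------------------------
# latent covariates

_SIZE_MEAN_MM, _SIZE_SD_MM = 10.0, 2.5
_ETA_MEAN, _ETA_SD = 2.5, 5.0 / math.sqrt(12.0)


def _draw_latents(rng: np.random.Generator, config: SimulationConfig) -> dict:
    edge_mm = config.volume_edge * min(config.voxel_spacing)
    max_size = 0.42 * edge_mm
    size_mm = float(np.clip(6.0 + rng.gamma(2.0, 2.0), 6.0, max_size))
    eta = float(rng.uniform(0.0, 5.0))
    n_lesions = 1 + int(rng.binomial(2, 0.2))
    lat = {
        "size_mm": size_mm,
        "eta": eta,
        "n_lesions": n_lesions,
        # standardized versions used in the linear predictor
        "size_z": (size_mm - _SIZE_MEAN_MM) / _SIZE_SD_MM,
        "eta_z": (eta - _ETA_MEAN) / _ETA_SD,
        "extra_lesions": n_lesions - 1,
        # clinical-only flags (marginals roughly matching the target population)
        "afp_gt_400": int(rng.random() < 0.40),
        "pvtt": int(rng.random() < 0.80),
        "ecog1": int(rng.random() < 0.43),
        "child_b": int(rng.random() < 0.17),
        "age": float(np.clip(rng.normal(58.0, 9.0), 25.0, 90.0)),
        "sex": "M" if rng.random() < 0.85 else "F",
        "hbv": int(rng.random() < 0.84),
        "cirrhosis": int(rng.random() < 0.75),
        "bclc": "C" if rng.random() < 0.90 else "B",
        "lung_met": int(rng.random() < 0.21),
        "bone_met": int(rng.random() < 0.04),
        "lymph_met": int(rng.random() < 0.30),
        "therapy_line": 2 if rng.random() < 0.13 else 1,
        "prior_local_therapy": int(rng.random() < 0.34),
    }
    return lat


def _linear_predictor(lat: dict, coeffs: dict) -> float:
    return float(sum(beta * lat[name] for name, beta in coeffs.items()))


def _mrecist_category(lp: float, rng: np.random.Generator) -> str:
    # ordered-logit response: lower latent utility = better response
    u = lp + rng.logistic(0.0, 1.0)
    if u < -2.6:
        return "CR"
    if u < -0.4:
        return "PR"
    if u < 1.2:
        return "SD"
    return "PD"


# ---------------------------------------------------------------------------
# image phantom


def _ellipsoid(shape: tuple, center: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return q < 1.0


def _smooth_noise(rng: np.random.Generator, shape: tuple, sigma: float) -> np.ndarray:
    """Gaussian-filtered white noise renormalized to unit variance."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def simulate_scan(rng: np.random.Generator, covariates: dict,
                  config: SimulationConfig, patient_id: str = "p") -> TriphasicScan:
    """Render one triphasic liver phantom from the patient's latents.

    The liver is a jittered ellipsoid with smooth Gaussian parenchymal
    texture; each tumor is an ellipsoid inside the liver whose largest
    diameter matches ``covariates['size_mm']`` (within a voxel) and whose
    internal HU texture amplitude grows linearly with ``covariates['eta']``.
    All three phases share geometry and masks and differ by the configured
    mean enhancement offsets plus independent scanner noise.
    """
    E = config.volume_edge
    shape = (E, E, E)
    spacing = tuple(float(s) for s in config.voxel_spacing)

    liver_semi = np.array([0.40, 0.36, 0.33]) * E * (1.0 + 0.05 * rng.uniform(-1, 1, 3))
    liver_center = E / 2.0 + rng.uniform(-1.5, 1.5, 3)
    liver = _ellipsoid(shape, liver_center, liver_semi)

    d_vox = covariates["size_mm"] / min(spacing)
    if d_vox / 2.0 > 0.9 * liver_semi.min():
        raise GenerationError(
            f"{patient_id}: tumor diameter {covariates['size_mm']} mm does not fit "
            f"inside the simulated liver"
        )

    tumor = np.zeros(shape, dtype=bool)
    n_lesions = int(covariates.get("n_lesions", 1))
    for lesion in range(n_lesions):
        r = d_vox / 2.0 if lesion == 0 else d_vox / 4.0
        semi = np.array([r, 0.92 * r, 0.85 * r])
        # sample a center such that the lesion's bounding ellipsoid stays inside
        for _ in range(200):
            u = rng.uniform(-1, 1, 3)
            if np.sum(u**2) > 1:
                continue
            center = liver_center + u * np.maximum(liver_semi - semi - 1.0, 0.0)
            if _ellipsoid_inside(center, semi, liver_center, liver_semi):
                break
        else:  # pragma: no cover - extremely unlikely at valid sizes
            raise GenerationError(f"{patient_id}: could not place lesion {lesion}")
        tumor |= _ellipsoid(shape, center, semi)
    tumor &= liver

    base = np.full(shape, config.background_hu, dtype=np.float32)
    liver_tex = _smooth_noise(rng, shape, sigma=3.0) * config.liver_texture_sd
    base[liver] = config.liver_hu + liver_tex[liver]
    eta = float(covariates.get("eta", 0.0))
    tumor_tex = _smooth_noise(rng, shape, sigma=1.5) * (eta * config.heterogeneity_scale)
    base[tumor] = config.tumor_hu + tumor_tex[tumor]

    noise_sd = 0.6 * config.noise_floor
    phases = {}
    for ph in PHASES:
        liver_off, tumor_off = config.phase_enhancement[ph]
        vol = base.copy()
        vol[liver] += liver_off
        vol[tumor] += tumor_off - liver_off  # tumor offset replaces liver offset
        vol += rng.normal(0.0, noise_sd, shape).astype(np.float32)
        phases[ph] = vol.astype(np.float32)

    return TriphasicScan(
        patient_id=patient_id,
        phases=phases,
        spacing=spacing,
        liver_mask=liver.astype(np.uint8),
        tumor_mask=tumor.astype(np.uint8),
    )


def _ellipsoid_inside(c: np.ndarray, semi: np.ndarray,
                      C: np.ndarray, SEMI: np.ndarray) -> bool:
    # sufficient condition: center offset in liver-normalized coordinates,
    # shrunk by the lesion's own extent along each axis
    margin = (SEMI - semi - 0.5)
    if np.any(margin <= 0):
        return False
    return bool(np.sum(((c - C) / margin) ** 2) < 1.0)


# ---------------------------------------------------------------------------
# survival times


def _weibull_time(rng: np.random.Generator, shape_k: float, scale: float,
                  lp: float) -> float:
    # proportional hazards: S(t) = exp(-(t/scale)^k * e^lp)
    u = rng.exponential(1.0)
    return float(scale * (u / math.exp(lp)) ** (1.0 / shape_k))


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)
_GL_U = 0.5 * (_GL_NODES + 1.0)  # map to (0, 1)
_GL_W = 0.5 * _GL_WEIGHTS


def _exp_censor_prob(lam: float, a: float, k: float) -> float:
    """P(C < T) for C ~ Exp(lam), T ~ Weibull with S(t)=exp(-a t^k)."""
    if lam <= 0:
        return 0.0
    c = -np.log1p(-_GL_U) / lam  # quantiles of the exponential
    return float(np.sum(_GL_W * np.exp(-a * c**k)))


def _censor_rate_for(lp: float, config: SimulationConfig) -> float:
    """Exponential censoring rate giving the configured censoring fraction."""
    q = config.censoring_rate
    if q <= 0:
        return 0.0
    k = config.baseline_shape
    a = math.exp(lp) / config.baseline_scale**k
    t_med = (math.log(2.0) / a) ** (1.0 / k)
    lo, hi = 1e-8 / t_med, 1e4 / t_med
    f = lambda lam: _exp_censor_prob(lam, a, k) - q
    if f(hi) < 0:
        return hi
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-10))


def simulate_survival(lp: float, config: SimulationConfig,
                      rng: np.random.Generator) -> tuple:
    """Draw one patient's (OS, PFS) labels under proportional hazards.

    Event times are Weibull with hazard multiplier ``exp(lp)``; PFS uses a
    larger baseline hazard and is capped at the OS time (progression cannot
    postdate death).  A single independent exponential censoring time,
    tuned so the expected OS censoring fraction equals
    ``config.censoring_rate``, right-censors both endpoints.
    """
    lp = float(np.clip(lp, -config.lp_clip, config.lp_clip))
    k = config.baseline_shape
    t_os = _weibull_time(rng, k, config.baseline_scale, lp)
    t_pfs = min(
        _weibull_time(rng, k, config.baseline_scale * config.pfs_scale_factor, lp),
        t_os,
    )
    if config.censoring_rate > 0:
        lam = _censor_rate_for(lp, config)
        c = float(rng.exponential(1.0 / lam))
    else:
        c = math.inf
    os_label = SurvivalLabel(time=max(min(t_os, c), 1e-6), event=int(t_os <= c), endpoint="OS")
    pfs_label = SurvivalLabel(time=max(min(t_pfs, c), 1e-6), event=int(t_pfs <= c), endpoint="PFS")
    return os_label, pfs_label, t_os, t_pfs, c


# ---------------------------------------------------------------------------
# cohort assembly


def simulate_cohort(config: SimulationConfig):
    """Generate a full synthetic cohort.

    Returns ``(scans, clinical, os_labels, pfs_labels, ground_truth)`` with
    one entry per patient.  Identical configs (including the seed) produce
    identical cohorts.
    """
    config.validate()
    coeffs = dict(config.hazard_coefficients)

    scans, clinical, os_labels, pfs_labels = [], [], [], []
    rows, lps, true_os, true_pfs, censors = [], [], [], [], []
    for i in range(config.n_patients):
        pid = f"pt{i:04d}"
        lat = _draw_latents(_stream(config.seed, i, "clinical"), config)
        lp = _linear_predictor(lat, coeffs)

        scan = None
        if config.render_images:
            scan = simulate_scan(_stream(config.seed, i, "image"), lat, config,
                                 patient_id=pid)
        surv_rng = _stream(config.seed, i, "survival")
        os_l, pfs_l, t_os, t_pfs, c = simulate_survival(lp, config, surv_rng)

        tumor_size_cm = round(lat["size_mm"] * 0.65, 2)  # reported clinical size
        record = ClinicalRecord(
            patient_id=pid,
            age=round(lat["age"], 1),
            sex=lat["sex"],
            afp_gt_400=lat["afp_gt_400"],
            hbv=lat["hbv"],
            cirrhosis=lat["cirrhosis"],
            child_pugh="B" if lat["child_b"] else "A",
            ecog=lat["ecog1"],
            bclc=lat["bclc"],
            up_to_seven=int(lat["n_lesions"] + tumor_size_cm <= 7),
            tumor_size_cm=tumor_size_cm,
            tumor_number=lat["n_lesions"],
            pvtt=lat["pvtt"],
            lung_met=lat["lung_met"],
            bone_met=lat["bone_met"],
            lymph_met=lat["lymph_met"],
            therapy_line=lat["therapy_line"],
            prior_local_therapy=lat["prior_local_therapy"],
            mrecist=_mrecist_category(lp, surv_rng),
        )
        record.validate()

        if scan is not None:
            scans.append(scan)
        clinical.append(record)
        os_labels.append(os_l)
        pfs_labels.append(pfs_l)
        rows.append({"patient_id": pid, **lat})
        lps.append(lp)
        true_os.append(t_os)
        true_pfs.append(t_pfs)
        censors.append(c)

    covariates = pd.DataFrame(rows)
    if not rows:
        covariates = pd.DataFrame(columns=["patient_id"])
    truth = GroundTruth(
        covariates=covariates,
        coefficients=coeffs,
        lp=np.asarray(lps, dtype=float),
        true_os=np.asarray(true_os, dtype=float),
        true_pfs=np.asarray(true_pfs, dtype=float),
        censor_times=np.asarray(censors, dtype=float),
    )
    return scans, clinical, os_labels, pfs_labels, truth
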