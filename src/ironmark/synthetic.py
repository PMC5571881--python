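"""Synthetic phantoms and clinical cohorts with retained ground truth.

Two generators stand in for the (undeposited) patient data of a USPIO-MRI
abdominal aortic aneurysm surveillance study:

* an **imaging phantom** — concentric ellipsoids (lumen, intraluminal
  thrombus, aneurysm wall) whose multi-echo gradient-echo signal decays
  mono-exponentially with tissue-specific T2*, with focal post-contrast T2*
  reduction in the wall (USPIO uptake), inter-visit rigid motion, and
  Rician magnitude noise;

* a **clinical cohort** — baseline covariates, a logistic model for USPIO
  enhancement, per-patient linear diameter growth observed through noisy
  serial ultrasound, and an exponential proportional-hazards model for the
  rupture-or-repair endpoint with administrative censoring.

Every generator records its ground truth so downstream estimates can be
scored against it, and all randomness flows from one integer seed through
a splittable ``numpy`` generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registration import RigidTransform, apply_transform
from .relaxometry import MultiEchoVolume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortSimParams",
    "CohortTable",
    "simulate_echo_signal",
    "generate_phantom_pair",
    "simulate_ultrasound_series",
    "simulate_cohort",
]

PRIMARY_EVENT_TYPES = ("rupture", "repair")

#: default split of fired events, proportional to the study's printed
#: counts (17 ruptures, 126 repairs, 17 aneurysm / 12 cardiovascular /
#: 19 other deaths); deaths censor the rupture-or-repair endpoint.
DEFAULT_EVENT_TYPE_PROBS = {
    "rupture": 17 / 191,
    "repair": 126 / 191,
    "death-aneurysm": 17 / 191,
    "death-cardiovascular": 12 / 191,
    "death-other": 19 / 191,
}


def _rng_from(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# echo-signal model
# ---------------------------------------------------------------------------

def simulate_echo_signal(s0, t2star, echo_times, noise_sigma=0.0, seed=None):
    """Magnitude signal of a voxel across an echo train.

    Noiseless value at echo time TE is ``s0 * exp(-TE / t2star)``; with
    ``noise_sigma > 0`` the magnitude is Rician:
    ``sqrt((S + e1)^2 + e2^2)`` with independent zero-mean Gaussians e1, e2
    of standard deviation ``noise_sigma`` (single receiver channel).
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    if t2star <= 0:
        raise ValueError("t2star must be positive")
    te = np.asarray(echo_times, dtype=float)
    clean = s0 * np.exp(-te / t2star)
    if noise_sigma == 0:
        return clean
    rng = _rng_from(seed)
    e1 = rng.normal(0.0, noise_sigma, size=te.shape)
    e2 = rng.normal(0.0, noise_sigma, size=te.shape)
    return np.sqrt((clean + e1) ** 2 + e2**2)


def _rician(clean: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return clean
    e1 = rng.normal(0.0, sigma, size=clean.shape)
    e2 = rng.normal(0.0, sigma, size=clean.shape)
    return np.sqrt((clean + e1) ** 2 + e2**2)


# ---------------------------------------------------------------------------
# imaging phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Concentric-ellipsoid aneurysm phantom.

    Radii are physical mm, nested lumen < thrombus < wall (outer surfaces).
    ``enhancement_lesions`` is a list of ``(center_voxel, radius_mm,
    post_fraction)``: inside the lesion sphere (intersected with the wall)
    the post-contrast T2* equals ``post_fraction`` times the pre value.
    """

    grid_shape: tuple[int, int, int] = (44, 44, 28)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lumen_radii: tuple[float, float, float] = (10.0, 10.0, 14.0)
    thrombus_radii: tuple[float, float, float] = (16.0, 16.0, 20.0)
    wall_radii: tuple[float, float, float] = (22.0, 22.0, 26.0)
    tissue_t2star: dict = field(
        default_factory=lambda: {
            "lumen": 40.0,
            "thrombus": 20.0,
            "wall": 30.0,
            "background": 15.0,
        }
    )
    s0: float = 1000.0
    enhancement_lesions: list = field(
        default_factory=lambda: [((31, 21, 13), 6.0, 0.2)]
    )
    echo_times: tuple = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    noise_sigma: float = 20.0
    inter_visit_motion: RigidTransform = field(
        default_factory=lambda: RigidTransform(
            rotation=(0.0, 0.0, 0.03), translation=(2.0, -1.5, 1.0), center=(43.0, 43.0, 27.0)
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for a in range(3):
            if not (self.lumen_radii[a] < self.thrombus_radii[a] < self.wall_radii[a]):
                raise ValueError("radii must nest: lumen < thrombus < wall")
        if any(v <= 0 for v in self.tissue_t2star.values()):
            raise ValueError("all tissue T2* values must be positive")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        for _, radius, frac in self.enhancement_lesions:
            if not (0 < frac <= 1):
                raise ValueError("lesion post-contrast fraction must be in (0, 1]")
            if radius <= 0:
                raise ValueError("lesion radius must be positive")
        te = np.asarray(self.echo_times)
        if te.size < 3 or np.any(np.diff(te) <= 0):
            raise ValueError("echo_times must be strictly increasing, length >= 3")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class PhantomTruth:
    """Ground truth carried alongside a phantom pair."""

    masks: dict  # lumen / thrombus / wall / background, disjoint cover
    t2star_pre: np.ndarray
    t2star_post: np.ndarray
    enhancement_mask: np.ndarray
    transform: RigidTransform  # aligns the post volume back onto the pre grid
    enhanced: bool  # whether any lesion was placed


def _ellipsoid(spec: PhantomSpec, radii) -> np.ndarray:
    shape = spec.grid_shape
    sp = spec.voxel_spacing
    center = [(n - 1) / 2 * s for n, s in zip(shape, sp)]
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, sp)], indexing="ij"
    )
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return q <= 1.0


def _sphere_at(spec: PhantomSpec, center_voxel, radius_mm) -> np.ndarray:
    sp = spec.voxel_spacing
    center = [i * s for i, s in zip(center_voxel, sp)]
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(spec.grid_shape, sp)], indexing="ij"
    )
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius_mm**2


def generate_phantom_pair(spec: PhantomSpec):
    """Simulate a pre/post-contrast visit pair.

    The post-contrast volume is the pre-contrast phantom with each lesion's
    T2* multiplied by its fraction, moved by ``inter_visit_motion``
    (resampling through the motion's inverse, so that applying the recorded
    truth transform re-aligns it), then Rician-noised.

    Returns ``(pre, post, truth)`` with ``pre``/``post`` as
    :class:`MultiEchoVolume`.
    """
    e_lumen = _ellipsoid(spec, spec.lumen_radii)
    e_thromb = _ellipsoid(spec, spec.thrombus_radii)
    e_wall = _ellipsoid(spec, spec.wall_radii)
    masks = {
        "lumen": e_lumen,
        "thrombus": e_thromb & ~e_lumen,
        "wall": e_wall & ~e_thromb,
        "background": ~e_wall,
    }

    t2_pre = np.full(spec.grid_shape, spec.tissue_t2star["background"])
    for name in ("lumen", "thrombus", "wall"):
        t2_pre[masks[name]] = spec.tissue_t2star[name]

    t2_post = t2_pre.copy()
    enh_mask = np.zeros(spec.grid_shape, dtype=bool)
    for center_voxel, radius_mm, frac in spec.enhancement_lesions:
        if not masks["wall"][tuple(center_voxel)]:
            raise ValueError(
                f"lesion centre {tuple(center_voxel)} lies outside the wall mask"
            )
        lesion = _sphere_at(spec, center_voxel, radius_mm) & masks["wall"]
        t2_post[lesion] = t2_pre[lesion] * frac
        enh_mask |= lesion

    te = np.asarray(spec.echo_times, dtype=float)
    rng = _rng_from(spec.seed)

    clean_pre = spec.s0 * np.exp(-te[None, None, None, :] / t2_pre[..., None])
    clean_post = spec.s0 * np.exp(-te[None, None, None, :] / t2_post[..., None])

    motion = spec.inter_visit_motion
    moved_post = np.empty_like(clean_post)
    inverse = motion.inverse()
    for e in range(te.size):
        moved_post[..., e] = apply_transform(
            clean_post[..., e], inverse, "linear", spec.voxel_spacing
        )

    pre = MultiEchoVolume(
        _rician(clean_pre, spec.noise_sigma, rng), te, spec.voxel_spacing
    )
    post = MultiEchoVolume(
        _rician(moved_post, spec.noise_sigma, rng), te, spec.voxel_spacing
    )
    truth = PhantomTruth(
        masks=masks,
        t2star_pre=t2_pre,
        t2star_post=t2_post,
        enhancement_mask=enh_mask,
        transform=motion,
        enhanced=bool(spec.enhancement_lesions),
    )
    return pre, post, truth


# ---------------------------------------------------------------------------
# clinical cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSimParams:
    """Calibration of the synthetic surveillance cohort.

    Defaults follow the study's printed summary statistics: baseline
    diameter 49.6 +/- 7.7 mm, growth 2.8 +/- 2.4 mm/yr with a 0.6 mm/yr
    shift in enhanced patients, ultrasound CV 3.5%, 6-monthly visits,
    ~3-year administrative censoring, diameter log-hazard ln(1.077)/mm and
    current-smoking log-hazard ln(1.464).  Covariate marginals not printed
    in the study (sex, smoking, blood pressure) use surveillance-population
    values.
    """

    n_patients: int = 342
    baseline_diameter_mean: float = 49.6
    baseline_diameter_sd: float = 7.7
    smoking_prevalence: float = 0.30
    male_fraction: float = 0.85
    sbp_mean: float = 140.0
    sbp_sd: float = 18.0
    # logistic model for true USPIO enhancement
    enhancement_intercept: float = -0.56
    enhancement_beta_diameter: float = 0.075  # per mm, centred at the mean
    enhancement_beta_smoking: float = 0.9
    # per-patient growth (mm/yr); marginal mean/sd, with enhanced shift
    growth_mean: float = 2.8
    growth_sd: float = 2.4
    growth_enhancement_shift: float = 0.6
    # exponential proportional-hazards event model (per day)
    baseline_hazard: float = 1.09e-3
    log_hr_diameter: float = float(np.log(1.077))  # per mm, centred
    log_hr_smoking: float = float(np.log(1.464))
    event_type_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_EVENT_TYPE_PROBS)
    )
    followup_days: float = 1095.0
    ultrasound_cv: float = 0.035
    visit_interval_days: float = 182.625
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for p in (self.smoking_prevalence, self.male_fraction):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if self.ultrasound_cv < 0:
            raise ValueError("ultrasound CV must be >= 0")
        probs = np.asarray(list(self.event_type_probs.values()))
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("event type probabilities must be >= 0 and sum to 1")


@dataclass
class CohortTable:
    """Per-patient covariates/outcomes plus the long-format ultrasound table.

    ``patients`` columns: patient_id, sex, current_smoker, sbp_mmhg,
    baseline_diameter_mm, true_enhanced, observed_status,
    true_growth_mm_per_yr, event_time_days, event, event_type.
    ``ultrasound`` columns: patient_id, time_years, diameter_mm.
    """

    patients: pd.DataFrame
    ultrasound: pd.DataFrame


def simulate_ultrasound_series(
    baseline_mm: float,
    slope_mm_per_yr: float,
    cv: float,
    visit_interval_days: float,
    max_days: float,
    rng,
):
    """Noisy serial diameters: (baseline + slope*t) * (1 + N(0, cv)) at
    6-monthly visits until ``max_days``; the baseline visit always exists."""
    rng = _rng_from(rng)
    times_days = np.arange(0.0, max_days + 1e-9, visit_interval_days)
    if times_days.size == 0:
        times_days = np.array([0.0])
    t_years = times_days / 365.25
    clean = baseline_mm + slope_mm_per_yr * t_years
    noise = rng.normal(0.0, cv, size=t_years.shape) if cv > 0 else 0.0
    return t_years, clean * (1.0 + noise)


def simulate_cohort(params: CohortSimParams | None = None) -> CohortTable:
    """Draw a synthetic surveillance cohort from the configured models."""
    params = params or CohortSimParams()
    root = np.random.SeedSequence(params.seed)
    rng_cov, rng_growth, rng_event, rng_us = [
        np.random.default_rng(s) for s in root.spawn(4)
    ]
    n = params.n_patients

    male = rng_cov.random(n) < params.male_fraction
    smoker = rng_cov.random(n) < params.smoking_prevalence
    sbp = rng_cov.normal(params.sbp_mean, params.sbp_sd, n)
    diam = rng_cov.normal(params.baseline_diameter_mean, params.baseline_diameter_sd, n)
    diam = np.clip(diam, 30.0, None)  # surveillance entry criterion

    dc = diam - params.baseline_diameter_mean
    logit = (
        params.enhancement_intercept
        + params.enhancement_beta_diameter * dc
        + params.enhancement_beta_smoking * smoker
    )
    p_enh = 1.0 / (1.0 + np.exp(-logit))
    enhanced = rng_cov.random(n) < p_enh

    slope = rng_growth.normal(
        params.growth_mean
        + params.growth_enhancement_shift * (enhanced - p_enh.mean()),
        params.growth_sd,
        n,
    )

    rate = params.baseline_hazard * np.exp(
        params.log_hr_diameter * dc + params.log_hr_smoking * smoker
    )
    raw_time = rng_event.exponential(1.0 / rate)
    fired = raw_time <= params.followup_days
    types = list(params.event_type_probs)
    type_probs = np.asarray([params.event_type_probs[t] for t in types])
    drawn = rng_event.choice(len(types), size=n, p=type_probs)
    event_type = np.where(fired, np.asarray(types, dtype=object)[drawn], "censored")
    event = np.array(
        [1 if t in PRIMARY_EVENT_TYPES else 0 for t in event_type], dtype=int
    )
    event_time = np.where(fired, raw_time, params.followup_days)

    us_rows = []
    for i in range(n):
        t_years, diams = simulate_ultrasound_series(
            diam[i],
            slope[i],
            params.ultrasound_cv,
            params.visit_interval_days,
            event_time[i],
            rng_us,
        )
        for t, d in zip(t_years, diams):
            us_rows.append((i, float(t), float(d)))

    patients = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "sex": np.where(male, "M", "F"),
            "current_smoker": smoker.astype(int),
            "sbp_mmhg": sbp,
            "baseline_diameter_mm": diam,
            "true_enhanced": enhanced.astype(int),
            "observed_status": np.where(enhanced, "enhanced", "nonenhanced"),
            "true_growth_mm_per_yr": slope,
            "event_time_days": event_time,
            "event": event,
            "event_type": event_type,
        }
    )
    ultrasound = pd.DataFrame(
        us_rows, columns=["patient_id", "time_years", "diameter_mm"]
    )
    return CohortTable(patients=patients, ultrasound=ultrasound)
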