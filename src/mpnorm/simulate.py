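"""Synthetic microperimetry cohorts.

Because real exam databases of this kind are private, this module
generates healthy and patient cohorts with the statistical structure the
analysis assumes, so every pipeline stage can be exercised and calibrated
end to end.

The healthy model for eye i, locus j is

    s_ij = round(intercept - age_slope * age_i - ecc_gradient * ecc_j
                 + b_i + eps_ij)              clipped to [-1, 36]

with a subject-level random effect b_i ~ N(0, subject_sd^2) and
independent locus noise eps_ij ~ N(0, locus_noise_sd^2).  The default
intercept (29.8 dB at age 0) and decline (0.03 dB/year) reproduce the
published healthy mean-sensitivity trend in expectation; ages are
truncated-normal with the healthy cohort's mean 53.5 and SD 14.6 years.
Rounding to integer dB emulates the device's discrete staircase output;
a full 4-2 staircase simulation is available as an optional fidelity
layer (``CohortConfig.use_staircase``).

Patient ("cuticular drusen") eyes use the published patient trend
(intercept 29.9 dB, decline 0.06 dB/year, ages 48.5 +/- 12.4) and then
receive localized sensitivity drops at a small number of loci sampled
with ring-dependent weights biased away from the grid centre; the
injected loci and depths are returned as ground truth for recovery tests.

Loci are conditionally independent given the subject effect; real exams
likely carry additional spatial correlation, which this model does not
emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .exams import CohortTable, FixationTrace, SensitivityExam
from .grid import N_LOCI, RINGS, TestGrid

#: Published cohort age distributions (years).
HEALTHY_AGE_MEAN, HEALTHY_AGE_SD = 53.5, 14.6
PATIENT_AGE_MEAN, PATIENT_AGE_SD = 48.5, 12.4


@dataclass
class CohortConfig:
    """Generative parameters for a healthy cohort."""

    n_eyes: int = 80
    age_mean: float = HEALTHY_AGE_MEAN
    age_sd: float = HEALTHY_AGE_SD
    age_range: tuple[float, float] = (18.0, 90.0)
    intercept: float = 29.8          # dB at age 0
    age_slope: float = 0.03          # dB lost per year
    ecc_gradient: float = 0.3        # dB lost per degree eccentricity
    subject_sd: float = 1.0          # between-eye random effect, dB
    locus_noise_sd: float = 1.5      # within-eye noise, dB
    bcea_range: tuple[float, float] = (0.5, 4.0)  # deg^2, all pass the default filter
    seed: int = 0
    use_staircase: bool = False
    staircase_start: int = 27

    def validate(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")
        for name in ("age_sd", "ecc_gradient", "subject_sd", "locus_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be non-degenerate")


def patient_config(**overrides) -> CohortConfig:
    """A CohortConfig with the published patient age distribution."""
    cfg = CohortConfig(n_eyes=27, age_mean=PATIENT_AGE_MEAN, age_sd=PATIENT_AGE_SD)
    return replace(cfg, **overrides)


@dataclass
class ScotomaConfig:
    """Localized sensitivity-drop injection for patient eyes."""

    n_affected_loci: int = 5
    depth_mean: float = 6.0          # dB
    depth_sd: float = 2.0            # dB
    # inner : middle : outer sampling weights; defaults bias lesions away
    # from the grid centre, matching the observed centrifugal distribution.
    ring_weights: tuple[float, float, float] = (1.0, 1.5, 1.3)
    patient_age_slope: float = 0.06  # dB lost per year
    patient_intercept: float = 29.9  # dB at age 0

    def validate(self) -> None:
        if not 0 <= self.n_affected_loci <= N_LOCI:
            raise ValueError(f"n_affected_loci must be in [0, {N_LOCI}]")
        if self.depth_mean < 0 or self.depth_sd < 0:
            raise ValueError("depth parameters must be non-negative")
        w = np.asarray(self.ring_weights, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("ring_weights must be 3 non-negative values, not all zero")


@dataclass
class Observer:
    """Psychometric observer for the staircase simulator.

    Sees a stimulus at level d (dB attenuation) with probability
    1 - lapse_rate when d <= true_threshold, else guess_rate.
    """

    true_threshold: float
    guess_rate: float = 0.0
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("guess_rate", "lapse_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.1:
                raise ValueError(f"{name} must be in [0, 0.1]")


def _truncnorm_ages(rng: np.random.Generator, cfg: CohortConfig) -> np.ndarray:
    lo, hi = cfg.age_range
    if cfg.age_sd == 0:
        return np.full(cfg.n_eyes, float(np.clip(cfg.age_mean, lo, hi)))
    a = (lo - cfg.age_mean) / cfg.age_sd
    b = (hi - cfg.age_mean) / cfg.age_sd
    return stats.truncnorm.rvs(a, b, loc=cfg.age_mean, scale=cfg.age_sd,
                               size=cfg.n_eyes, random_state=rng)


def _measure(true_thresholds: np.ndarray, cfg: CohortConfig,
             rng: np.random.Generator) -> np.ndarray:
    """Integer dB measurements from latent thresholds (rounding or staircase)."""
    if cfg.use_staircase:
        out = np.empty(true_thresholds.shape, dtype=int)
        flat = true_thresholds.ravel()
        res = np.empty(flat.shape, dtype=int)
        for k, t in enumerate(flat):
            res[k] = simulate_staircase_4_2(Observer(t), cfg.staircase_start, rng=rng)
        out = res.reshape(true_thresholds.shape)
        return out
    return np.clip(np.rint(true_thresholds), -1, 36).astype(int)


def _generate(cfg: CohortConfig, grid: TestGrid, intercept: float, age_slope: float,
              cohort_label: str, prefix: str, rng: np.random.Generator,
              injections: Optional[tuple[np.ndarray, np.ndarray]] = None) -> CohortTable:
    ecc = grid.eccentricities
    ages = _truncnorm_ages(rng, cfg)
    b = rng.normal(0.0, cfg.subject_sd, cfg.n_eyes) if cfg.subject_sd > 0 else np.zeros(cfg.n_eyes)
    eps = (rng.normal(0.0, cfg.locus_noise_sd, (cfg.n_eyes, N_LOCI))
           if cfg.locus_noise_sd > 0 else np.zeros((cfg.n_eyes, N_LOCI)))
    true_thr = (intercept - age_slope * ages[:, None]
                - cfg.ecc_gradient * ecc[None, :] + b[:, None] + eps)
    if injections is not None:
        loci, depths = injections
        rows = np.repeat(np.arange(cfg.n_eyes), loci.shape[1])
        true_thr[rows, loci.ravel()] -= depths.ravel()
    measured = _measure(true_thr, cfg, rng)
    bcea63 = rng.uniform(*cfg.bcea_range, cfg.n_eyes)
    exams = [
        SensitivityExam(
            subject_id=f"{prefix}{i:04d}",
            age=float(ages[i]),
            laterality="right",
            sensitivities=measured[i],
            bcea63=float(bcea63[i]),
            cohort_label=cohort_label,
        )
        for i in range(cfg.n_eyes)
    ]
    return CohortTable(exams, provenance=f"synthetic:{cohort_label}:seed={cfg.seed}")


def generate_healthy_cohort(config: CohortConfig, grid: TestGrid) -> CohortTable:
    """Generate a healthy cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    return _generate(config, grid, config.intercept, config.age_slope,
                     "healthy", "H", rng)


def generate_cd_cohort(config: CohortConfig, scotoma: ScotomaConfig, grid: TestGrid
                       ) -> tuple[CohortTable, pd.DataFrame]:
    """Generate a patient cohort with injected relative scotomas.

    Returns the cohort and a ground-truth table (subject_id, locus_id,
    depth_db) of the injected lesions.  Depths are N(depth_mean,
    depth_sd^2) clipped at 0 and subtracted from the latent threshold
    before measurement, so the injected loss interacts with rounding and
    the -1 floor the same way a real lesion would.
    """
    config.validate()
    scotoma.validate()
    rng = np.random.default_rng(config.seed)
    k = scotoma.n_affected_loci
    ring_w = dict(zip(RINGS, scotoma.ring_weights))
    w = np.array([ring_w[r] for r in grid.rings], dtype=float)
    p = w / w.sum()
    loci = np.empty((config.n_eyes, k), dtype=int)
    depths = np.empty((config.n_eyes, k))
    for i in range(config.n_eyes):
        loci[i] = rng.choice(N_LOCI, size=k, replace=False, p=p) if k else []
        depths[i] = np.clip(rng.normal(scotoma.depth_mean, scotoma.depth_sd, k), 0.0, None) \
            if scotoma.depth_sd > 0 else np.full(k, scotoma.depth_mean)
    table = _generate(config, grid, scotoma.patient_intercept, scotoma.patient_age_slope,
                      "cuticular_drusen", "P", rng, injections=(loci, depths))
    truth = pd.DataFrame(
        {
            "subject_id": np.repeat([e.subject_id for e in table.exams], k),
            "locus_id": loci.ravel(),
            "depth_db": depths.ravel(),
        }
    )
    return table, truth


def simulate_staircase_4_2(observer: Observer, start_db: int = 27,
                           rng: Optional[np.random.Generator] = None,
                           db_range: tuple[int, int] = (0, 36)) -> int:
    """Simulate a 4-2 staircase threshold measurement.

    Steps 4 dB (dimmer after seen, brighter after not seen) until the
    first response reversal, then 2 dB; terminates at the second reversal
    and returns the last-seen level.  A stimulus that is not seen at the
    device floor (0 dB, brightest) terminates with -1; a stimulus seen at
    the ceiling (36 dB, dimmest) terminates with 36.
    """
    lo, hi = db_range
    if not lo <= start_db <= hi:
        raise ValueError(f"start_db {start_db} outside range {db_range}")
    if (observer.guess_rate > 0 or observer.lapse_rate > 0) and rng is None:
        rng = np.random.default_rng()

    def seen(level: int) -> bool:
        p = (1.0 - observer.lapse_rate) if level <= observer.true_threshold else observer.guess_rate
        if p >= 1.0:
            return True
        if p <= 0.0:
            return False
        return bool(rng.random() < p)

    level = int(start_db)
    step = 4
    last_seen: Optional[int] = None
    prev: Optional[bool] = None
    reversals = 0
    for _ in range(500):  # hard cap; a lapsing observer cannot loop forever
        s = seen(level)
        if s:
            last_seen = level
        if prev is not None and s != prev:
            reversals += 1
            if reversals == 1:
                step = 2
            else:
                return last_seen if last_seen is not None else -1
        prev = s
        if s:
            nxt = level + step
            if nxt > hi:
                if level == hi:
                    return hi
                nxt = hi
        else:
            nxt = level - step
            if nxt < lo:
                if level == lo:
                    return -1
                nxt = lo
        level = nxt
    return last_seen if last_seen is not None else -1


def generate_fixation_trace(bcea63_target: float, n_samples: int, seed: int = 0,
                            coverage: float = 0.63) -> FixationTrace:
    """Isotropic bivariate-normal fixation trace with a set population BCEA.

    The population 63% BCEA of N(0, sigma^2 I) is 2*pi*(-ln 0.37)*sigma^2;
    sigma is chosen so that this equals ``bcea63_target``, so the empirical
    BCEA converges to the target as the trace grows.
    """
    if bcea63_target <= 0:
        raise ValueError("bcea63_target must be positive")
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    k = -math.log(1.0 - coverage)
    sigma = math.sqrt(bcea63_target / (2.0 * math.pi * k))
    rng = np.random.default_rng(seed)
    return FixationTrace(rng.normal(0.0, sigma, (n_samples, 2)))
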