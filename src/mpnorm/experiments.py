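"""Self-contained calibration and validation experiments.

These compose the generator, the quantile reference and the deviation
analysis into the three simulation studies the package uses to validate
itself:

* **null calibration** -- the 2.5th-percentile flagging rule should behave
  as a 2.5% rule on healthy eyes it has never seen;
* **trend recovery** -- ordinary least squares on simulated mean
  sensitivities should recover the generator's age decline;
* **dissociation** -- a cohort with a handful of moderately deep scotomas
  per eye should be flagged decisively by pointwise deviation while the
  mean-sensitivity comparison stays non-significant.

Every function takes a single integer seed and derives independent
sub-streams from it, so runs are reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .deviation import (
    ci95_mean,
    flag_matrix,
    ols_age_fit,
    pointwise_deviation,
    summarize_eye,
    welch_t_test,
)
from .exams import mean_sensitivity
from .grid import build_maia_grid
from .normative import build_reference
from .simulate import CohortConfig, ScotomaConfig, generate_cd_cohort, generate_healthy_cohort

#: Expected abnormal-locus count per healthy eye under the null: 37 * 0.025.
NULL_EXPECTED_N_ABNORMAL = 37 * 0.025


def _subseed(seed: int, k: int) -> int:
    """Independent 31-bit child seed k of a base seed."""
    return int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0] % (2**31))


def null_calibration_rate(seed: int, n_train: int = 2000, n_test: int = 2000) -> float:
    """Held-out flag percentage under the null model.

    Builds the tau=0.025 reference from ``n_train`` healthy eyes and scores
    ``n_test`` independent eyes from the same generative model.  Returns
    the percentage of locus observations falling strictly below their
    locus- and age-specific cutoff, averaged over loci.  A calibrated
    reference gives about 2.5%.
    """
    grid = build_maia_grid()
    train = generate_healthy_cohort(
        CohortConfig(n_eyes=n_train, seed=_subseed(seed, 0)), grid
    )
    test = generate_healthy_cohort(
        CohortConfig(n_eyes=n_test, seed=_subseed(seed, 1)), grid
    )
    ref = build_reference(train, grid)
    slopes, intercepts = ref.line_arrays(0.025)
    ages = test.ages()
    cutoffs = intercepts[None, :] + slopes[None, :] * ages[:, None]
    flags = test.sensitivity_matrix() < cutoffs
    return float(100.0 * flags.mean(axis=0).mean())


def trend_recovery_slope(seed: int, n_eyes: int = 500) -> float:
    """|OLS slope| of mean sensitivity on age, default healthy cohort of ``n_eyes``."""
    grid = build_maia_grid()
    cohort = generate_healthy_cohort(CohortConfig(n_eyes=n_eyes, seed=_subseed(seed, 2)), grid)
    ms = [mean_sensitivity(e) for e in cohort]
    fit = ols_age_fit(cohort.ages(), ms)
    return abs(fit.slope)


@dataclass
class DissociationResult:
    welch_p: float
    mean_n_abnormal: float
    ci_n_abnormal: tuple[float, float]
    mean_ms_patients: float
    mean_ms_healthy: float
    n_per_group: int


def dissociation_experiment(seed: int, n_reference: int = 400, n_per_group: int = 6,
                            n_scotoma_loci: int = 5, depth_db: float = 6.0) -> DissociationResult:
    """Pointwise-vs-mean dissociation in miniature.

    The patient group is drawn from the *healthy* trend coefficients with
    ``n_scotoma_loci`` loci deepened by exactly ``depth_db`` each, so the
    scotomas are the only systematic difference from the healthy
    comparison group.  Group sizes are deliberately small: the
    mean-sensitivity effect of 5 x 6 dB lesions is ~0.8 dB against a
    between-eye SD of ~1.1 dB, so the Welch test has little power at
    n = 6 per group, while the abnormal-locus count (about 5 per patient
    eye against a null expectation of 0.925) remains decisive.
    """
    grid = build_maia_grid()
    ref_cohort = generate_healthy_cohort(
        CohortConfig(n_eyes=n_reference, seed=_subseed(seed, 3)), grid
    )
    ref = build_reference(ref_cohort, grid)

    healthy_group = generate_healthy_cohort(
        CohortConfig(n_eyes=n_per_group, seed=_subseed(seed, 4)), grid
    )
    base = CohortConfig(n_eyes=n_per_group, seed=_subseed(seed, 5))
    patient_cfg = replace(base, age_mean=48.5, age_sd=12.4)
    scotoma = ScotomaConfig(
        n_affected_loci=n_scotoma_loci,
        depth_mean=depth_db,
        depth_sd=0.0,
        patient_intercept=base.intercept,   # healthy trend: isolate the lesions
        patient_age_slope=base.age_slope,
    )
    patients, _ = generate_cd_cohort(patient_cfg, scotoma, grid)

    dev_sets = [pointwise_deviation(e, ref) for e in patients]
    summaries = [summarize_eye(e, d, grid) for e, d in zip(patients, dev_sets)]
    n_abn = [s.n_abnormal for s in summaries]
    ms_p = [mean_sensitivity(e) for e in patients]
    ms_h = [mean_sensitivity(e) for e in healthy_group]
    welch = welch_t_test(ms_p, ms_h)
    return DissociationResult(
        welch_p=welch.p,
        mean_n_abnormal=float(np.mean(n_abn)),
        ci_n_abnormal=ci95_mean(n_abn),
        mean_ms_patients=float(np.mean(ms_p)),
        mean_ms_healthy=float(np.mean(ms_h)),
        n_per_group=n_per_group,
    )
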