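"""Pointwise deviation analysis and cohort statistics.

For a patient exam scored against the normative reference, each locus gets
a *pointwise deviation*: the observed sensitivity minus the age-matched
prediction of the median (tau = 0.5) line at that locus.  Negative values
mean the eye is less sensitive than an age- and location-adjusted normal
eye.  A locus is flagged *abnormal* (relative scotoma) when the observed
value falls strictly below the 2.5th-percentile line -- the lower bound of
the 95% prediction band -- at the subject's age.  Ties sitting exactly on
the line count as normal.

Per-eye summaries average the deviation over the whole grid (mean
sensitivity deviation) and count abnormal loci overall and per
eccentricity ring; cohort summaries add t-based 95% confidence intervals,
per-locus flag percentages with ring-level mean/SD, a Welch two-sample
t-test of mean sensitivity against a comparison cohort, and ordinary
least-squares fits of mean sensitivity on age.  No multiple-testing
correction is applied across the 37 loci: the flag counts are descriptive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import exams as ex
from .exams import CohortTable, SensitivityExam, apply_inclusion_filter, mean_sensitivity
from .grid import N_LOCI, RINGS, TestGrid, mirror_to_right_eye
from .normative import (
    DEFAULT_MIN_N,
    DEFAULT_TAUS,
    ExtrapolationWarning,
    NormativeReference,
    build_reference,
)

TAU_CUTOFF = 0.025
TAU_MEDIAN = 0.5


@dataclass(frozen=True)
class PointwiseDeviation:
    """Deviation record for a single locus of a single eye."""

    locus_id: int
    observed: float
    expected_median: float
    deviation: float
    cutoff_2p5: float
    abnormal: bool


@dataclass(frozen=True)
class EyeDeviationSummary:
    """Whole-grid summary of one eye's deviations."""

    subject_id: str
    age: float
    mean_sensitivity: float
    mean_sensitivity_deviation: float
    n_abnormal: int
    abnormal_by_ring: dict[str, int]


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    mean_diff: float
    ci95: tuple[float, float]


@dataclass
class OLSFit:
    slope: float
    intercept: float
    r_squared: float
    p: float


@dataclass
class CohortSummary:
    """Cohort-level deviation statistics (None fields where not applicable)."""

    n_eyes: int
    mean_n_abnormal: Optional[float] = None
    ci_n_abnormal: Optional[tuple[float, float]] = None
    mean_ms_deviation: Optional[float] = None
    ci_ms_deviation: Optional[tuple[float, float]] = None
    per_locus_pct: Optional[np.ndarray] = None
    ring_pct_mean: Optional[dict[str, float]] = None
    ring_pct_sd: Optional[dict[str, float]] = None
    ms_age_fit: Optional[OLSFit] = None
    welch_ms_vs_comparison: Optional[WelchResult] = None


def pointwise_deviation(exam: SensitivityExam, ref: NormativeReference,
                        tau_cutoff: float = TAU_CUTOFF,
                        tau_median: float = TAU_MEDIAN) -> list[PointwiseDeviation]:
    """Score one right-oriented exam against the reference, locus by locus."""
    if exam.laterality != "right":
        raise ValueError("exam must be in right-eye orientation (mirror first)")
    med_slope, med_int = ref.line_arrays(tau_median)
    cut_slope, cut_int = ref.line_arrays(tau_cutoff)
    lo, hi = ref.age_range
    if not lo <= exam.age <= hi:
        warnings.warn(
            f"{exam.subject_id}: age {exam.age:.1f} outside training range "
            f"[{lo:.1f}, {hi:.1f}]; extrapolating the reference lines",
            ExtrapolationWarning,
            stacklevel=2,
        )
    obs = np.asarray(exam.sensitivities, dtype=float)
    expected = med_int + med_slope * exam.age
    cutoff = cut_int + cut_slope * exam.age
    out = []
    for lid in range(N_LOCI):
        out.append(
            PointwiseDeviation(
                locus_id=lid,
                observed=float(obs[lid]),
                expected_median=float(expected[lid]),
                deviation=float(obs[lid] - expected[lid]),
                cutoff_2p5=float(cutoff[lid]),
                abnormal=bool(obs[lid] < cutoff[lid]),
            )
        )
    return out


def summarize_eye(exam: SensitivityExam, deviations: Sequence[PointwiseDeviation],
                  grid: TestGrid) -> EyeDeviationSummary:
    """Aggregate one eye's 37 deviation records."""
    if len(deviations) != N_LOCI:
        raise ValueError(f"expected {N_LOCI} deviations, got {len(deviations)}")
    rings = grid.rings
    by_ring = {r: 0 for r in RINGS}
    n_abn = 0
    for d in deviations:
        if d.abnormal:
            n_abn += 1
            by_ring[rings[d.locus_id]] += 1
    return EyeDeviationSummary(
        subject_id=exam.subject_id,
        age=exam.age,
        mean_sensitivity=mean_sensitivity(exam),
        mean_sensitivity_deviation=float(np.mean([d.deviation for d in deviations])),
        n_abnormal=n_abn,
        abnormal_by_ring=by_ring,
    )


def flag_matrix(deviation_sets: Sequence[Sequence[PointwiseDeviation]]) -> np.ndarray:
    """(n_eyes, 37) boolean abnormality matrix from per-eye deviation lists."""
    mat = np.zeros((len(deviation_sets), N_LOCI), dtype=bool)
    for i, devs in enumerate(deviation_sets):
        for d in devs:
            mat[i, d.locus_id] = d.abnormal
    return mat


def cohort_flag_percentages(flags: np.ndarray, grid: TestGrid
                            ) -> tuple[np.ndarray, dict[str, float], dict[str, float]]:
    """Per-locus flag percentages and their ring-level mean/SD.

    ``flags`` is an (n_eyes, 37) boolean matrix.  Percentages are
    100 * (eyes abnormal at the locus) / (total eyes); ring means and SDs
    (n-1 denominator) are taken across the member loci's percentages.
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.ndim != 2 or flags.shape[1] != N_LOCI:
        raise ValueError(f"flags must be (n_eyes, {N_LOCI})")
    if flags.shape[0] == 0:
        raise ValueError("empty cohort")
    pct = 100.0 * flags.mean(axis=0)
    ring_mean: dict[str, float] = {}
    ring_sd: dict[str, float] = {}
    for ring in RINGS:
        members = grid.ring_loci(ring)
        vals = pct[members]
        ring_mean[ring] = float(vals.mean())
        ring_sd[ring] = float(vals.std(ddof=1))
    return pct, ring_mean, ring_sd


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch two-sample t-test with Welch-Satterthwaite df and 95% CI of the mean difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("both groups have zero variance; t is undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(0.95)
    return WelchResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_diff=float(a.mean() - b.mean()),
        ci95=(float(ci.low), float(ci.high)),
    )


def ols_age_fit(ages: Sequence[float], ms: Sequence[float]) -> OLSFit:
    """OLS fit of mean sensitivity on age; R^2 = 1 - SSE/SST.

    A constant response is returned as slope 0, R^2 = 0, p = 1 (documented
    convention for the degenerate case).
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(ms, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("ages are all identical")
    if np.ptp(y) == 0:
        return OLSFit(slope=0.0, intercept=float(y[0]), r_squared=0.0, p=1.0)
    r = stats.linregress(x, y)
    return OLSFit(
        slope=float(r.slope),
        intercept=float(r.intercept),
        r_squared=float(r.rvalue**2),
        p=float(r.pvalue),
    )


def ci95_mean(values: Sequence[float], confidence: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval for a mean: mean +/- t_{1-alpha/2, n-1} * s/sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    m = v.mean()
    half = stats.t.ppf(0.5 + confidence / 2.0, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size)
    return (float(m - half), float(m + half))


@dataclass
class CohortAnalysisResult:
    """Everything the end-to-end cohort analysis produces."""

    reference: NormativeReference
    patient_summary: CohortSummary
    healthy_summary: CohortSummary
    eye_summaries: list[EyeDeviationSummary]
    eye_table: pd.DataFrame
    per_locus_pct: np.ndarray
    excluded_patients: list[str]
    excluded_healthy: list[str]


def _eye_table(summaries: Iterable[EyeDeviationSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "subject_id": s.subject_id,
                "age": s.age,
                "mean_sensitivity": s.mean_sensitivity,
                "mean_sensitivity_deviation": s.mean_sensitivity_deviation,
                "n_abnormal": s.n_abnormal,
                **{f"n_abnormal_{r}": s.abnormal_by_ring[r] for r in RINGS},
            }
        )
    return pd.DataFrame(rows)


def run_cohort_analysis(patients: CohortTable, healthy: CohortTable, grid: TestGrid,
                        taus: Iterable[float] = DEFAULT_TAUS,
                        bcea_limit: float = ex.BCEA_LIMIT,
                        min_n: int = DEFAULT_MIN_N) -> CohortAnalysisResult:
    """End-to-end analysis: mirror, filter, fit the reference, score patients.

    Deterministic given its inputs.  Stages: (1) mirror all exams to
    right-eye orientation; (2) apply the fixation-stability filter to both
    cohorts; (3) build the quantile reference from the healthy cohort;
    (4) compute pointwise deviations and per-eye summaries for patients;
    (5) aggregate cohort statistics, including the Welch comparison of
    mean sensitivity between the cohorts and per-cohort MS-on-age fits.
    """
    taus = tuple(taus)
    for needed in (TAU_CUTOFF, TAU_MEDIAN):
        if needed not in taus:
            raise ValueError(f"taus must include {needed}")

    def _prep(table: CohortTable, stage: str) -> tuple[CohortTable, list[str]]:
        try:
            mirrored = CohortTable(
                [mirror_to_right_eye(e, grid) for e in table.exams],
                provenance=table.provenance,
            )
            kept = apply_inclusion_filter(mirrored, bcea_limit)
        except Exception as err:
            raise RuntimeError(f"{stage}: {err}") from err
        kept_keys = {e.subject_id for e in kept}
        excluded = [e.subject_id for e in table.exams if e.subject_id not in kept_keys]
        return kept, excluded

    healthy_kept, excl_h = _prep(healthy, "healthy preprocessing")
    patients_kept, excl_p = _prep(patients, "patient preprocessing")
    if len(patients_kept) == 0:
        raise RuntimeError("patient preprocessing: no patient exams pass the inclusion filter")

    try:
        ref = build_reference(healthy_kept, grid, taus=taus, min_n=min_n)
    except Exception as err:
        raise RuntimeError(f"reference building: {err}") from err

    dev_sets = [pointwise_deviation(e, ref) for e in patients_kept]
    summaries = [summarize_eye(e, d, grid) for e, d in zip(patients_kept, dev_sets)]
    flags = flag_matrix(dev_sets)
    pct, ring_mean, ring_sd = cohort_flag_percentages(flags, grid)

    n_abn = np.array([s.n_abnormal for s in summaries], dtype=float)
    msd = np.array([s.mean_sensitivity_deviation for s in summaries])
    ms_p = np.array([s.mean_sensitivity for s in summaries])
    ms_h = np.array([mean_sensitivity(e) for e in healthy_kept])
    ages_p = np.array([s.age for s in summaries])
    ages_h = healthy_kept.ages()

    welch = welch_t_test(ms_p, ms_h) if len(ms_p) >= 2 else None
    patient_summary = CohortSummary(
        n_eyes=len(patients_kept),
        mean_n_abnormal=float(n_abn.mean()),
        ci_n_abnormal=ci95_mean(n_abn) if n_abn.size >= 2 else None,
        mean_ms_deviation=float(msd.mean()),
        ci_ms_deviation=ci95_mean(msd) if msd.size >= 2 else None,
        per_locus_pct=pct,
        ring_pct_mean=ring_mean,
        ring_pct_sd=ring_sd,
        ms_age_fit=ols_age_fit(ages_p, ms_p) if len(ms_p) >= 3 and np.ptp(ages_p) > 0 else None,
        welch_ms_vs_comparison=welch,
    )
    healthy_summary = CohortSummary(
        n_eyes=len(healthy_kept),
        ms_age_fit=ols_age_fit(ages_h, ms_h) if len(ms_h) >= 3 and np.ptp(ages_h) > 0 else None,
    )
    return CohortAnalysisResult(
        reference=ref,
        patient_summary=patient_summary,
        healthy_summary=healthy_summary,
        eye_summaries=summaries,
        eye_table=_eye_table(summaries),
        per_locus_pct=pct,
        excluded_patients=excl_p,
        excluded_healthy=excl_h,
    )
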