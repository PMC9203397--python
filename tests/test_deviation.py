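import math

import numpy as np
import pytest
from scipy import stats

from mpnorm.deviation import (
    ci95_mean,
    cohort_flag_percentages,
    flag_matrix,
    ols_age_fit,
    pointwise_deviation,
    run_cohort_analysis,
    summarize_eye,
    welch_t_test,
)
from mpnorm.exams import CohortTable, SensitivityExam
from mpnorm.normative import NormativeReference, QuantileFit
from mpnorm.simulate import CohortConfig, generate_healthy_cohort


def _flat_reference(grid, median=28.0, cutoff=24.0):
    """Reference with age-independent lines: median and cutoff constants."""
    fits = {
        lid: {
            0.5: QuantileFit(0.5, 0.0, median, 0.0, 30),
            0.025: QuantileFit(0.025, 0.0, cutoff, 0.0, 30),
        }
        for lid in range(37)
    }
    return NormativeReference(grid, fits, (20.0, 80.0), 30)


def _exam(sens, sid="p1", age=50.0):
    return SensitivityExam(sid, age, "right", np.asarray(sens, dtype=int), 2.0, "cuticular_drusen")


def _sloped_reference(grid):
    fits = {
        lid: {
            0.5: QuantileFit(0.5, -0.03, 29.8, 0.0, 30),
            0.025: QuantileFit(0.025, -0.03, 25.5, 0.0, 30),
        }
        for lid in range(37)
    }
    return NormativeReference(grid, fits, (20.0, 80.0), 30)


# ---------------------------------------------------------------- pointwise

def test_deviation_arithmetic(grid):
    ref = _sloped_reference(grid)
    sens = np.full(37, 28)
    sens[0] = 20
    devs = pointwise_deviation(_exam(sens, age=50.0), ref)
    # median line at 50y: 29.8 - 1.5 = 28.3; cutoff: 25.5 - 1.5 = 24.0
    assert devs[0].deviation == pytest.approx(20 - 28.3)
    assert devs[0].abnormal is True
    assert devs[1].deviation == pytest.approx(28 - 28.3)
    assert devs[1].abnormal is False
    for d in devs:
        assert d.deviation == pytest.approx(d.observed - d.expected_median)
        assert d.abnormal == (d.observed < d.cutoff_2p5)


def test_deviation_tie_on_cutoff_is_normal(grid):
    ref = _flat_reference(grid, median=28.0, cutoff=24.0)
    sens = np.full(37, 24)  # exactly on the 2.5th-percentile line
    devs = pointwise_deviation(_exam(sens), ref)
    assert not any(d.abnormal for d in devs)


def test_deviation_identity_case(grid):
    ref = _flat_reference(grid, median=28.0)
    devs = pointwise_deviation(_exam(np.full(37, 28)), ref)
    assert all(d.deviation == 0.0 for d in devs)
    s = summarize_eye(_exam(np.full(37, 28)), devs, grid)
    assert s.mean_sensitivity_deviation == 0.0
    assert s.n_abnormal == 0


def test_deviation_requires_right_eye(grid):
    ref = _flat_reference(grid)
    exam = SensitivityExam("x", 50.0, "left", np.full(37, 28), 2.0)
    with pytest.raises(ValueError, match="right-eye"):
        pointwise_deviation(exam, ref)


# ---------------------------------------------------------------- eye summary

def test_summarize_eye_ring_bookkeeping(grid):
    ref = _flat_reference(grid, median=28.0, cutoff=24.0)
    sens = np.full(37, 28)
    middle = grid.ring_loci("middle")[:3]
    sens[middle] = 20  # three abnormal loci, all at 4 degrees
    exam = _exam(sens)
    s = summarize_eye(exam, pointwise_deviation(exam, ref), grid)
    assert s.n_abnormal == 3
    assert s.abnormal_by_ring == {"inner": 0, "middle": 3, "outer": 0}
    assert s.n_abnormal == sum(s.abnormal_by_ring.values())


def test_summarize_eye_constant_deviation(grid):
    ref = _flat_reference(grid, median=29.0, cutoff=20.0)
    exam = _exam(np.full(37, 28))
    s = summarize_eye(exam, pointwise_deviation(exam, ref), grid)
    assert s.mean_sensitivity_deviation == pytest.approx(-1.0)
    assert s.mean_sensitivity == 28.0


# ---------------------------------------------------------------- cohort flags

def test_flag_percentages_match_published_fractions(grid):
    flags = np.zeros((27, 37), dtype=bool)
    flags[:3, 0] = True   # 3/27 abnormal at locus 0
    flags[:1, 20] = True  # 1/27 at locus 20
    pct, ring_mean, ring_sd = cohort_flag_percentages(flags, grid)
    assert pct[0] == pytest.approx(100 * 3 / 27, abs=0.05)  # 11.1%
    assert pct[20] == pytest.approx(100 * 1 / 27, abs=0.05)  # 3.7%
    assert round(pct[0]) == 11 and round(pct[20]) == 4


def test_flag_percentages_all_zero(grid):
    pct, ring_mean, ring_sd = cohort_flag_percentages(np.zeros((5, 37), dtype=bool), grid)
    assert np.all(pct == 0)
    assert all(v == 0 for v in ring_mean.values())
    assert all(v == 0 for v in ring_sd.values())


def test_flag_percentages_ring_means_are_member_means(grid):
    rng = np.random.default_rng(9)
    flags = rng.random((20, 37)) < 0.2
    pct, ring_mean, ring_sd = cohort_flag_percentages(flags, grid)
    for ring in ("inner", "middle", "outer"):
        members = grid.ring_loci(ring)
        assert ring_mean[ring] == pytest.approx(pct[members].mean())
        assert ring_sd[ring] == pytest.approx(pct[members].std(ddof=1))


def test_flag_percentages_empty_cohort(grid):
    with pytest.raises(ValueError, match="empty"):
        cohort_flag_percentages(np.zeros((0, 37), dtype=bool), grid)


# ---------------------------------------------------------------- statistics

def test_welch_identical_groups():
    a = [1.0, 2.0, 3.0, 4.0, 5.0]
    res = welch_t_test(a, a)
    assert res.t == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)
    assert res.mean_diff == 0.0


def test_welch_hand_computed():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    b = a + 1
    res = welch_t_test(a, b)
    se = math.sqrt(2.5 / 5 + 2.5 / 5)
    t_hand = (a.mean() - b.mean()) / se
    df_hand = se**4 / ((2.5 / 5) ** 2 / 4 + (2.5 / 5) ** 2 / 4)
    assert res.t == pytest.approx(t_hand)
    assert res.df == pytest.approx(df_hand)  # = 8 by Welch-Satterthwaite
    assert res.p == pytest.approx(2 * stats.t.sf(abs(t_hand), df_hand))


def test_welch_antisymmetry():
    rng = np.random.default_rng(8)
    a, b = rng.normal(0, 1, 10), rng.normal(0.5, 2, 15)
    r1, r2 = welch_t_test(a, b), welch_t_test(b, a)
    assert r1.t == pytest.approx(-r2.t)
    assert r1.p == pytest.approx(r2.p)


def test_welch_zero_variance_error():
    with pytest.raises(ValueError, match="zero variance"):
        welch_t_test([3.0, 3.0, 3.0], [4.0, 4.0])


def test_welch_agrees_with_permutation_test():
    rng = np.random.default_rng(12)
    a = rng.normal(0.0, 1.0, 8)
    b = rng.normal(1.0, 1.0, 8)
    res = welch_t_test(a, b)
    pooled = np.concatenate([a, b])
    t_obs = abs(res.t)
    count = 0
    n_perm = 20_000
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        pa, pb = perm[:8], perm[8:]
        se = math.sqrt(pa.var(ddof=1) / 8 + pb.var(ddof=1) / 8)
        count += abs((pa.mean() - pb.mean()) / se) >= t_obs - 1e-12
    p_perm = count / n_perm
    assert p_perm == pytest.approx(res.p, abs=0.04)


def test_ols_recovers_published_healthy_trend():
    ages = np.linspace(25, 80, 40)
    fit = ols_age_fit(ages, -0.03 * ages + 29.8)
    assert fit.slope == pytest.approx(-0.03, abs=1e-12)
    assert fit.intercept == pytest.approx(29.8, abs=1e-9)
    assert fit.r_squared == pytest.approx(1.0)


def test_ols_constant_response_convention():
    fit = ols_age_fit([30.0, 40.0, 50.0], [28.0, 28.0, 28.0])
    assert fit.slope == 0.0 and fit.r_squared == 0.0 and fit.p == 1.0


def test_ols_matches_normal_equations():
    rng = np.random.default_rng(6)
    x = rng.uniform(20, 80, 25)
    y = 30 - 0.05 * x + rng.normal(0, 1, 25)
    fit = ols_age_fit(x, y)
    slope_ne = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    assert fit.slope == pytest.approx(slope_ne, rel=1e-10)
    assert fit.intercept == pytest.approx(y.mean() - slope_ne * x.mean(), rel=1e-10)


def test_ols_degenerate():
    with pytest.raises(ValueError):
        ols_age_fit([50.0, 50.0, 50.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        ols_age_fit([50.0, 60.0], [1.0, 2.0])


def test_ci95_properties():
    assert ci95_mean([3.0, 3.0, 3.0]) == (3.0, 3.0)
    v = [1.0, 2.0, 3.0, 4.0, 10.0]
    lo, hi = ci95_mean(v)
    m, s = np.mean(v), np.std(v, ddof=1)
    half = stats.t.ppf(0.975, 4) * s / math.sqrt(5)
    assert lo == pytest.approx(m - half) and hi == pytest.approx(m + half)
    assert hi - m == pytest.approx(m - lo)
    with pytest.raises(ValueError):
        ci95_mean([1.0])


# ---------------------------------------------------------------- end to end

@pytest.fixture(scope="module")
def null_analysis(grid):
    """Patients drawn from the same healthy model as the reference cohort."""
    healthy = generate_healthy_cohort(CohortConfig(n_eyes=120, seed=41), grid)
    pseudo = generate_healthy_cohort(CohortConfig(n_eyes=40, seed=42), grid)
    patients = CohortTable(
        [
            SensitivityExam("P" + e.subject_id, e.age, e.laterality,
                            e.sensitivities, e.bcea63, "cuticular_drusen")
            for e in pseudo
        ]
    )
    return run_cohort_analysis(patients, healthy, grid)


def test_null_cohort_ms_deviation_ci_contains_zero(null_analysis):
    lo, hi = null_analysis.patient_summary.ci_ms_deviation
    assert lo < 0 < hi


def test_flag_count_consistency(null_analysis):
    """Sum of ring counts over eyes equals sum of per-locus flag counts."""
    summaries = null_analysis.eye_summaries
    total_by_ring = sum(sum(s.abnormal_by_ring.values()) for s in summaries)
    total_by_eye = sum(s.n_abnormal for s in summaries)
    n_eyes = null_analysis.patient_summary.n_eyes
    total_by_locus = np.sum(null_analysis.per_locus_pct / 100.0 * n_eyes)
    assert total_by_ring == total_by_eye
    assert total_by_locus == pytest.approx(total_by_eye)


def test_analysis_is_deterministic(grid, null_analysis):
    healthy = generate_healthy_cohort(CohortConfig(n_eyes=120, seed=41), grid)
    pseudo = generate_healthy_cohort(CohortConfig(n_eyes=40, seed=42), grid)
    patients = CohortTable(
        [
            SensitivityExam("P" + e.subject_id, e.age, e.laterality,
                            e.sensitivities, e.bcea63, "cuticular_drusen")
            for e in pseudo
        ]
    )
    again = run_cohort_analysis(patients, healthy, grid)
    assert again.patient_summary.mean_n_abnormal == null_analysis.patient_summary.mean_n_abnormal
    assert np.array_equal(again.per_locus_pct, null_analysis.per_locus_pct)


def test_patient_on_median_reference_has_no_abnormal_loci(grid):
    ref = _flat_reference(grid, median=28.0, cutoff=24.0)
    exam = _exam(np.full(37, 28))
    devs = pointwise_deviation(exam, ref)
    assert summarize_eye(exam, devs, grid).n_abnormal == 0


def test_missing_tau_in_reference(grid):
    fits = {lid: {0.5: QuantileFit(0.5, 0.0, 28.0, 0.0, 30)} for lid in range(37)}
    ref = NormativeReference(grid, fits, (20.0, 80.0), 30)
    with pytest.raises(KeyError, match="tau"):
        pointwise_deviation(_exam(np.full(37, 28)), ref)
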