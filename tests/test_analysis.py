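"""Analysis chain: exact tests, bias, latency, training criterion, fitting."""

import math

import numpy as np
import pytest
from scipy import stats

from psychopig.analysis import (
    AnalysisError,
    ContrastPerformancePoint,
    bias_correctness_correlation,
    binomial_vs_chance,
    fit_psychometric,
    holm_adjust,
    latency_summary,
    per_contrast_performance,
    session_summary,
    side_bias,
    training_success,
)
from psychopig.engine import SessionConfig, run_session, run_sessions
from psychopig.observer import ObserverParams, p_correct, preset
from tests.conftest import make_log


def enumerate_binomial_p(k: int, n: int) -> float:
    """Independent oracle: sum the probability of every outcome no more
    likely than k under Binomial(n, 0.5), by full enumeration."""
    pmf = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
    return min(1.0, sum(p for p in pmf if p <= pmf[k] * (1 + 1e-12)))


def test_binomial_matches_enumeration_oracle_small_n():
    for n in range(1, 26):
        for k in range(n + 1):
            assert binomial_vs_chance(k, n) == pytest.approx(
                enumerate_binomial_p(k, n), abs=1e-12
            ), (k, n)


def test_binomial_closed_form_examples():
    assert binomial_vs_chance(10, 10) == pytest.approx(2 * 0.5**10, abs=0)
    assert binomial_vs_chance(5, 10) == pytest.approx(1.0)
    assert binomial_vs_chance(35, 40) == pytest.approx(
        enumerate_binomial_p(35, 40), abs=1e-12
    )


def test_binomial_rejects_bad_counts():
    with pytest.raises(AnalysisError):
        binomial_vs_chance(5, 0)
    with pytest.raises(AnalysisError):
        binomial_vs_chance(11, 10)


def test_per_contrast_counts_and_percent():
    # 4 sessions x 10 reps at contrast 0.6, 7 correct each -> 40, 28, 70%
    logs = []
    for _ in range(4):
        trials = [(0.6, 1, 1, 2.0)] * 7 + [(0.6, 1, 2, 2.0)] * 3
        logs.append(make_log(trials))
    (point,) = per_contrast_performance(logs)
    assert (point.n, point.k) == (40, 28)
    assert point.percent_correct == pytest.approx(70.0)


def test_per_contrast_excludes_aborted_trials():
    log = make_log([(0.5, 1, 1, 2.0), (0.5, 1, None, None), (0.5, 2, 1, 2.0)])
    (point,) = per_contrast_performance([log])
    assert (point.n, point.k) == (2, 1)


def test_per_contrast_pooling_conserves_counts(good_cs_logs):
    pooled = per_contrast_performance(good_cs_logs)
    per_session = [per_contrast_performance([log]) for log in good_cs_logs]
    for point in pooled:
        k_sum = sum(q.k for pts in per_session for q in pts
                    if q.contrast == point.contrast)
        n_sum = sum(q.n for pts in per_session for q in pts
                    if q.contrast == point.contrast)
        assert (point.k, point.n) == (k_sum, n_sum)
        assert 0 <= point.percent_correct <= 100
        assert 0 < point.p_value_vs_chance <= 1


def test_perfect_observer_performance_is_100(experiment_config):
    logs = [run_session(experiment_config, preset("perfect"))]
    assert all(p.percent_correct == 100.0 for p in per_contrast_performance(logs))


def test_performance_tracks_generating_curve():
    obs = ObserverParams(alpha=0.3, beta=15.0, lapse=0.02, seed=5)
    logs = run_sessions(SessionConfig(seed=20), obs, 4)
    points = {p.contrast: p for p in per_contrast_performance(logs)}
    for c in (0.1, 1.0):
        expected = p_correct(obs, c)
        lo, hi = stats.binom.interval(0.95, 40, expected)
        assert lo <= points[c].k <= hi


def test_holm_adjustment_is_monotone_and_bounded():
    raw = [0.001, 0.04, 0.03, 0.5]
    adj = holm_adjust(raw)
    assert all(a >= r for a, r in zip(adj, raw))
    assert all(0 <= a <= 1 for a in adj)


def test_side_bias_percent_and_flag():
    log = make_log([(1.0, 1, 1, 2.0)] * 30 + [(1.0, 1, 2, 2.0)] * 30)
    pct, biased = side_bias(log)
    assert pct == pytest.approx(50.0) and not biased
    log = make_log([(1.0, 1, 1, 2.0)] * 10 + [(1.0, 1, 2, 2.0)] * 50)
    pct, biased = side_bias(log)
    assert pct == pytest.approx(100 / 6) and biased


def test_fully_biased_observer_flags_bias(experiment_config):
    obs = ObserverParams(alpha=0.3, beta=15.0, bias_strength=1.0, bias_side=2)
    pct, biased = side_bias(run_session(experiment_config, obs))
    assert pct == 0.0 and biased


def test_side_bias_undefined_when_all_aborted():
    log = make_log([(0.5, 1, None, None)] * 3)
    with pytest.raises(AnalysisError):
        side_bias(log)


def test_bias_correlation_perfectly_monotone():
    from psychopig.analysis import SessionSummary

    sums = [
        SessionSummary(animal_id="t", session_date=f"2026-01-0{i+1}",
                       n_trials_completed=100, percent_correct_overall=acc,
                       side1_touch_percent=pct1, biased=False,
                       mean_latency_correct_s=None, mean_latency_incorrect_s=None)
        for i, (acc, pct1) in enumerate([(90, 52), (80, 60), (70, 70), (60, 85)])
    ]
    rho, p = bias_correctness_correlation(sums)
    assert rho == pytest.approx(-1.0)


def test_bias_correlation_degenerate_input():
    log = make_log([(1.0, 1, 1, 2.0)] * 10)
    s = session_summary(log)
    with pytest.raises(AnalysisError):
        bias_correctness_correlation([s, s, s])


def test_latency_means_and_ratio():
    log = make_log([
        (1.0, 1, 1, 2.0), (1.0, 1, 1, 4.0),   # correct: mean 3
        (1.0, 1, 2, 6.0), (1.0, 1, 2, 12.0),  # incorrect: mean 9
    ])
    lat = latency_summary(log)
    assert lat.mean_latency_correct_s == pytest.approx(3.0)
    assert lat.mean_latency_incorrect_s == pytest.approx(9.0)
    assert lat.ratio_incorrect_over_correct == pytest.approx(3.0)


def test_latency_identical_samples_ratio_one():
    log = make_log([(1.0, 1, 1, 5.0)] * 4 + [(1.0, 1, 2, 5.0)] * 4)
    lat = latency_summary(log)
    assert lat.ratio_incorrect_over_correct == pytest.approx(1.0)
    assert lat.test_p_value == pytest.approx(1.0)


def test_latency_ratio_recovered_from_simulation():
    obs = ObserverParams(alpha=0.5, beta=5.0, latency_ratio_incorrect=3.0,
                         latency_sigma=0.5, seed=2)
    logs = run_sessions(SessionConfig(seed=2), obs, 5)
    lat = latency_summary(logs)
    assert 2.5 <= lat.ratio_incorrect_over_correct <= 3.5
    assert lat.test_p_value < 0.001


def test_latency_partial_without_incorrect_trials():
    log = make_log([(1.0, 1, 1, 5.0)] * 4)
    lat = latency_summary(log)
    assert lat.ratio_incorrect_over_correct is None
    assert lat.test_p_value is None
    assert lat.mean_latency_correct_s == pytest.approx(5.0)


def test_welch_option():
    log = make_log([(1.0, 1, 1, v) for v in (2.0, 3.0, 4.0)]
                   + [(1.0, 1, 2, v) for v in (8.0, 9.0, 10.0)])
    assert latency_summary(log, test="t").test_p_value < 0.01
    with pytest.raises(AnalysisError):
        latency_summary(log, test="bogus")


@pytest.mark.parametrize("k, expected", [(80, True), (76, True), (75, False)])
def test_training_success_is_strict(k, expected):
    trials = [(1.0, 1, 1, 2.0)] * k + [(1.0, 1, 2, 2.0)] * (100 - k)
    assert training_success(make_log(trials)) is expected


def test_training_success_needs_full_contrast_trials():
    with pytest.raises(AnalysisError):
        training_success(make_log([(0.5, 1, 1, 2.0)] * 10))


# --- psychometric fit -------------------------------------------------------

def synthetic_points(alpha, beta, lam, n=10_000):
    """Noiseless points on the generating curve at the standard contrasts."""
    pts = []
    for c in [round(0.1 * i, 1) for i in range(1, 11)]:
        p = p_correct(ObserverParams(alpha=alpha, beta=beta, lapse=lam), c)
        k = round(p * n)
        pts.append(ContrastPerformancePoint(
            contrast=c, n=n, k=k, percent_correct=100 * k / n,
            p_value_vs_chance=binomial_vs_chance(k, n),
        ))
    return pts


def test_fit_recovers_noiseless_threshold():
    fit = fit_psychometric(synthetic_points(0.4, 20.0, 0.0))
    assert fit.converged
    assert fit.threshold_corrected == pytest.approx(0.4, abs=0.02)
    assert fit.threshold_raw is None  # curve never falls to 50% with gamma=0.5


def test_fit_ceiling_flags_below_range():
    pts = [ContrastPerformancePoint(c, 100, 100, 100.0, binomial_vs_chance(100, 100))
           for c in (0.1, 0.4, 0.7, 1.0)]
    fit = fit_psychometric(pts)
    assert fit.threshold_corrected is not None
    assert fit.threshold_corrected <= 0.1
    assert "below measurable range" in fit.note


def test_fit_floor_flags_no_measurable_cs():
    pts = [ContrastPerformancePoint(c, 100, 50, 50.0, binomial_vs_chance(50, 100))
           for c in (0.1, 0.4, 0.7, 1.0)]
    fit = fit_psychometric(pts)
    assert fit.threshold_corrected is None
    assert "no measurable CS" in fit.note


def test_fitted_curve_is_monotone():
    fit = fit_psychometric(synthetic_points(0.5, 10.0, 0.05))
    grid = np.linspace(0, 1, 101)
    pred = fit.predict_percent_correct(grid)
    assert np.all(np.diff(pred) >= -1e-9)


def test_fit_requires_three_contrasts():
    pts = synthetic_points(0.4, 20.0, 0.0)[:2]
    with pytest.raises(AnalysisError):
        fit_psychometric(pts)
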