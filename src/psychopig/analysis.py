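"""Session-log statistics: performance, bias, latency, psychometric fit.

Implements the full analysis chain for the two-choice contrast task:

* per-contrast percent correct pooled across sessions, each level
  tested against the 50:50 chance level with an exact two-sided
  binomial test (minimum-likelihood two-sidedness);
* side-bias quantification (percent of touches on panel 1; touches
  below 25% on the minority side flag significant bias);
* Spearman correlation between per-session accuracy and bias
  magnitude;
* latency summaries per outcome with a Mann-Whitney U comparison
  (latencies are right-skewed; Welch's t-test available via flag);
* the training-success criterion (>75% correct at 100% contrast);
* maximum-likelihood psychometric fit with guess rate fixed at 0.5,
  yielding the contrast threshold.

Aborted trials (no touch within the configured timeout) are excluded
from every denominator.  No multiple-testing correction is applied
across contrast levels by default; a Holm option is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .engine import SessionLog
from .observer import GUESS_RATE

__all__ = [
    "ContrastPerformancePoint",
    "SessionSummary",
    "LatencySummary",
    "PsychometricFit",
    "logs_to_frame",
    "per_contrast_performance",
    "binomial_vs_chance",
    "side_bias",
    "session_summary",
    "bias_correctness_correlation",
    "latency_summary",
    "training_success",
    "fit_psychometric",
]

#: Minority-side touch percentage below which side bias is called significant.
BIAS_CUTOFF_PERCENT = 25.0


class AnalysisError(ValueError):
    """Undefined statistic for the given data."""


@dataclass(frozen=True)
class ContrastPerformancePoint:
    """Performance at one contrast level, pooled across sessions."""

    contrast: float
    n: int
    k: int
    percent_correct: float
    p_value_vs_chance: float


@dataclass(frozen=True)
class SessionSummary:
    animal_id: str
    session_date: str
    n_trials_completed: int
    percent_correct_overall: float
    side1_touch_percent: float
    biased: bool
    mean_latency_correct_s: Optional[float]
    mean_latency_incorrect_s: Optional[float]


@dataclass(frozen=True)
class LatencySummary:
    mean_latency_correct_s: Optional[float]
    mean_latency_incorrect_s: Optional[float]
    ratio_incorrect_over_correct: Optional[float]
    test_p_value: Optional[float]
    n_correct: int
    n_incorrect: int


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted psychometric curve and contrast thresholds.

    ``threshold_raw`` is the contrast where the fitted percent correct
    equals 50 — with the two-choice guess rate the fitted curve exceeds
    50% everywhere on [0, 1], so it is usually undefined and reported
    as None.  ``threshold_corrected`` is the contrast at 75% correct,
    i.e. the stimulus recognized on half of the non-guess trials, and
    is the headline threshold.
    """

    alpha_hat: float
    beta_hat: float
    lambda_hat: float
    threshold_raw: Optional[float]
    threshold_corrected: Optional[float]
    converged: bool
    note: str = ""
    log_likelihood: float = float("nan")

    def predict_percent_correct(self, contrast) -> np.ndarray:
        return 100.0 * _curve(np.asarray(contrast, float),
                              self.alpha_hat, self.beta_hat, self.lambda_hat)


def logs_to_frame(logs: SessionLog | Iterable[SessionLog]) -> pd.DataFrame:
    """Flatten one or more session logs to a tidy trial DataFrame."""
    if isinstance(logs, SessionLog):
        logs = [logs]
    rows = []
    for log in logs:
        for t in log.trials:
            rows.append({
                "animal_id": log.animal_id,
                "session_date": log.session_date,
                "phase": log.config.phase,
                "trial_index": t.trial_index,
                "contrast": t.contrast,
                "target_side": t.target_side,
                "chosen_side": t.chosen_side,
                "correct": t.correct,
                "latency_s": t.latency_s,
                "rewarded": t.rewarded,
                "aborted": t.aborted,
            })
    if not rows:
        raise AnalysisError("no trials in the supplied logs")
    return pd.DataFrame(rows)


def _completed(frame: pd.DataFrame) -> pd.DataFrame:
    return frame[~frame["aborted"]]


def binomial_vs_chance(k: int, n: int) -> float:
    """Exact two-sided binomial p-value against the 50:50 chance null.

    Two-sidedness by the minimum-likelihood rule: the p-value sums the
    probability of every outcome no more likely than the observed one
    under Binomial(n, 0.5).
    """
    if n < 1 or not 0 <= k <= n:
        raise AnalysisError(f"need 0 <= k <= n, n >= 1; got k={k}, n={n}")
    return float(stats.binomtest(int(k), int(n), 0.5, alternative="two-sided").pvalue)


def per_contrast_performance(
    logs: SessionLog | Iterable[SessionLog],
) -> list[ContrastPerformancePoint]:
    """Pool non-aborted trials per contrast level across sessions.

    Returns one point per distinct contrast with the exact binomial
    p-value against chance; contrasts with no completed presentations
    are omitted with a warning.
    """
    frame = _completed(logs_to_frame(logs))
    points = []
    for contrast, grp in frame.groupby("contrast", sort=True):
        n = len(grp)
        if n == 0:  # pragma: no cover - groupby drops empty groups
            continue
        k = int(grp["correct"].sum())
        points.append(ContrastPerformancePoint(
            contrast=float(contrast),
            n=n,
            k=k,
            percent_correct=100.0 * k / n,
            p_value_vs_chance=binomial_vs_chance(k, n),
        ))
    all_contrasts = {float(c) for log in ([logs] if isinstance(logs, SessionLog) else logs)
                     for c in log.config.contrast_levels}
    missing = all_contrasts - {p.contrast for p in points}
    if missing:
        warnings.warn(
            f"contrast levels with no completed trials omitted: {sorted(missing)}",
            stacklevel=2,
        )
    return points


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (off by default in reports)."""
    p = np.asarray(p_values, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def side_bias(logs: SessionLog | Iterable[SessionLog]) -> tuple[float, bool]:
    """Percent of non-aborted touches on panel 1 and the bias flag.

    The flag is True when the minority side receives under 25% of the
    touches (equivalently the majority side over 75%).
    """
    frame = _completed(logs_to_frame(logs))
    if frame.empty:
        raise AnalysisError("side bias undefined: all trials aborted")
    pct1 = 100.0 * float((frame["chosen_side"] == 1).mean())
    biased = min(pct1, 100.0 - pct1) < BIAS_CUTOFF_PERCENT
    return pct1, biased


def session_summary(log: SessionLog) -> SessionSummary:
    """Per-session accuracy, side-touch split and mean latencies."""
    frame = _completed(logs_to_frame(log))
    if frame.empty:
        raise AnalysisError(f"session {log.session_date}: all trials aborted")
    pct1, biased = side_bias(log)
    lat_c = frame.loc[frame["correct"] == True, "latency_s"].dropna()  # noqa: E712
    lat_i = frame.loc[frame["correct"] == False, "latency_s"].dropna()  # noqa: E712
    return SessionSummary(
        animal_id=log.animal_id,
        session_date=log.session_date,
        n_trials_completed=len(frame),
        percent_correct_overall=100.0 * float(frame["correct"].mean()),
        side1_touch_percent=pct1,
        biased=biased,
        mean_latency_correct_s=float(lat_c.mean()) if len(lat_c) else None,
        mean_latency_incorrect_s=float(lat_i.mean()) if len(lat_i) else None,
    )


def bias_correctness_correlation(
    summaries: Sequence[SessionSummary],
) -> tuple[float, float]:
    """Spearman correlation of per-session accuracy with bias magnitude.

    Bias magnitude is ``|side1_touch_percent - 50|``.  Ties are handled
    by scipy's mid-rank convention.  A strong side preference coupled
    with chance-level accuracy yields a large negative rho.
    """
    if len(summaries) < 3:
        raise AnalysisError("need at least 3 sessions for the correlation")
    acc = np.array([s.percent_correct_overall for s in summaries])
    mag = np.array([abs(s.side1_touch_percent - 50.0) for s in summaries])
    if np.ptp(acc) == 0 or np.ptp(mag) == 0:
        raise AnalysisError("correlation undefined: constant input vector")
    rho, p = stats.spearmanr(mag, acc)
    return float(rho), float(p)


def latency_summary(
    logs: SessionLog | Iterable[SessionLog],
    test: str = "mannwhitney",
) -> LatencySummary:
    """Mean activation-to-touch latency per outcome and their ratio.

    The two latency samples are compared with a two-sided Mann-Whitney
    U test by default (``test="t"`` switches to Welch's t).  With no
    incorrect trials the ratio and p-value are None.
    """
    frame = _completed(logs_to_frame(logs))
    lat_c = frame.loc[frame["correct"] == True, "latency_s"].dropna().to_numpy()  # noqa: E712
    lat_i = frame.loc[frame["correct"] == False, "latency_s"].dropna().to_numpy()  # noqa: E712
    mean_c = float(lat_c.mean()) if len(lat_c) else None
    mean_i = float(lat_i.mean()) if len(lat_i) else None
    ratio = p_val = None
    if mean_c and mean_i:
        ratio = mean_i / mean_c
        if len(lat_c) >= 1 and len(lat_i) >= 1:
            if test == "mannwhitney":
                p_val = float(stats.mannwhitneyu(
                    lat_c, lat_i, alternative="two-sided"
                ).pvalue)
            elif test == "t":
                p_val = float(stats.ttest_ind(
                    lat_c, lat_i, equal_var=False
                ).pvalue)
            else:
                raise AnalysisError(f"unknown latency test {test!r}")
    return LatencySummary(
        mean_latency_correct_s=mean_c,
        mean_latency_incorrect_s=mean_i,
        ratio_incorrect_over_correct=ratio,
        test_p_value=p_val,
        n_correct=len(lat_c),
        n_incorrect=len(lat_i),
    )


def training_success(logs: SessionLog | Iterable[SessionLog]) -> bool:
    """Training criterion: strictly over 75% correct at 100% contrast."""
    frame = _completed(logs_to_frame(logs))
    at_full = frame[np.isclose(frame["contrast"], 1.0)]
    if at_full.empty:
        raise AnalysisError("no completed trials at 100% contrast")
    return 100.0 * float(at_full["correct"].mean()) > 75.0


# --- psychometric fit -------------------------------------------------------

_LAPSE_MAX = 0.1


def _curve(c, alpha, beta, lam):
    f = special.expit(beta * (np.asarray(c, float) - alpha))
    return GUESS_RATE + (1.0 - GUESS_RATE - lam) * f


def _neg_log_likelihood(theta, c, k, n):
    alpha, log_beta, lam = theta
    p = np.clip(_curve(c, alpha, np.exp(log_beta), lam), 1e-9, 1 - 1e-9)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log(1 - p)))


def fit_psychometric(points: Sequence[ContrastPerformancePoint]) -> PsychometricFit:
    """Binomial maximum-likelihood fit of the logistic psychometric curve.

    The guess rate is fixed at 0.5 (two-choice task) and the lapse rate
    constrained to [0, 0.1]; the logistic parameterization guarantees a
    monotone fitted curve.  Several starting points are tried and the
    best likelihood kept.  Thresholds:

    * ``threshold_raw`` — fitted percent correct equals 50; undefined
      (None) whenever the curve stays above 50% on [0, 1], which is
      always the case with a 0.5 guess rate.
    * ``threshold_corrected`` — fitted percent correct equals 75, the
      guessing-corrected 50%-recognition point.  Flagged "below
      measurable range" when it falls under the smallest tested
      contrast and "no measurable CS" when the curve never reaches 75%
      on [0, 1].
    """
    if len({p.contrast for p in points}) < 3:
        raise AnalysisError("need at least 3 distinct contrast levels to fit")
    if any(p.n < 1 for p in points):
        raise AnalysisError("every point must have n >= 1")
    c = np.array([p.contrast for p in points])
    n = np.array([p.n for p in points], dtype=float)
    k = np.array([p.k for p in points], dtype=float)

    bounds = [(-0.5, 2.0), (np.log(0.5), np.log(500.0)), (0.0, _LAPSE_MAX)]
    starts = [
        (a0, np.log(b0), 0.02)
        for a0 in (0.2, 0.4, 0.6, 0.9)
        for b0 in (5.0, 20.0)
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _neg_log_likelihood, x0, args=(c, k, n),
            method="L-BFGS-B", bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    alpha_hat = float(best.x[0])
    beta_hat = float(np.exp(best.x[1]))
    lambda_hat = float(best.x[2])
    notes = []
    if not best.success:
        notes.append(f"optimizer did not converge: {best.message}")

    def invert(target_pc: float) -> Optional[float]:
        # solve curve(c) = target_pc/100 analytically via the logistic
        f_star = (target_pc / 100.0 - GUESS_RATE) / (1.0 - GUESS_RATE - lambda_hat)
        if not 0.0 < f_star < 1.0:
            return None
        return alpha_hat - np.log(1.0 / f_star - 1.0) / beta_hat

    raw = invert(50.0)
    if raw is None or not 0.0 <= raw <= 1.0:
        raw = None
        notes.append("50%-correct crossing undefined (curve above chance everywhere)")
    corrected = invert(75.0)
    if corrected is None or corrected > 1.0 or (
        100.0 * _curve(1.0, alpha_hat, beta_hat, lambda_hat) < 75.0
    ):
        corrected = None
        notes.append("no measurable CS: fitted curve never reaches 75% correct")
    elif corrected < c.min():
        notes.append("below measurable range: threshold under the smallest "
                     "tested contrast")
        corrected = float(max(corrected, 0.0))
    else:
        corrected = float(corrected)
    return PsychometricFit(
        alpha_hat=alpha_hat,
        beta_hat=beta_hat,
        lambda_hat=lambda_hat,
        threshold_raw=raw,
        threshold_corrected=corrected,
        converged=bool(best.success),
        note="; ".join(notes),
        log_likelihood=-float(best.fun),
    )
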