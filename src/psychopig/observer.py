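"""Parametric simulated animal for the two-choice contrast task.

The observer answers a single question per trial — which screen panel
holds the striped target — and the probability of answering correctly
follows a psychometric function in stimulus contrast ``c``:

    p(c) = (1 - b) * [gamma + (1 - gamma - lambda) * F(c; alpha, beta)] + b/2

where ``F`` is the logistic ``1 / (1 + exp(-beta * (c - alpha)))``,
``gamma = 0.5`` is the two-choice guess rate, ``lambda`` the lapse rate,
and ``b`` a side-bias mixture weight: with probability ``b`` the animal
touches its preferred panel regardless of the stimulus, which is correct
half the time under counterbalanced target sides.  This "lapse to the
preferred side" mixture is the simplest mechanism that couples side bias
with chance-level accuracy, as seen in poorly trained animals; it is a
modeling convenience, not a claim about pig cognition.

Latencies are log-normal (right-skewed, like behavioral response times)
with a median per outcome: incorrect touches take
``latency_ratio_incorrect`` times longer than correct ones at the
median.  Sessions end at a fatigue point of 50-100 trials, and training
is modeled as a per-session increment to the slope ``beta``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.special import expit

__all__ = [
    "ObserverParams",
    "GUESS_RATE",
    "p_correct",
    "respond",
    "advance_session",
    "load_observer",
    "preset",
    "preset_names",
]

#: Lower asymptote of the psychometric function; fixed by the two-choice task.
GUESS_RATE = 0.5


class ObserverError(ValueError):
    """Invalid observer parameters or query."""


@dataclass(frozen=True)
class ObserverParams:
    """Behavioral parameters of a simulated animal.

    Parameters
    ----------
    alpha
        Contrast threshold of the internal detection curve (logistic
        midpoint), as a fraction of full contrast.  Values above 1 put
        the whole tested range below threshold (a flat, chance-level
        curve).
    beta
        Logistic slope (per unit contrast); higher is a sharper
        transition.
    lapse
        Stimulus-independent error rate in [0, 0.1]; caps the upper
        asymptote at ``1 - lapse``.
    bias_side, bias_strength
        Preferred panel (1 or 2) and mixture weight ``b`` in [0, 1];
        ``b = 1`` means every touch lands on ``bias_side``.
    latency_median_correct_s, latency_sigma, latency_ratio_incorrect
        Log-normal latency model: median for correct touches (seconds),
        log-scale spread, and the multiplier (>= 1) applied to the
        median for incorrect touches.
    fatigue_trials
        Trials completed before the animal disengages (50-100 in
        practice); ``None`` means no fatigue.
    learning_rate
        Per-session increment to ``beta`` applied by
        :func:`advance_session`.
    seed
        Seed for the observer's private random stream.
    """

    alpha: float
    beta: float
    lapse: float = 0.02
    bias_side: int = 1
    bias_strength: float = 0.0
    latency_median_correct_s: float = 8.6
    latency_sigma: float = 0.5
    latency_ratio_incorrect: float = 3.0
    fatigue_trials: Optional[int] = None
    learning_rate: float = 0.0
    seed: int = 0

    # gamma is fixed by the task; exposed read-only to keep formulas honest.
    @property
    def guess(self) -> float:
        return GUESS_RATE

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ObserverError(f"beta must be positive, got {self.beta}")
        if not 0.0 <= self.lapse <= 0.1:
            raise ObserverError(f"lapse must be in [0, 0.1], got {self.lapse}")
        if self.bias_side not in (1, 2):
            raise ObserverError(f"bias_side must be 1 or 2, got {self.bias_side}")
        if not 0.0 <= self.bias_strength <= 1.0:
            raise ObserverError("bias_strength must be in [0, 1]")
        if self.latency_median_correct_s <= 0 or self.latency_sigma <= 0:
            raise ObserverError("latency parameters must be positive")
        if self.latency_ratio_incorrect < 1.0:
            raise ObserverError("latency_ratio_incorrect must be >= 1")
        if self.fatigue_trials is not None and self.fatigue_trials < 1:
            raise ObserverError("fatigue_trials must be positive or None")
        if self.learning_rate < 0:
            raise ObserverError("learning_rate must be >= 0")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path


def _detection(contrast, alpha: float, beta: float):
    return expit(beta * (np.asarray(contrast, dtype=float) - alpha))


def p_unbiased_correct(params: ObserverParams, contrast) -> np.ndarray | float:
    """Correct-choice probability on trials not captured by the bias."""
    f = _detection(contrast, params.alpha, params.beta)
    return GUESS_RATE + (1.0 - GUESS_RATE - params.lapse) * f


def p_correct(params: ObserverParams, contrast) -> np.ndarray | float:
    """Expected probability of a correct choice at the given contrast.

    Accepts a scalar or array of contrasts in [0, 1].  Monotone
    nondecreasing in contrast for every valid parameter set; equals 0.5
    for a fully biased observer (``bias_strength = 1``) because the
    preferred panel matches the counterbalanced target half the time.
    """
    c = np.asarray(contrast, dtype=float)
    if np.any(c < 0) or np.any(c > 1):
        raise ObserverError("contrast must be in [0, 1]")
    b = params.bias_strength
    p = (1.0 - b) * p_unbiased_correct(params, c) + b * 0.5
    return float(p) if np.isscalar(contrast) else p


def respond(
    params: ObserverParams,
    contrast: float,
    target_side: int,
    rng: np.random.Generator,
) -> tuple[int, float]:
    """Sample one (chosen_side, latency_s) response.

    With probability ``bias_strength`` the preferred panel is touched;
    otherwise the target panel is touched with the unbiased correct
    probability.  Latency is log-normal with the outcome-dependent
    median.
    """
    if target_side not in (1, 2):
        raise ObserverError(f"target_side must be 1 or 2, got {target_side}")
    if rng.random() < params.bias_strength:
        chosen = params.bias_side
    else:
        p = float(p_unbiased_correct(params, contrast))
        chosen = target_side if rng.random() < p else 3 - target_side
    correct = chosen == target_side
    median = params.latency_median_correct_s
    if not correct:
        median *= params.latency_ratio_incorrect
    latency = float(rng.lognormal(mean=math.log(median), sigma=params.latency_sigma))
    return chosen, latency


def advance_session(params: ObserverParams) -> ObserverParams:
    """Apply one session of training: slope grows by ``learning_rate``."""
    if params.learning_rate == 0:
        return params
    return dataclasses.replace(params, beta=params.beta + params.learning_rate)


def load_observer(path: str | Path) -> ObserverParams:
    """Load :class:`ObserverParams` from a JSON file."""
    data = json.loads(Path(path).read_text())
    try:
        return ObserverParams(**data)
    except TypeError as exc:
        raise ObserverError(f"bad observer JSON {path}: {exc}") from exc


def preset_names() -> list[str]:
    """Names of the shipped observer presets."""
    pkg = resources.files("psychopig") / "presets"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".json"))


def preset(name: str) -> ObserverParams:
    """Load a shipped observer preset by name (see :func:`preset_names`)."""
    res = resources.files("psychopig") / "presets" / f"{name}.json"
    if not res.is_file():
        raise ObserverError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        )
    return ObserverParams(**json.loads(res.read_text()))
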