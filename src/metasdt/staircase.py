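"""1-up/2-down adaptive contrast staircase and outlier exclusion.

The perceptual task presents six Gabor patches per interval at a baseline
contrast (0.20); one patch in one interval is a contrast oddball.  The
oddball contrast starts one full baseline step above the distractors
(+0.20) and moves by 0.03 per adjustment: up after every error, down after
two consecutive correct responses.  That rule converges where
P(correct)^2 = 1/2, i.e. ~70.7% correct, which is why staircase-controlled
accuracy clusters tightly around 71% regardless of the observer's acuity.

Step size is interpreted as absolute contrast (0.03 = 3 contrast
percentage points); the oddball is floored just above the distractor
baseline so it never disappears.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

__all__ = [
    "StaircaseState", "PsychometricObserver",
    "staircase_update", "run_staircase", "exclusion_filter",
    "threshold_from_trace",
    "BASELINE_CONTRAST", "INITIAL_INCREMENT", "STEP",
]

BASELINE_CONTRAST = 0.20     # distractor contrast
INITIAL_INCREMENT = 0.20     # oddball starts 20 contrast points above baseline
STEP = 0.03
_FLOOR_MARGIN = 0.005        # oddball stays strictly above the distractors

# 1-up/2-down equilibrium: p^2 = 0.5
CONVERGENCE_P = float(np.sqrt(0.5))


@dataclass(frozen=True)
class StaircaseState:
    """Current contrast level and run-of-correct counter, plus full history."""

    oddball_contrast: float = BASELINE_CONTRAST + INITIAL_INCREMENT
    consecutive_correct: int = 0
    step: float = STEP
    baseline: float = BASELINE_CONTRAST
    history: tuple = field(default_factory=tuple)  # (trial, contrast, correct)

    def __post_init__(self):
        if self.oddball_contrast <= self.baseline:
            raise ValueError("oddball contrast must exceed the distractor baseline")
        if self.consecutive_correct not in (0, 1):
            raise ValueError("consecutive_correct must be 0 or 1")

    @property
    def contrast_difference(self) -> float:
        return self.oddball_contrast - self.baseline


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Apply the 1-up/2-down rule to one trial outcome.

    Incorrect: contrast up one step, counter reset.  First correct in a
    run: contrast unchanged, counter 1.  Second consecutive correct:
    contrast down one step (floored just above baseline), counter reset.
    """
    trial = len(state.history)
    hist = state.history + ((trial, state.oddball_contrast, bool(correct)),)
    if not correct:
        return replace(state, oddball_contrast=state.oddball_contrast + state.step,
                       consecutive_correct=0, history=hist)
    if state.consecutive_correct == 0:
        return replace(state, consecutive_correct=1, history=hist)
    new_contrast = max(state.oddball_contrast - state.step,
                       state.baseline + _FLOOR_MARGIN)
    return replace(state, oddball_contrast=new_contrast,
                   consecutive_correct=0, history=hist)


@dataclass(frozen=True)
class PsychometricObserver:
    """Cumulative-Gaussian contrast-discrimination observer.

    P(correct | contrast difference d) rises from chance (0.5) at d = 0 to
    1 - lapse_rate, passing the 1-up/2-down convergence level (~70.7%)
    exactly at ``threshold``:

        P(d) = 0.5 + (0.5 - lapse) * (2 * Phi(d / sigma) - 1)

    with sigma set from threshold and slope so that P(threshold) equals
    the convergence point.  `slope` rescales sigma (1 = default steepness).
    """

    threshold: float
    slope: float = 1.0
    lapse_rate: float = 0.02

    def __post_init__(self):
        if self.threshold <= 0 or self.slope <= 0:
            raise ValueError("threshold and slope must be positive")
        if not 0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse rate must be in [0, 0.5)")

    @property
    def sigma(self) -> float:
        # Phi(threshold / sigma) = q solves 0.5 + (0.5 - lapse)(2q - 1) = p_conv
        q = ((CONVERGENCE_P - 0.5) / (0.5 - self.lapse_rate) + 1.0) / 2.0
        return self.threshold / norm.ppf(q) / self.slope

    def p_correct(self, contrast_difference: float | np.ndarray) -> np.ndarray:
        d = np.asarray(contrast_difference, dtype=float)
        base = 2.0 * norm.cdf(d / self.sigma) - 1.0
        return 0.5 + (0.5 - self.lapse_rate) * base


def run_staircase(observer: PsychometricObserver, n_trials: int = 180,
                  seed: int | np.random.Generator = 0,
                  state: StaircaseState | None = None):
    """Drive an observer through the staircase.

    Returns
    -------
    history : list of (trial, oddball_contrast, correct)
    accuracy : float
        Overall proportion correct over all `n_trials` (no burn-in, as the
        summary statistic of the study design).
    threshold_estimate : float
        Mean contrast *difference* over reversals after discarding the
        first 4 (nan if fewer than 2 usable reversals).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if state is None:
        state = StaircaseState()
    for _ in range(n_trials):
        p = float(observer.p_correct(state.contrast_difference))
        state = staircase_update(state, rng.random() < p)
    history = list(state.history)
    accuracy = float(np.mean([h[2] for h in history]))
    contrasts = np.array([h[1] for h in history])
    threshold = threshold_from_trace(contrasts, baseline=state.baseline)
    return history, accuracy, threshold


def threshold_from_trace(contrasts: np.ndarray, baseline: float = BASELINE_CONTRAST,
                         discard_reversals: int = 4) -> float:
    """Threshold estimate: mean contrast difference at staircase reversals.

    A reversal is a trial where the contrast's direction of change flips.
    The first `discard_reversals` reversals are treated as burn-in.
    """
    contrasts = np.asarray(contrasts, dtype=float)
    deltas = np.diff(contrasts)
    moves = deltas[deltas != 0]
    move_idx = np.nonzero(deltas)[0]
    if len(moves) < 2:
        return float("nan")
    flips = np.nonzero(np.sign(moves[1:]) != np.sign(moves[:-1]))[0]
    reversal_trials = move_idx[flips + 1]
    usable = reversal_trials[discard_reversals:]
    if len(usable) < 2:
        return float("nan")
    return float(np.mean(contrasts[usable] - baseline))


def exclusion_filter(accuracies, n_sd: float = 8.0) -> set:
    """Outlier rule: flag subjects with accuracy below mean - n_sd * SD.

    The reference statistics for each candidate are computed leave-one-out
    (population mean/SD of all *other* subjects): an extreme outlier must
    not inflate the very SD used to judge it, which with an 8-SD fence and
    a few dozen subjects would otherwise make exclusion mathematically
    impossible.  Deterministic and order-invariant; with zero variance
    nothing is excluded.
    """
    if hasattr(accuracies, "items"):
        keys = list(accuracies.keys())
        vals = np.array([accuracies[k] for k in keys], dtype=float)
    else:
        vals = np.asarray(list(accuracies), dtype=float)
        keys = list(range(len(vals)))
    n = len(vals)
    if n < 2:
        raise ValueError("exclusion rule needs at least 2 subjects")
    total, total_sq = vals.sum(), (vals**2).sum()
    flagged = set()
    for k, v in zip(keys, vals):
        mean_rest = (total - v) / (n - 1)
        var_rest = max((total_sq - v**2) / (n - 1) - mean_rest**2, 0.0)
        if v < mean_rest - n_sd * np.sqrt(var_rest):
            flagged.add(k)
    return flagged
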