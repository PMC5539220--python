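"""Synthetic confidence-rating observers and two-group cohort generation.

Generative model per trial
--------------------------
Evidence x ~ N(-mu/2, 1) for S1 stimuli and N(+mu/2, 1/s) for S2 (s = 1
for the perceptual task; s < 1 gives old items the larger evidence spread,
as in recognition memory).  The choice compares x + choice-noise to the
criterion; the confidence variable y = x + meta-noise is binned by K-1
monotone criteria on the chosen response's side of the criterion.  With
both noise channels at zero, confidence is a deterministic function of the
same evidence as the choice, so fitted meta-d' equals d' and M-ratio is 1.
Confidence noise pushes M-ratio below 1; choice noise (confidence reading
the cleaner pre-noise evidence) pushes it above 1.

Task designs emulated
---------------------
* Perceptual: 2-interval contrast-oddball search, 180 trials, difficulty
  driven by a 1-up/2-down staircase so accuracy clusters near 71%.  The
  trial's effective sensitivity comes from the observer's contrast
  psychometric function at the staircase's current contrast.
* Memory: old/new word recognition, 100 learned words tested among 200,
  imageability (high/low) crossed evenly with old/new.  Accuracy is not
  clamped, so it varies widely with the observer's sensitivity.

Response and confidence times are decorative lognormal draws matched to
group-level summary targets; they carry no coupling to accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .calibration import m_ratio_to_noise
from .staircase import (BASELINE_CONTRAST, PsychometricObserver, StaircaseState,
                        run_staircase, staircase_update, threshold_from_trace)

__all__ = [
    "ObserverParams", "TrialRecord", "TruncNormal", "GroupSpec", "CohortSpec",
    "simulate_trial", "simulate_perceptual_session", "simulate_memory_session",
    "simulate_cohort", "default_cohort_spec",
    "DEFAULT_CONFIDENCE_OFFSETS", "TRIAL_COLUMNS",
]

# Tuned once so that simulated mean confidence lands in the observed
# 4.6-4.9 band at mid-range sensitivity (see docs/methods.md).
DEFAULT_CONFIDENCE_OFFSETS = (0.06, 0.10, 0.17, 0.29, 0.50)

TRIAL_COLUMNS = [
    "subject_id", "group_label", "task", "trial_index", "stimulus_class",
    "response_class", "correct", "confidence", "rt_ms", "ct_ms",
    "contrast", "imageability",
]


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial: choice, confidence, timings, covariates."""

    subject_id: str
    group_label: str
    task: str                      # "perceptual" | "memory"
    trial_index: int
    stimulus_class: str            # "S1" | "S2"
    response_class: str
    correct: bool
    confidence: int                # 1..K
    rt_ms: int
    ct_ms: int
    contrast: float | None = None  # oddball contrast, perceptual only
    imageability: str = "none"     # "high" | "low" | "none"


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters for one synthetic subject."""

    sensitivity: float = 1.1        # target measured d' (memory); perceptual
                                    # sensitivity is induced via the staircase
    criterion: float = 0.0
    s: float = 1.0                  # S1-to-S2 evidence-SD ratio (zROC slope)
    meta_noise_sd: float = 0.0      # confidence-channel noise (tau_m)
    choice_noise_sd: float = 0.0    # choice-channel noise (tau_c)
    confidence_criteria: tuple = DEFAULT_CONFIDENCE_OFFSETS
    rt_model: dict = field(default_factory=lambda: {
        "rt_median_ms": 1200.0, "ct_median_ms": 600.0, "log_sd": 0.3})
    group_label: str = "control"
    psychometric: PsychometricObserver | None = None

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("s must be positive")
        if self.meta_noise_sd < 0 or self.choice_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        offs = np.asarray(self.confidence_criteria, dtype=float)
        if np.any(np.diff(offs) <= 0) or np.any(offs <= 0):
            raise ValueError("confidence criteria must be positive and increasing")

    @property
    def n_levels(self) -> int:
        return len(self.confidence_criteria) + 1


# ---------------------------------------------------------------------------
# evidence core

def _mu_for_measured_d(d_target: float, c: float, s: float, tau_c: float) -> float:
    """Mean separation giving measured d' = z(H) - z(F) = d_target.

    Accounts for the unequal variances and the choice-noise inflation of
    both evidence SDs.
    """
    a = 1.0 / np.sqrt(1.0 / s**2 + tau_c**2)   # old/S2 side precision
    b = 1.0 / np.sqrt(1.0 + tau_c**2)          # new/S1 side precision
    return 2.0 * (d_target - c * (b - a)) / (a + b)


def _simulate_choices(rng: np.random.Generator, stim: np.ndarray, mu,
                      params: ObserverParams):
    """Vectorized evidence/choice/confidence draws.

    stim : int array of 0 (S1) / 1 (S2); mu scalar or per-trial array.
    Returns (resp, correct, confidence) int/bool arrays.
    """
    n = len(stim)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (n,))
    sd = np.where(stim == 1, 1.0 / params.s, 1.0)
    x = rng.normal(np.where(stim == 1, mu / 2.0, -mu / 2.0), sd)
    xc = x if params.choice_noise_sd == 0 else x + rng.normal(
        0.0, params.choice_noise_sd, n)
    resp = (xc > params.criterion).astype(int)
    correct = resp == stim
    y = x if params.meta_noise_sd == 0 else x + rng.normal(
        0.0, params.meta_noise_sd, n)
    # criteria scaled to the confidence variable's spread, so the rating
    # distribution stays stable across noise levels
    scale = np.sqrt(1.0 + params.meta_noise_sd**2)
    offsets = np.asarray(params.confidence_criteria) * scale
    dist = np.where(resp == 1, y - params.criterion, params.criterion - y)
    confidence = 1 + (dist[:, None] > offsets[None, :]).sum(axis=1)
    return resp, correct, confidence


def _draw_times(rng: np.random.Generator, n: int, rt_model: dict):
    log_sd = rt_model.get("log_sd", 0.3)
    rt = rng.lognormal(np.log(rt_model["rt_median_ms"]), log_sd, n)
    ct = rng.lognormal(np.log(rt_model["ct_median_ms"]), log_sd, n)
    return np.round(rt).astype(int), np.round(ct).astype(int)


def simulate_trial(params: ObserverParams, stimulus_class: str,
                   rng: np.random.Generator, task: str = "memory",
                   subject_id: str = "s0", trial_index: int = 0,
                   contrast: float | None = None,
                   imageability: str = "none") -> TrialRecord:
    """Simulate a single trial (see module docstring for the model)."""
    stim = np.array([0 if stimulus_class == "S1" else 1])
    tau_c = params.choice_noise_sd
    mu = _mu_for_measured_d(params.sensitivity, params.criterion, params.s, tau_c)
    resp, correct, conf = _simulate_choices(rng, stim, mu, params)
    rt, ct = _draw_times(rng, 1, params.rt_model)
    return TrialRecord(
        subject_id=subject_id, group_label=params.group_label, task=task,
        trial_index=trial_index, stimulus_class=stimulus_class,
        response_class="S2" if resp[0] else "S1", correct=bool(correct[0]),
        confidence=int(conf[0]), rt_ms=int(rt[0]), ct_ms=int(ct[0]),
        contrast=contrast, imageability=imageability,
    )


# ---------------------------------------------------------------------------
# sessions

def simulate_perceptual_session(params: ObserverParams, n_trials: int = 180,
                                rng: np.random.Generator | int = 0,
                                subject_id: str = "s0") -> pd.DataFrame:
    """One staircase-controlled 2-interval oddball session.

    The staircase sets the oddball contrast; the observer's psychometric
    function converts the contrast difference into that trial's effective
    sensitivity (2 * z(P(correct)) at the choice stage), and evidence,
    choice and confidence are then drawn from the SDT core.
    """
    if params.psychometric is None:
        raise ValueError("perceptual simulation needs params.psychometric")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    tau_c = params.choice_noise_sd
    state = StaircaseState()
    rows = []
    for t in range(n_trials):
        p = float(params.psychometric.p_correct(state.contrast_difference))
        p = min(max(p, 0.5 + 1e-9), 1 - 1e-9)
        d_choice = 2.0 * ndtri(p)
        mu = d_choice * np.sqrt(1.0 + tau_c**2)
        stim = rng.integers(0, 2, 1)
        resp, correct, conf = _simulate_choices(rng, stim, mu, params)
        rows.append((stim[0], resp[0], bool(correct[0]), conf[0],
                     state.oddball_contrast))
        state = staircase_update(state, bool(correct[0]))
    stim, resp, correct, conf, contrast = map(np.array, zip(*rows))
    rt, ct = _draw_times(rng, n_trials, params.rt_model)
    return pd.DataFrame({
        "subject_id": subject_id, "group_label": params.group_label,
        "task": "perceptual", "trial_index": np.arange(n_trials),
        "stimulus_class": np.where(stim == 1, "S2", "S1"),
        "response_class": np.where(resp == 1, "S2", "S1"),
        "correct": correct, "confidence": conf,
        "rt_ms": rt, "ct_ms": ct, "contrast": contrast,
        "imageability": "none",
    })[TRIAL_COLUMNS]


def simulate_memory_session(params: ObserverParams, n_learn: int = 100,
                            n_test: int = 200, imageability_split: float = 0.5,
                            rng: np.random.Generator | int = 0,
                            subject_id: str = "s0",
                            imageability_d_effect: float = 0.0) -> pd.DataFrame:
    """One old/new recognition session: n_learn studied, n_test probed.

    Exactly half of the test words are old and, within old and new alike,
    half high- and half low-imageable (the default 50/50 split requires
    n_test = 2 * n_learn and divisibility by 4).  `imageability_d_effect`
    optionally shifts high-imageable sensitivity by +delta/2 and
    low-imageable by -delta/2 (0 by default: imageability is a label with
    no generative effect).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if n_test != 2 * n_learn:
        raise ValueError("design requires n_test = 2 * n_learn")
    if imageability_split != 0.5 or n_test % 4:
        raise ValueError("design requires an even old/new x high/low split")
    cell = n_test // 4
    stim = np.repeat([1, 1, 0, 0], cell)       # old, old, new, new
    imag = np.tile(["high", "low"], 2).repeat(cell)
    order = rng.permutation(n_test)
    stim, imag = stim[order], imag[order]

    d_eff = params.sensitivity + np.where(
        imag == "high", imageability_d_effect / 2, -imageability_d_effect / 2)
    mu = _mu_for_measured_d(d_eff, params.criterion, params.s,
                            params.choice_noise_sd)
    resp, correct, conf = _simulate_choices(rng, stim, mu, params)
    rt, ct = _draw_times(rng, n_test, params.rt_model)
    return pd.DataFrame({
        "subject_id": subject_id, "group_label": params.group_label,
        "task": "memory", "trial_index": np.arange(n_test),
        "stimulus_class": np.where(stim == 1, "S2", "S1"),
        "response_class": np.where(resp == 1, "S2", "S1"),
        "correct": correct, "confidence": conf,
        "rt_ms": rt, "ct_ms": ct, "contrast": np.nan,
        "imageability": imag,
    })[TRIAL_COLUMNS]


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class TruncNormal:
    """Truncated normal sampler (simple rejection; bounds inclusive)."""

    mean: float
    sd: float
    lo: float = -np.inf
    hi: float = np.inf

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return float(np.clip(self.mean, self.lo, self.hi))
        for _ in range(10000):
            v = rng.normal(self.mean, self.sd)
            if self.lo <= v <= self.hi:
                return float(v)
        raise RuntimeError("truncated-normal rejection failed; check bounds")

    @classmethod
    def with_mean(cls, target_mean: float, sd: float, lo: float,
                  hi: float) -> "TruncNormal":
        """Truncated normal whose *post-truncation* expectation is `target_mean`.

        Truncation shifts the mean of a plain N(target, sd) toward the
        interval center; this solves for the location parameter so that
        sampled values average to the target.
        """
        from scipy.optimize import brentq
        from scipy.stats import truncnorm as _tn

        if sd == 0 or not (lo < target_mean < hi):
            return cls(target_mean, sd, lo, hi)

        def gap(loc):
            a, b = (lo - loc) / sd, (hi - loc) / sd
            return _tn.mean(a, b, loc=loc, scale=sd) - target_mean

        span = 6 * sd + (hi - lo)
        loc = brentq(gap, target_mean - span, target_mean + span, xtol=1e-10)
        return cls(float(loc), sd, lo, hi)


@dataclass(frozen=True)
class GroupSpec:
    """Per-group generative distributions for the cohort simulator.

    The m-ratio targets are *measured-scale* targets: the cohort draws a
    target per subject and converts it to noise-channel SDs through the
    simulation-built calibration table.  Generative spreads are narrower
    than the observed group-summary SDs because single-session estimates add
    measurement noise on top (docs/methods.md, 'Variance budgeting').
    """

    label: str
    n_subjects: int
    contrast_threshold: TruncNormal
    perceptual_m_ratio: TruncNormal
    memory_d_prime: TruncNormal
    memory_m_ratio: TruncNormal
    memory_s: TruncNormal = TruncNormal(0.8, 0.08, 0.55, 1.05)
    memory_criterion: TruncNormal = TruncNormal(0.0, 0.1, -0.3, 0.3)
    perceptual_criterion: TruncNormal = TruncNormal(0.0, 0.15, -0.45, 0.45)
    perceptual_rt: TruncNormal = TruncNormal(1200, 300, 400, 4000)
    perceptual_ct: TruncNormal = TruncNormal(600, 250, 150, 4000)
    memory_rt: TruncNormal = TruncNormal(2000, 400, 600, 5000)
    memory_ct: TruncNormal = TruncNormal(600, 200, 150, 4000)

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError("group size must be positive")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple
    n_perceptual_trials: int = 180
    n_learn: int = 100
    n_test: int = 200
    imageability_d_effect: float = 0.0


# Study-condition defaults: group means/SDs follow the printed behavioral
# summaries (SDI vs control); generative SDs for measured quantities are
# deflated by the estimation-noise budget (docs/methods.md).
_MEAN_LOG_CORR = np.exp(0.3**2 / 2.0)   # lognormal median -> mean factor


def _rt_spec(mean: float, sd: float, lo: float = 250, hi: float = 6000) -> TruncNormal:
    # specs target the *mean* of subject means; medians are mean / exp(sig^2/2)
    return TruncNormal.with_mean(mean / _MEAN_LOG_CORR, sd, lo, hi)


def default_cohort_spec() -> CohortSpec:
    sdi = GroupSpec(
        label="SDI", n_subjects=23,
        contrast_threshold=TruncNormal.with_mean(0.19, 0.09, 0.043, 0.47),
        perceptual_m_ratio=TruncNormal.with_mean(0.67, 0.22, 0.02, 1.6),
        memory_d_prime=TruncNormal.with_mean(0.92, 0.40, 0.15, 2.2),
        memory_m_ratio=TruncNormal.with_mean(0.82, 0.25, 0.02, 1.6),
        perceptual_rt=_rt_spec(1358, 573), perceptual_ct=_rt_spec(831, 613, lo=180),
        memory_rt=_rt_spec(2146, 518), memory_ct=_rt_spec(683, 226, lo=180),
    )
    control = GroupSpec(
        label="control", n_subjects=24,
        contrast_threshold=TruncNormal.with_mean(0.16, 0.05, 0.043, 0.47),
        perceptual_m_ratio=TruncNormal.with_mean(1.01, 0.22, 0.02, 1.6),
        memory_d_prime=TruncNormal.with_mean(1.19, 0.36, 0.15, 2.2),
        memory_m_ratio=TruncNormal.with_mean(0.93, 0.20, 0.02, 1.6),
        perceptual_rt=_rt_spec(1099, 283), perceptual_ct=_rt_spec(510, 143, lo=180),
        memory_rt=_rt_spec(1964, 425), memory_ct=_rt_spec(577, 262, lo=180),
    )
    return CohortSpec(groups=(sdi, control))


def _subject_params(g: GroupSpec, rng: np.random.Generator):
    """Draw one subject's true parameters from a group spec."""
    thr = g.contrast_threshold.sample(rng)
    m_per = g.perceptual_m_ratio.sample(rng)
    m_mem = g.memory_m_ratio.sample(rng)
    tau_m_per, tau_c_per = m_ratio_to_noise(m_per)
    tau_m_mem, tau_c_mem = m_ratio_to_noise(m_mem)
    truth = {
        "group_label": g.label,
        "contrast_threshold": thr,
        "perceptual_m_ratio_target": m_per,
        "perceptual_meta_noise_sd": tau_m_per,
        "perceptual_choice_noise_sd": tau_c_per,
        "memory_d_prime_target": g.memory_d_prime.sample(rng),
        "memory_m_ratio_target": m_mem,
        "memory_meta_noise_sd": tau_m_mem,
        "memory_choice_noise_sd": tau_c_mem,
        "memory_s": g.memory_s.sample(rng),
        "memory_criterion": g.memory_criterion.sample(rng),
        "perceptual_criterion": g.perceptual_criterion.sample(rng),
        "perceptual_rt_median_ms": g.perceptual_rt.sample(rng),
        "perceptual_ct_median_ms": g.perceptual_ct.sample(rng),
        "memory_rt_median_ms": g.memory_rt.sample(rng),
        "memory_ct_median_ms": g.memory_ct.sample(rng),
    }
    percep = ObserverParams(
        criterion=truth["perceptual_criterion"], s=1.0,
        meta_noise_sd=tau_m_per, choice_noise_sd=tau_c_per,
        group_label=g.label,
        rt_model={"rt_median_ms": truth["perceptual_rt_median_ms"],
                  "ct_median_ms": truth["perceptual_ct_median_ms"], "log_sd": 0.3},
        psychometric=PsychometricObserver(threshold=thr),
    )
    memory = ObserverParams(
        sensitivity=truth["memory_d_prime_target"],
        criterion=truth["memory_criterion"], s=truth["memory_s"],
        meta_noise_sd=tau_m_mem, choice_noise_sd=tau_c_mem,
        group_label=g.label,
        rt_model={"rt_median_ms": truth["memory_rt_median_ms"],
                  "ct_median_ms": truth["memory_ct_median_ms"], "log_sd": 0.3},
    )
    return percep, memory, truth


def simulate_cohort(spec: CohortSpec | None = None, seed: int = 0):
    """Simulate a full two-group, two-task cohort.

    Returns
    -------
    trials : pandas.DataFrame
        One row per trial, both tasks, all subjects (TRIAL_COLUMNS schema).
    manifest : dict
        ``{"seed": ..., "subjects": {subject_id: true-parameter dict}}`` —
        every generative parameter actually used, for recovery tests.
    """
    if spec is None:
        spec = default_cohort_spec()
    rng = np.random.default_rng(seed)
    frames, manifest = [], {"seed": int(seed), "subjects": {}}
    idx = 0
    for g in spec.groups:
        for _ in range(g.n_subjects):
            sid = f"{g.label}_{idx:03d}"
            idx += 1
            percep, memory, truth = _subject_params(g, rng)
            frames.append(simulate_perceptual_session(
                percep, n_trials=spec.n_perceptual_trials, rng=rng, subject_id=sid))
            frames.append(simulate_memory_session(
                memory, n_learn=spec.n_learn, n_test=spec.n_test, rng=rng,
                subject_id=sid,
                imageability_d_effect=spec.imageability_d_effect))
            manifest["subjects"][sid] = truth
    trials = pd.concat(frames, ignore_index=True)
    return trials, manifest
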