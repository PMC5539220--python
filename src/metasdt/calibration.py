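"""Mapping between generative noise and metacognitive efficiency.

The observer model degrades (or sharpens) metacognition through two
additive Gaussian noise channels:

* ``meta_noise_sd`` (tau_m) — noise on the confidence variable only.
  Drives M-ratio continuously below 1 (1 at tau_m = 0).
* ``choice_noise_sd`` (tau_c) — noise on the choice variable only, with
  confidence read from the cleaner pre-noise evidence.  Drives M-ratio
  above 1.

Neither channel has a closed-form M-ratio (the type-2 fit conditions on
the realized choice), so the forward map is tabulated once by large-n
simulation (see ``scripts/build_calibration.py``, seed-fixed) and inverted
here by monotone interpolation.  The tabulated values are for a mid-range
sensitivity (d' ~ 1.1); M-ratio under these mechanisms is close to
performance-independent, which is exactly the property the measure is
designed for, so one table serves all sensitivities used by the cohort
generator.
"""

from __future__ import annotations

import numpy as np

__all__ = ["m_ratio_to_noise", "noise_to_m_ratio",
           "CONF_NOISE_GRID", "CONF_NOISE_M", "CHOICE_NOISE_GRID", "CHOICE_NOISE_M"]

# Built by scripts/build_calibration.py (2 x 10^5 trials per point, seed 20250919);
# regenerate after any change to the observer's confidence mechanism.
CONF_NOISE_GRID = np.array(
    [0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 9.0, 14.0])
CONF_NOISE_M = np.array(
    [0.9977, 0.8955, 0.7578, 0.6035, 0.5244, 0.3802, 0.2985, 0.1968,
     0.1599, 0.1120, 0.0646, 0.0402])
CHOICE_NOISE_GRID = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.3])
CHOICE_NOISE_M = np.array(
    [1.0083, 1.0543, 1.2632, 1.4898, 1.7572, 2.0116, 2.4267])


def noise_to_m_ratio(tau_m: float = 0.0, tau_c: float = 0.0) -> float:
    """Expected fitted M-ratio for one noise channel (the other at 0)."""
    if tau_m > 0 and tau_c > 0:
        raise ValueError("calibration covers one active noise channel at a time")
    if tau_c > 0:
        return float(np.interp(tau_c, CHOICE_NOISE_GRID, CHOICE_NOISE_M))
    return float(np.interp(tau_m, CONF_NOISE_GRID, CONF_NOISE_M))


def m_ratio_to_noise(m_target: float) -> tuple[float, float]:
    """Invert the calibration: target M-ratio -> (meta_noise_sd, choice_noise_sd).

    Targets at or above the zero-noise ceiling use the choice-noise
    channel; lower targets use confidence noise.  Targets below the
    tabulated floor clamp to the largest tabulated noise.
    """
    ceiling = CONF_NOISE_M[0]
    if m_target >= ceiling:
        m = min(m_target, CHOICE_NOISE_M[-1])
        tau_c = float(np.interp(m, CHOICE_NOISE_M, CHOICE_NOISE_GRID))
        return 0.0, tau_c
    m = max(m_target, CONF_NOISE_M[-1])
    # CONF_NOISE_M is decreasing; np.interp needs ascending x
    tau_m = float(np.interp(m, CONF_NOISE_M[::-1], CONF_NOISE_GRID[::-1]))
    return tau_m, 0.0
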