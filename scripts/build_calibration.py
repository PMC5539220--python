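"""Rebuild the noise <-> M-ratio calibration table in metasdt/calibration.py.

Simulates a large-n observer at mid-range sensitivity for each noise level,
fits meta-d', and prints the arrays to paste into calibration.py.  Run after
any change to the observer's confidence mechanism:

    python scripts/build_calibration.py
"""

import numpy as np

from metasdt.observer import ObserverParams, _mu_for_measured_d, _simulate_choices
from metasdt.tables import RatingTable
from metasdt.type2 import MetaDSDT

SEED = 20250919
N_TRIALS = 200_000
D_PRIME = 1.1

CONF_GRID = [0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 9.0, 14.0]
CHOICE_GRID = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.3]


def measure_m(tau_m: float, tau_c: float, rng: np.random.Generator) -> float:
    params = ObserverParams(sensitivity=D_PRIME, meta_noise_sd=tau_m,
                            choice_noise_sd=tau_c)
    mu = _mu_for_measured_d(D_PRIME, 0.0, 1.0, tau_c)
    stim = rng.integers(0, 2, N_TRIALS)
    resp, _, conf = _simulate_choices(rng, stim, mu, params)
    counts = np.zeros((2, 2, params.n_levels))
    np.add.at(counts, (stim, resp, conf - 1), 1.0)
    fit = MetaDSDT(RatingTable(counts), variance="equal").fit()
    return fit.m_ratio


def main():
    rng = np.random.default_rng(SEED)
    conf_m = [measure_m(t, 0.0, rng) for t in CONF_GRID]
    choice_m = [measure_m(0.0, t, rng) for t in CHOICE_GRID]
    fmt = lambda xs: "[" + ", ".join(f"{x:.4f}" for x in xs) + "]"
    print("CONF_NOISE_GRID =", CONF_GRID)
    print("CONF_NOISE_M =", fmt(conf_m))
    print("CHOICE_NOISE_GRID =", CHOICE_GRID)
    print("CHOICE_NOISE_M =", fmt(choice_m))


if __name__ == "__main__":
    main()
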