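"""Shared fixtures: an independent SDT trial simulator for oracle tests.

The simulator here is deliberately separate from metasdt.observer — tests
that check parameter recovery must not generate data through the code path
under test.
"""

import numpy as np
import pytest

from metasdt.tables import RatingTable


def sim_rating_counts(rng, n, d, c=0.0, tau=0.0, s=1.0, K=6,
                      crit=(0.2, 0.45, 0.75, 1.1, 1.5), flip_confidence=False):
    """Plain-numpy confidence-rating SDT simulator (independent of metasdt).

    Evidence x ~ N(-d/2, 1) / N(+d/2, 1/s); choice = x > c; confidence
    variable y = x + N(0, tau), binned by symmetric criteria around c on
    the chosen side.  ``flip_confidence`` inverts y around c to produce an
    anti-correlated (negative meta-d') observer.
    """
    stim = rng.integers(0, 2, n)
    x = rng.normal(np.where(stim == 1, d / 2.0, -d / 2.0),
                   np.where(stim == 1, 1.0 / s, 1.0))
    resp = (x > c).astype(int)
    y = x + rng.normal(0.0, tau, n) if tau > 0 else x.copy()
    if flip_confidence:
        y = 2 * c - y
    conf = np.ones(n, dtype=int)
    for cc in crit:
        conf += np.where(resp == 1, y > c + cc, y < c - cc).astype(int)
    counts = np.zeros((2, 2, K))
    np.add.at(counts, (stim, resp, conf - 1), 1.0)
    return counts


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def medium_table(rng):
    """300-trial table with moderate sensitivity and confidence noise."""
    return RatingTable(sim_rating_counts(rng, 300, d=1.2, c=0.1, tau=0.6))


@pytest.fixture
def large_ideal_table(rng):
    """Large zero-noise table: confidence deterministic in the choice evidence."""
    return RatingTable(sim_rating_counts(rng, 50_000, d=1.5))
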