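"""Rating-count tables: the sufficient statistic for type-1 and type-2 SDT fits.

A confidence-rating 2-AFC (or old/new) experiment with K confidence levels
produces, per subject and task, a ``stimulus x response x confidence`` count
cube.  Every estimator in this package consumes that cube, never raw trials,
so trial order can never influence an estimate.

Rating-criterion ordering convention
------------------------------------
The 2K response categories are ordered along the latent evidence axis from
strongest "S1" evidence to strongest "S2" evidence::

    (resp=S1, conf=K) ... (resp=S1, conf=1) (resp=S2, conf=1) ... (resp=S2, conf=K)

so "S2" responses occupy the upper K+1..2K end.  Cumulative hit / false-alarm
rates are taken from the S2 end of this ordering (2K-1 interior cut points).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

S1, S2 = 0, 1
CLASS_LABELS = ("S1", "S2")

__all__ = ["RatingTable", "counts_from_trials", "pad_counts", "S1", "S2"]


@dataclass(frozen=True)
class RatingTable:
    """Stimulus x response x confidence count cube.

    Parameters
    ----------
    counts : ndarray, shape (2, 2, K)
        ``counts[stim, resp, conf-1]``; non-negative.  Raw tallies are
        integers; padded tables carry fractional counts.
    task_label : str
        Free-form task tag (``"perceptual"`` or ``"memory"`` in the cohort
        design); carried through to provenance.
    padding_applied : bool
        True once :func:`pad_counts` has added pseudo-counts.
    """

    counts: np.ndarray
    task_label: str = ""
    padding_applied: bool = False
    padding_scheme: str | None = None

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 3 or counts.shape[:2] != (2, 2):
            raise ValueError(f"counts must have shape (2, 2, K); got {counts.shape}")
        if counts.shape[2] < 2:
            raise ValueError("need at least K=2 confidence levels")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("counts must be finite and non-negative")
        object.__setattr__(self, "counts", counts)

    # -- basic views -------------------------------------------------------

    @property
    def n_levels(self) -> int:
        return self.counts.shape[2]

    @property
    def n_trials(self) -> float:
        return float(self.counts.sum())

    def choice_table(self) -> np.ndarray:
        """Collapse over confidence: 2x2 (stimulus x response) choice counts."""
        return self.counts.sum(axis=2)

    def accuracy(self) -> float:
        tab = self.choice_table()
        return float((tab[S1, S1] + tab[S2, S2]) / tab.sum())

    # -- rating-axis views -------------------------------------------------

    def rating_vector(self, stim: int) -> np.ndarray:
        """Counts for one stimulus class along the 2K rating-category axis.

        Ordered (S1,K)...(S1,1),(S2,1)...(S2,K): ascending S2 evidence.
        """
        s1_side = self.counts[stim, S1, ::-1]  # conf K ... 1
        s2_side = self.counts[stim, S2, :]     # conf 1 ... K
        return np.concatenate([s1_side, s2_side])

    def cumulative_rates(self, stim: int) -> np.ndarray:
        """P(rating category above each of the 2K-1 interior cuts | stim).

        Element j is the probability mass in categories j+1..2K, i.e. the
        hit rate (stim=S2) or false-alarm rate (stim=S1) at rating
        criterion j, from most liberal (leftmost cut) to most conservative.
        """
        vec = self.rating_vector(stim)
        total = vec.sum()
        if total <= 0:
            raise ValueError("no trials for stimulus class " + CLASS_LABELS[stim])
        tail = np.cumsum(vec[::-1])[::-1][1:]  # mass strictly above each cut
        return tail / total

    def with_counts(self, counts: np.ndarray, **changes) -> "RatingTable":
        return replace(self, counts=counts, **changes)


def counts_from_trials(trials, task: str | None = None, n_levels: int = 6) -> RatingTable:
    """Tally trial records into a :class:`RatingTable`.

    Parameters
    ----------
    trials : iterable
        Trial records with attributes (or mapping keys) ``stimulus_class``,
        ``response_class`` in {"S1","S2"} and ``confidence`` in 1..n_levels.
        A pandas DataFrame with those columns is also accepted.
    task : str, optional
        If given, every trial's ``task`` field must match; becomes the
        table's ``task_label``.
    """
    counts = np.zeros((2, 2, n_levels))

    def _get(rec, key):
        if hasattr(rec, key):
            return getattr(rec, key)
        return rec[key]

    try:  # DataFrame fast path
        import pandas as pd

        if isinstance(trials, pd.DataFrame):
            df = trials
            if task is not None:
                bad = df.index[df["task"] != task]
                if len(bad):
                    raise ValueError(f"trial rows {list(bad[:5])} have task != {task!r}")
            conf = df["confidence"].to_numpy()
            if np.any((conf < 1) | (conf > n_levels) | (conf != np.floor(conf))):
                row = int(df.index[(conf < 1) | (conf > n_levels)][0])
                raise ValueError(f"confidence outside 1..{n_levels} at row {row}")
            si = (df["stimulus_class"].to_numpy() == "S2").astype(int)
            ri = (df["response_class"].to_numpy() == "S2").astype(int)
            np.add.at(counts, (si, ri, conf.astype(int) - 1), 1.0)
            return RatingTable(counts, task_label=task or "")
    except ImportError:  # pragma: no cover
        pass

    for i, rec in enumerate(trials):
        if task is not None and _get(rec, "task") != task:
            raise ValueError(f"trial {i} has task {_get(rec, 'task')!r}, expected {task!r}")
        conf = int(_get(rec, "confidence"))
        if not 1 <= conf <= n_levels:
            raise ValueError(f"trial {i}: confidence {conf} outside 1..{n_levels}")
        si = CLASS_LABELS.index(_get(rec, "stimulus_class"))
        ri = CLASS_LABELS.index(_get(rec, "response_class"))
        counts[si, ri, conf - 1] += 1
    return RatingTable(counts, task_label=task or "")


def pad_counts(table: RatingTable, scheme: str = "only-if-needed") -> RatingTable:
    """Guard zero cells before z-transforms by adding 1/(2K) pseudo-counts.

    Schemes
    -------
    ``"only-if-needed"`` (default)
        Add 1/(2K) to every cell iff any cumulative hit/FA tail is 0 or 1
        (the convention of the classic meta-d' code family).
    ``"always"``
        Unconditionally add 1/(2K) to every cell.
    ``"none"``
        Return the table unchanged (fits may then fail on degenerate data).
    """
    if scheme not in ("only-if-needed", "always", "none"):
        raise ValueError(f"unknown padding scheme {scheme!r}")
    if table.n_trials == 0:
        raise ValueError("no trials: cannot pad an all-zero table")
    for stim in (S1, S2):
        if table.counts[stim].sum() == 0:
            raise ValueError("no trials for stimulus class " + CLASS_LABELS[stim])

    def _needs_padding() -> bool:
        for stim in (S1, S2):
            rates = table.cumulative_rates(stim)
            if np.any(rates <= 0) or np.any(rates >= 1):
                return True
        return False

    pad = 1.0 / (2 * table.n_levels)
    if scheme == "always" or (scheme == "only-if-needed" and _needs_padding()):
        return table.with_counts(
            table.counts + pad, padding_applied=True, padding_scheme=scheme
        )
    return table.with_counts(table.counts, padding_applied=False, padding_scheme=scheme)
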