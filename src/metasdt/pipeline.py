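"""Per-subject measure extraction and group-level statistics.

The analysis battery for a two-group (SDI vs control), two-task
(perceptual vs memory) confidence-rating study:

* per-subject type-1 and type-2 SDT measures for both tasks, with memory
  metacognition computed three ways (unequal-variance meta-da/da,
  equal-variance meta-d'/d', and unequal-variance per imageability split);
* Levene-guided two-tailed t-tests (pooled when Levene's test does not
  reject equality of variances at alpha, Welch otherwise);
* mixed Group x Task ANOVAs with partial eta-squared;
* Pearson correlations.

No multiple-testing correction is applied anywhere in the battery — every
p-value is reported at face value against alpha = 0.05, mirroring the
analysis design this package re-implements; treat the family of tests
accordingly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .staircase import exclusion_filter, threshold_from_trace
from .tables import counts_from_trials
from .type1 import Type1SDT
from .type2 import MetaDSDT

log = logging.getLogger(__name__)

__all__ = [
    "SubjectMeasures", "GroupComparison", "AnovaEffect",
    "extract_measures", "compare_groups", "mixed_anova", "pearson",
    "MEASURE_COLUMNS",
]

ALPHA = 0.05

MEASURE_COLUMNS = [
    "subject_id", "group_label", "complete",
    "perceptual_accuracy", "contrast_threshold", "perceptual_d_prime",
    "perceptual_meta_d", "perceptual_m_ratio", "perceptual_mean_confidence",
    "perceptual_mean_rt_ms", "perceptual_mean_ct_ms",
    "memory_accuracy", "memory_d_prime", "memory_da", "memory_s",
    "memory_meta_d", "memory_meta_da", "memory_m_ratio_equal",
    "memory_m_ratio_unequal", "m_ratio_high_imageable", "m_ratio_low_imageable",
    "memory_mean_confidence", "memory_mean_rt_ms", "memory_mean_ct_ms",
]

# measure name -> (column A, column B, level A, level B, within-factor name)
ANOVA_DEPENDENTS = {
    "mean_confidence": ("perceptual_mean_confidence", "memory_mean_confidence",
                        "perceptual", "memory", "task"),
    "m_ratio_mixed": ("perceptual_m_ratio", "memory_m_ratio_unequal",
                      "perceptual", "memory", "task"),
    "m_ratio_equal": ("perceptual_m_ratio", "memory_m_ratio_equal",
                      "perceptual", "memory", "task"),
    "d_prime": ("perceptual_d_prime", "memory_d_prime",
                "perceptual", "memory", "task"),
    "m_ratio_imageability": ("m_ratio_high_imageable", "m_ratio_low_imageable",
                             "high", "low", "imageability"),
}


@dataclass(frozen=True)
class SubjectMeasures:
    """One subject's derived behavioral measures (the row unit of the group summary tables)."""

    subject_id: str
    group_label: str
    complete: bool
    values: dict = field(default_factory=dict)


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison of one measure (Levene-guided t-test)."""

    measure: str
    groups: tuple
    means: tuple
    sds: tuple
    ns: tuple
    levene_p: float
    variance_assumption: str   # "pooled" | "welch"
    t_statistic: float
    df: float
    p_value: float
    alpha: float = ALPHA

    def summary(self) -> str:
        g1, g2 = self.groups
        return (f"{self.measure}: {g1} {self.means[0]:.2f} ({self.sds[0]:.2f}) vs "
                f"{g2} {self.means[1]:.2f} ({self.sds[1]:.2f}); "
                f"Levene p = {self.levene_p:.3f} -> {self.variance_assumption}; "
                f"t({self.df:.1f}) = {self.t_statistic:.2f}, p = {self.p_value:.3f}")


@dataclass(frozen=True)
class AnovaEffect:
    effect: str
    F: float
    df1: float
    df2: float
    p_value: float
    partial_eta_sq: float
    degenerate: bool = False


def _safe_fits(table, want_unequal: bool, n_starts: int):
    """Type-1/type-2 fits with failures mapped to NaN (degenerate subjects)."""
    out = dict(d_prime=np.nan, meta_d=np.nan, m_ratio_equal=np.nan,
               da=np.nan, s=np.nan, meta_da=np.nan, m_ratio_unequal=np.nan)
    try:
        t1e = Type1SDT(table, variance="equal").fit()
        out["d_prime"] = t1e.d_prime
        f2e = MetaDSDT(table, variance="equal", type1=t1e).fit(n_starts=n_starts)
        out["meta_d"] = f2e.meta_d
        out["m_ratio_equal"] = f2e.m_ratio
    except (ValueError, RuntimeError) as err:
        log.warning("equal-variance fit failed: %s", err)
    if want_unequal:
        try:
            t1u = Type1SDT(table, variance="unequal").fit()
            out["da"], out["s"] = t1u.da, t1u.s
            f2u = MetaDSDT(table, variance="unequal", type1=t1u).fit(n_starts=n_starts)
            out["meta_da"] = f2u.meta_d
            out["m_ratio_unequal"] = f2u.m_ratio
        except (ValueError, RuntimeError) as err:
            log.warning("unequal-variance fit failed: %s", err)
    return out


def extract_measures(trials: pd.DataFrame, n_starts: int = 3,
                     imageability_split: bool = True) -> pd.DataFrame:
    """Compute per-subject measures from a trial-level dataset.

    Deterministic and invariant to row order (trials are re-sorted by
    subject/task/trial_index before any sequential computation).  Subjects
    missing a task are flagged ``complete = False``; degenerate fits yield
    NaN entries carried as missing.
    """
    trials = trials.sort_values(["subject_id", "task", "trial_index"])
    rows = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        rec = {c: np.nan for c in MEASURE_COLUMNS}
        rec["subject_id"] = sid
        rec["group_label"] = sub["group_label"].iloc[0]
        per = sub[sub.task == "perceptual"]
        mem = sub[sub.task == "memory"]
        rec["complete"] = bool(len(per)) and bool(len(mem))

        if len(per):
            rec["perceptual_accuracy"] = per.correct.mean()
            rec["contrast_threshold"] = threshold_from_trace(
                per.contrast.to_numpy())
            rec["perceptual_mean_confidence"] = per.confidence.mean()
            rec["perceptual_mean_rt_ms"] = per.rt_ms.mean()
            rec["perceptual_mean_ct_ms"] = per.ct_ms.mean()
            fits = _safe_fits(counts_from_trials(per, task="perceptual"),
                              want_unequal=False, n_starts=n_starts)
            rec["perceptual_d_prime"] = fits["d_prime"]
            rec["perceptual_meta_d"] = fits["meta_d"]
            rec["perceptual_m_ratio"] = fits["m_ratio_equal"]

        if len(mem):
            rec["memory_accuracy"] = mem.correct.mean()
            rec["memory_mean_confidence"] = mem.confidence.mean()
            rec["memory_mean_rt_ms"] = mem.rt_ms.mean()
            rec["memory_mean_ct_ms"] = mem.ct_ms.mean()
            fits = _safe_fits(counts_from_trials(mem, task="memory"),
                              want_unequal=True, n_starts=n_starts)
            rec["memory_d_prime"] = fits["d_prime"]
            rec["memory_meta_d"] = fits["meta_d"]
            rec["memory_m_ratio_equal"] = fits["m_ratio_equal"]
            rec["memory_da"], rec["memory_s"] = fits["da"], fits["s"]
            rec["memory_meta_da"] = fits["meta_da"]
            rec["memory_m_ratio_unequal"] = fits["m_ratio_unequal"]
            if imageability_split:
                for label in ("high", "low"):
                    split = mem[mem.imageability == label]
                    if len(split):
                        sf = _safe_fits(counts_from_trials(split, task="memory"),
                                        want_unequal=True, n_starts=n_starts)
                        rec[f"m_ratio_{label}_imageable"] = sf["m_ratio_unequal"]
        rows.append(rec)
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)


def compare_groups(measures: pd.DataFrame, measure: str,
                   alpha: float = ALPHA) -> GroupComparison:
    """Levene-guided two-tailed two-sample t-test on one measure column.

    Classic Levene (absolute deviations from the group *mean*); the pooled
    t-test is used unless Levene rejects equality of variances at `alpha`,
    in which case Welch's t with fractional df is reported.
    """
    groups = sorted(measures["group_label"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    a, b = (measures.loc[measures.group_label == g, measure].dropna().to_numpy()
            for g in groups)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"{measure}: need >= 2 finite values per group")
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        # degenerate: identical constant groups
        return GroupComparison(measure, tuple(groups),
                               (float(a.mean()), float(b.mean())),
                               (float(a.std(ddof=1)), float(b.std(ddof=1))),
                               (len(a), len(b)), 1.0, "pooled", 0.0,
                               float(len(a) + len(b) - 2), 1.0, alpha)
    lev = stats.levene(a, b, center="mean")
    equal_var = lev.pvalue >= alpha
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        measure=measure, groups=tuple(groups),
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        ns=(len(a), len(b)),
        levene_p=float(lev.pvalue),
        variance_assumption="pooled" if equal_var else "welch",
        t_statistic=float(res.statistic), df=float(res.df),
        p_value=float(res.pvalue), alpha=alpha,
    )


def mixed_anova(measures: pd.DataFrame, dependent: str) -> list[AnovaEffect]:
    """Mixed Group (between) x within-factor ANOVA on one measure.

    `dependent` is a key of :data:`ANOVA_DEPENDENTS` naming the pair of
    within-condition columns (task for most measures, imageability for the
    split metamemory analysis); subjects missing either value are dropped
    (logged).  Reports F, p and partial eta-squared for group, the within
    factor and their interaction.
    """
    import pingouin as pg

    if dependent not in ANOVA_DEPENDENTS:
        raise ValueError(f"unknown ANOVA dependent {dependent!r}; "
                         f"choose from {sorted(ANOVA_DEPENDENTS)}")
    col_a, col_b, lev_a, lev_b, within = ANOVA_DEPENDENTS[dependent]
    wide = measures[["subject_id", "group_label", col_a, col_b]].dropna()
    dropped = len(measures) - len(wide)
    if dropped:
        log.info("mixed_anova(%s): dropped %d subjects with missing data",
                 dependent, dropped)
    long = wide.melt(id_vars=["subject_id", "group_label"],
                     value_vars=[col_a, col_b],
                     var_name=within, value_name="value")
    long[within] = np.where(long[within] == col_a, lev_a, lev_b)
    if np.allclose(long["value"], long["value"].iloc[0]):
        return [AnovaEffect(e, 0.0, 1.0, float(len(wide) - 2), 1.0, 0.0, True)
                for e in ("group", within, "interaction")]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(data=long, dv="value", within=within,
                             between="group_label", subject="subject_id")
    name_map = {"group_label": "group", within: within,
                "Interaction": "interaction"}
    out = []
    for _, row in aov.iterrows():
        out.append(AnovaEffect(
            effect=name_map.get(row["Source"], row["Source"]),
            F=float(row["F"]), df1=float(row["DF1"]), df2=float(row["DF2"]),
            p_value=float(row["p_unc"]), partial_eta_sq=float(row["np2"]),
        ))
    return out


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with two-tailed p over paired finite values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need >= 3 paired finite values")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in a correlated variable")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def apply_exclusion(measures: pd.DataFrame, n_sd: float = 8.0):
    """Flag perceptual-accuracy outliers (below mean - n_sd * SD) for removal."""
    acc = dict(zip(measures.subject_id, measures.perceptual_accuracy))
    excluded = exclusion_filter(acc, n_sd=n_sd)
    if excluded:
        log.info("excluding %d outlier subjects: %s", len(excluded), sorted(excluded))
    kept = measures[~measures.subject_id.isin(excluded)].reset_index(drop=True)
    return kept, excluded
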