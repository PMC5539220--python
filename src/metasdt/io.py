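"""Trial CSV schema, run configuration, results bundle and text reports.

CSV dialect: UTF-8, comma-separated, header row, "." decimal point,
missing values as empty fields.  Times are integer milliseconds.  One row
per trial with columns (see README for full semantics)::

    subject_id, group_label, task, trial_index, stimulus_class,
    response_class, correct, confidence, rt_ms, ct_ms, contrast, imageability
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .observer import (CohortSpec, GroupSpec, TruncNormal, TRIAL_COLUMNS,
                       default_cohort_spec)
from .pipeline import (ANOVA_DEPENDENTS, apply_exclusion, compare_groups,
                       extract_measures, mixed_anova, pearson)

__all__ = ["read_trials", "write_trials", "RunConfig", "ResultsBundle",
           "analyze", "render_behavioral_table", "render_timing_table"]

_CATEGORICAL = {
    "task": {"perceptual", "memory"},
    "stimulus_class": {"S1", "S2"},
    "response_class": {"S1", "S2"},
    "imageability": {"high", "low", "none"},
}


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial dataset in the documented CSV dialect."""
    out = trials[TRIAL_COLUMNS].copy()
    out["correct"] = out["correct"].astype(int)
    out.to_csv(path, index=False, encoding="utf-8")


def read_trials(path) -> pd.DataFrame:
    """Read and hard-validate a trial CSV.

    Raises ``ValueError`` naming offending rows (0-based data rows) and
    fields on any schema violation.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    errors = []

    def check(mask, message):
        bad = df.index[mask]
        if len(bad):
            errors.append(f"{message} (rows {list(bad[:10])})")

    for col, allowed in _CATEGORICAL.items():
        check(~df[col].isin(allowed), f"{col} not in {sorted(allowed)}")
    conf = pd.to_numeric(df["confidence"], errors="coerce")
    check(conf.isna() | (conf < 1) | (conf > 6) | (conf != conf.round()),
          "confidence must be an integer in 1..6")
    perc = df["task"] == "perceptual"
    check(perc & (df["contrast"].isna() | (df["contrast"] <= 0)
                  | (df["contrast"] > 1)),
          "perceptual contrast must lie in (0, 1]")
    check(~perc & df["contrast"].notna(), "contrast must be empty on memory rows")
    for col in ("rt_ms", "ct_ms"):
        vals = pd.to_numeric(df[col], errors="coerce")
        check(vals.isna() | (vals <= 0), f"{col} must be a positive integer")
    if errors:
        raise ValueError("invalid trial CSV:\n  " + "\n  ".join(errors))
    df["correct"] = df["correct"].astype(bool)
    df["confidence"] = df["confidence"].astype(int)
    mismatch = (df["response_class"] == df["stimulus_class"]) != df["correct"]
    if mismatch.any():
        raise ValueError("correct flag inconsistent with stimulus/response "
                         f"(rows {list(df.index[mismatch][:10])})")
    return df


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class RunConfig:
    """Declarative run configuration (YAML round-trips losslessly).

    Defaults encode the study design: 6-point confidence scale, 180
    staircase-controlled perceptual trials (step 0.03, baseline contrast
    0.20), 100 learned / 200 tested memory words, alpha = 0.05, negative
    m-ratio subjects retained, outlier exclusion at mean - 8 SD.
    """

    seed: int = 0
    n_confidence_levels: int = 6
    n_perceptual_trials: int = 180
    n_learn: int = 100
    n_test: int = 200
    staircase_step: float = 0.03
    baseline_contrast: float = 0.20
    padding_scheme: str = "only-if-needed"
    n_starts: int = 3
    alpha: float = 0.05
    retain_negative_m_ratio: bool = True
    exclusion_n_sd: float = 8.0
    imageability_d_effect: float = 0.0
    cohort: dict = field(default_factory=dict)  # GroupSpec overrides, per label

    def cohort_spec(self) -> CohortSpec:
        base = default_cohort_spec()
        groups = []
        for g in base.groups:
            overrides = self.cohort.get(g.label, {})
            fields = {}
            for name, value in overrides.items():
                cur = getattr(g, name)
                if isinstance(cur, TruncNormal):
                    value = TruncNormal(**value) if isinstance(value, dict) \
                        else TruncNormal(*value)
                fields[name] = value
            groups.append(dataclasses.replace(g, **fields))
        return CohortSpec(groups=tuple(groups),
                          n_perceptual_trials=self.n_perceptual_trials,
                          n_learn=self.n_learn, n_test=self.n_test,
                          imageability_d_effect=self.imageability_d_effect)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, src) -> "RunConfig":
        if hasattr(src, "read"):
            data = yaml.safe_load(src.read())
        else:
            try:
                with open(src, "r", encoding="utf-8") as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(src)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# analysis bundle

_COMPARISON_MEASURES = [
    "contrast_threshold", "perceptual_accuracy", "perceptual_d_prime",
    "perceptual_mean_confidence", "perceptual_m_ratio",
    "memory_d_prime", "memory_mean_confidence",
    "memory_m_ratio_unequal", "memory_m_ratio_equal",
    "perceptual_mean_rt_ms", "perceptual_mean_ct_ms",
    "memory_mean_rt_ms", "memory_mean_ct_ms",
]

_CORRELATIONS = [
    ("perceptual_m_ratio", "perceptual_d_prime", "pooled"),
    ("memory_m_ratio_unequal", "memory_d_prime", "pooled"),
    ("perceptual_m_ratio", "memory_m_ratio_unequal", "pooled"),
    ("perceptual_m_ratio", "memory_m_ratio_unequal", "by-group"),
    ("m_ratio_high_imageable", "m_ratio_low_imageable", "by-group"),
]


@dataclass
class ResultsBundle:
    """Self-describing analysis output; deterministic for a given input."""

    measures: list
    excluded_subjects: list
    comparisons: dict
    anovas: dict
    correlations: dict
    provenance: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=_json_default)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _clean(record: dict) -> dict:
    return {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
            for k, v in record.items()}


def analyze(trials: pd.DataFrame, config: RunConfig | None = None,
            measures: pd.DataFrame | None = None) -> ResultsBundle:
    """Run the full group-level battery on a trial dataset.

    Extraction -> outlier exclusion (perceptual accuracy below
    mean - 8 SD) -> Levene-guided t-tests on the summary measures ->
    mixed Group x Task ANOVAs -> Pearson correlations.  Pass a
    pre-computed `measures` frame to skip extraction.
    """
    config = config or RunConfig()
    if measures is None:
        measures = extract_measures(trials, n_starts=config.n_starts)
    measures, excluded = apply_exclusion(measures, n_sd=config.exclusion_n_sd)
    if not config.retain_negative_m_ratio:
        neg = (measures[["perceptual_m_ratio", "memory_m_ratio_unequal"]] < 0
               ).any(axis=1)
        measures = measures[~neg].reset_index(drop=True)

    comparisons = {}
    for name in _COMPARISON_MEASURES:
        try:
            comparisons[name] = _clean(asdict(
                compare_groups(measures, name, alpha=config.alpha)))
        except ValueError as err:
            comparisons[name] = {"error": str(err)}

    anovas = {}
    for dep in ANOVA_DEPENDENTS:
        try:
            anovas[dep] = [_clean(asdict(e)) for e in mixed_anova(measures, dep)]
        except (ValueError, KeyError) as err:
            anovas[dep] = {"error": str(err)}

    correlations = {}
    for x, y, scope in _CORRELATIONS:
        key = f"{x}__vs__{y}"
        try:
            if scope == "pooled":
                r, p = pearson(measures[x], measures[y])
                correlations[key] = {"scope": "pooled", "r": r, "p": p,
                                     "n": int(np.isfinite(measures[x] * measures[y]).sum())}
            else:
                per_group = {}
                for lbl, sub in measures.groupby("group_label"):
                    r, p = pearson(sub[x], sub[y])
                    per_group[lbl] = {"r": r, "p": p}
                correlations[key + "__by_group"] = per_group
        except ValueError as err:
            correlations[key if scope == "pooled" else key + "__by_group"] = {
                "error": str(err)}

    return ResultsBundle(
        measures=[_clean(r) for r in measures.to_dict(orient="records")],
        excluded_subjects=sorted(excluded),
        comparisons=comparisons, anovas=anovas, correlations=correlations,
        provenance={"package_version": __version__, "seed": config.seed,
                    "config_sha256": config.digest(), "n_subjects": len(measures)},
    )


# ---------------------------------------------------------------------------
# reports

_BEHAVIORAL_ROWS = [
    ("Perceptual", None),
    ("Contrast Threshold", "contrast_threshold"),
    ("Accuracy", "perceptual_accuracy"),
    ("d'", "perceptual_d_prime"),
    ("Mean Confidence", "perceptual_mean_confidence"),
    ("M-ratio", "perceptual_m_ratio"),
    ("Memory", None),
    ("d'", "memory_d_prime"),
    ("Mean Confidence", "memory_mean_confidence"),
    ("Unequal Variance M-ratio", "memory_m_ratio_unequal"),
    ("Equal Variance M-ratio", "memory_m_ratio_equal"),
]

_TIMING_ROWS = [
    ("Perceptual", None),
    ("Mean RT", "perceptual_mean_rt_ms"),
    ("Mean CT", "perceptual_mean_ct_ms"),
    ("Memory", None),
    ("Mean RT", "memory_mean_rt_ms"),
    ("Mean CT", "memory_mean_ct_ms"),
]


def _render_measure_table(measures: pd.DataFrame, rows, title: str,
                          decimals: int = 2) -> str:
    groups = sorted(measures["group_label"].unique())
    width = max(len(label) for label, _ in rows) + 2
    head = f"{title:<{width}}" + "".join(f"{g:>18}" for g in groups)
    lines = [head, "-" * len(head)]
    for label, col in rows:
        if col is None:
            lines.append(label)
            continue
        cells = []
        for g in groups:
            vals = measures.loc[measures.group_label == g, col].dropna()
            if len(vals):
                cells.append(f"{vals.mean():.{decimals}f} ({vals.std(ddof=1):.{decimals}f})")
            else:
                cells.append("--")
        lines.append(f"  {label:<{width - 2}}" + "".join(f"{c:>18}" for c in cells))
    return "\n".join(lines)


def render_behavioral_table(measures: pd.DataFrame) -> str:
    """Mean (SD) behavioral measures per group (behavioral summary)."""
    return _render_measure_table(measures, _BEHAVIORAL_ROWS,
                                 "Behavioral measures: mean (SD)")


def render_timing_table(measures: pd.DataFrame) -> str:
    """Mean (SD) response/confidence times per group, in ms (timing summary)."""
    return _render_measure_table(measures, _TIMING_ROWS,
                                 "Timing measures, ms: mean (SD)", decimals=0)
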