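"""Clinical efficacy statistics for pre/post UPDRS scores.

The improvement rate of a patient is ``100 * (pre - post) / pre``
percent of the preoperative UPDRS.  Rates are classified into three
efficacy categories — markedly effective, improved, ineffective — and
tabulated per treatment group with row percentages.  Group differences
are tested with the Pearson chi-square statistic (no continuity
correction) and paired pre/post differences with the paired t-test.

The default classification cut-offs (markedly effective >= 50%
improvement, improved >= 20%) follow common usage in comparable
surgical-efficacy reports and are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._core import ValidationError
from .phantom import OutcomeRecord

__all__ = [
    "EfficacyThresholds",
    "ContingencyTable",
    "improvement_rate",
    "classify_outcome",
    "tabulate",
    "chi_square_test",
    "paired_t_test",
    "read_cohort_csv",
]

CATEGORIES = ("markedly_effective", "ineffective", "improved")


@dataclass(frozen=True)
class EfficacyThresholds:
    """Improvement-rate cut-offs (percent), boundaries inclusive."""

    markedly_effective_min: float = 50.0
    improved_min: float = 20.0

    def __post_init__(self):
        if not (0 < self.improved_min < self.markedly_effective_min <= 100):
            raise ValidationError(
                "need 0 < improved_min < markedly_effective_min <= 100")


@dataclass
class ContingencyTable:
    """Group-by-category counts with row percentages (one decimal)."""

    groups: list[str]
    categories: list[str]
    counts: np.ndarray
    percentages: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        self.percentages = np.asarray(self.percentages, dtype=float)
        if self.counts.shape != (len(self.groups), len(self.categories)):
            raise ValidationError("counts shape does not match labels")
        rowsum = self.percentages.sum(axis=1)
        if np.any(np.abs(rowsum - 100.0) > 0.1):
            raise ValidationError("row percentages must sum to 100 within 0.1")

    def to_frame(self) -> pd.DataFrame:
        recs = {}
        for j, cat in enumerate(self.categories):
            recs[f"{cat}_n"] = self.counts[:, j]
            recs[f"{cat}_pct"] = self.percentages[:, j]
        return pd.DataFrame(recs, index=self.groups)


def improvement_rate(updrs_pre: float, updrs_post: float) -> float:
    """Percent improvement 100*(pre - post)/pre; negative if worsened."""
    if updrs_pre <= 0:
        raise ValidationError("preoperative UPDRS must be > 0")
    return 100.0 * (updrs_pre - updrs_post) / updrs_pre


def classify_outcome(rate: float,
                     thresholds: EfficacyThresholds | None = None) -> str:
    """Map an improvement rate to its efficacy category."""
    thresholds = thresholds or EfficacyThresholds()
    if rate >= thresholds.markedly_effective_min:
        return "markedly_effective"
    if rate >= thresholds.improved_min:
        return "improved"
    return "ineffective"


def tabulate(records: list[OutcomeRecord],
             thresholds: EfficacyThresholds | None = None,
             counts: dict[str, dict[str, int]] | None = None) -> ContingencyTable:
    """Tabulate per-group efficacy counts and row percentages.

    Either classify ``records`` or, when ``counts`` is given (mapping
    group -> category -> count, e.g. a published table), tabulate
    those directly.
    """
    thresholds = thresholds or EfficacyThresholds()
    if counts is None:
        if not records:
            raise ValidationError("no records to tabulate")
        groups = list(dict.fromkeys(r.group for r in records))
        counts = {g: {c: 0 for c in CATEGORIES} for g in groups}
        for r in records:
            if r.group not in counts:
                raise ValidationError(f"unknown group {r.group!r}")
            cat = classify_outcome(improvement_rate(r.updrs_pre, r.updrs_post),
                                   thresholds)
            counts[r.group][cat] += 1
    groups = list(counts)
    mat = np.array([[counts[g].get(c, 0) for c in CATEGORIES] for g in groups],
                   dtype=int)
    if np.any(mat.sum(axis=1) == 0):
        raise ValidationError("every group needs at least one record")
    pct = np.round(100.0 * mat / mat.sum(axis=1, keepdims=True), 1)
    return ContingencyTable(groups=groups, categories=list(CATEGORIES),
                            counts=mat, percentages=pct)


def chi_square_test(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square on the counts, no continuity correction.

    Returns (statistic, degrees of freedom, p-value).  Expected counts
    must be positive; small expected counts (< 5) trigger a warning
    rather than a silent switch to another test.
    """
    obs = table.counts
    expected = stats.contingency.expected_freq(obs)
    if np.any(expected == 0):
        raise ValidationError(
            "zero expected count; merge sparse categories before testing")
    if np.any(expected < 5):
        warnings.warn("expected counts < 5; chi-square approximation is weak",
                      stacklevel=2)
    res = stats.chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def paired_t_test(pre, post) -> tuple[float, int, float]:
    """Two-sided paired t-test on (pre - post).

    Returns (t, df, p).  Raises when the differences have zero
    variance (the statistic is undefined there).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or len(pre) < 2:
        raise ValidationError("need two equal-length score vectors of length >= 2")
    diff = pre - post
    if np.var(diff, ddof=1) == 0:
        raise ValidationError("zero variance of paired differences")
    res = stats.ttest_rel(pre, post)
    return float(res.statistic), int(len(pre) - 1), float(res.pvalue)


def read_cohort_csv(path) -> list[OutcomeRecord]:
    """Load patient_id, group, updrs_pre, updrs_post records from CSV."""
    df = pd.read_csv(path)
    required = {"patient_id", "group", "updrs_pre", "updrs_post"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"cohort CSV missing columns {sorted(missing)}")
    return [OutcomeRecord(patient_id=str(r.patient_id), group=str(r.group),
                          updrs_pre=float(r.updrs_pre), updrs_post=float(r.updrs_post))
            for r in df.itertuples()]
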