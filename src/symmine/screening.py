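"""Pre-mining screening statistics for a binary symptom cohort.

Frequency descriptives, symptom × outcome 2×2 contingency tables with
Pearson chi-square tests, rank-based ROC cutoff selection for continuous
covariates, and a pooled-variance group-mean comparison. The chi-square
is deliberately uncorrected (no Yates continuity adjustment): on 2×2
tables of this size the uncorrected statistic is the one that matches
the printed p-values of the reference screen, and that choice is pinned
by a regression test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import Cohort
from .errors import DegenerateInputError
from .utils import round_half_up


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure × outcome contingency counts.

    Cell naming: first letter is exposure (e = absent/negative,
    p = present/positive), second is outcome. So ``c_pp`` counts
    exposure-positive, outcome-positive patients.
    """

    c_en: int
    c_ep: int
    c_pn: int
    c_pp: int
    exposure: str = "exposure"
    outcome: str = "outcome"

    def __post_init__(self) -> None:
        if min(self.c_en, self.c_ep, self.c_pn, self.c_pp) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.c_en + self.c_ep + self.c_pn + self.c_pp

    def as_array(self) -> np.ndarray:
        """Rows: exposure −/+; columns: outcome −/+."""
        return np.array([[self.c_en, self.c_ep], [self.c_pn, self.c_pp]])

    @property
    def exposure_margin(self) -> tuple[int, int]:
        return (self.c_en + self.c_ep, self.c_pn + self.c_pp)

    @property
    def outcome_margin(self) -> tuple[int, int]:
        return (self.c_en + self.c_pn, self.c_ep + self.c_pp)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class RocResult:
    auc: float
    p_value: float
    cutoff: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class GroupComparison:
    mean_pos: float
    mean_neg: float
    sd_pos: float
    sd_neg: float
    t: float
    p_value: float


def crosstab(cohort: Cohort, exposure: str, outcome: str | None = None) -> TwoByTwo:
    """Cross-tabulate one binary exposure against the outcome."""
    outcome = outcome if outcome is not None else cohort.outcome_column
    for col in (exposure, outcome):
        if col not in cohort.binary_columns:
            raise TypeError(f"column {col!r} is not a binary cohort column")
    e = cohort.data[exposure].to_numpy()
    o = cohort.data[outcome].to_numpy()
    return TwoByTwo(
        c_en=int(((e == 0) & (o == 0)).sum()),
        c_ep=int(((e == 0) & (o == 1)).sum()),
        c_pn=int(((e == 1) & (o == 0)).sum()),
        c_pp=int(((e == 1) & (o == 1)).sum()),
        exposure=exposure,
        outcome=outcome,
    )


def chi_square(table: TwoByTwo) -> ChiSquareResult:
    """Pearson chi-square on a 2×2 table, df = 1, no continuity correction."""
    if 0 in table.exposure_margin or 0 in table.outcome_margin:
        raise DegenerateInputError(
            f"zero margin in {table.exposure} × {table.outcome} table; "
            "expected counts undefined"
        )
    res = stats.chi2_contingency(table.as_array(), correction=False)
    return ChiSquareResult(float(res.statistic), 1, float(res.pvalue))


def roc_cutoff(scores, outcome) -> RocResult:
    """Rank-based ROC analysis of a continuous score against a 0/1 outcome.

    The AUC is the Mann–Whitney probability P(score+ > score−) with ties
    counted one half; its p-value (test of AUC = 0.5) comes from the
    tie-corrected normal approximation to the rank-sum statistic. The
    cutoff is the midpoint between adjacent distinct score values that
    maximizes Youden's J = sensitivity + specificity − 1, with positive
    classification meaning score > cutoff; ties on J resolve to the
    smallest candidate so output is deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome)
    if scores.shape != outcome.shape:
        raise ValueError("scores and outcome must have equal length")
    pos = scores[outcome == 1]
    neg = scores[outcome == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateInputError("both outcome classes must be non-empty")
    if np.unique(scores).size < 2:
        raise DegenerateInputError("constant scores admit no cutoff")
    mw = stats.mannwhitneyu(
        pos, neg, alternative="two-sided", use_continuity=False, method="asymptotic"
    )
    auc = float(mw.statistic) / (len(pos) * len(neg))

    uniq = np.unique(scores)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_j = -np.inf
    best = None
    for c in candidates:  # ascending, so the first argmax is the smallest
        sens = float(np.mean(pos > c))
        spec = float(np.mean(neg <= c))
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j = j
            best = (float(c), sens, spec)
    cutoff, sens, spec = best
    return RocResult(auc, float(mw.pvalue), cutoff, sens, spec)


def frequency_table(cohort: Cohort) -> pd.DataFrame:
    """Descriptive frequencies of every binary variable.

    Columns: ``count`` of 1s, ``percent`` of the whole cohort, and
    ``pct_within_positive`` — the variable's positivity rate among
    outcome-positive patients (so the outcome row itself reads 100).
    Percentages are half-up rounded to one decimal. Rows are ordered
    outcome first, then descending count, ties alphabetically.
    """
    out = cohort.data[cohort.outcome_column].to_numpy()
    n = cohort.n_rows
    n_pos = int(out.sum())
    rows = []
    for col in cohort.binary_columns:
        vals = cohort.data[col].to_numpy()
        count = int(vals.sum())
        within = int(vals[out == 1].sum()) if n_pos else 0
        rows.append(
            {
                "variable": col,
                "count": count,
                "percent": round_half_up(100.0 * count / n, 1) if n else 0.0,
                "pct_within_positive": (
                    round_half_up(100.0 * within / n_pos, 1) if n_pos else 0.0
                ),
            }
        )
    frame = pd.DataFrame(rows)
    is_outcome = frame["variable"].eq(cohort.outcome_column)
    frame = pd.concat(
        [
            frame[is_outcome],
            frame[~is_outcome].sort_values(
                ["count", "variable"], ascending=[False, True], kind="stable"
            ),
        ]
    ).reset_index(drop=True)
    return frame


def screen_table(cohort: Cohort) -> pd.DataFrame:
    """2×2 counts plus the uncorrected chi-square p for every symptom."""
    rows = []
    for col in cohort.binary_columns:
        if col == cohort.outcome_column:
            continue
        tab = crosstab(cohort, col)
        res = chi_square(tab)
        rows.append(
            {
                "exposure": col,
                "c_en": tab.c_en,
                "c_ep": tab.c_ep,
                "c_pn": tab.c_pn,
                "c_pp": tab.c_pp,
                "chi2": res.statistic,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def compare_group_means(values, outcome) -> GroupComparison:
    """Two-sample pooled-variance t-test of a numeric variable by outcome."""
    values = np.asarray(values, dtype=float)
    outcome = np.asarray(outcome)
    pos = values[outcome == 1]
    neg = values[outcome == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise DegenerateInputError("each outcome group needs at least 2 values")
    sd_pos = float(np.std(pos, ddof=1))
    sd_neg = float(np.std(neg, ddof=1))
    if sd_pos == 0.0 and sd_neg == 0.0:
        raise DegenerateInputError("zero pooled variance; t undefined")
    t, p = stats.ttest_ind(pos, neg, equal_var=True)
    return GroupComparison(
        float(np.mean(pos)), float(np.mean(neg)), sd_pos, sd_neg, float(t), float(p)
    )
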