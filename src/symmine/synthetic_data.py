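"""Synthetic symptom cohorts and the deterministic reference fixture.

Two generators live here.

``generate_cohort`` draws a cohort from a conditional-independence
model: the outcome is Bernoulli(prevalence) and each symptom is drawn
independently given the outcome with its own conditional probability
pair. Pairwise symptom–outcome margins are the only structure a
screening table constrains, so independence-given-outcome is the
maximum-entropy completion; higher-order structure is injected only
through explicit ``implications`` — itemsets that force the outcome
positive wherever all their members are present, creating confidence-1
rules by construction.

``table2_fixture`` builds a 520-patient cohort whose sixteen
symptom × outcome 2×2 tables equal, cell for cell, the published
contingency counts of the reference screen (320 outcome-positive /
200 outcome-negative; e.g. polyuria splits 243/15, polydipsia 225/8).
Placement is deterministic block-filling — the first rows of each
outcome block carry the 1s — so the fixture needs no seed and is
byte-identical across runs. Only its order-2 (pairwise) quantities are
faithful to the study; joint distributions of three or more symptoms
are construction artifacts (the first-rows placement maximally overlaps
symptoms) and must not be read as estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import Cohort
from .errors import ConfigurationError

#: Published 2×2 counts, symptom -> (c_en, c_ep, c_pn, c_pp): cells are
#: (exposure−,outcome−), (exposure−,outcome+), (exposure+,outcome−),
#: (exposure+,outcome+). Every row totals 520 with a 200/320 outcome split.
TABLE2_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "Gender": (181, 147, 19, 173),
    "Polyuria": (185, 77, 15, 243),
    "Polydipsia": (192, 95, 8, 225),
    "sudden.weight.loss": (171, 132, 29, 188),
    "weakness": (113, 102, 87, 218),
    "Polyphagia": (152, 131, 48, 189),
    "Genital.thrush": (167, 237, 33, 83),
    "visual.blurring": (142, 145, 58, 175),
    "Itching": (101, 166, 99, 154),
    "Irritability": (184, 210, 16, 110),
    "delayed.healing": (114, 167, 86, 153),
    "partial.paresis": (168, 128, 32, 192),
    "muscle.stiffness": (140, 185, 60, 135),
    "Alopecia": (99, 242, 101, 78),
    "Obesity": (173, 259, 27, 61),
    "Age": (121, 139, 79, 181),
}

FIXTURE_N = 520
FIXTURE_N_POSITIVE = 320
FIXTURE_OUTCOME = "Diabetes"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the conditional-independence cohort model.

    ``cond_probs`` maps each symptom name to
    ``(P(symptom=1 | outcome=1), P(symptom=1 | outcome=0))``.
    ``implications`` lists tuples of symptom column names; wherever all
    members of a tuple are 1 the outcome is forced to 1 after drawing.
    """

    n: int
    prevalence: float
    cond_probs: dict[str, tuple[float, float]]
    implications: tuple[tuple[str, ...], ...] = ()
    seed: int = 0
    outcome_column: str = FIXTURE_OUTCOME

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("n must be at least 1")
        probs = [self.prevalence]
        for p_pos, p_neg in self.cond_probs.values():
            probs += [p_pos, p_neg]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")
        for itemset in self.implications:
            unknown = set(itemset) - set(self.cond_probs)
            if unknown:
                raise ConfigurationError(f"implication uses unknown columns {unknown}")


def study_conditionals() -> dict[str, tuple[float, float]]:
    """Per-symptom conditional probabilities implied by the published screen."""
    n_pos = FIXTURE_N_POSITIVE
    n_neg = FIXTURE_N - FIXTURE_N_POSITIVE
    return {
        sym: (c_pp / n_pos, c_pn / n_neg)
        for sym, (c_en, c_ep, c_pn, c_pp) in TABLE2_COUNTS.items()
    }


def study_spec(n: int = FIXTURE_N, seed: int = 0, **overrides) -> SyntheticSpec:
    """A SyntheticSpec emulating the study cohort: 16 symptoms, prevalence
    320/520 ≈ 0.615, conditionals from the published 2×2 tables."""
    kwargs = dict(
        n=n,
        prevalence=FIXTURE_N_POSITIVE / FIXTURE_N,
        cond_probs=study_conditionals(),
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


def generate_cohort(spec: SyntheticSpec) -> Cohort:
    """Draw a cohort from the conditional-independence model.

    Deterministic under ``spec.seed`` (NumPy PCG64 via
    ``default_rng``). Implications are applied after drawing, so they
    raise the outcome prevalence slightly above ``spec.prevalence``.
    """
    rng = np.random.default_rng(spec.seed)
    outcome = (rng.random(spec.n) < spec.prevalence).astype(np.int8)
    data: dict[str, np.ndarray] = {}
    for sym, (p_pos, p_neg) in spec.cond_probs.items():
        p = np.where(outcome == 1, p_pos, p_neg)
        data[sym] = (rng.random(spec.n) < p).astype(np.int8)
    for itemset in spec.implications:
        joint = np.ones(spec.n, dtype=bool)
        for sym in itemset:
            joint &= data[sym] == 1
        outcome = np.where(joint, np.int8(1), outcome)
    data[spec.outcome_column] = outcome
    return Cohort(pd.DataFrame(data), spec.outcome_column)


def table2_fixture() -> Cohort:
    """The deterministic 520-row cohort embedding every published 2×2 table.

    Rows 0–319 are outcome-positive, rows 320–519 outcome-negative; for
    each symptom exactly its published outcome-positive count of 1s
    occupies the first rows of the positive block and its published
    outcome-negative count the first rows of the negative block.
    """
    n_pos, n = FIXTURE_N_POSITIVE, FIXTURE_N
    data: dict[str, np.ndarray] = {}
    for sym, (c_en, c_ep, c_pn, c_pp) in TABLE2_COUNTS.items():
        col = np.zeros(n, dtype=np.int8)
        col[:c_pp] = 1
        col[n_pos : n_pos + c_pn] = 1
        data[sym] = col
    outcome = np.zeros(n, dtype=np.int8)
    outcome[:n_pos] = 1
    data[FIXTURE_OUTCOME] = outcome
    return Cohort(pd.DataFrame(data), FIXTURE_OUTCOME)


def plant_implication(cohort: Cohort, itemset) -> Cohort:
    """Force the outcome positive wherever all ``itemset`` columns are 1.

    ``itemset`` holds cohort column names. All other cells are
    unchanged; returns a new cohort.
    """
    items = tuple(itemset)
    for col in items:
        if col not in cohort.binary_columns:
            raise ConfigurationError(f"unknown or non-binary column {col!r}")
    frame = cohort.data.copy()
    joint = np.ones(len(frame), dtype=bool)
    for col in items:
        joint &= frame[col].to_numpy() == 1
    out = frame[cohort.outcome_column].to_numpy().copy()
    out[joint] = 1
    frame[cohort.outcome_column] = out.astype(np.int8)
    return Cohort(frame, cohort.outcome_column, cohort.numeric_columns)
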