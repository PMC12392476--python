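"""Cohort ingestion, encoding, dichotomization, and transaction conversion.

A *cohort* is a patient-by-variable table of binary indicators (symptom
present / absent) with one designated outcome column, optionally carrying
raw numeric columns (age in years) alongside their dichotomized versions.
String-token files in the UCI early-diabetes dialect (Yes/No, Male/Female,
Positive/Negative) are mapped to {0, 1} on read; unmapped tokens and
missing cells are hard errors, never imputed.

For association mining a cohort is flattened to a :class:`TransactionSet`:
each patient becomes the set of ``"<Variable>=1"`` tokens for their
present indicators. Only presence tokens are emitted by default because
outcome-targeted rules are built from present symptoms; absence tokens
are available behind ``include_absence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EncodingError, ValidationError

#: Built-in token dialect for UCI-style symptom files. Female maps to 1
#: (women are the outcome-enriched stratum and are coded as the positive
#: exposure group); Positive/Yes map to 1. Keys are matched
#: case-insensitively after stripping whitespace.
UCI_DIALECT: dict[str, int] = {
    "yes": 1,
    "no": 0,
    "positive": 1,
    "negative": 0,
    "female": 1,
    "male": 0,
    "true": 1,
    "false": 0,
}


@dataclass(frozen=True)
class Cohort:
    """Validated patient × variable table.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per patient. Columns listed in ``numeric_columns`` hold
        raw numeric values (e.g. age in years); every other column must
        be a binary 0/1 indicator.
    outcome_column : str
        Name of the binary class variable (e.g. ``"Diabetes"``).
    numeric_columns : tuple of str
        Columns exempt from the binary invariant, kept for
        dichotomization and group-mean comparisons.
    """

    data: pd.DataFrame
    outcome_column: str
    numeric_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.outcome_column not in self.data.columns:
            raise ConfigurationError(
                f"outcome column {self.outcome_column!r} not in cohort columns"
            )
        if self.outcome_column in self.numeric_columns:
            raise ConfigurationError("outcome column must be binary, not numeric")
        for col in self.binary_columns:
            vals = self.data[col]
            if vals.isna().any():
                row = int(vals.index[vals.isna()][0])
                raise ValidationError(f"missing cell at row {row}, column {col!r}")
            bad = ~vals.isin((0, 1))
            if bad.any():
                row = int(vals.index[bad][0])
                raise ValidationError(
                    f"non-binary value {vals[row]!r} at row {row}, column {col!r}"
                )
        for col in self.numeric_columns:
            if col not in self.data.columns:
                raise ConfigurationError(f"numeric column {col!r} not in cohort")
            if self.data[col].isna().any():
                raise ValidationError(f"missing cell in numeric column {col!r}")

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def binary_columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c not in self.numeric_columns)


@dataclass(frozen=True)
class TransactionSet:
    """Per-patient sets of present-item tokens.

    ``n`` equals the source cohort's row count; rows with no present
    indicators contribute empty sets but still count toward ``n``.
    """

    transactions: tuple[frozenset[str], ...]
    item_universe: frozenset[str] = field(default=frozenset())

    @property
    def n(self) -> int:
        return len(self.transactions)


def _build_dialect(overrides: dict[str, int] | None) -> dict[str, int]:
    mapping = dict(UCI_DIALECT)
    if overrides:
        for token, value in overrides.items():
            if value not in (0, 1):
                raise ConfigurationError(
                    f"dialect must map tokens to 0 or 1, got {token!r} -> {value!r}"
                )
            mapping[str(token).strip().lower()] = int(value)
    return mapping


def read_cohort(
    path: str | Path,
    dialect: dict[str, int] | None = None,
    outcome_column: str = "Diabetes",
) -> Cohort:
    """Read a CSV cohort file and encode it to canonical 0/1 form.

    Columns whose every token parses as a number are taken numerically:
    all-{0,1} columns become binary indicators, anything else (e.g. age
    in years) is kept as a raw numeric column for later dichotomization.
    All other columns are mapped token-by-token through the dialect
    (built-in UCI tokens plus ``dialect`` overrides); an unmapped token
    or an empty cell raises, naming the offending row and column.
    """
    path = Path(path)
    mapping = _build_dialect(dialect)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    if outcome_column not in raw.columns:
        raise ConfigurationError(
            f"outcome column {outcome_column!r} not found in {path.name}; "
            f"columns are {list(raw.columns)}"
        )
    data: dict[str, object] = {}
    numeric_columns: list[str] = []
    for col in raw.columns:
        tokens = raw[col].str.strip()
        empty = tokens.eq("")
        if empty.any():
            row = int(empty.idxmax())
            raise ValidationError(f"missing cell at row {row}, column {col!r}")
        as_num = pd.to_numeric(tokens, errors="coerce")
        if not as_num.isna().any():
            if as_num.isin((0, 1)).all():
                data[col] = as_num.astype(np.int8)
            else:
                numeric_columns.append(col)
                data[col] = as_num
            continue
        lowered = tokens.str.lower()
        unknown = ~lowered.isin(mapping)
        if unknown.any():
            row = int(unknown.idxmax())
            raise EncodingError(
                f"unknown token {tokens[row]!r} at row {row}, column {col!r}; "
                "extend the dialect to map it to 0 or 1"
            )
        data[col] = lowered.map(mapping).astype(np.int8)
    frame = pd.DataFrame(data, columns=list(raw.columns))
    return Cohort(frame, outcome_column, tuple(numeric_columns))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as canonical CSV (0/1 cells, header row, UTF-8)."""
    cohort.data.to_csv(path, index=False)


def dichotomize(
    cohort: Cohort, column: str, cutoff: float, new_name: str
) -> Cohort:
    """Append a binary column that is 1 where ``column`` > ``cutoff``.

    The boundary is strict, so coding "47 and older" as positive is
    expressed with any cutoff in [46.5, 47) — the half-integer midpoint
    convention of ROC cutpoints. The raw numeric column is retained.
    """
    if column not in cohort.numeric_columns:
        raise TypeError(f"column {column!r} is not numeric; cannot dichotomize")
    if new_name in cohort.data.columns:
        raise ConfigurationError(f"column {new_name!r} already exists")
    if not np.isfinite(cutoff):
        raise ConfigurationError("cutoff must be finite")
    frame = cohort.data.copy()
    frame[new_name] = (frame[column] > cutoff).astype(np.int8)
    return Cohort(frame, cohort.outcome_column, cohort.numeric_columns)


def to_transactions(cohort: Cohort, include_absence: bool = False) -> TransactionSet:
    """Flatten a cohort to per-patient item sets.

    Each row becomes ``{"<Var>=1" for each 1-valued binary column}``;
    with ``include_absence`` the complementary ``"<Var>=0"`` tokens are
    also emitted. Numeric columns are ignored (dichotomize them first).
    """
    cols = cohort.binary_columns
    matrix = cohort.data[list(cols)].to_numpy()
    transactions = []
    for row in matrix:
        items = {f"{c}=1" for c, v in zip(cols, row) if v == 1}
        if include_absence:
            items |= {f"{c}=0" for c, v in zip(cols, row) if v == 0}
        transactions.append(frozenset(items))
    universe = frozenset().union(*transactions) if transactions else frozenset()
    return TransactionSet(tuple(transactions), universe)
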