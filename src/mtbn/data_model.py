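"""Longitudinal multimorbidity cohorts: representation, state coding and tabulation.

The data substrate is a complete-case longitudinal cohort: one row per
patient, a categorical demographic profile, and a binary diagnosis flag for
each of ``C`` chronic conditions in each of ``T`` yearly slices of care.
Cohorts travel as wide CSV files with one ``<condition>_y<t>`` column per
(condition, year) pair, ``t`` 1-based.

Condition-pattern states are encoded as digit strings ("0" for no
comorbidity, "125" for conditions 1, 2 and 5 jointly present), the coding
used throughout the transition-table reports.
"""

from __future__ import annotations

import io
import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VA_CONDITIONS",
    "VA_DEMOGRAPHIC_SCHEMA",
    "LongitudinalCohort",
    "CohortValidationError",
    "load_cohort",
    "write_cohort",
    "encode_state",
    "decode_state",
    "default_digit_map",
    "all_state_codes",
    "state_frequency_table",
    "demographic_frequency_table",
    "percent",
]

#: The five chronic conditions studied in the veteran cohort, in canonical order.
VA_CONDITIONS: tuple[str, ...] = ("TBI", "PTSD", "BaPa", "SuAb", "Depr")

#: Demographic variables and their level sets for the veteran-like cohort.
VA_DEMOGRAPHIC_SCHEMA: dict[str, tuple[str, ...]] = {
    "race": ("White", "Black", "Hispanic", "Asian", "Native", "Unknown"),
    "gender": ("Male", "Female"),
    "marital": ("Married", "Unmarried"),
    "age_group": ("18-30", "31-40", "41-50", "51+"),
    "education": (
        "Unknown",
        "<HighSchool",
        "HighSchool",
        "SomeCollege",
        "CollegeGraduate",
        "PostCollege",
    ),
}

_COND_COL_RE = re.compile(r"^(?P<cond>.+)_y(?P<year>\d+)$")


class CohortValidationError(ValueError):
    """Raised when a cohort file or in-memory cohort violates its contract."""


def percent(count: float, total: float, ndigits: int | None = 2) -> float:
    """Share of ``total`` as a percentage, rounded half-to-even to ``ndigits``.

    ``ndigits=None`` returns the unrounded value.
    """
    value = 100.0 * count / total
    if ndigits is None:
        return value
    return float(np.round(value, ndigits))


@dataclass(frozen=True)
class LongitudinalCohort:
    """A complete-case longitudinal cohort.

    Parameters
    ----------
    patient_ids : sequence of str
        Unique opaque identifiers, one per patient.
    demographics : pandas.DataFrame
        One string-valued column per demographic variable, one row per
        patient (positionally aligned with ``patient_ids``).
    panel : numpy.ndarray, shape (n_patients, n_years, n_conditions)
        Binary diagnosis flags; ``panel[i, t, c] == 1`` iff patient ``i``
        was diagnosed with condition ``c`` in year ``t + 1``.
    condition_names : sequence of str
    demographic_schema : mapping of variable name -> tuple of levels
    """

    patient_ids: tuple[str, ...]
    demographics: pd.DataFrame
    panel: np.ndarray
    condition_names: tuple[str, ...]
    demographic_schema: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "patient_ids", tuple(str(p) for p in self.patient_ids))
        object.__setattr__(self, "condition_names", tuple(self.condition_names))
        object.__setattr__(
            self,
            "demographic_schema",
            {k: tuple(v) for k, v in self.demographic_schema.items()},
        )
        panel = np.asarray(self.panel, dtype=np.int8)
        object.__setattr__(self, "panel", panel)
        n = len(self.patient_ids)
        if len(set(self.patient_ids)) != n:
            raise CohortValidationError("patient ids are not unique")
        if panel.ndim != 3 or panel.shape[0] != n:
            raise CohortValidationError(
                f"panel shape {panel.shape} does not match {n} patients"
            )
        if panel.shape[2] != len(self.condition_names):
            raise CohortValidationError("panel width does not match condition names")
        if not np.isin(panel, (0, 1)).all():
            raise CohortValidationError("panel entries must be 0/1")
        if list(self.demographics.columns) != list(self.demographic_schema):
            raise CohortValidationError(
                "demographic columns do not match the schema variables"
            )
        if len(self.demographics) != n:
            raise CohortValidationError("demographics row count does not match patients")
        for var, levels in self.demographic_schema.items():
            observed = set(self.demographics[var].astype(str))
            unknown = observed - set(levels)
            if unknown:
                raise CohortValidationError(
                    f"demographic variable {var!r} has undeclared levels {sorted(unknown)}"
                )

    # -- basic shape -----------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_years(self) -> int:
        return int(self.panel.shape[1])

    @property
    def n_conditions(self) -> int:
        return len(self.condition_names)

    @property
    def demographic_vars(self) -> tuple[str, ...]:
        return tuple(self.demographic_schema)

    def demographic_codes(self) -> np.ndarray:
        """Integer-coded demographics, shape (n_patients, n_variables).

        Codes index into the schema's level tuple for each variable.
        """
        if not self.demographic_schema:
            return np.zeros((self.n_patients, 0), dtype=np.int64)
        cols = []
        for var, levels in self.demographic_schema.items():
            index = {lev: i for i, lev in enumerate(levels)}
            cols.append(self.demographics[var].astype(str).map(index).to_numpy())
        return np.stack(cols, axis=1).astype(np.int64)

    def condition_values(self, year_index: int, condition: str) -> np.ndarray:
        """Binary column for one (condition, 0-based year) pair."""
        c = self.condition_names.index(condition)
        return self.panel[:, year_index, c].astype(np.int64)

    def subset(self, indices: Sequence[int]) -> "LongitudinalCohort":
        """Row-subset of the cohort (used for cross-validation folds)."""
        idx = np.asarray(indices, dtype=np.int64)
        return LongitudinalCohort(
            patient_ids=tuple(self.patient_ids[i] for i in idx),
            demographics=self.demographics.iloc[idx].reset_index(drop=True),
            panel=self.panel[idx],
            condition_names=self.condition_names,
            demographic_schema=self.demographic_schema,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LongitudinalCohort):
            return NotImplemented
        return (
            self.patient_ids == other.patient_ids
            and self.condition_names == other.condition_names
            and self.demographic_schema == other.demographic_schema
            and np.array_equal(self.panel, other.panel)
            and self.demographics.astype(str).equals(other.demographics.astype(str))
        )


# -- file IO -------------------------------------------------------------

def load_cohort(
    source,
    condition_names: Sequence[str] | None = None,
    demographic_schema: Mapping[str, Sequence[str]] | None = None,
    id_column: str = "patient_id",
) -> LongitudinalCohort:
    """Read a wide-CSV cohort.

    Condition columns follow the ``<condition>_y<t>`` pattern (t 1-based);
    every remaining non-id column is a demographic variable. Column order in
    the file does not affect the result. When ``demographic_schema`` is not
    given, level sets are inferred from the data (sorted lexicographically).
    """
    frame = pd.read_csv(source, dtype=str)
    if id_column not in frame.columns:
        raise CohortValidationError(f"missing id column {id_column!r}")

    cond_cols: dict[tuple[str, int], str] = {}
    demo_cols: list[str] = []
    for col in frame.columns:
        if col == id_column:
            continue
        m = _COND_COL_RE.match(col)
        if m:
            cond_cols[(m.group("cond"), int(m.group("year")))] = col
        else:
            demo_cols.append(col)
    if not cond_cols:
        raise CohortValidationError("no <condition>_y<t> columns found")

    # canonical (sorted) condition order unless the caller pins one, so the
    # result is invariant to column order in the file
    conds_in_file = sorted({c for c, _ in cond_cols})
    if condition_names is None:
        condition_names = conds_in_file
    elif sorted(condition_names) != conds_in_file:
        raise CohortValidationError(
            f"file conditions {conds_in_file} do not match requested {sorted(condition_names)}"
        )
    years = sorted({t for _, t in cond_cols})
    n_years = max(years)
    expected = {(c, t) for c in condition_names for t in range(1, n_years + 1)}
    missing = expected - set(cond_cols)
    if missing:
        raise CohortValidationError(f"missing condition columns for {sorted(missing)}")

    patient_ids = frame[id_column].tolist()
    n = len(patient_ids)
    panel = np.zeros((n, n_years, len(condition_names)), dtype=np.int8)
    for c, cond in enumerate(condition_names):
        for t in range(1, n_years + 1):
            col = cond_cols[(cond, t)]
            raw = frame[col]
            bad = raw.isna() | ~raw.isin(("0", "1"))
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortValidationError(
                    f"non-binary or missing flag in column {col!r} for patient "
                    f"{patient_ids[i]!r}: {raw.iloc[i]!r}"
                )
            panel[:, t - 1, c] = raw.astype(np.int8)

    demographics = frame[demo_cols].astype(str)
    if demographic_schema is None:
        schema = {v: tuple(sorted(demographics[v].unique())) for v in demo_cols}
    else:
        schema = {v: tuple(levels) for v, levels in demographic_schema.items()}
        if sorted(schema) != sorted(demo_cols):
            raise CohortValidationError(
                f"schema variables {sorted(schema)} do not match file columns {sorted(demo_cols)}"
            )
        demographics = demographics[list(schema)]
    return LongitudinalCohort(
        patient_ids=tuple(patient_ids),
        demographics=demographics[list(schema)].reset_index(drop=True),
        panel=panel,
        condition_names=tuple(condition_names),
        demographic_schema=schema,
    )


def write_cohort(cohort: LongitudinalCohort, dest) -> None:
    """Write the wide-CSV representation that :func:`load_cohort` reads."""
    data: dict[str, Sequence] = {"patient_id": list(cohort.patient_ids)}
    for var in cohort.demographic_vars:
        data[var] = cohort.demographics[var].tolist()
    for c, cond in enumerate(cohort.condition_names):
        for t in range(cohort.n_years):
            data[f"{cond}_y{t + 1}"] = cohort.panel[:, t, c]
    pd.DataFrame(data).to_csv(dest, index=False)


# -- state coding --------------------------------------------------------

def default_digit_map(condition_names: Sequence[str]) -> dict[str, str]:
    """Condition -> single ascending digit ("1".."9"), in the given order."""
    if len(condition_names) > 9:
        raise ValueError("digit coding supports at most 9 conditions")
    return {name: str(i + 1) for i, name in enumerate(condition_names)}


def encode_state(
    flags: Sequence[int], digit_map: Mapping[str, str], condition_names: Sequence[str]
) -> str:
    """Digit-string code for one year's condition pattern.

    Active conditions contribute their digit, concatenated in ascending
    digit order; the all-absent pattern encodes as ``"0"``.
    """
    flags = np.asarray(flags)
    if flags.shape != (len(condition_names),):
        raise ValueError(
            f"flag vector length {flags.shape} does not match {len(condition_names)} conditions"
        )
    if len(set(digit_map.values())) != len(digit_map):
        raise ValueError("digit_map must be injective")
    digits = sorted(digit_map[name] for name, f in zip(condition_names, flags) if f)
    return "".join(digits) if digits else "0"


def decode_state(
    code: str, digit_map: Mapping[str, str], condition_names: Sequence[str]
) -> np.ndarray:
    """Inverse of :func:`encode_state`."""
    reverse = {d: name for name, d in digit_map.items()}
    flags = np.zeros(len(condition_names), dtype=np.int8)
    if code == "0":
        return flags
    for d in code:
        flags[condition_names.index(reverse[d])] = 1
    return flags


def all_state_codes(condition_names: Sequence[str]) -> list[str]:
    """All 2^C state codes, ordered by number of active conditions then value.

    Matches the reporting order 0, 1, 2, ..., 12, 13, ..., 12345.
    """
    digit_map = default_digit_map(condition_names)
    codes = []
    for pattern in itertools.product((0, 1), repeat=len(condition_names)):
        codes.append(encode_state(pattern, digit_map, condition_names))
    return sorted(codes, key=lambda s: (0, 0) if s == "0" else (len(s), int(s)))


# -- frequency tabulation ------------------------------------------------

def state_frequency_table(cohort: LongitudinalCohort) -> pd.DataFrame:
    """Per-year counts and percentages of every condition pattern.

    Rows are indexed by the binary pattern tuple over conditions; columns are
    a (year, {count, percent}) MultiIndex. Per-year counts sum to the number
    of patients. Percentages use the cohort size as denominator and are
    rounded half-to-even to two decimals.
    """
    C = cohort.n_conditions
    patterns = list(itertools.product((0, 1), repeat=C))
    pattern_index = pd.MultiIndex.from_tuples(patterns, names=cohort.condition_names)
    weights = 1 << np.arange(C - 1, -1, -1)
    columns = {}
    for t in range(cohort.n_years):
        ids = cohort.panel[:, t, :].astype(np.int64) @ weights
        counts = np.bincount(ids, minlength=2**C)
        columns[(f"year_{t + 1}", "count")] = counts
        columns[(f"year_{t + 1}", "percent")] = [
            percent(c, cohort.n_patients) for c in counts
        ]
    table = pd.DataFrame(columns, index=pattern_index)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["year", "measure"])
    return table


def demographic_frequency_table(
    cohort: LongitudinalCohort, variables: Sequence[str] | None = None
) -> pd.DataFrame:
    """Cross-classified counts and cohort percentages of demographic levels.

    ``variables`` defaults to all demographic variables. Counts over the full
    cross-classification sum to the number of patients.
    """
    if variables is None:
        variables = cohort.demographic_vars
    for v in variables:
        if v not in cohort.demographic_schema:
            raise KeyError(f"unknown demographic variable {v!r}")
    levels = [cohort.demographic_schema[v] for v in variables]
    grouped = cohort.demographics.groupby(list(variables), observed=False).size()
    if len(variables) == 1:
        index = pd.Index(levels[0], name=variables[0])
    else:
        index = pd.MultiIndex.from_product(levels, names=list(variables))
    counts = grouped.reindex(index, fill_value=0)
    return pd.DataFrame(
        {
            "count": counts.astype(int),
            "percent": [percent(c, cohort.n_patients) for c in counts],
        },
        index=index,
    )
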