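"""Domain types and validation shared by every stage of the JEM pipeline.

A job exposure matrix (JEM) assigns exposure metrics to occupation codes so
that a worker's exposure can be estimated from their job title alone.  Here
the hazard is second-hand tobacco smoke (SHS) and the exposure metrics are
three ordinal ratings per 4-digit occupation code:

* **likelihood** (0/1) — whether at least 10% of jobholders are exposed at
  work;
* **frequency** (0–4) — from "never" up to "daily and more than 1 h of
  exposure per day";
* **intensity** (0–3) — from "none" up to "indoors in a poorly ventilated
  space".

The scheme is *conditional*: frequency and intensity are rated only when
likelihood is 1.  A rater who assigns likelihood 0 records nothing else for
that code, so missing ratings are a first-class concept, distinct from the
substantive level 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("jemforge")

# ---------------------------------------------------------------------------
# Rating scheme
# ---------------------------------------------------------------------------

AXES = ("likelihood", "frequency", "intensity")

_DEFAULT_LABELS: dict[str, dict[int, str]] = {
    "likelihood": {
        0: "<10% of jobholders exposed at work",
        1: "10% or more of jobholders exposed at work",
    },
    "frequency": {
        0: "Never",
        1: "Less than once per week",
        2: "At least once per week but less than daily",
        3: "Daily",
        4: "Daily and more than 1 h of exposure per day",
    },
    "intensity": {
        0: "None",
        1: "Outdoor or passing exposure",
        2: "Indoors in a well-ventilated space",
        3: "Indoors in a poorly ventilated space",
    },
}


class SchemeError(ValueError):
    """A rating scheme violates its structural invariants."""


@dataclass(frozen=True)
class RatingScheme:
    """The three ordinal axes of the SHS exposure rating scheme.

    Levels are small integers ordered worst-last.  ``level_labels`` maps each
    axis to a ``{level: human-readable label}`` dict; labels must be
    non-empty and unique within an axis.
    """

    likelihood_levels: tuple[int, ...] = (0, 1)
    frequency_levels: tuple[int, ...] = (0, 1, 2, 3, 4)
    intensity_levels: tuple[int, ...] = (0, 1, 2, 3)
    level_labels: Mapping[str, Mapping[int, str]] = field(
        default_factory=lambda: _DEFAULT_LABELS
    )

    def __post_init__(self) -> None:
        if len(self.likelihood_levels) != 2:
            raise SchemeError("likelihood axis must have exactly 2 levels")
        if len(self.frequency_levels) != 5:
            raise SchemeError("frequency axis must have exactly 5 levels")
        if len(self.intensity_levels) != 4:
            raise SchemeError("intensity axis must have exactly 4 levels")
        for axis in AXES:
            labels = self.level_labels.get(axis, {})
            expected = set(self.levels(axis))
            if set(labels) != expected:
                raise SchemeError(f"labels for axis {axis!r} must cover levels {sorted(expected)}")
            values = list(labels.values())
            if any(not v for v in values):
                raise SchemeError(f"axis {axis!r} has an empty label")
            if len(set(values)) != len(values):
                raise SchemeError(f"axis {axis!r} has duplicate labels")

    def levels(self, axis: str) -> tuple[int, ...]:
        """Ordered level set for ``axis``."""
        try:
            return getattr(self, f"{axis}_levels")
        except AttributeError:
            raise KeyError(f"unknown axis {axis!r}") from None

    def rated_levels(self, axis: str) -> tuple[int, ...]:
        """Levels legal for an axis that was actually rated.

        For the conditional axes (frequency, intensity) a rating is only
        collected when likelihood is 1, in which case level 0 ("never"/
        "none") is not an option.
        """
        lv = self.levels(axis)
        return lv if axis == "likelihood" else lv[1:]

    def max_severity(self) -> int:
        """Largest attainable compound severity under the conditional scheme."""
        return (
            max(self.likelihood_levels)
            * max(self.frequency_levels)
            * max(self.intensity_levels)
        )


DEFAULT_SCHEME = RatingScheme()

#: Severity values attainable under the default scheme (products of legal triples).
ATTAINABLE_SEVERITIES = frozenset({0, 1, 2, 3, 4, 6, 8, 9, 12})


# ---------------------------------------------------------------------------
# Occupation codes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OccupationCode:
    """One 4-digit occupation classification code.

    Codes are identifiers, not numbers: they are stored as strings to
    preserve leading zeros and dialect variants.  The 2-digit parent group
    is always the first two characters of the 4-digit code.
    """

    code4: str
    title: str = ""
    scheme_version: str = "SOC2020"

    def __post_init__(self) -> None:
        if len(self.code4) != 4 or not self.code4.isdigit():
            raise ValueError(f"code4 must be a 4-digit string, got {self.code4!r}")

    @property
    def code2(self) -> str:
        return self.code4[:2]


def code2_of(code4: str | pd.Series) -> str | pd.Series:
    """2-digit parent group of a 4-digit code (vectorised for Series)."""
    if isinstance(code4, pd.Series):
        return code4.str[:2]
    return code4[:2]


# ---------------------------------------------------------------------------
# Rating tables (long format: one row per rater x code x round)
# ---------------------------------------------------------------------------

RATING_COLUMNS = ("rater_id", "code4", "round", "likelihood", "frequency", "intensity")
JEM_COLUMNS = ("code4", "title", "likelihood", "frequency", "intensity")


class DuplicateKeyError(ValueError):
    """A table contains duplicate rows for a key that must be unique."""


def _apply_column_map(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return df


def read_ratings(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a per-rater ratings CSV.

    Expected columns: rater_id, code4, round, likelihood, frequency,
    intensity.  Empty cells are missing ratings.  ``column_map`` maps
    canonical names to the file's actual column names for dialect handling.
    """
    df = pd.read_csv(path, dtype={"code4": str}, keep_default_na=False, na_values=[""])
    df = _apply_column_map(df, column_map)
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ratings file {path} lacks columns {missing}")
    df = df.loc[:, list(RATING_COLUMNS)].copy()
    df["code4"] = df["code4"].astype(str)
    df["round"] = df["round"].astype(int)
    for axis in AXES:
        df[axis] = pd.to_numeric(df[axis], errors="raise").astype("Int64")
    return df


def write_ratings(df: pd.DataFrame, path) -> None:
    """Write a ratings table as CSV (UTF-8, header, empty cell = missing)."""
    df.loc[:, list(RATING_COLUMNS)].to_csv(path, index=False)


def read_jem(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a consensus JEM CSV (columns code4, title, likelihood, frequency,
    intensity; extra columns such as severity/provenance are preserved).

    ``column_map`` maps canonical column names to the file's names, so
    deposited tables with dialect headers can be ingested unchanged.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    df = _apply_column_map(df, column_map)
    missing = [c for c in JEM_COLUMNS if c not in df.columns and c != "title"]
    if missing:
        raise ValueError(f"JEM file {path} lacks columns {missing}")
    if "title" not in df.columns:
        df["title"] = ""
    df["code4"] = df["code4"].astype(str)
    for col in (*AXES, "severity"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise").astype("Int64")
    dup = df["code4"][df["code4"].duplicated()]
    if not dup.empty:
        raise DuplicateKeyError(f"duplicate code4 in JEM: {sorted(dup.unique())}")
    return df


def write_jem(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    """One invariant violation, tied to an identifiable input row."""

    rater_id: str
    code4: str
    round: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"(rater={self.rater_id}, code={self.code4}, round={self.round}): {self.message}"


def validate_rating_table(
    table: pd.DataFrame, scheme: RatingScheme = DEFAULT_SCHEME
) -> list[Violation]:
    """Check every row of a ratings table against the scheme's invariants.

    Returns the full list of violations (empty iff the table is valid):

    * levels outside the scheme's level sets;
    * conditional-rating breaches — likelihood 0 (or missing) with a
      frequency/intensity present, or likelihood 1 with either conditional
      axis missing or rated 0.

    Duplicate (rater_id, code4, round) rows are a hard error: the table is
    structurally unusable, not merely invalid.
    """
    if table.empty:
        raise ValueError("ratings table is empty")
    key = ["rater_id", "code4", "round"]
    dup_mask = table.duplicated(subset=key, keep=False)
    if dup_mask.any():
        dups = table.loc[dup_mask, key].drop_duplicates().itertuples(index=False)
        raise DuplicateKeyError(
            "duplicate (rater_id, code4, round) rows: "
            + ", ".join(f"({r.rater_id}, {r.code4}, {r.round})" for r in dups)
        )

    violations: list[Violation] = []

    def flag(row, message: str) -> None:
        violations.append(
            Violation(str(row.rater_id), str(row.code4), int(row.round), message)
        )

    for row in table.itertuples(index=False):
        levels = {axis: getattr(row, axis) for axis in AXES}
        for axis, value in levels.items():
            if pd.notna(value) and int(value) not in scheme.levels(axis):
                flag(row, f"level outside scheme: {axis}={int(value)}")
        lk = levels["likelihood"]
        fr, it = levels["frequency"], levels["intensity"]
        if pd.isna(lk) or (pd.notna(lk) and int(lk) == 0):
            if pd.notna(fr) or pd.notna(it):
                flag(row, "conditional rating breached: frequency/intensity present without likelihood=1")
        elif int(lk) == 1:
            for axis, value in (("frequency", fr), ("intensity", it)):
                if pd.isna(value):
                    flag(row, f"conditional rating breached: likelihood=1 but {axis} missing")
                elif int(value) == 0:
                    flag(row, f"conditional rating breached: likelihood=1 but {axis}=0")
    return violations


def validate_jem_table(jem: pd.DataFrame, scheme: RatingScheme = DEFAULT_SCHEME) -> list[str]:
    """Check a consensus JEM table against the JEM record invariants.

    Every code must carry a full (likelihood, frequency, intensity) triple;
    likelihood 0 forces frequency = intensity = 0; if a severity column is
    present it must equal the product and lie in the attainable set.
    """
    problems: list[str] = []
    for row in jem.itertuples(index=False):
        code = row.code4
        triple = tuple(getattr(row, axis) for axis in AXES)
        if any(pd.isna(v) for v in triple):
            problems.append(f"{code}: incomplete rating triple {triple}")
            continue
        lk, fr, it = (int(v) for v in triple)
        for axis, value in zip(AXES, (lk, fr, it)):
            if value not in scheme.levels(axis):
                problems.append(f"{code}: level outside scheme: {axis}={value}")
        if lk == 0 and (fr != 0 or it != 0):
            problems.append(f"{code}: likelihood=0 but frequency/intensity nonzero")
        if lk == 1 and (fr == 0 or it == 0):
            problems.append(f"{code}: likelihood=1 but frequency/intensity zero")
        if hasattr(row, "severity") and pd.notna(row.severity):
            sev = int(row.severity)
            if sev != lk * fr * it:
                problems.append(f"{code}: severity {sev} != product {lk * fr * it}")
    return problems
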