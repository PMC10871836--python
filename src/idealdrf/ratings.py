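"""Long-format rating tables for multi-observer classification studies.

A rating study records one categorical label per (subject, observer,
session, system).  Four classification systems are built in, modelled as
label alphabets only:

* ``IDEAL`` — fracture types I-III,
* ``Frykman`` — categories I-VIII,
* ``Fernandez`` — categories 1-5,
* ``AO`` — the nine main subgroups A1-C3 (a 27-label full-subgroup
  alphabet is available as :data:`AO_FULL_SUBGROUP_LABELS`).

Custom alphabets can be supplied to :class:`RatingTable` to override or
extend these.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SYSTEM_LABELS",
    "AO_FULL_SUBGROUP_LABELS",
    "RATING_COLUMNS",
    "ValidationIssue",
    "RatingValidationError",
    "RatingTable",
    "validate_rating_frame",
]

SYSTEM_LABELS: dict[str, tuple[str, ...]] = {
    "IDEAL": ("I", "II", "III"),
    "Frykman": ("I", "II", "III", "IV", "V", "VI", "VII", "VIII"),
    "Fernandez": ("1", "2", "3", "4", "5"),
    "AO": ("A1", "A2", "A3", "B1", "B2", "B3", "C1", "C2", "C3"),
}

#: Alternative AO alphabet at full-subgroup resolution (A1.1 ... C3.3).
AO_FULL_SUBGROUP_LABELS: tuple[str, ...] = tuple(
    f"{group}.{sub}" for group in SYSTEM_LABELS["AO"] for sub in (1, 2, 3)
)

RATING_COLUMNS = ("subject_id", "observer_id", "session", "system", "label")


@dataclass(frozen=True)
class ValidationIssue:
    """One problem found while validating a rating table.

    ``row`` is the 0-based data-row index in the source table (header
    excluded), when the issue is attributable to a single row.
    """

    severity: str  # "error" or "warning"
    message: str
    row: int | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f" (row {self.row})" if self.row is not None else ""
        return f"{self.severity}{loc}: {self.message}"


class RatingValidationError(ValueError):
    """Raised when a rating table contains hard errors."""

    def __init__(self, issues: Sequence[ValidationIssue]):
        self.issues = list(issues)
        errors = [str(i) for i in self.issues if i.severity == "error"]
        super().__init__("invalid rating table:\n" + "\n".join(errors))


def validate_rating_frame(
    df: pd.DataFrame, alphabets: Mapping[str, Sequence[str]] | None = None
) -> list[ValidationIssue]:
    """Validate a long-format rating frame; returns a list of issues.

    Errors: missing columns, unknown system, label outside the system's
    alphabet, duplicate (subject, observer, session, system) keys, missing
    values.  Warnings: incomplete subject/observer/session grids per system.
    """
    alphabets = dict(SYSTEM_LABELS if alphabets is None else alphabets)
    issues: list[ValidationIssue] = []

    missing_cols = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing_cols:
        issues.append(
            ValidationIssue("error", f"missing required columns: {missing_cols}")
        )
        return issues

    df = df.reset_index(drop=True)
    for col in RATING_COLUMNS:
        null_rows = df.index[df[col].isna()]
        for row in null_rows:
            issues.append(ValidationIssue("error", f"missing value in column {col!r}", int(row)))
    if any(i.severity == "error" for i in issues):
        return issues

    for row, system in df["system"].items():
        if system not in alphabets:
            issues.append(
                ValidationIssue(
                    "error",
                    f"unknown system {system!r}; known: {sorted(alphabets)}",
                    int(row),
                )
            )
    for row, (system, label) in df[["system", "label"]].iterrows():
        if system in alphabets and str(label) not in alphabets[system]:
            issues.append(
                ValidationIssue(
                    "error",
                    f"label {label!r} is not in the {system} alphabet {list(alphabets[system])}",
                    int(row),
                )
            )

    dup_mask = df.duplicated(subset=list(RATING_COLUMNS[:4]), keep="first")
    for row in df.index[dup_mask]:
        key = tuple(df.loc[row, list(RATING_COLUMNS[:4])])
        issues.append(
            ValidationIssue("error", f"duplicate rating for (subject, observer, session, system) = {key}", int(row))
        )

    # Completeness inventory: one warning per system with missing combinations.
    if not any(i.severity == "error" for i in issues):
        subjects = df["subject_id"].unique()
        observers = df["observer_id"].unique()
        sessions = df["session"].unique()
        for system, group in df.groupby("system", sort=False):
            expected = len(subjects) * len(observers) * len(sessions)
            if len(group) < expected:
                issues.append(
                    ValidationIssue(
                        "warning",
                        f"system {system}: {expected - len(group)} of {expected} "
                        "(subject, observer, session) combinations have no rating",
                    )
                )
    return issues


class RatingTable:
    """Validated collection of categorical ratings in long format.

    Wraps a :class:`pandas.DataFrame` with columns
    ``subject_id, observer_id, session, system, label`` (all strings) and
    guarantees uniqueness of the (subject, observer, session, system) key
    and membership of every label in its system's alphabet.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        alphabets: Mapping[str, Sequence[str]] | None = None,
        validate: bool = True,
    ):
        self.alphabets: dict[str, tuple[str, ...]] = {
            k: tuple(v) for k, v in (SYSTEM_LABELS if alphabets is None else alphabets).items()
        }
        df = df.loc[:, list(RATING_COLUMNS)].astype(str).reset_index(drop=True)
        if validate:
            issues = validate_rating_frame(df, self.alphabets)
            errors = [i for i in issues if i.severity == "error"]
            if errors:
                raise RatingValidationError(errors)
        self.df = df

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, str, str, str]],
        alphabets: Mapping[str, Sequence[str]] | None = None,
    ) -> "RatingTable":
        df = pd.DataFrame(list(records), columns=list(RATING_COLUMNS))
        return cls(df, alphabets=alphabets)

    @classmethod
    def from_csv(
        cls, path: str | Path, alphabets: Mapping[str, Sequence[str]] | None = None
    ) -> "RatingTable":
        return cls(pd.read_csv(path, dtype=str), alphabets=alphabets)

    # -- basic protocol -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"RatingTable({len(self)} ratings, {len(self.subjects)} subjects, "
            f"{len(self.observers)} observers, {len(self.sessions)} sessions, "
            f"systems={list(self.systems)})"
        )

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    # -- accessors ----------------------------------------------------------

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(sorted(self.df["subject_id"].unique()))

    @property
    def observers(self) -> tuple[str, ...]:
        return tuple(sorted(self.df["observer_id"].unique()))

    @property
    def sessions(self) -> tuple[str, ...]:
        return tuple(sorted(self.df["session"].unique()))

    @property
    def systems(self) -> tuple[str, ...]:
        present = self.df["system"].unique()
        return tuple(s for s in self.alphabets if s in present)

    def labels_for(self, system: str) -> tuple[str, ...]:
        try:
            return self.alphabets[system]
        except KeyError:
            raise KeyError(f"unknown system {system!r}") from None

    def subset(
        self,
        system: str | None = None,
        session: str | None = None,
        observer: str | None = None,
    ) -> pd.DataFrame:
        """Filtered view of the underlying frame."""
        df = self.df
        if system is not None:
            df = df[df["system"] == system]
        if session is not None:
            df = df[df["session"] == session]
        if observer is not None:
            df = df[df["observer_id"] == observer]
        return df

    def pivot(
        self,
        system: str,
        columns: str,
        session: str | None = None,
        observer: str | None = None,
    ) -> pd.DataFrame:
        """Subjects x raters label matrix (``columns`` in {"session",
        "observer_id"}); cells hold labels, NaN where no rating exists."""
        df = self.subset(system=system, session=session, observer=observer)
        return df.pivot(index="subject_id", columns=columns, values="label")
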