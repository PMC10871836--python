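"""Scoring engine for the IDEAL distal radius fracture classification.

IDEAL is a five-item mnemonic score for fractures of the distal extremity
of the radius: joint **I**ncongruity, **D**isplacement, trauma **E**nergy,
patient **A**ge and **A**ssociated **L**esions.  Each item contributes 0 or
1 point from simple radiographic/epidemiological criteria, and the total
(0-5) maps onto three fracture types carrying treatment and prognosis
guidance:

=====  ======  ====================  ==============================  ============
Type   Score   Description           Treatment                       Prognosis
=====  ======  ====================  ==============================  ============
I      0-1     Stable                Conservative                    Good
II     2-3     Potentially unstable  Pins/external fixation/plating  Intermediate
III    4-5     Complex               Associated methods/bone graft   Poor
=====  ======  ====================  ==============================  ============

Scoring criteria
----------------
* Incongruity: articular step or gap of at least 2 mm scores 1.
* Displacement: radial shortening > 3 mm, loss of volar tilt > 10 degrees
  or loss of radial inclination > 5 degrees scores 1; alternatively an
  explicit "requires reduction" judgement can override the thresholds.
* Energy: high-energy trauma (anything other than a fall from standing
  height) scores 1.
* Age: 60 years or older scores 1.
* Lesions: any associated lesion (radiocarpal dislocation/subluxation,
  carpal fracture, carpal or distal radioulnar instability, neurovascular
  injury, open fracture, distal ulnar fracture) scores 1.

The published criteria are internally inconsistent at two boundaries (the
2 mm step and age 60 appear with both strict and inclusive comparisons in
different places); this implementation fixes both boundaries as inclusive
(>= 2.0 mm scores 1, age >= 60 scores 1) and treats the three displacement
thresholds as strict.  See ``docs/methods.md`` for the rationale.

Units are fixed: millimetres for lengths, degrees for angles, years for
age.  No unit auto-detection is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import product
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "STEP_THRESHOLD_MM",
    "SHORTENING_THRESHOLD_MM",
    "VOLAR_TILT_THRESHOLD_DEG",
    "RADIAL_INCLINATION_THRESHOLD_DEG",
    "AGE_THRESHOLD_YEARS",
    "Energy",
    "FractureType",
    "RadiographicFindings",
    "CaseContext",
    "IdealResult",
    "score_incongruity",
    "score_displacement",
    "score_context",
    "type_for_total",
    "classify",
    "enumerate_score_space",
    "CASE_TABLE_COLUMNS",
    "load_case_table",
    "score_case_table",
    "score_cases_csv",
]

# Decision thresholds (mm / degrees / years).  The step and age cut-offs are
# inclusive; the three displacement cut-offs are strict.
STEP_THRESHOLD_MM = 2.0
SHORTENING_THRESHOLD_MM = 3.0
VOLAR_TILT_THRESHOLD_DEG = 10.0
RADIAL_INCLINATION_THRESHOLD_DEG = 5.0
AGE_THRESHOLD_YEARS = 60


class Energy(str, Enum):
    """Trauma energy. ``low`` = fall from standing height; ``high`` = other."""

    LOW = "low"
    HIGH = "high"


class FractureType(str, Enum):
    """IDEAL fracture type, ordered by severity (I < II < III)."""

    I = "I"
    II = "II"
    III = "III"

    @property
    def severity(self) -> int:
        return ("I", "II", "III").index(self.value)


_TYPE_GUIDANCE: dict[FractureType, tuple[str, str, str]] = {
    FractureType.I: ("Stable", "Conservative", "Good"),
    FractureType.II: (
        "Potentially unstable",
        "Pins/external fixation/plating",
        "Intermediate",
    ),
    FractureType.III: ("Complex", "Associated methods/bone graft", "Poor"),
}


def _checked_nonnegative(name: str, value: float) -> float:
    try:
        value = float(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{name} must be a number, got {value!r}") from exc
    if not math.isfinite(value) or value < 0.0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class RadiographicFindings:
    """Continuous radiographic measurements for one fracture.

    All four measurements are losses relative to normal anatomy and must be
    non-negative and finite: lengths in millimetres, angles in degrees.

    ``requires_reduction_override`` short-circuits the threshold-based
    displacement rule when a reviewer has already judged whether the
    fracture requires reduction; ``None`` (default) derives displacement
    from the thresholds.
    """

    articular_step_mm: float
    radial_shortening_mm: float = 0.0
    volar_tilt_loss_deg: float = 0.0
    radial_inclination_loss_deg: float = 0.0
    requires_reduction_override: bool | None = None

    def __post_init__(self) -> None:
        for field_name in (
            "articular_step_mm",
            "radial_shortening_mm",
            "volar_tilt_loss_deg",
            "radial_inclination_loss_deg",
        ):
            object.__setattr__(
                self, field_name, _checked_nonnegative(field_name, getattr(self, field_name))
            )
        if self.requires_reduction_override is not None:
            object.__setattr__(
                self, "requires_reduction_override", bool(self.requires_reduction_override)
            )


@dataclass(frozen=True)
class CaseContext:
    """Epidemiological context of one fracture case."""

    age_years: int
    energy: Energy = Energy.LOW
    lesions_present: bool = False

    def __post_init__(self) -> None:
        age = self.age_years
        if isinstance(age, float):
            if not age.is_integer():
                raise ValueError(f"age_years must be a whole number, got {age!r}")
            age = int(age)
        if not isinstance(age, int) or isinstance(age, bool):
            raise ValueError(f"age_years must be an integer, got {age!r}")
        if age < 0:
            raise ValueError(f"age_years must be >= 0, got {age}")
        object.__setattr__(self, "age_years", age)
        object.__setattr__(self, "energy", Energy(self.energy))
        object.__setattr__(self, "lesions_present", bool(self.lesions_present))


@dataclass(frozen=True)
class IdealResult:
    """The five component scores, the total and the resulting fracture type."""

    score_i: int
    score_d: int
    score_e: int
    score_a: int
    score_l: int
    total: int
    fracture_type: FractureType
    description: str
    treatment: str
    prognosis: str

    @property
    def components(self) -> tuple[int, int, int, int, int]:
        return (self.score_i, self.score_d, self.score_e, self.score_a, self.score_l)


def score_incongruity(findings: RadiographicFindings) -> int:
    """Score the joint-incongruity item: 1 iff step/gap >= 2.0 mm."""
    return int(findings.articular_step_mm >= STEP_THRESHOLD_MM)


def score_displacement(findings: RadiographicFindings) -> int:
    """Score the displacement item.

    If ``requires_reduction_override`` is set it wins outright; otherwise the
    item scores 1 iff shortening > 3 mm, volar tilt loss > 10 degrees or
    radial inclination loss > 5 degrees (all strict).
    """
    if findings.requires_reduction_override is not None:
        return int(findings.requires_reduction_override)
    return int(
        findings.radial_shortening_mm > SHORTENING_THRESHOLD_MM
        or findings.volar_tilt_loss_deg > VOLAR_TILT_THRESHOLD_DEG
        or findings.radial_inclination_loss_deg > RADIAL_INCLINATION_THRESHOLD_DEG
    )


def score_context(context: CaseContext) -> tuple[int, int, int]:
    """Score the (Energy, Age, Lesions) items as a tuple of 0/1 values."""
    e = int(context.energy is Energy.HIGH)
    a = int(context.age_years >= AGE_THRESHOLD_YEARS)
    l = int(context.lesions_present)
    return (e, a, l)


def type_for_total(total: int) -> FractureType:
    """Map a total score in [0, 5] onto the fracture type band."""
    if not isinstance(total, int) or isinstance(total, bool) or not 0 <= total <= 5:
        raise ValueError(f"total must be an integer in [0, 5], got {total!r}")
    if total <= 1:
        return FractureType.I
    if total <= 3:
        return FractureType.II
    return FractureType.III


def classify(findings: RadiographicFindings, context: CaseContext) -> IdealResult:
    """Classify one case: component scores, total and fracture type."""
    i = score_incongruity(findings)
    d = score_displacement(findings)
    e, a, l = score_context(context)
    total = i + d + e + a + l
    ftype = type_for_total(total)
    description, treatment, prognosis = _TYPE_GUIDANCE[ftype]
    return IdealResult(
        score_i=i,
        score_d=d,
        score_e=e,
        score_a=a,
        score_l=l,
        total=total,
        fracture_type=ftype,
        description=description,
        treatment=treatment,
        prognosis=prognosis,
    )


def enumerate_score_space() -> pd.DataFrame:
    """Exhaustively tabulate all 32 component vectors with total and type.

    Returns a 32-row frame with columns ``score_i .. score_l``, ``total``
    and ``fracture_type``; useful as a self-check that the band rule
    partitions the score space.
    """
    rows = []
    for vec in product((0, 1), repeat=5):
        total = sum(vec)
        rows.append(
            {
                "score_i": vec[0],
                "score_d": vec[1],
                "score_e": vec[2],
                "score_a": vec[3],
                "score_l": vec[4],
                "total": total,
                "fracture_type": type_for_total(total).value,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV case-table interface
# ---------------------------------------------------------------------------

CASE_TABLE_COLUMNS = (
    "case_id",
    "articular_step_mm",
    "radial_shortening_mm",
    "volar_tilt_loss_deg",
    "radial_inclination_loss_deg",
    "requires_reduction",
    "age_years",
    "energy",
    "lesions_present",
)

_TRUE_STRINGS = {"1", "true"}
_FALSE_STRINGS = {"0", "false"}


def _parse_bool(value: object, column: str, allow_missing: bool = False) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        if allow_missing:
            return None
        raise ValueError(f"missing value in required boolean column {column!r}")
    text = str(value).strip().lower()
    if text == "" and allow_missing:
        return None
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise ValueError(f"cannot parse {value!r} in column {column!r} as a 0/1/true/false boolean")


def load_case_table(path: str | Path) -> pd.DataFrame:
    """Read a per-case measurement CSV, checking the required header."""
    df = pd.read_csv(path, dtype={"case_id": str, "energy": str})
    missing = [c for c in CASE_TABLE_COLUMNS if c not in df.columns and c != "requires_reduction"]
    if missing:
        raise ValueError(f"case table is missing required columns: {missing}")
    if "requires_reduction" not in df.columns:
        df["requires_reduction"] = None
    return df


def _row_to_case(row: pd.Series) -> tuple[RadiographicFindings, CaseContext]:
    override = _parse_bool(row.get("requires_reduction"), "requires_reduction", allow_missing=True)
    findings = RadiographicFindings(
        articular_step_mm=row["articular_step_mm"],
        radial_shortening_mm=row["radial_shortening_mm"],
        volar_tilt_loss_deg=row["volar_tilt_loss_deg"],
        radial_inclination_loss_deg=row["radial_inclination_loss_deg"],
        requires_reduction_override=override,
    )
    context = CaseContext(
        age_years=int(row["age_years"]),
        energy=Energy(str(row["energy"]).strip().lower()),
        lesions_present=_parse_bool(row["lesions_present"], "lesions_present"),
    )
    return findings, context


def score_case_table(cases: pd.DataFrame) -> pd.DataFrame:
    """Score every row of a case table, appending result columns.

    Validation errors are reported with the offending case id.
    """
    out_rows = []
    for idx, row in cases.iterrows():
        case_id = row.get("case_id", idx)
        try:
            findings, context = _row_to_case(row)
            result = classify(findings, context)
        except ValueError as exc:
            raise ValueError(f"case {case_id!r}: {exc}") from exc
        out_rows.append(
            {
                "case_id": case_id,
                "score_i": result.score_i,
                "score_d": result.score_d,
                "score_e": result.score_e,
                "score_a": result.score_a,
                "score_l": result.score_l,
                "total": result.total,
                "fracture_type": result.fracture_type.value,
                "description": result.description,
                "treatment": result.treatment,
                "prognosis": result.prognosis,
            }
        )
    return pd.DataFrame(out_rows)


def score_cases_csv(path_in: str | Path, path_out: str | Path) -> pd.DataFrame:
    """Score a case CSV and write the scored table; returns the result frame."""
    scored = score_case_table(load_case_table(path_in))
    scored.to_csv(path_out, index=False)
    return scored
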