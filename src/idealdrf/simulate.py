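"""Synthetic multi-observer reproducibility-study generator.

Emulates the design of a classification-reproducibility study on distal
radius fracture radiographs: a panel of observers of heterogeneous skill
each classifies the same set of cases under four systems (IDEAL, Frykman,
Fernandez, AO) in several blinded, randomized sessions.  Ground truth is
known, so downstream agreement statistics can be checked against analytic
expectations.

Error model
-----------
* IDEAL ratings are produced mechanistically: the observer perceives each
  continuous radiographic measurement with additive Gaussian noise
  truncated at zero, may misjudge the binary context items (energy,
  lesions) with a flip probability, and the perceived case is re-scored
  with the IDEAL rule.
* The three morphological systems are modelled only through their label
  alphabets: each observer carries a row-stochastic confusion matrix per
  system giving the probability of reporting each label conditional on
  the true label.
* Within-observer session correlation rho: for each session after the
  first, with probability rho the observer reuses their session-1
  perception of the case, otherwise they re-perceive it independently.
  rho = 1 forces identical labels across sessions; rho = 0 gives
  conditionally independent sessions.
* Optional per-session error multipliers scale the noise SDs, the flip
  probabilities and the off-diagonal confusion mass, to emulate a
  learning (conditioning) effect across sessions.

Seeding: a single global seed expands into independent substreams — one
for case generation and one per observer — so adding observers never
perturbs the generated cases.

Closed forms for the model's expected agreement (and hence kappa) are
provided in :func:`analytic_cohen_kappa`, :func:`analytic_fleiss_kappa`
and :func:`analytic_intraobserver_kappa`; parameter-recovery tests
compare estimated kappas against them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CaseContext, Energy, RadiographicFindings, classify
from .ratings import RATING_COLUMNS, SYSTEM_LABELS, RatingTable

__all__ = [
    "CaseGeneratorConfig",
    "ObserverProfile",
    "symmetric_confusion",
    "uniform_confusion",
    "scale_confusion",
    "generate_cases",
    "simulate_ratings",
    "randomize_presentation",
    "presentation_schedule",
    "default_observer_panel",
    "analytic_cohen_kappa",
    "analytic_fleiss_kappa",
    "analytic_intraobserver_kappa",
    "load_simulation_config",
    "TRUTH_COLUMNS",
]

CATEGORICAL_SYSTEMS = ("Frykman", "Fernandez", "AO")

TRUTH_COLUMNS = (
    "case_id",
    "articular_step_mm",
    "radial_shortening_mm",
    "volar_tilt_loss_deg",
    "radial_inclination_loss_deg",
    "age_years",
    "energy",
    "lesions_present",
    "ideal_total",
    "true_IDEAL",
    "true_Frykman",
    "true_Fernandez",
    "true_AO",
)


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for a named substream of the global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _check_prob(name: str, p: float) -> float:
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
    return p


# ---------------------------------------------------------------------------
# Confusion-matrix helpers
# ---------------------------------------------------------------------------

def symmetric_confusion(n_labels: int, error_rate: float) -> np.ndarray:
    """Row-stochastic matrix: correct with prob 1 - e, else uniform error."""
    _check_prob("error_rate", error_rate)
    if n_labels < 2:
        raise ValueError("need at least 2 labels")
    off = error_rate / (n_labels - 1)
    mat = np.full((n_labels, n_labels), off)
    np.fill_diagonal(mat, 1.0 - error_rate)
    return mat


def uniform_confusion(n_labels: int) -> np.ndarray:
    """Labels reported independently of truth (pure chance agreement)."""
    return np.full((n_labels, n_labels), 1.0 / n_labels)


def scale_confusion(matrix: np.ndarray, multiplier: float) -> np.ndarray:
    """Scale the off-diagonal (error) mass of a confusion matrix.

    multiplier < 1 shrinks errors (learning), > 1 inflates them; the
    diagonal absorbs the difference and must remain non-negative.
    """
    if multiplier == 1.0:
        return matrix
    mat = np.asarray(matrix, dtype=float) * multiplier
    diag = 1.0 - (mat.sum(axis=1) - np.diag(mat))
    if np.any(diag < -1e-12):
        raise ValueError("error multiplier too large: confusion diagonal would go negative")
    np.fill_diagonal(mat, np.clip(diag, 0.0, 1.0))
    return mat


def _validate_confusion(system: str, matrix: np.ndarray, n_labels: int) -> np.ndarray:
    mat = np.asarray(matrix, dtype=float)
    if mat.shape != (n_labels, n_labels):
        raise ValueError(
            f"confusion matrix for {system} must be {n_labels}x{n_labels}, got {mat.shape}"
        )
    if np.any(mat < 0) or not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError(f"confusion matrix rows for {system} must be non-negative and sum to 1")
    return mat


# ---------------------------------------------------------------------------
# Configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CaseGeneratorConfig:
    """Case-mix parameters for the synthetic radiograph sample.

    The continuous findings follow a two-component mixture: with
    probability ``p_displaced`` the case is displaced and its shortening /
    tilt / inclination losses are drawn from zero-truncated normals with
    the stated means and SDs (mm, degrees); articular involvement occurs
    in a further fraction of displaced cases.  Undisplaced cases carry
    small half-normal residuals of scale ``undisplaced_scale``.  Ages are
    integer-rounded truncated normals; energy and lesions are Bernoulli.
    True labels for the morphological systems are sampled from the given
    category distributions (uniform by default) because no measurement
    model maps radiographic findings onto those alphabets here.
    """

    n_cases: int = 60
    seed: int = 0
    age_mean: float = 62.0
    age_sd: float = 16.0
    age_min: int = 18
    age_max: int = 95
    p_high_energy: float = 0.25
    p_lesions: float = 0.15
    p_displaced: float = 0.55
    p_articular_given_displaced: float = 0.45
    step_displaced_mean: float = 2.8
    step_displaced_sd: float = 1.0
    shortening_displaced_mean: float = 4.5
    shortening_displaced_sd: float = 2.0
    tilt_displaced_mean: float = 14.0
    tilt_displaced_sd: float = 5.0
    inclination_displaced_mean: float = 7.0
    inclination_displaced_sd: float = 3.0
    undisplaced_scale: float = 0.3
    frykman_probs: tuple[float, ...] | None = None
    fernandez_probs: tuple[float, ...] | None = None
    ao_probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        for name in ("p_high_energy", "p_lesions", "p_displaced", "p_articular_given_displaced"):
            _check_prob(name, getattr(self, name))
        if not self.age_min <= self.age_max:
            raise ValueError("age_min must not exceed age_max")
        for system, probs in (
            ("Frykman", self.frykman_probs),
            ("Fernandez", self.fernandez_probs),
            ("AO", self.ao_probs),
        ):
            if probs is not None:
                arr = np.asarray(probs, dtype=float)
                if arr.size != len(SYSTEM_LABELS[system]) or np.any(arr < 0) or not np.isclose(arr.sum(), 1.0):
                    raise ValueError(
                        f"{system} category probabilities must be a distribution over "
                        f"{len(SYSTEM_LABELS[system])} labels"
                    )

    def category_probs(self, system: str) -> np.ndarray:
        probs = {
            "Frykman": self.frykman_probs,
            "Fernandez": self.fernandez_probs,
            "AO": self.ao_probs,
        }[system]
        k = len(SYSTEM_LABELS[system])
        return np.full(k, 1.0 / k) if probs is None else np.asarray(probs, dtype=float)


@dataclass(frozen=True)
class ObserverProfile:
    """Error model for one observer.

    Continuous-measurement noise SDs are in the units of the finding (mm
    or degrees); ``p_flip_energy`` / ``p_flip_lesions`` are per-rating
    misjudgement probabilities for the binary context items; ``confusion``
    holds one row-stochastic matrix per categorical system;
    ``session_correlation`` is the probability of reusing the session-1
    perception in later sessions; ``session_error_multipliers`` (one per
    session) scale all error sources to model learning effects.
    """

    observer_id: str
    step_noise_sd_mm: float = 0.4
    shortening_noise_sd_mm: float = 0.8
    tilt_noise_sd_deg: float = 3.0
    inclination_noise_sd_deg: float = 2.0
    p_flip_energy: float = 0.02
    p_flip_lesions: float = 0.03
    confusion: Mapping[str, np.ndarray] = field(default_factory=dict)
    session_correlation: float = 0.0
    session_error_multipliers: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("step_noise_sd_mm", "shortening_noise_sd_mm", "tilt_noise_sd_deg", "inclination_noise_sd_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        _check_prob("p_flip_energy", self.p_flip_energy)
        _check_prob("p_flip_lesions", self.p_flip_lesions)
        _check_prob("session_correlation", self.session_correlation)
        validated = {
            system: _validate_confusion(system, mat, len(SYSTEM_LABELS[system]))
            for system, mat in self.confusion.items()
        }
        object.__setattr__(self, "confusion", validated)
        if self.session_error_multipliers is not None:
            mults = tuple(float(m) for m in self.session_error_multipliers)
            if any(m < 0 for m in mults):
                raise ValueError("session_error_multipliers must be >= 0")
            object.__setattr__(self, "session_error_multipliers", mults)

    @classmethod
    def from_error_rate(
        cls,
        observer_id: str,
        error_rate: float,
        noise_scale: float = 1.0,
        session_correlation: float = 0.0,
        session_error_multipliers: tuple[float, ...] | None = None,
        systems: Sequence[str] = CATEGORICAL_SYSTEMS,
    ) -> "ObserverProfile":
        """Build a profile from a single skill parameter.

        ``error_rate`` fills symmetric confusion matrices for the
        categorical systems; ``noise_scale`` multiplies the default
        measurement-noise SDs and flip probabilities.
        """
        base = cls(observer_id="_tmp")
        return cls(
            observer_id=observer_id,
            step_noise_sd_mm=base.step_noise_sd_mm * noise_scale,
            shortening_noise_sd_mm=base.shortening_noise_sd_mm * noise_scale,
            tilt_noise_sd_deg=base.tilt_noise_sd_deg * noise_scale,
            inclination_noise_sd_deg=base.inclination_noise_sd_deg * noise_scale,
            p_flip_energy=min(1.0, base.p_flip_energy * noise_scale),
            p_flip_lesions=min(1.0, base.p_flip_lesions * noise_scale),
            confusion={
                system: symmetric_confusion(len(SYSTEM_LABELS[system]), error_rate)
                for system in systems
            },
            session_correlation=session_correlation,
            session_error_multipliers=session_error_multipliers,
        )


def default_observer_panel(session_correlation: float = 0.35) -> list[ObserverProfile]:
    """Six observers of graded skill mirroring a mixed clinical panel.

    Profiles range from an experienced hand surgery specialist (low error)
    to medical students (high error); the per-system error rates and noise
    scales are generator defaults, not estimates from any real panel.
    """
    skills = [
        ("hand_surgery_specialist", 0.05, 0.7),
        ("hand_surgery_resident", 0.08, 0.9),
        ("general_orthopedic_surgeon", 0.10, 1.0),
        ("orthopedics_resident", 0.12, 1.1),
        ("medical_student_1", 0.30, 2.0),
        ("medical_student_2", 0.15, 1.3),
    ]
    return [
        ObserverProfile.from_error_rate(
            name, error_rate, noise_scale, session_correlation=session_correlation
        )
        for name, error_rate, noise_scale in skills
    ]


# ---------------------------------------------------------------------------
# Case generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) conditioned on being >= 0, by rejection."""
    out = rng.normal(mean, sd, size)
    bad = out < 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < 0
    return out


def _truncated_normal_int(
    rng: np.random.Generator, mean: float, sd: float, low: int, high: int, size: int
) -> np.ndarray:
    out = np.round(rng.normal(mean, sd, size))
    bad = (out < low) | (out > high)
    while np.any(bad):
        out[bad] = np.round(rng.normal(mean, sd, int(bad.sum())))
        bad = (out < low) | (out > high)
    return out.astype(int)


def generate_cases(config: CaseGeneratorConfig) -> pd.DataFrame:
    """Draw a synthetic case set with ground-truth labels for all systems.

    Deterministic given ``config.seed``.  True IDEAL labels are derived by
    scoring the true measurements; true labels for the morphological
    systems are sampled from the configured category distributions.
    """
    rng = _stream(config.seed, 0)
    n = config.n_cases

    ages = _truncated_normal_int(rng, config.age_mean, config.age_sd, config.age_min, config.age_max, n)
    energy = np.where(rng.random(n) < config.p_high_energy, "high", "low")
    lesions = rng.random(n) < config.p_lesions
    displaced = rng.random(n) < config.p_displaced
    articular = displaced & (rng.random(n) < config.p_articular_given_displaced)

    small = lambda: np.abs(rng.normal(0.0, config.undisplaced_scale, n))
    step = small()
    shortening = small()
    tilt = small()
    inclination = small()
    step[articular] = _truncated_normal(
        rng, config.step_displaced_mean, config.step_displaced_sd, int(articular.sum())
    )
    nd = int(displaced.sum())
    shortening[displaced] = _truncated_normal(
        rng, config.shortening_displaced_mean, config.shortening_displaced_sd, nd
    )
    tilt[displaced] = _truncated_normal(rng, config.tilt_displaced_mean, config.tilt_displaced_sd, nd)
    inclination[displaced] = _truncated_normal(
        rng, config.inclination_displaced_mean, config.inclination_displaced_sd, nd
    )

    rows = []
    width = max(3, len(str(n)))
    for i in range(n):
        findings = RadiographicFindings(
            articular_step_mm=float(step[i]),
            radial_shortening_mm=float(shortening[i]),
            volar_tilt_loss_deg=float(tilt[i]),
            radial_inclination_loss_deg=float(inclination[i]),
        )
        context = CaseContext(
            age_years=int(ages[i]),
            energy=Energy(energy[i]),
            lesions_present=bool(lesions[i]),
        )
        result = classify(findings, context)
        rows.append(
            {
                "case_id": f"C{i + 1:0{width}d}",
                "articular_step_mm": float(step[i]),
                "radial_shortening_mm": float(shortening[i]),
                "volar_tilt_loss_deg": float(tilt[i]),
                "radial_inclination_loss_deg": float(inclination[i]),
                "age_years": int(ages[i]),
                "energy": energy[i],
                "lesions_present": bool(lesions[i]),
                "ideal_total": result.total,
                "true_IDEAL": result.fracture_type.value,
            }
        )
    cases = pd.DataFrame(rows)
    for system in CATEGORICAL_SYSTEMS:
        labels = np.asarray(SYSTEM_LABELS[system])
        cases[f"true_{system}"] = rng.choice(labels, size=n, p=config.category_probs(system))
    return cases.loc[:, list(TRUTH_COLUMNS)]


# ---------------------------------------------------------------------------
# Rating simulation
# ---------------------------------------------------------------------------

def _perceive(
    case: Mapping,
    profile: ObserverProfile,
    multiplier: float,
    rng: np.random.Generator,
    systems: Sequence[str],
    label_indices: Mapping[str, Mapping[str, int]],
) -> dict[str, str]:
    """One independent perception of a case: a label per requested system."""
    labels: dict[str, str] = {}
    if "IDEAL" in systems:
        noisy = lambda value, sd: max(0.0, value + rng.normal(0.0, sd * multiplier)) if sd > 0 else value
        findings = RadiographicFindings(
            articular_step_mm=noisy(case["articular_step_mm"], profile.step_noise_sd_mm),
            radial_shortening_mm=noisy(case["radial_shortening_mm"], profile.shortening_noise_sd_mm),
            volar_tilt_loss_deg=noisy(case["volar_tilt_loss_deg"], profile.tilt_noise_sd_deg),
            radial_inclination_loss_deg=noisy(
                case["radial_inclination_loss_deg"], profile.inclination_noise_sd_deg
            ),
        )
        energy = case["energy"]
        if rng.random() < min(1.0, profile.p_flip_energy * multiplier):
            energy = "high" if energy == "low" else "low"
        lesions = bool(case["lesions_present"])
        if rng.random() < min(1.0, profile.p_flip_lesions * multiplier):
            lesions = not lesions
        context = CaseContext(age_years=int(case["age_years"]), energy=Energy(energy), lesions_present=lesions)
        labels["IDEAL"] = classify(findings, context).fracture_type.value
    for system in systems:
        if system == "IDEAL":
            continue
        if system not in profile.confusion:
            raise ValueError(
                f"observer {profile.observer_id!r} has no confusion matrix for system {system!r}"
            )
        mat = scale_confusion(profile.confusion[system], multiplier)
        truth_idx = label_indices[system][case[f"true_{system}"]]
        drawn = rng.choice(len(SYSTEM_LABELS[system]), p=mat[truth_idx])
        labels[system] = SYSTEM_LABELS[system][drawn]
    return labels


def simulate_ratings(
    cases: pd.DataFrame,
    profiles: Sequence[ObserverProfile],
    n_sessions: int = 3,
    seed: int = 0,
    systems: Sequence[str] = ("IDEAL",) + CATEGORICAL_SYSTEMS,
) -> RatingTable:
    """Simulate the full rating table for a panel of observers.

    Produces exactly one label per (case, observer, session, system);
    sessions are named T1, T2, ...  Deterministic given ``seed``; each
    observer draws from an independent substream keyed by their position
    in ``profiles``.
    """
    if not profiles:
        raise ValueError("need at least one observer profile")
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    ids = [p.observer_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("observer ids must be unique")
    for system in systems:
        if system not in SYSTEM_LABELS:
            raise ValueError(f"unknown system {system!r}")
        col = "articular_step_mm" if system == "IDEAL" else f"true_{system}"
        if col not in cases.columns:
            raise ValueError(f"case table lacks column {col!r} needed for system {system}")

    label_indices = {
        system: {label: i for i, label in enumerate(SYSTEM_LABELS[system])}
        for system in CATEGORICAL_SYSTEMS
    }
    session_names = [f"T{s + 1}" for s in range(n_sessions)]
    records: list[tuple[str, str, str, str, str]] = []
    case_dicts = cases.to_dict("records")
    for oi, profile in enumerate(profiles):
        rng = _stream(seed, 1, oi)
        mults = profile.session_error_multipliers or (1.0,) * n_sessions
        if len(mults) < n_sessions:
            raise ValueError(
                f"observer {profile.observer_id!r}: {len(mults)} session multipliers "
                f"for {n_sessions} sessions"
            )
        rho = profile.session_correlation
        for case in case_dicts:
            first: dict[str, str] | None = None
            for s in range(n_sessions):
                if s > 0 and rng.random() < rho:
                    labels = first
                else:
                    labels = _perceive(case, profile, mults[s], rng, systems, label_indices)
                if s == 0:
                    first = labels
                for system in systems:
                    records.append(
                        (case["case_id"], profile.observer_id, session_names[s], system, labels[system])
                    )
    df = pd.DataFrame(records, columns=list(RATING_COLUMNS))
    return RatingTable(df)


def randomize_presentation(n_cases: int, seed: int) -> np.ndarray:
    """Blinded presentation order: a permutation of case indices 0..n-1."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    return _stream(seed, 2).permutation(n_cases)


def presentation_schedule(
    n_cases: int,
    observer_ids: Sequence[str],
    n_sessions: int,
    seed: int,
) -> pd.DataFrame:
    """Independent randomized presentation order per (observer, session).

    Long-format frame with columns observer_id, session, position,
    case_index; deterministic given ``seed``.
    """
    rows = []
    for oi, observer in enumerate(observer_ids):
        for s in range(n_sessions):
            order = _stream(seed, 3, oi, s).permutation(n_cases)
            for pos, case_index in enumerate(order):
                rows.append((observer, f"T{s + 1}", pos, int(case_index)))
    return pd.DataFrame(rows, columns=["observer_id", "session", "position", "case_index"])


# ---------------------------------------------------------------------------
# Analytic expectations of the error model
# ---------------------------------------------------------------------------

def analytic_cohen_kappa(
    truth_probs: Sequence[float], confusion_a: np.ndarray, confusion_b: np.ndarray
) -> float:
    """Population Cohen kappa for two confusion-matrix observers.

    With true-label distribution p and row-stochastic confusion matrices A
    and B, the joint label distribution is P(a, b) = sum_t p_t A[t,a] B[t,b];
    p_o is its trace and p_e the product of its marginals.
    """
    p = np.asarray(truth_probs, dtype=float)
    a = np.asarray(confusion_a, dtype=float)
    b = np.asarray(confusion_b, dtype=float)
    joint = a.T @ (p[:, None] * b)
    p_o = float(np.trace(joint))
    marg_a = joint.sum(axis=1)
    marg_b = joint.sum(axis=0)
    p_e = float(marg_a @ marg_b)
    return (p_o - p_e) / (1.0 - p_e)


def analytic_fleiss_kappa(
    truth_probs: Sequence[float], confusions: Sequence[np.ndarray]
) -> float:
    """Population Fleiss kappa for a panel of confusion-matrix observers.

    Observed agreement is the mean pairwise agreement probability across
    the panel; chance agreement uses the panel-averaged label marginal, as
    in the multi-rater kappa definition.
    """
    p = np.asarray(truth_probs, dtype=float)
    mats = [np.asarray(c, dtype=float) for c in confusions]
    if len(mats) < 2:
        raise ValueError("need at least 2 observers")
    marginals = np.stack([c.T @ p for c in mats])
    p_bar = marginals.mean(axis=0)
    p_e = float(np.sum(p_bar**2))
    agreements = [
        float(p @ np.sum(mats[i] * mats[j], axis=1))
        for i in range(len(mats))
        for j in range(i + 1, len(mats))
    ]
    p_o = float(np.mean(agreements))
    return (p_o - p_e) / (1.0 - p_e)


def analytic_intraobserver_kappa(
    truth_probs: Sequence[float],
    confusion: np.ndarray,
    session_correlation: float,
    n_sessions: int = 3,
) -> float:
    """Population Fleiss kappa over one observer's correlated sessions.

    Under the reuse model, session s > 1 copies the session-1 perception
    with probability rho and redraws otherwise.  Two fresh perceptions
    agree with probability a = sum_t p_t sum_l C[t,l]^2, so session 1
    agrees with a later session with probability rho + (1 - rho) a, while
    two later sessions agree with probability rho^2 + (1 - rho^2) a.  The
    label marginal (hence p_e) is the same for every session.
    """
    if n_sessions < 2:
        raise ValueError("need at least 2 sessions")
    p = np.asarray(truth_probs, dtype=float)
    c = np.asarray(confusion, dtype=float)
    rho = _check_prob("session_correlation", session_correlation)
    a = float(p @ np.sum(c**2, axis=1))
    pair_agreements = []
    for s1 in range(n_sessions):
        for s2 in range(s1 + 1, n_sessions):
            if s1 == 0:
                pair_agreements.append(rho + (1.0 - rho) * a)
            else:
                pair_agreements.append(rho**2 + (1.0 - rho**2) * a)
    p_o = float(np.mean(pair_agreements))
    marginal = c.T @ p
    p_e = float(np.sum(marginal**2))
    return (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# JSON configuration
# ---------------------------------------------------------------------------

def load_simulation_config(path: str | Path) -> tuple[CaseGeneratorConfig, list[ObserverProfile], int, int]:
    """Parse a JSON simulation config.

    Schema::

        {
          "seed": 0,
          "n_sessions": 3,
          "cases": { ... CaseGeneratorConfig fields ... },
          "observers": [
            {"observer_id": "...", "error_rate": 0.1,
             "noise_scale": 1.0, "session_correlation": 0.3,
             "session_error_multipliers": [1.0, 1.0, 0.5]},
            ...
          ]
        }

    Observers may instead spell out full profiles (noise SDs, flip
    probabilities and per-system confusion matrices as nested lists).

    Returns (case_config, profiles, n_sessions, seed).
    """
    with open(path) as fh:
        raw = json.load(fh)
    seed = int(raw.get("seed", 0))
    n_sessions = int(raw.get("n_sessions", 3))
    case_kwargs = dict(raw.get("cases", {}))
    for key in ("frykman_probs", "fernandez_probs", "ao_probs"):
        if case_kwargs.get(key) is not None:
            case_kwargs[key] = tuple(case_kwargs[key])
    case_kwargs.setdefault("seed", seed)
    case_config = CaseGeneratorConfig(**case_kwargs)
    profiles = []
    for entry in raw.get("observers", []):
        entry = dict(entry)
        mults = entry.pop("session_error_multipliers", None)
        if mults is not None:
            mults = tuple(float(m) for m in mults)
        if "error_rate" in entry:
            profiles.append(
                ObserverProfile.from_error_rate(
                    entry["observer_id"],
                    error_rate=float(entry["error_rate"]),
                    noise_scale=float(entry.get("noise_scale", 1.0)),
                    session_correlation=float(entry.get("session_correlation", 0.0)),
                    session_error_multipliers=mults,
                )
            )
        else:
            confusion = {
                system: np.asarray(mat, dtype=float)
                for system, mat in entry.pop("confusion", {}).items()
            }
            profiles.append(
                ObserverProfile(confusion=confusion, session_error_multipliers=mults, **entry)
            )
    if not profiles:
        profiles = default_observer_panel()
    return case_config, profiles, n_sessions, seed
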