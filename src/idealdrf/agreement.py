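"""Chance-corrected agreement statistics for categorical ratings.

Implements Cohen's kappa for two raters and Fleiss's kappa for a fixed
number of raters per subject, together with the study-level arrangements
used in classification-reproducibility work:

* intraobserver agreement — one observer's repeated sessions treated as
  interchangeable replicate raters (Fleiss kappa over sessions);
* session drift — Cohen kappas between consecutive sessions of one
  observer, to detect a learning/conditioning effect;
* interobserver agreement — Fleiss kappa across observers at one session;
* mean pairwise Cohen kappa across all observer pairs at one session;
* interpretation bands (< 0.5 unsatisfactory, 0.5-0.75 satisfactory,
  > 0.75 excellent, boundaries inclusive in the middle band);
* cross-system comparison of kappa sets by one-way ANOVA (the classical
  Fisher F test), with an optional permutation p-value.

Standard errors are large-sample: the Fleiss-Cohen-Everitt asymptotic
variance for Cohen's kappa and the Fleiss-Nee-Landis formula for the
multi-rater kappa.  Confidence intervals use the normal approximation and
are clipped to [-1, 1].

Degenerate inputs — both raters constant and identical, or all rating
mass in a single category, i.e. expected agreement p_e = 1 — are flagged
(``degenerate=True``) with kappa defined as 1 and zero standard error
rather than returning NaN.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ratings import RatingTable

__all__ = [
    "UNSATISFACTORY",
    "SATISFACTORY",
    "EXCELLENT",
    "KappaEstimate",
    "ComparisonResult",
    "PairwiseKappaSummary",
    "IncompleteRatingsWarning",
    "DegeneratePairWarning",
    "interpret_kappa",
    "cohen_kappa",
    "fleiss_kappa",
    "fleiss_kappa_from_labels",
    "intraobserver_kappa",
    "session_drift",
    "interobserver_kappa",
    "pairwise_mean_kappa",
    "compare_kappa_sets",
]

UNSATISFACTORY = "unsatisfactory"
SATISFACTORY = "satisfactory"
EXCELLENT = "excellent"

_PE_DEGENERATE_TOL = 1e-12


class IncompleteRatingsWarning(UserWarning):
    """Subjects were dropped for lacking a complete rater/session panel."""


class DegeneratePairWarning(UserWarning):
    """An observer pair produced a degenerate kappa and was excluded."""


def interpret_kappa(kappa: float) -> str:
    """Map a kappa value onto its qualitative band.

    Values below 0.5 are unsatisfactory, values in [0.5, 0.75] are
    satisfactory (both boundaries inclusive) and values above 0.75 are
    excellent.
    """
    if not np.isfinite(kappa) or not -1.0 - 1e-9 <= kappa <= 1.0 + 1e-9:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa!r}")
    k = float(np.clip(kappa, -1.0, 1.0))
    if k < 0.5:
        return UNSATISFACTORY
    if k <= 0.75:
        return SATISFACTORY
    return EXCELLENT


@dataclass(frozen=True)
class KappaEstimate:
    """A kappa point estimate with large-sample uncertainty.

    ``interpretation`` is the qualitative band of the point estimate;
    ``degenerate`` marks estimates where expected agreement was 1 (kappa
    conventionally defined as 1); ``n_dropped_subjects`` counts subjects
    excluded for incomplete panels.
    """

    kappa: float
    standard_error: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_raters: int
    n_categories: int
    interpretation: str
    confidence_level: float = 0.95
    degenerate: bool = False
    n_dropped_subjects: int = 0
    method: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.kappa + 1e-12 and self.kappa - 1e-12 <= self.ci_high):
            raise ValueError("confidence interval must bracket the point estimate")

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "standard_error": self.standard_error,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_subjects": self.n_subjects,
            "n_raters": self.n_raters,
            "n_categories": self.n_categories,
            "interpretation": self.interpretation,
            "confidence_level": self.confidence_level,
            "degenerate": self.degenerate,
            "n_dropped_subjects": self.n_dropped_subjects,
            "method": self.method,
        }


def _normal_ci(kappa: float, se: float, confidence_level: float) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + confidence_level / 2.0)
    return (
        float(max(-1.0, kappa - z * se)),
        float(min(1.0, kappa + z * se)),
    )


def _degenerate_estimate(
    n_subjects: int, n_raters: int, n_categories: int, confidence_level: float, method: str,
    n_dropped: int = 0,
) -> KappaEstimate:
    return KappaEstimate(
        kappa=1.0,
        standard_error=0.0,
        ci_low=1.0,
        ci_high=1.0,
        n_subjects=n_subjects,
        n_raters=n_raters,
        n_categories=n_categories,
        interpretation=EXCELLENT,
        confidence_level=confidence_level,
        degenerate=True,
        n_dropped_subjects=n_dropped,
        method=method,
    )


# ---------------------------------------------------------------------------
# Cohen's kappa (two raters)
# ---------------------------------------------------------------------------

def cohen_kappa(
    labels_a: Sequence,
    labels_b: Sequence,
    categories: Sequence | None = None,
    confidence_level: float = 0.95,
    n_dropped_subjects: int = 0,
) -> KappaEstimate:
    """Cohen's kappa between two raters' label sequences.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed proportion of
    agreement and p_e the chance agreement from the marginal products.  The
    standard error is the Fleiss-Cohen-Everitt large-sample form (valid
    away from the null), and the CI is a normal approximation clipped to
    [-1, 1].

    ``categories`` fixes the category order; by default the sorted union of
    observed labels is used (category order does not affect the result).
    """
    a = np.asarray(list(labels_a))
    b = np.asarray(list(labels_b))
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label sequences must be one-dimensional and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 rated subjects")
    if categories is None:
        cats = sorted(set(a.tolist()) | set(b.tolist()))
    else:
        cats = list(categories)
        unknown = (set(a.tolist()) | set(b.tolist())) - set(cats)
        if unknown:
            raise ValueError(f"labels outside the declared categories: {sorted(unknown)}")
    k = len(cats)
    index = {c: i for i, c in enumerate(cats)}
    table = np.zeros((k, k))
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1.0
    p = table / n
    p_row = p.sum(axis=1)  # rater A marginal
    p_col = p.sum(axis=0)  # rater B marginal
    p_o = float(np.trace(p))
    p_e = float(p_row @ p_col)

    method = "Cohen kappa (SE: Fleiss-Cohen-Everitt)"
    if 1.0 - p_e < _PE_DEGENERATE_TOL:
        return _degenerate_estimate(n, 2, k, confidence_level, method, n_dropped_subjects)

    kappa = (p_o - p_e) / (1.0 - p_e)

    # Fleiss-Cohen-Everitt asymptotic variance of the sample kappa.
    diag = np.diag(p)
    term1 = float(
        np.sum(diag * ((1.0 - p_e) - (p_row + p_col) * (1.0 - p_o)) ** 2)
    )
    off = p.copy()
    np.fill_diagonal(off, 0.0)
    weights = (p_col[:, None] + p_row[None, :]) ** 2  # cell (i, j): (p_.i + p_j.)^2
    term2 = float((1.0 - p_o) ** 2 * np.sum(off * weights))
    term3 = float((p_o * p_e - 2.0 * p_e + p_o) ** 2)
    var = (term1 + term2 - term3) / (n * (1.0 - p_e) ** 4)
    se = float(np.sqrt(max(var, 0.0)))

    ci_low, ci_high = _normal_ci(kappa, se, confidence_level)
    return KappaEstimate(
        kappa=float(kappa),
        standard_error=se,
        ci_low=ci_low,
        ci_high=ci_high,
        n_subjects=n,
        n_raters=2,
        n_categories=k,
        interpretation=interpret_kappa(kappa),
        confidence_level=confidence_level,
        n_dropped_subjects=n_dropped_subjects,
        method=method,
    )


# ---------------------------------------------------------------------------
# Fleiss's kappa (m raters per subject)
# ---------------------------------------------------------------------------

def fleiss_kappa(
    count_matrix: np.ndarray | Sequence[Sequence[int]],
    raters_per_subject: int | None = None,
    confidence_level: float = 0.95,
    n_dropped_subjects: int = 0,
) -> KappaEstimate:
    """Fleiss's multi-rater kappa from a subjects x categories count matrix.

    Every row must sum to the same number of raters m >= 2.  The point
    estimate follows Fleiss's chance-corrected mean pairwise agreement; the
    standard error is the Fleiss-Nee-Landis large-sample formula (derived
    under the no-agreement null, the conventional reference SE for this
    statistic).
    """
    counts = np.asarray(count_matrix, dtype=float)
    if counts.ndim != 2:
        raise ValueError("count matrix must be 2-dimensional (subjects x categories)")
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    row_sums = counts.sum(axis=1)
    m = int(row_sums[0])
    if not np.all(row_sums == m):
        raise ValueError("ragged count matrix: all rows must sum to the same rater count")
    if raters_per_subject is not None and raters_per_subject != m:
        raise ValueError(
            f"rows sum to {m} raters but raters_per_subject={raters_per_subject}"
        )
    if m < 2:
        raise ValueError("need at least 2 raters per subject")
    n, k = counts.shape

    p_j = counts.sum(axis=0) / (n * m)
    p_e = float(np.sum(p_j**2))
    method = "Fleiss kappa (SE: Fleiss-Nee-Landis)"
    if 1.0 - p_e < _PE_DEGENERATE_TOL:
        return _degenerate_estimate(n, m, k, confidence_level, method, n_dropped_subjects)

    agree_i = (np.sum(counts**2, axis=1) - m) / (m * (m - 1))
    p_o = float(agree_i.mean())
    kappa = (p_o - p_e) / (1.0 - p_e)

    q_j = 1.0 - p_j
    s = float(np.sum(p_j * q_j))
    var = (
        2.0
        / (n * m * (m - 1))
        * (s**2 - float(np.sum(p_j * q_j * (q_j - p_j))))
        / s**2
    )
    se = float(np.sqrt(max(var, 0.0)))

    ci_low, ci_high = _normal_ci(kappa, se, confidence_level)
    return KappaEstimate(
        kappa=float(kappa),
        standard_error=se,
        ci_low=ci_low,
        ci_high=ci_high,
        n_subjects=n,
        n_raters=m,
        n_categories=k,
        interpretation=interpret_kappa(kappa),
        confidence_level=confidence_level,
        n_dropped_subjects=n_dropped_subjects,
        method=method,
    )


def fleiss_kappa_from_labels(
    label_matrix: pd.DataFrame | np.ndarray,
    categories: Sequence,
    confidence_level: float = 0.95,
    n_dropped_subjects: int = 0,
) -> KappaEstimate:
    """Fleiss kappa from a subjects x raters label matrix (no missing cells)."""
    labels = np.asarray(label_matrix)
    cats = list(categories)
    index = {c: i for i, c in enumerate(cats)}
    unknown = set(labels.ravel().tolist()) - set(cats)
    if unknown:
        raise ValueError(f"labels outside the declared categories: {sorted(unknown)}")
    counts = np.zeros((labels.shape[0], len(cats)), dtype=int)
    for i, row in enumerate(labels):
        for lab in row:
            counts[i, index[lab]] += 1
    return fleiss_kappa(
        counts,
        confidence_level=confidence_level,
        n_dropped_subjects=n_dropped_subjects,
    )


# ---------------------------------------------------------------------------
# Study-level arrangements on a RatingTable
# ---------------------------------------------------------------------------

def _complete_pivot(
    table: RatingTable,
    system: str,
    columns: str,
    session: str | None = None,
    observer: str | None = None,
    what: str = "analysis",
) -> tuple[pd.DataFrame, int]:
    """Pivot to a label matrix and drop subjects with any missing cell."""
    pivot = table.pivot(system, columns=columns, session=session, observer=observer)
    if pivot.empty:
        raise ValueError(f"no ratings available for {what}")
    complete = pivot.dropna(axis=0)
    n_dropped = len(pivot) - len(complete)
    if n_dropped:
        warnings.warn(
            f"{what}: dropped {n_dropped} subject(s) with incomplete ratings",
            IncompleteRatingsWarning,
            stacklevel=3,
        )
    if len(complete) < 2:
        raise ValueError(f"{what}: fewer than 2 subjects with complete ratings")
    return complete, n_dropped


def intraobserver_kappa(
    table: RatingTable,
    observer: str,
    system: str,
    confidence_level: float = 0.95,
) -> KappaEstimate:
    """Intraobserver agreement of one observer across all their sessions.

    The observer's sessions are treated as interchangeable replicate raters
    and Fleiss's kappa is applied; with exactly two sessions this reduces
    to a 2-replicate Fleiss kappa.  Subjects missing any session are
    dropped with a warning.
    """
    matrix, n_dropped = _complete_pivot(
        table,
        system,
        columns="session",
        observer=observer,
        what=f"intraobserver kappa ({observer}, {system})",
    )
    if matrix.shape[1] < 2:
        raise ValueError("intraobserver kappa needs at least 2 sessions")
    return fleiss_kappa_from_labels(
        matrix,
        categories=table.labels_for(system),
        confidence_level=confidence_level,
        n_dropped_subjects=n_dropped,
    )


def session_drift(
    table: RatingTable,
    observer: str,
    system: str,
    confidence_level: float = 0.95,
) -> dict[tuple[str, str], KappaEstimate]:
    """Cohen kappas between consecutive sessions of one observer.

    For the canonical three-session design this returns the T1-vs-T2 and
    T2-vs-T3 kappas, whose comparison reveals a conditioning (learning)
    effect.  Keys are (earlier_session, later_session) pairs.
    """
    matrix, _ = _complete_pivot(
        table,
        system,
        columns="session",
        observer=observer,
        what=f"session drift ({observer}, {system})",
    )
    sessions = sorted(matrix.columns)
    if len(sessions) < 2:
        raise ValueError("session drift needs at least 2 sessions")
    out: dict[tuple[str, str], KappaEstimate] = {}
    for s1, s2 in zip(sessions[:-1], sessions[1:]):
        out[(s1, s2)] = cohen_kappa(
            matrix[s1],
            matrix[s2],
            categories=table.labels_for(system),
            confidence_level=confidence_level,
        )
    return out


def interobserver_kappa(
    table: RatingTable,
    session: str,
    system: str,
    confidence_level: float = 0.95,
) -> KappaEstimate:
    """Fleiss kappa across observers for one session and system."""
    matrix, n_dropped = _complete_pivot(
        table,
        system,
        columns="observer_id",
        session=session,
        what=f"interobserver kappa ({session}, {system})",
    )
    if matrix.shape[1] < 2:
        raise ValueError("interobserver kappa needs at least 2 observers")
    return fleiss_kappa_from_labels(
        matrix,
        categories=table.labels_for(system),
        confidence_level=confidence_level,
        n_dropped_subjects=n_dropped,
    )


@dataclass(frozen=True)
class PairwiseKappaSummary:
    """Mean Cohen kappa over all observer pairs at one session.

    ``pair_kappas`` maps (observer_a, observer_b) to the pair's estimate;
    ``excluded_pairs`` lists pairs dropped as degenerate.
    """

    mean_kappa: float
    pair_kappas: dict[tuple[str, str], KappaEstimate]
    excluded_pairs: tuple[tuple[str, str], ...] = ()
    interpretation: str = ""

    @property
    def n_pairs(self) -> int:
        return len(self.pair_kappas)


def pairwise_mean_kappa(
    table: RatingTable,
    session: str,
    system: str,
    confidence_level: float = 0.95,
) -> PairwiseKappaSummary:
    """Unweighted mean of Cohen kappas over all observer pairs.

    Degenerate pairs (chance agreement of 1) are excluded with a warning
    rather than contributing a conventional value to the mean.
    """
    matrix, _ = _complete_pivot(
        table,
        system,
        columns="observer_id",
        session=session,
        what=f"pairwise kappas ({session}, {system})",
    )
    observers = sorted(matrix.columns)
    if len(observers) < 2:
        raise ValueError("pairwise mean kappa needs at least 2 observers")
    pair_kappas: dict[tuple[str, str], KappaEstimate] = {}
    excluded: list[tuple[str, str]] = []
    for o1, o2 in itertools.combinations(observers, 2):
        est = cohen_kappa(
            matrix[o1],
            matrix[o2],
            categories=table.labels_for(system),
            confidence_level=confidence_level,
        )
        if est.degenerate:
            warnings.warn(
                f"pair ({o1}, {o2}) degenerate for {system} at {session}; excluded from mean",
                DegeneratePairWarning,
                stacklevel=2,
            )
            excluded.append((o1, o2))
        else:
            pair_kappas[(o1, o2)] = est
    if not pair_kappas:
        raise ValueError("all observer pairs were degenerate")
    mean = float(np.mean([e.kappa for e in pair_kappas.values()]))
    return PairwiseKappaSummary(
        mean_kappa=mean,
        pair_kappas=pair_kappas,
        excluded_pairs=tuple(excluded),
        interpretation=interpret_kappa(mean),
    )


# ---------------------------------------------------------------------------
# Comparing kappa sets across classification systems
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    """One-way comparison of kappa sets across named groups.

    ``statistic`` / ``p_value`` are the overall F test across all groups;
    ``pairwise`` maps (group_a, group_b) to that pair's (F, p).  When a
    permutation test was requested its p-value is reported alongside.
    """

    statistic: float
    p_value: float
    groups: tuple[str, ...]
    method: str
    pairwise: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    permutation_p_value: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "groups": list(self.groups),
            "method": self.method,
            "pairwise": {
                " versus ".join(pair): {"statistic": f, "p_value": p}
                for pair, (f, p) in self.pairwise.items()
            },
            "permutation_p_value": self.permutation_p_value,
            "degenerate": self.degenerate,
        }


def _f_oneway_safe(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p, with explicit handling of zero-variance edges."""
    grand = np.concatenate(groups)
    group_means = np.array([g.mean() for g in groups])
    ss_between = float(sum(len(g) * (m - grand.mean()) ** 2 for g, m in zip(groups, group_means)))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, group_means)))
    if ss_between <= 1e-300:
        return 0.0, 1.0
    if ss_within <= 1e-300:
        return float("inf"), 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def compare_kappa_sets(
    groups: Mapping[str, Sequence[float]],
    permutations: int | None = None,
    seed: int | None = None,
) -> ComparisonResult:
    """Compare unit-level kappa values across groups with an F test.

    Units are whatever replicated the kappa within each group — observers
    for intraobserver comparisons, sessions for interobserver comparisons.
    An optional label-permutation test gives a p-value that does not rely
    on normality of the kappas.
    """
    names = tuple(groups.keys())
    if len(names) < 2:
        raise ValueError("need at least 2 groups to compare")
    arrays = [np.asarray(list(groups[name]), dtype=float) for name in names]
    for name, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 kappa values")

    degenerate = float(np.ptp(np.concatenate(arrays))) <= 1e-300
    f_obs, p_obs = _f_oneway_safe(arrays)

    pairwise: dict[tuple[str, str], tuple[float, float]] = {}
    for (na, ga), (nb, gb) in itertools.combinations(zip(names, arrays), 2):
        pairwise[(na, nb)] = _f_oneway_safe([ga, gb])

    perm_p = None
    if permutations is not None and not degenerate:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate(arrays)
        sizes = [a.size for a in arrays]
        hits = 0
        for _ in range(permutations):
            rng.shuffle(pooled)
            parts = np.split(pooled, np.cumsum(sizes)[:-1])
            f_perm, _ = _f_oneway_safe(parts)
            if f_perm >= f_obs:
                hits += 1
        perm_p = (hits + 1) / (permutations + 1)

    return ComparisonResult(
        statistic=f_obs,
        p_value=p_obs,
        groups=names,
        method="one-way ANOVA (Fisher F test)",
        pairwise=pairwise,
        permutation_p_value=perm_p,
        degenerate=degenerate,
    )
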