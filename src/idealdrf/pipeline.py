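"""End-to-end reproducibility analysis of a multi-observer rating table.

:func:`run_study` takes a validated rating table and produces the full
report of a classification-reproducibility study:

* per-(observer, system) intraobserver kappas, with two per-system
  aggregates — the arithmetic mean of the per-observer kappas and a
  pooled kappa computed over all (subject, observer) replicate panels;
* per-(session, system) interobserver kappas with the per-system mean
  over sessions;
* mean pairwise Cohen kappas per (session, system);
* consecutive-session drift kappas per (observer, system);
* cross-system F-test comparisons of the intraobserver (units =
  observers) and interobserver (units = sessions) kappa sets.

Reported values are rounded to 3 decimals with banker's (half-even)
rounding; the JSON report retains full precision alongside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import agreement
from .agreement import (
    ComparisonResult,
    KappaEstimate,
    PairwiseKappaSummary,
    interpret_kappa,
)
from .ratings import (
    RatingTable,
    RatingValidationError,
    ValidationIssue,
    validate_rating_frame,
)

__all__ = [
    "StudyReport",
    "run_study",
    "validate_ratings",
    "round_half_even",
    "mean_kappa",
]

logger = logging.getLogger(__name__)


def round_half_even(value: float, ndigits: int = 3) -> float:
    """Round to ``ndigits`` decimals with ties going to the even digit."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_EVEN))


def mean_kappa(values: Sequence[float], ndigits: int = 3) -> float:
    """Aggregate a set of kappas as their arithmetic mean, rounded.

    This is the aggregation step used for the per-system summary rows of
    the report tables (e.g. the mean over the three sessions'
    interobserver kappas).
    """
    values = list(values)
    if not values:
        raise ValueError("cannot average an empty kappa set")
    return round_half_even(float(np.mean(values)), ndigits)


@dataclass
class StudyReport:
    """Structured output of :func:`run_study`.

    Dictionary attributes are keyed by the obvious tuples (observer,
    system), (session, system) or system name; ``metadata`` records the
    study dimensions and any analyses skipped for lack of data.
    """

    intraobserver: dict[tuple[str, str], KappaEstimate]
    intraobserver_mean: dict[str, dict]
    interobserver: dict[tuple[str, str], KappaEstimate]
    interobserver_mean: dict[str, dict]
    pairwise_means: dict[tuple[str, str], PairwiseKappaSummary]
    drift: dict[tuple[str, str], dict[tuple[str, str], KappaEstimate]]
    comparisons: dict[str, ComparisonResult]
    metadata: dict = field(default_factory=dict)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        def est(e: KappaEstimate) -> dict:
            d = e.to_dict()
            d["kappa_rounded"] = round_half_even(d["kappa"])
            return d

        return {
            "metadata": self.metadata,
            "intraobserver": {
                f"{obs}|{system}": est(e) for (obs, system), e in self.intraobserver.items()
            },
            "intraobserver_mean": self.intraobserver_mean,
            "interobserver": {
                f"{session}|{system}": est(e)
                for (session, system), e in self.interobserver.items()
            },
            "interobserver_mean": self.interobserver_mean,
            "pairwise_means": {
                f"{session}|{system}": {
                    "mean_kappa": s.mean_kappa,
                    "mean_kappa_rounded": round_half_even(s.mean_kappa),
                    "interpretation": s.interpretation,
                    "n_pairs": s.n_pairs,
                    "pairs": {f"{a}|{b}": est(e) for (a, b), e in s.pair_kappas.items()},
                    "excluded_pairs": [list(p) for p in s.excluded_pairs],
                }
                for (session, system), s in self.pairwise_means.items()
            },
            "drift": {
                f"{obs}|{system}": {f"{s1}|{s2}": est(e) for (s1, s2), e in pairs.items()}
                for (obs, system), pairs in self.drift.items()
            },
            "comparisons": {name: c.to_dict() for name, c in self.comparisons.items()},
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_jsonify)

    # -- report tables ------------------------------------------------------

    def _systems(self) -> list[str]:
        return self.metadata.get("systems", [])

    def table3(self) -> pd.DataFrame:
        """Intraobserver kappas: observers x systems plus aggregate rows."""
        systems = self._systems()
        observers = self.metadata.get("observers", [])
        rows = []
        for obs in observers:
            row = {"observer": obs}
            for system in systems:
                e = self.intraobserver.get((obs, system))
                row[system] = round_half_even(e.kappa) if e else np.nan
            rows.append(row)
        mean_row = {"observer": "Mean"}
        pooled_row = {"observer": "Pooled"}
        for system in systems:
            agg = self.intraobserver_mean.get(system, {})
            mean_row[system] = agg.get("mean_of_observers_rounded", np.nan)
            pooled_row[system] = (
                round_half_even(agg["pooled"]["kappa"]) if "pooled" in agg else np.nan
            )
        rows.extend([mean_row, pooled_row])
        return pd.DataFrame(rows)

    def table4(self) -> pd.DataFrame:
        """Interobserver kappas: sessions x systems plus the mean row."""
        systems = self._systems()
        sessions = self.metadata.get("sessions", [])
        rows = []
        for session in sessions:
            row = {"session": session}
            for system in systems:
                e = self.interobserver.get((session, system))
                row[system] = round_half_even(e.kappa) if e else np.nan
            rows.append(row)
        mean_row = {"session": "Mean"}
        for system in systems:
            mean_row[system] = self.interobserver_mean.get(system, {}).get("mean_rounded", np.nan)
        rows.append(mean_row)
        return pd.DataFrame(rows)

    def table5(self) -> pd.DataFrame:
        """Cross-system comparison p-values for intra- and interobserver sets."""
        intra = self.comparisons.get("intraobserver")
        inter = self.comparisons.get("interobserver")
        rows = []
        if intra is not None and inter is not None:
            rows.append(
                {
                    "comparison": ", ".join(intra.groups),
                    "intraobserver_p": round_half_even(intra.p_value, 3),
                    "interobserver_p": round_half_even(inter.p_value, 3),
                }
            )
            for pair in intra.pairwise:
                rows.append(
                    {
                        "comparison": " versus ".join(pair),
                        "intraobserver_p": round_half_even(intra.pairwise[pair][1], 3),
                        "interobserver_p": round_half_even(inter.pairwise[pair][1], 3),
                    }
                )
        return pd.DataFrame(rows)

    def write_tables(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.table3().to_csv(directory / "table3.csv", index=False)
        self.table4().to_csv(directory / "table4.csv", index=False)
        self.table5().to_csv(directory / "table5.csv", index=False)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)!r}")


def validate_ratings(
    source: str | Path | pd.DataFrame,
    alphabets: Mapping[str, Sequence[str]] | None = None,
    on_error: str = "raise",
) -> tuple[RatingTable, list[ValidationIssue]]:
    """Load and validate a long-format rating CSV (or frame).

    Returns the typed table together with the full issue inventory
    (warnings included).  With ``on_error="raise"`` (default) any hard
    error aborts with :class:`RatingValidationError`; with
    ``on_error="drop"`` the offending rows are removed and reported as
    issues instead.
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, dtype=str)
    else:
        df = source.copy()
    issues = validate_rating_frame(df, alphabets)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        if on_error == "raise":
            raise RatingValidationError(errors)
        if on_error != "drop":
            raise ValueError(f"on_error must be 'raise' or 'drop', got {on_error!r}")
        bad_rows = sorted({i.row for i in errors if i.row is not None})
        df = df.reset_index(drop=True).drop(index=bad_rows)
        logger.warning("dropped %d invalid rating rows", len(bad_rows))
    table = RatingTable(df, alphabets=alphabets)
    return table, issues


def run_study(
    table: RatingTable,
    confidence_level: float = 0.95,
    permutations: int | None = None,
    seed: int | None = None,
    metadata: Mapping | None = None,
) -> StudyReport:
    """Run the complete agreement analysis on a rating table.

    Requires at least 2 observers and 2 sessions.  Analyses that lack
    sufficient data (e.g. an observer missing a whole session) are skipped
    with a log warning and recorded under ``metadata["skipped"]`` rather
    than reported as silent zeros.  The optional permutation test
    supplements the F-test comparisons.
    """
    observers = list(table.observers)
    sessions = list(table.sessions)
    systems = list(table.systems)
    if len(observers) < 2:
        raise ValueError("study analysis requires at least 2 observers")
    if len(sessions) < 2:
        raise ValueError("study analysis requires at least 2 sessions")

    skipped: list[dict] = []

    def _try(what: str, func, *args, **kwargs):
        try:
            return func(*args, **kwargs)
        except ValueError as exc:
            logger.warning("skipping %s: %s", what, exc)
            skipped.append({"analysis": what, "reason": str(exc)})
            return None

    intra: dict[tuple[str, str], KappaEstimate] = {}
    drift: dict[tuple[str, str], dict[tuple[str, str], KappaEstimate]] = {}
    for system in systems:
        for obs in observers:
            est = _try(
                f"intraobserver ({obs}, {system})",
                agreement.intraobserver_kappa,
                table, obs, system, confidence_level,
            )
            if est is not None:
                intra[(obs, system)] = est
            pairs = _try(
                f"session drift ({obs}, {system})",
                agreement.session_drift,
                table, obs, system, confidence_level,
            )
            if pairs is not None:
                drift[(obs, system)] = pairs

    intra_mean: dict[str, dict] = {}
    for system in systems:
        per_obs = {obs: intra[(obs, system)] for obs in observers if (obs, system) in intra}
        if not per_obs:
            continue
        kappas = [e.kappa for e in per_obs.values()]
        agg: dict = {
            "mean_of_observers": float(np.mean(kappas)),
            "mean_of_observers_rounded": mean_kappa(kappas),
            "n_observers": len(kappas),
            "interpretation": interpret_kappa(float(np.mean(kappas))),
        }
        pooled = _try(
            f"pooled intraobserver ({system})",
            _pooled_intraobserver,
            table, system, confidence_level,
        )
        if pooled is not None:
            agg["pooled"] = pooled.to_dict()
        intra_mean[system] = agg

    inter: dict[tuple[str, str], KappaEstimate] = {}
    pairwise: dict[tuple[str, str], PairwiseKappaSummary] = {}
    for system in systems:
        for session in sessions:
            est = _try(
                f"interobserver ({session}, {system})",
                agreement.interobserver_kappa,
                table, session, system, confidence_level,
            )
            if est is not None:
                inter[(session, system)] = est
            summary = _try(
                f"pairwise kappas ({session}, {system})",
                agreement.pairwise_mean_kappa,
                table, session, system, confidence_level,
            )
            if summary is not None:
                pairwise[(session, system)] = summary

    inter_mean: dict[str, dict] = {}
    for system in systems:
        kappas = [inter[(s, system)].kappa for s in sessions if (s, system) in inter]
        if not kappas:
            continue
        inter_mean[system] = {
            "mean": float(np.mean(kappas)),
            "mean_rounded": mean_kappa(kappas),
            "n_sessions": len(kappas),
            "interpretation": interpret_kappa(float(np.mean(kappas))),
        }

    comparisons: dict[str, ComparisonResult] = {}
    intra_groups = {
        system: [intra[(obs, system)].kappa for obs in observers if (obs, system) in intra]
        for system in systems
    }
    intra_groups = {k: v for k, v in intra_groups.items() if len(v) >= 2}
    if len(intra_groups) >= 2:
        comparisons["intraobserver"] = agreement.compare_kappa_sets(
            intra_groups, permutations=permutations, seed=seed
        )
    inter_groups = {
        system: [inter[(s, system)].kappa for s in sessions if (s, system) in inter]
        for system in systems
    }
    inter_groups = {k: v for k, v in inter_groups.items() if len(v) >= 2}
    if len(inter_groups) >= 2:
        comparisons["interobserver"] = agreement.compare_kappa_sets(
            inter_groups, permutations=permutations, seed=seed
        )

    meta = {
        "n_subjects": len(table.subjects),
        "n_observers": len(observers),
        "n_sessions": len(sessions),
        "n_ratings": len(table),
        "observers": observers,
        "sessions": sessions,
        "systems": systems,
        "confidence_level": confidence_level,
        "skipped": skipped,
    }
    if metadata:
        meta.update(dict(metadata))

    return StudyReport(
        intraobserver=intra,
        intraobserver_mean=intra_mean,
        interobserver=inter,
        interobserver_mean=inter_mean,
        pairwise_means=pairwise,
        drift=drift,
        comparisons=comparisons,
        metadata=meta,
    )


def _pooled_intraobserver(
    table: RatingTable, system: str, confidence_level: float
) -> KappaEstimate:
    """Pooled intraobserver kappa: all (subject, observer) session panels
    stacked as units of a single Fleiss kappa."""
    frames = []
    for obs in table.observers:
        pivot = table.pivot(system, columns="session", observer=obs).dropna(axis=0)
        if len(pivot):
            pivot = pivot.set_axis([f"{obs}|{s}" for s in pivot.index], axis=0)
            frames.append(pivot)
    if not frames:
        raise ValueError(f"no complete session panels for {system}")
    stacked = pd.concat(frames, axis=0)
    return agreement.fleiss_kappa_from_labels(
        stacked, categories=table.labels_for(system), confidence_level=confidence_level
    )
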