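"""Shared fixtures: tiny hand-built rating tables and simulated studies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from idealdrf import (
    CaseGeneratorConfig,
    RatingTable,
    default_observer_panel,
    generate_cases,
    simulate_ratings,
)


def make_rating_records(labels_by_observer_session, system="IDEAL", subjects=None):
    """Build long-format records from {observer: {session: [labels...]}}."""
    records = []
    for observer, sessions in labels_by_observer_session.items():
        for session, labels in sessions.items():
            ids = subjects or [f"S{i + 1:02d}" for i in range(len(labels))]
            for subject, label in zip(ids, labels):
                records.append((subject, observer, session, system, label))
    return records


@pytest.fixture
def perfect_table():
    """Two observers, three sessions, everyone repeats the same labels."""
    labels = ["I", "II", "III", "II", "I", "III"]
    records = make_rating_records(
        {
            "obs_a": {"T1": labels, "T2": labels, "T3": labels},
            "obs_b": {"T1": labels, "T2": labels, "T3": labels},
        }
    )
    return RatingTable.from_records(records)


@pytest.fixture(scope="session")
def small_simulated_study():
    """A compact simulated study reused across pipeline tests."""
    cases = generate_cases(CaseGeneratorConfig(n_cases=30, seed=11))
    panel = default_observer_panel()[:4]
    table = simulate_ratings(cases, panel, n_sessions=3, seed=11)
    return cases, panel, table
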