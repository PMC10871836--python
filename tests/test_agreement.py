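"""Tests for kappa estimation, interpretation and cross-system comparison.

Brute-force oracles: Cohen's kappa is recomputed directly from the
cross-tabulation, Fleiss's from the per-subject agreement and category
shares, independently of the library code paths; statsmodels provides an
additional third-party cross-check.
"""

import itertools
import warnings
from collections import Counter
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from idealdrf import (
    EXCELLENT,
    SATISFACTORY,
    UNSATISFACTORY,
    RatingTable,
    cohen_kappa,
    compare_kappa_sets,
    fleiss_kappa,
    fleiss_kappa_from_labels,
    interobserver_kappa,
    interpret_kappa,
    intraobserver_kappa,
    pairwise_mean_kappa,
    session_drift,
)
from idealdrf.agreement import DegeneratePairWarning, IncompleteRatingsWarning

from conftest import make_rating_records


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def cohen_oracle(a, b):
    """Cohen kappa straight from the cross-tabulation, in exact arithmetic."""
    n = len(a)
    joint = Counter(zip(a, b))
    ma, mb = Counter(a), Counter(b)
    p_o = Fraction(sum(c for (x, y), c in joint.items() if x == y), n)
    p_e = sum(Fraction(ma[c], n) * Fraction(mb[c], n) for c in set(a) | set(b))
    if p_e == 1:
        return None
    return float((p_o - p_e) / (1 - p_e))


def fleiss_oracle(counts):
    """Fleiss kappa from per-subject agreement P_i and category shares p_j."""
    counts = np.asarray(counts)
    n, _ = counts.shape
    m = counts.sum(axis=1)[0]
    p_j = [Fraction(int(c), int(n * m)) for c in counts.sum(axis=0)]
    p_e = sum(p**2 for p in p_j)
    if p_e == 1:
        return None
    p_i = [
        Fraction(int(np.sum(row**2) - m), int(m * (m - 1))) for row in counts
    ]
    p_o = sum(p_i) / n
    return float((p_o - p_e) / (1 - p_e))


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

class TestCohenKappa:
    def test_perfect_agreement(self):
        est = cohen_kappa(list("abcabc"), list("abcabc"))
        assert est.kappa == 1.0
        assert not est.degenerate
        assert est.interpretation == EXCELLENT

    def test_symmetric_complete_disagreement(self):
        est = cohen_kappa(["x", "y"], ["y", "x"])
        assert est.kappa == -1.0

    def test_matches_crosstab_oracle_on_random_sample(self):
        rng = np.random.default_rng(42)
        a = rng.choice(list("abc"), size=200, p=[0.5, 0.3, 0.2]).tolist()
        # rater B agrees with A 70% of the time, else uniform.
        b = [
            x if rng.random() < 0.7 else rng.choice(list("abc"))
            for x in a
        ]
        est = cohen_kappa(a, b)
        assert est.kappa == pytest.approx(cohen_oracle(a, b), abs=1e-12)

    def test_matches_statsmodels_point_and_variance(self):
        inter_rater = pytest.importorskip("statsmodels.stats.inter_rater")
        rng = np.random.default_rng(7)
        a = rng.choice(list("abc"), size=120).tolist()
        b = rng.choice(list("abc"), size=120).tolist()
        table = np.zeros((3, 3))
        for x, y in zip(a, b):
            table["abc".index(x), "abc".index(y)] += 1
        ref = inter_rater.cohens_kappa(table, return_results=True)
        est = cohen_kappa(a, b)
        assert est.kappa == pytest.approx(ref.kappa, abs=1e-12)
        assert est.standard_error == pytest.approx(ref.var_kappa**0.5, rel=1e-9)

    def test_degenerate_constant_identical_raters(self):
        est = cohen_kappa(["a", "a", "a"], ["a", "a", "a"])
        assert est.degenerate
        assert est.kappa == 1.0
        assert est.standard_error == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(["a", "b"], ["a"])
        with pytest.raises(ValueError):
            cohen_kappa(["a"], ["a"])

    @given(
        labels=st.lists(
            st.tuples(st.sampled_from("abc"), st.sampled_from("abc")),
            min_size=2,
            max_size=10,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_and_range(self, labels):
        a, b = zip(*labels)
        est_ab = cohen_kappa(a, b)
        est_ba = cohen_kappa(b, a)
        assert -1.0 - 1e-12 <= est_ab.kappa <= 1.0 + 1e-12
        assert est_ab.kappa == pytest.approx(est_ba.kappa, abs=1e-12)
        assert est_ab.ci_low <= est_ab.kappa <= est_ab.ci_high

    @given(
        labels=st.lists(
            st.tuples(st.sampled_from("abc"), st.sampled_from("abc")),
            min_size=2,
            max_size=10,
        ),
        perm=st.permutations("abc"),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariance_under_category_relabeling(self, labels, perm):
        a, b = zip(*labels)
        mapping = dict(zip("abc", perm))
        a2 = [mapping[x] for x in a]
        b2 = [mapping[x] for x in b]
        assert cohen_kappa(a, b).kappa == pytest.approx(
            cohen_kappa(a2, b2).kappa, abs=1e-12
        )


# ---------------------------------------------------------------------------
# Fleiss's kappa
# ---------------------------------------------------------------------------

class TestFleissKappa:
    def test_unanimous_raters_give_kappa_one(self):
        counts = [[3, 0], [0, 3], [3, 0], [0, 3]]
        est = fleiss_kappa(counts)
        assert est.kappa == 1.0
        assert not est.degenerate

    def test_small_fixture_matches_direct_formula(self):
        counts = [[3, 0, 0], [0, 3, 0], [1, 1, 1], [2, 0, 1]]
        est = fleiss_kappa(counts)
        assert est.kappa == pytest.approx(7 / 22, abs=1e-12)  # frozen from the oracle
        assert est.kappa == pytest.approx(fleiss_oracle(counts), abs=1e-12)

    def test_matches_statsmodels_point_estimate(self):
        inter_rater = pytest.importorskip("statsmodels.stats.inter_rater")
        rng = np.random.default_rng(3)
        counts = rng.multinomial(4, [0.5, 0.3, 0.2], size=25)
        est = fleiss_kappa(counts)
        assert est.kappa == pytest.approx(
            inter_rater.fleiss_kappa(counts, method="fleiss"), abs=1e-12
        )

    def test_random_ratings_near_zero(self):
        # Uniformly random ratings: kappa ~ 0 within 3 Monte-Carlo SEs.
        rng = np.random.default_rng(2024)
        n, m, k = 600, 4, 3
        labels = rng.integers(0, k, size=(n, m))
        counts = np.stack([np.bincount(row, minlength=k) for row in labels])
        est = fleiss_kappa(counts)
        assert abs(est.kappa) <= 3 * est.standard_error

    def test_two_raters_reduces_to_pair_case(self):
        rng = np.random.default_rng(5)
        a = rng.choice(list("ab"), size=40)
        b = rng.choice(list("ab"), size=40)
        counts = np.stack(
            [np.bincount(["ab".index(x), "ab".index(y)], minlength=2) for x, y in zip(a, b)]
        )
        est = fleiss_kappa(counts, raters_per_subject=2)
        assert est.n_raters == 2
        assert -1.0 <= est.kappa <= 1.0

    def test_ragged_rows_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            fleiss_kappa([[2, 1], [1, 1]])

    def test_single_category_mass_is_degenerate(self):
        est = fleiss_kappa([[3, 0], [3, 0], [3, 0]])
        assert est.degenerate
        assert est.kappa == 1.0

    @given(
        rows=st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 3)).filter(lambda t: sum(t) == 3),
            min_size=2,
            max_size=8,
        ),
        order=st.randoms(use_true_random=False),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_invariance_to_subject_order_and_category_swap(self, rows, order):
        counts = np.array(rows)
        est = fleiss_kappa(counts)
        perm = order.sample(range(len(counts)), len(counts))
        shuffled = counts[perm]
        swapped = counts[:, ::-1]
        assert fleiss_kappa(shuffled).kappa == pytest.approx(est.kappa, abs=1e-12)
        assert fleiss_kappa(swapped).kappa == pytest.approx(est.kappa, abs=1e-12)


# ---------------------------------------------------------------------------
# Interpretation bands
# ---------------------------------------------------------------------------

class TestInterpretation:
    @pytest.mark.parametrize(
        "kappa, band",
        [
            (0.771, EXCELLENT),
            (0.344, UNSATISFACTORY),
            (0.595, SATISFACTORY),
            (0.5, SATISFACTORY),   # boundary: inclusive
            (0.75, SATISFACTORY),  # boundary: inclusive
            (0.499999, UNSATISFACTORY),
            (0.750001, EXCELLENT),
            (-1.0, UNSATISFACTORY),
            (1.0, EXCELLENT),
        ],
    )
    def test_band_mapping(self, kappa, band):
        assert interpret_kappa(kappa) == band

    @pytest.mark.parametrize("bad", [1.5, -1.2, float("nan")])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            interpret_kappa(bad)


# ---------------------------------------------------------------------------
# RatingTable arrangements
# ---------------------------------------------------------------------------

class TestTableArrangements:
    def test_identical_sessions_give_intraobserver_one(self, perfect_table):
        est = intraobserver_kappa(perfect_table, "obs_a", "IDEAL")
        assert est.kappa == 1.0
        assert est.n_raters == 3  # sessions as replicate raters

    def test_two_sessions_reduce_to_two_replicate_fleiss(self):
        labels_t1 = ["I", "II", "III", "I", "II"]
        labels_t2 = ["I", "II", "II", "I", "III"]
        records = make_rating_records({"obs": {"T1": labels_t1, "T2": labels_t2}})
        table = RatingTable.from_records(records)
        est = intraobserver_kappa(table, "obs", "IDEAL")
        matrix = np.array([labels_t1, labels_t2]).T
        direct = fleiss_kappa_from_labels(matrix, categories=("I", "II", "III"))
        assert est.n_raters == 2
        assert est.kappa == pytest.approx(direct.kappa, abs=1e-12)

    def test_incomplete_subjects_dropped_with_warning(self):
        records = make_rating_records(
            {"obs": {"T1": ["I", "II", "III"], "T2": ["I", "II", "III"]}}
        )
        records.append(("S99", "obs", "T1", "IDEAL", "I"))  # no T2 rating
        table = RatingTable.from_records(records)
        with pytest.warns(IncompleteRatingsWarning):
            est = intraobserver_kappa(table, "obs", "IDEAL")
        assert est.n_dropped_subjects == 1
        assert est.n_subjects == 3

    def test_fewer_than_two_complete_subjects_is_error(self):
        records = [
            ("S1", "obs", "T1", "IDEAL", "I"),
            ("S1", "obs", "T2", "IDEAL", "I"),
            ("S2", "obs", "T1", "IDEAL", "II"),
        ]
        table = RatingTable.from_records(records)
        with pytest.warns(IncompleteRatingsWarning):
            with pytest.raises(ValueError, match="fewer than 2"):
                intraobserver_kappa(table, "obs", "IDEAL")

    def test_session_drift_identical_labels(self, perfect_table):
        drift = session_drift(perfect_table, "obs_a", "IDEAL")
        assert set(drift) == {("T1", "T2"), ("T2", "T3")}
        assert all(est.kappa == 1.0 for est in drift.values())

    def test_interobserver_all_agree(self, perfect_table):
        est = interobserver_kappa(perfect_table, "T1", "IDEAL")
        assert est.kappa == 1.0
        assert est.n_raters == 2

    def test_interobserver_two_observers_equals_fleiss_m2(self):
        rng = np.random.default_rng(9)
        la = rng.choice(["I", "II", "III"], size=20).tolist()
        lb = rng.choice(["I", "II", "III"], size=20).tolist()
        records = make_rating_records({"a": {"T1": la}, "b": {"T1": lb}})
        table = RatingTable.from_records(records)
        est = interobserver_kappa(table, "T1", "IDEAL")
        direct = fleiss_kappa_from_labels(
            np.array([la, lb]).T, categories=("I", "II", "III")
        )
        assert est.kappa == pytest.approx(direct.kappa, abs=1e-12)

    def test_pairwise_mean_equals_bruteforce_pair_enumeration(self):
        rng = np.random.default_rng(13)
        observers = {f"o{i}": {"T1": rng.choice(["I", "II", "III"], size=25).tolist()}
                     for i in range(6)}
        table = RatingTable.from_records(make_rating_records(observers))
        summary = pairwise_mean_kappa(table, "T1", "IDEAL")
        # Brute force: enumerate the 15 pairs independently.
        oracle_values = []
        for o1, o2 in itertools.combinations(sorted(observers), 2):
            oracle_values.append(cohen_oracle(observers[o1]["T1"], observers[o2]["T1"]))
        assert summary.n_pairs == 15
        assert summary.mean_kappa == pytest.approx(np.mean(oracle_values), abs=1e-12)

    def test_pairwise_mean_two_observers_equals_their_cohen(self):
        la = ["I", "II", "III", "I"]
        lb = ["I", "II", "II", "I"]
        table = RatingTable.from_records(
            make_rating_records({"a": {"T1": la}, "b": {"T1": lb}})
        )
        summary = pairwise_mean_kappa(table, "T1", "IDEAL")
        assert summary.mean_kappa == pytest.approx(cohen_kappa(la, lb).kappa, abs=1e-12)

    def test_degenerate_pair_excluded_with_warning(self):
        table = RatingTable.from_records(
            make_rating_records(
                {
                    "a": {"T1": ["I", "I", "I"]},
                    "b": {"T1": ["I", "I", "I"]},
                    "c": {"T1": ["I", "II", "I"]},
                }
            )
        )
        with pytest.warns(DegeneratePairWarning):
            summary = pairwise_mean_kappa(table, "T1", "IDEAL")
        assert ("a", "b") in summary.excluded_pairs
        assert summary.n_pairs == 2


# ---------------------------------------------------------------------------
# Cross-system comparison
# ---------------------------------------------------------------------------

class TestCompareKappaSets:
    def test_identical_groups_give_f_zero_p_one(self):
        result = compare_kappa_sets({"A": [0.5, 0.6], "B": [0.5, 0.6]})
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_matches_sums_of_squares_oracle(self):
        groups = {"A": [0.6, 0.8], "B": [0.2, 0.4]}
        result = compare_kappa_sets(groups)
        # Textbook one-way ANOVA by hand: SSB = 0.16 (df 1), SSW = 0.04 (df 2).
        f_oracle = (0.16 / 1) / (0.04 / 2)
        assert result.statistic == pytest.approx(8.0, abs=1e-9)
        assert result.statistic == pytest.approx(f_oracle, abs=1e-9)
        assert result.p_value == pytest.approx(float(stats.f.sf(8.0, 1, 2)), abs=1e-9)

    def test_pairwise_results_cover_all_pairs(self):
        groups = {"A": [0.6, 0.8], "B": [0.2, 0.4], "C": [0.5, 0.55]}
        result = compare_kappa_sets(groups)
        assert set(result.pairwise) == {("A", "B"), ("A", "C"), ("B", "C")}
        for stat, p in result.pairwise.values():
            assert 0.0 <= p <= 1.0

    def test_null_type_one_error_near_nominal(self):
        rng = np.random.default_rng(77)
        alpha, reps = 0.05, 2000
        hits = 0
        for _ in range(reps):
            groups = {name: rng.normal(0.6, 0.1, size=8) for name in "AB"}
            if compare_kappa_sets(groups).p_value < alpha:
                hits += 1
        rate = hits / reps
        se = (alpha * (1 - alpha) / reps) ** 0.5
        assert abs(rate - alpha) <= 3 * se

    def test_permutation_p_value_agrees_with_f_test_roughly(self):
        rng = np.random.default_rng(5)
        groups = {
            "A": rng.normal(0.7, 0.05, size=6),
            "B": rng.normal(0.4, 0.05, size=6),
        }
        result = compare_kappa_sets(groups, permutations=400, seed=1)
        assert result.permutation_p_value is not None
        assert result.p_value < 0.01
        assert result.permutation_p_value < 0.05

    def test_all_constant_flagged_degenerate(self):
        result = compare_kappa_sets({"A": [0.5, 0.5], "B": [0.5, 0.5]})
        assert result.degenerate
        assert result.p_value == 1.0
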