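"""Preference pairs, percent agreement, Cohen's kappa, and table aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vqmselect.agreement import (
    PreferencePair,
    RaterResponse,
    aggregate_overall,
    average_kappa,
    cohens_kappa,
    computer_responses,
    contingency_table,
    kappa_category,
    make_preference_pairs,
    percent_agreement,
    simulate_rater,
)
from vqmselect.datasets import COMPARISONS, OBSERVER_STUDY, REPORTED_OVERALL
from vqmselect.vqm import SelectionResult


def make_selections(n):
    return [
        SelectionResult(
            group_id=i,
            best=("70%", f"b{i}"),
            worst=("40%", f"b{i}"),
            ranking=[("70%", f"b{i}", 100.0), ("40%", f"b{i}", 50.0)],
            pairable=True,
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# pair construction
# ---------------------------------------------------------------------------

def test_one_pair_per_pairable_group_and_determinism():
    sels = make_selections(167)
    sels[10] = SelectionResult(10, ("70%", "x"), ("70%", "x"), [("70%", "x", 1.0)], False)
    pairs = make_preference_pairs(sels, seed=17)
    assert len(pairs) == 166  # non-pairable group skipped
    again = make_preference_pairs(sels, seed=17)
    assert [p.computer_best_side for p in pairs] == [p.computer_best_side for p in again]
    assert all(
        (p.left, p.right) in {(s.best, s.worst), (s.worst, s.best)}
        for p, s in zip(pairs, [s for s in sels if s.pairable])
    )


def test_side_randomization_is_balanced():
    pairs = make_preference_pairs(make_selections(10000), seed=3)
    frac_left = np.mean([p.computer_best_side == "left" for p in pairs])
    assert abs(frac_left - 0.5) <= 0.02


def test_pair_invariants():
    with pytest.raises(ValueError):
        PreferencePair(0, ("a", "b"), ("a", "b"), "left", 0)
    with pytest.raises(ValueError):
        PreferencePair(0, ("a", "b"), ("a", "c"), "top", 0)


# ---------------------------------------------------------------------------
# percent agreement
# ---------------------------------------------------------------------------

def test_percent_agreement_cases():
    a = [RaterResponse(i, "left") for i in range(4)]
    assert percent_agreement(a, a) == 1.0
    opposite = [RaterResponse(i, "right") for i in range(4)]
    assert percent_agreement(a, opposite) == 0.0
    three_of_four = [RaterResponse(i, "left" if i < 3 else "right") for i in range(4)]
    assert percent_agreement(a, three_of_four) == 0.75
    with pytest.raises(ValueError):
        percent_agreement(a, [RaterResponse(99, "left")])


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

def test_kappa_hand_cases():
    assert cohens_kappa([[10, 0], [0, 10]]) == 1.0
    assert cohens_kappa([[10, 5], [5, 10]]) == pytest.approx(1 / 3, abs=1e-12)
    assert cohens_kappa([[5, 5], [5, 5]]) == 0.0
    # perfect observed agreement with degenerate marginals: kappa = 1 by convention
    assert cohens_kappa([[10, 0], [0, 0]]) == 1.0
    with pytest.raises(ValueError):
        cohens_kappa([[0, 0], [0, 0]])


@settings(deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 30), min_size=4, max_size=4))
def test_kappa_symmetric_and_bounded(cells):
    t = np.array(cells).reshape(2, 2)
    if t.sum() == 0:
        return
    k = cohens_kappa(t)
    assert k <= 1.0 + 1e-12
    assert cohens_kappa(t.T) == pytest.approx(k, abs=1e-12)
    # simultaneous relabelling of both raters' categories
    assert cohens_kappa(t[::-1, ::-1]) == pytest.approx(k, abs=1e-12)


def test_kappa_matches_sklearn_on_random_responses(rng):
    from sklearn.metrics import cohen_kappa_score

    for _ in range(20):
        n = int(rng.integers(5, 60))
        a = rng.integers(0, 2, size=n)
        b = rng.integers(0, 2, size=n)
        ra = [RaterResponse(i, "left" if x else "right") for i, x in enumerate(a)]
        rb = [RaterResponse(i, "left" if x else "right") for i, x in enumerate(b)]
        ours = cohens_kappa(contingency_table(ra, rb))
        theirs = cohen_kappa_score(a, b)
        if np.isnan(theirs):  # sklearn yields nan for degenerate perfect tables
            assert ours == 1.0
        else:
            assert ours == pytest.approx(theirs, abs=1e-12)


def test_kappa_zero_when_observed_equals_chance(rng):
    # independent marginals: Po == Pe exactly for outer-product tables
    t = np.array([[9, 3], [3, 1]])  # rows/cols proportional -> po = pe
    assert cohens_kappa(t) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# category bins
# ---------------------------------------------------------------------------

def test_kappa_category_examples():
    assert kappa_category(0.49) == "Moderate"
    assert kappa_category(-0.13) == "Less than chance"
    assert kappa_category(0.87) == "Almost perfect"
    assert kappa_category(1.0) == "Almost perfect"
    with pytest.raises(ValueError):
        kappa_category(1.5)


def test_all_published_kappas_map_to_published_categories():
    for comp in COMPARISONS:
        got = [kappa_category(k) for k in OBSERVER_STUDY["kappa"][comp]]
        assert got == OBSERVER_STUDY["kappa_category"][comp]


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def test_aggregate_overall_reproduces_published_percents():
    n = OBSERVER_STUDY["n_pairs"]
    for comp in COMPARISONS:
        got = aggregate_overall(OBSERVER_STUDY["percent_agreement"][comp], n)
        assert got == REPORTED_OVERALL["percent_agreement"][comp]


def test_aggregate_overall_simple_cases():
    assert aggregate_overall([100], [7]) == 100
    assert aggregate_overall([50, 100], [10, 10]) == 75
    with pytest.raises(ValueError):
        aggregate_overall([50], [10, 10])


def test_average_kappa_reproduces_published_means():
    for comp in COMPARISONS:
        got = average_kappa(OBSERVER_STUDY["kappa"][comp])
        assert got == REPORTED_OVERALL["kappa"][comp]


def test_average_kappa_simple_cases():
    assert average_kappa([0.5]) == 0.5
    assert average_kappa([1.0, -1.0]) == 0.0
    with pytest.raises(ValueError):
        average_kappa([])


# ---------------------------------------------------------------------------
# end-to-end simulated observer
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p", [0.7, 0.9])
def test_simulated_rater_agreement_approaches_p(p):
    """With noise-free selection, rater-vs-computer agreement converges to p."""
    sels = make_selections(500)
    pairs = make_preference_pairs(sels, seed=23)
    true_best = {s.group_id: s.best for s in sels}  # selection is correct here
    rater = simulate_rater(pairs, true_best, p_correct=p, seed=41)
    agreement = percent_agreement(computer_responses(pairs), rater)
    assert abs(agreement - p) <= 0.05
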