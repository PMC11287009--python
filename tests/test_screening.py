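"""Protocol enumeration, occupancy integrals and the person-years
evaluator."""

import numpy as np
import pytest

from conftest import random_conservative_Q
from oracles import two_state_screen_person_years

from screenmark.fixtures import ckb_like_generator, initial_cohort_from_population
from screenmark.msm import IntensityMatrix, StateSpace
from screenmark.screening import (
    REFERENCE_FOUR,
    REFERENCE_THREE,
    InitialCohort,
    Protocol,
    enumerate_protocols,
    evaluation_generator,
    occupancy_integral,
    occupancy_integral_quadrature,
    person_years_unidentified,
)
from screenmark.screening import _occupancy_columns


# ---------------------------------------------------------------------------
# protocol grid
# ---------------------------------------------------------------------------


def test_three_category_grid_has_nine_protocols_with_reference():
    grid = enumerate_protocols("three_category")
    assert len(grid) == 9
    names = [p.name for p in grid]
    assert "3-3" in names
    assert names.count("3-3") == 1
    for p in grid[1:]:
        assert p.intervals[0] in range(3, 7) and p.intervals[1] in (1, 2)


def test_four_category_grid_has_eighteen_protocols():
    grid = enumerate_protocols("four_category")
    assert len(grid) == 18
    assert "6-3-2" in [p.name for p in grid]
    assert len({p.name for p in grid}) == 18


def test_both_schemes_total_twenty_seven():
    total = len(enumerate_protocols("three_category")) + len(
        enumerate_protocols("four_category")
    )
    assert total == 27


def test_protocol_validation():
    with pytest.raises(ValueError):
        Protocol("bad", "three_category", (0, 2))
    with pytest.raises(ValueError):
        Protocol("bad", "three_category", (3,))


# ---------------------------------------------------------------------------
# evaluation generator
# ---------------------------------------------------------------------------


def test_evaluation_generator_removes_reversals_and_conserves():
    Q = ckb_like_generator("three_category").intensity
    Qe = evaluation_generator(Q)
    h = Qe.space.index("high")
    assert Qe.Q[h, Qe.space.index("intermediate")] == 0.0
    assert np.max(np.abs(Qe.Q.sum(axis=1))) < 1e-14
    # other rows untouched
    for lab in ("low", "intermediate"):
        i = Q.space.index(lab)
        assert np.array_equal(Qe.Q[i], Q.Q[i])
    # idempotent on an already-clean generator
    Qe2 = evaluation_generator(Qe)
    assert np.array_equal(Qe2.Q, Qe.Q)


# ---------------------------------------------------------------------------
# occupancy integral
# ---------------------------------------------------------------------------


def test_occupancy_integral_closed_form(two_state):
    lam, Q = two_state
    got = occupancy_integral(Q, 0, 1, 3.0)
    want = 3.0 - (1 - np.exp(-3 * lam)) / lam
    assert got == pytest.approx(want, abs=1e-12)
    assert occupancy_integral(Q, 0, 1, 0.0) == 0.0
    # started absorbed: occupancy is the whole interval
    assert occupancy_integral(Q, 1, 1, 4.0) == pytest.approx(4.0, abs=1e-12)
    with pytest.raises(ValueError):
        occupancy_integral(Q, 0, 1, -1.0)


@pytest.mark.parametrize("seed", [0, 1])
def test_occupancy_integral_agrees_with_quadrature(seed):
    rng = np.random.default_rng(seed)
    Q = random_conservative_Q(4, rng, absorbing=1)
    for i, j, d in [(0, 2, 3.0), (1, 3, 6.0), (2, 0, 1.0)]:
        a = occupancy_integral(Q, i, j, d)
        b = occupancy_integral_quadrature(Q, i, j, d, step=1.0 / 240.0)
        assert a == pytest.approx(b, abs=1e-6)


# ---------------------------------------------------------------------------
# person-years evaluator
# ---------------------------------------------------------------------------


def toy_protocol(interval):
    return Protocol(str(interval), "toy", (interval,), categories=("low",))


def test_two_state_toy_matches_closed_form(two_state):
    lam, Q = two_state
    res = person_years_unidentified(
        Q, toy_protocol(3), InitialCohort({"low": 1.0}), horizon=10.0
    )
    oracle = two_state_screen_person_years(lam, [3, 3, 3, 1], 10.0)
    assert res.person_years_unidentified == pytest.approx(oracle, abs=1e-8)
    # screens at 3, 6, 9: attendees are everyone not yet identified at an
    # earlier screen (those found high at a screen do attend it)
    want_screens = 1.0 + np.exp(-lam * 3) + np.exp(-lam * 6)
    assert res.expected_screens == pytest.approx(want_screens, abs=1e-8)


def test_toy_person_years_monotone_in_interval(two_state):
    lam, Q = two_state
    py = [
        person_years_unidentified(
            Q, toy_protocol(k), InitialCohort({"low": 1.0}), horizon=10.0
        ).person_years_unidentified
        for k in (1, 3, 6)
    ]
    assert py[0] < py[1] < py[2]


def test_zero_rates_into_high_give_zero_person_years():
    labels = ("low", "intermediate", "high", "ascvd", "non_ascvd_death")
    Q = np.zeros((5, 5))
    Q[0, 1] = 0.1
    Q[1, 0] = 0.05
    Q[0, 3] = Q[1, 3] = 0.01
    np.fill_diagonal(Q, -Q.sum(axis=1))
    IQ = IntensityMatrix(Q, StateSpace.from_intensity_support(labels, Q))
    for proto in enumerate_protocols("three_category"):
        res = person_years_unidentified(
            IQ, proto, InitialCohort({"low": 100.0, "intermediate": 50.0})
        )
        assert res.person_years_unidentified == pytest.approx(0.0, abs=1e-12)


@pytest.fixture(scope="module")
def ckb_eval():
    Q = ckb_like_generator("three_category").intensity
    Qe = evaluation_generator(Q)
    cohort = InitialCohort({"low": 427.40, "intermediate": 151.62})
    return Qe, cohort


def test_mass_conservation_at_every_screen(ckb_eval):
    Qe, cohort = ckb_eval
    for proto in enumerate_protocols("three_category"):
        res = person_years_unidentified(Qe, proto, cohort)
        assert res.total_mass == pytest.approx(cohort.total, rel=1e-8)


def test_person_years_monotone_in_each_interval(ckb_eval):
    Qe, cohort = ckb_eval
    py = {
        p.intervals: person_years_unidentified(Qe, p, cohort).person_years_unidentified
        for p in enumerate_protocols("three_category")
    }
    for (a, b), v in py.items():
        for (a2, b2), v2 in py.items():
            if a2 == a and b2 > b:
                assert v2 >= v - 1e-9
            if b2 == b and a2 > a:
                assert v2 >= v - 1e-9


def test_horizon_zero_gives_zero_person_years(ckb_eval):
    Qe, cohort = ckb_eval
    res = person_years_unidentified(Qe, REFERENCE_THREE, cohort, horizon=0.0)
    assert res.person_years_unidentified == 0.0
    assert res.expected_screens == 0.0


def test_four_category_lumps_to_three_when_intermediates_identical():
    """Splitting the intermediate state into two lumpable halves with equal
    screening intervals must reproduce the three-category person-years."""
    labels3 = ("low", "intermediate", "high", "ascvd", "non_ascvd_death")
    Q3 = np.zeros((5, 5))
    Q3[0, [1, 2, 3, 4]] = [0.08, 0.004, 0.002, 0.004]
    Q3[1, [0, 2, 3, 4]] = [0.014, 0.158, 0.008, 0.009]
    Q3[2, [3, 4]] = [0.017, 0.13]
    np.fill_diagonal(Q3, -Q3.sum(axis=1))
    IQ3 = IntensityMatrix(Q3, StateSpace.from_intensity_support(labels3, Q3))

    labels4 = ("low", "intermediate_low", "intermediate_high", "high",
               "ascvd", "non_ascvd_death")
    Q4 = np.zeros((6, 6))
    # low splits its intermediate inflow between the halves
    Q4[0, [1, 2, 3, 4, 5]] = [0.05, 0.03, 0.004, 0.002, 0.004]
    # both halves leave each lumped class at identical rates; internal mixing
    # between the halves is allowed
    for i in (1, 2):
        Q4[i, [0, 3, 4, 5]] = [0.014, 0.158, 0.008, 0.009]
    Q4[1, 2] = 0.07
    Q4[2, 1] = 0.02
    Q4[3, [4, 5]] = [0.017, 0.13]
    np.fill_diagonal(Q4, -Q4.sum(axis=1))
    IQ4 = IntensityMatrix(Q4, StateSpace.from_intensity_support(labels4, Q4))

    cohort3 = InitialCohort({"low": 10.0, "intermediate": 6.0})
    cohort4 = InitialCohort(
        {"low": 10.0, "intermediate_low": 2.5, "intermediate_high": 3.5}
    )
    for lo, mid in [(3, 3), (6, 2), (4, 1)]:
        r3 = person_years_unidentified(
            IQ3, Protocol(f"{lo}-{mid}", "three_category", (lo, mid)), cohort3
        )
        r4 = person_years_unidentified(
            IQ4, Protocol(f"{lo}-{mid}-{mid}", "four_category", (lo, mid, mid)),
            cohort4,
        )
        assert r4.person_years_unidentified == pytest.approx(
            r3.person_years_unidentified, abs=1e-8
        )
        assert r4.expected_screens == pytest.approx(
            r3.expected_screens, abs=1e-8
        )


def test_annual_mode_close_to_continuous(ckb_eval):
    Qe, cohort = ckb_eval
    cont = person_years_unidentified(Qe, REFERENCE_THREE, cohort, mode="continuous")
    ann = person_years_unidentified(Qe, REFERENCE_THREE, cohort, mode="annual")
    # the discretisation changes the number, not its order of magnitude
    assert ann.person_years_unidentified == pytest.approx(
        cont.person_years_unidentified, rel=0.25
    )


def test_category_mismatch_rejected(ckb_eval):
    Qe, _ = ckb_eval
    with pytest.raises(ValueError, match="categories"):
        person_years_unidentified(
            Qe, REFERENCE_THREE, InitialCohort({"low": 1.0, "unknown": 1.0})
        )


def test_retained_reversal_rate_rejected():
    Q = ckb_like_generator("three_category").intensity
    with pytest.raises(ValueError, match="high"):
        person_years_unidentified(
            Q, REFERENCE_THREE, InitialCohort({"low": 1.0, "intermediate": 1.0})
        )
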