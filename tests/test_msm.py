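"""Core multistate-model machinery: transition probabilities, panel
likelihood, fitting, and summaries of the generator."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_conservative_Q
from oracles import ode_panel_loglik, uniformization_expm

from screenmark.msm import (
    FittedModel,
    IntensityMatrix,
    PanelData,
    PanelLikelihood,
    StateSpace,
    crude_init,
    expected_prevalence,
    fit,
    jump_probabilities,
    mean_sojourn,
    panel_loglik,
    transition_matrices,
    transition_matrix,
    uncertainty_draws,
)


def make_panel(rows):
    return PanelData(
        pd.DataFrame(rows, columns=["subject_id", "time_years", "state", "obs_type"])
    )


@pytest.fixture()
def exp_space():
    """Transient state 'a' decaying into absorbing 'b'."""
    return StateSpace(("a", "b"), (True, False), np.array([[False, True], [False, False]]))


# ---------------------------------------------------------------------------
# state space / intensity validation
# ---------------------------------------------------------------------------


def test_state_space_rejects_outgoing_from_absorbing():
    with pytest.raises(ValueError, match="absorbing"):
        StateSpace(("a", "b"), (True, False), np.array([[False, True], [True, False]]))


def test_intensity_matrix_rejects_disallowed_and_negative(exp_space):
    with pytest.raises(ValueError, match="not allowed"):
        IntensityMatrix(np.array([[-1.0, 1.0], [0.5, -0.5]]), exp_space)
    with pytest.raises(ValueError, match=">= 0"):
        IntensityMatrix(np.array([[1.0, -1.0], [0.0, 0.0]]), exp_space)


def test_ckb_structure_matches_fixture_support():
    from screenmark.fixtures import ckb_like_generator

    spec = ckb_like_generator("three_category")
    ckb = StateSpace.ckb(non_high=["low", "intermediate"])
    assert ckb.labels == spec.space.labels
    assert np.array_equal(ckb.adjacency, spec.space.adjacency)


# ---------------------------------------------------------------------------
# transition probabilities
# ---------------------------------------------------------------------------


def test_transition_matrix_identity_at_zero(exp_space):
    Q = IntensityMatrix(np.array([[-0.3, 0.3], [0, 0]]), exp_space)
    assert np.array_equal(transition_matrix(Q, 0.0), np.eye(2))
    with pytest.raises(ValueError):
        transition_matrix(Q, -1.0)


def test_transition_matrix_two_state_closed_form(exp_space):
    Q = IntensityMatrix(np.array([[-0.1, 0.1], [0, 0]]), exp_space)
    P = transition_matrix(Q, 10.0)
    assert P[0, 1] == pytest.approx(1 - np.exp(-1.0), abs=1e-12)


def test_transition_matrix_against_uniformization_oracle():
    rng = np.random.default_rng(42)
    Q = random_conservative_Q(5, rng, absorbing=1)
    P = transition_matrix(Q, 7.0)
    P_oracle = uniformization_expm(Q, 7.0)
    assert np.max(np.abs(P - P_oracle)) < 1e-10


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_chapman_kolmogorov_and_row_conservation(seed):
    rng = np.random.default_rng(seed)
    Q = random_conservative_Q(4, rng, absorbing=1)
    s, t = rng.uniform(0.1, 5.0, size=2)
    Pst = transition_matrix(Q, s + t)
    prod = transition_matrix(Q, s) @ transition_matrix(Q, t)
    assert np.max(np.abs(Pst - prod)) < 1e-10
    for u in (s, t, s + t):
        P = transition_matrix(Q, u)
        assert np.max(np.abs(P.sum(axis=1) - 1.0)) < 1e-12
    # absorbing row is a unit vector
    assert transition_matrix(Q, s)[3, 3] == pytest.approx(1.0, abs=1e-12)


def test_spectral_route_matches_expm_for_many_lags():
    rng = np.random.default_rng(3)
    Q = random_conservative_Q(5, rng, absorbing=2)
    ts = rng.uniform(0.01, 12.0, size=40)
    stack = transition_matrices(Q, ts)
    for k, t in enumerate(ts):
        assert np.max(np.abs(stack[k] - transition_matrix(Q, t))) < 1e-10


# ---------------------------------------------------------------------------
# panel likelihood
# ---------------------------------------------------------------------------


def test_panel_loglik_empty_is_zero(exp_space):
    Q = IntensityMatrix(np.array([[-0.1, 0.1], [0, 0]]), exp_space)
    empty = make_panel([])
    assert panel_loglik(Q, empty) == 0.0


def test_panel_loglik_pure_panel_closed_form(exp_space):
    Q = IntensityMatrix(np.array([[-0.1, 0.1], [0, 0]]), exp_space)
    panel = make_panel([(1, 0.0, "a", "screen"), (1, 10.0, "b", "screen")])
    ll = panel_loglik(Q, panel, exact_event_times=False)
    assert ll == pytest.approx(np.log(1 - np.exp(-1.0)), abs=1e-12)


@pytest.mark.parametrize("lam,dt", [(0.1, 10.0), (0.45, 2.5)])
def test_panel_loglik_exact_event_is_exponential_density(exp_space, lam, dt):
    Q = IntensityMatrix(np.array([[-lam, lam], [0, 0]]), exp_space)
    panel = make_panel([(1, 0.0, "a", "screen"), (1, dt, "b", "event")])
    ll = panel_loglik(Q, panel)
    assert ll == pytest.approx(np.log(lam) - lam * dt, abs=1e-12)


def test_panel_loglik_censoring_is_survival(exp_space):
    lam = 0.2
    Q = IntensityMatrix(np.array([[-lam, lam], [0, 0]]), exp_space)
    panel = make_panel([(1, 0.0, "a", "screen"), (1, 5.0, "", "censor")])
    assert panel_loglik(Q, panel) == pytest.approx(-lam * 5.0, abs=1e-12)


def test_panel_loglik_matches_ode_oracle_three_states():
    labels = ("s1", "s2", "dead")
    space = StateSpace(
        labels,
        (True, True, False),
        np.array([[0, 1, 1], [1, 0, 1], [0, 0, 0]], dtype=bool),
    )
    Q = IntensityMatrix(
        np.array([[-0.35, 0.25, 0.10], [0.15, -0.45, 0.30], [0, 0, 0]]), space
    )
    panel = make_panel(
        [
            (1, 0.0, "s1", "screen"), (1, 2.0, "s2", "screen"),
            (1, 5.5, "dead", "event"),
            (2, 0.0, "s2", "screen"), (2, 3.0, "s2", "screen"),
            (2, 8.0, "", "censor"),
            (3, 0.0, "s1", "screen"), (3, 4.2, "dead", "event"),
        ]
    )
    for exact in (True, False):
        if not exact:
            # pure-panel mode reads the absorbing record as a screen
            ll = panel_loglik(Q, panel, exact_event_times=False)
        else:
            ll = panel_loglik(Q, panel)
        oracle = ode_panel_loglik(Q.Q, space, panel, exact_event_times=exact)
        assert ll == pytest.approx(oracle, abs=1e-8)


def test_panel_loglik_zero_probability_pair_warns(exp_space):
    # 'b' is absorbing, so b -> a has probability zero
    space = StateSpace(
        ("a", "b", "c"),
        (True, True, False),
        np.array([[0, 1, 1], [0, 0, 1], [0, 0, 0]], dtype=bool),
    )
    Q = IntensityMatrix(
        np.array([[-0.2, 0.1, 0.1], [0, -0.1, 0.1], [0, 0, 0]]), space
    )
    panel = make_panel([(7, 0.0, "b", "screen"), (7, 1.0, "a", "screen")])
    with pytest.warns(RuntimeWarning, match="7"):
        ll = panel_loglik(Q, panel)
    assert ll == -np.inf


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def exponential_decay_panel():
    """Three subjects with exact event/censor times: the MLE of the decay
    rate is (number of events) / (total time at risk) = 2 / 8."""
    return make_panel(
        [
            (1, 0.0, "a", "screen"), (1, 1.0, "b", "event"),
            (2, 0.0, "a", "screen"), (2, 2.0, "b", "event"),
            (3, 0.0, "a", "screen"), (3, 5.0, "", "censor"),
        ]
    )


def test_fit_recovers_closed_form_exponential_mle(exp_space):
    fm = fit(exponential_decay_panel(), exp_space)
    assert fm.converged
    assert fm.Q.rate("a", "b") == pytest.approx(0.25, rel=1e-5)
    lam = 0.25
    expected_ll = 2 * np.log(lam) - lam * 8.0
    assert fm.loglik == pytest.approx(expected_ll, abs=1e-8)


def test_fit_from_optimum_stays_at_optimum(exp_space):
    opt = IntensityMatrix(np.array([[-0.25, 0.25], [0, 0]]), exp_space)
    fm = fit(exponential_decay_panel(), exp_space, init=opt)
    assert fm.Q.rate("a", "b") == pytest.approx(0.25, rel=1e-6)


def test_fit_warns_on_unobserved_states(exp_space):
    space = StateSpace(
        ("a", "x", "b"),
        (True, True, False),
        np.array([[0, 1, 1], [1, 0, 1], [0, 0, 0]], dtype=bool),
    )
    with pytest.warns(RuntimeWarning, match="unidentifiable"):
        fit(exponential_decay_panel(), space, maxiter=20, compute_cov=False)


def test_crude_init_counts_over_time(exp_space):
    q0 = crude_init(exponential_decay_panel(), exp_space)
    # 2 transitions over 8 person-years observed from 'a'
    assert q0.rate("a", "b") == pytest.approx(0.25, abs=1e-12)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("qii,expected", [(-1 / 10.5, 10.5), (-1.0, 1.0), (-0.2, 5.0)])
def test_mean_sojourn_reciprocal_rate(exp_space, qii, expected):
    Q = IntensityMatrix(np.array([[qii, -qii], [0, 0]]), exp_space)
    assert mean_sojourn(Q, "a") == pytest.approx(expected)
    with pytest.raises(ValueError, match="absorbing"):
        mean_sojourn(Q, "b")


def test_jump_probabilities_normalise():
    space = StateSpace(
        ("s", "d1", "d2", "d3"),
        (True, False, False, False),
        np.array(
            [[0, 1, 1, 1], [0, 0, 0, 0], [0, 0, 0, 0], [0, 0, 0, 0]], dtype=bool
        ),
    )
    Q = IntensityMatrix(
        np.array([[-4.0, 1.0, 1.0, 2.0], [0, 0, 0, 0], [0, 0, 0, 0], [0, 0, 0, 0]]),
        space,
    )
    jp = jump_probabilities(Q, "s")
    assert jp == {"d1": 0.25, "d2": 0.25, "d3": 0.5}
    with pytest.raises(ValueError):
        jump_probabilities(Q, "d1")


def test_expected_prevalence_exact_at_baseline_and_monotone_absorption(ckb_spec):
    from screenmark.synthetic import simulate_panel

    spec = ckb_spec
    small = type(spec)(
        state_labels=spec.state_labels,
        true_Q=spec.true_Q,
        initial_distribution=spec.initial_distribution,
        n_subjects=5_000,
        visit_schedule=spec.visit_schedule,
        resurvey_fraction=1.0,
        horizon=spec.horizon,
        seed=99,
    )
    panel = simulate_panel(small)
    prev = expected_prevalence(spec.intensity, panel, [0.0, 4.0, 9.0])
    at0 = prev[prev.time == 0.0]
    assert np.allclose(at0.observed, at0.expected)
    # self-consistency: data generated from the same Q
    for _, row in prev.iterrows():
        sd = np.sqrt(max(row.expected * (1 - row.expected / 5_000), 1.0))
        assert abs(row.observed - row.expected) <= 3 * sd
    # absorbed mass never decreases
    for state in ("ascvd", "non_ascvd_death"):
        e = prev[prev.state == state].sort_values("time").expected.to_numpy()
        assert np.all(np.diff(e) >= -1e-9)


# ---------------------------------------------------------------------------
# uncertainty draws
# ---------------------------------------------------------------------------


def fitted_stub(exp_space, lam=0.25, var=0.04):
    Q = IntensityMatrix(np.array([[-lam, lam], [0, 0]]), exp_space)
    return FittedModel(
        Q=Q,
        log_rates=np.array([np.log(lam)]),
        cov=np.array([[var]]),
        loglik=0.0,
        converged=True,
    )


def test_uncertainty_draws_zero_covariance_degenerate(exp_space):
    fm = fitted_stub(exp_space, var=0.0)
    draws = uncertainty_draws(fm, 20, seed=0)
    for d in draws:
        assert d.rate("a", "b") == pytest.approx(0.25, abs=1e-12)


def test_uncertainty_draws_mean_and_percentile_containment(exp_space):
    fm = fitted_stub(exp_space)
    n = 2_000
    draws = uncertainty_draws(fm, n, seed=1)
    logs = np.log([d.rate("a", "b") for d in draws])
    se = np.sqrt(fm.cov[0, 0])
    assert abs(logs.mean() - fm.log_rates[0]) < 3 * se / np.sqrt(n)
    soj = np.array([mean_sojourn(d, "a") for d in draws])
    lo, hi = np.percentile(soj, [2.5, 97.5])
    assert lo < mean_sojourn(fm.Q, "a") < hi


def test_uncertainty_draws_rejects_non_psd(exp_space):
    fm = fitted_stub(exp_space)
    fm.cov = np.array([[-1.0]])
    with pytest.raises(ValueError, match="positive semi-definite"):
        uncertainty_draws(fm, 10, seed=0)
    draws = uncertainty_draws(fm, 10, seed=0, repair_psd=True)
    assert len(draws) == 10
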