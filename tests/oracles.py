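"""Independent numerical oracles used to cross-check the implementation.

These deliberately use different algorithms from the package: the matrix
exponential via uniformization, the panel likelihood via direct numerical
integration of the Kolmogorov forward equations, and closed-form results
for two-state chains.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def uniformization_expm(Q: np.ndarray, t: float, tol: float = 1e-14) -> np.ndarray:
    """expm(Q t) through the uniformized jump chain: with Lam >= max |q_ii|
    and M = I + Q/Lam, P(t) = sum_k Poisson(Lam t)_k M^k."""
    n = Q.shape[0]
    lam = max(np.max(-np.diag(Q)), 1e-12)
    M = np.eye(n) + Q / lam
    mu = lam * t
    term = np.exp(-mu)  # Poisson weight at k = 0
    acc = term * np.eye(n)
    Mk = np.eye(n)
    k = 0
    weight_sum = term
    while weight_sum < 1.0 - tol and k < 100_000:
        k += 1
        term *= mu / k
        Mk = Mk @ M
        acc += term * Mk
        weight_sum += term
    return acc


def ode_transition_row(Q: np.ndarray, start: int, t: float) -> np.ndarray:
    """Row of P(t) by integrating p' = p Q from a unit vector."""
    def rhs(_, p):
        return p @ Q

    p0 = np.zeros(Q.shape[0])
    p0[start] = 1.0
    sol = solve_ivp(rhs, (0.0, t), p0, rtol=1e-11, atol=1e-13, dense_output=False)
    return sol.y[:, -1]


def ode_panel_loglik(Q: np.ndarray, space, data, exact_event_times=True) -> float:
    """Panel log-likelihood assembled pair by pair from ODE-integrated
    transition probabilities (no matrix exponential)."""
    idx = {l: i for i, l in enumerate(space.labels)}
    tr = space.transient_indices
    total = 0.0
    df = data.records
    for _, grp in df.groupby("subject_id", sort=False):
        times = grp["time_years"].to_numpy()
        states = grp["state"].to_numpy()
        types = grp["obs_type"].to_numpy()
        for k in range(len(times) - 1):
            dt = times[k + 1] - times[k]
            a = idx[states[k]]
            row = ode_transition_row(Q, a, dt)
            if types[k + 1] == "screen":
                total += np.log(row[idx[states[k + 1]]])
            elif types[k + 1] == "censor":
                total += np.log(row[tr].sum())
            else:
                d = idx[states[k + 1]]
                if exact_event_times:
                    total += np.log(row[tr] @ Q[tr, d])
                else:
                    total += np.log(row[d])
    return float(total)


def two_state_screen_person_years(lam: float, intervals, horizon: float) -> float:
    """Closed-form unidentified person-years for a low -> high chain with
    rate lam, screens at the cumulative interval times, per person."""
    total = 0.0
    t = 0.0
    for d in intervals:
        d = min(d, horizon - t)
        if d <= 0:
            break
        total += np.exp(-lam * t) * (d - (1 - np.exp(-lam * d)) / lam)
        t += d
    return total
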