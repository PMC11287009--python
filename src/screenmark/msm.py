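"""Continuous-time multistate Markov models estimated from panel data.

The progression of individuals through 10-year ASCVD risk categories is
modelled as a time-homogeneous continuous-time Markov chain (CTMC) on a
small state space: ordered risk categories (transient) plus two absorbing
states, an ASCVD event and death from non-ASCVD causes.  The chain is
characterised by an intensity (generator) matrix ``Q`` whose off-diagonal
entries are instantaneous per-year transition rates; transition
probabilities over a lag ``t`` are ``P(t) = expm(Q t)``.

Risk categories are only observed at survey visits (panel observation),
while the absorbing events carry exact dates from registry linkage.  The
likelihood of a subject's record sequence is a product over consecutive
record pairs:

* screen -> screen at lag ``dt``: ``P[a, b](dt)``,
* screen -> exactly dated absorbing event ``d`` at lag ``dt``:
  ``sum_j P[a, j](dt) * q[j, d]`` over transient ``j`` (the subject moved
  freely among transient states and jumped to ``d`` exactly at the end),
* screen -> censoring at lag ``dt``: ``sum_j P[a, j](dt)`` over transient
  ``j`` (alive and event-free, category unknown).

A pure-panel variant (``exact_event_times=False``) instead treats an
absorbing record like any other panel observation, ``P[a, d](dt)``, for
comparison with fitting conventions that ignore registry dates.

Maximisation is over the logs of the allowed off-diagonal rates (which
enforces positivity) with BFGS; the covariance of the log-rates comes from
the inverse numerical Hessian at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

__all__ = [
    "StateSpace",
    "IntensityMatrix",
    "PanelData",
    "FittedModel",
    "transition_matrix",
    "transition_matrices",
    "panel_loglik",
    "PanelLikelihood",
    "crude_init",
    "fit",
    "mean_sojourn",
    "jump_probabilities",
    "expected_prevalence",
    "uncertainty_draws",
]

OBS_SCREEN = "screen"
OBS_EVENT = "event"
OBS_CENSOR = "censor"


# ---------------------------------------------------------------------------
# state space and intensity matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class StateSpace:
    """Ordered state labels, transient flags and allowed-transition structure.

    ``adjacency[i, j]`` is True when the rate ``q_ij`` may be non-zero.
    Absorbing states must have no allowed outgoing transitions.
    """

    labels: tuple[str, ...]
    transient: tuple[bool, ...]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("state labels must be unique")
        if len(self.transient) != n:
            raise ValueError("transient flags must match labels")
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.shape != (n, n):
            raise ValueError("adjacency must be square over the labels")
        if adj.diagonal().any():
            raise ValueError("self-transitions are not allowed entries")
        for i, tr in enumerate(self.transient):
            if not tr and adj[i].any():
                raise ValueError(
                    f"absorbing state {self.labels[i]!r} has outgoing transitions"
                )
        object.__setattr__(self, "adjacency", adj)

    # -- convenience -------------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown state {label!r}") from None

    @property
    def transient_indices(self) -> np.ndarray:
        return np.flatnonzero(self.transient)

    @property
    def absorbing_indices(self) -> np.ndarray:
        return np.flatnonzero(~np.asarray(self.transient))

    @property
    def transient_labels(self) -> tuple[str, ...]:
        return tuple(l for l, t in zip(self.labels, self.transient) if t)

    @classmethod
    def ckb(
        cls,
        non_high: Sequence[str],
        high: str = "high",
        absorbing: Sequence[str] = ("ascvd", "non_ascvd_death"),
    ) -> "StateSpace":
        """Structure used for risk-category progression: bidirectional moves
        among non-high categories, every non-high category into high, high
        back to the adjacent (top non-high) category, and every transient
        state into both absorbing states."""
        labels = tuple(non_high) + (high,) + tuple(absorbing)
        n = len(labels)
        k = len(non_high)
        transient = tuple([True] * (k + 1) + [False] * len(absorbing))
        adj = np.zeros((n, n), dtype=bool)
        for i in range(k):
            for j in range(k):
                if i != j:
                    adj[i, j] = True
            adj[i, k] = True  # into high
        adj[k, k - 1] = True  # high reverses to the top non-high category
        for i in range(k + 1):
            for a in range(k + 1, n):
                adj[i, a] = True
        return cls(labels=labels, transient=transient, adjacency=adj)

    @classmethod
    def from_intensity_support(
        cls, labels: Sequence[str], Q: np.ndarray
    ) -> "StateSpace":
        """Derive the structure from the non-zero pattern of a generator:
        states whose rows vanish are absorbing; allowed transitions are the
        strictly positive off-diagonals."""
        Q = np.asarray(Q, dtype=float)
        n = len(labels)
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        if off.max() == 0:  # zero generator: nothing ever absorbs
            transient = (True,) * n
        else:
            transient = tuple(bool(np.any(off[i] > 0)) for i in range(n))
        return cls(labels=tuple(labels), transient=transient, adjacency=off > 0)


@dataclass(eq=False)
class IntensityMatrix:
    """Generator matrix of the CTMC together with its state space.

    Rows sum to zero, off-diagonals are non-negative and entries outside the
    allowed structure are exactly zero.  The diagonal is recomputed on
    construction so conservation holds to machine precision.
    """

    Q: np.ndarray
    space: StateSpace

    def __post_init__(self) -> None:
        Q = np.array(self.Q, dtype=float)
        n = self.space.n_states
        if Q.shape != (n, n):
            raise ValueError("Q shape does not match the state space")
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal intensities must be >= 0")
        if np.any(off[~self.space.adjacency] != 0):
            bad = np.argwhere((off != 0) & ~self.space.adjacency)
            i, j = bad[0]
            raise ValueError(
                f"rate {self.space.labels[i]} -> {self.space.labels[j]} "
                "is non-zero but not allowed by the state space"
            )
        if np.any(np.abs(Q.sum(axis=1)) > 1e-8 * max(1.0, np.abs(off).max())):
            raise ValueError("rows of Q must sum to zero")
        np.fill_diagonal(off, -off.sum(axis=1))
        self.Q = off

    def rate(self, frm: str, to: str) -> float:
        return float(self.Q[self.space.index(frm), self.space.index(to)])

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.Q.copy(), self.space)


# ---------------------------------------------------------------------------
# panel data container
# ---------------------------------------------------------------------------

PANEL_COLUMNS = ["subject_id", "time_years", "state", "obs_type"]


@dataclass(eq=False)
class PanelData:
    """Interval-censored observation records, one row per observation.

    Columns: ``subject_id``, ``time_years``, ``state`` (a label, empty for
    censoring records), ``obs_type`` in {screen, event, censor}.  Extra
    columns (e.g. ``sex``) are carried through untouched.  Within a subject
    times are strictly increasing, the first record is a screen at a
    transient state and at most one absorbing record appears, always last.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"panel data missing columns: {missing}")
        df = df.sort_values(["subject_id", "time_years"], kind="stable")
        self.records = df.reset_index(drop=True)

    def validate(self, space: StateSpace) -> None:
        df = self.records
        transient = set(space.transient_labels)
        known = set(space.labels)
        for sid, grp in df.groupby("subject_id", sort=False):
            t = grp["time_years"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"subject {sid}: times not strictly increasing")
            types = grp["obs_type"].to_numpy()
            states = grp["state"].to_numpy()
            if types[0] != OBS_SCREEN or states[0] not in transient:
                raise ValueError(
                    f"subject {sid}: first record must be a screen at a transient state"
                )
            n_events = int((types == OBS_EVENT).sum())
            if n_events > 1:
                raise ValueError(f"subject {sid}: more than one absorbing record")
            if n_events == 1 and types[-1] != OBS_EVENT:
                raise ValueError(f"subject {sid}: absorbing record is not last")
            for s, ot in zip(states, types):
                if ot == OBS_CENSOR:
                    continue
                if s not in known:
                    raise ValueError(f"subject {sid}: unknown state {s!r}")

    @property
    def n_subjects(self) -> int:
        return self.records["subject_id"].nunique()

    def subset(self, mask) -> "PanelData":
        return PanelData(self.records.loc[mask].copy())

    def to_csv(self, path, **kwargs) -> None:
        self.records.to_csv(path, index=False, **kwargs)

    @classmethod
    def from_csv(cls, path) -> "PanelData":
        df = pd.read_csv(
            path, comment="#", dtype={"state": str}, float_precision="round_trip"
        )
        df["state"] = df["state"].fillna("")
        return cls(df)


# ---------------------------------------------------------------------------
# transition probabilities
# ---------------------------------------------------------------------------


def _as_matrix(Q: "IntensityMatrix | np.ndarray") -> np.ndarray:
    return Q.Q if isinstance(Q, IntensityMatrix) else np.asarray(Q, dtype=float)


def transition_matrix(Q: "IntensityMatrix | np.ndarray", t: float) -> np.ndarray:
    """P(t) = expm(Q t), with rows renormalised only against ~1e-12 underflow."""
    if t < 0:
        raise ValueError("time lag must be non-negative")
    M = _as_matrix(Q)
    if t == 0:
        return np.eye(M.shape[0])
    P = expm(M * float(t))
    P = np.clip(P, 0.0, 1.0)
    return P


class _EigenPropagator:
    """Spectral form of t -> expm(Q t), for many lags at once.

    For a diagonalisable generator, ``P(t) = V diag(exp(lambda t)) V^{-1}``;
    one eigendecomposition then serves every observation lag in the data.
    Falls back to per-lag ``expm`` when the eigenvector matrix is close to
    defective.
    """

    def __init__(self, Q: np.ndarray, cond_limit: float = 1e8):
        self.Q = Q
        lam, V = np.linalg.eig(Q)
        ok = True
        try:
            cond = np.linalg.cond(V)
            ok = np.isfinite(cond) and cond < cond_limit
        except np.linalg.LinAlgError:
            ok = False
        if ok:
            self.lam = lam
            self.V = V
            self.Vinv = np.linalg.inv(V)
        else:
            self.lam = None

    @property
    def usable(self) -> bool:
        return self.lam is not None

    def at(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for each t, shape (len(ts), n, n)."""
        ts = np.asarray(ts, dtype=float)
        if self.usable:
            E = np.exp(np.multiply.outer(ts, self.lam))  # (m, n)
            P = np.einsum("ij,mj,jk->mik", self.V, E, self.Vinv).real
        else:
            P = np.stack([expm(self.Q * t) for t in ts])
        return np.clip(P, 0.0, 1.0)


def transition_matrices(Q: "IntensityMatrix | np.ndarray", ts: Iterable[float]) -> np.ndarray:
    """Transition probability matrices for several lags (spectral route)."""
    ts = np.asarray(list(ts), dtype=float)
    if np.any(ts < 0):
        raise ValueError("time lags must be non-negative")
    return _EigenPropagator(_as_matrix(Q)).at(ts)


# ---------------------------------------------------------------------------
# panel likelihood
# ---------------------------------------------------------------------------


class PanelLikelihood:
    """Pre-digested panel likelihood for repeated evaluation during fitting.

    Consecutive record pairs are aggregated once: screen->screen pairs by
    (from, to, lag) with counts, censoring pairs by (from, lag), and exactly
    dated absorbing pairs grouped by (from, destination) with the vector of
    individual lags.  Evaluation at a candidate ``Q`` then needs a single
    eigendecomposition.
    """

    def __init__(
        self,
        space: StateSpace,
        data: PanelData,
        exact_event_times: bool = True,
    ):
        self.space = space
        self.exact_event_times = exact_event_times
        self._digest(data)

    def _digest(self, data: PanelData) -> None:
        df = data.records
        idx_of = {l: i for i, l in enumerate(self.space.labels)}
        sid = df["subject_id"].to_numpy()
        t = df["time_years"].to_numpy(dtype=float)
        obs = df["obs_type"].to_numpy()
        state = df["state"].to_numpy()

        same = sid[1:] == sid[:-1]
        a_lab, b_lab = state[:-1][same], state[1:][same]
        dt = (t[1:] - t[:-1])[same]
        ob = obs[1:][same]
        if np.any(dt <= 0):
            raise ValueError("observation times must be strictly increasing")
        a_idx = np.array([idx_of[x] for x in a_lab])

        screen_mask = ob == OBS_SCREEN
        censor_mask = ob == OBS_CENSOR
        event_mask = ob == OBS_EVENT

        # screen -> screen: aggregate counts per (a, b, dt)
        b_idx_s = np.array([idx_of[x] for x in b_lab[screen_mask]], dtype=int)
        key = pd.DataFrame(
            {"a": a_idx[screen_mask], "b": b_idx_s, "dt": dt[screen_mask]}
        )
        self.screen_terms = (
            key.groupby(["a", "b", "dt"]).size().reset_index(name="count")
            if len(key)
            else pd.DataFrame(columns=["a", "b", "dt", "count"])
        )

        # censoring: aggregate per (a, dt); state column ignored
        key = pd.DataFrame({"a": a_idx[censor_mask], "dt": dt[censor_mask]})
        self.censor_terms = (
            key.groupby(["a", "dt"]).size().reset_index(name="count")
            if len(key)
            else pd.DataFrame(columns=["a", "dt", "count"])
        )

        # absorbing events: grouped by (from, destination) with raw lags
        d_idx = np.array([idx_of[x] for x in b_lab[event_mask]], dtype=int)
        self.event_groups: dict[tuple[int, int], np.ndarray] = {}
        ea = a_idx[event_mask]
        edt = dt[event_mask]
        for a in np.unique(ea):
            for d in np.unique(d_idx[ea == a]):
                m = (ea == a) & (d_idx == d)
                self.event_groups[(int(a), int(d))] = edt[m]

        self._subject_pairs = (sid[:-1][same], a_lab, b_lab, dt, ob)
        self.n_pairs = int(same.sum())

    # -- evaluation --------------------------------------------------------

    def loglik(self, Q: "IntensityMatrix | np.ndarray") -> float:
        M = _as_matrix(Q)
        tr = self.space.transient_indices
        prop = _EigenPropagator(M)
        total = 0.0

        if len(self.screen_terms):
            ts = self.screen_terms["dt"].to_numpy()
            uniq, inv = np.unique(ts, return_inverse=True)
            P = prop.at(uniq)
            vals = P[inv, self.screen_terms["a"].to_numpy(), self.screen_terms["b"].to_numpy()]
            if np.any(vals <= 0):
                return -np.inf
            total += float(np.dot(self.screen_terms["count"].to_numpy(), np.log(vals)))

        if len(self.censor_terms):
            ts = self.censor_terms["dt"].to_numpy()
            uniq, inv = np.unique(ts, return_inverse=True)
            P = prop.at(uniq)
            surv = P[:, :, tr].sum(axis=2)  # prob still transient
            vals = surv[inv, self.censor_terms["a"].to_numpy()]
            if np.any(vals <= 0):
                return -np.inf
            total += float(np.dot(self.censor_terms["count"].to_numpy(), np.log(vals)))

        for (a, d), dts in self.event_groups.items():
            if self.exact_event_times:
                # density of absorption into d at exact lag: sum_j P[a,j] q[j,d]
                P = prop.at(dts)
                dens = P[:, a, tr] @ M[tr, d]
            else:
                P = prop.at(dts)
                dens = P[:, a, d]
            if np.any(dens <= 0):
                return -np.inf
            total += float(np.log(dens).sum())
        return total

    def diagnose_zero_probability(self, Q: "IntensityMatrix | np.ndarray") -> list:
        """Subjects whose record pairs have zero probability under Q."""
        M = _as_matrix(Q)
        tr = self.space.transient_indices
        idx_of = {l: i for i, l in enumerate(self.space.labels)}
        sids, a_lab, b_lab, dt, ob = self._subject_pairs
        bad = []
        for s, a, b, d, o in zip(sids, a_lab, b_lab, dt, ob):
            P = transition_matrix(M, d)
            ai = idx_of[a]
            if o == OBS_SCREEN:
                v = P[ai, idx_of[b]]
            elif o == OBS_CENSOR:
                v = P[ai, tr].sum()
            else:
                bi = idx_of[b]
                v = (P[ai, tr] @ M[tr, bi]) if self.exact_event_times else P[ai, bi]
            if v <= 0:
                bad.append(s)
        return bad


def panel_loglik(
    Q: "IntensityMatrix | np.ndarray",
    data: PanelData,
    space: StateSpace | None = None,
    exact_event_times: bool = True,
) -> float:
    """Log-likelihood of panel records under generator ``Q``.

    Returns 0.0 for empty data and ``-inf`` (with a warning naming the
    subjects) if any record pair has zero probability.
    """
    if space is None:
        if not isinstance(Q, IntensityMatrix):
            raise ValueError("a StateSpace is required when Q is a bare array")
        space = Q.space
    if len(data.records) == 0:
        return 0.0
    lik = PanelLikelihood(space, data, exact_event_times)
    ll = lik.loglik(Q)
    if ll == -np.inf:
        bad = lik.diagnose_zero_probability(Q)
        warnings.warn(
            f"zero-probability record pairs for subjects {bad[:10]}"
            + ("..." if len(bad) > 10 else ""),
            RuntimeWarning,
        )
    return ll


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class FittedModel:
    """Maximum-likelihood estimate with log-scale uncertainty.

    ``log_rates`` orders the free parameters row-major over the allowed
    off-diagonal entries of the state space; ``cov`` is the observed-information
    covariance on that scale.
    """

    Q: IntensityMatrix
    log_rates: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    report: dict = field(default_factory=dict)

    @property
    def space(self) -> StateSpace:
        return self.Q.space

    @property
    def param_names(self) -> list[str]:
        labels = self.space.labels
        ii, jj = np.nonzero(self.space.adjacency)
        return [f"{labels[i]}->{labels[j]}" for i, j in zip(ii, jj)]

    def to_json_dict(self) -> dict:
        return {
            "labels": list(self.space.labels),
            "transient": list(self.space.transient),
            "Q": self.Q.Q.tolist(),
            "log_rates": self.log_rates.tolist(),
            "param_names": self.param_names,
            "cov_log_rates": self.cov.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "report": {k: v for k, v in self.report.items()},
        }


def _theta_to_Q(theta: np.ndarray, space: StateSpace) -> np.ndarray:
    n = space.n_states
    Q = np.zeros((n, n))
    Q[space.adjacency] = np.exp(theta)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def crude_init(
    data: PanelData, space: StateSpace, floor: float = 1e-4
) -> IntensityMatrix:
    """Initial rates: observed direct a->b moves divided by person-time whose
    interval started in ``a``, floored to keep every allowed rate positive."""
    df = data.records
    idx_of = {l: i for i, l in enumerate(space.labels)}
    sid = df["subject_id"].to_numpy()
    t = df["time_years"].to_numpy(dtype=float)
    state = df["state"].to_numpy()
    obs = df["obs_type"].to_numpy()
    same = sid[1:] == sid[:-1]
    n = space.n_states
    counts = np.zeros((n, n))
    time_at = np.zeros(n)
    for a, b, dt, ob in zip(
        state[:-1][same], state[1:][same], (t[1:] - t[:-1])[same], obs[1:][same]
    ):
        ai = idx_of[a]
        time_at[ai] += dt
        if ob == OBS_CENSOR:
            continue
        bi = idx_of[b]
        if ai != bi:
            counts[ai, bi] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(time_at[:, None] > 0, counts / time_at[:, None], 0.0)
    rates = np.where(space.adjacency, np.maximum(rates, floor), 0.0)
    np.fill_diagonal(rates, -rates.sum(axis=1))
    return IntensityMatrix(rates, space)


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; adequate for the smooth log-likelihood."""
    k = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
            H[j, i] = H[i, j]
    return H


def fit(
    data: PanelData,
    space: StateSpace,
    init: IntensityMatrix | None = None,
    exact_event_times: bool = True,
    loglik_tol: float = 1e-16,
    gtol: float = 1e-6,
    max_restarts: int = 3,
    maxiter: int = 500,
    compute_cov: bool = True,
) -> FittedModel:
    """Maximum-likelihood fit of the CTMC intensities to panel data.

    BFGS on log-rates; convergence is declared when a restart improves the
    log-likelihood by a relative amount <= ``loglik_tol`` (or the gradient
    norm falls below ``gtol``).  Non-convergence is reported in the result,
    never silently accepted.
    """
    if len(data.records) == 0:
        raise ValueError("cannot fit an empty panel")
    data.validate(space)
    _warn_unidentifiable(data, space)
    if init is None:
        init = crude_init(data, space)
    if init.space is not space and not np.array_equal(
        init.space.adjacency, space.adjacency
    ):
        raise ValueError("init does not respect the state-space structure")
    lik = PanelLikelihood(space, data, exact_event_times)
    theta0 = np.log(init.Q[space.adjacency])

    def nll(theta):
        v = lik.loglik(_theta_to_Q(theta, space))
        return np.inf if v == -np.inf else -v

    best = None
    n_iters = 0
    last_rel_improvement = np.inf
    for attempt in range(max_restarts):
        res = minimize(
            nll, theta0, method="BFGS", options={"gtol": gtol, "maxiter": maxiter}
        )
        n_iters += res.nit
        if best is not None:
            last_rel_improvement = (best.fun - res.fun) / max(1.0, abs(best.fun))
            if res.fun < best.fun:
                best = res
            if last_rel_improvement <= loglik_tol:
                break
        else:
            best = res
        theta0 = best.x

    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan
    # secondary guard: gradient small relative to the log-likelihood scale
    # (the finite-difference gradient cannot resolve below that)
    grad_ok = grad_norm < max(gtol, 1e-6 * max(1.0, abs(best.fun)))
    converged = bool(
        best.success or last_rel_improvement <= loglik_tol or grad_ok
    )
    if not converged:
        warnings.warn(
            f"fit did not converge: {best.message} (grad inf-norm {grad_norm:.3g})",
            RuntimeWarning,
        )

    theta_hat = best.x
    if compute_cov:
        H = _numerical_hessian(nll, theta_hat)
        H = 0.5 * (H + H.T)
        cov = np.linalg.pinv(H)
        cov = 0.5 * (cov + cov.T)
    else:
        cov = np.full((len(theta_hat), len(theta_hat)), np.nan)

    Q_hat = IntensityMatrix(_theta_to_Q(theta_hat, space), space)
    return FittedModel(
        Q=Q_hat,
        log_rates=theta_hat,
        cov=cov,
        loglik=-best.fun,
        converged=converged,
        report={
            "message": str(best.message),
            "n_iterations": int(n_iters),
            "grad_inf_norm": grad_norm,
            "last_rel_improvement": float(last_rel_improvement),
            "n_pairs": lik.n_pairs,
            "exact_event_times": exact_event_times,
        },
    )


def _warn_unidentifiable(data: PanelData, space: StateSpace) -> None:
    labels = space.labels
    seen_from = set(
        data.records.loc[data.records["obs_type"] == OBS_SCREEN, "state"]
    )
    seen_to = set(data.records.loc[data.records["obs_type"] != OBS_CENSOR, "state"])
    ii, jj = np.nonzero(space.adjacency)
    for i, j in zip(ii, jj):
        if labels[i] not in seen_from or labels[j] not in seen_to:
            warnings.warn(
                f"rate {labels[i]}->{labels[j]} may be structurally "
                "unidentifiable: its states are never observed",
                RuntimeWarning,
            )


# ---------------------------------------------------------------------------
# summaries of a generator
# ---------------------------------------------------------------------------


def mean_sojourn(Q: IntensityMatrix, state: str) -> float:
    """Expected continuous stay in a transient state, -1 / q_ii, in years."""
    i = Q.space.index(state)
    if not Q.space.transient[i]:
        raise ValueError(f"state {state!r} is absorbing; sojourn time undefined")
    qii = Q.Q[i, i]
    if qii == 0:
        return np.inf
    return -1.0 / qii


def jump_probabilities(Q: IntensityMatrix, from_state: str) -> dict[str, float]:
    """Embedded-chain next-jump distribution q_ij / (-q_ii) over destinations."""
    i = Q.space.index(from_state)
    if not Q.space.transient[i]:
        raise ValueError(f"state {from_state!r} is absorbing; no jumps out")
    total = -Q.Q[i, i]
    if total <= 0:
        raise ValueError(f"state {from_state!r} has zero exit rate")
    out = {}
    for j in np.flatnonzero(Q.space.adjacency[i]):
        out[Q.space.labels[j]] = float(Q.Q[i, j] / total)
    return out


def expected_prevalence(
    fitted: "FittedModel | IntensityMatrix",
    data: PanelData,
    grid: Sequence[float],
) -> pd.DataFrame:
    """Observed versus model-expected state counts along a time grid.

    Expected counts propagate the observed baseline distribution through
    ``P(t)``.  Observed counts use, for each subject, the record nearest in
    time to the grid point, with absorbing states persisting from the event
    time onward.
    """
    Q = fitted.Q if isinstance(fitted, FittedModel) else fitted
    space = Q.space
    df = data.records
    labels = list(space.labels)

    base = df.loc[df.groupby("subject_id")["time_years"].idxmin()]
    counts0 = base["state"].value_counts().reindex(labels, fill_value=0).to_numpy()

    rows = []
    for t in grid:
        P = transition_matrix(Q, float(t))
        expected = counts0 @ P
        observed = np.zeros(len(labels))
        for _, grp in df.groupby("subject_id", sort=False):
            times = grp["time_years"].to_numpy()
            states = grp["state"].to_numpy()
            types = grp["obs_type"].to_numpy()
            ev = types == OBS_EVENT
            if ev.any() and times[ev][0] <= t:
                observed[labels.index(states[ev][0])] += 1
                continue
            informative = types != OBS_CENSOR
            it, istate = times[informative], states[informative]
            k = int(np.argmin(np.abs(it - t)))
            observed[labels.index(istate[k])] += 1
        for lab, o, e in zip(labels, observed, expected):
            rows.append({"time": float(t), "state": lab, "observed": o, "expected": e})
    return pd.DataFrame(rows)


def uncertainty_draws(
    fitted: FittedModel,
    n_draws: int,
    seed: int,
    repair_psd: bool = False,
) -> list[IntensityMatrix]:
    """Parametric draws of the generator: multivariate normal on log-rates
    with the observed-information covariance, exponentiated back to rates."""
    cov = np.asarray(fitted.cov, dtype=float)
    if not np.all(np.isfinite(cov)):
        raise ValueError("fitted model has no usable covariance")
    eig = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    if eig.min() < -1e-10 * max(1.0, eig.max()):
        if not repair_psd:
            raise ValueError(
                "covariance is not positive semi-definite; pass repair_psd=True "
                "to project onto the nearest PSD matrix"
            )
        w, U = np.linalg.eigh(0.5 * (cov + cov.T))
        cov = (U * np.maximum(w, 0.0)) @ U.T
    rng = np.random.default_rng(seed)
    thetas = rng.multivariate_normal(fitted.log_rates, cov, size=n_draws, method="svd")
    return [
        IntensityMatrix(_theta_to_Q(th, fitted.space), fitted.space) for th in thetas
    ]
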