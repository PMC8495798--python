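"""Three-state hidden Markov model for annual presence-absence of a plant
species whose seed bank is never observed directly.

The hidden chain tracks the pair ``Z_t = (S_{t-1}, X_t)`` where ``S_t``
indicates seeds in the soil at year *t* and ``X_t`` is the above-ground
presence observed in the spring survey:

* state 1 = (0, 0): no seed bank, no standing flora;
* state 2 = (1, 0): seed bank present, standing flora absent;
* state 3 = (1, 1): seed bank present and standing flora present.

Emission is deterministic: states 1 and 2 emit "absent", state 3 emits
"present".  Four probabilities drive the dynamics: ``p0`` (seeds present
the year before the first survey), ``g`` (germination and survival to
adulthood), ``s`` (one-year seed-bank survival without new seed input) and
``c`` (external colonization).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "DemographicParams",
    "MISSING",
    "build_initial",
    "build_emission",
    "build_transition",
    "forward_loglik",
    "forward_loglik_grid",
    "brute_force_loglik",
    "simulate_chain",
    "stationary_distribution",
]

#: sentinel for an unsurveyed plot-year in an observation series
MISSING = -1


@dataclass(frozen=True)
class DemographicParams:
    """Demographic probabilities for one plot x species.

    Attributes
    ----------
    p0 : float
        Probability that seeds were in the soil the year before the first
        survey.
    g : float
        Joint probability of germination and survival to adulthood within
        a year.
    s : float
        Probability the seed bank survives one year without new seeds.
    c : float
        Probability at least one outside seed arrives and survives to the
        next season.
    """

    p0: float
    g: float
    s: float
    c: float

    def __post_init__(self) -> None:
        for name in ("p0", "g", "s", "c"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} outside [0, 1]")


def _check_unit(name: str, value) -> None:
    value = np.asarray(value)
    if np.any(value < 0.0) or np.any(value > 1.0) or not np.all(np.isfinite(value)):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


def build_initial(p0: float, g: float) -> np.ndarray:
    """Initial state distribution ``(1-p0, p0(1-g), p0*g)``.

    ``Z_1 = (S_0, X_1)``: with probability ``1-p0`` there were no seeds, so
    the species is certainly absent in year 1; otherwise it germinates
    (state 3) with probability ``g``.
    """
    _check_unit("p0", p0)
    _check_unit("g", g)
    return np.array([1.0 - p0, p0 * (1.0 - g), p0 * g])


def build_emission() -> np.ndarray:
    """Deterministic observation matrix: rows = states, columns = (absent, present)."""
    return np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])


def build_transition(g: float, s: float, c: float) -> np.ndarray:
    """One-year transition matrix between the three (seed bank, flora) states.

    From state 1 (empty) the seed bank can only be refounded by outside
    colonization.  From state 2 the bank persists by survival or is
    replenished by colonization.  From state 3 the standing plants set seed,
    so the bank is certainly present next year and ``trans[2, 0] = 0``.
    """
    _check_unit("g", g)
    _check_unit("s", s)
    _check_unit("c", c)
    keep = 1.0 - (1.0 - c) * (1.0 - s)  # seeds persist or arrive, from state 2
    return np.array(
        [
            [1.0 - c, c * (1.0 - g), c * g],
            [(1.0 - c) * (1.0 - s), keep * (1.0 - g), keep * g],
            [0.0, 1.0 - g, g],
        ]
    )


# observation -> indicator over states emitting it; MISSING marginalizes
_OBS_MASK = {
    0: np.array([1.0, 1.0, 0.0]),
    1: np.array([0.0, 0.0, 1.0]),
    MISSING: np.array([1.0, 1.0, 1.0]),
}


def _as_series(series) -> np.ndarray:
    arr = np.asarray(series)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("series must be a non-empty 1-D sequence")
    bad = ~np.isin(arr, (0, 1, MISSING))
    if bad.any():
        raise ValueError(f"series values must be 0, 1 or {MISSING} (missing); got {arr[bad]}")
    return arr.astype(np.int64)


def forward_loglik(series, params: DemographicParams) -> float:
    """Exact log-likelihood of one observation series, hidden states summed out.

    Uses the scaled forward recursion (normalize the filtered state
    distribution each step, accumulate the log normalizers), so arbitrarily
    long series do not underflow.  Missing observations contribute an
    emission row of ones: the hidden chain still advances one year.

    Returns ``-inf`` for a series impossible under ``params`` and ``0.0``
    for an all-missing series (probability one).
    """
    obs = _as_series(series)
    if np.all(obs == MISSING):  # marginalizes to exactly 1
        return 0.0
    alpha = build_initial(params.p0, params.g)
    trans = build_transition(params.g, params.s, params.c)
    loglik = 0.0
    for t, x in enumerate(obs):
        if t > 0:
            alpha = alpha @ trans
        alpha = alpha * _OBS_MASK[int(x)]
        norm = alpha.sum()
        if norm <= 0.0:
            return -np.inf
        loglik += np.log(norm)
        alpha = alpha / norm
    return float(loglik)


def forward_loglik_grid(
    obs: np.ndarray,
    p0: np.ndarray,
    g: np.ndarray,
    s: np.ndarray,
    c: np.ndarray,
) -> np.ndarray:
    """Vectorized forward log-likelihood for a batch of series.

    Parameters
    ----------
    obs : int array, shape (n, T)
        Observation series; entries 0, 1 or ``MISSING``.
    p0, g, s, c : float arrays broadcastable to shape (n,)
        Demographic probabilities per series.

    Returns
    -------
    float array, shape (n,)
        Log-likelihood of each series.  Rows that are impossible under
        their parameters return ``-inf``.
    """
    obs = np.ascontiguousarray(obs, dtype=np.int64)
    n, T = obs.shape
    p0, g, s, c = (
        np.ascontiguousarray(np.broadcast_to(np.asarray(a, dtype=float), (n,)))
        for a in (p0, g, s, c)
    )
    return _forward_kernel(obs, p0, g, s, c)


def _forward_kernel_py(obs, p0, g, s, c):
    """Scaled forward recursion over a batch of series; see forward_loglik_grid."""
    n, T = obs.shape
    loglik = np.zeros(n)
    for i in range(n):
        # transition entries for this series (row 3 column 1 is identically 0)
        keep = 1.0 - (1.0 - c[i]) * (1.0 - s[i])
        t00, t01, t02 = 1.0 - c[i], c[i] * (1.0 - g[i]), c[i] * g[i]
        t10 = (1.0 - c[i]) * (1.0 - s[i])
        t11, t12 = keep * (1.0 - g[i]), keep * g[i]
        t21, t22 = 1.0 - g[i], g[i]
        a0, a1, a2 = 1.0 - p0[i], p0[i] * (1.0 - g[i]), p0[i] * g[i]
        total = 0.0
        for t in range(T):
            if t > 0:
                a0, a1, a2 = (
                    a0 * t00 + a1 * t10,
                    a0 * t01 + a1 * t11 + a2 * t21,
                    a0 * t02 + a1 * t12 + a2 * t22,
                )
            x = obs[i, t]
            # deterministic emission: absent kills state 3, present kills 1 and 2
            if x == 0:
                a2 = 0.0
            elif x == 1:
                a0 = 0.0
                a1 = 0.0
            norm = a0 + a1 + a2
            if norm <= 0.0:
                total = -np.inf
                break
            total += np.log(norm)
            a0, a1, a2 = a0 / norm, a1 / norm, a2 / norm
        loglik[i] = total
    return loglik


try:  # compiled fast path; the pure-python kernel is the reference
    from numba import njit

    _forward_kernel = njit(cache=False)(_forward_kernel_py)
except ImportError:  # pragma: no cover
    _forward_kernel = _forward_kernel_py


def brute_force_loglik(series, params: DemographicParams, max_len: int = 12) -> float:
    """Enumeration oracle: sum P(path) * P(obs | path) over all 3^T paths.

    Cost is 3^T; refuses series longer than ``max_len``.  Built from exactly
    the same initial/emission/transition constructors as the forward
    recursion, so agreement between the two is a genuine cross-check of the
    dynamic program, not of the matrices.
    """
    obs = _as_series(series)
    T = obs.size
    if T > max_len:
        raise ValueError(f"series length {T} exceeds enumeration cap {max_len}")
    init = build_initial(params.p0, params.g)
    emit = build_emission()
    trans = build_transition(params.g, params.s, params.c)

    def emit_prob(state: int, x: int) -> float:
        if x == MISSING:
            return 1.0
        return emit[state, x]

    total = 0.0
    for path in product(range(3), repeat=T):
        p = init[path[0]] * emit_prob(path[0], obs[0])
        for t in range(1, T):
            p *= trans[path[t - 1], path[t]] * emit_prob(path[t], obs[t])
        total += p
    if total <= 0.0:
        return -np.inf
    return float(np.log(total))


def simulate_chain(
    params: DemographicParams, T: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate hidden states and observations for ``T`` years.

    Returns
    -------
    states : int array, shape (T,)
        Hidden states coded 0, 1, 2 (for states 1, 2, 3).
    observations : int array, shape (T,)
        0 = absent, 1 = present (deterministic given the state).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    init = build_initial(params.p0, params.g)
    trans = build_transition(params.g, params.s, params.c)
    states = np.empty(T, dtype=np.int64)
    u = rng.random(T)
    states[0] = np.searchsorted(np.cumsum(init), u[0], side="right")
    cum = np.cumsum(trans, axis=1)
    for t in range(1, T):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t], side="right")
    observations = (states == 2).astype(np.int64)
    return states, observations


def stationary_distribution(trans: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left unit eigenvector)."""
    vals, vecs = np.linalg.eig(trans.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()
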