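"""Exact fixation probabilities under death-Birth updating.

Two routes are provided:

* :func:`rho_exact` — the full absorbing Markov chain over the ``2^N``
  mutant configurations of an arbitrary small graph.  Each update picks a
  death vertex uniformly at random; the vacancy is then filled by
  neighbor ``j`` with probability proportional to ``f_j * w_jd``, where a
  mutant has fitness ``f = r`` and a resident ``f = 1``.  Fixation
  probability is the uniform average over single-mutant starting
  configurations of the probability of absorbing in the all-mutant state.

* closed forms for named families — the complete graph ``K_N``, star
  ``S_n``, cycle ``C_N``, and the ``eps -> 0`` limits of the Fan,
  Separated Hubs and Star of Islands, including their many-blade /
  many-island limits.

Every closed form has a removable singularity at ``r = 1`` (neutral
drift); inside a small window around 1 each switches to its first-order
expansion ``1/N + (r-1)(N_eff - 2)/(2N)``, whose slope comes from the
coalescence analysis of the same family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.sparse import coo_matrix, identity
from scipy.sparse.linalg import spsolve

from .coalescence import closed_form_neff_si_limit
from .graphs import (
    InvalidParameterError,
    InvalidSizeError,
    WeightedGraph,
)

__all__ = [
    "FixationCurve",
    "rho_exact",
    "rho_exact_per_vertex",
    "rho_complete",
    "rho_complete_limit",
    "rho_star",
    "rho_cycle",
    "rho_fan_limit",
    "rho_sh_limit",
    "rho_sh_inf",
    "rho_si_limit",
    "rho_si_inf",
    "fixation_curve",
]

#: Half-width of the window around r = 1 inside which closed forms switch
#: to their first-order series (sized so both branches agree to ~2e-10,
#: well inside the 1e-9 continuity budget).
SERIES_WINDOW = 5e-7

#: Default cap on exact-chain graph size (2^14 = 16384 states).
MAX_CHAIN_N = 14


def _check_r(r: float) -> float:
    r = float(r)
    if r <= 0:
        raise InvalidParameterError("mutant fitness r must be > 0")
    return r


# ---------------------------------------------------------------------------
# absorbing-chain solver
# ---------------------------------------------------------------------------

def rho_exact_per_vertex(
    G: WeightedGraph, r: float, max_n: int = MAX_CHAIN_N
) -> np.ndarray:
    """Fixation probability from each single-mutant start, by exact chain.

    Builds the absorbing Markov chain on mutant subsets encoded as
    bitmasks and solves the absorption system directly (sparse LU).
    Limited to ``N <= max_n`` (state space ``2^N``).
    """
    r = _check_r(r)
    G.require_connected()
    N = G.N
    if N > max_n:
        raise InvalidSizeError(
            f"exact chain supports N <= {max_n} (got N={N}); "
            "use the weak-selection or Monte Carlo routes instead"
        )
    w = G.w
    full = (1 << N) - 1
    n_states = full + 1

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    rhs = np.zeros(n_states)

    bits = 1 << np.arange(N)
    for S in range(1, full):
        member = (S & bits) != 0
        f = np.where(member, r, 1.0)
        totals = f @ w  # totals[d] = sum_k f_k w_kd
        mut_mass = (f * member) @ w
        p_mut = mut_mass / totals / N  # P(death at d AND mutant offspring)
        stay = 0.0
        for d in range(N):
            if member[d]:
                p_change = (1.0 / N) - p_mut[d]  # resident fills a mutant slot
                T = S & ~int(bits[d])
            else:
                p_change = p_mut[d]
                T = S | int(bits[d])
            if p_change != 0.0:
                if T == full:
                    rhs[S] += p_change
                elif T != 0:
                    rows.append(S)
                    cols.append(T)
                    vals.append(p_change)
            stay += (1.0 / N) - p_change
        rows.append(S)
        cols.append(S)
        vals.append(stay)

    # phi(S) = sum_T P(S,T) phi(T) + P(S -> full); solve (I - P) phi = rhs.
    # P has no entries in the absorbing rows 0 and full, so I - P already
    # carries the boundary conditions phi(0) = 0 and phi(full) = rhs[full].
    P = coo_matrix((vals, (rows, cols)), shape=(n_states, n_states))
    A = identity(n_states, format="csc") - P.tocsc()
    rhs[full] = 1.0
    phi = spsolve(A, rhs)
    return phi[bits]


def rho_exact(G: WeightedGraph, r: float, max_n: int = MAX_CHAIN_N) -> float:
    """Exact fixation probability of a uniformly placed single mutant."""
    return float(rho_exact_per_vertex(G, r, max_n).mean())


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def _series(N: float, n_eff: float, r: float) -> float:
    return 1.0 / N + (r - 1.0) * (n_eff - 2.0) / (2.0 * N)


def rho_complete(N: int, r: float) -> float:
    """Well-mixed fixation probability on ``K_N``.

    ``rho = (N-1)/N * (1 - 1/r) / (1 - r^-(N-1))``, with the first-order
    series used in a small window around the removable singularity at
    ``r = 1``.
    """
    if N < 2:
        raise InvalidSizeError("complete graph needs N >= 2")
    r = _check_r(r)
    if abs(r - 1.0) < SERIES_WINDOW:
        return _series(N, N, r)
    return (N - 1) / N * (1.0 - 1.0 / r) / (1.0 - r ** (-(N - 1)))


def rho_complete_limit(r: float) -> float:
    """Large-``N`` limit of the well-mixed curve: ``max(0, 1 - 1/r)``."""
    r = _check_r(r)
    return max(0.0, 1.0 - 1.0 / r)


def rho_star(n: int, r: float) -> float:
    """Star ``S_n`` fixation probability (population ``N = n + 1``).

    ``rho = ((N-1)r + 1) / (N(r+1)) * (1/N + r/(N + 2r - 2))``.  The star
    is a suppressor of selection under death-Birth updating.
    """
    if n < 2:
        raise InvalidSizeError("star needs n >= 2 leaves")
    r = _check_r(r)
    N = n + 1
    return ((N - 1) * r + 1) / (N * (r + 1)) * (1.0 / N + r / (N + 2 * r - 2))


def rho_cycle(N: int, r: float) -> float:
    """Cycle ``C_N`` fixation probability — a reducer of fixation.

    ``rho = 2(r-1) / (3r - 1 + r^-(N-3) - 3 r^-(N-2))``; series fallback
    near ``r = 1`` (the cycle is isothermal, so the slope is the
    well-mixed ``(N-2)/(2N)``).
    """
    if N < 3:
        raise InvalidSizeError("cycle needs N >= 3")
    r = _check_r(r)
    if abs(r - 1.0) < SERIES_WINDOW:
        return _series(N, N, r)
    return 2 * (r - 1) / (3 * r - 1 + r ** (-(N - 3)) - 3 * r ** (-(N - 2)))


def rho_fan_limit(n: int, m: int, r: float) -> float:
    """Fan ``F_{n,m}`` fixation probability in the ``eps -> 0`` limit.

    ``rho = n(m-1)(1 - 1/r)(1 - r^-(m+1)) /
    [(mn+1)(1 - r^-(m-1))(1 - r^-n(m+1))]``; near ``r = 1`` the series
    slope uses the limit effective size ``N_eff = nm + n - 1``.
    """
    if n < 2 or m < 2:
        raise InvalidParameterError("Fan needs n >= 2 and m >= 2")
    return rho_sh_limit(n, m, 1, r)


def rho_sh_limit(n: int, m: int, h: int, r: float) -> float:
    """Separated Hubs ``SH_{n,m,h}`` fixation probability, ``eps -> 0``.

    Same island-escape structure as the Fan but with population size
    ``N = nm + h``; ``h = 1`` is exactly the Fan.
    """
    if n < 2 or m < 2 or h < 1:
        raise InvalidParameterError("Separated Hubs needs n, m >= 2 and h >= 1")
    r = _check_r(r)
    N = n * m + h
    if abs(r - 1.0) < SERIES_WINDOW:
        return _series(N, n * m + n - 1, r)
    with np.errstate(over="ignore"):
        rp = np.float64(r)
        num = n * (m - 1) * (1 - 1 / rp) * (1 - rp ** (-(m + 1)))
        den = N * (1 - rp ** (-(m - 1))) * (1 - rp ** np.float64(-n * (m + 1)))
        return float(num / den)


def rho_sh_inf(m: int, r: float) -> float:
    """Many-blade limit of Separated Hubs (and the Fan): ``n -> inf``.

    Zero for ``r <= 1``; for ``r > 1``,
    ``rho = (m-1)/m * (1 - 1/r)(1 - r^-(m+1)) / (1 - r^-(m-1))``.
    """
    if m < 2:
        raise InvalidParameterError("needs m >= 2")
    r = _check_r(r)
    if r <= 1.0:
        return 0.0
    if r - 1.0 < SERIES_WINDOW:
        return (m + 1) / m * (r - 1.0)
    return (
        (m - 1) / m * (1 - 1 / r) * (1 - r ** (-(m + 1))) / (1 - r ** (-(m - 1)))
    )


def rho_si_limit(n: int, m: int, h: int, r: float) -> float:
    """Star of Islands ``SI_{n,m,h}`` fixation probability, ``eps -> 0``.

    Ratio of island-hopping polynomials with the auxiliary migration
    ratio ``x`` (see the methods note for the explicit expressions);
    near ``r = 1`` the series slope uses the limit effective size from
    :func:`coalfix.coalescence.closed_form_neff_si_limit`.
    """
    if n < 2 or m < 2 or h < 2:
        raise InvalidParameterError("Star of Islands needs n, m >= 2 and h >= 2")
    r = _check_r(r)
    N = n * m + h
    if abs(r - 1.0) < SERIES_WINDOW:
        return _series(N, closed_form_neff_si_limit(n, m, h), r)
    r = np.float64(r)
    am = r ** (m - 1) - 1.0
    ah = r ** (h - 1) - 1.0
    x = (m * r ** float(-m) * am + h * ah) / (m * r ** float(h) * am + h * ah)
    em = 1 - r ** (-(m - 1))
    eh = 1 - r ** (-(h - 1))
    num = (
        r**m
        * (1 - 1 / r)
        * (1 - r ** (-(h + m)))
        * (
            h * r**h * eh * (m * n * (m - 1) * r**m + h * (h - 1))
            + m * r**m * em * (m * n * (m - 1) + h * (h - 1) * r**h)
        )
    )
    with np.errstate(over="ignore"):
        xn = x ** np.float64(n)
        den = (
            N
            * (h * eh + m * r**m * em)
            * (m * r**m * em * (1 - xn) + h * eh * (r ** (h + m) - xn))
        )
        return float(num / den)


def rho_si_inf(m: int, h: int, r: float) -> float:
    """Many-island limit of the Star of Islands: ``n -> inf``.

    Zero for ``r <= 1``; for ``r > 1``,
    ``rho = (m-1)(1 - 1/r)(1 - r^-(h+m)) /
    [h r^-m (1 - r^-(h-1)) + m (1 - r^-(m-1))]``.
    """
    if m < 2 or h < 2:
        raise InvalidParameterError("needs m >= 2 and h >= 2")
    r = _check_r(r)
    if r <= 1.0:
        return 0.0
    if r - 1.0 < SERIES_WINDOW:
        return (m - 1) * (h + m) * (r - 1.0) / (h * (h - 1) + m * (m - 1))
    num = (m - 1) * (1 - 1 / r) * (1 - r ** (-(h + m)))
    den = h * r ** float(-m) * (1 - r ** (-(h - 1))) + m * (1 - r ** (-(m - 1)))
    return num / den


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------

@dataclass
class FixationCurve:
    """``rho(r)`` evaluated on a grid by one method.

    ``method`` is one of ``"exact-chain"``, ``"closed-form"`` or
    ``"monte-carlo"``; ``graph_descriptor`` names the family and its
    parameters (or an edge-list source).
    """

    r_values: np.ndarray
    rho_values: np.ndarray
    method: str
    graph_descriptor: str

    def __post_init__(self) -> None:
        self.r_values = np.asarray(self.r_values, dtype=float)
        self.rho_values = np.asarray(self.rho_values, dtype=float)
        if self.r_values.shape != self.rho_values.shape:
            raise ValueError("r and rho grids must have the same length")
        if np.any((self.rho_values < -1e-12) | (self.rho_values > 1 + 1e-12)):
            raise ValueError("fixation probabilities must lie in [0, 1]")


def fixation_curve(
    rho_fn: Callable[[float], float],
    r_values: Sequence[float],
    method: str,
    graph_descriptor: str,
) -> FixationCurve:
    """Evaluate ``rho_fn`` on a fitness grid and bundle the result."""
    r_arr = np.asarray(list(r_values), dtype=float)
    rho = np.array([rho_fn(float(r)) for r in r_arr])
    return FixationCurve(r_arr, rho, method, graph_descriptor)
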