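"""Coalescing random walks, effective population size, weak selection.

The ancestry of a pair of individuals under neutral death-Birth dynamics
is traced backwards by a pair of coalescing random walkers on the graph.
At each step one of the two walkers (chosen with equal probability) moves
according to the step probabilities ``p_ij``.  The expected meeting times
``tau_ij`` solve the linear system

    tau_ii = 0,
    tau_ij = 1 + (1/2) * sum_k (p_ik tau_jk + p_jk tau_ik),   i != j,

and the *remeeting time* of vertex ``i`` — the expected time for two
independent walkers launched at ``i`` to meet again — is

    tau_i = 1 + sum_j p_ij tau_ij.

Remeeting times obey Kac's return-time identity
``sum_i pi_i^2 tau_i = 1``.  The *effective population size*

    N_eff = sum_i pi_i tau_i

governs fixation under weak selection: a mutant of fitness ``r = 1 + d``
fixes with probability ``1/N + d (N_eff - 2)/(2N) + O(d^2)``.  A graph is
an amplifier (suppressor) of weak selection when ``N_eff > N``
(``N_eff < N``); isothermal graphs have ``N_eff = N`` exactly.

The module also provides closed forms for the effective size of the Fan,
Separated Hubs and Star of Islands families, the mean-field degree-moment
approximation ``N_eff ~ N mu1^2 / mu2``, the derivative of ``N_eff`` with
respect to an edge-weight perturbation of an isothermal graph, and the
perturbation recipe that manufactures amplifiers of weak selection from
isothermal graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix, diags, identity, kron
from scipy.sparse.linalg import lgmres, splu

from .graphs import (
    DisconnectedGraphError,
    InvalidParameterError,
    WeightedGraph,
    degree_moments,
    is_isothermal,
    stationary_distribution,
    step_probabilities,
    weighted_degrees,
)

__all__ = [
    "Tolerances",
    "CoalescenceResult",
    "WeakSelectionResult",
    "NumericalError",
    "coalescence_times",
    "remeeting_times",
    "effective_population_size",
    "weak_selection_fixation",
    "closed_form_neff_fan",
    "closed_form_neff_sh_limit",
    "closed_form_neff_si_limit",
    "meanfield_neff",
    "er_meanfield_ratio",
    "neff_gradient",
    "construct_amplifier",
    "covariance_identity_residual",
]


class NumericalError(RuntimeError):
    """The pairwise coalescence system could not be solved accurately."""


@dataclass(frozen=True)
class Tolerances:
    """Numerical tolerances used by the coalescence engine.

    Attributes
    ----------
    eq_residual
        Maximum allowed residual per pairwise-meeting-time equation.
    kac
        Maximum allowed deviation of ``sum_i pi_i^2 tau_i`` from 1.
    isothermal
        Relative spread of weighted degrees below which a graph is
        treated as isothermal.
    direct_max_n
        Largest ``N`` solved by sparse direct factorization (with
        iterative refinement); larger systems use a Krylov iteration.
    krylov_tol
        Relative tolerance of the Krylov route.
    fd_step
        Step used when cross-checking the analytic ``N_eff`` gradient by
        central finite differences.
    """

    eq_residual: float = 1e-9
    kac: float = 1e-8
    isothermal: float = 1e-10
    direct_max_n: int = 25
    krylov_tol: float = 1e-12
    fd_step: float = 1e-5


DEFAULT_TOL = Tolerances()


@dataclass
class CoalescenceResult:
    """Coalescence times, remeeting times and effective population size.

    ``tau_pair[i, j]`` is the expected pair-coalescence time from vertices
    ``i`` and ``j`` (in update steps of the alternating pair walk);
    ``tau_remeet[i]`` the remeeting time of vertex ``i``; ``pi`` the
    stationary distribution; ``n_eff = sum_i pi_i tau_i``; and
    ``kac_residual = |sum_i pi_i^2 tau_i - 1|``.
    """

    tau_pair: np.ndarray
    tau_remeet: np.ndarray
    pi: np.ndarray
    n_eff: float
    kac_residual: float

    @property
    def N(self) -> int:
        return self.pi.shape[0]

    def to_report(self, tol: float = 1e-9) -> dict:
        """JSON-ready summary with the weak-selection classification."""
        n = self.N
        if self.n_eff - n > tol * n:
            weak = "amplifier-of-weak-selection"
        elif self.n_eff - n < -tol * n:
            weak = "suppressor-of-weak-selection"
        else:
            weak = "neither"
        return {
            "N": n,
            "n_eff": self.n_eff,
            "ratio": self.n_eff / n,
            "kac_residual": self.kac_residual,
            "slope": (self.n_eff - 2) / (2 * n),
            "classification_weak": weak,
        }


@dataclass
class WeakSelectionResult:
    """First-order expansion of fixation probability around neutrality.

    For mutant fitness ``r = 1 + delta``,
    ``rho = 1/N + delta * slope + O(delta^2)`` with
    ``slope = (n_eff - 2) / (2 N)``.
    """

    N: int
    n_eff: float
    slope: float = field(init=False)

    def __post_init__(self) -> None:
        self.slope = (self.n_eff - 2.0) / (2.0 * self.N)

    def rho_at(self, delta: float) -> float:
        """Linearized fixation probability at selection coefficient ``delta``."""
        return 1.0 / self.N + delta * self.slope


def coalescence_times(
    G: WeightedGraph, tol: Tolerances = DEFAULT_TOL
) -> np.ndarray:
    """Solve the pairwise meeting-time system; return the full ``tau`` matrix.

    The pair walk is an absorbing chain on ordered vertex pairs whose
    generator has Kronecker structure ``(P (x) I + I (x) P) / 2``;
    diagonal pairs (already-met walkers) are absorbing with time 0.  The
    resulting sparse linear system is solved by direct LU factorization
    up to ``tol.direct_max_n`` vertices and by lgmres beyond.  Every
    equation's residual is verified against ``tol.eq_residual``; the
    equations for ``(i, j)`` and ``(j, i)`` coincide, so the solution is
    symmetric.
    """
    G.require_connected()
    N = G.N
    p = csr_matrix(step_probabilities(G))
    ident = identity(N, format="csr")
    A = identity(N * N, format="csr") - 0.5 * (kron(p, ident) + kron(ident, p))
    # absorbing rows for diagonal pairs: tau_ii = 0
    diag_idx = np.arange(N) * N + np.arange(N)
    keep = np.ones(N * N)
    keep[diag_idx] = 0.0
    R = diags(keep, format="csr")
    A = R @ A + diags(1.0 - keep, format="csr")
    b = keep.copy()  # 1 for off-diagonal pairs, 0 for diagonal

    # The pair graph is an expander, so LU fill-in grows quickly with N;
    # direct factorization is reserved for small systems (where it is
    # robust to the ill-conditioning of tiny-eps family graphs) and
    # Krylov iteration used beyond.  A couple of iterative-refinement
    # passes push the residual to the requested level in either case.
    try:
        if N <= tol.direct_max_n:
            lu = splu(A.tocsc())
            x = lu.solve(b)
            for _ in range(3):
                resid = b - A @ x
                if np.max(np.abs(resid)) <= tol.eq_residual:
                    break
                x = x + lu.solve(resid)
        else:
            x, info = lgmres(
                A.tocsr(), b, rtol=tol.krylov_tol, atol=0.0, maxiter=5000
            )
            if info != 0:
                raise NumericalError(f"lgmres did not converge (info={info})")
    except RuntimeError as exc:  # singular factorization
        raise NumericalError(f"coalescence system is singular: {exc}") from exc

    residual = np.max(np.abs(A @ x - b))
    if residual > tol.eq_residual:
        raise NumericalError(
            f"coalescence equations residual {residual:.3e} exceeds "
            f"{tol.eq_residual:.1e}"
        )

    tau = x.reshape(N, N)
    # equations are transpose-symmetric; enforce exact symmetry of the output
    tau = 0.5 * (tau + tau.T)
    np.fill_diagonal(tau, 0.0)
    return tau


def remeeting_times(G: WeightedGraph, tau_pair: np.ndarray) -> np.ndarray:
    """Remeeting times ``tau_i = 1 + sum_j p_ij tau_ij``."""
    tau_pair = np.asarray(tau_pair, dtype=float)
    if tau_pair.shape != (G.N, G.N):
        raise ValueError(
            f"tau_pair has shape {tau_pair.shape}, expected {(G.N, G.N)}"
        )
    p = step_probabilities(G)
    return 1.0 + (p * tau_pair).sum(axis=1)


def effective_population_size(
    G: WeightedGraph, tol: Tolerances = DEFAULT_TOL
) -> CoalescenceResult:
    """Full coalescence analysis of ``G``: ``tau_ij``, ``tau_i``, ``N_eff``.

    ``N_eff = sum_i pi_i tau_i``; Kac's identity
    ``sum_i pi_i^2 tau_i = 1`` is evaluated as a solver diagnostic and
    stored as ``kac_residual``.
    """
    tau_pair = coalescence_times(G, tol)
    tau_remeet = remeeting_times(G, tau_pair)
    pi = stationary_distribution(G)
    n_eff = float(pi @ tau_remeet)
    kac = float(abs(pi**2 @ tau_remeet - 1.0))
    return CoalescenceResult(
        tau_pair=tau_pair,
        tau_remeet=tau_remeet,
        pi=pi,
        n_eff=n_eff,
        kac_residual=kac,
    )


def weak_selection_fixation(
    G: WeightedGraph, tol: Tolerances = DEFAULT_TOL
) -> WeakSelectionResult:
    """Weak-selection expansion ``rho(1+d) = 1/N + d (N_eff-2)/(2N) + O(d^2)``."""
    res = effective_population_size(G, tol)
    return WeakSelectionResult(N=G.N, n_eff=res.n_eff)


# ---------------------------------------------------------------------------
# closed forms for the example families
# ---------------------------------------------------------------------------

def closed_form_neff_fan(n: int, m: int, eps: float) -> float:
    """Effective population size of the Fan ``F_{n,m}`` with hub weight ``eps``.

    ``eps = 0`` returns the analytic limit ``n m + n - 1`` (the graph
    itself is disconnected at ``eps = 0``; the limit is approached as
    ``eps -> 0``).  At the isothermal point ``eps = (m-1)/(n m - 1)`` the
    correction term vanishes and ``N_eff = N = n m + 1`` exactly.
    """
    if n < 2 or m < 2:
        raise InvalidParameterError("Fan needs n >= 2 and m >= 2")
    if eps < 0:
        raise InvalidParameterError("eps must be >= 0")
    if eps == 0:
        return float(n * m + n - 1)
    N = n * m + 1
    num = (m - 1 - eps * (n * m - 1)) * (
        m * (m - 1) * (n - 2)
        + eps * (n * m**2 + n * m - 4 * m + 2)
        + 2 * eps**2 * (n * m - 1)
    )
    den = (m - 1 + 2 * eps) * (
        m * (m - 1) + eps * (n * m + 2 * m - 1) + eps**2 * (n * m + 1)
    )
    return N + num / den


def closed_form_neff_sh_limit(n: int, m: int, h: int) -> float:
    """``eps -> 0`` effective size of Separated Hubs: ``n m + n - 1``.

    Remarkably independent of the number of hubs ``h`` (which still sets
    the actual size ``N = n m + h``, so the ratio ``N_eff/N`` falls to 0
    as ``h`` grows).
    """
    if n < 2 or m < 2 or h < 1:
        raise InvalidParameterError("Separated Hubs needs n, m >= 2 and h >= 1")
    return float(n * m + n - 1)


def closed_form_neff_si_limit(n: int, m: int, h: int) -> float:
    """``eps -> 0`` effective size of the Star of Islands ``SI_{n,m,h}``.

    The correction to ``N = n m + h`` carries the sign of ``m - h``:
    amplifier of weak selection for ``m > h``, suppressor for ``m < h``,
    and exactly ``N`` for ``m = h``.
    """
    if n < 2 or m < 2 or h < 2:
        raise InvalidParameterError("Star of Islands needs n, m >= 2 and h >= 2")
    N = n * m + h
    a = h * (h - 1)
    b = m * (m - 1)
    num = (m - h) * m * n * h * (a + b * (n - 2))
    den = (a + b) * (a + b * n)
    return N + num / den


def meanfield_neff(G: WeightedGraph) -> float:
    """Degree-moment approximation ``N_eff ~ N mu1^2 / mu2``.

    Derived by assuming all remeeting times equal and applying Kac's
    identity.  Always ``<= N`` (variance nonnegativity), with equality
    exactly for isothermal graphs — so amplification is invisible to this
    approximation.
    """
    mom = degree_moments(G)
    return G.N * mom.mu1**2 / mom.mu2


def er_meanfield_ratio(N: int, p: float) -> float:
    """Predicted ``N_eff/N`` for Erdős–Rényi graphs: ``(N-1)p/((N-2)p + 1)``.

    Obtained from the degree-moment approximation with each degree
    distributed as ``Binom(N-1, p)``.
    """
    if not 0 < p <= 1:
        raise InvalidParameterError("link probability p must be in (0, 1]")
    return (N - 1) * p / ((N - 2) * p + 1)


# ---------------------------------------------------------------------------
# perturbations of isothermal graphs
# ---------------------------------------------------------------------------

def _pi_derivative(
    G0: WeightedGraph, perturb: Mapping[tuple[int, int], float]
) -> np.ndarray:
    """d(pi)/d(eps) at eps = 0 for edge-weight direction ``perturb``.

    ``perturb[(i, j)] = dw_ij/deps``.  With ``W = sum_i w_i``,
    ``dpi_i = (dw_i W - w_i dW) / W^2`` where ``dw_i`` sums the perturbed
    weights incident to ``i`` and ``dW = sum_i dw_i``.
    """
    N = G0.N
    dw = np.zeros(N)
    for (i, j), dval in perturb.items():
        if i == j:
            raise InvalidParameterError("cannot perturb a self-loop")
        dw[i] += dval
        dw[j] += dval
    deg = weighted_degrees(G0)
    W = deg.sum()
    dW = dw.sum()
    return (dw * W - deg * dW) / W**2


def neff_gradient(
    G0: WeightedGraph,
    perturb: Mapping[tuple[int, int], float],
    tol: Tolerances = DEFAULT_TOL,
) -> float:
    """Derivative of ``N_eff`` along an edge-weight perturbation at eps = 0.

    For a family of graphs that is isothermal at ``eps = 0``,

        dN_eff/deps |_0 = - sum_i tau_i * dpi_i/deps |_0 ,

    with ``dpi/deps`` computed analytically from the degree perturbation.
    A positive gradient means the perturbation manufactures an amplifier
    of weak selection.
    """
    if not is_isothermal(G0, tol.isothermal):
        raise InvalidParameterError("base graph must be isothermal")
    res = effective_population_size(G0, tol)
    dpi = _pi_derivative(G0, perturb)
    return float(-(res.tau_remeet @ dpi))


def construct_amplifier(
    G0: WeightedGraph,
    eps: float,
    tol: Tolerances = DEFAULT_TOL,
    vertex: int | None = None,
    neighbor: int | None = None,
) -> tuple[WeightedGraph, CoalescenceResult]:
    """Perturb an isothermal graph towards an amplifier of weak selection.

    Recipe: find the vertex with the largest remeeting time (smallest
    index on ties, unless ``vertex`` overrides), pick the incident edge
    whose weight decrease gives the largest ``N_eff`` gradient (unless
    ``neighbor`` overrides), and reduce that edge's weight by ``eps``.
    Neighbors whose perturbed edge would disconnect the graph are passed
    over in favor of the next-best gradient.

    Returns the perturbed graph and its coalescence analysis; whether the
    perturbation actually amplifies (``n_eff > N``) is recorded in
    ``meta["amplifier_of_weak_selection"]``.
    """
    if not is_isothermal(G0, tol.isothermal):
        raise InvalidParameterError("base graph must be isothermal")
    if not 0 <= eps:
        raise InvalidParameterError("eps must be >= 0")
    res0 = effective_population_size(G0, tol)
    if vertex is None:
        vertex = int(np.argmax(np.round(res0.tau_remeet, 12)))
    if neighbor is None:
        candidates = sorted(
            (
                (neff_gradient(G0, {(vertex, int(j)): -1.0}, tol), int(j))
                for j in np.nonzero(G0.w[vertex] > 0)[0]
            ),
            key=lambda t: (-t[0], t[1]),
        )
        for _, j in candidates:
            trial = G0.copy()
            trial.w[vertex, j] -= eps
            trial.w[j, vertex] -= eps
            if eps <= G0.w[vertex, j] and trial.is_connected():
                neighbor = j
                break
        if neighbor is None:
            raise DisconnectedGraphError(
                "every candidate perturbation disconnects the graph"
            )
    if G0.w[vertex, neighbor] <= 0:
        raise InvalidParameterError(
            f"vertices {vertex} and {neighbor} are not adjacent"
        )
    if eps > G0.w[vertex, neighbor]:
        raise InvalidParameterError("eps exceeds the chosen edge weight")

    G = G0.copy()
    G.w[vertex, neighbor] -= eps
    G.w[neighbor, vertex] -= eps
    if not G.is_connected():
        raise DisconnectedGraphError("perturbation disconnects the graph")
    res = effective_population_size(G, tol)
    G.meta.update(
        {
            "perturbed_edge": (int(vertex), int(neighbor)),
            "eps": eps,
            "amplifier_of_weak_selection": bool(res.n_eff > G.N),
        }
    )
    return G, res


def covariance_identity_residual(
    G: WeightedGraph, tol: Tolerances = DEFAULT_TOL
) -> float:
    """Residual of the covariance form of the amplification criterion.

    ``(N - N_eff)/N^2`` equals the covariance of ``pi_i`` with
    ``pi_i tau_i`` over vertices; a graph amplifies weak selection iff
    that covariance is negative.  Returns the absolute mismatch between
    the two sides (should be at numerical noise level).
    """
    res = effective_population_size(G, tol)
    N = G.N
    lhs = (N - res.n_eff) / N**2
    x = res.pi
    y = res.pi * res.tau_remeet
    cov = float((x * y).mean() - x.mean() * y.mean())
    return abs(lhs - cov)
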