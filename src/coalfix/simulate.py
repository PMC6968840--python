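"""Seeded Monte Carlo simulation of death-Birth dynamics.

Each trial places a single mutant of fitness ``r`` at a uniformly random
vertex and iterates the update rule — a uniformly chosen individual dies
and the vacancy is filled by neighbor ``j`` with probability
proportional to ``f_j * w_jd`` — until the mutant lineage either fixes
or goes extinct.  On a connected graph absorption is almost sure, so no
step cap is applied by default; an optional ``max_steps`` guards
pathological near-disconnected graphs (capped trials are reported and
excluded from the estimate, never silently dropped).

Trials are advanced in a vectorized batch from a single explicitly
seeded generator, so a run is bit-reproducible given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import InvalidParameterError, WeightedGraph

__all__ = ["SimulationEstimate", "simulate_fixation"]


@dataclass(frozen=True)
class SimulationEstimate:
    """Monte Carlo fixation-probability estimate.

    ``rho_hat = fixed_count / trials`` over completed trials, with
    binomial standard error ``se = sqrt(rho_hat (1 - rho_hat) / trials)``.
    ``max_steps_hit`` counts trials that reached the step cap; those are
    excluded from ``trials``.
    """

    rho_hat: float
    trials: int
    fixed_count: int
    se: float
    seed: int
    max_steps_hit: int = 0

    def to_report(self) -> dict:
        return {
            "rho_hat": self.rho_hat,
            "trials": self.trials,
            "fixed_count": self.fixed_count,
            "se": self.se,
            "seed": self.seed,
            "max_steps_hit": self.max_steps_hit,
        }


def simulate_fixation(
    G: WeightedGraph,
    r: float,
    trials: int,
    seed: int,
    max_steps: int | None = None,
) -> SimulationEstimate:
    """Estimate the fixation probability of a single uniform mutant.

    Parameters
    ----------
    G
        Connected weighted graph.
    r
        Mutant fitness (> 0); residents have fitness 1.
    trials
        Number of independent trials.
    seed
        Seed of the single RNG stream driving all trials.
    max_steps
        Optional per-trial step cap; capped trials are counted in
        ``max_steps_hit`` and excluded from the estimate.
    """
    if r <= 0:
        raise InvalidParameterError("mutant fitness r must be > 0")
    if trials < 1:
        raise InvalidParameterError("trials must be >= 1")
    G.require_connected()
    N = G.N
    w = G.w
    rng = np.random.default_rng(seed)

    # state[t, i] True if vertex i is a mutant in trial t
    state = np.zeros((trials, N), dtype=bool)
    state[np.arange(trials), rng.integers(N, size=trials)] = True
    active = np.arange(trials)
    fixed = np.zeros(trials, dtype=bool)
    capped = np.zeros(trials, dtype=bool)

    steps = 0
    while active.size:
        sub = state[active]
        n_act = active.size
        d = rng.integers(N, size=n_act)
        # competition for each vacancy: scores_j = f_j * w_{j,d}
        f = np.where(sub, r, 1.0)
        scores = f * w[:, d].T
        totals = scores.sum(axis=1)
        # connected graph: every vertex has a positively weighted neighbor
        assert np.all(totals > 0), "vacant vertex with zero neighbor weight"
        u = rng.random(n_act) * totals
        parent = (np.cumsum(scores, axis=1) < u[:, None]).sum(axis=1)
        state[active, d] = state[active, parent]

        counts = state[active].sum(axis=1)
        done = (counts == 0) | (counts == N)
        fixed[active[counts == N]] = True
        steps += 1
        if max_steps is not None and steps >= max_steps:
            capped[active[~done]] = True
            active = active[:0]
        else:
            active = active[~done]

    completed = int(trials - capped.sum())
    n_fixed = int(fixed.sum())
    rho_hat = n_fixed / completed if completed else float("nan")
    se = (
        float(np.sqrt(rho_hat * (1.0 - rho_hat) / completed))
        if completed
        else float("nan")
    )
    return SimulationEstimate(
        rho_hat=rho_hat,
        trials=completed,
        fixed_count=n_fixed,
        se=se,
        seed=seed,
        max_steps_hit=int(capped.sum()),
    )
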