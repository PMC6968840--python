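"""Manufacturing an amplifier of weak selection from an isothermal graph.

Any isothermal graph has N_eff = N exactly.  Down-weighting an edge at
the vertex with the largest remeeting time pushes stationary mass away
from slow-remeeting vertices, so dN_eff/deps > 0 and the perturbed graph
amplifies weak selection.  This script runs that recipe on random
3-regular graphs of size 12 and also reports a full edge deletion that
stays an amplifier.
"""

import numpy as np

from coalfix.coalescence import construct_amplifier, effective_population_size
from coalfix.graphs import DisconnectedGraphError, make_random_regular

print("small perturbation (eps = 0.05) of the max-remeeting-time edge:")
for seed in (0, 100, 200, 300, 400):
    G0 = make_random_regular(12, 3, seed=seed)
    res0 = effective_population_size(G0)
    G1, res1 = construct_amplifier(G0, eps=0.05)
    u, v = G1.meta["perturbed_edge"]
    print(
        f"  seed {seed:3d}: max tau_i = {res0.tau_remeet.max():7.3f} "
        f"(chosen vertex {u}); edge ({u},{v}) -> "
        f"N_eff = {res1.n_eff:.4f}  (amplifier: {res1.n_eff > 12})"
    )

print("\nfull edge deletion (eps = 1), searching for a graph that stays an amplifier:")
for seed in range(200):
    G0 = make_random_regular(12, 3, seed=seed)
    try:
        G1, res1 = construct_amplifier(G0, eps=1.0)
    except DisconnectedGraphError:
        continue
    if res1.n_eff > 12:
        res0 = effective_population_size(G0)
        print(
            f"  seed {seed}: max tau_i = {res0.tau_remeet.max():.2f}, "
            f"deleted edge {G1.meta['perturbed_edge']}, N_eff = {res1.n_eff:.4f} > 12"
        )
        break

print(
    "\nEvery small perturbation amplifies (the gradient at an isothermal"
    "\ngraph is positive); staying an amplifier after deleting the whole"
    "\nedge is rarer, but the search finds such a graph."
)
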