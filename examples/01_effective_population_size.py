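"""Effective population size of small graphs via coalescing random walks.

Builds a few named graphs, solves the pairwise coalescence-time system,
and prints N_eff = sum_i pi_i tau_i next to the actual size N.  A graph
with N_eff > N amplifies weak selection; N_eff < N suppresses it;
isothermal graphs (uniform weighted degree) sit exactly at N_eff = N.
"""

from coalfix.coalescence import effective_population_size
from coalfix.graphs import (
    make_complete,
    make_cycle,
    make_fan,
    make_star,
    make_star_of_islands,
)

graphs = {
    "complete K_8 (well-mixed)": make_complete(8),
    "cycle C_8 (isothermal)": make_cycle(8),
    "star S_7 (hub + 7 leaves)": make_star(7),
    "Fan F_{3,2}, eps=0.1": make_fan(3, 2, 0.1),
    "Star of Islands SI_{2,3,3}, eps=0.1": make_star_of_islands(2, 3, 3, 0.1),
}

print(f"{'graph':40s} {'N':>3s} {'N_eff':>8s} {'N_eff/N':>8s}")
for name, G in graphs.items():
    res = effective_population_size(G)
    print(f"{name:40s} {G.N:3d} {res.n_eff:8.4f} {res.n_eff / G.N:8.4f}")

print(
    "\nThe star's N_eff = 4n/(n+1) < N marks it as a suppressor of weak"
    "\nselection; the small-eps Fan exceeds its actual size (amplifier);"
    "\nisothermal graphs (complete, cycle) sit exactly at N_eff = N."
)
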