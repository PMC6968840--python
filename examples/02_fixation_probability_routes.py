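"""Three routes to the same fixation probability.

For a 6-cycle and mutant fitness r = 2, computes rho by (i) the exact
2^N absorbing-chain solver, (ii) the closed-form cycle expression, and
(iii) seeded Monte Carlo simulation of the death-Birth process.  The
first two agree to solver precision; the Monte Carlo estimate lands
within a few binomial standard errors.
"""

from coalfix.exact import rho_cycle, rho_exact
from coalfix.graphs import make_cycle
from coalfix.simulate import simulate_fixation

G = make_cycle(6)
r = 2.0

exact = rho_exact(G, r)
closed = rho_cycle(6, r)
est = simulate_fixation(G, r, trials=50_000, seed=7)

print(f"cycle C_6, mutant fitness r = {r}")
print(f"  exact chain : rho = {exact:.10f}")
print(f"  closed form : rho = {closed:.10f}   (|diff| = {abs(exact-closed):.2e})")
print(f"  Monte Carlo : rho = {est.rho_hat:.4f} +/- {est.se:.4f}  ({est.trials} trials, seed {est.seed})")
print(
    f"\nA fitness-2 mutant fixes with probability ~{exact:.3f} here, below"
    f"\nthe well-mixed value — the cycle reduces fixation for every r != 1."
)
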