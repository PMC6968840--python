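"""The m=2 Fan as a transient amplifier of selection.

Classifies the eps->0 limit of the Fan against the well-mixed curve for
a range of blade counts, printing the verdict and, for transient
amplifiers, the crossing fitness r* beyond which amplification stops.
As n grows, r* approaches the golden ratio (1 + sqrt 5)/2.
"""

import math

from coalfix.classify import classify_full, find_crossing
from coalfix.exact import rho_fan_limit, rho_sh_inf

print(f"{'blades n':>8s} {'N':>4s} {'verdict':>22s} {'r*':>10s}")
for n in range(2, 9):
    rep = classify_full(lambda r: rho_fan_limit(n, 2, r), 2 * n + 1)
    r_star = f"{rep.r_star:.6f}" if rep.r_star else "-"
    print(f"{n:8d} {2 * n + 1:4d} {rep.verdict:>22s} {r_star:>10s}")

golden = (1 + math.sqrt(5)) / 2
r_inf = find_crossing(lambda r: rho_sh_inf(2, r), math.inf, (1.1, 10.0))
print(f"\nmany-blade limit: r* = {r_inf:.8f}  (golden ratio = {golden:.8f})")
print(
    "\nTwo blades give a reducer; three or more give a transient amplifier"
    "\nwhose amplification window 1 < r < r* widens toward the golden ratio."
)
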