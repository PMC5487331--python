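"""Choosing the Louvain resolution parameter for the karate club.

Sweeps gamma over 0.1-2.0, running Louvain 200 times per value (use
1000 for publication-grade curves), and reports the non-trivial gamma
values that minimise the global mean versatility, then inspects the
most versatile node at the winning resolution.
"""

import numpy as np

from versatility import (
    accumulate,
    find_optima,
    karate_fixture,
    louvain_adapter,
    run_ensemble,
    sweep_resolution,
    versatility,
)

G = karate_fixture()
gammas = [round(0.1 * k, 1) for k in range(1, 21)]
result = sweep_resolution(G, gammas, runs_per_gamma=200, base_seed=1)

print(result.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4f}"))

optima = find_optima(result)
print("\ncandidate optimal resolutions (best first):")
for gamma, kind in optima:
    print(f"  gamma = {gamma:g}  ({kind})")

best = optima[0][0]
ens = run_ensemble(G, louvain_adapter(best), 200, base_seed=2)
values = versatility(accumulate(ens)).values
top = int(np.argmax(values))
print(f"\nat gamma = {best:g}, most versatile node: {ens.node_ids[top]} "
      f"(V = {values[top]:.3f})")
print(
    "\nThe curve dips near gamma = 0.5, where the club splits into its"
    "\ntwo historical factions; the most versatile node is the member"
    "\nwith exactly one friendship on each side of the split."
)
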