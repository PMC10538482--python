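"""Greedy defense vs exhaustive enumeration on a tiny Beacon instance.

Every yes-response SNV can be flipped, masked, or reported truthfully —
3^|Q1| plans, all scored exactly.  The greedy objective can match but
never beat the enumeration optimum.
"""

import numpy as np

import beaconshield as bs

rng = np.random.default_rng(5)
p = rng.uniform(0.05, 0.4, 6)
q = 1.0 - (1.0 - p) ** 2
panel = bs.build_panel(
    (rng.random((4, 6)) < q).astype(int),
    (rng.random((4, 6)) < q).astype(int),
    p, gamma=1e-6, mode=bs.BEACON,
)
constants = bs.compute_constants(panel)
release = bs.make_release(panel)
eta = bs.beacon_scores(constants, release, None, panel.d)
spec = bs.AttackSpec(model="fixed", theta=float(np.median(eta)) + 0.2)

plan, point = bs.spg_b(panel, constants, release, spec, w=1.0, alpha=0.5)
sol = bs.exact_beacon(panel, constants, release, spec, w=1.0, alpha=0.5)
print(f"|Q1| = {len(release.Q1)}, plans enumerated: {sol.n_searched}")
print(f"greedy objective: {point.objective:.4f}")
print(f"exact  objective: {sol.objective:.4f}")
print("A zero gap means the greedy found an optimal plan on this instance; "
      "on small random instances it is optimal most of the time and never "
      "better than the oracle.")
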