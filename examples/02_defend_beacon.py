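"""Greedy Beacon defense (SPG-B) across privacy weights.

Each run flips or masks yes-responses until every member clears the
attacker's threshold, keeping the best objective α|F| + (1−α)|M| − w|Z|
seen.  Larger w buys more privacy at a utility cost.
"""

import numpy as np

import beaconshield as bs

cfg = bs.SimulationConfig(n=60, n_ref=60, m=400, seed=1)
panel = bs.simulate_panel(cfg)
constants = bs.compute_constants(panel)
release = bs.make_release(panel)
eta = bs.beacon_scores(constants, release, None, panel.d)
spec = bs.AttackSpec(model="fixed", theta=float(np.median(eta)))

print(f"{'w':>7} {'flips':>6} {'masks':>6} {'utility%':>9} {'privacy%':>9}")
for w in (0.01, 0.1, 1.0, 10.0):
    plan, point = bs.spg_b(panel, constants, release, spec, w, alpha=0.5)
    print(f"{w:7.2f} {int(plan.noise_l1()):6d} {plan.n_masked:6d} "
          f"{point.utility_pct:9.2f} {point.privacy_pct:9.2f}")
print("Privacy never decreases with w: the scalarization trades released "
      "responses for protected members along a single greedy trajectory.")
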