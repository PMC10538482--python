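"""Alternating noise/masking defense (SPG-R) for allele-frequency releases.

Alternates Laplace noise (best ε from a candidate grid, scale Δg/(n·ε))
with batched masking in marginal-contribution order, and compares the
worst-case sensitivity Δg = |Q∖M| with the bounded variant (average
member↔reference Hamming distance).
"""

import beaconshield as bs

cfg = bs.SimulationConfig(n=60, n_ref=60, m=400, mode=bs.AAF, seed=2)
panel = bs.simulate_panel(cfg)
release = bs.make_release(panel)
spec = bs.AttackSpec(model="fixed", theta=0.0)

print(f"bounded sensitivity: {bs.bounded_sensitivity(panel):.1f} "
      f"(worst case would be m = {panel.m})")

for mode in ("unbounded", "bounded"):
    lap = bs.LaplaceSpec(epsilon_grid=(30.0, 100.0, 300.0, 1000.0),
                         sensitivity_mode=mode)
    plan, point = bs.spg_r(panel, release, spec, w=1.0, alpha=0.5,
                           laplace=lap, t=20, seed=0)
    print(f"{mode:9s}: masked {plan.n_masked:3d}, noise L1 {plan.noise_l1():7.3f}, "
          f"utility {point.utility_pct:6.2f}%, privacy {point.privacy_pct:6.2f}%")
print("For the same ε grid the bounded scale injects less noise (higher "
      "utility, less protection), and the alternation can combine it with "
      "masking; the unbounded scale buys full protection with noise alone.")
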