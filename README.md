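# beaconshield

Membership-inference attacks on genomic summary releases, and
optimization-based defenses that trade utility for privacy.

Genomic data custodians often share only limited views of a cohort: a
**Beacon** answers yes/no queries about whether an alternate allele is
present anywhere in the data set, and summary-statistics services publish
per-variant **alternate-allele frequencies (AAFs)**. Both are vulnerable to
likelihood-ratio-test (LRT) membership inference: an attacker holding a
target genome can test whether that genome helped shape the release.
`beaconshield` implements the attacks, the defenses, and the evaluation
machinery around them, for researchers studying genomic privacy and for
custodians who want to pick an operating point on the privacy–utility
frontier rather than an all-or-nothing policy.

## The model

For a cohort *D* of *n* diploid individuals over *m* biallelic SNVs, let
*d<sub>ij</sub>* ∈ {0,1} say whether individual *i* carries at least one
alternate allele at SNV *j*, let *p̄<sub>j</sub>* be the population AAF, and
γ the sequencing-error rate. With
*R<sub>n</sub><sup>j</sup>* = (1 − *p̄<sub>j</sub>*)<sup>2n</sup>, the Beacon
LRT score of individual *i* for a response vector *x* is

L(i) = Σ_j d_ij [ x_j·A_j + (1 − x_j)·B_j ],
  A_j = log((1 − R_n^j)/(1 − γR_{n−1}^j)),
  B_j = log(R_n^j/(γR_{n−1}^j))

and for an AAF release *x*:

L(i) = Σ_j d_ij·log(p̄_j/x_j) + (1 − d_ij)·log((1 − p̄_j)/(1 − x_j)).

Members score low. The attacker claims membership below a threshold θ —
either fixed, or **adaptive**: the mean score of the K%-lowest-scoring
individuals in a reference panel, recomputed after the defense. A defense
is a masked SNV set *M* plus noise δ (response flips for Beacons, Laplace
noise for AAFs); the custodian solves

min over (M, δ) of α‖δ‖₁ + (1 − α)|M| − w·|Z(M, δ)|

where Z is the set of members whose scores stay at or above θ, α prices
noise against masking, and w prices privacy against utility. Implemented
solvers:

- **SPG-B** — greedy Beacon defense: per iteration, flip or mask the
  yes-response SNV with the best average marginal score gain per unit cost.
- **SPG-R** — AAF defense alternating calibrated Laplace noise (best ε from
  a candidate grid; worst-case or bounded sensitivity) with batched masking.
- **SPG-LD** — LD-aware SPG-B that edits whole correlated SNV groups, so a
  correlation attacker cannot infer edits by majority vote over LD
  neighbors.
- An exhaustive **exact oracle** for small instances (all 3^|Q1| Beacon
  plans), plus random-flipping, mask-only and noise-only baselines, a
  synthetic panel generator (beta-distributed AAFs, Hardy–Weinberg
  carriers, optional LD blocks), and utility/privacy frontier sweeps.

Utility is 100·[1 − (α‖δ‖₁ + (1 − α)|M|)/m] %, privacy the percentage of
protected members.

## Worked example

```python
import numpy as np
import beaconshield as bs

cfg = bs.SimulationConfig(n=60, n_ref=60, m=400, seed=1)
panel = bs.simulate_panel(cfg)
constants = bs.compute_constants(panel)
release = bs.make_release(panel)
eta = bs.beacon_scores(constants, release, None, panel.d)
spec = bs.AttackSpec(model="fixed", theta=float(np.median(eta)))

for w in (0.01, 0.1, 1.0, 10.0):
    plan, point = bs.spg_b(panel, constants, release, spec, w, alpha=0.5)
    print(w, int(plan.noise_l1()), plan.n_masked,
          round(point.utility_pct, 2), round(point.privacy_pct, 2))
```

prints (w, flips, masks, utility %, privacy %):

```
0.01 0 0 100.0 50.0
0.1 1 0 99.88 93.33
1.0 2 0 99.75 100.0
10.0 2 0 99.75 100.0
```

At w = 0.01 privacy is too cheap to buy and the release is untouched; half
the members happen to sit above the median threshold anyway. Two flipped
responses (0.25% of the release, costed at α = 0.5) already protect the
whole cohort. `examples/` holds one short script per capability — the plain
attack, both greedy defenses, the LD arms race, and the exact oracle — each
printing the numbers it computes and what they mean.

A thin CLI mirrors the library (`beaconshield simulate | attack | defend |
oracle | correlate | sweep`); panels travel as TSV, plans and releases as
JSON, and real genotypes can be read from biallelic VCF via
`beaconshield.io.read_vcf_carriers`.

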