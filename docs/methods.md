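# Methods

## Data representation

A panel holds binary carrier matrices for the protected cohort `D` (n × m)
and a disjoint reference panel `D̄` (n̄ × m), reference AAFs `p̄`, and a
sequencing-error rate `γ` (default 1e-6, the typical order for modern
platforms). "AAF" throughout means the **carrier frequency** — the fraction
of individuals with at least one alternate allele — matching the binary
carrier encoding; diploid allele dosage is never used, while the
no-carrier probability `R_n = (1 − p̄)^{2n}` retains the diploid exponent.
SNV indices are 0-based internally; VCF positions stay 1-based inside SNV
identifiers (`chrom:pos:ref:alt`).

Beacon mode assumes the alternate allele is the minor allele (`p̄ < 0.5`);
violating SNVs are rejected or dropped by flag. `p̄` is floored at 1e-4 in
Beacon mode (a zero frequency would make the yes-response constant
`A = log(1 − R_n) − …` undefined) and clipped to [1e-4, 0.9999] in AAF
mode, mirroring the clipping of released frequencies. Two error-rate gates
apply: `γ < 0.25` in Beacon mode (it makes the no-response constant
`B > 0`, so flips and masks can only raise member scores), and
`γ < min (1 − p̄)²` over minor-allele SNVs in both modes (the condition
under which masking an absent allele can never help the attacker). The
second gate deliberately skips major-allele SNVs, which exist only in AAF
mode: clipped frequencies near 1 would make it unsatisfiable for any
realistic γ, and the guarantee it backs concerns minor alternate alleles.

## Attack models

Scores follow the two log-likelihood-ratio statistics in the README, with
masked SNVs dropping out of the sum and noise entering through the
effective release `x + δ`. Membership is claimed strictly below the
threshold; a member whose score ties the threshold is protected. The
fixed-threshold attacker uses an exogenous constant θ. The adaptive
attacker uses the mean score of the `⌈(K/100)·n̄⌉` lowest-scoring
reference individuals, re-identified from post-defense scores at every
evaluation, since the threshold is defined as a function of the defense.
(K is a percentile, with ceiling rounding and a minimum of one
individual.)

One pseudocode convention had to be resolved: the AAF defense listing
tests `score ≤ θ` for a *claim*, while the formal privacy-set definition,
the Beacon listing and both flip/mask propositions require `score ≥ θ` for
*protection*. The protection-at-`≥ θ` convention is used everywhere; it is
the only reading under which the components are mutually consistent.

## SPG-B (greedy Beacon defense)

Per-SNV marginals for yes-response SNVs are `Δ^F = B − A` (flip) and
`Δ^M = −A` (mask). Each iteration scores every still-editable yes-SNV by
its average marginal contribution per unit cost over the not-yet-protected
members P — `|T_j|Δ_j/(cost·|P|)` with `T_j` the carriers of j in P and
cost α (flip) or 1 − α (mask) — applies the single best action, and
records the objective; the best solution visited is returned, with the
empty plan as the starting incumbent (so with `w = 0`, or with everyone
already protected, no edit is made). Ties break toward flipping and toward
the lowest SNV index, making runs deterministic; equal-objective solutions
found later replace earlier ones. The loop ends when every member is
protected or no admissible SNV remains. Under the fixed threshold the
protected set only grows, because every admissible action weakly raises
every member's score.

Against the adaptive attacker the marginals are re-centred each iteration
on the current K-lowest reference group — `Δ_j(K) = Δ_j(1 − mean of d_kj
over that group)` — and only strictly positive adjusted marginals are
admissible, since an edit that helps the lowest reference scores more than
the members would move the threshold up. Coverage may fluctuate; the best
visited solution is still what is returned.

## SPG-R (alternating AAF defense)

SNVs are ranked once, at the noiseless release, by their average marginal
masking contribution (mean over members of
`−d·A(x) − (1−d)·B(x)`; adaptive mode subtracts the same average over the
baseline K-lowest reference group). Recomputing the order after each noise
draw would change the algorithm's complexity class without a prescribed
schedule, so the precomputed order is treated as an input. Each cycle
draws fresh Laplace noise on the unmasked SNVs for every candidate ε
(default grid {1e4 … 1e7}: with very many SNVs the useful ε are far above
the single-digit values familiar from low-dimensional releases), keeps the
best-objective ε, then masks the next batch of `t` SNVs
(default `max(1, m/200)`, balancing runtime against the density of
intermediate solutions) and refunds any noise already placed on them —
noise lives on `Q∖M` only, so masked SNVs never carry noise cost.
Coverage is re-evaluated after masking rather than carried over from the
noise step (the listing is ambiguous there; re-evaluation reports the true
objective of the state being recorded). Post-noise frequencies are clipped
to [1e-4, 0.9999] and δ re-derived from the clipped values, so the
reported ℓ₁ cost is the realized one.

Noise scale is `Δg/(n·ε)` with `Δg` either the worst-case sensitivity
`|Q∖M|` or the **bounded** variant — the average Hamming distance between
member and reference carrier vectors restricted to unmasked SNVs, computed
in closed form from the two panels' carrier frequencies and recomputed on
the surviving SNV set each cycle. Identical panels give zero sensitivity;
that degenerate case warns and adds no noise. Randomness derives from one
master seed through per-(cycle, ε) substreams, so runs are bit-reproducible
and any parallel evaluation would be forced to agree with the serial order.

## Correlation attack and SPG-LD

LD is the covariance-form coefficient `P(AB) − P(A)P(B)` over carrier
indicators, bounded by ±0.25; neighbor maps keep pairs with coefficient
above `t_LD` (default 0.2) within ±250 index positions (the span is in SNV
order, not base pairs — the sorted variant index is what both sides can
compute). The attacker's map is estimated on the reference panel (they
lack the cohort); the defender's on the cohort; both are configurable.

The attacker, assumed to know which SNVs were edited (a worst-case
evaluation), votes over each edited SNV's positively correlated neighbors:
if ≥ 75% of the unmasked neighbors answer yes, the working response
becomes yes — flipped SNVs revert to their yes-contribution and masked
SNVs re-enter the score with a yes response. Masked neighbors are excluded
from the vote's denominator; an SNV with no voting neighbors is never
inferred. Scores and claims are then re-evaluated under the chosen
threshold model.

SPG-LD counters by dividing each SNV's greedy score by its correlation
group size `|N_LD(j)|` (treated as 1 when empty, so uncorrelated SNVs cost
one unit exactly as in SPG-B) and, whenever a grouped SNV is selected,
applying the same action to every group member that still has a yes
response — the whole group's cost counts in the objective. With an empty
map SPG-LD is identical to SPG-B by construction.

## Exact oracle

On instances with at most 12 yes-SNVs, all `3^{|Q1|}` flip/mask/truthful
assignments are enumerated and scored exactly, for both threat models
(adaptive thresholds recomputed per plan); ties resolve to the
lexicographically smallest assignment. Enumeration was chosen over an
ILP/MIP solver as the reference implementation: it is dependency-free,
bit-reproducible, and its output is the ground truth the greedy defenses
are tested against. The AAF variant enumerates mask subsets crossed with a
discrete per-SNV noise grid, guarded by a total-plan-count limit.

## Synthetic panels

Reference AAFs are drawn from Beta(0.5, 5) — right-skewed toward rare
alleles, as empirical site-frequency spectra are — truncated to (1e-4,
0.5) in Beacon mode to enforce the minor-allele assumption at generation
time, and each individual carries SNV j with the Hardy–Weinberg carrier
probability `1 − (1 − p̄_j)²`. Cohort and reference are i.i.d. from the
same model, so LRT separation arises solely from the release reflecting
the cohort — exactly the signal the attacks exploit. Defaults (400 + 400
individuals) mirror a typical cohort/reference split; tests and examples
use smaller panels, which scale the same way.

LD blocks copy a block-seed carrier column and independently resample each
cell with probability 1 − ρ, so ρ = 1 gives identical columns with
carrier-indicator LD `f(1 − f)` at carrier frequency f. Note the carrier
frequency, not p̄, sets the attainable LD: blocks constructed at
`p̄ = 1 − √0.5 ≈ 0.293` have carrier frequency 0.5 and within-block LD
0.25, the maximum. The generator does not model coalescent ancestry,
recombination-distance-decaying LD, population structure, or genotyping
error beyond γ; passing tests therefore demonstrate correctness of the
machinery under the generative assumptions the statistics themselves make,
not performance on real cohorts.

By default the attacker is handed the generative `p̄` (the strongest
attacker); a flag re-estimates frequencies from the reference panel via
the Hardy–Weinberg inversion `p̂ = 1 − √(1 − f̄)` to emulate realistic
attacker knowledge.

## Numerical conventions and edge cases

- All clipping bounds are [1e-4, 0.9999]; every log argument is therefore
  strictly positive and all scores finite.
- `A < 0` and the strict flip/mask inequalities hold mathematically, but
  once `R_n` falls below double-precision resolution (~1e-16; very common
  alleles at large n) `A` evaluates to exactly 0; score comparisons in
  tests use weak inequalities with 1e-12 slack for this reason.
- Greedy tie-breaks (flip over mask, lowest index), `≤`-updates of the
  incumbent, and seed-derived noise substreams make every defense
  deterministic given its inputs and seed; file writers emit 12
  significant digits so round-trips reproduce scores exactly.
- Degenerate inputs: an all-no Beacon yields the empty plan with objective
  `−w|Z(∅,0)|`; α ∈ {0, 1} is rejected (one action class would be free);
  an empty ε grid or empty reference panel under the adaptive model is a
  configuration error.

## Known limitations

The defenses protect against the two LRT threat models only; attacks
outside that family may defeat them. The correlation attack is evaluated
in its worst-case form (edited SNVs known to the attacker). The AAF
release is a carrier-frequency vector, not a dosage AAF; custodians
publishing dosage frequencies would need to re-derive the statistic.
Problem sizes beyond ~10⁵ SNVs are supported in principle (everything is
O(m·n) per greedy iteration) but untested at that scale here; test and
example panels use hundreds to thousands of SNVs.
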