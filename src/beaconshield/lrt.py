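"""Likelihood-ratio-test membership-inference scoring.

Low LRT scores indicate membership: a member's carried alleles drag the
score down because the release reflects their genome.  The attacker claims
membership for every individual whose score falls strictly below a
threshold; privacy holds for members with score at or above it,

    Z(M, δ) = {i ∈ D : L_i(M, δ) − θ(M, δ) ≥ 0}.

Scoring is defined for any defense plan: masked SNVs drop out of the sum,
Beacon flips swap a *yes* term ``d_ij A_j`` for a *no* term ``d_ij B_j``,
and AAF noise perturbs the released frequencies inside the log ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import (
    AAF,
    BEACON,
    AAFRelease,
    AttackSpec,
    BeaconRelease,
    DefensePlan,
    FREQ_CEIL,
    FREQ_FLOOR,
    GenotypePanel,
    SnvConstants,
)


def beacon_scores(
    constants: SnvConstants,
    release: BeaconRelease,
    plan: DefensePlan | None,
    d: np.ndarray,
) -> np.ndarray:
    """Beacon LRT scores for the rows of carrier matrix ``d``.

    ``L_i = Σ_{j∈Q∖M} d_ij [x'_j A_j + (1 − x'_j) B_j]`` with
    ``x' = x + δ``; masked SNVs contribute nothing.
    """
    d = np.atleast_2d(np.asarray(d))
    if plan is None:
        plan = DefensePlan.empty(release.x.shape[0], BEACON)
    x_eff = release.x + plan.delta
    per_snv = x_eff * constants.A + (1.0 - x_eff) * constants.B
    per_snv = np.where(plan.masked, 0.0, per_snv)
    return d @ per_snv


def aaf_scores(
    panel: GenotypePanel,
    release: AAFRelease,
    plan: DefensePlan | None,
    d: np.ndarray,
) -> np.ndarray:
    """AAF LRT scores: ``Σ_{j∈Q∖M} d_ij log(p̄_j/x'_j) + (1−d_ij) log((1−p̄_j)/(1−x'_j))``.

    ``x'`` is the noisy release clipped into ``[0.0001, 0.9999]``.
    """
    d = np.atleast_2d(np.asarray(d))
    if plan is None:
        plan = DefensePlan.empty(release.x.shape[0], AAF)
    x_eff = np.clip(release.x + plan.delta, FREQ_FLOOR, FREQ_CEIL)
    p = panel.p_ref
    carrier = np.log(p / x_eff)
    noncarrier = np.log((1.0 - p) / (1.0 - x_eff))
    keep = ~plan.masked
    return d[:, keep] @ carrier[keep] + (1.0 - d[:, keep]) @ noncarrier[keep]


def scores_for(
    panel: GenotypePanel,
    release,
    plan: DefensePlan | None,
    d: np.ndarray,
    constants: SnvConstants | None = None,
) -> np.ndarray:
    """Dispatch on release type."""
    if isinstance(release, BeaconRelease):
        if constants is None:
            raise ValueError("Beacon scoring requires precomputed SnvConstants")
        return beacon_scores(constants, release, plan, d)
    return aaf_scores(panel, release, plan, d)


def threshold(spec: AttackSpec, ref_scores: np.ndarray | None = None) -> float:
    """Realized prediction threshold under the threat model.

    Fixed: the exogenous constant θ.  Adaptive: the mean score of the
    ``⌈(K/100)·n̄⌉`` lowest-scoring reference individuals under the current
    defense.
    """
    if spec.model == "fixed":
        return float(spec.theta)
    if ref_scores is None or len(ref_scores) == 0:
        raise ValueError("adaptive threshold requires a non-empty reference panel")
    ref_scores = np.asarray(ref_scores, dtype=float)
    k = spec.k_count(len(ref_scores))
    lowest = np.partition(ref_scores, k - 1)[:k]
    return float(lowest.mean())


@dataclass(frozen=True)
class PrivacyOutcome:
    """Per-member attack result at a realized threshold."""

    protected: np.ndarray       # bool over members: L_i >= theta
    threshold_value: float
    scores: np.ndarray

    @property
    def claimed(self) -> np.ndarray:
        """Members the attacker claims (score strictly below threshold)."""
        return ~self.protected

    @property
    def n_protected(self) -> int:
        return int(self.protected.sum())


def privacy_outcome(member_scores: np.ndarray, theta_value: float) -> PrivacyOutcome:
    """Protected iff ``L_i − θ ≥ 0`` (ties protect the member)."""
    s = np.asarray(member_scores, dtype=float)
    return PrivacyOutcome(protected=s >= theta_value, threshold_value=float(theta_value), scores=s)


def evaluate_attack(
    panel: GenotypePanel,
    release,
    plan: DefensePlan | None,
    spec: AttackSpec,
    constants: SnvConstants | None = None,
) -> PrivacyOutcome:
    """Score members (and, if adaptive, the reference panel) under a plan."""
    member = scores_for(panel, release, plan, panel.d, constants)
    if spec.model == "adaptive":
        ref = scores_for(panel, release, plan, panel.d_ref, constants)
        theta = threshold(spec, ref)
    else:
        theta = threshold(spec)
    return privacy_outcome(member, theta)
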