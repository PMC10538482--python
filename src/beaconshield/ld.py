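"""Linkage disequilibrium: coefficients, neighbor maps, and the
correlation-based inference attack on defended Beacons.

The covariance-form coefficient ``LD = P(AB) − P(A)P(B)`` over binary
carrier indicators is bounded by ±0.25.  An attacker who knows which SNVs
were flipped or masked can vote over each edited SNV's positively
correlated neighbors: if at least 75% of the (unmasked) neighbors answer
*yes*, the true response is inferred to be *yes* and the edit is undone in
the attacker's re-scoring.  The SPG-LD defense (see
:func:`beaconshield.spg_beacon.spg_b` with an ``ld_map``) counters this by
editing whole correlation groups together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import lrt
from .panel import AttackSpec, BeaconRelease, DefensePlan, GenotypePanel, SnvConstants
from .spg_beacon import spg_b


def ld_coefficient(a, b) -> float:
    """Empirical ``P(AB) − P(A)P(B)`` for two binary columns."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("columns must be non-empty and of equal length")
    return float((a * b).mean() - a.mean() * b.mean())


def max_ld_coefficient() -> float:
    """Numerically maximize ``P(AB) − P(A)P(B)`` over valid joint distributions.

    The joint law of two binary alleles is a point on the 4-simplex
    ``(p_AB, p_Ab, p_aB, p_ab)``; the maximum of the coefficient over that
    simplex is 0.25, attained at perfectly coupled alleles with marginal
    frequency one half.
    """
    def neg(q):
        p_ab, p_aB, p_Ab = q  # p_AB = 1 - sum
        p_AB = 1.0 - q.sum()
        return -(p_AB - (p_AB + p_Ab) * (p_AB + p_aB))

    best = -np.inf
    for start in ([0.25, 0.25, 0.25], [0.1, 0.4, 0.4], [0.4, 0.1, 0.1]):
        res = minimize(
            neg, np.array(start), method="SLSQP",
            bounds=[(0.0, 1.0)] * 3,
            constraints={"type": "ineq", "fun": lambda q: 1.0 - q.sum()},
        )
        best = max(best, -res.fun)
    return float(best)


@dataclass(frozen=True)
class LDMap:
    """Positively correlated neighbors per SNV within an index window."""

    neighbors: dict            # j -> np.ndarray of neighbor indices
    coefficients: dict = field(default_factory=dict)  # (j, k) -> LD
    window: int = 250
    t_ld: float = 0.2
    source: str = "ref"


def build_ld_map(
    panel: GenotypePanel,
    window: int = 250,
    t_ld: float = 0.2,
    restrict_to=None,
    source: str = "ref",
) -> LDMap:
    """Neighbors with ``LD > t_ld`` within ±``window`` index positions.

    ``source`` chooses the panel the coefficients are estimated on:
    ``"ref"`` models the attacker (who lacks D), ``"members"`` the defender.
    ``restrict_to`` limits the SNVs a map is built for (worst-case attack
    evaluation over the known flipped/masked set).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    mat = panel.d_ref if source == "ref" else panel.d
    cols = mat.astype(float)
    mu = cols.mean(axis=0)
    m = panel.m
    targets = range(m) if restrict_to is None else sorted(int(j) for j in restrict_to)
    neighbors, coeffs = {}, {}
    for j in targets:
        lo, hi = max(0, j - window), min(m, j + window + 1)
        ks = [k for k in range(lo, hi) if k != j]
        found = []
        for k in ks:
            c = float((cols[:, j] * cols[:, k]).mean() - mu[j] * mu[k])
            if c > t_ld:
                found.append(k)
                coeffs[(j, k)] = c
        if found:
            neighbors[j] = np.asarray(found, dtype=int)
    return LDMap(neighbors=neighbors, coefficients=coeffs,
                 window=window, t_ld=t_ld, source=source)


def infer_edited_responses(
    release: BeaconRelease,
    plan: DefensePlan,
    ld: LDMap,
    vote_threshold: float = 0.75,
) -> np.ndarray:
    """Indices of flipped/masked SNVs the neighbor vote infers back to *yes*.

    Masked neighbors are excluded from a vote's denominator; an SNV with no
    voting neighbors is never inferred.
    """
    edited = np.flatnonzero((plan.delta == -1) | plan.masked)
    observed = release.x + plan.delta
    inferred = []
    for j in edited:
        nbrs = ld.neighbors.get(int(j))
        if nbrs is None or len(nbrs) == 0:
            continue
        voting = [k for k in nbrs if not plan.masked[k]]
        if not voting:
            continue
        if float(np.mean([observed[k] for k in voting])) >= vote_threshold:
            inferred.append(int(j))
    return np.asarray(inferred, dtype=int)


def correlation_attack(
    release: BeaconRelease,
    plan: DefensePlan,
    ld: LDMap,
    panel: GenotypePanel,
    spec: AttackSpec,
    constants: SnvConstants,
    vote_threshold: float = 0.75,
) -> lrt.PrivacyOutcome:
    """Re-score members after inferring edited responses from LD neighbors.

    For each flipped or masked SNV ``j`` with a non-empty neighbor set, the
    attacker looks at the *observed* post-defense responses of the
    neighbors (masked neighbors do not vote); if the *yes* fraction reaches
    ``vote_threshold`` the working response for ``j`` becomes *yes* —
    flipped SNVs revert to ``A_j`` contributions and masked SNVs re-enter
    the score with ``x_j = 1``.  Scores and membership claims are then
    re-evaluated under the given threat model.
    """
    observed = release.x + plan.delta          # post-defense responses
    x_work = observed.copy().astype(float)
    scored = (~plan.masked).copy()             # masked SNVs drop out unless inferred

    for j in infer_edited_responses(release, plan, ld, vote_threshold):
        x_work[j] = 1.0
        scored[j] = True

    per_snv = x_work * constants.A + (1.0 - x_work) * constants.B
    per_snv = np.where(scored, per_snv, 0.0)
    member = panel.d @ per_snv
    if spec.model == "adaptive":
        ref = panel.d_ref @ per_snv
        theta = lrt.threshold(spec, ref)
    else:
        theta = lrt.threshold(spec)
    return lrt.privacy_outcome(member, theta)


def spg_ld(
    panel: GenotypePanel,
    constants: SnvConstants,
    release: BeaconRelease,
    spec: AttackSpec,
    w: float,
    alpha: float,
    ld: LDMap,
):
    """LD-aware greedy Beacon defense (group-coupled SPG-B)."""
    return spg_b(panel, constants, release, spec, w, alpha, ld_map=ld)
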