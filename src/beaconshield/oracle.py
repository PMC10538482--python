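"""Exhaustive exact solver for the privacy–utility problem on small instances.

Beacon: every *yes*-response SNV can be reported truthfully, flipped or
masked, giving ``3^{|Q1|}`` candidate plans; each is scored exactly and the
argmin of ``α‖δ‖₁ + (1−α)|M| − w|Z|`` returned.  AAF: mask subsets crossed
with a discrete per-SNV noise grid.  Serves as the correctness oracle for
the greedy defenses — the greedy objective can never beat it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from . import lrt
from .panel import (
    AAF,
    BEACON,
    AttackSpec,
    DefensePlan,
    FREQ_CEIL,
    FREQ_FLOOR,
    GenotypePanel,
    SnvConstants,
)


class InstanceTooLarge(ValueError):
    pass


@dataclass(frozen=True)
class ExactSolution:
    plan: DefensePlan
    objective: float
    n_searched: int


TRUTHFUL, FLIP, MASK = 0, 1, 2


def exact_beacon(
    panel: GenotypePanel,
    constants: SnvConstants,
    release,
    spec: AttackSpec,
    w: float,
    alpha: float,
    limit: int = 12,
) -> ExactSolution:
    """Enumerate all ``3^{|Q1|}`` flip/mask/truthful assignments.

    Ties resolve to the lexicographically smallest assignment (truthful <
    flip < mask per SNV, earliest SNV most significant), which enumeration
    order delivers by keeping the first strict improvement.
    """
    q1 = release.Q1
    if q1.size > limit:
        raise InstanceTooLarge(f"|Q1| = {q1.size} exceeds limit {limit}")
    eta = lrt.beacon_scores(constants, release, None, panel.d)
    eta_ref = lrt.beacon_scores(constants, release, None, panel.d_ref)
    dF = (constants.B - constants.A)[q1]
    dM = (-constants.A)[q1]
    d_q = panel.d[:, q1].astype(float)
    dref_q = panel.d_ref[:, q1].astype(float)

    best_U, best_assign = np.inf, None
    count = 0
    for assign in itertools.product((TRUTHFUL, FLIP, MASK), repeat=q1.size):
        count += 1
        a = np.asarray(assign)
        gain = np.where(a == FLIP, dF, 0.0) + np.where(a == MASK, dM, 0.0)
        member = eta + d_q @ gain
        if spec.model == "adaptive":
            theta = lrt.threshold(spec, eta_ref + dref_q @ gain)
        else:
            theta = lrt.threshold(spec)
        n_protected = int((member >= theta).sum())
        nF = int((a == FLIP).sum())
        nM = int((a == MASK).sum())
        U = alpha * nF + (1.0 - alpha) * nM - w * n_protected
        if U < best_U:
            best_U, best_assign = U, a
    masked = np.zeros(panel.m, dtype=bool)
    delta = np.zeros(panel.m)
    if best_assign is not None:
        masked[q1[best_assign == MASK]] = True
        delta[q1[best_assign == FLIP]] = -1.0
    plan = DefensePlan(m=panel.m, mode=BEACON, masked=masked, delta=delta)
    return ExactSolution(plan=plan, objective=float(best_U), n_searched=count)


def exact_aaf(
    panel: GenotypePanel,
    release,
    spec: AttackSpec,
    w: float,
    alpha: float,
    noise_grid=(0.0,),
    limit: int = 12,
    max_plans: int = 500_000,
) -> ExactSolution:
    """Enumerate mask subsets × per-SNV noise levels from a discrete grid."""
    m = panel.m
    if m > limit:
        raise InstanceTooLarge(f"m = {m} exceeds limit {limit}")
    g = len(noise_grid)
    total = sum(g ** (m - k) * math.comb(m, k) for k in range(m + 1))
    if total > max_plans:
        raise InstanceTooLarge(f"{total} candidate plans exceed max_plans={max_plans}")

    best_U, best = np.inf, None
    count = 0
    for mask_bits in itertools.product((False, True), repeat=m):
        masked = np.asarray(mask_bits)
        free = np.flatnonzero(~masked)
        for levels in itertools.product(noise_grid, repeat=free.size):
            count += 1
            delta = np.zeros(m)
            delta[free] = levels
            # realized (clipped) noise determines the cost
            eff = np.clip(release.x + delta, FREQ_FLOOR, FREQ_CEIL) - release.x
            eff[masked] = 0.0
            plan = DefensePlan(m=m, mode=AAF, masked=masked, delta=eff)
            outcome = lrt.evaluate_attack(panel, release, plan, spec)
            U = alpha * np.abs(eff).sum() + (1.0 - alpha) * masked.sum() - w * outcome.n_protected
            if U < best_U:
                best_U, best = U, (masked.copy(), eff.copy())
    masked, delta = best
    plan = DefensePlan(m=m, mode=AAF, masked=masked, delta=delta)
    return ExactSolution(plan=plan, objective=float(best_U), n_searched=count)
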