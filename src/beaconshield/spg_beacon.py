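"""Greedy Beacon defense (SPG-B) and its marginal-contribution tables.

Each iteration flips or masks the single *yes*-response SNV with the
highest average marginal score gain per unit cost over the still-unprotected
members: flipping SNV ``j`` raises every carrier's score by
``Δ_j^F = B_j − A_j``, masking by ``Δ_j^M = −A_j``, and the averaged
per-cost versions are

    Δ̄_j^F(P) = |T_j| Δ_j^F / (α |P|),     Δ̄_j^M(P) = |T_j| Δ_j^M / ((1−α) |P|)

with ``T_j`` the unprotected carriers of ``j``.  Against the adaptive
attacker the marginals are re-centred on the K-lowest reference group,

    Δ_j(K) = Δ_j (1 − mean_{k ∈ D̄(K)} d_kj),

and only strictly positive adjusted marginals are admissible.  The best
objective value visited is returned, with the empty plan as the starting
incumbent.

The same routine drives the LD-aware variant (SPG-LD): scores are divided
by the correlation-group size ``|N_LD(j)|`` and a selected SNV drags its
whole positively-correlated group along, so a correlation attacker cannot
out an edit by majority-voting its neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import lrt
from .metrics import TradeoffPoint, tradeoff_point
from .panel import (
    BEACON,
    AttackSpec,
    BeaconRelease,
    DefensePlan,
    GenotypePanel,
    SnvConstants,
)


@dataclass(frozen=True)
class MarginalTable:
    """Per-SNV flip/mask marginal score contributions (``x_j = 1`` SNVs)."""

    delta_F: np.ndarray   # B_j - A_j
    delta_M: np.ndarray   # -A_j
    in_Q1: np.ndarray     # bool: x_j == 1


def marginal_table(constants: SnvConstants, release: BeaconRelease) -> MarginalTable:
    return MarginalTable(
        delta_F=constants.B - constants.A,
        delta_M=-constants.A,
        in_Q1=release.x == 1,
    )


def average_marginals(
    table: MarginalTable,
    carrier_counts: np.ndarray,
    n_uncovered: int,
    alpha: float,
    group_size: np.ndarray | None = None,
):
    """Average marginal contribution per unit cost over the uncovered set.

    ``carrier_counts[j] = |T_j|``, the number of uncovered members carrying
    ``j``.  ``group_size`` divides both scores for the LD-aware variant.
    Returns ``(flip_scores, mask_scores)``; entries outside ``Q1`` are 0.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly in (0, 1)")
    if n_uncovered <= 0:
        raise ValueError("uncovered set must be non-empty")
    flip = carrier_counts * table.delta_F / (alpha * n_uncovered)
    mask = carrier_counts * table.delta_M / ((1.0 - alpha) * n_uncovered)
    if group_size is not None:
        flip = flip / group_size
        mask = mask / group_size
    flip = np.where(table.in_Q1, flip, 0.0)
    mask = np.where(table.in_Q1, mask, 0.0)
    return flip, mask


def spg_b(
    panel: GenotypePanel,
    constants: SnvConstants,
    release: BeaconRelease,
    spec: AttackSpec,
    w: float,
    alpha: float,
    ld_map=None,
    allow_flip: bool = True,
    allow_mask: bool = True,
    method_name: str | None = None,
) -> tuple[DefensePlan, TradeoffPoint]:
    """Run the greedy Beacon defense; returns the best plan visited.

    ``ld_map`` switches on the LD-aware variant.  ``allow_flip`` /
    ``allow_mask`` restrict the action set (used by the mask-only baseline).
    """
    m = panel.m
    table = marginal_table(constants, release)
    if ld_map is not None:
        # |N_LD(j)| with empty groups costing one unit, as in plain SPG-B.
        group_size = np.array(
            [max(len(ld_map.neighbors.get(j, ())), 1) for j in range(m)], dtype=float
        )
    else:
        group_size = None

    member = lrt.beacon_scores(constants, release, None, panel.d).copy()
    ref = lrt.beacon_scores(constants, release, None, panel.d_ref).copy()

    flipped = np.zeros(m, dtype=bool)
    masked = np.zeros(m, dtype=bool)
    available = table.in_Q1.copy()

    def current_theta():
        return lrt.threshold(spec, ref) if spec.model == "adaptive" else lrt.threshold(spec)

    def coverage():
        return member >= current_theta()

    def apply(j: int, action: str):
        gain = table.delta_F[j] if action == "flip" else table.delta_M[j]
        member[:] = member + panel.d[:, j] * gain
        ref[:] = ref + panel.d_ref[:, j] * gain
        if action == "flip":
            flipped[j] = True
        else:
            masked[j] = True
        available[j] = False

    def snapshot(covered_n: int, w_=w):
        cost = alpha * flipped.sum() + (1.0 - alpha) * masked.sum()
        return cost - w_ * covered_n

    # The empty plan is the starting incumbent: with w = 0 (or everyone
    # already protected) no action can improve on it.
    covered = coverage()
    best_U = snapshot(int(covered.sum()))
    best = (flipped.copy(), masked.copy())

    while not covered.all():
        cand = np.flatnonzero(available)
        if cand.size == 0:
            break
        uncovered_rows = np.flatnonzero(~covered)
        T = panel.d[uncovered_rows][:, cand].sum(axis=0).astype(float)
        sub = MarginalTable(
            delta_F=table.delta_F[cand], delta_M=table.delta_M[cand],
            in_Q1=np.ones(cand.size, dtype=bool),
        )
        if spec.model == "adaptive":
            # Re-centre on the current K-lowest reference individuals.
            k = spec.k_count(panel.n_ref)
            low = np.argpartition(ref, k - 1)[:k]
            carr = panel.d_ref[low][:, cand].mean(axis=0)
            sub = MarginalTable(
                delta_F=sub.delta_F * (1.0 - carr),
                delta_M=sub.delta_M * (1.0 - carr),
                in_Q1=sub.in_Q1,
            )
        gsz = group_size[cand] if group_size is not None else None
        flip_sc, mask_sc = average_marginals(sub, T, uncovered_rows.size, alpha, gsz)
        if spec.model == "adaptive":
            # Only strictly positive adjusted marginals are admissible.
            flip_sc = np.where(sub.delta_F > 0, flip_sc, -np.inf)
            mask_sc = np.where(sub.delta_M > 0, mask_sc, -np.inf)
        if not allow_flip:
            flip_sc = np.full_like(mask_sc, -np.inf)
        if not allow_mask:
            mask_sc = np.full_like(flip_sc, -np.inf)

        best_f = flip_sc.max() if flip_sc.size else -np.inf
        best_m = mask_sc.max() if mask_sc.size else -np.inf
        if not np.isfinite(max(best_f, best_m)):
            break
        # Tie-breaks: flip beats mask at equal score; lowest index wins.
        if best_f >= best_m:
            action, j = "flip", int(cand[int(np.argmax(flip_sc))])
        else:
            action, j = "mask", int(cand[int(np.argmax(mask_sc))])
        apply(j, action)
        if ld_map is not None:
            for k_ in ld_map.neighbors.get(j, ()):
                # Drag the correlated group along; only actionable yes-responses.
                if available[k_]:
                    apply(int(k_), action)

        covered = coverage()
        U_t = snapshot(int(covered.sum()))
        if U_t <= best_U:  # later equal-objective solutions replace earlier ones
            best_U = U_t
            best = (flipped.copy(), masked.copy())

    bf, bm = best
    plan = DefensePlan(m=m, mode=BEACON, masked=bm, delta=np.where(bf, -1.0, 0.0))
    outcome = lrt.evaluate_attack(panel, release, plan, spec, constants)
    name = method_name or ("spg-ld" if ld_map is not None else "spg-b")
    point = tradeoff_point(name, plan, outcome, w, alpha, panel.n,
                           theta=spec.theta, K=spec.K)
    return plan, point
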