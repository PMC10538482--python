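"""Utility and privacy metrics, and the tradeoff-point record."""

from __future__ import annotations

from dataclasses import dataclass, field

from .lrt import PrivacyOutcome
from .panel import DefensePlan


def utility(plan: DefensePlan, alpha: float, m: int | None = None) -> float:
    """``100 [1 − (α‖δ‖₁ + (1−α)|M|) / m] %``.

    For Beacons ``‖δ‖₁`` is the number of flipped responses.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    m = plan.m if m is None else m
    cost = alpha * plan.noise_l1() + (1.0 - alpha) * plan.n_masked
    return 100.0 * (1.0 - cost / m)


def privacy(outcome: PrivacyOutcome, n: int | None = None) -> float:
    """Percentage of members whose score stays at or above the threshold."""
    n = len(outcome.protected) if n is None else n
    return 100.0 * outcome.n_protected / n


def objective(plan: DefensePlan, outcome: PrivacyOutcome, w: float, alpha: float) -> float:
    """SSPP objective ``α‖δ‖₁ + (1−α)|M| − w|Z|``."""
    return alpha * plan.noise_l1() + (1.0 - alpha) * plan.n_masked - w * outcome.n_protected


@dataclass(frozen=True)
class TradeoffPoint:
    """One solution on the privacy–utility frontier."""

    method: str
    w: float
    alpha: float
    utility_pct: float
    privacy_pct: float
    objective: float
    seed: int | None = None
    params: dict = field(default_factory=dict)


def tradeoff_point(
    method: str,
    plan: DefensePlan,
    outcome: PrivacyOutcome,
    w: float,
    alpha: float,
    n: int,
    seed: int | None = None,
    **params,
) -> TradeoffPoint:
    return TradeoffPoint(
        method=method,
        w=w,
        alpha=alpha,
        utility_pct=utility(plan, alpha),
        privacy_pct=privacy(outcome, n),
        objective=objective(plan, outcome, w, alpha),
        seed=seed,
        params=params,
    )
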