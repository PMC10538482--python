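"""Privacy–utility frontier sweeps and the reference baselines.

Baselines:

* **RF** (random flipping): every SNV carried by exactly one member (a
  "unique allele") is flipped — or masked, via ``action`` — independently
  with probability ``p``.
* **mask-only**: the greedy defenses restricted to masking.
* **noise-only**: the plain Laplace mechanism over the candidate ε grid
  with nothing masked; for each ``w`` the grid point minimizing the SSPP
  objective is selected.
"""

from __future__ import annotations

import numpy as np

from . import lrt
from .metrics import TradeoffPoint, objective, privacy, tradeoff_point, utility
from .panel import (
    AAF,
    BEACON,
    AAFRelease,
    AttackSpec,
    BeaconRelease,
    DefensePlan,
    GenotypePanel,
    SnvConstants,
)
from .spg_aaf import LaplaceSpec, laplace_noise, laplace_scale, spg_r
from .spg_beacon import spg_b

#: Default weight grids for the privacy-vs-utility scalarization.
DEFAULT_W_GRID_BEACON = (0.01, 0.1, 1.0, 10.0)
DEFAULT_W_GRID_AAF = (0.1, 1.0, 10.0, 100.0, 1000.0, 10000.0)


def baseline_rf(
    panel: GenotypePanel,
    release: BeaconRelease,
    p: float,
    seed: int = 0,
    action: str = "flip",
) -> DefensePlan:
    """Randomly flip (or mask) the unique alleles of the data set."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("flip probability must lie in [0, 1]")
    singles = np.flatnonzero(panel.d.sum(axis=0) == 1)
    rng = np.random.default_rng(seed)
    chosen = singles[rng.random(singles.size) < p]
    masked = np.zeros(panel.m, dtype=bool)
    delta = np.zeros(panel.m)
    if action == "mask":
        masked[chosen] = True
    else:
        delta[chosen] = -1.0
    return DefensePlan(m=panel.m, mode=BEACON, masked=masked, delta=delta)


def baseline_noise_only(
    panel: GenotypePanel,
    release: AAFRelease,
    spec: AttackSpec,
    w_grid,
    alpha: float,
    laplace: LaplaceSpec | None = None,
    seed: int = 0,
) -> list[TradeoffPoint]:
    """Laplace mechanism with no masking; argmin-U ε per ``w``."""
    laplace = laplace or LaplaceSpec()
    unmasked = np.ones(panel.m, dtype=bool)
    candidates = []
    for ei, eps in enumerate(laplace.epsilon_grid):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0, ei)))
        scale = laplace_scale(laplace, panel, unmasked, eps)
        delta = laplace_noise(rng, scale, release.x, unmasked)
        plan = DefensePlan(m=panel.m, mode=AAF, delta=delta)
        outcome = lrt.evaluate_attack(panel, release, plan, spec)
        candidates.append((plan, outcome, eps))
    points = []
    for w in sorted(w_grid):
        best = min(candidates, key=lambda c: objective(c[0], c[1], w, alpha))
        plan, outcome, eps = best
        points.append(
            tradeoff_point("noise-only", plan, outcome, w, alpha, panel.n,
                           seed=seed, epsilon=eps, theta=spec.theta, K=spec.K)
        )
    return points


def baseline_mask_only(
    panel: GenotypePanel,
    release,
    spec: AttackSpec,
    w_grid,
    alpha: float,
    constants: SnvConstants | None = None,
    t: int | None = None,
    seed: int = 0,
) -> list[TradeoffPoint]:
    """Greedy defense restricted to masking, one point per ``w``."""
    points = []
    for w in sorted(w_grid):
        if isinstance(release, BeaconRelease):
            _, pt = spg_b(panel, constants, release, spec, w, alpha,
                          allow_flip=False, method_name="mask-only")
        else:
            _, pt = spg_r(panel, release, spec, w, alpha, t=t, seed=seed,
                          add_noise=False, method_name="mask-only")
        points.append(pt)
    return points


def sweep(
    panel: GenotypePanel,
    release,
    method: str,
    spec: AttackSpec,
    alpha: float,
    w_grid=None,
    seeds=(0, 1, 2, 3, 4),
    constants: SnvConstants | None = None,
    ld_map=None,
    laplace: LaplaceSpec | None = None,
    t: int | None = None,
    rf_p_grid=(0.1, 0.25, 0.5, 0.75, 1.0),
) -> list[TradeoffPoint]:
    """One tradeoff point per (w, seed), sorted by ``w``.

    Deterministic methods (``spg-b``, ``spg-ld``, ``mask-only``) ignore the
    seed list; stochastic ones (``spg-r``, ``noise-only``, ``rf``) produce
    one point per seed — average with :func:`mean_frontier` to mirror the
    usual five-run reporting.  For ``rf`` the ``w`` grid selects, per
    ``w``, the flip probability whose plan best optimizes the objective.
    """
    if w_grid is None:
        w_grid = (
            DEFAULT_W_GRID_BEACON if isinstance(release, BeaconRelease) else DEFAULT_W_GRID_AAF
        )
    w_grid = sorted(w_grid)
    if len(w_grid) == 0:
        raise ValueError("w grid must be non-empty")
    points: list[TradeoffPoint] = []
    if method == "spg-b":
        for w in w_grid:
            points.append(spg_b(panel, constants, release, spec, w, alpha)[1])
    elif method == "spg-ld":
        for w in w_grid:
            points.append(spg_b(panel, constants, release, spec, w, alpha, ld_map=ld_map)[1])
    elif method == "spg-r":
        for w in w_grid:
            for s in seeds:
                points.append(spg_r(panel, release, spec, w, alpha,
                                    laplace=laplace, t=t, seed=s)[1])
    elif method == "mask-only":
        for s in (seeds if not isinstance(release, BeaconRelease) else [seeds[0]]):
            points.extend(
                baseline_mask_only(panel, release, spec, w_grid, alpha,
                                   constants=constants, t=t, seed=s)
            )
    elif method == "noise-only":
        for s in seeds:
            points.extend(baseline_noise_only(panel, release, spec, w_grid, alpha,
                                              laplace=laplace, seed=s))
    elif method == "rf":
        for s in seeds:
            plans = [
                (p, baseline_rf(panel, release, p, seed=s),)
                for p in rf_p_grid
            ]
            evaluated = [
                (p, plan, lrt.evaluate_attack(panel, release, plan, spec, constants))
                for p, plan in plans
            ]
            for w in w_grid:
                p, plan, outcome = min(
                    evaluated, key=lambda c: objective(c[1], c[2], w, alpha)
                )
                points.append(
                    tradeoff_point("rf", plan, outcome, w, alpha, panel.n,
                                   seed=s, p=p, theta=spec.theta, K=spec.K)
                )
    else:
        raise ValueError(f"unknown method {method!r}")
    points.sort(key=lambda pt: pt.w)
    return points


def mean_frontier(points: list[TradeoffPoint]) -> list[TradeoffPoint]:
    """Average utility/privacy/objective over seeds at each (method, w, alpha)."""
    groups: dict = {}
    for pt in points:
        groups.setdefault((pt.method, pt.w, pt.alpha), []).append(pt)
    out = []
    for (method, w, alpha), grp in sorted(groups.items(), key=lambda kv: kv[0][1]):
        out.append(
            TradeoffPoint(
                method=method, w=w, alpha=alpha,
                utility_pct=float(np.mean([p.utility_pct for p in grp])),
                privacy_pct=float(np.mean([p.privacy_pct for p in grp])),
                objective=float(np.mean([p.objective for p in grp])),
                seed=None,
                params={"n_runs": len(grp)},
            )
        )
    return out
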