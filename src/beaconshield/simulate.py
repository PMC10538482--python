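"""Synthetic genotype panels with the statistical structure the attacks assume.

Reference AAFs are drawn from a (truncated) beta distribution — the
classical generative model for allele frequencies in membership-inference
analyses — and each individual carries SNV ``j`` with the Hardy–Weinberg
carrier probability ``1 − (1 − p̄_j)²``.  Members and reference individuals
are i.i.d. from the same model; members still separate under the LRT
because the release is computed from their genomes.  Optional LD blocks
copy a block-seed carrier column and independently resample each cell with
probability ``1 − ρ``, giving within-block carrier correlation ≈ ρ.

Defaults mirror a small summary-release cohort: 400 members, 400 reference
individuals, and a desk-scale SNV count (the motivating releases carry
~1.3 M SNVs; everything here scales linearly in ``m``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import AAF, BEACON, FREQ_CEIL, FREQ_FLOOR, GenotypePanel, build_panel


@dataclass(frozen=True)
class SimulationConfig:
    n: int = 400
    n_ref: int = 400
    m: int = 2000
    beta_a: float = 0.5
    beta_b: float = 5.0
    gamma: float = 1e-6
    mode: str = BEACON
    block_len: int = 1        # >1 enables LD blocks
    rho: float = 0.0          # within-block copy fidelity
    block_p: float | None = None  # fixed p̄ for block columns (None: drawn)
    seed: int = 0

    def __post_init__(self):
        if min(self.n, self.n_ref, self.m, self.block_len) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")


def _draw_freqs(rng, config) -> np.ndarray:
    hi = 0.5 - 1e-9 if config.mode == BEACON else FREQ_CEIL
    p = np.empty(config.m)
    filled = 0
    while filled < config.m:  # rejection-sample into the truncation interval
        draw = rng.beta(config.beta_a, config.beta_b, size=config.m)
        ok = draw[(draw > FREQ_FLOOR) & (draw < hi)]
        take = min(ok.size, config.m - filled)
        p[filled : filled + take] = ok[:take]
        filled += take
    return p


def simulate_panel(
    config: SimulationConfig, attacker_freqs: str = "truth"
) -> GenotypePanel:
    """Generate a validated panel; deterministic given ``config.seed``.

    ``attacker_freqs`` selects the reference AAFs handed to the attacker:
    ``"truth"`` uses the generative frequencies, ``"estimate"`` re-derives
    them from the reference panel's carrier frequencies via
    ``p̂ = 1 − √(1 − f̄)`` (the Hardy–Weinberg inversion), emulating an
    attacker who must estimate the population from D̄.
    """
    rng = np.random.default_rng(config.seed)
    p = _draw_freqs(rng, config)
    total = config.n + config.n_ref

    if config.block_len > 1:
        carriers = np.empty((total, config.m), dtype=np.int8)
        for start in range(0, config.m, config.block_len):
            stop = min(start + config.block_len, config.m)
            if config.block_p is not None:
                p[start:stop] = config.block_p
            else:
                p[start:stop] = p[start]
            q = 1.0 - (1.0 - p[start]) ** 2
            seed_col = (rng.random(total) < q).astype(np.int8)
            for j in range(start, stop):
                col = seed_col.copy()
                resample = rng.random(total) >= config.rho
                col[resample] = (rng.random(int(resample.sum())) < q).astype(np.int8)
                carriers[:, j] = col
    else:
        q = 1.0 - (1.0 - p) ** 2
        carriers = (rng.random((total, config.m)) < q).astype(np.int8)

    d, d_ref = carriers[: config.n], carriers[config.n :]
    if attacker_freqs == "estimate":
        f = np.clip(d_ref.mean(axis=0), 0.0, 1.0 - 1e-9)
        p_out = np.clip(1.0 - np.sqrt(1.0 - f), FREQ_FLOOR, None)
        if config.mode == BEACON:
            p_out = np.minimum(p_out, 0.5 - 1e-9)
    else:
        p_out = p
    return build_panel(d, d_ref, p_out, gamma=config.gamma, mode=config.mode)


def empirical_check(panel: GenotypePanel, config: SimulationConfig) -> dict:
    """Summary of generator fidelity, used by tests and the examples.

    Reports the mean absolute deviation between empirical carrier
    frequencies and the Hardy–Weinberg expectation, and (when LD blocks are
    configured) the fraction of within-block pairs whose carrier LD exceeds
    0.2.
    """
    q = 1.0 - (1.0 - panel.p_ref) ** 2
    all_carriers = np.vstack([panel.d, panel.d_ref])
    emp = all_carriers.mean(axis=0)
    report = {"mean_abs_freq_dev": float(np.abs(emp - q).mean())}
    if config.block_len > 1:
        cols = all_carriers.astype(float)
        mu = cols.mean(axis=0)
        hits, pairs = 0, 0
        for start in range(0, config.m, config.block_len):
            stop = min(start + config.block_len, config.m)
            for j in range(start, stop):
                for k in range(j + 1, stop):
                    c = (cols[:, j] * cols[:, k]).mean() - mu[j] * mu[k]
                    pairs += 1
                    hits += c > 0.2
        report["block_pairs_above_0.2"] = hits / pairs if pairs else 0.0
    return report
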