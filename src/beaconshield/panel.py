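"""Core domain types: genotype panels, summary releases, defense plans.

A *panel* holds the binary carrier matrix for the protected data set ``D``
(``n`` individuals by ``m`` SNVs, entry 1 when the individual carries at
least one alternate allele), the disjoint reference panel ``D̄``, the
reference alternate-allele frequencies ``p̄`` and the sequencing-error rate
``γ``.  Two release models are supported:

* **Beacon** — a binary presence/absence vector, ``x_j = 1`` iff some member
  of ``D`` carries the alternate allele at SNV ``j``.
* **AAF** — the within-dataset carrier frequency, clipped to
  ``[0.0001, 0.9999]``.

The per-SNV constants used by the Beacon likelihood-ratio test are

    R_n^j      = (1 − p̄_j)^{2n}        (probability no member carries j)
    A_j        = log((1 − R_n^j) / (1 − γ R_{n−1}^j))
    B_j        = log(R_n^j / (γ R_{n−1}^j))

``A_j`` is the score contribution of a carrier when the Beacon answers
*yes*; ``B_j`` when it answers *no*.  Under the minor-allele assumption
(``p̄_j < 0.5``) and ``γ < 0.25``, ``B_j > 0`` and ``A_j < 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

BEACON = "beacon"
AAF = "aaf"

#: Released AAFs (and AAF-mode reference frequencies) are clipped into this
#: interval to keep every log-likelihood term finite.
FREQ_FLOOR = 0.0001
FREQ_CEIL = 0.9999


class PanelError(ValueError):
    """Structural or statistical-assumption violation in panel inputs."""


def _as_binary_matrix(a, name: str) -> np.ndarray:
    arr = np.asarray(a)
    if arr.ndim != 2:
        raise PanelError(f"{name} must be a 2-D matrix, got ndim={arr.ndim}")
    if not np.isin(arr, (0, 1)).all():
        raise PanelError(f"{name} must contain only 0/1 carrier indicators")
    return arr.astype(np.int8)


@dataclass(frozen=True)
class GenotypePanel:
    """Validated carrier matrices, reference AAFs and error rate.

    Construct through :func:`build_panel`, which enforces the statistical
    assumptions of the release mode.
    """

    d: np.ndarray          # (n, m) members of D
    d_ref: np.ndarray      # (n_ref, m) reference individuals
    p_ref: np.ndarray      # (m,) reference AAFs
    gamma: float
    mode: str
    snv_ids: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.d.shape[0]

    @property
    def n_ref(self) -> int:
        return self.d_ref.shape[0]

    @property
    def m(self) -> int:
        return self.d.shape[1]


def build_panel(
    d,
    d_ref,
    p_ref,
    gamma: float = 1e-6,
    mode: str = BEACON,
    snv_ids: Sequence[str] | None = None,
    on_major_allele: str = "error",
) -> GenotypePanel:
    """Validate inputs and return a :class:`GenotypePanel`.

    Parameters
    ----------
    gamma
        Sequencing-error probability; defaults to 1e-6, the typical order
        of magnitude for modern platforms.
    on_major_allele
        Beacon mode only: ``"error"`` rejects SNVs whose reference AAF is
        ≥ 0.5 (the minor-allele assumption), ``"drop"`` removes them.

    Raises
    ------
    PanelError
        On shape mismatch, non-binary matrices, a major alternate allele in
        Beacon mode, or an error rate violating ``γ < min_j (1 − p̄_j)²``
        (the condition under which masking an absent allele cannot help an
        attacker).
    """
    if mode not in (BEACON, AAF):
        raise PanelError(f"unknown mode {mode!r}")
    d = _as_binary_matrix(d, "d")
    d_ref = _as_binary_matrix(d_ref, "d_ref")
    p = np.asarray(p_ref, dtype=float).ravel()
    m = d.shape[1]
    if d_ref.shape[1] != m or p.shape[0] != m:
        raise PanelError(
            f"column mismatch: d has {m} SNVs, d_ref {d_ref.shape[1]}, p_ref {p.shape[0]}"
        )
    if snv_ids is not None and len(snv_ids) != m:
        raise PanelError("snv_ids length does not match number of SNVs")
    ids = tuple(snv_ids) if snv_ids is not None else tuple(f"snv{j}" for j in range(m))
    if not (0.0 <= p.min() and p.max() <= 1.0):
        raise PanelError("p_ref entries must lie in [0, 1]")
    gamma = float(gamma)
    if not gamma > 0.0:
        raise PanelError("gamma must be positive")

    if mode == BEACON:
        if gamma >= 0.25:
            raise PanelError(f"Beacon mode requires gamma < 0.25, got {gamma}")
        major = p >= 0.5
        if major.any():
            if on_major_allele == "drop":
                keep = ~major
                d, d_ref, p = d[:, keep], d_ref[:, keep], p[keep]
                ids = tuple(i for i, k in zip(ids, keep) if k)
            else:
                bad = int(np.flatnonzero(major)[0])
                raise PanelError(
                    f"Beacon mode assumes the alternate allele is the minor allele; "
                    f"p_ref[{bad}] = {p[major][0]:g} >= 0.5 (use on_major_allele='drop' to filter)"
                )
        # p̄ = 0 would make A_j = log 0; floor symmetrically with the AAF clip.
        p = np.clip(p, FREQ_FLOOR, None)
    else:
        p = np.clip(p, FREQ_FLOOR, FREQ_CEIL)

    # The masking-safety condition gamma < (1-p̄_j)^2 underpins the guarantee
    # that suppressing an absent allele cannot raise an attacker's score; it
    # concerns minor alternate alleles, so major-allele SNVs (possible only
    # in AAF mode) are exempt.
    minor = p < 0.5
    if minor.any():
        ratio_min = float(np.min((1.0 - p[minor]) ** 2))
        if gamma >= ratio_min:
            raise PanelError(
                f"gamma={gamma} violates gamma < min_j (1-p̄_j)^2 = {ratio_min:g}; "
                "masking guarantees no longer hold"
            )
    return GenotypePanel(d=d, d_ref=d_ref, p_ref=p, gamma=gamma, mode=mode, snv_ids=ids)


def prob_no_alt(p_ref, n: int) -> np.ndarray:
    """``R_n^j = (1 − p̄_j)^{2n}``: chance no one of *n* diploid individuals carries j."""
    return (1.0 - np.asarray(p_ref, dtype=float)) ** (2 * n)


@dataclass(frozen=True)
class SnvConstants:
    """Per-SNV Beacon LRT constants derived from a panel."""

    R_n: np.ndarray
    R_nm1: np.ndarray
    A: np.ndarray
    B: np.ndarray


def compute_constants(panel: GenotypePanel) -> SnvConstants:
    """Compute ``R_n``, ``R_{n−1}``, ``A`` and ``B`` for every SNV."""
    p, n, g = panel.p_ref, panel.n, panel.gamma
    R_n = prob_no_alt(p, n)
    R_nm1 = prob_no_alt(p, n - 1)
    with np.errstate(divide="raise", invalid="raise"):
        A = np.log((1.0 - R_n) / (1.0 - g * R_nm1))
        B = np.log(R_n / (g * R_nm1))
    return SnvConstants(R_n=R_n, R_nm1=R_nm1, A=A, B=B)


@dataclass(frozen=True)
class BeaconRelease:
    """Binary presence/absence response vector."""

    x: np.ndarray  # (m,) in {0,1}

    @property
    def Q1(self) -> np.ndarray:
        """Indices answering *yes*."""
        return np.flatnonzero(self.x == 1)

    @property
    def Q0(self) -> np.ndarray:
        return np.flatnonzero(self.x == 0)


@dataclass(frozen=True)
class AAFRelease:
    """Real-valued carrier-frequency vector, clipped to [0.0001, 0.9999]."""

    x: np.ndarray


def make_release(panel: GenotypePanel, mode: str | None = None):
    """Build the undefended release from the member matrix.

    Beacon: ``x_j = 1`` iff any member carries SNV ``j``.  AAF: the column
    mean of the carrier matrix, clipped to ``[0.0001, 0.9999]``.
    """
    mode = mode or panel.mode
    if mode == BEACON:
        return BeaconRelease(x=(panel.d.any(axis=0)).astype(np.int8))
    if mode == AAF:
        freq = panel.d.mean(axis=0)
        return AAFRelease(x=np.clip(freq, FREQ_FLOOR, FREQ_CEIL))
    raise PanelError(f"unknown mode {mode!r}")


@dataclass
class DefensePlan:
    """A defense: masked SNV set ``M`` plus noise ``δ`` on the rest.

    Beacon mode: ``δ_j ∈ {−1, 0}``, −1 flipping a *yes* response to *no*.
    AAF mode: real additive noise; post-noise frequencies are clipped.
    Masked indices always carry zero noise (``δ`` lives on ``Q∖M``).
    """

    m: int
    mode: str
    masked: np.ndarray = field(default=None)  # bool (m,)
    delta: np.ndarray = field(default=None)   # float (m,)

    def __post_init__(self):
        if self.masked is None:
            self.masked = np.zeros(self.m, dtype=bool)
        else:
            self.masked = np.asarray(self.masked, dtype=bool).copy()
        if self.delta is None:
            self.delta = np.zeros(self.m, dtype=float)
        else:
            self.delta = np.asarray(self.delta, dtype=float).copy()

    @classmethod
    def empty(cls, m: int, mode: str) -> "DefensePlan":
        return cls(m=m, mode=mode)

    @property
    def masked_indices(self) -> np.ndarray:
        return np.flatnonzero(self.masked)

    @property
    def flipped_indices(self) -> np.ndarray:
        if self.mode != BEACON:
            raise ValueError("flipped_indices only defined for Beacon plans")
        return np.flatnonzero(self.delta == -1)

    @property
    def n_masked(self) -> int:
        return int(self.masked.sum())

    def noise_l1(self) -> float:
        """ℓ₁ noise cost; for Beacons this is the number of flips."""
        return float(np.abs(self.delta).sum())

    def validate(self, release) -> None:
        """Check the plan against a release; raises ``ValueError`` on violation."""
        if self.delta[self.masked].any():
            raise ValueError("masked SNVs must carry zero noise")
        if self.mode == BEACON:
            if not np.isin(self.delta, (-1.0, 0.0)).all():
                raise ValueError("Beacon noise entries must be in {-1, 0}")
            flips = self.delta == -1
            if (release.x[flips] != 1).any():
                raise ValueError("only yes-responses (x_j = 1) may be flipped")
            if (release.x[self.masked] != 1).any():
                raise ValueError("only yes-responses (x_j = 1) may be masked")


@dataclass(frozen=True)
class AttackSpec:
    """Threat model: fixed threshold θ, or adaptive K-lowest-percentile.

    The adaptive attacker sets the threshold to the mean score of the
    ``⌈(K/100)·n̄⌉`` reference individuals with the lowest current scores,
    recomputed after the defense is applied.
    """

    model: str = "fixed"          # "fixed" | "adaptive"
    theta: float | None = None
    K: float | None = None        # percentile in (0, 100]

    def __post_init__(self):
        if self.model == "fixed":
            if self.theta is None:
                raise ValueError("fixed model requires theta")
        elif self.model == "adaptive":
            if self.K is None or not (0 < self.K <= 100):
                raise ValueError("adaptive model requires K in (0, 100]")
        else:
            raise ValueError(f"unknown attack model {self.model!r}")

    def k_count(self, n_ref: int) -> int:
        """Number of reference individuals forming the adaptive threshold."""
        return max(1, int(np.ceil(self.K / 100.0 * n_ref)))
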