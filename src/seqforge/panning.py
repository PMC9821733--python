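"""Multi-round phage-display panning simulator.

Each selection round exposes the pool to soluble target at a round-specific
concentration, captures phage in proportion to equilibrium occupancy
(efficiency x C / (C + KD)), removes bound phage during washes with
first-order dissociation exp(-kd * total wash time) and no rebinding, elutes
completely, and amplifies with a per-class growth bias.  The default round
series mirrors a five-round campaign with decreasing target (50, 40, 20, 10,
1 nM) and increasing wash stringency.

Deterministic mode propagates expected abundances; stochastic mode draws
binomial survivors per clone per stage from a single seeded generator and
converges to the deterministic trajectory for large pools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PhagePool",
    "RoundSpec",
    "CampaignResult",
    "capture_probability",
    "wash_survival",
    "run_campaign",
    "default_campaign_rounds",
]

#: Sentinel dissociation constant for clones that do not bind the target.
NON_BINDER = math.inf


@dataclass
class PhagePool:
    """Clone abundances (counts or frequencies) at one point in a campaign."""

    ids: list[str]
    classes: list[str]                       # sequestrin | monomer | dummy
    KD: np.ndarray                           # molar; inf for non-binders
    kd: np.ndarray                           # 1/s
    abundances: np.ndarray
    round_index: int = 0

    def __post_init__(self):
        self.KD = np.asarray(self.KD, dtype=float)
        self.kd = np.asarray(self.kd, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        n = len(self.ids)
        if not (len(self.classes) == self.KD.size == self.kd.size == self.abundances.size == n):
            raise ValueError("pool fields must have equal length")
        if (self.abundances < 0).any():
            raise ValueError("abundances must be nonnegative")

    @property
    def frequencies(self) -> np.ndarray:
        total = self.abundances.sum()
        if total == 0:
            raise ValueError("pool is extinct")
        return self.abundances / total


@dataclass(frozen=True)
class RoundSpec:
    """Conditions of one selection round."""

    target_concentration: float              # molar
    wash_schedule: tuple[float, ...] = ()    # individual wash durations, s
    growth_bias: dict = field(default_factory=dict)   # class -> amplification factor
    capture_efficiency: float = 1.0
    background_capture: float = 0.0          # carry-over of non-binders

    def __post_init__(self):
        if self.target_concentration < 0:
            raise ValueError("target concentration must be >= 0")
        if any(d < 0 for d in self.wash_schedule):
            raise ValueError("wash durations must be >= 0")
        if not 0 < self.capture_efficiency <= 1:
            raise ValueError("capture efficiency must be in (0, 1]")


@dataclass
class CampaignResult:
    """Trajectory of pools (input + after each round) and per-round recovery."""

    trajectory: list[PhagePool]
    recoveries: list[float]
    extinct: bool = False


def capture_probability(KD: float | np.ndarray, target_concentration: float,
                        capture_efficiency: float = 1.0,
                        background: float = 0.0) -> float | np.ndarray:
    """Probability that a clone is captured on target-loaded beads.

    Equilibrium occupancy times a bead-capture efficiency; non-binders
    (KD = inf) see only the background carry-over rate.
    """
    KD = np.asarray(KD, dtype=float)
    if (KD <= 0).any():
        raise ValueError("KD must be positive (inf for non-binders)")
    if target_concentration < 0:
        raise ValueError("target concentration must be >= 0")
    occupancy = np.where(np.isinf(KD), 0.0,
                         target_concentration / (target_concentration + KD))
    p = capture_efficiency * occupancy + background
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def wash_survival(kd: float | np.ndarray, wash_schedule) -> float | np.ndarray:
    """Probability of remaining bound through the whole wash schedule.

    First-order dissociation with no rebinding: exp(-kd * total seconds).
    """
    kd = np.asarray(kd, dtype=float)
    if (kd < 0).any():
        raise ValueError("kd must be >= 0")
    total = float(sum(wash_schedule))
    out = np.exp(-kd * total)
    return float(out) if out.ndim == 0 else out


def run_campaign(pool: PhagePool, rounds: list[RoundSpec], stochastic: bool = False,
                 seed: int | None = None) -> CampaignResult:
    """Run a multi-round selection; returns trajectory and recovery fractions.

    Per round: capture x wash survival (binomial sampling of survivors in
    stochastic mode), recovery fraction recorded, then amplification with the
    per-class growth bias and renormalization to input pool size.  An all-zero
    pool flags extinction and truncates the trajectory.
    """
    if pool.abundances.sum() == 0:
        raise ValueError("input pool is empty")
    if stochastic and seed is None:
        raise ValueError("stochastic mode requires an explicit seed")
    rng = np.random.default_rng(seed)

    trajectory = [pool]
    recoveries: list[float] = []
    current = pool
    classes = np.asarray(pool.classes)
    for i, spec in enumerate(rounds, start=1):
        p_survive = capture_probability(
            current.KD, spec.target_concentration,
            spec.capture_efficiency, spec.background_capture,
        ) * wash_survival(current.kd, spec.wash_schedule)
        input_total = current.abundances.sum()
        if stochastic:
            counts = np.round(current.abundances).astype(np.int64)
            recovered = rng.binomial(counts, p_survive).astype(float)
        else:
            recovered = current.abundances * p_survive
        recoveries.append(float(recovered.sum() / input_total))
        if recovered.sum() == 0:
            return CampaignResult(trajectory, recoveries, extinct=True)
        bias = np.array([spec.growth_bias.get(c, 1.0) for c in classes])
        amplified = recovered * bias
        amplified *= input_total / amplified.sum()
        current = PhagePool(
            ids=current.ids, classes=current.classes,
            KD=current.KD, kd=current.kd,
            abundances=amplified, round_index=i,
        )
        trajectory.append(current)
    return CampaignResult(trajectory, recoveries)


def default_campaign_rounds(capture_efficiency: float = 1.0,
                            growth_bias: dict | None = None) -> list[RoundSpec]:
    """The five-round reference scenario: decreasing target, rising stringency."""
    concentrations_nm = [50, 40, 20, 10, 1]
    washes = [
        (60.0,) * 2,
        (60.0,) * 4,
        (180.0,) * 5,
        (360.0,) * 5,
        (360.0,) * 4 + (7200.0, 360.0),
    ]
    bias = growth_bias or {}
    return [
        RoundSpec(target_concentration=c * 1e-9, wash_schedule=w,
                  growth_bias=bias, capture_efficiency=capture_efficiency)
        for c, w in zip(concentrations_nm, washes)
    ]
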