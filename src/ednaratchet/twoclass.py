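"""Two-class Wright–Fisher model of the least-loaded class versus the rest.

A one-locus, two-allele haploid caricature of the full model: n0 genomes
belong to the least-loaded class (frequency p), n1 = N − n0 to all other
classes.  Mutation moves mass from n0 to n1 at rate U′, selection favors n0
by s′, and HGT converts n0 → n1 at rate r01 and n1 → n0 at rate r10.  The
next-generation frequency is

    p′ = (1 − U′)(1 − r01) p / w̄  +  (1 − s′) r10 q / w̄ ,

with q = 1 − p and mean parental fitness w̄ = p + (1 − s′) q, the
normalizer whose no-HGT fixed point is the classical p̂ = 1 − U′/s′.
The stochastic model draws n0(t+1) ~ Binomial(N, p′) until the least-loaded
class goes extinct; the mean extinction time (normalized by the no-HGT
baseline) measures whether HGT helps or hurts persistence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import RandomStream

__all__ = [
    "TwoClassParams",
    "mean_field_step",
    "mean_field_fixed_point",
    "simulate_two_class",
    "extinction_times",
    "mean_extinction_time",
    "ExtinctionSummary",
]

DEFAULT_CAP = 10_000_000


@dataclass(frozen=True)
class TwoClassParams:
    N: int
    U_prime: float
    s_prime: float
    r01: float = 0.0
    r10: float = 0.0

    def __post_init__(self):
        if self.N <= 0:
            raise ValueError("N must be positive")
        if not 0 <= self.U_prime < 1:
            raise ValueError("U' must lie in [0, 1)")
        if not 0 < self.s_prime < 1:
            raise ValueError("s' must lie in (0, 1)")
        if not (0 <= self.r01 <= 1 and 0 <= self.r10 <= 1):
            raise ValueError("r01 and r10 must lie in [0, 1]")

    @property
    def p_hat(self) -> float:
        """No-HGT deterministic equilibrium frequency 1 − U′/s′ (may be ≤ 0
        when mutation overwhelms selection)."""
        return 1.0 - self.U_prime / self.s_prime


def mean_field_step(p: float, params: TwoClassParams) -> float:
    """Deterministic (infinite-N) one-generation update of p."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    q = 1.0 - p
    wbar = p + (1.0 - params.s_prime) * q
    p_next = (
        (1.0 - params.U_prime) * (1.0 - params.r01) * p
        + (1.0 - params.s_prime) * params.r10 * q
    ) / wbar
    return min(max(p_next, 0.0), 1.0)


def mean_field_fixed_point(
    params: TwoClassParams, p0: float | None = None, tol: float = 1e-12, max_iter: int = 10**6
) -> float:
    """Iterated fixed point of :func:`mean_field_step`."""
    p = params.p_hat if p0 is None else p0
    p = min(max(p, 0.0), 1.0)
    for _ in range(max_iter):
        p_next = mean_field_step(p, params)
        if abs(p_next - p) < tol:
            return p_next
        p = p_next
    return p


def simulate_two_class(
    params: TwoClassParams,
    p0: float,
    rng: RandomStream,
    cap: int = DEFAULT_CAP,
) -> tuple[int, bool]:
    """One stochastic trajectory: iterate n0(t+1) ~ Binomial(N, p′) from
    n0(0) = round(N·p0) until n0 = 0.

    Returns ``(t, censored)``: the first generation with n0 = 0, or the cap
    with ``censored=True`` if extinction did not occur in time.
    """
    if not 0 <= p0 <= 1:
        raise ValueError("p0 must lie in [0, 1]")
    n0 = int(round(params.N * p0))
    if n0 == 0:
        return 0, False
    for t in range(1, cap + 1):
        p_next = mean_field_step(n0 / params.N, params)
        n0 = int(rng.binomial(params.N, p_next))
        if n0 == 0:
            return t, False
    return cap, True


@dataclass(frozen=True)
class ExtinctionSummary:
    mean: float
    se: float
    normalized_mean: float
    n_censored: int
    baseline_mean: float
    lower_bound: bool  # True when censoring makes means lower bounds


def extinction_times(
    params: TwoClassParams,
    p0: float,
    replicates: int,
    rng: RandomStream,
    cap: int = DEFAULT_CAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized extinction times over independent replicates.

    Returns ``(times, censored)``; censored replicates carry the cap as
    their time.  Identical recursion to :func:`simulate_two_class`, run for
    all replicates in lock step."""
    n0 = np.full(replicates, int(round(params.N * p0)), dtype=np.int64)
    times = np.zeros(replicates, dtype=np.int64)
    alive = n0 > 0
    u, s, r01, r10 = params.U_prime, params.s_prime, params.r01, params.r10
    t = 0
    while alive.any() and t < cap:
        t += 1
        p = n0[alive] / params.N
        q = 1.0 - p
        wbar = p + (1.0 - s) * q
        p_next = ((1.0 - u) * (1.0 - r01) * p + (1.0 - s) * r10 * q) / wbar
        np.clip(p_next, 0.0, 1.0, out=p_next)
        draw = rng.binomial(params.N, p_next)
        n0[alive] = draw
        newly_dead = np.zeros_like(alive)
        newly_dead[alive] = draw == 0
        times[newly_dead] = t
        alive[alive] = draw > 0
    times[alive] = cap
    return times, alive


def mean_extinction_time(
    params: TwoClassParams,
    p0: float | None = None,
    replicates: int = 100,
    rng: RandomStream | None = None,
    cap: int = DEFAULT_CAP,
    seed: int = 0,
) -> ExtinctionSummary:
    """Mean time to extinction of the least-loaded class, with its standard
    error and the mean normalized by the r01 = r10 = 0 baseline (computed
    with the same replicate count and seed discipline).

    ``p0`` defaults to the no-HGT steady state 1 − U′/s′.  Censored
    replicates enter at the cap, so with any censoring the reported means
    are lower bounds (flagged on the summary).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if p0 is None:
        p0 = params.p_hat
        if not 0 < p0 <= 1:
            raise ValueError("default p0 = 1 - U'/s' is not in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    times, cens = extinction_times(params, p0, replicates, rng, cap)
    if params.r01 == 0 and params.r10 == 0:
        base_times, base_cens = times, cens  # already the baseline
    else:
        base_params = TwoClassParams(params.N, params.U_prime, params.s_prime, 0.0, 0.0)
        base_rng = np.random.default_rng(seed + 1)
        base_times, base_cens = extinction_times(base_params, p0, replicates, base_rng, cap)
    mean = float(times.mean())
    se = float(times.std(ddof=1) / math.sqrt(replicates)) if replicates > 1 else 0.0
    base_mean = float(base_times.mean())
    return ExtinctionSummary(
        mean=mean,
        se=se,
        normalized_mean=mean / base_mean,
        n_censored=int(cens.sum()),
        baseline_mean=base_mean,
        lower_bound=bool(cens.any() or base_cens.any()),
    )
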