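"""Closed-form companion quantities for the ratchet/HGT model.

These are the analytic anchors of the simulator: the mutation-selection
stationary profile of load classes, the regime solver that turns a target
value of the regime index s·n̄_LLC into a mutation rate, the single-event
conversion probabilities P10/P01 for HGT acting on (nearly) least-loaded
genomes, the locus number that maximizes P10, the per-generation production
rate of the least-loaded class by HGT, the mean mutation load of eDNA under
rapid turnover, and the steady-state disadvantage condition of the two-class
model.

All formulas assume multiplicative selection with per-mutation effect ``s``
(fitness (1-s)^m), Poisson mutation with genome-wide rate ``U``, and a very
large population at mutation-selection balance.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

__all__ = [
    "solve_mutation_rate",
    "stationary_distribution",
    "p10",
    "p01",
    "optimal_locus_number",
    "llc_production_rate",
    "edna_expected_load",
    "hgt_disadvantage_condition",
]


def solve_mutation_rate(N: int, s: float, target_sn: float) -> float:
    """Mutation rate U such that the regime index s·N·e^(−U/s) equals ``target_sn``.

    The regime index is s times the equilibrium size of the least-loaded
    class, n̄_LLC = N·e^(−U/s).  Values ≫ 1 give a slow ratchet, ≈ 1 a fast
    one.  Closed form: U = s·ln(sN / target_sn).

    Raises
    ------
    ValueError
        If ``target_sn`` exceeds s·N (no non-negative U can realize it).
    """
    if target_sn <= 0:
        raise ValueError("target_sn must be positive")
    if target_sn > s * N:
        raise ValueError(
            f"target_sn={target_sn} exceeds s*N={s * N}; no non-negative U exists"
        )
    return s * math.log(s * N / target_sn)


def stationary_distribution(
    N: int, U: float, s: float, m_llc: int = 0, k_max: int = 50
) -> np.ndarray:
    """Expected load-class sizes n̄_(m_llc+k) = N·e^(−U/s)·(U/s)^k / k!.

    Returns an array of length ``m_llc + k_max + 1`` indexed by absolute
    load; entries below ``m_llc`` are zero.  This is the classical Poisson
    profile of mutation-selection balance anchored at the current
    least-loaded class.
    """
    lam = U / s
    profile = N * stats.poisson.pmf(np.arange(k_max + 1), lam)
    out = np.zeros(m_llc + k_max + 1)
    out[m_llc:] = profile
    return out


def p10(l: int, U: float, s: float) -> float:
    """Probability that one HGT event converts a one-but-least-loaded genome
    into the least-loaded class.

    P10 = l⁻¹ (1 − l⁻¹) e^(−l⁻¹ U/s): the drawn allele must hit the single
    mutated locus (1/l), and the pool allele there must carry no mutation.
    Valid for very large N with rapid eDNA turnover (d_eDNA = 1).
    """
    z = 1.0 / l
    return z * (1.0 - z) * math.exp(-z * U / s)


def p01(l: int, U: float, s: float) -> float:
    """Probability that one HGT event introduces ≥1 mutation into a
    least-loaded-class genome: P01 = 1 − (1 − l⁻¹) e^(−l⁻¹ U/s)."""
    z = 1.0 / l
    return 1.0 - (1.0 - z) * math.exp(-z * U / s)


def optimal_locus_number(U: float, s: float) -> float:
    """Locus number l̃ (real-valued) maximizing P10 at fixed U/s.

    The maximizer of z(1−z)e^(−z·U/s) over z = 1/l is
    z̃ = s/U + 1/2 − sqrt((s/U)² + 1/4); returns l̃ = 1/z̃.
    """
    if U <= 0:
        raise ValueError("U must be positive")
    a = s / U
    z = a + 0.5 - math.sqrt(a * a + 0.25)
    return 1.0 / z


def llc_production_rate(r: float, N: int, U: float, s: float, l: int) -> float:
    """Expected per-generation production of least-loaded genomes by HGT
    acting on the one-but-least-loaded class: r · P10 · n̄_(LLC+1), with
    n̄_(LLC+1) = N·e^(−U/s)·(U/s) the stationary size of that class."""
    if r == 0:
        return 0.0
    n1 = N * math.exp(-U / s) * (U / s)
    return r * p10(l, U, s) * n1


def edna_expected_load(U: float, s: float) -> float:
    """Mean mutation load per genome-equivalent (l loci) of the eDNA pool
    under rapid turnover (d_eDNA = 1), at balance with m_LLC = 0: U/s + 1.

    Dead cells are death-weighted toward loaded genomes; at balance the
    excess over the population mean U/s is exactly one mutation.
    """
    if s <= 0:
        raise ValueError("s must be positive")
    return U / s + 1.0


def hgt_disadvantage_condition(
    U_prime: float, s_prime: float, r01: float, r10: float
) -> bool:
    """True iff HGT lowers the no-HGT steady-state size of the least-loaded
    class in the two-class model:

        r10 (1 − s′) U′/s′  <  r01 (1 − U′) (1 − U′/s′)

    evaluated at the no-HGT steady state n̄0 = N(1 − U′/s′).  Strict
    inequality: r01 = r10 = 0 returns False.
    """
    if not (0 < U_prime < s_prime < 1):
        raise ValueError("need 0 < U' < s' < 1")
    lhs = r10 * (1.0 - s_prime) * U_prime / s_prime
    rhs = r01 * (1.0 - U_prime) * (1.0 - U_prime / s_prime)
    return lhs < rhs
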