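"""Measurements on populations, eDNA pools and metapopulations.

Conventions: gene diversity H is the mean over loci of 1 − Σ_j x_j², with
x_j allele frequencies taken inside one genotype class (usually the
least-loaded class).  eDNA "quality" q and "toxicity" t are per-single-HGT-
event expectations of mutations removed from / introduced into a
least-loaded genome, computed against whole-pool allele fractions, so that
t − q is exactly the expected net load change per event.  Where a quantity
is undefined (empty class, empty pool) it is reported as NaN, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np

from .core import Population
from .edna import EdnaPool

__all__ = [
    "ObservableRecord",
    "least_loaded",
    "llc_members",
    "fixed_mutations",
    "gene_diversity",
    "allele_frequencies",
    "edna_quality_toxicity",
    "subdivision_diversity",
    "accumulation_rate",
    "click_times",
    "record",
]


@dataclass
class ObservableRecord:
    """One generation's measurements (NaN marks an undefined value)."""

    t: int
    m_llc: int
    n_mllc: int
    mean_load: float
    m_fix: int = -1
    H_mllc: float = float("nan")
    H_mllc_plus1: float = float("nan")
    q_edna: float = float("nan")
    t_edna: float = float("nan")
    H_S: float = float("nan")
    H_T: float = float("nan")
    G_ST: float = float("nan")
    mbar_fix: float = float("nan")

    @classmethod
    def columns(cls) -> list[str]:
        return [f.name for f in fields(cls)]


def least_loaded(pop: Population) -> tuple[int, int]:
    """(m_LLC, n_mLLC): minimum load and the number of individuals at it."""
    loads = pop.loads
    m = int(loads.min())
    return m, int(np.count_nonzero(loads == m))


def llc_members(pop: Population, offset: int = 0) -> np.ndarray:
    """Genotype matrix of the class at load m_LLC + offset (possibly empty)."""
    loads = pop.loads
    return pop.loci[loads == loads.min() + offset]


def fixed_mutations(pop: Population) -> int:
    """m_fix: mutations carried by every individual — the per-locus minimum
    count across the population, summed over loci."""
    return int(pop.loci.min(axis=0).sum())


def allele_frequencies(members: np.ndarray) -> np.ndarray:
    """x[k, j]: frequency of the j-mutation allele at locus k within one
    genotype class given as an (n × l) matrix."""
    members = np.asarray(members)
    if members.size == 0:
        raise ValueError("empty genotype class")
    n, l = members.shape
    amax = int(members.max())
    x = np.zeros((l, amax + 1))
    for j in range(amax + 1):
        x[:, j] = np.count_nonzero(members == j, axis=0)
    return x / n


def gene_diversity(members: np.ndarray) -> float:
    """H: mean over loci of 1 − Σ_j x_j² within a genotype class.

    Raises ValueError on an empty class (record as NaN upstream)."""
    x = allele_frequencies(members)
    return float(np.mean(1.0 - (x**2).sum(axis=1)))


def edna_quality_toxicity(
    llc: np.ndarray, pool: EdnaPool, per_locus: bool = False
) -> tuple[float, float]:
    """(q_eDNA, t_eDNA): expected mutations removed / introduced by one HGT
    event on a least-loaded-class genome.

    q = Σ_k Σ_j Σ_{i>j} (i−j)·x_ki·y_kj and t = Σ_k Σ_j Σ_{i<j} (j−i)·x_ki·y_kj,
    with x the LLC allele frequencies and y the pool allele fractions
    (whole-pool by default; ``per_locus=True`` uses within-locus fractions,
    which scales both sums by l on a balanced pool).
    """
    if pool.is_empty:
        raise ValueError("q/t are undefined for an empty pool")
    x = allele_frequencies(llc)
    y = pool.allele_fractions(per_locus=per_locus)
    ax, ay = x.shape[1], y.shape[1]
    a = max(ax, ay)
    if ax < a:
        x = np.pad(x, ((0, 0), (0, a - ax)))
    if ay < a:
        y = np.pad(y, ((0, 0), (0, a - ay)))
    diff = np.arange(a)[:, None] - np.arange(a)[None, :]  # i - j
    # per locus: sum_{i,j} x_ki y_kj * (i-j)^+  and  (j-i)^+
    cross = np.einsum("ki,kj->kij", x, y)
    q = float((cross * np.maximum(diff, 0)[None, :, :]).sum())
    t = float((cross * np.maximum(-diff, 0)[None, :, :]).sum())
    return q, t


def subdivision_diversity(demes: Sequence[Population]) -> tuple[float, float, float]:
    """(H_S, H_T, G_ST) over the per-deme least-loaded classes.

    H_S is the mean of per-deme LLC gene diversities weighted by LLC size;
    H_T is the gene diversity of all per-deme LLCs pooled together;
    G_ST = (H_T − H_S)/H_T, with 0 when H_T = 0.
    """
    mats, weights = [], []
    for pop in demes:
        m = llc_members(pop)
        mats.append(m)
        weights.append(m.shape[0])
    weights = np.asarray(weights, dtype=float)
    h_s = float(np.average([gene_diversity(m) for m in mats], weights=weights))
    h_t = gene_diversity(np.vstack(mats))
    g_st = 0.0 if h_t == 0 else (h_t - h_s) / h_t
    return h_s, h_t, g_st


def accumulation_rate(m_fix_end: int, t: int) -> tuple[float, float]:
    """Mutation accumulation rate m_fix/t with Poisson-count standard error
    sqrt(m_fix)/t."""
    if t <= 0:
        raise ValueError("t must be positive")
    return m_fix_end / t, np.sqrt(m_fix_end) / t


def click_times(m_llc_trace: Sequence[int], times: Sequence[int] | None = None) -> list[int]:
    """Generations at which the least-loaded class went extinct (ratchet
    clicks).  An increment of k in one step is reported as k simultaneous
    clicks."""
    trace = np.asarray(m_llc_trace)
    if times is None:
        times = np.arange(len(trace))
    else:
        times = np.asarray(times)
    out: list[int] = []
    inc = np.diff(trace)
    for idx in np.nonzero(inc > 0)[0]:
        out.extend([int(times[idx + 1])] * int(inc[idx]))
    return out


def record(
    t: int,
    pop: Population,
    pool: EdnaPool | None = None,
    full: bool = True,
) -> ObservableRecord:
    """Measure one generation of a single deme.

    ``full=False`` collects only the O(N) quantities (m_LLC, class size,
    mean load); ``full=True`` adds m_fix, the H's and the pool q/t.
    """
    m_llc, n_mllc = least_loaded(pop)
    rec = ObservableRecord(
        t=t, m_llc=m_llc, n_mllc=n_mllc, mean_load=float(pop.loads.mean())
    )
    if not full:
        return rec
    rec.m_fix = fixed_mutations(pop)
    llc = llc_members(pop)
    rec.H_mllc = gene_diversity(llc)
    plus1 = llc_members(pop, offset=1)
    if plus1.shape[0] > 0:
        rec.H_mllc_plus1 = gene_diversity(plus1)
    if pool is not None and not pool.is_empty:
        rec.q_edna, rec.t_edna = edna_quality_toxicity(llc, pool)
    return rec
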