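"""The extracellular-DNA pool: death-weighted production, spontaneous decay,
and transformation (HGT).

The pool is the per-locus census of free allele copies: ``e[i, j]`` counts
copies of the allele with ``j`` mutations at locus ``i``.  Each generation
the pool loses a fraction ``d_edna`` of every entry (spontaneous decay) and
gains the full genomes of N cells sampled with replacement from the living
population with death probabilities that increase with mutation load —
members of the least-loaded class never die, so eDNA is on average *more*
loaded than the population it came from.

HGT draws alleles from the pool in proportion to copy number and pastes
each one over the recipient's resident allele at the same locus.  Draws do
not deplete the pool: the pool changes only through decay and production,
and absolute eDNA concentration effects are absorbed into the HGT rate
``r``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _kernels
from .core import Population, RandomStream

__all__ = ["EdnaPool", "death_weights", "produce", "decay", "hgt", "sample_alleles"]


class EdnaPool:
    """Per-locus allele copy numbers, as an (l × A) integer matrix where A−1
    is the highest mutation count currently representable."""

    __slots__ = ("copies",)

    def __init__(self, copies: np.ndarray):
        copies = np.asarray(copies, dtype=np.int64)
        if copies.ndim != 2:
            raise ValueError("pool matrix must be 2-D (locus × allele load)")
        if np.any(copies < 0):
            raise ValueError("copy numbers must be non-negative")
        self.copies = copies

    @classmethod
    def empty(cls, l: int, max_load: int = 8) -> "EdnaPool":
        return cls(np.zeros((l, max_load + 1), dtype=np.int64))

    @classmethod
    def from_entries(cls, l: int, entries) -> "EdnaPool":
        """Build from an iterable of (locus, allele_load, copies) triples."""
        entries = list(entries)
        amax = max((j for _, j, _ in entries), default=0)
        mat = np.zeros((l, amax + 1), dtype=np.int64)
        for i, j, c in entries:
            mat[i, j] += c
        return cls(mat)

    @property
    def l(self) -> int:
        return self.copies.shape[0]

    @property
    def total(self) -> int:
        return int(self.copies.sum())

    @property
    def is_empty(self) -> bool:
        return not self.copies.any()

    def mean_load_per_genome(self) -> float:
        """Mean mutation load per genome-equivalent of l alleles:
        l · Σ e_ij·j / Σ e_ij.  Undefined (ValueError) on an empty pool."""
        tot = self.total
        if tot == 0:
            raise ValueError("mean load of an empty pool is undefined")
        j = np.arange(self.copies.shape[1])
        return float(self.l * (self.copies @ j).sum() / tot)

    def allele_fractions(self, per_locus: bool = False) -> np.ndarray:
        """y[k, j]: fraction of allele (k, j).  Whole-pool fractions by
        default (sum over the full matrix is 1); ``per_locus=True`` makes
        each locus row sum to 1 instead."""
        e = self.copies.astype(float)
        if per_locus:
            tot = e.sum(axis=1, keepdims=True)
            tot[tot == 0] = 1.0
            return e / tot
        return e / e.sum()

    def _grown(self, max_load: int) -> np.ndarray:
        """Copy of the matrix with at least max_load+1 allele columns."""
        a = self.copies.shape[1]
        if max_load < a:
            return self.copies.copy()
        out = np.zeros((self.l, max_load + 1), dtype=np.int64)
        out[:, :a] = self.copies
        return out

    def copy(self) -> "EdnaPool":
        return EdnaPool(self.copies.copy())

    def to_frame(self) -> pd.DataFrame:
        """Tidy snapshot: one row per nonzero (locus, allele_load, copies)."""
        i, j = np.nonzero(self.copies)
        return pd.DataFrame(
            {"locus": i, "allele_load": j, "copies": self.copies[i, j]}
        )


def death_weights(pop: Population, s: float) -> np.ndarray:
    """Per-individual probability of dying and releasing the genome into the
    eDNA pool this generation.

    ε_i ∝ 1 − f′_i where f′_i = (1−s)^(m_i − m_LLC) is fitness normalized by
    the least-loaded class; the least-loaded class itself never contributes.
    Degenerate case: a population entirely in its least-loaded class has all
    weights zero, and the uniform distribution is returned (the formula's
    normalizer vanishes there).
    """
    loads = pop.loads
    rel = loads - loads.min()
    w = 1.0 - (1.0 - s) ** rel
    tot = w.sum()
    if tot == 0.0:
        return np.full(pop.size, 1.0 / pop.size)
    return w / tot


def produce(pool: EdnaPool, pop: Population, s: float, rng: RandomStream) -> EdnaPool:
    """Add the genomes of ``pop.size`` dead cells, sampled with replacement
    under :func:`death_weights`, to the pool.  The pool total increases by
    exactly ``pop.size * l``."""
    eps = death_weights(pop, s)
    n_dead = rng.multinomial(pop.size, eps)  # deaths per individual
    chosen = np.nonzero(n_dead)[0]
    weights = n_dead[chosen]
    max_load = int(pop.loci[chosen].max(initial=0))
    mat = pool._grown(max_load)
    _kernels.add_genomes(mat, pop.loci, chosen, weights)
    return EdnaPool(mat)


def decay(pool: EdnaPool, d_edna: float, rng: RandomStream) -> EdnaPool:
    """Spontaneous decay: each entry e_ij loses round(d_edna·e_ij) copies when
    that expectation exceeds 1 (round half away from zero, clamped at e_ij),
    otherwise a Binomial(e_ij, d_edna) number.  d_edna = 1 empties the pool;
    d_edna = 0 is the identity."""
    if not 0 <= d_edna <= 1:
        raise ValueError("d_edna must lie in [0, 1]")
    if d_edna == 0 or pool.is_empty:
        return pool.copy()
    if d_edna == 1:
        return EdnaPool(np.zeros_like(pool.copies))
    e = pool.copies
    expected = d_edna * e
    loss = np.where(
        expected > 1,
        np.minimum(np.floor(expected + 0.5).astype(np.int64), e),
        rng.binomial(e, d_edna),
    )
    return EdnaPool(e - loss)


def sample_alleles(pool: EdnaPool, size: int, rng: RandomStream) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``size`` alleles from the pool with probability proportional to
    copy number over the whole pool (with replacement).  Returns the arrays
    ``(locus, allele_load)`` — the elementary draw behind one HGT event."""
    if pool.is_empty:
        raise ValueError("cannot sample from an empty pool")
    flat = pool.copies.ravel()
    p = flat / flat.sum()
    draws = rng.choice(flat.size, size=size, p=p)
    a = pool.copies.shape[1]
    return draws // a, (draws % a).astype(np.int16)


def hgt(pop: Population, pool: EdnaPool, r: float, rng: RandomStream) -> Population:
    """Transformation: each genome independently replaces Poisson(r) of its
    alleles with alleles drawn from the pool in proportion to copy number.

    A drawn allele lands at its own locus, discarding the resident allele;
    repeated draws at one locus apply sequentially (the last wins).  Draws
    are with replacement and leave the pool unchanged.  An empty pool or
    r = 0 makes this a no-op.
    """
    if r < 0:
        raise ValueError("r must be non-negative")
    if r == 0 or pool.is_empty:
        return pop
    if pool.l != pop.l:
        raise ValueError("pool and population disagree on locus number")
    events = rng.poisson(r, pop.size)
    total = int(events.sum())
    if total == 0:
        return pop
    mat = pop.loci.copy()
    loci_drawn, allele = sample_alleles(pool, total, rng)
    rows = np.repeat(np.arange(pop.size), events)
    # keep only the last event per (genome, locus): sequential overwrite
    key = rows * np.int64(pop.l) + loci_drawn
    _, last = np.unique(key[::-1], return_index=True)
    keep = total - 1 - last
    mat[rows[keep], loci_drawn[keep]] = allele[keep]
    return Population(mat)
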