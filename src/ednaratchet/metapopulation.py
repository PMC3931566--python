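"""Toroidal grid of demes with cell migration and eDNA diffusion.

The population is split into equal demes on a rows × cols torus (the
default elsewhere is 4 × 4).  Each deme runs its own Wright–Fisher /
mutation / HGT update and owns an eDNA pool.  Between the eDNA step and the
mutation step, neighboring demes exchange individuals (a symmetric swap of
k ~ Binomial(N_s/4, D_pop) cells per unordered neighbor pair, which keeps
every deme size exactly constant) and pools exchange allele copies
(fraction D_eDNA/4 per direction, deterministic rounding above expectation
1, multinomial below).  ``D_edna = inf`` replaces the 16 pools with one
pool shared by every deme.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from . import edna as edna_mod
from .core import ModelParams, Population, RandomStream, mutate, reproduce
from .edna import EdnaPool

__all__ = ["Metapopulation", "migrate", "diffuse_edna", "step"]


class Metapopulation:
    """Grid-indexed demes with per-deme (or one shared) eDNA pool."""

    def __init__(
        self,
        demes: Sequence[Population],
        pools: Sequence[EdnaPool] | EdnaPool,
        grid: tuple[int, int],
    ):
        rows, cols = grid
        if len(demes) != rows * cols:
            raise ValueError("deme count does not match grid shape")
        sizes = {d.size for d in demes}
        if len(sizes) != 1:
            raise ValueError("demes must have equal sizes")
        self.demes = list(demes)
        self.grid = grid
        if isinstance(pools, EdnaPool):
            self.shared_pool: EdnaPool | None = pools
            self.pools: list[EdnaPool] | None = None
        else:
            if len(pools) != rows * cols:
                raise ValueError("pool count does not match grid shape")
            self.shared_pool = None
            self.pools = list(pools)

    @classmethod
    def initial(cls, params: ModelParams, rng: RandomStream) -> "Metapopulation":
        """Mutation-free monomorphic demes; pools seeded by one production
        step (uniform weights, since the starting population is monomorphic)
        so HGT is well-defined from the first generation."""
        demes = [
            Population.monomorphic(params.deme_size, params.l)
            for _ in range(params.n_demes)
        ]
        if math.isinf(params.D_edna):
            pool = EdnaPool.empty(params.l)
            for d in demes:
                pool = edna_mod.produce(pool, d, params.s, rng)
            return cls(demes, pool, params.grid)
        pools = [
            edna_mod.produce(EdnaPool.empty(params.l), d, params.s, rng)
            for d in demes
        ]
        return cls(demes, pools, params.grid)

    @property
    def deme_size(self) -> int:
        return self.demes[0].size

    def pool_of(self, idx: int) -> EdnaPool:
        return self.shared_pool if self.shared_pool is not None else self.pools[idx]

    def neighbor_pairs(self) -> list[tuple[int, int]]:
        """Unordered 4-neighborhood pairs on the torus (deduplicated, so a
        1×1 grid has none and degenerate 2-wide wraps count once)."""
        rows, cols = self.grid
        pairs = set()
        for i in range(rows):
            for j in range(cols):
                a = i * cols + j
                for b in (i * cols + (j + 1) % cols, ((i + 1) % rows) * cols + j):
                    if a != b:
                        pairs.add((min(a, b), max(a, b)))
        return sorted(pairs)

    def neighbors_of(self, idx: int) -> list[int]:
        rows, cols = self.grid
        i, j = divmod(idx, cols)
        out = [
            i * cols + (j + 1) % cols,
            i * cols + (j - 1) % cols,
            ((i + 1) % rows) * cols + j,
            ((i - 1) % rows) * cols + j,
        ]
        return [b for b in out if b != idx]


def migrate(meta: Metapopulation, D_pop: float, rng: RandomStream) -> Metapopulation:
    """Symmetric exchange of individuals between neighboring demes.

    For each unordered neighbor pair, k ~ Binomial(N_s/4, D_pop) cells,
    chosen uniformly without replacement on each side, swap demes.  All k
    are drawn against the pre-migration state; deme sizes never change.
    """
    if not 0 <= D_pop <= 1:
        raise ValueError("D_pop must lie in [0, 1]")
    pairs = meta.neighbor_pairs()
    if D_pop == 0 or not pairs:
        return meta
    ns = meta.deme_size
    trials = ns // 4
    ks = rng.binomial(trials, D_pop, size=len(pairs))
    mats = [d.loci.copy() for d in meta.demes]
    for (a, b), k in zip(pairs, ks):
        if k == 0:
            continue
        ia = rng.choice(ns, size=k, replace=False)
        ib = rng.choice(ns, size=k, replace=False)
        mats[a][ia], mats[b][ib] = mats[b][ib].copy(), mats[a][ia].copy()
    meta.demes = [Population(m) for m in mats]
    return meta


def _outflow(e: np.ndarray, D_edna: float, rng: RandomStream) -> np.ndarray:
    """Per-direction outflow (4 × l × A) from one pool, pre-step state.

    Entries with per-direction expectation D·e/4 > 1 send the rounded
    expectation each way (clamped so at most e copies leave in total);
    smaller entries draw the four outflows from a multinomial with success
    probability D/4 per direction.
    """
    expected = D_edna * e / 4.0
    det = expected > 1
    out = np.zeros((4,) + e.shape, dtype=np.int64)
    if det.any():
        per_dir = np.floor(expected[det] + 0.5).astype(np.int64)
        per_dir = np.minimum(per_dir, e[det] // 4)  # conserve copies
        out[:, det] = per_dir
    sto = ~det & (e > 0)
    if sto.any():
        # multinomial over (4 directions, stay) via sequential binomials
        rem = e[sto].copy()
        p_left = np.ones(rem.shape)
        for d in range(4):
            p = np.minimum(D_edna / 4.0 / p_left, 1.0)
            draw = rng.binomial(rem, p)
            out[d][sto] = draw
            rem -= draw
            p_left -= D_edna / 4.0
    return out


def diffuse_edna(meta: Metapopulation, D_edna: float, rng: RandomStream) -> Metapopulation:
    """Synchronous eDNA diffusion on the torus: every pool's outflows are
    computed from the pre-step state and applied at once; the grid-total
    copy number is conserved exactly.  No-op for a shared pool."""
    if meta.shared_pool is not None or D_edna == 0:
        return meta
    if not 0 <= D_edna <= 1:
        raise ValueError("D_edna must lie in [0, 1] or be infinite")
    amax = max(p.copies.shape[1] for p in meta.pools)
    mats = [p._grown(amax - 1) for p in meta.pools]
    deltas = [np.zeros_like(m) for m in mats]
    for idx, m in enumerate(mats):
        nbrs = meta.neighbors_of(idx)
        out = _outflow(m, D_edna, rng)
        # fewer than 4 distinct neighbors (tiny grids): route per direction,
        # cycling over the distinct ones so copies are still conserved
        for d in range(4):
            tgt = nbrs[d % len(nbrs)]
            deltas[idx] -= out[d]
            deltas[tgt] += out[d]
    meta.pools = [EdnaPool(m + dm) for m, dm in zip(mats, deltas)]
    return meta


def step(meta: Metapopulation, params: ModelParams, rng: RandomStream) -> Metapopulation:
    """One full generation of the metapopulation, in the model's order:

    1. Wright–Fisher reproduction in every deme;
    2. eDNA decay then death-weighted production, per pool (a shared pool
       decays once and receives every deme's dead);
    3. migration of cells and diffusion of eDNA;
    4. mutation then HGT in every deme.
    """
    meta.demes = [reproduce(d, params.s, rng) for d in meta.demes]
    if meta.shared_pool is not None:
        pool = edna_mod.decay(meta.shared_pool, params.d_edna, rng)
        for d in meta.demes:
            pool = edna_mod.produce(pool, d, params.s, rng)
        meta.shared_pool = pool
    else:
        meta.pools = [
            edna_mod.produce(edna_mod.decay(p, params.d_edna, rng), d, params.s, rng)
            for p, d in zip(meta.pools, meta.demes)
        ]
    meta = migrate(meta, params.D_pop, rng)
    if not math.isinf(params.D_edna):
        meta = diffuse_edna(meta, params.D_edna, rng)
    meta.demes = [mutate(d, params.U, rng) for d in meta.demes]
    if params.r > 0:
        meta.demes = [
            edna_mod.hgt(d, meta.pool_of(i), params.r, rng)
            for i, d in enumerate(meta.demes)
        ]
    return meta
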