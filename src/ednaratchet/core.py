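"""Domain types and the selection/mutation steps of the per-generation update.

The population is a fixed-size collection of haploid genomes.  A genome is a
vector of ``l`` non-negative integers: entry ``k`` counts the deleterious
mutations carried by the allele at locus ``k``.  Fitness is multiplicative
without epistasis, f_m = (1 − s)^m with m the total load, so selection and
drift act through a single Wright–Fisher multinomial resampling per
generation; mutation adds a Poisson(U) number of new hits per genome, each
at a uniformly chosen locus.

Internally a population is stored as a dense (size × l) integer matrix,
which stays cheap up to N ≈ 10^5–10^6 and vectorizes every update.
Genotype-class and load-class aggregations are exposed as methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = ["ModelParams", "Genome", "Population", "reproduce", "mutate", "step_deme"]

#: eDNA diffusion value meaning "all demes share one pool".
INFINITE = math.inf

RandomStream = np.random.Generator
"""Seeded pseudo-random generator; identical seed + call sequence gives an
identical trajectory.  Alias of :class:`numpy.random.Generator`."""


def _as_diffusion(value: Union[float, str]) -> float:
    if isinstance(value, str):
        if value.lower() in ("inf", "infinite", "infinity"):
            return math.inf
        try:
            return float(value)
        except ValueError:
            raise ValueError(f"unrecognized D_eDNA value {value!r}") from None
    return float(value)


@dataclass(frozen=True)
class ModelParams:
    """Full-model configuration (symbols follow the field's convention).

    Parameters
    ----------
    N : total population size (summed over demes).
    U : deleterious mutation rate per genome per generation.
    s : fitness effect per mutation, fitness (1-s)^m.
    r : HGT (transformation) events per genome per generation.
    l : number of loci (recombinable segments) per genome.
    d_edna : eDNA turnover (decay) rate per generation, in [0, 1].
    D_pop : migration rate between neighboring demes, in [0, 1].
    D_edna : eDNA diffusion rate in [0, 1], or ``math.inf`` / ``"infinite"``
        for a single pool shared by all demes.
    grid : (rows, cols) of the toroidal deme grid; (1, 1) = undivided.
    generations : default run length.
    seed : RNG seed for the run.
    """

    N: int
    U: float
    s: float = 0.01
    r: float = 0.0
    l: int = 100
    d_edna: float = 1.0
    D_pop: float = 0.0
    D_edna: float = 0.0
    grid: tuple[int, int] = (1, 1)
    generations: int = 10_000
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "D_edna", _as_diffusion(self.D_edna))
        if self.N <= 0 or self.l <= 0 or self.generations <= 0:
            raise ValueError("N, l and generations must be positive")
        if self.U < 0 or self.r < 0:
            raise ValueError("U and r must be non-negative")
        if not 0 < self.s < 1:
            raise ValueError("s must lie in (0, 1)")
        if not 0 <= self.d_edna <= 1:
            raise ValueError("d_edna must lie in [0, 1]")
        if not 0 <= self.D_pop <= 1:
            raise ValueError("D_pop must lie in [0, 1]")
        if not math.isinf(self.D_edna) and not 0 <= self.D_edna <= 1:
            raise ValueError("D_edna must lie in [0, 1] or be infinite")
        rows, cols = self.grid
        if rows <= 0 or cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.N % (rows * cols) != 0:
            raise ValueError(
                f"N={self.N} is not divisible by the number of demes {rows * cols}"
            )

    @property
    def n_demes(self) -> int:
        return self.grid[0] * self.grid[1]

    @property
    def deme_size(self) -> int:
        return self.N // self.n_demes


@dataclass(frozen=True)
class Genome:
    """One haploid genome: per-locus deleterious-mutation counts."""

    loci: tuple[int, ...]

    def __post_init__(self):
        if any(c < 0 for c in self.loci):
            raise ValueError("mutation counts must be non-negative")

    @property
    def load(self) -> int:
        return sum(self.loci)

    def fitness(self, s: float) -> float:
        return (1.0 - s) ** self.load


class Population:
    """Fixed-size deme of genomes, backed by a (size × l) count matrix."""

    __slots__ = ("loci", "_loads")

    def __init__(self, loci: np.ndarray):
        loci = np.asarray(loci)
        if loci.ndim != 2 or loci.shape[0] == 0:
            raise ValueError("population matrix must be 2-D and non-empty")
        if loci.dtype != np.int16:
            if np.any(loci < 0):
                raise ValueError("mutation counts must be non-negative")
            loci = loci.astype(np.int16)
        self.loci = loci
        self._loads: np.ndarray | None = None

    # -- constructors ------------------------------------------------------
    @classmethod
    def monomorphic(cls, size: int, l: int, genome: Sequence[int] | None = None) -> "Population":
        if genome is None:
            mat = np.zeros((size, l), dtype=np.int16)
        else:
            mat = np.tile(np.asarray(genome, dtype=np.int16), (size, 1))
        return cls(mat)

    @classmethod
    def from_genomes(cls, genomes: Iterable[Genome | Sequence[int]]) -> "Population":
        rows = [g.loci if isinstance(g, Genome) else tuple(g) for g in genomes]
        return cls(np.array(rows, dtype=np.int16))

    # -- views -------------------------------------------------------------
    @property
    def size(self) -> int:
        return self.loci.shape[0]

    @property
    def l(self) -> int:
        return self.loci.shape[1]

    @property
    def loads(self) -> np.ndarray:
        """Per-individual total mutation load."""
        if self._loads is None:
            self._loads = self.loci.sum(axis=1, dtype=np.int64)
        return self._loads

    def load_histogram(self) -> np.ndarray:
        """Count of individuals per load value, indexed by load."""
        return np.bincount(self.loads)

    def genotype_classes(self) -> tuple[np.ndarray, np.ndarray]:
        """(unique genotype matrix, counts); counts sum to the size."""
        return np.unique(self.loci, axis=0, return_counts=True)

    def copy(self) -> "Population":
        return Population(self.loci.copy())

    def __len__(self) -> int:
        return self.size


def reproduce(pop: Population, s: float, rng: RandomStream) -> Population:
    """One Wright–Fisher generation: multinomial resampling with weights
    proportional to (1 − s)^load.  Size is preserved; offspring genotypes
    are a subset of the parents'."""
    loads = pop.loads
    rel = loads - loads.min()  # normalize so weights stay O(1)
    w = (1.0 - s) ** rel
    p = w / w.sum()
    counts = rng.multinomial(pop.size, p)
    parents = np.repeat(np.arange(pop.size), counts)
    return Population(pop.loci[parents])


def mutate(pop: Population, U: float, rng: RandomStream) -> Population:
    """Each genome gains Poisson(U) new deleterious mutations, each at a
    uniformly chosen locus."""
    if U < 0:
        raise ValueError("U must be non-negative")
    if U == 0:
        return pop
    hits = rng.poisson(U, pop.size)
    total = int(hits.sum())
    mat = pop.loci.copy()
    if total:
        rows = np.repeat(np.arange(pop.size), hits)
        cols = rng.integers(0, pop.l, total)
        np.add.at(mat, (rows, cols), 1)
    return Population(mat)


def step_deme(pop, pool, params: ModelParams, rng: RandomStream):
    """One generation of a single, undivided deme.

    Order of events: Wright–Fisher reproduction; eDNA pool decay then
    death-weighted production (sampled from the post-selection,
    pre-mutation population); mutation; HGT.

    Returns the updated ``(Population, EdnaPool)`` pair.
    """
    from . import edna  # local import to avoid a cycle

    pop = reproduce(pop, params.s, rng)
    pool = edna.decay(pool, params.d_edna, rng)
    pool = edna.produce(pool, pop, params.s, rng)
    pop = mutate(pop, params.U, rng)
    pop = edna.hgt(pop, pool, params.r, rng)
    return pop, pool
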