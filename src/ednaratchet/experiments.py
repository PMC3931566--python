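"""Experiment runners, synthetic fixtures, and TSV output.

Every runner is deterministic given the ``seed`` in its configuration, and
every output file echoes the full configuration in '#'-prefixed header
lines.  Runners come in two flavors: time-series runs, which record an
:class:`~ednaratchet.observables.ObservableRecord` stream, and sweep runs,
which record one summary row (accumulation rate, standard error, click
count) per parameter value.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import edna as edna_mod
from . import metapopulation as meta_mod
from . import observables as obs
from .core import ModelParams, Population, RandomStream, step_deme
from .edna import EdnaPool
from .metapopulation import Metapopulation

__all__ = [
    "ExperimentConfig",
    "initial_state",
    "run_single",
    "run_rate",
    "run_metapopulation_rate",
    "run_quality_persistence",
    "run_sweep",
    "run_experiment",
    "make_fixture",
    "write_tsv",
]

EXPERIMENTS = (
    "single-run",
    "r-sweep",
    "l-sweep",
    "dedna-sweep",
    "dpop-sweep",
    "phase-diagram",
    "two-class-grid",
)


@dataclass(frozen=True)
class ExperimentConfig:
    """A named experiment over a base parameter set and one sweep axis."""

    experiment: str
    base: ModelParams
    sweep_values: tuple = ()
    replicates: int = 1
    out: str | None = None
    thin: int = 1  # record every `thin` generations
    cap: int = 10_000_000  # two-class extinction cap (generations)

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; expected one of {EXPERIMENTS}"
            )
        if self.replicates < 1 or self.thin < 1:
            raise ValueError("replicates and thin must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = ModelParams(**{k: tuple(v) if k == "grid" else v for k, v in raw.pop("base").items()})
        raw["sweep_values"] = tuple(raw.get("sweep_values", ()))
        return cls(base=base, **raw)

    def header_lines(self) -> list[str]:
        cfg = dataclasses.asdict(self)
        cfg["base"] = dataclasses.asdict(self.base)
        return [f"# {line}" for line in yaml.safe_dump(cfg, sort_keys=True).strip().splitlines()]


def write_tsv(df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """TSV with '#'-prefixed metadata lines and NA for missing values."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# state construction


def initial_state(params: ModelParams, rng: RandomStream) -> tuple[Population, EdnaPool]:
    """Mutation-free monomorphic population; pool seeded with one production
    step (uniform dead-cell weights in the monomorphic start) so HGT is
    well-defined at t = 1."""
    pop = Population.monomorphic(params.N, params.l)
    pool = edna_mod.produce(EdnaPool.empty(params.l), pop, params.s, rng)
    return pop, pool


# ---------------------------------------------------------------------------
# single-deme runners


def run_single(
    params: ModelParams,
    generations: int | None = None,
    thin: int = 1,
    full_every: int | None = None,
    rng: RandomStream | None = None,
) -> pd.DataFrame:
    """Single undivided run recording the observable stream.

    Cheap observables (m_LLC, class size, mean load) are recorded every
    ``thin`` generations; the expensive ones (m_fix, gene diversities,
    pool q/t) every ``full_every`` (defaults to ``thin``).
    """
    if params.n_demes != 1:
        raise ValueError("run_single requires a 1x1 grid")
    generations = generations or params.generations
    full_every = full_every or thin
    rng = rng or np.random.default_rng(params.seed)
    pop, pool = initial_state(params, rng)
    rows = []
    for t in range(1, generations + 1):
        pop, pool = step_deme(pop, pool, params, rng)
        if t % thin == 0:
            rows.append(obs.record(t, pop, pool, full=(t % full_every == 0)))
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def run_rate(
    params: ModelParams,
    generations: int | None = None,
    rng: RandomStream | None = None,
) -> dict:
    """Long-run mutation-accumulation summary for one parameter set:
    final m_fix, the accumulation rate m_fix/t with SE sqrt(m_fix)/t, and
    the number of ratchet clicks."""
    generations = generations or params.generations
    rng = rng or np.random.default_rng(params.seed)
    pop, pool = initial_state(params, rng)
    clicks = 0
    m_llc_prev = 0
    for t in range(1, generations + 1):
        pop, pool = step_deme(pop, pool, params, rng)
        m_llc = int(pop.loads.min())
        if m_llc > m_llc_prev:
            clicks += m_llc - m_llc_prev
            m_llc_prev = m_llc
    m_fix = obs.fixed_mutations(pop)
    rate, se = obs.accumulation_rate(m_fix, generations)
    return {
        "m_fix": m_fix,
        "t": generations,
        "rate": rate,
        "se": se,
        "clicks": clicks,
        "m_llc": m_llc_prev,
    }


def run_metapopulation_rate(
    params: ModelParams,
    generations: int | None = None,
    rng: RandomStream | None = None,
    measure_diversity: bool = False,
) -> dict:
    """Subdivided-run summary: m̄_fix (unweighted mean of per-deme m_fix),
    its accumulation rate, and optionally the end-of-run (H_S, H_T, G_ST)."""
    generations = generations or params.generations
    rng = rng or np.random.default_rng(params.seed)
    meta = Metapopulation.initial(params, rng)
    for _ in range(generations):
        meta = meta_mod.step(meta, params, rng)
    mbar_fix = float(np.mean([obs.fixed_mutations(d) for d in meta.demes]))
    rate = mbar_fix / generations
    se = math.sqrt(mbar_fix) / generations
    out = {"mbar_fix": mbar_fix, "t": generations, "rate": rate, "se": se}
    if measure_diversity:
        h_s, h_t, g_st = obs.subdivision_diversity(meta.demes)
        out.update({"H_S": h_s, "H_T": h_t, "G_ST": g_st})
    return out


def run_quality_persistence(
    params: ModelParams,
    generations: int,
    rng: RandomStream | None = None,
    min_clicks: int = 5,
) -> dict:
    """Persistence of eDNA quality after ratchet clicks.

    Runs the single-deme model recording m_LLC and q_eDNA every generation;
    for each click (increase of m_LLC) measures the number of generations
    until the first subsequent generation with q_eDNA = 0.  Clicks whose
    q never hits zero before the run ends contribute their elapsed time, so
    the reported mean is a lower bound in that case.
    """
    rng = rng or np.random.default_rng(params.seed)
    pop, pool = initial_state(params, rng)
    m_prev = 0
    pending: list[int] = []  # click times still waiting for q = 0
    waits: list[int] = []
    n_clicks = 0
    for t in range(1, generations + 1):
        pop, pool = step_deme(pop, pool, params, rng)
        m_llc = int(pop.loads.min())
        if m_llc > m_prev:
            n_clicks += m_llc - m_prev
            pending.extend([t] * (m_llc - m_prev))
            m_prev = m_llc
        if pending:
            llc = obs.llc_members(pop)
            q, _ = obs.edna_quality_toxicity(llc, pool)
            if q == 0.0:
                waits.extend(t - tc for tc in pending)
                pending.clear()
    censored = [generations - tc for tc in pending]
    all_waits = waits + censored
    return {
        "n_clicks": n_clicks,
        "n_resolved": len(waits),
        "n_censored": len(censored),
        "mean_wait": float(np.mean(all_waits)) if all_waits else float("nan"),
        "mean_wait_resolved": float(np.mean(waits)) if waits else float("nan"),
        "lower_bound": bool(censored),
    }


# ---------------------------------------------------------------------------
# sweeps


def _sweep_param(experiment: str) -> str:
    return {
        "r-sweep": "r",
        "l-sweep": "l",
        "dedna-sweep": "d_edna",
        "dpop-sweep": "D_pop",
    }[experiment]


def run_sweep(config: ExperimentConfig, generations: int | None = None) -> pd.DataFrame:
    """Run one summary row per sweep value (× replicate)."""
    axis = _sweep_param(config.experiment)
    rows = []
    for value in config.sweep_values:
        for rep in range(config.replicates):
            params = dataclasses.replace(
                config.base, **{axis: value}, seed=config.base.seed + rep
            )
            if params.n_demes == 1:
                summary = run_rate(params, generations)
            else:
                summary = run_metapopulation_rate(params, generations)
            rows.append({axis: value, "seed": params.seed, **summary})
    return pd.DataFrame(rows)


def run_phase_diagram(config: ExperimentConfig, generations: int | None = None) -> pd.DataFrame:
    """Fig 10-style comparison: for each (d_eDNA, D_eDNA) sweep value pair,
    the sign of the rate difference between a subdivided (D_pop = 1e-5) and
    a well-mixed (D_pop = 1e-1) population.  ``sweep_values`` holds
    (d_edna, D_edna) pairs; sign < 0 means subdivision is advantageous."""
    rows = []
    for d_edna, D_edna in config.sweep_values:
        rates = {}
        for dpop in (1e-5, 1e-1):
            params = dataclasses.replace(
                config.base, d_edna=d_edna, D_edna=D_edna, D_pop=dpop
            )
            rates[dpop] = run_metapopulation_rate(params, generations)["rate"]
        diff = rates[1e-5] - rates[1e-1]
        rows.append(
            {
                "d_edna": d_edna,
                "D_edna": D_edna,
                "rate_subdivided": rates[1e-5],
                "rate_mixed": rates[1e-1],
                "sign": int(np.sign(diff)),
            }
        )
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig, generations: int | None = None) -> pd.DataFrame:
    """Dispatch a configured experiment and (optionally) write its TSV."""
    if config.experiment == "single-run":
        df = run_single(config.base, generations, thin=config.thin)
    elif config.experiment == "phase-diagram":
        df = run_phase_diagram(config, generations)
    elif config.experiment == "two-class-grid":
        from .twoclass import TwoClassParams, mean_extinction_time

        rows = []
        for r01, r10 in config.sweep_values:
            params = TwoClassParams(
                config.base.N, config.base.U, config.base.s, r01, r10
            )
            summ = mean_extinction_time(
                params, replicates=config.replicates, seed=config.base.seed,
                cap=config.cap,
            )
            rows.append(
                {
                    "r01": r01,
                    "r10": r10,
                    "mean_time": summ.mean,
                    "se": summ.se,
                    "normalized": summ.normalized_mean,
                    "censored": summ.n_censored,
                }
            )
        df = pd.DataFrame(rows)
    else:
        df = run_sweep(config, generations)
    if config.out:
        write_tsv(df, config.out, config.header_lines())
    return df


# ---------------------------------------------------------------------------
# fixtures


def make_fixture(kind: str, size: int, seed: int = 0, l: int = 100, **kw):
    """Deterministic small synthetic objects for tests and oracles.

    Kinds
    -----
    monomorphic : load-``kw['load']`` (default 0) population of ``size``.
    poisson-balance : population with Poisson(U/s) loads at random loci
        (requires ``U`` and ``s``), the mutation-selection profile.
    two-class : ``kw['k']`` genomes of load 1 (each at a random locus), the
        rest mutation-free.
    pool-uniform : EdnaPool with ``size`` copies of every zero-mutation
        allele at each locus.
    pool-single-mutants : EdnaPool with ``size`` copies per locus of the
        one-mutation allele.
    metapopulation : grid of monomorphic demes (requires ``grid``).
    """
    rng = np.random.default_rng(seed)
    if kind == "monomorphic":
        load = kw.get("load", 0)
        genome = np.zeros(l, dtype=np.int16)
        genome[:load] = 1
        return Population.monomorphic(size, l, genome)
    if kind == "poisson-balance":
        lam = kw["U"] / kw["s"]
        mat = np.zeros((size, l), dtype=np.int16)
        hits = rng.poisson(lam, size)
        rows = np.repeat(np.arange(size), hits)
        cols = rng.integers(0, l, int(hits.sum()))
        np.add.at(mat, (rows, cols), 1)
        return Population(mat)
    if kind == "two-class":
        k = kw.get("k", size // 2)
        mat = np.zeros((size, l), dtype=np.int16)
        cols = rng.integers(0, l, k)
        mat[np.arange(k), cols] = 1
        return Population(mat)
    if kind == "pool-uniform":
        return EdnaPool.from_entries(l, [(i, 0, size) for i in range(l)])
    if kind == "pool-single-mutants":
        return EdnaPool.from_entries(l, [(i, 1, size) for i in range(l)])
    if kind == "metapopulation":
        grid = kw["grid"]
        n_demes = grid[0] * grid[1]
        demes = [Population.monomorphic(size, l) for _ in range(n_demes)]
        pools = [EdnaPool.empty(l) for _ in range(n_demes)]
        return Metapopulation(demes, pools, grid)
    raise ValueError(f"unknown fixture kind {kind!r}")
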