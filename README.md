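# ednaratchet

Forward-time simulation of **Muller's ratchet** in prokaryotic populations
that take up DNA released by their own dead — horizontal gene transfer
(HGT) by natural transformation from an extracellular-DNA (eDNA) pool —
with optional population subdivision on a toroidal deme grid.

The package is for population geneticists and microbial evolution
researchers who want to ask: can "sex with dead cells" stop the
stochastic, irreversible loss of the least-loaded genome class, even
though eDNA carries *more* deleterious mutations than the DNA of living
cells? And does splitting a population into semi-isolated subpopulations
that cross-reference each other's genes through a shared eDNA pool make
HGT more effective?

## The model

A haploid population of fixed size *N* evolves by discrete Wright–Fisher
generations. Each genome has *l* loci; the allele at locus *k* is labeled
by its count of deleterious mutations, and fitness is multiplicative,
*f_m* = (1 − *s*)^*m* with *m* the total load. Each generation:

1. **Selection/drift** — multinomial resampling weighted by fitness.
2. **eDNA pool update** — every entry *e_ij* (copies of the *j*-mutation
   allele at locus *i*) decays at rate *d*_eDNA; then *N* dead cells,
   sampled with probability ε_i ∝ 1 − (1 − *s*)^(*m_i* − *m*_LLC), add all
   their alleles to the pool. Members of the least-loaded class (LLC)
   never die, so the pool is loaded: at balance it carries *U*/*s* + 1
   mutations per genome-equivalent.
3. **Migration/diffusion** (subdivided runs) — neighboring demes on a
   4 × 4 torus swap Binomial(*N_s*/4, *D*_pop) individuals per pair, and
   pools exchange a fraction *D*_eDNA/4 of each entry per direction
   (*D*_eDNA = ∞ means one pool shared by all demes).
4. **Mutation and HGT** — each genome gains Poisson(*U*) new mutations at
   uniform loci, then replaces Poisson(*r*) alleles with copy-number-
   weighted draws from the pool.

Companion closed forms (`ednaratchet.theory`) include the stationary class
profile n̄_(LLC+k) = *N*e^(−*U*/*s*)(*U*/*s*)^k/k!, the single-event
conversion probabilities P10 = *l*⁻¹(1 − *l*⁻¹)e^(−*U*/(*sl*)) and
P01, the P10-maximizing locus number, and the steady-state disadvantage
condition of a simplified two-class model
(`ednaratchet.twoclass`) in which HGT converts the least-loaded class at
rate r01 and regenerates it at rate r10.

## Worked example

Parameter report for the slow-ratchet reference regime
(*N* = 10⁵, *s*·n̄_LLC = 10):

```
$ ednaratchet theory-report --N 100000 --sn-llc 10
quantity	value
U	0.0460517
sn_llc	10
n_llc	1000
n_llc_plus1	4605.17
P10	0.00945443
P01	0.0545573
l_opt	5.81294
llc_production_rate	0.435392
edna_mean_load	5.60517
```

The regime solver inverts *s·N·*e^(−*U*/*s*) = 10 to *U* ≈ 0.046
mutations/genome/generation; the least-loaded class then holds ~1000
cells. One HGT event on a one-but-least-loaded genome restores the LLC
with probability P10 ≈ 0.0095, and at *r* = 0.01 HGT rebuilds
≈ 0.44 LLC genomes per generation — the scale on which the ratchet stops.
Each dead genome in the pool carries ≈ 5.6 mutations, one more than the
population mean *U*/*s*: eDNA is toxic on average, yet still rescues.

A small ratchet-arrest experiment (fast regime, *N* = 2000):

```python
>>> from ednaratchet import ModelParams
>>> from ednaratchet.experiments import run_rate
>>> run_rate(ModelParams(N=2000, U=2.9957e-2, r=0.0, seed=11), generations=5000)
{'m_fix': 9, 't': 5000, 'rate': 0.0018, 'se': 0.0006, 'clicks': 12, 'm_llc': 12}
>>> run_rate(ModelParams(N=2000, U=2.9957e-2, r=0.1, seed=11), generations=5000)
{'m_fix': 3, 't': 5000, 'rate': 0.0006, 'se': 0.00035, 'clicks': 4, 'm_llc': 4}
```

Without HGT the population fixes deleterious mutations at
1.8 × 10⁻³ per generation; at *r* = 0.1 the rate drops threefold — HGT
from dead cells is slowing the ratchet.

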