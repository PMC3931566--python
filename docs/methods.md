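# Methods

## Model

One deme is a haploid Wright–Fisher population of constant size holding a
matrix of per-locus deleterious-mutation counts; an allele is identified
by its locus and its count, so two genomes mutated the same number of
times at the same locus carry the same allele. Fitness is (1 − s)^m in
the total load m, with no epistasis, back mutation, or beneficial
mutation. A generation applies, in order: (1) fitness-weighted multinomial
resampling; (2) eDNA pool decay followed by death-weighted production;
(3) migration of cells and diffusion of eDNA between demes (subdivided
runs only); (4) Poisson(U) mutation at uniformly chosen loci, then
Poisson(r) HGT replacements drawn from the pool in proportion to copy
number. Within step 4 mutation precedes HGT; at the rates studied the two
orders differ only at second order in U·r, and the choice is fixed so
trajectories are reproducible.

Death weights are ε_i ∝ 1 − (1 − s)^(m_i − m_LLC): the normalization by
the least-loaded class's fitness keeps the pool's load distribution
stationary relative to the moving m_LLC, and it is the most pessimistic
choice for HGT (the best genomes never enter the pool). When the whole
deme sits in its least-loaded class the formula degenerates to 0/0; we
then sample the dead uniformly. This arises at initialization — the run
starts from a mutation-free monomorphic population whose pool is seeded
with one uniform production step so that HGT is defined at t = 1 — and
transiently whenever a deme becomes monomorphic.

Integer rounding in pool decay and diffusion follows a threshold rule:
an entry with expected loss d·e (or outflow D·e/4 per direction) above 1
loses the rounded expectation (half away from zero, clamped so counts
never go negative and diffusion conserves grid totals); below 1 the loss
is binomial (multinomial over the four directions for diffusion). The
tie at exactly .5 rounds away from zero. HGT draws are with replacement
and do not deplete the pool: pool copy numbers change only through decay
and production, with concentration effects absorbed into r.

Migration swaps k ~ Binomial(N_s/4, D_pop) individuals per unordered
neighbor pair on the torus, drawn against the pre-migration state; the
symmetric swap keeps every deme at exactly N_s. eDNA diffusion is applied
synchronously from the pre-step state, so the order of demes is
immaterial. D_eDNA = ∞ is implemented literally as a single pool shared
by all demes. A 1 × 1 grid reduces exactly — same random stream — to the
undivided model.

## Parameters and defaults

| symbol | meaning | default | why |
|---|---|---|---|
| s | fitness cost per mutation | 0.01 | reference value for weak deleterious effects |
| l | loci (recombinable segments) | 100 | ~10 kb segments on a ~1 Mb genome |
| d_eDNA | pool turnover per generation | 1 | most conservative: no pool memory |
| grid | deme layout | 1×1 (4×4 for subdivided runs) | |
| U | mutation rate | from the regime index | see below |

U is usually set through the regime index s·n̄_LLC = s·N·e^(−U/s)
(`theory.solve_mutation_rate`): values ≫ 1 give a slow ratchet whose
clicks are rare and well separated, ≈ 1 a fast ratchet with overlapping
click–fixation cycles.

## Observables

m_LLC is the minimum load; m_fix the per-locus minimum count summed over
loci; a click is any increase of m_LLC (an increase by k counts as k
simultaneous clicks). Gene diversity H is the mean over loci of
1 − Σ_j x_j² with allele frequencies x taken within one genotype class;
the class above the LLC can be transiently empty, in which case H is
recorded as missing (NA in TSV output), never 0. eDNA quality q and
toxicity t are the expected mutations removed/introduced by a single HGT
event on an LLC genome. Pool allele fractions y_kj enter as whole-pool
fractions (e_kj divided by the grand total) so that t − q is literally
the net expected load change per event; the per-locus convention, which
scales both sums by l on a balanced pool, is available as an option.
For subdivided runs H_S is the LLC-size-weighted mean of per-deme LLC
diversities, H_T the diversity of the pooled per-deme LLCs,
G_ST = (H_T − H_S)/H_T (0 when H_T = 0), and m̄_fix the unweighted mean
of per-deme m_fix. The accumulation rate is m_fix/t with standard error
sqrt(m_fix)/t, the Poisson counting error of the number of fixation
events — "m_fix over t, squared" renderings of this quantity resolve to
sqrt(m_fix)/t dimensionally.

## Two-class model

`twoclass` collapses the population to the least-loaded class (frequency
p) versus everything else. The update
p′ = [(1 − U′)(1 − r01)p + (1 − s′)r10(1 − p)] / w̄ uses the mean
parental fitness w̄ = p + (1 − s′)(1 − p); this is the unique normalizer
whose no-HGT fixed point is the classical p̂ = 1 − U′/s′, and it keeps
p′ in [0, 1]. The second term carries no extra (1 − U′) factor —
converted cells are not additionally mutated within the same generation.
Stochastic runs draw n₀(t+1) ~ Binomial(N, p′) until n₀ = 0, starting by
default from p̂; mean extinction times are normalized by an
r01 = r10 = 0 baseline run with the same replicate count and seed
discipline, and censored replicates (default cap 10⁷ generations) make
the reported means explicit lower bounds.

## Numerical choices

The population is a dense (N × l) int16 matrix; class views are computed
on demand. All stochastic draws consume a single seeded
`numpy.random.Generator` in the fixed order of the generation schedule,
so a seed fully determines a trajectory. Repeated HGT draws at one
(genome, locus) pair resolve to the last draw. Closed forms use log-space
intermediates where e^(−U/s) underflows. The eDNA production scatter is
the only compiled kernel (numba, with an integer-exact numpy fallback).
The P10-maximizing locus number uses the exact root
z̃ = s/U + 1/2 − sqrt((s/U)² + 1/4); its small-s/U series is
s/U − (s/U)², which we do not use for any reported value.

## What the tests show — and at what scale

The synthetic runs in the test suite emulate the model's own study
conditions, not any empirical data set: all inputs are generated in-repo.
Problem sizes are chosen so the whole suite runs on a desk machine:

- stationary-profile and eDNA-load checks: N = 10⁴, U = 0.023026
  (s·n̄_LLC = 10), 12 000 and 2 500 generations;
- single-event P10 checks: N = 10⁴, l ∈ {10, 100}, 10⁵ events over 25
  decorrelated snapshots;
- ratchet arrest: N = 2 000 in the fast regime (U = 2.9957 × 10⁻²,
  s·n̄_LLC = 1), 4 × 10⁴ generations per HGT rate. The slow regime at
  this N clicks fewer than once per ~4 × 10⁶ generations (we measured
  zero clicks in a 4 × 10⁶-generation load-class run), so the arrest
  property is exercised where the baseline ratchet is measurable; the
  slow-regime behavior at large N is covered by the analytic production-
  rate anchors instead;
- two-class model: exact absorbing-Markov-chain oracle at N = 50;
  persistence-versus-disadvantage at N = 10³ with s′ = 0.1, U′ = 0.09
  (s′·n̄₀ = 10 — at N = 10³ this index cannot be reached with s′ = 0.01,
  which would force U′ = 0, so the whole Fig-4-style point is scaled by
  ten);
- eDNA-quality persistence: N = 10⁵, U = 6.9078 × 10⁻², d_eDNA = 0.1,
  5 000–6 000 generations; clicks whose q_eDNA never reaches zero in the
  window contribute their elapsed time, making the reported mean a lower
  bound;
- subdivision: N = 1 600 on a 4 × 4 grid (deme size 100), 3 000
  generations, three seeds per condition, with U set by s·n̄ = 1 for the
  undivided total.

Passing these checks shows the implementation agrees with the model's
analytic structure and qualitative phase behavior at reduced scale; it
does not by itself certify quantitative rate curves at N = 10⁵–10⁶ over
10⁹ generations, nor anything about real microbial populations, whose
death, uptake and spatial processes are far richer than ε_i, r, and a
4-neighbor torus.

## Known limitations

No epistasis, beneficial or back mutations, diploidy, overlapping
generations, sequence-divergence-dependent recombination, DNA fragment
length, active DNA release, or nutrient use of eDNA. Migration trials
use integer N_s/4; deme sizes not divisible by 4 truncate. Extremely
large U/s (> ~500) would overflow the int16 locus counts long before any
realistic parameterization does.
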