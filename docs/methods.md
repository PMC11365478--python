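# Methods

## Model overview

`evonet` simulates, forward in time, a population of N haploid individuals
whose phenotype is produced by a gene regulatory network (GRN).  Each
individual carries n genes; gene i owns two binary regulatory regions of
length L: a *cis* region (what regulation the gene accepts) and a *trans*
region (how the gene regulates others).  Positions 1..L-1 are strength
bits, position L is the type bit.

### Interactions

The effect of gene j's trans region on gene i's cis region is

    M[i, j] = s_j * popcount(cis_i[1:L-1] & trans_j[1:L-1]) / L

if the cis type bit of gene i is 1, and 0 otherwise; the sign s_j is +1
for an activator trans type bit (1) and -1 for a repressor (0).  The
denominator is L, so |M[i, j]| <= (L-1)/L.  The diagonal (self-regulation)
is computed by the same rule.  The full matrix is maintained incrementally:
a cis mutation refreshes one row, a trans mutation one column, and tests
hold the result bit-identical to a from-scratch rebuild.

### Maturation

A newborn starts from the constant all-ones expression vector and iterates

    E(t+1)[i] = 1  if  sum_j M[i, j] E(t)[j] > 0,  else 0

synchronously until a previously visited state recurs: a period-1 revisit
is a fixed point, period k >= 2 a cycle, and no revisit within the step cap
(default 10,000) marks the individual non-viable (fitness 0).  For n <= 13
the 2^n state space guarantees an attractor below the cap.

Two numerical choices deserve note.  First, the threshold is strictly
positive and a zero input switches the gene off; the all-off state is
therefore absorbing whenever the matrix is zero, which pins generation-0
populations (whose cis regions accept nothing) at the all-off phenotype.
Second, the birth vector must be nonzero for regulation to act at all —
with a zero start the product M·E is identically zero — so all-ones is the
default and the vector is configurable.  A spin-state variant (off genes
contributing -1) was evaluated and rejected: with the standard
initialization (all trans activators) a gene could then only switch on via
net *repressive* input, and full-scale runs never left the generation-0
fitness.

### Fitness and selection

Fitness is exponential in the Euclidean distance between the matured
binary expression vector and an optimum vector over the genes under
selection: F = exp(-sqrt(k)/sigma^2) for k mismatched selected genes
(sigma^2 = 5 by default, i.e. selection intensity 1/5).  Genes marked FREE
in the optimum are neutral: their state never enters the distance.  Cyclic
individuals score the minimum fitness over one full period (transients
excluded); non-viable individuals score 0.  Parents are drawn i.i.d.
proportionally to fitness (Wright-Fisher, non-overlapping generations,
constant N).  Because expression is binary, attainable fitness values form
the discrete ladder {exp(-sqrt(k)/sigma^2)}; mean-fitness trajectories
plateau on these rungs.

### Mutation

The number of bit flips per offspring genome is Poisson(mu) (default
mu = 0.005 per genome per generation).  Each flip picks one of the 2n
regions uniformly.  Trans-region flips hit the type bit with probability
1% — switching an established regulator between activator and repressor is
rare — and otherwise a uniform strength bit.  Cis-region flips are uniform
over all L positions: gaining or losing the ability to accept regulation
is an ordinary promoter-scale event.  (Applying the 1% rule to cis type
bits as well throttles adaptation to ~1 fitness rung per 15,000
generations and suppresses the ladder; the asymmetric rule restores the
observed multi-rung climbing.)

### Recombination

Two models, selected per run; an offspring has two parents with
probability `recombination_prob` (0.5 when a model is enabled):

* **wagner** — row swapping: all trans regions from one parent, each cis
  region from either parent with probability 1/2.
* **r1r2** — a single breakpoint j uniform on {1..n-1}: the first j genes
  contribute both regions from one parent, the rest from the other.

In both cases the child's interaction matrix is re-evaluated from its own
regions, never copied from a parent.

### Initialization

Generation 0 is clonal: every cis type bit 0 (no gene accepts regulation),
every trans type bit 1 (all activators), strength bits all zero by default
(`zeros`; `random` and `ones` are options).  Zero strength bits make
evolved interactions shallow (1-3 shared bits), so injected mutations can
actually sever them; with random initialization (~7-8 shared bits per
pair) single flips almost never change the sign topology and robustness
probing loses its signal.

## Experiments

* **Robustness probing** clones the population, injects a fixed number of
  uniformly placed mutations into every clone, matures both copies and
  reports (a) expression robustness — mean fraction of genes with equal
  post-maturation binary expression — and (b) topology robustness — mean
  fraction of matching entries of the sign-discretized matrices.  For
  cyclic attractors the representative phenotype is the first-reached
  recurring state.  Probes draw from a dedicated random stream, so the
  evolutionary trajectory is bit-identical with and without probing.
* **Exploration accounting** counts cumulative distinct genotypes (exact
  equality of the full 2nL-bit genome; a sign-matrix identity is a config
  switch).  The selection arm evolves toward the optimum with R1R2
  recombination; the neutral arm leaves genotype frequencies to mutation
  and drift alone, with no recombination, so that every novel genotype
  stems from mutation.  This scenario split reproduces the reported
  asymmetry; with recombination matched across arms the two counts are
  statistically indistinguishable at every scale we measured.
* **Neutral-gene accounting** counts sign-matrix entries linking a neutral
  and a selected gene (both directions; optionally gated on the source
  gene being expressed, since silent genes contribute nothing to the
  dynamics).
* **GRN-less baseline** strips the regulatory layer: gene states are the
  genotype, Poisson(mu) flips act on them directly, fitness is the same
  exponential distance, no maturation.  It runs through the identical
  engine loop by dependency injection.  For buffering comparisons,
  attainment of the optimum is measured at the population level (mean
  fitness >= 0.95): one lucky offspring can touch the optimum under any
  load, so the mutational-load effect is invisible in first-touch times.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| N | 100 | haploid population size |
| n | 10 | genes |
| L | 30 | bits per regulatory region |
| mu | 0.005 | mutations per genome per generation |
| sigma2 | 5 | selection-strength denominator |
| optimum | all-ones | target expression |
| generations | 15,000 | run length |
| step_cap | 10,000 | maturation step limit |
| recombination | none (prob 0.5 when enabled) | offspring bi-parentality |

## Reduced problem sizes

The test suite exercises the headline behaviors at sizes a laptop handles
in minutes, chosen before freezing the tests by matching per-run mutation
supply or rung-supply rate to the full-scale runs rather than by tuning:

* exploration contrast: N=50, 2,000 generations, mu=0.075 (preserves
  N·mu·generations = 7,500), 20 replicates per arm;
* robustness probing: N=50, 3,000 generations, probe interval 250, 15
  injected mutations, mu=0.3 so the optimum is reached mid-run;
* buffering: mu in {0.01, 1.0}, N=50, 20 replicates, 3,000-generation cap;
* neutral genes: 5 selected/5 neutral, N=50, mu=0.2, 6 replicates.

## Known limitations

* The synthetic populations are the study system; no empirical data enter.
* Cross-partition interaction counts rise monotonically toward a high
  drift equilibrium: an interaction "exists" as soon as one strength bit
  is shared and the cis type bit is set, and symmetric bit-flip mutation
  pushes that indicator toward saturation.  Any selective pruning of
  neutral-selected interactions at the optimum is swamped by this
  accumulation at every mutation rate we probed, so the package does not
  reproduce a post-optimum *decline* in cross-partition counts; the
  corresponding test documents the expected direction and currently fails.
* Expression during maturation is strictly binary; graded expression,
  asynchronous updates, diploidy and epigenetic marks are out of scope.
* Robustness probes are placement-noise limited: with 15 mutations per
  clone the probe-to-probe variance is comparable to the canalization
  signal, so phase comparisons average several replicates.
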