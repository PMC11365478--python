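# evonet

Forward-in-time simulation of gene-regulatory-network (GRN) evolution in a
haploid Wright–Fisher population, for population geneticists and systems
biologists studying how selection, drift, mutation and recombination shape
regulatory networks rather than single loci.

Each of the N individuals carries n genes with binary *cis* and *trans*
regulatory regions of length L.  The signed interaction of gene j on gene
i is

    M[i,j] = ± popcount(cis_i ∧ trans_j) / L

gated by the cis type bit (does gene i accept regulation?) and signed by
the trans type bit (activator/repressor).  A newborn matures by iterating
the expression dynamics E(t+1)[i] = [ (M·E(t))_i > 0 ] to a fixed point or
cycle, and is scored by stabilizing/directional selection toward an
optimum expression vector:

    F(E) = exp(−‖E − E_opt‖ / σ²)

with the Euclidean norm over the genes under selection (cycles score the
minimum over one period; attractor-less individuals are non-viable).
Because expression is binary, attainable fitness values form a discrete
ladder exp(−√k/σ²), and mean-fitness trajectories climb it in visible
steps.  Built-in experiment harnesses measure mutational robustness
(core/branch population cloning), genotype-space exploration under
selection vs neutrality, neutral-gene interactions, and mutational
buffering against a GRN-less baseline.

## Worked example

```
evonet run --pop-size 100 --generations 3000 --mu 0.05 \
           --recombination r1r2 --seed 42 --out stats.tsv
```

prints

```
final mean fitness: 0.707222
cumulative distinct genotypes: 90022
```

and writes `stats.tsv` (one row per generation), a TSV edge list of the
final network, and a JSON manifest of the resolved configuration.  The
final mean fitness 0.7072 is exactly the ladder rung exp(−√3/5) — the
population has fixed networks that express 7 of the 10 genes demanded by
the all-ones optimum — and 90,022 distinct genotypes passed through the
population on the way.  The first stats rows show the run starting on the
bottom rung exp(−√10/5) ≈ 0.5313, where the generation-0 genomes (which
accept no regulation) mature to the all-off phenotype.

The same machinery is available as a library:

```python
from evonet import SimulationConfig, run
stats = run(SimulationConfig(N=100, generations=3000, mu=0.05,
                             recombination_model="r1r2", seed=42)).stats
```

Other subcommands: `evonet robustness` (clone the population at intervals,
inject mutations, report expression/topology identity) and
`evonet buffering` (time to the optimum for the full model vs a baseline
without a regulatory layer, across a mutation-rate grid).

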