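# ednasim

A mechanistic simulator of eDNA metabarcoding, for ecologists and
bioinformaticians who want to understand — or anticipate — what PCR does to
their community data.

Metabarcoding surveys amplify a marker gene from mixed environmental DNA and
sequence the amplicons. Two researcher-controlled choices dominate the
outcome: the number of PCR cycles, and the primer set (through the
distribution of per-taxon amplification efficiencies). Because PCR is
exponential and competitive, small efficiency differences compound into large
distortions of read proportions, and the sequencer imposes an arbitrary
total, making the data compositional. `ednasim` simulates the full causal
chain so these effects can be quantified:

1. **Biomass** — proportional biomass `B_i` of `N` taxa, either uniform
   (`B_i = 1/N`) or a symmetric Dirichlet(γ) draw;
2. **Shedding / ambient eDNA** — `D_i = B_i·s_i` with lognormal shedding
   rates `s_i ~ LogNormal(0.5, 0.5)` (log-scale mean and sd), assuming
   equilibrium between production and loss;
3. **PCR** — `A_i = D_i·(1 + a_i)^{N_cycles}·ε_i`, with per-taxon efficiency
   `a_i ∈ [0, 1]` drawn from a Beta or two-component Beta mixture and small
   lognormal process noise `ε` (σ = 0.05);
4. **Sequencing** — read depth `round(Beta(30, 30)·10⁶)` and a multinomial
   sample with probabilities `A / ΣA`.

Three built-in primer cases span real use-cases: `A` Beta(5, 5)
(broad-spectrum primers), `B` Beta(0.5, 1.5) (right-skewed), `C`
0.1·Beta(2.1, 0.58) + 0.9·Beta(0.01, 10) (taxon-specific primers).

On top of the simulator the package provides:

* **diversity** — richness and Shannon diversity, PCR cycle sweeps,
  sample-based species-accumulation curves, per-taxon detection
  probability vs amplification efficiency, and balanced two-factor ANOVA
  variance partitioning (primer case vs biomass distribution);
* **indices** — seven within-sample abundance transformations (raw counts,
  eDNA index, frequency, chord-normalized, rank, Hellinger, log₂+1), a
  per-taxon Spearman benchmark of each index against true biomass over a
  time series, a matrix-shuffle permutation null, and performance summaries
  stratified by abundance quartile or efficiency bin;
* **calibration** — inversion of the amplification model on mock-community
  data to estimate relative per-taxon efficiencies
  (`g_i = (Y_i/D₀_i)^{1/N}`, anchored to the best amplifier), plus Beta
  fitting by method of moments or maximum likelihood;
* **a CLI** (`ednasim`) that runs the standard experiments and applies the
  indices to any taxa × samples OTU/ASV count table.

## Worked example

```python
import numpy as np
from ednasim import (CASE_PRESETS, PCRParams, cycle_sweep,
                     draw_efficiencies, simulate_community, simulate_sample,
                     richness, shannon)

community = simulate_community(1000, rng_seed=1)        # 1000 taxa, Dirichlet(5)
eff = draw_efficiencies(1000, CASE_PRESETS["A"], rng_seed=2)
reads = simulate_sample(community, eff, PCRParams(n_cycles=35), rng_seed=3)
print(richness(reads), round(shannon(reads), 3))
```

```
748 4.442
```

After 35 cycles with broad-spectrum (Case A) primers, only 748 of 1000 taxa
are still detected, and the Shannon index (4.44) sits well below the true
community's 6.81 — the low-efficiency tail has been competitively excluded
and the read distribution skewed toward efficient amplifiers.

```python
df = cycle_sweep(n_replicates=100, n_taxa=1000, cases=("A", "C"),
                 cycle_grid=(20, 40), rng_seed=1)
print(df.groupby(["case", "n_cycles"])["richness"].median())
```

```
case  n_cycles
A     20          977.0
      40          644.0
C     20          109.0
      40           83.0
```

Cycle number matters enormously for broad primers (977 → 644 taxa between 20
and 40 cycles) while taxon-specific Case C primers detect a small, relatively
stable subset — the fraction of taxa their efficiency mixture amplifies well.

For the quantitative side, `timeseries_experiment()` simulates 25 timepoints
of a fluctuating community and correlates each abundance index with true
biomass per taxon; the eDNA index (read proportions rescaled to each taxon's
maximum) reaches a median Spearman ρ ≈ 0.85, and ρ ≈ 0.97 for taxa that
amplify at efficiency ≥ 0.6.

From the shell:

```bash
ednasim sweep --seed 1 --out results/
ednasim indices --seed 1 --out results/
ednasim index-table my_otu_table.csv --index edna_index --out results/
ednasim calibrate mock.csv --cycles 35 --out results/
```

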