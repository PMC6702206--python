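# Methods

## The generative model

`ednasim` models an eDNA metabarcoding survey as five processes in series.
Random and systematic error at each stage propagates to the next, which is
why the chain is simulated end to end rather than stage by stage.

**Biomass.** A community of `N` taxa carries proportional biomass
`B = (B_1, …, B_N)`, `ΣB_i = 1`. Proportions rather than absolute biomass
are the right currency here: PCR is a competitive reaction among template
molecules, so only relative concentrations matter downstream. Two
distributions are supported: exactly uniform (`B_i = 1/N`) and symmetric
Dirichlet(γ). All Dirichlet scenarios share the same mean `1/N`, so
comparisons across scenarios vary only the among-taxon spread; γ = 5 is the
"moderately variable" default, γ = 1 highly variable, and the uniform model
is the γ → ∞ limit.

**Shedding and ambient eDNA.** Each taxon sheds DNA at rate
`s_i ~ LogNormal(0.5, 0.5)`. The parameters are the mean and standard
deviation of log s (so the median rate is e^0.5 ≈ 1.65 and rates span
roughly two orders of magnitude, matching the spread measured for marine
fishes). Loss of DNA from the environment is assumed constant among taxa and
in equilibrium with production, so the ambient template concentration is the
point value `D_i = B_i·s_i` with no decay dynamics. Collection and
extraction are assumed unbiased and are identity maps. The simulation is
spatially inexplicit.

**PCR.** Each taxon has an amplification efficiency `a_i ∈ [0, 1]` for a
given primer set (`a = 1` doubles every cycle), fixed per taxon because it
is a property of the primer–template interaction, independent of community
context. After `N_cycles` cycles,

    A_i = D_i · (1 + a_i)^N_cycles · ε_i ,   ε_i ~ LogNormal(0, σ),

with σ = 0.05 on the log scale by default and ε applied once per taxon per
amplification event, not per cycle. Amplicon abundances stay real-valued.
Per-cycle chemistry (reagent depletion, plateau, chimeras) is deliberately
not modelled; in the exponential regime it would only rescale the shared
total, which the multinomial below cancels anyway.

Efficiencies are drawn from a Beta distribution or a two-component Beta
mixture. The three presets describe recognizable primer archetypes:

| case | model | mean (sd) | reads as |
|------|-------|-----------|----------|
| A | Beta(5, 5) | 0.50 (0.15) | broad-spectrum primers: most taxa amplify, few very well or very poorly |
| B | Beta(0.5, 1.5) | 0.25 (0.25) | primers that amplify few taxa well, most poorly |
| C | 0.1·Beta(2.1, 0.58) + 0.9·Beta(0.01, 10) | ≈ 0.079 | taxon-specific primers: a small target group amplifies well, the rest essentially not at all |

**Sequencing.** The read depth is `round(P_samp·10⁶)` with
`P_samp ~ Beta(30, 30)` (mean depth 5×10⁵, always in (0, 10⁶)), and reads
are a multinomial draw with probabilities `A/ΣA`. This is where the data
become compositional: any common rescaling of `A` (or of `D`) is invisible.

## Diversity analyses

Richness is the number of taxa with ≥ 1 read (the threshold is
configurable); Shannon diversity is `H = −Σ p ln p` over detected-taxon read
proportions, natural log by default. The cycle sweep redraws community and
efficiencies per replicate but holds each replicate's efficiency vector
fixed across the whole cycle grid, so the cycle effect is not confounded
with primer-draw noise. Species-accumulation curves are sample-based, by
default averaging cumulative richness over 100 random sample orderings; an
exact analytic expectation (hypergeometric inclusion probabilities) is
available and agrees with the permutation estimate.

The variance-partition experiment crosses the three primer cases with the
three biomass scenarios at a fixed cycle count (default 35), 100 replicates
per cell. One efficiency vector per case is drawn once and shared across all
replicates and biomass scenarios, so the partition isolates primer identity
from community structure; biomass and shedding are redrawn per replicate and
every case amplifies the same community draw. The partition itself is a
balanced two-factor fixed-effects ANOVA on main effects
(`R² = SS_factor/SS_total`; under balance sequential and marginal sums of
squares coincide, and the omitted interaction folds into the residual).
A caveat worth stating: because a single shared efficiency draw per case
randomizes the case means themselves, the Shannon R² values are noticeably
run-dependent (case R² ≈ 0.76 ± 0.07 across master seeds in our runs); the
richness partition (≈ 0.996 / 0.001) is highly stable.

## Abundance indices and the benchmark

A single metabarcoded sample says little about biomass because efficiencies
are unknown and dominate read counts. But if `a_i` is constant across
samples, *trends* in an index of read counts can track trends in biomass.
Seven per-sample transformations are implemented; all map zero counts to
zero, so they agree on incidence:

1. raw counts;
2. **eDNA index** — within-sample proportions `p_ij` rescaled by each
   taxon's maximum proportion across samples, `p_ij / max_j p_ij`
   (equivalently a Wisconsin-style double standardization; linear correlates
   such as the χ² transformation and geometric-mean size-factor scalings
   behave identically and are not shipped separately);
3. frequency — `p_ij·N_j` with `N_j` the number of detected taxa, so
   nonzero entries of a sample average 1;
4. chord-normalized counts — columns scaled to unit Euclidean norm;
5. rank — ascending average ranks of nonzero counts within a sample;
6. Hellinger — `sqrt(p_ij)`;
7. `log₂(Y)+1` for positive counts.

The time-series benchmark simulates 25 timepoints: biomass is redrawn
i.i.d. Dirichlet(γ=5) per timepoint (taxa fluctuate around a stable
expectation) while shedding rates and efficiencies stay fixed per taxon, and
each timepoint is an independent PCR + sequencing event. Per taxon, the
benchmark reports Spearman's ρ (average-rank ties, computed as a vectorized
rank-Pearson) between the index series and the true biomass series, with
zeros kept in the series. Taxa detected in fewer than 5 of 25 timepoints are
excluded from the headline summaries — with fewer detections the series is
mostly tied zeros and ρ is dominated by noise. Zero-variance series are
flagged undefined and excluded from medians rather than set to 0. The
permutation null shuffles all cells of the count matrix jointly (a
per-column shuffle is available), preserving the multiset of counts, then
indexes and correlates identically; its ρ distribution is symmetric about 0.

Performance summaries stratify the per-taxon ρ two ways. Abundance quartiles
are computed among incidence-eligible taxa from log₁₀ of the mean
within-sample read proportion over the timepoints where the taxon was
detected (the log base only relabels the axis; membership is unchanged).
Efficiency strata use configurable thresholds, by default 0.35 and 0.6 —
the cut-points below which indexing degrades toward the null and above
which it tracks biomass almost perfectly. The efficiency strata are computed
over *every* detected (correlatable) taxon rather than only
incidence-eligible ones: the efficiency axis is precisely where
low-incidence taxa live, and restricting to eligible taxa selects the
luckiest low-efficiency taxa and biases their stratum upward. Because only
~100 of 1000 taxa fall below efficiency 0.35 after the incidence of
detection is accounted for, that stratum's median carries appreciable
run-to-run spread (± ~0.04); the package reports medians only (a histogram
mode is binning-dependent).

A single-timepoint comparison (ρ across taxa within one sample) is also
computed for contrast; it is weak by construction, since within one sample
efficiency differences, not biomass, dominate read counts.

## Calibration from mock communities

With known input proportions `D₀`, observed reads `Y`, and the cycle count,
inverting the amplification model gives each taxon's per-cycle fold change
`g_i = (Y_i/D₀_i)^{1/N}`. The overall sequencing scale is unknowable from
reads alone, so only the max-anchored relative efficiency
`r_i = g_i/max g_i = (1+a_i)/(1+a_max)` is identifiable; absolute `a_i` is
not, and the package reports only the relative scale. Taxa with zero reads
are detection-limited: they get fold change 0 and are excluded from Beta
fitting by default (optionally included as boundary-clamped values). Beta
fitting uses method of moments (deterministic) with values clamped to
[10⁻⁶, 1−10⁻⁶]; an MLE refinement with fixed support is behind a flag.
Tail probabilities `P(a > t)` come from the mixture's Beta survival
functions.

## Seeds, determinism, and numerics

All randomness flows through numpy Generators. Every function takes a seed
or Generator; the experiment drivers derive independent substreams from one
master seed keyed by (experiment, stage) via CRC-32-hashed SeedSequence
entropy, so changing one experiment's replicate count cannot perturb
another's draws. Identical seeds reproduce outputs bit for bit, including
CSV bytes. The cycle sweep amplifies in log space and rescales by the
column maximum before exponentiating — a harmless shift, since multinomial
probabilities are scale-free — to keep 50-cycle amplifications well inside
floating-point range. Depths are rounded to nearest and floored at 1 read.
Degenerate inputs (all-zero amplicon pools, zero-depth samples, zero-variance
Beta fits, unbalanced ANOVA designs) raise errors rather than propagate
NaNs.

## What the simulations do and do not show

The generator produces idealized data: no sequencing error, no chimeras or
index hopping, no taxonomic mis-assignment, no spatial structure, i.i.d.
biomass across timepoints (no autocorrelation), and efficiencies exactly
constant within a taxon. Results therefore isolate the distortions
attributable to PCR bias, cycle number, and compositional sampling alone;
on real data all of those omitted processes add further noise, so the
benchmark's correlation levels are best read as upper bounds and its
qualitative contrasts (efficiency strata, abundance quartiles, cycle
effects) as the transferable findings. Default problem sizes — 1000 taxa,
100 replicate communities, 25 timepoints — are the package's standard study
conditions; all experiments are vectorized across taxa and complete in
seconds on one CPU.
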