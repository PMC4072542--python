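# Methods

## The BGS model

We model the reduction of neutral diversity caused by purifying selection at
linked sites with the classical structured-coalescent/recurrent-sweepout
result: at a focal neutral site, the expected diversity relative to free
recombination is

    B = exp( − Σ_i u_i · K(r_i) ),
    K(r) = ∫ φ(s) · s·h / (s·h + r·(1 − s·h))² ds,

where the sum runs over all selected sites i on the same chromosome, u_i is
the per-site per-haploid-copy per-generation deleterious mutation rate, s the
homozygous selection coefficient drawn from the DDFE φ, h the dominance
coefficient (0.5 throughout the default models) and r_i the recombination
frequency per generation between the focal and selected site. At r = 0 the
kernel reduces to E[1/(s·h)] and the exponent to the classical mutational
load limit U/(2·s·h); this limit is asserted in the tests with a point-mass
DDFE. Assumptions: semidominant selection, multiplicative fitness across
sites, demographic equilibrium, and selection strong relative to drift for
the mutations retained after truncation (see below).

### DDFEs, truncation and lethals

Two parameterizations are supported, plus a point mass for closed-form
checks:

| family    | parameters                      | default source of values     |
|-----------|---------------------------------|------------------------------|
| lognormal | median s = 2.31e-4, σ(ln s) = 5.308 | mutation-accumulation / polymorphism fits for *Drosophila* |
| gamma     | shape k = 0.3, mean s = 2.5e-3  | divergence-based DFE fits    |

σ is the standard deviation of **natural** log s; this is the only reading
that reproduces the published effectively-neutral percentages, and a test
pins it. Mutations with s below the drift threshold s_T ≈ 1/Nₑ (Nₑ = 10⁶ by
default) contribute no BGS: the kernel integrates the density conditioned on
s ≥ s_T and the mutation rate is multiplied by the surviving mass
(log-normal: 84.7%, gamma: 92.6% on autosomes). The log-normal places 5.7%
of its mass above s = 1; we clamp that mass to s = 1 (a point mass of
lethals) rather than discarding it, since lethal mutations do remove linked
variation for the single generation they exist. The choice is nearly
inconsequential for B (strongly deleterious mutations contribute little to
the exponent at any r) but keeps the density normalized.

On the X chromosome selection acts on s_X = (2/3)·s_A (genic selection,
equal sex ratio), drift on N_eX = 0.75·Nₑ, so the X threshold satisfies
N_eX·s_X ≈ 1, i.e. s_T,X = 1/(0.75·Nₑ) on the X-scaled axis (equivalently
2/Nₑ on the autosomal axis). Neutral fractions rise to 18.5% (log-normal)
and 9.1% (gamma).

### Mutation rates

`StdMut` uses u = 8.4e-9 /bp/generation (diploid genome-wide U ≈ 1.2,
including the TE-insertion contribution), `LowMut` u = 4.2e-9 (U ≈ 0.6,
point mutations and small indels only). The TE rate itself is derived from
mutation–selection balance: with 633 TEs in 21 Mb of exon across 15 sampled
chromosomes, P_seg = 3.0e-5/bp, q = P_seg/15 = 2.0e-6, and u_TE = q·s_h ≈
5e-9 with s_h = 0.0025. All constants live in `bgsmap.models`, never inside
operations.

### Recombination

Crossover rates come as piecewise-constant windows (cM/Mb per female
meiosis, 100-kb resolution by default); genetic distance is the exact
integral of the map. Gene conversion adds the tract-overlap term
γ·L_GC·(1 − e^(−d/L_GC)) with γ = 1.25e-7 /bp/female meiosis and
L_GC = 518 bp — linear in d for d ≪ L_GC, plateau γ·L_GC beyond. The exact
functional form of the published crossover+conversion combination is not
recoverable from the source text, so this standard form is used and is
pluggable (`RecombinationMap.gc_function`). Sex averaging multiplies by 0.5
(autosomes) or 0.66 (X; kept verbatim rather than 2/3 to match the published
constant). Frequencies below 10⁻¹⁰ are set to 0 and values are capped at 1.
Chromosome trimming removes each end up to the first run of ≥3 consecutive
100-kb windows with c > 1 cM/Mb.

## Numerical scheme for B

* **Kernel grid.** K(r) is computed by adaptive quadrature (in ln s, with
  the lethal point mass added analytically) at 512 log-spaced r values in
  [10⁻¹⁰, 1], plus K(0); interpolation is linear in (ln r, ln K). The grid
  resolution (~51 points/decade) holds interpolation error well below the
  oracle tolerance.
* **Windowing.** Selected sites are aggregated into 1-kb windows; for far
  windows all pairs use the center-to-center r. Because K(r) varies steeply
  for r within ~10⁻⁴ of zero (the truncated density concentrates weakly
  selected mutations just above s_T, each contributing ≈1/(s·h)), the focal
  window and its ±3 neighbours are instead integrated over exact per-bp
  distances using the per-bp class weights carried on the selected-site
  track (falling back to a uniform-within-window assumption when only
  counts are available). Treating a window's own sites as fully linked
  (r = 0) would overstate the exponent by ~40× for those sites and bias B
  by tens of percent; the near-field integration removes this.
* **Validation.** `oracle_B` recomputes B with no windowing and no r grid —
  a direct double loop over focal points × selected bp with a fixed-node
  trapezoid quadrature (512 nodes in ln s), an independent integration
  path. On the 100-kb fixture the windowed computation agrees with the
  oracle to ≤10⁻⁴ relative for log-normal, gamma and hybrid models (the
  acceptance tolerance is 1%). The oracle is guarded to chromosomes
  ≤200 kb (quadratic cost).
* **D_B quantiles.** The interval around a focal window grows symmetrically
  in physical distance, one window per side per step (clamped at chromosome
  ends), until its summed exponent reaches the requested fraction of the
  whole-chromosome exponent; the growth rule is a design choice (the
  alternatives — genetic-distance or greedy growth — give nested intervals
  of similar size on smooth landscapes).

## Diversity estimation

Per-site π is the unbiased pairwise estimator (m/(m−1))·(1 − Σp²) over the
site's m non-N alleles, requiring m ≥ 10 by default; window π_sil averages
per-site values over intronic + intergenic sites, and windows with ≤500
(1-kb) or ≤1,000 (10-kb) analyzable silent sites are flagged excluded.
Tajima's D uses the standard a₁/a₂/e₁/e₂ constants and is normalized by
|D_min|, the value attained when all S variants are singletons, preserving
sign: all-singleton windows score −1, intermediate-frequency excess is
positive. Columns containing any N are excluded from D (keeping n constant
within a window); with the default 2% masking and 15 haplotypes this retains
~74% of sites and does not bias π, whose estimator is per-site unbiased
under random masking.

## Baseline fit and outliers

"Generalized regression" is implemented as OLS of π_sil on B with intercept,
fitted separately for autosomes and X so no X/A ratio is assumed; the slope
absorbs θ₀ = 4Nₑu. Departures are externally studentized residuals
(observation left out of the variance estimate), two-sided P from t with
n − 3 df; at the sample sizes used they differ from standardized residuals
by <1%. Residual normality is checked by χ² over 24 equal-probability bins
(df = 23). BH FDR runs at q = 0.10. A caveat the synthetic tests expose:
sampling variance of window π grows with B, so OLS residuals are mildly
heteroscedastic; at the fixture's B range this inflates the nominal 5% tail
rate by well under a binomial confidence interval, but on data with a much
wider B range a variance-stabilizing weight would be warranted.

## Protein evolution

The gene table (dN, dS, ω per gene on a focal lineage, with an
M1a-vs-M2a positive-selection q value) is consumed, not computed — codon
model fitting is out of scope. Filters: CDS < 450 bp, < 100 aligned amino
acids, premature stops, positive-selection q < 0.05, ω > 0.75. ω_R is the
OLS residual of ω on dS per chromosome group, controlling for coalescent
time and mutation-rate variation; gene-to-B assignment uses the CDS
midpoint (a gene-span average differs negligibly at 1-kb B resolution).

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure the analysis assumes,
not population-genetic dynamics. One 4-kb gene per 10-kb unit (1,000 bp
5'UTR; 300/600/600 bp coding exons; 1,000 and 200 bp introns; 300 bp
3'UTR; intergenic filler), TEs only in intergenic spacers, and a 100-kb
crossover map. The default profile (0.3, 1.5, 3.0, 4.0, 2.0, 1.0, 2.5,
3.5, 1.2, 0.4 cM/Mb) emulates a chromosome arm: low sub-telomeric and
sub-centromeric rates — so the trimming rule has something to trim — and
arm variation in the experimentally observed range (median ≈ 1.8 cM/Mb).

Polymorphism is drawn site-by-site from a (possibly tilted) neutral SFS
scaled so that E[π_site] = θ₀·B·multiplier exactly under the package's own
estimator, with θ₀ = 0.01, 15 haplotypes, and 2% random N-masking. Planted
sweeps (multiplier 0.2, singleton-tilted SFS, ∝k^−2.5) and balanced regions
(multiplier 3, Gaussian tilt at k ≈ n/2) give the residual scan and the
D/Dmin concordance known signs. Sites are independent — there is no linkage
disequilibrium, no coalescent variance shared between sites, and no
demography; passing tests therefore demonstrate the inference contract
(calibration, power, sign conventions) rather than robustness to the
correlated noise of real data. Forward simulation is deliberately out of
scope. Gene tables plant ω = 0.15 + 0.5·dS − effect·B + N(0, 0.02²), plus a
configurable rate of filter violations.

All generators are deterministic given the spec seed (numpy
`default_rng((seed, stream))`), and generated files round-trip through the
package's own readers without warnings.

## Problem sizes

The shipped analyses and tests use a 1-Mb standard genome (100 genes,
~700 analyzable 1-kb windows), a 100-kb oracle-comparison fixture, 20
replicates for power estimates, and 5,000-gene tables — sizes at which every
stage completes in seconds to a few minutes on one core while leaving
Monte-Carlo error far below the tested effect sizes. Full-genome runs
(~25-Mb chromosome arms) are supported by the same code path via chunked
matrix evaluation; `count_selected_sites(keep_per_bp=False)` drops the
per-bp arrays if memory is tight (the near field then uses the uniform
fallback).

## Known limitations

* The B model ignores interference among deleterious mutations and assumes
  equilibrium; strong-BGS regions (B ≪ 0.1) are where the underlying
  approximation is least reliable.
* Within-window heterogeneity is resolved only in the near field; selected
  sites in far windows are treated as co-located at window centers.
* D/Dmin is computed on fully covered sites only; heavy masking shrinks the
  usable site set quadratically in sample size.
* The outlier scan inherits OLS homoscedasticity; see above.
* X-chromosome analyses reuse autosomal mutation rates, as in the source
  parameterization.
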