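# bgsmap

High-resolution background-selection landscapes and diversity baselines for
compact genomes.

Background selection (BGS) — the continual removal of deleterious mutations —
depresses neutral diversity at linked sites. The strength of the effect at a
focal position is summarized by **B = π/π₀**: expected neutral diversity
relative to what it would be under free recombination (B = 1, no effect).
`bgsmap` computes B at 1-kb resolution from three ingredients:

1. a genome annotation (GFF3 gene models + BED TE/repeat tracks), reduced to
   per-window counts of constrained sites by class (nonsynonymous,
   UTR/intron, intergenic, using constrained fractions 0.92/0.81/0.56/0.5);
2. a windowed crossover map plus a gene-conversion model (initiation rate γ,
   mean tract length L_GC), combined into pairwise recombination frequencies
   r = sex_factor × [d_CO + γ·L_GC·(1 − e^(−d/L_GC))];
3. a distribution of deleterious fitness effects (DDFE) — log-normal
   (median s = 2.31×10⁻⁴, σ of ln s = 5.308) or gamma (shape 0.3, mean
   s = 2.5×10⁻³) — truncated at the effectively-neutral threshold
   s_T ≈ 1/Nₑ, with the deleterious mutation rate scaled accordingly.

The core quantity is the classical structured-coalescent exponent

```
B_j = exp( − Σ_i u_i · ∫ φ(s) · s·h / (s·h + r_ji·(1 − s·h))² ds )
```

with the inner integral precomputed on a log-spaced grid of r ∈ [10⁻¹⁰, 1]
and the near field (the focal 1-kb window and its neighbours, where the
integral varies steeply with r) integrated over exact per-bp distances. A
brute-force per-bp oracle with independent quadrature validates the
approximations to ≲0.1%.

On top of the B landscape the package estimates silent diversity (π_sil) and
normalized Tajima's D (D/|D_min|) from N-masked population alignments, fits
the baseline π_sil ~ B by OLS, flags diversity outliers with externally
studentized residuals and Benjamini–Hochberg FDR (candidate sweeps =
deficits, balancing selection = excesses), measures the genomic scale of BGS
(D_B50/75/90), and correlates efficacy-of-selection residuals ω_R (ω after
controlling for dS) with B. A first-class synthetic-data module generates
annotations, crossover maps, calibrated polymorphism (E[π] = θ₀·B) with
planted sweep/balanced regions, and gene tables, so every stage is testable
without external downloads.

Audience: population geneticists who want a linked-selection baseline for
scans of selection, or a testbed for baseline-based outlier detection.

## Worked example

The numbered scripts under `analysis/` run the whole study on the standard
synthetic genome (1 Mb, 100 genes, chromosome-like crossover profile):

```bash
python analysis/01_simulate_genome.py      # annotation + TEs + crossover map
python analysis/02_compute_b_landscapes.py # B for the 8 single-DDFE models + 2 hybrids
python analysis/03_window_diversity.py     # calibrated polymorphism, pi_sil, D/Dmin
python analysis/04_baseline_outliers.py    # baseline fit + studentized residual scan
python analysis/05_bgs_spatial_scale.py    # D_B50/75/90 quantiles
python analysis/06_protein_evolution.py    # omega_R vs B
```

Selected output (seed 1):

```
pairwise Spearman rho across the 8 single-DDFE models: min=0.9888 max=1.0000
crossover-only median B is 23% lower than CO+GC
baseline fit over 695 windows: pi_sil = 0.00050 + 0.00932 x B (slope se 0.00080)
outliers at nominal P<0.05: 7 deficit, 16 excess; 7 pass BH q<0.1
rho(pi_sil-R, D/Dmin) = 0.438 (P = 7.28e-34)
median D_B90: 387 kb, 0.831 cM
rho(B, omega_R) [gene]: -0.210 (P = 3.31e-46, n = 4500)
```

Reading this: the B ranking is essentially model-independent (ρ ≥ 0.989);
ignoring gene conversion overstates linkage and depresses B by ~23%; the
baseline regression recovers the generator's θ₀ = 0.01 within one standard
error; the planted 3× balanced and 0.2× swept regions are the windows
passing FDR, with the expected residual signs; residuals co-vary with the
site-frequency spectrum; 90% of a window's BGS exponent accumulates over
hundreds of kb; and ω_R declines with B, the Hill–Robertson signature of
reduced selection efficacy under strong linked selection.

The same stages are exposed as a CLI for file-based use:
`bgsmap simulate | compute | diversity | outliers | dbscale | protevo`
(e.g. `bgsmap compute --annotation g.gff3 --recmap map.tsv --model
"M_LN,StdMut,CO+GC" --chromosome chr2L --out B.tsv`).

## Layout

- `src/bgsmap/` — the library: `ddfe`, `recmap`, `annotation`, `bgs`
  (kernels, `compute_B`, `oracle_B`, D_B), `diversity`, `outliers`,
  `protein`, `simulate`, `models`, `io`, `cli`.
- `analysis/` — numbered narrative drivers writing under `results/`.
- `tests/` — unit, property and acceptance tests.
- `docs/methods.md` — model assumptions, parameter defaults, numerical
  choices and limitations.
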