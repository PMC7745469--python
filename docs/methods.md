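# Methods

## Setting and assumptions

The package implements two-sample summary-data Mendelian randomization: the
SNP–exposure and SNP–outcome associations come from non-overlapping study
samples and are combined as ratio estimates. Instruments are assumed
relevant (associated with the exposure at genome-wide significance),
independent (pairwise LD r² below a clumping threshold), and — per
estimator — exchangeable with respect to pleiotropy in the sense each
estimator requires: none pleiotropic (IVW), pleiotropy independent of
instrument strength (Egger/InSIDE), a valid weighted majority (weighted
median), or a valid plurality (weighted mode). Binary outcomes are handled
on the log-odds scale throughout; exponentiating a log-odds estimate gives
an odds ratio per SD of exposure.

## Harmonization

Exposure and outcome records are aligned onto the exposure's effect-allele
frame. Same-order alleles pass through; swapped alleles negate the outcome
beta and reflect its allele frequency; strand complements are complemented
first and then treated the same way. Palindromic variants (A/T, C/G) cannot
be resolved from alleles alone: they are aligned by comparing which side of
0.5 each study's effect-allele frequency falls on, and only when both
frequencies fall outside the ambiguity window (0.42, 0.58). Anything else —
frequency inside the window, frequency missing, irreconcilable alleles, or
a variant absent from the outcome — is dropped with a recorded reason and a
per-status count in the harmonization report. The window is the
conventional default of forward-strand harmonization workflows; both
bounds are configurable. Harmonization is idempotent and all downstream
estimates are invariant (to 1e-12) under relabeling any record's alleles
with the corresponding sign flip.

## Instrument selection and strength

Clumping is greedy: candidates below the p-value threshold (default
5×10⁻⁸) are ranked by p-value (ties broken lexicographically by variant id,
for exact reproducibility), the best remaining candidate is kept, and all
candidates with r² ≥ 0.001 (default) to a kept variant are removed. The LD
matrix is supplied explicitly (user data or the generator); the package
does not compute LD from genotype panels.

Per-variant strength is F = (β̂/σ̂)². Variance explained uses the
large-sample form R²ⱼ = β̂² / (β̂² + n·σ̂²), algebraically equivalent to the
standard approximation for a standardized trait; the aggregate
F = (R²/(1−R²))·((N−K−1)/K) summarises K independent instruments.
Conditional strength of exposure k in a multivariable model minimises
Q = Σⱼ (β̂ₖⱼ − Σₗ δₗ β̂ₗⱼ)² / (σ̂ₖⱼ² + Σₗ δₗ² σ̂ₗⱼ²) over δ (Nelder–Mead from
δ = 0 plus five jittered restarts, tolerance 1e-8) and reports
F = Q_min/(J−K+1); cross-study covariances are taken as zero, which is the
two-sample design's defining assumption. Exposure columns that are exactly
zero are excluded from both the regression and the δ minimisation — they
carry no information and would otherwise make the variance-weighted
objective degenerate.

## Estimators: numerical conventions

- Confidence intervals use the normal multiplier 1.959964; p-values are
  two-sided normal everywhere, including Egger (no t-correction), matching
  the convention of reporting normal-based intervals throughout.
- Random effects are multiplicative and floored at one:
  φ = max(1, √(Q/df)) scales the fixed-effect SE for IVW (df = J−1), Egger
  (df = J−2) and MVMR (df = J−K). Heterogeneity never deflates an SE.
- The Wald ratio SE is first-order delta method (σ_Y/|β_X|); exposure
  uncertainty is ignored, as is standard for genome-wide-significant
  instruments.
- Egger regression orients exposure betas non-negative internally (the
  orientation is idempotent, so pre-oriented input is unaffected). With all
  exposure betas identical the slope and intercept are collinear and the
  fit raises an identifiability error.
- Weighted-median interpolation uses standardized cumulative weights
  sⱼ = Σₖ≤ⱼ wₖ − wⱼ/2 and linear interpolation at s = 0.5.
- The weighted-mode bandwidth is h = φ·0.9·min(sd, 1.4826·MAD)·J^(−1/5)
  with φ = 1 by default; when the MAD is zero but the ratios are not all
  equal, the sd alone is used rather than collapsing the bandwidth to zero.
  The density is maximised on a 10,000-point grid spanning the ratios ± 3h;
  the grid is a reproducibility choice and its resolution bounds the
  estimate's discretisation error. If all ratios coincide that common value
  is returned directly.
- Median and mode SEs come from a parametric bootstrap (default 1000
  replicates) that redraws both samples' betas from their SEs under a
  seeded generator; results are bit-reproducible for a fixed seed. Exact
  zero draws of an exposure beta are nudged to the smallest positive float
  so the ratio stays defined.
- Power for a binary outcome uses the normal approximation: the test
  statistic is centred at log(OR)·√(n·v(1−v)·R²) with v the case fraction.
  This targets the fixed-effect IVW test; the random-effects floor makes
  the realised test slightly conservative in small-J designs.

## The synthetic-data generator

The generator emulates the statistical structure of a two-sample adiposity
→ metabolome → colorectal-cancer study. Defaults are the scale of the real
data sources: 312 exposure instruments from an exposure GWAS of
N = 806,810; a 123-trait metabolite panel at N = 24,925 in ten named
classes; an outcome of 58,221 cases and 67,694 controls. The variance of
true instrument effects (τ² = 3.4×10⁻⁴) is set so the mean per-variant F is
≈ 100 — inside the 75–125 range typical of adiposity instruments — giving
≈ 4% of exposure variance explained; the default causal effect is
log(1.12) per SD, an odds ratio of the size reported for BMI on colorectal
cancer. Metabolite-class instrument effects (sd 0.13 at N = 24,925) give
per-variant F around 100–160, within the 30–220 range typical of NMR
metabolite instruments.

Standard errors follow the large-sample approximations for standardized
traits: σ = 1/√(2pq·n) for continuous traits and σ = 1/√(2pq·n·v(1−v)) for
the log-odds outcome. The continuous and binary formulas are mutually
consistent with the analytic power approximation above, which is what makes
the Monte-Carlo/analytic power cross-check meaningful. Observed betas are
drawn Normal(truth, σ²) independently per trait table, realising the
two-sample design; empirical calibration of the emitted SEs is tested to
within 3%.

Causal structure: each metabolite class has one latent factor. The exposure
shifts the latent by κ_c, class members load on it with λ_m ~ U(0.7, 1),
and the latent shifts the outcome by θ_c, so the total effect is
θ_total = θ_direct + Σ_c κ_c·θ_c. The latent design reproduces the known
redundancy of NMR panels (many correlated subclass measures), makes
representative-per-class selection meaningful, and means adjusting for any
one member of a mediating class blocks that class's mediated path. True
instrument effects are oriented positive by default — the effect allele is
the exposure-increasing allele, as published instrument lists are usually
reported — which is what makes *directional* pleiotropy directional: with
symmetric instrument effects, a constant direct effect would average out of
the IVW estimand. Pleiotropy is configurable as (fraction, mean, sd) of
per-variant direct outcome effects, optionally correlated with instrument
strength to break InSIDE. Palindromic alleles, strand flips and allele
swaps are injected into the outcome table at configurable rates; block LD
is realised as proxy variants with attenuated marginal effects.

What the generator does **not** emulate: individual-level genotypes,
cross-study allele-frequency differences (both studies report the same
frequency, so palindrome resolution is cleaner than in real data), sample
overlap between the two studies, non-normal effect-size distributions,
fine-scale LD beyond exchangeable blocks, and selection effects such as
winner's curse in the exposure GWAS. Passing tests therefore demonstrate
correctness of the estimators and pipeline under the stated model, not
robustness to those real-data complications.

## Mediation pipeline conventions

Step 1 regresses each metabolite on the exposure's instruments (IVW, or the
Wald ratio with a single instrument). The FDR screen applies
Benjamini–Hochberg within each exposure across the panel and takes the
union over exposures of metabolites with adjusted p ≤ 0.05; a joint-family
option exists in the config. Step 2 estimates each selected metabolite's
effect on the outcome from the metabolite's own instruments. A path is
classified *consistent* when sign(step 1)·sign(step 2) equals the sign of
the total effect, *weak_step2* when the step-2 interval spans zero; no
proportion-mediated point estimate is computed. Class representatives are
the members with maximal aggregate F (ties lexicographic). Multivariable
adjustment pairs each exposure with one representative at a time over the
union of both traits' instruments; the alternative adiposity trait serves
as a positive control. Stage failures are recorded in the JSON manifest and
dependent stages are skipped while independent stages proceed; two runs
with the same config and seed produce byte-identical tables.

## Benchmark problem sizes

`scripts/acceptance.py` uses: 500 replicates at J = 100 for bias/coverage
and pleiotropy recovery, 1000 for type-I error and Q calibration, a full
123-metabolite panel run for the FDR screen, 200 replicates of a reduced
panel (6 metabolites, one mediating class, J = 60) for attenuation
behaviour, and 2000 replicates per design for the power cross-check. The
power Monte-Carlo uses few, strong instruments (J = 8 at R² = 0.3%,
J = 100 at 5%) so that exposure-side noise — which the analytic
approximation ignores — contributes regression dilution well under the
comparison tolerance; the comparison is made against the fixed-effect test
the approximation targets. In replicated designs a replicate is skipped
when no member of the focal metabolite class reaches genome-wide
significance (the pipeline's own behaviour for unestimable stages); skip
rates are a few percent and are reported via the `n` field.

## Known limitations

- Finite-sample attenuation of the Egger intercept: instruments whose
  observed exposure beta fluctuates across zero are re-oriented, flipping
  the sign of their pleiotropic contribution; at mean F ≈ 100 this shrinks
  a true mean intercept of 0.02 by ≈ 0.003. It vanishes as instrument
  strength grows and is a property of the estimator's orientation
  convention, not of the implementation.
- No correlated-instrument (generalized) IVW, MR-PRESSO, contamination
  mixture, proxy-SNP lookup, or overlapping-sample corrections; multi-allelic
  variants are out of scope.
- The conditional-F minimisation is derivative-free and intended for small
  numbers of exposures (K ≤ 3), which covers one-exposure-one-covariate
  adjustment designs.
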