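# Methods

This note documents the statistical models implemented in `mrpleio`, the
choices made where the design was genuinely open, and what the synthetic
data used by the test suite does and does not emulate.

## Summary-statistics model and harmonization

The unit of data is a per-variant association record (effect allele,
other allele, effect-allele frequency, per-allele β, SE, p, N). The
canonical statistic is z = β/SE; stored p-values are regenerated from z
when missing or underflowed, so downstream stages never see p = 0.
Coordinates are 1-based inclusive. Indels and multi-allelic records are
rejected at read time — every method here assumes biallelic SNVs.

Harmonization aligns the outcome record to the exposure's effect allele:
a literal allele swap negates the outcome β and reflects the EAF; for
non-palindromic variants a strand complement (possibly with a swap) is
tried next. A/T and C/G pairs map onto themselves under complementation,
so for them frequency is the only signal: variants with EAF in
[0.42, 0.58] on either trait are dropped (the common MR convention for
"intermediate allele frequencies"; both the window and whether either
trait's EAF may trigger the drop are config-exposed, since conventions
differ), outside the window the minor-allele side must agree or a strand
flip is inferred, and when EAF is missing palindromic variants are always
dropped (conservative). Every intersection variant leaves harmonization
with exactly one recorded action, which keeps the selection ledger
reason-complete.

## LD-score regression

Single trait: E[χ²ⱼ] = 1 + Na + (N h²/M) ℓⱼ, fitted as a weighted
regression of χ² on Nℓⱼ/M with a free intercept (1 + Na). The intercept is
always free — constrained-intercept variants are deliberately out of scope
because the workflow relies on the intercept to absorb population
structure and sample overlap. Weights are
1/(max(ℓⱼ,1)·vⱼ) with vⱼ the squared expected statistic, updated in two
passes: a crude slope from the mean χ² seeds the first pass, the fitted
slope/intercept the second. The first factor corrects for counting a
variant once per LD partner; the second for the variance of a χ² variate.
Variants with χ² > max(80, 0.001N) are dropped before fitting (standard
practice, config-exposed).

Cross-trait: E[z₁ⱼz₂ⱼ] = ρ_int + (√(N₁N₂)·gencov/M) ℓⱼ, and
r_g = gencov/√(h²₁h²₂). The intercept ρ_int ≈ n_s·ρ_pheno/√(N₁N₂) absorbs
correlated estimation noise from shared samples. Within the ratio, the h²
slopes are computed with the same weights as the gencov slope: weights
affect efficiency, not consistency, and sharing them makes r_g of a trait
with itself exactly 1 — a useful internal identity.

Standard errors come from a delete-one-block jackknife over 200 contiguous
SNP blocks (the convention of the reference implementation; the number is
an argument). For r_g the delete-block estimates are of the *ratio*, so
the SE propagates the h² uncertainty. The heritability gate keeps traits
with z = h²/SE strictly greater than 4. The published worked-example table
contains one row flagged as underpowered despite z = 4.5; the gate follows
the stated rule (keeps it) and emits a warning rather than silently
replicating the flag.

p-values for r_g are two-sided normal on r_g/SE, matching how the printed
tables pair (r_g, SE) with p.

## Gene-level pleiotropy

SNPs are assigned to genes by a ±500 kb window around the gene body
(inclusive bounds). Each gene is tested with the SNP-wise mean χ²
statistic; under the null, Σχ² over the k member SNPs is distributed as
Σλᵢχ²₁ with λ the eigenvalues of the member-SNP LD correlation matrix.
The tail is evaluated by Imhof numerical integration, with two fallbacks:
equal eigenvalues reduce exactly to χ²_k, and when the oscillatory
integral fails to converge (or underflows, p ≲ 1e-12) a two-moment
Satterthwaite/Brown approximation c·χ²_df is used and the switch logged.
Eigenvalues are floored at 10⁻⁴ of the leading eigenvalue to regularize
near-singular LD. Only the SNP-wise mean model is implemented; top-SNP and
multi-model gene statistics are out of scope.

A gene is trait-associated when p < 0.05/G (G = annotated genes); if fewer
than five genes pass, the threshold relaxes to 5/G. The rule is applied
literally in that order (count under the primary rule first, then fall
back). Note the fallback is only meaningful for G in the hundreds or more;
at very small G, 5/G approaches 1 and the rule degenerates — the test
suite therefore always evaluates it at realistic G. Pleiotropy between an
exposure and an outcome is summarized as |shared genes| / |exposure
genes|, and all SNPs annotated to shared genes are exported for
instrument exclusion.

## Locus-level pleiotropy

For each locus in a non-overlapping partition (the real analysis uses
~1,700 LD-independent loci; the simulator emits one locus per LD block),
five models are compared: no association, exposure-only, outcome-only,
shared association through one variant, and association through two
distinct variants. Per-variant evidence is the Wakefield approximate
Bayes factor, lnABF = ½ln(V/(V+W)) + ½z²W/(V+W), averaged on the natural
scale over the prior-SD grid {0.01, 0.1, 0.5} with equal weights (the
convention of the pairwise-GWAS literature; the source analysis does not
state its grid). Regional Bayes factors put a uniform prior on which
member SNP is causal: BF₁ = meanᵢABF₁ᵢ, BF₂ = meanᵢABF₂ᵢ,
BF₃ = meanᵢABF₁ᵢABF₂ᵢ, and BF₄ averages ABF₁ᵢABF₂ⱼ over ordered pairs
i ≠ j (so a single-SNP locus has PPA4 = 0 by construction). Model priors
are fixed at (0.80, 0.05, 0.05, 0.05, 0.05), config-exposed; the original
tool's hierarchical EM estimation of priors is out of scope in this
version. All evidence combination is done in log space.

A locus is pleiotropic when PPA3 ≥ 0.9 (inclusive). The summary statistic
is Σppa3 / Σ(ppa1+ppa3+ppa4) across loci; summing posteriors rather than
counting thresholded loci uses the full posterior mass (the alternative
count ratio is available behind a flag, since the verbal definition is
ambiguous between the two). SNPs carrying ≥ 50% of a called locus's
model-3 evidence are exported as pleiotropic.

## Instrument selection

Four reported steps, each with a count in the ledger:

1. **Threshold + clumping.** Candidates at p < 5×10⁻⁸, relaxed to 5×10⁻⁶
   when fewer than 10 candidates exist (the "limited number" is not
   defined in the source; 10 is this package's documented default and the
   decision record flags when it drove the choice) or when strictly more
   than 65% of candidates are absent from the outcome GWAS. Greedy
   clumping: sort by p (ties by chromosome, position), accept a variant
   iff r² < 0.001 with every accepted variant within 10 Mb
   (center-to-center, inclusive). Variants absent from the LD reference
   are treated as independent, with a warning.
2. **Harmonization** including palindrome removal (above); candidates
   missing from the outcome table are recorded here.
3. **Filters:** confounder blocklist (a static file replaces live
   variant-annotation service queries, which are not reproducible),
   outcome-correlation rule p_outcome < p_exposure, and weak instruments
   F = β²/SE² < 10. This yields the *initial* set.
4. **Pleiotropy-driven removals** (the *final* set): SNPs from the gene
   and locus scans, radial-IVW outliers (per-variant Q p < 0.05), and —
   only when the genome-wide threshold was used — instruments with
   outcome p < 0.05. The overlap between outliers and outcome-associated
   instruments is reported.

## Univariable MR estimators

All estimators consume Wald ratios βⱼ = b_yⱼ/b_xⱼ.

- **IVW**: θ̂ = Σwⱼβⱼ/Σwⱼ. First-order weights wⱼ = b_xⱼ²/SE_yⱼ²;
  second-order adds the b_x measurement-error term per variant; modified
  second-order iterates wⱼ(θ̂) = b_xⱼ²/(SE_yⱼ² + θ̂²SE_xⱼ²) from the
  first-order solution to |Δθ̂| < 10⁻¹⁰ (≤ 100 iterations). The SE is
  1/√Σw, inflated multiplicatively by max(1, √(Q/(k−1))) when the Cochran
  Q p-value is below 0.05 (fixed/random always available explicitly).
- **Radial IVW** refits the same estimator in radial coordinates; its
  point estimate coincides with modified-second-order IVW (asserted to
  10⁻⁸ in tests), and the per-variant Qⱼ = wⱼ(βⱼ−θ̂)² against χ²₁ flags
  outliers at α = 0.05 (the radial-regression convention; config).
- **MR-Egger**: weighted regression with free intercept, variants
  oriented to positive exposure effect, weights SE_y⁻², t inference with
  k−2 df and multiplicative SE inflation max(1, σ̂²).
- **Weighted median**: interpolated weighted quantile at cumulative
  weight 0.5; parametric bootstrap SE (resampling b_x and b_y from their
  normal sampling distributions, n_boot = 1000, seeded).
- **Weighted mode**: mode of the weighted Gaussian-KDE of ratios,
  Silverman-type bandwidth 0.9·min(sd, IQR/1.349)·k^(−1/5) scaled by φ
  (default 1), evaluated on a 2048-point grid; bootstrap SE. Known
  property, reproduced here: the bootstrap SE overestimates the mode's
  sampling SD (~1.4× in our null study), so the test is conservative
  (~1% empirical size at nominal 5%). This matches the estimator's own
  literature and is documented rather than corrected.
- **RAPS**: minimizes Σρ_Huber(tⱼ(θ)) with
  tⱼ = (b_yⱼ−θb_xⱼ)/√(SE_yⱼ²+θ²SE_xⱼ²+τ²), Huber k = 1.345. The
  overdispersion τ² (on by default) solves mean[ψ(t)·t] = E[ψ(Z)Z] =
  2Φ(k)−1 under the standard normal. The SE is the M-estimation sandwich
  with expected ψ-moments (E[ψ'] and E[ψ²] under N(0,1)); the fully
  empirical sandwich proved anti-conservative at k ≈ 30 instruments.
- **MR-PRESSO**: observed RSS uses leave-one-out IVW predictions; the
  null distribution comes from n_sim = 1000 parametric draws of b_y
  around those predictions (p-values are (1+r)/(n_sim+1), so the
  per-variant Bonferroni-adjusted outlier p has a floor of k/(n_sim+1) —
  raising n_sim is the remedy, and n_sim < 100 is refused). Outliers are
  only called when the global test is significant; the distortion test
  compares the corrected-vs-raw shift against random same-size exclusion
  sets.
- **Steiger**: per-variant r² = z²/(z²+N−2) summed per trait; direction
  is correct when instruments explain more exposure than outcome
  variance; p from the z-test on Fisher-transformed explained
  correlations.

Two-sided p-values throughout; normal reference except Egger (t).

## Multivariable MR

MV-IVW regresses b_y on the k×p exposure-effect matrix with weights
SE_y⁻² and no intercept; heterogeneity Q has k−p df and drives the same
multiplicative SE inflation. Exposure columns with zero norm are dropped
from the design (their estimates reported as undefined) so nested designs
reduce exactly to univariable fits; genuinely collinear designs abort
with the condition number. MV-Egger adds a free intercept with variants
oriented to the first exposure's positive effects (t, k−p−1 df).
MV-median solves weighted L1 regression by iteratively reweighted least
squares (tolerance 10⁻⁸), with seeded parametric-bootstrap SEs.
Instruments come from the union of per-exposure candidates, jointly
re-clumped keeping per LD clique the variant with the smallest minimum p
across exposures, restricted to variants present in every table, with
the outcome-correlation rule applied against the best exposure p and the
weak-instrument rule requiring F ≥ 10 for at least one exposure.
Conditional F statistics (effects of one exposure regressed on the
others, residual-based) are reported for diagnostics only.

## Pipeline and multiplicity

The study flow is gate → genetic correlation (gated traits only) →
pleiotropy per exposure–outcome pair → initial instruments → univariable
MR suite → final instruments → MR again → MVMR for exposure pairs whose
genetic correlation is significant. Study-wide significance uses
α/(n_exposures × n_outcomes); the MVMR trigger uses that Bonferroni
threshold by default, with a nominal-α option, because the source design
is ambiguous about which it used. When the MR-PRESSO global test is
significant the corrected estimate is the primary one in the report. All
stochastic steps derive from one integer seed; reports serialize to JSON
byte-identically under a fixed seed.

## The synthetic-data generator

Generated directly at the summary-statistics level (no individual-level
genotypes): per-block AR(1) LD with exact LD scores, EAFs uniform on the
MAF range, standardized effect sizes (a variant contributes 2p(1−p)β² to
trait variance — the h² definition LDSC assumes), marginal effects as
R·b within blocks, and estimation noise z = √N·(Rb) + ε with ε ~ N(0, R)
and cross-trait noise correlation n_s·ρ_pheno/√(N_xN_y) (the mechanism
the cross-trait intercept captures).

Architecture: exposure effects are spike-and-slab over a random half of
the LD blocks ("active" blocks, emulating the sparse locus structure of
real GWAS); the outcome receives θ·b_x plus an outcome-specific
spike-and-slab component and optional direct effects on
`n_horizontal_pleio` exposure-associated variants (horizontal pleiotropy
that instruments can pick up). The causal pathway alone induces a
total-effect correlation θ√(h²_x/h²_y); with `rg=None` (default) that is
the realized genetic correlation, while an explicit `rg` calibrates the
total-effect correlation to the requested value, which necessarily
realizes the excess over the causal part as correlated pleiotropy — a
deliberate stress-test mode, not the clean-MR condition.

Defaults mirror the statistical regime of large-biobank mineral-metabolism
GWAS: h² = 0.1 for both traits, N = 10⁵, θ = 0.1 outcome units per
exposure unit, 10% of SNPs causal, 10 horizontally pleiotropic variants
with per-variant effect variance 5×10⁻⁴ (comparable to the slab), 20%
palindromic variants, no sample overlap. The desk-scale genome is 2,000
SNPs in 40 blocks of 50 at 25 kb spacing (so a ±500 kb gene window covers
about one block); parameter-recovery work uses 50,000 SNPs in 1,000
blocks.

What the generator does **not** emulate: real LD panels (no long-range
LD, no MAF–LD correlation), binary outcomes on the liability scale (CKD-
like traits are treated as continuous), population stratification (the
LDSC intercept deviates from 1 only through sample overlap), winner's-
curse-free replication designs, and genome-scale SNP counts — at 50k SNPs
the LDSC sampling error is far larger than in a million-SNP analysis, so
passing recovery tests demonstrate calibration (CI coverage), not the
precision attainable on real data.

## Test and acceptance problem sizes

The suite validates closed-form oracles exactly (IVW weighted means,
radial/IVW identity, Wakefield arithmetic, weighted-χ² tails against
5×10⁵ Monte-Carlo draws), parameter recovery at m = 5×10⁴, N = 10⁵ over
50 replicates (≥ 90% jackknife-CI coverage for h² and r_g), null
calibration over 400 replicates of 30 instruments per estimator, and
MR-PRESSO global-p uniformity over 200 replicates — sizes chosen to give
binomial error bars tight enough to detect miscalibration while keeping
the full suite in a few minutes on one CPU.

## Known limitations

- No partitioned/annotation-stratified heritability; no >2-trait LDSC.
- Gene test implements the SNP-wise mean model only.
- Locus model priors are fixed, not EM-estimated; no correction for
  overlapping cohorts inside the locus model.
- No proxy-SNP lookup for instruments missing in the outcome GWAS; no
  liftover; no VCF input.
- No correlated-instrument (generalized) IVW; no contamination-mixture
  or Lasso-based MVMR variants.
- The weighted-mode test is conservative (see above).
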