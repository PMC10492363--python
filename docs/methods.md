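# Methods

## Setting

`mrkit` implements two-sample Mendelian randomization (MR) from GWAS
summary statistics. Genetic variants serve as instrumental variables for an
exposure: because alleles are assigned at conception, a variant that
robustly shifts the exposure can probe the downstream effect of that
exposure on an outcome free of classical confounding and reverse causation,
provided the variant affects the outcome only through the exposure.

The motivating application is the bidirectional analysis of coffee
consumption and periodontitis: a continuous coffee-consumption GWAS
(N = 375,833) supplying 8 instruments against the GLIDE periodontitis GWAS
(N = 49,066; 17,672 cases / 31,394 controls; no published effect-allele
frequencies), and the reverse direction with periodontitis instruments at a
relaxed significance threshold. The 8-SNP instrument table is packaged as
`mrkit.summary_data.load_table1_fixture()` and drives the worked example.

## Model

For SNP j, let b_Xj (SE s_Xj) be the per-allele effect on the exposure and
b_Yj (SE s_Yj) the effect on the outcome (log odds for binary traits), both
oriented to the same effect allele. Under valid instruments each ratio
b_Yj / b_Xj estimates one causal parameter θ, giving the generative
regression b_Yj ≈ θ b_Xj with known outcome-side noise.

### Estimators

- **Wald ratio** (single SNP): θ̂_j = b_Yj / b_Xj, SE s_Yj / |b_Xj|
  (first-order delta; exposure-side noise ignored, standard two-sample
  practice).
- **IVW**: weighted least squares of b_Y on b_X through the origin with
  weights w_j = 1 / s_Yj²; θ̂ = Σ w_j b_Xj b_Yj / Σ w_j b_Xj². The SE is
  the fixed-effect SE 1/√(Σ w_j b_Xj²) multiplied by the residual scale
  √(Σ w_j r_j² / (n−1)) **floored at one** — multiplicative random effects
  that collapse to the fixed-effect SE under underdispersion. This floored
  convention is the package default because it is what the reference R
  tooling reports and it reproduces the worked example's interval and
  p-value; pure `fixed` and `random` modes are selectable.
- **MR-Egger**: the same weighted regression with an unconstrained
  intercept after orienting all b_Xj ≥ 0 (negating both effects of a SNP
  where needed). The slope estimates θ under the InSIDE assumption; the
  intercept estimates average directional pleiotropy. Inference uses the t
  distribution with n−2 df, and the coefficient covariance applies the same
  residual-scale floor.
- **Weighted median**: per-SNP ratios with second-order delta variances
  V_j = s_Yj²/b_Xj² + b_Yj² s_Xj²/b_Xj⁴ as inverse weights; the estimate
  interpolates the ratio at cumulative weight 0.5. Consistent when valid
  instruments carry ≥ 50% of weight. The second-order variance (keeping the
  exposure-noise term) is deliberate: the first-order weights shift the
  worked example's fourth decimal. The SE comes from a parametric bootstrap
  (redraw both effect vectors at their reported SEs; default 1,000 draws,
  seed 20230909) with a normal-approximation p and CI; the point estimate
  never depends on the bootstrap. Percentile intervals would be a defensible
  alternative and can move borderline p-values.

Binary outcomes are reported both on the log-odds (beta) scale and as
OR = exp(β) with exponentiated CI bounds. 95% intervals use the normal
quantile 1.959964 everywhere except MR-Egger (t quantile, n−2 df).

### Diagnostics

Cochran's Q is the weighted residual sum of squares around the IVW
(df = n−1) or Egger (df = n−2) fit with the same weights 1/s_Yj² as the
fit, referred to the upper chi-square tail. The Egger intercept test is the
t test of the intercept (n−2 df). Leave-one-out refits IVW without each SNP
in turn and is the basis of the exported forest-style table.

### MR-PRESSO

The global test measures total residual heterogeneity with leave-one-out
fitted values: RSS = Σ_j w_j (b_Yj − θ̂₍₋ⱼ₎ b_Xj)². Its null distribution
is simulated by redrawing b*_Xj ~ N(b_Xj, s_Xj) and
b*_Yj ~ N(θ̂₍₋ⱼ₎ b_Xj, s_Yj) and recomputing the statistic (leave-one-out
slopes included) on each draw; p = (1 + #{RSS* ≥ RSS}) / (1 + n_sim), the
add-one estimate that never returns an exact zero. The per-SNP outlier test
ranks each observed weighted squared residual in its own simulated
distribution, Bonferroni-adjusts across SNPs, and flags adjusted p < 0.05.
The distortion test compares the raw and outlier-pruned IVW slopes against
pruning the same number of random SNPs. Note the detection floor: the
smallest achievable Bonferroni-adjusted p is n_snp/(n_sim+1), so n_sim must
comfortably exceed n_snp/α for the outlier test to have any power; the
default is n_sim = 1,000. Under gross contamination the outlier test can
flag most of the panel (every leave-one-out slope is distorted); the
corrected refit is attempted only when ≥ 2 SNPs survive.

### Selection and harmonization

Instrument selection runs in a fixed order: strict p < threshold (5e-8
forward; 5e-6 for the weakly powered reverse exposure), greedy LD clumping
(keep the lowest-p leader, discard neighbours with r² > 0.001 within
10,000 kb; ties on p break lexicographically on rsID so results are
input-order invariant; SNPs absent from the LD matrix are treated as
independent and logged), confounder screening (drop SNPs associated at
p < 5e-8 with the outcome or with ≥ 2 listed risk factors), then the weak
instrument filter F > 10 with F = (β/SE)² — the summary-data proxy that
needs no allele frequency. An allele-frequency-based alternative
F = R²(N−2)/(1−R²), R² = 2·EAF(1−EAF)β², is available for standardized
continuous traits. On the (β/SE)² scale one packaged instrument
(rs1057868) scores ≈ 9.7, just below the conventional cutoff, although it
was part of the published set; the published F values were evidently
computed on another scale, so the packaged fixture is treated as a curated
instrument list and not re-filtered.

Harmonization orients every outcome record to the exposure's effect allele:
identical pairs pass, swapped pairs flip the outcome beta (and EAF),
strand-complement pairs are complemented first, palindromic (A/T, C/G) SNPs
are always dropped — never frequency-rescued, which would be impossible for
an outcome source without EAF anyway — and residual mismatches are dropped
and logged.

### Decision flow

After estimation, the gate requires all three of {Q_IVW p, Q_Egger p,
Egger-intercept p} > 0.05 to accept the fits as they stand; otherwise
MR-PRESSO runs, flagged outliers are pruned and the suite is refitted.
PRESSO can also run in validation mode on clean sets (reported, never
prunes), mirroring how it is commonly run as a confirmation. The final
label `causal_evidence` requires IVW p < 0.05, sign agreement of Egger and
weighted-median slopes with IVW (zero does not contradict), and ≥ 3
instruments; it is a reporting convention, not a test, and no
multiple-testing adjustment is applied across directions.

## Synthetic data generator

`synthetic_gwas` draws the generative model the estimators assume:
maf_j ~ U(maf_range); γ_j ~ N(0, γ_sd²); s_Xj = 1/√(2 maf(1−maf) N_exp)
(unit-variance trait); b_Xj ~ N(γ_j, s_Xj²); pleiotropy α_j = 0 with
probability 1−π else N(μ_α, σ_α²), entering the outcome as
sign(γ_j)·α_j — directional pleiotropy is defined relative to the
exposure-increasing allele, since allele coding is arbitrary and a
fixed-sign shift on arbitrary codings would cancel under Egger orientation;
s_Yj has the same form at N_out with the 1/√(cf(1−cf)) logistic inflation
for a binary outcome with case fraction cf; b_Yj ~ N(θγ_j + sign(γ_j)α_j,
s_Yj²). α is drawn independently of γ, so InSIDE holds by construction.
Defaults mirror the motivating datasets: N_exp = 375,833, N_out = 49,066
with cf = 0.360, maf ∈ [0.05, 0.5], γ_sd = 0.02 (so that a consortium-scale
exposure GWAS yields genome-wide-significant instruments), θ = 0.1,
pleiotropy off, 10% palindromic SNPs. LD is block-diagonal (constant r²
inside consecutive blocks laid out within a 10 Mb span, zero across), which
is what the clumping rule needs to be exercised; truth (θ, γ, α) is
returned separately from the Study objects so pipeline code cannot read it.

What the generator does **not** emulate: realistic LD decay, allele-frequency
spectra, winner's-curse selection of instruments from the same sample,
sample overlap between exposure and outcome GWAS, and non-normal effect
distributions. Passing recovery/coverage tests therefore validates the
estimators under their own assumptions, not robustness to those
real-data complications.

## Validation problem sizes

The test suite recovers θ = 0.1 with |bias| < 0.01 over 200 replicates at
N = 100,000 (100 SNPs per replicate), checks 95% CI coverage within
[0.90, 0.98] over 500 null replicates, recovers a directional-pleiotropy
intercept of 0.05 over 30 replicates of 200 tight-SE SNPs, and flags a
tenfold-inflated strong instrument via PRESSO in ≥ 95/100 replicates at
n_sim = 1,000. These sizes give binomial/Monte-Carlo error well inside the
asserted bands while keeping the whole suite under a minute of simulation.

## Known limitations

- The reverse-direction published tables (6 periodontitis instruments and
  the binary-coffee analyses) are not packaged; only the 8-SNP forward
  table is public in full, so the reverse direction is exercised on
  synthetic data.
- Weighted-median inference is bootstrap-normal; published p-values using
  other bootstrap conventions can differ in the second decimal.
- No Steiger filtering, mode-based estimators, multivariable MR, or
  I²/Rucker model selection; proxy-SNP lookup for instruments missing from
  the outcome GWAS is out of scope (such SNPs are dropped and logged).
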