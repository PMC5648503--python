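# Methods

## Model

For subject i = 1..n and tissue j = 1..t, expression of one transcript at
one locus is modeled conditionally on genotype g ∈ {0,1,2} (minor-allele
count) and promoter-CpG methylation m as

y_ij = α_j + β g_i + λ m_ij + φ m_ij g_i + a_i + b_ij g_i + c_ij m_ij g_i + d_ij m_ij + ξ_ij

with fixed effects α (tissue intercepts), β (additive genotype), λ (overall
methylation slope), φ (genotype × methylation), and zero-mean Gaussian
random effects a_i ~ N(0, τ) (subject intercept), b_ij ~ N(0, γ) (G×T),
c_ij ~ N(0, δ) (G×M×T), d_ij ~ N(0, θ) (tissue-methylation), ξ_ij ~ N(0, ε).
All random effects are independent across subjects, so vec(Y) (subject-major,
tissue-fastest) has a block-diagonal covariance with per-subject blocks

Σ_i = ε I_t + τ 1 1ᵀ + γ g_i² I_t + δ g_i² diag(m_i∘m_i) + θ diag(m_i∘m_i).

An alternative reading of the tissue-level effects — one t-vector shared by
all subjects — was rejected: it makes a 7% G×T variance share detectable
with near-certainty at n = 500, t = 5, which is inconsistent with the
modest power levels this design is meant to exhibit, and it breaks subject
exchangeability. The per-subject reading keeps subjects i.i.d.

### Null model and REML

The joint null H₀: β = φ = γ = δ = 0 leaves Y = Jα + Mλ + Au + Dx + ξ with
covariance blocks S_i = ε I + τ 1 1ᵀ + θ diag(m_i∘m_i) — a diagonal matrix
plus a rank-1 term, inverted in closed form by Sherman–Morrison, so all
solves are O(nt) and nothing of size nt×nt is ever formed. (τ, θ, ε) are
estimated by REML; (α, λ) are profiled out by GLS at each variance iterate.
REML rather than ML keeps the variance components unbiased, which matters
because they feed the null moments of the test statistic.

Optimization profiles out the residual scale analytically: with
Σ = ε·V(τ/ε, θ/ε), the REML-optimal ε given the ratios is
ε̂ = quad/(nt−p), leaving a 2-parameter search over log variance ratios in
[log 1e−8, log 1e8] by bound-constrained quasi-Newton (L-BFGS-B, relative
objective tolerance 1e−8, ≤ 200 iterations), with a derivative-free
Nelder–Mead fallback if the gradient search stalls against the singular
corners of the ratio space. Numerically singular iterates return a large
finite penalty so the line search backtracks. Boundary estimates (τ or θ at
zero) land at the 1e−8 floor. The fit was checked against lme4 on the
identical model (`y ~ 0 + tissue + m + (1|subject) + (0 + m|obs)`): variance
components, λ̂ and the restricted log-likelihood agree to ~6 digits.

Missing data are rejected (complete cases only); in genome scans a SNP with
missing calls is tested on its complete cases with the null model refit on
that subset.

### Efficient scores and the joint statistic

With Ŷ the GLS residuals and Σ̂ the fitted null covariance,

- U_β = Ŷᵀ Σ̂⁻¹ (G − Ḡ), U_φ = Ŷᵀ Σ̂⁻¹ (MG − M̄G̅) (linear, signed),
- U_γ = ½ Ŷᵀ Σ̂⁻¹ BBᵀ Σ̂⁻¹ Ŷ, U_δ = ½ Ŷᵀ Σ̂⁻¹ CCᵀ Σ̂⁻¹ Ŷ (quadratic, ≥ 0),

where G is the genotype expanded over tissue slots, MG its product with
vec(m), and B, C the nt×t stacked designs (column j carries g_i, resp.
m_ij g_i, in tissue slot j). The joint statistic
U_ζ = a_β U_β² + a_φ U_φ² + a_γ U_γ + a_δ U_δ is a single quadratic form
Yᵀ P₀ K P₀ Y in the data, where K is the weighted kernel (rank ≤ 2t+2) and
P₀ the precision projected off the null fixed design. Since P₀ Σ̂ P₀ = P₀,
the null moments are E = tr(P₀K) and Var = 2 tr(P₀KP₀K), evaluated through
the (2t+2)×(2t+2) gram matrix LᵀP₀L in O(n t² · rank); covariances between
all four components are thereby included exactly under Gaussianity.
P-values use the Satterthwaite scaled chi-square κχ²_ν with κ = Var/2E,
ν = 2E²/Var; for a rank-1 kernel this is exactly χ²₁.

**Weights.** The combination rule standardizes each component to unit null
standard deviation, a_c = 1/SD₀(component), with each SD₀ computed by the
same P₀-trace machinery applied to the component's own kernel. This is a
normalization convention — some convention is required, since scaling all
weights down trivially reduces Var(U_ζ) — and it is the one place where a
different choice could reorder the tests' power (see Limitations).

**Degenerate inputs.** A monomorphic SNP, or a kernel whose null variance
vanishes (Var < 1e−12·E²), returns p = 1 with a degenerate flag. Scores are
evaluated per SNP against a null fit estimated once per transcript–CpG pair.

### Comparators

- **TBT**: per-tissue OLS of expression on genotype, two-sided t-test on
  the slope; multi-tissue summary is the minimum p across tissues, judged
  at the Bonferroni level α/t.
- **TBTm**: per-tissue OLS with design [1, m_j, g, g·m_j]; the tested
  hypothesis is the joint (β, φ) = 0 by a 2-df F-test, so the baseline can
  detect both additive and interaction signal. (A test of β alone or φ
  alone would be defensible; the joint test is the choice that lets the
  baseline respond to every alternative in the study grid.)
- **Genotype + G×T joint score test** ("jaguar-style"): the same score
  machinery with the methylation terms removed from the null model
  (λ = θ = 0) and only a_β U_β² + a_γ U_γ combined.

### Multiple testing

Storey q-values: π₀ is estimated by a cubic smoother of
π₀(λ) = #{p > λ}/(m(1−λ)) on λ ∈ {0.05, …, 0.95}, evaluated at λ = 0.95 and
clipped to (0, 1], falling back to π₀ = 1 (plain Benjamini–Hochberg)
whenever the estimate leaves that interval; q_i = min_{p_j ≥ p_i}
π₀ m p_j / rank(p_j), clipped to [0, 1]. With π₀ = 1 the q-values equal BH
adjusted p-values exactly.

### Cis pairing and genome scans

A candidate triplet joins a transcript with every CpG strictly within
1.5 kb of its TSS and every SNP within 100 kb of the TSS inclusive, same
chromosome, 1-based coordinates. The boundary conventions differ
deliberately: the SNP window is closed ("does not exceed"), the CpG window
open ("less than"). Mixed-model scans pool all p-values into one q-value
set; tissue-by-tissue scans compute per-tissue q-values and summarize by
the minimum q across tissues at the threshold FDR/t. Within significant
joint-test triplets, driver flags mark which score components are
marginally significant at 0.05 (an interpretive rule; the marginal
reference is each component's own Satterthwaite approximation).

## Synthetic-data conventions

The generator is the model above. Genotypes are Binomial(2, MAF) with
MAF = 0.3 by default (HWE); methylation rows are MVN(0, Σ_m) with Σ_m
compound-symmetric, unit variance, correlation 0.5 — the simplest
positive-definite structure with cross-tissue correlation. Interaction
variances are specified through their share of the total random variance,
PVE_γ = γ/(θ+τ+ε+γ+δ) and likewise PVE_δ, solved as a linear system
(γ, δ) = PVE·(τ+θ+ε)/(1−PVE_γ−PVE_δ).

Defaults chosen once and documented here, because the quantities are not
derivable from the study design itself: nuisance variances τ = θ = ε = 1
(symmetric, making PVE the sole driver of interaction strength); fixed
effects β = λ = φ = 0.3 when "on" (moderate effects); α = 0 (intercepts are
absorbed by projection and affect nothing). Replicate r of a study cell
uses seed base_seed + r, so replicates are paired across cells and
independently reproducible.

Two conventions for the study cells deserve emphasis:

- The **complete-null / single-effect cells** (type-I error; pure-G×T;
  pure-G×M×T) set λ = θ = 0, i.e. no methylation effects at all. This is
  required for a meaningful baseline: with a per-subject M×T random effect
  present (θ = 1), the homoscedastic OLS behind TBTm is misspecified — its
  residual variance is ε + τ + θm², largest exactly where the interaction
  regressor has leverage — and it rejects at ≈ 0.17 under the genetic
  null. That miscalibration is a finding about TBTm, not a bug, and it
  disappears when θ = 0.
- The full study grid (2 × 2 × 3 × 3 cells) keeps θ = 1, λ = 0.3 as the
  methylation-present convention.

What the generator does *not* emulate: linkage disequilibrium between
SNPs, beta-distributed (bounded) methylation values, genomic coordinate
realism, batch structure, or missingness. Passing tests therefore
demonstrate the statistical machinery under the stated Gaussian model, not
robustness to the artifacts of real array data.

## Problem sizes used in the shipped checks

Type-I error uses 1000 replicates at n = 500, t = 5; power cells use 500;
the QQ-calibration check uses 2000 replicates at n = 100, t = 3; REML
recovery uses 100 fits at n = 2000, t = 5 with asymptotic standard errors
from the observed information (numerical Hessian of the restricted
log-likelihood); planted-signal scan recovery uses 20 scans of 60 triplets
at n = 300. These sizes were chosen so the whole suite runs comfortably on
a single CPU while keeping Monte-Carlo error well below the margins tested.

## Known limitations

- **Absolute power levels are convention-dependent.** The test statistics
  and their calibration are fully determined, but power at a given PVE
  depends on the unpublished simulation settings of the original study
  design (nuisance variance magnitudes, the methylation variance scale,
  the exact weight rule). Under the defaults above, the pure-G×M×T cell at
  PVE 10% yields power ≈ 0.13–0.16 for both the joint test and TBTm —
  the qualitative pattern (both methods comparable, both well above the
  null rate) reproduces, the absolute level does not.
- **Power ordering against the methylation-free joint test.** With no
  methylation effects in the generator, the four-component joint test here
  is slightly *more* powerful than the two-component genotype + G×T test,
  not marginally less: under the per-subject generative model the
  methylation-weighted components U_φ, U_δ also absorb G×T signal. A
  different weight convention could reverse this; ours is fixed a priori.
- The Satterthwaite approximation matches two moments only; extreme tail
  p-values (≪ 1e−8) from mixtures with very unequal weights are
  approximate. Exact mixture-of-chi-square tail inversion is out of scope.
- θ is weakly identified at small t (it is a variance over t·n per-cell
  slopes but separates from ε only through the m² heteroscedasticity);
  at t = 5, n = 500 its REML spread is substantial, which the score test
  tolerates but downstream interpretation of θ̂ itself should not.
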