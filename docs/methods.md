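# Methods

## The trait model

Body length (or any Gaussian trait) of individual *i* is modelled as

y_i = x_i'β + Σ_r u_{r,g_r(i)} + e_i,  u_r ~ N(0, σ²_r I),  e ~ N(0, σ²_e I),

with fixed terms drawn from {intercept, population, stream,
population×stream} (treatment coding, first level as reference) and random
grouping factors from {family, sire, dam, population, stream}. Four model
presets cover the analysis:

| preset | fixed | random | purpose |
|---|---|---|---|
| `M1` | population, stream, interaction | family | reaction norms, variance congruence |
| `M2` | intercept | population, family | per-stream divergence (σ²_B, σ²_W) |
| `M_icc` | intercept | population, stream, family | variance partitioning |
| `M_h2_fullsib` / `M_h2_diallel` | intercept | population+family / sire+dam | heritability |

Treating population as random in `M2`/`M_icc` yields a proper posterior for
σ²_population, which is what enters P_ST and ICC; the alternative (deriving
σ²_B from the spread of fixed population coefficients) is deliberately not
the primary route, because a variance computed from a handful of fixed
effects has no coherent posterior of its own.

## Gibbs sampler

Priors are flat (improper) on fixed effects and scaled inverse-gamma with
shape = scale = 10⁻³ on every variance component — the conventional "locally
uninformative" parametrization of animal-model software. Two blocks are
alternated:

1. **All location effects jointly.** θ = (β, u_1, …, u_k) is drawn from
   N(C⁻¹W'y, σ²_e C⁻¹) with W = [X Z₁ … Z_k] and
   C = W'W + blockdiag(0, λ_1 I, …, λ_k I), λ_r = σ²_e/σ²_r (Henderson's
   mixed-model equations). The joint update matters: separate β and u blocks
   mix catastrophically slowly when a random factor (family) is nested
   inside a fixed one (population) — lag-1 autocorrelations of thinned
   draws drop from ≈0.7 to ≤0.1 with the joint draw. C is dense but small
   (tens to a few hundred columns), so one Cholesky per iteration is cheap.
2. **Variances.** Conjugate inverse-gamma draws from
   InvGamma(a + q_r/2, b + u_r'u_r/2) and InvGamma(a + n/2, b + e'e/2).

Chains are seeded from independent `SeedSequence` children of one root seed
and started from dispersed initial variances (jittered around the sample
variance), so the Gelman–Rubin diagnostic is meaningful. Retained draws are
the post-burn-in iterations at every `thin`-th step:
n_chains × (n_iter − n_burnin)//thin. The full-scale regime
(6 chains × 2,000,000 iterations, 800,000 burn-in, thin 800 → 9,000 draws)
is available as the `full` preset; the `desk` preset
(4 × 20,000, burn-in 5,000, thin 10) is the default working regime and is
what the acceptance script runs — on balanced data of a few thousand records
it converges with R̂ ≤ 1.01 and |lag-1 autocorrelation| ≲ 0.08.

Degenerate factors (a single level in a data subset, e.g. stream in a
per-stream fit) are dropped with a warning rather than raising, so the same
model spec can be mapped over stream subsets. A rank-deficient fixed design
(confounded factors) is an error.

## REML cross-check

The same models are fit by direct numerical optimization of −2 × restricted
log-likelihood over log-variances (L-BFGS-B with a Nelder–Mead fallback).
The Woodbury identity keeps every evaluation at O(q³) for q total random
levels: with A = Z'Z + σ²_e G⁻¹,

−2ℓ_R = (n−q)·log σ²_e + log|G| + log|A| + log|X'V⁻¹X| + (y−Xβ̂)'V⁻¹(y−Xβ̂).

Because the likelihood becomes flat in log σ²_r as a component approaches
zero, components that finish ≳6 log-units below the residual variance are
snapped to the boundary when that does not worsen the fit, then re-polished.
REML serves as the independent oracle for the sampler: posterior means of
variance components agree with REML within 10% on simulated datasets (and
the REML fitter itself is cross-checked against statsmodels' `MixedLM` on a
single-factor model in the test suite).

## Heritability

Narrow-sense heritability is computed draw-wise:

* **fullsib** (unique-pair design): full-sib family variance contains half
  the additive variance, so h² = 2σ²_family/(σ²_family + σ²_resid) by
  default. The factor is a parameter (`family_factor`), since treating the
  family variance as V_A directly (factor 1) is also defensible when
  dominance or common-environment effects are suspected; 2 is the default
  because non-additive between-population variance is separately absorbed by
  the c parameter of P_ST.
* **diallel**: V_A = 2(σ²_sire + σ²_dam) and
  h² = V_A/(σ²_sire + σ²_dam + σ²_resid).

A σ²_population term, if present, is excluded from the denominator —
heritability is a within-population quantity. Draws outside [0, 1] are
clipped and the clip count reported; on well-specified fixtures the clip
fraction is ≈0.

## P_ST and the F_ST comparison

Per retained draw *i* of the per-stream divergence model,

P_ST(i) = c·σ²_pop(i) / (c·σ²_pop(i) + 2·h²(i)·σ²_W(i)),

with h² draws paired by index with the divergence draws (valid as a
Monte-Carlo approximation of two independent posteriors when both fits used
the same MCMC regime). σ²_W(i) defaults to σ²_family(i) + σ²_resid(i) — the
total within-population phenotypic variance — with a `within='residual'`
switch, since "within-population (residual) variation" is ambiguous between
the two readings; the total is the default because P_ST's denominator is
phenotypic by definition. The heritability is estimated in the
best-survival (experimental) stream and assumed transferable to the other
environments, mirroring the equal-within-variance assumption of Q_ST
studies.

The verdict against the neutral reference `fst_upper` (a supplied scalar,
e.g. the upper 95% quantile of marker F_ST — not estimated here) is
*divergent* if the 2.5% quantile of P_ST exceeds it, *stabilizing* if the
97.5% quantile is below it, *neutral* otherwise.

ICCs divide each variance component of the `M_icc` fit — including the
residual — by the per-draw total, so they sum to 1 exactly in every draw.
The ICC model includes a family random term (not only population and
stream) to avoid treating siblings as independent; with it, the population
and stream ICCs are fractions of a correctly decomposed total.

The reaction-norm summary reconstructs every population×stream cell mean
per draw from the `M1` fixed effects and reports a coding-invariant
parallelism ratio: SD of the interaction deviations of the cell-mean matrix
over SD of its population main-effect deviations. Zero simulated
interaction yields posterior median ratios well below 0.2.

## Survival bootstrap

Survival analysis uses natural streams only (the experimental stream has a
qualitatively different mortality regime and would dominate any
interaction). The cutoff is ceil(1/grand-mean survival), grand mean = total
recaptured / total stocked over the supplied records, i.e. the smallest egg
number for which the expected survivor count reaches one; families stocked
below it are discarded (their expected survivor count rounds to zero). An
explicit cutoff can be supplied instead, for fidelity to an existing
analysis whose pooling or rounding convention differs from this rule or
cannot be recovered from its reported totals. Family proportions are
kept per (family, stream) by default because CIs are reported within each
stream; population replicate means weight families equally (population
means "from family means", not egg-weighted). 1,000 replicates by default;
no p-values are produced — inference is by CI overlap and by pairwise
difference CIs, both reported.

## Synthetic data

The generator mirrors the analysis models exactly: fixed
population/stream/interaction shifts, family effects (or sire + dam +
optional cross effects in diallel mode), Gaussian residuals, and independent
per-family binomial survival. Survivor counts for phenotype records default
to the survival model but can be fixed, decoupling trait tests from binomial
noise. Ground truth defines σ²_B as the empirical (k−1 denominator)
variance of the population shifts — the same convention by which a posterior
over k population effects is summarized — and true P_ST by the P_ST formula
at the true components.

Default scales are chosen to be realistic for first-season juvenile
salmonids: grand mean 70 mm, residual SD 8 mm, σ²_family giving h² ≈ 0.3,
population shifts of a few mm giving P_ST ≈ 0.5 (hatchery lines largest),
survival ≈ 0.3% in natural streams and ≈ 7–9% in the predator-free
experimental channel. The trait's unit is configuration metadata; nothing
in the analysis depends on it.

What the generator does **not** emulate: growth–survival correlations,
maternal egg-size effects, competition between families, dispersal out of
the sampled reach, and unequal within-population genetic variances. Passing
recovery tests therefore demonstrate the estimators are correct under the
stated model, not that the model captures every feature of field data —
in particular, maternal effects would inflate both family variance and
apparent population divergence in real data.

## Problem sizes and numerical choices

Tests and the acceptance script run reduced-scale versions of every check,
chosen as the smallest designs at which the statistical property is
informative: diagnostics on 3,600 balanced records with 4 × 20,000-iteration
chains; P_ST recovery over 50 replicates of a 5-population × 12-family ×
30-offspring design (truth 0.5; 95% CIs cover truth in ≥ 80% of replicates,
median bias < 0.1); Gibbs/REML congruence over 20 datasets of 100 families;
bootstrap null coverage over 100 seeded runs. The inverse-gamma prior with
shape/scale 10⁻³ is effectively flat for these data sizes but keeps variance
draws strictly positive; with ~5 population levels the σ²_population
posterior is heavy-tailed, which is exactly why P_ST intervals are wide and
why the Bayesian route (rather than a point estimate) is used for the F_ST
comparison.

## Known limitations

* Q_ST's downward bias with few populations (< 20) is not corrected; with
  5 populations the estimates are conservative for detecting divergence.
* No multi-trait P_ST, no F_ST estimation from genotypes, no GLM survival
  models (binomial/Poisson GLMs are unstable at these survival rates —
  that instability is the reason the bootstrap exists).
* Chains run sequentially; the `full` MCMC regime is provided for fidelity
  but is hours of compute — the `desk` regime reaches the same diagnostics
  thresholds on the data sizes used here.
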