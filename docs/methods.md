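# Methods

`mrbp` implements a complete two-sample Mendelian-randomization (MR) analysis
of blood pressure (BP) on atrial fibrillation (AF) risk from GWAS summary
statistics, together with the drug-target proxy analyses and diagnostic
calculations that accompany such a study, and a synthetic summary-statistic
generator used to validate every stage without external data.

## Model and assumptions

For variant *j*, let γ_j be its effect on the exposure (mmHg per effect
allele) and Γ_j its effect on the outcome (log-odds per allele). Under the
instrumental-variable assumptions (relevance, independence from confounders,
no direct effect on the outcome except through the exposure),

    Γ_j = θ·γ_j,

where θ is the causal effect in log-odds per mmHg. Each variant gives a Wald
ratio θ̂_j = Γ̂_j/γ̂_j with first-order SE σ_yj/|γ̂_j|. Violations of the
exclusion restriction enter as a direct (pleiotropic) effect α_j:
Γ_j = θ·γ_j + α_j.

Effects on BP are reported per 10-mmHg increment (OR = exp(10·θ)), a
clinically conventional scale. Drug-class effects are reported per 10-mmHg
*decrease* (the per-mmHg estimate is negated before exponentiation), so a
protective BP-lowering effect appears as OR < 1.

## Estimators

* **IVW, multiplicative random effects** (primary): the σ_y⁻²-weighted
  regression of Γ̂ on γ̂ through the origin. The fixed-effect SE is inflated
  by max(1, √(Q/(J−1))), Q being Cochran's heterogeneity statistic on the
  ratio estimates. The multiplicative (residual-inflation) flavour is used
  rather than an additive between-variant variance because it is the
  convention of the standard two-sample MR toolchain this pipeline mirrors;
  the floor at 1 prevents anti-conservative SEs under underdispersion. With
  one instrument the estimate reduces to the Wald ratio. p-values are
  two-sided normal.
* **Weighted median** (sensitivity): order the ratios ascending with
  normalized weights w_j = (γ̂_j/σ_yj)²; with breakpoints
  p_j = (cumsum(w)_j − w_j/2)/Σw the estimate interpolates the ordered
  ratios linearly at p = 0.5. It is consistent when ≥50% of weight comes
  from valid instruments. The SE is a parametric bootstrap (default 1000
  resamples of per-variant betas from their sampling distributions, seeded
  from the run seed); an analytic approximation exists but the bootstrap is
  the documented choice here.
* **MR-Egger** (pleiotropy diagnosis): orient each variant so γ̂_j > 0
  (ratios are invariant to joint negation), then fit the weighted regression
  *with* intercept. The intercept estimates average directional pleiotropy;
  the slope is a pleiotropy-adjusted effect, valid under InSIDE (pleiotropy
  independent of instrument strength). SEs use the same multiplicative
  scaling floored at 1; p-values and CIs use a t-reference with J−2 degrees
  of freedom, a deliberately conservative choice at small J. Requires J ≥ 3
  and variation in γ̂.

All estimators operate identically on `HarmonizedInstrument` sequences or on
raw effect arrays.

## Instrument construction

* **Selection**: strictly P < 5×10⁻⁸ (genome-wide significance, as
  printed).
* **Clumping**: greedy by ascending p-value; a variant is removed when it
  lies within the window (center-to-center ≤ window_kb×1000 bp, same
  chromosome) of an index variant *and* has r² above the threshold with it.
  Defaults: r² < 0.001 with a 10,000-kb window for the primary instrument;
  r² < 0.1 for cis drug-target variants, where correlated variants at one
  locus are expected. Ties in p break by smaller SE, then lexical variant
  ID, making output order-independent. Variants absent from the LD matrix
  are treated as unlinked with a warning, which permits desk-scale runs with
  partial LD panels.
* **Harmonization**: outcome effects are re-expressed on the exposure's
  effect allele; swapped alleles negate the outcome beta and complement its
  frequency; strand flips are resolved via allele complements for
  non-palindromic pairs. Palindromic (A/T, C/G) variants default to
  frequency inference: both frequencies must fall outside the ambiguous band
  [0.42, 0.58] (configurable cutoff), discordant frequency signs imply a
  strand flip, otherwise the variant is dropped. An irreconcilable allele
  pair is always dropped with a reason code, never silently aligned.
  Harmonizing an already-harmonized set is the identity
  (`harmonize_involution_check`).

Coordinates are 1-based inclusive throughout, including region catalogs; a
reader flag converts true 0-based half-open BED input.

## Instrument strength and sample overlap

Per-variant variance explained is
R² = 2·MAF(1−MAF)β² / (2·MAF(1−MAF)β² + 2·MAF(1−MAF)N·se²) — algebraically
β²/(β² + N·se²), hence invariant to MAF and to the sign of β — and
F = R²(N−2)/(1−R²), with the exact inversion r² = F/(F+N−2).

Participant overlap between the exposure and outcome GWAS correlates their
sampling errors, pulling the MR estimate toward the confounded observational
association with magnitude inversely proportional to instrument strength:

    bias ≈ overlap_fraction × β_obs / E[F],

with β_obs the observational log-odds per mmHg (log OR per 10 divided by 10,
so bias shares the per-mmHg scale of the instrument effects) and
E[F] = (N_exposure/K)·R²/(1−R²) for K instruments explaining R² jointly. An
alternative `per_variant` convention (the single-variant F at R²/K) is
configurable; the two differ by ~4% at the study's dimensions and the exact
convention of the original interactive calculator is not recoverable. The
type-I error is the two-sided rejection probability of the nominal test when
the standardized statistic is shifted by bias/se_IV, with
se_IV = 1/√(N_outcome·φ(1−φ)·R²) (φ the case fraction) the asymptotic IVW SE
per mmHg. Zero overlap returns bias 0 and exactly the nominal level.

## Drug-target proxies

The gene-region route intersects SBP-associated variants (strict genome-wide
threshold) with the class's target-gene/promoter/enhancer intervals
(boundaries inclusive), clumps at r² < 0.1 and harmonizes against the
outcome; a variant inside regions of two classes is kept in both and
flagged. The eQTL route keeps the smallest-nominal-p eQTL per variant–gene
pair (ties across tissues break lexically by tissue label), validates it as
an SBP instrument by a Wald-ratio MR of expression on SBP at p < 0.05, and
harmonizes survivors. The two routes are never merged. Region and eQTL
catalogs are consumed as authoritative input tables; curating them is out of
scope. Orientation to "drug effect" is purely the SBP-lowering sign; no
agonism/antagonism per target is modelled.

## Synthetic data

`generate_summary_pair` simulates summary statistics directly — the analysis
consumes nothing else, and direct simulation keeps full Monte-Carlo runs in
seconds. Per variant: MAF uniform on (0.05, 0.5); γ_j ~ N(0, gamma_sd²) with
the exposure phenotype standardized to unit variance; α_j zero, balanced
N(0, sd²), or directional; Γ_j = θγ_j + α_j; sampling SEs follow the closed
forms se_x = 1/√(2·maf(1−maf)·N_x) and
se_y = 1/√(2·maf(1−maf)·N_y·φ(1−φ)); observed betas are drawn jointly
normal with error correlation overlap_fraction·√(min(N)/max(N)). LD is
block-diagonal with constant within-block r², which is all the clumping
logic requires. A single seed drives a hierarchical `SeedSequence` scheme
(children: effects, sampling errors, fixtures), so each piece is
independently reproducible and a fixed seed yields byte-identical tables.

Directional pleiotropy is coded relative to the **exposure-raising allele**:
α_j = sign(γ_j)·N(pleiotropy_mean, sd²). Allele coding is a re-labelling, so
a fixed-mean α under arbitrary coding would cancel under the re-orientation
every estimator applies and "directional" would be indistinguishable from
balanced; coding it directionally makes the generator's parameter the
estimand of the Egger intercept. InSIDE holds by construction.

Defaults mirror the published study's scale: N_exposure = 757,601; outcome
65,446 cases/522,744 controls; J = 400; θ = 0.0157 (OR 1.17 per 10 mmHg);
gamma_sd = 0.015, chosen so that ~400 instruments explain ≈4% of exposure
variance with mean per-variant F ≈ 76, matching the reported instrument
strength. Because the exposure is simulated on the unit-variance scale, one
"mmHg" of simulated exposure carries less precision than a real mmHg; single
replicates are correspondingly noisy and calibration claims are made on
Monte-Carlo averages.

What the generator does **not** emulate: realistic genome-wide LD, liability
-scale subtleties of the binary outcome beyond the case-control variance
inflation, allele-frequency differences between studies, population
stratification, or winner's curse from discovery in the same sample. Passing
tests therefore validate the estimators and pipeline logic under the stated
sampling model, not robustness to those real-data features.

## Validation problem sizes

Estimator equivalence is checked against independent brute-force references
on 200 random 3–12-instrument sets to 1e-10 relative error. Parameter
recovery runs 500 replicates at J = 400, θ = 0.0157 (mean IVW OR within 2
Monte-Carlo SEs of 1.17; 95% CI coverage within [0.93, 0.97]). Pleiotropy
behaviour runs 500 replicates at J = 200 with the genome-wide selection
stage applied before estimation — selection is part of the study pipeline
and guarantees each instrument's orientation is identified; without it,
variants whose observed effect sign misidentifies the exposure-raising
allele attenuate the Egger intercept.

## Known limitations

* The sample-overlap approximation is first-order in 1/F and analytic; it
  does not replicate the original calculator's interface and its printed
  reference values are reproducible only to their mutual consistency (see
  the R² convention note above).
* Weighted-median p-values are normal-theory on a bootstrap SE; quantile
  bootstrap CIs are not implemented.
* No proxy-SNP lookup for outcome variants missing from the exposure set,
  no liftover between genome builds, no LD computation from genotypes.
* MR-PRESSO, mode-based estimators, multivariable MR and Steiger filtering
  are out of scope.
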