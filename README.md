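# mrbp — two-sample Mendelian randomization of blood pressure on atrial fibrillation

`mrbp` is a Python library for estimating the causal effect of blood
pressure (BP) on atrial fibrillation (AF) risk from GWAS summary statistics,
and for asking the pharmacological follow-up question: does BP lowering
through the protein targets of specific antihypertensive drug classes
(e.g. calcium-channel blockers, β-blockers) reduce AF risk? It is aimed at
genetic epidemiologists who work with summary-level GWAS data and want a
tested, scriptable implementation of the full pipeline: instrument
construction, harmonization, estimation, diagnostics, and drug-target proxy
analyses — plus a synthetic summary-statistics generator so every stage can
be exercised and calibrated without downloading consortium data.

## The model

For variant *j* with exposure effect γ̂_j (SE σ_xj, mmHg per allele) and
outcome effect Γ̂_j (SE σ_yj, log-odds per allele), the causal effect θ
(log-odds AF per mmHg) satisfies Γ_j = θ·γ_j for valid instruments. The
package implements:

* **IVW with multiplicative random effects** — σ_y⁻²-weighted regression of
  Γ̂ on γ̂ through the origin; SE inflated by max(1, √(Q/(J−1)));
* **weighted median** — the 50% point of the weight-ordered Wald ratios
  Γ̂_j/γ̂_j, parametric-bootstrap SE; consistent if ≥50% of weight is valid;
* **MR-Egger** — weighted regression with intercept after orienting
  exposure effects positive; the intercept tests directional pleiotropy;
* **instrument metrics** — per-variant R² = β²/(β²+N·se²) and
  F = R²(N−2)/(1−R²), and an analytic approximation of the bias and type-I
  error induced by exposure–outcome sample overlap,
  bias ≈ overlap × β_obs / E[F];
* **instrument construction** — genome-wide selection (P < 5×10⁻⁸), greedy
  LD clumping (r² < 0.001, 10,000-kb window; r² < 0.1 for cis drug-target
  variants), allele harmonization with frequency-based orientation of
  palindromic SNPs;
* **drug-target proxies** — instruments restricted to target-gene /
  promoter / enhancer regions of a drug class, or to GTEx-style best eQTLs
  validated against SBP, with effects reported per 10-mmHg SBP decrease.

Results are reported as odds ratios per 10-mmHg BP increment
(OR = exp(10·θ)).

## Worked example

Simulate an SBP-scale study (400 variants, true OR 1.17 per 10 mmHg,
exposure GWAS of 757,601, outcome of 65,446 cases / 522,744 controls) and
run the primary pipeline (`python examples/01_primary_mr.py`):

```
  trait             method  n_snp  or_per_10  ci_or_low_10  ci_or_high_10   pvalue
SBP_sim ivw_random_effects    186   0.876338      0.555031       1.383649 0.571075
SBP_sim    weighted_median    186   0.752334      0.378856       1.493989 0.416202
SBP_sim        egger_slope    186   0.520766      0.167505       1.619039 0.257911
SBP_sim    egger_intercept    186   1.011975      0.988256       1.036263 0.323355
...
mean IVW OR per 10 mmHg over 50 replicates: 1.201 (MC-SE 0.042; truth 1.17)
```

186 of 400 simulated variants pass genome-wide significance and clumping;
one replicate is noisy at the simulated (unit-variance) precision — its 95%
CI covers the truth — while the 50-replicate average recovers the planted
OR. The sample-overlap diagnostic at the published study dimensions
(`python examples/03_overlap_bias.py`):

```
observational OR 1.3 per 10 mmHg: bias 0.000332 log-odds/mmHg, type-I error 0.0500 (expected instrument F 79.1)
observational OR 1.6 per 10 mmHg: bias 0.000594 log-odds/mmHg, type-I error 0.0501 (expected instrument F 79.1)
```

i.e. even 100% participant overlap between the BP and AF GWAS would bias the
estimate by well under 4% of the causal effect scale and leave the 5% test
at its nominal size. `examples/02_drug_target_proxies.py` and
`examples/04_harmonization.py` demonstrate the drug-class routes and the
allele-harmonization rules.

A thin CLI wraps the same functions for shell use:

```bash
mrbp simulate --out sim/ --n-snps 400 --seed 11
mrbp primary --config config.yaml --output-dir results/
mrbp drug-target --config config.yaml
mrbp overlap-bias --n-exposure 757601 --cases 65446 --controls 522744 \
    --overlap 1.0 --obs-or-per-10 1.6 --instrument-r2 0.04 --n-instruments 399
```

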