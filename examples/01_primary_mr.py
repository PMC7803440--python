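"""Primary analysis on a simulated blood-pressure GWAS.

Simulates an SBP-scale exposure/outcome summary-statistic pair (400 variants,
true effect 0.0157 log-odds AF per mmHg, i.e. OR 1.17 per 10 mmHg), then runs
the full primary pipeline: genome-wide selection, LD clumping, harmonization,
and IVW / weighted-median / MR-Egger estimation on the per-10-mmHg OR scale.
"""

from mrbp import (
    AnalysisConfig,
    SyntheticStudyConfig,
    generate_summary_pair,
    run_primary_analysis,
)

study = generate_summary_pair(SyntheticStudyConfig(n_snps=400, seed=11))
config = AnalysisConfig(n_boot=200, seed=11)

report = run_primary_analysis(
    config,
    exposures={"SBP_sim": study.exposure_records()},
    outcome=study.outcome_records(),
    ld=study.ld,
)

cols = ["trait", "method", "n_snp", "or_per_10", "ci_or_low_10", "ci_or_high_10", "pvalue"]
print(report.estimates[cols].to_string(index=False))
print()
print(report.strength.to_string(index=False))
print()
print("Stage counts:")
print(report.stage_log.to_string(index=False))
print()
print(
    "or_per_10 is the odds ratio of the outcome per 10-mmHg increment of the\n"
    "exposure; the planted truth is exp(0.157) = 1.17, and the IVW interval\n"
    "should cover it. total_r2/mean_f describe instrument strength after\n"
    "selection and clumping. A single replicate is noisy at this simulated\n"
    "precision, so we also average IVW over 50 independent replicates:"
)

import numpy as np

from mrbp import ivw_random_effects

ors = []
for s in range(50):
    rep = generate_summary_pair(SyntheticStudyConfig(n_snps=400, seed=1000 + s))
    est = ivw_random_effects(
        (
            rep.exposure["beta"].to_numpy(),
            rep.exposure["se"].to_numpy(),
            rep.outcome["beta"].to_numpy(),
            rep.outcome["se"].to_numpy(),
        )
    )
    ors.append(est.or_per_10)
print(
    f"mean IVW OR per 10 mmHg over 50 replicates: {np.mean(ors):.3f} "
    f"(MC-SE {np.std(ors, ddof=1) / np.sqrt(50):.3f}; truth 1.17)"
)
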