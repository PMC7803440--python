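"""Instrument strength (per-variant R² and F) and sample-overlap bias.

For a variant with exposure effect β, standard error *se*, effect-allele
frequency MAF and sample size N, the proportion of phenotypic variance
explained is

    R² = 2·MAF(1−MAF)·β² / (2·MAF(1−MAF)·β² + 2·MAF(1−MAF)·N·se²)

(the MAF factor cancels algebraically, leaving β²/(β² + N·se²)), and the
instrument-strength F statistic is F = R²(N−2)/(1−R²).

When participants appear in both the exposure and the outcome GWAS, the
two-sample estimator partially inherits the confounded observational
association.  The weak-instrument approximation used here is

    bias ≈ overlap_fraction × β_obs / E[F]

with β_obs the observational log-odds per mmHg and E[F] the expected
instrument F statistic; the inflation of the nominal type-I error follows
from shifting the test statistic by bias/se_IV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, EstimationError
from .summary_data import SummaryStatRecord

__all__ = [
    "InstrumentStrength",
    "OverlapScenario",
    "OverlapBiasResult",
    "variant_r2",
    "variant_f",
    "instrument_summary",
    "overlap_bias",
]


@dataclass(frozen=True)
class InstrumentStrength:
    """Aggregated per-variant variance explained and F statistics."""

    per_variant_r2: tuple[float, ...]
    total_r2: float
    per_variant_f: tuple[float, ...]
    mean_f: float
    min_f: float
    max_f: float


@dataclass(frozen=True)
class OverlapScenario:
    """Inputs of a sample-overlap bias calculation.

    ``observational_or_per_10`` is the confounded observational odds ratio
    per 10-mmHg increment; ``instrument_r2`` the total variance explained by
    the ``n_instruments`` instruments in the exposure GWAS of size
    ``n_exposure``; ``overlap_fraction`` the fraction of exposure-GWAS
    participants also present in the outcome GWAS.
    """

    n_exposure: int
    n_outcome_cases: int
    n_outcome_controls: int
    overlap_fraction: float
    observational_or_per_10: float
    instrument_r2: float
    n_instruments: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise DomainError("overlap_fraction must lie in [0, 1]")
        for name in ("n_exposure", "n_outcome_cases", "n_outcome_controls", "n_instruments"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if not (0.0 < self.instrument_r2 < 1.0):
            raise DomainError("instrument_r2 must lie in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise DomainError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class OverlapBiasResult:
    bias: float  # log-odds per mmHg
    type1_error: float
    expected_f: float
    se_iv: float
    scenario: OverlapScenario


def variant_r2(beta: float, se: float, maf: float, n: int) -> float:
    """Proportion of phenotype variance explained by one variant.

    The full formula keeps the 2·MAF(1−MAF) factor, which cancels; the result
    is invariant to MAF and to the sign of beta.
    """
    if not (0.0 < maf < 1.0):
        raise DomainError("maf must lie strictly inside (0, 1)")
    if se <= 0:
        raise DomainError("se must be positive")
    if n <= 2:
        raise DomainError("n must exceed 2")
    het = 2.0 * maf * (1.0 - maf)
    return (het * beta**2) / (het * beta**2 + het * n * se**2)


def variant_f(r2: float, n: int) -> float:
    """Per-variant F statistic, F = R²(N−2)/(1−R²)."""
    if not (0.0 <= r2 < 1.0):
        raise DomainError("r2 must lie in [0, 1)")
    if n <= 2:
        raise DomainError("n must exceed 2")
    return r2 * (n - 2) / (1.0 - r2)


def instrument_summary(records: Sequence[SummaryStatRecord]) -> InstrumentStrength:
    """Aggregate per-variant R² and F over a clumped instrument set."""
    if len(records) == 0:
        raise EstimationError("instrument_summary requires a nonempty record set")
    r2s = tuple(variant_r2(r.beta, r.se, r.eaf, r.n) for r in records)
    fs = tuple(variant_f(r2, r.n) for r2, r in zip(r2s, records))
    return InstrumentStrength(
        per_variant_r2=r2s,
        total_r2=float(sum(r2s)),
        per_variant_f=fs,
        mean_f=float(np.mean(fs)),
        min_f=float(min(fs)),
        max_f=float(max(fs)),
    )


def _expected_f(scenario: OverlapScenario, convention: str) -> float:
    r2, n, k = scenario.instrument_r2, scenario.n_exposure, scenario.n_instruments
    if convention == "expected":
        return (n / k) * r2 / (1.0 - r2)
    if convention == "per_variant":
        r2_per = r2 / k
        return r2_per * (n - 2) / (1.0 - r2_per)
    raise DomainError(f"unknown expected-F convention {convention!r}")


def overlap_bias(
    scenario: OverlapScenario, f_convention: str = "expected"
) -> OverlapBiasResult:
    """Analytic bias and type-I error from exposure–outcome sample overlap.

    bias = overlap_fraction × (log observational OR per mmHg) / E[F], with
    E[F] = (n_exposure/K)·R²/(1−R²) under the default ``expected`` convention
    (``per_variant`` uses the single-variant F at R²/K).  The type-I error is
    the two-sided rejection probability of the nominal α-level test when the
    standardized estimate is shifted by bias/se_IV, where
    se_IV = 1/sqrt(N_outcome·φ(1−φ)·R²) (φ the case fraction) is the
    asymptotic IVW standard error per mmHg.  At zero overlap the bias is 0
    and the type-I error equals α exactly.
    """
    f_exp = _expected_f(scenario, f_convention)
    beta_obs = math.log(scenario.observational_or_per_10) / 10.0
    bias = scenario.overlap_fraction * beta_obs / f_exp

    n_out = scenario.n_outcome_cases + scenario.n_outcome_controls
    phi = scenario.n_outcome_cases / n_out
    se_iv = 1.0 / math.sqrt(n_out * phi * (1.0 - phi) * scenario.instrument_r2)
    if scenario.overlap_fraction == 0.0:
        type1 = scenario.alpha
    else:
        z = stats.norm.ppf(1.0 - scenario.alpha / 2.0)
        delta = bias / se_iv
        type1 = float(stats.norm.cdf(-z - delta) + stats.norm.cdf(-z + delta))
    return OverlapBiasResult(
        bias=float(bias),
        type1_error=type1,
        expected_f=float(f_exp),
        se_iv=float(se_iv),
        scenario=scenario,
    )
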