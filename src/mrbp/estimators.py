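"""Causal-effect estimators for two-sample Mendelian randomization.

Given J harmonized instruments with exposure effects γ̂_j (se σ_xj) and
outcome effects Γ̂_j (se σ_yj), the per-variant Wald ratio is
θ̂_j = Γ̂_j / γ̂_j with first-order standard error σ_yj / |γ̂_j|.  The
estimators combine these ratios:

* IVW — the σ_yj⁻²-weighted regression of Γ̂ on γ̂ through the origin;
  the multiplicative random-effects variant inflates the fixed-effect SE by
  max(1, sqrt(Q/(J−1))) where Q is Cochran's heterogeneity statistic.
* Weighted median — the 50% point of the inverse-variance-weight-ordered
  Wald ratios, with a parametric-bootstrap SE; consistent when at least half
  the weight comes from valid instruments.
* MR-Egger — the weighted regression *with* an intercept after orienting all
  exposure effects positive; the intercept estimates average directional
  pleiotropy, the slope is a pleiotropy-adjusted causal estimate (valid
  under the InSIDE assumption).

Effects are in log-odds per mmHg; results also carry the odds ratio per
10-mmHg increment, the clinically conventional scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import EstimationError
from .summary_data import HarmonizedInstrument, retained

__all__ = [
    "MREstimate",
    "EggerResult",
    "effects",
    "wald_ratios",
    "ivw",
    "ivw_random_effects",
    "weighted_median",
    "egger",
    "to_or_per_10mmhg",
    "flip_exposure_direction",
]


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate in log-odds per mmHg with 95% interval.

    ``or_per_10 = exp(10·beta)`` and its CI restate the effect per 10-mmHg
    increment of the exposure.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int
    cochran_q: float = float("nan")
    or_per_10: float = float("nan")
    ci_or_low_10: float = float("nan")
    ci_or_high_10: float = float("nan")


@dataclass(frozen=True)
class EggerResult:
    slope: MREstimate
    intercept: MREstimate


def _with_or(est: MREstimate) -> MREstimate:
    return replace(
        est,
        or_per_10=math.exp(10.0 * est.beta),
        ci_or_low_10=math.exp(10.0 * est.ci_low),
        ci_or_high_10=math.exp(10.0 * est.ci_high),
    )


def to_or_per_10mmhg(estimate: MREstimate) -> MREstimate:
    """Attach the OR per 10-mmHg increment (monotone transform of beta and CI)."""
    return _with_or(estimate)


def effects(
    instruments: Sequence[HarmonizedInstrument] | tuple,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Coerce instruments to (beta_exposure, se_exposure, beta_outcome, se_outcome).

    Accepts a sequence of retained :class:`HarmonizedInstrument` or a 4-tuple
    of array-likes.
    """
    if isinstance(instruments, tuple) and len(instruments) == 4:
        bx, sx, by, sy = (np.asarray(a, dtype=float) for a in instruments)
    else:
        keep = retained(instruments)  # type: ignore[arg-type]
        bx = np.array([h.beta_exposure for h in keep], dtype=float)
        sx = np.array([h.se_exposure for h in keep], dtype=float)
        by = np.array([h.beta_outcome for h in keep], dtype=float)
        sy = np.array([h.se_outcome for h in keep], dtype=float)
    if not (len(bx) == len(sx) == len(by) == len(sy)):
        raise EstimationError("effect arrays have mismatched lengths")
    return bx, sx, by, sy


def wald_ratios(instruments) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant ratio estimates θ̂_j = Γ̂_j/γ̂_j with first-order SEs.

    Instruments with a zero exposure effect are excluded (their ratio is
    undefined).
    """
    bx, _, by, sy = effects(instruments)
    ok = bx != 0.0
    if not ok.all():
        import warnings

        warnings.warn(
            f"excluded {int((~ok).sum())} instrument(s) with zero exposure effect",
            stacklevel=2,
        )
    bx, by, sy = bx[ok], by[ok], sy[ok]
    return by / bx, sy / np.abs(bx)


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def ivw(instruments, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted estimate (regression through the origin).

    With a single instrument the estimate reduces to the Wald ratio.  The
    multiplicative random-effects SE inflates the fixed-effects SE by
    max(1, sqrt(Q/(J−1))); Cochran's Q is reported either way.
    """
    bx, sx, by, sy = effects(instruments)
    ok = bx != 0.0
    bx, sx, by, sy = bx[ok], sx[ok], by[ok], sy[ok]
    j = len(bx)
    if j == 0:
        raise EstimationError("IVW requires at least one instrument")
    w = 1.0 / sy**2
    beta = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se_fixed = float(np.sqrt(1.0 / np.sum(w * bx**2)))
    q = float(np.sum(w * (by - beta * bx) ** 2))
    if j == 1:
        se = sy[0] / abs(bx[0])
        q = float("nan")
    elif random_effects:
        se = se_fixed * max(1.0, math.sqrt(q / (j - 1)))
    else:
        se = se_fixed
    z = beta / se
    half = 1.959963984540054 * se
    method = "ivw_random_effects" if random_effects else "ivw_fixed"
    return _with_or(
        MREstimate(
            method=method,
            beta=beta,
            se=float(se),
            ci_low=beta - half,
            ci_high=beta + half,
            pvalue=_normal_p(z),
            n_snp=j,
            cochran_q=q,
        )
    )


def ivw_random_effects(instruments) -> MREstimate:
    """IVW with multiplicative random effects (the primary-analysis model)."""
    return ivw(instruments, random_effects=True)


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta, kind="stable")
    t = theta[order]
    wn = w[order] / w.sum()
    p = np.cumsum(wn) - wn / 2.0
    if 0.5 <= p[0]:
        return float(t[0])
    if 0.5 >= p[-1]:
        return float(t[-1])
    return float(np.interp(0.5, p, t))


def weighted_median(instruments, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap standard error.

    Ratios are ordered ascending with normalized inverse-variance weights
    w_j = (γ̂_j/σ_yj)²; the estimate linearly interpolates the ordered ratios
    at cumulative weight 0.5.  The SE is the standard deviation of the
    estimate over ``n_boot`` parametric resamples of the per-variant betas.
    """
    bx, sx, by, sy = effects(instruments)
    j = len(bx)
    if j < 3:
        raise EstimationError("weighted median requires at least 3 instruments")
    theta = by / bx
    w = (bx / sy) ** 2
    beta = _weighted_median_point(theta, w)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    bxs = rng.normal(bx, sx, size=(n_boot, j))
    bys = rng.normal(by, sy, size=(n_boot, j))
    for b in range(n_boot):
        bxb = bxs[b]
        ok = bxb != 0.0
        boots[b] = _weighted_median_point(
            bys[b][ok] / bxb[ok], (bxb[ok] / sy[ok]) ** 2
        )
    se = float(boots.std(ddof=1))
    half = 1.959963984540054 * se
    return _with_or(
        MREstimate(
            method="weighted_median",
            beta=beta,
            se=se,
            ci_low=beta - half,
            ci_high=beta + half,
            pvalue=_normal_p(beta / se) if se > 0 else 0.0,
            n_snp=j,
        )
    )


def egger(instruments) -> EggerResult:
    """MR-Egger regression: pleiotropy-adjusted slope and bias intercept.

    Instruments are oriented so every exposure effect is positive (both betas
    negated where needed; the ratio is invariant).  A σ_y⁻²-weighted linear
    regression of Γ̂ on γ̂ with intercept is fitted in closed form; SEs use
    multiplicative residual scaling floored at 1, and p-values/CIs use a
    t-reference with J−2 degrees of freedom.
    """
    bx, sx, by, sy = effects(instruments)
    j = len(bx)
    if j < 3:
        raise EstimationError("MR-Egger requires at least 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.allclose(bx, bx[0]):
        raise EstimationError("MR-Egger requires variation in exposure effects")
    w = 1.0 / sy**2
    sw = w.sum()
    xbar = np.sum(w * bx) / sw
    ybar = np.sum(w * by) / sw
    sxx = np.sum(w * (bx - xbar) ** 2)
    slope = float(np.sum(w * (bx - xbar) * (by - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = by - intercept - slope * bx
    q = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(q / (j - 2)))
    se_slope = math.sqrt(1.0 / sxx) * scale
    se_int = math.sqrt(1.0 / sw + xbar**2 / sxx) * scale
    tq = float(stats.t.ppf(0.975, j - 2))

    def est(method: str, b: float, se: float) -> MREstimate:
        p = float(2.0 * stats.t.sf(abs(b / se), j - 2))
        return _with_or(
            MREstimate(
                method=method,
                beta=b,
                se=se,
                ci_low=b - tq * se,
                ci_high=b + tq * se,
                pvalue=p,
                n_snp=j,
                cochran_q=q,
            )
        )

    return EggerResult(
        slope=est("egger_slope", slope, se_slope),
        intercept=est("egger_intercept", intercept, se_int),
    )


def flip_exposure_direction(estimate: MREstimate) -> MREstimate:
    """Restate an estimate per unit *decrease* of the exposure.

    Negates the effect (swapping CI bounds) and recomputes the per-10-mmHg
    odds ratio, so a protective exposure-lowering effect yields OR < 1.
    """
    return _with_or(
        replace(
            estimate,
            beta=-estimate.beta,
            ci_low=-estimate.ci_high,
            ci_high=-estimate.ci_low,
        )
    )
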