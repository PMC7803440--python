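"""GWAS summary statistics: reading, validation, selection, LD clumping, harmonization.

The analysis consumes only summary-level data: one row per variant with the
estimated per-allele effect on a trait, its standard error, the effect-allele
frequency and the sample size.  This module turns delimited files into
validated records, selects genome-wide significant variants, thins them to an
approximately independent set by greedy LD clumping, and harmonizes exposure
and outcome effects onto a shared effect allele so that downstream estimators
can form per-variant ratio estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "SummaryStatRecord",
    "HarmonizedInstrument",
    "LdMatrix",
    "ReadResult",
    "DEFAULT_DIALECT",
    "read_summary_stats",
    "records_from_frame",
    "records_to_frame",
    "select_genomewide",
    "clump",
    "harmonize",
    "retained",
    "harmonize_involution_check",
    "harmonized_to_frame",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Column names of a common GWAS summary-statistic export (PLINK-style).
DEFAULT_DIALECT: Mapping[str, str] = {
    "variant_id": "SNP",
    "chromosome": "CHR",
    "position": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` (mmHg for blood
    pressure traits, log-odds for atrial fibrillation); ``eaf`` is the
    effect-allele frequency.
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int
    trait: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())
        problems = self.problems()
        if problems:
            raise DataError(
                f"invalid record {self.variant_id!r}: " + "; ".join(problems)
            )

    def problems(self) -> list[str]:
        """Invariant violations, empty when the record is valid."""
        out: list[str] = []
        if self.effect_allele not in _VALID_ALLELES:
            out.append(f"effect_allele {self.effect_allele!r} not in A/C/G/T")
        if self.other_allele not in _VALID_ALLELES:
            out.append(f"other_allele {self.other_allele!r} not in A/C/G/T")
        if self.effect_allele == self.other_allele:
            out.append("effect_allele equals other_allele")
        if not (math.isfinite(self.beta)):
            out.append("beta not finite")
        if not (math.isfinite(self.se) and self.se > 0):
            out.append("se must be finite and > 0")
        if not (0.0 <= self.eaf <= 1.0):
            out.append("eaf outside [0, 1]")
        if not (0.0 < self.pvalue <= 1.0):
            out.append("pvalue outside (0, 1]")
        if not self.n > 0:
            out.append("n must be positive")
        return out

    @property
    def maf(self) -> float:
        """Minor-allele frequency."""
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def palindromic(self) -> bool:
        """True for A/T or C/G variants, whose strand cannot be resolved."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A variant with exposure and outcome effects on a shared effect allele.

    Entries with ``action_taken == "dropped"`` carry the reason in
    ``drop_reason`` and NaN outcome fields; use :func:`retained` to filter to
    usable instruments.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float
    eaf_outcome: float
    palindromic: bool
    action_taken: str  # {"unchanged", "allele_flip", "dropped"}
    drop_reason: str | None = None

    def __post_init__(self) -> None:
        if self.action_taken not in ("unchanged", "allele_flip", "dropped"):
            raise DataError(f"unknown action_taken {self.action_taken!r}")
        if self.action_taken != "dropped":
            if not (self.se_exposure > 0 and self.se_outcome > 0):
                raise DataError(
                    f"{self.variant_id}: harmonized SEs must be positive"
                )


@dataclass(frozen=True)
class LdMatrix:
    """Pairwise squared correlations (r²) for an ordered set of variants.

    Stands in for an external LD reference panel; symmetric, unit diagonal,
    entries in [0, 1].
    """

    variant_ids: tuple[str, ...]
    r2: np.ndarray
    positions: tuple[int, ...] | None = None
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if r2.shape != (k, k):
            raise DataError(f"LD matrix shape {r2.shape} != ({k}, {k})")
        if not np.allclose(r2, r2.T, atol=1e-8):
            raise DataError("LD matrix is asymmetric beyond tolerance 1e-8")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-8):
            raise DataError("LD matrix diagonal must be 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
            raise DataError("LD r² values must lie in [0, 1]")
        object.__setattr__(self, "r2", np.clip(r2, 0.0, 1.0))
        object.__setattr__(self, "variant_ids", tuple(self.variant_ids))
        object.__setattr__(
            self, "_index", {v: i for i, v in enumerate(self.variant_ids)}
        )

    def lookup(self, a: str, b: str) -> float | None:
        """r² between two variants, or None when either is absent."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    @classmethod
    def from_file(cls, path: str | Path) -> "LdMatrix":
        """Read a square delimited matrix with a variant-ID header row and column."""
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        ids = [str(c) for c in df.columns]
        if list(map(str, df.index)) != ids:
            raise DataError("LD matrix row and column variant IDs disagree")
        return cls(variant_ids=tuple(ids), r2=df.to_numpy(dtype=float))

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t", float_format="%.10g"
        )


@dataclass
class ReadResult:
    """Validated records plus the per-row rejections the reader reports."""

    records: list[SummaryStatRecord]
    rejections: list[tuple[int, str]]  # (1-based data line number, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def read_summary_stats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    trait: str = "",
) -> ReadResult:
    """Read a delimited summary-statistics file into validated records.

    ``dialect`` maps record field names to file column names; the default
    matches common GWAS exports (SNP/CHR/BP/A1/A2/EAF/BETA/SE/P/N).  Rows that
    violate record invariants (or are non-numeric) are rejected individually,
    with 1-based data line numbers; a missing mapped column raises
    :class:`ConfigError`.
    """
    dialect = dict(dialect or DEFAULT_DIALECT)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [col for col in dialect.values() if col not in df.columns]
    if missing:
        raise ConfigError(
            f"{path}: missing mandatory column(s) {missing}; found {list(df.columns)}"
        )
    renamed = df.rename(columns={v: k for k, v in dialect.items()})
    return records_from_frame(renamed, trait=trait)


def records_from_frame(df: pd.DataFrame, trait: str = "") -> ReadResult:
    """Validate a DataFrame already using canonical field names as columns."""
    records: list[SummaryStatRecord] = []
    rejections: list[tuple[int, str]] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = SummaryStatRecord(
                variant_id=str(row.variant_id),
                chromosome=str(row.chromosome),
                position=int(float(row.position)),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                eaf=float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pvalue=float(row.pvalue),
                n=int(float(row.n)),
                trait=trait or str(getattr(row, "trait", "")),
            )
        except (DataError, ValueError, TypeError) as exc:
            rejections.append((line_no, str(exc)))
            continue
        records.append(rec)
    return ReadResult(records=records, rejections=rejections)


def records_to_frame(records: Iterable[SummaryStatRecord]) -> pd.DataFrame:
    """Records as a DataFrame with canonical field names."""
    return pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "chromosome": r.chromosome,
                "position": r.position,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": r.n,
                "trait": r.trait,
            }
            for r in records
        ]
    )


def select_genomewide(
    records: Sequence[SummaryStatRecord], p_threshold: float = 5e-8
) -> list[SummaryStatRecord]:
    """Variants with p strictly below the genome-wide threshold (P < 5×10⁻⁸)."""
    return [r for r in records if r.pvalue < p_threshold]


def _clump_sort_key(r: SummaryStatRecord):
    # ties: smaller p, then smaller se, then lexical variant_id
    return (r.pvalue, r.se, r.variant_id)


def clump(
    records: Sequence[SummaryStatRecord],
    ld: LdMatrix | None = None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> list[SummaryStatRecord]:
    """Greedy LD clumping by ascending p-value.

    The best remaining variant becomes an index; any variant on the same
    chromosome within ``window_kb`` (center-to-center, ≤ window_kb×1000 bp)
    and with r² > ``r2_threshold`` to an index is removed.  Variants absent
    from the LD matrix are treated as unlinked (r² = 0) with a warning.
    Returns the index set ordered by ascending p.
    """
    order = sorted(records, key=_clump_sort_key)
    window_bp = window_kb * 1000.0
    kept: list[SummaryStatRecord] = []
    warned_missing = False
    for cand in order:
        removed = False
        for idx in kept:
            if cand.chromosome != idx.chromosome:
                continue
            if abs(cand.position - idx.position) > window_bp:
                continue
            r2 = ld.lookup(cand.variant_id, idx.variant_id) if ld is not None else None
            if r2 is None:
                if ld is not None and not warned_missing:
                    warnings.warn(
                        "variant(s) missing from LD matrix treated as unlinked (r²=0)",
                        stacklevel=2,
                    )
                    warned_missing = True
                r2 = 0.0
            if r2 > r2_threshold:
                removed = True
                break
        if not removed:
            kept.append(cand)
    return kept


def _alleles_compatible(ea_x: str, oa_x: str, ea_y: str, oa_y: str) -> str | None:
    """How the outcome allele pair maps onto the exposure pair.

    Returns "same", "swap", or None when irreconcilable.  Strand flips
    (complementary alleles) are resolved for non-palindromic pairs.
    """
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "same"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "swap"
    cea, coa = _COMPLEMENT[ea_y], _COMPLEMENT[oa_y]
    if (cea, coa) == (ea_x, oa_x):
        return "same"
    if (cea, coa) == (oa_x, ea_x):
        return "swap"
    return None


def harmonize(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    palindrome_policy: str = "infer_by_frequency",
    freq_cutoff: float = 0.42,
) -> list[HarmonizedInstrument]:
    """Express exposure and outcome effects on the exposure's effect allele.

    Variants absent from the outcome are emitted as dropped
    (``missing_outcome``).  When outcome alleles are swapped relative to the
    exposure, the outcome beta is negated and its frequency complemented.
    Palindromic (A/T, C/G) variants are dropped under policy ``drop``; under
    ``infer_by_frequency`` they are oriented by allele frequency when both
    frequencies lie outside the ambiguous band [freq_cutoff, 1−freq_cutoff]
    and dropped otherwise.  Irreconcilable allele pairs are dropped with
    reason ``allele_mismatch``, never silently aligned.
    """
    if palindrome_policy not in ("drop", "infer_by_frequency"):
        raise ConfigError(f"unknown palindrome_policy {palindrome_policy!r}")
    by_id = {r.variant_id: r for r in outcome}
    out: list[HarmonizedInstrument] = []

    def dropped(x: SummaryStatRecord, reason: str, y: SummaryStatRecord | None = None):
        return HarmonizedInstrument(
            variant_id=x.variant_id,
            effect_allele=x.effect_allele,
            other_allele=x.other_allele,
            beta_exposure=x.beta,
            se_exposure=x.se,
            beta_outcome=float("nan"),
            se_outcome=float("nan"),
            eaf_exposure=x.eaf,
            eaf_outcome=y.eaf if y is not None else float("nan"),
            palindromic=x.palindromic,
            action_taken="dropped",
            drop_reason=reason,
        )

    for x in exposure:
        y = by_id.get(x.variant_id)
        if y is None:
            out.append(dropped(x, "missing_outcome"))
            continue
        rel = _alleles_compatible(
            x.effect_allele, x.other_allele, y.effect_allele, y.other_allele
        )
        if rel is None:
            out.append(dropped(x, "allele_mismatch", y))
            continue
        beta_y, eaf_y = y.beta, y.eaf
        action = "unchanged"
        if rel == "swap":
            beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            action = "allele_flip"
        if x.palindromic:
            if palindrome_policy == "drop":
                out.append(dropped(x, "palindromic", y))
                continue
            ambiguous = (
                min(x.eaf, 1.0 - x.eaf) >= freq_cutoff
                or min(eaf_y, 1.0 - eaf_y) >= freq_cutoff
            )
            if ambiguous:
                out.append(dropped(x, "palindromic_ambiguous_frequency", y))
                continue
            if (x.eaf - 0.5) * (eaf_y - 0.5) < 0:
                # frequencies disagree: outcome is on the opposite strand,
                # which for a palindromic pair is an allele swap
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
                action = "unchanged" if action == "allele_flip" else "allele_flip"
        out.append(
            HarmonizedInstrument(
                variant_id=x.variant_id,
                effect_allele=x.effect_allele,
                other_allele=x.other_allele,
                beta_exposure=x.beta,
                se_exposure=x.se,
                beta_outcome=beta_y,
                se_outcome=y.se,
                eaf_exposure=x.eaf,
                eaf_outcome=eaf_y,
                palindromic=x.palindromic,
                action_taken=action,
            )
        )
    return out


def retained(harmonized: Iterable[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    """Instruments usable for estimation (everything not dropped)."""
    return [h for h in harmonized if h.action_taken != "dropped"]


def harmonize_involution_check(
    harmonized: Sequence[HarmonizedInstrument],
    palindrome_policy: str = "infer_by_frequency",
    freq_cutoff: float = 0.42,
) -> bool:
    """Re-harmonizing an already harmonized pair must be the identity.

    Rebuilds exposure and outcome record sets from the retained instruments
    (both on the shared effect allele), harmonizes again, and checks that no
    action other than ``unchanged`` occurs and that effects are preserved.
    """
    keep = retained(harmonized)
    if not keep:
        return True

    def fake(h: HarmonizedInstrument, beta: float, se: float, eaf: float, i: int):
        return SummaryStatRecord(
            variant_id=h.variant_id,
            chromosome="1",
            position=i + 1,
            effect_allele=h.effect_allele,
            other_allele=h.other_allele,
            eaf=eaf,
            beta=beta,
            se=se,
            pvalue=0.5,
            n=1000,
        )

    expo = [fake(h, h.beta_exposure, h.se_exposure, h.eaf_exposure, i) for i, h in enumerate(keep)]
    outc = [fake(h, h.beta_outcome, h.se_outcome, h.eaf_outcome, i) for i, h in enumerate(keep)]
    again = retained(harmonize(expo, outc, palindrome_policy, freq_cutoff))
    if len(again) != len(keep):
        return False
    for h0, h1 in zip(keep, again):
        if h1.action_taken != "unchanged":
            return False
        if not (
            math.isclose(h0.beta_outcome, h1.beta_outcome, rel_tol=0, abs_tol=1e-12)
            and math.isclose(h0.beta_exposure, h1.beta_exposure, rel_tol=0, abs_tol=1e-12)
        ):
            return False
    return True


def harmonized_to_frame(harmonized: Iterable[HarmonizedInstrument]) -> pd.DataFrame:
    """Harmonization output as a tidy table with the action_taken column."""
    return pd.DataFrame(
        [
            {
                "variant_id": h.variant_id,
                "effect_allele": h.effect_allele,
                "other_allele": h.other_allele,
                "beta_exposure": h.beta_exposure,
                "se_exposure": h.se_exposure,
                "beta_outcome": h.beta_outcome,
                "se_outcome": h.se_outcome,
                "eaf_exposure": h.eaf_exposure,
                "eaf_outcome": h.eaf_outcome,
                "palindromic": h.palindromic,
                "action_taken": h.action_taken,
                "drop_reason": h.drop_reason or "",
            }
            for h in harmonized
        ]
    )
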