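"""Genetic proxies for antihypertensive drug classes.

Two routes construct instruments for the SBP-lowering action of a drug
class, mirroring how drug-target MR is done with summary data:

1. *Gene-region route* — SBP-associated variants (P < 5×10⁻⁸) lying within
   the class's target genes, promoters or enhancers, clumped at a permissive
   r² < 0.1 (cis variants at one locus are expected to be correlated).
2. *eQTL route* — the best (smallest nominal p) eQTL per variant–gene pair
   for each target gene, validated as an SBP instrument by a two-sample MR
   of expression on SBP (Wald ratio, p < 0.05).

Class effects on the outcome are reported as odds ratios per 10-mmHg SBP
*decrease*, so a protective drug-class effect appears as OR < 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError, EstimationError
from .estimators import (
    MREstimate,
    flip_exposure_direction,
    ivw,
    weighted_median,
)
from .summary_data import (
    HarmonizedInstrument,
    LdMatrix,
    SummaryStatRecord,
    clump,
    harmonize,
    retained,
    select_genomewide,
)

__all__ = [
    "KNOWN_DRUG_CLASSES",
    "GeneRegion",
    "EqtlRecord",
    "DrugClassInstrumentSet",
    "read_region_catalog",
    "read_eqtl_catalog",
    "select_gene_region_instruments",
    "select_eqtl_instruments",
    "estimate_drug_class_effect",
]

#: The twelve antihypertensive drug classes considered (the five with
#: DrugBank/GeneHancer region catalogs are ACEi, ARB, BB, CCB, thiazide).
KNOWN_DRUG_CLASSES = frozenset(
    {
        "ACEi",
        "ARB",
        "BB",
        "CCB",
        "thiazide",
        "adrenergic_neuron_blocker",
        "alpha_blocker",
        "centrally_acting",
        "loop_diuretic",
        "potassium_sparing_diuretic",
        "renin_inhibitor",
        "vasodilator",
    }
)

_ELEMENT_TYPES = frozenset({"gene_body", "promoter", "enhancer"})


@dataclass(frozen=True)
class GeneRegion:
    """A drug-target genomic interval (1-based inclusive coordinates)."""

    gene_symbol: str
    drug_class: str
    chromosome: str
    start: int
    end: int
    element_type: str = "gene_body"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(f"{self.gene_symbol}: start > end")
        if self.element_type not in _ELEMENT_TYPES:
            raise DataError(
                f"{self.gene_symbol}: element_type {self.element_type!r} not in {sorted(_ELEMENT_TYPES)}"
            )
        if self.drug_class not in KNOWN_DRUG_CLASSES:
            raise ConfigError(
                f"unknown drug_class label {self.drug_class!r} (known: {sorted(KNOWN_DRUG_CLASSES)})"
            )

    def contains(self, chromosome: str, position: int) -> bool:
        return self.chromosome == chromosome and self.start <= position <= self.end


@dataclass(frozen=True)
class EqtlRecord:
    """A variant–gene–tissue expression association from an eQTL catalog."""

    variant_id: str
    target_gene: str
    tissue: str
    beta_expression: float
    se_expression: float
    pvalue_nominal: float
    drug_class: str

    def __post_init__(self) -> None:
        if self.se_expression <= 0:
            raise DataError(f"{self.variant_id}: se_expression must be > 0")
        if self.drug_class not in KNOWN_DRUG_CLASSES:
            raise ConfigError(
                f"unknown drug_class label {self.drug_class!r} (known: {sorted(KNOWN_DRUG_CLASSES)})"
            )


@dataclass
class DrugClassInstrumentSet:
    """Instruments for one drug class from one selection route."""

    drug_class: str
    route: str  # {"gene_region", "eqtl"}
    instruments: list[HarmonizedInstrument]
    orientation: str = "or_per_10mmHg_sbp_decrease"
    shared_variants: dict[str, list[str]] | None = None  # variant -> other classes
    notes: list[str] | None = None

    @property
    def n_snp(self) -> int:
        return len(retained(self.instruments))


def read_region_catalog(
    path: str | Path, zero_based_half_open: bool = False
) -> list[GeneRegion]:
    """Read a BED-like TSV region catalog.

    Columns: chromosome, start, end, gene_symbol, drug_class, element_type.
    Coordinates are 1-based inclusive by default; pass
    ``zero_based_half_open=True`` to ingest true BED intervals (converted by
    start+1).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    needed = ["chromosome", "start", "end", "gene_symbol", "drug_class", "element_type"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: region catalog missing column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if zero_based_half_open:
            start += 1
        out.append(
            GeneRegion(
                gene_symbol=str(row.gene_symbol),
                drug_class=str(row.drug_class),
                chromosome=str(row.chromosome),
                start=start,
                end=end,
                element_type=str(row.element_type),
            )
        )
    return out


def read_eqtl_catalog(path: str | Path) -> list[EqtlRecord]:
    """Read an eQTL TSV (variant_id, gene, tissue, beta, se, p, drug_class)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    needed = ["variant_id", "gene", "tissue", "beta", "se", "p", "drug_class"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: eQTL catalog missing column(s) {missing}")
    return [
        EqtlRecord(
            variant_id=str(r.variant_id),
            target_gene=str(r.gene),
            tissue=str(r.tissue),
            beta_expression=float(r.beta),
            se_expression=float(r.se),
            pvalue_nominal=float(r.p),
            drug_class=str(r.drug_class),
        )
        for r in df.itertuples(index=False)
    ]


def select_gene_region_instruments(
    sbp_stats: Sequence[SummaryStatRecord],
    regions: Sequence[GeneRegion],
    outcome_stats: Sequence[SummaryStatRecord],
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.1,
    ld: LdMatrix | None = None,
    window_kb: float = 10_000,
) -> dict[str, DrugClassInstrumentSet]:
    """Gene-region instruments per drug class.

    Variants positioned within any region of a class (boundaries inclusive)
    with p below the genome-wide threshold are clumped at the permissive
    r² threshold and harmonized against the outcome.  A variant mapping to
    regions of several classes is retained in each and flagged.  Classes with
    no qualifying variant yield an empty set with a warning.
    """
    classes = sorted({r.drug_class for r in regions})
    membership: dict[str, set[str]] = {c: set() for c in classes}
    for rec in sbp_stats:
        for reg in regions:
            if reg.contains(rec.chromosome, rec.position):
                membership[reg.drug_class].add(rec.variant_id)

    shared: dict[str, list[str]] = {}
    for c in classes:
        for vid in membership[c]:
            others = [c2 for c2 in classes if c2 != c and vid in membership[c2]]
            if others:
                shared[vid] = sorted(set(shared.get(vid, [])) | set(others + [c]))

    out: dict[str, DrugClassInstrumentSet] = {}
    for c in classes:
        in_region = [r for r in sbp_stats if r.variant_id in membership[c]]
        significant = select_genomewide(in_region, p_threshold)
        clumped = clump(significant, ld=ld, r2_threshold=r2_threshold, window_kb=window_kb)
        notes: list[str] = []
        if not clumped:
            warnings.warn(f"drug class {c}: no qualifying variants", stacklevel=2)
            notes.append("no qualifying variants")
            out[c] = DrugClassInstrumentSet(
                drug_class=c, route="gene_region", instruments=[], notes=notes
            )
            continue
        harmonized = harmonize(clumped, outcome_stats)
        out[c] = DrugClassInstrumentSet(
            drug_class=c,
            route="gene_region",
            instruments=harmonized,
            shared_variants={
                v: [x for x in cls if x != c]
                for v, cls in shared.items()
                if any(h.variant_id == v for h in harmonized)
            }
            or None,
            notes=notes,
        )
    return out


def best_eqtl_per_gene(eqtl_records: Iterable[EqtlRecord]) -> list[EqtlRecord]:
    """Smallest nominal-p eQTL per (drug_class, gene); ties broken by tissue label."""
    best: dict[tuple[str, str], EqtlRecord] = {}
    for e in eqtl_records:
        key = (e.drug_class, e.target_gene)
        cur = best.get(key)
        if cur is None or (e.pvalue_nominal, e.tissue) < (cur.pvalue_nominal, cur.tissue):
            best[key] = e
    return [best[k] for k in sorted(best)]


def select_eqtl_instruments(
    eqtl_records: Sequence[EqtlRecord],
    sbp_stats: Sequence[SummaryStatRecord],
    outcome_stats: Sequence[SummaryStatRecord],
    validation_p: float = 0.05,
) -> dict[str, DrugClassInstrumentSet]:
    """eQTL instruments per drug class, validated against SBP.

    For each variant–gene pair the smallest nominal-p eQTL is kept; its
    effect on SBP is tested by a two-sample Wald ratio of expression on SBP
    (first-order SE), and eQTLs with validation p < ``validation_p`` are
    harmonized against the outcome.  eQTL variants absent from the SBP stats
    are dropped with a reason.
    """
    sbp_by_id = {r.variant_id: r for r in sbp_stats}
    best = best_eqtl_per_gene(eqtl_records)
    by_class: dict[str, list[SummaryStatRecord]] = {}
    notes: dict[str, list[str]] = {}
    for e in best:
        notes.setdefault(e.drug_class, [])
        sbp = sbp_by_id.get(e.variant_id)
        if sbp is None:
            notes[e.drug_class].append(f"{e.variant_id}: absent from SBP stats")
            continue
        # expression -> SBP Wald ratio; its z equals beta_sbp/se_sbp
        wald = sbp.beta / e.beta_expression
        wald_se = sbp.se / abs(e.beta_expression)
        p_val = float(2.0 * stats.norm.sf(abs(wald / wald_se)))
        if not p_val < validation_p:
            notes[e.drug_class].append(
                f"{e.variant_id} ({e.target_gene}): failed SBP validation (p={p_val:.3g})"
            )
            continue
        by_class.setdefault(e.drug_class, []).append(sbp)

    out: dict[str, DrugClassInstrumentSet] = {}
    for c in sorted(notes):
        selected = by_class.get(c, [])
        harmonized = harmonize(selected, outcome_stats) if selected else []
        out[c] = DrugClassInstrumentSet(
            drug_class=c, route="eqtl", instruments=harmonized, notes=notes[c]
        )
    return out


def estimate_drug_class_effect(
    instrument_set: DrugClassInstrumentSet,
    estimator: str = "ivw",
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Class effect on the outcome, as OR per 10-mmHg SBP decrease.

    The per-mmHg-increase estimate from the set's instruments is negated
    before the per-10 exponentiation, so SBP lowering through the class's
    targets with a protective effect yields OR < 1.
    """
    keep = retained(instrument_set.instruments)
    if not keep:
        raise EstimationError(
            f"drug class {instrument_set.drug_class} ({instrument_set.route}): "
            "no instruments; effect not assessable"
        )
    if estimator == "ivw":
        est = ivw(keep, random_effects=True)
    elif estimator == "weighted_median":
        est = weighted_median(keep, n_boot=n_boot, seed=seed)
    else:
        raise ConfigError(f"unknown estimator {estimator!r}")
    return flip_exposure_direction(est)
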