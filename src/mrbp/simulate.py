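"""Synthetic paired GWAS summary statistics with known causal structure.

The generator emulates the summary-level structure a two-sample MR analysis
of blood pressure on atrial fibrillation consumes, without individual-level
genotypes: per-variant true exposure effects γ_j (mmHg per allele, phenotype
variance standardized to 1), pleiotropic direct effects α_j on the outcome,
true outcome effects Γ_j = θ·γ_j + α_j (log-odds per allele), and observed
effect estimates drawn around the truth with the closed-form sampling SEs

    se_x = 1/sqrt(2·maf(1−maf)·N_exposure)
    se_y = 1/sqrt(2·maf(1−maf)·N_outcome·φ(1−φ))

(φ the outcome case fraction; the φ(1−φ) factor is the case-control
variance inflation of a log-odds effect).  Participant overlap between the
two GWAS induces a correlation overlap_fraction·sqrt(min(N)/max(N)) between
the exposure and outcome sampling errors of each variant.

Defaults mirror the scale of the published study: N_exposure = 757,601
(ICBP+UK Biobank blood-pressure GWAS), an outcome of 65,446 cases and
522,744 controls (AFGen atrial-fibrillation GWAS), J = 400 instruments, a
causal effect θ = 0.0157 log-odds per mmHg (OR ≈ 1.17 per 10 mmHg), and
γ_j dispersion chosen so the instruments explain ≈4% of exposure variance
(mean per-variant F ≈ 76).

One integer seed drives a hierarchical ``numpy.random.SeedSequence`` scheme
(children: effects, sampling errors, fixtures) so each piece is reproducible
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .drug_targets import EqtlRecord, GeneRegion
from .errors import DomainError
from .summary_data import LdMatrix, SummaryStatRecord, records_from_frame
from scipy import stats

__all__ = [
    "SyntheticStudyConfig",
    "SimulatedStudy",
    "RegionFixture",
    "EqtlFixture",
    "generate_summary_pair",
    "generate_region_fixture",
    "generate_eqtl_fixture",
]

_AF_CASES = 65_446
_AF_CONTROLS = 522_744


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Full parameterization of one simulated exposure/outcome GWAS pair."""

    n_snps: int = 400
    theta: float = 0.0157  # log-odds per mmHg
    pleiotropy_mode: str = "none"  # {"none", "balanced", "directional"}
    pleiotropy_sd: float = 0.002  # log-odds
    pleiotropy_mean: float = 0.001  # log-odds, directional mode only
    gamma_sd: float = 0.015  # mmHg (SD of true exposure effects)
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exposure: int = 757_601
    n_outcome: int = _AF_CASES + _AF_CONTROLS
    case_fraction: float = _AF_CASES / (_AF_CASES + _AF_CONTROLS)
    overlap_fraction: float = 0.0
    ld_block_size: int = 1
    ld_within_r2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise DomainError("maf_range must lie within (0, 0.5]")
        for name in ("case_fraction", "overlap_fraction", "ld_within_r2"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise DomainError(f"{name} must lie in [0, 1]")
        if self.case_fraction in (0.0, 1.0):
            raise DomainError("case_fraction must be strictly inside (0, 1)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise DomainError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.n_snps <= 0 or self.ld_block_size <= 0:
            raise DomainError("n_snps and ld_block_size must be positive")


@dataclass
class SimulatedStudy:
    """Generated exposure/outcome tables, LD matrix, and the truth record."""

    exposure: pd.DataFrame
    outcome: pd.DataFrame
    ld: LdMatrix
    truth: pd.DataFrame
    config: SyntheticStudyConfig

    def exposure_records(self) -> list[SummaryStatRecord]:
        return records_from_frame(self.exposure, trait="SBP_sim").records

    def outcome_records(self) -> list[SummaryStatRecord]:
        return records_from_frame(self.outcome, trait="AF_sim").records

    def write(self, directory: str | Path) -> None:
        """Write the TSV dialect the readers consume, plus LD and truth tables."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, df in (("exposure", self.exposure), ("outcome", self.outcome)):
            out = df.rename(
                columns={
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
            )
            out.to_csv(directory / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
        self.ld.to_file(directory / "ld.tsv")
        self.truth.to_csv(directory / "truth.tsv", sep="\t", index=False, float_format="%.10g")


_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]  # non-palindromic


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, np.nextafter(0, 1), 1.0)


def _positions(n_snps: int, block_size: int) -> tuple[list[str], np.ndarray]:
    """Chromosome labels and positions: 10 kb within-block spacing, blocks 50 Mb
    apart (beyond the 10,000-kb clumping window), four blocks per chromosome."""
    chroms: list[str] = []
    pos = np.empty(n_snps, dtype=int)
    for j in range(n_snps):
        block, offset = divmod(j, block_size)
        chrom = 1 + (block // 4) % 22
        chroms.append(str(chrom))
        pos[j] = 1_000_000 + (block % 4) * 50_000_000 + offset * 10_000
    return chroms, pos


def generate_summary_pair(config: SyntheticStudyConfig) -> SimulatedStudy:
    """Simulate one exposure/outcome summary-statistic pair with known truth."""
    ss = np.random.SeedSequence(config.seed)
    rng_eff, rng_err, _ = (np.random.default_rng(s) for s in ss.spawn(3))
    j = config.n_snps

    maf = rng_eff.uniform(*config.maf_range, size=j)
    gamma = rng_eff.normal(0.0, config.gamma_sd, size=j)
    if config.pleiotropy_mode == "none":
        alpha = np.zeros(j)
    elif config.pleiotropy_mode == "balanced":
        alpha = rng_eff.normal(0.0, config.pleiotropy_sd, size=j)
    else:
        # directional pleiotropy is defined relative to the exposure-raising
        # allele (allele coding is a re-labelling; a fixed mean on arbitrary
        # coding would cancel under re-orientation)
        alpha = np.sign(gamma) * rng_eff.normal(
            config.pleiotropy_mean, config.pleiotropy_sd, size=j
        )
    big_gamma = config.theta * gamma + alpha

    het = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(het * config.n_exposure)
    phi = config.case_fraction
    se_y = 1.0 / np.sqrt(het * config.n_outcome * phi * (1.0 - phi))

    n_min = min(config.n_exposure, config.n_outcome)
    n_max = max(config.n_exposure, config.n_outcome)
    rho = config.overlap_fraction * np.sqrt(n_min / n_max)
    z = rng_err.standard_normal((j, 2))
    eps_x = z[:, 0]
    eps_y = rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1]
    beta_x = gamma + se_x * eps_x
    beta_y = big_gamma + se_y * eps_y

    chroms, pos = _positions(j, config.ld_block_size)
    ids = [f"rs{k + 1:06d}" for k in range(j)]
    ea, oa = zip(*(_ALLELE_PAIRS[k % len(_ALLELE_PAIRS)] for k in range(j)))

    def frame(beta, se, n):
        return pd.DataFrame(
            {
                "variant_id": ids,
                "chromosome": chroms,
                "position": pos,
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": maf,
                "beta": beta,
                "se": se,
                "pvalue": _pvalues(beta, se),
                "n": n,
            }
        )

    r2 = np.zeros((j, j))
    for start in range(0, j, config.ld_block_size):
        end = min(start + config.ld_block_size, j)
        r2[start:end, start:end] = config.ld_within_r2
    np.fill_diagonal(r2, 1.0)
    ld = LdMatrix(variant_ids=tuple(ids), r2=r2, positions=tuple(int(p) for p in pos))

    truth = pd.DataFrame(
        {
            "variant_id": ids,
            "gamma": gamma,
            "alpha": alpha,
            "big_gamma": big_gamma,
            "theta": config.theta,
        }
    )
    return SimulatedStudy(
        exposure=frame(beta_x, se_x, config.n_exposure),
        outcome=frame(beta_y, se_y, config.n_outcome),
        ld=ld,
        truth=truth,
        config=config,
    )


@dataclass
class RegionFixture:
    """A drug-class region catalog with SBP/outcome stats planted inside it."""

    regions: list[GeneRegion]
    sbp: pd.DataFrame
    outcome: pd.DataFrame

    def sbp_records(self) -> list[SummaryStatRecord]:
        return records_from_frame(self.sbp, trait="SBP_sim").records

    def outcome_records(self) -> list[SummaryStatRecord]:
        return records_from_frame(self.outcome, trait="AF_sim").records


def generate_region_fixture(
    classes: dict[str, list[str]],
    snps_per_gene: int = 3,
    effect_enrichment: float = 1.0,
    theta: float = 0.0157,
    n_exposure: int = 757_601,
    n_outcome: int = _AF_CASES + _AF_CONTROLS,
    case_fraction: float = _AF_CASES / (_AF_CASES + _AF_CONTROLS),
    n_null_outside: int = 5,
    seed: int = 0,
) -> RegionFixture:
    """Build a gene-region catalog plus consistent summary statistics.

    ``classes`` maps drug-class labels to gene symbols; a symbol shared by
    two classes yields overlapping regions (and variants retained in both).
    round(effect_enrichment × snps_per_gene) variants per gene are planted at
    genome-wide significance (|z| = 8); the rest, and ``n_null_outside``
    out-of-region variants, are null.  Outcome effects follow Γ = θ·γ.
    """
    if not (0.0 <= effect_enrichment <= 1.0):
        raise DomainError("effect_enrichment must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    regions: list[GeneRegion] = []
    rows: list[dict] = []
    gene_span = 10_000
    gene_coords: dict[str, tuple[str, int]] = {}
    next_start = 1_000_000
    chrom = "2"
    n_sig = round(effect_enrichment * snps_per_gene)
    vid = 0
    phi = case_fraction

    def add_variant(pos: int, significant: bool):
        nonlocal vid
        vid += 1
        maf = float(rng.uniform(0.1, 0.5))
        het = 2.0 * maf * (1.0 - maf)
        se_x = 1.0 / np.sqrt(het * n_exposure)
        se_y = 1.0 / np.sqrt(het * n_outcome * phi * (1.0 - phi))
        z = 8.0 * np.sign(rng.standard_normal()) if significant else rng.normal(0, 0.5)
        gamma = float(z * se_x)
        beta_y = float(theta * gamma + se_y * rng.normal(0, 0.2))
        rows.append(
            {
                "variant_id": f"rsdt{vid:05d}",
                "chromosome": chrom,
                "position": pos,
                "effect_allele": "A",
                "other_allele": "G",
                "eaf": maf,
                "beta": gamma,
                "se": se_x,
                "pvalue": float(_pvalues(np.array([gamma]), np.array([se_x]))[0]),
                "n": n_exposure,
                "beta_y": beta_y,
                "se_y": se_y,
            }
        )

    for drug_class, genes in classes.items():
        for gene in genes:
            if gene not in gene_coords:
                gene_coords[gene] = (chrom, next_start)
                start = next_start
                next_start += 20_000_000  # far beyond the clumping window
                spacing = gene_span // (snps_per_gene + 1)
                for s in range(snps_per_gene):
                    add_variant(start + (s + 1) * spacing, significant=s < n_sig)
            start = gene_coords[gene][1]
            regions.append(
                GeneRegion(
                    gene_symbol=gene,
                    drug_class=drug_class,
                    chromosome=gene_coords[gene][0],
                    start=start,
                    end=start + gene_span,
                    element_type="gene_body",
                )
            )
    for _ in range(n_null_outside):
        add_variant(next_start, significant=False)
        next_start += 20_000_000

    df = pd.DataFrame(rows)
    sbp = df.drop(columns=["beta_y", "se_y"])
    outcome = df.assign(
        beta=df["beta_y"],
        se=df["se_y"],
        pvalue=_pvalues(df["beta_y"].to_numpy(), df["se_y"].to_numpy()),
        n=n_outcome,
    ).drop(columns=["beta_y", "se_y"])
    return RegionFixture(regions=regions, sbp=sbp, outcome=outcome)


@dataclass
class EqtlFixture:
    """An eQTL catalog with planted expression→SBP validation structure."""

    eqtls: list[EqtlRecord]
    sbp: pd.DataFrame
    outcome: pd.DataFrame

    def sbp_records(self) -> list[SummaryStatRecord]:
        return records_from_frame(self.sbp, trait="SBP_sim").records

    def outcome_records(self) -> list[SummaryStatRecord]:
        return records_from_frame(self.outcome, trait="AF_sim").records


def generate_eqtl_fixture(
    n_genes: int,
    frac_validating: float,
    seed: int = 0,
    classes: tuple[str, ...] = ("CCB", "BB"),
    theta: float = 0.0157,
    n_exposure: int = 757_601,
    n_outcome: int = _AF_CASES + _AF_CONTROLS,
    case_fraction: float = _AF_CASES / (_AF_CASES + _AF_CONTROLS),
) -> EqtlFixture:
    """eQTL catalog where exactly round(frac_validating·n_genes) genes have a
    best eQTL whose expression→SBP Wald test passes p < 0.05 by construction
    (|z_SBP| = 8 for validating genes, 0.5 otherwise)."""
    if not (0.0 <= frac_validating <= 1.0):
        raise DomainError("frac_validating must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
    n_valid = round(frac_validating * n_genes)
    eqtls: list[EqtlRecord] = []
    rows: list[dict] = []
    phi = case_fraction
    for g in range(n_genes):
        vid = f"rseq{g + 1:05d}"
        maf = float(rng.uniform(0.1, 0.5))
        het = 2.0 * maf * (1.0 - maf)
        se_x = 1.0 / np.sqrt(het * n_exposure)
        se_y = 1.0 / np.sqrt(het * n_outcome * phi * (1.0 - phi))
        z = 8.0 if g < n_valid else 0.5
        gamma = float(z * se_x * np.sign(rng.standard_normal()))
        beta_y = float(theta * gamma + se_y * rng.normal(0, 0.2))
        rows.append(
            {
                "variant_id": vid,
                "chromosome": "3",
                "position": 1_000_000 + g * 20_000_000,
                "effect_allele": "A",
                "other_allele": "G",
                "eaf": maf,
                "beta": gamma,
                "se": se_x,
                "pvalue": float(_pvalues(np.array([gamma]), np.array([se_x]))[0]),
                "n": n_exposure,
                "beta_y": beta_y,
                "se_y": se_y,
            }
        )
        eqtls.append(
            EqtlRecord(
                variant_id=vid,
                target_gene=f"GENE{g + 1}",
                tissue="Artery_Tibial",
                beta_expression=float(rng.uniform(0.2, 0.8) * np.sign(rng.standard_normal())),
                se_expression=0.05,
                pvalue_nominal=1e-12,
                drug_class=classes[g % len(classes)],
            )
        )
    df = pd.DataFrame(rows)
    sbp = df.drop(columns=["beta_y", "se_y"])
    outcome = df.assign(
        beta=df["beta_y"],
        se=df["se_y"],
        pvalue=_pvalues(df["beta_y"].to_numpy(), df["se_y"].to_numpy()),
        n=n_outcome,
    ).drop(columns=["beta_y", "se_y"])
    return EqtlFixture(eqtls=eqtls, sbp=sbp, outcome=outcome)
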