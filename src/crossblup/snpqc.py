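"""Marker and individual quality control, and missing-genotype imputation.

Filters mirror standard SNP-chip practice for multi-population pig data:
SNPs are dropped for call rate < 0.95, minor allele frequency < 0.01, a
Hardy-Weinberg goodness-of-fit chi-square above 600 (an extreme threshold
that only removes gross genotyping artifacts, so pooling lines despite the
Wahlund effect is immaterial), or residence on excluded chromosomes (X, Y,
unmapped); individuals are dropped when more than 5% of their genotypes are
missing.  Remaining missing genotypes are imputed either with the mean
dosage 2p or by sampling Hardy-Weinberg genotypes at p, with p estimated
within the animal's line by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import DataError, GenotypeMatrix

DEFAULT_EXCLUDE_CHROMS = frozenset({"X", "Y", "unmapped"})


@dataclass
class QCReport:
    """Per-filter removal counts plus per-SNP and per-animal diagnostics."""

    n_snps_in: int = 0
    n_snps_out: int = 0
    n_animals_in: int = 0
    n_animals_out: int = 0
    snp_removed_by: dict = field(default_factory=dict)  # filter -> count (non-exclusive)
    n_snps_removed: int = 0
    n_animals_removed: int = 0
    thresholds: dict = field(default_factory=dict)
    snp_stats: pd.DataFrame | None = None
    animal_stats: pd.DataFrame | None = None
    log: list = field(default_factory=list)

    def check_conservation(self) -> None:
        assert self.n_snps_removed + self.n_snps_out == self.n_snps_in
        assert self.n_animals_removed + self.n_animals_out == self.n_animals_in


def hwe_chi2(dosages: np.ndarray) -> np.ndarray:
    """1-df Hardy-Weinberg goodness-of-fit chi-square per SNP.

    Sum over the three genotype classes of (obs-exp)^2/exp, with expected
    counts from the observed allele frequency and the non-missing call count.
    Monomorphic SNPs (expected het = 0) return 0.
    """
    obs0 = np.nansum(dosages == 0, axis=0).astype(float)
    obs1 = np.nansum(dosages == 1, axis=0).astype(float)
    obs2 = np.nansum(dosages == 2, axis=0).astype(float)
    n = obs0 + obs1 + obs2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * obs2 + obs1) / (2 * n)
        exp = np.stack([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
        obs = np.stack([obs0, obs1, obs2])
        terms = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
        chi2 = terms.sum(axis=0)
    chi2[n == 0] = 0.0
    return chi2


def snp_stats(g: GenotypeMatrix, per_line: bool = False) -> pd.DataFrame:
    miss = g.missing_mask
    call_rate = 1.0 - miss.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(g.dosages, axis=0) / 2.0
    p = np.where(np.isnan(p), 0.0, p)
    maf = np.minimum(p, 1.0 - p)
    df = pd.DataFrame(
        {
            "snp": g.snp_ids,
            "chrom": g.chrom,
            "call_rate": call_rate,
            "freq": p,
            "maf": maf,
            "hwe_chi2": hwe_chi2(g.dosages),
        }
    )
    if per_line and g.lines is not None:
        for lab in pd.unique(pd.Series(g.lines)):
            df[f"hwe_chi2_{lab}"] = hwe_chi2(g.dosages[g.lines == lab])
    return df


def snp_filters(
    g: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
    hwe_chi2_max: float = 600.0,
    exclude_chroms=DEFAULT_EXCLUDE_CHROMS,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs failing call rate, MAF, HWE, or chromosome exclusion.

    A SNP is removed when call_rate < call_rate_min OR maf < maf_min OR
    HWE chi2 > hwe_chi2_max OR its chromosome is excluded (strict
    inequalities on the thresholds, so exactly attained values are kept).
    """
    if g.n_snps == 0 or g.n_animals == 0:
        raise DataError("empty genotype matrix")
    stats = snp_stats(g, per_line=g.lines is not None)
    fail_cr = stats["call_rate"].to_numpy() < call_rate_min
    fail_maf = stats["maf"].to_numpy() < maf_min
    fail_hwe = stats["hwe_chi2"].to_numpy() > hwe_chi2_max
    fail_chr = np.isin(np.asarray(g.chrom, dtype=object), list(exclude_chroms))
    removed = fail_cr | fail_maf | fail_hwe | fail_chr
    if removed.all():
        raise DataError("every SNP fails QC; review thresholds")
    stats["removed"] = removed
    keep = [s for s, r in zip(g.snp_ids, removed) if not r]
    report = QCReport(
        n_snps_in=g.n_snps,
        n_snps_out=len(keep),
        n_animals_in=g.n_animals,
        n_animals_out=g.n_animals,
        snp_removed_by={
            "call_rate": int(fail_cr.sum()),
            "maf": int(fail_maf.sum()),
            "hwe": int(fail_hwe.sum()),
            "chromosome": int(fail_chr.sum()),
        },
        n_snps_removed=int(removed.sum()),
        thresholds={
            "call_rate_min": call_rate_min,
            "maf_min": maf_min,
            "hwe_chi2_max": hwe_chi2_max,
            "exclude_chroms": sorted(exclude_chroms),
        },
        snp_stats=stats,
        log=[f"SNP filters removed {int(removed.sum())} of {g.n_snps} SNPs"],
    )
    report.check_conservation()
    return g.subset(snps=keep), report


def individual_filter(
    g: GenotypeMatrix, missing_max: float = 0.05
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove animals whose missing-genotype fraction exceeds missing_max.

    Strict inequality: an animal at exactly the threshold is retained.
    """
    if g.n_snps == 0 or g.n_animals == 0:
        raise DataError("empty genotype matrix")
    miss = g.missing_mask.mean(axis=1)
    removed = miss > missing_max
    if removed.all():
        raise DataError("every animal fails the missingness filter")
    keep = [a for a, r in zip(g.animal_ids, removed) if not r]
    report = QCReport(
        n_snps_in=g.n_snps,
        n_snps_out=g.n_snps,
        n_animals_in=g.n_animals,
        n_animals_out=len(keep),
        n_animals_removed=int(removed.sum()),
        thresholds={"missing_max": missing_max},
        animal_stats=pd.DataFrame(
            {"animal": g.animal_ids, "missing_rate": miss, "removed": removed}
        ),
        log=[f"individual filter removed {int(removed.sum())} of {g.n_animals} animals"],
    )
    report.check_conservation()
    return g.subset(animals=keep), report


def impute_missing(
    g: GenotypeMatrix,
    mode: str = "mean",
    per_line: bool = True,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Fill missing dosages from estimated allele frequencies.

    mode="mean" fills 2p (real-valued); mode="draw" samples {0,1,2} from
    Hardy-Weinberg proportions at p.  p is the observed frequency within the
    animal's line when per_line is set (the default for line-structured
    data), else pooled over all animals.
    """
    if mode not in ("mean", "draw"):
        raise DataError(f"unknown imputation mode {mode!r}")
    X = g.dosages.copy()
    if not np.isnan(X).any():
        return g
    rng = np.random.default_rng(seed)
    groups: list[np.ndarray]
    if per_line and g.lines is not None:
        groups = [np.flatnonzero(g.lines == lab) for lab in pd.unique(pd.Series(g.lines))]
    else:
        groups = [np.arange(g.n_animals)]
    for rows in groups:
        block = X[rows]
        miss = np.isnan(block)
        if not miss.any():
            continue
        all_missing = miss.all(axis=0) & np.isnan(X).all(axis=0)
        if all_missing.any():
            bad = g.snp_ids[np.flatnonzero(all_missing)][:5]
            raise DataError(f"SNPs with no observed calls cannot be imputed: {list(bad)}")
        with np.errstate(invalid="ignore"):
            p = np.nanmean(block, axis=0) / 2.0
        # a line may have a fully missing column; borrow the pooled frequency
        pooled = np.nanmean(X, axis=0) / 2.0
        p = np.where(np.isnan(p), pooled, p)
        if mode == "mean":
            fill = np.broadcast_to(2.0 * p, block.shape)
            block[miss] = fill[miss]
        else:
            draws = rng.binomial(2, np.broadcast_to(p, block.shape).clip(0, 1)).astype(float)
            block[miss] = draws[miss]
        X[rows] = block
    out = GenotypeMatrix(
        dosages=X,
        animal_ids=g.animal_ids,
        snp_ids=g.snp_ids,
        lines=g.lines,
        chrom=g.chrom,
        pos=g.pos,
    )
    return out


def qc_pipeline(
    g: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
    hwe_chi2_max: float = 600.0,
    exclude_chroms=DEFAULT_EXCLUDE_CHROMS,
    missing_max: float = 0.05,
    impute_mode: str = "mean",
    per_line: bool = True,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """SNP filters, then individual filter, then imputation (single pass).

    Filter order is logged explicitly; the SNP call rate is not re-checked
    after animal removal.
    """
    g1, rep1 = snp_filters(g, call_rate_min, maf_min, hwe_chi2_max, exclude_chroms)
    g2, rep2 = individual_filter(g1, missing_max)
    g3 = impute_missing(g2, mode=impute_mode, per_line=per_line, seed=seed)
    report = QCReport(
        n_snps_in=g.n_snps,
        n_snps_out=g3.n_snps,
        n_animals_in=g.n_animals,
        n_animals_out=g3.n_animals,
        snp_removed_by=rep1.snp_removed_by,
        n_snps_removed=rep1.n_snps_removed,
        n_animals_removed=rep2.n_animals_removed,
        thresholds={**rep1.thresholds, **rep2.thresholds, "impute_mode": impute_mode},
        snp_stats=rep1.snp_stats,
        animal_stats=rep2.animal_stats,
        log=rep1.log + rep2.log + ["order: SNP filters -> individual filter -> imputation"],
    )
    report.check_conservation()
    return g3, report
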