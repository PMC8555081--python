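"""SNP and individual quality control.

Filter order (deterministic): individuals with missing rate above the
threshold are removed first; SNP statistics are then computed on the
retained individuals and SNPs are dropped sequentially by call rate, MAF,
and HWE.  Residual missing dosages are mean-imputed per SNP (replacing the
imputation step of a full pipeline) and flagged in the report.

Boundary semantics: keep MAF >= maf_min; keep SNP missing rate <
snp_missing_max; keep HWE p >= hwe_p_min; remove individuals with missing
rate > ind_missing_max.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix

__all__ = ["QCReport", "EmptyPanelError", "allele_stats", "hwe_test", "apply_filters"]


class EmptyPanelError(ValueError):
    """All SNPs (or all individuals) were removed by filtering."""


@dataclass
class QCReport:
    n_snps_in: int
    n_individuals_in: int
    removed_snps: dict = field(default_factory=dict)  # filter name -> count
    removed_individuals: dict = field(default_factory=dict)
    snp_stats: pd.DataFrame | None = None  # per-SNP maf, call_rate, hwe_p
    n_imputed_calls: int = 0
    thresholds: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    @property
    def n_snps_out(self) -> int:
        return self.n_snps_in - sum(self.removed_snps.values())

    @property
    def n_individuals_out(self) -> int:
        return self.n_individuals_in - sum(self.removed_individuals.values())

    def to_json(self) -> str:
        payload = {
            "n_snps_in": self.n_snps_in,
            "n_snps_out": self.n_snps_out,
            "n_individuals_in": self.n_individuals_in,
            "n_individuals_out": self.n_individuals_out,
            "removed_snps": self.removed_snps,
            "removed_individuals": self.removed_individuals,
            "n_imputed_calls": self.n_imputed_calls,
            "thresholds": self.thresholds,
            "notes": self.notes,
        }
        return json.dumps(payload, indent=2)


def allele_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP ALT frequency, MAF, call rate and genotype counts.

    Computed over non-missing integer calls only; fractional (imputed)
    entries are excluded from genotype counts but included in call rate.
    """
    if g.n_snps == 0 or g.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    d = g.dosages
    called = ~np.isnan(d)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        alt_freq = np.nansum(d, axis=0) / (2.0 * n_called)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    is_int = called & np.isin(d, [0.0, 1.0, 2.0])
    n_aa = (is_int & (d == 0.0)).sum(axis=0)
    n_ab = (is_int & (d == 1.0)).sum(axis=0)
    n_bb = (is_int & (d == 2.0)).sum(axis=0)
    return pd.DataFrame(
        {
            "snp": g.snp_map["snp"].to_numpy(),
            "alt_freq": alt_freq,
            "maf": maf,
            "call_rate": n_called / g.n_individuals,
            "n_aa": n_aa,
            "n_ab": n_ab,
            "n_bb": n_bb,
        }
    )


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square goodness-of-fit p-value against Hardy-Weinberg.

    Expected genotype counts come from the observed allele frequency;
    no continuity correction.  Monomorphic sites return p = 1.
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("zero total genotype count")
    p = (2 * n_bb + n_ab) / (2 * n)
    q = 1.0 - p
    expected = n * np.array([q * q, 2 * p * q, p * p])
    if p == 0.0 or q == 0.0:
        return 1.0
    chi2 = ((counts - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(chi2, df=1))


def hwe_pvalues(stat: pd.DataFrame) -> np.ndarray:
    """Vectorized HWE p-values for an allele_stats frame."""
    n_aa = stat["n_aa"].to_numpy(float)
    n_ab = stat["n_ab"].to_numpy(float)
    n_bb = stat["n_bb"].to_numpy(float)
    n = n_aa + n_ab + n_bb
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n_bb + n_ab) / (2 * n)
        q = 1.0 - p
        e_aa, e_ab, e_bb = n * q * q, 2 * n * p * q, n * p * p
        chi2 = (
            (n_aa - e_aa) ** 2 / e_aa
            + (n_ab - e_ab) ** 2 / e_ab
            + (n_bb - e_bb) ** 2 / e_bb
        )
    pvals = stats.chi2.sf(chi2, df=1)
    pvals[~np.isfinite(chi2)] = 1.0  # monomorphic or empty
    return pvals


def apply_filters(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    snp_missing_max: float = 0.60,
    ind_missing_max: float = 0.30,
    hwe_p_min: float = 1e-4,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the standard QC cascade and mean-impute residual missingness."""
    for name, v in (
        ("maf_min", maf_min),
        ("snp_missing_max", snp_missing_max),
        ("ind_missing_max", ind_missing_max),
        ("hwe_p_min", hwe_p_min),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {v}")

    report = QCReport(
        n_snps_in=g.n_snps,
        n_individuals_in=g.n_individuals,
        thresholds={
            "maf_min": maf_min,
            "snp_missing_max": snp_missing_max,
            "ind_missing_max": ind_missing_max,
            "hwe_p_min": hwe_p_min,
        },
        notes=[
            "individuals filtered before SNP statistics",
            "keep MAF >= maf_min; keep SNP missing < snp_missing_max; "
            "keep HWE p >= hwe_p_min; remove individuals with missing > ind_missing_max",
        ],
    )

    ind_missing = np.isnan(g.dosages).mean(axis=1)
    keep_ind = ind_missing <= ind_missing_max
    report.removed_individuals["missing_rate"] = int((~keep_ind).sum())
    if not keep_ind.any():
        raise EmptyPanelError("all individuals removed by missing-rate filter")
    g = g.subset(individuals=np.flatnonzero(keep_ind))

    stat = allele_stats(g)
    stat["hwe_p"] = hwe_pvalues(stat)
    report.snp_stats = stat

    keep = np.ones(g.n_snps, dtype=bool)
    # "missing < max" => keep; boundary equality fails the filter
    fail_call = (1.0 - stat["call_rate"].to_numpy()) >= snp_missing_max
    report.removed_snps["missing_rate"] = int((fail_call & keep).sum())
    keep &= ~fail_call
    fail_maf = stat["maf"].to_numpy() < maf_min
    report.removed_snps["maf"] = int((fail_maf & keep).sum())
    keep &= ~fail_maf
    fail_hwe = stat["hwe_p"].to_numpy() < hwe_p_min
    report.removed_snps["hwe"] = int((fail_hwe & keep).sum())
    keep &= ~fail_hwe

    if not keep.any():
        raise EmptyPanelError("all SNPs removed by QC filters")
    g = g.subset(snps=np.flatnonzero(keep))

    d = g.dosages.astype(np.float64)
    missing = np.isnan(d)
    report.n_imputed_calls = int(missing.sum())
    if report.n_imputed_calls:
        col_means = np.nanmean(d, axis=0)
        d[missing] = np.broadcast_to(col_means, d.shape)[missing]
        report.notes.append("residual missing dosages mean-imputed per SNP")
        g = GenotypeMatrix(d.astype(np.float32), list(g.sample_ids), g.snp_map.copy(), imputed=True)
    return g, report
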