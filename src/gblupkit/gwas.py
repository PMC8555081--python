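"""Single-SNP mixed-linear-model association and LD utilities.

The association test is the standard two-step approximation: variance
components are fitted once under the null model (polygenic kernel, no SNP),
the phenotypic covariance is frozen, and each SNP is then tested by
generalized least squares in the eigenbasis of the kernel — a Wald
chi-square on the SNP fixed effect.  The tested SNP stays in the kernel
(no leave-one-chromosome-out).

LD is the squared Pearson correlation between unphased dosage vectors
(composite LD).  QTL intervals extend from the lead SNP while r^2 with the
lead stays >= the cutoff; pruning is greedy and windowed, dropping the
later-positioned SNP of every over-threshold pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .genio import GenotypeMatrix
from .kinship import RelationshipMatrix
from .varcomp import VarianceComponents, fit_reml, make_spec

__all__ = [
    "AssociationResult",
    "QTLInterval",
    "mlm_assoc",
    "bonferroni_threshold",
    "ld_r2",
    "define_qtl_interval",
    "ld_prune",
]


@dataclass
class AssociationResult:
    """Per-SNP effect, SE and Wald p-value plus the null-model metadata."""

    table: pd.DataFrame  # snp chrom pos beta se p flag
    vc: VarianceComponents
    metadata: dict = field(default_factory=dict)

    def significant(self, threshold: float) -> pd.DataFrame:
        return self.table[self.table["p"] < threshold]

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class QTLInterval:
    """Closed 1-based interval [start_bp, end_bp] around a lead SNP."""

    chrom: str
    start_bp: int
    end_bp: int
    lead_snp: str
    lead_p: float
    member_snps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("interval start after end")

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == str(chrom) and self.start_bp <= pos <= self.end_bp


def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Genome-wide per-test threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if m_tests < 1:
        raise ValueError(f"m_tests must be >= 1, got {m_tests}")
    return alpha / m_tests


def mlm_assoc(
    g: GenotypeMatrix,
    pheno: pd.DataFrame,
    trait: str,
    G: RelationshipMatrix,
    vc: VarianceComponents | None = None,
) -> AssociationResult:
    """Mixed-linear-model GWAS of one trait over the whole panel.

    ``pheno`` rows are matched to ``G`` ids; individuals missing the trait
    are dropped.  If ``vc`` is given the null fit is skipped and those
    components are reused.
    """
    spec = make_spec(pheno, trait, [G], kernel_names=["polygenic"])
    if vc is None:
        vc = fit_reml(spec)
    ids = spec.obs_ids
    H = spec.kernels[0].obs_matrix()
    w, U = linalg.eigh(H)
    v = vc.sigma2[0] * np.clip(w, 0.0, None) + vc.sigma2_e
    sw = 1.0 / np.sqrt(v)

    yw = (U.T @ spec.y) * sw
    Xw = (U.T @ spec.X) * sw[:, None]

    row_of = {s: i for i, s in enumerate(g.sample_ids)}
    try:
        rows = np.array([row_of[i] for i in ids])
    except KeyError as exc:
        raise KeyError(f"phenotyped id missing from genotype matrix: {exc}") from exc
    S = g.dosages[rows, :].astype(np.float64)
    if np.isnan(S).any():
        raise ValueError("association requires complete dosages (run QC first)")
    Sw = (U.T @ S) * sw[:, None]

    # residualize on the fixed effects
    Q, _ = linalg.qr(Xw, mode="economic")
    yr = yw - Q @ (Q.T @ yw)
    Sr = Sw - Q @ (Q.T @ Sw)

    ss = np.einsum("ij,ij->j", Sr, Sr)
    sy = Sr.T @ yr
    mono = ss <= 1e-10 * max(1.0, float(ss.max(initial=0.0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(mono, 0.0, sy / ss)
        se = np.where(mono, np.nan, 1.0 / np.sqrt(ss))
        chi2 = np.where(mono, 0.0, beta * beta * ss)
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(mono, 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            "snp": g.snp_map["snp"].to_numpy(),
            "chrom": g.snp_map["chrom"].to_numpy(),
            "pos": g.snp_map["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "p": p,
            "flag": np.where(mono, "monomorphic", ""),
        }
    )
    return AssociationResult(
        table=table,
        vc=vc,
        metadata={
            "trait": trait,
            "n": len(ids),
            "two_step": True,
            "kernel_includes_tested_snp": True,
        },
    )


def ld_r2(
    g: GenotypeMatrix,
    focal_snp: str,
    window_kb: float = 20_000,
    max_snps: int = 15_000,
) -> pd.DataFrame:
    """r^2 between the focal SNP and every panel SNP within the window.

    The window is ``window_kb`` kilobases either side on the same
    chromosome, capped at ``max_snps`` markers of separation.  Returns a
    frame (snp, pos, r2) including the focal SNP itself (r2 = 1).
    """
    j = int(g.snp_indices([focal_snp])[0])
    smap = g.snp_map
    chrom = smap["chrom"].iloc[j]
    pos = int(smap["pos"].iloc[j])
    on_c = np.flatnonzero(smap["chrom"].to_numpy() == chrom)
    near = on_c[
        (np.abs(smap["pos"].to_numpy()[on_c] - pos) <= window_kb * 1000)
        & (np.abs(on_c - j) <= max_snps)
    ]
    d = g.dosages[:, near].astype(np.float64)
    focal = g.dosages[:, j].astype(np.float64)
    dc = d - d.mean(axis=0)
    fc = focal - focal.mean()
    denom = np.sqrt((dc**2).sum(axis=0) * (fc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (dc.T @ fc) / denom
    r2 = np.where(denom > 0, r**2, 0.0)
    r2[near == j] = 1.0
    return pd.DataFrame(
        {"snp": smap["snp"].to_numpy()[near], "pos": smap["pos"].to_numpy()[near], "r2": r2}
    )


def define_qtl_interval(
    assoc: AssociationResult,
    g: GenotypeMatrix,
    threshold: float,
    r2_cutoff: float = 0.2,
    window_kb: float = 20_000,
    max_snps: int = 15_000,
) -> list[QTLInterval]:
    """LD-delimited QTL intervals around each significant lead SNP.

    Per chromosome the most significant unassigned SNP seeds an interval
    extended marker-by-marker while r^2 with the lead stays >= the cutoff;
    the boundary is the last marker above the cutoff (closed interval).
    Overlapping intervals on a chromosome are merged; the output is sorted.
    """
    tab = assoc.table
    sig = tab[tab["p"] < threshold].copy()
    if sig.empty:
        return []
    intervals: list[QTLInterval] = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        pending = grp.sort_values(["p", "pos"]).copy()
        chrom_intervals: list[QTLInterval] = []
        while not pending.empty:
            lead = pending.iloc[0]
            ld = ld_r2(g, lead["snp"], window_kb=window_kb, max_snps=max_snps)
            ld = ld.sort_values("pos").reset_index(drop=True)
            li = int(np.flatnonzero(ld["snp"].to_numpy() == lead["snp"])[0])
            lo = li
            while lo - 1 >= 0 and ld["r2"].iloc[lo - 1] >= r2_cutoff:
                lo -= 1
            hi = li
            while hi + 1 < len(ld) and ld["r2"].iloc[hi + 1] >= r2_cutoff:
                hi += 1
            start, end = int(ld["pos"].iloc[lo]), int(ld["pos"].iloc[hi])
            members = grp[(grp["pos"] >= start) & (grp["pos"] <= end)]
            chrom_intervals.append(
                QTLInterval(
                    chrom=str(chrom),
                    start_bp=start,
                    end_bp=end,
                    lead_snp=str(lead["snp"]),
                    lead_p=float(lead["p"]),
                    member_snps=members["snp"].tolist(),
                )
            )
            pending = pending[(pending["pos"] < start) | (pending["pos"] > end)]
        # merge overlaps, strongest lead wins
        chrom_intervals.sort(key=lambda iv: iv.start_bp)
        merged: list[QTLInterval] = []
        for iv in chrom_intervals:
            if merged and iv.start_bp <= merged[-1].end_bp:
                prev = merged[-1]
                best = iv if iv.lead_p < prev.lead_p else prev
                merged[-1] = QTLInterval(
                    chrom=prev.chrom,
                    start_bp=min(prev.start_bp, iv.start_bp),
                    end_bp=max(prev.end_bp, iv.end_bp),
                    lead_snp=best.lead_snp,
                    lead_p=best.lead_p,
                    member_snps=sorted(set(prev.member_snps) | set(iv.member_snps)),
                )
            else:
                merged.append(iv)
        intervals.extend(merged)
    intervals.sort(key=lambda iv: (int(iv.chrom) if iv.chrom.isdigit() else iv.chrom, iv.start_bp))
    return intervals


def ld_prune(
    g: GenotypeMatrix,
    r2_max: float = 0.9,
    window: int = 50,
    step: int = 5,
) -> list[str]:
    """Greedy windowed LD pruning; returns the retained SNP ids.

    Within each sliding window (``window`` markers, advanced by ``step``),
    every remaining pair with r^2 > ``r2_max`` loses its later-positioned
    member.  Pruning the retained set again is a no-op.
    """
    if np.isnan(g.dosages).any():
        raise ValueError("pruning requires complete dosages")
    keep = np.ones(g.n_snps, dtype=bool)
    smap = g.snp_map
    d = g.dosages.astype(np.float64)
    for chrom in smap["chrom"].unique():
        cols = np.flatnonzero(smap["chrom"].to_numpy() == chrom)
        for start in range(0, len(cols), step):
            win = cols[start : start + window]
            alive = win[keep[win]]
            if alive.size < 2:
                continue
            block = d[:, alive]
            bc = block - block.mean(axis=0)
            sd = bc.std(axis=0)
            sd[sd == 0] = np.inf  # monomorphic: correlates with nothing
            corr = (bc / sd).T @ (bc / sd) / block.shape[0]
            r2 = corr**2
            local_keep = np.ones(alive.size, dtype=bool)
            for a in range(alive.size):
                if not local_keep[a]:
                    continue
                for b in range(a + 1, alive.size):
                    if local_keep[b] and r2[a, b] > r2_max:
                        local_keep[b] = False
            keep[alive[~local_keep]] = False
            if start + window >= len(cols):
                break
    return smap["snp"].to_numpy()[keep].tolist()
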