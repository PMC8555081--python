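"""QTL contribution analyses.

Three procedures quantify how much a QTL (or a ranked SNP set) contributes
to heritability and prediction accuracy:

* ``reduced_model_contribution`` — refit with the interval's significant
  SNPs as fixed covariates and compare to the full genomic model:
  C(H2) = (h2 - h2_i) / h2 and C(R) = (R - R_i) / R.
* ``gfblup_partition_contribution`` — split the panel into the significant
  set and the rest, fit both kernels jointly:
  C(H2) = h2_qtl / (h2_qtl + h2_snp), C(R) = (R - R_s) / R with R_s the
  accuracy of the remainder-only model.
* ``top_snp_removal_curve`` — LD-prune the panel, rank the tagged SNPs by a
  reference-only GWAS per fold, drop the top fraction, rebuild the GRM and
  re-evaluate: C(R) = (r - r_f) / r, C(H2) = (h2 - h2_f) / h2.

For all three, the change in inflation is
C(Inflation) = |inflation_reduced - 1| - |inflation_full - 1|.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evalx import CVPlan, DataBundle, cv_run
from .gwas import QTLInterval, mlm_assoc
from .kinship import compute_grm, compute_grm_pair
from .varcomp import fit_reml, heritability, make_spec

__all__ = [
    "ContributionReport",
    "reduced_model_contribution",
    "gfblup_partition_contribution",
    "top_snp_removal_curve",
]


@dataclass
class ContributionReport:
    method: str  # reduced_model | gfblup_partition | top_snp_removal
    rows: pd.DataFrame
    full_metrics: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "rows": self.rows.to_dict(orient="records"),
                "full_metrics": self.full_metrics,
                "notes": self.notes,
            },
            indent=2,
            default=float,
        )

    @classmethod
    def from_json(cls, text: str) -> "ContributionReport":
        d = json.loads(text)
        return cls(
            method=d["method"],
            rows=pd.DataFrame(d["rows"]),
            full_metrics=d["full_metrics"],
            notes=d.get("notes", []),
        )

    def write_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _c_inflation(infl_reduced: float, infl_full: float) -> float:
    return abs(infl_reduced - 1.0) - abs(infl_full - 1.0)


def _dedup_collinear(cols: np.ndarray) -> tuple[np.ndarray, int]:
    """Greedily keep columns that increase rank; order (position) preserved.

    Returns (kept column indices, number dropped).
    """
    kept: list[int] = []
    basis: np.ndarray | None = None
    n_drop = 0
    for j in range(cols.shape[1]):
        v = cols[:, j]
        if basis is None:
            if np.std(v) > 0:
                kept.append(j)
                basis = v[:, None] / np.linalg.norm(v)
            else:
                n_drop += 1
            continue
        r = v - basis @ (basis.T @ v)
        if np.linalg.norm(r) > 1e-8 * max(1.0, np.linalg.norm(v)):
            kept.append(j)
            basis = np.column_stack([basis, r / np.linalg.norm(r)])
        else:
            n_drop += 1
    return np.array(kept, dtype=int), n_drop


def _cohort_h2(bundle: DataBundle, kernels, covariates=None, kernel_names=None):
    """REML heritability on the bundle's full cohort (all phenotyped ids in kernels)."""
    spec = make_spec(
        bundle.pheno.reset_index(drop=True),
        bundle.trait,
        kernels,
        covariates=covariates,
        kernel_names=kernel_names,
    )
    vc = fit_reml(spec)
    return vc, heritability(vc)


def reduced_model_contribution(
    intervals: list[QTLInterval],
    bundle: DataBundle,
    plan: CVPlan,
) -> ContributionReport:
    """Full-vs-reduced GBLUP contribution of each QTL interval.

    The reduced model for interval i fits that interval's significant SNPs
    as fixed covariates (jointly) while keeping the full GRM as the random
    effect.  Perfectly collinear significant SNPs are dropped
    (later-positioned first) with a note.
    """
    if bundle.genotypes is None:
        raise ValueError("bundle.genotypes required for the reduced model")
    g = bundle.genotypes
    vc_full, h2_full = _cohort_h2(bundle, [bundle.G])
    cv_full = cv_run("gblup", plan, bundle)

    notes: list[str] = []
    rows = []
    pheno_ids = bundle.pheno["id"].astype(str).to_numpy()
    row_of = {s: i for i, s in enumerate(g.sample_ids)}
    g_rows = np.array([row_of[i] for i in pheno_ids])
    for iv in intervals:
        label = f"{iv.chrom}:{iv.start_bp}-{iv.end_bp}"
        if not iv.member_snps:
            rows.append(
                {
                    "target": label,
                    "c_h2": 0.0,
                    "c_r_obs": 0.0,
                    "c_r_theo": 0.0,
                    "c_inflation": 0.0,
                    "h2_reduced": h2_full.h2_total,
                    "r_obs_reduced": cv_full.observed,
                    "r_theo_reduced": cv_full.theoretical,
                    "inflation_reduced": cv_full.inflation,
                    "n_fixed_snps": 0,
                }
            )
            continue
        # order members by map position for a deterministic collinearity tie-break
        cols_idx = g.snp_indices(iv.member_snps)
        order = np.argsort(g.snp_map["pos"].to_numpy()[cols_idx], kind="stable")
        cols_idx = cols_idx[order]
        cov = g.dosages[g_rows][:, cols_idx].astype(np.float64)
        kept, n_drop = _dedup_collinear(cov)
        if n_drop:
            notes.append(f"{label}: dropped {n_drop} collinear significant SNP(s)")
        cov = cov[:, kept]
        _vc_r, h2_r = _cohort_h2(bundle, [bundle.G], covariates=cov)
        cv_r = cv_run("gblup", plan, bundle, covariates=cov)
        rows.append(
            {
                "target": label,
                "c_h2": (h2_full.h2_total - h2_r.h2_total) / h2_full.h2_total
                if h2_full.h2_total > 0
                else 0.0,
                "c_r_obs": (cv_full.observed - cv_r.observed) / cv_full.observed
                if cv_full.observed
                else 0.0,
                "c_r_theo": (cv_full.theoretical - cv_r.theoretical) / cv_full.theoretical
                if cv_full.theoretical
                else 0.0,
                "c_inflation": _c_inflation(cv_r.inflation, cv_full.inflation),
                "h2_reduced": h2_r.h2_total,
                "r_obs_reduced": cv_r.observed,
                "r_theo_reduced": cv_r.theoretical,
                "inflation_reduced": cv_r.inflation,
                "n_fixed_snps": len(kept),
            }
        )
    return ContributionReport(
        method="reduced_model",
        rows=pd.DataFrame(rows),
        full_metrics={
            "h2": h2_full.h2_total,
            "r_obs": cv_full.observed,
            "r_theo": cv_full.theoretical,
            "inflation": cv_full.inflation,
        },
        notes=notes,
    )


def gfblup_partition_contribution(
    sig_snps,
    bundle: DataBundle,
    plan: CVPlan,
) -> ContributionReport:
    """Two-kernel partition contribution of a significant SNP set."""
    sig_snps = list(sig_snps)
    if not sig_snps:
        raise ValueError("significant SNP set is empty")
    if bundle.genotypes is None and (bundle.Gs is None or bundle.Ga is None):
        raise ValueError("bundle needs genotypes or a precomputed kernel pair")
    if bundle.Gs is None or bundle.Ga is None:
        gs, ga = compute_grm_pair(bundle.genotypes, sig_snps)
        bundle = DataBundle(
            pheno=bundle.pheno,
            trait=bundle.trait,
            yc=bundle.yc,
            G=bundle.G,
            A=bundle.A,
            Gs=gs,
            Ga=ga,
            genotypes=bundle.genotypes,
        )
    vc2, _h2 = _cohort_h2(
        bundle, [bundle.Gs, bundle.Ga], kernel_names=["feature", "rest"]
    )
    h2_qtl, h2_snp = (
        heritability(vc2).h2_per_kernel["feature"],
        heritability(vc2).h2_per_kernel["rest"],
    )
    notes = []
    if vc2.boundary and vc2.sigma2[0] <= vc2.sigma2[1] * 1e-6:
        notes.append("feature variance hit the zero boundary; C(H2) reported as 0")
        c_h2 = 0.0
    else:
        c_h2 = h2_qtl / (h2_qtl + h2_snp) if (h2_qtl + h2_snp) > 0 else 0.0

    cv_both = cv_run("gfblup", plan, bundle)
    rest_bundle = DataBundle(
        pheno=bundle.pheno, trait=bundle.trait, yc=bundle.yc, G=bundle.Ga
    )
    cv_rest = cv_run("gblup", plan, rest_bundle)

    rows = pd.DataFrame(
        [
            {
                "target": f"{len(sig_snps)}-SNP feature set",
                "c_h2": c_h2,
                "c_r_obs": (cv_both.observed - cv_rest.observed) / cv_both.observed
                if cv_both.observed
                else 0.0,
                "c_r_theo": (cv_both.theoretical - cv_rest.theoretical) / cv_both.theoretical
                if cv_both.theoretical
                else 0.0,
                "c_inflation": _c_inflation(cv_rest.inflation, cv_both.inflation),
                "h2_qtl": h2_qtl,
                "h2_snp": h2_snp,
                "r_obs_rest": cv_rest.observed,
                "r_theo_rest": cv_rest.theoretical,
                "inflation_rest": cv_rest.inflation,
            }
        ]
    )
    return ContributionReport(
        method="gfblup_partition",
        rows=rows,
        full_metrics={
            "h2_total": heritability(vc2).h2_total,
            "r_obs": cv_both.observed,
            "r_theo": cv_both.theoretical,
            "inflation": cv_both.inflation,
        },
        notes=notes,
    )


def top_snp_removal_curve(
    fractions,
    bundle: DataBundle,
    plan: CVPlan,
    prune_r2: float = 0.9,
    reml_tol: float = 1e-6,
) -> ContributionReport:
    """Accuracy/heritability collapse as top GWAS SNPs are removed.

    Per fold: a GWAS restricted to the fold's reference birds ranks the
    LD-pruned (tagged) SNPs; for each fraction the top-ranked tagged SNPs
    are removed, the GRM is rebuilt from the remainder, and the validation
    birds are re-predicted.  Results are averaged across folds.
    """
    from .blup import solve_mme
    from .gwas import ld_prune

    fractions = sorted(float(f) for f in fractions)
    if any(not 0.0 <= f < 1.0 for f in fractions):
        raise ValueError("fractions must lie in [0, 1)")
    g = bundle.genotypes
    if g is None:
        raise ValueError("bundle.genotypes required")

    tagged = ld_prune(g, r2_max=prune_r2)
    tagged_idx = g.snp_indices(tagged)
    if fractions and int(np.ceil(max(fractions) * len(tagged))) >= len(tagged):
        raise ValueError("largest fraction would remove every tagged SNP")

    cohort_ids = [
        i for i in bundle.pheno["id"].astype(str) if i in set(plan.eval_ids)
    ]
    g_cohort = g.subset(individuals=[g.sample_ids.index(i) for i in cohort_ids])
    pheno = bundle.pheno[bundle.pheno["id"].astype(str).isin(set(cohort_ids))].reset_index(
        drop=True
    )
    G_tagged = compute_grm(g_cohort, snp_subset=tagged)

    # full-model (all tagged SNPs) CV baseline
    base_bundle = DataBundle(pheno=pheno, trait=bundle.trait, yc=bundle.yc, G=G_tagged)
    cv_full = cv_run("gblup", plan, base_bundle, reml_tol=reml_tol)

    per_fold_rows = []
    for f in range(plan.k):
        ref_ids, val_ids = plan.fold_ids(f)
        ref_ids = [i for i in ref_ids if i in set(cohort_ids)]
        val_ids = [i for i in val_ids if i in bundle.yc.index and i in set(cohort_ids)]
        ref_pheno = pheno[pheno["id"].astype(str).isin(set(ref_ids))].reset_index(drop=True)
        g_ref = g_cohort.subset(
            individuals=[g_cohort.sample_ids.index(i) for i in ref_pheno["id"].astype(str)]
        )
        assoc = mlm_assoc(
            g_ref, ref_pheno, bundle.trait, G_tagged.submatrix(ref_pheno["id"].astype(str).tolist())
        )
        p_tagged = assoc.table["p"].to_numpy()[tagged_idx]
        rank = np.argsort(p_tagged, kind="stable")  # most significant first
        for frac in fractions:
            n_drop = int(np.ceil(frac * len(tagged)))
            keep_tagged = [tagged[i] for i in np.sort(rank[n_drop:])]
            Gf = compute_grm(g_cohort, snp_subset=keep_tagged)
            spec = make_spec(ref_pheno, bundle.trait, [Gf.submatrix(cohort_ids)])
            vc = fit_reml(spec, tol=reml_tol)
            report = solve_mme(spec, vc, model="GBLUP")
            pos = report.by_id(val_ids)
            preds = report.gebv[pos]
            ycv = bundle.yc.loc[val_ids].to_numpy()
            if preds.std() == 0 or ycv.std() == 0:
                obs, slope = np.nan, np.nan
            else:
                obs = float(np.corrcoef(preds, ycv)[0, 1])
                slope = float(np.cov(ycv, preds)[0, 1] / np.var(preds, ddof=1))
            per_fold_rows.append(
                {
                    "fold": f,
                    "fraction": frac,
                    "observed": obs,
                    "theoretical": float(np.mean(report.accuracy[pos])),
                    "inflation": slope,
                    "h2": heritability(vc).h2_total,
                }
            )

    per_fold = pd.DataFrame(per_fold_rows)
    rows = []
    for frac, grp in per_fold.groupby("fraction"):
        r_f = float(np.nanmean(grp["observed"]))
        h2_f = float(np.nanmean(grp["h2"]))
        infl_f = float(np.nanmean(grp["inflation"]))
        theo_f = float(np.nanmean(grp["theoretical"]))
        rows.append(
            {
                "target": f"top {frac:.0%} removed",
                "fraction": frac,
                "c_r_obs": (cv_full.observed - r_f) / cv_full.observed
                if cv_full.observed
                else 0.0,
                "c_r_theo": (cv_full.theoretical - theo_f) / cv_full.theoretical
                if cv_full.theoretical
                else 0.0,
                "c_h2": (cv_full.h2_mean - h2_f) / cv_full.h2_mean
                if cv_full.h2_mean > 0
                else 0.0,
                "c_inflation": _c_inflation(infl_f, cv_full.inflation),
                "r_obs": r_f,
                "r_theo": theo_f,
                "h2": h2_f,
                "inflation": infl_f,
            }
        )
    return ContributionReport(
        method="top_snp_removal",
        rows=pd.DataFrame(rows),
        full_metrics={
            "h2": cv_full.h2_mean,
            "r_obs": cv_full.observed,
            "r_theo": cv_full.theoretical,
            "inflation": cv_full.inflation,
            "n_tagged": len(tagged),
        },
        notes=[],
    )
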