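"""Cross-validation orchestration and the three evaluation statistics.

For every fold the variance components are refit on the reference birds
only, the validation birds are predicted through the kernel covariances,
and three statistics are computed on the validation set:

* observed accuracy — Pearson correlation of predictions with the adjusted
  phenotype Yc (phenotype minus the fixed-effect estimates of an all-data
  pedigree-BLUP fit);
* theoretical accuracy — mean of sqrt(1 - PEV / sigma2_a) over validation
  individuals;
* inflation — OLS slope of Yc on the predictions (1 = no dispersion bias).

Validation phenotypes never enter reference-side fitting; an id audit
enforces this per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .blup import fit_gfblup, solve_mme
from .kinship import RelationshipMatrix, compute_nrm
from .varcomp import VarianceComponents, fit_reml, heritability, make_spec

__all__ = [
    "AdjustedPhenotype",
    "CVPlan",
    "CVResult",
    "DataBundle",
    "adjust_phenotype",
    "make_cv_plan",
    "cv_run",
    "reference_size_curve",
]


@dataclass
class AdjustedPhenotype:
    """Yc = y - X b-hat from an all-data pedigree-BLUP fit."""

    yc: pd.Series  # indexed by id
    beta: np.ndarray
    vc: VarianceComponents
    trait: str


@dataclass
class CVPlan:
    """Discovery/evaluation split plus fold assignment for the evaluation set."""

    eval_ids: list[str]
    fold: np.ndarray  # int fold per eval id
    discovery_ids: list[str]
    k: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.fold) != len(self.eval_ids):
            raise ValueError("fold vector must match eval_ids")
        if set(self.discovery_ids) & set(self.eval_ids):
            raise ValueError("discovery and evaluation sets overlap")

    @property
    def n_evaluation(self) -> int:
        return len(self.eval_ids)

    def fold_ids(self, f: int) -> tuple[list[str], list[str]]:
        """(reference ids, validation ids) for fold f."""
        mask = self.fold == f
        val = [i for i, m in zip(self.eval_ids, mask) if m]
        ref = [i for i, m in zip(self.eval_ids, mask) if not m]
        return ref, val


@dataclass
class DataBundle:
    """Everything a CV or contribution run needs, keyed by individual id."""

    pheno: pd.DataFrame
    trait: str
    yc: pd.Series
    G: RelationshipMatrix | None = None
    A: RelationshipMatrix | None = None
    Gs: RelationshipMatrix | None = None
    Ga: RelationshipMatrix | None = None
    genotypes: object = None  # GenotypeMatrix, when SNP-level work is needed

    def kernels_for(self, model: str) -> list[RelationshipMatrix]:
        model = model.lower()
        if model == "ablup":
            if self.A is None:
                raise ValueError("bundle has no pedigree matrix for ABLUP")
            return [self.A]
        if model == "gblup":
            if self.G is None:
                raise ValueError("bundle has no genomic matrix for GBLUP")
            return [self.G]
        if model == "gfblup":
            if self.Gs is None or self.Ga is None:
                raise ValueError("bundle has no kernel pair for GFBLUP")
            return [self.Gs, self.Ga]
        raise ValueError(f"unknown model {model!r}")


@dataclass
class CVResult:
    model: str
    per_fold: pd.DataFrame
    observed: float
    theoretical: float
    inflation: float
    h2_mean: float
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "observed_accuracy": self.observed,
            "theoretical_accuracy": self.theoretical,
            "inflation": self.inflation,
            "h2_mean": self.h2_mean,
            "flags": self.flags,
        }


def adjust_phenotype(
    pheno: pd.DataFrame,
    ped: pd.DataFrame,
    trait: str,
    A: RelationshipMatrix | None = None,
) -> AdjustedPhenotype:
    """Fixed-effect-adjusted phenotype from an all-data pedigree-BLUP fit.

    The pedigree relationship matrix may be passed to avoid recomputation.
    """
    A = A if A is not None else compute_nrm(ped)
    spec = make_spec(pheno, trait, [A], kernel_names=["pedigree"])
    vc = fit_reml(spec)
    # GLS fixed effects at the fitted components
    H = spec.kernels[0].obs_matrix()
    V = vc.sigma2[0] * H + vc.sigma2_e * np.eye(spec.n)
    cf = linalg.cho_factor(V, lower=True)
    Vi_X = linalg.cho_solve(cf, spec.X)
    beta = linalg.solve(spec.X.T @ Vi_X, Vi_X.T @ spec.y, assume_a="pos")
    yc = spec.y - spec.X @ beta
    return AdjustedPhenotype(
        yc=pd.Series(yc, index=pd.Index(spec.obs_ids, name="id")),
        beta=beta,
        vc=vc,
        trait=trait,
    )


def make_cv_plan(
    ids,
    k: int = 10,
    discovery_n: int = 0,
    seed: int = 0,
) -> CVPlan:
    """Random discovery split plus a k-fold partition of the remainder.

    Fold sizes differ by at most one; identical seed gives an identical plan.
    """
    ids = [str(i) for i in ids]
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 0 <= discovery_n < len(ids):
        raise ValueError("discovery_n must be in [0, n)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    discovery = [ids[i] for i in perm[:discovery_n]]
    eval_ids = [ids[i] for i in perm[discovery_n:]]
    fold = np.arange(len(eval_ids)) % k
    return CVPlan(eval_ids=eval_ids, fold=fold, discovery_ids=discovery, k=k, seed=seed)


def _fold_metrics(
    preds: np.ndarray, yc: np.ndarray, theo: np.ndarray
) -> tuple[float, float, float, str]:
    flag = ""
    if preds.std() == 0 or yc.std() == 0:
        obs = np.nan
        slope = np.nan
        flag = "zero-variance predictions"
    else:
        obs = float(np.corrcoef(preds, yc)[0, 1])
        slope = float(np.cov(yc, preds)[0, 1] / np.var(preds, ddof=1))
    return obs, slope, float(np.mean(theo)), flag


def cv_run(
    model: str,
    plan: CVPlan,
    bundle: DataBundle,
    covariates: np.ndarray | None = None,
    reml_tol: float = 1e-6,
) -> CVResult:
    """k-fold cross-validation of one prediction model.

    ``covariates`` (one row per ``bundle.pheno`` row) are extra fixed-effect
    columns — used by the reduced models that fit significant SNPs as fixed
    covariates.
    """
    kernels = bundle.kernels_for(model)
    cohort = set(plan.eval_ids)
    pheno = bundle.pheno[bundle.pheno["id"].astype(str).isin(cohort)].reset_index(drop=True)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        keep = bundle.pheno["id"].astype(str).isin(cohort).to_numpy()
        covariates = covariates[keep]
    # one kernel over the whole evaluation cohort, subset per fold via spec
    cohort_ids = pheno["id"].astype(str).tolist()
    kernels = [k.submatrix(cohort_ids) for k in kernels]

    rows = []
    flags: list[str] = []
    for f in range(plan.k):
        ref_ids, val_ids = plan.fold_ids(f)
        ref_set = set(ref_ids) & set(cohort_ids)
        mask_ref = pheno["id"].astype(str).isin(ref_set).to_numpy()
        ref_pheno = pheno[mask_ref].reset_index(drop=True)
        cov_ref = covariates[mask_ref] if covariates is not None else None
        spec = make_spec(
            ref_pheno,
            bundle.trait,
            kernels,
            covariates=cov_ref,
            kernel_names=["feature", "rest"] if model.lower() == "gfblup" else ["additive"],
        )
        leaked = set(spec.obs_ids) & set(val_ids)
        if leaked:
            raise AssertionError(f"validation ids leaked into reference fit: {sorted(leaked)[:3]}")
        vc = fit_reml(spec, tol=reml_tol)
        if model.lower() == "gfblup":
            report = fit_gfblup(spec, vc)
        else:
            report = solve_mme(spec, vc, model=model.upper())
        val_in = [i for i in val_ids if i in bundle.yc.index and i in set(report.ids)]
        pos = report.by_id(val_in)
        preds = report.gebv[pos]
        theo = report.accuracy[pos]
        ycv = bundle.yc.loc[val_in].to_numpy()
        obs, slope, theo_mean, flag = _fold_metrics(preds, ycv, theo)
        if flag:
            flags.append(f"fold {f}: {flag}")
        rows.append(
            {
                "fold": f,
                "n_ref": len(spec.obs_ids),
                "n_val": len(val_in),
                "observed": obs,
                "theoretical": theo_mean,
                "inflation": slope,
                "h2": heritability(vc).h2_total,
                "converged": vc.converged,
            }
        )
    per_fold = pd.DataFrame(rows)
    return CVResult(
        model=model.upper(),
        per_fold=per_fold,
        observed=float(np.nanmean(per_fold["observed"])),
        theoretical=float(np.nanmean(per_fold["theoretical"])),
        inflation=float(np.nanmean(per_fold["inflation"])),
        h2_mean=float(np.nanmean(per_fold["h2"])),
        flags=flags,
    )


def reference_size_curve(
    sizes,
    bundle: DataBundle,
    seed: int = 0,
    model: str = "gblup",
) -> pd.DataFrame:
    """Prediction metrics as a function of reference-set size.

    For each requested size the cohort is subsampled, split into 11 equal
    portions, 10 of which form the reference set and 1 the validation set
    (size 550 -> reference 500, validation 50).
    """
    kernels = bundle.kernels_for(model)
    avail = [
        i
        for i in bundle.pheno["id"].astype(str)
        if i in set(kernels[0].ids) and i in bundle.yc.index
    ]
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        size = int(size)
        if size > len(avail):
            raise ValueError(f"size {size} exceeds cohort size {len(avail)}")
        chosen = [avail[i] for i in rng.choice(len(avail), size=size, replace=False)]
        n_val = size // 11
        val_ids, ref_ids = chosen[:n_val], chosen[n_val:]
        sub = [k.submatrix(chosen) for k in kernels]
        pheno_ref = bundle.pheno[bundle.pheno["id"].astype(str).isin(set(ref_ids))]
        spec = make_spec(pheno_ref.reset_index(drop=True), bundle.trait, sub)
        vc = fit_reml(spec)
        report = solve_mme(spec, vc, model=model.upper())
        pos = report.by_id(val_ids)
        preds = report.gebv[pos]
        ycv = bundle.yc.loc[val_ids].to_numpy()
        obs, slope, theo_mean, _flag = _fold_metrics(preds, ycv, report.accuracy[pos])
        rows.append(
            {
                "size": size,
                "n_ref": len(ref_ids),
                "n_val": n_val,
                "observed": obs,
                "theoretical": theo_mean,
                "inflation": slope,
            }
        )
    return pd.DataFrame(rows)
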