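"""Best linear unbiased prediction with one or two relationship kernels.

Predictions are computed from the variance form of the mixed-model
equations: with V = Z (sum_i sigma2_i K_i) Z' + sigma2_e I and b-hat the
GLS fixed-effect solution,

    u-hat = Cov(u, y) V^-1 (y - X b-hat),

which is algebraically identical to Henderson's equations but needs no
kernel inverse, handles unphenotyped individuals through the kernel
covariances, and yields the prediction error variance

    PEV = Var(u) - Cov(u, y) P Cov(y, u),  P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1,

whose diagonal accounts for fixed-effect uncertainty exactly as the inverse
coefficient matrix does.  For two-kernel (feature) models the total genetic
value s + a is predicted jointly, so combined PEV includes the
cross-covariance terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .varcomp import MixedModelSpec, VarianceComponents

__all__ = ["PredictionReport", "solve_mme", "fit_gfblup"]


@dataclass
class PredictionReport:
    """Per-individual breeding values with PEV and theoretical accuracy."""

    ids: list[str]
    gebv: np.ndarray
    pev: np.ndarray
    accuracy: np.ndarray
    model: str
    vc: VarianceComponents
    components: dict = field(default_factory=dict)  # kernel name -> per-id values
    phenotyped: np.ndarray | None = None  # bool mask over ids

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "gebv": self.gebv,
                "pev": self.pev,
                "accuracy": self.accuracy,
            }
        )
        for name, vals in self.components.items():
            df[f"gebv_{name}"] = vals
        if self.phenotyped is not None:
            df["phenotyped"] = self.phenotyped
        return df

    def by_id(self, ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.ids)}
        return np.array([pos[str(i)] for i in ids], dtype=int)


def solve_mme(
    spec: MixedModelSpec, vc: VarianceComponents, model: str = "GBLUP"
) -> PredictionReport:
    """BLUP solutions for every individual covered by the kernels.

    ``spec`` holds phenotyped individuals only; each kernel's ``ids`` may be
    a superset (validation individuals receive predictions through the
    kernel covariances, with PEV = sigma2_a for isolated individuals).
    """
    if len(vc.sigma2) != len(spec.kernels):
        raise ValueError("variance components do not match the kernel list")
    ids = spec.kernels[0].ids
    for k in spec.kernels[1:]:
        if k.ids != ids:
            raise ValueError("all kernels must be indexed by the same id list")
    y, X = spec.y, spec.X
    n_obs = y.shape[0]
    idx = spec.kernels[0].idx

    sig_a = float(sum(vc.sigma2))
    V = vc.sigma2_e * np.eye(n_obs)
    for s2, k in zip(vc.sigma2, spec.kernels):
        V += s2 * k.obs_matrix()
    try:
        cf = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError("singular phenotypic covariance V") from exc
    Vi_X = linalg.cho_solve(cf, X)
    XtViX = X.T @ Vi_X
    cfx = linalg.cho_factor(XtViX)
    beta = linalg.cho_solve(cfx, Vi_X.T @ y)
    resid = y - X @ beta
    Vi_r = linalg.cho_solve(cf, resid)

    # Cov(total genetic value, y) over all kernel ids: rows = individuals
    n_all = len(ids)
    C = np.zeros((n_all, n_obs))
    comp: dict[str, np.ndarray] = {}
    var_t = np.zeros(n_all)
    for s2, k in zip(vc.sigma2, spec.kernels):
        Ck = s2 * k.K[:, k.idx]
        comp[k.name] = Ck @ Vi_r
        C += Ck
        var_t += s2 * np.diag(k.K)
    gebv = C @ Vi_r

    # PEV: diag(Var(t) - C P C')
    Ct = C.T  # (n_obs, n_all)
    PCt = linalg.cho_solve(cf, Ct) - Vi_X @ linalg.cho_solve(cfx, Vi_X.T @ Ct)
    explained = np.einsum("ij,ji->i", C, PCt)
    pev = np.clip(var_t - explained, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(sig_a > 0, 1.0 - pev / sig_a, 0.0)
    accuracy = np.sqrt(np.clip(rel, 0.0, 1.0))

    phenotyped = np.zeros(n_all, dtype=bool)
    phenotyped[idx] = True
    return PredictionReport(
        ids=list(ids),
        gebv=gebv,
        pev=pev,
        accuracy=accuracy,
        model=model,
        vc=vc,
        components=comp,
        phenotyped=phenotyped,
    )


def fit_gfblup(spec: MixedModelSpec, vc: VarianceComponents) -> PredictionReport:
    """Two-kernel (feature + remainder) BLUP; total genetic value = s + a.

    Combined reliability comes from the joint PEV of s + a, cross terms
    included; theoretical accuracy is its square root scaled by the summed
    genetic variance.
    """
    if len(spec.kernels) != 2:
        raise ValueError("GFBLUP needs exactly two kernels (feature, remainder)")
    k1, k2 = spec.kernels
    if k1.K.shape == k2.K.shape and np.allclose(k1.K, k2.K, atol=1e-10):
        raise ValueError("feature and remainder kernels are identical; "
                         "the two genetic components would not be identifiable")
    return solve_mme(spec, vc, model="GFBLUP")
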