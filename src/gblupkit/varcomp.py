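"""REML variance-component estimation for one- and two-kernel mixed models.

Model: y = X b + sum_i Z_i u_i + e with Var(u_i) = sigma2_i K_i and
Var(e) = sigma2_e I.  Fitting is EM-REML warm-started, switching to
average-information (AI) steps once the EM phase ends; AI steps that would
decrease the restricted likelihood or cross the zero boundary are halved
back, so the likelihood trace is monotone during the EM phase and
non-decreasing overall.

The single-kernel path eigendecomposes the kernel once and runs every
iteration in rotated coordinates at O(n p^2) cost; multi-kernel fits use
dense V factorizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .kinship import RelationshipMatrix

__all__ = [
    "Kernel",
    "MixedModelSpec",
    "VarianceComponents",
    "HeritabilityEstimate",
    "NonIdentifiableError",
    "build_design",
    "make_spec",
    "fit_reml",
    "reml_loglik",
    "heritability",
]


class NonIdentifiableError(ValueError):
    """Kernel indistinguishable from the residual (flat eigenvalue spectrum)."""


@dataclass
class Kernel:
    """A random effect: covariance K over kernel ids, incidence via idx.

    ``idx[i]`` is the row of ``K`` for observation i, so Z K Z' equals
    ``K[idx][:, idx]``.  ``ids`` keeps the kernel's full id list so
    unphenotyped individuals can be predicted later.
    """

    K: np.ndarray
    idx: np.ndarray
    ids: list[str]
    name: str = "additive"

    def obs_matrix(self) -> np.ndarray:
        return self.K[np.ix_(self.idx, self.idx)]


@dataclass
class MixedModelSpec:
    y: np.ndarray
    X: np.ndarray
    kernels: list[Kernel]
    obs_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X rows must match y length")
        if not self.kernels:
            raise ValueError("at least one kernel required")
        for k in self.kernels:
            if k.idx.shape[0] != self.y.shape[0]:
                raise ValueError(f"kernel {k.name}: incidence length != n")
        self.X = _full_rank(self.X)

    @property
    def n(self) -> int:
        return self.y.shape[0]


@dataclass
class VarianceComponents:
    sigma2: list[float]  # per kernel, in spec.kernels order
    sigma2_e: float
    loglik: float
    converged: bool
    n_iter: int
    kernel_names: list[str] = field(default_factory=list)
    trace: list = field(default_factory=list)  # (phase, loglik, params)
    boundary: bool = False

    @property
    def sigma2_total(self) -> float:
        return float(sum(self.sigma2) + self.sigma2_e)

    def to_dict(self) -> dict:
        return {
            "sigma2": dict(zip(self.kernel_names, self.sigma2)),
            "sigma2_e": self.sigma2_e,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "boundary": self.boundary,
        }


@dataclass
class HeritabilityEstimate:
    h2_per_kernel: dict
    h2_total: float
    definition: str = "sigma2_genetic / (sigma2_genetic + sigma2_e)"


def _full_rank(X: np.ndarray) -> np.ndarray:
    """Drop linearly dependent columns (pivoted QR), preserving column order."""
    if X.size == 0:
        raise ValueError("empty design matrix")
    _q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    return X[:, keep]


def build_design(
    pheno: pd.DataFrame,
    trait: str,
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Response and fixed-effect design: intercept + batch-sex interaction
    dummies (first level as reference) + optional covariate columns.

    Rows with a missing trait value are dropped.  Returns (y, X, kept ids).
    """
    if trait not in pheno.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    ok = pheno[trait].notna().to_numpy()
    sub = pheno.loc[ok]
    y = sub[trait].to_numpy(dtype=float)
    cell = sub["batch"].astype(str) + ":" + sub["sex"].astype(str)
    levels = sorted(cell.unique())
    cols = [np.ones(len(sub))]
    cols += [(cell == lv).to_numpy(dtype=float) for lv in levels[1:]]
    X = np.column_stack(cols)
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != len(pheno):
            raise ValueError("covariates must have one row per phenotype row")
        X = np.column_stack([X, cov[ok]])
    return y, X, sub["id"].astype(str).tolist()


def make_spec(
    pheno: pd.DataFrame,
    trait: str,
    kernels: Sequence[RelationshipMatrix],
    covariates: np.ndarray | None = None,
    kernel_names: Sequence[str] | None = None,
) -> MixedModelSpec:
    """Assemble a MixedModelSpec, aligning phenotype rows to kernel ids.

    Individuals absent from any kernel are dropped from the analysis.
    """
    y, X, ids = build_design(pheno, trait, covariates)
    id_sets = [set(k.ids) for k in kernels]
    keep = np.array([all(i in s for s in id_sets) for i in ids])
    if not keep.all():
        y, X = y[keep], X[keep]
        ids = [i for i, k in zip(ids, keep) if k]
    names = list(kernel_names) if kernel_names else [f"k{i}" for i in range(len(kernels))]
    kobjs = [
        Kernel(K=rm.values, idx=rm.index_of(ids), ids=list(rm.ids), name=name)
        for rm, name in zip(kernels, names)
    ]
    return MixedModelSpec(y=y, X=X, kernels=kobjs, obs_ids=ids)


# ---------------------------------------------------------------------------
# Likelihood backends.  Both expose, at the current parameter vector
# (sigma2_1..sigma2_k, sigma2_e):
#   ll        restricted log-likelihood
#   kpy()     [K_1 Py, ..., K_k Py, Py]
#   apply_p() action of P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1
#   tr_pk()   [tr(P K_1), ..., tr(P K_k), tr(P)]
# ---------------------------------------------------------------------------


class _DenseBackend:
    def __init__(self, y: np.ndarray, X: np.ndarray, Hs: list[np.ndarray]):
        self.y, self.X, self.Hs = y, X, Hs
        self.n, self.p = X.shape

    def set_params(self, params: np.ndarray) -> float:
        V = params[-1] * np.eye(self.n)
        for s, H in zip(params[:-1], self.Hs):
            V += s * H
        self._cf = linalg.cho_factor(V, lower=True)
        logdet_v = 2.0 * np.sum(np.log(np.diag(self._cf[0])))
        self._Vi = linalg.cho_solve(self._cf, np.eye(self.n))
        self._Vi_X = self._Vi @ self.X
        XtViX = self.X.T @ self._Vi_X
        self._cfx = linalg.cho_factor(XtViX)
        logdet_x = 2.0 * np.sum(np.log(np.diag(self._cfx[0])))
        beta = linalg.cho_solve(self._cfx, self._Vi_X.T @ self.y)
        self.Py = self._Vi @ self.y - self._Vi_X @ beta
        ypy = float(self.y @ self.Py)
        self.ll = -0.5 * (logdet_v + logdet_x + ypy + (self.n - self.p) * np.log(2 * np.pi))
        return self.ll

    def apply_p(self, v: np.ndarray) -> np.ndarray:
        return self._Vi @ v - self._Vi_X @ linalg.cho_solve(self._cfx, self._Vi_X.T @ v)

    def kpy(self) -> list[np.ndarray]:
        return [H @ self.Py for H in self.Hs] + [self.Py]

    def tr_pk(self) -> list[float]:
        out = []
        for H in self.Hs + [None]:
            if H is None:
                t = np.trace(self._Vi)
                M = self._Vi_X.T @ self._Vi_X
            else:
                t = float((self._Vi * H).sum())  # tr(V^-1 H), H symmetric
                M = self._Vi_X.T @ (H @ self._Vi_X)
            t -= np.trace(linalg.cho_solve(self._cfx, M))
            out.append(float(t))
        return out


class _EigenBackend:
    """Single-kernel path: rotate by the kernel eigenbasis once, then every
    iteration is O(n p^2) with a diagonal V."""

    def __init__(self, y: np.ndarray, X: np.ndarray, H: np.ndarray):
        w, U = linalg.eigh(H)
        self.d = np.clip(w, 0.0, None)
        self.y = U.T @ y
        self.X = U.T @ X
        self.n, self.p = X.shape

    def set_params(self, params: np.ndarray) -> float:
        self.v = params[0] * self.d + params[-1]
        vi = 1.0 / self.v
        self._Vi_X = self.X * vi[:, None]
        XtViX = self.X.T @ self._Vi_X
        self._cfx = linalg.cho_factor(XtViX)
        logdet_x = 2.0 * np.sum(np.log(np.diag(self._cfx[0])))
        beta = linalg.cho_solve(self._cfx, self._Vi_X.T @ self.y)
        self.Py = self.y * vi - self._Vi_X @ beta
        ypy = float(self.y @ self.Py)
        logdet_v = float(np.sum(np.log(self.v)))
        self.ll = -0.5 * (logdet_v + logdet_x + ypy + (self.n - self.p) * np.log(2 * np.pi))
        return self.ll

    def apply_p(self, u: np.ndarray) -> np.ndarray:
        return u / self.v - self._Vi_X @ linalg.cho_solve(self._cfx, self._Vi_X.T @ u)

    def kpy(self) -> list[np.ndarray]:
        return [self.d * self.Py, self.Py]

    def tr_pk(self) -> list[float]:
        out = []
        for dvec in (self.d, np.ones(self.n)):
            t = float(np.sum(dvec / self.v))
            M = self._Vi_X.T @ (dvec[:, None] * self._Vi_X)
            t -= np.trace(linalg.cho_solve(self._cfx, M))
            out.append(t)
        return out

    def profile(self, lam: float) -> tuple[float, float, float]:
        """Profiled REML over the variance-ratio lam = sigma2_a / sigma2_e.

        Returns (loglik, sigma2_a, sigma2_e) with the scale maximized in
        closed form: sigma2_e* = y' P0 y / (n - p) at unit scale.
        """
        ll0 = self.set_params(np.array([lam, 1.0]))
        ypy = float(self.y @ self.Py)
        df = self.n - self.p
        se = ypy / df
        if not np.isfinite(se) or se <= 0.0:
            return -np.inf, lam, 0.0
        ll = ll0 + 0.5 * ypy - 0.5 * df * (np.log(se) + 1.0)
        return float(ll), lam * se, se


def reml_loglik(spec: MixedModelSpec, sigma2: Sequence[float], sigma2_e: float) -> float:
    """Restricted log-likelihood at the given variance components."""
    Hs = [k.obs_matrix() for k in spec.kernels]
    backend = _DenseBackend(spec.y, spec.X, Hs)
    return float(backend.set_params(np.array(list(sigma2) + [sigma2_e], dtype=float)))


def fit_reml(
    spec: MixedModelSpec,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_em: int = 3,
    polish: bool = True,
    verbose: bool = False,
) -> VarianceComponents:
    """Hybrid EM -> AI REML.

    Components are kept above 1e-8 x Var(y); convergence is declared when
    the largest relative parameter change drops below ``tol``.  On
    non-convergence the last iterate is returned with ``converged=False``.
    """
    y, X = spec.y, spec.X
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need n >= rank(X) + 2 (n={n}, rank={p})")
    Hs = [k.obs_matrix() for k in spec.kernels]
    vary = float(np.var(y))
    if vary == 0.0:
        raise ValueError("response has zero variance")
    floor = 1e-8 * vary

    if len(Hs) == 1:
        backend = _EigenBackend(y, X, Hs[0])
        d = backend.d
        if d.max() - d.min() < 1e-8 * (1.0 + abs(d.max())):
            raise NonIdentifiableError(
                "kernel eigenvalues are flat (identity-like); genetic and "
                "residual variances are not separable"
            )
    else:
        backend = _DenseBackend(y, X, Hs)

    nk = len(Hs)
    params = np.full(nk + 1, vary / (nk + 1))
    ll = backend.set_params(params)
    trace: list = [("init", ll, params.copy())]
    converged = False
    it = 0
    n_flat = 0
    for it in range(1, max_iter + 1):
        tr_pk = backend.tr_pk()
        kpy = backend.kpy()
        ypkpy = [float(backend.Py @ v) for v in kpy]
        phase = "em" if it <= n_em else "ai"
        if phase == "em":
            new = np.maximum(
                params + (params**2 / n) * (np.array(ypkpy) - np.array(tr_pk)), floor
            )
        else:
            score = -0.5 * (np.array(tr_pk) - np.array(ypkpy))
            ai = np.empty((nk + 1, nk + 1))
            pkpy = [backend.apply_p(v) for v in kpy]
            for i in range(nk + 1):
                for j in range(i, nk + 1):
                    ai[i, j] = ai[j, i] = 0.5 * float(kpy[i] @ pkpy[j])
            # active set: components pinned at the zero boundary whose score
            # points outward are frozen, otherwise they corrupt the AI step
            pinned = (params <= floor * (1.0 + 1e-9)) & (score < 0.0)
            free = np.flatnonzero(~pinned)
            delta = np.zeros(nk + 1)
            if free.size:
                sub = ai[np.ix_(free, free)]
                try:
                    delta[free] = linalg.solve(sub, score[free], assume_a="pos")
                except linalg.LinAlgError:
                    delta[free] = linalg.lstsq(sub, score[free])[0]
            new = np.maximum(params + delta, floor)
        ll_new = backend.set_params(new)
        if phase == "ai":
            step = 1.0
            while ll_new < ll - 1e-10 and step > 1e-3:
                step /= 2.0
                new = np.maximum(params + step * delta, floor)
                ll_new = backend.set_params(new)
            if ll_new < ll - 1e-10:
                # AI direction failed even when damped: take an EM step
                new = np.maximum(
                    params + (params**2 / n) * (np.array(ypkpy) - np.array(tr_pk)),
                    floor,
                )
                ll_new = backend.set_params(new)
        # components pinned at the floor would never satisfy a pure relative
        # criterion; measure change against a small fraction of Var(y) too
        denom = np.maximum(np.abs(params), 1e-4 * vary)
        rel_change = float(np.max(np.abs(new - params) / denom))
        n_flat = n_flat + 1 if abs(ll_new - ll) < 1e-9 * max(1.0, abs(ll)) else 0
        params, ll = new, ll_new
        trace.append((phase, ll, params.copy()))
        if verbose:
            print(f"iter {it} [{phase}] ll={ll:.6f} params={params}")
        if rel_change < tol or n_flat >= 3:
            converged = True
            break

    if polish and len(Hs) == 1:
        # profile-likelihood polish over the variance ratio: guards against
        # spurious convergence on the zero boundary and refines the optimum
        from scipy import optimize

        lam_grid = np.concatenate([[1e-10], np.logspace(-6, 6, 37)])
        profs = [backend.profile(lam) for lam in lam_grid]
        k_best = int(np.argmax([p[0] for p in profs]))
        lo = np.log(lam_grid[max(k_best - 1, 1)] / 10.0)
        hi = np.log(lam_grid[min(k_best + 1, len(lam_grid) - 1)] * 10.0)
        res = optimize.minimize_scalar(
            lambda t: -backend.profile(np.exp(t))[0], bounds=(lo, hi),
            method="bounded", options={"xatol": 1e-10},
        )
        candidates = [profs[k_best], backend.profile(np.exp(res.x))]
        ll_p, sa_p, se_p = max(candidates, key=lambda c: c[0])
        if ll_p > ll + 1e-10:
            params = np.maximum(np.array([sa_p, se_p]), floor)
            ll = backend.set_params(params)
            converged = True
            trace.append(("profile", ll, params.copy()))

    boundary = bool((params <= floor * (1.0 + 1e-9)).any())
    return VarianceComponents(
        sigma2=[float(v) for v in params[:-1]],
        sigma2_e=float(params[-1]),
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        kernel_names=[k.name for k in spec.kernels],
        trace=trace,
        boundary=boundary,
    )


def heritability(vc: VarianceComponents) -> HeritabilityEstimate:
    """h2 per kernel and in total: genetic variance over total variance."""
    tot = vc.sigma2_total
    names = vc.kernel_names or [f"k{i}" for i in range(len(vc.sigma2))]
    per = {name: (s / tot if tot > 0 else 0.0) for name, s in zip(names, vc.sigma2)}
    h2 = sum(vc.sigma2) / tot if tot > 0 else 0.0
    return HeritabilityEstimate(h2_per_kernel=per, h2_total=float(h2))
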