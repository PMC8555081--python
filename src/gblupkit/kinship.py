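"""Relationship matrices: genomic (VanRaden method 1), pedigree (tabular
numerator relationship matrix), feature-partitioned pairs, and PCA.

The genomic matrix is G = Zc Zc' / sum_j 2 p_j (1 - p_j) with Zc the
dosage matrix centered by twice the allele frequency observed in the same
cohort.  When a SNP subset is requested, allele frequencies still come from
the full retained panel, which makes the weighted recomposition
(d_s * G_s + d_a * G_a) / (d_s + d_a) = G exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .genio import GenotypeMatrix

__all__ = [
    "RelationshipMatrix",
    "compute_grm",
    "compute_grm_pair",
    "compute_nrm",
    "grm_pca",
]


@dataclass
class RelationshipMatrix:
    """Symmetric kinship matrix with an ID index.

    kind is one of genomic / pedigree / feature.  ``sum2pq`` stores the
    VanRaden denominator for genomic/feature matrices so partition pairs can
    be recombined exactly.
    """

    values: np.ndarray
    ids: list[str]
    kind: str = "genomic"
    n_markers: int | None = None
    sum2pq: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.ids = [str(i) for i in self.ids]
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix is {self.values.shape} but {n} ids supplied")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > 1e-10:
            raise ValueError(f"matrix asymmetric (max |K-K'| = {asym:.3g})")
        if self.kind not in ("genomic", "pedigree", "feature"):
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"ids not in matrix: {missing[:5]}")
        return np.array([lookup[s] for s in ids], dtype=int)

    def submatrix(self, ids: Sequence[str]) -> "RelationshipMatrix":
        idx = self.index_of(ids)
        return RelationshipMatrix(
            self.values[np.ix_(idx, idx)].copy(),
            [str(s) for s in ids],
            kind=self.kind,
            n_markers=self.n_markers,
            sum2pq=self.sum2pq,
        )

    def stabilized(self, eps: float = 1e-6) -> np.ndarray:
        """Values with a small ridge on the diagonal (PSD insurance)."""
        return self.values + eps * np.eye(self.n)


def compute_grm(
    g: GenotypeMatrix,
    snp_subset: Sequence[str] | None = None,
    kind: str | None = None,
) -> RelationshipMatrix:
    """VanRaden method-1 GRM from complete (post-QC) dosages."""
    d = g.dosages.astype(np.float64)
    if np.isnan(d).any():
        raise ValueError("GRM requires complete dosages; run QC/imputation first")
    p = d.mean(axis=0) / 2.0  # full-panel frequencies, also used for subsets
    if snp_subset is not None:
        cols = g.snp_indices(snp_subset)
        if cols.size == 0:
            raise ValueError("empty SNP subset")
    else:
        cols = np.arange(g.n_snps)
    pj = p[cols]
    denom = float(np.sum(2.0 * pj * (1.0 - pj)))
    if denom <= 0.0:
        raise ValueError("subset contains only monomorphic SNPs (denominator 0)")
    z = d[:, cols] - 2.0 * pj
    values = (z @ z.T) / denom
    return RelationshipMatrix(
        (values + values.T) / 2.0,
        list(g.sample_ids),
        kind=kind or ("feature" if snp_subset is not None else "genomic"),
        n_markers=len(cols),
        sum2pq=denom,
    )


def compute_grm_pair(
    g: GenotypeMatrix, feature_snps: Sequence[str]
) -> tuple[RelationshipMatrix, RelationshipMatrix]:
    """(G_s, G_a): feature-subset GRM and complement GRM partitioning the panel."""
    feature = list(dict.fromkeys(feature_snps))
    all_snps = g.snp_map["snp"].tolist()
    feature_set = set(feature)
    rest = [s for s in all_snps if s not in feature_set]
    if not feature:
        raise ValueError("feature SNP set is empty")
    if not rest:
        raise ValueError("feature SNP set covers the whole panel")
    gs = compute_grm(g, snp_subset=feature, kind="feature")
    ga = compute_grm(g, snp_subset=rest, kind="feature")
    return gs, ga


def compute_nrm(ped: pd.DataFrame) -> RelationshipMatrix:
    """Pedigree numerator relationship matrix by the tabular method.

    Founders are assumed unrelated and non-inbred; the input frame must have
    parents before offspring (see :func:`gblupkit.genio.validate_pedigree`).
    """
    from .genio import validate_pedigree

    ped = validate_pedigree(ped)
    ids = ped["id"].tolist()
    pos = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    sire = [pos.get(s) if pd.notna(s) else None for s in ped["sire"]]
    dam = [pos.get(s) if pd.notna(s) else None for s in ped["dam"]]
    a = np.zeros((n, n))
    for i in range(n):
        si, di = sire[i], dam[i]
        a[i, i] = 1.0 + (0.5 * a[si, di] if si is not None and di is not None else 0.0)
        if i:
            row = np.zeros(i)
            if si is not None:
                row += a[:i, si]
            if di is not None:
                row += a[:i, di]
            a[i, :i] = a[:i, i] = 0.5 * row
    return RelationshipMatrix(a, ids, kind="pedigree")


def grm_pca(G: RelationshipMatrix, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k eigenpairs of a relationship matrix, descending.

    Returns (eigenvalues (k,), eigenvectors (n, k)).  Small negative
    eigenvalues from roundoff are clipped at -1e-8 tolerance.
    """
    if not 0 < k < G.n:
        raise ValueError(f"k must be in (0, n); got k={k}, n={G.n}")
    w, v = linalg.eigh(G.values)
    order = np.argsort(w)[::-1][:k]
    w, v = w[order], v[:, order]
    if (w < -1e-8 * max(1.0, abs(w[0]))).any():
        raise ValueError("matrix has substantially negative eigenvalues")
    return w, v
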