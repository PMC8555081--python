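"""Readers and writers for every on-disk format the pipeline touches.

Formats: VCF v4.2 (GT only), PLINK 1 text (PED/MAP) and binary (BED/BIM/FAM),
TSV phenotype/covariate tables, CSV pedigrees, and a gzip-compressed text
exchange format for relationship matrices.

Conventions: positions are 1-based inclusive; dosage is the count of the
alternate (ALT) allele in {0, 1, 2}, with ``NaN`` marking a missing call.
PLINK files, which are minor-allele oriented, are re-oriented on load so
that dosages always count the ALT allele of the accompanying map.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "MultiallelicSiteError",
    "DuplicateIDError",
    "GenotypeMatrix",
    "read_genotypes",
    "write_genotypes",
    "read_matrix",
    "write_matrix",
    "read_phenotypes",
    "write_phenotypes",
    "read_pedigree",
    "write_pedigree",
    "validate_pedigree",
]

SNP_MAP_COLUMNS = ["snp", "chrom", "pos", "ref", "alt"]
PEDIGREE_COLUMNS = ["id", "sire", "dam", "sex", "generation", "batch"]


class FormatError(ValueError):
    """A file failed to parse; the message names the offending line or site."""


class MultiallelicSiteError(FormatError):
    """A site with more than one ALT allele was encountered."""


class DuplicateIDError(FormatError):
    """A sample or SNP identifier occurred more than once."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive dosage matrix with its marker map.

    Attributes
    ----------
    dosages : ndarray, shape (n_individuals, n_snps)
        ALT-allele counts as float32; integer values 0/1/2 for called
        genotypes, ``NaN`` for missing.  After mean imputation (see
        :mod:`gblupkit.qc`) entries may be fractional and ``imputed`` is True.
    sample_ids : list of str
    snp_map : DataFrame with columns (snp, chrom, pos, ref, alt)
    """

    dosages: np.ndarray
    sample_ids: list[str]
    snp_map: pd.DataFrame
    imputed: bool = False

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{n} dosage rows but {len(self.sample_ids)} sample ids"
            )
        if list(self.snp_map.columns[:5]) != SNP_MAP_COLUMNS:
            raise ValueError(f"snp_map must have columns {SNP_MAP_COLUMNS}")
        if m != len(self.snp_map):
            raise ValueError(f"{m} dosage columns but {len(self.snp_map)} map rows")
        if len(set(self.sample_ids)) != n:
            raise DuplicateIDError("duplicated sample id")
        if self.snp_map["snp"].duplicated().any():
            dup = self.snp_map.loc[self.snp_map["snp"].duplicated(), "snp"].iloc[0]
            raise DuplicateIDError(f"duplicated SNP id: {dup}")
        # positions must be sorted within chromosome
        for chrom, grp in self.snp_map.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"positions not sorted on chromosome {chrom}")
        called = self.dosages[~np.isnan(self.dosages)]
        if not self.imputed and called.size and not np.isin(called, [0.0, 1.0, 2.0]).all():
            raise ValueError("dosages must be in {0,1,2} or missing")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset(
        self,
        individuals: Sequence[int] | np.ndarray | None = None,
        snps: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Positional subset along either axis; returns a new matrix."""
        d = self.dosages
        ids = self.sample_ids
        smap = self.snp_map
        if individuals is not None:
            individuals = np.asarray(individuals)
            d = d[individuals, :]
            ids = [ids[i] for i in individuals]
        if snps is not None:
            snps = np.asarray(snps)
            d = d[:, snps]
            smap = smap.iloc[snps].reset_index(drop=True)
        return GenotypeMatrix(d.copy(), ids, smap.copy(), imputed=self.imputed)

    def snp_indices(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Positions of the given SNP ids in the panel (order preserved)."""
        lookup = {s: i for i, s in enumerate(self.snp_map["snp"])}
        missing = [s for s in snp_ids if s not in lookup]
        if missing:
            raise KeyError(f"SNPs not in panel: {missing[:5]}")
        return np.array([lookup[s] for s in snp_ids], dtype=int)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _read_vcf(path: Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires cyvcf2") from exc

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:
        raise FormatError(f"{path}: malformed VCF ({exc})") from exc
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise DuplicateIDError(f"{path}: duplicated sample id in header")
    rows = []
    map_rows = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise MultiallelicSiteError(
                f"multiallelic site {v.ID or '.'} at {v.CHROM}:{v.POS} (ALT={','.join(v.ALT)})"
            )
        dose = np.full(len(samples), np.nan, dtype=np.float32)
        for j, gt in enumerate(v.genotypes):
            a = gt[:-1]  # trailing element is the phased flag
            if len(a) == 2 and a[0] >= 0 and a[1] >= 0:
                dose[j] = float(a[0] + a[1])  # half calls stay missing
        rows.append(dose)
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        map_rows.append((vid, str(v.CHROM), int(v.POS), v.REF, v.ALT[0]))
    if not map_rows:
        raise FormatError(f"{path}: no variant records")
    snp_map = pd.DataFrame(map_rows, columns=SNP_MAP_COLUMNS)
    return GenotypeMatrix(np.array(rows, dtype=np.float32).T, samples, snp_map)


def _write_vcf(g: GenotypeMatrix, path: Path) -> None:
    codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        d = g.dosages
        for j, row in enumerate(g.snp_map.itertuples(index=False)):
            gts = [
                "./." if np.isnan(d[i, j]) else codes[round(float(d[i, j]), 0)]
                for i in range(g.n_individuals)
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp}\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# PLINK text (PED/MAP) and binary (BED/BIM/FAM)
# ---------------------------------------------------------------------------

def _read_map(path: Path, *, with_alleles: bool = False) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            f = line.split()
            if not f:
                continue
            want = 6 if with_alleles else 4
            if len(f) < want:
                raise FormatError(f"{path.name} line {lineno}: expected {want} columns")
            if with_alleles:  # BIM: chrom snp cm pos a1 a2
                rows.append((f[1], f[0], int(f[3]), f[5], f[4]))
            else:  # MAP: chrom snp cm pos
                rows.append((f[1], f[0], int(f[3]), "A", "B"))
    return pd.DataFrame(rows, columns=SNP_MAP_COLUMNS)


def _read_plink_text(ped_path: Path) -> GenotypeMatrix:
    ped_path = Path(ped_path)
    map_path = ped_path.with_suffix(".map")
    snp_map = _read_map(map_path)
    m = len(snp_map)
    samples: list[str] = []
    geno_rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            f = line.split()
            if not f:
                continue
            if len(f) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path.name} line {lineno}: expected {6 + 2 * m} fields, got {len(f)}"
                )
            samples.append(f[1])
            geno_rows.append(f[6:])
    alleles = np.array(geno_rows, dtype="U2").reshape(len(samples), m, 2)
    dos = np.full((len(samples), m), np.nan, dtype=np.float32)
    ref = np.empty(m, dtype="U2")
    alt = np.empty(m, dtype="U2")
    for j in range(m):
        col = alleles[:, j, :]
        missing = (col == "0").any(axis=1)
        obs = np.unique(col[~missing])
        if len(obs) > 2:
            raise MultiallelicSiteError(
                f"site {snp_map['snp'].iloc[j]}: more than two alleles {sorted(obs)}"
            )
        if len(obs) == 0:
            ref[j], alt[j] = "A", "B"
            continue
        # orient: minor allele (least frequent) becomes ALT, counted by dosage
        if len(obs) == 1:
            ref[j], alt[j] = obs[0], "B"
            dos[~missing, j] = 0.0
            continue
        counts = [(col[~missing] == a).sum() for a in obs]
        alt_a = obs[int(np.argmin(counts))]
        ref_a = obs[1 - int(np.argmin(counts))]
        ref[j], alt[j] = ref_a, alt_a
        dos[~missing, j] = (col[~missing] == alt_a).sum(axis=1)
    snp_map = snp_map.copy()
    snp_map["ref"] = ref
    snp_map["alt"] = alt
    return GenotypeMatrix(dos, samples, snp_map)


def _write_plink_text(g: GenotypeMatrix, ped_path: Path) -> None:
    ped_path = Path(ped_path)
    map_path = ped_path.with_suffix(".map")
    with open(map_path, "w") as fh:
        for row in g.snp_map.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp}\t0\t{row.pos}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            cells = []
            for j in range(g.n_snps):
                d = g.dosages[i, j]
                ref = g.snp_map["ref"].iloc[j]
                alt = g.snp_map["alt"].iloc[j]
                if np.isnan(d):
                    cells.append("0 0")
                elif d == 0:
                    cells.append(f"{ref} {ref}")
                elif d == 1:
                    cells.append(f"{ref} {alt}")
                else:
                    cells.append(f"{alt} {alt}")
            fh.write(f"FAM {sid} 0 0 0 -9 " + " ".join(cells) + "\n")


_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes, SNP-major: 00 hom A1, 01 missing, 10 het, 11 hom A2
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0], dtype=np.float32)  # A1 counts


def _read_plink_bed(bed_path: Path) -> GenotypeMatrix:
    bed_path = Path(bed_path)
    snp_map = _read_map(bed_path.with_suffix(".bim"), with_alleles=True)
    fam = pd.read_csv(
        bed_path.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str
    )
    samples = fam[1].tolist()
    n, m = len(samples), len(snp_map)
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise FormatError(f"{bed_path.name}: not a SNP-major PLINK BED file")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_snp * m:
        raise FormatError(f"{bed_path.name}: truncated (expected {bytes_per_snp * m} bytes)")
    body = body.reshape(m, bytes_per_snp)
    codes = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    # BIM column a1 was stored as alt in _read_map; dosage counts A1 = ALT
    dos = _BED_DECODE[codes[:, :n]].T.copy()
    return GenotypeMatrix(dos, samples, snp_map)


def _write_plink_bed(g: GenotypeMatrix, bed_path: Path) -> None:
    bed_path = Path(bed_path)
    with open(bed_path.with_suffix(".bim"), "w") as fh:
        for row in g.snp_map.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp}\t0\t{row.pos}\t{row.alt}\t{row.ref}\n")
    with open(bed_path.with_suffix(".fam"), "w") as fh:
        for sid in g.sample_ids:
            fh.write(f"FAM {sid} 0 0 0 -9\n")
    n, m = g.n_individuals, g.n_snps
    encode = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
    bytes_per_snp = (n + 3) // 4
    out = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for j in range(m):
        for i in range(n):
            d = g.dosages[i, j]
            code = 0b01 if np.isnan(d) else encode[float(d)]
            out[j, i // 4] |= code << (2 * (i % 4))
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC)
        out.tofile(fh)


_READERS = {"vcf": _read_vcf, "plink_text": _read_plink_text, "plink_bed": _read_plink_bed}
_WRITERS = {"vcf": _write_vcf, "plink_text": _write_plink_text, "plink_bed": _write_plink_bed}


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Read a genotype matrix.

    ``format`` is one of ``vcf`` (plain-text VCF v4.2), ``plink_text``
    (PED; the matching .map is found by suffix substitution) or
    ``plink_bed`` (BED; .bim/.fam found likewise).  Biallelic sites only;
    half-calls become missing.
    """
    path = Path(path)
    if format not in _READERS:
        raise ValueError(f"unknown format {format!r}; choose from {sorted(_READERS)}")
    if not path.exists():
        raise FileNotFoundError(path)
    return _READERS[format](path)


def write_genotypes(g: GenotypeMatrix, path: str | Path, format: str = "vcf") -> None:
    if format not in _WRITERS:
        raise ValueError(f"unknown format {format!r}; choose from {sorted(_WRITERS)}")
    if g.imputed:
        raise ValueError("cannot write imputed (fractional) dosages to genotype formats")
    _WRITERS[format](g, Path(path))


# ---------------------------------------------------------------------------
# Relationship-matrix exchange format
# ---------------------------------------------------------------------------

def write_matrix(matrix, path: str | Path) -> None:
    """Write a RelationshipMatrix as gzip text: ID header, then the lower
    triangle row by row at 12 significant digits."""
    vals = np.asarray(matrix.values, dtype=float)
    asym = np.abs(vals - vals.T).max() if vals.size else 0.0
    if asym > 1e-8:
        raise ValueError(f"matrix asymmetric beyond 1e-8 (max |K-K'| = {asym:.3g})")
    with gzip.open(path, "wt") as fh:
        fh.write("\t".join(str(i) for i in matrix.ids) + "\n")
        fh.write(f"#kind={matrix.kind}\tn_markers={matrix.n_markers or 0}\n")
        for i in range(vals.shape[0]):
            fh.write("\t".join(f"{v:.12g}" for v in vals[i, : i + 1]) + "\n")


def read_matrix(path: str | Path):
    from .kinship import RelationshipMatrix  # local import: avoid cycle

    with gzip.open(path, "rt") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 2:
        raise FormatError(f"{path}: truncated matrix file")
    ids = lines[0].split("\t")
    meta = dict(kv.split("=") for kv in lines[1].lstrip("#").split("\t"))
    n = len(ids)
    if len(lines) - 2 != n:
        raise FormatError(f"{path}: expected {n} matrix rows, found {len(lines) - 2}")
    vals = np.zeros((n, n))
    for i, ln in enumerate(lines[2:]):
        row = ln.split("\t")
        if len(row) != i + 1:
            raise FormatError(f"{path}: row {i} has {len(row)} entries, expected {i + 1}")
        vals[i, : i + 1] = [float(v) for v in row]
    vals = vals + np.tril(vals, -1).T
    n_markers = int(meta.get("n_markers", 0)) or None
    return RelationshipMatrix(vals, ids, kind=meta.get("kind", "genomic"), n_markers=n_markers)


# ---------------------------------------------------------------------------
# Phenotypes and pedigrees
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype TSV: columns id, sex, batch, generation, then trait columns.

    Empty fields / 'NA' are missing.  One row per id is enforced.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, na_values=["NA", ""])
    for col in ("id", "sex", "batch"):
        if col not in df.columns:
            raise FormatError(f"{path}: phenotype table lacks column '{col}'")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise DuplicateIDError(f"{path}: duplicated phenotype id {dup}")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def validate_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Check ids unique, parents known-or-NA, and ordering acyclic.

    Returns the frame sorted so that parents precede offspring.
    """
    for col in ("id", "sire", "dam"):
        if col not in ped.columns:
            raise FormatError(f"pedigree lacks column '{col}'")
    ped = ped.copy()
    ped["id"] = ped["id"].astype(str)
    for col in ("sire", "dam"):
        ped[col] = ped[col].astype("string").replace({"0": pd.NA, "nan": pd.NA, "<NA>": pd.NA})
    if ped["id"].duplicated().any():
        raise DuplicateIDError("duplicated pedigree id")
    known = set(ped["id"])
    for col in ("sire", "dam"):
        bad = ped.loc[ped[col].notna() & ~ped[col].isin(known), col]
        if len(bad):
            raise FormatError(f"unknown {col} id: {bad.iloc[0]}")
    # Kahn topological sort; cycle -> error
    order: list[int] = []
    placed: set[str] = set()
    remaining = ped
    while len(remaining):
        ready = remaining[
            (remaining["sire"].isna() | remaining["sire"].isin(placed))
            & (remaining["dam"].isna() | remaining["dam"].isin(placed))
        ]
        if ready.empty:
            raise ValueError("pedigree contains a cycle")
        order.extend(ready.index.tolist())
        placed.update(ready["id"])
        remaining = remaining.drop(ready.index)
    return ped.loc[order].reset_index(drop=True)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    ped = pd.read_csv(path, dtype=str)
    return validate_pedigree(ped)


def write_pedigree(ped: pd.DataFrame, path: str | Path) -> None:
    ped.to_csv(path, index=False, na_rep="")
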