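"""I/O: VCF/PLINK round trips, typed parse errors, matrix exchange format."""

import gzip

import numpy as np
import pandas as pd
import pytest

from gblupkit import genio
from gblupkit.genio import (
    DuplicateIDError,
    FormatError,
    GenotypeMatrix,
    MultiallelicSiteError,
    read_genotypes,
    read_matrix,
    read_pedigree,
    validate_pedigree,
    write_genotypes,
    write_matrix,
)
from gblupkit.kinship import RelationshipMatrix


def _matrix(dosages, ids=None, chrom="1"):
    dosages = np.asarray(dosages, dtype=np.float32)
    n, m = dosages.shape
    ids = ids or [f"s{i}" for i in range(n)]
    smap = pd.DataFrame(
        {
            "snp": [f"v{j}" for j in range(m)],
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * 100,
            "ref": "A",
            "alt": "C",
        }
    )
    return GenotypeMatrix(dosages, ids, smap)


def _write_vcf_text(path, body, samples=("s1", "s2")):
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    lines += body
    path.write_text("\n".join(lines) + "\n")


class TestVCF:
    def test_direct_gt_coding(self, tmp_path):
        p = tmp_path / "t.vcf"
        _write_vcf_text(
            p,
            [
                "1\t100\tv1\tA\tC\t.\t.\t.\tGT\t0/0\t0/0",
                "1\t200\tv2\tA\tC\t.\t.\t.\tGT\t0/1\t0/1",
                "1\t300\tv3\tA\tC\t.\t.\t.\tGT\t1/1\t1/1",
            ],
        )
        g = read_genotypes(p, "vcf")
        assert g.sample_ids == ["s1", "s2"]
        np.testing.assert_array_equal(g.dosages[0], [0, 1, 2])
        assert g.snp_map["pos"].tolist() == [100, 200, 300]

    def test_missing_and_half_calls(self, tmp_path):
        p = tmp_path / "t.vcf"
        _write_vcf_text(
            p,
            ["1\t100\tv1\tA\tC\t.\t.\t.\tGT\t./.\t./1"],
        )
        g = read_genotypes(p, "vcf")
        assert np.isnan(g.dosages).all()

    def test_multiallelic_rejected_names_site(self, tmp_path):
        p = tmp_path / "t.vcf"
        _write_vcf_text(
            p,
            [
                "1\t100\tv1\tA\tC\t.\t.\t.\tGT\t0/0\t0/1",
                "1\t200\tbad_site\tA\tC,G\t.\t.\t.\tGT\t1/2\t0/0",
            ],
        )
        with pytest.raises(MultiallelicSiteError, match="bad_site"):
            read_genotypes(p, "vcf")

    def test_round_trip(self, tmp_path, rng):
        d = rng.integers(0, 3, size=(5, 8)).astype(np.float32)
        d[1, 2] = np.nan
        g = _matrix(d)
        write_genotypes(g, tmp_path / "rt.vcf", "vcf")
        g2 = read_genotypes(tmp_path / "rt.vcf", "vcf")
        np.testing.assert_array_equal(np.nan_to_num(g.dosages, nan=-1),
                                      np.nan_to_num(g2.dosages, nan=-1))
        assert g2.sample_ids == g.sample_ids
        assert g2.snp_map["snp"].tolist() == g.snp_map["snp"].tolist()

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_genotypes(tmp_path / "nope.vcf", "vcf")

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError, match="unknown format"):
            read_genotypes(tmp_path / "x", "bgen")


class TestPlink:
    def test_text_round_trip(self, tmp_path, rng):
        d = rng.integers(0, 3, size=(6, 10)).astype(np.float32)
        # guarantee every SNP is polymorphic with ALT minor so orientation survives
        d[:, :] = np.clip(d, 0, 2)
        d[0] = 0
        d[1] = np.where(d[1] > 1, 1, d[1])
        g = _matrix(d)
        write_genotypes(g, tmp_path / "t.ped", "plink_text")
        g2 = read_genotypes(tmp_path / "t.ped", "plink_text")
        # orientation may flip where ALT is the major allele: compare MAF pattern
        f1 = np.nanmean(g.dosages, axis=0) / 2
        f2 = np.nanmean(g2.dosages, axis=0) / 2
        np.testing.assert_allclose(np.minimum(f1, 1 - f1), np.minimum(f2, 1 - f2), atol=1e-6)

    def test_bed_round_trip(self, tmp_path, rng):
        d = rng.integers(0, 3, size=(7, 9)).astype(np.float32)
        d[2, 4] = np.nan
        g = _matrix(d)
        write_genotypes(g, tmp_path / "t.bed", "plink_bed")
        g2 = read_genotypes(tmp_path / "t.bed", "plink_bed")
        np.testing.assert_array_equal(np.nan_to_num(g.dosages, nan=-1),
                                      np.nan_to_num(g2.dosages, nan=-1))
        assert g2.sample_ids == g.sample_ids

    def test_bed_bad_magic(self, tmp_path):
        (tmp_path / "t.bim").write_text("1\tv1\t0\t100\tC\tA\n")
        (tmp_path / "t.fam").write_text("FAM s1 0 0 0 -9\n")
        (tmp_path / "t.bed").write_bytes(b"\x00\x00\x00\x00")
        with pytest.raises(FormatError, match="BED"):
            read_genotypes(tmp_path / "t.bed", "plink_bed")


class TestMatrixExchange:
    def test_identity_round_trip(self, tmp_path):
        rm = RelationshipMatrix(np.eye(3), ["a", "b", "c"], kind="pedigree")
        write_matrix(rm, tmp_path / "m.txt.gz")
        rm2 = read_matrix(tmp_path / "m.txt.gz")
        np.testing.assert_array_equal(rm2.values, np.eye(3))
        assert rm2.ids == ["a", "b", "c"]
        assert rm2.kind == "pedigree"

    def test_spd_round_trip_precision(self, tmp_path, rng):
        b = rng.normal(size=(50, 60))
        k = b @ b.T / 60
        rm = RelationshipMatrix(k, [f"i{j}" for j in range(50)], n_markers=60)
        write_matrix(rm, tmp_path / "m.txt.gz")
        rm2 = read_matrix(tmp_path / "m.txt.gz")
        assert np.abs(rm2.values - k).max() < 1e-10
        assert rm2.n_markers == 60

    def test_asymmetric_rejected(self, tmp_path):
        rm = RelationshipMatrix.__new__(RelationshipMatrix)
        rm.values = np.array([[1.0, 0.5], [0.2, 1.0]])
        rm.ids = ["a", "b"]
        rm.kind = "genomic"
        rm.n_markers = None
        rm.sum2pq = None
        with pytest.raises(ValueError, match="asymmetric"):
            write_matrix(rm, tmp_path / "m.txt.gz")

    def test_tampered_missing_row(self, tmp_path):
        rm = RelationshipMatrix(np.eye(3), ["a", "b", "c"])
        write_matrix(rm, tmp_path / "m.txt.gz")
        with gzip.open(tmp_path / "m.txt.gz", "rt") as fh:
            lines = fh.readlines()
        with gzip.open(tmp_path / "m.txt.gz", "wt") as fh:
            fh.writelines(lines[:-1])
        with pytest.raises(FormatError):
            read_matrix(tmp_path / "m.txt.gz")


class TestTypes:
    def test_duplicate_sample_id(self):
        with pytest.raises(DuplicateIDError):
            _matrix(np.zeros((2, 3)), ids=["a", "a"])

    def test_unsorted_positions_rejected(self):
        smap = pd.DataFrame(
            {"snp": ["v1", "v2"], "chrom": "1", "pos": [200, 100], "ref": "A", "alt": "C"}
        )
        with pytest.raises(ValueError, match="sorted"):
            GenotypeMatrix(np.zeros((1, 2), dtype=np.float32), ["s"], smap)

    def test_bad_dosage_value(self):
        with pytest.raises(ValueError, match="dosages"):
            _matrix(np.array([[3.0, 0.0]]))

    def test_pedigree_cycle(self):
        ped = pd.DataFrame(
            {"id": ["a", "b"], "sire": ["b", "a"], "dam": [None, None]}
        )
        with pytest.raises(ValueError, match="cycle"):
            validate_pedigree(ped)

    def test_pedigree_unknown_parent(self):
        ped = pd.DataFrame({"id": ["a"], "sire": ["ghost"], "dam": [None]})
        with pytest.raises(FormatError, match="ghost"):
            validate_pedigree(ped)

    def test_pedigree_round_trip(self, tmp_path):
        ped = pd.DataFrame(
            {
                "id": ["f1", "f2", "k1"],
                "sire": [None, None, "f1"],
                "dam": [None, None, "f2"],
                "sex": ["M", "F", "M"],
                "generation": [0, 0, 1],
                "batch": [0, 0, 1],
            }
        )
        genio.write_pedigree(ped, tmp_path / "p.csv")
        ped2 = read_pedigree(tmp_path / "p.csv")
        assert ped2["id"].tolist() == ["f1", "f2", "k1"]
        assert ped2["sire"].tolist()[-1] == "f1"
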