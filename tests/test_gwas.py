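"""GWAS: calibration, thresholds, LD, interval delimitation, pruning."""

import numpy as np
import pandas as pd
import pytest

from gblupkit.genio import GenotypeMatrix
from gblupkit.gwas import (
    bonferroni_threshold,
    define_qtl_interval,
    ld_prune,
    ld_r2,
    mlm_assoc,
)
from gblupkit.kinship import compute_grm


def _geno(d, chrom=None, pos=None):
    d = np.asarray(d, dtype=np.float32)
    n, m = d.shape
    smap = pd.DataFrame(
        {
            "snp": [f"v{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "ref": "A",
            "alt": "C",
        }
    )
    return GenotypeMatrix(d, [f"i{k}" for k in range(n)], smap)


def _pheno(ids, y):
    return pd.DataFrame({"id": ids, "sex": "M", "batch": 1, "y": y})


class TestBonferroni:
    def test_printed_threshold(self):
        # 0.05 / 151,519 = 3.30e-7 to three significant figures
        thr = bonferroni_threshold(0.05, 151_519)
        assert f"{thr:.3g}" == "3.3e-07"
        assert thr == pytest.approx(3.30e-7, rel=5e-3)

    def test_single_test(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_hundred_tests(self):
        assert bonferroni_threshold(0.01, 100) == pytest.approx(1e-4)

    def test_validation(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestMLMAssoc:
    def test_qtl_snp_is_top_hit(self, rng):
        n, m = 500, 400
        p = rng.uniform(0.2, 0.8, size=m)
        d = rng.binomial(2, p, size=(n, m))
        g = _geno(d)
        zc = d - d.mean(axis=0)
        qtl = 137
        gval = zc[:, qtl] * 1.0
        gval = gval / gval.std() * np.sqrt(0.20)
        e = rng.normal(size=n) * np.sqrt(0.80)
        ph = _pheno(g.sample_ids, 3.0 + gval + e)
        assoc = mlm_assoc(g, ph, "y", compute_grm(g))
        assert assoc.table["p"].idxmin() == qtl

    def test_pvalues_invariant_to_shift_and_scale(self, rng):
        n, m = 200, 100
        d = rng.binomial(2, 0.4, size=(n, m))
        g = _geno(d)
        y = rng.normal(size=n)
        a1 = mlm_assoc(g, _pheno(g.sample_ids, y), "y", compute_grm(g))
        a2 = mlm_assoc(g, _pheno(g.sample_ids, 100.0 + 7.0 * y), "y", compute_grm(g))
        np.testing.assert_allclose(a1.table["p"], a2.table["p"], rtol=1e-6)

    def test_monomorphic_flagged(self, rng):
        d = rng.binomial(2, 0.4, size=(100, 10))
        d[:, 3] = 2
        g = _geno(d)
        ph = _pheno(g.sample_ids, rng.normal(size=100))
        assoc = mlm_assoc(g, ph, "y", compute_grm(g))
        row = assoc.table.iloc[3]
        assert row["flag"] == "monomorphic"
        assert row["p"] == 1.0

    def test_permutation_null(self, rng):
        """Permuted phenotypes: no Bonferroni hit in >= 19 of 20 permutations."""
        n, m = 300, 600
        p = rng.uniform(0.1, 0.9, size=m)
        d = rng.binomial(2, p, size=(n, m))
        g = _geno(d)
        G = compute_grm(g)
        zc = d - d.mean(axis=0)
        y = 0.1 * zc @ rng.normal(size=m) + rng.normal(size=n)
        thr = bonferroni_threshold(0.05, m)
        hits = 0
        for _rep in range(20):
            perm = rng.permutation(n)
            assoc = mlm_assoc(g, _pheno(g.sample_ids, y[perm]), "y", G)
            if (assoc.table["p"] < thr).any():
                hits += 1
        assert hits <= 1

    def test_deterministic(self, cohort_small, mid_analysis):
        g = cohort_small["genotypes"]
        ph = cohort_small["phenotypes"]
        G = compute_grm(g)
        a1 = mlm_assoc(g, ph, "adg", G)
        a2 = mlm_assoc(g, ph, "adg", G)
        pd.testing.assert_frame_equal(a1.table, a2.table)


class TestLDr2:
    def test_self_r2_is_one(self, rng):
        g = _geno(rng.binomial(2, 0.4, size=(50, 20)))
        out = ld_r2(g, "v5")
        assert out.loc[out["snp"] == "v5", "r2"].iloc[0] == 1.0

    def test_independent_snps_near_zero(self, rng):
        d = rng.binomial(2, 0.5, size=(2000, 2))
        g = _geno(d)
        out = ld_r2(g, "v0")
        assert out.loc[out["snp"] == "v1", "r2"].iloc[0] < 0.01

    def test_hand_computed_pearson(self, rng):
        a = rng.binomial(2, 0.5, size=100).astype(float)
        b = a.copy()
        b[3] = 2 - b[3]
        b[57] = 2 - b[57]
        g = _geno(np.column_stack([a, b]))
        out = ld_r2(g, "v0")
        expected = np.corrcoef(a, b)[0, 1] ** 2
        assert out.loc[out["snp"] == "v1", "r2"].iloc[0] == pytest.approx(expected, abs=1e-8)

    def test_window_limits(self, rng):
        d = rng.binomial(2, 0.4, size=(30, 10))
        pos = (np.arange(10) * 30_000_000 + 1).tolist()  # 30 Mb apart
        g = _geno(d, pos=pos)
        out = ld_r2(g, "v0", window_kb=20_000)
        assert out["snp"].tolist() == ["v0"]  # everything else out of window


def _block_panel(rng, n=400, flank=10):
    """LD block (20 near-copies) flanked by independent markers."""
    block_core = rng.binomial(2, 0.5, size=n)
    cols, chroms = [], []
    for j in range(flank):  # left flank, independent
        cols.append(rng.binomial(2, 0.5, size=n))
    for j in range(20):  # the block: copies with 0.5% flips (pairwise r2 ~ 0.96)
        c = block_core.copy()
        flip = rng.random(n) < 0.005
        c[flip] = 2 - c[flip]
        cols.append(c)
    for j in range(flank):  # right flank
        cols.append(rng.binomial(2, 0.5, size=n))
    return np.column_stack(cols), block_core


class TestIntervals:
    def test_block_interval_excludes_flanks(self, rng):
        d, core = _block_panel(rng, n=1200, flank=80)
        g = _geno(d)
        zc = core - core.mean()
        y = zc / zc.std() * np.sqrt(0.3) + rng.normal(size=len(core)) * np.sqrt(0.7)
        assoc = mlm_assoc(g, _pheno(g.sample_ids, y), "y", compute_grm(g))
        thr = 1e-6
        ivs = define_qtl_interval(assoc, g, thr)
        assert len(ivs) == 1
        iv = ivs[0]
        block_pos = g.snp_map["pos"].iloc[80:100]
        assert iv.start_bp >= g.snp_map["pos"].iloc[79]
        assert iv.end_bp <= g.snp_map["pos"].iloc[100]
        lead_in_block = np.argmin(assoc.table["p"].iloc[80:100].to_numpy())
        assert iv.start_bp <= block_pos.iloc[lead_in_block] <= iv.end_bp

    def test_isolated_snp_degenerate_interval(self, rng):
        n, m = 300, 30
        d = rng.binomial(2, 0.5, size=(n, m))
        g = _geno(d)
        zc = d[:, 11] - d[:, 11].mean()
        y = zc / zc.std() * np.sqrt(0.25) + rng.normal(size=n) * np.sqrt(0.75)
        assoc = mlm_assoc(g, _pheno(g.sample_ids, y), "y", compute_grm(g))
        thr = float(assoc.table["p"].iloc[11]) * 1.001
        ivs = define_qtl_interval(assoc, g, thr)
        lead = [iv for iv in ivs if iv.lead_snp == "v11"]
        assert lead and lead[0].start_bp == lead[0].end_bp == g.snp_map["pos"].iloc[11]

    def test_two_chromosomes_never_merged(self, rng):
        n = 400
        d = rng.binomial(2, 0.5, size=(n, 40))
        chrom = ["1"] * 20 + ["2"] * 20
        pos = list(np.arange(1, 21) * 1000) * 2
        g = _geno(d, chrom=chrom, pos=pos)
        z1 = d[:, 5] - d[:, 5].mean()
        z2 = d[:, 25] - d[:, 25].mean()
        y = (z1 / z1.std() + z2 / z2.std()) * np.sqrt(0.15) + rng.normal(size=n) * 0.8
        assoc = mlm_assoc(g, _pheno(g.sample_ids, y), "y", compute_grm(g))
        thr = max(assoc.table["p"].iloc[5], assoc.table["p"].iloc[25]) * 1.001
        ivs = define_qtl_interval(assoc, g, thr)
        assert {iv.chrom for iv in ivs} == {"1", "2"}

    def test_none_significant_empty(self, rng):
        d = rng.binomial(2, 0.5, size=(100, 20))
        g = _geno(d)
        assoc = mlm_assoc(g, _pheno(g.sample_ids, rng.normal(size=100)), "y",
                          compute_grm(g))
        assert define_qtl_interval(assoc, g, 1e-30) == []

    def test_deterministic(self, mid_analysis, cohort_mid):
        ivs1 = define_qtl_interval(
            mid_analysis["assoc"], cohort_mid["genotypes"], mid_analysis["threshold"]
        )
        ivs2 = mid_analysis["intervals"]
        assert [(i.chrom, i.start_bp, i.end_bp) for i in ivs1] == [
            (i.chrom, i.start_bp, i.end_bp) for i in ivs2
        ]


class TestPruning:
    def test_no_high_ld_all_retained(self, rng):
        d = rng.binomial(2, 0.5, size=(500, 40))
        g = _geno(d)
        assert ld_prune(g) == g.snp_map["snp"].tolist()

    def test_duplicate_column_one_retained(self, rng):
        a = rng.binomial(2, 0.5, size=200)
        d = np.column_stack([a, a, rng.binomial(2, 0.5, size=200)])
        g = _geno(d)
        kept = ld_prune(g)
        assert "v0" in kept and "v1" not in kept and "v2" in kept

    def test_block_pruned_and_tagging_oracle(self, rng):
        d, _core = _block_panel(rng)
        g = _geno(d)
        kept = ld_prune(g, r2_max=0.9)
        kept_set = set(kept)
        all_snps = g.snp_map["snp"].tolist()
        # all independent flanks retained
        for s in all_snps[:10] + all_snps[30:]:
            assert s in kept_set
        block = all_snps[10:30]
        n_kept_block = sum(s in kept_set for s in block)
        assert n_kept_block < 10  # far fewer than 20
        # every dropped SNP is tagged at r2 > 0.9 by a survivor
        dall = d.astype(float)
        idx = {s: j for j, s in enumerate(all_snps)}
        for s in block:
            if s in kept_set:
                continue
            r2s = [
                np.corrcoef(dall[:, idx[s]], dall[:, idx[t]])[0, 1] ** 2
                for t in kept
            ]
            assert max(r2s) > 0.9

    def test_idempotent(self, rng):
        d, _core = _block_panel(rng)
        g = _geno(d)
        kept = ld_prune(g)
        sub = g.subset(snps=g.snp_indices(kept))
        assert ld_prune(sub) == kept
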