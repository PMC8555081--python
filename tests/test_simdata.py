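"""Simulator: LD structure, gene dropping, architecture recovery, determinism."""

import numpy as np
import pandas as pd
import pytest

from gblupkit.simdata import (
    SimConfig,
    TraitArchitecture,
    mask_missing,
    simulate_founder_haplotypes,
    simulate_pedigree_and_drop,
)


def _adjacent_r2(hap):
    h = hap.astype(float)
    c = np.corrcoef(h, rowvar=False)
    return np.array([c[j, j + 1] ** 2 for j in range(h.shape[1] - 1)])


def _r2_at_sep(hap, sep):
    h = hap.astype(float)
    c = np.corrcoef(h, rowvar=False)
    return np.array([c[j, j + sep] ** 2 for j in range(h.shape[1] - sep)])


class TestFounderHaplotypes:
    def test_rho_zero_independence(self):
        cfg = SimConfig(n_founders=500, n_chromosomes=1, snps_per_chromosome=200,
                        ld_decay_rho=0.0, seed=5)
        f = simulate_founder_haplotypes(cfg)
        r2 = _adjacent_r2(f["haplotypes"]["1"])
        # 1000 haplotypes: E[r2] under independence ~ 1/n
        assert np.nanmean(r2) < 0.01

    def test_ld_decays_with_distance(self):
        cfg = SimConfig(n_founders=500, n_chromosomes=1, snps_per_chromosome=200,
                        ld_decay_rho=0.95, seed=5)
        f = simulate_founder_haplotypes(cfg)
        hap = f["haplotypes"]["1"]
        assert np.nanmean(_adjacent_r2(hap)) > np.nanmean(_r2_at_sep(hap, 50))

    def test_seed_determinism(self):
        cfg = SimConfig(n_founders=50, n_chromosomes=2, snps_per_chromosome=100, seed=9)
        a = simulate_founder_haplotypes(cfg)
        b = simulate_founder_haplotypes(cfg)
        for c in a["haplotypes"]:
            np.testing.assert_array_equal(a["haplotypes"][c], b["haplotypes"][c])

    def test_allele_freq_range(self):
        cfg = SimConfig(n_founders=400, n_chromosomes=1, snps_per_chromosome=300, seed=2)
        f = simulate_founder_haplotypes(cfg)
        freq = f["haplotypes"]["1"].mean(axis=0)
        assert freq.min() > 0.0 and freq.max() < 1.0

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_founders=0)
        with pytest.raises(ValueError):
            SimConfig(ld_decay_rho=1.0)


class TestGeneDropping:
    def test_no_recombination_copies_parent(self):
        # ~10 kb chromosome => expected crossovers 1e-4; none occur in practice
        cfg = SimConfig(n_founders=2, n_offspring=10, n_chromosomes=1,
                        snps_per_chromosome=50, chrom_length_bp=10_000,
                        ld_decay_rho=0.0, seed=3, n_sires=1, n_dams=1)
        f = simulate_founder_haplotypes(cfg)
        matings = pd.DataFrame(
            {"id": [f"kid{i}" for i in range(10)], "sire": "F0000", "dam": "F0001",
             "generation": 1}
        )
        ped, geno, store = simulate_pedigree_and_drop(cfg, f, matings=matings)
        sire_haps = store["F0000"]["1"]
        dam_haps = store["F0001"]["1"]
        for kid in matings["id"]:
            pat, mat = store[kid]["1"]
            assert any((pat == h).all() for h in sire_haps)
            assert any((mat == h).all() for h in dam_haps)

    def test_unknown_parent_rejected(self):
        cfg = SimConfig(n_founders=4, n_offspring=2, n_chromosomes=1,
                        snps_per_chromosome=20, seed=1, n_sires=1, n_dams=3)
        f = simulate_founder_haplotypes(cfg)
        matings = pd.DataFrame({"id": ["x"], "sire": ["nobody"], "dam": ["F0001"],
                                "generation": [1]})
        with pytest.raises(ValueError, match="unknown parent"):
            simulate_pedigree_and_drop(cfg, f, matings=matings)

    def test_parent_offspring_dosage_correlation(self):
        # independent markers: corr(parent dosage, child dosage) ~ 0.5 (a = 0.5)
        cfg = SimConfig(n_founders=220, n_offspring=200, n_chromosomes=2,
                        snps_per_chromosome=300, ld_decay_rho=0.0, seed=4,
                        n_sires=20, n_dams=200)
        f = simulate_founder_haplotypes(cfg)
        ped, geno, store = simulate_pedigree_and_drop(cfg, f)
        gen1 = ped[ped["generation"] == 1]
        # correlate each gen-1 bird with its sire (founder) over SNPs; dosages
        # must be centered per SNP or allele-frequency variation dominates
        chroms = sorted(store["F0000"], key=int)
        def dosage(i):
            return np.concatenate([store[i][c].sum(axis=0) for c in chroms]).astype(float)
        founder_ids = ped.loc[ped["generation"] == 0, "id"]
        center = np.mean([dosage(i) for i in founder_ids], axis=0)
        cors = []
        for row in gen1.head(200).itertuples(index=False):
            a, b = dosage(row.id) - center, dosage(row.sire) - center
            if a.std() and b.std():
                cors.append(np.corrcoef(a, b)[0, 1])
        assert len(cors) >= 150
        assert abs(np.mean(cors) - 0.5) < 0.07

    def test_full_sibs_more_similar_than_unrelated(self):
        cfg = SimConfig(n_founders=40, n_offspring=30, n_chromosomes=1,
                        snps_per_chromosome=400, ld_decay_rho=0.0, seed=8,
                        n_sires=2, n_dams=38)
        f = simulate_founder_haplotypes(cfg)
        sibs = pd.DataFrame({"id": [f"sib{i}" for i in range(30)], "sire": "F0000",
                             "dam": "F0002", "generation": 1})
        other = pd.DataFrame({"id": [f"un{i}" for i in range(30)], "sire": "F0001",
                              "dam": "F0003", "generation": 1})
        ped, geno, store = simulate_pedigree_and_drop(
            cfg, f, matings=pd.concat([sibs, other], ignore_index=True)
        )
        d = geno.dosages.astype(float)
        ids = geno.sample_ids
        def mean_corr(group_a, group_b):
            cors = []
            for i in group_a:
                for j in group_b:
                    if i < j:
                        a, b = d[ids.index(i)], d[ids.index(j)]
                        cors.append(np.corrcoef(a, b)[0, 1])
            return np.mean(cors)
        sib_ids = [f"sib{i}" for i in range(10)]
        un_ids = [f"un{i}" for i in range(10)]
        within_sibs = mean_corr(sib_ids, sib_ids)
        across = np.mean([np.corrcoef(d[ids.index(a)], d[ids.index(b)])[0, 1]
                          for a in sib_ids for b in un_ids])
        assert within_sibs > across

    def test_pedigree_bookkeeping(self, cohort_small):
        ped = cohort_small["pedigree"]
        assert set(ped["generation"].unique()) == {0, 1, 2}
        off = ped[ped["generation"] > 0]
        assert off["sire"].notna().all() and off["dam"].notna().all()
        assert set(off["batch"].unique()) <= set(range(1, 7))
        assert set(off["sex"].unique()) == {"M", "F"}


class TestPhenotypes:
    def test_adg_identity_exact(self, cohort_small):
        ph = cohort_small["phenotypes"]
        np.testing.assert_array_equal(
            ph["adg"].to_numpy(), ((ph["dw84"] - ph["dw42"]) / 42.0).to_numpy()
        )

    def test_truth_is_dosage_weighted_sum(self, cohort_small):
        g = cohort_small["genotypes"]
        tr = cohort_small["truth"]
        d = g.dosages.astype(float)
        zc = d - d.mean(axis=0)
        np.testing.assert_allclose(
            zc @ tr.snp_effects["effect"].to_numpy(), tr.genetic_value, atol=1e-8
        )

    def test_zero_heritability(self):
        cfg = SimConfig(n_founders=300, n_offspring=1000, n_chromosomes=2,
                        snps_per_chromosome=200, seed=21)
        arch = TraitArchitecture(h2_target=0.0, major_qtl=("1", 25_000_000, 0.30),
                                 polygenic_fraction=0.70)
        from gblupkit.simdata import simulate_cohort
        c = simulate_cohort(cfg, arch)
        assert np.allclose(c["truth"].genetic_value, 0.0)
        assert np.allclose(c["truth"].snp_effects["effect"], 0.0)
        ph = c["phenotypes"]
        resid = ph["dw84"] - ph["dw42"]
        cell = ph["batch"].astype(str) + ph["sex"]
        within = resid - resid.groupby(cell).transform("mean")
        assert abs(within.var() / arch.gain_sd**2 - 1.0) < 0.05

    def test_h2_recovered_from_truth(self):
        cfg = SimConfig(n_founders=300, n_offspring=1000, n_chromosomes=2,
                        snps_per_chromosome=200, seed=22)
        arch = TraitArchitecture(h2_target=0.4, major_qtl=("1", 25_000_000, 0.30),
                                 polygenic_fraction=0.70)
        from gblupkit.simdata import simulate_cohort
        c = simulate_cohort(cfg, arch)
        ph = c["phenotypes"]
        cell = ph["batch"].astype(str) + ph["sex"]
        y = ph["adg"] - ph["adg"].groupby(cell).transform("mean")
        ratio = (c["truth"].genetic_value / 42.0).var() / y.var()
        assert 0.35 < ratio < 0.45

    def test_major_qtl_fraction(self, cohort_mid):
        tr = cohort_mid["truth"]
        total = tr.genetic_value.var()
        major = tr.component_values["major"].to_numpy()
        assert 0.25 < major.var() / total < 0.35

    def test_component_decomposition_consistent(self, cohort_mid):
        tr = cohort_mid["truth"]
        cv = tr.component_values
        np.testing.assert_allclose(
            cv.sum(axis=1).to_numpy(), tr.genetic_value, atol=1e-8
        )
        # polygenic part is orthogonal to the QTL columns by construction
        corr = np.corrcoef(cv["major"], cv["polygenic"])[0, 1]
        assert abs(corr) < 1e-8

    def test_fraction_sum_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TraitArchitecture(major_qtl=("1", 1000, 0.5), polygenic_fraction=0.7)
        with pytest.raises(ValueError, match="h2_target"):
            TraitArchitecture(h2_target=1.5)

    def test_bit_exact_reproducibility(self):
        from gblupkit.simdata import simulate_cohort
        cfg = SimConfig(n_founders=60, n_offspring=80, n_chromosomes=2,
                        snps_per_chromosome=100, seed=31)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        np.testing.assert_array_equal(a["genotypes"].dosages, b["genotypes"].dosages)
        pd.testing.assert_frame_equal(a["phenotypes"], b["phenotypes"])
        np.testing.assert_array_equal(a["truth"].genetic_value, b["truth"].genetic_value)


class TestMasking:
    def test_mask_rate(self, cohort_small):
        g = mask_missing(cohort_small["genotypes"], 0.2, seed=1)
        rate = np.isnan(g.dosages).mean()
        assert 0.17 < rate < 0.23

    def test_mask_validation(self, cohort_small):
        with pytest.raises(ValueError):
            mask_missing(cohort_small["genotypes"], 1.2)
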