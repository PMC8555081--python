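"""Shared fixtures: simulated cohorts at two scales, plus a fully analysed
mid-size cohort (kinships, GWAS, CV plan) reused by the integration tests.

Everything is generated at test time from fixed seeds; no data files ship
with the repository.
"""

import numpy as np
import pytest

from gblupkit.evalx import DataBundle, adjust_phenotype, make_cv_plan
from gblupkit.gwas import bonferroni_threshold, define_qtl_interval, mlm_assoc
from gblupkit.kinship import compute_grm, compute_nrm
from gblupkit.simdata import SimConfig, TraitArchitecture, simulate_cohort


@pytest.fixture(scope="session")
def cohort_small():
    """~400 genotyped birds, 900 SNPs, one 30% major QTL."""
    cfg = SimConfig(
        n_founders=120,
        n_offspring=200,
        n_chromosomes=3,
        snps_per_chromosome=300,
        chrom_length_bp=50_000_000,
        ld_decay_rho=0.9,
        seed=11,
    )
    arch = TraitArchitecture(
        h2_target=0.4,
        major_qtl=("1", 25_000_000, 0.30),
        minor_qtl=[],
        polygenic_fraction=0.70,
        n_polygenic_snps=400,
    )
    return simulate_cohort(cfg, arch)


@pytest.fixture(scope="session")
def cohort_mid():
    """~1000 genotyped birds, 1800 SNPs, major + minor QTL + polygenic tail."""
    cfg = SimConfig(
        n_founders=250,
        n_offspring=500,
        n_chromosomes=3,
        snps_per_chromosome=600,
        chrom_length_bp=60_000_000,
        ld_decay_rho=0.92,
        seed=7,
    )
    arch = TraitArchitecture(
        h2_target=0.4,
        major_qtl=("1", 30_000_000, 0.30),
        minor_qtl=[("2", 20_000_000, 0.03), ("3", 45_000_000, 0.02)],
        polygenic_fraction=0.65,
        n_polygenic_snps=600,
    )
    return simulate_cohort(cfg, arch)


@pytest.fixture(scope="session")
def mid_analysis(cohort_mid):
    """Kinships, GWAS, adjusted phenotype, CV plan and bundle for cohort_mid."""
    g = cohort_mid["genotypes"]
    ph = cohort_mid["phenotypes"]
    ped = cohort_mid["pedigree"]
    G = compute_grm(g)
    A = compute_nrm(ped)
    assoc = mlm_assoc(g, ph, "adg", G)
    thr = bonferroni_threshold(0.05, g.n_snps)
    intervals = define_qtl_interval(assoc, g, thr)
    adj = adjust_phenotype(ph, ped, "adg", A=A)
    plan = make_cv_plan(g.sample_ids, k=5, seed=1)
    bundle = DataBundle(pheno=ph, trait="adg", yc=adj.yc, G=G, A=A, genotypes=g)
    return {
        "G": G,
        "A": A,
        "assoc": assoc,
        "threshold": thr,
        "intervals": intervals,
        "yc": adj.yc,
        "plan": plan,
        "bundle": bundle,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
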