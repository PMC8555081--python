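# gblupkit

Genomic evaluation of simulated two-generation breeding cohorts: mixed-linear-model
GWAS, GBLUP / GFBLUP / ABLUP prediction with tenfold cross-validation, and
QTL-contribution statistics — exercised end to end on a built-in cohort simulator,
so the whole pipeline is testable without any external data.

## What's inside

| module    | role |
|-----------|------|
| `simdata` | synthetic cohorts: LD-structured founder haplotypes, gene dropping through a two-generation pedigree, batch/sex fixed effects, one major QTL + minor QTL + polygenic tail, four growth traits (42/84-day weight, ADG, FCR) with exact truth sidecars |
| `genio`   | VCF v4.2 (GT), PLINK PED/MAP and BED/BIM/FAM, phenotype/pedigree tables, gzip text exchange format for relationship matrices |
| `qc`      | MAF / missing-rate / Hardy-Weinberg filters with reconciled removal bookkeeping and per-SNP mean imputation |
| `kinship` | VanRaden method-1 GRM (with exact feature/remainder partition pairs), tabular pedigree NRM, PCA |
| `varcomp` | EM -> average-information REML for one- and two-kernel mixed models; genomic heritability |
| `blup`    | mixed-model solutions for ABLUP/GBLUP/GFBLUP with prediction error variance and theoretical accuracy, including unphenotyped (validation) individuals |
| `gwas`    | single-SNP mixed-linear-model association (two-step GLS in the kernel eigenbasis), Bonferroni thresholds, LD r², LD-delimited QTL intervals, windowed LD pruning |
| `evalx`   | adjusted phenotypes (Yc), cross-validation plans, observed/theoretical accuracy and inflation, reference-size curves |
| `contrib` | QTL contributions: full-vs-reduced model, two-GRM partition, top-SNP removal curves |
| `app`     | one-command pipeline (`sim -> qc -> grm -> gwas -> cv -> gfblup -> contrib`) with provenance, plus the CLI |

## Quick start (Python)

```python
from gblupkit.simdata import SimConfig, TraitArchitecture, simulate_cohort
from gblupkit.kinship import compute_grm, compute_nrm
from gblupkit.evalx import adjust_phenotype, make_cv_plan, cv_run, DataBundle

cohort = simulate_cohort(
    SimConfig(n_founders=250, n_offspring=500, n_chromosomes=3,
              snps_per_chromosome=600, seed=7),
    TraitArchitecture(h2_target=0.4, major_qtl=("1", 30_000_000, 0.30),
                      polygenic_fraction=0.70),
)
G = compute_grm(cohort["genotypes"])
A = compute_nrm(cohort["pedigree"])
adj = adjust_phenotype(cohort["phenotypes"], cohort["pedigree"], "adg", A=A)
plan = make_cv_plan(cohort["genotypes"].sample_ids, k=10, seed=1)
bundle = DataBundle(pheno=cohort["phenotypes"], trait="adg", yc=adj.yc,
                    G=G, A=A, genotypes=cohort["genotypes"])
print(cv_run("gblup", plan, bundle).to_dict())
print(cv_run("ablup", plan, bundle).to_dict())
```

## Command line

```bash
gblupkit run --seed 1 --out runs/demo            # full pipeline, default config
gblupkit sim --config cfg.json --seed 1 --out runs/sim
gblupkit qc --vcf genotypes.vcf --out runs/qc
gblupkit grm --vcf genotypes.vcf --out runs/grm  # --subset snps.txt for G_s/G_a
gblupkit reml --pheno phenotypes.tsv --trait adg --grm grm.txt.gz --out vc.json
gblupkit gwas --vcf genotypes.vcf --pheno phenotypes.tsv --trait adg --out runs/gwas
gblupkit predict --pheno phenotypes.tsv --trait adg --grm grm.txt.gz \
    --model gblup --out gebv.tsv
```

Configs are JSON, YAML or TOML; every run directory contains a
`provenance.json` (config hash, seed, version) sufficient to reproduce it.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: exact threshold and
cohort-bookkeeping arithmetic, oracle equivalences (ridge SNP-BLUP vs GBLUP,
dense GLS and Henderson-MME vs the solver, Monte-Carlo gene-dropping IBD vs
the tabular NRM, a REML grid-search oracle), parameter-recovery and GWAS
calibration suites, and the directional properties (GBLUP > ABLUP,
GFBLUP >= GBLUP under a major QTL, accuracy vs reference size, accuracy and
heritability collapse as top GWAS SNPs are removed).

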