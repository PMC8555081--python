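"""Pipeline orchestration, configuration and the command-line interface.

``run_pipeline`` executes the full synthetic study end to end:
sim -> qc -> grm -> gwas -> cv (ABLUP, GBLUP) -> gfblup -> contrib,
writing every report plus a provenance JSON (config hash, seeds, version)
into a run directory.  Reruns with the same config reproduce identical
numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__
from .blup import fit_gfblup, solve_mme
from .contrib import (
    gfblup_partition_contribution,
    reduced_model_contribution,
    top_snp_removal_curve,
)
from .evalx import DataBundle, adjust_phenotype, cv_run, make_cv_plan
from .genio import (
    read_genotypes,
    read_matrix,
    read_phenotypes,
    write_genotypes,
    write_matrix,
    write_pedigree,
    write_phenotypes,
)
from .gwas import bonferroni_threshold, define_qtl_interval, ld_prune, mlm_assoc
from .kinship import compute_grm, compute_grm_pair, compute_nrm
from .qc import apply_filters
from .simdata import SimConfig, TraitArchitecture, simulate_cohort
from .varcomp import fit_reml, heritability, make_spec


@dataclass
class RunConfig:
    """End-to-end run settings; all thresholds validated on construction."""

    sim: dict = field(default_factory=dict)
    arch: dict = field(default_factory=dict)
    trait: str = "adg"
    alpha: float = 0.05
    ld_interval_r2: float = 0.2
    ld_prune_r2: float = 0.9
    qc: dict = field(default_factory=dict)
    cv_k: int = 5
    discovery_frac: float = 0.25
    top_fractions: list = field(default_factory=lambda: [0.01, 0.10, 0.30])
    seed: int = 0
    stages: list = field(
        default_factory=lambda: ["sim", "qc", "grm", "gwas", "cv", "gfblup", "contrib"]
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        for name in ("ld_interval_r2", "ld_prune_r2"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0,1], got {v}")
        if self.cv_k < 2:
            raise ValueError("cv_k must be >= 2")
        if not 0.0 <= self.discovery_frac < 1.0:
            raise ValueError("discovery_frac must be in [0,1)")
        if any(not 0.0 <= f < 1.0 for f in self.top_fractions):
            raise ValueError("top_fractions must lie in [0,1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        elif path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _log(msg: str, logfile=None) -> None:
    line = f"[{time.strftime('%H:%M:%S')}] {msg}"
    print(line, file=sys.stderr)
    if logfile is not None:
        logfile.write(line + "\n")
        logfile.flush()


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run all enabled stages; artifacts and provenance land in ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logfile = open(outdir / "run.log", "w")
    state: dict = {}
    stage_order = ["sim", "qc", "grm", "gwas", "cv", "gfblup", "contrib"]
    stages = [s for s in stage_order if s in config.stages]

    provenance = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages_run": [],
    }

    def run_stage(name, fn):
        _log(f"stage {name}: start", logfile)
        try:
            fn()
        except Exception as exc:
            _log(f"stage {name}: FAILED ({exc})", logfile)
            provenance["failed_stage"] = name
            (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        provenance["stages_run"].append(name)
        _log(f"stage {name}: done", logfile)

    def stage_sim():
        sim_cfg = SimConfig(**{**config.sim, "seed": config.seed})
        arch = TraitArchitecture(**config.arch) if config.arch else TraitArchitecture()
        cohort = simulate_cohort(sim_cfg, arch)
        state.update(cohort)
        write_genotypes(cohort["genotypes"], outdir / "genotypes.vcf", format="vcf")
        write_phenotypes(cohort["phenotypes"], outdir / "phenotypes.tsv")
        write_pedigree(cohort["pedigree"], outdir / "pedigree.csv")
        ind, eff = cohort["truth"].to_frames()
        ind.to_csv(outdir / "true_genetic_values.tsv", sep="\t", index=False, float_format="%.8g")
        eff.to_csv(outdir / "true_snp_effects.tsv", sep="\t", index=False, float_format="%.8g")

    def stage_qc():
        g, report = apply_filters(state["genotypes"], **config.qc)
        state["genotypes"] = g
        (outdir / "qc_report.json").write_text(report.to_json())

    def stage_grm():
        G = compute_grm(state["genotypes"])
        A = compute_nrm(state["pedigree"])
        state["G"], state["A"] = G, A
        write_matrix(G, outdir / "grm.txt.gz")
        write_matrix(A, outdir / "nrm.txt.gz")

    def stage_gwas():
        g = state["genotypes"]
        pheno = state["phenotypes"]
        n = g.n_individuals
        discovery_n = int(config.discovery_frac * n)
        plan = make_cv_plan(g.sample_ids, k=config.cv_k, discovery_n=discovery_n, seed=config.seed)
        state["plan"] = plan
        disc = plan.discovery_ids if discovery_n else list(g.sample_ids)
        rows = [g.sample_ids.index(i) for i in disc]
        g_disc = g.subset(individuals=rows)
        pheno_disc = pheno[pheno["id"].isin(set(disc))].reset_index(drop=True)
        G_disc = compute_grm(g_disc)
        assoc = mlm_assoc(g_disc, pheno_disc, config.trait, G_disc)
        assoc.write_tsv(outdir / "gwas.tsv")
        thr = bonferroni_threshold(config.alpha, g.n_snps)
        intervals = define_qtl_interval(assoc, g_disc, thr, r2_cutoff=config.ld_interval_r2)
        state["assoc"], state["threshold"], state["intervals"] = assoc, thr, intervals
        pd.DataFrame(
            [
                {
                    "chrom": iv.chrom,
                    "start_bp": iv.start_bp,
                    "end_bp": iv.end_bp,
                    "lead_snp": iv.lead_snp,
                    "lead_p": iv.lead_p,
                    "n_sig_snps": len(iv.member_snps),
                }
                for iv in intervals
            ]
        ).to_csv(outdir / "qtl_intervals.tsv", sep="\t", index=False)
        # manhattan-plot data export (plotting left to the user)
        assoc.table[["snp", "chrom", "pos", "p"]].to_csv(
            outdir / "manhattan.tsv", sep="\t", index=False, float_format="%.6g"
        )

    def stage_cv():
        pheno = state["phenotypes"]
        adj = adjust_phenotype(pheno, state["pedigree"], config.trait, A=state["A"])
        state["yc"] = adj.yc
        bundle = DataBundle(
            pheno=pheno,
            trait=config.trait,
            yc=adj.yc,
            G=state["G"],
            A=state["A"],
            genotypes=state["genotypes"],
        )
        state["bundle"] = bundle
        results = {}
        for model in ("ablup", "gblup"):
            res = cv_run(model, state["plan"], bundle)
            res.per_fold.to_csv(
                outdir / f"cv_{model}.tsv", sep="\t", index=False, float_format="%.6g"
            )
            results[model] = res.to_dict()
        state["cv_results"] = results
        (outdir / "cv_summary.json").write_text(json.dumps(results, indent=2))

    def stage_gfblup():
        sig = state["assoc"].significant(state["threshold"])["snp"].tolist()
        panel = set(state["genotypes"].snp_map["snp"])
        sig = [s for s in sig if s in panel]
        if not sig or len(sig) >= len(panel):
            _log("gfblup: no usable significant SNP set; skipped", logfile)
            state["sig_snps"] = []
            return
        state["sig_snps"] = sig
        gs, ga = compute_grm_pair(state["genotypes"], sig)
        bundle = state["bundle"]
        bundle.Gs, bundle.Ga = gs, ga
        res = cv_run("gfblup", state["plan"], bundle)
        res.per_fold.to_csv(outdir / "cv_gfblup.tsv", sep="\t", index=False, float_format="%.6g")
        state["cv_results"]["gfblup"] = res.to_dict()
        (outdir / "cv_summary.json").write_text(json.dumps(state["cv_results"], indent=2))

    def stage_contrib():
        bundle = state["bundle"]
        plan = state["plan"]
        if state["intervals"]:
            rep = reduced_model_contribution(state["intervals"], bundle, plan)
            rep.write_tsv(outdir / "contrib_reduced.tsv")
            (outdir / "contrib_reduced.json").write_text(rep.to_json())
        if state.get("sig_snps"):
            rep = gfblup_partition_contribution(state["sig_snps"], bundle, plan)
            rep.write_tsv(outdir / "contrib_partition.tsv")
            (outdir / "contrib_partition.json").write_text(rep.to_json())
        rep = top_snp_removal_curve(config.top_fractions, bundle, plan, prune_r2=config.ld_prune_r2)
        rep.write_tsv(outdir / "contrib_topsnp.tsv")
        (outdir / "contrib_topsnp.json").write_text(rep.to_json())

    fns = {
        "sim": stage_sim,
        "qc": stage_qc,
        "grm": stage_grm,
        "gwas": stage_gwas,
        "cv": stage_cv,
        "gfblup": stage_gfblup,
        "contrib": stage_contrib,
    }
    for name in stages:
        run_stage(name, fns[name])

    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    logfile.close()
    return outdir


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.version_option(__version__)
def cli() -> None:
    """Genomic evaluation toolkit for simulated breeding cohorts."""


@cli.command("sim")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), required=True)
def cli_sim(config_path, seed, out):
    """Simulate a cohort and write genotypes, phenotypes, pedigree, truth."""
    cfg = RunConfig.from_file(config_path) if config_path else RunConfig()
    cfg.seed = seed
    cfg.stages = ["sim"]
    run_pipeline(cfg, out)


@cli.command("qc")
@click.option("--vcf", type=click.Path(exists=True), required=True)
@click.option("--maf-min", type=float, default=0.05)
@click.option("--snp-missing-max", type=float, default=0.60)
@click.option("--ind-missing-max", type=float, default=0.30)
@click.option("--hwe-p-min", type=float, default=1e-4)
@click.option("--out", type=click.Path(), required=True)
def cli_qc(vcf, maf_min, snp_missing_max, ind_missing_max, hwe_p_min, out):
    """Filter a VCF and write the retained panel plus a QC report."""
    g = read_genotypes(vcf, "vcf")
    g2, report = apply_filters(
        g,
        maf_min=maf_min,
        snp_missing_max=snp_missing_max,
        ind_missing_max=ind_missing_max,
        hwe_p_min=hwe_p_min,
    )
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    if not g2.imputed:
        write_genotypes(g2, out / "filtered.vcf", format="vcf")
    (out / "qc_report.json").write_text(report.to_json())
    click.echo(f"kept {report.n_snps_out}/{report.n_snps_in} SNPs, "
               f"{report.n_individuals_out}/{report.n_individuals_in} individuals")


@cli.command("grm")
@click.option("--vcf", type=click.Path(exists=True), required=True)
@click.option("--subset", type=click.Path(exists=True), default=None,
              help="file with one SNP id per line; emits the G_s/G_a pair")
@click.option("--out", type=click.Path(), required=True)
def cli_grm(vcf, subset, out):
    """Compute VanRaden GRM(s) from a VCF."""
    g = read_genotypes(vcf, "vcf")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    if subset:
        snps = [s.strip() for s in Path(subset).read_text().splitlines() if s.strip()]
        gs, ga = compute_grm_pair(g, snps)
        write_matrix(gs, out / "grm_feature.txt.gz")
        write_matrix(ga, out / "grm_rest.txt.gz")
    else:
        write_matrix(compute_grm(g), out / "grm.txt.gz")


@cli.command("reml")
@click.option("--pheno", type=click.Path(exists=True), required=True)
@click.option("--trait", required=True)
@click.option("--grm", "grms", type=click.Path(exists=True), multiple=True, required=True)
@click.option("--out", type=click.Path(), required=True)
def cli_reml(pheno, trait, grms, out):
    """REML variance components for one or two kernels."""
    ph = read_phenotypes(pheno)
    kernels = [read_matrix(p) for p in grms]
    spec = make_spec(ph, trait, kernels)
    vc = fit_reml(spec)
    h2 = heritability(vc)
    payload = vc.to_dict()
    payload["h2"] = h2.h2_per_kernel
    payload["h2_total"] = h2.h2_total
    Path(out).write_text(json.dumps(payload, indent=2))
    click.echo(json.dumps(payload, indent=2))


@cli.command("gwas")
@click.option("--vcf", type=click.Path(exists=True), required=True)
@click.option("--pheno", type=click.Path(exists=True), required=True)
@click.option("--trait", required=True)
@click.option("--alpha", type=float, default=0.05)
@click.option("--out", type=click.Path(), required=True)
def cli_gwas(vcf, pheno, trait, alpha, out):
    """Mixed-linear-model GWAS with Bonferroni threshold and QTL intervals."""
    g = read_genotypes(vcf, "vcf")
    ph = read_phenotypes(pheno)
    G = compute_grm(g)
    assoc = mlm_assoc(g, ph, trait, G)
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    assoc.write_tsv(out / "gwas.tsv")
    thr = bonferroni_threshold(alpha, g.n_snps)
    intervals = define_qtl_interval(assoc, g, thr)
    pd.DataFrame(
        [
            {
                "chrom": iv.chrom,
                "start_bp": iv.start_bp,
                "end_bp": iv.end_bp,
                "lead_snp": iv.lead_snp,
                "lead_p": iv.lead_p,
                "n_sig_snps": len(iv.member_snps),
            }
            for iv in intervals
        ]
    ).to_csv(out / "qtl_intervals.tsv", sep="\t", index=False)
    click.echo(f"threshold {thr:.3g}; {len(intervals)} interval(s)")


@cli.command("predict")
@click.option("--pheno", type=click.Path(exists=True), required=True)
@click.option("--trait", required=True)
@click.option("--grm", "grms", type=click.Path(exists=True), multiple=True, required=True)
@click.option("--model", type=click.Choice(["ablup", "gblup", "gfblup"]), default="gblup")
@click.option("--out", type=click.Path(), required=True)
def cli_predict(pheno, trait, grms, model, out):
    """Fit variance components and solve the mixed-model equations."""
    ph = read_phenotypes(pheno)
    kernels = [read_matrix(p) for p in grms]
    spec = make_spec(ph, trait, kernels)
    vc = fit_reml(spec)
    report = fit_gfblup(spec, vc) if model == "gfblup" else solve_mme(spec, vc, model.upper())
    report.to_frame().to_csv(out, sep="\t", index=False, float_format="%.6g")


@cli.command("cv")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), required=True)
def cli_cv(config_path, seed, out):
    """Simulate (or load) and cross-validate ABLUP/GBLUP/GFBLUP."""
    cfg = RunConfig.from_file(config_path) if config_path else RunConfig()
    cfg.seed = seed
    cfg.stages = ["sim", "qc", "grm", "gwas", "cv", "gfblup"]
    run_pipeline(cfg, out)


@cli.command("contrib")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), required=True)
def cli_contrib(config_path, seed, out):
    """Run the QTL-contribution analyses on a fresh simulated cohort."""
    cfg = RunConfig.from_file(config_path) if config_path else RunConfig()
    cfg.seed = seed
    run_pipeline(cfg, out)


@cli.command("run")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), required=True)
def cli_run(config_path, seed, out):
    """Full pipeline: sim -> qc -> grm -> gwas -> cv -> gfblup -> contrib."""
    cfg = RunConfig.from_file(config_path) if config_path else RunConfig()
    cfg.seed = seed
    run_pipeline(cfg, out)


if __name__ == "__main__":
    cli()
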