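"""Synthetic breeding-cohort generator.

Produces two non-founder generations of birds hatched in batches, with
sex-dimorphic growth traits, LD-structured SNP panels, and a configurable
additive architecture (one major QTL, several minor QTL, a polygenic tail).
Everything downstream of raw data collection can be exercised on its output.

The LD model is a first-order Markov chain along each chromosome: adjacent
markers have haplotype correlation ``ld_decay_rho``, so r^2 decays roughly
geometrically with marker distance.  Recombination during gene dropping uses
a uniform 1 cM/Mb map with Poisson crossover counts and no interference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genio import SNP_MAP_COLUMNS, GenotypeMatrix, validate_pedigree

__all__ = [
    "SimConfig",
    "TraitArchitecture",
    "TrueGeneticValues",
    "simulate_founder_haplotypes",
    "simulate_pedigree_and_drop",
    "simulate_phenotypes",
    "simulate_cohort",
    "mask_missing",
]

TRAITS = ("dw42", "dw84", "adg", "fcr")


@dataclass
class SimConfig:
    """Cohort dimensions and LD structure.

    ``n_offspring`` is the number of birds in *each* of the two non-founder
    generations.  ``n_sires``/``n_dams`` control how many parents are drawn
    (at random) per generation; offspring get a random sire and dam, giving a
    mixture of full- and half-sib families.
    """

    n_founders: int = 200
    n_offspring: int = 500
    n_batches: int = 6
    n_chromosomes: int = 3
    snps_per_chromosome: int = 1000
    chrom_length_bp: int = 50_000_000
    ld_decay_rho: float = 0.9
    seed: int = 0
    n_sires: int | None = None
    n_dams: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "n_founders",
            "n_offspring",
            "n_batches",
            "n_chromosomes",
            "snps_per_chromosome",
            "chrom_length_bp",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if not 0.0 <= self.ld_decay_rho < 1.0:
            raise ValueError(f"ld_decay_rho must be in [0,1), got {self.ld_decay_rho}")
        if self.n_sires is None:
            self.n_sires = max(1, self.n_founders // 16)
        if self.n_dams is None:
            self.n_dams = max(1, self.n_founders - self.n_sires)
        if self.n_sires + self.n_dams > self.n_founders:
            raise ValueError("n_sires + n_dams exceeds n_founders")

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.snps_per_chromosome


@dataclass
class TraitArchitecture:
    """Additive architecture of the latent weight-gain trait.

    Variance fractions of (major QTL, each minor QTL, polygenic tail) must
    sum to 1.  Sex and batch enter as pure intercept shifts; defaults are on
    the scale of a broiler cohort (grams, males heavier).
    """

    h2_target: float = 0.4
    major_qtl: tuple[str, int, float] = ("1", 25_000_000, 0.30)
    minor_qtl: list[tuple[str, int, float]] = field(default_factory=list)
    polygenic_fraction: float = 0.70
    n_polygenic_snps: int = 1000
    sex_means: dict = field(
        default_factory=lambda: {
            # Table-scale male/female means: dw42 854/731 g, dw84 2472/2006 g
            "M": {"dw42": 853.9, "dw84": 2472.0},
            "F": {"dw42": 731.3, "dw84": 2005.9},
        }
    )
    batch_effects: Sequence[float] | None = None
    gain_sd: float = 150.0
    dw42_resid_sd: float = 55.0
    feed_kappa: float = 3.0  # feed intake ~ kappa * gain + noise, so FCR ~ 3
    feed_noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_target < 1.0:
            raise ValueError(f"h2_target must be in [0,1), got {self.h2_target}")
        fracs = [self.major_qtl[2]] + [q[2] for q in self.minor_qtl] + [self.polygenic_fraction]
        if any(f < 0 for f in fracs):
            raise ValueError("variance fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"QTL + polygenic fractions must sum to 1, got {sum(fracs)}")

    @property
    def qtl(self) -> list[tuple[str, int, float]]:
        return [self.major_qtl] + list(self.minor_qtl)


@dataclass
class TrueGeneticValues:
    """Simulation truth: per-bird additive values and per-SNP effects.

    ``genetic_value`` is on the weight-gain scale (grams over days 42-84);
    the true additive value for ADG is ``genetic_value / 42`` and for 84 DW
    it equals ``genetic_value`` (42 DW carries no genetic signal by design).
    ``component`` labels each causal SNP major/minor/polygenic, and
    ``component_values`` decomposes each bird's genetic value into mutually
    orthogonal major / minor / polygenic parts that sum to ``genetic_value``.
    """

    ids: list[str]
    genetic_value: np.ndarray
    snp_effects: pd.DataFrame  # columns: snp, effect, component
    component_values: pd.DataFrame | None = None  # columns: major, minor, polygenic

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        ind = pd.DataFrame({"id": self.ids, "true_genetic_value": self.genetic_value})
        return ind, self.snp_effects


# ---------------------------------------------------------------------------
# Founder haplotypes
# ---------------------------------------------------------------------------

def _markov_haplotypes(
    rng: np.random.Generator, n_hap: int, freqs: np.ndarray, rho: float
) -> np.ndarray:
    """Binary haplotypes with target marginal freqs and adjacent correlation rho.

    First-order Markov chain: transition probabilities are chosen so that
    corr(X_j, X_{j+1}) = rho exactly when unclipped; with extreme frequency
    jumps the conditional probability is clipped to [0,1] and the realized
    correlation falls slightly short.
    """
    m = len(freqs)
    hap = np.empty((n_hap, m), dtype=np.int8)
    hap[:, 0] = rng.random(n_hap) < freqs[0]
    for j in range(1, m):
        p0, p1 = freqs[j - 1], freqs[j]
        cov = rho * np.sqrt(p0 * (1 - p0) * p1 * (1 - p1))
        p_given1 = np.clip(p1 + cov / p0, 0.0, 1.0)
        p_given0 = np.clip(p1 - cov / (1 - p0), 0.0, 1.0)
        cond = np.where(hap[:, j - 1] == 1, p_given1, p_given0)
        hap[:, j] = rng.random(n_hap) < cond
    return hap


def default_snp_map(config: SimConfig) -> pd.DataFrame:
    """Evenly spaced biallelic markers on each chromosome."""
    rows = []
    spacing = config.chrom_length_bp // (config.snps_per_chromosome + 1)
    for c in range(1, config.n_chromosomes + 1):
        for j in range(config.snps_per_chromosome):
            pos = (j + 1) * spacing
            rows.append((f"snp{c}_{pos}", str(c), pos, "A", "B"))
    return pd.DataFrame(rows, columns=SNP_MAP_COLUMNS)


def simulate_founder_haplotypes(config: SimConfig) -> dict:
    """Founder haplotypes per chromosome.

    Returns a dict with ``haplotypes`` — mapping chromosome name to an
    (2*n_founders, snps_per_chromosome) int8 array — plus the ``snp_map``
    and the allele frequencies the markers were drawn at (uniform on
    [0.05, 0.95]).  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    snp_map = default_snp_map(config)
    haplotypes: dict[str, np.ndarray] = {}
    freqs: dict[str, np.ndarray] = {}
    n_hap = 2 * config.n_founders
    for c in range(1, config.n_chromosomes + 1):
        f = _smooth_uniform_freqs(rng, config.snps_per_chromosome)
        haplotypes[str(c)] = _markov_haplotypes(rng, n_hap, f, config.ld_decay_rho)
        freqs[str(c)] = f
    return {"haplotypes": haplotypes, "snp_map": snp_map, "freqs": freqs, "config": config}


def _smooth_uniform_freqs(
    rng: np.random.Generator, m: int, smooth: float = 0.9
) -> np.ndarray:
    """Allele frequencies with uniform [0.05, 0.95] marginals that vary
    smoothly along the chromosome (Gaussian-copula AR(1)).

    Smoothness keeps adjacent frequencies close, so the Markov copying
    transition probabilities of :func:`_markov_haplotypes` are rarely
    clipped and the realized adjacent correlation tracks ``ld_decay_rho``.
    """
    from scipy.stats import norm

    z = np.empty(m)
    z[0] = rng.normal()
    eps = rng.normal(size=m - 1) * np.sqrt(1.0 - smooth**2)
    for j in range(1, m):
        z[j] = smooth * z[j - 1] + eps[j - 1]
    return 0.05 + 0.90 * norm.cdf(z)


# ---------------------------------------------------------------------------
# Pedigree and gene dropping
# ---------------------------------------------------------------------------

def _meiosis(
    rng: np.random.Generator,
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    positions_bp: np.ndarray,
    chrom_length_bp: int,
) -> np.ndarray:
    """One gamete from a parent's two haplotypes; 1 cM/Mb Poisson crossovers."""
    expected_co = chrom_length_bp / 1e8  # bp -> Morgans at 1 cM/Mb
    k = rng.poisson(expected_co)
    start = int(rng.integers(2))
    if k == 0:
        return (hap_a if start == 0 else hap_b).copy()
    cuts = np.sort(rng.integers(1, chrom_length_bp, size=k))
    phase = (start + np.searchsorted(cuts, positions_bp)) % 2
    return np.where(phase == 0, hap_a, hap_b)


def simulate_pedigree_and_drop(
    config: SimConfig,
    founders: dict,
    matings: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, GenotypeMatrix, dict]:
    """Drop founder haplotypes through two offspring generations.

    Parameters
    ----------
    founders : output of :func:`simulate_founder_haplotypes`
    matings : optional DataFrame with columns (id, sire, dam, generation)
        overriding the random mating design; parents must already exist when
        a row is processed.

    Returns (pedigree, genotypes, haplotype store).  The pedigree has columns
    id, sire, dam, sex, generation, batch; founders are generation 0 with
    unknown parents.  The genotype matrix covers the two offspring
    generations only (the genotyped cohort), in pedigree order.
    """
    rng = np.random.default_rng(config.seed + 1)
    snp_map = founders["snp_map"]
    chroms = sorted(founders["haplotypes"], key=lambda c: int(c))
    pos = {c: snp_map.loc[snp_map["chrom"] == c, "pos"].to_numpy() for c in chroms}

    # haplotype store: id -> {chrom: (2, m) int8}
    store: dict[str, dict[str, np.ndarray]] = {}
    ped_rows: list[tuple] = []
    founder_ids = [f"F{i:04d}" for i in range(config.n_founders)]
    for i, fid in enumerate(founder_ids):
        store[fid] = {c: founders["haplotypes"][c][2 * i : 2 * i + 2] for c in chroms}
        sex = "M" if i < config.n_sires else "F"
        ped_rows.append((fid, None, None, sex, 0, 0))

    def make_child(cid: str, sire: str, dam: str, gen: int, batch: int, sex: str) -> None:
        store[cid] = {}
        for c in chroms:
            pat = _meiosis(rng, *store[sire][c], pos[c], config.chrom_length_bp)
            mat = _meiosis(rng, *store[dam][c], pos[c], config.chrom_length_bp)
            store[cid][c] = np.stack([pat, mat])
        ped_rows.append((cid, sire, dam, sex, gen, batch))

    if matings is not None:
        for row in matings.itertuples(index=False):
            known = {r[0] for r in ped_rows}
            if row.sire not in known or row.dam not in known:
                raise ValueError(f"offspring {row.id} references unknown parent")
            sex = getattr(row, "sex", None) or ("M" if rng.random() < 0.5 else "F")
            batch = int(getattr(row, "batch", 0) or rng.integers(1, config.n_batches + 1))
            make_child(str(row.id), str(row.sire), str(row.dam), int(row.generation), batch, sex)
        offspring_ids = [str(i) for i in matings["id"]]
    else:
        offspring_ids = []
        males, females = founder_ids[: config.n_sires], founder_ids[config.n_sires :]
        for gen in (1, 2):
            sires = list(rng.choice(males, size=min(config.n_sires, len(males)), replace=False))
            dams = list(rng.choice(females, size=min(config.n_dams, len(females)), replace=False))
            new_ids, new_m, new_f = [], [], []
            for i in range(config.n_offspring):
                cid = f"G{gen}_{i:05d}"
                sire = sires[int(rng.integers(len(sires)))]
                dam = dams[int(rng.integers(len(dams)))]
                sex = "M" if rng.random() < 0.5 else "F"
                batch = int(rng.integers(1, config.n_batches + 1))
                make_child(cid, sire, dam, gen, batch, sex)
                new_ids.append(cid)
                (new_m if sex == "M" else new_f).append(cid)
            offspring_ids.extend(new_ids)
            males, females = new_m, new_f
            if not males or not females:
                raise ValueError("a generation ended up single-sex; increase n_offspring")

    ped = pd.DataFrame(ped_rows, columns=["id", "sire", "dam", "sex", "generation", "batch"])
    ped = validate_pedigree(ped)

    dosages = np.empty((len(offspring_ids), len(snp_map)), dtype=np.float32)
    col0 = 0
    for c in chroms:
        m = len(pos[c])
        for i, oid in enumerate(offspring_ids):
            dosages[i, col0 : col0 + m] = store[oid][c].sum(axis=0)
        col0 += m
    genotypes = GenotypeMatrix(dosages, offspring_ids, snp_map.copy())
    return ped, genotypes, store


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    pedigree: pd.DataFrame,
    arch: TraitArchitecture,
    seed: int = 0,
) -> tuple[pd.DataFrame, TrueGeneticValues]:
    """Simulate the four growth traits for every genotyped bird.

    The latent trait is weight gain over days 42-84:
    ``gain = sex_mean_gap + batch_offset + g + e`` with realized
    Var(g)/Var(g+e) equal to ``arch.h2_target``.  Then

    * ``dw42`` = sex mean + batch offset + environmental noise (no genetics),
    * ``dw84`` = dw42 + gain,
    * ``adg``  = (dw84 - dw42) / 42 exactly,
    * ``fcr``  = feed intake / gain with feed = kappa * gain + noise.

    Effect sizes are rescaled so each configured variance fraction is hit on
    the realized cohort; the dosage-weighted sum identity
    ``g = Z @ effects`` holds exactly for the returned truth.
    """
    rng = np.random.default_rng(seed)
    smap = genotypes.snp_map
    n = genotypes.n_individuals
    d = genotypes.dosages.astype(np.float64)
    if np.isnan(d).any():
        raise ValueError("phenotype simulation requires complete genotypes")

    # resolve QTL positions to nearest marker on their chromosome
    qtl_idx: list[int] = []
    for chrom, bp, _frac in arch.qtl:
        on_c = np.flatnonzero(smap["chrom"].to_numpy() == str(chrom))
        if on_c.size == 0:
            raise ValueError(f"QTL chromosome {chrom} not in SNP map")
        j = on_c[np.argmin(np.abs(smap["pos"].to_numpy()[on_c] - bp))]
        qtl_idx.append(int(j))
    if len(set(qtl_idx)) != len(qtl_idx):
        raise ValueError("two QTL mapped to the same marker; spread positions out")

    gain_var = arch.gain_sd**2
    genetic_var = arch.h2_target * gain_var

    zc_all = d - d.mean(axis=0)
    effects = np.zeros(genotypes.n_snps)
    component = np.full(genotypes.n_snps, "", dtype=object)
    comp_vals = {
        "major": np.zeros(n),
        "minor": np.zeros(n),
        "polygenic": np.zeros(n),
    }

    if genetic_var > 0:
        # QTL coefficients hit their configured variance share exactly
        qtl_coef = np.zeros(len(qtl_idx))
        for k, ((_chrom, _bp, frac), j) in enumerate(zip(arch.qtl, qtl_idx)):
            sd_j = zc_all[:, j].std()
            if sd_j == 0:
                raise ValueError(f"QTL marker {smap['snp'].iloc[j]} is monomorphic")
            qtl_coef[k] = np.sqrt(frac * genetic_var) / sd_j
            label = "major" if k == 0 else "minor"
            component[j] = label
            comp_vals[label] = comp_vals[label] + zc_all[:, j] * qtl_coef[k]

        # polygenic tail, orthogonalized against the QTL columns so the
        # configured fractions are orthogonal variance shares (LD between
        # background SNPs and the QTL would otherwise shift them)
        poly_pool = np.setdiff1d(np.arange(genotypes.n_snps), qtl_idx)
        n_poly = min(arch.n_polygenic_snps, poly_pool.size)
        poly_idx = np.sort(rng.choice(poly_pool, size=n_poly, replace=False))
        raw = rng.normal(size=n_poly)
        p0 = zc_all[:, poly_idx] @ raw
        zq = zc_all[:, qtl_idx]
        gamma, *_ = np.linalg.lstsq(zq, p0, rcond=None)
        p_perp = p0 - zq @ gamma
        target_poly = arch.polygenic_fraction * genetic_var
        s_p = np.sqrt(target_poly / p_perp.var()) if p_perp.var() > 0 else 0.0
        comp_vals["polygenic"] = s_p * p_perp
        component[poly_idx] = "polygenic"

        effects[poly_idx] = s_p * raw
        effects[qtl_idx] = qtl_coef - s_p * gamma

        g = zc_all @ effects
        # final common rescale so the total realized genetic variance is exact
        scale = np.sqrt(genetic_var / g.var())
        effects *= scale
        for key in comp_vals:
            comp_vals[key] = comp_vals[key] * scale
        g = zc_all @ effects
    else:
        g = np.zeros(n)

    resid_var = (1.0 - arch.h2_target) * gain_var
    e = rng.normal(size=n)
    e = e - e.mean()
    if resid_var > 0:
        e *= np.sqrt(resid_var) / e.std()
    else:
        e[:] = 0.0

    ped_idx = pedigree.set_index("id")
    sex = ped_idx.loc[genotypes.sample_ids, "sex"].to_numpy()
    batch = ped_idx.loc[genotypes.sample_ids, "batch"].to_numpy().astype(int)
    gen = ped_idx.loc[genotypes.sample_ids, "generation"].to_numpy().astype(int)

    batch_eff = (
        np.asarray(arch.batch_effects, dtype=float)
        if arch.batch_effects is not None
        else np.linspace(-25.0, 25.0, max(batch.max(), 1))
    )
    b_off = batch_eff[np.clip(batch - 1, 0, len(batch_eff) - 1)]

    mean42 = np.array([arch.sex_means[s]["dw42"] for s in sex])
    mean84 = np.array([arch.sex_means[s]["dw84"] for s in sex])
    gain_mean = mean84 - mean42

    dw42 = mean42 + b_off * 0.4 + rng.normal(scale=arch.dw42_resid_sd, size=n)
    gain = gain_mean + b_off + g + e
    dw84 = dw42 + gain
    adg = (dw84 - dw42) / 42.0
    feed = arch.feed_kappa * gain + rng.normal(
        scale=arch.feed_noise_cv * arch.feed_kappa * abs(gain_mean).mean(), size=n
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        fcr = feed / gain

    pheno = pd.DataFrame(
        {
            "id": genotypes.sample_ids,
            "sex": sex,
            "batch": batch,
            "generation": gen,
            "dw42": dw42,
            "dw84": dw84,
            "adg": adg,
            "fcr": fcr,
        }
    )
    truth = TrueGeneticValues(
        ids=list(genotypes.sample_ids),
        genetic_value=g,
        snp_effects=pd.DataFrame(
            {"snp": smap["snp"], "effect": effects, "component": component}
        ),
        component_values=pd.DataFrame(comp_vals, index=genotypes.sample_ids),
    )
    return pheno, truth


def simulate_cohort(
    config: SimConfig, arch: TraitArchitecture | None = None
) -> dict:
    """One-call cohort: haplotypes -> pedigree/genotypes -> phenotypes.

    Returns a dict with keys pedigree, genotypes, phenotypes, truth.
    """
    arch = arch or TraitArchitecture()
    founders = simulate_founder_haplotypes(config)
    ped, geno, _store = simulate_pedigree_and_drop(config, founders)
    pheno, truth = simulate_phenotypes(geno, ped, arch, seed=config.seed + 2)
    return {"pedigree": ped, "genotypes": geno, "phenotypes": pheno, "truth": truth}


def mask_missing(g: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set a random fraction of calls to missing (QC-exercise utility)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0,1)")
    rng = np.random.default_rng(seed)
    d = g.dosages.copy()
    mask = rng.random(d.shape) < rate
    d[mask] = np.nan
    return GenotypeMatrix(d, list(g.sample_ids), g.snp_map.copy())
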