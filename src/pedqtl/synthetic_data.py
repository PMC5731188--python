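"""Simulation of pedigreed two-breed populations with LD, planted trait
QTL, polygenic covariance and negative-binomial expression counts.

All randomness flows from one ``numpy.random.Generator`` seeded once per
run, in a fixed draw order, so every stage is replayable bit-for-bit
from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .core_io import GenotypeMatrix, Pedigree, PedigreeRecord, PhenotypeTable
from .eqtl import ExpressionMatrix, GenomicWindow
from .relationship import RelationshipMatrix


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length_bp: int
    length_morgans: float
    n_variants: int


@dataclass(frozen=True)
class TraitSpec:
    name: str = "trait"
    h2: float = 0.5
    sigma2_P: float = 1.0
    #: list of (variant_id, beta) planted QTL; beta in trait units per alt allele
    causal_variants: tuple[tuple[str, float], ...] = ()


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    window: GenomicWindow
    causal_variant: str | None = None
    log_fold: float = 0.0  # additive on log scale per alt allele
    base_log_mean: float = 5.0


@dataclass(frozen=True)
class ExpressionSpec:
    genes: tuple[GeneSpec, ...] = ()
    dispersion: float = 0.1
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    n_samples: int = 0  # 0 => all animals


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    breeds: tuple[str, str] = ("HF", "JE")
    n_founders_per_breed: int = 40
    n_generations: int = 3
    matings_per_generation: int = 200
    crossbreed_prob: float = 0.2
    chromosomes: tuple[ChromosomeSpec, ...] = (
        ChromosomeSpec("1", 100_000_000, 1.0, 1000),
    )
    base_freq_range: tuple[float, float] = (0.05, 0.95)
    fst: float = 0.1  # Balding-Nichols breed divergence
    haplotype_corr: float = 0.9  # adjacent-marker latent correlation
    trait: TraitSpec = TraitSpec()
    expression: ExpressionSpec | None = None

    def __post_init__(self) -> None:
        for prob in (self.crossbreed_prob, self.haplotype_corr):
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"probability {prob} outside [0, 1]")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if self.n_founders_per_breed < 1:
            raise ValueError("need at least one founder per breed")

    @property
    def n_variants(self) -> int:
        return sum(c.n_variants for c in self.chromosomes)

    @property
    def expected_cohort_size(self) -> int:
        return (
            len(self.breeds) * self.n_founders_per_breed
            + self.n_generations * self.matings_per_generation
        )


@dataclass
class SimOutput:
    pedigree: Pedigree
    founder_haplotypes: dict[str, np.ndarray]
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable | None
    expression: ExpressionMatrix | None
    truth: dict


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Discrete-generation pedigree: founders of two labelled breeds, each
    non-founder bred from a sire and dam of the previous generation.

    Sexes alternate deterministically within each generation so both are
    always available; with probability ``crossbreed_prob`` a mating picks
    its sire from a different dominant-breed group than the dam.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    records: list[PedigreeRecord] = []
    # dominant breed tracked for mate choice only; labels persist on founders
    males: dict[str, list[str]] = {}
    females: dict[str, list[str]] = {}
    for b in cfg.breeds:
        males[b], females[b] = [], []
        for k in range(cfg.n_founders_per_breed):
            aid = f"G0_{b}_{k:04d}"
            records.append(PedigreeRecord(aid, None, None, b))
            (males[b] if k % 2 == 0 else females[b]).append(aid)
    dominant = {r.animal_id: r.breed for r in records}

    for gen in range(1, cfg.n_generations + 1):
        new_m: dict[str, list[str]] = {b: [] for b in cfg.breeds}
        new_f: dict[str, list[str]] = {b: [] for b in cfg.breeds}
        breeds = list(cfg.breeds)
        for k in range(cfg.matings_per_generation):
            dam_breed = breeds[int(rng.integers(len(breeds)))]
            if not females[dam_breed]:
                dam_breed = next(b for b in breeds if females[b])
            dam = females[dam_breed][int(rng.integers(len(females[dam_breed])))]
            cross = rng.random() < cfg.crossbreed_prob
            sire_pool_breeds = (
                [b for b in breeds if b != dominant[dam] and males[b]]
                if cross
                else [dominant[dam]]
            )
            if not sire_pool_breeds or not males[sire_pool_breeds[0]]:
                sire_pool_breeds = [b for b in breeds if males[b]]
            sb = sire_pool_breeds[int(rng.integers(len(sire_pool_breeds)))]
            sire = males[sb][int(rng.integers(len(males[sb])))]
            aid = f"G{gen}_{k:04d}"
            records.append(PedigreeRecord(aid, sire, dam, None))
            child_breed = dominant[sire] if rng.random() < 0.5 else dominant[dam]
            dominant[aid] = child_breed
            (new_m[child_breed] if k % 2 == 0 else new_f[child_breed]).append(aid)
        # keep breeds usable even if a group emptied this generation
        for b in breeds:
            males[b] = new_m[b] or males[b]
            females[b] = new_f[b] or females[b]
    return Pedigree.from_records(records)


# ---------------------------------------------------------------------------
# Founder haplotypes
# ---------------------------------------------------------------------------

def _variant_table(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for c in cfg.chromosomes:
        pos = np.linspace(1, c.length_bp, c.n_variants, dtype=np.int64)
        pos = np.unique(pos)  # guards tiny chromosomes
        for p in pos:
            rows.append((f"v{c.name}_{p}", c.name, int(p), "A", "B"))
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt"])


def simulate_founder_haplotypes(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, np.ndarray], pd.DataFrame, dict]:
    """Balding-Nichols breed frequencies + Gaussian-copula AR(1) haplotypes.

    Base frequencies are uniform on ``base_freq_range``; each breed draws
    p_b ~ Beta(p(1-F)/F, (1-p)(1-F)/F). Haplotypes are thresholded AR(1)
    latent Gaussians (chain restarted at each chromosome boundary), giving
    tunable adjacent-marker LD.

    Returns (pools, variant_table, freqs) where pools maps breed ->
    (2 * n_founders, n_variants) int8 array.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    variants = _variant_table(cfg)
    m = len(variants)
    lo, hi = cfg.base_freq_range
    base = rng.uniform(lo, hi, size=m)
    F = cfg.fst
    pools: dict[str, np.ndarray] = {}
    breed_freqs: dict[str, np.ndarray] = {}
    n_hap = 2 * cfg.n_founders_per_breed
    rho = cfg.haplotype_corr
    chrom_sizes = [
        int((variants["chrom"] == c.name).sum()) for c in cfg.chromosomes
    ]
    for b in cfg.breeds:
        p_b = rng.beta(base * (1 - F) / F, (1 - base) * (1 - F) / F)
        p_b = np.clip(p_b, 1e-4, 1 - 1e-4)
        breed_freqs[b] = p_b
        e = rng.standard_normal((n_hap, m))
        z = np.empty_like(e)
        s = np.sqrt(1.0 - rho**2)
        start = 0
        for size in chrom_sizes:
            blk = e[:, start:start + size].copy()
            if rho > 0:
                blk[:, 0] /= s  # so the first column keeps unit variance
                z[:, start:start + size] = signal.lfilter([s], [1.0, -rho], blk, axis=1)
            else:
                z[:, start:start + size] = blk
            start += size
        thresh = stats.norm.ppf(p_b)
        pools[b] = (z < thresh[None, :]).astype(np.int8)
    freqs = {"base": base, "breed": breed_freqs}
    return pools, variants, freqs


# ---------------------------------------------------------------------------
# Gene drop
# ---------------------------------------------------------------------------

def _recombine(
    hap_pair: np.ndarray,
    chrom_slices: list[tuple[slice, np.ndarray, int, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from a (2, m) haplotype pair: per chromosome, Poisson
    crossover count (mean = length in Morgans), uniform positions, random
    starting phase."""
    gamete = np.empty(hap_pair.shape[1], dtype=np.int8)
    for sl, pos, length_bp, morgans in chrom_slices:
        block = hap_pair[:, sl]
        size = block.shape[1]
        phase = int(rng.integers(2))
        n_cx = rng.poisson(morgans)
        if n_cx == 0:
            gamete[sl] = block[phase]
            continue
        cx_bp = np.sort(rng.uniform(0, length_bp, size=n_cx))
        seg = np.searchsorted(cx_bp, pos)  # phase switches at each crossover
        gamete[sl] = block[(phase + seg) % 2, np.arange(size)]
    return gamete


def gene_drop(
    p: Pedigree,
    pools: dict[str, np.ndarray],
    variants: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Drop founder haplotypes through the pedigree with recombination.

    Founders consume haplotypes from their breed pool in pedigree order
    (unlabelled founders draw from a random breed). Returns the dosage
    matrix and the full (2n, m) haplotype array.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    m = len(variants)
    n = len(p)
    H = np.zeros((2 * n, m), dtype=np.int8)
    chrom_slices = []
    start = 0
    for c in cfg.chromosomes:
        sel = variants["chrom"] == c.name
        size = int(sel.sum())
        pos = variants.loc[sel, "pos"].to_numpy(dtype=float)
        chrom_slices.append(
            (slice(start, start + size), pos, c.length_bp, c.length_morgans)
        )
        start += size
    next_hap = {b: 0 for b in pools}
    breeds = list(pools)
    for i, rec in enumerate(p.records):
        if rec.is_founder:
            b = rec.breed if rec.breed in pools else breeds[int(rng.integers(len(breeds)))]
            pool = pools[b]
            for k in range(2):
                H[2 * i + k] = pool[next_hap[b] % pool.shape[0]]
                next_hap[b] += 1
        else:
            for k, pid in enumerate((rec.sire_id, rec.dam_id)):
                j = p.index_of(pid)
                H[2 * i + k] = _recombine(H[2 * j:2 * j + 2], chrom_slices, rng)
    dosages = (H[0::2] + H[1::2]).astype(float)
    return GenotypeMatrix(p.animal_ids, variants.copy(), dosages), H


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def cholesky_factor(A: RelationshipMatrix, jitter: float = 1e-8) -> np.ndarray:
    """Lower Cholesky factor of A (+ jitter I); reusable across replicate
    phenotype draws on a fixed cohort."""
    return np.linalg.cholesky(A.A + jitter * np.eye(len(A)))


def simulate_phenotype(
    g: GenotypeMatrix,
    A: RelationshipMatrix,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    chol: np.ndarray | None = None,
) -> tuple[PhenotypeTable, dict]:
    """y = sum_j beta_j (g_j - mean) + u + e.

    The polygenic term u has covariance (h2 sigma2_P - planted QTL
    variance) * A via a Cholesky factor (pass ``chol`` to reuse one across
    replicates); e is iid with variance (1 - h2) sigma2_P. Raises if the
    planted variance exceeds the additive budget h2 * sigma2_P.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    spec = cfg.trait
    if g.animal_ids != A.animal_ids:
        raise ValueError("genotype and relationship animal orders differ")
    n = g.n_animals
    y = np.zeros(n)
    qtl_var = 0.0
    causal_info = []
    for vid, beta in spec.causal_variants:
        d = g.dosage_of(vid)
        freq = np.nanmean(d) / 2.0
        qtl_var += 2.0 * freq * (1.0 - freq) * beta**2
        y += beta * (np.where(np.isfinite(d), d, 2 * freq) - 2 * freq)
        causal_info.append({"variant_id": vid, "beta": beta, "alt_freq": float(freq)})
    additive_budget = spec.h2 * spec.sigma2_P
    if qtl_var > additive_budget + 1e-12:
        raise ValueError(
            f"planted causal variance {qtl_var:.4g} exceeds h2*sigma2_P "
            f"= {additive_budget:.4g}"
        )
    u_var = additive_budget - qtl_var
    u = np.zeros(n)
    if u_var > 0:
        L = cholesky_factor(A) if chol is None else chol
        u = np.sqrt(u_var) * (L @ rng.standard_normal(n))
    e_var = (1.0 - spec.h2) * spec.sigma2_P
    e = np.sqrt(e_var) * rng.standard_normal(n) if e_var > 0 else np.zeros(n)
    y = y + u + e
    table = PhenotypeTable(pd.DataFrame({spec.name: y}, index=g.animal_ids))
    truth = {
        "trait": spec.name,
        "h2": spec.h2,
        "sigma2_P": spec.sigma2_P,
        "causal_variants": causal_info,
        "qtl_variance": qtl_var,
        "polygenic_variance": u_var,
        "breeding_values": (y - e).tolist(),
    }
    return table, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    g: GenotypeMatrix,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, dict]:
    """NB counts with genotype-dependent mean:
    count ~ NB(mean = s_i * exp(mu_gene + b * dosage), dispersion alpha).

    The expression cohort is a random subset of the genotyped animals
    (``n_samples``; 0 means everyone).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    spec = cfg.expression
    if spec is None:
        raise ValueError("config has no expression spec")
    if not spec.dispersion > 0:
        raise ValueError("NB dispersion must be positive")
    n_total = g.n_animals
    if spec.n_samples and spec.n_samples < n_total:
        idx = np.sort(rng.choice(n_total, size=spec.n_samples, replace=False))
    else:
        idx = np.arange(n_total)
    samples = [g.animal_ids[i] for i in idx]
    lo, hi = spec.size_factor_range
    sf = rng.uniform(lo, hi, size=len(samples))
    alpha = spec.dispersion
    rows = {}
    gene_truth = []
    for gene in spec.genes:
        eta = np.full(len(samples), gene.base_log_mean)
        if gene.causal_variant is not None and gene.log_fold != 0.0:
            d = g.dosage_of(gene.causal_variant)[idx]
            eta = eta + gene.log_fold * np.where(np.isfinite(d), d, np.nanmean(d))
        mean = sf * np.exp(eta)
        nb_n = 1.0 / alpha
        nb_p = nb_n / (nb_n + mean)
        rows[gene.gene_id] = rng.negative_binomial(nb_n, nb_p)
        gene_truth.append(
            {
                "gene_id": gene.gene_id,
                "causal_variant": gene.causal_variant,
                "log_fold": gene.log_fold,
                "window": vars(gene.window),
            }
        )
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    truth = {
        "dispersion": alpha,
        "size_factors": dict(zip(samples, sf.tolist())),
        "genes": gene_truth,
    }
    return ExpressionMatrix(counts=counts), truth


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate(cfg: SimConfig) -> SimOutput:
    """Run the full generator: pedigree, founder haplotypes, gene drop,
    phenotype and (optionally) expression, all from one seeded stream."""
    from .relationship import build_numerator_relationship

    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    pools, variants, freqs = simulate_founder_haplotypes(cfg, rng)
    geno, _haps = gene_drop(ped, pools, variants, cfg, rng)
    A = build_numerator_relationship(ped)
    pheno, trait_truth = simulate_phenotype(geno, A, cfg, rng)
    expr, expr_truth = (
        simulate_expression(geno, cfg, rng)
        if cfg.expression is not None
        else (None, None)
    )
    truth = {
        "seed": cfg.seed,
        "trait": trait_truth,
        "expression": expr_truth,
        "base_freqs": freqs["base"].tolist(),
    }
    return SimOutput(
        pedigree=ped,
        founder_haplotypes=pools,
        genotypes=geno,
        phenotypes=pheno,
        expression=expr,
        truth=truth,
    )
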