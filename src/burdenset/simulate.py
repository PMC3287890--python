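"""Synthetic genotype/phenotype studies for evaluating the two-step pipeline.

The generator emulates the structure of a mini-exome association study of
unrelated individuals: many genes of heterogeneous size mixing rare
(MAF <= 0.01) and common variants, a quantitative trait driven additively by
a small group of causal genes, and many phenotype replicates over one fixed
genotype matrix. Optionally, designated pairs of genes receive correlated
genotypes through a shared latent factor, so that a non-causal gene tracks a
causal partner — the long-distance-correlation mechanism that produces
"spurious" genes downstream.

Genotypes are Hardy–Weinberg: dosage ~ Binomial(2, MAF), variants
independent within and between genes unless a confounder couples them.
Variant MAFs are drawn log-uniformly inside the rare range (rare site
frequencies are heavily skewed toward the rarest classes) and uniformly
inside the common range.

Phenotypes: each causal gene g contributes its standardized additive burden
(equal per-variant weights over the gene's causal variants) scaled to a
configured variance share h2_g; residual noise is scaled so the shares are
heritabilities, and each replicate redraws only the noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
import numpy as np
import yaml
from scipy import stats

from .data_model import GeneMap, GenotypeMatrix, Phenotype

__all__ = [
    "ConfigError",
    "ConfounderSpec",
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_study",
    "mini_exome_preset",
]


class ConfigError(ValueError):
    """Invalid or infeasible simulation configuration."""


@dataclass(frozen=True)
class ConfounderSpec:
    """Couple two genes' genotypes through a shared latent factor with the
    given correlation on the latent (liability) scale."""

    gene_a: str
    gene_b: str
    rho: float

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise ConfigError("confounder rho must be in (0, 1)")


@dataclass
class SimulationConfig:
    """Study-generating parameters.

    ``causal_h2`` maps causal gene id to its heritability share (variance
    fraction of the trait explained by that gene's burden); the shares must
    sum to < 1 and the remainder is residual noise. ``variant_effects``
    optionally gives explicit per-variant relative weights within causal
    genes (default: every rare variant of a causal gene contributes equally;
    genes without rare variants use all their variants).
    """

    n_individuals: int = 697
    n_genes: int = 300
    gene_size_range: tuple[int, int] = (1, 60)
    gene_sizes: tuple[int, ...] | None = None  # explicit per-gene sizes override the range
    fraction_rare: float = 0.75
    rare_maf_range: tuple[float, float] = (0.001, 0.01)
    common_maf_range: tuple[float, float] = (0.011, 0.4)
    causal_h2: dict[str, float] = field(default_factory=dict)
    variant_effects: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 25
    confounders: tuple[ConfounderSpec, ...] = ()
    seed: int = 0
    gene_prefix: str = "G"

    def __post_init__(self) -> None:
        lo, hi = self.gene_size_range
        if not 1 <= lo <= hi:
            raise ConfigError("gene_size_range must satisfy 1 <= min <= max")
        if self.gene_sizes is not None:
            self.gene_sizes = tuple(int(s) for s in self.gene_sizes)
            if len(self.gene_sizes) != self.n_genes or min(self.gene_sizes) < 1:
                raise ConfigError("gene_sizes must list a positive size per gene")
        if not 0.0 <= self.fraction_rare <= 1.0:
            raise ConfigError("fraction_rare must be in [0, 1]")
        for name, (a, b) in (
            ("rare_maf_range", self.rare_maf_range),
            ("common_maf_range", self.common_maf_range),
        ):
            if not 0.0 < a <= b <= 0.5:
                raise ConfigError(f"{name} must be a non-empty subrange of (0, 0.5]")
        if self.fraction_rare > 0 and self.rare_maf_range[1] > 0.01:
            raise ConfigError("rare_maf_range must lie within (0, 0.01]")
        total = sum(self.causal_h2.values())
        if any(h <= 0 for h in self.causal_h2.values()) or total >= 1.0:
            raise ConfigError("per-gene heritability shares must be positive and sum to < 1")
        self.confounders = tuple(
            c if isinstance(c, ConfounderSpec) else ConfounderSpec(**c) for c in self.confounders
        )
        seen: set[str] = set()
        for c in self.confounders:
            if c.gene_a in seen or c.gene_b in seen or c.gene_a == c.gene_b:
                raise ConfigError("each gene may appear in at most one confounded pair")
            seen.update((c.gene_a, c.gene_b))

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"{self.gene_prefix}{i + 1:0{width}d}" for i in range(self.n_genes)]

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("gene_size_range", "rare_maf_range", "common_maf_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["confounders"] = [asdict(c) for c in self.confounders]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class SimulatedStudy:
    """One genotype draw plus its phenotype replicates and the truth record."""

    genotypes: GenotypeMatrix
    gene_map: GeneMap
    phenotypes: list[Phenotype]
    causal_h2: dict[str, float]
    confounders: tuple[ConfounderSpec, ...]
    config: SimulationConfig

    @property
    def causal_genes(self) -> list[str]:
        return list(self.causal_h2)


def simulate_genotypes(cfg: SimulationConfig) -> tuple[GenotypeMatrix, GeneMap]:
    """Draw the fixed genotype matrix and gene map for a study.

    Unconfounded variants are independent Binomial(2, MAF). Variants of a
    confounded gene pair are generated through a Gaussian copula: both allele
    draws of every variant in either gene load on the pair's shared standard
    normal latent factor with loading sqrt(rho), with thresholds set so each
    variant keeps its marginal MAF exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_ids
    sizes = _gene_sizes(cfg, rng)
    confounded = {c.gene_a: c for c in cfg.confounders} | {c.gene_b: c for c in cfg.confounders}
    missing = set(confounded) - set(genes)
    if missing:
        raise ConfigError(f"confounder names unknown genes: {sorted(missing)}")

    n = cfg.n_individuals
    columns: list[np.ndarray] = []
    variant_ids: list[str] = []
    mapping: dict[str, list[int]] = {}
    latents = {c: rng.standard_normal(n) for c in cfg.confounders}
    col = 0
    for gene, size in zip(genes, sizes):
        mafs = _variant_mafs(cfg, size, rng)
        spec = confounded.get(gene)

        def draw() -> np.ndarray:
            if spec is None:
                return rng.binomial(2, mafs, size=(n, size)).astype(float)
            z = latents[spec]
            load = math.sqrt(spec.rho)
            resid = math.sqrt(1.0 - spec.rho)
            thresh = stats.norm.isf(mafs)  # upper-tail threshold per variant
            d = np.zeros((n, size))
            for _ in range(2):  # two allele draws per genotype
                u = load * z[:, None] + resid * rng.standard_normal((n, size))
                d += (u > thresh[None, :]).astype(float)
            return d

        dos = draw()
        if gene in cfg.causal_h2:
            # a causal gene with no observed minor allele is undetectable and
            # would not be a designated risk gene; condition on polymorphism
            # by redrawing (marginal MAFs unchanged)
            for _ in range(1000):
                if dos.std(axis=0).max() > 0:
                    break
                dos = draw()
            else:
                raise ConfigError(f"causal gene {gene!r} never polymorphic")
        columns.append(dos)
        mapping[gene] = list(range(col, col + size))
        variant_ids.extend(f"{gene}_v{j + 1}" for j in range(size))
        col += size
    dosages = np.concatenate(columns, axis=1)
    return GenotypeMatrix(dosages, [f"S{i + 1:04d}" for i in range(n)], variant_ids), GeneMap(
        mapping, n_variants=col
    )


def _gene_sizes(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.gene_sizes is not None:
        return np.asarray(cfg.gene_sizes, dtype=int)
    lo, hi = cfg.gene_size_range
    if lo == hi:
        return np.full(cfg.n_genes, lo)
    # log-uniform: small genes are the common case, as in exome gene panels
    u = rng.uniform(math.log(lo), math.log(hi + 1), size=cfg.n_genes)
    return np.minimum(np.floor(np.exp(u)).astype(int), hi)


def _variant_mafs(cfg: SimulationConfig, size: int, rng: np.random.Generator) -> np.ndarray:
    rare = rng.random(size) < cfg.fraction_rare
    mafs = np.empty(size)
    a, b = cfg.rare_maf_range
    mafs[rare] = np.exp(rng.uniform(math.log(a), math.log(b), size=int(rare.sum())))
    a, b = cfg.common_maf_range
    mafs[~rare] = rng.uniform(a, b, size=int((~rare).sum()))
    return mafs


def _causal_weights(
    g: GenotypeMatrix, gene_map: GeneMap, gene: str, cfg: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Variant indices and relative effect weights for one causal gene."""
    idx = gene_map[gene]
    if cfg.variant_effects:
        vids = [g.variant_ids[i] for i in idx]
        w = np.array([cfg.variant_effects.get(v, 0.0) for v in vids])
        if np.any(w != 0):
            return idx[w != 0], w[w != 0]
    maf = g.variant_maf[idx]
    rare = idx[(maf > 0) & (maf <= cfg.rare_maf_range[1])]
    chosen = rare if rare.size else idx[maf > 0]
    return chosen, np.ones(chosen.size)


def simulate_phenotypes(
    g: GenotypeMatrix,
    gene_map: GeneMap,
    causal_h2: dict[str, float],
    n_replicates: int,
    rng: np.random.Generator | int,
    cfg: SimulationConfig | None = None,
) -> list[Phenotype]:
    """Additive phenotype replicates over fixed genotypes.

    Each causal gene's burden is standardized to unit sample variance and
    scaled by sqrt of its heritability share; residual noise (variance
    1 - sum of shares) is redrawn independently per replicate.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    cfg = cfg or SimulationConfig(
        n_individuals=g.n_samples, n_genes=len(gene_map), causal_h2=dict(causal_h2)
    )
    total_h2 = sum(causal_h2.values())
    if total_h2 >= 1.0:
        raise ConfigError("heritability shares must sum to < 1")
    n = g.n_samples
    genetic = np.zeros(n)
    X = g.imputed()
    for gene, h2 in causal_h2.items():
        idx, w = _causal_weights(g, gene_map, gene, cfg)
        burden = X[:, idx] @ w
        sd = burden.std()
        if sd == 0:
            raise ConfigError(f"causal gene {gene!r} has zero genetic variance")
        genetic += math.sqrt(h2) * (burden - burden.mean()) / sd
    resid_sd = math.sqrt(1.0 - total_h2)
    out = []
    for _ in range(n_replicates):
        y = genetic + resid_sd * rng.standard_normal(n)
        out.append(Phenotype(list(g.sample_ids), y))
    return out


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Genotypes plus phenotype replicates, fully determined by the config
    (identical config, including seed, reproduces the study bit for bit)."""
    genotypes, gene_map = simulate_genotypes(cfg)
    pheno_rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2**31 - 1))
    phenotypes = simulate_phenotypes(
        genotypes, gene_map, cfg.causal_h2, cfg.n_replicates, pheno_rng, cfg
    )
    return SimulatedStudy(genotypes, gene_map, phenotypes, dict(cfg.causal_h2), cfg.confounders, cfg)


def mini_exome_preset(seed: int = 0) -> SimulationConfig:
    """Desk-scale preset emulating a mini-exome study: 697 unrelated
    individuals, 300 genes (scaled down from thousands), 13 causal genes
    with heritability shares spanning weak to strong, 25 phenotype
    replicates, and 5 non-causal genes confounded with the strongest causal
    genes.

    The per-gene effect sizes are illustrative: they are chosen to spread
    single-gene detection power over roughly the full (near 0 to near 1)
    range at this sample size, not calibrated to any particular dataset.
    """
    cfg = SimulationConfig(seed=seed)
    genes = cfg.gene_ids
    causal = genes[:13]
    shares = np.geomspace(0.004, 0.045, 13)
    confounders = tuple(
        ConfounderSpec(causal[-(i + 1)], genes[23 + i], 0.8) for i in range(5)
    )
    return SimulationConfig(
        causal_h2={g: float(h) for g, h in zip(causal, shares)},
        confounders=confounders,
        seed=seed,
    )
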