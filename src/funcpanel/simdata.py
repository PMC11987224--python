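"""Synthetic populations, annotated variant catalogs, phenotypes and
molecular count data.

The generator emulates the statistical structure a functional-panel
genomic-prediction study relies on, without claiming population-genetic
realism:

* diploid genotypes with block-wise LD on several chromosomes, built as
  recombinant mosaics of a finite haplotype pool;
* a variant catalog carrying functional-class annotations with causal
  variants enriched in the functional classes;
* raw phenotypes = fixed effects (contemporary group, breed, heterosis
  and inbreeding covariates) + additive genetic value + residual, for
  two milk-composition percent traits and a volume trait, with yield
  traits formed as percent x volume so that yields carry compounded
  measurement noise;
* per-feature allelic read counts and spliced/unspliced read counts for
  the molecular-QTL tests.

All generators are deterministic given ``SimConfig.seed``: every source
of randomness flows from one ``numpy.random.SeedSequence`` spawned per
generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._core import FUNCTIONAL_CLASSES, ConfigError, GenotypeMatrix

__all__ = [
    "FixedEffectSpec",
    "SimConfig",
    "simulate_population",
    "assign_functional_classes",
    "simulate_traits",
    "simulate_allelic_counts",
    "simulate_splice_counts",
    "simulate_all",
]


@dataclass
class FixedEffectSpec:
    """Categorical factors (name -> number of levels) and covariates.

    Covariates are drawn uniformly on [0, 1] (heterosis-coefficient-like)
    or from a Beta(1, 20) (inbreeding-coefficient-like) depending on the
    distribution tag.  Factor level effects are N(0, factor_sd); covariate
    slopes are N(0, covariate_sd).
    """

    factors: dict[str, int] = field(
        default_factory=lambda: {"contemporary_group": 10, "breed": 3}
    )
    covariates: dict[str, str] = field(
        default_factory=lambda: {"heterosis": "uniform", "inbreeding": "beta"}
    )
    factor_sd: float = 0.5
    covariate_sd: float = 0.5


def _default_class_proportions() -> dict[str, float]:
    # relative sizes loosely follow the ordering of class counts seen on
    # real functional catalogs: open-chromatin classes largest, GWAS and
    # splicing classes smallest
    return {
        "GWAS": 0.02,
        "eeQTL": 0.06,
        "aseQTL": 0.05,
        "ieQTL": 0.02,
        "seQTL": 0.01,
        "asbQTL": 0.05,
        "ChIPseqQTL": 0.05,
        "ATACQTL": 0.10,
        "coding": 0.02,
    }


def _default_enrichment() -> dict[str, float]:
    return {
        "GWAS": 8.0,
        "eeQTL": 4.0,
        "coding": 4.0,
        "aseQTL": 3.0,
        "asbQTL": 2.0,
        "ChIPseqQTL": 2.0,
        "ATACQTL": 2.0,
        "ieQTL": 2.0,
        "seQTL": 2.0,
    }


@dataclass
class SimConfig:
    """Configuration for the synthetic study population.

    Defaults describe a desk-scale population: 1000 cows, 3 chromosomes of
    10 Mb with 400 variants each, a 30-haplotype founder pool, percent
    traits at h2 = 0.5 and a volume trait at h2 = 0.3 (typical dairy
    values), and yield traits carrying 5% multiplicative measurement
    noise on top of the percent x volume product.
    """

    n_individuals: int = 1000
    n_chromosomes: int = 3
    variants_per_chromosome: int = 400
    chromosome_length_bp: int = 10_000_000
    haplotype_pool_size: int = 30
    recombination_rate: float = 1.0
    class_proportions: dict[str, float] = field(default_factory=_default_class_proportions)
    causal_enrichment: dict[str, float] = field(default_factory=_default_enrichment)
    multilabel_rate: float = 0.15
    n_causal_per_trait: int = 30
    trait_heritabilities: dict[str, float] = field(
        default_factory=lambda: {
            "fat_percent": 0.5,
            "protein_percent": 0.5,
            "milk_volume": 0.3,
        }
    )
    volume_trait_name: str = "milk_volume"
    percent_trait_names: tuple[str, ...] = ("fat_percent", "protein_percent")
    trait_means: dict[str, float] = field(
        default_factory=lambda: {
            "fat_percent": 4.8,
            "protein_percent": 3.9,
            "milk_volume": 18.0,
        }
    )
    yield_noise_cv: float = 0.05
    fixed_effect_spec: FixedEffectSpec | None = field(default_factory=FixedEffectSpec)
    # molecular-data knobs
    n_ase_features: int = 40
    ase_depth: float = 100.0
    ase_fraction: float = 0.7
    n_splice_features: int = 40
    splice_depth: float = 200.0
    splice_logit_effect: float = 0.5
    splice_base_logit: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "n_individuals",
            "n_chromosomes",
            "variants_per_chromosome",
            "chromosome_length_bp",
            "haplotype_pool_size",
            "n_causal_per_trait",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.variants_per_chromosome < 2:
            raise ConfigError("variants_per_chromosome must be >= 2")
        if self.recombination_rate < 0:
            raise ConfigError("recombination_rate must be >= 0")
        unknown = set(self.class_proportions) - set(FUNCTIONAL_CLASSES)
        if unknown:
            raise ConfigError(f"unknown functional classes: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if total > 1.0 + 1e-12 or any(v < 0 for v in self.class_proportions.values()):
            raise ConfigError("class_proportions must be non-negative and sum to <= 1")
        for trait, h2 in self.trait_heritabilities.items():
            if not 0.0 <= h2 <= 1.0:
                raise ConfigError(f"heritability of {trait} outside [0,1]")
        if self.yield_noise_cv < 0:
            raise ConfigError("yield_noise_cv must be >= 0")

    @property
    def yield_trait_names(self) -> tuple[str, ...]:
        return tuple(p.replace("_percent", "") + "_yield" for p in self.percent_trait_names)

    def trait_names(self) -> tuple[str, ...]:
        return (
            tuple(self.percent_trait_names)
            + (self.volume_trait_name,)
            + self.yield_trait_names
        )

    def seed_sequences(self) -> dict[str, np.random.SeedSequence]:
        """One child SeedSequence per generator, spawned in fixed order."""
        root = np.random.SeedSequence(self.seed)
        names = ["population", "classes", "traits", "ase", "splice"]
        return dict(zip(names, root.spawn(len(names))))


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def _build_haplotype_pool(rng: np.random.Generator, m: int, pool_size: int) -> np.ndarray:
    """Founder haplotype pool for one chromosome.

    A small set of base haplotypes is drawn site-wise from a U-shaped
    allele-frequency distribution (Beta(0.5, 0.5), giving many rare
    variants); the rest of the pool is filled with gene-conversion-style
    mosaics of two already-present haplotypes, which is what creates
    shared segments and hence block-wise LD.
    """
    n_base = max(2, pool_size // 4)
    freqs = rng.beta(0.5, 0.5, size=m)
    pool = np.empty((pool_size, m), dtype=np.int8)
    pool[:n_base] = (rng.random((n_base, m)) < freqs).astype(np.int8)
    for h in range(n_base, pool_size):
        a, b = rng.choice(h, size=2, replace=False)
        n_switch = 1 + rng.poisson(2)
        cuts = np.sort(rng.integers(1, m, size=n_switch))
        take_b = np.zeros(m, dtype=bool)
        current = False
        prev = 0
        for c in list(cuts) + [m]:
            take_b[prev:c] = current
            current = not current
            prev = c
        pool[h] = np.where(take_b, pool[b], pool[a])
    return pool


def _recombine(rng: np.random.Generator, pool: np.ndarray, rate: float, n: int) -> np.ndarray:
    """n haplotypes, each a crossover mosaic of two pool haplotypes."""
    pool_size, m = pool.shape
    out = np.empty((n, m), dtype=np.int8)
    for i in range(n):
        a, b = rng.integers(0, pool_size, size=2)
        n_cross = rng.poisson(rate) if rate > 0 else 0
        if n_cross == 0 or a == b:
            out[i] = pool[a]
            continue
        cuts = np.sort(rng.integers(1, m, size=n_cross))
        take_b = np.zeros(m, dtype=bool)
        current = False
        prev = 0
        for c in list(cuts) + [m]:
            take_b[prev:c] = current
            current = not current
            prev = c
        out[i] = np.where(take_b, pool[b], pool[a])
    return out


_BASES = np.array(list("ACGT"))


def simulate_population(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate diploid genotypes and the variant catalog skeleton.

    Each chromosome gets its own haplotype pool; every individual draws
    two recombinant haplotypes per chromosome, and the dosage is their
    sum.  MAF in the catalog is computed from the realized dosage matrix.
    """
    config.validate()
    rng = np.random.Generator(np.random.PCG64(config.seed_sequences()["population"]))
    n = config.n_individuals
    m_chr = config.variants_per_chromosome

    dosage_parts = []
    records = []
    for chrom in range(1, config.n_chromosomes + 1):
        positions = np.sort(
            rng.choice(
                np.arange(1, config.chromosome_length_bp + 1),
                size=m_chr,
                replace=False,
            )
        )
        pool = _build_haplotype_pool(rng, m_chr, config.haplotype_pool_size)
        hap1 = _recombine(rng, pool, config.recombination_rate, n)
        hap2 = _recombine(rng, pool, config.recombination_rate, n)
        dosage_parts.append((hap1 + hap2).astype(np.float64))
        ref = _BASES[rng.integers(0, 4, size=m_chr)]
        alt_shift = rng.integers(1, 4, size=m_chr)
        alt = _BASES[(np.searchsorted(_BASES, ref) + alt_shift) % 4]
        for j in range(m_chr):
            records.append(
                {
                    "variant_id": f"chr{chrom}:{positions[j]}",
                    "chromosome": chrom,
                    "position_bp": int(positions[j]),
                    "ref_allele": ref[j],
                    "alt_allele": alt[j],
                }
            )

    dosage = np.concatenate(dosage_parts, axis=1)
    catalog = pd.DataFrame.from_records(records)
    gm = GenotypeMatrix(
        individual_ids=[f"ind{i:05d}" for i in range(n)],
        variant_ids=catalog["variant_id"].tolist(),
        dosage=dosage,
    )
    catalog["maf"] = gm.maf()
    catalog["classes"] = [frozenset()] * len(catalog)
    return gm, catalog


# ---------------------------------------------------------------------------
# functional classes
# ---------------------------------------------------------------------------

def assign_functional_classes(catalog: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Assign functional-class labels by weighted sampling.

    Each variant first draws a primary class from ``class_proportions``
    (the remaining probability mass leaves it unannotated); annotated
    variants then gain a secondary label with probability
    ``multilabel_rate`` so that variants can carry signals in multiple
    categories, as real functional catalogs do.
    """
    config.validate()
    rng = np.random.Generator(np.random.PCG64(config.seed_sequences()["classes"]))
    labels = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in labels])
    m = len(catalog)

    out = catalog.copy()
    classes: list[frozenset] = []
    if probs.sum() == 0:
        out["classes"] = [frozenset()] * m
        return out
    choices = rng.choice(
        len(labels) + 1, size=m, p=np.append(probs, 1.0 - probs.sum())
    )
    extra_draw = rng.random(m)
    for j in range(m):
        if choices[j] == len(labels):
            classes.append(frozenset())
            continue
        members = {labels[choices[j]]}
        if extra_draw[j] < config.multilabel_rate and len(labels) > 1:
            other = labels[rng.choice(len(labels))]
            members.add(other)
        classes.append(frozenset(members))
    out["classes"] = classes
    return out


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _sample_fixed_effects(
    rng: np.random.Generator, spec: FixedEffectSpec | None, n: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw per-individual fixed-effect columns and their phenotypic contribution."""
    if spec is None:
        return pd.DataFrame(index=range(n)), np.zeros(n)
    cols: dict[str, np.ndarray] = {}
    contribution = np.zeros(n)
    for name, n_levels in spec.factors.items():
        levels = rng.integers(0, n_levels, size=n)
        effects = rng.normal(0.0, spec.factor_sd, size=n_levels)
        cols[name] = levels
        contribution += effects[levels]
    for name, dist in spec.covariates.items():
        if dist == "uniform":
            x = rng.random(n)
        elif dist == "beta":
            x = rng.beta(1.0, 20.0, size=n)
        else:
            raise ConfigError(f"unknown covariate distribution {dist!r}")
        slope = rng.normal(0.0, spec.covariate_sd)
        cols[name] = x
        contribution += slope * x
    return pd.DataFrame(cols), contribution


def _causal_weights(catalog: pd.DataFrame, enrichment: dict[str, float]) -> np.ndarray:
    """Causal-sampling weight per variant: product of class odds multipliers."""
    w = np.ones(len(catalog))
    for j, cls in enumerate(catalog["classes"]):
        for c in cls:
            w[j] *= enrichment.get(c, 1.0)
    # monomorphic variants cannot carry trait variance
    w[catalog["maf"].to_numpy() <= 0] = 0.0
    return w


def simulate_traits(
    genotypes: GenotypeMatrix, catalog: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate raw phenotypes; returns (phenotype table, updated catalog).

    For each primary trait (the percent traits and the volume trait)
    causal variants are drawn with class-enrichment odds, effects are
    Normal and rescaled so the realized genetic variance hits the target
    h2 on a unit total-variance scale, and the phenotype is
    mean + fixed effects + genetic value + Normal residual.  Yield traits
    are then formed as percent x volume with lognormal multiplicative
    noise of coefficient of variation ``yield_noise_cv``, so they inherit
    the compounded error of both parents.

    The returned phenotype table carries the fixed-effect columns and,
    as simulation truth, one ``tgv_<trait>`` column per trait.
    """
    config.validate()
    rng = np.random.Generator(np.random.PCG64(config.seed_sequences()["traits"]))
    n = genotypes.n_individuals
    if list(catalog["variant_id"]) != list(genotypes.variant_ids):
        raise ValueError("catalog and genotype matrix not aligned")

    fixed_df, fixed_contrib = _sample_fixed_effects(rng, config.fixed_effect_spec, n)
    weights = _causal_weights(catalog, config.causal_enrichment)

    table = pd.DataFrame({"individual_id": genotypes.individual_ids})
    for col in fixed_df.columns:
        table[col] = fixed_df[col].to_numpy()

    cat = catalog.copy()
    primary = list(config.percent_trait_names) + [config.volume_trait_name]
    genetic: dict[str, np.ndarray] = {}
    for trait in primary:
        h2 = config.trait_heritabilities.get(trait, 0.3)
        causal = np.zeros(len(cat), dtype=bool)
        effects = np.zeros(len(cat))
        g = np.zeros(n)
        if h2 > 0 and weights.sum() > 0:
            k = min(config.n_causal_per_trait, int((weights > 0).sum()))
            idx = rng.choice(len(cat), size=k, replace=False, p=weights / weights.sum())
            raw = rng.normal(0.0, 1.0, size=k)
            Z = genotypes.dosage[:, idx]
            g_raw = Z @ raw
            sd = g_raw.std()
            scale = math.sqrt(h2) / sd if sd > 0 else 0.0
            effects[idx] = raw * scale
            g = g_raw * scale
            causal[idx] = True
        resid = rng.normal(0.0, math.sqrt(max(0.0, 1.0 - h2)), size=n)
        mean = config.trait_means.get(trait, 0.0) if config.fixed_effect_spec else 0.0
        table[trait] = mean + fixed_contrib + g + resid
        table[f"tgv_{trait}"] = g
        genetic[trait] = g
        cat[f"causal_{trait}"] = causal
        cat[f"effect_{trait}"] = effects

    vol = config.volume_trait_name
    mu_v = config.trait_means.get(vol, 0.0) if config.fixed_effect_spec else 0.0
    sigma = math.sqrt(math.log1p(config.yield_noise_cv**2))
    for pct, yld in zip(config.percent_trait_names, config.yield_trait_names):
        noise = (
            np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n)) if sigma > 0 else np.ones(n)
        )
        table[yld] = table[pct].to_numpy() * table[vol].to_numpy() * noise
        mu_p = config.trait_means.get(pct, 0.0) if config.fixed_effect_spec else 0.0
        g_p, g_v = genetic[pct], genetic[vol]
        table[f"tgv_{yld}"] = (mu_p + g_p) * (mu_v + g_v) - mu_p * mu_v
        cat[f"causal_{yld}"] = cat[f"causal_{pct}"] | cat[f"causal_{vol}"]
        cat[f"effect_{yld}"] = 0.0
    return table, cat


# ---------------------------------------------------------------------------
# molecular counts
# ---------------------------------------------------------------------------

def _pick_feature_variants(
    rng: np.random.Generator,
    catalog: pd.DataFrame,
    n_features: int,
    preferred_class: str,
    maf_min: float = 0.1,
    pair_window: int = 200_000,
) -> pd.DataFrame:
    """Pick (regulatory variant, transcribed marker) pairs for features.

    Regulatory variants are preferentially drawn from ``preferred_class``;
    the transcribed marker is a nearby common variant whose heterozygotes
    define the informative individuals.  The feature position is the
    midpoint of the pair.
    """
    ok = catalog[catalog["maf"] >= maf_min]
    pref = ok[[preferred_class in c for c in ok["classes"]]]
    source = pref if len(pref) >= n_features else ok
    if len(source) < 1:
        raise ConfigError("no variants eligible as regulatory variants")
    reg_idx = rng.choice(source.index.to_numpy(), size=min(n_features, len(source)), replace=False)

    rows = []
    for i, ridx in enumerate(reg_idx):
        reg = catalog.loc[ridx]
        near = ok[
            (ok["chromosome"] == reg["chromosome"])
            & (ok["variant_id"] != reg["variant_id"])
            & ((ok["position_bp"] - reg["position_bp"]).abs() <= pair_window)
        ]
        if len(near) == 0:
            near = ok[
                (ok["chromosome"] == reg["chromosome"])
                & (ok["variant_id"] != reg["variant_id"])
            ]
            if len(near) == 0:
                continue
        marker = catalog.loc[rng.choice(near.index.to_numpy())]
        rows.append(
            {
                "feature_id": f"feat{i:04d}",
                "chromosome": int(reg["chromosome"]),
                "position_bp": int((reg["position_bp"] + marker["position_bp"]) // 2),
                "regulatory_variant_id": reg["variant_id"],
                "transcribed_variant_id": marker["variant_id"],
            }
        )
    return pd.DataFrame(rows)


def simulate_allelic_counts(
    genotypes: GenotypeMatrix,
    catalog: pd.DataFrame,
    config: SimConfig,
    allelic_fraction: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate maternal/paternal allele counts per feature.

    Only individuals heterozygous at the feature's transcribed marker get
    rows.  For those also heterozygous at the linked regulatory variant,
    the maternal fraction is shifted from 0.5 to ``allelic_fraction``
    (parental phase is known in simulation and taken as aligned:
    the maternal haplotype carries the alternate allele); homozygotes
    stay balanced.  Total read depth is Poisson.

    Returns (count table, feature table).
    """
    config.validate()
    p_shift = config.ase_fraction if allelic_fraction is None else allelic_fraction
    if not 0.0 <= p_shift <= 1.0:
        raise ConfigError("allelic fraction must be in [0,1]")
    rng = np.random.Generator(np.random.PCG64(config.seed_sequences()["ase"]))
    features = _pick_feature_variants(rng, catalog, config.n_ase_features, "aseQTL")

    rows = []
    for _, feat in features.iterrows():
        marker_dos = genotypes.column(feat["transcribed_variant_id"])
        reg_dos = genotypes.column(feat["regulatory_variant_id"])
        carriers = np.where(np.isclose(marker_dos, 1.0))[0]
        for i in carriers:
            p = p_shift if np.isclose(reg_dos[i], 1.0) else 0.5
            total = rng.poisson(config.ase_depth)
            if total == 0:
                continue
            mat = rng.binomial(total, p)
            rows.append(
                {
                    "individual_id": genotypes.individual_ids[i],
                    "feature_id": feat["feature_id"],
                    "maternal_count": int(mat),
                    "paternal_count": int(total - mat),
                    "regulatory_variant_id": feat["regulatory_variant_id"],
                }
            )
    counts = pd.DataFrame(
        rows,
        columns=[
            "individual_id",
            "feature_id",
            "maternal_count",
            "paternal_count",
            "regulatory_variant_id",
        ],
    )
    return counts, features


def simulate_splice_counts(
    genotypes: GenotypeMatrix,
    catalog: pd.DataFrame,
    config: SimConfig,
    logit_effect: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate spliced/unspliced read counts per splice junction.

    Every individual gets a row per feature; the splicing proportion is
    sigmoid(base_logit + effect x regulatory dosage), so the regulatory
    variant shifts splicing efficiency additively on the logit scale.

    Returns (count table, feature table).
    """
    config.validate()
    eff = config.splice_logit_effect if logit_effect is None else logit_effect
    rng = np.random.Generator(np.random.PCG64(config.seed_sequences()["splice"]))
    features = _pick_feature_variants(rng, catalog, config.n_splice_features, "seQTL")

    n = genotypes.n_individuals
    rows = []
    for _, feat in features.iterrows():
        reg_dos = genotypes.column(feat["regulatory_variant_id"])
        logits = config.splice_base_logit + eff * reg_dos
        p = 1.0 / (1.0 + np.exp(-logits))
        totals = rng.poisson(config.splice_depth, size=n)
        spliced = rng.binomial(totals, p)
        for i in range(n):
            if totals[i] == 0:
                continue
            rows.append(
                {
                    "individual_id": genotypes.individual_ids[i],
                    "feature_id": feat["feature_id"],
                    "spliced_count": int(spliced[i]),
                    "unspliced_count": int(totals[i] - spliced[i]),
                }
            )
    counts = pd.DataFrame(
        rows,
        columns=["individual_id", "feature_id", "spliced_count", "unspliced_count"],
    )
    return counts, features


def simulate_all(config: SimConfig):
    """Run every generator; returns a dict with all synthetic artifacts."""
    gm, catalog = simulate_population(config)
    catalog = assign_functional_classes(catalog, config)
    phenotypes, catalog = simulate_traits(gm, catalog, config)
    ase_counts, ase_features = simulate_allelic_counts(gm, catalog, config)
    splice_counts, splice_features = simulate_splice_counts(gm, catalog, config)
    return {
        "genotypes": gm,
        "catalog": catalog,
        "phenotypes": phenotypes,
        "ase_counts": ase_counts,
        "ase_features": ase_features,
        "splice_counts": splice_counts,
        "splice_features": splice_features,
    }
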