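import numpy as np
import pandas as pd
import pytest
from scipy import stats

from funcpanel._core import ConfigError
from funcpanel.simdata import (
    SimConfig,
    assign_functional_classes,
    simulate_allelic_counts,
    simulate_population,
    simulate_splice_counts,
    simulate_traits,
)


def small_config(**kw):
    base = dict(
        n_individuals=200,
        n_chromosomes=2,
        variants_per_chromosome=100,
        seed=3,
    )
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"variants_per_chromosome": 1},
            {"n_individuals": 0},
            {"recombination_rate": -0.1},
            {"trait_heritabilities": {"fat_percent": 1.5}},
            {"class_proportions": {"notaclass": 0.1}},
            {"class_proportions": {"GWAS": 0.9, "coding": 0.2}},
            {"yield_noise_cv": -1.0},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigError):
            small_config(**kw)


class TestPopulation:
    def test_same_seed_identical_output(self):
        cfg = small_config()
        gm1, cat1 = simulate_population(cfg)
        gm2, cat2 = simulate_population(small_config())
        assert np.array_equal(gm1.dosage, gm2.dosage)
        pd.testing.assert_frame_equal(cat1, cat2)

    def test_catalog_maf_matches_dosage(self):
        gm, cat = simulate_population(small_config())
        recomputed = np.minimum(gm.dosage.mean(axis=0) / 2, 1 - gm.dosage.mean(axis=0) / 2)
        assert np.max(np.abs(recomputed - cat["maf"].to_numpy())) < 1e-12

    def test_positions_strictly_increasing(self):
        _, cat = simulate_population(small_config())
        for _, grp in cat.groupby("chromosome"):
            assert np.all(np.diff(grp["position_bp"].to_numpy()) > 0)

    def test_no_recombination_two_haplotypes_gives_complete_linkage(self):
        cfg = small_config(recombination_rate=0.0, haplotype_pool_size=2, n_individuals=100)
        gm, cat = simulate_population(cfg)
        for chrom in (1, 2):
            cols = gm.dosage[:, (cat["chromosome"] == chrom).to_numpy()]
            poly = cols[:, cols.std(axis=0) > 0]
            if poly.shape[1] < 2:
                continue
            r = np.corrcoef(poly.T)
            assert np.min(r**2) > 1 - 1e-9

    def test_maf_spectrum_skewed_toward_rare(self):
        cfg = SimConfig(n_individuals=500, n_chromosomes=2, variants_per_chromosome=500, seed=5)
        gm, _ = simulate_population(cfg)
        maf = np.minimum(gm.dosage.mean(axis=0) / 2, 1 - gm.dosage.mean(axis=0) / 2)
        assert (maf < 0.1).mean() >= 0.30


class TestFunctionalClasses:
    def test_zero_proportions_leave_all_unannotated(self):
        cfg = small_config(class_proportions={})
        gm, cat = simulate_population(cfg)
        cat = assign_functional_classes(cat, cfg)
        assert all(len(c) == 0 for c in cat["classes"])

    def test_saturated_proportion_labels_everything(self):
        cfg = small_config(class_proportions={"coding": 1.0})
        gm, cat = simulate_population(cfg)
        cat = assign_functional_classes(cat, cfg)
        assert all("coding" in c for c in cat["classes"])

    def test_annotated_fraction_within_binomial_bounds(self):
        cfg = SimConfig(
            n_individuals=50,
            n_chromosomes=10,
            variants_per_chromosome=1000,
            class_proportions={"GWAS": 0.1, "eeQTL": 0.2, "coding": 0.1},
            seed=11,
        )
        gm, cat = simulate_population(cfg)
        cat = assign_functional_classes(cat, cfg)
        m = len(cat)
        annotated = sum(len(c) > 0 for c in cat["classes"])
        lo, hi = stats.binom.ppf([0.005, 0.995], m, 0.4)
        assert lo <= annotated <= hi


class TestTraits:
    def test_zero_heritability_gives_flat_genetics(self):
        cfg = small_config(trait_heritabilities={"fat_percent": 0.0, "protein_percent": 0.5, "milk_volume": 0.3})
        gm, cat = simulate_population(cfg)
        cat = assign_functional_classes(cat, cfg)
        phen, _ = simulate_traits(gm, cat, cfg)
        assert phen["tgv_fat_percent"].var() == 0.0

    def test_noiseless_limit_phenotype_equals_genetic_value(self):
        cfg = small_config(
            trait_heritabilities={"fat_percent": 1.0, "protein_percent": 1.0, "milk_volume": 1.0},
            yield_noise_cv=0.0,
            fixed_effect_spec=None,
        )
        gm, cat = simulate_population(cfg)
        cat = assign_functional_classes(cat, cfg)
        phen, _ = simulate_traits(gm, cat, cfg)
        for trait in ("fat_percent", "milk_volume", "fat_yield"):
            np.testing.assert_allclose(
                phen[trait].to_numpy(), phen[f"tgv_{trait}"].to_numpy(), rtol=0, atol=1e-10
            )

    def test_phenotype_regression_on_truth_near_unity(self):
        cfg = SimConfig(
            n_individuals=2000, n_chromosomes=3, variants_per_chromosome=300, seed=17
        )
        gm, cat = simulate_population(cfg)
        cat = assign_functional_classes(cat, cfg)
        phen, _ = simulate_traits(gm, cat, cfg)
        g = phen["tgv_fat_percent"].to_numpy()
        y = phen["fat_percent"].to_numpy()
        slope = np.polyfit(g, y, 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_realized_heritability_near_target(self):
        cfg = SimConfig(
            n_individuals=2000, n_chromosomes=3, variants_per_chromosome=300,
            fixed_effect_spec=None, seed=19,
        )
        gm, cat = simulate_population(cfg)
        cat = assign_functional_classes(cat, cfg)
        phen, _ = simulate_traits(gm, cat, cfg)
        h2 = phen["tgv_fat_percent"].var() / phen["fat_percent"].var()
        assert abs(h2 - 0.5) < 0.1

    def test_yield_traits_carry_larger_residual_share(self, sim_art):
        phen = sim_art["phenotypes"]
        for pct, yld in (("fat_percent", "fat_yield"), ("protein_percent", "protein_yield")):
            share = lambda t: 1 - np.corrcoef(phen[t], phen[f"tgv_{t}"])[0, 1] ** 2
            assert share(yld) > share(pct)

    def test_causal_variants_enriched_in_functional_classes(self, sim_art):
        cat = sim_art["catalog"]
        annotated = np.array([len(c) > 0 for c in cat["classes"]])
        causal = cat["causal_fat_percent"].to_numpy()
        assert causal[annotated].mean() > causal.mean()


class TestAllelicCounts:
    def test_null_effect_pooled_fraction_balanced(self):
        cfg = small_config(n_individuals=400)
        gm, cat = simulate_population(cfg)
        cat = assign_functional_classes(cat, cfg)
        counts, _ = simulate_allelic_counts(gm, cat, cfg, allelic_fraction=0.5)
        M = counts["maternal_count"].sum()
        T = M + counts["paternal_count"].sum()
        lo, hi = stats.binom.ppf([0.005, 0.995], T, 0.5)
        assert lo <= M <= hi

    def test_saturated_effect_silences_paternal_allele(self):
        cfg = small_config(n_individuals=300)
        gm, cat = simulate_population(cfg)
        cat = assign_functional_classes(cat, cfg)
        counts, feats = simulate_allelic_counts(gm, cat, cfg, allelic_fraction=1.0)
        reg = feats.set_index("feature_id")["regulatory_variant_id"]
        for _, row in counts.iterrows():
            dos = gm.column(reg[row["feature_id"]])[gm.individual_ids.index(row["individual_id"])]
            if np.isclose(dos, 1.0):
                assert row["paternal_count"] == 0

    def test_mean_maternal_fraction_tracks_allelic_effect(self):
        cfg = SimConfig(
            n_individuals=600, n_chromosomes=2, variants_per_chromosome=150,
            n_ase_features=20, ase_depth=100.0, seed=23,
        )
        gm, cat = simulate_population(cfg)
        cat = assign_functional_classes(cat, cfg)
        counts, feats = simulate_allelic_counts(gm, cat, cfg, allelic_fraction=0.7)
        reg = feats.set_index("feature_id")["regulatory_variant_id"]
        iidx = {s: i for i, s in enumerate(gm.individual_ids)}
        fracs = []
        for _, row in counts.iterrows():
            if np.isclose(gm.column(reg[row["feature_id"]])[iidx[row["individual_id"]]], 1.0):
                tot = row["maternal_count"] + row["paternal_count"]
                fracs.append(row["maternal_count"] / tot)
        assert len(fracs) >= 200
        assert 0.66 <= np.mean(fracs) <= 0.74


class TestSpliceCounts:
    def test_null_effect_uncorrelated_with_dosage(self):
        cfg = small_config(n_individuals=300, n_splice_features=10)
        gm, cat = simulate_population(cfg)
        cat = assign_functional_classes(cat, cfg)
        counts, feats = simulate_splice_counts(gm, cat, cfg, logit_effect=0.0)
        reg = feats.set_index("feature_id")["regulatory_variant_id"]
        iidx = {s: i for i, s in enumerate(gm.individual_ids)}
        null_bound = stats.norm.ppf(0.995) / np.sqrt(cfg.n_individuals)
        n_exceed = 0
        for fid, grp in counts.groupby("feature_id"):
            p = (grp["spliced_count"] + 0.5) / (
                grp["spliced_count"] + grp["unspliced_count"] + 1.0
            )
            logit = np.log(p / (1 - p))
            dos = np.array([gm.column(reg[fid])[iidx[s]] for s in grp["individual_id"]])
            if dos.std() == 0:
                continue
            if abs(np.corrcoef(logit, dos)[0, 1]) > null_bound:
                n_exceed += 1
        # each feature exceeds the 99% null bound with prob 0.01
        assert n_exceed <= 2

    def test_saturating_effect_removes_unspliced_reads(self):
        cfg = small_config(n_individuals=200, splice_base_logit=30.0)
        gm, cat = simulate_population(cfg)
        cat = assign_functional_classes(cat, cfg)
        counts, _ = simulate_splice_counts(gm, cat, cfg, logit_effect=0.0)
        assert (counts["unspliced_count"] == 0).all()

    def test_logit_slope_recovers_planted_effect(self):
        cfg = SimConfig(
            n_individuals=371, n_chromosomes=2, variants_per_chromosome=150,
            n_splice_features=15, splice_depth=200.0, seed=29,
        )
        gm, cat = simulate_population(cfg)
        cat = assign_functional_classes(cat, cfg)
        counts, feats = simulate_splice_counts(gm, cat, cfg, logit_effect=0.5)
        reg = feats.set_index("feature_id")["regulatory_variant_id"]
        iidx = {s: i for i, s in enumerate(gm.individual_ids)}
        slopes = []
        for fid, grp in counts.groupby("feature_id"):
            p = (grp["spliced_count"] + 0.5) / (
                grp["spliced_count"] + grp["unspliced_count"] + 1.0
            )
            logit = np.log(p / (1 - p))
            dos = np.array([gm.column(reg[fid])[iidx[s]] for s in grp["individual_id"]])
            if dos.std() > 0 and (np.isclose(dos, 1).any() and np.isclose(dos, 0).any()):
                slopes.append(np.polyfit(dos, logit, 1)[0])
        assert len(slopes) >= 5
        assert 0.4 <= np.mean(slopes) <= 0.6
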