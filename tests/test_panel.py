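import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from funcpanel._core import GenotypeMatrix
from funcpanel.panel import (
    LdBlockAssignment,
    Panel,
    assign_ld_blocks,
    benchmark_qc_filter,
    final_filter,
    hwe_exact_midp,
    maf_bin_histogram,
    match_maf_spectrum,
    pairwise_r2,
    sample_matched_random_panel,
    select_block_representatives,
)

from conftest import independent_genotypes


def make_catalog(ids, mafs=None, classes=None, alts=None, positions=None):
    m = len(ids)
    return pd.DataFrame(
        {
            "variant_id": ids,
            "chromosome": 1,
            "position_bp": positions or [1000 * (j + 1) for j in range(m)],
            "ref_allele": "A",
            "alt_allele": alts or ["C"] * m,
            "maf": mafs if mafs is not None else [0.3] * m,
            "classes": classes or [frozenset()] * m,
        }
    )


class TestHweExactMidp:
    def test_matches_full_enumeration(self):
        # independent oracle: enumerate all tables for small n directly
        def brute(n_het, n_rare_hom, n_common_hom):
            import math

            n = n_het + n_rare_hom + n_common_hom
            rare = 2 * n_rare_hom + n_het
            rare = min(rare, 2 * n - rare)
            probs = {}
            for h in range(rare % 2, rare + 1, 2):
                hr = (rare - h) // 2
                hc = n - h - hr
                if hc < 0:
                    continue
                probs[h] = (
                    math.comb(n, h)
                    * math.comb(n - h, hr)
                    * 2**h
                    / math.comb(2 * n, rare)
                )
            obs = probs[n_het]
            return sum(
                p if p < obs - 1e-12 else (0.5 * p if p <= obs + 1e-12 else 0.0)
                for p in probs.values()
            )

        for het, rare, common in [(5, 2, 13), (0, 5, 5), (10, 0, 0), (3, 3, 3), (20, 5, 25)]:
            assert hwe_exact_midp(het, rare, common) == pytest.approx(
                brute(het, rare, common), abs=1e-10
            )

    def test_extreme_deficit_of_heterozygotes_is_significant(self):
        assert hwe_exact_midp(0, 20, 20) < 1e-6

    def test_empty_sample_returns_one(self):
        assert hwe_exact_midp(0, 0, 0) == 1.0


class TestBenchmarkQc:
    def test_hand_computed_toy_survivors(self):
        # five variants: low MAF, low call rate, a duplicate pair, one clean
        n = 50
        rng = np.random.default_rng(4)
        hwe_ok = rng.binomial(2, 0.5, n).astype(float)  # common, near-HWE
        other = rng.binomial(2, 0.4, n).astype(float)
        rare = np.zeros(n)
        rare[0] = 1.0  # MAF 0.01
        dosage = np.column_stack([rare, other, hwe_ok, hwe_ok, other * 0 + hwe_ok * 0 + rng.binomial(2, 0.5, n)])
        missing = np.zeros_like(dosage, dtype=bool)
        missing[: int(0.8 * n), 1] = True  # call rate 0.2
        ids = [f"chr1:{p}" for p in (100, 200, 300, 400, 500)]
        gm = GenotypeMatrix([f"i{i}" for i in range(n)], ids, dosage.copy(), missing)
        dup_idx = 3
        gm.dosage[:, dup_idx] = gm.dosage[:, 2]  # exact duplicate of chr1:300
        cat = make_catalog(ids, positions=[100, 200, 300, 400, 500])
        panel = benchmark_qc_filter(gm, cat)
        # expected by hand: chr1:100 fails MAF, chr1:200 fails call rate,
        # chr1:400 pruned against chr1:300; chr1:300 and chr1:500 survive
        # provided they pass the HWE screen (checked below)
        assert hwe_exact_midp(*_counts(gm.dosage[:, 2])) >= 0.15
        assert hwe_exact_midp(*_counts(gm.dosage[:, 4])) >= 0.15
        assert panel.variant_ids == ["chr1:300", "chr1:500"]

    def test_identical_variants_collapse_to_one(self):
        n = 60
        rng = np.random.default_rng(8)
        col = rng.binomial(2, 0.5, n).astype(float)
        while hwe_exact_midp(*_counts(col)) < 0.15:
            col = rng.binomial(2, 0.5, n).astype(float)
        dosage = np.column_stack([col] * 4)
        ids = [f"chr1:{1000 * (j + 1)}" for j in range(4)]
        gm = GenotypeMatrix([f"i{i}" for i in range(n)], ids, dosage)
        panel = benchmark_qc_filter(gm, make_catalog(ids))
        assert len(panel) == 1

    def test_hwe_filter_removes_expected_fraction_under_null(self):
        # under HWE-conforming data the mid-p is ~uniform, so p < 0.15
        # removes ~15% of variants
        gm, cat = independent_genotypes(400, 600, seed=12, freq_low=0.2, freq_high=0.5)
        panel = benchmark_qc_filter(gm, cat, ld_r2_max=1.1)  # disable pruning
        removed = gm.n_variants - len(panel)
        lo, hi = stats.binom.ppf([0.005, 0.995], 600, 0.15)
        assert lo <= removed <= hi

    def test_empty_survivor_set_raises(self):
        n = 50
        dosage = np.zeros((n, 2))
        ids = ["chr1:100", "chr1:200"]
        gm = GenotypeMatrix([f"i{i}" for i in range(n)], ids, dosage)
        with pytest.raises(ValueError):
            benchmark_qc_filter(gm, make_catalog(ids))


def _counts(col):
    d = np.rint(col).astype(int)
    n0, n1, n2 = (d == 0).sum(), (d == 1).sum(), (d == 2).sum()
    return int(n1), int(min(n0, n2)), int(max(n0, n2))


class TestLdBlocks:
    def test_unattainable_threshold_gives_singletons(self):
        gm, cat = independent_genotypes(80, 20, seed=1)
        blocks = assign_ld_blocks(gm, list(gm.variant_ids), cat, r2_threshold=1.01)
        assert blocks.n_blocks() == 20

    def test_identical_columns_share_a_block(self):
        gm, cat = independent_genotypes(80, 5, seed=2)
        gm.dosage[:, 1] = gm.dosage[:, 0]
        blocks = assign_ld_blocks(gm, list(gm.variant_ids), cat)
        assert (
            blocks.variant_to_block[gm.variant_ids[0]]
            == blocks.variant_to_block[gm.variant_ids[1]]
        )

    @pytest.mark.parametrize("threshold", [0.5, 0.8, 0.98])
    def test_matches_brute_force_transitive_closure(self, threshold):
        from funcpanel.simdata import SimConfig, simulate_population

        cfg = SimConfig(
            n_individuals=150, n_chromosomes=1, variants_per_chromosome=60,
            haplotype_pool_size=8, recombination_rate=0.5, seed=33,
        )
        gm, cat = simulate_population(cfg)
        cands = list(gm.variant_ids)
        blocks = assign_ld_blocks(gm, cands, cat, r2_threshold=threshold, window_bp=None)

        # oracle: boolean-matrix transitive closure over the full r2 matrix
        m = len(cands)
        A = np.eye(m, dtype=bool)
        for i, j in itertools.combinations(range(m), 2):
            if pairwise_r2(gm.dosage[:, i], gm.dosage[:, j]) >= threshold:
                A[i, j] = A[j, i] = True
        reach = A.copy()
        for _ in range(m):
            new = reach @ reach
            if (new == reach).all():
                break
            reach = new
        oracle_labels = {}
        for i in range(m):
            key = tuple(np.where(reach[i])[0])
            oracle_labels[cands[i]] = key
        ours = {v: blocks.variant_to_block[v] for v in cands}
        # partitions equal iff the induced equivalences match
        for a, b in itertools.combinations(cands, 2):
            assert (ours[a] == ours[b]) == (oracle_labels[a] == oracle_labels[b])


class TestRepresentatives:
    def _blocks(self, members):
        return LdBlockAssignment(
            variant_to_block={v: 0 for v in members}, block_members={0: list(members)}
        )

    def test_coding_beats_chromatin_classes(self):
        cat = make_catalog(
            ["v1", "v2"], classes=[frozenset({"ATACQTL"}), frozenset({"coding"})]
        )
        assert select_block_representatives(self._blocks(["v1", "v2"]), cat) == ["v2"]

    def test_expression_tier_beats_coding_and_gwas(self):
        cat = make_catalog(
            ["v1", "v2", "v3"],
            classes=[frozenset({"coding"}), frozenset({"eeQTL"}), frozenset({"GWAS"})],
        )
        assert select_block_representatives(self._blocks(["v1", "v2", "v3"]), cat) == ["v2"]

    def test_singleton_block_represents_itself(self):
        cat = make_catalog(["v1"])
        assert select_block_representatives(self._blocks(["v1"]), cat) == ["v1"]

    def test_tie_breaks_by_label_count_then_position(self):
        cat = make_catalog(
            ["v1", "v2", "v3"],
            classes=[
                frozenset({"GWAS"}),
                frozenset({"GWAS", "ATACQTL"}),
                frozenset({"GWAS"}),
            ],
        )
        assert select_block_representatives(self._blocks(["v1", "v2", "v3"]), cat) == ["v2"]


class TestMafHistogram:
    def test_half_open_bin_edges(self):
        cat = make_catalog(["v1", "v2"], mafs=[0.049, 0.05])
        hist = maf_bin_histogram(["v1", "v2"], cat)
        assert hist[0] == 1 and hist[1] == 1

    def test_empty_panel_all_zero(self):
        cat = make_catalog(["v1"])
        assert maf_bin_histogram([], cat).sum() == 0

    def test_maf_half_lands_in_top_bin(self):
        cat = make_catalog(["v1"], mafs=[0.5])
        assert maf_bin_histogram(["v1"], cat)[9] == 1

    def test_out_of_range_maf_rejected(self):
        cat = make_catalog(["v1"], mafs=[0.6])
        with pytest.raises(ValueError):
            maf_bin_histogram(["v1"], cat)

    def test_uniform_mafs_fill_bins_evenly(self):
        rng = np.random.default_rng(3)
        mafs = rng.uniform(0, 0.5, 1000)
        ids = [f"v{j}" for j in range(1000)]
        cat = make_catalog(ids, mafs=list(mafs))
        hist = maf_bin_histogram(ids, cat)
        assert hist.sum() == 1000
        # multinomial 99% bounds per bin (Bonferroni across 10 bins)
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 1000, 0.1)
        assert all(lo <= h <= hi for h in hist)


class TestMatchMafSpectrum:
    def test_reference_equal_to_candidates_returns_everything(self):
        rng = np.random.default_rng(9)
        ids = [f"v{j}" for j in range(200)]
        cat = make_catalog(ids, mafs=list(rng.uniform(0, 0.5, 200)))
        ref = maf_bin_histogram(ids, cat)
        panel = match_maf_spectrum(ids, ref, cat, seed=0)
        assert sorted(panel.variant_ids) == sorted(ids)

    def test_all_zero_reference_gives_empty_panel(self):
        cat = make_catalog(["v1", "v2"])
        panel = match_maf_spectrum(["v1", "v2"], np.zeros(10, dtype=int), cat, seed=0)
        assert len(panel) == 0

    def test_output_histogram_equals_reference_without_shortfall(self):
        rng = np.random.default_rng(10)
        ids = [f"v{j}" for j in range(1000)]
        cat = make_catalog(
            ids,
            mafs=list(rng.uniform(0, 0.5, 1000)),
            classes=[frozenset(rng.choice(["GWAS", "eeQTL", "coding"], rng.integers(0, 3), replace=False)) for _ in range(1000)],
        )
        ref = (maf_bin_histogram(ids, cat) // 2).astype(int)
        panel = match_maf_spectrum(ids, ref, cat, seed=1)
        assert not panel.provenance["shortfalls"]
        np.testing.assert_array_equal(maf_bin_histogram(panel.variant_ids, cat), ref)

    def test_shortfall_logged_and_bin_kept_whole(self):
        cat = make_catalog(["v1", "v2"], mafs=[0.01, 0.02])
        ref = np.zeros(10, dtype=int)
        ref[0] = 5
        panel = match_maf_spectrum(["v1", "v2"], ref, cat, seed=0)
        assert panel.provenance["shortfalls"] == {0: 3}
        assert sorted(panel.variant_ids) == ["v1", "v2"]


class TestFinalFilter:
    def test_maf_boundary(self):
        cat = make_catalog(["v1", "v2"], mafs=[0.09, 0.10])
        panel = final_filter(Panel("p", ["v1", "v2"]), cat)
        assert panel.variant_ids == ["v2"]

    def test_multiallelic_removed(self):
        cat = make_catalog(["v1", "v2"], alts=["C", "C,G"], mafs=[0.3, 0.3])
        panel = final_filter(Panel("p", ["v1", "v2"]), cat)
        assert panel.variant_ids == ["v1"]

    def test_survivor_count_on_printed_toy(self):
        mafs = [0.30, 0.05, 0.25, 0.09, 0.45, 0.12, 0.50, 0.20, 0.15, 0.33]
        alts = ["C", "C", "C,T", "C", "C", "C", "C", "C", "C", "C"]
        ids = [f"v{j}" for j in range(10)]
        cat = make_catalog(ids, mafs=mafs, alts=alts)
        panel = final_filter(Panel("p", ids), cat)
        # failing: v1 (maf .05), v3 (maf .09), v2 (triallelic) -> 7 survive
        assert len(panel) == 7


class TestRandomBaseline:
    def test_full_draw_returns_whole_panel_canonicalized(self):
        p = Panel("cur", ["b", "a", "c"])
        out = sample_matched_random_panel(p, 3, seed=5)
        assert out.variant_ids == ["a", "b", "c"]

    def test_zero_draw_empty(self):
        p = Panel("cur", ["a", "b"])
        assert len(sample_matched_random_panel(p, 0, seed=1)) == 0

    def test_deterministic_given_seed_and_varies_across_seeds(self):
        p = Panel("cur", [f"v{j}" for j in range(100)])
        a = sample_matched_random_panel(p, 30, seed=1)
        b = sample_matched_random_panel(p, 30, seed=1)
        c = sample_matched_random_panel(p, 30, seed=2)
        assert a.variant_ids == b.variant_ids
        assert a.variant_ids != c.variant_ids

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            sample_matched_random_panel(Panel("cur", ["a"]), 2, seed=0)


def test_pipeline_composition_monotone(sim_art):
    """candidates -> blocks -> representatives -> MAF match -> final filter."""
    gm, cat = sim_art["genotypes"], sim_art["catalog"]
    candidates = cat.loc[[len(c) > 0 for c in cat["classes"]], "variant_id"].tolist()
    blocks = assign_ld_blocks(gm, candidates, cat)
    reps = select_block_representatives(blocks, cat)
    assert len(reps) == blocks.n_blocks() <= len(candidates)
    bench = benchmark_qc_filter(gm, cat)
    ref = maf_bin_histogram(bench.variant_ids, cat)
    matched = match_maf_spectrum(reps, ref, cat, seed=3)
    assert len(matched) <= len(reps)
    final = final_filter(matched, cat)
    assert len(final) <= len(matched)
    assert sum(final.provenance["maf_histogram"]) == len(final)
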