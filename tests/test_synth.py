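import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from panelgwas import assoc, enrich, qc, synth
from panelgwas.synth.newick import parse_newick


def _config(**kw):
    base = dict(n_individuals=500, n_variants=40, seed=3)
    base.update(kw)
    return synth.SimConfig(**base)


class TestSimConfig:
    def test_rejects_too_many_causal(self):
        with pytest.raises(ValueError):
            _config(n_causal=41, effect_sizes=[0.1] * 41)

    def test_rejects_effect_size_mismatch(self):
        with pytest.raises(ValueError):
            _config(n_causal=2, effect_sizes=[0.1])

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            _config(n_individuals=0)


class TestSimulateCohort:
    def test_deterministic(self):
        a = synth.simulate_cohort(_config())
        b = synth.simulate_cohort(_config())
        np.testing.assert_array_equal(a.dosage, b.dosage)
        np.testing.assert_array_equal(a.phenotype, b.phenotype)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_different_seed_differs(self):
        a = synth.simulate_cohort(_config())
        b = synth.simulate_cohort(_config(seed=4))
        assert not np.array_equal(a.dosage, b.dosage)

    def test_empirical_af_within_binomial_tolerance(self):
        co = synth.simulate_cohort(_config(n_individuals=2000, n_variants=500, seed=5))
        af = co.variants["af"].to_numpy()
        sd = np.sqrt(af * (1 - af) / (2 * co.n_individuals))
        ok = np.abs(co.empirical_af() - af) <= 3 * sd
        assert ok.mean() >= 0.99

    def test_hardy_weinberg_screen(self):
        co = synth.simulate_cohort(_config(n_individuals=4000, n_variants=200, seed=6))
        pvals = []
        for j in range(co.n_variants):
            counts = np.bincount(co.dosage[:, j], minlength=3)
            p = counts @ np.array([0, 1, 2]) / (2 * counts.sum())
            if p in (0, 1):
                continue
            expected = counts.sum() * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            if expected.min() < 5:
                continue
            pvals.append(sps.chisquare(counts, expected, ddof=1).pvalue)
        assert np.mean(np.array(pvals) < 0.01) < 0.05

    def test_null_cohort_type_i_error(self):
        co = synth.simulate_cohort(_config(n_individuals=2000, n_variants=2000, seed=7))
        out = assoc.assoc_scan(co.dosage, co.phenotype, co.covariates, co.variants)
        frac = (out["PVAL"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(out))
        assert abs(frac - 0.05) < 3 * se

    def test_planted_causal_power(self):
        hits = 0
        for seed in range(20):
            cfg = _config(
                n_individuals=5000, n_variants=5, seed=200 + seed,
                n_causal=1, effect_sizes=[0.3], fixed_afs=[0.3] * 5,
            )
            co = synth.simulate_cohort(cfg)
            out = assoc.assoc_scan(co.dosage, co.phenotype, co.covariates, co.variants)
            causal = int(np.flatnonzero(co.variants["is_causal"])[0])
            hits += out["PVAL"][causal] < 5e-8
        assert hits >= 19

    def test_variants_sorted_within_chromosome(self):
        co = synth.simulate_cohort(_config(chrom_lengths={"chr1": 10**7, "chr2": 10**7}, n_variants=100))
        for _, grp in co.variants.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing


def _panel_specs(drop_enriched_rare=False):
    flat = synth.step_info_curve([], [0.9])
    dropout = None
    if drop_enriched_rare:
        def dropout(variants):
            return variants["planted_enriched"].to_numpy() & (variants["af"].to_numpy() < 0.2)
    return [
        synth.PanelSpec("local", flat),
        synth.PanelSpec("global", synth.step_info_curve([0.01], [0.95, 0.7]), dropout),
    ]


class TestImputedPanels:
    def test_info_one_reproduces_truth(self, small_cohort):
        spec = [synth.PanelSpec("local", synth.step_info_curve([], [1.0]))]
        panel = synth.simulate_imputed_panels(small_cohort, spec)[0]
        np.testing.assert_allclose(panel.dosage, small_cohort.dosage)

    def test_info_zero_uncorrelated(self):
        co = synth.simulate_cohort(_config(n_individuals=3000, n_variants=20, seed=9, fixed_afs=[0.3] * 20))
        spec = [synth.PanelSpec("p", synth.step_info_curve([], [0.0]))]
        panel = synth.simulate_imputed_panels(co, spec)[0]
        r = [np.corrcoef(panel.dosage[:, j], co.dosage[:, j])[0, 1] for j in range(5)]
        assert np.max(np.abs(r)) < 0.06

    def test_info_target_r2(self):
        co = synth.simulate_cohort(_config(n_individuals=2000, n_variants=30, seed=10, fixed_afs=[0.25] * 30))
        spec = [synth.PanelSpec("p", synth.step_info_curve([], [0.6]))]
        panel = synth.simulate_imputed_panels(co, spec)[0]
        r2 = np.array([np.corrcoef(panel.dosage[:, j], co.dosage[:, j])[0, 1] ** 2 for j in range(30)])
        assert abs(r2.mean() - 0.6) < 0.05

    def test_invalid_info_raises(self, small_cohort):
        bad = synth.PanelSpec("p", lambda af: np.full(af.size, 1.5))
        with pytest.raises(ValueError, match="INFO"):
            synth.simulate_imputed_panels(small_cohort, [bad])

    def test_dropout_and_meta_union(self):
        co = synth.simulate_cohort(_config(n_individuals=400, n_variants=50, seed=12))
        ref, planted = synth.simulate_reference_af(
            co.variants["af"].to_numpy(), synth.EnrichmentSpec(fraction=0.2, maf_min=0.0), seed=12
        )
        co.variants["planted_enriched"] = planted
        panels = synth.simulate_imputed_panels(co, _panel_specs(drop_enriched_rare=True))
        local, glob = panels
        assert local.present.all()
        dropped = planted & (co.variants["af"].to_numpy() < 0.2)
        assert (~glob.present[dropped]).all()
        assert np.all(np.isnan(glob.dosage[:, dropped]))
        meta = synth.make_meta_panel(panels)
        np.testing.assert_array_equal(meta.present, local.present | glob.present)
        # meta carries the higher INFO wherever both panels have the variant
        both = local.present & glob.present
        np.testing.assert_allclose(
            meta.info[both], np.maximum(local.info[both], glob.info[both])
        )

    def test_meta_tie_prefers_first_panel(self, small_cohort):
        flat = synth.step_info_curve([], [0.8])
        panels = synth.simulate_imputed_panels(
            small_cohort, [synth.PanelSpec("local", flat), synth.PanelSpec("global", flat)]
        )
        meta = synth.make_meta_panel(panels)
        np.testing.assert_allclose(meta.dosage, panels[0].dosage)


class TestReferenceAF:
    def test_fraction_zero_nothing_enriched(self):
        afs = np.linspace(0.01, 0.4, 50)
        ref, planted = synth.simulate_reference_af(afs, synth.EnrichmentSpec(fraction=0.0), seed=1)
        assert not planted.any()
        cls = enrich.classify(afs, ref)
        assert not cls["enriched"].any()

    def test_planted_fraction_recovered(self):
        rng = np.random.default_rng(0)
        afs = rng.uniform(0.001, 0.5, size=2000)
        spec = synth.EnrichmentSpec(fraction=0.05, fold_sampler=lambda r, n: np.full(n, 8.0))
        ref, planted = synth.simulate_reference_af(afs, spec, seed=2)
        cls = enrich.classify(afs, ref)
        assert planted.sum() == 100
        recovered = cls["enriched"] & planted
        assert recovered.sum() / planted.sum() > 0.99
        # drift alone almost never crosses the 4-fold threshold
        assert (cls["enriched"] & ~planted).sum() <= 2

    def test_clipping_arithmetic(self):
        spec = synth.EnrichmentSpec(fraction=1.0, fold_sampler=lambda r, n: np.full(n, 8.0), maf_min=0.0)
        ref, planted = synth.simulate_reference_af(np.array([0.5]), spec, seed=3)
        assert planted[0]
        assert ref[0] == pytest.approx(0.0625)
        assert 0.0 < ref[0] < 1.0

    def test_invalid_fold_raises(self):
        spec = synth.EnrichmentSpec(fraction=0.5, fold_sampler=lambda r, n: np.full(n, -1.0), maf_min=0.0)
        with pytest.raises(ValueError, match="fold"):
            synth.simulate_reference_af(np.array([0.3, 0.4]), spec, seed=1)

    def test_invalid_cohort_af_raises(self):
        with pytest.raises(ValueError):
            synth.simulate_reference_af(np.array([0.0, 0.3]), synth.EnrichmentSpec(), seed=1)


class TestGenealogy:
    def test_single_leaf(self):
        tree = synth.simulate_genealogy(1, seed=1)
        assert tree.n_leaves == 1
        assert tree.carriers() == {"L0"}
        assert tree.tmrca_all() == 0.0

    def test_zero_leaves_raises(self):
        with pytest.raises(ValueError):
            synth.simulate_genealogy(0, seed=1)

    def test_times_increase_rootward(self):
        tree = synth.simulate_genealogy(30, seed=2)
        for node, par in enumerate(tree.parent):
            if par >= 0:
                assert tree.time[node] < tree.time[par]

    def test_tmrca_equals_root_time(self):
        tree = synth.simulate_genealogy(16, seed=3)
        assert tree.tmrca_all() == tree.time[tree.root]

    def test_carriers_match_bruteforce_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            tree = synth.simulate_genealogy(int(rng.integers(2, 65)), seed=int(rng.integers(1 << 30)))
            oracle = set()
            for leaf in range(tree.n_leaves):
                node = leaf
                while node >= 0:
                    if node == tree.mutated_node:
                        oracle.add(tree.leaf_labels[leaf])
                        break
                    node = int(tree.parent[node])
            assert tree.carriers() == oracle

    def test_deterministic(self):
        a = synth.simulate_genealogy(20, seed=5)
        b = synth.simulate_genealogy(20, seed=5)
        np.testing.assert_array_equal(a.parent, b.parent)
        assert a.mutated_node == b.mutated_node

    def test_newick_round_trip(self):
        tree = synth.simulate_genealogy(12, seed=6)
        parsed = parse_newick(tree.to_newick())
        assert parsed.n_leaves == 12
        assert parsed.tmrca_all() == pytest.approx(tree.tmrca_all(), rel=1e-4)
        assert set(parsed.leaf_labels) == set(tree.leaf_labels)


class TestArrayBatches:
    def test_deterministic(self):
        a = synth.simulate_array_batches([100, 100], 50, 0.0, seed=1)
        b = synth.simulate_array_batches([100, 100], 50, 0.0, seed=1)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)

    def test_needs_two_arrays(self):
        with pytest.raises(ValueError):
            synth.simulate_array_batches([100], 10, 0.0, seed=1)

    def test_delta_out_of_range_raises(self):
        with pytest.raises(ValueError):
            synth.simulate_array_batches([100, 100], 200, 0.96, seed=1)

    def test_null_pvalues_uniform(self):
        data = synth.simulate_array_batches([1000, 1000], 400, 0.0, seed=2)
        out = qc.batch_lrt_scan(data.genotypes, data.pcs, data.arrays)
        assert sps.kstest(out["p"], "uniform").pvalue > 0.001

    def test_planted_shift_detected(self):
        data = synth.simulate_array_batches([2000, 2000], 100, 0.08, seed=3)
        out = qc.batch_lrt_scan(data.genotypes, data.pcs, data.arrays)
        power = out.loc[data.shifted, "reject"].mean()
        assert power > 0.9


class TestSVCallset:
    def test_dup_fraction_zero_dedup_removes_nothing(self):
        cs = synth.simulate_sv_callset(50, 0.0, seed=1)
        kept, removed = qc.dedup_svs(cs.records)
        assert len(removed) == 0 and len(kept) == 50

    def test_identical_ac_pairs_remove_shorter(self):
        cs = synth.simulate_sv_callset(40, 0.2, seed=2, ac_diff_pct=0.0)
        kept, removed = qc.dedup_svs(cs.records)
        assert len(removed) == len(cs.pairs)
        # the duplicate is constructed strictly shorter, so it is the victim
        assert set(removed.index) == set(cs.pairs["duplicate"])

    def test_five_pct_ac_difference_keeps_both(self):
        cs = synth.simulate_sv_callset(40, 0.2, seed=3, ac_diff_pct=5.0)
        kept, removed = qc.dedup_svs(cs.records)
        assert len(removed) == 0

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            synth.simulate_sv_callset(10, 1.5, seed=1)

    def test_deterministic(self):
        a = synth.simulate_sv_callset(30, 0.1, seed=9)
        b = synth.simulate_sv_callset(30, 0.1, seed=9)
        pd.testing.assert_frame_equal(a.records, b.records)
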