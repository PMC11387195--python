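"""Synthetic-data generators: determinism, truth-label consistency, LD physics."""

import json

import numpy as np
import pytest

from polyorigin.genotype_io import read_vcf
from polyorigin.ld_decay import bin_curve, half_max_distance, pairwise_r2
from polyorigin.origin_stats import SiteClass, classify_sites
from polyorigin.simulate import (
    ChloroSimConfig,
    PanelScenarioConfig,
    SiteCategory,
    WFConfig,
    simulate_chloroplast_set,
    simulate_tetraploid_panel,
    simulate_wf_population,
    write_fixture_bundle,
)
from polyorigin.mnr import scan_mnr


class TestPanelConfig:
    def test_rejects_theta_sum_above_one(self):
        with pytest.raises(ValueError):
            PanelScenarioConfig(theta_B=0.6, theta_A=0.5)

    def test_rejects_rates_outside_unit_interval(self):
        with pytest.raises(ValueError):
            PanelScenarioConfig(het_rate=1.5)


class TestTetraploidPanel:
    def test_degenerate_config_no_fixed_differences(self):
        cfg = PanelScenarioConfig(theta_B=0.0, theta_A=0.0, het_rate=0.0,
                                  n_sites=300, seed=1)
        gm, truth = simulate_tetraploid_panel(cfg)
        cats = truth.counts()
        assert cats["FIXED_DIFF"] == 0 and cats["SHARED_POLY"] == 0
        classes = classify_sites(gm, gm.samples[:30], gm.samples[30:])
        assert (classes != SiteClass.P_B).all()

    def test_fixed_diff_count_within_binomial_3sigma(self):
        cfg = PanelScenarioConfig(n_sites=2000, theta_B=0.3, seed=42)
        _, truth = simulate_tetraploid_panel(cfg)
        k = truth.counts()["FIXED_DIFF"]
        mu, sigma = 2000 * 0.3, np.sqrt(2000 * 0.3 * 0.7)
        assert abs(k - mu) <= 3 * sigma

    def test_classification_reproduces_truth_on_clean_data(self):
        cfg = PanelScenarioConfig(n_sites=400, theta_B=0.2, theta_A=0.1,
                                  het_rate=0.0, missing_rate=0.0, seed=7)
        gm, truth = simulate_tetraploid_panel(cfg)
        classes = classify_sites(gm, gm.samples[:30], gm.samples[30:],
                                 min_called_per_group=1)
        cats = truth.categories
        assert ((classes == SiteClass.P_B) ==
                (cats == SiteCategory.FIXED_DIFF)).all()
        assert ((classes == SiteClass.P_A) ==
                (cats == SiteCategory.SHARED_POLY)).all()

    def test_fixed_diff_frequencies_exactly_zero_and_one(self):
        cfg = PanelScenarioConfig(n_sites=300, theta_B=0.5, seed=3)
        gm, truth = simulate_tetraploid_panel(cfg)
        fixed = truth.categories == SiteCategory.FIXED_DIFF
        assert (gm.dosage[:30][:, fixed] == 0).all()
        assert (gm.dosage[30:][:, fixed] == 2).all()

    def test_label_counts_sum_to_n_sites(self):
        cfg = PanelScenarioConfig(n_sites=500, seed=9, het_rate=0.01,
                                  missing_rate=0.05)
        gm, truth = simulate_tetraploid_panel(cfg)
        assert sum(truth.counts().values()) == gm.n_sites

    def test_deterministic_given_seed(self):
        cfg = PanelScenarioConfig(n_sites=200, seed=5, het_rate=0.02,
                                  missing_rate=0.03)
        a, ta = simulate_tetraploid_panel(cfg)
        b, tb = simulate_tetraploid_panel(cfg)
        assert np.array_equal(a.dosage, b.dosage)
        assert np.array_equal(ta.categories, tb.categories)
        assert a.pos.tolist() == b.pos.tolist()


class TestChloroplastSet:
    def test_zero_length_branches_identical_sequences(self):
        cfg = ChloroSimConfig(genome_length=2000, mnr_seed_count=10, seed=1,
                              tree_newick="((x:0,y:0):0,z:0):0;")
        seqs, _, log = simulate_chloroplast_set(cfg)
        assert len(set(seqs.values())) == 1
        assert log == []

    def test_elongated_branches_recover_cherries(self):
        from polyorigin.chloro import Alignment, nj_tree, pairwise_distance

        cfg = ChloroSimConfig(
            genome_length=3000, mnr_seed_count=0, indel_rate=0.0, seed=4,
            tree_newick="(a:0.001,b:0.001,(c:0.08,d:0.08):0.04):0;")
        seqs, _, _ = simulate_chloroplast_set(cfg)
        a = Alignment.from_sequences(sorted(seqs.items()))
        tree = nj_tree(pairwise_distance(a), a.names)
        assert frozenset(["c", "d"]) in tree.bipartitions() or \
            frozenset(["a", "b"]) in tree.bipartitions()

    def test_seeded_tracts_recoverable_in_leaves(self):
        cfg = ChloroSimConfig(genome_length=5000, mnr_seed_count=40,
                              indel_rate=0.2, seed=8,
                              tree_newick="(p:0.01,q:0.01):0;")
        seqs, _, _ = simulate_chloroplast_set(cfg)
        for seq in seqs.values():
            assert scan_mnr(seq).sum() >= 40 * 0.8

    def test_gc_content_near_target(self):
        cfg = ChloroSimConfig(genome_length=20_000, mnr_seed_count=0,
                              gc_content=0.36, seed=2,
                              tree_newick="(u:0,v:0):0;")
        seqs, _, _ = simulate_chloroplast_set(cfg)
        seq = seqs["u"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.36) < 0.02

    def test_event_log_nonempty_under_mutation(self):
        cfg = ChloroSimConfig(genome_length=2000, mnr_seed_count=5, seed=3,
                              tree_newick="(m:0.05,n:0.05):0;")
        _, _, log = simulate_chloroplast_set(cfg)
        assert len(log) > 0
        assert {e.kind for e in log} <= {"SUB", "INS", "DEL"}


class TestWrightFisher:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            WFConfig(sample_size=50, pop_size=10)
        with pytest.raises(ValueError):
            WFConfig(selfing_rate=1.5)

    def test_complete_linkage_without_recombination(self):
        # two-haplotype population: derived alleles on one background only
        from conftest import make_matrix

        hapA = [2, 2, 2]
        hapRef = [0, 0, 0]
        d = np.array([hapA] * 4 + [hapRef] * 4, dtype=np.int8)
        gm = make_matrix(d, pos=[10, 500, 900])
        pairs = list(pairwise_r2(gm, max_dist=1000))
        assert len(pairs) == 3
        assert all(r == pytest.approx(1.0) for _, r in pairs)

    def test_deterministic_and_segregating_only(self):
        cfg = WFConfig(pop_size=40, region_length=20_000, generations=60,
                       sample_size=20, mutation_per_bp=2e-5, seed=12)
        a = simulate_wf_population(cfg)
        b = simulate_wf_population(cfg)
        assert np.array_equal(a.dosage, b.dosage)
        totals = a.dosage.sum(axis=0)
        assert ((totals > 0) & (totals < 2 * a.n_samples)).all()

    def test_ld_decays_with_distance_pooled_seeds(self):
        pairs = []
        for seed in range(1, 7):
            gm = simulate_wf_population(WFConfig(
                pop_size=60, region_length=30_000, recomb_per_bp=2e-5,
                selfing_rate=0.3, mutation_per_bp=3e-5, generations=150,
                sample_size=30, seed=seed))
            pairs.extend(pairwise_r2(gm, max_dist=30_000))
        curve = bin_curve(pairs, bin_bp=500, max_dist=30_000)
        filled = curve.mean_r2[curve.n_pairs > 0]
        third = len(filled) // 3
        assert filled[:third].mean() > filled[-third:].mean()

    def test_selfing_and_recombination_shift_half_max(self):
        """Pooled over seeds: more recombination shortens the half-max
        distance; more selfing lengthens it."""

        def pooled_half_max(selfing, recomb):
            pairs = []
            for seed in range(1, 7):
                gm = simulate_wf_population(WFConfig(
                    pop_size=60, region_length=30_000, recomb_per_bp=recomb,
                    selfing_rate=selfing, mutation_per_bp=3e-5,
                    generations=150, sample_size=30, seed=seed))
                pairs.extend(pairwise_r2(gm, max_dist=30_000))
            res = half_max_distance(
                bin_curve(pairs, bin_bp=500, max_dist=30_000))
            return np.inf if res.half_max_bp is None else res.half_max_bp

        low_rec = pooled_half_max(0.3, 2e-6)
        high_rec = pooled_half_max(0.3, 2e-5)
        high_selfing = pooled_half_max(0.9, 2e-5)
        assert high_rec < low_rec
        assert high_selfing > high_rec


class TestFixtureBundle:
    def test_round_trip_and_manifest(self, tmp_path):
        cfg = PanelScenarioConfig(n_sites=60, seed=2, missing_rate=0.04)
        gm, truth = simulate_tetraploid_panel(cfg)
        manifest = write_fixture_bundle({"panel": (gm, truth, cfg)}, tmp_path)
        back, _ = read_vcf(tmp_path / "panel.vcf")
        assert np.array_equal(back.dosage, gm.dosage)
        assert manifest["configs"]["panel"]["seed"] == 2
        stored = json.loads((tmp_path / "manifest.json").read_text())
        assert stored["configs"]["panel"]["n_sites"] == 60

    def test_rerun_same_seed_byte_identical_vcf(self, tmp_path):
        cfg = PanelScenarioConfig(n_sites=40, seed=6, het_rate=0.02)
        for sub in ("a", "b"):
            gm, truth = simulate_tetraploid_panel(cfg)
            write_fixture_bundle({"panel": (gm, truth, cfg)}, tmp_path / sub)
        assert (tmp_path / "a" / "panel.vcf").read_bytes() \
            == (tmp_path / "b" / "panel.vcf").read_bytes()

    def test_empty_matrix_valid_vcf(self, tmp_path):
        from conftest import make_matrix
        from polyorigin.genotype_io import write_vcf

        gm = make_matrix(np.zeros((3, 0)))
        write_vcf(gm, tmp_path / "e.vcf")
        back, _ = read_vcf(tmp_path / "e.vcf")
        assert back.n_sites == 0 and back.samples == gm.samples
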