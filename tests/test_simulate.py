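"""Generator contracts: determinism, HWE, sparse effects, round trips, planted recovery."""

import numpy as np
import pandas as pd
import pytest

import rfuwas as rw


class TestConfig:
    def test_invalid_fields_rejected(self):
        with pytest.raises(ValueError):
            rw.SimulationConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            rw.SimulationConfig(baseline_prevalence=1.5)
        with pytest.raises(ValueError):
            rw.SimulationConfig(repertoire_size_range=(100, 50))
        with pytest.raises(ValueError):
            rw.SimulationConfig(n_individuals=0)

    def test_named_substreams_are_independent(self):
        cfg = rw.SimulationConfig(seed=5)
        a = cfg.rng("genotypes").normal(size=4)
        b = cfg.rng("effects").normal(size=4)
        assert not np.allclose(a, b)
        np.testing.assert_array_equal(a, cfg.rng("genotypes").normal(size=4))


class TestGenotypes:
    def test_same_seed_is_bit_identical(self, small_cfg):
        g1 = rw.simulate_genotypes(small_cfg)
        g2 = rw.simulate_genotypes(small_cfg)
        pd.testing.assert_frame_equal(g1.dosages, g2.dosages)
        pd.testing.assert_frame_equal(g1.variants, g2.variants)

    def test_heterozygote_fraction_at_half_maf(self):
        cfg = rw.SimulationConfig(n_individuals=10_000, n_variants_per_locus={"TRB": 1},
                                  maf_range=(0.5, 0.5), seed=1)
        g = rw.simulate_genotypes(cfg)
        het = (g.dosages.to_numpy() == 1).mean()
        sd = np.sqrt(0.5 * 0.5 / 10_000)
        assert abs(het - 0.5) < 3 * sd

    def test_empirical_maf_within_three_sds(self):
        cfg = rw.SimulationConfig(n_individuals=5000, n_variants_per_locus={"TRB": 1},
                                  maf_range=(0.2, 0.2), seed=2)
        g = rw.simulate_genotypes(cfg)
        p_hat = g.dosages.to_numpy().mean() / 2
        sd = np.sqrt(0.2 * 0.8 / (2 * 5000))
        assert abs(p_hat - 0.2) < 3 * sd

    def test_variants_tagged_with_locus_and_positions(self, genotypes):
        assert set(genotypes.variants["locus"]) == {"TRB", "HLA"}
        assert (genotypes.variants["pos"] >= 1).all()
        trb = genotypes.variants.query("locus == 'TRB'")
        assert trb["chrom"].eq("7").all()

    def test_simulated_genotypes_pass_hwe_filter(self, genotypes):
        phwe = genotypes.computed_phwe()
        assert (phwe > 1e-6).mean() > 0.95


class TestEffects:
    def test_zero_causal_gives_all_zero_effects(self, genotypes):
        cfg = rw.SimulationConfig(n_causal_variants_per_rfu=0, seed=3)
        eff = rw.simulate_rfu_effects(cfg, genotypes)
        assert not eff.effects.to_numpy().any()

    def test_exact_causal_cardinality(self, small_cfg, effects):
        nz = (effects.effects.to_numpy() != 0).sum(axis=0)
        assert (nz == small_cfg.n_causal_variants_per_rfu).all()
        for rfu, ids in effects.causal.items():
            assert len(ids) == small_cfg.n_causal_variants_per_rfu

    def test_effect_sd_matches_configuration(self):
        cfg = rw.SimulationConfig(n_rfus=1000, n_variants_per_locus={"TRB": 100},
                                  n_causal_variants_per_rfu=3, effect_size_sd=0.5, seed=4)
        eff = rw.simulate_rfu_effects(cfg)
        nonzeros = eff.effects.to_numpy()[eff.effects.to_numpy() != 0]
        assert abs(nonzeros.std() - 0.5) / 0.5 < 0.1

    def test_too_many_causal_variants_rejected(self):
        cfg = rw.SimulationConfig(n_variants_per_locus={"TRB": 2}, n_causal_variants_per_rfu=5)
        with pytest.raises(ValueError, match="exceeds"):
            rw.simulate_rfu_effects(cfg)


class TestRepertoires:
    def test_round_trip_assignment_recovers_intended_rfu(self, small_cfg, centroids_templates):
        """>= 95% of generated clones re-assign to the RFU that emitted them."""
        centroids, templates = centroids_templates
        assigner = rw.RFUAssigner().fit(centroids)
        rng = small_cfg.rng("roundtrip_check")
        ok = total = 0
        for r in range(centroids.n_rfus):
            from rfuwas.simulate import _clones_for_rfu
            seqs = _clones_for_rfu(templates[r], r, 50, rng, assigner)
            idx = assigner.assign_indices(seqs)
            ok += int((idx == r).sum())
            total += len(seqs)
        assert ok / total >= 0.95

    def test_zero_effects_zero_noise_share_expected_proportions(self):
        cfg = rw.SimulationConfig(
            n_individuals=30, n_rfus=8, n_causal_variants_per_rfu=0,
            latent_noise_sd=0.0, repertoire_size_range=(2000, 2000),
            n_variants_per_locus={"TRB": 10, "HLA": 5}, seed=6,
        )
        g = rw.simulate_genotypes(cfg)
        eff = rw.simulate_rfu_effects(cfg, g)
        centroids, templates = rw.simulate_centroids(cfg)
        reps = rw.simulate_repertoires(g, eff, centroids, cfg, templates)
        from scipy.special import softmax
        base = cfg.rng("base_abundance").normal(0.0, 1.0, size=cfg.n_rfus)
        expected = softmax(base)
        counts = rw.RFUAssigner().fit(centroids).transform(reps).data.to_numpy()
        props = counts / counts.sum(axis=1, keepdims=True)
        # every individual's proportions near softmax(base) within multinomial error
        tol = 4 * np.sqrt(expected * (1 - expected) / 2000) + 0.01
        assert (np.abs(props - expected) < tol).all()

    def test_large_effect_variant_orders_dosage_groups(self):
        cfg = rw.SimulationConfig(
            n_individuals=150, n_rfus=6, n_causal_variants_per_rfu=0,
            latent_noise_sd=0.05, repertoire_size_range=(800, 1200),
            n_variants_per_locus={"TRB": 10, "HLA": 5}, maf_range=(0.4, 0.5), seed=7,
        )
        g = rw.simulate_genotypes(cfg)
        eff = rw.simulate_rfu_effects(cfg, g)
        eff.effects.loc["TRB_v0", "RFU5"] = 1.0  # plant one strong effect
        centroids, templates = rw.simulate_centroids(cfg)
        reps = rw.simulate_repertoires(g, eff, centroids, cfg, templates)
        counts = rw.RFUAssigner().fit(centroids).transform(reps)
        from scipy.stats import rankdata
        ranked = rankdata(counts.data["RFU5"] / counts.data.sum(axis=1))
        dosage = g.dosages["TRB_v0"].to_numpy()
        means = [ranked[dosage == d].mean() for d in (0, 1, 2)]
        assert means[0] < means[1] < means[2]

    def test_determinism(self, small_cfg, genotypes, effects, centroids_templates, repertoires):
        centroids, templates = centroids_templates
        again = rw.simulate_repertoires(genotypes, effects, centroids, small_cfg, templates)
        assert [r.clones for r in again] == [r.clones for r in repertoires]


class TestPhenotypes:
    def gvals(self, cfg):
        g = rw.simulate_genotypes(cfg)
        return rw.latent_genetic_values(g, rw.simulate_rfu_effects(cfg, g))

    def test_null_disease_effect_matches_baseline_prevalence(self):
        cfg = rw.SimulationConfig(n_individuals=20_000, disease_effect=0.0,
                                  baseline_prevalence=0.05, seed=8,
                                  n_variants_per_locus={"TRB": 20, "HLA": 10}, n_rfus=5)
        pheno = rw.simulate_phenotypes(self.gvals(cfg), cfg, sex_effect=0.0, age_effect=0.0)
        frac = pheno.binary["disease_RFU0"].mean()
        sd = np.sqrt(0.05 * 0.95 / 20_000)
        assert abs(frac - 0.05) < 3 * sd

    def test_unit_hazard_ratio_is_null_for_cox(self):
        cfg = rw.SimulationConfig(n_individuals=1200, hazard_ratio=1.0, seed=9,
                                  n_variants_per_locus={"TRB": 20, "HLA": 10}, n_rfus=5)
        gv = self.gvals(cfg)
        pheno = rw.simulate_phenotypes(gv, cfg)
        out = rw.cox_scan(gv[["RFU0"]], pheno, covariates=pheno.covariates[["sex"]],
                          min_events=50)
        assert abs(out["log_hr"].iloc[0]) < 0.1
        assert out["p"].iloc[0] > 0.001

    def test_censoring_rate_near_configured_value(self):
        cfg = rw.SimulationConfig(n_individuals=5000, hazard_ratio=1.0,
                                  censoring_rate=0.2, seed=10,
                                  n_variants_per_locus={"TRB": 20, "HLA": 10}, n_rfus=5)
        pheno = rw.simulate_phenotypes(self.gvals(cfg), cfg)
        censored = 1 - pheno.survival["survival_RFU0"]["event"].mean()
        assert abs(censored - 0.2) < 0.03

    def test_bad_prevalence_rejected(self):
        with pytest.raises(ValueError):
            rw.SimulationConfig(baseline_prevalence=0.0)


class TestSortedSubsetsAndAntigenDB:
    def test_planted_subset_enrichment_recovered_end_to_end(self, small_cfg, centroids_templates):
        centroids, templates = centroids_templates
        profiles = {s: np.ones(centroids.n_rfus) for s in ("TN", "CM", "Treg", "Tscm")}
        profiles["TN"] = profiles["TN"].copy()
        profiles["TN"][7] = 8.0
        reps, truth = rw.simulate_sorted_subsets(centroids, templates, profiles, small_cfg,
                                                 n_individuals=15, repertoire_size=1500)
        assert truth == {centroids.rfu_ids[7]: "TN"}
        assigner = rw.RFUAssigner().fit(centroids)
        mats = {s: assigner.transform(r) for s, r in reps.items()}
        out = rw.annotate_subsets(mats, n_rfus_tested=centroids.n_rfus)
        assert out[7].label == "TN"

    def test_uniform_profiles_annotate_almost_nothing(self, small_cfg, centroids_templates):
        centroids, templates = centroids_templates
        profiles = {s: np.ones(centroids.n_rfus) for s in ("TN", "CM", "Treg", "Tscm")}
        reps, truth = rw.simulate_sorted_subsets(centroids, templates, profiles, small_cfg,
                                                 n_individuals=12, repertoire_size=1000)
        assert truth == {}
        assigner = rw.RFUAssigner().fit(centroids)
        mats = {s: assigner.transform(r) for s, r in reps.items()}
        out = rw.annotate_subsets(mats, n_rfus_tested=centroids.n_rfus)
        labelled = sum(a.label != "unannotated" for a in out)
        assert labelled / len(out) <= 0.05

    def test_empty_profile_rejected(self, small_cfg, centroids_templates):
        centroids, templates = centroids_templates
        with pytest.raises(ValueError, match="empty"):
            rw.simulate_sorted_subsets(centroids, templates, {}, small_cfg)

    def test_antigen_db_empty_for_no_specific_rfus(self, small_cfg, centroids_templates):
        centroids, templates = centroids_templates
        db = rw.simulate_antigen_db(centroids, templates, set(), small_cfg)
        assert len(db.table) == 0

    def test_antigen_db_sequences_map_back(self, small_cfg, centroids_templates):
        centroids, templates = centroids_templates
        db = rw.simulate_antigen_db(centroids, templates, {"RFU2", "RFU8"}, small_cfg)
        mapping = rw.map_antigen_specificity(db, centroids)
        assert set(mapping) == {"RFU2", "RFU8"}

    def test_multiple_antigens_per_sequence_inherited(self, small_cfg, centroids_templates):
        centroids, templates = centroids_templates
        db = rw.simulate_antigen_db(
            centroids, templates, {"RFU4"}, small_cfg,
            antigens={"RFU4": ["gliadin", "GAD65"]},
        )
        mapping = rw.map_antigen_specificity(db, centroids)
        assert mapping["RFU4"] == {"gliadin", "GAD65"}
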