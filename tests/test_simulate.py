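import numpy as np
import pandas as pd
import pytest

import spikeqc as sq
from spikeqc.quality import impute_info, quality_table
from spikeqc.simulate import (
    DeletionConfig,
    DiseaseLocus,
    SimConfig,
    apply_deletion_mask,
    make_truth,
    sample_case_control,
    simulate_cohort,
    simulate_haplotype_pool,
    surrogate_impute,
)
from spikeqc.spikes import aggregate, annotate_spikes


def tiny_config(**kw):
    base = dict(
        n_snps=120,
        n_cases=80,
        n_controls=80,
        panel_size=60,
        spacing_bp=25000,
        disease_loci=(DiseaseLocus(None, 3.0, "additive"),),
        deletion=DeletionConfig("scaffold", 0.2),
        ld_decay=0.05,
        seed=1,
    )
    base.update(kw)
    return SimConfig(**base)


class TestHaplotypePool:
    def test_determinism(self):
        cfg = tiny_config()
        a = simulate_haplotype_pool(cfg)
        b = simulate_haplotype_pool(cfg)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert a.disease_loci == b.disease_loci

    def test_zero_decay_gives_constant_haplotypes(self):
        pool = simulate_haplotype_pool(tiny_config(ld_decay=0.0))
        assert (pool.haplotypes == pool.haplotypes[:, [0]]).all()

    def test_full_decay_gives_independent_adjacent_snps(self):
        # 10,000 haplotypes: adjacent-column correlation should vanish
        cfg = tiny_config(ld_decay=1.0, panel_size=4840, n_snps=30)
        pool = simulate_haplotype_pool(cfg)
        H = pool.haplotypes.astype(float)
        assert H.shape[0] == 10_000
        for j in range(5):
            r = np.corrcoef(H[:, j], H[:, j + 1])[0, 1]
            assert abs(r) < 0.05

    def test_disease_locus_maf_in_range(self):
        pool = simulate_haplotype_pool(tiny_config())
        freq = pool.allele_freq()
        for d in pool.disease_loci:
            maf = min(freq[d.index], 1 - freq[d.index])
            assert 0.05 <= maf <= 0.4


class TestCaseControl:
    def test_null_model_gives_equal_frequencies(self):
        cfg = tiny_config(
            disease_loci=(DiseaseLocus(None, 1.0, "additive"),), n_cases=300,
            n_controls=300, panel_size=200, seed=5,
        )
        pool = simulate_haplotype_pool(cfg)
        study, _ = sample_case_control(pool, cfg)
        j = pool.disease_loci[0].index
        fc = study.cases.dosage()[:, j].mean() / 2
        ft = study.controls.dosage()[:, j].mean() / 2
        se = np.sqrt(fc * (1 - fc) / (2 * 300) + ft * (1 - ft) / (2 * 300))
        assert abs(fc - ft) < 3 * se

    def test_dominant_coding_equates_het_and_hom(self):
        d = DiseaseLocus(0, 3.0, "dominant")
        g = np.array([0, 1, 2])
        code = d.risk_code(g)
        assert code[1] == code[2] != code[0]

    def test_power_at_reference_conditions(self):
        """Odds ratio 3, additive, MAF near 0.3, 1000 cases and controls:
        the gold-standard association at the disease locus must clear 5e-8
        in at least 95% of seeded replicates."""
        hits = 0
        n_rep = 20
        for s in range(n_rep):
            cfg = SimConfig(
                n_snps=24,
                n_cases=1000,
                n_controls=1000,
                panel_size=2,
                spacing_bp=25000,
                maf_range=(0.25, 0.35),
                disease_loci=(DiseaseLocus(None, 3.0, "additive"),),
                ld_decay=0.3,
                seed=1000 + s,
            )
            pool = simulate_haplotype_pool(cfg)
            study, _ = sample_case_control(pool, cfg)
            truth = make_truth(study)
            j = pool.disease_loci[0].index
            if truth.table["p_gold"].iloc[j] < 5e-8:
                hits += 1
        assert hits >= 0.95 * n_rep

    def test_complete_data_is_degenerate(self):
        cfg = tiny_config()
        study, panels = sample_case_control(simulate_haplotype_pool(cfg), cfg)
        probs = study.combined_gp().probs
        assert set(np.unique(probs)) <= {0.0, 1.0}
        assert panels["cases"].shape == panels["controls"].shape

    def test_unattainable_prevalence_raises(self, monkeypatch):
        import spikeqc.simulate as sim_mod

        monkeypatch.setattr(sim_mod, "MAX_SAMPLING_BATCHES", 1)
        cfg = tiny_config(n_cases=5000, prevalence=0.001)
        pool = simulate_haplotype_pool(cfg)
        with pytest.raises(RuntimeError, match="prevalence"):
            sample_case_control(pool, cfg)


class TestDeletionMask:
    def test_uniform_deletion_binomial_bounds(self):
        cfg = tiny_config(
            n_snps=1000, deletion=DeletionConfig("uniform", 0.8), seed=3,
            n_cases=20, n_controls=20, panel_size=20,
        )
        pool = simulate_haplotype_pool(cfg)
        study, _ = sample_case_control(pool, cfg)
        masked = apply_deletion_mask(study, cfg)
        n_typed = int(masked.variants.typed.sum())
        assert 150 <= n_typed <= 250
        # deleted entries are NaN but stay in the variant table
        assert masked.cases.missing_mask().sum() > 0
        assert len(masked.variants) == 1000

    def test_full_scaffold_deletes_nothing(self):
        cfg = tiny_config(deletion=DeletionConfig("scaffold", 1.0))
        pool = simulate_haplotype_pool(cfg)
        study, _ = sample_case_control(pool, cfg)
        masked = apply_deletion_mask(study, cfg)
        assert masked.variants.typed.all()
        assert not masked.cases.missing_mask().any()

    def test_disease_loci_get_no_protection(self):
        cfg = tiny_config(
            n_snps=400, deletion=DeletionConfig("uniform", 0.8), seed=2,
            n_cases=20, n_controls=20, panel_size=20,
        )
        pool = simulate_haplotype_pool(cfg)
        study, _ = sample_case_control(pool, cfg)
        masked = apply_deletion_mask(study, cfg)
        # with 80% deletion the locus is (almost always) untyped; assert the
        # mask simply ignores locus positions
        j = pool.disease_loci[0].index
        assert masked.variants.typed[j] in (True, False)
        assert abs(masked.variants.typed.mean() - 0.2) < 0.08


class TestSurrogateImpute:
    def test_perfect_ld_recovers_truth(self):
        cfg = tiny_config(ld_decay=0.0, deletion=DeletionConfig("scaffold", 0.2))
        sim = simulate_cohort(cfg)
        np.testing.assert_allclose(
            sim["imputed"].combined_gp().probs,
            sim["complete"].combined_gp().probs,
            atol=0.02,
        )
        np.testing.assert_array_equal(
            sim["imputed"].combined_gp().best_guess(),
            sim["complete"].combined_gp().best_guess(),
        )

    def test_single_reference_pair_gives_degenerate_triplets(self):
        cfg = tiny_config()
        pool = simulate_haplotype_pool(cfg)
        study, panels = sample_case_control(pool, cfg)
        masked = apply_deletion_mask(study, cfg)
        tiny_panels = {g: h[:2] for g, h in panels.items()}
        imputed = surrogate_impute(masked, tiny_panels, config=cfg)
        probs = imputed.combined_gp().probs
        assert set(np.unique(np.round(probs, 9))) <= {0.0, 1.0}

    def test_typed_snps_are_conserved(self):
        sim = simulate_cohort(tiny_config())
        typed = sim["imputed"].variants.typed
        np.testing.assert_array_equal(
            sim["imputed"].cases.probs[:, typed],
            sim["complete"].cases.probs[:, typed],
        )

    def test_standard_scenario_produces_midrange_snps(self, small_sim):
        qt = quality_table(small_sim["imputed"])
        imputed = ~small_sim["imputed"].variants.typed
        info = qt["impute_info"][imputed]
        assert ((info > 0.3) & (info < 0.8)).any()

    def test_cohort_determinism(self):
        cfg = tiny_config(seed=9)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        np.testing.assert_array_equal(
            a["imputed"].combined_gp().probs, b["imputed"].combined_gp().probs
        )
        pd.testing.assert_frame_equal(a["truth"].table, b["truth"].table)

    def test_background_frequency_conservation(self):
        cfg = tiny_config(
            disease_loci=(DiseaseLocus(None, 1.0, "additive"),), seed=8,
            n_cases=200, n_controls=200, panel_size=100,
        )
        pool = simulate_haplotype_pool(cfg)
        study, _ = sample_case_control(pool, cfg)
        pool_freq = pool.allele_freq()
        cohort_freq = study.combined_gp().dosage().mean(axis=0) / 2
        # two sampling stages: cohort haplotypes drawn from the study half,
        # study half drawn from the pool
        n_cohort = 2 * 400
        n_half = pool.n_haplotypes // 2
        var = np.maximum(pool_freq * (1 - pool_freq), 1e-4) * (
            1 / n_cohort + 1 / n_half
        )
        frac_within = (np.abs(cohort_freq - pool_freq) < 3 * np.sqrt(var)).mean()
        assert frac_within > 0.95

    def test_denser_scaffold_does_not_reduce_quality(self):
        medians = []
        for frac in (0.08, 0.18, 0.30):
            vals = []
            for s in range(7):
                cfg = tiny_config(
                    n_snps=200, deletion=DeletionConfig("scaffold", frac),
                    seed=100 + s, ld_decay=0.04,
                )
                sim = simulate_cohort(cfg)
                qt = quality_table(sim["imputed"])
                imp = ~sim["imputed"].variants.typed
                vals.extend(qt["impute_info"][imp].tolist())
            medians.append(np.median(vals))
        assert medians[0] <= medians[1] + 0.02
        assert medians[1] <= medians[2] + 0.02


class TestTruthLabels:
    def test_no_gold_significance_makes_all_imputed_hits_false(self):
        table = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [1, 2], "p": [0.5, 0.6],
             "converged": True}
        )
        variants = sq.VariantTable.from_arrays("1", [1, 2])
        probs = np.full((4, 2, 3), 1 / 3)
        study = sq.CohortStudy(
            cases=sq.GPMatrix(probs[:2]), controls=sq.GPMatrix(probs[2:]),
            variants=variants,
        )
        truth = make_truth(study, gold_assoc=table.assign(p=[0.5, 0.6]))
        assert not truth.table["sig_gold"].any()
        # an imputed-data hit at any of these SNPs is therefore false
        assert not truth.snp_truth().loc[("1", 1)]

    def test_spike_with_one_true_member_is_true(self):
        gold = pd.DataFrame(
            {"chrom": ["1"] * 4, "pos": [10, 20, 30, 40],
             "p": [1e-9, 0.5, 0.5, 0.5]}
        )
        variants = sq.VariantTable.from_arrays("1", [10, 20, 30, 40])
        probs = np.full((2, 4, 3), 1 / 3)
        study = sq.CohortStudy(
            cases=sq.GPMatrix(probs[:1]), controls=sq.GPMatrix(probs[1:]),
            variants=variants,
        )
        truth = make_truth(study, gold_assoc=gold)
        (spike,) = aggregate({"1": [10, 20, 30, 40]})
        assert truth.spike_is_true(spike)

    def test_empty_significant_set_gives_no_spikes(self):
        spikes = aggregate({"1": []})
        assert spikes == []
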