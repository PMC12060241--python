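import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

import spikeqc as sq
from spikeqc.quality import MEASURES, quality_table

from conftest import degenerate_gp, hwe_genotypes


def column(*triplets):
    return np.array(triplets, dtype=float)


class TestImputeInfo:
    def test_symmetric_uncertain_triplets_score_zero(self):
        # e=1, f=1.5, theta=0.5: 1 - 1.0/1.0
        assert sq.impute_info(column((0.25, 0.5, 0.25), (0.25, 0.5, 0.25))) == 0.0

    def test_degenerate_polymorphic_scores_one(self):
        gp = degenerate_gp(np.array([0, 1, 2, 1])[None, :])[0]
        assert sq.impute_info(gp) == 1.0

    def test_monomorphic_convention_is_one(self):
        assert sq.impute_info(column((1, 0, 0), (1, 0, 0))) == 1.0


class TestMachR2:
    def test_hard_genotypes_score_one(self):
        gp = degenerate_gp(np.array([0, 1, 1, 2])[None, :])[0]
        assert sq.mach_r2(gp) == pytest.approx(1.0)

    def test_constant_dosage_scores_zero(self):
        assert sq.mach_r2(column((0, 1, 0), (0, 1, 0))) == 0.0

    def test_can_exceed_one(self):
        gp = degenerate_gp(np.array([0, 2])[None, :])[0]
        assert sq.mach_r2(gp) == pytest.approx(2.0)


class TestBeagleDr2:
    def test_degenerate_polymorphic_is_one(self):
        gp = degenerate_gp(np.array([0, 1, 2, 0])[None, :])[0]
        assert sq.beagle_dr2(gp) == pytest.approx(1.0)

    def test_constant_best_guess_is_zero(self):
        gp = column((0.6, 0.4, 0.0), (0.6, 0.0, 0.4), (0.6, 0.2, 0.2))
        assert sq.beagle_dr2(gp) == 0.0

    def test_matches_direct_correlation(self):
        rng = np.random.default_rng(0)
        gp = rng.dirichlet([1, 1, 1], size=40)
        e = gp[:, 1] + 2 * gp[:, 2]
        g = gp.argmax(axis=1)
        expected = np.corrcoef(e, g)[0, 1] ** 2
        assert sq.beagle_dr2(gp) == pytest.approx(expected, abs=1e-10)
        assert 0 < sq.beagle_dr2(gp) < 1

    def test_singleton_column_rejected(self):
        with pytest.raises(ValueError):
            sq.beagle_dr2(column((0.2, 0.3, 0.5)))


class TestIamScores:
    def test_uniform_triplets_give_chance_zero_combined_one(self):
        chance, hwe, combined = sq.iam_scores(np.full((5, 3), 1 / 3))
        assert chance == 0.0 and hwe == 0.0 and combined == 1.0

    def test_hwe_triplets_give_combined_one_minus_chance(self):
        # (0.25, 0.5, 0.25) is exactly HWE for theta=0.5; TV to uniform is
        # 1/6, normalised by 2/3 -> 0.25
        chance, hwe, combined = sq.iam_scores(np.tile([0.25, 0.5, 0.25], (4, 1)))
        assert hwe == pytest.approx(0.0)
        assert chance == pytest.approx(0.25)
        assert combined == pytest.approx(0.75)

    @given(
        st.lists(
            st.tuples(*(st.floats(0.01, 1.0),) * 3), min_size=1, max_size=20
        )
    )
    def test_ordering_and_range(self, raw):
        gp = np.array(raw)
        gp = gp / gp.sum(axis=1, keepdims=True)
        chance, hwe, combined = sq.iam_scores(gp)
        assert hwe <= chance + 1e-12
        assert 0.0 <= combined <= 1.0 + 1e-12
        assert combined == pytest.approx(hwe - chance + 1.0)


class TestHiq:
    def test_monomorphic_is_zero(self):
        assert sq.hiq(np.tile([1.0, 0.0, 0.0], (6, 1))) == pytest.approx(0.0)

    def test_uniform_mean_is_one(self):
        assert sq.hiq(np.full((6, 3), 1 / 3)) == pytest.approx(1.0)

    def test_half_and_half_homozygotes(self):
        gp = np.vstack([np.tile([1, 0, 0], (3, 1)), np.tile([0, 0, 1], (3, 1))])
        assert sq.hiq(gp.astype(float)) == pytest.approx(0.75)


def make_study(case_probs, ctrl_probs):
    m = case_probs.shape[1]
    variants = sq.VariantTable.from_arrays("1", np.arange(1, m + 1) * 100,
                                           typed=np.zeros(m, bool))
    return sq.CohortStudy(
        cases=sq.GPMatrix(case_probs), controls=sq.GPMatrix(ctrl_probs),
        variants=variants,
    )


class TestQualityTable:
    def test_identical_groups_equal_combined_under_all_rules(self):
        rng = np.random.default_rng(1)
        probs = rng.dirichlet([1, 1, 1], size=(10, 3))
        for rule in ("min", "mean", "max"):
            qt = quality_table(make_study(probs, probs.copy()), group_combine=rule)
            for m in MEASURES:
                np.testing.assert_allclose(qt[m], qt[f"{m}_cases"])

    def test_group_combination_arithmetic(self):
        rng = np.random.default_rng(2)
        ca = rng.dirichlet([2, 2, 2], size=(30, 5))
        co = rng.dirichlet([0.7, 0.7, 0.7], size=(30, 5))
        study = make_study(ca, co)
        tables = {r: quality_table(study, group_combine=r) for r in ("min", "mean", "max")}
        for m in MEASURES:
            a = tables["min"][f"{m}_cases"].to_numpy()
            b = tables["min"][f"{m}_controls"].to_numpy()
            np.testing.assert_allclose(tables["min"][m], np.minimum(a, b))
            np.testing.assert_allclose(tables["max"][m], np.maximum(a, b))
            np.testing.assert_allclose(tables["mean"][m], (a + b) / 2)
            assert (tables["min"][m] <= tables["mean"][m] + 1e-12).all()
            assert (tables["mean"][m] <= tables["max"][m] + 1e-12).all()

    def test_min_combination_is_what_the_filter_reads(self):
        hits = sq.load_psycourse_hits()
        row = hits[(hits.chrom == "6") & (hits.pos == 130733300)].iloc[0]
        # the per-group minimum of the recalculated quality (0.238) is far
        # below the jointly-computed initial value (0.659); the filter must
        # consume the per-group minimum column
        assert row.quality_initial == pytest.approx(0.659)
        assert row.quality_min == pytest.approx(0.238)
        assert row.quality_min < 0.3 < row.quality_initial

    def test_order_invariance_and_ranges(self, small_sim):
        study = small_sim["imputed"]
        qt = quality_table(study)
        rng = np.random.default_rng(5)
        perm_cases = sq.GPMatrix(study.cases.probs[rng.permutation(study.n_cases)])
        perm = sq.CohortStudy(cases=perm_cases, controls=study.controls,
                              variants=study.variants)
        qt2 = quality_table(perm)
        for m in MEASURES:
            np.testing.assert_allclose(qt[m], qt2[m], atol=1e-12)
        for m in ("impute_info", "beagle_dr2", "iam_chance", "iam_hwe",
                  "iam_combined", "hiq"):
            assert ((qt[m] >= 0) & (qt[m] <= 1 + 1e-12)).all()
        assert (qt["mach_r2"] >= 0).all()

    def test_degenerate_polymorphic_population_scores(self):
        rng = np.random.default_rng(7)
        g = hwe_genotypes(rng, 600, 4, 0.3)
        probs = degenerate_gp(g)
        qt = quality_table(make_study(probs, probs.copy()))
        np.testing.assert_allclose(qt["impute_info"], 1.0)
        np.testing.assert_allclose(qt["beagle_dr2"], 1.0)
        np.testing.assert_allclose(qt["mach_r2"], 1.0, atol=0.15)

    def test_info_and_mach_rank_agreement(self):
        """Across the full quality gradient the classical measures rank
        SNPs almost identically; pool cohorts from three imputation
        regimes to span the gradient."""
        from spikeqc.simulate import DeletionConfig, DiseaseLocus, SimConfig, simulate_cohort

        info, mach = [], []
        for seed, kw in [
            (1, dict(ld_decay=0.02, panel_size=300, deletion=DeletionConfig("scaffold", 0.25))),
            (2, dict(ld_decay=0.03, panel_size=150, deletion=DeletionConfig("scaffold", 0.18))),
            (3, dict(ld_decay=0.08, panel_size=50, deletion=DeletionConfig("scaffold", 0.12), mismatch=True)),
        ]:
            cfg = SimConfig(
                n_snps=300, n_cases=120, n_controls=120, spacing_bp=25000,
                disease_loci=(DiseaseLocus(None, 3.0, "additive"),), seed=seed, **kw,
            )
            sim = simulate_cohort(cfg)
            qt = quality_table(sim["imputed"])
            imputed = ~sim["imputed"].variants.typed
            info.extend(qt["impute_info"][imputed])
            mach.extend(qt["mach_r2"][imputed])
        assert spearmanr(info, mach).statistic > 0.8

    def test_unknown_combine_rule_rejected(self):
        probs = np.full((2, 2, 3), 1 / 3)
        variants = sq.VariantTable.from_arrays("1", [1, 2])
        study = sq.CohortStudy(
            cases=sq.GPMatrix(probs), controls=sq.GPMatrix(probs), variants=variants
        )
        with pytest.raises(ValueError, match="group_combine"):
            quality_table(study, group_combine="median")
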