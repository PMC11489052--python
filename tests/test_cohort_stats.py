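"""Differential-expression statistics, effect sizes, filtering, enrichment."""

import numpy as np
import pandas as pd
import pytest

from cohortpbn.cohort_stats import (ExpressionMatrix, TargetFilterConfig,
                                    bh_adjust, cl_empirical, cl_from_d,
                                    cl_one_sample, cohens_d,
                                    compute_cohort_profile,
                                    enrich_hypergeometric,
                                    filter_mirna_targets, log2_fold_change,
                                    match_literature_direction, paired_t_test,
                                    size_factors)


def make_matrix(case, ctrl, paired=True, mirnas=None):
    case = np.atleast_2d(case)
    ctrl = np.atleast_2d(ctrl)
    n = case.shape[1]
    cs = [f"case{i}" for i in range(n)]
    ts = [f"ctrl{i}" for i in range(ctrl.shape[1])]
    counts = pd.DataFrame(np.hstack([case, ctrl]),
                          index=mirnas or [f"m{i}" for i in
                                           range(case.shape[0])],
                          columns=cs + ts)
    groups = {**{s: "case" for s in cs}, **{s: "control" for s in ts}}
    pairing = dict(zip(cs, ts)) if paired and len(cs) == len(ts) else None
    return ExpressionMatrix(counts=counts, sample_groups=groups,
                            pairing=pairing)


# ---------------------------------------------------------------------------
# Normalisation / log2FC
# ---------------------------------------------------------------------------

class TestLog2FoldChange:
    def test_doubled_case_means_give_log2fc_one(self):
        mat = make_matrix([[200, 200], [100, 100]],
                          [[100, 100], [100, 100]])
        # miRNA 0 is 2x in cases; size factors absorb some of the shift,
        # so compare against the un-normalized expectation loosely
        lfc = log2_fold_change(mat, pseudocount=0.0)
        assert lfc["m0"] > lfc["m1"]

    def test_identical_groups_give_zero(self):
        mat = make_matrix([[50, 60], [80, 90]], [[50, 60], [80, 90]])
        np.testing.assert_allclose(log2_fold_change(mat), 0.0, atol=1e-12)

    def test_hand_computed_size_factors_and_ratios(self):
        # 2 miRNAs x 4 samples, all-positive: geometric means are
        # ref = (sqrt(1*4), sqrt(100*400)) = (2, 200); per-sample ratios
        # (1/2, 100/200)=0.5, (4/2, 400/200)=2 -> size factors (0.5,2,0.5,2)
        counts = pd.DataFrame([[1, 4, 1, 4], [100, 400, 100, 400]],
                              index=["m0", "m1"],
                              columns=["case0", "case1", "ctrl0", "ctrl1"])
        sf = size_factors(counts)
        np.testing.assert_allclose(sf, [0.5, 2.0, 0.5, 2.0])
        mat = ExpressionMatrix(counts=counts,
                               sample_groups={"case0": "case",
                                              "case1": "case",
                                              "ctrl0": "control",
                                              "ctrl1": "control"})
        # normalized counts equal (2,2,2,2) and (200,200,200,200)
        np.testing.assert_allclose(log2_fold_change(mat, 0.0), 0.0,
                                   atol=1e-12)

    def test_all_zero_matrix_rejected(self):
        counts = pd.DataFrame(np.zeros((2, 2), dtype=int),
                              columns=["a", "b"])
        with pytest.raises(ValueError, match="reference"):
            size_factors(counts)


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

class TestPairedT:
    def test_textbook_differences(self):
        # differences [1,2,3,4]: mean 2.5, sd 1.2910, t = 3.873, p = 0.0305
        t, p = paired_t_test(np.array([1., 2., 3., 4.]),
                             np.zeros(4))
        assert t == pytest.approx(3.873, abs=1e-3)
        assert p == pytest.approx(0.0305, abs=1e-3)

    def test_zero_variance_flagged_as_nan(self):
        t, p = paired_t_test(np.array([1., 2., 3.]), np.array([1., 2., 3.]))
        assert np.isnan(t) and np.isnan(p)

    def test_sign_flip_negates_t_keeps_p(self):
        x, y = np.array([3., 1., 4., 1.5]), np.array([1., 0.5, 2., 1.0])
        t1, p1 = paired_t_test(x, y)
        t2, p2 = paired_t_test(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_type_one_error_calibration_under_null(self):
        """2,000 null paired features at alpha=0.05 -> rejection rate
        within [0.035, 0.065]."""
        rng = np.random.default_rng(777)
        x = rng.normal(size=(2000, 20))
        y = rng.normal(size=(2000, 20))
        _, p = paired_t_test(x, y)
        rate = (p < 0.05).mean()
        assert 0.035 <= rate <= 0.065


class TestBHAdjust:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_and_tied_values_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([0.1, 0.1, 0.1]), [0.1] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_invariant_under_permutation(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------

class TestCohensD:
    def test_identical_means_give_zero(self):
        assert cohens_d(np.array([1., 2., 3.]),
                        np.array([3., 2., 1.])) == pytest.approx(0.0)

    def test_hand_computed_pooled_sd(self):
        # x=[4,5,6], y=[1,2,3]: pooled SD 1, d = 3
        assert cohens_d(np.array([4., 5., 6.]),
                        np.array([1., 2., 3.])) == pytest.approx(3.0)

    def test_antisymmetry(self):
        x, y = np.array([4., 7., 5.]), np.array([1., 3., 2.])
        assert cohens_d(x, y) == pytest.approx(-cohens_d(y, x))

    def test_planted_effect_recovery(self):
        """d=1.0 planted in normal data, n=100/group, 500 replicates:
        the mean estimate must land within 1.0 +/- 0.1."""
        rng = np.random.default_rng(2024)
        x = rng.normal(1.0, 1.0, size=(500, 100))
        y = rng.normal(0.0, 1.0, size=(500, 100))
        assert abs(cohens_d(x, y).mean() - 1.0) < 0.1


class TestCommonLanguage:
    def test_zero_effect_is_half(self):
        assert cl_from_d(0.0) == 0.5

    def test_unit_effect_value(self):
        # Phi(1/sqrt(2)) from the normal CDF
        assert cl_from_d(1.0) == pytest.approx(0.7602, abs=1e-4)

    @pytest.mark.parametrize("d", [-3.0, -0.7, 0.0, 0.4, 2.5])
    def test_symmetry_cl_d_plus_cl_minus_d(self, d):
        assert cl_from_d(d) + cl_from_d(-d) == pytest.approx(1.0, abs=1e-12)

    def test_one_sample_variant_differs(self):
        assert cl_one_sample(1.0) == pytest.approx(0.8413, abs=1e-4)

    @pytest.mark.parametrize("d", [0.0, 0.5, 1.0, 2.0])
    def test_closed_form_matches_probability_of_superiority(self, d):
        """|Phi(d_hat/sqrt2) - empirical P(X>Y)| <= 0.02 at n=10,000."""
        rng = np.random.default_rng(int(10 * d) + 1)
        x = rng.normal(d, 1.0, 10_000)
        y = rng.normal(0.0, 1.0, 10_000)
        d_hat = cohens_d(x, y)
        assert abs(cl_from_d(d_hat) - cl_empirical(x, y)) <= 0.02


class TestClEmpirical:
    def test_complete_separation(self):
        assert cl_empirical([5, 6], [1, 2]) == 1.0

    def test_tie_counts_half(self):
        assert cl_empirical([2.0], [2.0]) == 0.5

    def test_exhaustive_pair_count(self):
        # pairs (1,2): 0; (3,2): 1 -> 1/2
        assert cl_empirical([1, 3], [2]) == 0.5


# ---------------------------------------------------------------------------
# Profile-level invariants
# ---------------------------------------------------------------------------

class TestCohortProfile:
    def test_cl_constant_across_targets_of_one_mirna(self):
        """A miRNA's CL parameterizes all its targets identically."""
        rng = np.random.default_rng(8)
        mat = make_matrix(rng.poisson(100, size=(5, 10)),
                          rng.poisson(100, size=(5, 10)))
        profile = compute_cohort_profile(mat)
        targets = pd.DataFrame({"mirna": ["m0", "m0", "m1"],
                                "gene": ["BAG4", "ULK1", "ATXN3"]})
        merged = targets.merge(profile[["cl"]], left_on="mirna",
                               right_index=True)
        m0 = merged[merged["mirna"] == "m0"]["cl"]
        assert m0.nunique() == 1

    def test_welch_fallback_without_pairing(self):
        rng = np.random.default_rng(9)
        mat = make_matrix(rng.poisson(100, size=(3, 8)),
                          rng.poisson(100, size=(3, 6)), paired=False)
        profile = compute_cohort_profile(mat)
        assert profile["p_value"].notna().all()


# ---------------------------------------------------------------------------
# Target filtering
# ---------------------------------------------------------------------------

class TestFilterMirnaTargets:
    primary = pd.DataFrame({
        "mirna": ["miR-1", "miR-2", "miR-3"],
        "gene": ["G1", "G2", "G3"],
        "evidence_level": ["A", "B", "A"],
    })
    secondary = pd.DataFrame({
        "mirna": ["miR-1", "miR-2", "miR-3"],
        "gene": ["G1", "G2", "G3"],
        "n_supporting_studies": [3, 1, 2],
    })

    def test_level_a_pair_in_tissue_retained(self):
        out = filter_mirna_targets(self.primary, [self.secondary],
                                   ["G1"], ["miR-1"])
        assert out.to_dict("records") == [{"mirna": "miR-1", "gene": "G1"}]

    def test_single_study_level_b_pair_dropped(self):
        out = filter_mirna_targets(self.primary, [self.secondary],
                                   ["G1", "G2", "G3"],
                                   ["miR-1", "miR-2", "miR-3"])
        assert "miR-2" not in set(out["mirna"])

    def test_de_mirna_with_target_outside_tissue_dropped_entirely(self):
        out = filter_mirna_targets(self.primary, [self.secondary],
                                   ["G1"], ["miR-1", "miR-3"])
        assert set(out["mirna"]) == {"miR-1"}


# ---------------------------------------------------------------------------
# Literature matching
# ---------------------------------------------------------------------------

class TestMatchLiterature:
    literature = pd.DataFrame({"mirna": ["miR-1", "miR-2"],
                               "direction": ["Up", "Up"]})

    def profile(self, lfc):
        return pd.DataFrame({"log2FC": lfc},
                            index=[f"miR-{i + 1}" for i in range(len(lfc))])

    def test_agreeing_sign_matched(self):
        out = match_literature_direction(self.profile([1.2]), self.literature)
        assert out.loc["miR-1", "status"] == "matched"
        assert not out.loc["miR-1", "excluded"]

    def test_disagreeing_sign_mismatched_and_excluded(self):
        out = match_literature_direction(self.profile([-0.8]), self.literature)
        assert out.loc["miR-1", "status"] == "mismatched"
        assert out.loc["miR-1", "excluded"]

    def test_absent_mirna_is_unreviewed(self):
        out = match_literature_direction(
            pd.DataFrame({"log2FC": [0.5]}, index=["miR-99"]),
            self.literature)
        assert out.loc["miR-99", "status"] == "unreviewed"

    def test_conflicting_reports_count_as_matched_when_one_agrees(self):
        lit = pd.DataFrame({"mirna": ["miR-1", "miR-1"],
                            "direction": ["Up", "Down"]})
        out = match_literature_direction(self.profile([-0.8]), lit)
        assert out.loc["miR-1", "status"] == "matched"


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

class TestEnrichment:
    universe = [f"g{i}" for i in range(10)]

    def test_exact_hypergeometric_tail_by_hand(self):
        # universe 10, set 5, query 3 all inside: p = C(5,3)/C(10,3) = 1/12
        out = enrich_hypergeometric(["g0", "g1", "g2"],
                                    {"S": ["g0", "g1", "g2", "g3", "g4"]},
                                    self.universe)
        assert out["p_value"].iloc[0] == pytest.approx(1 / 12)

    def test_disjoint_query_has_p_one(self):
        out = enrich_hypergeometric(["g9"], {"S": ["g0", "g1"]},
                                    self.universe)
        assert out["p_value"].iloc[0] == 1.0

    def test_set_equal_to_universe_has_p_one(self):
        out = enrich_hypergeometric(["g0", "g1"], {"S": self.universe},
                                    self.universe)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            enrich_hypergeometric([], {"S": []}, [])
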