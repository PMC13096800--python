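"""Differential testing: mean reference, NB Wald, moderated t, adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from photoxl import differential
from photoxl.differential import (
    abundance_change,
    adjust_pvalues,
    build_mean_reference,
    estimate_variance_prior,
    moderated_t_test,
    nbm_test,
)

from conftest import make_qm


class TestMeanReference:
    def test_replicatewise_mean(self):
        values = np.array([[3.0, 1, 6.0, 1, 9.0, 1]])  # rep1/rep2 per condition
        qm = make_qm(values, ("A", "B", "C"), 2)
        out = build_mean_reference(qm, ["A", "B", "C"])
        assert out.n_samples == 8
        mean_cols = out.samples_for("mean")
        assert out.intensities[0, mean_cols[0]] == 6.0
        assert out.intensities[0, mean_cols[1]] == 1.0

    def test_single_condition_errors(self):
        qm = make_qm(np.ones((2, 3)), ("A",), 3)
        with pytest.raises(ValueError, match="2 conditions"):
            build_mean_reference(qm, ["A"])

    def test_matches_brute_force(self, rng):
        values = rng.lognormal(5, 1, size=(10, 4))
        qm = make_qm(values, ("A", "B"), 2)
        out = build_mean_reference(qm, ["A", "B"])
        mean_cols = out.samples_for("mean")
        for j in range(2):
            expected = (values[:, j] + values[:, 2 + j]) / 2
            np.testing.assert_allclose(
                out.intensities[:, mean_cols[j]], expected
            )


class TestAdjustPvalues:
    def test_holm_hand_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03], "holm"), [0.03, 0.04, 0.04]
        )

    def test_bh_hand_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03], "bh"), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        for method in ("bh", "holm"):
            np.testing.assert_allclose(adjust_pvalues([0.2], method), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "bh")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_holm_dominates_bh_elementwise(self, p):
        holm = adjust_pvalues(p, "holm")
        bh = adjust_pvalues(p, "bh")
        assert np.all(holm >= bh - 1e-12)
        assert np.all((0 <= holm) & (holm <= 1))


class TestNbmTest:
    def test_identical_groups_null(self, rng):
        block = rng.poisson(200, size=(50, 3)).astype(float)
        qm = make_qm(np.hstack([block, block]), ("A", "B"), 3)
        res = nbm_test(qm, "A", "B")
        assert all(r.log2_fc == 0 for r in res)
        assert all(r.p_raw > 0.999 for r in res)

    def test_group_label_swap_flips_sign(self, rng):
        values = rng.poisson(100, size=(30, 6)).astype(float) + 1
        qm = make_qm(values, ("A", "B"), 3)
        ab = nbm_test(qm, "A", "B")
        ba = nbm_test(qm, "B", "A")
        np.testing.assert_allclose(
            [r.log2_fc for r in ab], [-r.log2_fc for r in ba], rtol=1e-9
        )
        np.testing.assert_allclose(
            [r.p_raw for r in ab], [r.p_raw for r in ba], rtol=1e-9
        )

    def test_sample_order_invariance(self, rng):
        values = rng.poisson(150, size=(20, 6)).astype(float) + 1
        qm = make_qm(values, ("A", "B"), 3)
        perm = [2, 0, 1, 5, 3, 4]  # within-group permutation
        qm_perm = qm.select_samples(perm)
        a = nbm_test(qm, "A", "B")
        b = nbm_test(qm_perm, "A", "B")
        np.testing.assert_allclose(
            [r.log2_fc for r in a], [r.log2_fc for r in b], rtol=1e-9
        )

    def test_matches_statsmodels_glm(self, rng):
        """Cross-check the Newton MLE against an independent GLM fit."""
        import statsmodels.api as sm

        counts = rng.negative_binomial(20, 20 / 120, size=(8, 6)).astype(float)
        counts += 1  # keep all groups informative
        qm = make_qm(counts, ("A", "B"), 3)
        res = nbm_test(qm, "A", "B")
        sf = differential._size_factors(counts)
        q = counts / sf
        alpha = differential._dispersion_estimates(q, [0, 1, 2], [3, 4, 5])
        for i, r in enumerate(res):
            design = np.column_stack(
                [np.ones(6), np.repeat([1.0, 0.0], 3)]
            )
            fit = sm.GLM(
                counts[i], design,
                family=sm.families.NegativeBinomial(alpha=alpha[i]),
                offset=np.log(sf),
            ).fit()
            assert r.log2_fc == pytest.approx(
                fit.params[1] / np.log(2), abs=1e-6
            )
            assert r.se == pytest.approx(
                fit.bse[1] / np.log(2), rel=1e-4
            )

    def test_all_zero_group_errors(self):
        values = np.hstack([np.zeros((3, 3)), np.ones((3, 3))])
        qm = make_qm(values, ("A", "B"), 3)
        with pytest.raises(ValueError, match="all-zero"):
            nbm_test(qm, "A", "B")

    def test_mean_reference_method_tag(self, rng):
        block = rng.poisson(100, size=(10, 6)).astype(float) + 1
        qm = make_qm(block, ("A", "B"), 3)
        ref = build_mean_reference(qm, ["A", "B"])
        res = nbm_test(ref, "A", "mean")
        assert all(r.method == "nbm_vs_mean" for r in res)


class TestModeratedT:
    def test_zero_prior_df_is_ordinary_t(self, rng):
        values = rng.normal(20, 1, size=(40, 6))
        qm = make_qm(values, ("A", "B"), 3)
        res = moderated_t_test(qm, "A", "B", prior_df=0)
        t_ref, p_ref = stats.ttest_ind(values[:, :3].T, values[:, 3:].T)
        np.testing.assert_allclose([r.statistic for r in res], t_ref,
                                   rtol=1e-9)
        np.testing.assert_allclose([r.p_raw for r in res], p_ref, rtol=1e-9)

    def test_identical_variances_unchanged_by_moderation(self, rng):
        # every protein has the same residual pattern -> identical s^2
        base = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        shifts = rng.normal(0, 5, size=(20, 1))
        values = shifts + base[None, :]
        qm = make_qm(values, ("A", "B"), 3)
        res0 = moderated_t_test(qm, "A", "B", prior_df=0)
        res = moderated_t_test(qm, "A", "B", prior_df=10.0)
        np.testing.assert_allclose(
            [r.se for r in res], [r.se for r in res0], rtol=1e-9
        )

    def test_prior_recovery_on_scaled_f_variances(self, rng):
        d, d0, s0_sq = 4, 8.0, 0.25
        n = 20000
        chi_d = rng.chisquare(d, n) / d
        chi_d0 = rng.chisquare(d0, n) / d0
        s2 = s0_sq * chi_d / chi_d0
        d0_hat, s0_hat = estimate_variance_prior(s2, d)
        assert d0_hat == pytest.approx(d0, rel=0.15)
        assert s0_hat == pytest.approx(s0_sq, rel=0.05)

    def test_too_few_replicates_errors(self, rng):
        qm = make_qm(rng.normal(size=(5, 2)), ("A", "B"), 1)
        with pytest.raises(ValueError, match="2 replicates"):
            moderated_t_test(qm, "A", "B")

    def test_missing_values_rejected(self, rng):
        values = rng.normal(size=(5, 6))
        values[0, 0] = np.nan
        qm = make_qm(np.abs(values), ("A", "B"), 3)
        with pytest.raises(ValueError, match="impute"):
            moderated_t_test(qm, "A", "B")


class TestAbundanceChange:
    def test_equal_groups_zero(self, rng):
        block = rng.random((10, 3))
        qm = make_qm(np.hstack([block, block]), ("A", "B"), 3)
        out = abundance_change(qm, "A", "B")
        np.testing.assert_allclose(out["abundance_change"], 0.0, atol=1e-15)

    def test_example_difference_tops_ranking(self):
        values = np.array([[0.10, 0.10, 0.02, 0.02],
                           [0.90, 0.90, 0.98, 0.98]])
        qm = make_qm(values, ("A", "B"), 2)
        out = abundance_change(qm, "A", "B")
        assert out.iloc[0]["protein_id"] == "P0000"
        assert out.iloc[0]["abundance_change"] == pytest.approx(0.08)

    def test_ranking_matches_brute_force(self, rng):
        values = rng.random((10, 6))
        qm = make_qm(values, ("A", "B"), 3)
        out = abundance_change(qm, "A", "B")
        diffs = values[:, :3].mean(axis=1) - values[:, 3:].mean(axis=1)
        expected = [qm.protein_ids[i] for i in np.argsort(-diffs)]
        assert out["protein_id"].tolist() == expected


class TestTwoPulseMixtureClosure:
    def test_observed_fold_matches_closed_form(self):
        """Recruited protein, weights 1:5, state-2 4x -> observed fold 3.5."""
        from photoxl import synthetic_data as sd

        cfg = sd.TwoPulseConfig(n_recruited=1, n_released=0, n_stable=0,
                                noise_cv=0.0, seed=0)
        qm, truth = sd.generate_two_pulse(cfg)
        imm = qm.intensities[0, qm.samples_for("immediate")]
        dly = qm.intensities[0, qm.samples_for("delayed")]
        assert dly.mean() / imm.mean() == pytest.approx(3.5, rel=1e-12)
        assert truth["true_group_fold"].iloc[0] == pytest.approx(3.5)
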