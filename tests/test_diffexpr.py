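import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from vdresponse import (
    anova2,
    baseline_status_diff,
    bh_adjust,
    concordance_fit,
    ddct_relative_expression,
    de_table,
    gen_expression,
    paired_log2_fc,
    select_responsive,
    select_vdre_candidates,
)
from vdresponse.synthetic import (
    PlantedGene,
    TruthDesign,
    default_study_cohort,
)

from conftest import make_matrix

LOG2_15 = np.log2(1.5)


def _balanced_matrix(values):
    return make_matrix(
        values,
        subjects=["s1", "s2", "s3", "s4"],
        doses=[400, 400, 2000, 2000],
        statuses=["deficient"] * 2 + ["insufficient_sufficient"] * 2,
    )


# ---------------------------------------------------------------------------
# paired fold change
# ---------------------------------------------------------------------------

class TestPairedLog2Fc:
    def test_no_change_gives_zero(self):
        base = np.random.default_rng(0).normal(8, 1, size=(3, 4))
        values = np.repeat(base, 2, axis=1)  # followup == baseline
        fc = paired_log2_fc(_balanced_matrix(values))
        np.testing.assert_allclose(fc.to_numpy(), 0.0, atol=1e-12)

    def test_uniform_shift_gives_exact_boundary_fold_change(self):
        values = np.zeros((2, 8)) + 8.0
        values[:, 1::2] += LOG2_15  # every followup column
        fc = paired_log2_fc(_balanced_matrix(values))
        np.testing.assert_allclose(2.0 ** fc.to_numpy(), 1.5)

    def test_antisymmetry_under_visit_swap(self):
        rng = np.random.default_rng(1)
        values = rng.normal(8, 1, size=(5, 8))
        m = _balanced_matrix(values)
        swapped = values.copy()
        swapped[:, 0::2], swapped[:, 1::2] = values[:, 1::2], values[:, 0::2]
        m2 = _balanced_matrix(swapped)
        fc1 = 2.0 ** paired_log2_fc(m)
        fc2 = 2.0 ** paired_log2_fc(m2)
        np.testing.assert_allclose(fc1.to_numpy(), 1.0 / fc2.to_numpy())

    def test_unpaired_subject_named_in_error(self):
        m = _balanced_matrix(np.zeros((2, 8)))
        broken = m.values.drop(columns=["s3_followup"])
        from vdresponse.matrix import ExpressionMatrix

        bad = ExpressionMatrix(broken, m.meta.loc[broken.columns])
        with pytest.raises(ValueError, match="s3"):
            paired_log2_fc(bad)


# ---------------------------------------------------------------------------
# split-plot two-way ANOVA
# ---------------------------------------------------------------------------

class TestAnova2:
    def test_constant_matrix_reports_p_one(self):
        out = anova2(_balanced_matrix(np.full((3, 8), 5.0)))
        assert (out["p_time"] == 1.0).all()
        assert (out["p_dose"] == 1.0).all()
        assert (out["p_interaction"] == 1.0).all()

    def test_matches_statsmodels_ols_oracle(self):
        rng = np.random.default_rng(2)
        values = rng.normal(8, 1, size=(6, 8))
        m = _balanced_matrix(values)
        out = anova2(m)
        # oracle: per gene, OLS of within-subject differences (visit and
        # interaction tests) and subject means (dose test) on an
        # effect-coded dose covariate
        g = np.array([-0.5, -0.5, 0.5, 0.5])
        X = sm.add_constant(g)
        for i, gene in enumerate(m.gene_ids):
            base = values[i, 0::2]
            follow = values[i, 1::2]
            fit_d = sm.OLS(follow - base, X).fit()
            fit_m = sm.OLS((follow + base) / 2, X).fit()
            assert out.loc[gene, "p_time"] == pytest.approx(fit_d.pvalues[0])
            assert out.loc[gene, "p_interaction"] == pytest.approx(fit_d.pvalues[1])
            assert out.loc[gene, "p_dose"] == pytest.approx(fit_m.pvalues[1])

    def test_hand_computed_worked_example(self):
        # 1 gene, 4 subjects (2 per arm); differences d = (1, 3, 5, 7):
        # arm means 2 and 6 -> visit effect beta0 = 4, interaction
        # beta1 = 4; residuals (-1, 1, -1, 1) -> RSS = 4 on 2 df, s2 = 2.
        # With effect coding g = +-1/2: (X'X)^-1 diag = (1/4, 1), so
        # se(beta0) = sqrt(2/4), se(beta1) = sqrt(2).
        values = np.zeros((1, 8))
        base = np.array([8.0, 8.0, 8.0, 8.0])
        follow = base + np.array([1.0, 3.0, 5.0, 7.0])
        values[0, 0::2] = base
        values[0, 1::2] = follow
        out = anova2(_balanced_matrix(values))
        from scipy import stats

        assert out["p_time"].iloc[0] == pytest.approx(
            2 * stats.t.sf(4.0 / np.sqrt(0.5), 2)
        )
        assert out["p_interaction"].iloc[0] == pytest.approx(
            2 * stats.t.sf(4.0 / np.sqrt(2.0), 2)
        )

    def test_planted_time_effect_and_null_dose(self):
        rng = np.random.default_rng(3)
        n = 2000
        values = rng.normal(8, 0.1, size=(n, 16))
        values[:, 1::2] += 1.0  # pure time effect, no dose effect
        out = anova2(
            make_matrix(
                values,
                subjects=[f"s{i}" for i in range(1, 9)],
                doses=[400] * 4 + [2000] * 4,
                statuses=["deficient"] * 4 + ["insufficient_sufficient"] * 4,
            )
        )
        assert (out["p_time"] < 1e-4).mean() > 0.99
        frac = (out["p_dose"] < 0.05).mean()
        assert 0.02 < frac < 0.09  # ~uniform null

    def test_single_dose_arm_rejected(self):
        m = make_matrix(
            np.zeros((2, 4)),
            subjects=["s1", "s2"],
            doses=[400, 400],
            statuses=["deficient", "deficient"],
        )
        with pytest.raises(ValueError):
            anova2(m)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def _bh_oracle(p):
    """Brute-force step-up: min over suffixes of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        adj[order[rank - 1]] = running
    return adj


class TestBhAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @pytest.mark.parametrize("n", [10, 100, 1000])
    def test_matches_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        p = rng.uniform(size=n)
        np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_dominates_raw(self, pvals):
        adj = bh_adjust(pvals)
        floored = np.maximum(pvals, np.finfo(float).eps)
        assert (adj >= floored - 1e-15).all()
        assert (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# responsive selection
# ---------------------------------------------------------------------------

class TestSelectResponsive:
    def test_global_null_selects_nothing(self):
        cohort = default_study_cohort(4)
        truth = TruthDesign(n_genes=500, residual_sd=0.1, seed=4)
        matrix, _ = gen_expression(cohort, truth)
        sel = select_responsive(de_table(matrix))
        assert sel.n_selected == 0

    def test_noiseless_recovery_is_exact(self):
        cohort = default_study_cohort(5)
        universe = [f"G{i + 1:05d}" for i in range(500)]
        planted = [
            PlantedGene(universe[i], "up" if i % 3 else "down", 0.8 + 0.01 * i)
            for i in range(0, 50)
        ]
        truth = TruthDesign(n_genes=500, responsive=planted, residual_sd=0.0,
                            seed=5)
        matrix, _ = gen_expression(cohort, truth)
        sel = select_responsive(de_table(matrix))
        assert set(sel.up) | set(sel.down) == {p.gene_id for p in planted}
        assert set(sel.up) == {p.gene_id for p in planted if p.direction == "up"}


# ---------------------------------------------------------------------------
# status subgroup contrast
# ---------------------------------------------------------------------------

class TestBaselineStatusDiff:
    def _status_matrix(self, values):
        return make_matrix(
            values,
            subjects=[f"s{i}" for i in range(1, 9)],
            doses=[400, 400, 400, 2000, 2000, 2000, 2000, 2000],
            statuses=["deficient"] * 4 + ["insufficient_sufficient"] * 4,
        )

    def test_identical_group_means_select_nothing(self):
        rng = np.random.default_rng(6)
        base = rng.normal(8, 0.05, size=(20, 1))
        values = np.repeat(base, 16, axis=1)
        out = baseline_status_diff(self._status_matrix(values))
        assert not out["selected66"].any()

    def test_t_statistic_matches_pooled_variance_oracle(self):
        rng = np.random.default_rng(7)
        values = rng.normal(8, 1, size=(5, 16))
        m = self._status_matrix(values)
        out = baseline_status_diff(m)
        a = values[:, 0:8:2]  # deficient baselines
        b = values[:, 8:16:2]
        from scipy import stats as ss

        for i in range(5):
            na, nb = 4, 4
            sp2 = ((na - 1) * a[i].var(ddof=1) + (nb - 1) * b[i].var(ddof=1)) / (
                na + nb - 2
            )
            t = (a[i].mean() - b[i].mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            p = 2 * ss.t.sf(abs(t), na + nb - 2)
            assert out["p_baseline"].iloc[i] == pytest.approx(p)

    def test_small_status_group_rejected(self):
        m = make_matrix(
            np.zeros((2, 8)),
            subjects=["s1", "s2", "s3", "s4"],
            doses=[400, 400, 2000, 2000],
            statuses=["deficient"] + ["insufficient_sufficient"] * 3,
        )
        with pytest.raises(ValueError):
            baseline_status_diff(m)


class TestSelectVdreCandidates:
    def test_planted_dual_responders_recovered_exactly(self):
        # gene A: baseline status difference AND before/after change in
        # both groups; gene B: baseline difference only; gene C: null
        values = np.zeros((3, 16)) + 8.0
        values[0, 0:8:2] += 2.0  # A deficient baseline up
        values[0, 1::2] += 1.5  # A followup shift in everyone
        values[1, 0:8:2] += 2.0  # B deficient baseline up only
        rng = np.random.default_rng(8)
        values += rng.normal(0, 0.05, size=values.shape)
        m = make_matrix(
            values,
            subjects=[f"s{i}" for i in range(1, 9)],
            doses=[400, 400, 400, 2000, 2000, 2000, 2000, 2000],
            statuses=["deficient"] * 4 + ["insufficient_sufficient"] * 4,
            gene_ids=["A", "B", "C"],
        )
        out = select_vdre_candidates(baseline_status_diff(m))
        assert set(out.index[out["selected66"]]) == {"A", "B"}
        assert set(out.index[out["selected17"]]) == {"A"}

    def test_candidate_subset_of_status_genes(self):
        rng = np.random.default_rng(9)
        values = rng.normal(8, 1, size=(50, 16))
        m = make_matrix(
            values,
            subjects=[f"s{i}" for i in range(1, 9)],
            doses=[400] * 3 + [2000] * 5,
            statuses=["deficient"] * 4 + ["insufficient_sufficient"] * 4,
        )
        out = select_vdre_candidates(baseline_status_diff(m))
        assert (out["selected17"] <= out["selected66"]).all()


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

class TestDdct:
    def _records(self, ct_target_ref, ct_target_cond, ct_control=15.0):
        return pd.DataFrame(
            {
                "gene_id": ["g"] * 2,
                "sample_id": ["ref", "cond"],
                "condition": ["baseline", "followup"],
                "ct_target": [ct_target_ref, ct_target_cond],
                "ct_control": [ct_control, ct_control],
            }
        )

    def test_equal_cts_give_rq_one(self):
        out = ddct_relative_expression(self._records(20.0, 20.0), "baseline")
        assert out.loc[out["condition"] == "followup", "rq"].iloc[0] == 1.0

    def test_one_cycle_more_halves_expression(self):
        out = ddct_relative_expression(self._records(20.0, 21.0), "baseline")
        assert out.loc[out["condition"] == "followup", "rq"].iloc[0] == 0.5

    def test_two_cycles_fewer_quadruples_expression(self):
        out = ddct_relative_expression(self._records(20.0, 18.0), "baseline")
        assert out.loc[out["condition"] == "followup", "rq"].iloc[0] == 4.0

    def test_missing_control_rejected(self):
        rec = self._records(20.0, 21.0)
        rec.loc[1, "ct_control"] = np.nan
        with pytest.raises(ValueError, match="cond"):
            ddct_relative_expression(rec, "baseline")


class TestConcordanceFit:
    def test_identity_line(self):
        x = np.array([-1.0, 0.0, 1.0, 2.0])
        fit = concordance_fit(x, x)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r == pytest.approx(1.0)

    def test_affine_noiseless(self):
        x = np.array([-1.0, 0.0, 1.0, 2.0])
        fit = concordance_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_prediction_interval_matches_statsmodels(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.1, 0.9, 2.2, 2.8])
        fit = concordance_fit(x, y)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        pred = ols.get_prediction(sm.add_constant(x)).summary_frame(alpha=0.05)
        expected_hw = (pred["obs_ci_upper"] - pred["obs_ci_lower"]) / 2
        np.testing.assert_allclose(fit.pi_halfwidths, expected_hw, rtol=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            concordance_fit([0.0, 1.0], [0.0, 1.0])
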