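"""Per-CpG linear models, BH-FDR, dose-response and descriptives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

import ewasmed as em
from ewasmed.simulate import CohortDataset

from conftest import PLANTED_PROBE


def brute_force_bh(p):
    """Definitional BH: q_i = min over {j: p_(j) >= p_i} of m p_(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        cands = [
            m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i] or j == i
        ]
        q[i] = min(1.0, min(cands))
    return q


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(
            em.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_of_one(self):
        assert em.bh_fdr([1.0]) == pytest.approx([1.0])

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60)
    )
    def test_agrees_with_bruteforce_and_statsmodels(self, p):
        q = em.bh_fdr(p)
        np.testing.assert_allclose(q, brute_force_bh(p), atol=1e-12)
        np.testing.assert_allclose(
            q, multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=60)
    )
    def test_q_monotone_in_sorted_p_order(self, p):
        q = em.bh_fdr(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(np.asarray(q)[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            em.bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            em.bh_fdr([])


class TestFitProbeModel:
    def _design(self, exposure):
        return pd.DataFrame(
            {"intercept": np.ones(len(exposure)), "exposure": exposure}
        )

    def test_no_covariates_coefficient_is_group_mean_difference(self):
        rng = np.random.default_rng(0)
        exposure = np.repeat([0, 1], [10, 12])
        y = rng.uniform(0.2, 0.8, 22)
        coef, se, t, p = em.fit_probe_model(y, self._design(exposure))
        expected = y[exposure == 1].mean() - y[exposure == 0].mean()
        assert coef == pytest.approx(expected, rel=1e-12)

    def test_zero_residual_fit_guards_p_underflow(self):
        exposure = np.repeat([0.0, 1.0], 5)
        y = 0.3 + 0.1 * exposure
        coef, se, t, p = em.fit_probe_model(y, self._design(exposure))
        assert coef == pytest.approx(0.1)
        assert se < 1e-12  # exact fit up to floating-point roundoff
        assert p < 1e-12

    def test_rank_deficiency_names_aliased_columns(self):
        exposure = np.repeat([0.0, 1.0], 5)
        X = self._design(exposure)
        X["exposure_copy"] = X["exposure"]
        with pytest.raises(ValueError, match="exposure_copy"):
            em.fit_probe_model(np.linspace(0, 1, 10), X)

    def test_planted_shift_within_2se_in_95pct_of_replicates(self):
        """-0.073 beta shift at n = 255: nominal 2-SE coverage >= 95%."""
        rng = np.random.default_rng(12)
        n_rep, shift = 2000, -0.073
        exposure = np.repeat([0.0, 1.0], [126, 129])
        X = self._design(exposure)
        Y = 0.6 + shift * exposure[:, None] + rng.normal(0, 0.1, (255, n_rep))
        from ewasmed.ewas import _ols_term

        coef, se, *_ = _ols_term(Y, X.to_numpy(), 1)
        coverage = (np.abs(coef - shift) <= 2 * se).mean()
        assert coverage >= 0.94

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(13)
        n_rep = 10_000
        exposure = np.repeat([0.0, 1.0], [126, 129])
        X = self._design(exposure)
        Y = rng.normal(0.5, 0.1, (255, n_rep))
        from ewasmed.ewas import _ols_term

        *_, p, _ = _ols_term(Y, X.to_numpy(), 1)
        rate = (p < 0.05).mean()
        mc_se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3 * mc_se


class TestRunEwas:
    def test_planted_probe_attains_smallest_p(self, filtered, proportions):
        res = em.run_ewas(filtered, proportions)
        assert res["p"].idxmin() == PLANTED_PROBE
        assert res.loc[PLANTED_PROBE, "q"] < 0.05

    def test_null_ewas_counts_match_binomial_oracle(self, null_ewas):
        m = len(null_ewas)
        n05 = (null_ewas["p"] < 0.05).sum()
        assert abs(n05 - 0.05 * m) <= 3 * np.sqrt(m * 0.05 * 0.95)
        assert (null_ewas["q"] < 0.05).sum() <= 2

    def test_null_pvalues_uniform_by_ks(self, null_ewas):
        stat, p = stats.kstest(null_ewas["p"], "uniform")
        assert p > 0.01

    def test_output_invariant_to_probe_and_sample_order(
        self, filtered, proportions
    ):
        res = em.run_ewas(filtered, proportions)
        probe_perm = filtered.beta.sample(frac=1.0, random_state=1).index
        sample_perm = list(
            filtered.samples.sample(frac=1.0, random_state=2).index
        )
        shuffled = filtered.subset(probes=list(probe_perm),
                                   samples=sample_perm)
        res2 = em.run_ewas(shuffled, proportions)
        pd.testing.assert_frame_equal(
            res.sort_index(), res2.sort_index(), atol=1e-10, rtol=1e-8
        )

    def test_cell_correction_changes_q_list(self, filtered, proportions):
        with_cells = em.run_ewas(filtered, proportions)
        without = em.run_ewas(filtered, None)
        assert not np.allclose(with_cells["q"], without["q"])

    def test_missing_proportions_rejected(self, filtered, proportions):
        with pytest.raises(ValueError, match="missing"):
            em.run_ewas(filtered, proportions.iloc[:-3])

    def test_raw_difference_equals_coefficient_without_covariates(
        self, filtered
    ):
        res = em.run_ewas(filtered, None, covariates=())
        np.testing.assert_allclose(
            res["coefficient"], res["raw_difference"], atol=1e-12
        )


class TestDoseResponse:
    def test_planted_dose_effect_recovered_within_2se(self, reference):
        cfg = em.SimulationConfig(
            n_probes=300, missing_covariate_rate=0.0, seed=31
        )
        ds = em.generate_cohort(cfg, reference)
        # plant a linear dose effect on one probe within the exposed group
        slope = 0.004
        probe = "cg00000150"
        exposed = ds.samples["exposure"] == 1
        cigs = ds.samples.loc[exposed, "cigarettes_per_day"]
        ds.beta.loc[probe, exposed.to_numpy()] += slope * (
            cigs - cigs.mean()
        ).to_numpy()
        res = em.dose_response_test(ds, [probe])
        assert abs(res.loc[probe, "slope"] - slope) <= 2 * res.loc[probe, "se"]
        assert not res.loc[probe, "low_n"]

    def test_constant_cigarettes_rejected(self, reference):
        cfg = em.SimulationConfig(
            n_probes=300, missing_covariate_rate=0.0, seed=32
        )
        ds = em.generate_cohort(cfg, reference)
        ds.samples.loc[ds.samples["exposure"] == 1, "cigarettes_per_day"] = 10
        with pytest.raises(ValueError, match="variance"):
            em.dose_response_test(ds, [PLANTED_PROBE])

    def test_small_exposed_group_flagged_low_n(self, reference):
        cfg = em.SimulationConfig(
            n_probes=300, n_exposed=8, n_unexposed=50,
            missing_covariate_rate=0.0, seed=33,
        )
        ds = em.generate_cohort(cfg, reference)
        with pytest.warns(UserWarning, match="exposed samples"):
            res = em.dose_response_test(ds, [PLANTED_PROBE], covariates=())
        assert res["low_n"].all()


class TestDescriptives:
    def _sheet(self, bw_unexposed, bw_exposed):
        n0, n1 = len(bw_unexposed), len(bw_exposed)
        return pd.DataFrame(
            {
                "exposure": [0] * n0 + [1] * n1,
                "birthweight": list(bw_unexposed) + list(bw_exposed),
                "sex": [0, 1] * ((n0 + n1) // 2),
            },
            index=[f"S{i}" for i in range(n0 + n1)],
        )

    def _dataset(self, sheet):
        beta = pd.DataFrame(
            np.full((2, len(sheet)), 0.5),
            index=["cgA", "cgB"],
            columns=sheet.index,
        )
        return CohortDataset(beta, beta.copy(), sheet)

    def test_birthweight_difference_matches_group_means(self):
        ds = self._dataset(self._sheet([3600.0, 3770.0], [3300.0, 3508.0]))
        table = em.descriptive_table(ds)
        assert table.loc["birthweight", "unexposed_mean"] == 3685.0
        assert table.loc["birthweight", "exposed_mean"] == 3404.0
        assert table.loc["birthweight", "difference"] == -281.0

    def test_identical_groups_give_p_one(self):
        ds = self._dataset(self._sheet([3400.0, 3700.0], [3400.0, 3700.0]))
        table = em.descriptive_table(ds)
        assert table.loc["birthweight", "p"] == pytest.approx(1.0)
        assert table.loc["sex", "p"] == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        ds = self._dataset(self._sheet([], [3400.0, 3700.0]))
        with pytest.raises(ValueError):
            em.descriptive_table(ds)

    def test_full_cohort_descriptives_have_expected_rows(self, filtered):
        table = em.descriptive_table(filtered)
        assert {"birthweight", "maternal_age", "sex", "education"} <= set(
            table.index
        )
        assert table["p"].between(0, 1).all()
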