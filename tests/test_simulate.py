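"""Generator contracts: determinism, planted structure, invariants."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import ewasmed as em
from ewasmed.simulate import DEFAULT_DIRICHLET

from conftest import PLANTED_BB, PLANTED_PROBE, PLANTED_SHIFT


def _null_config(**kw):
    conc = DEFAULT_DIRICHLET["unexposed"]
    defaults = dict(
        n_probes=200,
        dirichlet_concentrations={"unexposed": conc, "exposed": conc},
        missing_covariate_rate=0.0,
        detection_fail_rate=0.0,
        seed=5,
    )
    defaults.update(kw)
    return em.SimulationConfig(**defaults)


class TestReferencePanel:
    def test_full_column_rank_and_shape(self):
        ref = em.generate_celltype_reference(100, 6, separation=0.3, seed=1)
        assert ref.signature.shape == (100, 6)
        assert np.linalg.matrix_rank(ref.signature.to_numpy()) == 6

    def test_discriminating_probes_have_required_spread(self):
        ref = em.generate_celltype_reference(80, 6, separation=0.3, seed=2)
        spread = ref.signature.loc[list(ref.discriminating_probes)].apply(
            np.ptp, axis=1
        )
        assert (spread >= 0.3).all()

    def test_entries_in_unit_interval(self):
        ref = em.generate_celltype_reference(50, 4, separation=0.9, seed=3)
        assert ref.signature.to_numpy().min() >= 0
        assert ref.signature.to_numpy().max() <= 1

    def test_deterministic_under_seed(self):
        a = em.generate_celltype_reference(60, 6, seed=7)
        b = em.generate_celltype_reference(60, 6, seed=7)
        pd.testing.assert_frame_equal(a.signature, b.signature)

    @pytest.mark.parametrize("n_probes,n_types", [(0, 6), (10, 0), (3, 6)])
    def test_invalid_dimensions_rejected(self, n_probes, n_types):
        with pytest.raises(ValueError):
            em.generate_celltype_reference(n_probes, n_types)


class TestGenerateCohort:
    def test_deterministic_under_seed(self, reference):
        cfg = _null_config(n_probes=300)
        a = em.generate_cohort(cfg, reference)
        b = em.generate_cohort(cfg, reference)
        pd.testing.assert_frame_equal(a.beta, b.beta)
        pd.testing.assert_frame_equal(a.detection_p, b.detection_p)
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_null_config_gives_no_group_difference(self):
        ref = em.generate_celltype_reference(200, 6, seed=9)
        ds = em.generate_cohort(_null_config(), ref)
        exposed = ds.samples["exposure"] == 1
        diff = (
            ds.beta.loc[:, exposed.to_numpy()].mean(axis=1)
            - ds.beta.loc[:, (~exposed).to_numpy()].mean(axis=1)
        )
        # Monte-Carlo error of a mean difference at sd 0.1, n ~ 127/group
        mc_se = 0.1 * np.sqrt(1 / 129 + 1 / 126)
        assert np.abs(diff).max() < 5 * mc_se

    def test_planted_shift_appears_in_group_means(self, cohort):
        exposed = cohort.samples["exposure"] == 1
        diff = (
            cohort.beta.loc[PLANTED_PROBE, exposed.to_numpy()].mean()
            - cohort.beta.loc[PLANTED_PROBE, (~exposed).to_numpy()].mean()
        )
        assert diff == pytest.approx(PLANTED_SHIFT, abs=0.05)

    def test_missing_covariate_rate_controls_missingness(self):
        ref = em.generate_celltype_reference(200, 6, seed=9)
        ds = em.generate_cohort(
            _null_config(missing_covariate_rate=0.03, n_exposed=500,
                         n_unexposed=500),
            ref,
        )
        frac = ds.samples["maternal_bmi"].isna().mean()
        assert frac == pytest.approx(0.03, abs=0.02)
        assert ds.samples["birthweight"].notna().all()

    def test_true_cell_proportions_form_a_simplex(self, cohort):
        props = cohort.truth["cell_proportions"].to_numpy()
        assert (props >= 0).all()
        np.testing.assert_allclose(props.sum(axis=1), 1.0, atol=1e-12)

    def test_clipping_is_rare_at_default_noise(self, cohort):
        assert cohort.truth["clipped_fraction"] < 0.01

    def test_cigarettes_only_for_exposed_with_stated_range(self, cohort):
        sheet = cohort.samples
        cigs = sheet["cigarettes_per_day"]
        assert cigs[sheet["exposure"] == 0].isna().all()
        exposed_cigs = cigs[sheet["exposure"] == 1]
        assert exposed_cigs.between(1, 30).all()
        assert 5 <= exposed_cigs.median() <= 15

    def test_outcome_carries_mediated_exposure_effect(self, cohort):
        # total effect ~ direct + shift * bb, visible in raw group means
        sheet = cohort.samples
        diff = (
            sheet.loc[sheet["exposure"] == 1, "birthweight"].mean()
            - sheet.loc[sheet["exposure"] == 0, "birthweight"].mean()
        )
        expected = -143.3 + PLANTED_SHIFT * PLANTED_BB
        assert diff == pytest.approx(expected, abs=150)

    def test_shift_outside_unit_interval_rejected(self, reference):
        cfg = _null_config(
            n_probes=300, true_cpg_effects={PLANTED_PROBE: -0.95}
        )
        with pytest.raises(ValueError, match="outside"):
            em.generate_cohort(cfg, reference)

    def test_probe_count_mismatch_rejected(self, reference):
        with pytest.raises(ValueError, match="probes"):
            em.generate_cohort(_null_config(n_probes=10), reference)

    def test_detection_failures_planted_for_failed_samples(self, cohort):
        failed = cohort.truth["failed_samples"]
        assert len(failed) == 1
        frac_called = (cohort.detection_p[failed[0]] < 0.05).mean()
        assert frac_called < 0.99


class TestMultiCohort:
    SHARED = {PLANTED_PROBE: (PLANTED_SHIFT, PLANTED_BB)}

    def test_three_cohorts_share_planted_effects(self, reference):
        configs = [
            _null_config(n_probes=300, n_exposed=65, n_unexposed=62, seed=1),
            _null_config(n_probes=300, n_exposed=65, n_unexposed=63, seed=2),
            _null_config(n_probes=300, n_exposed=55, n_unexposed=75, seed=3),
        ]
        cohorts = em.generate_multi_cohort(configs, self.SHARED, reference)
        assert len(cohorts) == 3
        for ds in cohorts:
            exposed = ds.samples["exposure"] == 1
            diff = (
                ds.beta.loc[PLANTED_PROBE, exposed.to_numpy()].mean()
                - ds.beta.loc[PLANTED_PROBE, (~exposed).to_numpy()].mean()
            )
            assert diff == pytest.approx(PLANTED_SHIFT, abs=0.08)

    def test_single_config_rejected(self, reference):
        with pytest.raises(ValueError, match="two"):
            em.generate_multi_cohort([_null_config(n_probes=300)], self.SHARED,
                                     reference)

    def test_mismatched_probe_sets_rejected(self, reference):
        configs = [_null_config(n_probes=300), _null_config(n_probes=200)]
        with pytest.raises(ValueError, match="mismatch"):
            em.generate_multi_cohort(configs, self.SHARED, reference)

    def test_identical_configs_and_seeds_identical_cohorts(self, reference):
        configs = [_null_config(n_probes=300, seed=4)] * 2
        a, b = em.generate_multi_cohort(configs, self.SHARED, reference)
        pd.testing.assert_frame_equal(a.beta, b.beta)


def test_config_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        em.SimulationConfig(n_exposed=0)
    with pytest.raises(ValueError):
        em.SimulationConfig(missing_covariate_rate=1.0)
    with pytest.raises(ValueError):
        em.SimulationConfig(n_probes=1, true_cpg_effects={"a": 0.1, "b": 0.2})
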