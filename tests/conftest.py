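import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ewasmed as em
from ewasmed.qc import default_annotation

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

#: lead planted CpG: beta shift (exposed - unexposed) and grams per unit beta
PLANTED_PROBE = "cg00000100"
PLANTED_SHIFT = -0.105
PLANTED_BB = 1190.0


@pytest.fixture(scope="session")
def reference():
    return em.generate_celltype_reference(300, 6, separation=0.3, seed=11)


@pytest.fixture(scope="session")
def cohort(reference):
    """129 exposed / 126 unexposed cohort with one planted mediating CpG."""
    cfg = em.SimulationConfig(
        n_probes=300,
        true_cpg_effects={PLANTED_PROBE: PLANTED_SHIFT},
        mediator_outcome_effects={PLANTED_PROBE: PLANTED_BB},
        n_failed_samples=1,
        seed=20,
    )
    return em.generate_cohort(cfg, reference)


@pytest.fixture(scope="session")
def annotation(cohort):
    return default_annotation(cohort.beta.index)


@pytest.fixture(scope="session")
def filtered(cohort, annotation):
    dataset, report = em.apply_qc(cohort, annotation)
    return dataset


@pytest.fixture(scope="session")
def proportions(filtered, reference):
    return em.estimate_cell_proportions(filtered.beta, reference)


@pytest.fixture(scope="session")
def null_ewas():
    """EWAS on a fully null cohort: no planted effects, no composition shift.

    10,000 probes so the p-value distribution can be tested for uniformity.
    """
    conc = em.simulate.DEFAULT_DIRICHLET["unexposed"]
    cfg = em.SimulationConfig(
        n_probes=10_000,
        dirichlet_concentrations={"unexposed": conc, "exposed": conc},
        missing_covariate_rate=0.0,
        detection_fail_rate=0.0,
        seed=77,
    )
    ref = em.generate_celltype_reference(10_000, 6, seed=78)
    dataset = em.generate_cohort(cfg, ref)
    props = em.estimate_cell_proportions(dataset.beta, ref)
    return em.run_ewas(dataset, props)
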