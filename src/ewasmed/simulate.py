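"""Synthetic methylation cohorts with cell-type confounding and a mediated outcome.

The generator emulates a two-group (exposed / unexposed) birth cohort
assayed on a beta-value methylation array:

* each sample's baseline methylation is a mixture ``reference @ proportions``
  of cell-type signature profiles, with the mixing proportions drawn from
  group-specific Dirichlet distributions (so cell composition confounds the
  exposure unless adjusted for);
* exposed samples receive planted beta-scale shifts at designated CpGs;
* a continuous outcome (birthweight, grams) is generated as
  ``intercept + direct_effect * exposure + sum(b_j * beta_j) + covariates + noise``
  so the exposure effect is partly mediated through the planted CpGs;
* detection p-values are near zero with configurable planted failures, to
  exercise the quality-control filters.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so identical configs give bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Leukocyte types of the default six-type blood reference.
DEFAULT_CELL_TYPES = ("Bcell", "Granulocyte", "Monocyte", "NK", "CD4T", "CD8T")

#: Group-specific Dirichlet concentrations (cord-blood-like, granulocyte
#: dominated).  The exposed group is shifted toward granulocytes and away
#: from T cells so that cell composition genuinely confounds the exposure.
DEFAULT_DIRICHLET = {
    "unexposed": (3.0, 30.0, 4.0, 2.0, 12.0, 6.0),
    "exposed": (3.0, 38.0, 4.0, 2.0, 8.0, 4.0),
}

_CLIP_TOL = 1e-9


@dataclass(frozen=True)
class CellTypeReferencePanel:
    """Mean-beta signature matrix, probes x cell types."""

    signature: pd.DataFrame
    discriminating_probes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = self.signature.to_numpy()
        if vals.size and (vals.min() < -_CLIP_TOL or vals.max() > 1 + _CLIP_TOL):
            raise ValueError("reference signature entries must lie in [0, 1]")

    @property
    def cell_type_names(self) -> list[str]:
        return list(self.signature.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.signature.index)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic cohort.

    Effect-size defaults follow the motivating study design: 129 exposed vs
    126 unexposed newborns, a planted methylation shift of -0.105 beta units
    at the lead mediating CpG, a mediator-to-outcome slope of 1190 g per unit
    beta, and a direct exposure effect of -143 g.
    """

    n_exposed: int = 129
    n_unexposed: int = 126
    n_probes: int = 1000
    true_cpg_effects: Mapping[str, float] = field(default_factory=dict)
    mediator_outcome_effects: Mapping[str, float] = field(default_factory=dict)
    direct_exposure_effect: float = -143.3
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "sex": 120.0,
            "gestational_age": 130.0,
            "maternal_bmi": 15.0,
            "maternal_age": 0.0,
            "education": 0.0,
        }
    )
    cell_type_count: int = 6
    dirichlet_concentrations: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_DIRICHLET)
    )
    noise_sd_beta: float = 0.1
    noise_sd_outcome: float = 420.0
    missing_covariate_rate: float = 0.02
    detection_fail_rate: float = 0.001
    n_failed_samples: int = 0
    include_paternal_smoking: bool = False
    mean_birthweight_unexposed: float = 3685.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_exposed", "n_unexposed", "n_probes", "cell_type_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_probes < len(self.true_cpg_effects):
            raise ValueError("n_probes must cover all keyed true effects")
        if not 0 <= self.missing_covariate_rate < 1:
            raise ValueError("missing_covariate_rate must be in [0, 1)")
        if not 0 <= self.detection_fail_rate < 1:
            raise ValueError("detection_fail_rate must be in [0, 1)")
        for group in ("exposed", "unexposed"):
            conc = np.asarray(self.dirichlet_concentrations[group], dtype=float)
            if conc.shape != (self.cell_type_count,) or (conc <= 0).any():
                raise ValueError(
                    f"dirichlet_concentrations[{group!r}] must be "
                    f"{self.cell_type_count} positive values"
                )


@dataclass
class CohortDataset:
    """Beta matrix, detection p matrix, sample sheet and (optionally) truth.

    ``beta`` and ``detection_p`` are probes x samples DataFrames with
    identical indexing; ``samples`` rows correspond one-to-one with the
    matrix columns.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    samples: pd.DataFrame
    truth: dict | None = None

    def validate(self) -> None:
        if not self.beta.index.equals(self.detection_p.index):
            raise ValueError("beta and detection_p probe indices differ")
        if not self.beta.columns.equals(self.detection_p.columns):
            raise ValueError("beta and detection_p sample columns differ")
        if not self.beta.columns.equals(self.samples.index):
            raise ValueError("sample sheet rows do not match beta columns")
        if not self.samples["exposure"].isin([0, 1]).all():
            raise ValueError("exposure must be binary 0/1")

    def subset(self, probes=None, samples=None) -> "CohortDataset":
        beta, detp, sheet = self.beta, self.detection_p, self.samples
        if probes is not None:
            beta = beta.loc[probes]
            detp = detp.loc[probes]
        if samples is not None:
            beta = beta[samples]
            detp = detp[samples]
            sheet = sheet.loc[samples]
        return CohortDataset(beta, detp, sheet, self.truth)


def _probe_ids(n_probes: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(n_probes)]


def generate_celltype_reference(
    n_probes: int,
    n_types: int = 6,
    separation: float = 0.3,
    seed: int = 0,
    n_discriminating: int | None = None,
) -> CellTypeReferencePanel:
    """Build a synthetic cell-type signature panel of full column rank.

    A designated subset of "discriminating" probes is near-dichotomous: one
    cell type sits ``separation`` above a low baseline, guaranteeing
    between-type spread >= ``separation`` and identifiable deconvolution.
    Remaining probes vary little across types.  This panel is synthetic; it
    plays the role a measured sorted-cell reference dataset plays on real
    arrays.
    """
    if n_probes <= 0 or n_types <= 0:
        raise ValueError("n_probes and n_types must be positive")
    if n_probes < n_types:
        raise ValueError("need at least as many probes as cell types")
    if not 0 < separation <= 1:
        raise ValueError("separation must be in (0, 1]")
    if n_discriminating is None:
        n_discriminating = min(n_probes, 10 * n_types)
    if not n_types <= n_discriminating <= n_probes:
        raise ValueError("n_discriminating must be in [n_types, n_probes]")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    # Baselines are kept away from the [0, 1] edges so that probe-level
    # noise at realistic levels rarely clips.
    low = min(0.2, (1 - separation) / 2)
    sig = np.empty((n_probes, n_types))

    # Discriminating block: probe i marks type i % n_types.  Low types are
    # jittered downward and the marked type upward, so the between-type
    # spread never falls below `separation`.
    jitter_scale = min(0.02, low, max(0.0, 1 - separation - low))
    for i in range(n_discriminating):
        t = i % n_types
        base = low - rng.uniform(0, jitter_scale, size=n_types)
        base[t] = low + separation + rng.uniform(0, jitter_scale)
        sig[i] = base
    # Non-discriminating block: common level, tiny between-type spread.
    n_rest = n_probes - n_discriminating
    if n_rest:
        level = rng.uniform(0.2, 0.8, size=(n_rest, 1))
        sig[n_discriminating:] = level + rng.normal(0, 0.002, size=(n_rest, n_types))
    sig = np.clip(sig, 0.0, 1.0)

    probes = _probe_ids(n_probes)
    panel = CellTypeReferencePanel(
        signature=pd.DataFrame(
            sig, index=probes, columns=list(DEFAULT_CELL_TYPES[:n_types])
            if n_types <= len(DEFAULT_CELL_TYPES)
            else [f"type{j}" for j in range(n_types)]
        ),
        discriminating_probes=tuple(probes[:n_discriminating]),
    )
    if np.linalg.matrix_rank(panel.signature.to_numpy()) < n_types:
        raise RuntimeError("generated reference is rank deficient")  # pragma: no cover
    return panel


def _draw_cigarettes(rng: np.random.Generator, n: int) -> np.ndarray:
    """Cigarettes/day for exposed mothers: discrete, median ~10, range 1-30."""
    raw = np.rint(rng.lognormal(mean=np.log(10.0), sigma=0.55, size=n))
    return np.clip(raw, 1, 30).astype(int)


def _expected_beta_check(reference, config) -> None:
    """Planted shifts must keep expected betas inside [0, 1]."""
    mean_props = {}
    for group in ("exposed", "unexposed"):
        conc = np.asarray(config.dirichlet_concentrations[group], dtype=float)
        mean_props[group] = conc / conc.sum()
    sig = reference.signature
    for probe, shift in config.true_cpg_effects.items():
        base = float(sig.loc[probe].to_numpy() @ mean_props["exposed"])
        shifted = base + shift
        if shifted < -_CLIP_TOL or shifted > 1 + _CLIP_TOL:
            raise ValueError(
                f"planted effect {shift:+.3f} at {probe} pushes expected beta "
                f"to {shifted:.3f}, outside [0, 1]"
            )


def generate_cohort(
    config: SimulationConfig, reference: CellTypeReferencePanel
) -> CohortDataset:
    """Generate one cohort under ``config`` using ``reference`` signatures.

    Returns a :class:`CohortDataset` whose ``truth`` record stores the true
    per-sample cell proportions and every generative parameter, for use as a
    recovery oracle in tests.
    """
    sig = reference.signature
    if sig.shape[0] != config.n_probes:
        raise ValueError(
            f"reference has {sig.shape[0]} probes but config.n_probes="
            f"{config.n_probes}"
        )
    if sig.shape[1] != config.cell_type_count:
        raise ValueError("reference cell-type count does not match config")
    missing = [p for p in config.true_cpg_effects if p not in sig.index]
    missing += [p for p in config.mediator_outcome_effects if p not in sig.index]
    if missing:
        raise ValueError(f"effect probes not in reference: {sorted(set(missing))}")
    _expected_beta_check(reference, config)

    ss = np.random.SeedSequence(config.seed)
    (s_props, s_noise, s_cov, s_out, s_det, s_miss) = [
        np.random.default_rng(c) for c in ss.spawn(6)
    ]

    n_un, n_ex = config.n_unexposed, config.n_exposed
    n = n_un + n_ex
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    exposure = np.concatenate([np.zeros(n_un, dtype=int), np.ones(n_ex, dtype=int)])

    # --- true cell proportions and baseline betas -----------------------
    conc_un = np.asarray(config.dirichlet_concentrations["unexposed"], float)
    conc_ex = np.asarray(config.dirichlet_concentrations["exposed"], float)
    props = np.vstack(
        [s_props.dirichlet(conc_un, size=n_un), s_props.dirichlet(conc_ex, size=n_ex)]
    )  # n x types
    beta = sig.to_numpy() @ props.T  # probes x n

    probe_index = sig.index
    for probe, shift in config.true_cpg_effects.items():
        i = probe_index.get_loc(probe)
        beta[i, exposure == 1] += shift

    beta_noisy = beta + s_noise.normal(0.0, config.noise_sd_beta, size=beta.shape)
    clipped = (beta_noisy < 0) | (beta_noisy > 1)
    beta_noisy = np.clip(beta_noisy, 0.0, 1.0)

    # --- covariates (group-specific distributions) ----------------------
    def per_group(unexposed_draw, exposed_draw):
        return np.concatenate([unexposed_draw(n_un), exposed_draw(n_ex)])

    sex = per_group(
        lambda k: (s_cov.random(k) < 0.524).astype(int),
        lambda k: (s_cov.random(k) < 0.543).astype(int),
    )
    gest_age = per_group(
        lambda k: s_cov.normal(39.8, 1.2, k), lambda k: s_cov.normal(39.7, 1.3, k)
    )
    maternal_age = per_group(
        lambda k: s_cov.normal(31.1, 3.6, k), lambda k: s_cov.normal(29.7, 4.7, k)
    )
    maternal_bmi = per_group(
        lambda k: s_cov.normal(23.9, 3.3, k), lambda k: s_cov.normal(24.9, 5.1, k)
    )
    education = per_group(  # 1 = university
        lambda k: (s_cov.random(k) < 0.444).astype(int),
        lambda k: (s_cov.random(k) < 0.186).astype(int),
    )
    plate = np.array([f"P{(i % 3) + 1}" for i in s_cov.permutation(n)])
    cigarettes = np.full(n, np.nan)
    cigarettes[exposure == 1] = _draw_cigarettes(s_cov, n_ex)

    # --- outcome ---------------------------------------------------------
    cov_values = {
        "sex": sex,
        "gestational_age": gest_age,
        "maternal_age": maternal_age,
        "maternal_bmi": maternal_bmi,
        "education": education,
    }
    lin = np.zeros(n)
    for name, eff in config.covariate_effects.items():
        if name not in cov_values:
            raise ValueError(f"unknown covariate effect: {name}")
        lin += eff * cov_values[name]
    mediated = np.zeros(n)
    for probe, bb in config.mediator_outcome_effects.items():
        mediated += bb * beta_noisy[probe_index.get_loc(probe), :]

    # Anchor the unexposed-group expectation at mean_birthweight_unexposed.
    unexp = exposure == 0
    intercept = config.mean_birthweight_unexposed - np.mean(
        (lin + mediated)[unexp]
    )
    birthweight = (
        intercept
        + config.direct_exposure_effect * exposure
        + mediated
        + lin
        + s_out.normal(0.0, config.noise_sd_outcome, size=n)
    )

    # --- detection p-values ---------------------------------------------
    detp = s_det.uniform(0.0, 0.01, size=beta_noisy.shape)
    if config.detection_fail_rate > 0:
        fails = s_det.random(beta_noisy.shape) < config.detection_fail_rate
        detp[fails] = s_det.uniform(0.05, 1.0, size=int(fails.sum()))
    failed_samples: list[str] = []
    if config.n_failed_samples > 0:
        idx = s_det.choice(n, size=config.n_failed_samples, replace=False)
        for j in idx:
            # fail 2% of probes: well below the 99% call-rate criterion
            bad = s_det.random(config.n_probes) < 0.02
            detp[bad, j] = s_det.uniform(0.05, 1.0, size=int(bad.sum()))
            failed_samples.append(sample_ids[j])

    # --- sample sheet with planted missingness ---------------------------
    sheet = pd.DataFrame(
        {
            "exposure": exposure,
            "birthweight": birthweight,
            "sex": sex,
            "gestational_age": gest_age,
            "maternal_age": maternal_age,
            "maternal_bmi": maternal_bmi,
            "education": education.astype(float),
            "plate": plate,
            "cigarettes_per_day": cigarettes,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if config.include_paternal_smoking:
        pat = np.zeros(n, dtype=int)
        pat[exposure == 1] = (s_cov.random(n_ex) < 0.30).astype(int)
        sheet["paternal_smoking"] = pat
    missing_mask = {}
    if config.missing_covariate_rate > 0:
        for col in ("gestational_age", "maternal_bmi", "education"):
            mask = s_miss.random(n) < config.missing_covariate_rate
            sheet.loc[mask, col] = np.nan
            missing_mask[col] = [s for s, m in zip(sample_ids, mask) if m]

    truth = {
        "config": dataclasses.asdict(config),
        "intercept": float(intercept),
        "cell_proportions": pd.DataFrame(
            props, index=sheet.index, columns=reference.cell_type_names
        ),
        "clipped_fraction": float(clipped.mean()),
        "failed_samples": failed_samples,
        "missing_covariates": missing_mask,
    }
    dataset = CohortDataset(
        beta=pd.DataFrame(beta_noisy, index=probe_index, columns=sheet.index),
        detection_p=pd.DataFrame(detp, index=probe_index, columns=sheet.index),
        samples=sheet,
        truth=truth,
    )
    dataset.validate()
    return dataset


def generate_multi_cohort(
    configs: Sequence[SimulationConfig],
    shared_truth: Mapping[str, tuple[float, float]],
    reference: CellTypeReferencePanel | None = None,
) -> list[CohortDataset]:
    """Generate several cohorts sharing true effects at the same probes.

    ``shared_truth`` maps probe id -> (beta-scale shift, outcome slope in
    grams per unit beta).  Cohorts may differ in size, noise and covariate
    structure but share the planted effects, emulating a discovery +
    replication design.
    """
    if len(configs) < 2:
        raise ValueError("need at least two cohort configs")
    n_probes = {c.n_probes for c in configs}
    if len(n_probes) != 1:
        raise ValueError("mismatched probe sets: all configs must share n_probes")
    if reference is None:
        reference = generate_celltype_reference(
            configs[0].n_probes, configs[0].cell_type_count, seed=configs[0].seed
        )
    for probe in shared_truth:
        if probe not in reference.signature.index:
            raise ValueError(f"shared probe {probe} not in reference panel")

    cohorts = []
    for cfg in configs:
        cfg = dataclasses.replace(
            cfg,
            true_cpg_effects={p: s for p, (s, _) in shared_truth.items()},
            mediator_outcome_effects={p: b for p, (_, b) in shared_truth.items()},
        )
        cohorts.append(generate_cohort(cfg, reference))
    return cohorts
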