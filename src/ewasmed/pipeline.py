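"""End-to-end orchestration: simulate -> qc -> celltype -> ewas -> mediate -> meta.

Every stage writes its table under the configured output directory and
the run ends with a JSON manifest (package version, seed, row/column
counts per stage, thresholds, output file hashes) sufficient to re-run
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .celltype import estimate_cell_proportions, select_discriminating_probes
from .ewas import DEFAULT_COVARIATES, descriptive_table, run_ewas
from .mediation import mediation_table
from .meta import CohortEffect, fixed_effects_meta, meta_mediation
from .qc import QcThresholds, apply_qc, default_annotation
from .simulate import (
    SimulationConfig,
    generate_celltype_reference,
    generate_cohort,
    generate_multi_cohort,
)


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML via :meth:`from_yaml`."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    # simulation (ignored when beta_path is given)
    n_exposed: int = 129
    n_unexposed: int = 126
    n_probes: int = 1000
    planted_effects: dict = field(
        default_factory=lambda: {"cg00000000": [-0.105, 1190.0]}
    )
    direct_exposure_effect: float = -143.3
    noise_sd_beta: float = 0.1
    n_failed_samples: int = 1
    # optional file inputs instead of simulation
    beta_path: str | None = None
    detection_p_path: str | None = None
    samples_path: str | None = None
    annotation_path: str | None = None
    reference_path: str | None = None
    # analysis settings
    qc: QcThresholds = field(default_factory=QcThresholds)
    covariates: tuple = DEFAULT_COVARIATES
    n_discriminating_probes: int = 100
    cell_correction: bool = True
    sensitivity_no_cells: bool = False
    mediation_probes: list | None = None  # default: planted / top-FDR probes
    # replication cohorts to simulate and meta-analyse: list of [n_exp, n_unexp]
    replication_sizes: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "qc" in raw and isinstance(raw["qc"], dict):
            raw["qc"] = QcThresholds(**raw["qc"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _simulation_config(cfg: PipelineConfig, seed: int, sizes=None) -> SimulationConfig:
    n_exp, n_unexp = sizes if sizes else (cfg.n_exposed, cfg.n_unexposed)
    return SimulationConfig(
        n_exposed=n_exp,
        n_unexposed=n_unexp,
        n_probes=cfg.n_probes,
        true_cpg_effects={p: v[0] for p, v in cfg.planted_effects.items()},
        mediator_outcome_effects={p: v[1] for p, v in cfg.planted_effects.items()},
        direct_exposure_effect=cfg.direct_exposure_effect,
        noise_sd_beta=cfg.noise_sd_beta,
        n_failed_samples=cfg.n_failed_samples,
        seed=seed,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    def stage(name):
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    try:
        # ---- input: simulate or load --------------------------------
        info = stage("input")
        if config.beta_path:
            dataset = io.read_cohort(Path(config.beta_path).parent)
            annotation = (
                io.read_annotation(config.annotation_path)
                if config.annotation_path
                else default_annotation(dataset.beta.index)
            )
            reference = (
                io.read_reference(config.reference_path)
                if config.reference_path
                else None
            )
            info["mode"] = "files"
        else:
            reference = generate_celltype_reference(
                config.n_probes, seed=config.seed
            )
            dataset = generate_cohort(
                _simulation_config(config, config.seed), reference
            )
            annotation = default_annotation(
                dataset.beta.index, n_control=0, n_sex=0
            )
            io.write_cohort(dataset, out / "cohort")
            io.write_reference(reference, out / "reference.tsv")
            info["mode"] = "simulate"
        info["n_probes"], info["n_samples"] = dataset.beta.shape
    except Exception as exc:
        raise PipelineError("input", exc) from exc

    try:
        # ---- qc ------------------------------------------------------
        filtered, report = apply_qc(dataset, annotation, config.qc)
        stage("qc").update(report)
        with open(out / "qc_report.json", "w") as fh:
            json.dump(report, fh, indent=1)
    except Exception as exc:
        raise PipelineError("qc", exc) from exc

    try:
        # ---- cell-type proportions ----------------------------------
        props = None
        if config.cell_correction:
            if reference is None:
                raise ValueError("cell correction requested but no reference panel")
            ref_avail = dataclasses.replace(
                reference,
                signature=reference.signature.loc[
                    reference.signature.index.intersection(filtered.beta.index)
                ],
            )
            k = min(config.n_discriminating_probes, ref_avail.signature.shape[0])
            probes = select_discriminating_probes(ref_avail, k)
            props = estimate_cell_proportions(filtered.beta, ref_avail, probes)
            props.to_csv(out / "cell_proportions.csv", index_label="sample_id")
            stage("celltype")["n_discriminating_probes"] = k
    except Exception as exc:
        raise PipelineError("celltype", exc) from exc

    try:
        # ---- descriptives & ewas ------------------------------------
        desc = descriptive_table(filtered)
        io.write_results(desc, out / "descriptives.tsv")
        ewas_res = run_ewas(filtered, props, config.covariates)
        io.write_results(ewas_res, out / "ewas.tsv")
        stage("ewas").update(
            {
                "n_tested": int(len(ewas_res)),
                "n_fdr05": int((ewas_res["q"] < 0.05).sum()),
                "n_bonferroni": int(ewas_res["bonferroni_significant"].sum()),
            }
        )
        if config.sensitivity_no_cells and props is not None:
            no_cells = run_ewas(filtered, None, config.covariates)
            io.write_results(no_cells, out / "ewas_no_cell_correction.tsv")
            stage("ewas_no_cell_correction")["n_fdr05"] = int(
                (no_cells["q"] < 0.05).sum()
            )
    except Exception as exc:
        raise PipelineError("ewas", exc) from exc

    try:
        # ---- mediation ----------------------------------------------
        probes = config.mediation_probes
        if probes is None:
            planted = [
                p for p in config.planted_effects if p in filtered.beta.index
            ]
            probes = planted or list(ewas_res.sort_values("p").head(3).index)
        med = mediation_table(filtered, props, probes, config.covariates)
        io.write_results(med, out / "mediation.tsv")
        stage("mediation")["n_probes"] = len(probes)
    except Exception as exc:
        raise PipelineError("mediation", exc) from exc

    try:
        # ---- replication + meta -------------------------------------
        if config.replication_sizes:
            shared = {
                p: (v[0], v[1]) for p, v in config.planted_effects.items()
            }
            configs = [_simulation_config(config, config.seed)] + [
                _simulation_config(config, config.seed + 1 + i, sizes=tuple(sz))
                for i, sz in enumerate(config.replication_sizes)
            ]
            cohorts = generate_multi_cohort(configs, shared, reference)
            rows = []
            for label, cohort in zip(
                ["discovery"]
                + [f"replication{i + 1}" for i in range(len(cohorts) - 1)],
                cohorts,
            ):
                c_filt, _ = apply_qc(
                    cohort, default_annotation(cohort.beta.index), config.qc
                )
                c_props = (
                    estimate_cell_proportions(c_filt.beta, reference)
                    if config.cell_correction
                    else None
                )
                c_ewas = run_ewas(c_filt, c_props, config.covariates)
                c_med = mediation_table(
                    c_filt, c_props, list(shared), config.covariates
                )
                for p in shared:
                    rows.append(
                        {
                            "cohort": label,
                            "probe_id": p,
                            "effect": c_ewas.loc[p, "coefficient"],
                            "se": c_ewas.loc[p, "se"],
                            "delta": c_med.loc[p, "delta"],
                            "sobel_p": c_med.loc[p, "sobel_p"],
                        }
                    )
            per_cohort = pd.DataFrame(rows)
            io.write_results(per_cohort.set_index("cohort"), out / "cohort_effects.tsv")
            meta_rows = []
            for p in shared:
                sub = per_cohort[per_cohort["probe_id"] == p]
                ew = fixed_effects_meta(
                    [
                        CohortEffect(r["cohort"], r["effect"], se=r["se"])
                        for _, r in sub.iterrows()
                    ]
                )
                md = meta_mediation(
                    [
                        (r["cohort"], r["delta"], r["sobel_p"])
                        for _, r in sub.iterrows()
                    ]
                )
                meta_rows.append(
                    {
                        "probe_id": p,
                        "pooled_effect": ew.effect,
                        "pooled_se": ew.se,
                        "pooled_p": ew.p,
                        "pooled_delta": md.effect,
                        "pooled_delta_p": md.p,
                        "k": ew.k,
                    }
                )
            io.write_results(
                pd.DataFrame(meta_rows).set_index("probe_id"), out / "meta.tsv"
            )
            stage("meta")["k_cohorts"] = len(cohorts)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("meta", exc) from exc

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")
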