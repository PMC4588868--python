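"""Sample/probe quality filters and single-value covariate imputation.

Filtering conventions: a measurement is *called* when its detection
p-value is strictly below the cutoff (default 0.05); a sample is retained
when at least ``sample_probe_fraction`` (default 99%) of its probes are
called, and — after sample filtering — a probe is retained when it is
called in at least ``probe_sample_fraction`` of the retained samples, is
not a control probe, and does not map to a sex chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import CohortDataset

SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY"}
ANNOTATION_COLUMNS = ["probe_id", "chromosome", "gene", "probe_class"]


@dataclass(frozen=True)
class QcThresholds:
    detection_p_cutoff: float = 0.05
    sample_probe_fraction: float = 0.99
    probe_sample_fraction: float = 0.99

    def __post_init__(self) -> None:
        for name in (
            "detection_p_cutoff",
            "sample_probe_fraction",
            "probe_sample_fraction",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


def filter_samples_by_detection(
    detection_p: pd.DataFrame, thresholds: QcThresholds = QcThresholds()
) -> tuple[list[str], list[str]]:
    """Split samples into (kept, dropped) by per-sample probe call rate.

    A sample is kept iff the fraction of its probes with detection p
    strictly below the cutoff is >= ``sample_probe_fraction``; input column
    order is preserved in both lists.
    """
    if detection_p.size == 0:
        raise ValueError("detection_p matrix is empty")
    called = (detection_p.to_numpy() < thresholds.detection_p_cutoff).mean(axis=0)
    keep = called >= thresholds.sample_probe_fraction
    cols = list(detection_p.columns)
    kept = [c for c, k in zip(cols, keep) if k]
    dropped = [c for c, k in zip(cols, keep) if not k]
    return kept, dropped


def filter_probes(
    detection_p: pd.DataFrame,
    annotation: pd.DataFrame,
    thresholds: QcThresholds = QcThresholds(),
) -> list[str]:
    """Probes passing class, chromosome and detection criteria.

    ``annotation`` must cover every probe in ``detection_p`` and carry
    columns ``probe_id``, ``chromosome``, ``gene``, ``probe_class``.  The
    detection fraction is computed over the samples present in the passed
    matrix, so sample filtering should be applied first.
    """
    if detection_p.size == 0:
        raise ValueError("detection_p matrix is empty")
    annot = annotation.set_index("probe_id") if "probe_id" in annotation else annotation
    missing = detection_p.index.difference(annot.index)
    if len(missing):
        raise KeyError(f"probes missing from annotation: {list(missing[:5])}")
    annot = annot.reindex(detection_p.index)

    not_control = ~annot["probe_class"].astype(str).str.lower().eq("control")
    autosomal = ~annot["chromosome"].astype(str).isin(SEX_CHROMOSOMES)
    called = (detection_p.to_numpy() < thresholds.detection_p_cutoff).mean(axis=1)
    detected = called >= thresholds.probe_sample_fraction
    keep = not_control.to_numpy() & autosomal.to_numpy() & detected
    return [p for p, k in zip(detection_p.index, keep) if k]


def impute_covariates(
    samples: pd.DataFrame, rules: dict[str, str]
) -> pd.DataFrame:
    """Fill missing covariate entries with the column mean or median.

    ``rules`` maps covariate name to ``"mean"`` or ``"median"``.  The
    statistic is computed over non-missing values of the full sheet; a
    boolean ``<covariate>_imputed`` provenance column is added for each
    covariate that had missing entries.  Non-missing entries are never
    altered; a sheet with nothing to impute is returned unchanged.
    """
    out = samples
    for cov, rule in rules.items():
        if cov not in samples.columns:
            raise KeyError(f"covariate {cov!r} not in sample sheet")
        col = samples[cov]
        miss = col.isna()
        if not miss.any():
            continue
        if miss.all():
            raise ValueError(f"covariate {cov!r} is entirely missing")
        if rule == "mean":
            value = col.mean()
        elif rule == "median":
            value = col.median()
        else:
            raise ValueError(f"unknown imputation rule {rule!r} for {cov!r}")
        if out is samples:
            out = samples.copy()
        out[cov] = col.fillna(value)
        out[f"{cov}_imputed"] = miss
    return out


DEFAULT_IMPUTATION_RULES = {
    "gestational_age": "mean",
    "maternal_age": "mean",
    "maternal_bmi": "mean",
    "education": "median",
}


def apply_qc(
    dataset: CohortDataset,
    annotation: pd.DataFrame,
    thresholds: QcThresholds = QcThresholds(),
    imputation_rules: dict[str, str] | None = None,
) -> tuple[CohortDataset, dict]:
    """Run sample filter, then probe filter, then covariate imputation.

    Returns the filtered dataset and a QC report (thresholds used, ids and
    counts dropped at each step).
    """
    kept_samples, dropped_samples = filter_samples_by_detection(
        dataset.detection_p, thresholds
    )
    if not kept_samples:
        raise ValueError("all samples failed detection QC")
    detp = dataset.detection_p[kept_samples]
    kept_probes = filter_probes(detp, annotation, thresholds)
    filtered = dataset.subset(probes=kept_probes, samples=kept_samples)
    rules = DEFAULT_IMPUTATION_RULES if imputation_rules is None else imputation_rules
    rules = {c: r for c, r in rules.items() if c in filtered.samples.columns}
    filtered.samples = impute_covariates(filtered.samples, rules)
    report = {
        "thresholds": {
            "detection_p_cutoff": thresholds.detection_p_cutoff,
            "sample_probe_fraction": thresholds.sample_probe_fraction,
            "probe_sample_fraction": thresholds.probe_sample_fraction,
        },
        "n_samples_in": int(dataset.detection_p.shape[1]),
        "n_samples_kept": len(kept_samples),
        "dropped_samples": dropped_samples,
        "n_probes_in": int(dataset.detection_p.shape[0]),
        "n_probes_kept": len(kept_probes),
        "n_probes_dropped": int(dataset.detection_p.shape[0]) - len(kept_probes),
        "imputed": {
            c: int(filtered.samples[f"{c}_imputed"].sum())
            for c in rules
            if f"{c}_imputed" in filtered.samples.columns
        },
    }
    return filtered, report


def default_annotation(
    probe_ids,
    n_control: int = 0,
    n_sex: int = 0,
    genes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Autosomal assay-probe annotation for synthetic panels.

    The first ``n_control`` probes are marked control class and the next
    ``n_sex`` are placed on the X chromosome, so both exclusion rules can
    be exercised on generated data.
    """
    probe_ids = list(probe_ids)
    n = len(probe_ids)
    chrom = [str((i % 22) + 1) for i in range(n)]
    klass = ["assay"] * n
    for i in range(min(n_control, n)):
        klass[i] = "control"
    for i in range(n_control, min(n_control + n_sex, n)):
        chrom[i] = "X"
    gene_col = [(genes or {}).get(p, "") for p in probe_ids]
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": chrom,
            "gene": gene_col,
            "probe_class": klass,
        }
    )
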