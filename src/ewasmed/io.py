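"""Flat-file layouts for cohorts, references, annotations and results.

* beta / detection-p matrices: TSV, probes as rows, header = sample ids,
  index column ``probe_id``;
* sample sheet: CSV indexed by ``sample_id``, missing values as empty fields;
* probe annotation: TSV with columns probe_id, chromosome, gene, probe_class;
* reference panel: TSV, probes x cell types, header = type names;
* result tables: TSV indexed by probe_id.

Floats are written at full round-trip precision, so write followed by
read is the identity for finite values.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pandas.errors import ParserError

from .qc import ANNOTATION_COLUMNS
from .simulate import CellTypeReferencePanel, CohortDataset


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id", float_format="%.17g")


def read_matrix(path) -> pd.DataFrame:
    df = _read(path, sep="\t")
    if "probe_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'probe_id'")
    return df.set_index("probe_id")


def _read(path, sep) -> pd.DataFrame:
    try:
        # round_trip parsing so write/read is the identity to the last ulp
        return pd.read_csv(path, sep=sep, float_precision="round_trip")
    except ParserError as exc:  # pandas reports the offending line number
        raise ValueError(f"{path}: malformed table: {exc}") from exc


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index_label="sample_id", float_format="%.17g")


def read_samples(path) -> pd.DataFrame:
    df = _read(path, sep=",")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sample_id'")
    df = df.set_index("sample_id")
    required = {"exposure"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    df = _read(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df


def write_reference(reference: CellTypeReferencePanel, path) -> None:
    reference.signature.to_csv(path, sep="\t", index_label="probe_id", float_format="%.17g")


def read_reference(path) -> CellTypeReferencePanel:
    return CellTypeReferencePanel(signature=read_matrix(path))


def write_cohort(dataset: CohortDataset, outdir) -> dict[str, str]:
    """Write beta.tsv, detection_p.tsv, samples.csv (+ truth.json) to outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": str(outdir / "beta.tsv"),
        "detection_p": str(outdir / "detection_p.tsv"),
        "samples": str(outdir / "samples.csv"),
    }
    write_matrix(dataset.beta, paths["beta"])
    write_matrix(dataset.detection_p, paths["detection_p"])
    write_samples(dataset.samples, paths["samples"])
    if dataset.truth is not None:
        truth = {
            k: v for k, v in dataset.truth.items() if k != "cell_proportions"
        }
        props = dataset.truth.get("cell_proportions")
        if props is not None:
            truth["cell_proportions"] = {
                "index": list(props.index),
                "columns": list(props.columns),
                "values": props.to_numpy().tolist(),
            }
        paths["truth"] = str(outdir / "truth.json")
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=1, default=_jsonable)
    return paths


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def read_cohort(indir) -> CohortDataset:
    indir = Path(indir)
    beta = read_matrix(indir / "beta.tsv")
    detp = read_matrix(indir / "detection_p.tsv")
    samples = read_samples(indir / "samples.csv")
    truth = None
    truth_path = indir / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)
        props = truth.get("cell_proportions")
        if props is not None:
            truth["cell_proportions"] = pd.DataFrame(
                props["values"], index=props["index"], columns=props["columns"]
            )
    ds = CohortDataset(beta=beta, detection_p=detp, samples=samples, truth=truth)
    ds.validate()
    return ds


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", float_format="%.17g")


def read_cohort_effects(path) -> pd.DataFrame:
    """Cohort-results table for meta-analysis: cohort, probe, effect, se, p."""
    df = _read(path, sep="\t")
    missing = {"cohort", "probe_id", "effect"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df
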