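"""Delimited-text readers and writers for trial data, truth sidecars and configs.

All exchange formats are UTF-8 CSV with a header row, '.' decimals, and empty
strings as missing markers — the domain's norm for plot-level trial data.
Ground truth travels in a JSON sidecar so the text round trip is exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import DESIGN_COLUMNS, GroundTruth, TrialDataset

__all__ = [
    "read_trial",
    "write_trial",
    "read_truth",
    "write_truth",
    "load_yaml_config",
]

MANDATORY = ["study", "environment", "replication", "genotype", "treatment", "seed_yield"]


def write_trial(dataset: TrialDataset, path: str | Path, truth_path: str | Path | None = None) -> None:
    """Write plot records as CSV (missing cells empty); truth to a JSON sidecar."""
    path = Path(path)
    dataset.records.to_csv(path, index=False, float_format="%.10g")
    if truth_path is not None and dataset.truth is not None:
        write_truth(dataset.truth, truth_path)


def read_trial(path: str | Path, truth_path: str | Path | None = None) -> TrialDataset:
    """Read plot records; malformed numeric cells are reported with line numbers.

    A missing mandatory column raises, naming it; empty trait cells become
    missing markers (NaN), never zero.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in MANDATORY:
        if col not in df.columns:
            raise ValueError(f"mandatory column {col!r} missing from {path}")
    numeric_cols = [c for c in df.columns if c not in MANDATORY[:5]]
    out = df.copy()
    for col in numeric_cols:
        raw = df[col].mask(df[col] == "")
        vals = pd.to_numeric(raw, errors="coerce")
        bad = raw.notna() & vals.isna()
        if bad.any():
            lines = [int(i) + 2 for i in df.index[bad][:5]]  # +2: header + 1-based
            raise ValueError(f"non-numeric value in column {col!r} at line(s) {lines} of {path}")
        out[col] = vals
    if out["seed_yield"].isna().any():
        n = int(out["seed_yield"].isna().sum())
        raise ValueError(f"{n} rows with missing seed_yield in {path}; yield must be present or the rows dropped")
    truth = read_truth(truth_path) if truth_path is not None and Path(truth_path).exists() else None
    return TrialDataset(out, truth)


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "genotype_effects": truth.genotype_effects,
        "shifted_genotypes": truth.shifted_genotypes,
        "true_fit_classes": truth.true_fit_classes,
        "dg_shift": truth.dg_shift,
        "missing_mask": [[r, c] for r, c in truth.missing_mask],
        "outlier_mask": [[r, c, s] for r, c, s in truth.outlier_mask],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        genotype_effects=payload.get("genotype_effects", {}),
        shifted_genotypes=payload.get("shifted_genotypes", {}),
        true_fit_classes=payload.get("true_fit_classes", {}),
        dg_shift=payload.get("dg_shift", {}),
        missing_mask=[(int(r), str(c)) for r, c in payload.get("missing_mask", [])],
        outlier_mask=[(int(r), str(c), float(s)) for r, c, s in payload.get("outlier_mask", [])],
    )


def load_yaml_config(path: str | Path) -> dict:
    """Load a YAML run configuration as a plain mapping (validated downstream)."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} must contain a mapping")
    return data


def trait_matrix(dataset: TrialDataset) -> pd.DataFrame:
    """The predictor-trait matrix of a dataset (design and yield columns dropped)."""
    return dataset.records[[c for c in dataset.records.columns if c not in DESIGN_COLUMNS]]
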