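"""Readers and writers for the pipeline's tabular and JSON artifacts.

Feature tables and metadata travel as tab-separated text; panels and
validation reports as JSON; run configuration as YAML. Missing measurements
are empty cells on disk and NaN in memory — I/O is lossless and imputation
happens only inside the normalizer.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .core import (
    FeatureMatrix,
    FormatError,
    Panel,
    PipelineConfig,
    SampleRecord,
)

logger = logging.getLogger(__name__)

_SUBSCALES = ("reexperiencing", "avoidance", "hyperarousal")


def read_feature_matrix(path: str | Path, type_map_path: str | Path) -> FeatureMatrix:
    """Read a samples x features TSV plus a two-column feature->type map.

    First column of the table is the sample id; the header row carries
    feature ids. Unparseable cells become missing (NaN). Duplicate ids or a
    feature absent from the type map raise :class:`FormatError`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    values = df.apply(pd.to_numeric, errors="coerce")

    tm = pd.read_csv(type_map_path, sep="\t", dtype=str)
    if tm.shape[1] < 2:
        raise FormatError(
            f"type map {type_map_path} must have two columns (feature_id, type)"
        )
    fcol, tcol = tm.columns[:2]
    feature_types = {
        str(f).strip(): str(t).strip()
        for f, t in zip(tm[fcol], tm[tcol])
    }
    missing = [f for f in values.columns if f not in feature_types]
    if missing:
        raise FormatError(
            f"features in {path} absent from type map: {missing}"
        )
    types = {f: feature_types[f] for f in values.columns}
    return FeatureMatrix(values=values, feature_types=types)


def write_feature_matrix(
    fm: FeatureMatrix, path: str | Path, type_map_path: str | Path
) -> None:
    fm.values.to_csv(path, sep="\t", index_label="sample_id", na_rep="")
    tm = pd.DataFrame(
        {"feature_id": fm.feature_ids,
         "type": [fm.feature_types[f] for f in fm.feature_ids]}
    )
    tm.to_csv(type_map_path, sep="\t", index=False)


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read one :class:`SampleRecord` per row from a TSV.

    Expected columns: sample_id, subject_id, cohort, label, caps_total,
    caps_reexperiencing, caps_avoidance, caps_hyperarousal, ethnicity, mdd,
    timepoint. Label/CAPS consistency is enforced on construction.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        logger.warning("metadata file %s is empty", path)
        return []
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample ids in metadata: {dups}")
    records = []
    for _, row in df.iterrows():
        subscales = {
            s: float(row[f"caps_{s}"])
            for s in _SUBSCALES
            if f"caps_{s}" in row and pd.notna(row[f"caps_{s}"])
        }
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]).strip(),
                subject_id=str(row["subject_id"]).strip(),
                cohort=str(row["cohort"]).strip(),
                label=str(row["label"]).strip(),
                caps_total=float(row["caps_total"]),
                caps_subscales=subscales,
                ethnicity=str(row.get("ethnicity", "unknown")).strip(),
                mdd=str(row.get("mdd", "False")).strip().lower()
                in ("true", "1", "yes"),
                timepoint=str(row.get("timepoint", "T0")).strip(),
            )
        )
    return records


def write_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "subject_id": r.subject_id,
            "cohort": r.cohort,
            "label": r.label,
            "caps_total": r.caps_total,
            "ethnicity": r.ethnicity,
            "mdd": r.mdd,
            "timepoint": r.timepoint,
        }
        for s in _SUBSCALES:
            if s in r.caps_subscales:
                row[f"caps_{s}"] = r.caps_subscales[s]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_panel(panel: Panel, path: str | Path) -> None:
    doc = {
        "stage": panel.stage,
        "feature_ids": panel.feature_ids,
        "provenance": {f: sorted(panel.provenance[f]) for f in panel.feature_ids},
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_panel(path: str | Path) -> Panel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed panel file {path}: {exc}") from exc
    for key in ("stage", "feature_ids", "provenance"):
        if key not in doc:
            raise FormatError(f"panel file {path} missing key {key!r}")
    return Panel(
        feature_ids=list(doc["feature_ids"]),
        provenance={f: set(v) for f, v in doc["provenance"].items()},
        stage=doc["stage"],
    )


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json(doc: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_to_jsonable(doc), indent=2) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def read_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML mapping (unknown keys rejected)."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise FormatError(f"config {path} must be a YAML mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**doc)
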