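"""Shared domain types for the biomarker discovery pipeline.

The pipeline operates on three linked case-control cohorts of combat-exposed
veterans: a *discovery* cohort used to nominate candidate biomarkers, a
*recall* cohort (re-assessed discovery participants, some with changed
symptom status) used for panel down-selection, and an independent
*validation* cohort used once for final evaluation.

Feature data live in a :class:`FeatureMatrix` (samples x features, each
feature annotated with its molecular data type); participant-visit metadata
live in :class:`SampleRecord`; ordered marker sets with selector provenance
live in :class:`Panel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

COHORTS = ("discovery", "recall", "validation")
LABELS = ("ptsd", "control", "subthreshold")
TIMEPOINTS = ("T0", "T1")
FEATURE_TYPES = (
    "methylation",
    "mirna",
    "protein",
    "metabolite",
    "clinical_lab",
    "physiological",
    "derived",
)
#: data types whose raw values are positive concentrations/counts, so that
#: fold change is meaningfully a ratio of group means
RATIO_SCALE_TYPES = frozenset({"mirna", "protein", "metabolite", "clinical_lab"})

PANEL_STAGES = ("candidate", "stage1", "final", "datatype_subset", "single")

#: CAPS severity boundaries for diagnostic labels: cases scored >= 40 at
#: inclusion, controls < 20, and recalled participants with intermediate
#: symptoms (20 <= CAPS < 40) are labelled subthreshold.
CAPS_PTSD_MIN = 40.0
CAPS_CONTROL_MAX = 20.0


class FormatError(ValueError):
    """Raised for malformed input tables or serializations."""


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass
class FeatureMatrix:
    """Samples x features table with per-feature data-type annotation.

    ``values`` is a float DataFrame indexed by sample id with feature-id
    columns; NaN encodes a missing measurement. ``feature_types`` maps every
    feature id to one of :data:`FEATURE_TYPES`.
    """

    values: pd.DataFrame
    feature_types: dict[str, str]
    #: True once values are z-scored; lifts natural-scale range invariants
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        validate_feature_matrix(self)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "FeatureMatrix":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.values.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return FeatureMatrix(self.values.loc[ids], dict(self.feature_types),
                             normalized=self.normalized)

    def subset_features(self, feature_ids: Iterable[str]) -> "FeatureMatrix":
        ids = list(feature_ids)
        missing = [f for f in ids if f not in self.values.columns]
        if missing:
            raise KeyError(f"unknown feature ids: {missing}")
        types = {f: self.feature_types[f] for f in ids}
        return FeatureMatrix(self.values[ids], types,
                             normalized=self.normalized)

    def types_of(self, feature_ids: Iterable[str]) -> dict[str, str]:
        return {f: self.feature_types[f] for f in feature_ids}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.values, other.values,
                                          check_names=False)
        except AssertionError:
            return False
        return self.feature_types == other.feature_types


def validate_feature_matrix(fm: FeatureMatrix) -> None:
    idx = fm.values.index
    cols = fm.values.columns
    dup_samples = idx[idx.duplicated()].unique().tolist()
    if dup_samples:
        raise FormatError(f"duplicate sample ids: {dup_samples}")
    dup_features = cols[cols.duplicated()].unique().tolist()
    if dup_features:
        raise FormatError(f"duplicate feature ids: {dup_features}")
    untyped = [f for f in cols if f not in fm.feature_types]
    if untyped:
        raise FormatError(f"features missing from type map: {untyped}")
    bad_types = {f: t for f, t in fm.feature_types.items() if t not in FEATURE_TYPES}
    if bad_types:
        raise FormatError(
            f"unknown feature types {bad_types}; allowed: {FEATURE_TYPES}"
        )
    meth = [] if fm.normalized else [
        f for f in cols if fm.feature_types[f] == "methylation"
    ]
    if meth:
        block = fm.values[meth]
        out = ((block < 0.0) | (block > 1.0)) & block.notna()
        if out.any().any():
            offenders = out.any(axis=0)
            names = offenders[offenders].index.tolist()
            raise ValidationError(
                f"methylation features outside [0, 1]: {names} "
                "(beta values must lie in the unit interval)"
            )


@dataclass(frozen=True)
class SampleRecord:
    """One participant visit: identity, cohort, diagnosis, and covariates.

    ``subject_id`` links the T0 discovery visit with the T1 recall visit of
    the same participant. Label/CAPS consistency follows the study's
    inclusion criteria: ptsd requires caps_total >= 40, control < 20,
    subthreshold in [20, 40) and only in the recall cohort.
    """

    sample_id: str
    subject_id: str
    cohort: str
    label: str
    caps_total: float
    caps_subscales: Mapping[str, float] = field(default_factory=dict)
    ethnicity: str = "unknown"
    mdd: bool = False
    timepoint: str = "T0"

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValidationError(
                f"{self.sample_id}: unknown cohort {self.cohort!r}"
            )
        if self.label not in LABELS:
            raise ValidationError(f"{self.sample_id}: unknown label {self.label!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"{self.sample_id}: unknown timepoint {self.timepoint!r}"
            )
        if self.caps_total < 0 or not np.isfinite(self.caps_total):
            raise ValidationError(
                f"{self.sample_id}: caps_total must be a finite non-negative score"
            )
        if any(v < 0 for v in self.caps_subscales.values()):
            raise ValidationError(
                f"{self.sample_id}: caps subscale scores must be non-negative"
            )
        if self.label == "ptsd" and self.caps_total < CAPS_PTSD_MIN:
            raise ValidationError(
                f"{self.sample_id}: label=ptsd requires caps_total >= "
                f"{CAPS_PTSD_MIN:g}, got {self.caps_total:g}"
            )
        if self.label == "control" and self.caps_total >= CAPS_CONTROL_MAX:
            raise ValidationError(
                f"{self.sample_id}: label=control requires caps_total < "
                f"{CAPS_CONTROL_MAX:g}, got {self.caps_total:g}"
            )
        if self.label == "subthreshold":
            if not (CAPS_CONTROL_MAX <= self.caps_total < CAPS_PTSD_MIN):
                raise ValidationError(
                    f"{self.sample_id}: label=subthreshold requires "
                    f"{CAPS_CONTROL_MAX:g} <= caps_total < {CAPS_PTSD_MIN:g}, "
                    f"got {self.caps_total:g}"
                )
            if self.cohort != "recall":
                raise ValidationError(
                    f"{self.sample_id}: subthreshold label only occurs in the "
                    f"recall cohort, got cohort={self.cohort!r}"
                )


@dataclass
class Panel:
    """Ordered, duplicate-free marker set with per-feature selector provenance."""

    feature_ids: list[str]
    provenance: dict[str, set[str]] = field(default_factory=dict)
    stage: str = "candidate"

    def __post_init__(self) -> None:
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dups = [f for f in self.feature_ids if self.feature_ids.count(f) > 1]
            raise ValidationError(f"panel has duplicate feature ids: {sorted(set(dups))}")
        if self.stage not in PANEL_STAGES:
            raise ValidationError(f"unknown panel stage {self.stage!r}")
        self.provenance = {f: set(self.provenance.get(f, set())) for f in self.feature_ids}

    def __len__(self) -> int:
        return len(self.feature_ids)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.provenance

    def restricted_to(self, feature_ids: Iterable[str], stage: str | None = None) -> "Panel":
        keep = set(feature_ids)
        ids = [f for f in self.feature_ids if f in keep]
        return Panel(
            feature_ids=ids,
            provenance={f: set(self.provenance[f]) for f in ids},
            stage=stage or self.stage,
        )


@dataclass
class PipelineConfig:
    """Tunable settings for every pipeline stage.

    Defaults mirror the study's stated choices where it states them: the
    importance-pruning rule keeps markers scoring above 30% of the maximum
    random-forest importance, and evaluation uses 2000 bootstrap iterations
    for 95% confidence intervals.
    """

    # candidate selection
    alpha: float = 0.05
    q_threshold: float = 0.10
    fold_change_threshold: float = 0.5
    svm_rfe_step: float = 0.1
    svm_rfe_top_k: int = 50
    rf_rank_top_k: int = 50
    # down-selection
    cv_folds: int = 5
    cv_repeats: int = 5
    min_panel_size: int = 20
    importance_fraction: float = 0.30
    elimination_scorer: str = "univariate_mean"
    subthreshold_mapping: str = "exclude"
    # evaluation
    n_bootstrap: int = 2000
    ci_level: float = 0.95
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.importance_fraction <= 1.0:
            raise ValidationError(
                f"importance_fraction must be in (0, 1], got {self.importance_fraction}"
            )
        if self.n_bootstrap < 1:
            raise ValidationError("n_bootstrap must be >= 1")
        if self.cv_folds < 2:
            raise ValidationError("cv folds must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0.0 < self.ci_level < 1.0:
            raise ValidationError("ci_level must be in (0, 1)")
        if self.subthreshold_mapping not in ("exclude", "as_case", "as_control"):
            raise ValidationError(
                f"unknown subthreshold_mapping {self.subthreshold_mapping!r}"
            )

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def labels_for(
    records: Iterable[SampleRecord],
    sample_ids: Iterable[str] | None = None,
    subthreshold: str = "exclude",
) -> pd.Series:
    """Binary case/control labels (1=ptsd, 0=control) for model fitting.

    Subthreshold recall participants do not fit the binary contrast; they are
    dropped by default, or force-mapped with ``subthreshold='as_case'`` /
    ``'as_control'``. Returns a Series indexed by sample id.
    """
    if subthreshold not in ("exclude", "as_case", "as_control"):
        raise ValidationError(
            "subthreshold samples present: map them explicitly with "
            "subthreshold='exclude', 'as_case', or 'as_control' "
            f"(got {subthreshold!r})"
        )
    by_id = {r.sample_id: r for r in records}
    ids = list(sample_ids) if sample_ids is not None else list(by_id)
    out: dict[str, int] = {}
    for sid in ids:
        rec = by_id.get(sid)
        if rec is None:
            raise KeyError(f"no metadata record for sample {sid!r}")
        if rec.label == "ptsd":
            out[sid] = 1
        elif rec.label == "control":
            out[sid] = 0
        elif subthreshold == "as_case":
            out[sid] = 1
        elif subthreshold == "as_control":
            out[sid] = 0
        # exclude: skip
    return pd.Series(out, dtype=int)
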