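"""Derived nonlinear features, leakage-safe normalization, and cross-cohort
fold-change direction analysis.

Two metabolite ratios are first-class derived features: the Global Arginine
Bioavailability Ratio (GABR = arginine / (ornithine + citrulline)) and
lactate/citrate. Both are dimensionless and invariant under common positive
rescaling of their inputs, which partially sidesteps single-sample
normalization problems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import FeatureMatrix, SampleRecord, ValidationError, labels_for

logger = logging.getLogger(__name__)

GABR_ID = "GABR"
LACTATE_CITRATE_ID = "lactate_citrate"

STUDY_COHORTS = ("discovery", "recall", "validation")


class RatioError(ValueError):
    """Undefined ratio: nonpositive denominator or negative concentration."""


def compute_gabr(arginine: float, ornithine: float, citrulline: float) -> float:
    """Global Arginine Bioavailability Ratio: arginine / (ornithine + citrulline)."""
    if arginine < 0 or ornithine < 0 or citrulline < 0:
        raise RatioError("concentrations must be non-negative")
    denom = ornithine + citrulline
    if denom <= 0:
        raise RatioError("ornithine + citrulline must be positive")
    return arginine / denom


def compute_ratio(numerator: float, denominator: float) -> float:
    if denominator <= 0:
        raise RatioError(f"denominator must be positive, got {denominator}")
    return numerator / denominator


def add_ratio_feature(
    fm: FeatureMatrix, new_id: str, numerator_id: str, denominator_id: str
) -> FeatureMatrix:
    """Append numerator/denominator as a ``derived`` feature column.

    Rows where the denominator is missing or nonpositive get a missing ratio.
    """
    for f in (numerator_id, denominator_id):
        if f not in fm.values.columns:
            raise KeyError(f"feature {f!r} not in matrix")
    num = fm.values[numerator_id]
    den = fm.values[denominator_id]
    ratio = num / den.where(den > 0)
    values = fm.values.copy()
    values[new_id] = ratio
    types = dict(fm.feature_types)
    types[new_id] = "derived"
    return FeatureMatrix(values=values, feature_types=types,
                         normalized=fm.normalized)


def add_gabr_feature(
    fm: FeatureMatrix,
    arginine_id: str,
    ornithine_id: str,
    citrulline_id: str,
    new_id: str = GABR_ID,
) -> FeatureMatrix:
    for f in (arginine_id, ornithine_id, citrulline_id):
        if f not in fm.values.columns:
            raise KeyError(f"feature {f!r} not in matrix")
    den = fm.values[ornithine_id] + fm.values[citrulline_id]
    ratio = fm.values[arginine_id] / den.where(den > 0)
    values = fm.values.copy()
    values[new_id] = ratio
    types = dict(fm.feature_types)
    types[new_id] = "derived"
    return FeatureMatrix(values=values, feature_types=types,
                         normalized=fm.normalized)


@dataclass
class NormalizationStats:
    """Per-feature location/scale estimated on training samples only."""

    location: pd.Series
    scale: pd.Series
    dropped: list[str]

    def __post_init__(self) -> None:
        if (self.scale <= 0).any():
            bad = self.scale.index[self.scale <= 0].tolist()
            raise ValidationError(f"nonpositive scale for features: {bad}")


def fit_normalizer(fm: FeatureMatrix, training_ids: list[str]) -> NormalizationStats:
    """Estimate per-feature mean and sd from the training subset only.

    Features constant (or entirely missing) in training are dropped with a
    warning — they carry no contrast and would divide by zero.
    """
    if not list(training_ids):
        raise ValidationError("training subset is empty")
    sub = fm.values.loc[list(training_ids)]
    loc = sub.mean(axis=0, skipna=True)
    scale = sub.std(axis=0, ddof=1, skipna=True)
    constant = scale.index[(scale.isna()) | (scale == 0.0)].tolist()
    if constant:
        logger.warning(
            "dropping %d constant/empty training feature(s): %s",
            len(constant), constant,
        )
    keep = [f for f in fm.feature_ids if f not in set(constant)]
    return NormalizationStats(
        location=loc[keep], scale=scale[keep], dropped=constant
    )


def apply_normalizer(stats: NormalizationStats, fm: FeatureMatrix) -> FeatureMatrix:
    """Z-score with training statistics; missing values imputed to 0 (the
    training mean on the z scale)."""
    missing = [f for f in stats.location.index if f not in fm.values.columns]
    if missing:
        raise KeyError(f"matrix lacks features covered by stats: {missing}")
    keep = [f for f in fm.feature_ids if f in stats.location.index]
    z = (fm.values[keep] - stats.location[keep]) / stats.scale[keep]
    z = z.fillna(0.0)
    types = {f: fm.feature_types[f] for f in keep}
    return FeatureMatrix(values=z, feature_types=types, normalized=True)


def direction_table(
    matrices: dict[str, FeatureMatrix],
    metadata: list[SampleRecord],
    panel_features: list[str],
) -> pd.DataFrame:
    """Sign (up/down) of the case-minus-control mean per feature per cohort.

    Computed on raw values — directions describe biological up/down
    regulation, not model coefficients. Subthreshold samples are excluded.
    An exact zero difference is deterministically called "up".
    """
    out = pd.DataFrame(index=list(panel_features),
                       columns=list(matrices), dtype=object)
    for cohort, fm in matrices.items():
        recs = [r for r in metadata
                if r.cohort == cohort and r.sample_id in fm.values.index]
        cases = [r.sample_id for r in recs if r.label == "ptsd"]
        controls = [r.sample_id for r in recs if r.label == "control"]
        if not cases or not controls:
            raise ValidationError(
                f"cohort {cohort!r} needs at least one case and one control"
            )
        sub = fm.values[list(panel_features)]
        diff = sub.loc[cases].mean(axis=0) - sub.loc[controls].mean(axis=0)
        out[cohort] = np.where(diff >= 0, "up", "down")
    return out


def consistency_counts(table: pd.DataFrame) -> dict[str, int]:
    """Cross-cohort agreement of fold-change directions.

    ``n_all_consistent``: features whose sign agrees in discovery, recall,
    and validation; ``n_disc_recall_consistent``: agreement between discovery
    and recall only.
    """
    for c in STUDY_COHORTS:
        if c not in table.columns:
            raise ValidationError(f"direction table lacks cohort {c!r}")
    if table.empty:
        return {"n_all_consistent": 0, "n_disc_recall_consistent": 0}
    all_same = (
        (table["discovery"] == table["recall"])
        & (table["recall"] == table["validation"])
    )
    disc_recall = table["discovery"] == table["recall"]
    return {
        "n_all_consistent": int(all_same.sum()),
        "n_disc_recall_consistent": int(disc_recall.sum()),
    }


def load_published_directions() -> pd.DataFrame:
    """Published cross-cohort fold-change directions of the final 28-marker
    PTSD panel, transcribed from the study's marker overview table.

    Index: marker id; columns: data_type, discovery, recall, validation
    (values "up"/"down").
    """
    with resources.files("ptsdpanel.data").joinpath(
        "panel_directions.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return df
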