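"""Two-stage panel refinement on the recall cohort.

Stage 1: greedy backward elimination — repeatedly drop the single marker
whose removal leaves the remaining set with the largest mean AUC, recording
the full trajectory, then keep the set at the trajectory's AUC maximum
("largest average AUC prior to the final performance decline").

Stage 2: fit a random forest on the surviving markers and keep only those
with variable importance above a fraction (default 30%) of the maximum
importance.

The "average AUC of the remaining set" admits two readings, both available
behind :class:`CvSpec.scorer`:

* ``model_cv`` — repeated stratified-CV ROC-AUC of a random-forest
  classifier on the remaining markers. This is the only reading that can
  *decline* as markers are removed, so it is the semantically faithful one;
  it is also O(k^2) classifier fits per elimination run.
* ``univariate_mean`` — mean over markers of the orientation-corrected
  single-marker AUC max(a, 1-a). Cheap and provably equivalent to removing
  the weakest marker each round; its trajectory is monotone nondecreasing,
  so the maximum sits at the minimum panel size. Used as the fast mode and
  as the exhaustive-search oracle's subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score

from .core import FeatureMatrix, Panel, ValidationError

SCORERS = ("model_cv", "univariate_mean")


@dataclass
class CvSpec:
    folds: int = 5
    repeats: int = 5
    stratified: bool = True
    seed: int = 0
    scorer: str = "model_cv"
    n_trees: int = 500

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")
        if self.scorer not in SCORERS:
            raise ValidationError(
                f"scorer must be one of {SCORERS}, got {self.scorer!r}"
            )


@dataclass
class EliminationStep:
    removed: str | None
    remaining_size: int
    mean_auc: float


@dataclass
class EliminationTrajectory:
    steps: list[EliminationStep]
    initial_panel: Panel
    selected_index: int = 0

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValidationError("trajectory must have at least the initial step")
        if self.steps[0].removed is not None:
            raise ValidationError("first trajectory step must be the initial set")
        for prev, cur in zip(self.steps, self.steps[1:]):
            if cur.remaining_size != prev.remaining_size - 1:
                raise ValidationError("remaining_size must decrease by 1 per step")
        for s in self.steps:
            if not 0.0 <= s.mean_auc <= 1.0:
                raise ValidationError("mean_auc must lie in [0, 1]")

    def remaining_at(self, index: int) -> list[str]:
        removed = {s.removed for s in self.steps[1 : index + 1]}
        return [f for f in self.initial_panel.feature_ids if f not in removed]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(len(self.steps)),
                "removed_feature": [s.removed or "" for s in self.steps],
                "remaining_size": [s.remaining_size for s in self.steps],
                "mean_auc": [s.mean_auc for s in self.steps],
            }
        )


def univariate_auc(values: pd.Series, y: np.ndarray, oriented: bool = True) -> float:
    """Single-feature ROC-AUC; orientation-corrected to max(a, 1-a) so that
    a marker's direction does not matter. Missing values are dropped."""
    mask = values.notna().to_numpy()
    if (~mask).any():
        values, y = values[mask], np.asarray(y)[mask]
    a = roc_auc_score(y, values.to_numpy(dtype=float))
    return float(max(a, 1.0 - a)) if oriented else float(a)


def _prepare(fm: FeatureMatrix, labels: pd.Series, features: list[str]):
    ids = [s for s in labels.index if s in fm.values.index]
    X = fm.values.loc[ids, features]
    y = labels.loc[ids].to_numpy()
    if len(np.unique(y)) != 2:
        raise ValidationError("both classes must be present")
    return X, y


def panel_mean_auc(
    fm: FeatureMatrix,
    labels: pd.Series,
    panel_features: list[str],
    cv: CvSpec,
) -> float:
    """Mean AUC of a marker set under the configured scorer (see module doc)."""
    if not panel_features:
        raise ValidationError("panel is empty")
    X, y = _prepare(fm, labels, list(panel_features))
    counts = np.bincount(y)
    if cv.scorer == "univariate_mean":
        return float(np.mean([univariate_auc(X[f], y) for f in panel_features]))
    if counts.min() < cv.folds:
        raise ValidationError(
            f"need >= {cv.folds} samples per class for {cv.folds}-fold CV"
        )
    Xv = X.fillna(X.mean(axis=0)).fillna(0.0).to_numpy(dtype=float)
    splitter = RepeatedStratifiedKFold(
        n_splits=cv.folds, n_repeats=cv.repeats, random_state=cv.seed
    )
    clf = RandomForestClassifier(
        n_estimators=cv.n_trees, random_state=cv.seed, max_features="sqrt"
    )
    scores = cross_val_score(clf, Xv, y, cv=splitter, scoring="roc_auc")
    return float(np.mean(scores))


def backward_eliminate(
    fm: FeatureMatrix,
    labels: pd.Series,
    panel: Panel,
    cv: CvSpec,
    min_size: int = 1,
) -> EliminationTrajectory:
    """Greedy one-by-one elimination down to ``min_size`` markers.

    At each step every candidate single-marker removal is scored with an
    identical CV-split realization and the removal leaving the largest mean
    AUC is committed; ties break by ascending feature id of the removed
    marker.
    """
    if not 1 <= min_size < len(panel):
        raise ValidationError(
            f"need panel size ({len(panel)}) > min_size ({min_size}) >= 1"
        )
    features = list(panel.feature_ids)

    if cv.scorer == "univariate_mean":
        X, y = _prepare(fm, labels, features)
        cache = {f: univariate_auc(X[f], y) for f in features}

        def score(subset: list[str]) -> float:
            return float(np.mean([cache[f] for f in subset]))
    else:
        def score(subset: list[str]) -> float:
            return panel_mean_auc(fm, labels, subset, cv)

    steps = [EliminationStep(None, len(features), score(features))]
    remaining = list(features)
    while len(remaining) > min_size:
        best: tuple[float, str] | None = None
        for f in sorted(remaining):  # ascending id ⇒ first max wins ties
            auc = score([g for g in remaining if g != f])
            if best is None or auc > best[0]:
                best = (auc, f)
        auc, removed = best
        remaining.remove(removed)
        steps.append(EliminationStep(removed, len(remaining), auc))
    traj = EliminationTrajectory(steps=steps, initial_panel=panel)
    traj.selected_index = _argmax_earliest(traj)
    return traj


def _argmax_earliest(traj: EliminationTrajectory) -> int:
    aucs = [s.mean_auc for s in traj.steps]
    return int(np.argmax(aucs))  # argmax returns the first (earliest) maximum


def select_stage1(trajectory: EliminationTrajectory) -> Panel:
    """Marker set at the trajectory's global AUC maximum (earliest such step
    on ties, i.e. the largest remaining panel)."""
    idx = _argmax_earliest(trajectory)
    trajectory.selected_index = idx
    keep = trajectory.remaining_at(idx)
    return trajectory.initial_panel.restricted_to(keep, stage="stage1")


def rf_importances(
    fm: FeatureMatrix,
    labels: pd.Series,
    panel_features: list[str],
    n_trees: int = 500,
    seed: int = 0,
    max_features: int | str = 2,
) -> pd.Series:
    """Impurity-decrease variable importances of a random forest fit on the
    panel's markers.

    Defaults to strongly decorrelated trees (``max_features=2``): impurity
    importance with the usual sqrt(p) candidate pool concentrates on the few
    strongest markers and masks complementary weak ones, which is exactly
    the signal a multi-marker panel wants to keep. With a near-random split
    variable, each marker's importance tracks its marginal utility.
    """
    X, y = _prepare(fm, labels, list(panel_features))
    Xv = X.fillna(X.mean(axis=0)).fillna(0.0).to_numpy(dtype=float)
    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, max_features=max_features
    )
    clf.fit(Xv, y)
    return pd.Series(clf.feature_importances_, index=list(panel_features))


def prune_by_importance(
    importances: pd.Series, panel: Panel, fraction: float
) -> Panel:
    """Keep markers with importance strictly above fraction x max.

    At fraction=1.0 the strict rule would keep nothing, so the argmax
    marker(s) (importance == max) are kept instead — the result is never
    empty. Output ordered by descending importance, ties by ascending id.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValidationError("fraction must be in (0, 1]")
    imax = float(importances.max())
    if imax <= 0.0:
        raise ValidationError("all importances are zero: degenerate fit")
    if fraction == 1.0:
        keep = importances.index[importances == imax].tolist()
    else:
        keep = importances.index[importances > fraction * imax].tolist()
    keep = sorted(keep, key=lambda f: (-float(importances[f]), f))
    return Panel(
        feature_ids=keep,
        provenance={f: set(panel.provenance.get(f, set())) for f in keep},
        stage="final",
    )


def importance_prune(
    fm: FeatureMatrix,
    labels: pd.Series,
    panel: Panel,
    fraction: float = 0.30,
    n_trees: int = 500,
    seed: int = 0,
    max_features: int | str = 2,
) -> Panel:
    """Random-forest importance pruning of a panel (stage 2 refinement)."""
    if not len(panel):
        raise ValidationError("panel is empty")
    imp = rf_importances(fm, labels, panel.feature_ids, n_trees=n_trees,
                         seed=seed, max_features=max_features)
    return prune_by_importance(imp, panel, fraction)
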