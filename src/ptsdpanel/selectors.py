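"""Ensemble ("wisdom of crowds") candidate biomarker selection.

Each selector nominates an ordered marker list from the discovery cohort;
:func:`union_panels` merges them into one candidate panel, recording which
selectors chose each feature. External published selectors (hybrid or
hypothesis-driven approaches, literature lists, polygenic scores) plug in
through :class:`FixedListSelector`.

All selectors are deterministic given their seed, and ranking ties break by
ascending feature id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .core import (
    FeatureMatrix,
    Panel,
    RATIO_SCALE_TYPES,
    ValidationError,
)

import logging

logger = logging.getLogger(__name__)


@dataclass
class SelectorResult:
    selector_name: str
    selected: list[str]
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [f for f in self.selected if f not in self.scores]
        if missing:
            raise ValidationError(
                f"{self.selector_name}: selected features missing scores: {missing}"
            )


def _check_two_classes(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError(
            f"need exactly two classes, got {classes.tolist()}"
        )
    case_mask = y == classes.max()
    ctrl_mask = y == classes.min()
    if case_mask.sum() < 2 or ctrl_mask.sum() < 2:
        raise ValidationError("each class needs at least 2 samples")
    return case_mask, ctrl_mask


def _aligned(fm: FeatureMatrix, labels: pd.Series) -> tuple[pd.DataFrame, np.ndarray]:
    ids = [s for s in labels.index if s in fm.values.index]
    return fm.values.loc[ids], labels.loc[ids].to_numpy()


def welch_pvalues(fm: FeatureMatrix, labels: pd.Series) -> pd.Series:
    """Two-sided Welch t-test p-value per feature (NaN-tolerant)."""
    X, y = _aligned(fm, labels)
    case_mask, ctrl_mask = _check_two_classes(y)
    _, p = stats.ttest_ind(
        X[case_mask], X[ctrl_mask], equal_var=False, nan_policy="omit"
    )
    return pd.Series(np.asarray(p, dtype=float), index=X.columns)


def pvalue_filter(fm: FeatureMatrix, labels: pd.Series, alpha: float) -> SelectorResult:
    """Select features with Welch-t p < alpha, ordered by ascending p."""
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    p = welch_pvalues(fm, labels)
    hits = p[p < alpha]
    order = sorted(hits.index, key=lambda f: (hits[f], f))
    return SelectorResult("pvalue_filter", order, p.to_dict())


def qvalue_filter(fm: FeatureMatrix, labels: pd.Series, q_threshold: float) -> SelectorResult:
    """Benjamini-Hochberg adjusted p-values; select q < q_threshold."""
    if not 0.0 < q_threshold < 1.0:
        raise ValidationError("q_threshold must be in (0, 1)")
    p = welch_pvalues(fm, labels)
    finite = p.fillna(1.0)
    _, q, _, _ = multipletests(finite.to_numpy(), method="fdr_bh")
    q = pd.Series(q, index=finite.index)
    hits = q[q < q_threshold]
    order = sorted(hits.index, key=lambda f: (hits[f], f))
    return SelectorResult("qvalue_filter", order, q.to_dict())


def fold_change_filter(
    fm: FeatureMatrix, labels: pd.Series, min_abs_log2fc: float
) -> SelectorResult:
    """Effect-magnitude filter.

    For ratio-scale data types (miRNA, protein, metabolite, clinical lab)
    the score is |log2(case mean / control mean)|; features with a
    nonpositive group mean are skipped with a warning. For bounded or signed
    types (methylation, physiological, derived) a ratio of means is
    meaningless, so the score is the absolute standardized mean difference
    (pooled-sd units) on the same threshold scale.
    """
    X, y = _aligned(fm, labels)
    case_mask, ctrl_mask = _check_two_classes(y)
    mc = X[case_mask].mean(axis=0, skipna=True)
    m0 = X[ctrl_mask].mean(axis=0, skipna=True)
    sc = X[case_mask].std(axis=0, ddof=1)
    s0 = X[ctrl_mask].std(axis=0, ddof=1)
    n1, n0 = int(case_mask.sum()), int(ctrl_mask.sum())
    pooled = np.sqrt(((n1 - 1) * sc**2 + (n0 - 1) * s0**2) / (n1 + n0 - 2))
    scores: dict[str, float] = {}
    for f in X.columns:
        if fm.feature_types[f] in RATIO_SCALE_TYPES:
            if mc[f] <= 0 or m0[f] <= 0:
                logger.warning(
                    "fold_change_filter: skipping %s (nonpositive group mean)", f
                )
                continue
            scores[f] = abs(float(np.log2(mc[f] / m0[f])))
        else:
            if pooled[f] == 0 or np.isnan(pooled[f]):
                scores[f] = 0.0
            else:
                scores[f] = abs(float((mc[f] - m0[f]) / pooled[f]))
    hits = [f for f, s in scores.items() if s >= min_abs_log2fc]
    order = sorted(hits, key=lambda f: (-scores[f], f))
    return SelectorResult("fold_change_filter", order, scores)


def svm_rfe_select(
    fm: FeatureMatrix,
    labels: pd.Series,
    step: float | int = 0.1,
    top_k: int = 50,
) -> SelectorResult:
    """Linear SVM recursive feature elimination.

    Refits a soft-margin linear SVM (C=1) each round and removes the
    ``step`` features with smallest squared weight (``step`` < 1 is a
    fraction of the current set, at least one per round), until ``top_k``
    survive. Returned order: survivors ranked by final-model weight, then
    the eliminated features in reverse elimination order. Scores are rank
    weights (higher = retained longer / larger weight).
    """
    X, y = _aligned(fm, labels)
    _check_two_classes(y)
    if top_k < 1 or top_k > X.shape[1]:
        raise ValidationError(f"top_k must be in [1, {X.shape[1]}]")
    step_is_fraction = isinstance(step, float) and 0.0 < step < 1.0
    if not step_is_fraction and (float(step) != int(step) or int(step) < 1):
        raise ValidationError("step must be a positive int or a fraction in (0,1)")
    Xv = X.fillna(X.mean(axis=0)).to_numpy(dtype=float)
    remaining = list(X.columns)
    eliminated: list[str] = []
    col_of = {f: i for i, f in enumerate(X.columns)}
    while len(remaining) > top_k:
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(Xv[:, [col_of[f] for f in remaining]], y)
        w2 = np.square(np.asarray(clf.coef_).ravel())
        if isinstance(step, float) and 0 < step < 1:
            n_drop = max(1, int(step * len(remaining)))
        else:
            n_drop = int(step)
        n_drop = min(n_drop, len(remaining) - top_k)
        # smallest squared weight first; ties by ascending feature id
        order = sorted(range(len(remaining)),
                       key=lambda i: (w2[i], remaining[i]))
        drop = [remaining[i] for i in order[:n_drop]]
        for f in drop:
            eliminated.append(f)
            remaining.remove(f)
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(Xv[:, [col_of[f] for f in remaining]], y)
    w2 = np.square(np.asarray(clf.coef_).ravel())
    survivors = sorted(remaining,
                       key=lambda f: (-w2[remaining.index(f)], f))
    ranking = survivors + eliminated[::-1]
    scores = {f: float(len(ranking) - i) for i, f in enumerate(ranking)}
    return SelectorResult("svm_rfe", survivors, scores)


def rf_rank_select(
    fm: FeatureMatrix,
    labels: pd.Series,
    top_k: int = 50,
    seed: int = 0,
    n_trees: int = 500,
) -> SelectorResult:
    """Top-k features by random-forest impurity-decrease importance."""
    X, y = _aligned(fm, labels)
    _check_two_classes(y)
    if top_k < 0 or top_k > X.shape[1]:
        raise ValidationError(f"top_k must be in [0, {X.shape[1]}]")
    Xv = X.fillna(X.mean(axis=0)).to_numpy(dtype=float)
    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, max_features="sqrt"
    )
    clf.fit(Xv, y)
    imp = pd.Series(clf.feature_importances_, index=X.columns)
    order = sorted(X.columns, key=lambda f: (-imp[f], f))
    return SelectorResult("rf_rank", order[:top_k], imp.to_dict())


def fixed_list_select(
    fm: FeatureMatrix, feature_list: list[str], name: str = "literature_list"
) -> SelectorResult:
    """Pluggable slot for external/hypothesis-driven selectors: injects a
    user-supplied marker list (unknown ids dropped with a warning)."""
    known = [f for f in feature_list if f in fm.values.columns]
    unknown = [f for f in feature_list if f not in fm.values.columns]
    if unknown:
        logger.warning("%s: dropping unknown features %s", name, unknown)
    return SelectorResult(name, known, {f: 1.0 for f in known})


def union_panels(results: list[SelectorResult]) -> Panel:
    """Duplicate-free union in first-seen order, with full provenance."""
    if not results:
        raise ValidationError("need at least one selector result")
    order: list[str] = []
    provenance: dict[str, set[str]] = {}
    for res in results:
        for f in res.selected:
            if f not in provenance:
                order.append(f)
                provenance[f] = set()
            provenance[f].add(res.selector_name)
    return Panel(feature_ids=order, provenance=provenance, stage="candidate")
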