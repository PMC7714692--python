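"""Final-model training and the validation protocol.

A random forest is trained on the combined discovery + recall cohorts
(normalizer fit on training samples only — validation data never touch any
fitted statistic) and evaluated once on the independent validation cohort:
ROC with a class-stratified percentile-bootstrap confidence interval,
operating point closest to (0,1), correlation of predicted case probability
with CAPS severity among cases, stratified subsets (ethnicity within
stratum; comorbid-MDD cases against all controls), per-data-type sub-panels,
and single-marker accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

from .core import FeatureMatrix, Panel, SampleRecord, ValidationError, labels_for
from .features import NormalizationStats, apply_normalizer, fit_normalizer


class LeakageError(RuntimeError):
    """A validation sample or subject appeared in training data."""


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    n_bootstrap: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_bootstrap": self.n_bootstrap,
            "fpr": list(map(float, self.fpr)),
            "tpr": list(map(float, self.tpr)),
            "thresholds": list(map(float, self.thresholds)),
        }


@dataclass
class OperatingPointMetrics:
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class StratumResult:
    roc: RocResult | None
    n_cases: int
    n_controls: int
    reason: str | None = None  # set when not evaluable

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "reason": self.reason,
            "roc": self.roc.to_dict() if self.roc else None,
        }


@dataclass
class PanelModel:
    """Frozen trained state: panel, training-only normalizer, fitted forest."""

    panel: Panel
    normalizer: NormalizationStats
    classifier: RandomForestClassifier
    training_sample_ids: list[str]
    seed: int

    @property
    def model_features(self) -> list[str]:
        return [f for f in self.panel.feature_ids
                if f in self.normalizer.location.index]


def train_panel_model(
    training_matrix: FeatureMatrix,
    metadata: list[SampleRecord],
    panel: Panel,
    seed: int = 0,
    n_trees: int = 500,
    subthreshold: str = "exclude",
    validation_sample_ids: list[str] | None = None,
) -> PanelModel:
    """Fit normalizer + random forest on the panel's markers.

    ``training_matrix`` holds the combined discovery + recall samples.
    ``validation_sample_ids``, when given, guards against leakage: any
    overlap with training raises :class:`LeakageError`.
    """
    if not len(panel):
        raise ValidationError("panel is empty")
    if validation_sample_ids is not None:
        leak = set(training_matrix.sample_ids) & set(validation_sample_ids)
        if leak:
            raise LeakageError(
                f"validation samples present in training data: {sorted(leak)}"
            )
    y = labels_for(metadata, sample_ids=None, subthreshold=subthreshold)
    train_ids = [s for s in training_matrix.sample_ids if s in y.index]
    y = y.loc[train_ids]
    if len(np.unique(y)) != 2:
        raise ValidationError("both classes must be present in training data")
    sub = training_matrix.subset_features(panel.feature_ids)
    norm = fit_normalizer(sub, train_ids)
    z = apply_normalizer(norm, sub.subset_samples(train_ids))
    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, max_features="sqrt"
    )
    clf.fit(z.values.to_numpy(dtype=float), y.to_numpy())
    return PanelModel(
        panel=panel,
        normalizer=norm,
        classifier=clf,
        training_sample_ids=train_ids,
        seed=seed,
    )


def predict_scores(
    model: PanelModel, fm: FeatureMatrix, sample_ids: list[str] | None = None
) -> pd.Series:
    """Predicted case probability per sample, in [0, 1]."""
    feats = model.model_features
    missing = [f for f in feats if f not in fm.values.columns]
    if missing:
        raise KeyError(f"matrix lacks panel features: {missing}")
    ids = list(sample_ids) if sample_ids is not None else fm.sample_ids
    sub = fm.subset_features(feats).subset_samples(ids)
    z = apply_normalizer(model.normalizer, sub)
    proba = model.classifier.predict_proba(z.values.to_numpy(dtype=float))
    case_col = int(np.argmax(model.classifier.classes_))
    return pd.Series(proba[:, case_col], index=ids)


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney pairwise statistic
    (#concordant + 0.5 #ties) / (n1 * n0)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValidationError("both classes must be present")
    diff = cases[:, None] - controls[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
                 / (len(cases) * len(controls)))


def roc_with_bootstrap(
    scores: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    n_bootstrap: int = 2000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> RocResult:
    """Empirical ROC/AUC with a class-stratified percentile bootstrap CI.

    The point estimate is computed on the full data; each bootstrap
    iteration resamples cases and controls separately with replacement, so
    every replicate retains both classes.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) != 2:
        raise ValidationError("both classes must be present")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        ci = rng.choice(case_idx, size=len(case_idx), replace=True)
        ki = rng.choice(ctrl_idx, size=len(ctrl_idx), replace=True)
        idx = np.concatenate([ci, ki])
        boot[b] = roc_auc_score(y[idx], s[idx])
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])
    return RocResult(
        fpr=fpr, tpr=tpr, thresholds=thr, auc=auc,
        ci_low=float(lo), ci_high=float(hi), n_bootstrap=n_bootstrap,
    )


def closest_to_01(
    scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray
) -> OperatingPointMetrics:
    """Operating point minimizing the distance to the perfect corner (0, 1).

    Candidate thresholds are the distinct scores plus one above the maximum
    (predict-none); a sample scoring >= threshold is called a case. Ties in
    distance prefer higher sensitivity, then higher specificity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be present")
    cand = np.unique(s)
    cand = np.append(cand, cand[-1] + 1.0)
    best = None
    for t in cand:
        pred = s >= t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        tpr = tp / n1
        fpr = fp / n0
        dist = float(np.hypot(fpr, 1.0 - tpr))
        key = (dist, -tpr, fpr)
        if best is None or key < best[0]:
            best = (key, t, tpr, fpr, tp, fp)
    _, t, tpr, fpr, tp, fp = best
    tn = n0 - fp
    acc = (tp + tn) / (n1 + n0)
    return OperatingPointMetrics(
        threshold=float(t), sensitivity=float(tpr),
        specificity=float(1.0 - fpr), accuracy=float(acc),
    )


def severity_correlation(
    case_scores: pd.Series, caps_totals: pd.Series
) -> tuple[float, float]:
    """Pearson r (and exact-t two-sided p) between predicted case
    probability and CAPS total among cases."""
    x = np.asarray(case_scores, dtype=float)
    c = np.asarray(caps_totals.loc[case_scores.index]
                   if isinstance(caps_totals, pd.Series) else caps_totals,
                   dtype=float)
    if len(x) < 3:
        raise ValidationError("need at least 3 cases")
    if np.std(x) == 0 or np.std(c) == 0:
        raise ValidationError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, c)
    return float(r), float(p)


def subscale_correlations(
    case_scores: pd.Series, records: list[SampleRecord]
) -> dict[str, float]:
    """Pearson r of predicted probability vs each CAPS subscale, cases only."""
    by_id = {r.sample_id: r for r in records}
    out: dict[str, float] = {}
    ids = list(case_scores.index)
    for sub in ("reexperiencing", "avoidance", "hyperarousal"):
        vals = np.array([by_id[s].caps_subscales.get(sub, np.nan) for s in ids])
        mask = ~np.isnan(vals)
        if mask.sum() < 3 or np.std(vals[mask]) == 0:
            continue
        r, _ = stats.pearsonr(np.asarray(case_scores)[mask], vals[mask])
        out[sub] = float(r)
    return out


def stratified_performance(
    scores: pd.Series,
    records: list[SampleRecord],
    strata: Mapping[str, str] | None = None,
    n_bootstrap: int = 2000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> dict[str, StratumResult]:
    """Per-stratum ROC on the validation scores.

    ``strata`` maps stratum name -> mode: ``"within"`` compares cases vs
    controls inside the stratum (ethnicity strata); ``"cases_vs_all_controls"``
    compares the stratum's cases against every control (comorbid-MDD strata,
    where controls are MDD-free by design). Default strata: each observed
    ethnicity (within) plus mdd_positive / mdd_negative cases vs all
    controls. Strata lacking a class are reported not-evaluable.
    """
    by_id = {r.sample_id: r for r in records if r.sample_id in scores.index}
    ids = [s for s in scores.index if s in by_id]
    y = pd.Series({s: 1 if by_id[s].label == "ptsd" else 0
                   for s in ids if by_id[s].label in ("ptsd", "control")})
    if strata is None:
        strata = {f"ethnicity:{e}": "within"
                  for e in sorted({by_id[s].ethnicity for s in ids})}
        strata = {**strata, "mdd_positive": "cases_vs_all_controls",
                  "mdd_negative": "cases_vs_all_controls"}
    all_controls = [s for s in y.index if y[s] == 0]
    out: dict[str, StratumResult] = {}
    for name, mode in strata.items():
        if name.startswith("ethnicity:"):
            eth = name.split(":", 1)[1]
            members = [s for s in y.index if by_id[s].ethnicity == eth]
        elif name == "mdd_positive":
            members = [s for s in y.index if by_id[s].mdd]
        elif name == "mdd_negative":
            members = [s for s in y.index if not by_id[s].mdd]
        elif name == "all":
            members = list(y.index)
        else:
            raise ValidationError(f"unknown stratum {name!r}")
        cases = [s for s in members if y[s] == 1]
        if mode == "cases_vs_all_controls":
            controls = all_controls
        else:
            controls = [s for s in members if y[s] == 0]
        if not cases or not controls:
            out[name] = StratumResult(
                roc=None, n_cases=len(cases), n_controls=len(controls),
                reason="needs at least one case and one control",
            )
            continue
        sel = cases + controls
        out[name] = StratumResult(
            roc=roc_with_bootstrap(
                scores.loc[sel], y.loc[sel], n_bootstrap=n_bootstrap,
                ci_level=ci_level, seed=seed,
            ),
            n_cases=len(cases), n_controls=len(controls),
        )
    return out


def datatype_subpanels(
    training_matrix: FeatureMatrix,
    metadata: list[SampleRecord],
    panel: Panel,
    validation_matrix: FeatureMatrix,
    seed: int = 0,
    n_trees: int = 500,
    n_bootstrap: int = 2000,
    ci_level: float = 0.95,
    subthreshold: str = "exclude",
) -> dict[str, RocResult]:
    """Retrain and validate the panel restricted to each molecular data type."""
    types = training_matrix.types_of(panel.feature_ids)
    y_val = labels_for(
        metadata, sample_ids=validation_matrix.sample_ids, subthreshold="exclude"
    )
    out: dict[str, RocResult] = {}
    for dtype in sorted(set(types.values())):
        feats = [f for f in panel.feature_ids if types[f] == dtype]
        if not feats:
            continue
        sub_panel = panel.restricted_to(feats, stage="datatype_subset")
        model = train_panel_model(
            training_matrix, metadata, sub_panel, seed=seed, n_trees=n_trees,
            subthreshold=subthreshold,
        )
        s = predict_scores(model, validation_matrix, list(y_val.index))
        out[dtype] = roc_with_bootstrap(
            s, y_val, n_bootstrap=n_bootstrap, ci_level=ci_level, seed=seed
        )
    return out


def single_marker_accuracy(
    validation_matrix: FeatureMatrix,
    labels: pd.Series,
    panel: Panel,
) -> dict[str, float]:
    """Closest-to-(0,1) accuracy of each marker alone, orientation-free
    (the better of the raw and sign-flipped score is reported)."""
    ids = [s for s in labels.index if s in validation_matrix.values.index]
    y = labels.loc[ids]
    out: dict[str, float] = {}
    for f in panel.feature_ids:
        v = validation_matrix.values.loc[ids, f]
        mask = v.notna()
        acc_fwd = closest_to_01(v[mask], y[mask]).accuracy
        acc_rev = closest_to_01(-v[mask], y[mask]).accuracy
        out[f] = max(acc_fwd, acc_rev)
    return out


@dataclass
class ValidationReport:
    roc: RocResult
    op: OperatingPointMetrics
    severity_r: float
    severity_p: float
    subscale_r: dict[str, float] = field(default_factory=dict)
    strata: dict[str, StratumResult] = field(default_factory=dict)
    datatype_rocs: dict[str, RocResult] = field(default_factory=dict)
    single_marker_acc: dict[str, float] = field(default_factory=dict)
    panel_size: int = 0

    def to_dict(self) -> dict:
        return {
            "panel_size": self.panel_size,
            "roc": self.roc.to_dict(),
            "operating_point": self.op.to_dict(),
            "severity_correlation": {"r": self.severity_r, "p": self.severity_p},
            "subscale_correlations": self.subscale_r,
            "strata": {k: v.to_dict() for k, v in self.strata.items()},
            "datatype_panels": {k: v.to_dict() for k, v in self.datatype_rocs.items()},
            "single_marker_accuracy": self.single_marker_acc,
        }

    def summary(self) -> str:
        lines = [
            f"Panel size: {self.panel_size}",
            (f"Validation AUC: {self.roc.auc:.2f} "
             f"(bootstrap CI {self.roc.ci_low:.2f}-{self.roc.ci_high:.2f}, "
             f"{self.roc.n_bootstrap} iterations)"),
            (f"Operating point (closest to (0,1)): accuracy "
             f"{100 * self.op.accuracy:.0f}%, sensitivity "
             f"{100 * self.op.sensitivity:.0f}%, specificity "
             f"{100 * self.op.specificity:.0f}%"),
            (f"Severity correlation among cases: r = {self.severity_r:.2f} "
             f"(p = {self.severity_p:.3g})"),
        ]
        for sub, r in self.subscale_r.items():
            lines.append(f"  CAPS {sub}: r = {r:.2f}")
        for name, res in self.strata.items():
            if res.roc is None:
                lines.append(f"Stratum {name}: not evaluable ({res.reason})")
            else:
                lines.append(
                    f"Stratum {name}: AUC {res.roc.auc:.2f} "
                    f"({res.n_cases} cases vs {res.n_controls} controls)"
                )
        for dtype, roc in self.datatype_rocs.items():
            lines.append(f"Data-type panel {dtype}: AUC {roc.auc:.2f}")
        if self.single_marker_acc:
            top = sorted(self.single_marker_acc.items(),
                         key=lambda kv: -kv[1])[:5]
            lines.append("Top single markers by accuracy: "
                         + ", ".join(f"{f} ({100 * a:.0f}%)" for f, a in top))
        return "\n".join(lines)


def compile_report(
    roc: RocResult,
    op: OperatingPointMetrics,
    severity: tuple[float, float],
    subscale_r: dict[str, float] | None = None,
    strata: dict[str, StratumResult] | None = None,
    datatype_rocs: dict[str, RocResult] | None = None,
    single_marker_acc: dict[str, float] | None = None,
    panel_size: int = 0,
) -> ValidationReport:
    return ValidationReport(
        roc=roc, op=op, severity_r=severity[0], severity_p=severity[1],
        subscale_r=subscale_r or {}, strata=strata or {},
        datatype_rocs=datatype_rocs or {},
        single_marker_acc=single_marker_acc or {}, panel_size=panel_size,
    )
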