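"""End-to-end orchestration: simulate -> select -> downselect -> validate ->
report, with per-stage derived seeds, structured logging, and a run manifest
digesting every written artifact."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import FeatureMatrix, Panel, PipelineConfig, labels_for
from .downselect import (
    CvSpec,
    backward_eliminate,
    importance_prune,
    select_stage1,
)
from .evaluate import (
    closest_to_01,
    compile_report,
    datatype_subpanels,
    predict_scores,
    roc_with_bootstrap,
    severity_correlation,
    single_marker_accuracy,
    stratified_performance,
    subscale_correlations,
    train_panel_model,
)
from .features import apply_normalizer, fit_normalizer
from .io import (
    read_feature_matrix,
    read_metadata,
    write_feature_matrix,
    write_json,
    write_metadata,
    write_panel,
)
from .selectors import (
    fold_change_filter,
    pvalue_filter,
    qvalue_filter,
    rf_rank_select,
    svm_rfe_select,
    union_panels,
)
from .simulate import SimulationConfig, SyntheticStudy, generate_study

logger = logging.getLogger("ptsdpanel.pipeline")

STAGES = ("simulate", "select", "downselect", "validate", "report")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: hash of stage name + global seed, below 2^31."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def log_event(stage: str, level: int, message: str) -> None:
    logger.log(level, "stage=%s %s", stage, message)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def simulation_config_from_yaml(path: str | Path) -> SimulationConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimulationConfig(**doc)


def load_study(data_dir: str | Path) -> SyntheticStudy:
    """Load cohorts previously written by the simulate stage (or supplied by
    the user in the same layout)."""
    from .simulate import PlantedFeature

    data_dir = Path(data_dir)
    matrices = {}
    for cohort in ("discovery", "recall", "validation"):
        matrices[cohort] = read_feature_matrix(
            data_dir / f"{cohort}_features.tsv", data_dir / "feature_types.tsv"
        )
    metadata = read_metadata(data_dir / "metadata.tsv")
    truth: list[PlantedFeature] = []
    truth_path = data_dir / "truth.tsv"
    if truth_path.exists():
        tdf = pd.read_csv(truth_path, sep="\t")
        truth = [
            PlantedFeature(str(r.feature_id), float(r.d), int(r.sign))
            for r in tdf.itertuples()
        ]
    return SyntheticStudy(matrices=matrices, metadata=metadata, truth=truth)


def write_study(study: SyntheticStudy, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for cohort, fm in study.matrices.items():
        p = out / f"{cohort}_features.tsv"
        write_feature_matrix(fm, p, out / "feature_types.tsv")
        written.append(p)
    written.append(out / "feature_types.tsv")
    write_metadata(study.metadata, out / "metadata.tsv")
    written.append(out / "metadata.tsv")
    if study.truth:
        pd.DataFrame(
            [{"feature_id": t.feature_id, "d": t.d, "sign": t.sign}
             for t in study.truth]
        ).to_csv(out / "truth.tsv", sep="\t", index=False)
        written.append(out / "truth.tsv")
    return written


def run_candidate_selection(
    study: SyntheticStudy, config: PipelineConfig, seed: int
) -> Panel:
    """Ensemble selection on the discovery cohort."""
    fm = study.matrices["discovery"]
    labels = labels_for(study.records_for("discovery"),
                        sample_ids=fm.sample_ids)
    # statistical filters and classifiers see z-scored values; fold change
    # stays on the raw scale where ratios mean something
    norm = fit_normalizer(fm, fm.sample_ids)
    z = apply_normalizer(norm, fm)
    results = [
        pvalue_filter(z, labels, config.alpha),
        qvalue_filter(z, labels, config.q_threshold),
        fold_change_filter(fm, labels, config.fold_change_threshold),
        svm_rfe_select(z, labels, step=config.svm_rfe_step,
                       top_k=config.svm_rfe_top_k),
        rf_rank_select(z, labels, top_k=config.rf_rank_top_k, seed=seed),
    ]
    for r in results:
        log_event("select", logging.INFO,
                  f"selector={r.selector_name} n_selected={len(r.selected)}")
    return union_panels(results)


def refinement_data(study: SyntheticStudy, use_both_visits: bool = True):
    """Samples feeding panel refinement: the recalled participants.

    By default both of their visits contribute — the baseline (T0) rows from
    the discovery matrix plus the follow-up (T1) rows — so markers are
    rewarded for tracking each subject's phenotype over time and the
    refinement sees roughly twice the samples. ``use_both_visits=False``
    restricts to the follow-up visit only.
    """
    recall_records = study.records_for("recall")
    records = list(recall_records)
    values = study.matrices["recall"].values
    if use_both_visits:
        subjects = {r.subject_id for r in recall_records}
        t0 = [r for r in study.records_for("discovery")
              if r.subject_id in subjects]
        values = pd.concat(
            [study.matrices["discovery"].values.loc[[r.sample_id for r in t0]],
             values]
        )
        records = t0 + records
    fm = FeatureMatrix(values, dict(study.matrices["recall"].feature_types))
    return fm, records


def run_downselection(
    study: SyntheticStudy, candidates: Panel, config: PipelineConfig, seed: int
):
    """Two-stage refinement on the recall cohort (subthreshold handled per
    config)."""
    fm, records = refinement_data(study)
    labels = labels_for(records, sample_ids=fm.sample_ids,
                        subthreshold=config.subthreshold_mapping)
    cv = CvSpec(folds=config.cv_folds, repeats=config.cv_repeats, seed=seed,
                scorer=config.elimination_scorer)
    norm = fit_normalizer(fm.subset_features(candidates.feature_ids),
                          fm.sample_ids)
    usable = candidates.restricted_to(list(norm.location.index))
    z = apply_normalizer(norm, fm.subset_features(usable.feature_ids))
    min_size = min(config.min_panel_size, len(usable) - 1)
    trajectory = backward_eliminate(z, labels, usable, cv, min_size=min_size)
    stage1 = select_stage1(trajectory)
    final = importance_prune(
        z, labels, stage1, fraction=config.importance_fraction, seed=seed
    )
    return trajectory, stage1, final


def run_validation(
    study: SyntheticStudy, panel: Panel, config: PipelineConfig, seed: int
):
    """Train on discovery + recall, evaluate once on validation."""
    disc = study.matrices["discovery"]
    recall = study.matrices["recall"]
    val = study.matrices["validation"]
    combined = FeatureMatrix(
        pd.concat([disc.values, recall.values], axis=0),
        dict(disc.feature_types),
    )
    model = train_panel_model(
        combined, study.metadata, panel, seed=seed,
        subthreshold=config.subthreshold_mapping,
        validation_sample_ids=val.sample_ids,
    )
    val_records = study.records_for("validation")
    y_val = labels_for(val_records, sample_ids=val.sample_ids)
    scores = predict_scores(model, val, list(y_val.index))
    roc = roc_with_bootstrap(scores, y_val, n_bootstrap=config.n_bootstrap,
                             ci_level=config.ci_level, seed=seed)
    op = closest_to_01(scores, y_val)
    case_ids = [s for s in y_val.index if y_val[s] == 1]
    caps = pd.Series({r.sample_id: r.caps_total for r in val_records})
    severity = severity_correlation(scores.loc[case_ids], caps)
    sub_r = subscale_correlations(scores.loc[case_ids], val_records)
    strata = stratified_performance(
        scores, val_records, n_bootstrap=config.n_bootstrap,
        ci_level=config.ci_level, seed=seed,
    )
    dtype_rocs = datatype_subpanels(
        combined, study.metadata, panel, val, seed=seed,
        n_bootstrap=config.n_bootstrap, ci_level=config.ci_level,
        subthreshold=config.subthreshold_mapping,
    )
    single = single_marker_accuracy(val, y_val, panel)
    report = compile_report(
        roc, op, severity, subscale_r=sub_r, strata=strata,
        datatype_rocs=dtype_rocs, single_marker_acc=single,
        panel_size=len(panel),
    )
    return model, scores, report


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    sim_config: SimulationConfig | None = None,
    data_dir: str | Path | None = None,
) -> dict:
    """Execute all stages; returns the run manifest (also written to disk).

    Cohorts come either from the synthetic generator (``sim_config``) or
    from a directory in the simulate stage's layout (``data_dir``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    manifest: dict = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
        "artifacts": {},
    }
    written: list[Path] = []
    stage = "simulate"
    try:
        t0 = time.time()
        log_event(stage, logging.INFO, "start")
        if data_dir is not None:
            study = load_study(data_dir)
        else:
            sim = sim_config or SimulationConfig(seed=derive_seed(seed, stage))
            study = generate_study(sim)
            written += write_study(study, out / "data")
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        log_event(stage, logging.INFO, "end")

        stage = "select"
        t0 = time.time()
        log_event(stage, logging.INFO, "start")
        candidates = run_candidate_selection(study, config,
                                             derive_seed(seed, stage))
        write_panel(candidates, out / "candidates.json")
        written.append(out / "candidates.json")
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "n_candidates": len(candidates),
        }
        log_event(stage, logging.INFO, f"end n_candidates={len(candidates)}")

        stage = "downselect"
        t0 = time.time()
        log_event(stage, logging.INFO, "start")
        trajectory, stage1, final = run_downselection(
            study, candidates, config, derive_seed(seed, stage)
        )
        trajectory.to_frame().to_csv(out / "trajectory.tsv", sep="\t",
                                     index=False)
        write_panel(stage1, out / "stage1_panel.json")
        write_panel(final, out / "final_panel.json")
        written += [out / "trajectory.tsv", out / "stage1_panel.json",
                    out / "final_panel.json"]
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "n_stage1": len(stage1),
            "n_final": len(final),
        }
        log_event(stage, logging.INFO,
                  f"end n_stage1={len(stage1)} n_final={len(final)}")

        stage = "validate"
        t0 = time.time()
        log_event(stage, logging.INFO, "start")
        model, scores, report = run_validation(
            study, final, config, derive_seed(seed, stage)
        )
        write_json(report.to_dict(), out / "report.json")
        scores.rename("score").to_csv(out / "validation_scores.tsv", sep="\t")
        pd.DataFrame({"fpr": report.roc.fpr, "tpr": report.roc.tpr,
                      "threshold": report.roc.thresholds}).to_csv(
            out / "roc_points.tsv", sep="\t", index=False)
        written += [out / "report.json", out / "validation_scores.tsv",
                    out / "roc_points.tsv"]
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "validation_auc": report.roc.auc,
        }
        log_event(stage, logging.INFO, f"end auc={report.roc.auc:.3f}")

        stage = "report"
        t0 = time.time()
        (out / "report.txt").write_text(report.summary() + "\n")
        written.append(out / "report.txt")
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
    except Exception as exc:  # partial outputs stay on disk for debugging
        log_event(stage, logging.ERROR, f"failed: {exc}")
        raise StageFailure(stage, exc) from exc

    manifest["artifacts"] = {
        str(p.relative_to(out)): _sha256(p) for p in written
    }
    write_json(manifest, out / "manifest.json")
    return manifest
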