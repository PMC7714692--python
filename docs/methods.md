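# Methods

`ptsdpanel` implements a three-stage blood-biomarker discovery workflow for
case-control psychiatric phenotypes, modelled on multi-omic PTSD panels in
combat-exposed veteran cohorts, together with a synthetic multi-cohort
generator that makes every stage testable without participant data.

## Study design being modelled

Three linked cohorts:

* **discovery** — 77 PTSD cases / 74 trauma-exposed controls, used only to
  nominate candidate markers;
* **recall** — 55 discovery participants re-assessed roughly three years
  later (15 still PTSD, 11 with intermediate "subthreshold" symptoms,
  29 controls), used only for panel refinement;
* **validation** — an independent 26/26 sample, touched once, for the final
  performance estimate.

Diagnosis is anchored to the Clinician-Administered PTSD Scale (CAPS):
cases score ≥ 40 at inclusion, controls < 20, subthreshold in [20, 40).
Markers span six data types: DNA methylation (beta values in [0, 1]),
miRNAs, proteins, metabolites, routine clinical labs, and physiological
measurements, plus `derived` ratio features.

## Stage 1 — ensemble candidate selection (discovery cohort)

Five selectors run on the discovery cohort and their selections are
unioned with provenance ("wisdom of crowds"):

* Welch t-test filter, p < α (default α = 0.05);
* Benjamini–Hochberg q-value filter, q < 0.10;
* fold-change filter: |log2(case mean / control mean)| ≥ 0.5 for positive
  concentration-scale types; |standardized mean difference| ≥ 0.5 for
  bounded/signed types, where a mean ratio is meaningless;
* linear SVM-RFE (C = 1): refit each round, drop the 10% of features with
  smallest squared weight, keep the top 50;
* random-forest importance ranking (500 trees, √p features per split),
  top 50.

External hypothesis-driven selectors (literature lists, polygenic scores,
published hybrid algorithms) plug in through `fixed_list_select`; the union
architecture treats them like any other selector. Statistical filters and
classifiers see z-scored values; the fold-change filter sees raw values.

## Stage 2 — two-step refinement (recall cohort)

**Refinement data.** Recalled participants carry two visits. By default both
feed refinement — their baseline (T0) rows plus follow-up (T1) rows, with
each visit labelled by its own diagnosis — because the refinement cohort's
purpose is precisely to reward markers that track phenotype over time, and
because importance estimates on the ~44 labelled follow-up samples alone
are too unstable to rank weak complementary markers reliably. A
`use_both_visits=False` switch restricts to T1. Subthreshold visits are
excluded from binary labels by default (configurable `as_case` /
`as_control`).

**Backward elimination.** Repeatedly remove the single marker whose removal
leaves the remaining set with the largest "average AUC", recording the full
trajectory; the set at the trajectory's maximum (earliest step on ties,
i.e. the largest panel) becomes the stage-1 panel. Two scorers define
"average AUC" behind `CvSpec.scorer`:

* `model_cv` — mean ROC-AUC of a 500-tree random forest over repeated
  stratified CV (5 × 5 by default). Faithful to a trajectory that can
  *decline*, but O(k²) classifier fits; practical only for small panels.
* `univariate_mean` — mean over markers of the orientation-corrected
  single-marker AUC max(a, 1 − a). Removing the weakest marker is then
  provably optimal, the trajectory is monotone nondecreasing, and the
  whole elimination reduces to cached arithmetic. This is the pipeline's
  default scorer and the subject of the exhaustive-search oracle test.
  Under it the stage-1 panel is exactly the top `min_panel_size` markers
  (default 20).

Within an elimination step every candidate removal shares one CV-split
realization, so split noise cancels out of the comparison. Ties break by
ascending feature id everywhere.

**Importance pruning.** A random forest is fit on the stage-1 markers and
markers with impurity-decrease importance strictly above 30% of the maximum
are retained (at fraction 1.0 the rule degenerates, so the argmax marker(s)
are kept). The importance forest uses `max_features=2` rather than √p:
with larger candidate pools per split, impurity importance concentrates on
the two or three strongest markers and masks weak complementary ones —
exactly the markers a multi-marker panel exists to keep. With near-random
split-variable choice each marker's importance tracks its marginal utility;
in simulation this raises weak planted markers (d ≈ 1.2) from ~0.15 to
~0.4–0.8 of the maximum importance while markers with no true effect stay
below the 0.30 bar. The final classifier and the ranking selector keep √p.

## Stage 3 — validation

A 500-tree random forest is trained on the combined discovery + recall
samples (z-scoring statistics fit on training samples only; missing values
imputed to the training mean, i.e. 0 after scaling; constant features
dropped with a warning) and applied once to the validation cohort. A
leakage guard raises if any validation sample id appears in training.
Reported:

* ROC/AUC with a class-stratified percentile bootstrap CI (2000 resamples,
  95% by default). Percentile rather than BCa: the simplest defensible
  method when nothing more specific is required.
* Operating point closest to (0, 1): threshold minimizing
  √(FPR² + (1 − TPR)²) over all distinct scores; ties prefer higher
  sensitivity, then higher specificity; a score equal to the threshold is
  called positive. Sensitivity, specificity, and accuracy at that point.
* Pearson correlation (exact-t two-sided p) of predicted case probability
  with CAPS total among cases, plus per-subscale correlations
  (re-experiencing, avoidance, hyperarousal).
* Stratified ROC: within-stratum cases vs controls for ethnicity strata;
  comorbid-MDD strata compare stratum cases against *all* controls
  (controls are MDD-free by design, so a within-stratum contrast is
  impossible). Strata lacking a class are reported not-evaluable.
* Per-data-type sub-panels (model retrained on panel ∩ type) and
  orientation-free single-marker accuracies.

Derived metabolite ratios — GABR = arginine / (ornithine + citrulline) and
lactate/citrate — are appended as `derived` features; both are invariant
under common positive rescaling of their inputs. Fold-change *directions*
(Table of up/down calls per cohort) are computed on raw values as the sign
of the case-minus-control mean; an exact zero is deterministically "up"
(reproducibility; zero ties are measure-zero on real data). The package
ships the published 28-marker three-cohort direction table; counting its
arrows gives 16 markers consistent across all three cohorts and 22
consistent between discovery and recall.

## Synthetic data generator

Each feature is a standard-normal latent variable mapped monotonically to
its type's natural scale: logistic squash for methylation (strictly inside
(0, 1)), log-normal for miRNA/protein/metabolite/clinical labs, affine
(70 ± 10, heart-rate-like) for physiological. Within a type, features form
clusters of 5 sharing a latent factor with loading √ρ (pairwise correlation
ρ, default 0.3 — "small clusters of moderately correlated features").
Planted markers (default 10 among ~1,000 features, standardized effects
d spaced over [1.2, 2.0], alternating signs, spread round-robin across
types) are shifted in cases on the latent scale by
d·sign·[(1 − κ)·φ + κ·s(CAPS)], where φ is 1 for cases, 0 for controls and
intermediate for subthreshold participants, s(·) is a linear severity map
anchored at 0 for the control CAPS mean (3.6) and 1 for the case mean (68),
and κ (default 0.5) couples marker biology to symptom severity. Because the
scale maps are monotone, a planted marker's population univariate AUC is
Φ(d/√2), which the tests use as a closed-form oracle.

CAPS totals are drawn from Normal(68.0, 16.1) truncated to [40, 136] for
cases, Normal(3.6, 4.9) truncated to [0, 20) for controls, and uniform
[20, 40) for subthreshold — matching the cohorts' published summary
statistics. Ethnicity and comorbid-MDD flags follow the published
per-cohort frequencies; an optional shared MDD effect on the planted
markers (default off) emulates MDD-linked signal. The recall cohort
re-samples discovery subjects: transition probabilities (defaults 0.15
case→subthreshold, 0.05 case→control, 0.10 control→subthreshold) decide how
many follow-up subthreshold/control slots are filled from former cases,
then exact published label counts (15/11/29) are met by sampling from the
eligible pools; CAPS is re-drawn for the new label and planted effects
re-scale to the new severity, so recalled biology tracks phenotype change.
Everything is bit-reproducible from one seed.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: genome-wide methylation array structure
(~10⁶ probes; the default ~1,000 features preserve only the p ≫ n regime),
miRNA count overdispersion, batch and platform effects, assay missingness
patterns, subject-level longitudinal correlation between visits (T0 and T1
noise are independent draws), and any real biology of subthreshold
returnees (their intermediate-effect scaling is a modelling choice).

## Numerical and reproducibility choices

One global seed fans out to per-stage seeds via a stable hash of the stage
name, kept below 2³¹, so stages rerun in isolation reproduce the pipeline
run; two runs with the same config and seed produce byte-identical
artifacts (verified by manifest digests). AUC is computed so that it equals
the pairwise Mann–Whitney statistic (#concordant + ½ #ties)/(n₁n₀) exactly;
the operating point equals exhaustive threshold search exactly. Identifier
matching is case-sensitive and whitespace-stripped. Problem sizes used by
the test suite and the acceptance script — 20 seeds at the study's cohort
sizes with ~1,000 features for end-to-end recovery, 100 scaled (200-resample)
runs for null CI coverage, 10⁴ samples for the closed-form AUC check — were
chosen to hold Monte-Carlo error well below the tested margins.

## Known limitations

* The univariate-mean elimination scorer cannot exhibit the
  performance-decline trajectory shape that motivates selecting "the set
  before the decline"; with it, stage 1 is a top-k cut. The model-CV scorer
  reproduces the decline but is quadratic in panel size.
* Impurity-based importances remain biased toward high-cardinality
  continuous features and are estimated on refinement data that already
  selected the markers; the 30%-of-max rule therefore cannot remove
  markers whose apparent refinement-cohort signal is luck shared across
  both refinement steps.
* Bootstrap CIs are percentile CIs on 52 validation samples; below ~30
  samples per class their coverage degrades.
* The generator's independence of visit-level noise slightly understates
  the value of longitudinal consistency filtering on real data.
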