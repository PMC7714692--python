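"""Synthetic multi-cohort, multi-omic study generator.

Emulates the statistical structure the discovery/down-selection/validation
pipeline assumes, at desk scale:

* three linked cohorts — discovery (77 PTSD / 74 control), recall (15 PTSD /
  11 subthreshold / 29 control, drawn from discovery subjects with symptom
  transitions at follow-up), validation (26 / 26, independent);
* six molecular data-type blocks on their natural scales (methylation betas
  in (0,1), log-normal miRNA/protein/metabolite/clinical-lab concentrations,
  Gaussian physiological measurements);
* within-type correlation clusters via shared latent factors;
* a small set of planted discriminative features whose standardized effect
  d is partially coupled to the continuous CAPS severity score, so that
  predicted case probabilities can correlate with symptom severity and
  recalled participants' biology tracks their phenotype change.

Effects are planted additively on the standard-normal latent scale and then
pushed through a monotone map to each type's natural scale, so d stays
interpretable: a single planted feature has population univariate AUC
Phi(d / sqrt(2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import truncnorm

from .core import FeatureMatrix, SampleRecord, ValidationError
import pandas as pd

#: CAPS-total distribution anchors: cases 68.0 (sd 16.1), controls 3.6 (4.9)
CAPS_PTSD_MEAN, CAPS_PTSD_SD = 68.0, 16.1
CAPS_CONTROL_MEAN, CAPS_CONTROL_SD = 3.6, 4.9
CAPS_MAX = 136.0

_ETHNICITIES = ("hispanic", "nh_asian", "nh_black", "nh_white", "nh_other")

# per (cohort, label): ethnicity frequencies and MDD prevalence, matching the
# study's demographic tables
_ETHNICITY_FREQS = {
    ("discovery", "ptsd"): (0.44, 0.01, 0.27, 0.23, 0.04),
    ("discovery", "control"): (0.32, 0.07, 0.22, 0.32, 0.07),
    ("validation", "ptsd"): (0.42, 0.12, 0.19, 0.27, 0.00),
    ("validation", "control"): (0.08, 0.15, 0.15, 0.62, 0.00),
}
_MDD_PREVALENCE = {
    ("discovery", "ptsd"): 0.55,
    ("discovery", "control"): 0.0,
    ("validation", "ptsd"): 0.35,
    ("validation", "control"): 0.04,
}

# natural-scale parameters per data type: (kind, location, spread)
_TYPE_SCALES = {
    "methylation": ("logistic", 0.0, 1.0),
    "mirna": ("lognormal", np.log(100.0), 0.8),
    "protein": ("lognormal", np.log(1000.0), 0.6),
    "metabolite": ("lognormal", np.log(50.0), 0.7),
    "clinical_lab": ("lognormal", np.log(20.0), 0.5),
    "physiological": ("raw", 70.0, 10.0),
}

_TYPE_PREFIX = {
    "methylation": "meth",
    "mirna": "mir",
    "protein": "prot",
    "metabolite": "metab",
    "clinical_lab": "lab",
    "physiological": "phys",
}


def default_features_per_type() -> dict[str, int]:
    """~1,000 features total: desk scale, but still p >> n (1,000 >> 151)."""
    return {
        "methylation": 400,
        "mirna": 150,
        "protein": 150,
        "metabolite": 150,
        "clinical_lab": 100,
        "physiological": 50,
    }


def default_cohort_sizes() -> dict[str, dict[str, int]]:
    return {
        "discovery": {"ptsd": 77, "control": 74},
        "recall": {"ptsd": 15, "subthreshold": 11, "control": 29},
        "validation": {"ptsd": 26, "control": 26},
    }


@dataclass
class SimulationConfig:
    """Generative settings; defaults are the study's cohort structure."""

    cohort_sizes: dict[str, dict[str, int]] = field(default_factory=default_cohort_sizes)
    n_features_per_type: dict[str, int] = field(default_factory=default_features_per_type)
    n_informative: int = 10
    effect_sizes: list[float] | None = None  # default: linspace(1.2, 2.0)
    effect_directions: list[int] | None = None  # default: alternating +1/-1
    block_correlation: float = 0.3
    cluster_size: int = 5
    severity_coupling: float = 0.5
    recall_transition_probs: dict[str, float] = field(
        default_factory=lambda: {
            "ptsd_to_subthreshold": 0.15,
            "ptsd_to_control": 0.05,
            "control_to_subthreshold": 0.10,
        }
    )
    mdd_effect_size: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_sizes is None:
            self.effect_sizes = list(np.linspace(1.2, 2.0, self.n_informative))
        if self.effect_directions is None:
            self.effect_directions = [(-1) ** i for i in range(self.n_informative)]
        if len(self.effect_sizes) != self.n_informative:
            raise ValidationError("effect_sizes length must equal n_informative")
        if len(self.effect_directions) != self.n_informative:
            raise ValidationError("effect_directions length must equal n_informative")
        if not all(np.isfinite(self.effect_sizes)):
            raise ValidationError("effect sizes must be finite")
        if not all(s in (-1, 1) for s in self.effect_directions):
            raise ValidationError("effect directions must be +1 or -1")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValidationError("block_correlation must be in [0, 1)")
        if not 0.0 <= self.severity_coupling <= 1.0:
            raise ValidationError("severity_coupling must be in [0, 1]")
        for k, p in self.recall_transition_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"transition probability {k} outside [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")
        for c, counts in self.cohort_sizes.items():
            if any(n <= 0 for n in counts.values()):
                raise ValidationError(f"cohort {c}: counts must be positive")
        total = sum(self.n_features_per_type.values())
        if self.n_informative > total:
            raise ValidationError(
                f"n_informative={self.n_informative} exceeds total feature "
                f"count {total}"
            )


@dataclass(frozen=True)
class PlantedFeature:
    feature_id: str
    d: float
    sign: int


@dataclass
class SyntheticStudy:
    matrices: dict[str, FeatureMatrix]
    metadata: list[SampleRecord]
    truth: list[PlantedFeature]

    @property
    def truth_ids(self) -> list[str]:
        return [t.feature_id for t in self.truth]

    def records_for(self, cohort: str) -> list[SampleRecord]:
        return [r for r in self.metadata if r.cohort == cohort]


def simulate_caps(label: str, rng: np.random.Generator) -> float:
    """Draw a CAPS total consistent with the diagnostic label.

    PTSD: Normal(68.0, 16.1) truncated to [40, 136]; control: Normal(3.6,
    4.9) truncated to [0, 20); subthreshold: uniform on [20, 40).
    """
    if label == "ptsd":
        a = (40.0 - CAPS_PTSD_MEAN) / CAPS_PTSD_SD
        b = (CAPS_MAX - CAPS_PTSD_MEAN) / CAPS_PTSD_SD
        return float(
            truncnorm.rvs(a, b, loc=CAPS_PTSD_MEAN, scale=CAPS_PTSD_SD,
                          random_state=rng)
        )
    if label == "control":
        a = (0.0 - CAPS_CONTROL_MEAN) / CAPS_CONTROL_SD
        b = (20.0 - CAPS_CONTROL_MEAN) / CAPS_CONTROL_SD
        v = float(
            truncnorm.rvs(a, b, loc=CAPS_CONTROL_MEAN, scale=CAPS_CONTROL_SD,
                          random_state=rng)
        )
        return min(v, np.nextafter(20.0, 0.0))
    if label == "subthreshold":
        return float(rng.uniform(20.0, 40.0))
    raise ValidationError(f"unknown label {label!r}")


def severity_scale(caps_total: float) -> float:
    """Monotone severity map: 0 at the control CAPS mean, 1 at the case mean.

    Linear in CAPS, floored at 0; the CAPS ceiling of 136 bounds it near 2.
    """
    if caps_total < 0:
        raise ValidationError("caps_total must be non-negative")
    return max(0.0, (caps_total - CAPS_CONTROL_MEAN)
               / (CAPS_PTSD_MEAN - CAPS_CONTROL_MEAN))


def _phenotype_intensity(label: str, caps: float, kappa: float) -> float:
    # baseline intensity by label; severity coupling blends in the continuous
    # CAPS position. Subthreshold participants sit between the groups.
    base = {"ptsd": 1.0, "control": 0.0}.get(label)
    if base is None:  # subthreshold: intermediate by severity
        base = min(1.0, severity_scale(caps))
    return (1.0 - kappa) * base + kappa * severity_scale(caps)


def _subscale_split(caps: float, rng: np.random.Generator) -> dict[str, float]:
    w = rng.dirichlet((7.0, 6.0, 7.0))
    return {
        "reexperiencing": round(float(caps * w[0]), 1),
        "avoidance": round(float(caps * w[1]), 1),
        "hyperarousal": round(float(caps * w[2]), 1),
    }


def _feature_layout(cfg: SimulationConfig):
    """Deterministic feature ids, type map, and cluster assignment."""
    feature_ids: list[str] = []
    types: dict[str, str] = {}
    cluster_of: list[int] = []
    next_cluster = 0
    for ftype in _TYPE_PREFIX:
        n = cfg.n_features_per_type.get(ftype, 0)
        for j in range(n):
            fid = f"{_TYPE_PREFIX[ftype]}_{j:04d}"
            feature_ids.append(fid)
            types[fid] = ftype
            cluster_of.append(next_cluster + j // cfg.cluster_size)
        next_cluster += (n + cfg.cluster_size - 1) // cfg.cluster_size
    return feature_ids, types, np.asarray(cluster_of), next_cluster


def _pick_planted(cfg: SimulationConfig, feature_ids, types,
                  rng: np.random.Generator) -> list[PlantedFeature]:
    # round-robin across data types so the signal spans multiple blocks
    by_type: dict[str, list[str]] = {}
    for f in feature_ids:
        by_type.setdefault(types[f], []).append(f)
    present = [t for t in _TYPE_PREFIX if by_type.get(t)]
    planted: list[PlantedFeature] = []
    used: set[str] = set()
    i = 0
    while len(planted) < cfg.n_informative:
        pool = [f for f in by_type[present[i % len(present)]] if f not in used]
        i += 1
        if not pool:
            continue
        fid = pool[int(rng.integers(len(pool)))]
        used.add(fid)
        k = len(planted)
        planted.append(
            PlantedFeature(fid, float(cfg.effect_sizes[k]),
                           int(cfg.effect_directions[k]))
        )
    return planted


def _latent_block(n: int, cluster_of: np.ndarray, n_clusters: int, rho: float,
                  rng: np.random.Generator) -> np.ndarray:
    factors = rng.standard_normal((n, n_clusters))
    noise = rng.standard_normal((n, len(cluster_of)))
    return np.sqrt(rho) * factors[:, cluster_of] + np.sqrt(1.0 - rho) * noise


def _to_natural_scale(z: np.ndarray, feature_ids, types,
                      baseline: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    for j, fid in enumerate(feature_ids):
        kind, loc, spread = _TYPE_SCALES[types[fid]]
        shifted = loc + baseline[j] + spread * z[:, j] if kind != "logistic" \
            else baseline[j] + z[:, j]
        if kind == "logistic":
            out[:, j] = expit(shifted)
        elif kind == "lognormal":
            out[:, j] = np.exp(shifted)
        else:
            out[:, j] = shifted
    return out


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate the three linked cohorts; bit-reproducible from ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    feature_ids, types, cluster_of, n_clusters = _feature_layout(cfg)
    planted = _pick_planted(cfg, feature_ids, types, rng)
    planted_idx = {p.feature_id: feature_ids.index(p.feature_id) for p in planted}
    # per-feature baseline offsets differentiate features within a type
    baseline = rng.normal(0.0, 0.3, size=len(feature_ids))

    metadata: list[SampleRecord] = []
    matrices: dict[str, FeatureMatrix] = {}

    def draw_cohort(cohort: str, records: list[SampleRecord]) -> FeatureMatrix:
        n = len(records)
        z = _latent_block(n, cluster_of, n_clusters, cfg.block_correlation, rng)
        for i, rec in enumerate(records):
            m = _phenotype_intensity(rec.label, rec.caps_total,
                                     cfg.severity_coupling)
            if cfg.mdd_effect_size and rec.mdd:
                m_extra = cfg.mdd_effect_size
            else:
                m_extra = 0.0
            for p in planted:
                z[i, planted_idx[p.feature_id]] += p.sign * (p.d * m + m_extra)
        x = _to_natural_scale(z, feature_ids, types, baseline)
        if cfg.missing_rate > 0:
            mask = rng.random(x.shape) < cfg.missing_rate
            x = np.where(mask, np.nan, x)
        df = pd.DataFrame(x, index=[r.sample_id for r in records],
                          columns=feature_ids)
        return FeatureMatrix(values=df, feature_types=dict(types))

    def make_record(sample_id, subject_id, cohort, label, rng,
                    ethnicity=None, mdd=None, timepoint="T0") -> SampleRecord:
        caps = simulate_caps(label, rng)
        if ethnicity is None:
            freqs = _ETHNICITY_FREQS[(cohort, label)]
            probs = np.asarray(freqs) / np.sum(freqs)
            ethnicity = _ETHNICITIES[int(rng.choice(len(_ETHNICITIES), p=probs))]
        if mdd is None:
            mdd = bool(rng.random() < _MDD_PREVALENCE[(cohort, label)])
        return SampleRecord(
            sample_id=sample_id, subject_id=subject_id, cohort=cohort,
            label=label, caps_total=caps,
            caps_subscales=_subscale_split(caps, rng),
            ethnicity=ethnicity, mdd=mdd, timepoint=timepoint,
        )

    # --- discovery (T0) ---
    disc_records: list[SampleRecord] = []
    counter = 0
    for label in ("ptsd", "control"):
        for _ in range(cfg.cohort_sizes["discovery"][label]):
            counter += 1
            subj = f"subj_{counter:04d}"
            disc_records.append(
                make_record(f"{subj}_T0", subj, "discovery", label, rng)
            )
    matrices["discovery"] = draw_cohort("discovery", disc_records)
    metadata.extend(disc_records)

    # --- recall (T1): re-sampled discovery subjects with transitions ---
    recall_sizes = cfg.cohort_sizes["recall"]
    tp = cfg.recall_transition_probs
    disc_ptsd = [r for r in disc_records if r.label == "ptsd"]
    disc_ctrl = [r for r in disc_records if r.label == "control"]
    rng.shuffle(disc_ptsd)
    rng.shuffle(disc_ctrl)

    n_sub = recall_sizes.get("subthreshold", 0)
    p_ps, p_cs = tp["ptsd_to_subthreshold"], tp["control_to_subthreshold"]
    w = p_ps / (p_ps + p_cs) if (p_ps + p_cs) > 0 else 0.5
    n_sub_from_ptsd = int(rng.binomial(n_sub, w)) if n_sub else 0
    n_ctrl_from_ptsd = int(rng.binomial(recall_sizes["control"],
                                        tp["ptsd_to_control"]))
    # clip to pool availability: shed converts first, then raise if the
    # stay-PTSD target alone exceeds the discovery pool
    deficit = (recall_sizes["ptsd"] + n_sub_from_ptsd + n_ctrl_from_ptsd
               - len(disc_ptsd))
    if deficit > 0:
        take = min(deficit, n_ctrl_from_ptsd)
        n_ctrl_from_ptsd -= take
        deficit -= take
        take = min(deficit, n_sub_from_ptsd)
        n_sub_from_ptsd -= take
        deficit -= take
        if deficit > 0:
            raise ValidationError(
                "recall ptsd target exceeds the discovery ptsd pool"
            )
    if (n_sub - n_sub_from_ptsd
            + recall_sizes["control"] - n_ctrl_from_ptsd) > len(disc_ctrl):
        raise ValidationError(
            "recall subthreshold/control targets exceed the discovery "
            "control pool"
        )

    recall_plan: list[tuple[SampleRecord, str]] = []
    pool_p = iter(disc_ptsd)
    pool_c = iter(disc_ctrl)
    for _ in range(recall_sizes["ptsd"]):
        recall_plan.append((next(pool_p), "ptsd"))
    for _ in range(n_sub_from_ptsd):
        recall_plan.append((next(pool_p), "subthreshold"))
    for _ in range(n_ctrl_from_ptsd):
        recall_plan.append((next(pool_p), "control"))
    for _ in range(n_sub - n_sub_from_ptsd):
        recall_plan.append((next(pool_c), "subthreshold"))
    for _ in range(recall_sizes["control"] - n_ctrl_from_ptsd):
        recall_plan.append((next(pool_c), "control"))

    recall_records = [
        make_record(f"{orig.subject_id}_T1", orig.subject_id, "recall",
                    new_label, rng, ethnicity=orig.ethnicity, mdd=orig.mdd,
                    timepoint="T1")
        for orig, new_label in recall_plan
    ]
    matrices["recall"] = draw_cohort("recall", recall_records)
    metadata.extend(recall_records)

    # --- validation: independent draw from the same generative law ---
    val_records: list[SampleRecord] = []
    for label in ("ptsd", "control"):
        for _ in range(cfg.cohort_sizes["validation"][label]):
            counter += 1
            subj = f"subj_{counter:04d}"
            val_records.append(
                make_record(f"{subj}_T0", subj, "validation", label, rng)
            )
    matrices["validation"] = draw_cohort("validation", val_records)
    metadata.extend(val_records)

    return SyntheticStudy(matrices=matrices, metadata=metadata, truth=planted)
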