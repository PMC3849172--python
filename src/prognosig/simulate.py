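"""Synthetic mini-array datasets with planted differential and prognostic genes.

The generator emulates a paired malignant/premalignant custom-array study:
each of ``n_pairs`` patients contributes a tumor and a premalignant sample; a
planted subset of candidate probes is differentially expressed between the
lesion types, and a planted sub-subset of those additionally separates
good- from poor-prognosis patients in the tumor samples. Survival is
exponential with a group-specific hazard, administratively censored.

Generative model (all on the log2 scale)::

    x[p, s] = b[p] + o[patient(s)] + de[p]·1{s malignant}
              + prog[p]·1{s malignant, patient poor} + ε[p, s]

with per-probe baselines ``b ~ N(baseline_mean, baseline_sd²)``, a scalar
per-patient offset ``o ~ N(0, patient_sd²)`` shared by both lesion samples
(this makes the paired design strictly more powerful than an unpaired
comparison, and — being constant across probes — leaves Pearson-based
clustering and centroid classification untouched), fixed-magnitude planted
effects with random sign, and i.i.d. Gaussian noise ``ε``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .io import (
    ANNOTATION_COLUMNS,
    LESION_MALIGNANT,
    LESION_PREMALIGNANT,
    ROLE_CANDIDATE,
    ROLE_NORMALIZATION,
    ROLE_PANEL,
    SCALE_LOG2,
    ExpressionMatrix,
    validate_sample_annotation,
)

GOOD = "good"
POOR = "poor"

_STAGES = ["I", "II", "III", "IV"]
_STAGE_PROBS = {GOOD: [0.35, 0.30, 0.30, 0.05], POOR: [0.05, 0.15, 0.40, 0.40]}
_PATHOLOGIES = [
    "Moderately to well differentiated adenocarcinoma",
    "Poorly differentiated adenocarcinoma",
    "Signet ring cell carcinoma",
    "Mucinous adenocarcinoma",
]
_PATHOLOGY_PROBS = {GOOD: [0.70, 0.20, 0.08, 0.02], POOR: [0.30, 0.40, 0.10, 0.20]}

# offset for the derived validation-cohort RNG stream
_VALIDATION_STREAM = 104729


@dataclass
class SimulationConfig:
    """Parameters of the synthetic mini-array study.

    Defaults mirror the array design and cohort the pipeline was built
    around: 696 candidate genes, 915 normalization probes, a 44+54-gene
    auxiliary panel, 20 patient pairs, 371 planted differential genes of
    which 74 carry prognostic signal, and an 11-patient tumor-only
    validation cohort.
    """

    n_pairs: int = 20
    n_candidate_probes: int = 696
    n_normalization_probes: int = 915
    n_panel_probes: int = 98  # 44 collagen-like + 54 hormone-like
    n_de_genes: int = 371
    n_prognosis_genes: int = 74
    de_log2_effect: float = 2.0
    prognosis_log2_effect: float = 1.5
    noise_sd: float = 0.5
    poor_fraction: float = 0.5
    hazard_ratio: float = 4.0
    censor_time: float = 60.0  # months
    n_validation: int = 11
    # nuisance structure (realism knobs, not planted signal)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    patient_sd: float = 0.3
    median_survival_good: float = 60.0  # months
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the first violated invariant."""
        for name in (
            "n_pairs",
            "n_candidate_probes",
            "n_normalization_probes",
            "n_panel_probes",
            "n_de_genes",
            "n_prognosis_genes",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"invariant violated: {name} > 0 (got {getattr(self, name)})")
        if not self.n_prognosis_genes <= self.n_de_genes <= self.n_candidate_probes:
            raise ConfigurationError(
                "invariant violated: n_prognosis_genes <= n_de_genes <= n_candidate_probes "
                f"(got {self.n_prognosis_genes}, {self.n_de_genes}, {self.n_candidate_probes})"
            )
        if not 0.0 < self.poor_fraction < 1.0:
            raise ConfigurationError(
                f"invariant violated: 0 < poor_fraction < 1 (got {self.poor_fraction})"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"invariant violated: noise_sd >= 0 (got {self.noise_sd})")
        for name in ("hazard_ratio", "censor_time", "median_survival_good"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"invariant violated: {name} > 0 (got {getattr(self, name)})")
        if self.n_validation < 0:
            raise ConfigurationError(f"invariant violated: n_validation >= 0 (got {self.n_validation})")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """The planted structure of a simulated dataset (for recovery tests)."""

    de_effects: pd.Series  # probe -> signed log2 effect, malignant vs premalignant
    prognosis_effects: pd.Series  # probe -> signed log2 shift, poor vs good tumors
    patient_groups: pd.Series  # patient -> good | poor
    true_centroid: pd.Series  # noiseless good-prognosis tumor profile, prognosis probes
    probe_baselines: pd.Series = field(repr=False)  # probe -> baseline log2 level

    @property
    def de_probe_ids(self) -> pd.Index:
        return self.de_effects.index

    @property
    def prognosis_probe_ids(self) -> pd.Index:
        return self.prognosis_effects.index


def _probe_ids(config: SimulationConfig):
    cand = [f"CAND{i + 1:04d}" for i in range(config.n_candidate_probes)]
    panel = [f"PNL{i + 1:03d}" for i in range(config.n_panel_probes)]
    norm = [f"NORM{i + 1:04d}" for i in range(config.n_normalization_probes)]
    ids = pd.Index(cand + panel + norm, name="probe_id")
    roles = pd.Series(
        [ROLE_CANDIDATE] * len(cand) + [ROLE_PANEL] * len(panel) + [ROLE_NORMALIZATION] * len(norm),
        index=ids,
    )
    return ids, roles


def _draw_survival(rng, groups: pd.Series, config: SimulationConfig):
    """Exponential survival with group-specific hazard, censored at the horizon."""
    hazard_good = np.log(2.0) / config.median_survival_good
    hazards = np.where(groups.values == POOR, hazard_good * config.hazard_ratio, hazard_good)
    raw = rng.exponential(1.0 / hazards)
    time = np.minimum(raw, config.censor_time)
    event = (raw < config.censor_time).astype(int)
    return time, event


def _patient_rows(rng, patients, groups, time, event, cohort):
    stages = [
        rng.choice(_STAGES, p=_STAGE_PROBS[groups[p]]) for p in patients
    ]
    pathologies = [
        rng.choice(_PATHOLOGIES, p=_PATHOLOGY_PROBS[groups[p]]) for p in patients
    ]
    met = np.where(event == 1, "yes", "no")
    return stages, pathologies, met


def generate_dataset(config: SimulationConfig):
    """Generate a paired training dataset.

    Returns ``(matrix, annotation, truth)``: a log2-scale
    :class:`~prognosig.io.ExpressionMatrix` with ``2·n_pairs`` sample columns
    (``P01T``, ``P01S``, …; T = tumor/malignant, S = premalignant), a sample
    annotation table, and the planted :class:`GroundTruth`. Identical
    configurations (including seed) give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    probe_ids, roles = _probe_ids(config)
    n_probes = len(probe_ids)

    baselines = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, n_probes), index=probe_ids
    )

    cand_ids = probe_ids[: config.n_candidate_probes]
    de_pos = np.sort(rng.choice(config.n_candidate_probes, config.n_de_genes, replace=False))
    de_ids = cand_ids[de_pos]
    de_signs = rng.choice([-1.0, 1.0], config.n_de_genes)
    de_effects = pd.Series(de_signs * config.de_log2_effect, index=de_ids)

    prog_pos = np.sort(rng.choice(config.n_de_genes, config.n_prognosis_genes, replace=False))
    prog_ids = de_ids[prog_pos]
    prog_signs = rng.choice([-1.0, 1.0], config.n_prognosis_genes)
    prog_effects = pd.Series(prog_signs * config.prognosis_log2_effect, index=prog_ids)

    patients = [f"P{i + 1:02d}" for i in range(config.n_pairs)]
    n_poor = int(round(config.poor_fraction * config.n_pairs))
    n_poor = min(max(n_poor, 1), config.n_pairs - 1)  # keep both groups nonempty
    poor_idx = rng.choice(config.n_pairs, n_poor, replace=False)
    group_values = np.array([GOOD] * config.n_pairs, dtype=object)
    group_values[poor_idx] = POOR
    groups = pd.Series(group_values, index=patients)

    offsets = rng.normal(0.0, config.patient_sd, config.n_pairs)

    de_full = de_effects.reindex(probe_ids, fill_value=0.0).values
    prog_full = prog_effects.reindex(probe_ids, fill_value=0.0).values
    base = baselines.values

    columns, data = [], []
    noise = rng.normal(0.0, config.noise_sd, (2 * config.n_pairs, n_probes))
    for i, patient in enumerate(patients):
        mal = base + offsets[i] + de_full + (prog_full if groups[patient] == POOR else 0.0)
        pre = base + offsets[i]
        columns += [f"{patient}T", f"{patient}S"]
        data += [mal + noise[2 * i], pre + noise[2 * i + 1]]
    values = pd.DataFrame(np.column_stack(data), index=probe_ids, columns=columns)
    matrix = ExpressionMatrix(values, roles, SCALE_LOG2)

    time, event = _draw_survival(rng, groups, config)
    stages, pathologies, met = _patient_rows(rng, patients, groups, time, event, "training")
    rows = []
    for i, patient in enumerate(patients):
        for lesion, suffix in ((LESION_MALIGNANT, "T"), (LESION_PREMALIGNANT, "S")):
            rows.append(
                {
                    "sample_id": f"{patient}{suffix}",
                    "patient_id": patient,
                    "lesion": lesion,
                    "stage": stages[i],
                    "pathology": pathologies[i],
                    "metastasis_5yr": met[i],
                    "survival_months": float(time[i]),
                    "event": int(event[i]),
                    "cohort": "training",
                }
            )
    annotation = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    validate_sample_annotation(annotation)

    true_centroid = (baselines + de_effects.reindex(probe_ids, fill_value=0.0)).loc[prog_ids]
    truth = GroundTruth(
        de_effects=de_effects,
        prognosis_effects=prog_effects,
        patient_groups=groups,
        true_centroid=true_centroid,
        probe_baselines=baselines,
    )
    return matrix, annotation, truth


def generate_validation_cohort(config: SimulationConfig, truth: GroundTruth, n_patients=None):
    """Generate an independent tumor-only validation cohort.

    New patients (default ``config.n_validation``) are drawn from the same
    generative model using the training run's planted effects and baselines,
    so the probe set is identical to the training matrix. The RNG stream is
    derived from the config seed but distinct from the training stream.
    """
    config.validate()
    if n_patients is None:
        n_patients = config.n_validation
    if n_patients < 0:
        raise ConfigurationError(f"invariant violated: n_patients >= 0 (got {n_patients})")
    probe_ids, roles = _probe_ids(config)
    if not truth.probe_baselines.index.equals(probe_ids):
        raise DataError(
            "probe-set mismatch between ground truth and configuration "
            f"({len(truth.probe_baselines)} vs {len(probe_ids)} probes)"
        )
    rng = np.random.default_rng([_VALIDATION_STREAM, config.seed])

    patients = [f"V{i + 1:02d}" for i in range(n_patients)]
    annotation = pd.DataFrame(columns=ANNOTATION_COLUMNS)
    if n_patients == 0:
        values = pd.DataFrame(index=probe_ids, dtype=float)
        return ExpressionMatrix(values, roles, SCALE_LOG2), annotation

    n_poor = int(round(config.poor_fraction * n_patients))
    poor_idx = rng.choice(n_patients, n_poor, replace=False) if n_poor else []
    group_values = np.array([GOOD] * n_patients, dtype=object)
    group_values[list(poor_idx)] = POOR
    groups = pd.Series(group_values, index=patients)

    offsets = rng.normal(0.0, config.patient_sd, n_patients)
    noise = rng.normal(0.0, config.noise_sd, (n_patients, len(probe_ids)))
    base = truth.probe_baselines.values
    de_full = truth.de_effects.reindex(probe_ids, fill_value=0.0).values
    prog_full = truth.prognosis_effects.reindex(probe_ids, fill_value=0.0).values

    columns, data = [], []
    for i, patient in enumerate(patients):
        profile = base + offsets[i] + de_full
        if groups[patient] == POOR:
            profile = profile + prog_full
        columns.append(f"{patient}T")
        data.append(profile + noise[i])
    values = pd.DataFrame(np.column_stack(data), index=probe_ids, columns=columns)
    matrix = ExpressionMatrix(values, roles, SCALE_LOG2)

    time, event = _draw_survival(rng, groups, config)
    stages, pathologies, met = _patient_rows(rng, patients, groups, time, event, "validation")
    rows = []
    for i, patient in enumerate(patients):
        rows.append(
            {
                "sample_id": f"{patient}T",
                "patient_id": patient,
                "lesion": LESION_MALIGNANT,
                "stage": stages[i],
                "pathology": pathologies[i],
                "metastasis_5yr": met[i],
                "survival_months": float(time[i]),
                "event": int(event[i]),
                "cohort": "validation",
            }
        )
    annotation = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    validate_sample_annotation(annotation)
    # record the planted groups so recovery experiments can score accuracy
    kept = truth.patient_groups[~truth.patient_groups.index.isin(groups.index)]
    truth.patient_groups = pd.concat([kept, groups])
    return matrix, annotation


def simulate_replicate_ratios(config: SimulationConfig, truth: GroundTruth,
                              patient: str, seed: int) -> pd.Series:
    """A fresh technical-replicate measurement of one patient's tumor/premalignant
    log2 ratio profile (planted effects plus two independent hybridizations'
    noise), for platform-concordance experiments."""
    if patient not in truth.patient_groups.index:
        raise DataError(f"unknown patient {patient!r}")
    rng = np.random.default_rng([7919, config.seed, seed])
    probe_ids = truth.probe_baselines.index
    signal = truth.de_effects.reindex(probe_ids, fill_value=0.0)
    if truth.patient_groups[patient] == POOR:
        signal = signal + truth.prognosis_effects.reindex(probe_ids, fill_value=0.0)
    noise = rng.normal(0.0, np.sqrt(2.0) * config.noise_sd, len(probe_ids))
    return pd.Series(signal.values + noise, index=probe_ids)


__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_validation_cohort",
    "simulate_replicate_ratios",
    "GOOD",
    "POOR",
]
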