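"""Cross-sectional feature engineering from baseline-window observations.

Time-varying observations in the baseline time window (BTW) collapse into one
row per patient:

* DSH risk variables: per-condition sum, mean and last observed score of the
  time-varying severity trajectory;
* comorbidity variables: rolling indicator (condition persisted through the
  BTW under chronic-disease stickiness) and the most frequent per-encounter
  indication;
* medication variables: per drug class, order frequency and an any-use flag;
* lab/vital variables: frequency, median and last observed value, with
  columns at or above 35% missingness dropped and the remainder imputed by
  iterative random-forest conditional modeling.

Feature sets mirror the three predictor groups used for model comparison:
``DSH-RS`` (severity scores + demographics), ``COM`` (comorbidities +
medications + demographics), and ``COM+LB/VS`` (COM plus labs and vitals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .ehr_data import (
    ConditionDefinition,
    ConfigurationError,
    PatientTimeline,
    StudyConfig,
    condition_indication,
)
from .dsh_core import ScoreTrajectory, build_tree, score_trajectory

logger = logging.getLogger(__name__)

PROVENANCE_TAGS = ("dsh", "comorbidity", "medication", "lab_vital", "demographic")

FEATURE_SETS: dict[str, frozenset[str]] = {
    "DSH-RS": frozenset({"dsh", "demographic"}),
    "COM": frozenset({"comorbidity", "medication", "demographic"}),
    "COM+LB/VS": frozenset({"comorbidity", "medication", "lab_vital", "demographic"}),
}


@dataclass
class FeatureMatrix:
    """One row per patient; column provenance and pre-imputation missingness."""

    data: pd.DataFrame
    provenance: dict[str, str]
    missing_mask: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.missing_mask is None:
            self.missing_mask = self.data.isna()
        if len(set(self.data.columns)) != len(self.data.columns):
            raise ConfigurationError("duplicate feature column names")

    def columns_with_tag(self, tag: str) -> list[str]:
        return [c for c, t in self.provenance.items() if t == tag and c in self.data.columns]

    def subset(self, tags: Iterable[str]) -> "FeatureMatrix":
        tags = set(tags)
        cols = [c for c in self.data.columns if self.provenance[c] in tags]
        return FeatureMatrix(
            data=self.data[cols].copy(),
            provenance={c: self.provenance[c] for c in cols},
            missing_mask=self.missing_mask[cols].copy(),
        )


def aggregate_dsh(trajectory: ScoreTrajectory) -> tuple[float, float, float]:
    """Sum, mean and last observed value of a score trajectory; zeros if empty."""
    scores = trajectory.scores
    if not scores:
        return (0.0, 0.0, 0.0)
    return (float(np.sum(scores)), float(np.mean(scores)), float(scores[-1]))


def comorbidity_features(
    timeline: PatientTimeline,
    condition_def: ConditionDefinition,
    btw: tuple[float, float],
    measurement_units: Mapping[str, str] | None = None,
) -> tuple[int, int]:
    """Rolling comorbidity and most-frequent indication over BTW encounters.

    Rolling: the condition, once indicated, persists through the end of the
    window (sticky chronic-disease reading), so it reduces to ever-indicated.
    Most frequent: the modal raw per-encounter indication, ties broken to 1.
    """
    indications = condition_indication(timeline, condition_def, btw, measurement_units)
    if not indications:
        return (0, 0)
    flags = [f for _, f in indications]
    rolling = int(any(flags))
    ones = sum(flags)
    most_frequent = int(ones >= len(flags) - ones)  # ties -> 1
    if ones == 0:
        most_frequent = 0
    return (rolling, most_frequent)


def medication_features(
    timeline: PatientTimeline,
    drug_classes: Sequence[str],
    btw: tuple[float, float],
) -> dict[str, tuple[int, int]]:
    """Per drug class: order frequency in BTW and an any-use indicator."""
    counts = {c: 0 for c in drug_classes}
    for e in timeline.events_in(btw):
        if e.kind == "medication" and e.code in counts:
            counts[e.code] += 1
    return {c: (n, int(n > 0)) for c, n in counts.items()}


def lab_vital_features(
    timeline: PatientTimeline,
    measurement: str,
    btw: tuple[float, float],
) -> tuple[int, float, float]:
    """Frequency, median and last observed value; (0, NaN, NaN) if unobserved."""
    obs = [
        (e.event_age, e.value)
        for e in timeline.events_in(btw)
        if e.kind in ("lab", "vital") and e.code == measurement
    ]
    if not obs:
        return (0, float("nan"), float("nan"))
    for _, v in obs:
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise TypeError(f"non-numeric value {v!r} for measurement {measurement!r}")
    obs.sort()
    values = [v for _, v in obs]
    return (len(values), float(np.median(values)), float(values[-1]))


def missingness_filter(matrix: FeatureMatrix, max_fraction: float = 0.35) -> FeatureMatrix:
    """Drop lab/vital columns whose missing fraction reaches ``max_fraction``.

    The retained set is the strict "< max_fraction" reading; dropped columns
    are reported via logging.
    """
    drop: list[str] = []
    for col in matrix.columns_with_tag("lab_vital"):
        frac = float(matrix.missing_mask[col].mean())
        if frac >= max_fraction:
            drop.append(col)
            logger.info("dropping %s: %.1f%% missing (threshold %.0f%%)",
                        col, 100 * frac, 100 * max_fraction)
    keep = [c for c in matrix.data.columns if c not in drop]
    return FeatureMatrix(
        data=matrix.data[keep].copy(),
        provenance={c: matrix.provenance[c] for c in keep},
        missing_mask=matrix.missing_mask[keep].copy(),
    )


def make_imputer(seed: int = 0) -> IterativeImputer:
    """Iterative random-forest imputer (missForest-style), deterministic per seed."""
    return IterativeImputer(
        estimator=RandomForestRegressor(n_estimators=30, random_state=seed, n_jobs=1),
        random_state=seed,
        max_iter=5,
        sample_posterior=False,
        keep_empty_features=True,
    )


def impute(matrix: FeatureMatrix, seed: int = 0) -> FeatureMatrix:
    """Fill missing lab/vital cells by iterative tree-ensemble modeling.

    Only lab/vital columns can be missing (all other provenance groups are
    structurally complete); they are imputed conditional on every feature
    column.  A column that is entirely missing should have been removed by
    :func:`missingness_filter` first.
    """
    data = matrix.data
    if not data.isna().any().any():
        return matrix
    all_missing = [c for c in data.columns if data[c].isna().all()]
    if all_missing:
        raise ValueError(f"all-missing column(s) reached imputation: {all_missing}")
    imputer = make_imputer(seed)
    filled = pd.DataFrame(
        imputer.fit_transform(data.to_numpy(dtype=float)),
        index=data.index,
        columns=data.columns,
    )
    return FeatureMatrix(data=filled, provenance=dict(matrix.provenance),
                         missing_mask=matrix.missing_mask.copy())


def impute_train_test(
    train: FeatureMatrix, test: FeatureMatrix, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Fit the imputer on training rows only and apply it to both splits."""
    if not train.data.isna().any().any() and not test.data.isna().any().any():
        return train, test
    imputer = make_imputer(seed)
    tr = imputer.fit_transform(train.data.to_numpy(dtype=float))
    te = imputer.transform(test.data.to_numpy(dtype=float))
    mk = lambda m, arr: FeatureMatrix(
        data=pd.DataFrame(arr, index=m.data.index, columns=m.data.columns),
        provenance=dict(m.provenance),
        missing_mask=m.missing_mask.copy(),
    )
    return mk(train, tr), mk(test, te)


def _demographic_columns(cohort: Sequence[PatientTimeline]) -> pd.DataFrame:
    rows = []
    for tl in cohort:
        rows.append({"patient_id": tl.patient_id, "sex": tl.demographics.sex,
                     "race": tl.demographics.race})
    df = pd.DataFrame(rows).set_index("patient_id")
    out = pd.DataFrame(index=df.index)
    sexes = sorted(df["sex"].unique())
    for s in sexes[1:]:  # first level is the reference
        out[f"sex_{s}"] = (df["sex"] == s).astype(float)
    races = sorted(df["race"].unique())
    for r in races[1:]:
        out[f"race_{r}"] = (df["race"] == r).astype(float)
    return out


def build_feature_matrix(
    cohort: Sequence[PatientTimeline],
    config: StudyConfig,
    feature_set: str = "COM+LB/VS",
    btw: tuple[float, float] | None = None,
    n_levels: int = 4,
    max_missing_fraction: float = 0.35,
) -> FeatureMatrix:
    """Assemble the named feature set for a cohort (pre-imputation).

    ``btw`` defaults per patient to ``[age_at_index, followup entry)``.  The
    returned matrix may contain missing lab/vital cells; apply
    :func:`impute` (or :func:`impute_train_test` inside cross-validation)
    before model fitting.
    """
    if feature_set not in FEATURE_SETS:
        raise ConfigurationError(
            f"unknown feature set {feature_set!r}; expected one of {sorted(FEATURE_SETS)}"
        )
    tags = FEATURE_SETS[feature_set]
    units = config.measurement_units
    trees = {name: build_tree(cd, n_levels) for name, cd in config.conditions.items()}

    def patient_btw(tl: PatientTimeline) -> tuple[float, float]:
        if btw is not None:
            return btw
        return (tl.demographics.age_at_index, tl.followup.entry_age)

    records: list[dict[str, float]] = []
    provenance: dict[str, str] = {}
    for tl in cohort:
        w = patient_btw(tl)
        row: dict[str, float] = {"patient_id": tl.patient_id}
        if "dsh" in tags:
            for name, cd in config.conditions.items():
                traj = score_trajectory(tl, trees[name], cd, w, units)
                s, m, last = aggregate_dsh(traj)
                row[f"dsh_{name}_sum"] = s
                row[f"dsh_{name}_mean"] = m
                row[f"dsh_{name}_last"] = last
                provenance.update({f"dsh_{name}_{a}": "dsh" for a in ("sum", "mean", "last")})
        if "comorbidity" in tags:
            for name, cd in config.conditions.items():
                rolling, mf = comorbidity_features(tl, cd, w, units)
                row[f"com_{name}_rolling"] = float(rolling)
                row[f"com_{name}_most_frequent"] = float(mf)
                provenance[f"com_{name}_rolling"] = "comorbidity"
                provenance[f"com_{name}_most_frequent"] = "comorbidity"
        if "medication" in tags:
            classes = sorted(config.drug_vocabulary)
            med = medication_features(tl, classes, w)
            for c in classes:
                freq, any_ = med[c]
                row[f"med_{c}_freq"] = float(freq)
                row[f"med_{c}_any"] = float(any_)
                provenance[f"med_{c}_freq"] = "medication"
                provenance[f"med_{c}_any"] = "medication"
        if "lab_vital" in tags:
            for meas in sorted(config.measurement_vocabulary):
                freq, med_v, last_v = lab_vital_features(tl, meas, w)
                row[f"lv_{meas}_freq"] = float(freq)
                row[f"lv_{meas}_median"] = med_v
                row[f"lv_{meas}_last"] = last_v
                provenance[f"lv_{meas}_freq"] = "lab_vital"
                provenance[f"lv_{meas}_median"] = "lab_vital"
                provenance[f"lv_{meas}_last"] = "lab_vital"
        records.append(row)

    data = pd.DataFrame(records).set_index("patient_id")
    demo = _demographic_columns(cohort)
    for c in demo.columns:
        provenance[c] = "demographic"
    data = data.join(demo)
    matrix = FeatureMatrix(data=data, provenance=provenance)
    return missingness_filter(matrix, max_missing_fraction)


def export_features(matrix: FeatureMatrix, csv_path, meta_path) -> None:
    """Write features.csv plus a sidecar with provenance and missingness."""
    import json

    matrix.data.to_csv(csv_path)
    meta = {
        c: {
            "provenance": matrix.provenance[c],
            "missing_fraction_before_imputation": float(matrix.missing_mask[c].mean()),
        }
        for c in matrix.data.columns
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
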