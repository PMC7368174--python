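"""Censoring-aware evaluation at fixed age horizons.

Classification metrics at a horizon age ``h`` treat "event by ``h``" as the
positive class and "still event-free at ``h``" as the negative class.  With
right censoring the class label of patients censored before ``h`` is unknown,
so all quantities are computed with inverse-probability-of-censoring weights
(IPCW, cumulative/dynamic): a Kaplan-Meier fit of the censoring distribution
on the age scale (respecting delayed entry) supplies ``G``, and

* a patient with an observed event at age ``t <= h`` gets weight ``1/G(t-)``,
* a patient under observation past ``h`` gets weight ``1/G(h)``,
* a patient censored before ``h`` gets weight 0.

On top of the weighted confusion counts sit the horizon AUC (weighted
probability that an event patient outranks a survivor, ties counted 1/2),
the cumulative gain curve with its Gini score (area between the gain curve
and the diagonal, normalized by the same area for a perfect ranker),
decision-curve net benefit, and calibration by predicted-risk bins.

``compare_models`` runs the full nested-cross-validation comparison of the
three predictor groups (DSH-RS, COM, COM+LB/VS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from sklearn.model_selection import StratifiedKFold

from .ehr_data import PatientTimeline, StudyConfig
from .features import FEATURE_SETS, build_feature_matrix, impute_train_test
from .survival import (
    CoxnetCPH,
    PenaltyGrid,
    SurvivalRecord,
    make_survival_records,
)

logger = logging.getLogger(__name__)


class MetricsUndefinedError(ValueError):
    """No events by the horizon: classification metrics are undefined."""


@dataclass
class HorizonMetrics:
    horizon_age: float
    accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    threshold: float
    n_effective: int

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
        }


@dataclass
class GainCurve:
    fractions: np.ndarray  # of population flagged, ascending, starts at 0
    captured: np.ndarray  # cumulative fraction of (weighted) events captured
    gini: float


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.treat_none is None:
            self.treat_none = np.zeros_like(self.thresholds)


def _arrays(records: Sequence[SurvivalRecord]):
    entry = np.array([r.entry_age for r in records])
    exit_ = np.array([r.exit_age for r in records])
    event = np.array([r.event for r in records], dtype=int)
    return entry, exit_, event


def censoring_weights(
    records: Sequence[SurvivalRecord],
    horizon_age: float,
    cap: float = 1e4,
    km_records: Optional[Sequence[SurvivalRecord]] = None,
) -> np.ndarray:
    """IPCW weights at a horizon from a KM fit of the censoring distribution.

    ``km_records`` optionally supplies a larger sample (e.g. the full cohort
    when weighting one cross-validation fold) for the censoring KM fit.
    """
    entry, exit_, event = _arrays(records)
    km_entry, km_exit, km_event = (
        _arrays(km_records) if km_records is not None else (entry, exit_, event)
    )
    kmf = KaplanMeierFitter()
    kmf.fit(durations=km_exit, event_observed=1 - km_event, entry=km_entry,
            label="censoring")

    def g(times: np.ndarray) -> np.ndarray:
        return kmf.survival_function_at_times(times).to_numpy()

    w = np.zeros(len(records), dtype=float)
    eps = 1e-9
    is_event_by_h = (exit_ <= horizon_age) & (event == 1)
    is_survivor = exit_ > horizon_age
    w[is_event_by_h] = 1.0 / np.maximum(g(exit_[is_event_by_h] - eps), eps)
    w[is_survivor] = 1.0 / np.maximum(g(np.full(is_survivor.sum(), horizon_age)), eps)
    if np.any(w > cap):
        logger.warning("capping %d IPCW weights at %.0f (censoring survival near 0)",
                       int((w > cap).sum()), cap)
        w = np.minimum(w, cap)
    return w


def _evaluable(records: Sequence[SurvivalRecord], horizon_age: float):
    """Masks for horizon classification among patients at risk before horizon."""
    entry, exit_, event = _arrays(records)
    eligible = entry < horizon_age
    pos = eligible & (exit_ <= horizon_age) & (event == 1)
    neg = eligible & (exit_ > horizon_age)
    return eligible, pos, neg


def weighted_auc(risks: np.ndarray, pos: np.ndarray, neg: np.ndarray,
                 w: np.ndarray) -> float:
    """Weighted probability an event patient outranks a survivor (ties 1/2)."""
    u = w * pos
    v = w * neg
    total = u.sum() * v.sum()
    if total <= 0:
        raise MetricsUndefinedError("need both events and survivors for AUC")
    order = np.argsort(risks, kind="stable")
    r, us, vs = risks[order], u[order], v[order]
    # group ties, accumulate controls seen strictly below each case
    conc = 0.0
    cum_v = 0.0
    i = 0
    n = len(r)
    while i < n:
        j = i
        while j < n and r[j] == r[i]:
            j += 1
        grp_u = us[i:j].sum()
        grp_v = vs[i:j].sum()
        conc += grp_u * (cum_v + 0.5 * grp_v)
        cum_v += grp_v
        i = j
    return float(conc / total)


def horizon_metrics(
    risks: np.ndarray,
    records: Sequence[SurvivalRecord],
    horizon_age: float,
    threshold_rule: str = "youden",
    threshold: Optional[float] = None,
    weights: Optional[np.ndarray] = None,
) -> HorizonMetrics:
    """IPCW-weighted accuracy/AUC/sensitivity/specificity/PPV at a horizon.

    The decision threshold is either supplied explicitly or chosen to
    maximize the weighted Youden index on the given data.
    """
    risks = np.asarray(risks, dtype=float)
    if len(risks) != len(records):
        raise ValueError("risks and records are not aligned")
    w = censoring_weights(records, horizon_age) if weights is None else weights
    _, pos, neg = _evaluable(records, horizon_age)
    pw, nw = (w * pos).sum(), (w * neg).sum()
    if pw <= 0:
        raise MetricsUndefinedError(f"no events by horizon {horizon_age}")
    if nw <= 0:
        raise MetricsUndefinedError(f"no survivors past horizon {horizon_age}")

    auc = weighted_auc(risks, pos, neg, w)

    if threshold is None:
        if threshold_rule != "youden":
            raise ValueError(f"unknown threshold rule {threshold_rule!r}")
        candidates = np.unique(risks[pos | neg])
        best_j, threshold = -np.inf, candidates[0]
        for t in candidates:
            predicted = risks >= t
            sens = (w * pos * predicted).sum() / pw
            spec = (w * neg * ~predicted).sum() / nw
            j = sens + spec - 1
            if j > best_j:
                best_j, threshold = j, float(t)

    predicted = risks >= threshold
    tp = (w * pos * predicted).sum()
    fn = (w * pos * ~predicted).sum()
    fp = (w * neg * predicted).sum()
    tn = (w * neg * ~predicted).sum()
    sens = tp / pw
    spec = tn / nw
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    acc = (tp + tn) / (pw + nw)
    n_eff = int(((pos | neg) & (w > 0)).sum())
    return HorizonMetrics(horizon_age, float(acc), float(auc), float(sens),
                          float(spec), float(ppv), float(threshold), n_eff)


def gain_and_gini(
    risks: np.ndarray,
    records: Sequence[SurvivalRecord],
    horizon_age: float,
    weights: Optional[np.ndarray] = None,
) -> GainCurve:
    """Cumulative gain curve and Gini score for event capture at a horizon."""
    risks = np.asarray(risks, dtype=float)
    w = censoring_weights(records, horizon_age) if weights is None else weights
    _, pos, neg = _evaluable(records, horizon_age)
    mask = (pos | neg) & (w > 0)
    if (w * pos).sum() <= 0:
        raise MetricsUndefinedError(f"no events by horizon {horizon_age}")
    r = risks[mask]
    wm = w[mask]
    ev = pos[mask].astype(float)

    def curve(order_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # pool tied scores so exchangeable risks give the diagonal
        order = np.argsort(-order_scores, kind="stable")
        s, wt, e = order_scores[order], wm[order], (wm * ev)[order]
        boundaries = np.flatnonzero(np.diff(s)) + 1
        cw = np.add.reduceat(wt, np.concatenate([[0], boundaries]))
        ce = np.add.reduceat(e, np.concatenate([[0], boundaries]))
        x = np.concatenate([[0.0], np.cumsum(cw) / wt.sum()])
        y = np.concatenate([[0.0], np.cumsum(ce) / (wm * ev).sum()])
        return x, y

    x, y = curve(r)
    xp, yp = curve(ev)  # perfect ranker: true labels as scores

    def area_above_diagonal(xc: np.ndarray, yc: np.ndarray) -> float:
        return float(np.trapezoid(yc, xc) - 0.5)

    denom = area_above_diagonal(xp, yp)
    gini = area_above_diagonal(x, y) / denom if denom > 0 else 0.0
    return GainCurve(fractions=x, captured=y, gini=float(gini))


def net_benefit(
    risks: np.ndarray,
    records: Sequence[SurvivalRecord],
    horizon_age: float,
    thresholds: Sequence[float],
    weights: Optional[np.ndarray] = None,
) -> DecisionCurve:
    """Decision-curve net benefit NB(p) = (TP - FP * p/(1-p)) / n at a horizon."""
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    risks = np.asarray(risks, dtype=float)
    w = censoring_weights(records, horizon_age) if weights is None else weights
    _, pos, neg = _evaluable(records, horizon_age)
    n_eff = (w * (pos | neg)).sum()
    nb = np.empty_like(thresholds)
    ta = np.empty_like(thresholds)
    tp_all = (w * pos).sum()
    fp_all = (w * neg).sum()
    for i, p in enumerate(thresholds):
        odds = p / (1 - p)
        flag = risks >= p
        tp = (w * pos * flag).sum()
        fp = (w * neg * flag).sum()
        nb[i] = (tp - fp * odds) / n_eff
        ta[i] = (tp_all - fp_all * odds) / n_eff
    return DecisionCurve(thresholds=thresholds, net_benefit=nb, treat_all=ta)


def calibration(
    risks: np.ndarray,
    records: Sequence[SurvivalRecord],
    horizon_age: float,
    n_bins: int = 10,
    weights: Optional[np.ndarray] = None,
) -> list[tuple[float, float, int]]:
    """Equal-frequency calibration bins: (mean predicted, weighted observed, n)."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    risks = np.asarray(risks, dtype=float)
    w = censoring_weights(records, horizon_age) if weights is None else weights
    _, pos, neg = _evaluable(records, horizon_age)
    mask = (pos | neg) & (w > 0)
    r, wm, ev = risks[mask], w[mask], pos[mask].astype(float)
    n_distinct = len(np.unique(r))
    if n_distinct < n_bins:
        logger.warning("only %d distinct risks; merging into %d bin(s)",
                       n_distinct, n_distinct)
    bins = pd.qcut(r, q=min(n_bins, n_distinct), duplicates="drop")
    out: list[tuple[float, float, int]] = []
    df = pd.DataFrame({"r": r, "w": wm, "ev": ev, "bin": bins})
    for _, g in df.groupby("bin", observed=True, sort=True):
        if len(g) == 0:
            continue
        observed = float((g["w"] * g["ev"]).sum() / g["w"].sum())
        out.append((float(g["r"].mean()), observed, int(len(g))))
    return out


# ---------------------------------------------------------------------------
# Model comparison (nested cross-validation over feature sets)


def compare_models(
    cohort: Sequence[PatientTimeline],
    config: StudyConfig,
    outcome: str = "ACM",
    horizons: Sequence[float] = (60.0, 65.0, 75.0, 80.0),
    feature_sets: Sequence[str] = ("DSH-RS", "COM", "COM+LB/VS"),
    truncation_age: float = 51.0,
    n_levels: int = 4,
    outer_folds: int = 10,
    grid: PenaltyGrid | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Held-out horizon metrics for each predictor group.

    Outer stratified k-fold: each model is trained (imputation fit,
    penalty selection by inner CV, final refit) on the training folds and its
    risks evaluated on the held-out fold; decision thresholds are chosen on
    the training fold by weighted Youden and applied unchanged to the held-out
    fold.  Returns a long table (model, outcome, horizon, metric, estimate,
    lo, hi) where lo/hi are the normal-approximation 95% CI over folds.
    """
    for fs in feature_sets:
        if fs not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {fs!r}")
    records = make_survival_records(cohort, outcome, truncation_age)
    if sum(r.event for r in records) == 0:
        raise MetricsUndefinedError(f"outcome {outcome}: no events in the cohort")
    kept = {r.patient_id for r in records}
    cohort = [tl for tl in cohort if tl.patient_id in kept]
    inner = grid or PenaltyGrid()

    event = np.array([r.event for r in records])
    skf = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(records)), event))

    matrices = {
        fs: build_feature_matrix(cohort, config, feature_set=fs, n_levels=n_levels)
        for fs in feature_sets
    }
    order = [r.patient_id for r in records]

    per_fold: dict[tuple[str, float, str], list[float]] = {}
    for f, (tr_idx, te_idx) in enumerate(splits):
        rec_tr = [records[i] for i in tr_idx]
        rec_te = [records[i] for i in te_idx]
        for fs in feature_sets:
            m = matrices[fs]
            full = m.data.loc[order]
            tr = full.iloc[tr_idx]
            te = full.iloc[te_idx]
            from .features import FeatureMatrix  # local to avoid cycle at import

            mtr = FeatureMatrix(tr.copy(), dict(m.provenance))
            mte = FeatureMatrix(te.copy(), dict(m.provenance))
            mtr, mte = impute_train_test(mtr, mte, seed=seed + f)
            inner_grid = PenaltyGrid(
                l1_ratios=inner.l1_ratios, n_lambdas=inner.n_lambdas,
                lambda_min_ratio=inner.lambda_min_ratio, lambdas=inner.lambdas,
                folds=inner.folds, seed=seed + f,
            )
            model = CoxnetCPH(mtr.data, rec_tr, grid=inner_grid).fit()
            for h in horizons:
                risk_tr = model.predict_risk(mtr.data, h)
                risk_te = model.predict_risk(mte.data, h)
                try:
                    # censoring KM from the full cohort for stable fold weights
                    w_tr = censoring_weights(rec_tr, h, km_records=records)
                    w_te = censoring_weights(rec_te, h, km_records=records)
                    thr = horizon_metrics(risk_tr, rec_tr, h, weights=w_tr).threshold
                    hm = horizon_metrics(risk_te, rec_te, h, threshold=thr, weights=w_te)
                except MetricsUndefinedError as exc:
                    logger.warning("fold %d, %s, horizon %g: %s", f, fs, h, exc)
                    continue
                for metric, value in hm.as_dict().items():
                    per_fold.setdefault((fs, h, metric), []).append(value)

    rows = []
    for (fs, h, metric), values in sorted(per_fold.items()):
        v = np.asarray(values, dtype=float)
        v = v[~np.isnan(v)]
        est = float(v.mean())
        se = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")
        rows.append({
            "model": fs, "outcome": outcome, "horizon": h, "metric": metric,
            "estimate": est, "lo": est - 1.96 * se, "hi": est + 1.96 * se,
            "n_folds": len(v),
        })
    return pd.DataFrame(rows)
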