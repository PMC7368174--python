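"""Left-truncated, age-scale, elastic-net-regularized Cox proportional hazards.

The model is the Cox proportional hazards model on the age-time scale with
delayed entry: a patient contributes to the risk set of an event at age ``t``
only when ``entry_age < t <= exit_age``, so survivorship before study entry
never distorts the comparison.  Ties are handled with the Breslow
approximation.  The penalized partial likelihood

    -(1/n) * pl(beta) + lambda * sum_j pf_j * (alpha*|b_j| + (1-alpha)/2*b_j^2)

is maximized by cyclic coordinate descent on iteratively reweighted least
squares, giving exact zeros under the lasso part.  The penalty pair
(mixing ``alpha`` in [0,1], strength ``lambda``) is selected on a grid by
k-fold cross-validated partial-likelihood deviance (Verweij & Van
Houwelingen's construction, robust to folds with few events), with folds
stratified by event status.  Demographic adjusters can be left unpenalized.

``CoxnetCPH`` is the model object; ``fit()`` returns a ``CoxnetResults``
carrying coefficients on the original feature scale, the chosen penalties,
the Breslow baseline cumulative hazard on the age scale, per-grid-point CV
deviances, and ``predict_risk`` for fixed age horizons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .ehr_data import ConfigurationError, PatientTimeline

logger = logging.getLogger(__name__)

OUTCOMES = ("ACM", "MCE")


class FitError(RuntimeError):
    """The model could not be fit (e.g. no usable cross-validation folds)."""


class ContractError(ValueError):
    """Prediction inputs do not match the fitted model."""


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    entry_age: float
    exit_age: float
    event: int

    def __post_init__(self) -> None:
        if not self.entry_age < self.exit_age:
            raise ValueError(
                f"entry_age {self.entry_age} must precede exit_age {self.exit_age}"
            )


def make_survival_records(
    cohort: Sequence[PatientTimeline],
    outcome: str = "ACM",
    truncation_age: float = 51.0,
) -> list[SurvivalRecord]:
    """Build left-truncated age-interval records for one outcome.

    Entry is the later of follow-up entry and the truncation age; patients
    whose follow-up ends on or before their truncated entry have an empty
    risk interval and are excluded with a report.
    """
    if outcome not in OUTCOMES:
        raise ConfigurationError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    records: list[SurvivalRecord] = []
    excluded: list[str] = []
    for tl in cohort:
        fu = tl.followup
        entry = max(fu.entry_age, truncation_age)
        if fu.exit_age <= entry:
            excluded.append(tl.patient_id)
            continue
        event = fu.acm_event if outcome == "ACM" else fu.mce_event
        records.append(SurvivalRecord(tl.patient_id, entry, fu.exit_age, int(event)))
    if excluded:
        logger.info("excluded %d patients with empty risk interval after truncation "
                    "at age %.1f: %s%s", len(excluded), truncation_age,
                    excluded[:10], "..." if len(excluded) > 10 else "")
    return records


@dataclass
class PenaltyGrid:
    """Elastic-net tuning grid: mixing values x regularization strengths."""

    l1_ratios: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    n_lambdas: int = 50
    lambda_min_ratio: float = 0.01
    lambdas: Optional[tuple[float, ...]] = None  # explicit strengths override
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.l1_ratios or any(not 0 <= a <= 1 for a in self.l1_ratios):
            raise ConfigurationError("l1_ratios must be a nonempty subset of [0, 1]")
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if self.lambdas is not None and len(self.lambdas) == 0:
            raise ConfigurationError("explicit lambda sequence is empty")


# ---------------------------------------------------------------------------
# Partial-likelihood machinery (Breslow ties, delayed entry)


class _RiskSetIndex:
    """Precomputed sort orders for O(n log n) risk-set sums."""

    def __init__(self, entry: np.ndarray, exit_: np.ndarray, event: np.ndarray):
        self.entry = entry
        self.exit = exit_
        self.event = event.astype(bool)
        self.exit_sorted_idx = np.argsort(exit_, kind="stable")
        self.exit_sorted = exit_[self.exit_sorted_idx]
        self.entry_sorted_idx = np.argsort(entry, kind="stable")
        self.entry_sorted = entry[self.entry_sorted_idx]
        times, counts = np.unique(exit_[self.event], return_counts=True)
        self.event_times = times
        self.d = counts.astype(float)

    def risk_sums(self, w: np.ndarray) -> np.ndarray:
        """sum of w over {j : entry_j < t_k <= exit_j} for each event time."""
        suffix_exit = np.concatenate(
            [np.cumsum(w[self.exit_sorted_idx][::-1])[::-1], [0.0]]
        )
        idx_exit = np.searchsorted(self.exit_sorted, self.event_times, side="left")
        a = suffix_exit[idx_exit]
        suffix_entry = np.concatenate(
            [np.cumsum(w[self.entry_sorted_idx][::-1])[::-1], [0.0]]
        )
        idx_entry = np.searchsorted(self.entry_sorted, self.event_times, side="left")
        b = suffix_entry[idx_entry]
        return a - b

    def cum_over_interval(self, per_event: np.ndarray) -> np.ndarray:
        """For each subject i: sum of per_event over {k : entry_i < t_k <= exit_i}."""
        cum = np.concatenate([[0.0], np.cumsum(per_event)])
        hi = cum[np.searchsorted(self.event_times, self.exit, side="right")]
        lo = cum[np.searchsorted(self.event_times, self.entry, side="right")]
        return hi - lo


_ETA_CLIP = 30.0
_BETA_CLIP = 15.0  # per-coefficient bound on the standardized scale


def _stabilized(eta: np.ndarray) -> np.ndarray:
    """Center and clip the linear predictor (shift-invariant likelihood)."""
    centered = eta - np.mean(eta)
    return np.clip(centered, -_ETA_CLIP, _ETA_CLIP)


def partial_loglik(eta: np.ndarray, entry: np.ndarray, exit_: np.ndarray,
                   event: np.ndarray, index: _RiskSetIndex | None = None) -> float:
    """Breslow partial log-likelihood under delayed entry."""
    idx = index or _RiskSetIndex(entry, exit_, np.asarray(event))
    if idx.event_times.size == 0:
        return 0.0
    eta_s = _stabilized(np.asarray(eta, dtype=float))
    w = np.exp(eta_s)
    s = idx.risk_sums(w)
    if np.any(s <= 0):
        raise FitError("empty risk set at an event time")
    return float(np.sum(eta_s[idx.event.astype(bool)]) - np.sum(idx.d * np.log(s)))


def _mu(eta: np.ndarray, idx: _RiskSetIndex) -> np.ndarray:
    """Expected event counts exp(eta_i) * sum_{k at risk} d_k / S_k."""
    w = np.exp(_stabilized(eta))
    s = idx.risk_sums(w)
    if np.any(s <= 0):
        raise FitError("empty risk set at an event time")
    h = idx.d / s  # hazard increments; the centering shift cancels in w*h
    c = idx.cum_over_interval(h)
    return w * c


def _coordinate_descent(
    xs: np.ndarray,
    beta: np.ndarray,
    eta: np.ndarray,
    w: np.ndarray,
    z: np.ndarray,
    lam: float,
    alpha: float,
    pf: np.ndarray,
    tol: float,
    max_sweeps: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted penalized least squares by cyclic coordinate descent.

    Uses the glmnet active-set strategy: converge on the nonzero set, then a
    full sweep to admit violators, repeating until no coordinate moves.
    """
    n, p = xs.shape
    r = z - eta  # working residual, kept incremental
    wxs = xs * w[:, None]
    a = (w @ (xs * xs)) / n  # curvature per coordinate (fixed within the call)
    ridge = lam * (1 - alpha) * pf
    l1 = lam * alpha * pf

    def sweep(indices) -> float:
        md = 0.0
        for j in indices:
            aj = a[j] + ridge[j]
            if aj <= 0:
                continue
            num = (wxs[:, j] @ r) / n + a[j] * beta[j]
            if num > l1[j]:
                nb = (num - l1[j]) / aj
            elif num < -l1[j]:
                nb = (num + l1[j]) / aj
            else:
                nb = 0.0
            # box safeguard on the standardized scale: a hazard ratio beyond
            # e^15 per SD signals separation, not signal
            nb = min(max(nb, -_BETA_CLIP), _BETA_CLIP)
            delta = nb - beta[j]
            if delta != 0.0:
                r[:] = r - xs[:, j] * delta
                beta[j] = nb
                md = max(md, abs(delta))
        return md

    all_idx = range(p)
    md = sweep(all_idx)
    for _ in range(5):  # admit violators a few times, converging on the active set
        if md < tol:
            break
        active = np.flatnonzero(beta != 0)
        for _ in range(max_sweeps):
            if sweep(active) < tol:
                break
        md = sweep(all_idx)
    return beta, z - r


def _fit_point(
    xs: np.ndarray,
    idx: _RiskSetIndex,
    lam: float,
    alpha: float,
    pf: np.ndarray,
    beta0: np.ndarray | None = None,
    tol: float = 1e-5,
    max_newton: int = 25,
) -> np.ndarray:
    """Penalized fit at one (lambda, alpha) point via IRLS + coordinate descent."""
    n, p = xs.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    eta = xs @ beta
    event = idx.event.astype(float)
    last_obj = np.inf
    for _ in range(max_newton):
        mu = _mu(eta, idx)
        w = np.maximum(mu, 1e-10)
        z = eta + (event - mu) / w
        beta_old = beta.copy()
        beta, eta = _coordinate_descent(xs, beta, eta, w, z, lam, alpha, pf,
                                        tol=max(tol, 1e-7))
        if np.max(np.abs(beta - beta_old)) < tol:
            break
        obj = (-partial_loglik(eta, idx.entry, idx.exit, idx.event, idx) / n
               + lam * np.sum(pf * (alpha * np.abs(beta)
                                    + 0.5 * (1 - alpha) * beta ** 2)))
        if abs(last_obj - obj) < 1e-8 * (1.0 + abs(obj)):
            break
        last_obj = obj
    return beta


def _lambda_path(xs: np.ndarray, idx: _RiskSetIndex, alpha: float, pf: np.ndarray,
                 grid: PenaltyGrid) -> np.ndarray:
    if grid.lambdas is not None:
        return np.asarray(sorted(grid.lambdas, reverse=True), dtype=float)
    n = xs.shape[0]
    # gradient at beta=0 after fitting any unpenalized columns
    beta0 = np.zeros(xs.shape[1])
    if np.any(pf == 0):
        huge = 1e10
        beta0 = _fit_point(xs, idx, huge, 1.0, pf, tol=1e-8)
    eta0 = xs @ beta0
    mu = _mu(eta0, idx)
    g = np.abs(xs.T @ (idx.event.astype(float) - mu)) / n
    g = g[pf > 0]
    if g.size == 0:
        return np.array([1e-4])
    alpha_eff = max(alpha, 1e-3)
    lam_max = float(np.max(g) / alpha_eff) * 1.0001
    lam_min = lam_max * grid.lambda_min_ratio
    return np.geomspace(lam_max, lam_min, grid.n_lambdas)


def _fit_path(xs: np.ndarray, idx: _RiskSetIndex, alpha: float,
              lambdas: np.ndarray, pf: np.ndarray) -> np.ndarray:
    """Warm-started solutions along a descending lambda sequence."""
    p = xs.shape[1]
    betas = np.empty((len(lambdas), p))
    beta = None
    for i, lam in enumerate(lambdas):
        beta = _fit_point(xs, idx, lam, alpha, pf, beta0=beta)
        betas[i] = beta
    return betas


# ---------------------------------------------------------------------------
# Model / Results objects


class CoxnetCPH:
    """Elastic-net Cox model on the age scale with delayed entry.

    Parameters
    ----------
    X : pandas.DataFrame
        One row per record, numeric features, no missing values.
    records : sequence of SurvivalRecord
        Row-aligned with ``X``.
    grid : PenaltyGrid, optional
        Cross-validation grid; defaults to 5 mixing values x 50 strengths.
    unpenalized : iterable of str, optional
        Columns exempt from the penalty (demographic adjusters by default
        when column names start with ``sex_`` or ``race_``).
    """

    def __init__(
        self,
        X: pd.DataFrame,
        records: Sequence[SurvivalRecord],
        grid: PenaltyGrid | None = None,
        unpenalized: Iterable[str] | None = None,
    ):
        if len(X) != len(records):
            raise ConfigurationError(
                f"features ({len(X)}) and records ({len(records)}) are not row-aligned"
            )
        if X.isna().any().any():
            bad = X.columns[X.isna().any()].tolist()
            raise ConfigurationError(f"missing values in feature column(s): {bad}")
        self.X = X.astype(float)
        self.records = list(records)
        self.grid = grid or PenaltyGrid()
        if unpenalized is None:
            unpenalized = [c for c in X.columns
                           if c.startswith("sex_") or c.startswith("race_")]
        self.unpenalized = [c for c in unpenalized if c in X.columns]
        self.entry = np.array([r.entry_age for r in self.records])
        self.exit = np.array([r.exit_age for r in self.records])
        self.event = np.array([r.event for r in self.records], dtype=float)

    @classmethod
    def from_feature_matrix(cls, matrix, records, grid=None, unpenalized=None):
        order = [r.patient_id for r in records]
        X = matrix.data.loc[order]
        return cls(X, records, grid=grid, unpenalized=unpenalized)

    # -- internals ----------------------------------------------------------

    def _standardize(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x = X.to_numpy(dtype=float)
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        return (x - mean) / sd_safe, mean, sd_safe

    def _cv_folds(self):
        skf = StratifiedKFold(n_splits=self.grid.folds, shuffle=True,
                              random_state=self.grid.seed)
        return list(skf.split(np.zeros(len(self.records)), self.event.astype(int)))

    def fit(self, verbose: bool = False) -> "CoxnetResults":
        """Select penalties by cross-validated deviance and refit on all data."""
        cols = list(self.X.columns)
        xs, mean, sd = self._standardize(self.X)
        pf = np.array([0.0 if c in self.unpenalized else 1.0 for c in cols])
        idx_all = _RiskSetIndex(self.entry, self.exit, self.event)
        if idx_all.event_times.size == 0:
            raise FitError("no events in the data")

        cv_rows = []
        best = None  # (mean cv deviance, mixing, strength)
        folds = self._cv_folds()
        for alpha in self.grid.l1_ratios:
            lambdas = _lambda_path(xs, idx_all, alpha, pf, self.grid)
            dev = np.zeros((len(folds), len(lambdas)))
            used = np.zeros(len(folds), dtype=bool)
            for f, (tr, te) in enumerate(folds):
                ev_tr = self.event[tr]
                if ev_tr.sum() == 0:
                    logger.warning("fold %d has no events; skipped", f)
                    continue
                used[f] = True
                idx_tr = _RiskSetIndex(self.entry[tr], self.exit[tr], ev_tr)
                betas = _fit_path(xs[tr], idx_tr, alpha, lambdas, pf)
                for i in range(len(lambdas)):
                    eta_all = xs @ betas[i]
                    ll_all = partial_loglik(eta_all, self.entry, self.exit,
                                            self.event, idx_all)
                    ll_tr = partial_loglik(eta_all[tr], self.entry[tr],
                                           self.exit[tr], ev_tr, idx_tr)
                    dev[f, i] = -2.0 * (ll_all - ll_tr)
            if not used.any():
                raise FitError("every cross-validation fold lacked events")
            mean_dev = dev[used].mean(axis=0)
            se_dev = dev[used].std(axis=0, ddof=1) / np.sqrt(used.sum()) if used.sum() > 1 else np.zeros_like(mean_dev)
            for i, lam in enumerate(lambdas):
                cv_rows.append({"l1_ratio": alpha, "lambda": lam,
                                "mean_deviance": mean_dev[i], "se_deviance": se_dev[i]})
            i_best = int(np.argmin(mean_dev))  # first (largest lambda) on ties
            if best is None or mean_dev[i_best] < best[0]:
                best = (mean_dev[i_best], alpha, float(lambdas[i_best]))
            if verbose:
                logger.info("alpha=%.2f best lambda=%.4g cvdev=%.3f",
                            alpha, lambdas[i_best], mean_dev[i_best])

        _, alpha_best, lam_best = best
        beta_std = _fit_point(xs, idx_all, lam_best, alpha_best, pf, tol=1e-7)
        beta = beta_std / sd
        lp = self.X.to_numpy(dtype=float) @ beta
        lp_mean = float(lp.mean())
        h0 = _breslow_baseline(lp - lp_mean, idx_all)
        return CoxnetResults(
            feature_names=cols,
            params=pd.Series(beta, index=cols, name="coef"),
            l1_ratio_=alpha_best,
            lambda_=lam_best,
            cv_results_=pd.DataFrame(cv_rows),
            baseline_times_=idx_all.event_times.copy(),
            baseline_cumhaz_=h0,
            lp_mean_=lp_mean,
            unpenalized=list(self.unpenalized),
            n_obs=len(self.records),
            n_events=int(self.event.sum()),
            folds=self.grid.folds,
            seed=self.grid.seed,
        )


def _breslow_baseline(eta_centered: np.ndarray, idx: _RiskSetIndex) -> np.ndarray:
    w = np.exp(np.clip(eta_centered, -_ETA_CLIP, _ETA_CLIP))
    s = idx.risk_sums(w)
    return np.cumsum(idx.d / s)


@dataclass
class CoxnetResults:
    """Fitted left-truncated elastic-net Cox model."""

    feature_names: list[str]
    params: pd.Series
    l1_ratio_: float
    lambda_: float
    cv_results_: pd.DataFrame
    baseline_times_: np.ndarray
    baseline_cumhaz_: np.ndarray  # for a subject at the mean linear predictor
    lp_mean_: float
    unpenalized: list[str] = field(default_factory=list)
    n_obs: int = 0
    n_events: int = 0
    folds: int = 10
    seed: int = 0

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise ContractError(f"feature(s) missing from prediction input: {missing}")
        return X[self.feature_names].to_numpy(dtype=float) @ self.params.to_numpy()

    def cumulative_hazard_at(self, age: float) -> float:
        """Baseline cumulative hazard (mean-lp reference) at an age."""
        i = int(np.searchsorted(self.baseline_times_, age, side="right"))
        return 0.0 if i == 0 else float(self.baseline_cumhaz_[i - 1])

    def predict_risk(self, X: pd.DataFrame, horizon_age: float) -> np.ndarray:
        """P(event by horizon age | features), i.e. 1 - S(horizon | x)."""
        lp = self.linear_predictor(X)
        h0 = self.cumulative_hazard_at(horizon_age)
        return 1.0 - np.exp(-h0 * np.exp(np.clip(lp - self.lp_mean_, -50, 50)))

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "coef": self.params,
            "exp(coef)": np.exp(self.params),
            "penalized": [c not in self.unpenalized for c in self.feature_names],
        })
        df.attrs["l1_ratio"] = self.l1_ratio_
        df.attrs["lambda"] = self.lambda_
        df.attrs["n_obs"] = self.n_obs
        df.attrs["n_events"] = self.n_events
        return df

    def __str__(self) -> str:
        head = (f"Left-truncated elastic-net Cox (age scale)\n"
                f"n={self.n_obs}, events={self.n_events}, "
                f"l1_ratio={self.l1_ratio_:g}, lambda={self.lambda_:.5g}, "
                f"{self.folds}-fold CV\n")
        return head + self.summary().to_string(float_format=lambda v: f"{v: .4f}")

    # -- serialization -------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "feature_names": self.feature_names,
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "l1_ratio": self.l1_ratio_,
            "lambda": self.lambda_,
            "baseline_times": [float(t) for t in self.baseline_times_],
            "baseline_cumhaz": [float(h) for h in self.baseline_cumhaz_],
            "lp_mean": self.lp_mean_,
            "unpenalized": self.unpenalized,
            "n_obs": self.n_obs,
            "n_events": self.n_events,
            "folds": self.folds,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CoxnetResults":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(source).read_text()
        d = json.loads(text)
        return cls(
            feature_names=d["feature_names"],
            params=pd.Series(d["coefficients"]).reindex(d["feature_names"]),
            l1_ratio_=d["l1_ratio"],
            lambda_=d["lambda"],
            cv_results_=pd.DataFrame(),
            baseline_times_=np.asarray(d["baseline_times"]),
            baseline_cumhaz_=np.asarray(d["baseline_cumhaz"]),
            lp_mean_=d["lp_mean"],
            unpenalized=d.get("unpenalized", []),
            n_obs=d.get("n_obs", 0),
            n_events=d.get("n_events", 0),
            folds=d.get("folds", 10),
            seed=d.get("seed", 0),
        )


def fit_coxnet(
    features: pd.DataFrame,
    records: Sequence[SurvivalRecord],
    grid: PenaltyGrid | None = None,
    unpenalized: Iterable[str] | None = None,
) -> CoxnetResults:
    """Fit the left-truncated elastic-net Cox model with CV penalty selection."""
    return CoxnetCPH(features, records, grid=grid, unpenalized=unpenalized).fit()


def predict_risk(model: CoxnetResults, features: pd.DataFrame, horizon_age: float) -> np.ndarray:
    """Functional alias for :meth:`CoxnetResults.predict_risk`."""
    return model.predict_risk(features, horizon_age)
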