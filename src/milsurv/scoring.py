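"""Mortality score, Breslow baseline, and cohort-level recalibration.

The mortality score condenses a predicted survival curve into one number:
the cumulative hazard summed over the 60 monthly intervals,

    M = sum_{k=1}^{60} H(k)  =  sum_{j=1}^{60} (61 - j) * eta_j .

Higher M means a steeper predicted drop in survival.  For transfer to a
cohort whose overall event level differs from the training cohort (scanner,
site or case-mix shift), the predicted hazard is recalibrated Cox-style:
a proportional-hazards model with the mortality score as single covariate
is fitted on the training cohort (giving the score effect beta-hat), the
baseline cumulative hazard is re-estimated on the target cohort by the
Breslow estimator with the score effect held fixed, and the recalibrated
curve is S(t | X) = exp(-H0_new(t) * exp(beta_hat * M(X))) on the monthly
grid.  Ranking of patients is unchanged by construction; only the absolute
level of the curves moves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import HORIZON
from .objectives import administrative_censor

__all__ = [
    "mortality_score",
    "StepFunction",
    "breslow_baseline",
    "CoxFit",
    "fit_score_cox",
    "recalibrate",
    "calibration_curve",
]


def mortality_score(etas: np.ndarray) -> float | np.ndarray:
    """Mortality score(s) from monthly hazard vector(s).

    Accepts a single 60-vector or an (n, 60) batch.  Uses the closed form
    ``M = sum_j (61 - j) eta_j`` equivalent to summing the cumulative
    hazard over the 60 intervals.
    """
    etas = np.asarray(etas, dtype=float)
    coef = np.arange(HORIZON, 0, -1)  # 60, 59, ..., 1
    out = etas @ coef
    return float(out) if np.ndim(out) == 0 else out


def curve_mortality_score(curves: np.ndarray) -> np.ndarray:
    """Mortality score from survival curve(s): M = -sum_k log S(k)."""
    curves = np.asarray(curves, dtype=float)
    return -np.log(curves).sum(axis=-1)


@dataclass
class StepFunction:
    """Right-continuous step function, 0 before the first jump time."""

    times: np.ndarray
    values: np.ndarray

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        pos = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(pos >= 0, self.values[np.clip(pos, 0, None)], 0.0)
        return out if out.ndim else float(out)


def breslow_baseline(
    linear_predictors: np.ndarray, times: np.ndarray, events: np.ndarray
) -> StepFunction:
    """Breslow baseline cumulative hazard of a Cox model.

    Increment at each distinct event time = (events there) / sum of
    exp(linear predictor) over the risk set.  With all-zero predictors this
    reduces to the Nelson-Aalen estimator.
    """
    lp = np.asarray(linear_predictors, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if not events.any():
        raise ValueError("Breslow baseline requires at least one event")
    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted, lp_sorted = times[order], events[order], lp[order]
    elp = np.exp(lp_sorted)
    # risk-set sums via suffix cumsum: risk set at t = {i : t_i >= t}
    suffix = np.cumsum(elp[::-1])[::-1]
    uniq, start = np.unique(t_sorted, return_index=True)
    incr = np.zeros(len(uniq))
    for i, s in enumerate(start):
        stop = start[i + 1] if i + 1 < len(uniq) else len(t_sorted)
        d = int(e_sorted[s:stop].sum())
        if d:
            incr[i] = d / suffix[s]
    keep = incr > 0
    return StepFunction(times=uniq[keep], values=np.cumsum(incr[keep]))


@dataclass
class CoxFit:
    """Fitted Cox model: coefficients plus Breslow baseline cumulative hazard."""

    beta: np.ndarray
    baseline_cumhaz: StepFunction
    covariates: list
    summary: pd.DataFrame | None = None

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.beta

    def predict_survival(self, X: np.ndarray, grid=None) -> np.ndarray:
        """S(t | X) = exp(-H0(t) * exp(beta'X)) on the monthly grid."""
        if grid is None:
            grid = np.arange(1, HORIZON + 1)
        h0 = np.asarray(self.baseline_cumhaz(np.asarray(grid, dtype=float)))
        lp = self.linear_predictor(X)
        return np.exp(-np.outer(np.exp(lp), h0))


def fit_score_cox(scores: np.ndarray, times: np.ndarray, events: np.ndarray) -> CoxFit:
    """Cox fit with the mortality score as the single covariate.

    The score effect is estimated by lifelines' partial-likelihood Newton
    solver (Breslow ties); the baseline comes from :func:`breslow_baseline`
    at the fitted coefficient.  Constant scores give beta = 0 (no
    information) rather than an error.
    """
    from lifelines import CoxPHFitter

    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if not events.any():
        raise ValueError("Cox fit requires at least one event")
    if np.ptp(scores) == 0:
        beta = np.zeros(1)
    else:
        df = pd.DataFrame({"score": scores, "T": times, "E": events.astype(int)})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E",
                fit_options={"precision": 1e-9})
        beta = cph.params_.to_numpy()
    baseline = breslow_baseline(scores * beta[0], times, events)
    return CoxFit(beta=beta, baseline_cumhaz=baseline, covariates=["score"])


def recalibrate(
    scores: np.ndarray,
    fit_train: CoxFit,
    target_times: np.ndarray,
    target_events: np.ndarray,
) -> np.ndarray:
    """Recalibrated survival curves for the target cohort, shape (n, 60).

    Keeps the training score effect beta-hat and re-estimates the baseline
    cumulative hazard on the target cohort (Breslow with the linear
    predictor fixed at beta-hat * score).
    """
    scores = np.asarray(scores, dtype=float)
    lp = scores * fit_train.beta[0]
    h0_new = breslow_baseline(lp, target_times, target_events)
    grid = np.arange(1, HORIZON + 1, dtype=float)
    return np.exp(-np.outer(np.exp(lp), np.asarray(h0_new(grid))))


def calibration_curve(
    curves: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Observed vs predicted five-year event probability by prediction decile.

    Patients are binned by predicted event probability 1 - S(60) into
    equal-count bins; the observed probability is 1 minus the Kaplan-Meier
    survival at 60 months within the bin.  Bins emptied by ties are merged
    into their neighbour (the returned frame then has fewer rows).
    """
    from lifelines import KaplanMeierFitter

    curves = np.asarray(curves, dtype=float)
    if curves.shape[0] < n_bins:
        raise ValueError("need at least n_bins patients")
    pred = 1.0 - curves[:, -1]
    times, events = administrative_censor(times, events)
    order = np.argsort(pred, kind="stable")
    bins = np.array_split(order, n_bins)
    # merge bins whose predicted range collapses onto the previous bin (ties)
    merged: list[np.ndarray] = []
    for b in bins:
        if merged and pred[b].min() <= pred[merged[-1]].max():
            merged[-1] = np.concatenate([merged[-1], b])
        else:
            merged.append(b)
    rows = []
    for b in merged:
        kmf = KaplanMeierFitter().fit(times[b], events[b])
        observed = 1.0 - float(
            kmf.survival_function_at_times(HORIZON).iloc[0]
        )
        rows.append(
            {"predicted": float(pred[b].mean()), "observed": observed, "n": len(b)}
        )
    return pd.DataFrame(rows)
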