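"""Clinical risk strata and score-based nested risk groups.

Patients are first stratified by UICC stage: stages I-IIa form the clinical
low-risk stratum (CLR), stages IIb-IV the clinical high-risk stratum (CHR).
Within a stratum, a mortality-score (or binary risk-score) cutoff splits
patients into nested lower-/higher-risk groups.  The cutoff is found on the
cross-validation folds: every observed score except the ten lowest and ten
highest is tried as a threshold, the two-group log-rank p-value is recorded,
the p-vs-threshold curves of the folds are linearly interpolated onto a
common grid (step 0.1 for mortality scores, 0.01 for risk scores) over the
intersection of the fold score ranges, averaged, smoothed with a Gaussian
kernel of one grid step, and the threshold minimizing the smoothed curve is
returned (smallest threshold on ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import chi2

from .data import CHR_STAGES, CLR_STAGES, UICC_STAGES, ClinicalCovariates

__all__ = [
    "assign_clinical_risk",
    "KMEstimate",
    "km_estimate",
    "logrank_test",
    "RiskGroupCutoff",
    "threshold_search",
    "assign_nested_groups",
]


def assign_clinical_risk(cov) -> str:
    """CHR/CLR stratum from UICC stage; missing stage excludes the patient."""
    uicc = cov.UICC if isinstance(cov, ClinicalCovariates) else cov
    if uicc is None or uicc == "":
        return "missing"
    if uicc in CLR_STAGES:
        return "CLR"
    if uicc in CHR_STAGES:
        return "CHR"
    raise ValueError(f"unknown UICC stage {uicc!r}; expected one of {sorted(UICC_STAGES)}")


@dataclass
class KMEstimate:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        pos = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(pos >= 0, self.survival[np.clip(pos, 0, None)], 1.0)
        return out if out.ndim else float(out)


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMEstimate:
    """Kaplan-Meier estimator; censorings at tied times occur after events."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("empty cohort")
    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    uniq, start = np.unique(t_sorted, return_index=True)
    n = len(times)
    surv, s = np.ones(len(uniq)), 1.0
    at_risk = n - start
    for i, st in enumerate(start):
        stop = start[i + 1] if i + 1 < len(uniq) else n
        d = int(e_sorted[st:stop].sum())
        if d:
            s *= 1.0 - d / at_risk[i]
        surv[i] = s
    return KMEstimate(times=uniq, survival=surv, at_risk=at_risk)


def logrank_test(
    times_a, events_a, times_b, events_b
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    eb = np.asarray(events_b, dtype=bool)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be nonempty")
    if not (ea.any() or eb.any()):
        raise ValueError("log-rank test undefined without events")
    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(len(ta), dtype=bool), np.ones(len(tb), dtype=bool)])
    ev_times = np.unique(t_all[e_all])
    # counts per distinct event time, vectorized over the time grid
    n_all = (t_all[None, :] >= ev_times[:, None]).sum(axis=1)
    n_b = ((t_all[None, :] >= ev_times[:, None]) & grp[None, :]).sum(axis=1)
    d_all = ((t_all[None, :] == ev_times[:, None]) & e_all[None, :]).sum(axis=1)
    d_b = (
        (t_all[None, :] == ev_times[:, None]) & e_all[None, :] & grp[None, :]
    ).sum(axis=1)
    expected = d_all * n_b / n_all
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(
            n_all > 1,
            d_all * (n_b / n_all) * (1 - n_b / n_all) * (n_all - d_all) / (n_all - 1),
            0.0,
        )
    o_minus_e = float((d_b - expected).sum())
    v = float(var.sum())
    if v == 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / v
    return stat, float(chi2.sf(stat, df=1))


@dataclass
class RiskGroupCutoff:
    """Result of the smoothed cross-validated log-rank threshold search."""

    cutoff: float
    grid: np.ndarray
    p_smoothed: np.ndarray
    p_at_cutoff: float
    stratum: str | None = None


def _fold_p_curve(scores, times, events):
    order = np.argsort(scores, kind="stable")
    s = np.asarray(scores, dtype=float)[order]
    n = len(s)
    candidates = np.unique(s[10 : n - 10])
    ps = np.empty(len(candidates))
    for i, theta in enumerate(candidates):
        mask_lo = np.asarray(scores) <= theta
        ps[i] = logrank_test(
            np.asarray(times)[mask_lo],
            np.asarray(events)[mask_lo],
            np.asarray(times)[~mask_lo],
            np.asarray(events)[~mask_lo],
        )[1]
    return candidates, ps


def threshold_search(
    per_fold: list,
    grid_step: float = 0.1,
    sigma: float = 1.0,
    stratum: str | None = None,
) -> RiskGroupCutoff:
    """Cross-validated cutoff by smoothed log-rank p-value minimization.

    ``per_fold`` is a list of ``(scores, times, events)`` triples, one per
    validation fold.  Every fold needs more than 21 patients so that
    admissible thresholds remain after dropping the ten lowest and ten
    highest scores.
    """
    curves = []
    ranges = []
    for scores, times, events in per_fold:
        scores = np.asarray(scores, dtype=float)
        if len(scores) <= 21:
            raise ValueError(
                f"fold with {len(scores)} patients has no admissible thresholds "
                "after excluding the ten lowest and ten highest scores"
            )
        cand, ps = _fold_p_curve(scores, times, events)
        curves.append((cand, ps))
        ranges.append((cand.min(), cand.max()))
    lo = max(r[0] for r in ranges)
    hi = min(r[1] for r in ranges)
    if hi < lo:
        raise ValueError("fold score ranges do not overlap; no common grid")
    grid = np.arange(np.ceil(lo / grid_step) * grid_step, hi + 1e-12, grid_step)
    if len(grid) == 0:
        raise ValueError("empty threshold grid")
    interp = np.stack([np.interp(grid, cand, ps) for cand, ps in curves])
    mean_curve = interp.mean(axis=0)
    smoothed = gaussian_filter1d(mean_curve, sigma=sigma, mode="reflect", truncate=4.0)
    best = int(np.argmin(smoothed))  # first minimum = smallest threshold
    return RiskGroupCutoff(
        cutoff=float(grid[best]),
        grid=grid,
        p_smoothed=smoothed,
        p_at_cutoff=float(smoothed[best]),
        stratum=stratum,
    )


def assign_nested_groups(scores: np.ndarray, cutoff: float) -> np.ndarray:
    """Nested risk labels: score <= cutoff is 'lower-risk', else 'higher-risk'."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    scores = np.asarray(scores, dtype=float)
    labels = np.where(scores <= cutoff, "lower-risk", "higher-risk")
    if len(np.unique(labels)) < 2 and len(scores) > 0:
        warnings.warn("degenerate split: all patients fall in one nested group")
    return labels
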