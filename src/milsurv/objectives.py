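"""Discrete-time survival objectives on a monthly grid.

The survival head parametrizes a piecewise-constant continuous-time hazard:
within month interval j (the half-open window ``(j-1, j]``) the hazard is a
constant mass ``eta_j > 0``.  A follow-up time t maps to the interval index
``k(t) = ceil(t)`` and the fraction ``rho(t) = t - (k-1)`` of that last
interval, with ``rho = 1`` at integer times.  The negative log-likelihood of
a batch is

    loss = -(1/n) * sum_i [ d_i * log eta_{k(t_i)}
                            - eta_{k(t_i)} * rho(t_i)
                            - sum_{j < k(t_i)} eta_j ]

where ``d_i`` is the event indicator.  Survival follows as
``S(k) = exp(-sum_{j<=k} eta_j)``.

The binary five-year head is trained with an IPCW-weighted cross-entropy:
patients censored before the 60-month horizon carry no label and weight 0;
events before the horizon are up-weighted by the inverse Kaplan-Meier
survival of the censoring distribution at their event time, patients still
at risk at the horizon by the inverse censoring survival just before it.
"""

from __future__ import annotations

import numpy as np

from .data import HORIZON

__all__ = [
    "interval_index",
    "administrative_censor",
    "pchazard_nll",
    "pchazard_nll_grad",
    "hazards_to_survival",
    "censoring_survival",
    "ipcw_weights",
    "weighted_bce",
]


def interval_index(t: float) -> tuple[int, float]:
    """Map a time in ``(0, 60]`` to ``(k, rho)`` on the monthly grid.

    Intervals are half-open ``(k-1, k]``; integer times get ``rho = 1``.
    """
    t = float(t)
    if t <= 0:
        raise ValueError(f"time must be positive, got {t}")
    if t > HORIZON:
        raise ValueError(
            f"time {t} exceeds the {HORIZON}-month horizon; "
            "apply administrative_censor first"
        )
    k = int(np.ceil(t))
    rho = t - (k - 1)
    return k, rho


def administrative_censor(
    times: np.ndarray, events: np.ndarray, horizon: float = HORIZON
) -> tuple[np.ndarray, np.ndarray]:
    """Truncate follow-up at the horizon; longer follow-up becomes censored.

    Idempotent: applying it twice equals applying it once.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    over = times > horizon
    return np.where(over, horizon, times), np.where(over, False, events)


def _interval_arrays(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0) or np.any(times > HORIZON):
        raise ValueError("times must lie in (0, 60] after administrative censoring")
    k = np.ceil(times).astype(int)
    rho = times - (k - 1)
    return k, rho


def pchazard_nll(etas: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Mean negative log-likelihood of the piecewise-constant hazard model."""
    etas = np.asarray(etas, dtype=float)
    if etas.ndim == 1:
        etas = etas[None, :]
    if etas.shape[0] == 0:
        raise ValueError("empty batch")
    if np.any(etas <= 0):
        raise ValueError("hazards must be strictly positive")
    events = np.asarray(events, dtype=bool)
    k, rho = _interval_arrays(times)
    n = etas.shape[0]
    idx = np.arange(n)
    eta_k = etas[idx, k - 1]
    cum = np.cumsum(etas, axis=1)
    # sum_{j<k} eta_j = cum[k-1] - eta_k
    prior = cum[idx, k - 1] - eta_k
    ll = events * np.log(eta_k) - eta_k * rho - prior
    return float(-np.mean(ll))


def pchazard_nll_grad(
    etas: np.ndarray, times: np.ndarray, events: np.ndarray
) -> np.ndarray:
    """Gradient of :func:`pchazard_nll` with respect to the hazard matrix."""
    etas = np.asarray(etas, dtype=float)
    single = etas.ndim == 1
    if single:
        etas = etas[None, :]
    events = np.asarray(events, dtype=float)
    k, rho = _interval_arrays(times)
    n, m = etas.shape
    idx = np.arange(n)
    grad = np.zeros_like(etas)
    # d(-ll_i)/d eta_j = 1 for j < k, (rho - d_i/eta_k) for j = k, 0 after
    mask = np.arange(m)[None, :] < (k - 1)[:, None]
    grad[mask] = 1.0
    grad[idx, k - 1] = rho - events / etas[idx, k - 1]
    grad /= n
    return grad[0] if single else grad


def hazards_to_survival(etas: np.ndarray) -> np.ndarray:
    """Survival curve(s) ``S(k) = exp(-cumsum(eta))`` on the monthly grid."""
    etas = np.asarray(etas, dtype=float)
    return np.exp(-np.cumsum(etas, axis=-1))


def censoring_survival(times: np.ndarray, events: np.ndarray):
    """Kaplan-Meier survival of the censoring distribution.

    Censoring is treated as the event of interest; at tied times actual
    events happen first, so a censoring at time t removes mass only for
    times strictly greater than t.  Returns ``G(t, left=...)`` evaluating
    the right-continuous step (``left=False``) or its left limit.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    cens_sorted = ~events[order]
    n = len(times)
    # risk set at a censoring time t: everyone with follow-up >= t
    uniq, start = np.unique(t_sorted, return_index=True)
    n_cens = np.zeros(len(uniq), dtype=int)
    for i, t in enumerate(uniq):
        stop = start[i + 1] if i + 1 < len(uniq) else n
        n_cens[i] = int(cens_sorted[start[i]:stop].sum())
    at_risk = n - start
    with np.errstate(divide="ignore"):
        factors = 1.0 - n_cens / at_risk
    surv = np.cumprod(factors)

    def G(t, left: bool = False):
        t = np.asarray(t, dtype=float)
        if left:
            pos = np.searchsorted(uniq, t, side="left") - 1
        else:
            pos = np.searchsorted(uniq, t, side="right") - 1
        out = np.where(pos >= 0, surv[np.clip(pos, 0, None)], 1.0)
        return out if out.ndim else float(out)

    return G


def ipcw_weights(
    times: np.ndarray, events: np.ndarray, tau: float = HORIZON
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-probability-of-censoring weights and five-year labels.

    Returns ``(weights, labels)`` aligned with the input.  Patients censored
    before ``tau`` without an event get weight 0 (their label entry is 0 but
    carries no weight).  Raises if no patient has a usable label.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    died = events & (times <= tau)
    # administrative censoring puts survivors at exactly t = tau with
    # event = False; they are "at risk at tau", not lost to follow-up
    at_risk = (times > tau) | ((times == tau) & ~events)
    usable = died | at_risk
    if not usable.any():
        raise ValueError("all patients censored before the horizon; no usable labels")
    G = censoring_survival(times, events)
    weights = np.zeros(len(times))
    labels = np.zeros(len(times))
    labels[died] = 1.0
    g_event = G(times[died], left=True)
    g_tau = G(tau, left=True)
    if np.any(g_event <= 0) or g_tau <= 0:
        raise ValueError("censoring survival reached zero before the horizon")
    weights[died] = 1.0 / g_event
    weights[at_risk] = 1.0 / g_tau
    return weights, labels


def weighted_bce(
    probs: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
    clip: float = 1e-12,
) -> float:
    """Weighted binary cross-entropy, normalized by the weight sum."""
    probs = np.clip(np.asarray(probs, dtype=float), clip, 1.0 - clip)
    labels = np.asarray(labels, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("all weights are zero")
    ll = labels * np.log(probs) + (1.0 - labels) * np.log1p(-probs)
    return float(-(weights * ll).sum() / wsum)
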