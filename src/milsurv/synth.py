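"""Synthetic multi-cohort generator for tile-feature survival analysis.

Each synthetic patient carries a latent risk ``r ~ N(0, 1)`` that drives
both the tile features and the survival time:

* a fraction of the patient's tiles is *informative*: those tiles are unit
  Gaussian noise shifted by ``signal_strength * r`` along the first feature
  axis; the remaining tiles are pure noise.  This mimics a slide on which
  only some tiles (e.g. tumor regions) carry prognostic morphology.
* the event time is drawn from a proportional-hazards model with a monthly
  piecewise-constant baseline: ``h(t | r) = h0(k(t)) * exp(beta_true * r)``,
  inverted analytically from a unit exponential draw.  Beyond the 60-month
  grid the last month's baseline hazard is carried forward.
* independent random censoring is exponential, with its rate calibrated by
  bisection (against the closed-form censoring probability, integrating the
  latent risk by Gauss-Hermite quadrature) so that the expected fraction of
  patients censored before month 60 equals ``censor_rate``.

Staging covariates (T/N/M/UICC) come from a monotone map of the latent-risk
quantile, so the clinical high-risk stratum (UICC IIb-IV) is enriched for
high latent risk, as staging is for real tumours.  Cohort shift — the
situation recalibration addresses — is emulated by rescaling the baseline
hazard and applying an affine transform to all tile features.

Generated times are continuous; administrative censoring at 60 months is a
separate, explicit step (:func:`milsurv.objectives.administrative_censor`).
Every patient has an independent random substream derived from
``(seed, patient index)``, so growing a cohort does not reshuffle existing
patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import ndtr

from .data import AGE_GROUPS, ClinicalCovariates, Cohort, FeatureBag, SurvivalRecord

__all__ = [
    "CohortConfig",
    "ShiftConfig",
    "default_clinical_link",
    "generate_cohort",
    "sample_survival_time",
    "apply_cohort_shift",
    "censoring_rate_param",
]

N_MONTHS = 60


def default_clinical_link(q: float) -> dict:
    """Monotone map from a latent-risk quantile to T/N/M/UICC categories.

    Stage cut points give roughly 20% stage I, 20% IIa, 10% IIb, 30% III
    and 20% IV, a plausible mix for a resected colorectal-cancer cohort.
    """
    if q < 0.20:
        uicc = "I"
    elif q < 0.40:
        uicc = "IIa"
    elif q < 0.50:
        uicc = "IIb"
    elif q < 0.80:
        uicc = "III"
    else:
        uicc = "IV"
    t_map = {"I": "T2", "IIa": "T3", "IIb": "T4", "III": "T3", "IV": "T4"}
    n_map = {"I": "N0", "IIa": "N0", "IIb": "N0", "III": "N1", "IV": "N2"}
    return {
        "T": t_map[uicc],
        "N": n_map[uicc],
        "M": "M1" if uicc == "IV" else "M0",
        "UICC": uicc,
    }


@dataclass
class CohortConfig:
    """Generator settings; defaults give a cohort with a clear but noisy
    image signal, proportional-hazards event times with a ~30% five-year
    event fraction, and 10% random censoring."""

    n_patients: int
    feature_dim: int = 512
    tiles_per_patient: tuple = (100, 1000)
    informative_fraction: float = 0.2
    signal_strength: float = 2.0
    beta_true: float = 1.0
    baseline_hazard: np.ndarray = None
    censor_rate: float = 0.1
    clinical_link: Callable[[float], dict] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be positive")
        k_min, k_max = self.tiles_per_patient
        if k_min < 1 or k_max < k_min:
            raise ValueError("tiles_per_patient must satisfy 1 <= K_min <= K_max")
        if not 0.0 <= self.informative_fraction <= 1.0:
            raise ValueError("informative_fraction must lie in [0, 1]")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be non-negative")
        if self.baseline_hazard is None:
            self.baseline_hazard = np.full(N_MONTHS, 0.006)
        self.baseline_hazard = np.asarray(self.baseline_hazard, dtype=float)
        if self.baseline_hazard.shape != (N_MONTHS,):
            raise ValueError(f"baseline_hazard must have length {N_MONTHS}")
        if np.any(self.baseline_hazard < 0) or not self.baseline_hazard.sum() > 0:
            raise ValueError("baseline_hazard must be non-negative and not all zero")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")


@dataclass
class ShiftConfig:
    """Cohort shift: baseline-hazard scaling plus an affine feature map."""

    hazard_scale: float = 1.0
    feature_scale: float | np.ndarray = 1.0
    feature_offset: float | np.ndarray = 0.0
    censor_rate_new: float | None = None

    def __post_init__(self) -> None:
        if not self.hazard_scale > 0:
            raise ValueError("hazard_scale must be positive")


def _censor_probability(lam: float, config: CohortConfig, nodes, weights) -> float:
    """P(random censoring strikes before month 60), in closed form.

    For each Gauss-Hermite node of the latent risk, integrate
    lam * exp(-lam c) * S_T(c | r) month by month (both factors are
    exponentials within a month).
    """
    h0 = config.baseline_hazard
    cum0 = np.concatenate([[0.0], np.cumsum(h0)])  # H0 at months 0..60
    scale = np.exp(config.beta_true * nodes)  # (R,)
    k = np.arange(N_MONTHS)
    a = scale[:, None] * h0[None, :] + lam  # (R, 60)
    pref = lam * np.exp(-lam * k[None, :] - scale[:, None] * cum0[None, :-1])
    with np.errstate(invalid="ignore"):
        frac = np.where(a > 0, -np.expm1(-a) / np.where(a > 0, a, 1.0), 1.0)
    p_r = (pref * frac).sum(axis=1)
    return float(weights @ p_r)


def censoring_rate_param(config: CohortConfig) -> float:
    """Exponential censoring rate hitting ``censor_rate`` by bisection."""
    if config.censor_rate == 0:
        return 0.0
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    weights = weights / weights.sum()  # probabilists' Hermite: nodes are N(0,1)
    lo, hi = 0.0, 1.0
    while _censor_probability(hi, config, nodes, weights) < config.censor_rate:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("censoring-rate calibration failed to bracket")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _censor_probability(mid, config, nodes, weights) < config.censor_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _invert_event_time(target: float, h0: np.ndarray) -> float:
    """Solve H0(t) = target for the piecewise-linear cumulative hazard."""
    cum = np.cumsum(h0)
    if target <= cum[-1]:
        k = int(np.searchsorted(cum, target, side="left"))
        prev = cum[k - 1] if k > 0 else 0.0
        return k + (target - prev) / h0[k]
    tail = h0[-1] if h0[-1] > 0 else h0[h0 > 0][-1]
    return N_MONTHS + (target - cum[-1]) / tail


def sample_survival_time(
    latent_risk: float,
    config: CohortConfig,
    rng: np.random.Generator,
    censor_lambda: float | None = None,
) -> SurvivalRecord:
    """Draw one (time, event) record for a patient with the given risk.

    Event times invert the piecewise-constant cumulative hazard
    ``H(t | r) = H0(t) * exp(beta_true * r)`` at a unit exponential draw;
    random censoring is exponential with the calibrated rate.
    """
    if censor_lambda is None:
        censor_lambda = censoring_rate_param(config)
    e = rng.exponential()
    t_event = _invert_event_time(e / np.exp(config.beta_true * latent_risk),
                                 config.baseline_hazard)
    if censor_lambda > 0:
        t_cens = rng.exponential(1.0 / censor_lambda)
    else:
        t_cens = np.inf
    if t_event <= t_cens:
        return SurvivalRecord(time_months=t_event, event=True)
    return SurvivalRecord(time_months=t_cens, event=False)


def _patient_rng(seed: int, index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index, stream]))


def _make_bag(
    pid: str, r: float, config: CohortConfig, rng: np.random.Generator
) -> tuple[FeatureBag, int]:
    k_min, k_max = config.tiles_per_patient
    K = int(rng.integers(k_min, k_max + 1))
    features = rng.standard_normal((K, config.feature_dim))
    n_inf = int(round(config.informative_fraction * K))
    # informative tiles are the leading rows, shifted along the first axis
    features[:n_inf, 0] += config.signal_strength * r
    return FeatureBag(patient_id=pid, features=features), n_inf


def generate_cohort(config: CohortConfig, name: str = "cohort") -> Cohort:
    """Generate a full synthetic cohort; deterministic given the seed."""
    censor_lambda = censoring_rate_param(config)
    link = config.clinical_link or default_clinical_link
    bags, records, covs = [], [], []
    risks = np.empty(config.n_patients)
    n_informative = np.empty(config.n_patients, dtype=int)
    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        r = float(rng.standard_normal())
        risks[i] = r
        bag, n_inf = _make_bag(f"{name}-{i:05d}", r, config, rng)
        n_informative[i] = n_inf
        bags.append(bag)
        records.append(sample_survival_time(r, config, rng, censor_lambda))
        stage = link(float(ndtr(r)))
        covs.append(
            ClinicalCovariates(
                age_group=AGE_GROUPS[rng.choice(4, p=[0.25, 0.35, 0.3, 0.1])],
                **stage,
            )
        )
    return Cohort(
        bags=bags,
        records=records,
        covariates=covs,
        latent_risk=risks,
        name=name,
        extra={"config": config, "n_informative": n_informative},
    )


def apply_cohort_shift(cohort: Cohort, shift: ShiftConfig) -> Cohort:
    """Move a cohort to a shifted 'site': redraw event times under a scaled
    baseline hazard (same latent risks, fresh substreams) and transform all
    tile features affinely.  Patient ids are preserved."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    config: CohortConfig = cohort.extra["config"]
    import dataclasses

    new_config = dataclasses.replace(
        config,
        baseline_hazard=config.baseline_hazard * shift.hazard_scale,
        censor_rate=(
            config.censor_rate
            if shift.censor_rate_new is None
            else shift.censor_rate_new
        ),
    )
    hazard_unchanged = shift.hazard_scale == 1.0 and shift.censor_rate_new is None
    censor_lambda = None if hazard_unchanged else censoring_rate_param(new_config)
    scale = np.asarray(shift.feature_scale)
    offset = np.asarray(shift.feature_offset)
    bags, records = [], []
    for i, bag in enumerate(cohort.bags):
        if hazard_unchanged:
            # a pure feature shift leaves the survival records untouched
            records.append(cohort.records[i])
        else:
            rng = _patient_rng(config.seed, i, stream=1)
            records.append(
                sample_survival_time(
                    float(cohort.latent_risk[i]), new_config, rng, censor_lambda
                )
            )
        bags.append(
            FeatureBag(bag.patient_id, bag.features * scale + offset)
        )
    return Cohort(
        bags=bags,
        records=records,
        covariates=list(cohort.covariates),
        latent_risk=cohort.latent_risk.copy(),
        name=cohort.name + "-shifted",
        extra={"config": new_config, "n_informative": cohort.extra.get("n_informative")},
    )
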