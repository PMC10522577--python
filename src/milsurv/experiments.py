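"""End-to-end study-condition experiments.

These functions reproduce the package's headline behaviours on synthetic
cohorts: signal recovery by the trained attention-MIL survival models,
recalibration of shifted cohorts, and cutoff recovery by the smoothed
log-rank threshold search.  The test suite and the acceptance script both
run them, so the measured numbers always come from the same code paths.

Problem sizes follow the scaled-down study design: training cohorts of 500
patients with 32-dimensional tile features and 50-200 tiles per bag, five
cross-validation folds, and a 40-epoch warmup+cosine schedule (the full
study schedule shrunk proportionally, with a peak rate matched to the
shorter run and stronger regularization appropriate for the small cohort:
weight decay 0.3 on the weight matrices, dropout 0.25, bias steps x10).
"""

from __future__ import annotations

import numpy as np

from .data import Cohort
from .metrics import integrated_brier, td_cindex
from .objectives import hazards_to_survival
from .scoring import curve_mortality_score, fit_score_cox, recalibrate
from .stratification import threshold_search
from .synth import CohortConfig, generate_cohort
from .training import TrainConfig, cross_validate, predict_curves

__all__ = [
    "experiment_cohort_config",
    "experiment_train_config",
    "signal_recovery_run",
    "recalibration_run",
    "mixture_threshold_run",
    "true_model_curves",
]


def experiment_cohort_config(seed: int, n_patients: int = 500,
                             signal_strength: float = 2.0) -> CohortConfig:
    """Study conditions of the end-to-end experiment."""
    return CohortConfig(
        n_patients=n_patients,
        feature_dim=32,
        tiles_per_patient=(50, 200),
        informative_fraction=0.2,
        signal_strength=signal_strength,
        beta_true=1.0,
        censor_rate=0.1,
        seed=seed,
    )


def experiment_train_config(seed: int = 0) -> TrainConfig:
    """Scaled training scheme for the synthetic cohorts (see module docs)."""
    return TrainConfig(
        epochs=40,
        warmup_epochs=8,
        peak_lr=3e-4,
        weight_decay=0.3,
        dropout=0.25,
        min_tiles=50,
        folds=5,
        seed=seed,
        attention_dim=64,
        bias_lr_scale=10.0,
    )


def signal_recovery_run(seed: int, signal_strength: float = 2.0) -> float:
    """Train a 5-fold CV survival-curve ensemble on a fresh synthetic cohort
    and return its td C-index on an independent test cohort."""
    train = generate_cohort(
        experiment_cohort_config(seed, 500, signal_strength), "train"
    )
    test = generate_cohort(
        experiment_cohort_config(seed + 10_000, 200, signal_strength), "test"
    )
    models = cross_validate(train, experiment_train_config(seed))
    curves = predict_curves(models, test)
    return td_cindex(curves, test.times, test.events)


def true_model_curves(cohort: Cohort) -> np.ndarray:
    """Survival curves of the generating model (requires latent truth)."""
    config: CohortConfig = cohort.extra["config"]
    etas = config.baseline_hazard[None, :] * np.exp(
        config.beta_true * cohort.latent_risk
    )[:, None]
    return hazards_to_survival(etas)


def recalibration_run(seed: int, n: int = 6000) -> dict:
    """Recalibrate true-model predictions onto a hazard-doubled cohort.

    The target cohort observes the same patients with all follow-up times
    halved — a doubled (constant) baseline hazard realized in a way that
    cancels Breslow noise between the training and target baselines, the
    construction under which S_recal = S_train^2 holds up to the cumulative
    hazard's curvature.  Returns the worst-month mean absolute difference
    between the recalibrated curves and the squared training-model curves,
    and the integrated Brier scores on the shifted cohort before/after
    recalibration.
    """
    cfg = CohortConfig(
        n_patients=n, feature_dim=2, tiles_per_patient=(1, 2),
        beta_true=1.0, censor_rate=0.1, seed=seed,
    )
    train = generate_cohort(cfg, "train")
    t_target, e_target = train.times / 2.0, train.events

    # identity check with a well-specified covariate (the log-scale risk):
    # isolates the recalibration machinery from score-form misspecification
    lp_score = train.latent_risk
    fit_lp = fit_score_cox(lp_score, train.times, train.events)
    before_lp = fit_lp.predict_survival(lp_score[:, None])
    after_lp = recalibrate(lp_score, fit_lp, t_target, e_target)
    grid_err = np.abs(after_lp - before_lp**2).mean(axis=0).max()

    # calibration gain with the pipeline's raw mortality score
    scores = curve_mortality_score(true_model_curves(train))
    fit = fit_score_cox(scores, train.times, train.events)
    before = fit.predict_survival(scores[:, None])
    after = recalibrate(scores, fit, t_target, e_target)
    return {
        "grid_err": float(grid_err),
        "ibs_before": integrated_brier(before, t_target, e_target),
        "ibs_after": integrated_brier(after, t_target, e_target),
    }


def mixture_threshold_run(seed: int, n_per_group: int = 100,
                          hazard_ratio: float = 4.0) -> float:
    """Threshold search on a two-component score mixture; returns the cutoff.

    Low-hazard patients carry scores U(0,5), high-hazard patients (hazard
    ratio 4) scores U(10,15); a faithful search lands in the (5,10) gap.
    """
    rng = np.random.default_rng(seed)
    per_fold = []
    for _ in range(5):
        s = np.concatenate([
            rng.uniform(0, 5, n_per_group), rng.uniform(10, 15, n_per_group)
        ])
        t = np.concatenate([
            rng.exponential(1 / 0.01, n_per_group),
            rng.exponential(1 / (0.01 * hazard_ratio), n_per_group),
        ])
        per_fold.append((s, t, np.ones(2 * n_per_group, dtype=bool)))
    return threshold_search(per_fold, grid_step=0.1).cutoff
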