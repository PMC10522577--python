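"""Cross-validation mechanics, schedule, subsampling, early stopping,
ensembling."""

import numpy as np
import pytest

from milsurv.data import Cohort, FeatureBag
from milsurv.mil import init_params
from milsurv.training import (
    FoldModel,
    TrainConfig,
    cross_validate,
    ensemble_predict,
    kfold_split,
    learning_rate,
    predict_curves,
    subsample_bag,
    train_model,
)


class TestKFold:
    def test_full_size_cohort_splits_evenly(self):
        folds = kfold_split(2205, 5, seed=0)
        assert [len(f) for f in folds] == [441] * 5

    def test_uneven_split(self):
        folds = kfold_split(7, 5, seed=0)
        assert sorted(len(f) for f in folds) == [1, 1, 1, 2, 2]

    def test_partition_and_determinism(self):
        a = kfold_split(100, 5, seed=3)
        b = kfold_split(100, 5, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        allidx = np.concatenate(a)
        assert len(allidx) == 100 and len(np.unique(allidx)) == 100

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            kfold_split(4, 5, seed=0)


class TestSubsample:
    def test_small_bag_returned_whole(self, rng):
        F = rng.standard_normal((800, 4))
        out = subsample_bag(F, 1000, rng)
        assert out.shape == (800, 4)
        assert out is F

    def test_subsample_size_distribution(self):
        """Drawn size is uniform on [min_tiles, K] (chi-square over 1e4)."""
        from scipy.stats import chisquare

        rng = np.random.default_rng(0)
        F = np.zeros((60, 2))
        sizes = np.array([subsample_bag(F, 50, rng).shape[0] for _ in range(10_000)])
        assert sizes.min() >= 50 and sizes.max() <= 60
        counts = np.bincount(sizes - 50, minlength=11)
        assert chisquare(counts).pvalue > 0.001

    def test_deterministic_given_state(self):
        F = np.arange(40.0).reshape(20, 2)
        a = subsample_bag(F, 5, np.random.default_rng(9))
        b = subsample_bag(F, 5, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_without_replacement(self, rng):
        F = np.arange(30.0).reshape(15, 2)
        out = subsample_bag(F, 5, rng)
        assert len(np.unique(out[:, 0])) == out.shape[0]


class TestSchedule:
    def test_trace_matches_closed_form(self):
        cfg = TrainConfig(epochs=100, warmup_epochs=20, peak_lr=1e-5)
        for e in range(1, 101):
            lr = learning_rate(e, cfg)
            if e <= 20:
                expected = 1e-5 * e / 20
            else:
                expected = 1e-5 * 0.5 * (1 + np.cos(np.pi * (e - 20) / 80))
            assert lr == pytest.approx(expected, abs=1e-12)
        assert learning_rate(100, cfg) == pytest.approx(0.0, abs=1e-12)
        assert learning_rate(20, cfg) == pytest.approx(1e-5)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=10, warmup_epochs=10)
        with pytest.raises(ValueError):
            TrainConfig(head="multiclass")


def _mini_train_cohorts():
    from milsurv.synth import CohortConfig, generate_cohort

    cfg = CohortConfig(n_patients=60, feature_dim=6, tiles_per_patient=(4, 8),
                       signal_strength=2.0, censor_rate=0.1, seed=31)
    cohort = generate_cohort(cfg)
    return cohort.subset(np.arange(40)), cohort.subset(np.arange(40, 60))


@pytest.mark.parametrize("head", ["survival", "binary"])
def test_train_model_runs_and_early_stops(head):
    train, val = _mini_train_cohorts()
    cfg = TrainConfig(epochs=6, warmup_epochs=2, peak_lr=1e-3, min_tiles=4,
                      folds=2, seed=0, head=head, attention_dim=8, hidden=(8,))
    model = train_model(train, val, cfg)
    losses = [h["val_loss"] for h in model.history]
    assert len(losses) == 6
    assert model.best_epoch == int(np.argmin(losses)) + 1
    assert np.isfinite(losses).all()


def test_no_leakage_between_folds():
    from milsurv.synth import CohortConfig, generate_cohort

    cohort = generate_cohort(
        CohortConfig(n_patients=23, feature_dim=4, tiles_per_patient=(2, 3), seed=5)
    )
    folds = kfold_split(cohort, 5, seed=1)
    for val_idx in folds:
        train_idx = np.setdiff1d(np.arange(len(cohort)), val_idx)
        assert len(np.intersect1d(train_idx, val_idx)) == 0


class TestEnsemble:
    @staticmethod
    def _const_model(curve_level, rng):
        # build a FoldModel whose hazards are constant via zeroed params
        p = init_params(4, head="survival", attention_dim=3, hidden=(4,), rng=rng)
        for w in p.head.weights:
            w[:] = 0.0
        for b in p.head.biases:
            b[:] = 0.0
        # softplus(b) = eta ; choose bias so that S(k) = level ** k
        eta = -np.log(curve_level)
        p.head.biases[-1][:] = np.log(np.expm1(eta))
        return FoldModel(fold=0, params=p, best_epoch=1)

    def test_single_model_identity(self, rng):
        m = self._const_model(0.8, rng)
        bag = FeatureBag("p", rng.standard_normal((3, 4)))
        single = ensemble_predict([m], bag)
        expected = 0.8 ** np.arange(1, 61)
        assert np.allclose(single, expected, atol=1e-6)

    def test_pointwise_mean_of_two_members(self, rng):
        """Members with flat monthly survival ratios 0.8 and 0.6 average to
        0.7 of the respective powers at every month."""
        m1 = self._const_model(0.8, rng)
        m2 = self._const_model(0.6, rng)
        bag = FeatureBag("p", rng.standard_normal((3, 4)))
        ens = ensemble_predict([m1, m2], bag)
        expected = 0.5 * (0.8 ** np.arange(1, 61) + 0.6 ** np.arange(1, 61))
        assert np.allclose(ens, expected, atol=1e-6)

    def test_ensemble_curve_is_monotone_probability(self, rng):
        models = [self._const_model(l, rng) for l in (0.95, 0.7, 0.85)]
        bag = FeatureBag("p", rng.standard_normal((5, 4)))
        ens = ensemble_predict(models, bag)
        assert np.all(np.diff(ens) <= 0)
        assert np.all((ens > 0) & (ens <= 1))

    def test_mixed_heads_raise(self, rng):
        m1 = self._const_model(0.8, rng)
        p2 = init_params(4, head="binary", attention_dim=3, hidden=(4,), rng=rng)
        m2 = FoldModel(fold=1, params=p2, best_epoch=1)
        with pytest.raises(ValueError):
            ensemble_predict([m1, m2], FeatureBag("p", rng.standard_normal((2, 4))))

    def test_empty_ensemble_raises(self, rng):
        with pytest.raises(ValueError):
            ensemble_predict([], FeatureBag("p", rng.standard_normal((2, 4))))


def test_projection_ensemble_members_differ_and_average():
    """Extractor-style members train on distinct random projections; their
    averaged prediction is a valid monotone survival curve."""
    from milsurv.synth import CohortConfig, generate_cohort
    from milsurv.training import ensemble_members_predict, projection_ensemble

    cohort = generate_cohort(
        CohortConfig(n_patients=24, feature_dim=6, tiles_per_patient=(3, 5),
                     signal_strength=1.0, censor_rate=0.0, seed=77)
    )
    cfg = TrainConfig(epochs=3, warmup_epochs=1, peak_lr=1e-3, min_tiles=3,
                      folds=2, seed=0, attention_dim=6, hidden=(8,))
    members = projection_ensemble(cohort, cfg, n_members=2, seed=1)
    assert not np.allclose(members[0].projection, members[1].projection)
    curves = ensemble_members_predict(members, cohort)
    assert curves.shape == (24, 60)
    assert np.all(np.diff(curves, axis=1) <= 1e-12)
    assert np.all((curves > 0) & (curves <= 1))


def test_cross_validation_and_ensemble_dispersion():
    """The fold-ensemble's test C-index varies less across replicate
    cohorts than individual fold models do (robustness of averaging)."""
    from milsurv.metrics import td_cindex
    from milsurv.synth import CohortConfig, generate_cohort

    ens_scores, member_sds = [], []
    cfg_t = TrainConfig(epochs=5, warmup_epochs=1, peak_lr=3e-3, min_tiles=6,
                        folds=3, seed=0, attention_dim=8, hidden=(16,))
    member_vals = []
    for seed in range(10):
        cohort = generate_cohort(
            CohortConfig(n_patients=60, feature_dim=8, tiles_per_patient=(5, 10),
                         signal_strength=2.0, censor_rate=0.0, seed=100 + seed)
        )
        test = generate_cohort(
            CohortConfig(n_patients=60, feature_dim=8, tiles_per_patient=(5, 10),
                         signal_strength=2.0, censor_rate=0.0, seed=900 + seed)
        )
        models = cross_validate(cohort, cfg_t)
        curves = predict_curves(models, test)
        ens_scores.append(td_cindex(curves, test.times, test.events))
        member_vals.append([
            td_cindex(predict_curves([m], test), test.times, test.events)
            for m in models
        ])
    ens_sd = np.std(ens_scores)
    member_sd = np.mean(np.std(np.array(member_vals), axis=0))
    assert ens_sd <= member_sd + 0.01
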