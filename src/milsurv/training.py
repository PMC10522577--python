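"""Five-fold cross-validated training of the MIL survival models.

Follows the frozen-feature training scheme: batch size 1, random tile
subsampling (at least ``min_tiles`` up to the full bag; bags smaller than
``min_tiles`` are used whole), dropout 0.5 in the head, AdamW with
decoupled weight decay 1e-6, learning rate warmed up linearly to 1e-5 over
the first 20 epochs then cosine-annealed to 0 at epoch 100, and early
stopping by the lowest validation loss.  Validation and test predictions
always use all tiles of a bag.

Fold models are ensembled by averaging predictions: pointwise mean of
survival curves or mean of binary probabilities.  A "feature extractor"
ensemble is emulated by training members on independent random linear
projections of the same tile features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data import Cohort, FeatureBag
from .mil import MILParams, backward_bag, forward_bag, init_params
from .objectives import (
    administrative_censor,
    hazards_to_survival,
    ipcw_weights,
    pchazard_nll,
    weighted_bce,
)

__all__ = [
    "TrainConfig",
    "FoldModel",
    "kfold_split",
    "subsample_bag",
    "learning_rate",
    "AdamW",
    "train_model",
    "cross_validate",
    "ensemble_predict",
    "predict_curves",
    "predict_risks",
    "EnsembleMember",
    "projection_ensemble",
    "ensemble_members_predict",
]


@dataclass
class TrainConfig:
    epochs: int = 100
    warmup_epochs: int = 20
    peak_lr: float = 1e-5
    weight_decay: float = 1e-6
    dropout: float = 0.5
    batch_size: int = 1
    min_tiles: int = 1000
    folds: int = 5
    seed: int = 0
    head: str = "survival"
    attention_dim: int = 128
    hidden: tuple = (128, 64)
    #: relative learning rate of the bias parameters; the hazard head's
    #: output biases must travel far (from softplus(0) to the cohort's
    #: hazard level) while the weights need many small steps, so small
    #: cohorts benefit from a larger bias group rate
    bias_lr_scale: float = 1.0
    dtype: type = np.float32

    def __post_init__(self) -> None:
        if not self.warmup_epochs < self.epochs:
            raise ValueError("warmup_epochs must be smaller than epochs")
        if self.min_tiles < 1:
            raise ValueError("min_tiles must be >= 1")
        if self.head not in ("survival", "binary"):
            raise ValueError("head must be 'survival' or 'binary'")


@dataclass
class FoldModel:
    fold: int
    params: MILParams
    best_epoch: int
    history: list = field(default_factory=list)

    @property
    def head(self) -> str:
        return "survival" if self.params.head.activation == "softplus" else "binary"


def kfold_split(cohort, k: int = 5, seed: int = 0) -> list:
    """Random partition of patients into k folds with sizes differing by <= 1."""
    n = len(cohort) if not isinstance(cohort, (int, np.integer)) else int(cohort)
    if n < k:
        raise ValueError(f"need at least {k} patients for {k} folds, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def subsample_bag(bag, min_tiles: int, rng: np.random.Generator):
    """Training-time tile subsample: all tiles if the bag is small, else a
    uniform count in ``[min_tiles, K]`` drawn without replacement."""
    F = bag.features if isinstance(bag, FeatureBag) else bag
    K = F.shape[0]
    if K <= min_tiles:
        sub = F
    else:
        m = int(rng.integers(min_tiles, K + 1))
        sub = F[rng.choice(K, size=m, replace=False)]
    if isinstance(bag, FeatureBag):
        return FeatureBag(bag.patient_id, sub)
    return sub


def learning_rate(epoch: int, config: TrainConfig) -> float:
    """Schedule value for a 1-based epoch: linear warmup then cosine to 0."""
    if epoch <= config.warmup_epochs:
        return config.peak_lr * epoch / config.warmup_epochs
    frac = (epoch - config.warmup_epochs) / (config.epochs - config.warmup_epochs)
    return config.peak_lr * 0.5 * (1.0 + np.cos(np.pi * frac))


class AdamW:
    """Adam with decoupled weight decay acting on a list of arrays in place.

    ``weight_decay`` and ``lr_scale`` may be scalars or arrays broadcasting
    against the corresponding parameter (used for parameter groups: decay on
    weight matrices only, larger steps for biases).
    """

    def __init__(self, params: list, weight_decay=0.0, lr_scale=None,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.lr_scale = lr_scale
        self.t = 0

    def step(self, grads: list, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for idx, (p, g, m, v) in enumerate(zip(self.params, grads, self.m, self.v)):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            step = lr if self.lr_scale is None else lr * (
                self.lr_scale[idx] if isinstance(self.lr_scale, list)
                else self.lr_scale
            )
            p -= step * (m / c1 / (np.sqrt(v / c2) + self.eps)
                         + self.weight_decay * p)


def _prepare(cohort: Cohort, dtype) -> tuple[list, np.ndarray, np.ndarray]:
    feats = [np.ascontiguousarray(b.features, dtype=dtype) for b in cohort.bags]
    times, events = administrative_censor(cohort.times, cohort.events)
    return feats, times, events


def _flat_view(params: MILParams) -> tuple[np.ndarray, MILParams]:
    """Repack parameters into one flat buffer; the returned MILParams holds
    views into it, so a single optimizer update moves every array."""
    from .mil import AttentionParams, HeadParams

    arrs = params.arrays()
    flat = np.concatenate([a.ravel() for a in arrs])
    views, off = [], 0
    for a in arrs:
        views.append(flat[off : off + a.size].reshape(a.shape))
        off += a.size
    n_w = len(params.head.weights)
    head = HeadParams(
        views[2 : 2 + n_w], views[2 + n_w :],
        params.head.activation, params.head.dropout,
    )
    return flat, MILParams(AttentionParams(views[0], views[1]), head)


def _validation_loss(params, feats, times, events, head, ipcw=None) -> float:
    if head == "survival":
        etas = np.stack([forward_bag(F, params)[0] for F in feats])
        return pchazard_nll(etas, times, events)
    logits = np.array([forward_bag(F, params)[0][0] for F in feats])
    probs = expit(logits)
    weights, labels = ipcw
    return weighted_bce(probs, labels, weights)


def train_model(train_cohort: Cohort, val_cohort: Cohort,
                config: TrainConfig, fold: int = 0) -> FoldModel:
    """Train one fold and return the parameters of the best-validation epoch."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, fold]))
    feats, times, events = _prepare(train_cohort, config.dtype)
    vfeats, vtimes, vevents = _prepare(val_cohort, config.dtype)
    feature_dim = feats[0].shape[1]
    params = init_params(
        feature_dim,
        head=config.head,
        attention_dim=config.attention_dim,
        hidden=config.hidden,
        dropout=config.dropout,
        rng=rng,
        dtype=config.dtype,
    )
    sizes = [a.size for a in params.arrays()]
    n_weight_arrays = 2 + len(config.hidden) + 1  # V, w, and the W matrices
    flat, params = _flat_view(params)
    # parameter groups: decay acts on weight matrices only; biases may get a
    # larger step (see TrainConfig.bias_lr_scale)
    wd_mask = np.zeros_like(flat)
    lr_mask = np.ones_like(flat)
    off = 0
    for ai, size in enumerate(sizes):
        if ai < n_weight_arrays:
            wd_mask[off : off + size] = config.weight_decay
        else:
            lr_mask[off : off + size] = config.bias_lr_scale
        off += size
    opt = AdamW([flat], weight_decay=wd_mask, lr_scale=lr_mask)

    if config.head == "binary":
        weights, labels = ipcw_weights(times, events)
        usable = np.flatnonzero(weights > 0)
        mean_w = weights[usable].mean()
        val_ipcw = ipcw_weights(vtimes, vevents)
    else:
        usable = np.arange(len(feats))
        val_ipcw = None

    # per-patient interval index and last-interval fraction, fixed over epochs
    k_idx = np.ceil(times).astype(int) - 1
    rho = times - k_idx
    d_f = events.astype(float)

    best = (np.inf, None, -1)
    history = []
    for epoch in range(1, config.epochs + 1):
        lr = learning_rate(epoch, config)
        order = rng.permutation(usable)
        epoch_loss = 0.0
        for i in order:
            F = subsample_bag(feats[i], config.min_tiles, rng)
            out, cache = forward_bag(F, params, train=True, rng=rng)
            if config.head == "survival":
                k = k_idx[i]
                eta_k = out[k]
                loss = -(d_f[i] * np.log(eta_k) - eta_k * rho[i] - out[:k].sum())
                dout = np.zeros_like(out)
                dout[:k] = 1.0
                dout[k] = rho[i] - d_f[i] / eta_k
            else:
                p = float(expit(out[0]))
                w, y = weights[i] / mean_w, labels[i]
                loss = w * -(y * np.log(max(p, 1e-12))
                             + (1 - y) * np.log(max(1 - p, 1e-12)))
                dout = np.array([w * (p - y)], dtype=config.dtype)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training loss diverged at epoch {epoch} (fold {fold})"
                )
            grads = backward_bag(dout, cache)
            opt.step([np.concatenate([g.ravel() for g in grads])], lr)
            epoch_loss += float(loss)
        val_loss = _validation_loss(
            params, vfeats, vtimes, vevents, config.head, val_ipcw
        )
        history.append(
            {"epoch": epoch, "lr": lr,
             "train_loss": epoch_loss / max(len(order), 1), "val_loss": val_loss}
        )
        if val_loss < best[0]:
            best = (val_loss, params.copy(), epoch)
    return FoldModel(fold=fold, params=best[1], best_epoch=best[2], history=history)


def cross_validate(cohort: Cohort, config: TrainConfig) -> list:
    """Standard k-fold CV: each fold serves once as the validation set."""
    folds = kfold_split(cohort, config.folds, config.seed)
    models = []
    for j, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(cohort)), val_idx)
        models.append(
            train_model(cohort.subset(train_idx), cohort.subset(val_idx), config, fold=j)
        )
    return models


def _single_prediction(model: FoldModel, F: np.ndarray):
    out, _ = forward_bag(F, model.params)
    if model.head == "survival":
        return hazards_to_survival(out)
    return float(expit(out[0]))


def ensemble_predict(models: list, bag):
    """Average fold/member predictions: pointwise mean survival curve, or
    mean probability for the binary head."""
    if len(models) == 0:
        raise ValueError("need at least one model")
    heads = {m.head for m in models}
    if len(heads) > 1:
        raise ValueError("cannot ensemble mixed head types")
    F = bag.features if isinstance(bag, FeatureBag) else np.asarray(bag)
    preds = [_single_prediction(m, F) for m in models]
    return np.mean(preds, axis=0) if heads == {"survival"} else float(np.mean(preds))


def predict_curves(models: list, cohort: Cohort) -> np.ndarray:
    """Ensemble survival curves for every patient, shape (n, 60)."""
    return np.stack([ensemble_predict(models, b) for b in cohort.bags])


def predict_risks(models: list, cohort: Cohort) -> np.ndarray:
    """Ensemble binary five-year risks for every patient."""
    return np.array([ensemble_predict(models, b) for b in cohort.bags])


@dataclass
class EnsembleMember:
    """One emulated 'feature extractor': a fixed random linear projection of
    the tile features plus the CV fold models trained on it."""

    projection: np.ndarray
    models: list

    def project(self, cohort: Cohort) -> Cohort:
        bags = [FeatureBag(b.patient_id, b.features @ self.projection)
                for b in cohort.bags]
        return Cohort(bags, cohort.records, cohort.covariates,
                      cohort.latent_risk, cohort.name, cohort.extra)


def projection_ensemble(cohort: Cohort, config: TrainConfig,
                        n_members: int = 3, seed: int = 0) -> list:
    """Train an extractor-style ensemble on random projections of the bags."""
    d = cohort.bags[0].features.shape[1]
    members = []
    for m in range(n_members):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 97, m]))
        proj = rng.standard_normal((d, d)) / np.sqrt(d)
        member = EnsembleMember(projection=proj, models=[])
        import dataclasses

        cfg = dataclasses.replace(config, seed=config.seed + m)
        member.models = cross_validate(member.project(cohort), cfg)
        members.append(member)
    return members


def ensemble_members_predict(members: list, cohort: Cohort) -> np.ndarray:
    """Fold-average within each member, then average across members."""
    per_member = [predict_curves(m.models, m.project(cohort)) for m in members]
    return np.mean(per_member, axis=0)
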