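"""Seeded PU-MIL training loop, checkpointing, and prediction.

Each epoch: (1) score every unlabeled bag with the pooled site probability
F(B); (2) take the |P| lowest-scoring unlabeled bags as reliable negatives,
so positives and negatives are balanced; (3) minimize L = L_m + L_p by
mini-batch Adam over bags, where L_m is the bag-classifier cross-entropy on
labeled positives plus current reliable negatives and L_p is the Noisy-OR
Bernoulli likelihood with an L2 penalty on the Platt scalars.

Batches are built from shuffled (positive, reliable-negative) pairs, so
every gradient step sees balanced classes.  All randomness flows from the
config seed; two runs with the same config produce identical checkpoints.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import model as M
from . import pooling as P
from .bags import POSITIVE, UNLABELED, PUBagDataset, SiteBag

logger = logging.getLogger("pumil.train")


@dataclass
class TrainConfig:
    epochs: int = 60
    learning_rate: float = 1e-2
    normalize: bool = True                # z-score features on the training bags
    site_center: bool = True              # on 40-feature data, center signal
                                          # medians/means within each site
    bag_batch_size: int = 32
    seed: int = 0
    lam: float = 1e-3                     # Platt L2 penalty weight
    weight_decay: float = 3e-3            # L2 on network weights; curbs
                                          # attention saturation / lock-in
    epsilon_clip: float = M.EPS_CLIP
    pooling_variant: str = "weighted_noisy_or"
    warmup_epochs: int | None = None      # epochs trained with plain Noisy-OR
                                          # before the rank-weighted variant;
                                          # None = epochs // 3
    attention_pooling: bool = True        # False = "no_attention" ablation (mean pool)
    dim_embed: int = 16
    dim_att: int = 8
    reliable_negative_refresh: bool = True
    early_stop_patience: int | None = None
    read_subsample: float | None = 0.7    # per-epoch fraction of reads kept
                                          # per training bag (None = all)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class TrainReport:
    epochs_run: int = 0
    loss: list[float] = field(default_factory=list)
    loss_mil: list[float] = field(default_factory=list)
    loss_pu: list[float] = field(default_factory=list)
    n_pos: int = 0
    n_reliable_neg: list[int] = field(default_factory=list)
    val_bag_auc: list[float] = field(default_factory=list)


@dataclass
class FittedModel:
    """Trained parameters plus the config and feature normalizer used."""

    params: M.AttentionParams
    config: TrainConfig
    normalizer: "Normalizer | None" = None


@dataclass
class SitePrediction:
    """Per-site output: pooled probability plus per-read detail."""

    bag_id: str
    site_prob: float
    instance_probs: np.ndarray
    attention_weights: np.ndarray
    n_reads: int
    instance_ids: list[str] = field(default_factory=list)


@dataclass
class Normalizer:
    """Feature normalization fitted on the training bags.

    Optionally centers selected columns within each bag first (used for the
    signal location statistics of the 40-feature schema, where absolute
    current levels are 5-mer-specific and would otherwise fingerprint
    individual sites), then applies global per-feature z-scoring.  Constant
    features get SD 1 so they pass through unchanged (centered).
    """

    mean: np.ndarray
    sd: np.ndarray
    center_idx: tuple[int, ...] | None = None

    @classmethod
    def fit(cls, bags: Sequence[SiteBag],
            center_idx: tuple[int, ...] | None = None) -> "Normalizer":
        mats = [cls._center(b.feature_matrix(), center_idx) for b in bags]
        X = np.concatenate(mats)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        return cls(X.mean(axis=0), sd, center_idx)

    @staticmethod
    def _center(X: np.ndarray, center_idx) -> np.ndarray:
        if center_idx:
            X = X.copy()
            idx = list(center_idx)
            X[:, idx] -= X[:, idx].mean(axis=0)
        return X

    def transform_bag(self, bag: SiteBag) -> SiteBag:
        from .bags import InstanceFeature
        if bag.dim != self.mean.shape[0]:
            raise ValueError(
                f"feature dimension mismatch: model expects {self.mean.shape[0]}, "
                f"bag {bag.bag_id!r} has {bag.dim}"
            )
        X = (self._center(bag.feature_matrix(), self.center_idx)
             - self.mean) / self.sd
        insts = [
            InstanceFeature(i.instance_id, X[j], hidden_label=i.hidden_label)
            for j, i in enumerate(bag.instances)
        ]
        return SiteBag(bag.bag_id, insts, bag.bag_label, bag.hidden_bag_label)

    def transform(self, bags: Sequence[SiteBag]) -> list[SiteBag]:
        return [self.transform_bag(b) for b in bags]

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist(),
                "center_idx": list(self.center_idx) if self.center_idx else None}

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        ci = d.get("center_idx")
        return cls(np.asarray(d["mean"], dtype=float),
                   np.asarray(d["sd"], dtype=float),
                   tuple(ci) if ci else None)


class _Adam:
    def __init__(self, shapes: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in shapes.items()}
        self.v = {k: np.zeros_like(v) for k, v in shapes.items()}
        self.t = 0

    def step(self, params: M.AttentionParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, g in grads.items():
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1 ** self.t)
            vhat = self.v[key] / (1 - self.b2 ** self.t)
            update = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            cur = getattr(params, key)
            if np.isscalar(cur) or np.ndim(cur) == 0:
                setattr(params, key, float(cur - update.ravel()[0]))
            else:
                setattr(params, key, cur - update.reshape(np.shape(cur)))


def _bag_F(fw: M.BagForwardResult, params: M.AttentionParams,
           variant: str, eps: float) -> tuple[float, np.ndarray]:
    f = P.platt(fw.atts, P.PlattParams(params.alpha, params.beta))
    return P.bag_probability(f, variant, eps), f


def score_bags(params: M.AttentionParams, bags: Sequence[SiteBag],
               variant: str = "weighted_noisy_or", mean_pool: bool = False,
               eps: float = M.EPS_CLIP) -> dict[str, float]:
    """F(B) for each bag, keyed by bag_id."""
    out = {}
    for bag in bags:
        fw = M.bag_forward(bag.feature_matrix(), params, mean_pool=mean_pool)
        out[bag.bag_id] = _bag_F(fw, params, variant, eps)[0]
    return out


def _subsample(bag: SiteBag, frac: float | None,
               rng: np.random.Generator) -> SiteBag:
    """Random per-epoch read subset of a training bag (regularization)."""
    if frac is None or frac >= 1.0 or bag.size <= 3:
        return bag
    keep = max(3, int(round(frac * bag.size)))
    idx = np.sort(rng.choice(bag.size, size=keep, replace=False))
    return SiteBag(bag.bag_id, [bag.instances[i] for i in idx],
                   bag.bag_label, None)


def _bag_summary(bag: SiteBag) -> np.ndarray:
    X = bag.feature_matrix()
    return np.concatenate([X.mean(axis=0), X.std(axis=0)])


def initial_reliable_negatives(positives: Sequence[SiteBag],
                               unlabeled: Sequence[SiteBag],
                               rng: np.random.Generator | None = None
                               ) -> set[str]:
    """Model-free seed for the reliable-negative set.

    An untrained model scores bags arbitrarily, and seeding R from it can
    select hidden positives and lock training into an inverted solution.
    Instead each bag is summarized by its per-feature mean and spread, a
    regularized logistic regression separates labeled-positive summaries
    from the unlabeled pool (the usual first step of two-step PU learning),
    and the lowest-scoring unlabeled bags become the initial R.  Later
    epochs re-select R from model probabilities.

    With ``rng``, the regression is fitted on a bootstrap resample, so
    ensemble members seeded differently get decorrelated anchors.
    """
    from sklearn.linear_model import LogisticRegression

    pos = np.stack([_bag_summary(b) for b in positives])
    unl = np.stack([_bag_summary(b) for b in unlabeled])
    fit_pos, fit_unl = pos, unl
    if rng is not None:
        fit_pos = pos[rng.integers(len(pos), size=len(pos))]
        fit_unl = unl[rng.integers(len(unl), size=len(unl))]
    X = np.vstack([fit_pos, fit_unl])
    y = np.concatenate([np.ones(len(fit_pos)), np.zeros(len(fit_unl))])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    clf = LogisticRegression(max_iter=2000, C=0.5).fit((X - mu) / sd, y)
    scores = clf.predict_proba((unl - mu) / sd)[:, 1]
    order = sorted(range(len(unlabeled)),
                   key=lambda i: (scores[i], unlabeled[i].bag_id))
    return {unlabeled[i].bag_id for i in order[:len(positives)]}


def _bag_losses_and_grads(bag: SiteBag, y: int, params: M.AttentionParams,
                          grads: dict[str, np.ndarray], cfg: TrainConfig,
                          variant: str | None = None) -> tuple[float, float]:
    """Accumulate gradients of this bag's L_m and L_p terms; return both."""
    eps = cfg.epsilon_clip
    if variant is None:
        variant = cfg.pooling_variant
    mean_pool = not cfg.attention_pooling
    fw = M.bag_forward(bag.feature_matrix(), params, mean_pool=mean_pool)

    # --- L_m term: cross-entropy of classifier head P against y
    Pc = min(max(fw.P, eps), 1.0 - eps)
    lm = -(y * np.log(Pc) + (1 - y) * np.log(1.0 - Pc))
    dP = (-y / Pc + (1 - y) / (1.0 - Pc)) if eps < fw.P < 1.0 - eps else 0.0

    # --- L_p term through F(B)
    f = P.platt(fw.atts, P.PlattParams(params.alpha, params.beta))
    F, dFdf = P.bag_probability_grad(f, variant, eps)
    Fc = min(max(F, eps), 1.0 - eps)
    lp = -np.log(Fc) if y == 1 else -np.log(1.0 - Fc)
    if eps < F < 1.0 - eps:
        dF = -1.0 / Fc if y == 1 else 1.0 / (1.0 - Fc)
    else:
        dF = 0.0
    df = dF * dFdf                       # dL/df_j
    sig_grad = f * (1.0 - f)             # df/d(linear)
    datts = df * sig_grad * params.alpha
    grads["alpha"] += np.sum(df * sig_grad * fw.atts)
    grads["beta"] += np.sum(df * sig_grad)

    M.bag_backward(fw, params, grads, dP=float(dP), datts=datts)
    return float(lm), float(lp)


def train(dataset: PUBagDataset, config: TrainConfig,
          val_bags: Sequence[SiteBag] | None = None,
          ) -> tuple[FittedModel, TrainReport]:
    """Fit the PU-MIL model on a bag dataset.

    Requires at least one labeled-positive and one unlabeled bag.  Returns
    the fitted model (parameters + normalizer) and a per-epoch report.
    """
    normalizer = None
    if config.normalize and dataset.bags:
        center_idx = None
        if config.site_center:
            from .features import N_FEATURES, SIGNAL_LOCATION_IDX
            if dataset.bags[0].dim == N_FEATURES:
                center_idx = SIGNAL_LOCATION_IDX
        normalizer = Normalizer.fit(dataset.bags, center_idx)
    if normalizer is not None:
        dataset = PUBagDataset(normalizer.transform(dataset.bags),
                               dataset.label_frequency, dataset.fold_assignments)
        if val_bags is not None:
            val_bags = normalizer.transform(val_bags)
    positives = dataset.labeled_positives()
    unlabeled = dataset.unlabeled()
    if not positives:
        raise ValueError("training requires at least one labeled positive bag")
    if not unlabeled:
        raise ValueError("training requires at least one unlabeled bag")
    if len(unlabeled) < len(positives):
        raise ValueError(
            f"cannot select {len(positives)} reliable negatives from "
            f"{len(unlabeled)} unlabeled bags"
        )

    dim_in = positives[0].dim
    params = M.init_params(dim_in, config.dim_embed, config.dim_att, seed=config.seed)
    report = TrainReport(n_pos=len(positives))
    rng = np.random.default_rng(config.seed + 1)
    opt = _Adam(params.flatten(), config.learning_rate)
    by_id = {b.bag_id: b for b in unlabeled}
    mean_pool = not config.attention_pooling
    reliable: set[str] | None = None
    best_loss, stall = np.inf, 0

    warmup = (config.epochs // 3 if config.warmup_epochs is None
              else config.warmup_epochs)
    # the heuristic reliable-negative set is held fixed during warm-up for
    # every pooling variant; the plain-Noisy-OR gradient bridge applies only
    # when training targets the rank-weighted variant
    r_freeze = warmup
    if config.pooling_variant not in ("weighted_noisy_or",):
        warmup = 0

    for epoch in range(config.epochs):
        variant = "noisy_or" if epoch < warmup else config.pooling_variant
        if reliable is None:
            reliable = initial_reliable_negatives(positives, unlabeled, rng)
        elif config.reliable_negative_refresh and epoch >= r_freeze:
            probs = score_bags(params, unlabeled, variant,
                               mean_pool, config.epsilon_clip)
            reliable = P.select_reliable_negatives(probs, len(positives))
        rel_bags = [by_id[b] for b in sorted(reliable)]
        assert len(rel_bags) == len(positives)  # |R| = |P| balance contract

        pos_order = rng.permutation(len(positives))
        neg_order = rng.permutation(len(rel_bags))
        pairs = [(_subsample(positives[i], config.read_subsample, rng),
                  _subsample(rel_bags[j], config.read_subsample, rng))
                 for i, j in zip(pos_order, neg_order)]
        pairs_per_batch = max(config.bag_batch_size // 2, 1)

        ep_lm = ep_lp = 0.0
        for start in range(0, len(pairs), pairs_per_batch):
            batch = pairs[start:start + pairs_per_batch]
            grads = M.zero_grads(params)
            lm_sum = lp_sum = 0.0
            for pos_bag, neg_bag in batch:
                lm, lp = _bag_losses_and_grads(pos_bag, 1, params, grads,
                                               config, variant)
                lm_sum += lm; lp_sum += lp
                lm, lp = _bag_losses_and_grads(neg_bag, 0, params, grads,
                                               config, variant)
                lm_sum += lm; lp_sum += lp
            # Platt L2 penalty, once per step
            lp_sum += config.lam * (params.alpha ** 2 + params.beta ** 2)
            grads["alpha"] += 2.0 * config.lam * params.alpha
            grads["beta"] += 2.0 * config.lam * params.beta
            if config.weight_decay:
                for key in ("W1", "W2", "V", "w_att", "classifier_w"):
                    grads[key] += 2.0 * config.weight_decay * getattr(params, key)
            if not np.isfinite(lm_sum + lp_sum):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch starting with bag "
                    f"{batch[0][0].bag_id!r} (L_m={lm_sum}, L_p={lp_sum})"
                )
            opt.step(params, grads)
            ep_lm += lm_sum; ep_lp += lp_sum

        total = P.total_loss(ep_lm, ep_lp)
        report.loss.append(total)
        report.loss_mil.append(ep_lm)
        report.loss_pu.append(ep_lp)
        report.n_reliable_neg.append(len(rel_bags))
        report.epochs_run = epoch + 1
        msg = (f"epoch={epoch} L={total:.4f} L_m={ep_lm:.4f} L_p={ep_lp:.4f} "
               f"|P|={len(positives)} |R|={len(rel_bags)}")
        if val_bags is not None:
            auc = _val_auc(params, val_bags, config)
            if auc is not None:
                report.val_bag_auc.append(auc)
                msg += f" val_bag_auc={auc:.4f}"
        logger.info(msg)

        if config.early_stop_patience is not None:
            if total < best_loss - 1e-9:
                best_loss, stall = total, 0
            else:
                stall += 1
                if stall >= config.early_stop_patience:
                    logger.info("early stop at epoch %d", epoch)
                    break
    return FittedModel(params, config, normalizer), report


def train_ensemble(dataset: PUBagDataset, config: TrainConfig,
                   members: int = 3,
                   val_bags: Sequence[SiteBag] | None = None
                   ) -> tuple[list[FittedModel], list[TrainReport]]:
    """Train ``members`` models from different seeded initializations.

    Averaging the members' probabilities at prediction time reduces the
    seed-to-seed variance of the PU objective.  Member seeds derive
    deterministically from the config seed.
    """
    member_seeds = (np.random.SeedSequence(config.seed)
                    .generate_state(members) % (2 ** 31)).tolist()
    models, reports = [], []
    for s in member_seeds:
        cfg = TrainConfig(**{**config.to_dict(), "seed": int(s)})
        model, report = train(dataset, cfg, val_bags=val_bags)
        models.append(model)
        reports.append(report)
    return models, reports


def predict_ensemble(models: Sequence[FittedModel], bags: Sequence[SiteBag],
                     ) -> list[SitePrediction]:
    """Average site and read probabilities over ensemble members."""
    all_preds = [predict(m, bags) for m in models]
    out = []
    for i, bag in enumerate(bags):
        site = float(np.mean([p[i].site_prob for p in all_preds]))
        inst = np.mean([p[i].instance_probs for p in all_preds], axis=0)
        att = np.mean([p[i].attention_weights for p in all_preds], axis=0)
        out.append(SitePrediction(bag.bag_id, site, inst, att, bag.size,
                                  [x.instance_id for x in bag.instances]))
    return out


def _val_auc(params: M.AttentionParams, val_bags: Sequence[SiteBag],
             cfg: TrainConfig) -> float | None:
    labels = [b.hidden_bag_label for b in val_bags]
    if any(l is None for l in labels) or len(set(labels)) < 2:
        return None
    probs = score_bags(params, val_bags, cfg.pooling_variant,
                       not cfg.attention_pooling, cfg.epsilon_clip)
    from .metrics import roc_pr
    scores = [probs[b.bag_id] for b in val_bags]
    return roc_pr(scores, labels)[0]


def predict(model: "FittedModel | M.AttentionParams", bags: Sequence[SiteBag],
            pooling_variant: str | None = None,
            attention_pooling: bool | None = None,
            eps: float = M.EPS_CLIP) -> list[SitePrediction]:
    """Score bags with a trained model; output order matches input order.

    Accepts either a :class:`FittedModel` (normalization and pooling config
    applied automatically) or bare :class:`AttentionParams`.
    """
    if isinstance(model, FittedModel):
        params = model.params
        if pooling_variant is None:
            pooling_variant = model.config.pooling_variant
        if attention_pooling is None:
            attention_pooling = model.config.attention_pooling
        if model.normalizer is not None:
            bags = model.normalizer.transform(bags)
    else:
        params = model
    if pooling_variant is None:
        pooling_variant = "weighted_noisy_or"
    if attention_pooling is None:
        attention_pooling = True
    preds = []
    for bag in bags:
        fw = M.bag_forward(bag.feature_matrix(), params,
                           mean_pool=not attention_pooling)
        f = P.platt(fw.atts, P.PlattParams(params.alpha, params.beta))
        F = P.bag_probability(f, pooling_variant, eps)
        preds.append(SitePrediction(
            bag_id=bag.bag_id,
            site_prob=F,
            instance_probs=f,
            attention_weights=fw.a,
            n_reads=bag.size,
            instance_ids=[i.instance_id for i in bag.instances],
        ))
    return preds


# ---------------------------------------------------------------------------
# Checkpoint I/O


def save_checkpoint(path: str | Path, model: FittedModel,
                    report: TrainReport | None = None) -> None:
    extra = {"config": model.config.to_dict()}
    if model.normalizer is not None:
        extra["normalizer"] = model.normalizer.to_dict()
    if report is not None:
        extra["final_loss"] = report.loss[-1] if report.loss else None
        extra["epochs_run"] = report.epochs_run
    Path(path).write_text(json.dumps(M.params_to_dict(model.params, extra)))


def load_checkpoint(path: str | Path) -> FittedModel:
    d = json.loads(Path(path).read_text())
    norm = Normalizer.from_dict(d["normalizer"]) if "normalizer" in d else None
    return FittedModel(M.params_from_dict(d),
                       TrainConfig.from_dict(d.get("config", {})), norm)
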