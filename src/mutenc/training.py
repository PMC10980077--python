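"""Pretraining, dual-phase finetuning and closed-form ridge heads.

Pretraining minimizes the sum over score terms of the per-term mean squared
error, with AdamW (weight decay 0.01), linear learning-rate warmup over 2% of
steps, gradient-norm clipping at 0.5, and batches that are always homogeneous
in base protein so one relative-distance map serves a whole batch.

Finetuning is dual-phase: 250 epochs training only the head on a frozen
backbone (learning rate 1e-3), then 250 epochs training everything at 1e-4,
each phase with 1% linear warmup followed by cosine decay, weight decay 0.1,
batch 128, clipping 0.5.  The returned model is the epoch with the lowest
validation loss when the validation set is large enough to be reliable
(>= 32 rows by default), otherwise the last epoch.  During phase 1 the frozen
backbone runs in evaluation mode and its features are computed once and
cached; the 0.5 dropout between backbone and head stays active.

Feature extraction is the alternative head-only strategy: ridge regression
(alpha 1.0, Cholesky solver) on the cached backbone features, written back
into the model's linear head so predictions come from the same forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import SourceModel, TargetModel, encode_sequences
from .nn import AdamW, Tensor, clip_grad_norm_, lr_at_step
from .simulate import ExperimentalDataset
from .structures import ProteinStructure
from .variants import apply_variant, parse_variant


class TrainingError(ValueError):
    pass


@dataclass
class TrainConfig:
    epochs: int = 30
    base_lr: float = 1e-3
    lr_phase2: float | None = None  # dual-phase finetuning only
    warmup_frac: float = 0.02
    cosine_decay: bool = False
    batch_size: int = 128
    weight_decay: float = 0.01
    betas: tuple = (0.9, 0.999)
    eps: float = 1e-8
    grad_clip_norm: float = 0.5
    seed: int = 0
    accum_chunks: int = 1  # gradient accumulation to honor an effective batch size


def config_from_yaml(path) -> TrainConfig:
    """Load a TrainConfig from a YAML mapping of field overrides."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise TrainingError("training config YAML must be a mapping")
    unknown = set(data) - set(TrainConfig.__dataclass_fields__)
    if unknown:
        raise TrainingError(f"unknown training config fields: {sorted(unknown)}")
    if "betas" in data:
        data["betas"] = tuple(data["betas"])
    return TrainConfig(**data)


def config_to_yaml(cfg: TrainConfig, path) -> None:
    import yaml
    from dataclasses import asdict

    data = asdict(cfg)
    data["betas"] = list(data["betas"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def pretrain_config(**overrides) -> TrainConfig:
    cfg = TrainConfig(
        epochs=30, base_lr=1e-3, warmup_frac=0.02, cosine_decay=False,
        batch_size=2048, weight_decay=0.01, grad_clip_norm=0.5,
    )
    return replace(cfg, **overrides)


def finetune_config(**overrides) -> TrainConfig:
    cfg = TrainConfig(
        epochs=250, base_lr=1e-3, lr_phase2=1e-4, warmup_frac=0.01,
        cosine_decay=True, batch_size=128, weight_decay=0.1, grad_clip_norm=0.5,
    )
    return replace(cfg, **overrides)


@dataclass
class TrainHistory:
    train_losses: list = field(default_factory=list)
    val_losses: list = field(default_factory=list)
    grad_norms_preclip: list = field(default_factory=list)
    grad_norms_postclip: list = field(default_factory=list)
    selected_epoch: int | None = None
    selection_rule: str = "last-epoch"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_losses)),
                "train_loss": self.train_losses,
                "val_loss": self.val_losses
                if self.val_losses
                else [np.nan] * len(self.train_losses),
            }
        )


def multitask_loss(pred: Tensor, y: np.ndarray, scale: float = 1.0) -> Tensor:
    """Sum over tasks of the per-task batch MSE (optionally rescaled)."""
    diff = pred - Tensor(y)
    return (diff * diff).mean(axis=0).sum() * scale


def _pdb_batches(table: pd.DataFrame, row_ids, batch_size: int, rng) -> list:
    """Seeded batches, each homogeneous in base_pdb, union covering row_ids."""
    row_ids = np.asarray(row_ids)
    batches = []
    for _, group in table.loc[row_ids].groupby("base_pdb", sort=False):
        ids = group.index.to_numpy()
        ids = ids[rng.permutation(len(ids))]
        batches.extend(ids[i : i + batch_size] for i in range(0, len(ids), batch_size))
    order = rng.permutation(len(batches))
    return [batches[i] for i in order]


def _optimizer_step(params, loss_closure, optimizer, cfg, lr, history):
    """One step with optional gradient accumulation over loss closures."""
    for p in params:
        p.grad = None
    for closure in loss_closure:
        closure().backward()
    pre = clip_grad_norm_(params, cfg.grad_clip_norm)
    history.grad_norms_preclip.append(pre)
    history.grad_norms_postclip.append(min(pre, cfg.grad_clip_norm))
    optimizer.lr = lr
    optimizer.step()


def pretrain(
    model: SourceModel,
    table: pd.DataFrame,
    splits: dict,
    cfg: TrainConfig,
    structures,
) -> tuple[SourceModel, TrainHistory]:
    """Train a source model on a standardized attribute table.

    ``splits`` maps "train"/"val" to row-index arrays of ``table``;
    ``structures`` is a ProteinStructure or a dict keyed by base_pdb.  Raises
    if the training rows look unstandardized (per-group train stats far from
    mean 0 / sd 1).
    """
    if isinstance(structures, ProteinStructure):
        structures = {structures.id: structures}
    term_cols = [c for c in table.columns if c not in ("base_pdb", "variant")]
    if len(term_cols) != model.cfg.n_tasks:
        raise TrainingError(
            f"table has {len(term_cols)} tasks but model expects {model.cfg.n_tasks}"
        )
    train_ids = np.asarray(splits["train"])
    val_ids = np.asarray(splits.get("val", []))
    train_view = table.loc[train_ids]
    for pdb, group in train_view.groupby("base_pdb"):
        mu = group[term_cols].mean().abs().max()
        sd_err = (group[term_cols].std(ddof=0) - 1.0).abs().max()
        if mu > 0.5 or sd_err > 0.5:
            raise TrainingError(
                f"group {pdb!r} does not look standardized (max |mean| {mu:.2f}, "
                f"max |sd-1| {sd_err:.2f}); run standardize_attributes first"
            )

    # encode every row once, grouped by base pdb
    tokens_by_row = {}
    dist_cache = {}
    for pdb, group in table.groupby("base_pdb", sort=False):
        if pdb not in structures:
            raise TrainingError(f"no structure provided for base_pdb {pdb!r}")
        base_seq = structures[pdb].sequence
        seqs = [
            apply_variant(base_seq, parse_variant(v, base_seq))
            for v in group["variant"]
        ]
        toks = encode_sequences(seqs)
        for row, tok in zip(group.index, toks):
            tokens_by_row[row] = tok

    y_all = table[term_cols].to_numpy(dtype=float)
    row_pos = {row: i for i, row in enumerate(table.index)}

    def batch_arrays(ids):
        toks = np.stack([tokens_by_row[r] for r in ids])
        ys = y_all[[row_pos[r] for r in ids]]
        return toks, ys

    def set_batch_structure(pdb):
        if model.cfg.rpe_mode == "3d":
            if pdb not in dist_cache:
                model.set_structure(structures[pdb])
                dist_cache[pdb] = (model._dist_idx, model.structure_id)
            else:
                model._dist_idx, model.structure_id = dist_cache[pdb]

    params = list(model.parameters())
    optimizer = AdamW(
        params, lr=cfg.base_lr, betas=cfg.betas, eps=cfg.eps,
        weight_decay=cfg.weight_decay,
    )
    rng = np.random.default_rng(cfg.seed)
    n_batches = len(_pdb_batches(table, train_ids, cfg.batch_size, np.random.default_rng(0)))
    total_steps = cfg.epochs * max(n_batches, 1)
    history = TrainHistory()
    step = 0
    for epoch in range(cfg.epochs):
        epoch_losses = []
        for ids in _pdb_batches(table, train_ids, cfg.batch_size, rng):
            pdb = table.loc[ids[0], "base_pdb"]
            set_batch_structure(pdb)
            toks, ys = batch_arrays(ids)
            lr = lr_at_step(step, total_steps, cfg.base_lr, cfg.warmup_frac, cfg.cosine_decay)
            chunks = np.array_split(np.arange(len(ids)), cfg.accum_chunks)
            chunks = [c for c in chunks if len(c)]
            closures = [
                (lambda c=c: multitask_loss(
                    model(toks[c], train=True, rng=rng), ys[c], scale=len(c) / len(ids)
                ))
                for c in chunks
            ]
            model.zero_grad()
            _optimizer_step(params, closures, optimizer, cfg, lr, history)
            with np.errstate(all="ignore"):
                pred = model(toks).data
            epoch_losses.append(float(((pred - ys) ** 2).mean(axis=0).sum()))
            step += 1
        history.train_losses.append(float(np.mean(epoch_losses)))
        if len(val_ids):
            history.val_losses.append(
                _eval_multitask_loss(model, table, val_ids, batch_arrays, set_batch_structure, cfg)
            )
    history.selected_epoch = cfg.epochs - 1
    return model, history


def _eval_multitask_loss(model, table, ids, batch_arrays, set_batch_structure, cfg):
    total, n = 0.0, 0
    rng = np.random.default_rng(0)
    for batch in _pdb_batches(table, ids, cfg.batch_size, rng):
        set_batch_structure(table.loc[batch[0], "base_pdb"])
        toks, ys = batch_arrays(batch)
        pred = model(toks).data
        total += float(((pred - ys) ** 2).sum(axis=0).sum())
        n += len(batch)
    return total / max(n, 1)


# ---------------------------------------------------------------------------
# target-model training
# ---------------------------------------------------------------------------

def _dataset_arrays(d: ExperimentalDataset):
    tokens = encode_sequences(d.sequences())
    return tokens, d.scores()


def _split_indices(split) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(split, dict):
        train, val = split["train"], split.get("val", [])
    else:
        train, val = split.train, split.val
    train, val = np.asarray(train, dtype=int), np.asarray(val, dtype=int)
    if len(np.intersect1d(train, val)):
        raise TrainingError("train and validation indices overlap")
    return train, val


def finetune_dual_phase(
    model: TargetModel,
    d: ExperimentalDataset,
    split,
    cfg: TrainConfig | None = None,
    selection_threshold: int = 32,
) -> tuple[TargetModel, TrainHistory]:
    """Dual-phase finetuning with best-validation-epoch selection.

    Phase 1 trains only the head on frozen-backbone features; the backbone
    weights are bit-identical before and after.  Phase 2 trains all weights at
    ``cfg.lr_phase2``.  Model selection over all epochs of both phases by
    lowest validation loss iff ``len(val) >= selection_threshold``, else the
    final weights are kept.
    """
    cfg = cfg or finetune_config()
    train_ids, val_ids = _split_indices(split)
    if len(train_ids) == 0:
        raise TrainingError("empty training set")
    tokens, y = _dataset_arrays(d)
    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()
    select = len(val_ids) >= selection_threshold
    history.selection_rule = "best-validation" if select else "last-epoch"
    best = {"loss": np.inf, "state": None, "epoch": None}

    def val_loss(feats_cache=None):
        if len(val_ids) == 0:
            return np.nan
        if feats_cache is not None:
            pred = feats_cache[val_ids] @ model.head.weight.data[:, 0] + model.head.bias.data[0]
        else:
            pred = model(tokens[val_ids]).data
        return float(((pred - y[val_ids]) ** 2).mean())

    def record_epoch(train_loss, vloss, epoch):
        history.train_losses.append(train_loss)
        history.val_losses.append(vloss)
        if select and np.isfinite(vloss) and vloss < best["loss"]:
            best.update(loss=vloss, state=model.state_dict(), epoch=epoch)

    # phase 1: frozen backbone, cached evaluation-mode features
    feats = _backbone_features(model, tokens)
    head_params = list(model.head_parameters())
    optimizer = AdamW(head_params, betas=cfg.betas, eps=cfg.eps, weight_decay=cfg.weight_decay)
    steps_per_epoch = max(1, int(np.ceil(len(train_ids) / cfg.batch_size)))
    total_steps = cfg.epochs * steps_per_epoch
    step = 0
    for epoch in range(cfg.epochs):
        order = train_ids[rng.permutation(len(train_ids))]
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            ids = order[lo : lo + cfg.batch_size]
            lr = lr_at_step(step, total_steps, cfg.base_lr, cfg.warmup_frac, cfg.cosine_decay)
            x = model.drop(Tensor(feats[ids]), train=True, rng=rng)
            loss = (model.head(x).reshape(-1) - Tensor(y[ids])) ** 2
            loss = loss.mean()
            model.zero_grad()
            _optimizer_step(head_params, [lambda l=loss: l], optimizer, cfg, lr, history)
            losses.append(float(loss.data))
            step += 1
        record_epoch(float(np.mean(losses)), val_loss(feats_cache=feats), epoch)

    # phase 2: all weights at the reduced rate
    lr2 = cfg.lr_phase2 if cfg.lr_phase2 is not None else cfg.base_lr * 0.1
    params = list(model.parameters())
    optimizer = AdamW(params, betas=cfg.betas, eps=cfg.eps, weight_decay=cfg.weight_decay)
    step = 0
    for epoch in range(cfg.epochs):
        order = train_ids[rng.permutation(len(train_ids))]
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            ids = order[lo : lo + cfg.batch_size]
            lr = lr_at_step(step, total_steps, lr2, cfg.warmup_frac, cfg.cosine_decay)
            chunks = np.array_split(np.arange(len(ids)), cfg.accum_chunks)
            chunks = [c for c in chunks if len(c)]
            closures = [
                (lambda c=c: (
                    (model(tokens[ids[c]], train=True, rng=rng) - Tensor(y[ids[c]])) ** 2
                ).mean() * (len(c) / len(ids)))
                for c in chunks
            ]
            model.zero_grad()
            _optimizer_step(params, closures, optimizer, cfg, lr, history)
            pred = model(tokens[ids]).data
            losses.append(float(((pred - y[ids]) ** 2).mean()))
            step += 1
        record_epoch(float(np.mean(losses)), val_loss(), cfg.epochs + epoch)

    if select and best["state"] is not None:
        model.load_state_dict(best["state"])
        history.selected_epoch = best["epoch"]
    else:
        history.selected_epoch = 2 * cfg.epochs - 1
    return model, history


def _backbone_features(model: TargetModel, tokens, batch_size: int = 512) -> np.ndarray:
    out = [
        model.features(tokens[i : i + batch_size]).data
        for i in range(0, len(tokens), batch_size)
    ]
    return np.concatenate(out, axis=0)


def fit_ridge_head(
    model: TargetModel,
    d: ExperimentalDataset,
    split,
    alpha: float = 1.0,
) -> TargetModel:
    """Closed-form L2-regularized head on frozen backbone features.

    Solves ridge regression (Cholesky solver) on the training rows and writes
    the coefficients into the model's linear head, so ``model(tokens)`` in
    evaluation mode reproduces the ridge predictions exactly.
    """
    from sklearn.linear_model import Ridge

    train_ids, _ = _split_indices(split)
    if len(train_ids) < 1:
        raise TrainingError("ridge head needs at least one training row")
    tokens, y = _dataset_arrays(d)
    feats = _backbone_features(model, tokens)
    ridge = Ridge(alpha=alpha, solver="cholesky")
    ridge.fit(feats[train_ids], y[train_ids])
    model.head.weight.data = ridge.coef_.reshape(-1, 1).astype(float)
    model.head.bias.data = np.array([float(ridge.intercept_)])
    return model
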