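"""Training loop with gradient-norm task balancing, plus inference endpoints.

The total objective is ``w_type * smoothed weighted CE + w_prot * censored
MSE`` with the task weights updated once per mini-batch so that each task's
gradient norm on the shared embedding weights tracks its relative training
rate.  Protein targets are per-cell normalized + log1p, then z-scored per
protein with reference statistics computed over measured entries only.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import MergedReference, QueryDataset, merge_panels
from .features import (
    FeatureConfig,
    FeatureMatrix,
    FeatureTransform,
    assemble_features,
    fit_feature_transform,
    normalize_log,
)
from .network import MultiTaskModel, NetworkConfig, build_model
from .objectives import (
    GradNormState,
    censored_mse,
    gradnorm_step,
    log_class_weights,
    smoothed_weighted_ce,
)


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 512
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1
    patience: int = 10
    seed: int = 0
    single_task_mode: str = "both"  # both | type_only | protein_only
    epsilon_smoothing: float = 0.1
    alpha_w: float = 1.0
    alpha_gradnorm: float = 1.0
    gradnorm_lr: float = 0.025
    weight_floor: float = 1e-3

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in [0, 1)")
        if self.single_task_mode not in ("both", "type_only", "protein_only"):
            raise ValueError(f"unknown single_task_mode {self.single_task_mode!r}")


@dataclasses.dataclass
class PredictionResult:
    labels: np.ndarray
    probabilities: np.ndarray
    proteins: np.ndarray
    embedding: np.ndarray
    class_catalog: list
    protein_ids: list


@dataclasses.dataclass
class FittedModel:
    """A trained network plus the catalogs/statistics needed at inference."""

    model: MultiTaskModel
    class_catalog: list
    protein_ids: list
    protein_mean: np.ndarray
    protein_sd: np.ndarray

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.model.save(directory / "model.npz")
        meta = {
            "class_catalog": list(self.class_catalog),
            "protein_ids": list(self.protein_ids),
            "protein_mean": list(map(float, self.protein_mean)),
            "protein_sd": list(map(float, self.protein_sd)),
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "FittedModel":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        return cls(
            model=MultiTaskModel.load(directory / "model.npz"),
            class_catalog=meta["class_catalog"],
            protein_ids=meta["protein_ids"],
            protein_mean=np.array(meta["protein_mean"]),
            protein_sd=np.array(meta["protein_sd"]),
        )


# ---------------------------------------------------------------------------
# Protein target transform
# ---------------------------------------------------------------------------

def transform_protein_targets(protein: np.ndarray, mask: np.ndarray, target_total: float = 1e4):
    """Per-cell normalize over measured entries + log1p (cells with an empty
    panel pass through as zeros)."""
    p = np.asarray(protein, dtype=float)
    m = np.asarray(mask, dtype=bool)
    totals = np.where(m, p, 0.0).sum(axis=1)
    scale = np.where(totals > 0, target_total / np.maximum(totals, 1e-12), 0.0)
    return np.log1p(p * scale[:, None])


def fit_protein_scaler(log_targets: np.ndarray, mask: np.ndarray):
    """Per-protein mean/sd over measured entries only."""
    m = np.asarray(mask, dtype=bool)
    n_obs = m.sum(axis=0)
    safe = np.maximum(n_obs, 1)
    mean = np.where(m, log_targets, 0.0).sum(axis=0) / safe
    var = np.where(m, (log_targets - mean) ** 2, 0.0).sum(axis=0) / safe
    sd = np.sqrt(var)
    sd = np.where(sd > 0, sd, 1.0)
    mean = np.where(n_obs > 0, mean, 0.0)
    return mean, sd


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _stratified_split(labels_int: np.ndarray, fraction: float, rng: np.random.Generator):
    """Per-class split keeping at least one training cell per class."""
    train_idx, val_idx = [], []
    for c in np.unique(labels_int):
        idx = np.where(labels_int == c)[0]
        idx = rng.permutation(idx)
        n_val = min(int(round(fraction * len(idx))), len(idx) - 1)
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def train(
    merged: MergedReference,
    features: FeatureMatrix,
    net_config: NetworkConfig,
    train_config: TrainConfig = TrainConfig(),
):
    """Train the multi-task model; returns ``(FittedModel, log DataFrame)``.

    The log has one row per epoch: per-task losses, task weights, balancing
    loss, and validation accuracy.
    """
    train_config.validate()
    mode = train_config.single_task_mode
    catalog = list(merged.class_catalog)
    label_to_int = {c: i for i, c in enumerate(catalog)}
    y = np.array([label_to_int[c] for c in merged.cell_types], dtype=int)
    if len(catalog) < 2 and mode != "protein_only":
        raise ValueError("need at least 2 classes for the annotation task")
    x = features.values
    if x.shape[0] != merged.n_cells:
        raise ValueError("features not aligned to merged cells")

    log_targets = transform_protein_targets(merged.protein, merged.protein_mask)
    p_mean, p_sd = fit_protein_scaler(log_targets, merged.protein_mask)
    targets = (log_targets - p_mean) / p_sd
    mask = merged.protein_mask

    rng = np.random.default_rng(train_config.seed)
    tr_idx, val_idx = _stratified_split(y, train_config.validation_fraction, rng)

    counts = np.bincount(y[tr_idx], minlength=len(catalog))
    class_w = log_class_weights(np.maximum(counts, 1), train_config.alpha_w).weight

    model = build_model(net_config)
    opt = Adam(model.params, lr=train_config.learning_rate)
    gn_state = GradNormState(
        n_tasks=2,
        alpha_g=train_config.alpha_gradnorm,
        lr=train_config.gradnorm_lr,
        weight_floor=train_config.weight_floor,
    )
    if mode == "type_only":
        gn_state.w = np.array([2.0, 0.0])
    elif mode == "protein_only":
        gn_state.w = np.array([0.0, 2.0])

    rows = []
    best_val = np.inf
    best_state = None
    bad_epochs = 0
    step = 0
    bs = train_config.batch_size
    for epoch in range(train_config.epochs):
        order = rng.permutation(tr_idx)
        ep_ce, ep_mse, ep_lgrad, n_batches = 0.0, 0.0, 0.0, 0
        for start in range(0, len(order), bs):
            bi = order[start : start + bs]
            if len(bi) < 2:
                continue
            _, logits, prot = model.forward(x[bi], train=True)
            ce, d_logits = smoothed_weighted_ce(
                logits, y[bi], class_w, train_config.epsilon_smoothing, return_grad=True
            )
            mse, d_prot = censored_mse(prot, targets[bi], mask[bi], return_grad=True)
            if not (np.isfinite(ce) and np.isfinite(mse)):
                raise FloatingPointError(
                    f"nonfinite loss at epoch {epoch}, batch {start // bs}: "
                    f"ce={ce}, mse={mse}"
                )

            l_grad = 0.0
            if mode == "both" and step > 0:
                zeros_p = np.zeros_like(d_prot)
                zeros_t = np.zeros_like(d_logits)
                g_type = np.linalg.norm(model.embedding_weight_grad(d_logits, zeros_p))
                g_prot = np.linalg.norm(model.embedding_weight_grad(zeros_t, d_prot))
                l_grad = gradnorm_step(gn_state, [ce, mse], [g_type, g_prot])

            w1, w2 = gn_state.w
            grads, _ = model.backward(w1 * d_logits, w2 * d_prot)
            opt.step(model.params, grads)
            step += 1
            ep_ce += ce
            ep_mse += mse
            ep_lgrad += l_grad
            n_batches += 1

        # validation
        val_acc = np.nan
        val_loss = ep_ce / max(n_batches, 1)
        if len(val_idx):
            _, vlogits, vprot = model.forward(x[val_idx], train=False)
            vce = smoothed_weighted_ce(
                vlogits, y[val_idx], class_w, train_config.epsilon_smoothing
            )
            vmse = censored_mse(vprot, targets[val_idx], mask[val_idx])
            val_acc = float(np.mean(vlogits.argmax(axis=1) == y[val_idx]))
            val_loss = vmse if mode == "protein_only" else vce
        rows.append(
            {
                "epoch": epoch,
                "loss_type": ep_ce / max(n_batches, 1),
                "loss_protein": ep_mse / max(n_batches, 1),
                "w_type": float(gn_state.w[0]),
                "w_protein": float(gn_state.w[1]),
                "gradnorm_loss": ep_lgrad / max(n_batches, 1),
                "val_accuracy": val_acc,
            }
        )
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > train_config.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)

    fitted = FittedModel(
        model=model,
        class_catalog=catalog,
        protein_ids=list(merged.protein_ids),
        protein_mean=p_mean,
        protein_sd=p_sd,
    )
    return fitted, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def annotate(fitted: FittedModel, query_features) -> PredictionResult:
    """Label every query cell (argmax over class probabilities, no abstention)."""
    x = query_features.values if isinstance(query_features, FeatureMatrix) else np.asarray(query_features)
    emb, logits, prot = fitted.model.forward(x, train=False)
    probs = _softmax(logits)
    labels = np.array([fitted.class_catalog[i] for i in probs.argmax(axis=1)], dtype=object)
    return PredictionResult(
        labels=labels,
        probabilities=probs,
        proteins=prot,
        embedding=emb,
        class_catalog=list(fitted.class_catalog),
        protein_ids=list(fitted.protein_ids),
    )


def predict_proteins(fitted: FittedModel, query_features, inverse: bool = False) -> np.ndarray:
    """Protein predictions in protein-catalog order.

    By default in the transformed (normalized/log/z-scored) target space;
    ``inverse=True`` maps back to normalized count scale.
    """
    x = query_features.values if isinstance(query_features, FeatureMatrix) else np.asarray(query_features)
    _, _, prot = fitted.model.forward(x, train=False)
    if inverse:
        prot = np.clip(np.expm1(prot * fitted.protein_sd + fitted.protein_mean), 0.0, None)
    return prot


def embed(fitted: FittedModel, features) -> np.ndarray:
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    emb, _, _ = fitted.model.forward(x, train=False)
    return emb


# ---------------------------------------------------------------------------
# End-to-end pipeline helper (shared by CLI and tests)
# ---------------------------------------------------------------------------

def align_query(query: QueryDataset, gene_ids: list) -> np.ndarray:
    """Reorder query RNA columns to the merged gene catalog."""
    col = {g: j for j, g in enumerate(query.gene_ids)}
    missing = [g for g in gene_ids if g not in col]
    if missing:
        raise ValueError(f"query lacks genes from the merged catalog: {missing[:5]}")
    return query.rna[:, [col[g] for g in gene_ids]]


def run_pipeline(
    references,
    query: Optional[QueryDataset],
    feature_config: FeatureConfig,
    net_config_overrides: Optional[dict] = None,
    train_config: TrainConfig = TrainConfig(),
):
    """Merge -> features (transductive if a query is given) -> train.

    Returns ``(fitted, transform, log, query_features)``; query_features is
    None when no query was supplied.
    """
    merged = merge_panels(references, query)
    ref_log = normalize_log(merged.rna, feature_config.normalize_total)
    if query is not None and feature_config.transductive:
        q_rna = align_query(query, merged.gene_ids)
        q_log = normalize_log(q_rna, feature_config.normalize_total)
        joint = np.vstack([ref_log, q_log])
        batches = np.concatenate(
            [merged.batch_ids, np.full(q_log.shape[0], query.batch_id, dtype=object)]
        )
        transform = fit_feature_transform(joint, batches, feature_config)
        ref_feats = transform.apply(ref_log, merged.batch_ids)
        q_feats = transform.apply(
            q_log, np.full(q_log.shape[0], query.batch_id, dtype=object)
        )
    else:
        transform = fit_feature_transform(ref_log, merged.batch_ids, feature_config)
        ref_feats = transform.apply(ref_log, merged.batch_ids)
        q_feats = None
        if query is not None:
            q_rna = align_query(query, merged.gene_ids)
            q_log = normalize_log(q_rna, feature_config.normalize_total)
            q_feats = transform.apply(
                q_log, np.full(q_log.shape[0], query.batch_id, dtype=object)
            )

    net_config = NetworkConfig(
        input_dim=ref_feats.width,
        n_classes=len(merged.class_catalog),
        n_proteins=max(len(merged.protein_ids), 1),
        seed=train_config.seed,
        **(net_config_overrides or {}),
    )
    if len(merged.protein_ids) == 0:
        # RNA-only references: protein head trains on an empty measured set
        merged = dataclasses.replace(
            merged,
            protein=np.zeros((merged.n_cells, 1)),
            protein_mask=np.zeros((merged.n_cells, 1), dtype=bool),
            protein_ids=["__none__"],
        )
    fitted, log = train(merged, ref_feats, net_config, train_config)
    return fitted, transform, log, q_feats
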