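"""Loss components and gradient-norm task balancing.

Three pieces: logarithmic class weights for imbalanced labels, label-smoothed
weighted cross-entropy for the annotation head, and a censored mean-squared
error that only scores protein entries measured in a cell's source panel.
Task weights are balanced online so each task's shared-parameter gradient
norm tracks a target set by its relative training rate.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np


@dataclasses.dataclass
class ClassWeights:
    counts: np.ndarray
    alpha_w: float
    weight: np.ndarray


def log_class_weights(counts: Sequence[int], alpha_w: float = 1.0) -> ClassWeights:
    """weight_c = log(total / count_c + alpha_w), natural log.

    Rarer classes receive strictly larger weights; equal counts give equal
    weights.  A zero count is an error (the class is absent from the
    reference and cannot be learned).
    """
    counts = np.asarray(counts, dtype=float)
    if alpha_w <= 0:
        raise ValueError("alpha_w must be > 0")
    if np.any(counts < 1):
        raise ValueError("every class must have at least one reference cell")
    total = counts.sum()
    return ClassWeights(counts=counts, alpha_w=alpha_w, weight=np.log(total / counts + alpha_w))


def smoothed_weighted_ce(
    type_logits: np.ndarray,
    true_labels: np.ndarray,
    class_weights: Optional[np.ndarray] = None,
    epsilon: float = 0.1,
    return_grad: bool = False,
):
    """Label-smoothed cross-entropy, weighted by the true class's weight.

    Target distribution is ``(1-eps) * one-hot + eps/K * uniform``; the
    per-cell loss is scaled by ``class_weights[true]`` and averaged.
    """
    if not (0.0 <= epsilon < 1.0):
        raise ValueError("epsilon must be in [0, 1)")
    logits = np.asarray(type_logits, dtype=float)
    y = np.asarray(true_labels, dtype=int)
    n, k = logits.shape
    if class_weights is None:
        class_weights = np.ones(k)
    w = np.asarray(class_weights, dtype=float)[y]

    m = logits.max(axis=1, keepdims=True)
    logz = m + np.log(np.exp(logits - m).sum(axis=1, keepdims=True))
    logp = logits - logz

    target = np.full((n, k), epsilon / k)
    target[np.arange(n), y] += 1.0 - epsilon
    loss = float(np.mean(w * -(target * logp).sum(axis=1)))
    if not return_grad:
        return loss
    grad = w[:, None] * (np.exp(logp) - target) / n
    return loss, grad


def censored_mse(
    protein_pred: np.ndarray,
    protein_true: np.ndarray,
    protein_mask: np.ndarray,
    return_grad: bool = False,
):
    """MSE over measured entries only; censored entries carry no signal.

    An all-false mask is the defined degenerate case: loss 0, zero gradient.
    """
    pred = np.asarray(protein_pred, dtype=float)
    true = np.asarray(protein_true, dtype=float)
    mask = np.asarray(protein_mask, dtype=bool)
    if pred.shape != true.shape or pred.shape != mask.shape:
        raise ValueError("shape mismatch between predictions, targets and mask")
    n_obs = int(mask.sum())
    if n_obs == 0:
        loss = 0.0
        return (loss, np.zeros_like(pred)) if return_grad else loss
    diff = np.where(mask, pred - true, 0.0)
    loss = float((diff ** 2).sum() / n_obs)
    if not return_grad:
        return loss
    return loss, 2.0 * diff / n_obs


# ---------------------------------------------------------------------------
# Gradient-norm balancing
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GradNormState:
    """Task weights and running quantities of the balancing objective."""

    n_tasks: int = 2
    alpha_g: float = 1.0
    lr: float = 0.025
    weight_floor: float = 1e-3
    w: np.ndarray = None
    initial_losses: Optional[np.ndarray] = None
    t: int = 0

    def __post_init__(self):
        if self.w is None:
            self.w = np.ones(self.n_tasks)


def gradnorm_loss(
    w: np.ndarray,
    unweighted_grad_norms: np.ndarray,
    losses: np.ndarray,
    initial_losses: np.ndarray,
    alpha_g: float = 1.0,
):
    """Balancing loss and its gradient wrt the task weights.

    ``G_i = w_i * ||grad_W L_i||`` ;  targets ``Gbar * r_i^alpha`` are
    treated as constants (no gradient flows through them), so
    ``dL/dw_i = sign(G_i - target_i) * ||grad_W L_i||``.
    """
    w = np.asarray(w, dtype=float)
    gn = np.asarray(unweighted_grad_norms, dtype=float)
    losses = np.asarray(losses, dtype=float)
    l0 = np.asarray(initial_losses, dtype=float)

    G = w * gn
    Gbar = G.mean()
    ltilde = losses / np.maximum(l0, 1e-12)
    r = ltilde / ltilde.mean()
    target = Gbar * r ** alpha_g
    diff = G - target
    l_grad = float(np.abs(diff).sum())
    dw = np.sign(diff) * gn
    return l_grad, dw, target


def gradnorm_step(
    state: GradNormState,
    per_task_losses: Sequence[float],
    unweighted_grad_norms: Sequence[float],
) -> float:
    """One balancing update: gradient step on the weights, floor, renormalize.

    Returns the balancing loss before the update.  The weight sum is
    conserved at ``n_tasks`` after every step.
    """
    losses = np.asarray(per_task_losses, dtype=float)
    for i, li in enumerate(losses):
        if not np.isfinite(li):
            raise FloatingPointError(f"nonfinite loss for task {i}")
    gn = np.asarray(unweighted_grad_norms, dtype=float)
    if state.initial_losses is None:
        state.initial_losses = losses.copy()
    l_grad, dw, _ = gradnorm_loss(state.w, gn, losses, state.initial_losses, state.alpha_g)
    w = state.w - state.lr * dw
    w = np.maximum(w, state.weight_floor)
    state.w = w * (state.n_tasks / w.sum())
    state.t += 1
    return l_grad
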