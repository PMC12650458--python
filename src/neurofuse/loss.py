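"""Weighted multi-loss: global cross-entropy plus accuracy-weighted
branch cross-entropies.

The total objective is L = L_global + mu * L_local, where L_local is a
weighted sum of the three branch losses (EEG, fNIRS, cross-modal) and
each weight is the branch's running accuracy normalised so that the
three weights sum to one:

    w_k = a_k / (a_e + a_f + a_ef)

Branch accuracies are exponential moving averages over training, updated
once per epoch and treated as constants in the gradient, so a branch
cannot lower its own weight through the backward pass. With mu = 0 the
objective reduces to the plain global loss; with unit weights it reduces
to the unweighted multi-loss variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LossState",
    "cross_entropy",
    "branch_weights",
    "local_loss",
    "total_loss",
    "update_branch_accuracies",
]

BRANCHES = ("eeg", "fnirs", "xmodal")
_EPS = 1e-12


def cross_entropy(y: np.ndarray, y_hat: np.ndarray) -> float:
    """-sum_i y_i log(yhat_i) with the log clamped at 1e-12."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError("label and prediction shapes differ")
    return float(-(y * np.log(np.clip(y_hat, _EPS, None))).sum())


def branch_weights(a_e: float, a_f: float, a_ef: float) -> tuple[float, float, float]:
    """Accuracy-proportional branch weights, normalised to sum to one.

    All-zero accuracies (cold start) fall back to uniform 1/3 weights.
    """
    accs = np.array([a_e, a_f, a_ef], dtype=np.float64)
    if ((accs < 0) | (accs > 1)).any():
        raise ValueError("accuracies must lie in [0, 1]")
    s = accs.sum()
    if s <= 0:
        return (1 / 3, 1 / 3, 1 / 3)
    w = accs / s
    return (float(w[0]), float(w[1]), float(w[2]))


def local_loss(
    l_e: float, l_f: float, l_ef: float, weights: tuple[float, float, float]
) -> float:
    """Weighted branch-loss sum; unit weights give the unweighted variant."""
    w_e, w_f, w_ef = weights
    return w_e * l_e + w_f * l_f + w_ef * l_ef


def total_loss(l_global: float, l_local: float, mu: float) -> float:
    """L_global + mu * L_local; mu = 0 disables branch supervision."""
    if mu < 0:
        raise ValueError("mu must be >= 0")
    return l_global + mu * l_local


@dataclass
class LossState:
    """Running branch accuracies, their weights, and the balance mu."""

    mu: float = 1.0
    ema_decay: float = 0.9
    branch_acc: dict[str, float] = field(
        default_factory=lambda: {b: 0.0 for b in BRANCHES}
    )

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if not 0.0 <= self.ema_decay < 1.0:
            raise ValueError("ema_decay must lie in [0, 1)")

    def weights(self) -> tuple[float, float, float]:
        return branch_weights(
            self.branch_acc["eeg"], self.branch_acc["fnirs"], self.branch_acc["xmodal"]
        )


def update_branch_accuracies(
    state: LossState,
    batch_predictions: dict[str, np.ndarray],
    labels: np.ndarray,
) -> LossState:
    """EMA update a_k <- d*a_k + (1-d)*(batch accuracy of branch k).

    Intended to run once per epoch on that epoch's training predictions.
    An empty batch leaves the state unchanged with a warning.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        warnings.warn("empty batch: branch accuracies left unchanged")
        return state
    d = state.ema_decay
    new_acc = dict(state.branch_acc)
    for k in BRANCHES:
        preds = np.asarray(batch_predictions[k])
        if preds.shape[0] != labels.shape[0]:
            raise ValueError(f"branch {k}: prediction/label length mismatch")
        acc = float((preds == labels).mean())
        new_acc[k] = d * new_acc[k] + (1.0 - d) * acc
    return LossState(mu=state.mu, ema_decay=state.ema_decay, branch_acc=new_acc)
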