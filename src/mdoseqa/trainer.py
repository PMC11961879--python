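"""Cohort splitting, L1-supervised training and prediction.

The training engine lives in :class:`mdoseqa.estimator.MDoseRegressor`; the
functions here are the case-level surface used by the pipeline and CLI:
``split_cohort`` shuffles and partitions a cohort reproducibly, ``train``
fits a chosen network variant on PatientCase lists, ``predict`` applies a
trained model to one case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import PatientCase, VolumeGrid

__all__ = ["TrainConfig", "split_cohort", "l1_loss", "train", "predict"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    The clinical-scale defaults are RMSprop with learning rate 5e-5, batch
    size one and up to 200 epochs; desk-scale runs typically shrink
    ``max_epochs`` and raise the learning rate.
    """

    learning_rate: float = 5e-5
    batch_size: int = 1
    max_epochs: int = 200
    optimizer: str = "rmsprop"
    seed: int = 0
    split_fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2)
    patience: int | None = 20          # early stop on validation L1; None = fixed epochs
    rmsprop_alpha: float = 0.99
    rmsprop_eps: float = 1e-8

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.batch_size != 1:
            raise ValueError("only batch size 1 is supported")
        if self.optimizer != "rmsprop":
            raise ValueError("only the rmsprop optimizer is supported")


def split_cohort(
    cases: Sequence,
    fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> Tuple[list, list, list]:
    """Seeded disjoint, exhaustive train/val/test split.

    Validation and test sizes are ``round(n * fraction)``; the remainder
    goes to training (310 cases at 0.6/0.2/0.2 give 186/62/62).
    """
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative and sum to 1")
    n = len(cases)
    if n < 3:
        raise ValueError("need at least 3 cases to split")
    n_val = int(round(n * fractions[1]))
    n_test = int(round(n * fractions[2]))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 0 or n_train == 0:
        raise ValueError(f"degenerate split sizes ({n_train}, {n_val}, {n_test})")
    order = np.random.default_rng(seed).permutation(n)
    train_idx = order[:n_train]
    val_idx = order[n_train : n_train + n_val]
    test_idx = order[n_train + n_val :]
    pick = lambda idx: [cases[i] for i in idx]
    return pick(train_idx), pick(val_idx), pick(test_idx)


def l1_loss(pred: np.ndarray, ref: np.ndarray) -> float:
    """Mean absolute difference over all voxels (the supervision loss)."""
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    return float(np.mean(np.abs(pred - ref)))


def _stack_cases(cases: Sequence[PatientCase]):
    X = np.stack(
        [np.stack([c.ct.data, c.rtdose.data]) for c in cases]
    )
    y = np.stack([c.mdose.data for c in cases])
    rx = np.asarray([c.prescription_dose for c in cases], dtype=float)
    return X, y, rx


def train(cases_train: Sequence[PatientCase], cases_val: Sequence[PatientCase],
          model_config=None, train_config: TrainConfig | None = None):
    """Fit a network variant on PatientCase lists.

    Returns ``(regressor, history)`` where ``history`` is a DataFrame with
    per-epoch train/validation L1 loss (normalized dose units) and the
    regressor holds the best-validation weights.
    """
    from .estimator import MDoseRegressor
    from .fusion_net import ModelConfig

    if not cases_train or not cases_val:
        raise ValueError("train and validation splits must be non-empty")
    for c in list(cases_train) + list(cases_val):
        if c.mdose is None:
            raise ValueError(f"case {c.case_id} has no MDose ground truth")
    model_config = model_config if model_config is not None else ModelConfig()
    cfg = train_config if train_config is not None else TrainConfig()
    cfg.validate()
    reg = MDoseRegressor(
        variant=model_config.variant,
        levels=model_config.levels,
        base_channels=model_config.base_channels,
        se_reduction=model_config.se_reduction,
        learning_rate=cfg.learning_rate,
        max_epochs=cfg.max_epochs,
        patience=cfg.patience,
        seed=cfg.seed,
        rmsprop_alpha=cfg.rmsprop_alpha,
        rmsprop_eps=cfg.rmsprop_eps,
    )
    Xt, yt, rxt = _stack_cases(cases_train)
    Xv, yv, rxv = _stack_cases(cases_val)
    reg.fit(Xt, yt, prescription=rxt, X_val=Xv, y_val=yv, prescription_val=rxv)
    return reg, reg.history_


def predict(regressor, case: PatientCase) -> VolumeGrid:
    """Predicted measured-dose volume (Gy, non-negative) on the case's CT grid."""
    net = getattr(regressor, "net_", regressor)  # accept estimator or raw net
    pred = net.predict_volume(case.ct.data, case.rtdose.data, case.prescription_dose)
    return case.ct.copy_with(pred)
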