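"""Scikit-learn style estimator for measured-dose prediction.

``MDoseRegressor`` wraps the network family behind the familiar
``fit(X, y)`` / ``predict(X)`` interface so it composes with sklearn model
selection.  ``X`` has shape ``(n_cases, 2, D, H, W)`` — channel 0 the CT in
HU, channel 1 the planned dose in Gy — and ``y`` is the measured dose in Gy
with shape ``(n_cases, D, H, W)``.  Doses are normalized by the per-case
prescription (``prescription`` fit/predict parameter), CT by a fixed HU
window; training minimizes the mean-absolute (L1) voxel error with RMSprop
at batch size one.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from . import nn
from .fusion_net import FusionNet, ModelConfig, pad_to_divisible

__all__ = ["MDoseRegressor"]


class _RMSprop:
    """Root-mean-square propagation with uncentered second-moment average."""

    def __init__(self, params, lr: float, alpha: float = 0.99, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.sq = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.sq):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            v *= self.alpha
            v += (1.0 - self.alpha) * g * g
            p.data = p.data - (self.lr * g / (np.sqrt(v) + self.eps)).astype(p.data.dtype)


class MDoseRegressor(RegressorMixin, BaseEstimator):
    """Measured-dose predictor with a gated modality-fusion 3D network.

    Parameters
    ----------
    variant : {"baseline", "cpf", "ccf", "spf", "scf"}
        Backbone variant; see :mod:`mdoseqa.fusion_net`.
    levels, base_channels, se_reduction : int
        Backbone depth and width.
    learning_rate, max_epochs, patience : optimization settings.
        ``patience`` epochs without validation improvement stop training
        early (``None`` trains the full ``max_epochs``).
    val_fraction : float
        Fraction of the training set held out for validation when no
        explicit validation data is passed to :meth:`fit`.
    seed : int
        Seeds weight initialization and epoch shuffling.

    Attributes
    ----------
    net_ : FusionNet
        The fitted network, holding the best-validation weights.
    history_ : pandas.DataFrame
        Per-epoch train/validation L1 loss in normalized dose units.
    best_epoch_ : int
    """

    def __init__(
        self,
        variant: str = "spf",
        levels: int = 3,
        base_channels: int = 8,
        se_reduction: int = 4,
        learning_rate: float = 1e-3,
        max_epochs: int = 50,
        patience: int | None = 20,
        val_fraction: float = 0.2,
        seed: int = 0,
        rmsprop_alpha: float = 0.99,
        rmsprop_eps: float = 1e-8,
        residual_head: bool = True,
        verbose: bool = False,
    ):
        self.variant = variant
        self.levels = levels
        self.base_channels = base_channels
        self.se_reduction = se_reduction
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed
        self.rmsprop_alpha = rmsprop_alpha
        self.rmsprop_eps = rmsprop_eps
        self.residual_head = residual_head
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            variant=self.variant,
            levels=self.levels,
            base_channels=self.base_channels,
            se_reduction=self.se_reduction,
            residual_head=self.residual_head,
        )

    @staticmethod
    def _check_X(X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 5 or X.shape[1] != 2:
            raise ValueError(
                f"X must have shape (n_cases, 2, D, H, W); got {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    def _normalize(self, X, y, prescription):
        net = self.net_
        n = X.shape[0]
        rx = np.broadcast_to(np.asarray(prescription, dtype=float), (n,))
        cts, rts, ys = [], [], []
        d = 2 ** (self.levels - 1)
        for i in range(n):
            scale = net.dose_scale(rx[i])
            ct, _ = pad_to_divisible(net.normalize_ct(X[i, 0]), d)
            rt, _ = pad_to_divisible((X[i, 1] / scale).astype(net.dtype), d)
            cts.append(ct)
            rts.append(rt)
            if y is not None:
                yy, _ = pad_to_divisible((y[i] / scale).astype(net.dtype), d)
                ys.append(yy)
        return cts, rts, (ys if y is not None else None)

    def _epoch_val_loss(self, cts, rts, ys) -> float:
        total = 0.0
        for ct, rt, yy in zip(cts, rts, ys):
            out = self.net_.forward(nn.Tensor(ct[None, None]), nn.Tensor(rt[None, None]))
            total += float(np.mean(np.abs(out.data[0, 0] - yy)))
        return total / len(cts)

    # ------------------------------------------------------------------
    def fit(
        self,
        X,
        y,
        prescription: float | Sequence[float] = None,
        X_val=None,
        y_val=None,
        prescription_val=None,
    ):
        """Fit on volumes X=(n,2,D,H,W), y=(n,D,H,W).

        ``prescription`` (Gy) normalizes the dose channels; a scalar or one
        value per case.  Explicit validation data bypasses the internal
        ``val_fraction`` split.
        """
        X = self._check_X(X)
        y = np.asarray(y)
        if y.shape != (X.shape[0],) + X.shape[2:]:
            raise ValueError(f"y shape {y.shape} does not match X {X.shape}")
        if prescription is None:
            raise ValueError("prescription dose is required to normalize dose volumes")

        self.net_ = FusionNet(self._model_config(), seed=self.seed)
        rng = np.random.default_rng(self.seed + 1)

        if X_val is None:
            n = X.shape[0]
            n_val = max(1, int(round(n * self.val_fraction)))
            if n - n_val < 1:
                raise ValueError("training split would be empty")
            order = rng.permutation(n)
            vi, ti = order[:n_val], order[n_val:]
            rx = np.broadcast_to(np.asarray(prescription, dtype=float), (n,))
            X_val, y_val, prescription_val = X[vi], y[vi], rx[vi]
            X, y, prescription = X[ti], y[ti], rx[ti]
        elif y_val is None or prescription_val is None:
            raise ValueError("X_val requires y_val and prescription_val")

        tr = self._normalize(X, y, prescription)
        va = self._normalize(self._check_X(X_val), np.asarray(y_val), prescription_val)

        opt = _RMSprop(
            self.net_.parameters(), self.learning_rate, self.rmsprop_alpha, self.rmsprop_eps
        )
        n_train = len(tr[0])
        # pre-training validation loss anchors early stopping: the fitted
        # model can never end worse on validation than its initial state
        best_val = self._epoch_val_loss(*va)
        best_state = self.net_.state_dict()
        best_epoch = 0
        rows = [{"epoch": 0, "train_loss": np.nan, "val_loss": best_val}]
        stall = 0
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n_train)
            train_total = 0.0
            for i in order:
                self.net_.zero_grad()
                out = self.net_.forward(
                    nn.Tensor(tr[0][i][None, None]), nn.Tensor(tr[1][i][None, None])
                )
                loss = nn.l1_loss(out, tr[2][i][None, None])
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch}: loss={loss.data!r}"
                    )
                loss.backward()
                opt.step()
                train_total += float(loss.data)
            val_loss = self._epoch_val_loss(*va)
            if not np.isfinite(val_loss):
                raise FloatingPointError(f"validation loss diverged at epoch {epoch}")
            rows.append(
                {"epoch": epoch, "train_loss": train_total / n_train, "val_loss": val_loss}
            )
            if self.verbose:
                print(f"epoch {epoch:3d}  train {rows[-1]['train_loss']:.5f}  val {val_loss:.5f}")
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = self.net_.state_dict()
                best_epoch = epoch
                stall = 0
            else:
                stall += 1
                if self.patience is not None and stall >= self.patience:
                    break
        self.net_.load_state_dict(best_state)
        self.history_ = pd.DataFrame(rows)
        self.best_epoch_ = best_epoch
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    # ------------------------------------------------------------------
    def predict(self, X, prescription: float | Sequence[float] = None) -> np.ndarray:
        """Predicted measured dose in Gy, shape (n, D, H, W), non-negative."""
        if not hasattr(self, "net_"):
            raise AttributeError("this MDoseRegressor instance is not fitted yet")
        X = self._check_X(X)
        if prescription is None:
            raise ValueError("prescription dose is required to normalize dose volumes")
        rx = np.broadcast_to(np.asarray(prescription, dtype=float), (X.shape[0],))
        return np.stack(
            [self.net_.predict_volume(X[i, 0], X[i, 1], rx[i]) for i in range(X.shape[0])]
        )

    def score(self, X, y, prescription: float | Sequence[float] = None) -> float:
        """Negative mean absolute error in Gy (higher is better)."""
        pred = self.predict(X, prescription=prescription)
        return -float(np.mean(np.abs(pred - np.asarray(y))))
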