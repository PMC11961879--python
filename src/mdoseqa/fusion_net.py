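"""Dose-prediction network family: SE-residual baseline and gated fusion variants.

The task is voxel-wise regression of the measurement-reconstructed dose
(MDose) from a CT volume and the planned dose (RTDose).  Five variants share
one SE-residual encoder-decoder backbone:

``baseline``
    Single encoder; CT and RTDose concatenated as a 2-channel input
    (3D ResUNet with squeeze-and-excitation residual blocks).
``cpf`` / ``ccf``
    Dual encoders (one per modality) whose per-level features interact
    through *concatenation* fusion: a conv over the concatenated features is
    transformed per branch and added back to the same branch (parallel, CPF)
    or to the opposite branch (cross, CCF).
``spf`` / ``scf``
    *Squeezed* fusion: the concatenated features are globally average-pooled
    to a channel descriptor, fully connected gates (sigmoid) reweight each
    branch channel-wise, and the gated features are added back parallel
    (SPF) or crossed (SCF).

In the dual-encoder variants a single shared decoder fuses the per-level
branch features with the upsampled deeper feature,
``F_i = Conv(Concat(Up(F_{i+1}), Conv(Concat(f̄CT_i, f̄RT_i))))``,
iterated until full input resolution; a final 1x1x1 linear convolution
predicts the normalized absolute dose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Tuple

import numpy as np

from . import nn
from .nn import (
    Conv3d,
    InstanceNorm3d,
    Linear,
    Module,
    Parameter,
    SEGate,
    SEResBlock,
    Tensor,
    add,
    channel_scale,
    concat,
    global_avg_pool,
    relu,
    sigmoid,
    upsample2x,
)

__all__ = [
    "ModelConfig",
    "CPFusion",
    "CCFusion",
    "SPFusion",
    "SCFusion",
    "DecoderFuse",
    "FusionNet",
    "build_model",
    "se_residual_block",
    "fuse_cpf",
    "fuse_ccf",
    "fuse_spf",
    "fuse_scf",
    "decoder_fuse",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("baseline", "cpf", "ccf", "spf", "scf")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and normalization constants of the network family."""

    variant: str = "spf"
    levels: int = 4
    base_channels: int = 16
    se_reduction: int = 4
    gate_activation: str = "sigmoid"
    hu_window: Tuple[float, float] = (-1000.0, 1500.0)
    dose_divisor: float | None = None  # None -> divide by per-case prescription
    residual_head: bool = True  # predict plan + correction rather than absolute dose

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.base_channels % self.se_reduction:
            raise ValueError("se_reduction must divide base_channels")
        if self.gate_activation != "sigmoid":
            raise ValueError("only sigmoid gate activation is supported")
        if self.hu_window[1] <= self.hu_window[0]:
            raise ValueError("hu_window must be increasing")

    @property
    def channels(self) -> List[int]:
        return [self.base_channels * 2**i for i in range(self.levels)]


# ---------------------------------------------------------------------------
# fusion modules (encoder side)
# ---------------------------------------------------------------------------

class _ConcatFusion(Module):
    """Shared machinery of the concatenation fusion pair (parallel / cross).

    f̃ = Conv(Concat(fCT, fRT)); per-branch transforms f̃CT = Conv_CT(f̃),
    f̃RT = Conv_RT(f̃).  The convolutions are plain (no normalization or
    activation), so zeroed parameters reduce the module to the identity.
    """

    cross = False

    def __init__(self, channels: int, rng=None, dtype=np.float32):
        self.conv_fuse = Conv3d(2 * channels, channels, 3, 1, rng, dtype)
        self.conv_ct = Conv3d(channels, channels, 3, 1, rng, dtype)
        self.conv_rt = Conv3d(channels, channels, 3, 1, rng, dtype)

    def branch_transforms(self, f_ct: Tensor, f_rt: Tensor) -> Tuple[Tensor, Tensor]:
        if f_ct.shape != f_rt.shape:
            raise ValueError(f"branch shape mismatch: {f_ct.shape} vs {f_rt.shape}")
        fused = self.conv_fuse(concat([f_ct, f_rt], axis=1))
        return self.conv_ct(fused), self.conv_rt(fused)

    def forward(self, f_ct: Tensor, f_rt: Tensor) -> Tuple[Tensor, Tensor]:
        t_ct, t_rt = self.branch_transforms(f_ct, f_rt)
        if self.cross:
            return add(f_ct, t_rt), add(f_rt, t_ct)
        return add(f_ct, t_ct), add(f_rt, t_rt)


class CPFusion(_ConcatFusion):
    """Concatenation parallel fusion: f̄b = fb + f̃b."""

    cross = False


class CCFusion(_ConcatFusion):
    """Concatenation cross fusion: f̄CT = fCT + f̃RT, f̄RT = fRT + f̃CT."""

    cross = True


class _SqueezedFusion(Module):
    """Shared machinery of the squeezed fusion pair (parallel / cross).

    The concatenated features are squeezed to a channel descriptor by global
    average pooling; two independent FC heads with sigmoid gates produce
    per-channel weights that rescale each branch, and the gated features are
    added back.  With zeroed FC parameters the gates sit at sigmoid(0)=0.5.
    """

    cross = False

    def __init__(self, channels: int, rng=None, dtype=np.float32):
        self.fc_ct = Linear(2 * channels, channels, rng, dtype)
        self.fc_rt = Linear(2 * channels, channels, rng, dtype)

    def branch_transforms(self, f_ct: Tensor, f_rt: Tensor) -> Tuple[Tensor, Tensor]:
        if f_ct.shape != f_rt.shape:
            raise ValueError(f"branch shape mismatch: {f_ct.shape} vs {f_rt.shape}")
        squeezed = global_avg_pool(concat([f_ct, f_rt], axis=1))
        w_ct = sigmoid(self.fc_ct(squeezed))
        w_rt = sigmoid(self.fc_rt(squeezed))
        return channel_scale(f_ct, w_ct), channel_scale(f_rt, w_rt)

    def forward(self, f_ct: Tensor, f_rt: Tensor) -> Tuple[Tensor, Tensor]:
        t_ct, t_rt = self.branch_transforms(f_ct, f_rt)
        if self.cross:
            return add(f_ct, t_rt), add(f_rt, t_ct)
        return add(f_ct, t_ct), add(f_rt, t_rt)


class SPFusion(_SqueezedFusion):
    """Squeezed parallel fusion: f̄b = fb + w_b ⊗ fb."""

    cross = False


class SCFusion(_SqueezedFusion):
    """Squeezed cross fusion: f̄CT = fCT + w_RT ⊗ fRT and vice versa."""

    cross = True


_FUSIONS = {"cpf": CPFusion, "ccf": CCFusion, "spf": SPFusion, "scf": SCFusion}


# ---------------------------------------------------------------------------
# decoder fusion (Eq.-style plain convolutions)
# ---------------------------------------------------------------------------

class DecoderFuse(Module):
    """F_i = Conv(Concat(Up(F_{i+1}), Conv(Concat(f̄CT_i, f̄RT_i)))).

    ``inner`` abstracts the concatenated branch features; ``outer`` merges
    them with the trilinearly upsampled deeper decoder feature.  Both are
    plain convolutions (linear), so the module obeys exact superposition.
    """

    def __init__(self, channels: int, next_channels: int, rng=None, dtype=np.float32):
        self.inner = Conv3d(2 * channels, channels, 3, 1, rng, dtype)
        self.outer = Conv3d(channels + next_channels, channels, 3, 1, rng, dtype)

    def forward(self, f_next: Tensor, f_ct: Tensor, f_rt: Tensor) -> Tensor:
        up = upsample2x(f_next)
        if up.shape[2:] != f_ct.shape[2:]:
            raise ValueError(
                f"spatial mismatch after upsampling: {up.shape[2:]} vs {f_ct.shape[2:]}"
            )
        skip = self.inner(concat([f_ct, f_rt], axis=1))
        return self.outer(concat([up, skip], axis=1))


# functional wrappers -------------------------------------------------------

def se_residual_block(x: Tensor, params: SEResBlock) -> Tensor:
    return params(x)


def fuse_cpf(f_ct: Tensor, f_rt: Tensor, params: CPFusion) -> Tuple[Tensor, Tensor]:
    return params(f_ct, f_rt)


def fuse_ccf(f_ct: Tensor, f_rt: Tensor, params: CCFusion) -> Tuple[Tensor, Tensor]:
    return params(f_ct, f_rt)


def fuse_spf(f_ct: Tensor, f_rt: Tensor, params: SPFusion) -> Tuple[Tensor, Tensor]:
    return params(f_ct, f_rt)


def fuse_scf(f_ct: Tensor, f_rt: Tensor, params: SCFusion) -> Tuple[Tensor, Tensor]:
    return params(f_ct, f_rt)


def decoder_fuse(f_next: Tensor, f_ct: Tensor, f_rt: Tensor, params: DecoderFuse) -> Tensor:
    return params(f_next, f_ct, f_rt)


# ---------------------------------------------------------------------------
# backbone pieces
# ---------------------------------------------------------------------------

class _ConvNormAct(Module):
    def __init__(self, cin, cout, stride=1, rng=None, dtype=np.float32):
        self.conv = Conv3d(cin, cout, 3, stride, rng, dtype)
        self.norm = InstanceNorm3d(cout, dtype)

    def forward(self, x: Tensor) -> Tensor:
        return relu(self.norm(self.conv(x)))


class _Encoder(Module):
    """Multi-scale feature extractor; spatial dims halve per level."""

    def __init__(self, in_channels, channels, se_reduction, rng=None, dtype=np.float32):
        self.stem = _ConvNormAct(in_channels, channels[0], 1, rng, dtype)
        self.blocks = [SEResBlock(c, se_reduction, rng, dtype) for c in channels]
        self.downs = [
            _ConvNormAct(channels[i], channels[i + 1], 2, rng, dtype)
            for i in range(len(channels) - 1)
        ]

    def forward(self, x: Tensor) -> List[Tensor]:
        feats = []
        h = self.blocks[0](self.stem(x))
        feats.append(h)
        for down, block in zip(self.downs, self.blocks[1:]):
            h = block(down(h))
            feats.append(h)
        return feats


class _RefineBlock(Module):
    """Post-fusion decoder refinement: norm + activation + SE-residual block."""

    def __init__(self, channels, se_reduction, rng=None, dtype=np.float32):
        self.norm = InstanceNorm3d(channels, dtype)
        self.block = SEResBlock(channels, se_reduction, rng, dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.block(relu(self.norm(x)))


class _BaselineDecode(Module):
    """Plain U-Net skip fusion for the single-encoder baseline."""

    def __init__(self, channels, next_channels, rng=None, dtype=np.float32):
        self.outer = Conv3d(channels + next_channels, channels, 3, 1, rng, dtype)

    def forward(self, f_next: Tensor, skip: Tensor) -> Tensor:
        up = upsample2x(f_next)
        if up.shape[2:] != skip.shape[2:]:
            raise ValueError(
                f"spatial mismatch after upsampling: {up.shape[2:]} vs {skip.shape[2:]}"
            )
        return self.outer(concat([up, skip], axis=1))


# ---------------------------------------------------------------------------
# the full model
# ---------------------------------------------------------------------------

class FusionNet(Module):
    """Volumetric dose predictor; see module docstring for the variants."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.channels
        red = config.se_reduction
        self.dtype = dtype

        if config.variant == "baseline":
            self.encoder = _Encoder(2, ch, red, rng, dtype)
            self.decodes = [
                _BaselineDecode(ch[i], ch[i + 1], rng, dtype) for i in range(config.levels - 1)
            ]
        else:
            self.encoder_ct = _Encoder(1, ch, red, rng, dtype)
            self.encoder_rt = _Encoder(1, ch, red, rng, dtype)
            fusion_cls = _FUSIONS[config.variant]
            self.fusions = [fusion_cls(c, rng, dtype) for c in ch]
            self.bottom = Conv3d(2 * ch[-1], ch[-1], 3, 1, rng, dtype)
            self.decodes = [
                DecoderFuse(ch[i], ch[i + 1], rng, dtype) for i in range(config.levels - 1)
            ]
        self.refines = [_RefineBlock(ch[i], red, rng, dtype) for i in range(config.levels)]
        self.head = Conv3d(ch[0], 1, 1, 1, rng, dtype)
        if config.residual_head:
            # start exactly at the identity map (prediction = plan)
            self.head.weight.data[:] = 0

    # -- forward ----------------------------------------------------------
    def forward(self, ct: Tensor, rt: Tensor) -> Tensor:
        """Normalized inputs (N, 1, D, H, W) -> normalized dose (N, 1, D, H, W)."""
        if ct.shape != rt.shape:
            raise ValueError(f"input shape mismatch: {ct.shape} vs {rt.shape}")
        d = 2 ** (self.config.levels - 1)
        if any(s % d for s in ct.shape[2:]):
            raise ValueError(f"spatial dims {ct.shape[2:]} not divisible by {d}")

        if self.config.variant == "baseline":
            feats = self.encoder(concat([ct, rt], axis=1))
            f = self.refines[-1](feats[-1])
            for i in range(self.config.levels - 2, -1, -1):
                f = self.refines[i](self.decodes[i](f, feats[i]))
        else:
            feats_ct = self.encoder_ct(ct)
            feats_rt = self.encoder_rt(rt)
            fused = [
                fusion(fc, fr)
                for fusion, fc, fr in zip(self.fusions, feats_ct, feats_rt)
            ]
            f = self.refines[-1](self.bottom(concat(list(fused[-1]), axis=1)))
            for i in range(self.config.levels - 2, -1, -1):
                f = self.refines[i](self.decodes[i](f, fused[i][0], fused[i][1]))
        out = self.head(f)
        if self.config.residual_head:
            out = add(out, rt)
        return out

    # -- normalization & volume-level prediction --------------------------
    def normalize_ct(self, hu: np.ndarray) -> np.ndarray:
        lo, hi = self.config.hu_window
        return ((np.clip(hu, lo, hi) - lo) / (hi - lo)).astype(self.dtype)

    def dose_scale(self, prescription: float | None) -> float:
        if self.config.dose_divisor is not None:
            return float(self.config.dose_divisor)
        if prescription is None or prescription <= 0:
            raise ValueError("prescription dose required to normalize dose inputs")
        return float(prescription)

    def predict_volume(
        self, ct_hu: np.ndarray, rt_gy: np.ndarray, prescription: float | None = None
    ) -> np.ndarray:
        """Predict the measured-dose volume in Gy (non-negative, input shape)."""
        scale = self.dose_scale(prescription)
        ct_n = self.normalize_ct(np.asarray(ct_hu))
        rt_n = (np.asarray(rt_gy) / scale).astype(self.dtype)
        d = 2 ** (self.config.levels - 1)
        ct_p, sl = pad_to_divisible(ct_n, d)
        rt_p, _ = pad_to_divisible(rt_n, d)
        out = self.forward(Tensor(ct_p[None, None]), Tensor(rt_p[None, None]))
        pred = out.data[0, 0][sl]
        return np.clip(pred.astype(np.float64) * scale, 0.0, None)


def pad_to_divisible(arr: np.ndarray, d: int):
    """Zero-pad trailing edges of a 3D array so every dim divides ``d``.

    Returns the padded array and the slices recovering the original region.
    """
    pads = [(0, (-arr.shape[i]) % d) for i in range(3)]
    sl = tuple(slice(0, arr.shape[i]) for i in range(3))
    if any(p[1] for p in pads):
        arr = np.pad(arr, pads)
    return arr, sl


def build_model(config: ModelConfig, seed: int = 0, dtype=np.float32) -> FusionNet:
    """Construct a seeded, normally-initialized model of the given variant."""
    return FusionNet(config, seed=seed, dtype=dtype)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: FusionNet, path: str | Path, extra: dict | None = None) -> Path:
    """Save config + weights (+ optional metadata) to an .npz archive."""
    path = Path(path)
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    meta = {"config": asdict(model.config), "extra": extra or {}}
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)
    return path


def load_checkpoint(path: str | Path) -> tuple[FusionNet, dict]:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        cfg_dict = meta["config"]
        cfg_dict["hu_window"] = tuple(cfg_dict["hu_window"])
        config = ModelConfig(**cfg_dict)
        model = FusionNet(config)
        state = {k[len("param/"):]: archive[k] for k in archive.files if k.startswith("param/")}
    model.load_state_dict(state)
    return model, meta["extra"]
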