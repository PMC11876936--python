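"""The two-branch fusion network and its loss/schedule closed forms.

Architecture
------------
A 3-level 3D U-Net segments the lesion; the channel-mean of each of its
subsampling (post-pooling encoder) activations, squashed through a
sigmoid, forms a *prior attention* map in [0, 1].  A mirrored 3D CNN
classification branch is modulated at each matching scale by
``(1 + attention)`` — residual multiplicative modulation, so attention
can emphasise lesion regions without ever zeroing gradients.  The
classification stack global-average-pools into a semantic vector.

A self-attention module scores each radiomics feature (one learnable
linear scorer), softmax-normalizes the scores into simplex weights, and
rescales the weighted features by the feature count; the weights are
the per-study feature-significance read-out.

Three softmax classifier heads: radiomics-only, CNN-only, and a
combined MLP over [semantic vector ‖ attention-weighted radiomics].
Final head layers are zero-initialized, so an untrained model emits
(0.5, 0.5) from every head.

Training losses: Dice loss for segmentation, cross-entropy for the
heads; stage 1 minimizes DiceLoss + L_cnn, stage 2 minimizes
L_rad + L_com.  Learning rate decays exponentially per epoch,
lr(t) = lr0 * decay^t (defaults lr0 = 1e-4, decay = 0.98).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn.autodiff import (avgpool3d, concat, leaky_relu, log_softmax, relu,
                          sigmoid, softmax, tmean, tsum, upsample3d)

DICE_EPS = 1e-6
CE_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class NetConfig:
    """Architecture knobs (the source description leaves sizes open)."""

    in_channels: int = 1
    channels: tuple[int, int, int] = (16, 32, 64)
    n_features: int = 32           # radiomics vector length
    semantic_dim: int = 64
    fusion_hidden: int = 64
    input_shape: tuple[int, int, int] = (32, 64, 64)


@dataclass
class LossBundle:
    l_seg: float = 0.0
    l_cnn: float = 0.0
    l_rad: float = 0.0
    l_com: float = 0.0

    @property
    def stage1(self) -> float:
        return self.l_seg + self.l_cnn

    @property
    def stage2(self) -> float:
        return self.l_rad + self.l_com


def lr_schedule(t: int, lr0: float = 1e-4, decay: float = 0.98) -> float:
    """Exponentially decayed learning rate at epoch t: lr0 * decay**t."""
    if t < 0:
        raise ValueError("epoch must be >= 0")
    return lr0 * decay ** t


def dice_loss(pred_probs, true_mask) -> Tensor:
    """1 - (2 Σ p·m + ε) / (Σ p + Σ m + ε), elementwise over the batch."""
    pred = nn.as_tensor(pred_probs)
    mask = np.asarray(true_mask.data if isinstance(true_mask, Tensor) else true_mask,
                      dtype=np.float64)
    if pred.data.shape != mask.shape:
        raise ValueError(f"shape mismatch {pred.data.shape} vs {mask.shape}")
    inter = tsum(pred * Tensor(mask))
    denom = tsum(pred) + float(mask.sum())
    return 1.0 - (2.0 * inter + DICE_EPS) / (denom + DICE_EPS)


def class_cross_entropy(probs, label: int) -> float:
    """−log p[label] with a numerical floor (plain-number closed form)."""
    p = float(np.asarray(probs)[label])
    return -float(np.log(max(p, CE_PROB_FLOOR)))


def nll_from_log_probs(logp: Tensor, labels: np.ndarray) -> Tensor:
    """Mean −log p[label] over a batch from a (N, 2) log-prob tensor."""
    labels = np.asarray(labels, dtype=int)
    onehot = np.zeros(logp.data.shape)
    onehot[np.arange(labels.size), labels] = 1.0
    return -tmean(tsum(logp * Tensor(onehot), axis=1))


def stage_losses(l_seg: float, l_cnn: float, l_rad: float, l_com: float
                 ) -> tuple[float, float]:
    """Stage composites: (DiceLoss + L_cnn, L_rad + L_com)."""
    return l_seg + l_cnn, l_rad + l_com


def prior_attention(encoder_activation: Tensor) -> Tensor:
    """Channel-mean of a (N, C, D, H, W) activation through a sigmoid.

    Zero activation maps to a uniform 0.5 attention; the classification
    feature at the same scale is multiplied by (1 + attention).
    """
    return sigmoid(tmean(encoder_activation, axis=1, keepdims=True))


class RadiomicsAttention(nn.Module):
    """Learnable self-attention over the radiomics feature vector."""

    def __init__(self, d: int, rng: np.random.Generator):
        self.scorer = nn.Linear(d, d, rng, zero_init=True)
        self.d = d

    def __call__(self, z: Tensor) -> tuple[Tensor, Tensor]:
        scores = self.scorer(z)
        weights = softmax(scores, axis=-1)  # per-study simplex vector
        weighted = float(self.d) * weights * z  # rescaled to O(features)
        return weights, weighted


class FusionModel(nn.Module):
    """Two-branch segmentation-guided classifier with three heads."""

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        cin, (c1, c2, c3) = config.in_channels, config.channels

        # segmentation branch (U-Net)
        self.enc1 = nn.Conv3d(cin, c1, 3, rng)
        self.enc2 = nn.Conv3d(c1, c2, 3, rng)
        self.enc3 = nn.Conv3d(c2, c3, 3, rng)
        self.bottleneck = nn.Conv3d(c3, c3, 3, rng)
        self.dec3 = nn.Conv3d(c3 + c3, c2, 3, rng)
        self.dec2 = nn.Conv3d(c2 + c2, c1, 3, rng)
        self.dec1 = nn.Conv3d(c1 + c1, c1, 3, rng)
        self.seg_head = nn.Conv3d(c1, 1, 1, rng)
        # start near the low foreground prevalence of lesion masks so the
        # Dice term is informative from the first steps
        self.seg_head.bias.data[:] = -3.0

        # classification branch mirroring the encoder scales
        self.cls1 = nn.Conv3d(cin, c1, 3, rng)
        self.cls2 = nn.Conv3d(c1, c2, 3, rng)
        self.cls3 = nn.Conv3d(c2, c3, 3, rng)
        self.cls_final = nn.Conv3d(c3, c3, 3, rng)  # Grad-CAM target layer
        self.semantic = nn.Linear(c3, config.semantic_dim, rng)

        # heads (zero-init => symmetric (0.5, 0.5) before training)
        self.head_cnn = nn.Linear(config.semantic_dim, 2, rng, zero_init=True)
        self.attention = RadiomicsAttention(config.n_features, rng)
        self.head_rad = nn.Linear(config.n_features, 2, rng, zero_init=True)
        self.fusion_in = nn.Linear(config.semantic_dim + config.n_features,
                                   config.fusion_hidden, rng)
        self.head_com = nn.Linear(config.fusion_hidden, 2, rng, zero_init=True)

    # -- branch passes --------------------------------------------------
    def seg_forward(self, x: Tensor):
        """Returns (seg_probs, [post-pooling encoder activations])."""
        e1 = relu(self.enc1(x))
        p1 = avgpool3d(e1)
        e2 = relu(self.enc2(p1))
        p2 = avgpool3d(e2)
        e3 = relu(self.enc3(p2))
        p3 = avgpool3d(e3)
        b = relu(self.bottleneck(p3))
        d3 = relu(self.dec3(concat([upsample3d(b), e3], axis=1)))
        d2 = relu(self.dec2(concat([upsample3d(d3), e2], axis=1)))
        d1 = relu(self.dec1(concat([upsample3d(d2), e1], axis=1)))
        seg = sigmoid(self.seg_head(d1))
        return seg, [p1, p2, p3]

    def cls_forward(self, x: Tensor, attentions: list[Tensor]):
        """Prior-attention-modulated classification stack.

        Returns (semantic vector (N, semantic_dim), target-layer
        activation for Grad-CAM).
        """
        # leaky activations: the classification path must survive the
        # aggressive short-schedule learning rates without dying
        a1, a2, a3 = attentions
        q1 = avgpool3d(leaky_relu(self.cls1(x))) * (1.0 + a1)
        q2 = avgpool3d(leaky_relu(self.cls2(q1))) * (1.0 + a2)
        c3 = leaky_relu(self.cls3(q2))
        cam = leaky_relu(self.cls_final(c3))  # last conv, pre-pool scale
        q3 = avgpool3d(cam) * (1.0 + a3)
        pooled = tmean(q3, axis=(2, 3, 4))  # global average pool -> (N, C3)
        h = leaky_relu(self.semantic(pooled))
        return h, cam

    def forward_graph(self, x: Tensor, z: Tensor, detach_extractors: bool = False):
        """Full forward pass returning the live graph nodes.

        Keys: seg, logp_cnn, logp_rad, logp_com, attn_weights, cam,
        attention maps.  ``detach_extractors`` severs the stage-1
        sub-network so stage-2 losses cannot update it.
        """
        seg, pools = self.seg_forward(x)
        attn_maps = [prior_attention(p) for p in pools]
        h, cam = self.cls_forward(x, attn_maps)
        logp_cnn = log_softmax(self.head_cnn(h), axis=-1)

        h_for_fusion = h.detach() if detach_extractors else h
        w, zw = self.attention(z)
        logp_rad = log_softmax(self.head_rad(zw), axis=-1)
        fused = relu(self.fusion_in(concat([h_for_fusion, zw], axis=1)))
        logp_com = log_softmax(self.head_com(fused), axis=-1)
        return {"seg": seg, "logp_cnn": logp_cnn, "logp_rad": logp_rad,
                "logp_com": logp_com, "attn_weights": w, "cam": cam,
                "attn_maps": attn_maps}

    def forward(self, model_input, vector) -> tuple[np.ndarray, ...]:
        """Inference: (seg_map, p_rad, p_cnn, p_com) as numpy arrays.

        Accepts a single study (C,D,H,W) + feature vector (d,) or a
        batch (N,C,D,H,W) + (N,d).  Deterministic for a fixed parameter
        state; no augmentation or dropout exists at inference.
        """
        x = np.asarray(model_input.data if hasattr(model_input, "data")
                       and not isinstance(model_input, np.ndarray)
                       else model_input, dtype=np.float64)
        z = np.asarray(vector.to_array() if hasattr(vector, "to_array")
                       else vector, dtype=np.float64)
        single = x.ndim == 4
        if single:
            x, z = x[None], z[None]
        out = self.forward_graph(Tensor(x), Tensor(z))
        seg = out["seg"].data[:, 0]
        p_rad = np.exp(out["logp_rad"].data)
        p_cnn = np.exp(out["logp_cnn"].data)
        p_com = np.exp(out["logp_com"].data)
        if single:
            return seg[0], p_rad[0], p_cnn[0], p_com[0]
        return seg, p_rad, p_cnn, p_com

    # -- parameter groups for the two training stages -------------------
    def stage1_modules(self):
        return [self.enc1, self.enc2, self.enc3, self.bottleneck, self.dec3,
                self.dec2, self.dec1, self.seg_head, self.cls1, self.cls2,
                self.cls3, self.cls_final, self.semantic, self.head_cnn]

    def stage2_modules(self):
        return [self.attention, self.head_rad, self.fusion_in, self.head_com]

    def stage1_parameters(self):
        return [p for m in self.stage1_modules() for p in m.parameters()]

    def stage2_parameters(self):
        return [p for m in self.stage2_modules() for p in m.parameters()]
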