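"""Grad-CAM saliency and feature-significance ranking (FSR).

Grad-CAM: channel weights are the global average of the gradient of
the target-class logit with respect to the target convolutional
activation; the map is ReLU of the weighted channel sum, trilinearly
upsampled to the model-input grid and min–max normalized.  A map that
is identically zero (constant activation, dead gradient) is returned
as all-zeros and flagged degenerate.

FSR: the significance of a radiomics feature is the cohort mean of its
self-attention weight; per-class views average over studies the model
*predicts* into that class (an option switches to true labels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom

from .nn import Tensor
from .nn.autodiff import concat, relu, tsum
from .network import FusionModel, prior_attention
from .radiomics import FEATURE_NAMES


@dataclass
class SaliencyMap:
    grid: np.ndarray           # (D, H, W) in [0, 1]
    target_head: str
    target_class: int
    target_layer: str
    degenerate: bool = False


@dataclass
class FSRRanking:
    feature_names: tuple[str, ...]
    overall: np.ndarray                 # mean simplex vector, sums to 1
    per_class: dict[int, np.ndarray | None]
    order: np.ndarray                   # feature indices, significance desc
    top_k: int = 8

    def top_features(self, k: int | None = None) -> list[tuple[str, float]]:
        k = k or self.top_k
        return [(self.feature_names[i], float(self.overall[i]))
                for i in self.order[:k]]


def grad_cam(model: FusionModel, model_input, feature_vector,
             target_class: int = 1, target_head: str = "cnn",
             target_layer: str = "cls_final") -> SaliencyMap:
    """Saliency of ``target_class`` for one study on the model-input grid."""
    if target_layer != "cls_final":
        raise KeyError(f"unknown target layer {target_layer!r}")
    if target_head not in ("cnn", "combined"):
        raise KeyError(f"unknown target head {target_head!r}")
    x_np = np.asarray(model_input.data if hasattr(model_input, "data")
                      else model_input, dtype=np.float64)
    if x_np.ndim == 3:
        x_np = x_np[None]
    z_np = np.asarray(feature_vector.to_array() if hasattr(feature_vector, "to_array")
                      else feature_vector, dtype=np.float64)

    x = Tensor(x_np[None])
    seg, pools = model.seg_forward(x)
    h, cam = model.cls_forward(x, [prior_attention(p) for p in pools])
    if target_head == "cnn":
        logits = model.head_cnn(h)
    else:
        w, zw = model.attention(Tensor(z_np[None]))
        fused = relu(model.fusion_in(concat([h, zw], axis=1)))
        logits = model.head_com(fused)
    onehot = np.zeros((1, 2))
    onehot[0, target_class] = 1.0
    score = tsum(logits * Tensor(onehot))
    model.zero_grad()
    score.backward()

    act = cam.data[0]                      # (C, d, h, w)
    grad = cam.grad[0] if cam.grad is not None else np.zeros_like(act)
    weights = grad.mean(axis=(1, 2, 3))    # global-average pooled gradients
    raw = np.maximum((weights[:, None, None, None] * act).sum(axis=0), 0.0)

    target_shape = x_np.shape[1:]
    factors = [t / s for t, s in zip(target_shape, raw.shape)]
    up = zoom(raw, factors, order=1) if raw.shape != tuple(target_shape) else raw
    up = np.maximum(up, 0.0)
    mx = up.max()
    if mx <= 0.0:
        return SaliencyMap(grid=np.zeros(target_shape), target_head=target_head,
                           target_class=target_class, target_layer=target_layer,
                           degenerate=True)
    return SaliencyMap(grid=up / mx, target_head=target_head,
                       target_class=target_class, target_layer=target_layer)


def attention_weight_rows(model: FusionModel, feats: np.ndarray) -> np.ndarray:
    """Per-study self-attention simplex vectors for a feature matrix."""
    w, _ = model.attention(Tensor(np.asarray(feats, dtype=np.float64)))
    return w.data.copy()


def fsr_ranking(weight_rows: np.ndarray, predictions: np.ndarray,
                top_k: int = 8) -> FSRRanking:
    """Average significance of each feature, overall and per class.

    ``weight_rows`` is (n_studies, n_features) of simplex vectors;
    ``predictions`` the model's class per study.  Ranking is by overall
    significance, descending; ties resolved by the fixed feature order.
    """
    weight_rows = np.asarray(weight_rows, dtype=np.float64)
    if weight_rows.ndim != 2 or weight_rows.shape[0] < 1:
        raise ValueError("need at least one study's weight row")
    predictions = np.asarray(predictions, dtype=int)
    overall = weight_rows.mean(axis=0)
    per_class: dict[int, np.ndarray | None] = {}
    for cls in (0, 1):
        sel = predictions == cls
        per_class[cls] = weight_rows[sel].mean(axis=0) if sel.any() else None
    # stable sort on -overall => ties keep the documented feature order
    order = np.argsort(-overall, kind="stable")
    names = FEATURE_NAMES if weight_rows.shape[1] == len(FEATURE_NAMES) \
        else tuple(f"f{i}" for i in range(weight_rows.shape[1]))
    return FSRRanking(feature_names=names, overall=overall,
                      per_class=per_class, order=order, top_k=top_k)


def fsr_to_frame(ranking: FSRRanking):
    """FSR as a DataFrame: feature, family, overall, class0, class1, rank."""
    import pandas as pd

    inv_rank = np.empty(len(ranking.order), dtype=int)
    inv_rank[ranking.order] = np.arange(1, len(ranking.order) + 1)
    rows = []
    for i, name in enumerate(ranking.feature_names):
        rows.append({
            "feature": name,
            "family": name.split("_")[0],
            "overall": float(ranking.overall[i]),
            "class0": None if ranking.per_class[0] is None else float(ranking.per_class[0][i]),
            "class1": None if ranking.per_class[1] is None else float(ranking.per_class[1][i]),
            "rank": int(inv_rank[i]),
        })
    return pd.DataFrame(rows).sort_values("rank").reset_index(drop=True)


def plot_top_features(ranking: FSRRanking, k: int = 8, path=None):
    """Horizontal bar plot of the top-k average significances."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = ranking.top_features(k)
    names = [n for n, _ in top][::-1]
    vals = [v for _, v in top][::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * k + 1))
    ax.barh(names, vals)
    ax.set_xlabel("average significance (attention weight)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
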