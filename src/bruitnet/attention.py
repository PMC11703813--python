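"""Convolutional Block Attention Module (CBAM) — functional surface.

Channel attention reweights feature-map channels (weights M_c in R^{Cx1x1});
spatial attention reweights locations (M_s in R^{1xHxW}); both are sigmoid
outputs in (0, 1) applied by broadcast element-wise multiplication:

    F1 = M_c(F) * F        (channel)
    F2 = M_s(F1) * F1      (spatial)

Internals follow the canonical CBAM design: dual global average/max pooling
feeding a shared two-layer bottleneck (reduction ratio, default 16) for the
channel branch, and a single k x k convolution (default 7) over stacked
channel-mean/max maps for the spatial branch.

This module exposes seeded functional wrappers over the differentiable
layers in :mod:`bruitnet.nn` for single (C, H, W) numpy feature maps; the
classifier itself uses the layer classes directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import ChannelAttention, SpatialAttention, Tensor


@dataclass
class AttentionMaps:
    """Channel (C,1,1) and spatial (1,H,W) sigmoid weights, each in (0,1)."""

    channel_weights: np.ndarray
    spatial_weights: np.ndarray

    def __post_init__(self) -> None:
        cw, sw = np.asarray(self.channel_weights), np.asarray(self.spatial_weights)
        if cw.ndim != 3 or cw.shape[1:] != (1, 1):
            raise ValueError(f"channel weights must be (C,1,1), got {cw.shape}")
        if sw.ndim != 3 or sw.shape[0] != 1:
            raise ValueError(f"spatial weights must be (1,H,W), got {sw.shape}")
        for name, w in (("channel", cw), ("spatial", sw)):
            if not ((w > 0) & (w < 1)).all():
                raise ValueError(f"{name} weights must lie strictly in (0,1)")
        self.channel_weights = cw
        self.spatial_weights = sw


def _as_batch(fmap: np.ndarray) -> Tensor:
    fmap = np.asarray(fmap, dtype=np.float64)
    if fmap.ndim != 3:
        raise ValueError(f"feature map must be (C,H,W), got shape {fmap.shape}")
    if not np.all(np.isfinite(fmap)):
        raise ValueError("non-finite feature map")
    return Tensor(fmap[np.newaxis])


def channel_attention(fmap: np.ndarray, reduction: int = 16, seed: int = 0) -> np.ndarray:
    """Channel weights (C,1,1) for one (C,H,W) map, seeded bottleneck."""
    x = _as_batch(fmap)
    module = ChannelAttention(fmap.shape[0], reduction, np.random.default_rng(seed))
    return module.weights(x).data[0]


def spatial_attention(fmap: np.ndarray, kernel: int = 7, seed: int = 0) -> np.ndarray:
    """Spatial weights (1,H,W) for one (C,H,W) map, seeded convolution."""
    x = _as_batch(fmap)
    module = SpatialAttention(kernel, np.random.default_rng(seed))
    return module.weights(x).data[0]


def compute_attention_maps(
    fmap: np.ndarray, reduction: int = 16, kernel: int = 7, seed: int = 0
) -> AttentionMaps:
    """Both attention maps for one feature map (spatial computed on F1)."""
    cw = channel_attention(fmap, reduction=reduction, seed=seed)
    f1 = np.asarray(fmap, dtype=np.float64) * cw
    sw = spatial_attention(f1, kernel=kernel, seed=seed)
    return AttentionMaps(channel_weights=cw, spatial_weights=sw)


def apply_cbam(fmap: np.ndarray, maps: AttentionMaps) -> np.ndarray:
    """F2 = M_s * (M_c * F); shape preserved."""
    fmap = np.asarray(fmap, dtype=np.float64)
    if fmap.ndim != 3:
        raise ValueError(f"feature map must be (C,H,W), got {fmap.shape}")
    if maps.channel_weights.shape[0] != fmap.shape[0]:
        raise ValueError("channel-weight count does not match feature map")
    if maps.spatial_weights.shape[1:] != fmap.shape[1:]:
        raise ValueError("spatial-weight shape does not match feature map")
    return maps.spatial_weights * (maps.channel_weights * fmap)
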