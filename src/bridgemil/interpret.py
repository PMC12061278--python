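"""Interpretability: integrated gradients on omics features and
per-patch attention export.

Integrated gradients attribute the scalar risk score to each standardized
omics feature along the straight path from a baseline (by default the
zero vector, i.e. the training-cohort mean in standardized space):

    IG_i = (x_i - b_i) * (1/m) * sum_t dF/dx_i |_{b + ((t+0.5)/m)(x-b)}

using the midpoint rule with m steps. The completeness residual
|sum_i IG_i - (F(x) - F(b))| is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .encoders import SlideEmbedding
from .model import TrainedBridge
from .nn import Tensor, concat

__all__ = ["IGResult", "integrated_gradients", "risk_from_omics_fn",
           "rank_features", "export_attention_map"]


@dataclass
class IGResult:
    attributions: np.ndarray
    completeness_residual: float
    delta_f: float   # F(x) - F(baseline)


def integrated_gradients(risk_fn, x: np.ndarray,
                         baseline: np.ndarray | None = None,
                         steps: int = 50) -> IGResult:
    """Midpoint-rule path integral of gradients of `risk_fn`.

    `risk_fn` maps a batched Tensor (B, F) of omics vectors to a (B,)
    Tensor of risks and must be differentiable through the autodiff graph.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = np.asarray(x, dtype=float)
    b = np.zeros_like(x) if baseline is None else np.asarray(baseline,
                                                             dtype=float)
    ts = (np.arange(steps) + 0.5) / steps
    points = b[None, :] + ts[:, None] * (x - b)[None, :]
    pts = Tensor(points, requires_grad=True)
    risks = risk_fn(pts)
    risks.sum().backward()
    avg_grad = pts.grad.mean(axis=0)
    ig = (x - b) * avg_grad
    ends = Tensor(np.stack([x, b]))
    fx, fb = risk_fn(ends).data
    delta = float(fx - fb)
    return IGResult(ig, float(abs(ig.sum() - delta)), delta)


def risk_from_omics_fn(trained: TrainedBridge, h_w_data: np.ndarray):
    """Build F(x) = risk(fuse(h_w, SNN(x))) for a fixed slide embedding.

    For omics-only models the slide embedding is ignored. Returns a
    callable mapping a (B, F) Tensor to a (B,) risk Tensor.
    """
    net = trained.net
    net.eval()

    def fn(x: Tensor) -> Tensor:
        B = x.shape[0]
        h_o = net.omics_encoder.forward(x)
        if net.modality == "multimodal":
            h_w = Tensor(np.tile(h_w_data, (B, 1)))
            z = concat([h_w, h_o], axis=1)
        else:
            z = h_o
        logits = net.head(z)
        h = logits.sigmoid()
        # survival S(j) = prod_{k<=j}(1-h_k) via cumulative sums of logs
        log1mh = (1.0 - h).log()
        nb = logits.shape[-1]
        # lower-triangular ones matrix gives cumulative sums
        tri = Tensor(np.tril(np.ones((nb, nb))))
        logS = log1mh @ tri.transpose()
        return -(logS.exp().sum(axis=-1))

    return fn


def rank_features(ig_matrix: np.ndarray, feature_names: list[str]
                  ) -> pd.DataFrame:
    """Cohort-level attribution table: mean |IG| per feature, descending.

    `ig_matrix` is (patients, features); ranks start at 1.
    """
    ig = np.atleast_2d(np.asarray(ig_matrix, dtype=float))
    if ig.shape[0] < 1:
        raise ValueError("need at least one patient")
    mean_abs = np.abs(ig).mean(axis=0)
    mean_signed = ig.mean(axis=0)
    order = np.argsort(-mean_abs, kind="stable")
    table = pd.DataFrame({
        "feature": np.asarray(feature_names)[order],
        "mean_abs_ig": mean_abs[order],
        "mean_ig": mean_signed[order],
        "rank": np.arange(1, len(order) + 1),
    })
    return table.reset_index(drop=True)


def export_attention_map(slide: SlideEmbedding, coords: np.ndarray,
                         csv_path: str | Path,
                         png_path: str | Path | None = None) -> dict:
    """Write per-patch attention scores as (x, y, score) CSV rows;
    optionally rasterize the grid to a PNG for synthetic fixtures.

    Returns a small report dict; a constant attention vector is flagged
    as an uninformative map.
    """
    if len(slide.attention) != len(coords):
        raise ValueError("attention and coords length mismatch")
    df = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1],
                       "score": slide.attention})
    df.to_csv(csv_path, index=False)
    uninformative = bool(np.all(slide.attention == slide.attention[0]))
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        side_x = int(coords[:, 0].max()) + 1
        side_y = int(coords[:, 1].max()) + 1
        img = np.zeros((side_y, side_x))
        img[coords[:, 1], coords[:, 0]] = slide.attention
        plt.imsave(png_path, img, cmap="inferno", vmin=0.0, vmax=1.0)
    return {"patient_id": slide.patient_id, "n_patches": len(coords),
            "uninformative": uninformative}
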