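"""Receptive fields and the context-dependent/independent neuron taxonomy.

A first-layer hidden neuron's receptive field (RF) is its column of incoming
weights, split into the five visible channels.  For deeper layers the
effective RF is computed by combining the weight matrices of the lower
layers after thresholding each at |w| >= theta (default 0.5) to keep only
the stronger connections, then multiplying the thresholded matrices.

A neuron is context-dependent when the absolute difference between its mean
context-A and mean context-B weights reaches theta_ctx (default 0.3); the
sign of the difference gives its preferred context.  Context-independent
neurons show positively correlated action and stimulus maps for both
colours; context-dependent neurons correlate the action map positively with
the colour their preferred context makes relevant and negatively with the
other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .analysis import RegionMeans, evaluate_condition
from .dbn import DeepNetwork
from .task_data import (
    ACTION_OFFSET,
    CTX_A_OFFSET,
    CTX_B_OFFSET,
    CTX_UNITS,
    Dataset,
    GREEN_OFFSET,
    MAP_UNITS,
    RED_OFFSET,
)

ContextClass = Literal["none", "cA_gt_cB", "cB_gt_cA"]


@dataclass
class ReceptiveField:
    """A neuron's effective incoming weights, split by visible channel."""

    red_map: np.ndarray  # (625,)
    green_map: np.ndarray  # (625,)
    action_map: np.ndarray  # (625,)
    ctx_a: np.ndarray  # (25,)
    ctx_b: np.ndarray  # (25,)

    def concatenate(self) -> np.ndarray:
        """Reassemble the 1925-unit visible-layer vector."""
        return np.concatenate(
            [self.red_map, self.green_map, self.ctx_a, self.ctx_b, self.action_map]
        )


def split_visible(column: np.ndarray) -> ReceptiveField:
    """Split a 1925-long visible-layer vector into the five channels."""
    if column.shape != (ACTION_OFFSET + MAP_UNITS,):
        raise ValueError("expected a 1925-long weight column")
    return ReceptiveField(
        red_map=column[RED_OFFSET : RED_OFFSET + MAP_UNITS].copy(),
        green_map=column[GREEN_OFFSET : GREEN_OFFSET + MAP_UNITS].copy(),
        action_map=column[ACTION_OFFSET : ACTION_OFFSET + MAP_UNITS].copy(),
        ctx_a=column[CTX_A_OFFSET : CTX_A_OFFSET + CTX_UNITS].copy(),
        ctx_b=column[CTX_B_OFFSET : CTX_B_OFFSET + CTX_UNITS].copy(),
    )


def layer1_rf(net: DeepNetwork, j: int) -> ReceptiveField:
    """Receptive field of first-layer neuron j: its raw weight column."""
    w = net.layers[0].weights
    if not 0 <= j < w.shape[1]:
        raise IndexError(f"neuron index {j} out of range for layer of {w.shape[1]}")
    return split_visible(w[:, j])


def _effective_matrix(
    net: DeepNetwork, layer: int, theta: float, threshold_first: bool
) -> np.ndarray:
    """(1925, n_hidden) linear projection of layer ``layer`` to the visible layer."""
    mats = [net.layers[k].weights for k in range(layer)]
    if threshold_first:
        mats = [np.where(np.abs(m) >= theta, m, 0.0) for m in mats]
        prod = mats[0]
        for m in mats[1:]:
            prod = prod @ m
    else:
        prod = mats[0]
        for m in mats[1:]:
            prod = prod @ m
        prod = np.where(np.abs(prod) >= theta, prod, 0.0)
    return prod


def effective_rf(
    net: DeepNetwork,
    layer: int,
    j: int,
    theta: float = 0.5,
    threshold_first: bool = True,
) -> ReceptiveField:
    """Effective receptive field of neuron j in layer 2 or 3.

    Each lower weight matrix is thresholded entrywise (|w| < theta set to 0)
    and the thresholded matrices are multiplied; with
    ``threshold_first=False`` the product is formed first and thresholded
    afterwards.  theta=0 gives the exact linear path sum.
    """
    if layer == 1:
        return layer1_rf(net, j)
    if not 2 <= layer <= net.n_layers:
        raise ValueError(f"layer must be in [1, {net.n_layers}]")
    prod = _effective_matrix(net, layer, theta, threshold_first)
    if not 0 <= j < prod.shape[1]:
        raise IndexError(f"neuron index {j} out of range")
    return split_visible(prod[:, j])


@dataclass
class NeuronClassification:
    """Context class and action-stimulus RF correlations of one neuron."""

    layer: int
    index: int
    context_class: ContextClass
    r_action_red: float
    r_action_green: float
    degenerate: bool = False  # a zero-variance map made a correlation undefined

    @property
    def context_dependent(self) -> bool:
        return self.context_class != "none"


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0, True
    r, _ = stats.pearsonr(x, y)
    return float(r), False


def classify_neuron(
    rf: ReceptiveField, theta_ctx: float = 0.3, layer: int = 0, index: int = 0
) -> NeuronClassification:
    """Classify one neuron from its receptive field.

    s = mean(ctxA weights) - mean(ctxB weights); |s| < theta_ctx -> context
    independent ('none'); otherwise the sign gives the preferred context.
    """
    s = float(rf.ctx_a.mean() - rf.ctx_b.mean())
    if abs(s) < theta_ctx:
        cls: ContextClass = "none"
    elif s > 0:
        cls = "cA_gt_cB"
    else:
        cls = "cB_gt_cA"
    r_red, d1 = _safe_pearson(rf.action_map, rf.red_map)
    r_green, d2 = _safe_pearson(rf.action_map, rf.green_map)
    return NeuronClassification(
        layer=layer,
        index=index,
        context_class=cls,
        r_action_red=r_red,
        r_action_green=r_green,
        degenerate=d1 or d2,
    )


def classify_network(
    net: DeepNetwork, theta: float = 0.5, theta_ctx: float = 0.3
) -> list[NeuronClassification]:
    """Classify every hidden neuron of every layer."""
    out: list[NeuronClassification] = []
    for layer_idx in range(net.n_layers):
        layer_no = layer_idx + 1
        if layer_no == 1:
            cols = net.layers[0].weights
        else:
            cols = _effective_matrix(net, layer_no, theta, threshold_first=True)
        for j in range(cols.shape[1]):
            rf = split_visible(cols[:, j])
            out.append(classify_neuron(rf, theta_ctx, layer=layer_no, index=j))
    return out


def classification_table(classes: list[NeuronClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "layer": [c.layer for c in classes],
            "index": [c.index for c in classes],
            "context_class": [c.context_class for c in classes],
            "r_action_red": [c.r_action_red for c in classes],
            "r_action_green": [c.r_action_green for c in classes],
        }
    )


def classify_population(
    net: DeepNetwork, theta: float = 0.5, theta_ctx: float = 0.3
) -> dict[int, dict[str, float]]:
    """Per-layer fractions of each context class.

    ``context_dependent`` aggregates cA_gt_cB and cB_gt_cA.
    """
    classes = classify_network(net, theta, theta_ctx)
    out: dict[int, dict[str, float]] = {}
    for layer_no in sorted({c.layer for c in classes}):
        sub = [c for c in classes if c.layer == layer_no]
        n = len(sub)
        props = {
            cls: sum(c.context_class == cls for c in sub) / n
            for cls in ("none", "cA_gt_cB", "cB_gt_cA")
        }
        props["context_dependent"] = props["cA_gt_cB"] + props["cB_gt_cA"]
        out[layer_no] = props
    return out


def class_filter(
    net: DeepNetwork,
    keep: Literal["context_independent", "context_dependent"],
    theta: float = 0.5,
    theta_ctx: float = 0.3,
) -> list[np.ndarray]:
    """Per-layer keep masks (1 = active) selecting one neuron class."""
    if keep not in ("context_independent", "context_dependent"):
        raise ValueError(f"unknown class {keep!r}")
    classes = classify_network(net, theta, theta_ctx)
    masks = []
    for layer_idx in range(net.n_layers):
        layer_no = layer_idx + 1
        sub = sorted(
            (c for c in classes if c.layer == layer_no), key=lambda c: c.index
        )
        dep = np.array([c.context_dependent for c in sub])
        masks.append(
            dep.astype(float) if keep == "context_dependent" else (~dep).astype(float)
        )
    return masks


def class_ablation(
    net: DeepNetwork,
    keep: Literal["context_independent", "context_dependent"],
    test_set: Dataset,
    theta: float = 0.5,
    theta_ctx: float = 0.3,
) -> RegionMeans:
    """Reconstruction quality when only one neuron class is allowed to operate.

    Excluded neurons have their activations zeroed in all hidden layers on
    both the up and down passes.
    """
    filt = class_filter(net, keep, theta, theta_ctx)
    return evaluate_condition(net, test_set, depth=net.n_layers, class_filter=filt)
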