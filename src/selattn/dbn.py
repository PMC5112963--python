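"""Restricted Boltzmann Machine stack with CD-1 learning.

The generative model is a stack of RBMs (1925 -> 300 -> 200 -> 100 by
default), trained greedily layer by layer with one-step contrastive
divergence (CD-1) and per-epoch dropout of hidden units.  Each layer pair is
fully connected through a single symmetric weight matrix used for both the
recognition (up) and generative (down) passes.

Training follows the online update rule

    dw_ij = eps * (v+_i h+_j - v-_i h-_j)

applied per pattern, where (v+, h+) are data-driven activities and (v-, h-)
are the one-step reconstruction-driven activities.  Hidden and visible
biases are trained with the same rate.  Dropout excludes each hidden unit
from computation and learning for an entire epoch with probability p.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.linalg.blas import dger
from scipy.special import expit as logistic  # noqa: F401  (re-exported)

DEFAULT_LAYER_SIZES = (300, 200, 100)


@dataclass
class TrainingConfig:
    """Hyperparameters of the greedy layer-wise CD-1 training.

    epochs
        Training epochs per layer (each epoch presents every pattern once).
    learning_rate
        Per-pattern step size eps; 0.002 with dropout, 0.0002 without.
    dropout_p
        Probability that a hidden unit is dropped for a whole epoch (0.5;
        0 disables dropout).
    sampling
        ``bernoulli_hidden``: positive-phase hidden states are sampled as
        Bernoulli(h+) to drive the negative phase, while all statistics use
        probabilities.  ``all_probabilities``: fully deterministic mean-field
        CD (used by small enumeration tests).
    test_scale
        How dropout is compensated at test time: ``none`` keeps activations
        as computed; ``retention`` multiplies every hidden activation by the
        retention probability (1 - dropout_p).
    minibatch_size
        1 (online) by default; larger values accumulate the summed update of
        a minibatch in one rank-k step (an optimisation knob, not used by
        the study configurations).
    """

    epochs: int = 500
    learning_rate: float = 0.002
    dropout_p: float = 0.5
    layer_sizes: tuple[int, ...] = DEFAULT_LAYER_SIZES
    minibatch_size: int = 1
    sampling: str = "bernoulli_hidden"
    test_scale: str = "none"
    connectivity: str = "full"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.sampling not in ("bernoulli_hidden", "all_probabilities"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")
        if self.test_scale not in ("none", "retention"):
            raise ValueError(f"unknown test_scale {self.test_scale!r}")

    @property
    def retention_p(self) -> float:
        return 1.0 - self.dropout_p


@dataclass
class RBMLayer:
    """One visible/hidden layer pair with symmetric weights.

    ``weights`` has shape (n_visible, n_hidden) and is shared by the up and
    down passes.  ``connectivity_mask`` (same shape, optional) pins the
    masked entries to exactly 0 through initialisation and training — used
    by the modular-architecture control.
    """

    weights: np.ndarray
    hidden_bias: np.ndarray
    visible_bias: np.ndarray
    connectivity_mask: Optional[np.ndarray] = None

    @property
    def n_visible(self) -> int:
        return self.weights.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.weights.shape[1]

    @classmethod
    def initialize(
        cls,
        n_visible: int,
        n_hidden: int,
        rng: np.random.Generator,
        connectivity_mask: Optional[np.ndarray] = None,
        weight_sigma: float = 0.1,
    ) -> "RBMLayer":
        """Weights ~ Normal(0, 0.1); all biases 0."""
        w = rng.normal(0.0, weight_sigma, size=(n_visible, n_hidden))
        if connectivity_mask is not None:
            if connectivity_mask.shape != w.shape:
                raise ValueError("connectivity mask shape mismatch")
            w *= connectivity_mask
        # Fortran order so BLAS rank-1 updates run in place.
        return cls(
            weights=np.asfortranarray(w),
            hidden_bias=np.zeros(n_hidden),
            visible_bias=np.zeros(n_visible),
            connectivity_mask=connectivity_mask,
        )

    def copy(self) -> "RBMLayer":
        return RBMLayer(
            weights=self.weights.copy(order="F"),
            hidden_bias=self.hidden_bias.copy(),
            visible_bias=self.visible_bias.copy(),
            connectivity_mask=None
            if self.connectivity_mask is None
            else self.connectivity_mask.copy(),
        )


def up_pass(
    layer: RBMLayer, v: np.ndarray, dropout_mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """Hidden probabilities h_j = logistic(sum_i w_ij v_i + b_j).

    ``v`` may be a single vector or a (n, n_visible) batch.  Dropped hidden
    units (mask entry 0) output exactly 0.
    """
    if v.shape[-1] != layer.n_visible:
        raise ValueError(
            f"visible dimension mismatch: got {v.shape[-1]}, "
            f"expected {layer.n_visible}"
        )
    h = logistic(v @ layer.weights + layer.hidden_bias)
    if dropout_mask is not None:
        h = h * dropout_mask
    return h


def down_pass(layer: RBMLayer, h: np.ndarray) -> np.ndarray:
    """Visible probabilities v_i = logistic(sum_j w_ij h_j + c_i)."""
    if h.shape[-1] != layer.n_hidden:
        raise ValueError(
            f"hidden dimension mismatch: got {h.shape[-1]}, "
            f"expected {layer.n_hidden}"
        )
    return logistic(h @ layer.weights.T + layer.visible_bias)


def cd1_step(
    layer: RBMLayer,
    v_plus: np.ndarray,
    eps: float,
    dropout_mask: Optional[np.ndarray],
    rng: np.random.Generator,
    sampling: str = "bernoulli_hidden",
) -> float:
    """One online CD-1 update, in place.  Returns the reconstruction error.

    Positive phase: h+ = up(v+); hidden states driving the negative phase
    are Bernoulli(h+) samples (or the probabilities themselves under
    ``all_probabilities``).  Negative phase: v- = down(h_states),
    h- = up(v-), both probabilities.  Statistics use probabilities on both
    sides; the error returned is mean |v+ - v-|.
    """
    h_plus = up_pass(layer, v_plus, dropout_mask)
    if sampling == "bernoulli_hidden":
        h_states = (rng.random(layer.n_hidden) < h_plus).astype(float)
    else:
        h_states = h_plus
    v_minus = down_pass(layer, h_states)
    h_minus = up_pass(layer, v_minus, dropout_mask)

    if layer.connectivity_mask is not None:
        delta = eps * (
            v_plus[:, None] * h_plus[None, :] - v_minus[:, None] * h_minus[None, :]
        )
        layer.weights += delta * layer.connectivity_mask
    else:
        dger(eps, v_plus, h_plus, a=layer.weights, overwrite_a=1)
        dger(-eps, v_minus, h_minus, a=layer.weights, overwrite_a=1)
    layer.hidden_bias += eps * (h_plus - h_minus)
    layer.visible_bias += eps * (v_plus - v_minus)
    return float(np.mean(np.abs(v_plus - v_minus)))


def _cd1_minibatch(
    layer: RBMLayer,
    v_plus: np.ndarray,
    eps: float,
    dropout_mask: Optional[np.ndarray],
    rng: np.random.Generator,
    sampling: str,
) -> float:
    """Summed CD-1 update for a (m, n_visible) minibatch."""
    h_plus = up_pass(layer, v_plus, dropout_mask)
    if sampling == "bernoulli_hidden":
        h_states = (rng.random(h_plus.shape) < h_plus).astype(float)
    else:
        h_states = h_plus
    v_minus = down_pass(layer, h_states)
    h_minus = up_pass(layer, v_minus, dropout_mask)
    delta = eps * (v_plus.T @ h_plus - v_minus.T @ h_minus)
    if layer.connectivity_mask is not None:
        delta *= layer.connectivity_mask
    layer.weights += delta
    layer.hidden_bias += eps * (h_plus - h_minus).sum(axis=0)
    layer.visible_bias += eps * (v_plus - v_minus).sum(axis=0)
    return float(np.mean(np.abs(v_plus - v_minus)))


def train_layer(
    layer: RBMLayer,
    data: np.ndarray,
    config: TrainingConfig,
    rng: np.random.Generator,
) -> list[float]:
    """Train one RBM with CD-1; returns the per-epoch mean reconstruction error.

    Each epoch draws one dropout mask (each hidden unit dropped with
    probability p for the whole epoch), shuffles the pattern order, and
    applies the update per pattern.
    """
    if len(data) == 0:
        raise ValueError("training data is empty")
    log: list[float] = []
    for _ in range(config.epochs):
        if config.dropout_p > 0:
            mask = (rng.random(layer.n_hidden) >= config.dropout_p).astype(float)
        else:
            mask = None
        order = rng.permutation(len(data))
        errs = 0.0
        if config.minibatch_size <= 1:
            for i in order:
                errs += cd1_step(
                    layer, data[i], config.learning_rate, mask, rng, config.sampling
                )
            log.append(errs / len(data))
        else:
            n_batches = 0
            for start in range(0, len(order), config.minibatch_size):
                batch = data[order[start : start + config.minibatch_size]]
                errs += _cd1_minibatch(
                    layer, batch, config.learning_rate, mask, rng, config.sampling
                )
                n_batches += 1
            log.append(errs / n_batches)
    return log


@dataclass
class DeepNetwork:
    """Greedily trained stack of RBMs (default 1925 -> 300 -> 200 -> 100)."""

    layers: list[RBMLayer]
    config: TrainingConfig = field(default_factory=TrainingConfig)

    def __post_init__(self) -> None:
        for lower, upper in zip(self.layers, self.layers[1:]):
            if lower.n_hidden != upper.n_visible:
                raise ValueError(
                    f"adjacent layer dims mismatch: {lower.n_hidden} != "
                    f"{upper.n_visible}"
                )

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @classmethod
    def initialize(
        cls,
        n_visible: int,
        config: TrainingConfig,
        rng: np.random.Generator,
        connectivity_masks: Optional[Sequence[Optional[np.ndarray]]] = None,
    ) -> "DeepNetwork":
        dims = (n_visible,) + tuple(config.layer_sizes)
        if connectivity_masks is None:
            connectivity_masks = [None] * len(config.layer_sizes)
        layers = [
            RBMLayer.initialize(nv, nh, rng, connectivity_mask=m)
            for nv, nh, m in zip(dims, dims[1:], connectivity_masks)
        ]
        return cls(layers=layers, config=config)

    def copy(self) -> "DeepNetwork":
        return DeepNetwork(
            layers=[l.copy() for l in self.layers], config=replace(self.config)
        )

    def save(self, path: str) -> None:
        arrays = {}
        for k, layer in enumerate(self.layers):
            arrays[f"w{k}"] = np.ascontiguousarray(layer.weights)
            arrays[f"bh{k}"] = layer.hidden_bias
            arrays[f"bv{k}"] = layer.visible_bias
            if layer.connectivity_mask is not None:
                arrays[f"mask{k}"] = layer.connectivity_mask
        np.savez_compressed(path, n_layers=self.n_layers, **arrays)

    @classmethod
    def load(cls, path: str, config: Optional[TrainingConfig] = None) -> "DeepNetwork":
        with np.load(path) as data:
            n = int(data["n_layers"])
            layers = [
                RBMLayer(
                    weights=np.asfortranarray(data[f"w{k}"]),
                    hidden_bias=data[f"bh{k}"],
                    visible_bias=data[f"bv{k}"],
                    connectivity_mask=data[f"mask{k}"]
                    if f"mask{k}" in data
                    else None,
                )
                for k in range(n)
            ]
        cfg = config or TrainingConfig(
            layer_sizes=tuple(l.n_hidden for l in layers)
        )
        return cls(layers=layers, config=cfg)


def train_network(
    net: DeepNetwork,
    data: np.ndarray,
    rng: np.random.Generator,
    config: Optional[TrainingConfig] = None,
    progress: Optional[callable] = None,
) -> list[list[float]]:
    """Greedy layer-wise training; returns one error log per layer.

    Layer 1 trains on the data; the data is then propagated through the
    trained layer as deterministic probabilities (no dropout, no sampling)
    to form the training input of the next layer, and so on.  Each layer
    receives the full epoch budget.
    """
    config = config or net.config
    logs: list[list[float]] = []
    acts = data
    for k, layer in enumerate(net.layers):
        logs.append(train_layer(layer, acts, config, rng))
        if progress is not None:
            progress(k, logs[-1])
        if k + 1 < net.n_layers:
            acts = up_pass(layer, acts)
    return logs


ClassFilter = Sequence[Optional[np.ndarray]]  # per-layer keep mask (1=active)


def _apply_hidden_mods(
    h: np.ndarray,
    layer_idx: int,
    net: DeepNetwork,
    class_filter: Optional[ClassFilter],
    scale: float,
) -> np.ndarray:
    if class_filter is not None and class_filter[layer_idx] is not None:
        h = h * class_filter[layer_idx]
    if scale != 1.0:
        h = h * scale
    return h


def reconstruct(
    net: DeepNetwork,
    v_in: np.ndarray,
    depth: int = 3,
    class_filter: Optional[ClassFilter] = None,
) -> np.ndarray:
    """Deterministic mean-field reconstruction through ``depth`` layers.

    Propagates probabilities up through layers 1..depth and back down (no
    sampling, no dropout).  ``class_filter`` zeroes the activations of
    excluded hidden neurons in every layer on both passes.  Under
    ``test_scale='retention'`` every hidden activation is multiplied by the
    dropout retention probability.  Accepts a single vector or a batch.
    """
    if not 1 <= depth <= net.n_layers:
        raise ValueError(f"depth must be in [1, {net.n_layers}]")
    scale = (
        net.config.retention_p if net.config.test_scale == "retention" else 1.0
    )
    acts = v_in
    for k in range(depth):
        acts = up_pass(net.layers[k], acts)
        acts = _apply_hidden_mods(acts, k, net, class_filter, scale)
    for k in reversed(range(depth)):
        acts = down_pass(net.layers[k], acts)
        if k > 0:  # intermediate results are hidden activations of layer k-1
            acts = _apply_hidden_mods(acts, k - 1, net, class_filter, scale)
    return acts


def iterate_generation(
    net: DeepNetwork,
    v0: np.ndarray,
    steps: int,
    class_filter: Optional[ClassFilter] = None,
) -> list[np.ndarray]:
    """Let the network run on its own reconstructions.

    x_1 = reconstruct(v0); x_{t+1} = reconstruct(x_t).  Returns
    [x_1, ..., x_steps].
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    out = []
    x = v0
    for _ in range(steps):
        x = reconstruct(net, x, depth=net.n_layers, class_filter=class_filter)
        out.append(x)
    return out


def free_energy_unnormalized_prob(layer: RBMLayer, v: np.ndarray) -> float:
    """Unnormalized probability of a visible configuration.

    p*(v) = sum_h exp(-E(v, h)) with
    E(v, h) = -v'Wh - c'v - b'h; computed by brute-force enumeration of all
    hidden states, so only usable on tiny RBMs (diagnostic/test helper).
    """
    nh = layer.n_hidden
    total = 0.0
    for code in range(2**nh):
        h = np.array([(code >> j) & 1 for j in range(nh)], dtype=float)
        energy = -(
            v @ layer.weights @ h + layer.visible_bias @ v + layer.hidden_bias @ h
        )
        total += np.exp(-energy)
    return float(total)


def modular_masks(
    visible_blocks: Sequence[int],
    hidden_block_plan: Sequence[Optional[Sequence[int]]],
) -> list[Optional[np.ndarray]]:
    """Block-diagonal connectivity masks for the modular control architecture.

    ``visible_blocks`` partitions the visible layer (e.g. stimuli/context/
    action = 1250/50/625); each entry of ``hidden_block_plan`` is either a
    partition of that layer's hidden units into the same number of blocks,
    or None for full connectivity.  Each layer's hidden partition becomes
    the visible partition of the next layer.
    """
    masks: list[Optional[np.ndarray]] = []
    vis = list(visible_blocks)
    for plan in hidden_block_plan:
        if plan is None:
            masks.append(None)
            vis = [sum(vis)]
            continue
        if len(plan) != len(vis):
            raise ValueError("hidden block count must match visible block count")
        mask = np.zeros((sum(vis), sum(plan)))
        r = c = 0
        for nv, nh in zip(vis, plan):
            mask[r : r + nv, c : c + nh] = 1.0
            r += nv
            c += nh
        masks.append(mask)
        vis = list(plan)
    return masks
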