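"""Region-wise reconstruction metrics and network-level experiments.

Evaluation uses double-stimulus test patterns.  The 1925 visible units are
partitioned, per pattern, into seven disjoint regions: the 25 units of the
context-relevant stimulus square, the 25 of the irrelevant stimulus square,
the 25 action units at the relevant location (correct action), the 25 at the
irrelevant location (incorrect action), the two 25-unit context blocks
(correct and incorrect), and all remaining units.  The headline selective
attention effect is a higher mean reconstruction over the relevant-stimulus
region than over the irrelevant one.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
from scipy import stats

from .dbn import ClassFilter, DeepNetwork, iterate_generation, reconstruct
from .task_data import (
    CTX_A_OFFSET,
    CTX_B_OFFSET,
    CTX_UNITS,
    Dataset,
    N_VISIBLE,
    PatternSpec,
    square_indices,
)

REGION_NAMES = (
    "relevant_stim",
    "irrelevant_stim",
    "correct_action",
    "incorrect_action",
    "correct_context",
    "incorrect_context",
    "remaining",
)


@dataclass(frozen=True)
class RegionMeans:
    """Mean activation over each of the seven evaluation regions."""

    relevant_stim: float
    irrelevant_stim: float
    correct_action: float
    incorrect_action: float
    correct_context: float
    incorrect_context: float
    remaining: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in REGION_NAMES])

    @classmethod
    def from_array(cls, a: np.ndarray) -> "RegionMeans":
        return cls(**{n: float(x) for n, x in zip(REGION_NAMES, a)})


def region_masks(spec: PatternSpec) -> dict[str, np.ndarray]:
    """The seven disjoint index sets for a double-stimulus trial.

    Raises for single-stimulus specs (the irrelevant region is undefined).
    The sets partition {0..1924}.
    """
    if not spec.double_stimulus:
        raise ValueError("region masks are defined only for double-stimulus specs")
    rel_colour = "red" if spec.context == "A" else "green"
    irr_colour = "green" if spec.context == "A" else "red"
    rel_pos, irr_pos = spec.relevant_pos, spec.irrelevant_pos
    ctx_corr = CTX_A_OFFSET if spec.context == "A" else CTX_B_OFFSET
    ctx_inc = CTX_B_OFFSET if spec.context == "A" else CTX_A_OFFSET
    masks = {
        "relevant_stim": square_indices(rel_pos, rel_colour),
        "irrelevant_stim": square_indices(irr_pos, irr_colour),
        "correct_action": square_indices(rel_pos, "action"),
        "incorrect_action": square_indices(irr_pos, "action"),
        "correct_context": np.arange(ctx_corr, ctx_corr + CTX_UNITS),
        "incorrect_context": np.arange(ctx_inc, ctx_inc + CTX_UNITS),
    }
    named = np.concatenate(list(masks.values()))
    masks["remaining"] = np.setdiff1d(np.arange(N_VISIBLE), named)
    return masks


def region_means(recon: np.ndarray, spec: PatternSpec) -> RegionMeans:
    """Arithmetic mean of a reconstruction over each region."""
    if recon.shape[-1] != N_VISIBLE:
        raise ValueError("reconstruction length mismatch")
    masks = region_masks(spec)
    return RegionMeans(
        **{name: float(recon[idx].mean()) for name, idx in masks.items()}
    )


def _batch_region_means(recons: np.ndarray, specs: list[PatternSpec]) -> np.ndarray:
    """(n, 7) per-pattern region means for a batch of reconstructions."""
    out = np.empty((len(specs), len(REGION_NAMES)))
    for i, (recon, spec) in enumerate(zip(recons, specs)):
        masks = region_masks(spec)
        for j, name in enumerate(REGION_NAMES):
            out[i, j] = recon[masks[name]].mean()
    return out


def evaluate_condition(
    net: DeepNetwork,
    test_set: Dataset,
    depth: int = 3,
    class_filter: Optional[ClassFilter] = None,
) -> RegionMeans:
    """Average region means of the network reconstructions of a test set."""
    recons = reconstruct(net, test_set.vectors, depth=depth, class_filter=class_filter)
    per_pattern = _batch_region_means(recons, test_set.specs)
    return RegionMeans.from_array(per_pattern.mean(axis=0))


@dataclass
class ReplicationSet:
    """Per-replication region means for one condition (one row per network)."""

    means: list[RegionMeans]
    condition: str
    seeds: list[int]

    def field(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.means])

    def mean(self, name: str) -> float:
        return float(self.field(name).mean())

    def sd(self, name: str) -> float:
        return float(self.field(name).std(ddof=1))


def compare_conditions(
    a: ReplicationSet | np.ndarray,
    b: ReplicationSet | np.ndarray,
    a_field: Optional[str] = None,
    b_field: Optional[str] = None,
    paired: bool = True,
) -> tuple[float, float]:
    """Two-tailed t-test between two replication samples.

    Replications play the role of individuals; the test is paired when both
    samples come from the same trained networks (the default), independent
    otherwise.  Returns (t, p).
    """
    xa = a.field(a_field) if isinstance(a, ReplicationSet) else np.asarray(a)
    xb = b.field(b_field or a_field) if isinstance(b, ReplicationSet) else np.asarray(b)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need at least two replications per sample")
    if paired:
        if len(xa) != len(xb):
            raise ValueError("paired test requires equal replication counts")
        if np.array_equal(xa, xb):
            return 0.0, 1.0
        t, p = stats.ttest_rel(xa, xb)
    else:
        t, p = stats.ttest_ind(xa, xb)
    return float(t), float(p)


def run_layer_ablation(
    net: DeepNetwork, test_set: Dataset
) -> dict[int, RegionMeans]:
    """Reconstruction quality when only the first k layers operate, k=1..3."""
    return {
        depth: evaluate_condition(net, test_set, depth=depth)
        for depth in range(1, net.n_layers + 1)
    }


def run_iterative_generation(
    net: DeepNetwork, test_set: Dataset, steps: int = 5
) -> list[RegionMeans]:
    """Average region means after 1..steps self-generated processing steps."""
    seq = iterate_generation(net, test_set.vectors, steps)
    return [
        RegionMeans.from_array(_batch_region_means(x, test_set.specs).mean(axis=0))
        for x in seq
    ]


def replication_set(
    nets: list[DeepNetwork],
    test_set: Dataset,
    condition: str,
    seeds: Optional[list[int]] = None,
    depth: int = 3,
    class_filter: Optional[ClassFilter] = None,
) -> ReplicationSet:
    """Evaluate each replication network on a shared test set."""
    means = [
        evaluate_condition(net, test_set, depth=depth, class_filter=class_filter)
        for net in nets
    ]
    return ReplicationSet(
        means=means, condition=condition, seeds=seeds or list(range(len(nets)))
    )
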