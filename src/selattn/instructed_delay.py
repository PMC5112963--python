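"""Instructed-delay protocol: staggered presentation of stimuli and context.

The trained network is probed over eight processing steps.  One item (the
two stimuli together, or the context cue) is presented externally for two
steps, followed by a two-step blank, then the other item for two steps and
a final blank.  The action channel is never provided.  From step 2 on, the
input is a 9:1 mixture of the external template and the network's previous
reconstruction, so self-generated activity persists through the blanks.

This mirrors primate instructed-delay reaching experiments in which both
candidate actions are represented until the context cue resolves the
choice (stimuli-first order), while a context presented first allows the
correct action alone to rise as soon as the stimuli appear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .analysis import REGION_NAMES, RegionMeans, _batch_region_means, compare_conditions
from .dbn import DeepNetwork, reconstruct
from .task_data import (
    CTX_A_OFFSET,
    CTX_B_OFFSET,
    CTX_UNITS,
    N_VISIBLE,
    PatternSpec,
    square_indices,
)

N_STEPS = 8
EXTERNAL_WEIGHT = 0.9  # external fraction of the mixed input from step 2 on

Order = Literal["stimuli_first", "context_first"]


@dataclass
class Schedule:
    """Per-step external input templates (8 x 1925) for one trial."""

    spec: PatternSpec
    order: Order
    external: np.ndarray  # (8, 1925)


def _stimuli_vector(spec: PatternSpec) -> np.ndarray:
    v = np.zeros(N_VISIBLE)
    v[square_indices(spec.red_pos, "red")] = 1.0
    v[square_indices(spec.green_pos, "green")] = 1.0
    return v


def _context_vector(spec: PatternSpec) -> np.ndarray:
    v = np.zeros(N_VISIBLE)
    off = CTX_A_OFFSET if spec.context == "A" else CTX_B_OFFSET
    v[off : off + CTX_UNITS] = 1.0
    return v


def build_schedule(spec: PatternSpec, order: Order) -> Schedule:
    """Steps 1-2: first item; 3-4: blank; 5-6: second item; 7-8: blank.

    In ``stimuli_first`` the stimulus maps come first and the context block
    second; ``context_first`` reverses the roles.  Unpresented channels are
    externally 0 (in particular the context blocks carry no 1/0 code during
    stimulus-only steps), and the action channel is zero at every step.
    """
    if not spec.double_stimulus:
        raise ValueError("instructed-delay trials require double-stimulus specs")
    if order not in ("stimuli_first", "context_first"):
        raise ValueError(f"unknown order {order!r}")
    stim, ctx = _stimuli_vector(spec), _context_vector(spec)
    first, second = (stim, ctx) if order == "stimuli_first" else (ctx, stim)
    blank = np.zeros(N_VISIBLE)
    external = np.stack([first, first, blank, blank, second, second, blank, blank])
    return Schedule(spec=spec, order=order, external=external)


@dataclass
class TimeCourse:
    """Region means at each of the eight steps (+ optional reconstructions)."""

    steps: list[RegionMeans]
    reconstructions: Optional[np.ndarray] = None  # (8, 1925) if retained

    def field(self, name: str) -> np.ndarray:
        return np.array([getattr(s, name) for s in self.steps])


def run_trial(
    net: DeepNetwork, schedule: Schedule, keep_reconstructions: bool = False
) -> TimeCourse:
    """Run one instructed-delay trial.

    input_1 = ext_1; for t >= 2, input_t = 0.9*ext_t + 0.1*recon_{t-1};
    recon_t = reconstruct(input_t) through the full stack.
    """
    recons = np.empty((N_STEPS, N_VISIBLE))
    prev = None
    for t in range(N_STEPS):
        ext = schedule.external[t]
        inp = ext if prev is None else EXTERNAL_WEIGHT * ext + (1 - EXTERNAL_WEIGHT) * prev
        prev = reconstruct(net, inp, depth=net.n_layers)
        recons[t] = prev
    from .analysis import region_means

    steps = [region_means(r, schedule.spec) for r in recons]
    return TimeCourse(steps=steps, reconstructions=recons if keep_reconstructions else None)


def _run_trials_batched(
    net: DeepNetwork, specs: list[PatternSpec], order: Order
) -> np.ndarray:
    """(n_trials, 8, 7) per-step region means, computed with batched passes."""
    ext = np.stack([build_schedule(s, order).external for s in specs])  # (n,8,1925)
    n = len(specs)
    out = np.empty((n, N_STEPS, len(REGION_NAMES)))
    prev = None
    for t in range(N_STEPS):
        inp = ext[:, t]
        if prev is not None:
            inp = EXTERNAL_WEIGHT * inp + (1 - EXTERNAL_WEIGHT) * prev
        prev = reconstruct(net, inp, depth=net.n_layers)
        out[:, t, :] = _batch_region_means(prev, specs)
    return out


@dataclass
class ExperimentResult:
    """Averaged instructed-delay time course over trials and replications."""

    order: Order
    per_net: np.ndarray  # (n_nets, 8, 7): trial-averaged region means per net
    mean: TimeCourse  # averaged over nets

    def net_field(self, name: str) -> np.ndarray:
        """(n_nets, 8) per-net time course of one region."""
        return self.per_net[:, :, REGION_NAMES.index(name)]

    def stepwise_test(self, field_a: str, field_b: str) -> list[tuple[float, float]]:
        """Paired t-test between two regions at each step, across nets."""
        return [
            compare_conditions(
                self.net_field(field_a)[:, t], self.net_field(field_b)[:, t]
            )
            for t in range(N_STEPS)
        ]


def run_experiment(
    nets: list[DeepNetwork],
    order: Order,
    n_trials: int = 1000,
    rng: Optional[np.random.Generator] = None,
    specs: Optional[list[PatternSpec]] = None,
) -> ExperimentResult:
    """Average the protocol over fresh double-stimulus trials and replications.

    Trials are balanced over contexts.  All replications see the same trials.
    """
    if specs is None:
        if rng is None:
            raise ValueError("provide either specs or an rng")
        from .task_data import sample_spec

        specs = [
            sample_spec(rng, True, ctx)
            for ctx in ("A", "B")
            for _ in range(n_trials // 2)
        ]
    per_net = np.stack(
        [_run_trials_batched(net, specs, order).mean(axis=0) for net in nets]
    )
    mean_steps = [
        RegionMeans.from_array(per_net[:, t, :].mean(axis=0)) for t in range(N_STEPS)
    ]
    return ExperimentResult(order=order, per_net=per_net, mean=TimeCourse(mean_steps))
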