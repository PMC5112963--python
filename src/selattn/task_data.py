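"""Synthetic context-dependent stimulus/action dataset.

The visible layer of the network is a 1925-unit binary vector laid out as the
ordered concatenation of five channels:

====================  ======  ==========================================
channel               units   content
====================  ======  ==========================================
red map               625     25x25 grid, a red 5x5 square stimulus
green map             625     25x25 grid, a green 5x5 square stimulus
context A block       25      all 1.0 when context A is active, else 0.0
context B block       25      all 1.0 when context B is active, else 0.0
action map            625     25x25 grid, a 5x5 square at the location of
                              the context-relevant stimulus
====================  ======  ==========================================

Stimuli are 5x5 blocks of ones placed at a random position inside the 25x25
grid (441 admissible top-left corners).  In context A the red stimulus is
relevant and the action targets the red location; in context B the green
stimulus is relevant.  When both stimuli are present their footprints never
overlap spatially (enforced by rejection sampling).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

# Channel geometry (row-major 25x25 maps; channel order is fixed).
GRID = 25
SQUARE = 5
MAX_CORNER = GRID - SQUARE  # 20
N_POSITIONS = (MAX_CORNER + 1) ** 2  # 441 admissible top-left corners
MAP_UNITS = GRID * GRID  # 625
CTX_UNITS = 25

RED_OFFSET = 0
GREEN_OFFSET = MAP_UNITS
CTX_A_OFFSET = 2 * MAP_UNITS
CTX_B_OFFSET = 2 * MAP_UNITS + CTX_UNITS
ACTION_OFFSET = 2 * MAP_UNITS + 2 * CTX_UNITS
N_VISIBLE = ACTION_OFFSET + MAP_UNITS  # 1925

CHANNEL_OFFSETS = {"red": RED_OFFSET, "green": GREEN_OFFSET, "action": ACTION_OFFSET}

Channel = Literal["red", "green", "action"]
Context = Literal["A", "B"]

# Corners used by the two-locations control condition.
TOP_LEFT = (0, 0)
BOTTOM_RIGHT = (MAX_CORNER, MAX_CORNER)


@dataclass(frozen=True)
class GridPosition:
    """Top-left corner of a 5x5 square inside the 25x25 grid (0-based)."""

    row: int
    col: int

    def __post_init__(self) -> None:
        if not 0 <= self.row <= MAX_CORNER:
            raise ValueError(f"row {self.row} out of range [0, {MAX_CORNER}]")
        if not 0 <= self.col <= MAX_CORNER:
            raise ValueError(f"col {self.col} out of range [0, {MAX_CORNER}]")


def positions_overlap(a: GridPosition, b: GridPosition) -> bool:
    """True when the two 5x5 footprints share at least one grid cell."""
    return abs(a.row - b.row) < SQUARE and abs(a.col - b.col) < SQUARE


@dataclass(frozen=True)
class PatternSpec:
    """Symbolic description of one trial.

    The action, when present, always targets the location of the stimulus
    whose colour matches the active context (red in A, green in B); that
    stimulus is always present.
    """

    context: Context
    red_pos: Optional[GridPosition] = None
    green_pos: Optional[GridPosition] = None
    action_present: bool = True

    def __post_init__(self) -> None:
        if self.red_pos is None and self.green_pos is None:
            raise ValueError("at least one stimulus must be present")
        if self.context == "A" and self.red_pos is None:
            raise ValueError("context A requires the red stimulus")
        if self.context == "B" and self.green_pos is None:
            raise ValueError("context B requires the green stimulus")
        if (
            self.red_pos is not None
            and self.green_pos is not None
            and positions_overlap(self.red_pos, self.green_pos)
        ):
            raise ValueError("red and green footprints overlap")

    @property
    def action_pos(self) -> GridPosition:
        pos = self.red_pos if self.context == "A" else self.green_pos
        assert pos is not None
        return pos

    @property
    def relevant_pos(self) -> GridPosition:
        return self.action_pos

    @property
    def irrelevant_pos(self) -> Optional[GridPosition]:
        return self.green_pos if self.context == "A" else self.red_pos

    @property
    def double_stimulus(self) -> bool:
        return self.red_pos is not None and self.green_pos is not None

    def to_dict(self) -> dict:
        def _pos(p):
            return None if p is None else [p.row, p.col]

        return {
            "context": self.context,
            "red_pos": _pos(self.red_pos),
            "green_pos": _pos(self.green_pos),
            "action_present": self.action_present,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatternSpec":
        def _pos(p):
            return None if p is None else GridPosition(*p)

        return cls(
            context=d["context"],
            red_pos=_pos(d["red_pos"]),
            green_pos=_pos(d["green_pos"]),
            action_present=d["action_present"],
        )


def square_indices(pos: GridPosition, channel: Channel) -> np.ndarray:
    """Flat visible-vector indices of the 25 cells of a 5x5 square.

    Indices are row-major within the channel's 25x25 map and offset by the
    channel's position in the 1925-unit layout.
    """
    if channel not in CHANNEL_OFFSETS:
        raise ValueError(f"unknown channel {channel!r}")
    rows = np.arange(pos.row, pos.row + SQUARE)
    cols = np.arange(pos.col, pos.col + SQUARE)
    cells = (rows[:, None] * GRID + cols[None, :]).ravel()
    return cells + CHANNEL_OFFSETS[channel]


def render(spec: PatternSpec, include_action: bool = True) -> np.ndarray:
    """Render a PatternSpec into a binary 1925-unit visible vector."""
    v = np.zeros(N_VISIBLE)
    if spec.red_pos is not None:
        v[square_indices(spec.red_pos, "red")] = 1.0
    if spec.green_pos is not None:
        v[square_indices(spec.green_pos, "green")] = 1.0
    ctx_off = CTX_A_OFFSET if spec.context == "A" else CTX_B_OFFSET
    v[ctx_off : ctx_off + CTX_UNITS] = 1.0
    if include_action and spec.action_present:
        v[square_indices(spec.action_pos, "action")] = 1.0
    return v


def _sample_position(rng: np.random.Generator) -> GridPosition:
    return GridPosition(
        int(rng.integers(0, MAX_CORNER + 1)), int(rng.integers(0, MAX_CORNER + 1))
    )


def sample_spec(
    rng: np.random.Generator,
    two_stimuli: bool,
    context: Context,
    two_locations_mode: bool = False,
) -> PatternSpec:
    """Draw one trial specification.

    Positions are uniform over the 441 admissible corners; with two stimuli,
    pairs are redrawn until the footprints are spatially disjoint.  In
    ``two_locations_mode`` positions come only from the top-left and
    bottom-right corners (the simplified control condition); with two stimuli
    the colours occupy the two different corners.
    """
    if two_locations_mode:
        corners = (GridPosition(*TOP_LEFT), GridPosition(*BOTTOM_RIGHT))
        if two_stimuli:
            i = int(rng.integers(0, 2))
            red, green = corners[i], corners[1 - i]
        else:
            pos = corners[int(rng.integers(0, 2))]
            red, green = (pos, None) if context == "A" else (None, pos)
    elif two_stimuli:
        while True:
            red, green = _sample_position(rng), _sample_position(rng)
            if not positions_overlap(red, green):
                break
    else:
        pos = _sample_position(rng)
        # Single-stimulus trials pair the stimulus colour with its context.
        red, green = (pos, None) if context == "A" else (None, pos)
    return PatternSpec(context=context, red_pos=red, green_pos=green)


@dataclass
class Dataset:
    """A list of trials together with their rendered visible vectors."""

    specs: list[PatternSpec]
    vectors: np.ndarray  # (n, 1925)
    condition: str
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.specs)

    def save(self, prefix: str) -> None:
        """Persist as <prefix>.npz (vectors) + <prefix>.json (specs)."""
        np.savez_compressed(f"{prefix}.npz", vectors=self.vectors)
        meta = {
            "condition": self.condition,
            "seed": self.seed,
            "specs": [s.to_dict() for s in self.specs],
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, prefix: str) -> "Dataset":
        vectors = np.load(f"{prefix}.npz")["vectors"]
        with open(f"{prefix}.json") as fh:
            meta = json.load(fh)
        return cls(
            specs=[PatternSpec.from_dict(d) for d in meta["specs"]],
            vectors=vectors,
            condition=meta["condition"],
            seed=meta["seed"],
        )


def generate_training_set(
    rng: np.random.Generator,
    n: int = 5000,
    two_locations: bool = False,
    double_only: bool = False,
) -> Dataset:
    """Generate the training set.

    Half the patterns carry a single stimulus (with its matching context and
    action) and half carry both stimuli; contexts A and B each make up half
    of each group.  ``double_only`` drops the single-stimulus half (a control
    condition), keeping the context balance.

    ``n`` must be divisible by 4 (or by 2 with ``double_only``) so the
    composition is exact.
    """
    specs: list[PatternSpec] = []
    if double_only:
        if n % 2:
            raise ValueError("n must be divisible by 2 in double_only mode")
        groups = [(True, "A", n // 2), (True, "B", n // 2)]
    else:
        if n % 4:
            raise ValueError("n must be divisible by 4")
        groups = [
            (False, "A", n // 4),
            (False, "B", n // 4),
            (True, "A", n // 4),
            (True, "B", n // 4),
        ]
    for two_stim, ctx, count in groups:
        for _ in range(count):
            specs.append(sample_spec(rng, two_stim, ctx, two_locations))
    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]
    vectors = np.stack([render(s, include_action=True) for s in specs])
    return Dataset(specs=specs, vectors=vectors, condition="train")


def generate_test_set(
    rng: np.random.Generator,
    condition: str = "complete",
    n: int = 1000,
    two_locations: bool = False,
) -> Dataset:
    """Generate a double-stimulus test set, 50% per context.

    ``condition`` is ``complete`` (action channel provided) or ``no_action``
    (action channel externally zeroed).
    """
    if condition not in ("complete", "no_action"):
        raise ValueError(f"unknown condition {condition!r}")
    if n % 2:
        raise ValueError("n must be divisible by 2")
    include_action = condition == "complete"
    specs = [
        sample_spec(rng, True, ctx, two_locations)
        for ctx in ("A", "B")
        for _ in range(n // 2)
    ]
    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]
    vectors = np.stack([render(s, include_action=include_action) for s in specs])
    return Dataset(specs=specs, vectors=vectors, condition=condition)
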