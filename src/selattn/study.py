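"""Study orchestration: the baseline experiment and its eight controls.

Each study condition trains a number of replication networks (ten at full
scale) that differ only in their random seed, evaluates them on shared
double-stimulus test sets (with and without the action input), and reports
the per-region reconstruction means.  The control conditions vary one
factor each: training-set composition, training duration, dropout, stimulus
location variability, connectivity, and network size.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import analysis, dbn, task_data
from .analysis import RegionMeans, ReplicationSet
from .dbn import DeepNetwork, TrainingConfig, modular_masks

# Visible-layer partition used by the modular control: the two stimulus
# maps, the two context blocks, and the action map are contiguous.
MODULAR_VISIBLE_BLOCKS = (1250, 50, 625)
MODULAR_HIDDEN_PLAN = ((150, 50, 100), (100, 25, 75), None)

CONDITION_NAMES = (
    "baseline",
    "no_single_stim",
    "half_epochs",
    "double_epochs",
    "no_dropout",
    "two_locations",
    "modular",
    "half_neurons",
    "double_neurons",
)


@dataclass
class StudyConfig:
    """One study condition: a named set of overrides of the baseline."""

    condition: str = "baseline"
    replications: int = 10
    n_train: int = 5000
    n_test: int = 1000
    training: TrainingConfig = field(default_factory=TrainingConfig)
    two_locations: bool = False  # corner-only sampler for training AND testing
    double_only: bool = False  # drop single-stimulus training patterns
    seed: int = 0

    def scaled(self, scale: float) -> "StudyConfig":
        """Shrink epochs, pattern counts, and layer sizes uniformly."""
        if scale == 1.0:
            return self
        tr = dataclasses.replace(
            self.training,
            epochs=max(1, round(self.training.epochs * scale)),
            layer_sizes=tuple(
                max(2, round(s * scale)) for s in self.training.layer_sizes
            ),
        )
        return dataclasses.replace(
            self,
            training=tr,
            n_train=max(4, 4 * round(self.n_train * scale / 4)),
            n_test=max(2, 2 * round(self.n_test * scale / 2)),
        )


def make_study_config(condition: str, seed: int = 0, **overrides) -> StudyConfig:
    """Build the configuration of a named condition.

    Overrides per condition: half/double epochs use 250/1000 epochs;
    no_dropout disables dropout and lowers the learning rate to 0.0002;
    modular uses block connectivity in layers 1-2 with hidden blocks
    (150, 50, 100) and (100, 25, 75); half/double neurons use layer sizes
    (150, 100, 50) / (600, 400, 200).
    """
    if condition not in CONDITION_NAMES:
        raise ValueError(f"unknown condition {condition!r}")
    tr = TrainingConfig()
    cfg = StudyConfig(condition=condition, seed=seed, training=tr)
    if condition == "no_single_stim":
        cfg.double_only = True
    elif condition == "half_epochs":
        tr.epochs = 250
    elif condition == "double_epochs":
        tr.epochs = 1000
    elif condition == "no_dropout":
        tr.dropout_p = 0.0
        tr.learning_rate = 0.0002
    elif condition == "two_locations":
        cfg.two_locations = True
    elif condition == "modular":
        tr.connectivity = "modular"
    elif condition == "half_neurons":
        tr.layer_sizes = (150, 100, 50)
    elif condition == "double_neurons":
        tr.layer_sizes = (600, 400, 200)
    for k, v in overrides.items():
        if hasattr(tr, k):
            setattr(tr, k, v)
        elif hasattr(cfg, k):
            setattr(cfg, k, v)
        else:
            raise ValueError(f"unknown override {k!r}")
    return cfg


def desk_scale_config(condition: str = "baseline", seed: int = 0) -> StudyConfig:
    """The reduced-scale study used by the default test battery.

    100 epochs per layer, 1000 training patterns, (150, 100, 50) hidden
    units, 2 replications — small enough to train in about a minute per
    replication while preserving the full pipeline.
    """
    cfg = make_study_config(condition, seed=seed)
    cfg.replications = 2
    cfg.n_train = 1000
    cfg.training.epochs = 100
    cfg.training.layer_sizes = (150, 100, 50)
    return cfg


def _connectivity_masks(cfg: StudyConfig):
    if cfg.training.connectivity != "modular":
        return None
    plan = [
        blocks
        if blocks is None
        else tuple(round(b * s / sum(blocks)) for b in blocks)
        for blocks, s in zip(MODULAR_HIDDEN_PLAN, cfg.training.layer_sizes)
    ]
    # Repair rounding so each layer's blocks sum to its size.
    fixed = []
    for blocks, s in zip(plan, cfg.training.layer_sizes):
        if blocks is None:
            fixed.append(None)
        else:
            blocks = list(blocks)
            blocks[-1] += s - sum(blocks)
            fixed.append(tuple(blocks))
    return modular_masks(MODULAR_VISIBLE_BLOCKS, fixed)


def train_replications(
    cfg: StudyConfig,
    progress: Optional[Callable[[int, int], None]] = None,
) -> tuple[list[DeepNetwork], task_data.Dataset]:
    """Train ``cfg.replications`` networks on a shared training set.

    Replications share the training data and differ in their weight
    initialisation and in the stochastic choices made during training
    (dropout masks, pattern order, hidden sampling).
    """
    root = np.random.SeedSequence(cfg.seed)
    data_seed, *rep_seeds = root.spawn(cfg.replications + 1)
    data_rng = np.random.default_rng(data_seed)
    train = task_data.generate_training_set(
        data_rng,
        n=cfg.n_train,
        two_locations=cfg.two_locations,
        double_only=cfg.double_only,
    )
    masks = _connectivity_masks(cfg)
    nets = []
    for r, seq in enumerate(rep_seeds):
        rng = np.random.default_rng(seq)
        net = DeepNetwork.initialize(
            task_data.N_VISIBLE, cfg.training, rng, connectivity_masks=masks
        )
        dbn.train_network(net, train.vectors, rng, cfg.training)
        nets.append(net)
        if progress is not None:
            progress(r + 1, cfg.replications)
    return nets, train


def make_test_sets(cfg: StudyConfig) -> dict[str, task_data.Dataset]:
    """Shared complete and no-action test sets (seeded from the study seed)."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    out = {}
    for condition in ("complete", "no_action"):
        out[condition] = task_data.generate_test_set(
            rng, condition=condition, n=cfg.n_test, two_locations=cfg.two_locations
        )
    return out


@dataclass
class StudyResults:
    """Everything one study condition produces."""

    config: StudyConfig
    evaluations: dict[str, ReplicationSet]  # complete / no_action
    layer_ablation: Optional[dict[int, list[RegionMeans]]] = None  # depth -> per net
    iterative: Optional[list[list[RegionMeans]]] = None  # per net, per step
    delay: Optional[dict] = None  # order -> ExperimentResult
    rf_proportions: Optional[list[dict]] = None  # per net
    class_ablations: Optional[dict[str, list[RegionMeans]]] = None

    def summary_row(self) -> dict:
        """One row of the control-conditions summary table."""
        ev = self.evaluations["complete"]
        return {
            "condition": self.config.condition,
            "replications": self.config.replications,
            "relevant_stim": ev.mean("relevant_stim"),
            "relevant_stim_sd": ev.sd("relevant_stim"),
            "irrelevant_stim": ev.mean("irrelevant_stim"),
            "irrelevant_stim_sd": ev.sd("irrelevant_stim"),
            "correct_action": ev.mean("correct_action"),
            "correct_action_sd": ev.sd("correct_action"),
            "incorrect_action": ev.mean("incorrect_action"),
            "incorrect_action_sd": ev.sd("incorrect_action"),
        }


def run_study(
    cfg: StudyConfig,
    full_analyses: bool = False,
    delay_trials: int = 200,
    progress: Optional[Callable[[int, int], None]] = None,
) -> StudyResults:
    """Train all replications of one condition and evaluate them.

    The basic evaluation (always run) reconstructs the complete and
    no-action test sets.  With ``full_analyses`` the layer ablation,
    iterative generation, instructed-delay and receptive-field analyses are
    added (the battery reported for the baseline condition).
    """
    nets, _ = train_replications(cfg, progress=progress)
    tests = make_test_sets(cfg)
    evaluations = {
        name: analysis.replication_set(nets, ds, name)
        for name, ds in tests.items()
    }
    results = StudyResults(config=cfg, evaluations=evaluations)
    if full_analyses:
        from . import instructed_delay as idly
        from . import receptive_fields as rf

        no_action = tests["no_action"]
        results.layer_ablation = {
            depth: [
                analysis.evaluate_condition(net, no_action, depth=depth)
                for net in nets
            ]
            for depth in range(1, len(cfg.training.layer_sizes) + 1)
        }
        results.iterative = [
            analysis.run_iterative_generation(net, no_action, steps=5)
            for net in nets
        ]
        trial_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xDE1A)))
        specs = [
            task_data.sample_spec(trial_rng, True, ctx, cfg.two_locations)
            for ctx in ("A", "B")
            for _ in range(delay_trials // 2)
        ]
        results.delay = {
            order: idly.run_experiment(nets, order, specs=specs)
            for order in ("stimuli_first", "context_first")
        }
        results.rf_proportions = [rf.classify_population(net) for net in nets]
        results.class_ablations = {
            f"{keep}_{cond}": [
                rf.class_ablation(net, keep, tests[cond]) for net in nets
            ]
            for keep in ("context_independent", "context_dependent")
            for cond in ("complete", "no_action")
        }
    return results


def evaluations_frame(results: list[StudyResults]) -> pd.DataFrame:
    """Long-format table: condition x test input x replication x region."""
    rows = []
    for res in results:
        for test_name, rep in res.evaluations.items():
            for r, means in enumerate(rep.means):
                for region, value in means.as_dict().items():
                    rows.append(
                        {
                            "condition": res.config.condition,
                            "test_input": test_name,
                            "replication": r,
                            "region": region,
                            "mean_activation": value,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["condition", "test_input", "replication", "region", "mean_activation"],
    )


def summary_table(results: list[StudyResults]) -> pd.DataFrame:
    """Per-condition means and SDs of the four headline regions."""
    cols = [
        "condition",
        "replications",
        "relevant_stim",
        "relevant_stim_sd",
        "irrelevant_stim",
        "irrelevant_stim_sd",
        "correct_action",
        "correct_action_sd",
        "incorrect_action",
        "incorrect_action_sd",
    ]
    return pd.DataFrame([r.summary_row() for r in results], columns=cols)


def write_report(results: list[StudyResults], out_dir: str) -> None:
    """Write the CSV/JSON report bundle for a list of study results."""
    os.makedirs(out_dir, exist_ok=True)
    summary_table(results).to_csv(
        os.path.join(out_dir, "summary.csv"), index=False
    )
    evaluations_frame(results).to_csv(
        os.path.join(out_dir, "evaluations.csv"), index=False
    )
    extras: dict = {}
    for res in results:
        name = res.config.condition
        if res.layer_ablation is not None:
            extras.setdefault("layer_ablation", {})[name] = {
                str(depth): [m.as_dict() for m in per_net]
                for depth, per_net in res.layer_ablation.items()
            }
        if res.iterative is not None:
            extras.setdefault("iterative_generation", {})[name] = [
                [m.as_dict() for m in steps] for steps in res.iterative
            ]
        if res.delay is not None:
            extras.setdefault("instructed_delay", {})[name] = {
                order: [m.as_dict() for m in exp.mean.steps]
                for order, exp in res.delay.items()
            }
        if res.rf_proportions is not None:
            extras.setdefault("rf_proportions", {})[name] = res.rf_proportions
        if res.class_ablations is not None:
            extras.setdefault("class_ablations", {})[name] = {
                key: [m.as_dict() for m in per_net]
                for key, per_net in res.class_ablations.items()
            }
    with open(os.path.join(out_dir, "analyses.json"), "w") as fh:
        json.dump(extras, fh, indent=1)
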