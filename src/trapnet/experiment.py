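"""Orchestration: hyperparameter grid search and the full model comparison.

The comparison mirrors the study design this package implements: train the
2-layer CNN, the 13-layer CNN and the capsule network on a common dataset
with and without training-set augmentation, evaluate everything on the
shared test split in the biological 4-category space, build all four
validation-accuracy-weighted ensembles from the three augmented models,
and emit one consistent report (per-model metrics, mddC/mduC
correct/mispredict split tables before merging, totals, ensemble results).

The default hyperparameter grid spans the six searched axes — routing
iterations, learning rate, batch size, additive training noise, epochs,
augmentation — and enumerates 108 combinations.  For the two CNNs the
routing-iterations axis is collapsed (routing exists only in the capsule
network), which the ranking manifest records.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentationConfig
from .data import TrapDataset
from .synthetic import SceneParams, generate_dataset
from .ensemble import build_ensemble, enumerate_ensembles
from .evaluate import confusion, metrics, MetricsReport
from .labels import merge_label, CATEGORIES_4, CATEGORIES_5
from .models import (
    HyperParams,
    ModelSpec,
    TrainingResult,
    build_capsnet,
    build_cnn2,
    build_cnn13,
    train,
)


@dataclass(frozen=True)
class HyperParamGrid:
    """The six searched axes; total combinations = product of lengths."""

    routing_iterations: tuple[int, ...] = (1, 3, 5)
    learning_rate: tuple[float, ...] = (1e-3, 3e-4, 1e-4)
    batch_size: tuple[int, ...] = (32, 64, 128)
    add_noise: tuple[bool, ...] = (True, False)
    epochs: tuple[int, ...] = (5, 20)
    augmentation: tuple[bool, ...] = (True,)

    def __post_init__(self):
        for name in ("routing_iterations", "learning_rate", "batch_size",
                     "add_noise", "epochs", "augmentation"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"grid axis {name!r} is empty")

    def __len__(self) -> int:
        return (len(self.routing_iterations) * len(self.learning_rate)
                * len(self.batch_size) * len(self.add_noise)
                * len(self.epochs) * len(self.augmentation))

    def combinations(self, architecture_id: str = "capsnet") -> list[HyperParams]:
        """Deterministic cartesian product of the axes, as HyperParams.

        For non-capsule architectures the routing axis collapses to a
        single value, since routing iterations are meaningless there.
        """
        routing = (self.routing_iterations if architecture_id == "capsnet"
                   else self.routing_iterations[:1])
        out = []
        for r, lr, bs, noise, ep, aug in itertools.product(
            routing, self.learning_rate, self.batch_size,
            self.add_noise, self.epochs, self.augmentation,
        ):
            out.append(HyperParams(
                routing_iterations=r, learning_rate=lr, batch_size=bs,
                add_noise=noise, epochs=ep, augmentation=aug,
            ))
        return out


def grid_search(
    architecture_spec: ModelSpec,
    grid: HyperParamGrid,
    dataset: TrapDataset,
    seed: int = 0,
    top_k: int = 10,
    augmentation_config: AugmentationConfig | None = None,
    verbose: bool = False,
) -> list[TrainingResult]:
    """Train one model per grid combination; rank by validation accuracy.

    Ties break toward fewer epochs, then lower learning rate.  Returns the
    ``top_k`` best results (all of them if fewer).
    """
    combos = grid.combinations(architecture_spec.architecture_id)
    results = []
    for hp in combos:
        hp = replace(hp, seed=seed, augmentation_config=augmentation_config)
        results.append(train(architecture_spec, dataset, hp, verbose=verbose))
    results.sort(key=lambda r: (
        -r.validation_accuracy, r.hyperparams.epochs, r.hyperparams.learning_rate,
    ))
    return results[:top_k]


@dataclass(frozen=True)
class ExperimentConfig:
    """Problem sizes and hyperparameters for one full comparison run.

    The default widths are deliberately compact so that the whole
    comparison (six trainings plus four ensembles) completes on one CPU
    core in minutes; full-scale architecture specs from
    ``build_cnn2()/build_cnn13()/build_capsnet()`` drop in unchanged.  At
    these widths the 13-layer network scales its per-layer dropout down to
    10% (25% per layer starves 8-32-channel feature maps within a 5-epoch
    budget).  Learning rate and batch size are per-architecture, standing
    in for the per-architecture winners a hyperparameter grid search would
    select; the epoch and data budget is shared so the architecture
    comparison stays like-for-like.
    """

    cnn2_spec: ModelSpec = field(default_factory=lambda: build_cnn2((16, 32), dense=64))
    cnn13_spec: ModelSpec = field(default_factory=lambda: ModelSpec(
        "cnn13",
        cnn13_channels=(8, 8, 8, 8, 16, 16, 16, 16, 32, 32, 32, 32, 32),
        dropout=0.10))
    capsnet_spec: ModelSpec = field(default_factory=lambda: build_capsnet(
        conv1_channels=16, primary_capsule_types=4, decoder_widths=(64, 128)))
    cnn2_hp: HyperParams = field(default_factory=lambda: HyperParams(
        epochs=5, learning_rate=1e-3, batch_size=16))
    cnn13_hp: HyperParams = field(default_factory=lambda: HyperParams(
        epochs=5, learning_rate=3e-3, batch_size=16))
    capsnet_hp: HyperParams = field(default_factory=lambda: HyperParams(
        epochs=5, learning_rate=1e-3, batch_size=32, routing_iterations=3))
    augmentation_config: AugmentationConfig = field(
        default_factory=lambda: AugmentationConfig(multiplier=4))
    seed: int = 0

    @property
    def specs(self) -> dict[str, ModelSpec]:
        return {"cnn2": self.cnn2_spec, "cnn13": self.cnn13_spec,
                "capsnet": self.capsnet_spec}

    def hp_for(self, arch: str) -> HyperParams:
        return {"cnn2": self.cnn2_hp, "cnn13": self.cnn13_hp,
                "capsnet": self.capsnet_hp}[arch]


@dataclass
class ModelEvaluation:
    """Test-split evaluation of one fitted model (or ensemble)."""

    name: str
    confusion5: np.ndarray | None
    confusion4: np.ndarray
    metrics4: MetricsReport
    n_test: int
    n_correct: int
    n_mispredicted: int
    orientation_table: pd.DataFrame | None = None   # mddC/mduC split detail


def _evaluate_predictions(name: str, true5: list[str], probs5: np.ndarray) -> ModelEvaluation:
    pred5 = [CATEGORIES_5[i] for i in np.argmax(probs5, axis=1)]
    true4 = [merge_label(l) for l in true5]
    pred4 = [merge_label(l) for l in pred5]
    c5 = confusion(true5, pred5, space=5)
    c4 = confusion(true4, pred4, space=4)
    m4 = metrics(c4)
    n_correct = int(np.trace(c4))
    rows = []
    for cls in ("mddC", "mduC"):
        mask = [t == cls for t in true5]
        n = sum(mask)
        preds = [p for p, m in zip(pred5, mask) if m]
        correct4 = sum(merge_label(p) == "mdC" for p in preds)
        rows.append({
            "true_class": cls,
            "n": n,
            "correct_mdC": correct4,
            "mispredicted": n - correct4,
            "predicted_mddC": sum(p == "mddC" for p in preds),
            "predicted_mduC": sum(p == "mduC" for p in preds),
        })
    return ModelEvaluation(
        name=name, confusion5=c5, confusion4=c4, metrics4=m4,
        n_test=len(true5), n_correct=n_correct,
        n_mispredicted=len(true5) - n_correct,
        orientation_table=pd.DataFrame(rows),
    )


def evaluate_on_test(name: str, model, test: TrapDataset) -> ModelEvaluation:
    """Evaluate any object with ``predict(images) -> (n, 5)`` on a test split."""
    probs = np.asarray(model.predict(test.images))
    return _evaluate_predictions(name, test.labels, probs)


@dataclass
class ExperimentReport:
    """All evaluations from one comparison run, internally consistent."""

    evaluations: dict[str, ModelEvaluation]
    models: dict[str, TrainingResult] = field(default_factory=dict, repr=False)
    config: ExperimentConfig | None = field(default=None, repr=False)

    def accuracy(self, name: str) -> float:
        return self.evaluations[name].metrics4.overall_accuracy

    def summary(self) -> str:
        lines = ["model comparison on the shared test split (4-category space)"]
        for name, ev in self.evaluations.items():
            lines.append(
                f"  {name:<16} accuracy {ev.metrics4.overall_accuracy:.4f}  "
                f"macro P {ev.metrics4.macro_precision:.4f}  "
                f"macro R {ev.metrics4.macro_recall:.4f}  "
                f"({ev.n_correct}/{ev.n_test} correct)"
            )
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary = {}
        for name, ev in self.evaluations.items():
            ev.metrics4.per_category.to_csv(out_dir / f"{name}_metrics4.csv")
            pd.DataFrame(ev.confusion4, index=CATEGORIES_4,
                         columns=CATEGORIES_4).to_csv(out_dir / f"{name}_confusion4.csv")
            if ev.confusion5 is not None:
                pd.DataFrame(ev.confusion5, index=CATEGORIES_5,
                             columns=CATEGORIES_5).to_csv(out_dir / f"{name}_confusion5.csv")
            if ev.orientation_table is not None:
                ev.orientation_table.to_csv(
                    out_dir / f"{name}_orientation.csv", index=False)
            summary[name] = {
                "overall_accuracy": ev.metrics4.overall_accuracy,
                "macro_precision": ev.metrics4.macro_precision,
                "macro_recall": ev.metrics4.macro_recall,
                "n_test": ev.n_test,
                "n_correct": ev.n_correct,
                "n_mispredicted": ev.n_mispredicted,
            }
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))


def run_comparison(dataset: TrapDataset, config: ExperimentConfig | None = None,
                   verbose: bool = False) -> ExperimentReport:
    """Train and compare all three architectures with and without
    augmentation, plus the four ensembles, on fixed splits.

    The test split is touched exactly once per model, after all training
    and selection; ensemble weights come from validation accuracy.
    """
    config = config or ExperimentConfig()
    for split in ("train", "val", "test"):
        if len(dataset.split(split)) == 0:
            raise ValueError(f"dataset is missing a non-empty {split!r} split")
    test = dataset.split("test")
    models: dict[str, TrainingResult] = {}
    evaluations: dict[str, ModelEvaluation] = {}
    for arch, spec in config.specs.items():
        for aug in (False, True):
            hp = replace(
                config.hp_for(arch),
                augmentation=aug,
                augmentation_config=config.augmentation_config if aug else None,
                seed=config.seed,
            )
            name = f"{arch}_aug" if aug else f"{arch}_noaug"
            result = train(spec, dataset, hp, verbose=verbose)
            models[name] = result
            evaluations[name] = evaluate_on_test(name, result, test)
            if verbose:
                print(evaluations[name].metrics4.summary())
    member_names = ["cnn2_aug", "cnn13_aug", "capsnet_aug"]
    members = [models[n] for n in member_names]
    for ens in enumerate_ensembles(members):
        idx = [int(i) for i in ens.name.split("+")]
        name = "ens_" + "+".join(member_names[i].replace("_aug", "") for i in idx)
        evaluations[name] = evaluate_on_test(name, ens, test)
    return ExperimentReport(evaluations=evaluations, models=models, config=config)


def smoke_benchmark(seed: int = 0, per_class: int = 100,
                    verbose: bool = False) -> dict:
    """The package's standard small-scale benchmark on synthetic data.

    Runs the full comparison (three architectures, with/without
    augmentation, four ensembles) on hard-mode scenes, then trains the
    three architectures with augmentation on easy-mode scenes, at
    ``per_class`` images per category and the compact default widths.
    Returns a flat dict of 4-category test accuracies plus the problem
    size; everything derives deterministically from ``seed``.
    """
    config = ExperimentConfig(seed=seed)
    counts = {c: per_class for c in CATEGORIES_5}
    hard = generate_dataset(counts, SceneParams.hard(), seed=seed * 31 + 1)
    report = run_comparison(hard, config, verbose=verbose)
    out = {"n_per_class": per_class,
           "n_test": report.evaluations["cnn2_aug"].n_test}
    for name, ev in report.evaluations.items():
        out[f"hard_{name}_acc"] = ev.metrics4.overall_accuracy
    singles = [out["hard_cnn2_aug_acc"], out["hard_cnn13_aug_acc"],
               out["hard_capsnet_aug_acc"]]
    out["hard_best_single_acc"] = max(singles)
    out["hard_ensemble3_acc"] = out["hard_ens_cnn2+cnn13+capsnet_acc"]

    easy = generate_dataset(counts, SceneParams.easy(), seed=seed * 31 + 2)
    easy_test = easy.split("test")
    for arch, spec in config.specs.items():
        hp = replace(config.hp_for(arch), augmentation=True,
                     augmentation_config=config.augmentation_config,
                     seed=seed)
        result = train(spec, easy, hp, verbose=verbose)
        ev = evaluate_on_test(f"easy_{arch}", result, easy_test)
        out[f"easy_{arch}_acc"] = ev.metrics4.overall_accuracy
    return out
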