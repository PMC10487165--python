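"""End-to-end experiment helpers: feasibility reports, per-wavelength-set
CNN training/evaluation, and CNN-driven selection losses.

These are the building blocks behind the command-line interface and the
desk-scale validation experiments.  Desk-scale defaults (small filter
counts, ~150 epochs) keep a single training run in the seconds range on one
CPU; the full-scale configuration (16/32 filters, 1000 epochs) remains
available through :class:`~specfood.cnn.CnnConfig`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cnn import CnnConfig, EvalReport, TrainResult, build_model, evaluate, train
from .io import MultispectralStack
from .preprocess import (NormalizationReference, assemble_input,
                         replace_zero_calories)
from .selection import (MemoizedLoss, SelectionResult, canonical_key,
                        run_selection)
from .spectral import (band_maxima, compare_band_correlations,
                       correlation_profile, cumulative_ratio_grid,
                       pairwise_distance_table, pooled_histogram)
from .wavelengths import WavelengthLabel

DESK_EPOCHS = 150
DESK_FILTERS = (8, 16)


# ---------------------------------------------------------------------------
# data marshalling
# ---------------------------------------------------------------------------

def arrays_from_stacks(stacks: Sequence[MultispectralStack],
                       labels: pd.DataFrame,
                       selected: Iterable[WavelengthLabel],
                       task: str,
                       reference: NormalizationReference | None = None,
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (X, y, item_ids) for one wavelength set.

    ``labels`` carries one row per (item, view); regression targets have
    exact zeros replaced by the nutrition-table minimum.
    """
    selected = sorted(set(selected))
    lab = labels.set_index(["item_id", "view_index"])
    xs, ys, items = [], [], []
    for stack in stacks:
        row = lab.loc[(stack.item_id, stack.view_index)]
        inp = assemble_input(stack, selected, reference=reference,
                             class_index=int(row["class_index"]),
                             calorie_kcal=float(row["calorie_kcal"]))
        xs.append(inp.channels)
        ys.append(row["class_index"] if task == "classification" else row["calorie_kcal"])
        items.append(stack.item_id)
    x = np.stack(xs)
    y = np.asarray(ys)
    if task == "regression":
        y = replace_zero_calories(y)
    else:
        y = y.astype(int)
    return x, y, np.asarray(items)


def split_stacks(stacks: Sequence[MultispectralStack], labels: pd.DataFrame
                 ) -> tuple[list[MultispectralStack], list[MultispectralStack]]:
    """Partition stacks into train/validation views per the label table."""
    tag = labels.set_index(["item_id", "view_index"])["split"]
    train_s = [s for s in stacks if tag.loc[(s.item_id, s.view_index)] == "train"]
    val_s = [s for s in stacks if tag.loc[(s.item_id, s.view_index)] == "val"]
    return train_s, val_s


# ---------------------------------------------------------------------------
# one wavelength set -> trained CNN -> report
# ---------------------------------------------------------------------------

def make_config(selected: Sequence[WavelengthLabel], task: str, *,
                epochs: int = DESK_EPOCHS,
                conv_filters: tuple[int, int] = DESK_FILTERS,
                learning_rate: float = 1e-3,
                n_classes: int | None = None,
                seed: int = 0) -> CnnConfig:
    n_channels = sum(3 if w.is_rgb else 1 for w in set(selected))
    n_targets = 1 if task == "regression" else int(n_classes)
    return CnnConfig(task=task, n_targets=n_targets, input_channels=n_channels,
                     conv1_filters=conv_filters[0], conv2_filters=conv_filters[1],
                     epochs=epochs, learning_rate=learning_rate, seed=seed)


@dataclass
class SetExperiment:
    """Evaluation of one wavelength set on one dataset."""

    wavelengths: tuple[str, ...]
    n_images: int
    report: EvalReport
    result: TrainResult


def train_and_evaluate(stacks: Sequence[MultispectralStack],
                       labels: pd.DataFrame,
                       selected: Iterable[WavelengthLabel],
                       task: str, *,
                       reference: NormalizationReference | None = None,
                       seed: int = 0,
                       epochs: int = DESK_EPOCHS,
                       conv_filters: tuple[int, int] = DESK_FILTERS,
                       learning_rate: float = 1e-3) -> SetExperiment:
    """Train the CNN on the train views and evaluate on the held-out views."""
    selected = sorted(set(selected))
    tr, va = split_stacks(stacks, labels)
    n_classes = labels.class_index.nunique()
    x_tr, y_tr, _ = arrays_from_stacks(tr, labels, selected, task, reference)
    x_va, y_va, items_va = arrays_from_stacks(va, labels, selected, task, reference)
    config = make_config(selected, task, epochs=epochs, conv_filters=conv_filters,
                         learning_rate=learning_rate, n_classes=n_classes, seed=seed)
    result = train(build_model(config), x_tr, y_tr, x_va, y_va, config)
    report = evaluate(result.model, x_va, y_va, item_ids=items_va)
    n_images = len(selected)  # RGB is one shot regardless of its three planes
    return SetExperiment(wavelengths=canonical_key(selected), n_images=n_images,
                         report=report, result=result)


def wavelength_curve(stacks, labels, sets: Sequence[Iterable[WavelengthLabel]],
                     task: str, **kwargs) -> pd.DataFrame:
    """Accuracy/MAPE-versus-image-count curve over a list of wavelength
    sets (the x-axis counts the RGB shot as one image)."""
    rows = []
    for s in sets:
        exp = train_and_evaluate(stacks, labels, s, task, **kwargs)
        rows.append((exp.n_images, " ".join(exp.wavelengths), exp.report.overall,
                     exp.report.pearson_r))
    return pd.DataFrame(rows, columns=["n_images", "wavelengths", "metric", "pearson_r"])


# ---------------------------------------------------------------------------
# CNN-driven selection loss
# ---------------------------------------------------------------------------

def derive_set_seed(global_seed: int, wavelengths: Iterable[WavelengthLabel]) -> int:
    """Deterministic per-set training seed from the global seed and the
    canonical set key; keeps losses comparable and cacheable."""
    key = ",".join(canonical_key(wavelengths))
    return int((zlib.crc32(key.encode()) ^ (global_seed * 2654435761)) % (2 ** 31))


def make_cnn_loss(stacks: Sequence[MultispectralStack], labels: pd.DataFrame,
                  task: str, *, global_seed: int = 0,
                  reference: NormalizationReference | None = None,
                  epochs: int = DESK_EPOCHS,
                  conv_filters: tuple[int, int] = DESK_FILTERS,
                  learning_rate: float = 1e-3) -> MemoizedLoss:
    """Selection loss L(S): train the task CNN on wavelength set S and
    return its final validation loss (cross-entropy for classification,
    MAPE for regression)."""

    def loss(wavelengths: frozenset[WavelengthLabel]) -> float:
        exp = train_and_evaluate(
            stacks, labels, wavelengths, task, reference=reference,
            seed=derive_set_seed(global_seed, wavelengths),
            epochs=epochs, conv_filters=conv_filters, learning_rate=learning_rate)
        return exp.result.final_val_loss

    return MemoizedLoss(loss)


def select_wavelengths(stacks, labels, task: str,
                       candidates: Sequence[WavelengthLabel], *,
                       include_rgb: bool = False, global_seed: int = 0,
                       max_cardinality: int | None = None,
                       **loss_kwargs) -> SelectionResult:
    loss = make_cnn_loss(stacks, labels, task, global_seed=global_seed, **loss_kwargs)
    return run_selection(candidates, loss, include_rgb=include_rgb,
                         max_cardinality=max_cardinality)


# ---------------------------------------------------------------------------
# feasibility report
# ---------------------------------------------------------------------------

def feasibility_report(stacks: Sequence[MultispectralStack],
                       labels: pd.DataFrame, *,
                       bins: int = 256,
                       thresholds: Sequence[float] = (0.2, 0.3, 0.4, 0.5),
                       ) -> dict[str, object]:
    """The preliminary feasibility statistics on one dataset.

    Pools each item's views into one histogram per wavelength, computes the
    all-pairs Bhattacharyya distance table, per-band maxima, the F_C grid
    over the given thresholds, the per-wavelength correlation profile
    against caloric differences, and the VIS-vs-UV/NIR band comparison.
    """
    by_item: dict[int, dict] = {}
    for stack in stacks:
        for w, shot in stack.shots.items():
            by_item.setdefault(stack.item_id, {}).setdefault(w, []).append(shot)
    histograms = {item: {w: pooled_histogram(shots, bins=bins)
                         for w, shots in per_wl.items()}
                  for item, per_wl in by_item.items()}
    table = pairwise_distance_table(histograms)
    maxima = band_maxima(table)
    grid = cumulative_ratio_grid(maxima, thresholds, thresholds)
    calories = (labels.groupby("item_id")["calorie_kcal"].first().dropna().to_dict())
    profile = correlation_profile(table, calories)
    try:
        mean_v, mean_nv, p = compare_band_correlations(profile)
    except ValueError:
        # too few items/pairs for per-wavelength correlations
        mean_v = mean_nv = p = None
    return {"distances": table, "band_maxima": maxima, "fc_grid": grid,
            "correlation_profile": profile,
            "band_comparison": {"mean_vis": mean_v, "mean_non_vis": mean_nv,
                                "p_value": p,
                                "test": "two-sample t on Fisher-z transformed rho"}}
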