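"""Piecewise (forward-backward-forward) wavelength-subset selection.

A wrapper search over illumination channels: each candidate set is scored by
a loss callback (in production, the final validation loss of a CNN trained
on exactly those channels).  One iteration grows the working set by one
wavelength via three steps:

1. forward selection  - add the channel whose addition minimises the loss;
2. backward elimination - remove the member whose removal minimises the loss;
3. final forward selection - add the best channel from outside the reduced
   set (the one just removed may come straight back).

Iterating until the working set equals the full set yields one best set per
cardinality; the overall optimum is the recorded set with the smallest loss.
Ties always break toward the shorter wavelength, with RGB outranking all, so
runs are reproducible.  In ``include_rgb`` mode the search starts from
{RGB} and never removes it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Collection, Iterable, Sequence

import pandas as pd

from .wavelengths import Band, RGB, WavelengthLabel

LossFn = Callable[[frozenset[WavelengthLabel]], float]


def canonical_key(wavelengths: Iterable[WavelengthLabel]) -> tuple[str, ...]:
    """Stable identity of a wavelength set: names sorted RGB-first."""
    return tuple(w.name for w in sorted(set(wavelengths)))


class MemoizedLoss:
    """Caches a loss callback by canonical set key, so each candidate set
    trains at most one CNN per run; records every evaluation for audit."""

    def __init__(self, fn: LossFn):
        self._fn = fn
        self._cache: dict[tuple[str, ...], float] = {}
        self.n_calls = 0

    def __call__(self, wavelengths: Collection[WavelengthLabel]) -> float:
        key = canonical_key(wavelengths)
        if key not in self._cache:
            self.n_calls += 1
            self._cache[key] = float(self._fn(frozenset(wavelengths)))
        return self._cache[key]


@dataclass
class SelectionResult:
    """Outcome of one selection run."""

    per_cardinality: dict[int, tuple[frozenset[WavelengthLabel], float]]
    best_set: frozenset[WavelengthLabel]
    best_loss: float
    trace: pd.DataFrame  # iteration, step, candidate, loss (every evaluation)
    include_rgb: bool

    def table(self) -> pd.DataFrame:
        """Per-cardinality report: number of images -> selected wavelengths."""
        rows = [(k, " ".join(canonical_key(s)), loss)
                for k, (s, loss) in sorted(self.per_cardinality.items())]
        return pd.DataFrame(rows, columns=["n_images", "wavelengths", "loss"])


def _argmin_candidate(candidates: Sequence[tuple[WavelengthLabel, float]]
                      ) -> WavelengthLabel:
    best_loss = min(loss for _, loss in candidates)
    tied = [w for w, loss in candidates if loss == best_loss]
    return min(tied)  # WavelengthLabel ordering: RGB first, then ascending nm


def forward_step(current: Collection[WavelengthLabel],
                 full: Collection[WavelengthLabel],
                 loss_fn: LossFn,
                 ) -> tuple[WavelengthLabel, frozenset[WavelengthLabel], list]:
    """Add the complement wavelength minimising the loss of the grown set."""
    current = frozenset(current)
    complement = sorted(frozenset(full) - current)
    if not complement:
        raise ValueError("forward step requires a non-empty complement")
    evals = [(w, loss_fn(current | {w})) for w in complement]
    best = _argmin_candidate(evals)
    return best, current | {best}, evals


def backward_step(current: Collection[WavelengthLabel], loss_fn: LossFn,
                  protected: Collection[WavelengthLabel] = (),
                  ) -> tuple[WavelengthLabel, frozenset[WavelengthLabel], list]:
    """Remove the member whose removal minimises the loss of the shrunk set;
    ``protected`` members (RGB in include_rgb mode) are never candidates."""
    current = frozenset(current)
    removable = sorted(current - frozenset(protected))
    if not removable:
        raise ValueError("backward step has nothing removable")
    evals = [(w, loss_fn(current - {w})) for w in removable]
    best = _argmin_candidate(evals)
    return best, current - {best}, evals


def final_forward_step(reduced: Collection[WavelengthLabel],
                       full: Collection[WavelengthLabel], loss_fn: LossFn,
                       ) -> tuple[WavelengthLabel, frozenset[WavelengthLabel], list]:
    """Forward step from the reduced set; the just-removed wavelength is an
    eligible candidate again."""
    return forward_step(reduced, full, loss_fn)


def run_selection(full: Collection[WavelengthLabel], loss_fn: LossFn,
                  *, include_rgb: bool = False,
                  max_cardinality: int | None = None) -> SelectionResult:
    """Run the piecewise search until the working set reaches the full set
    (or ``max_cardinality``), recording the best set at every cardinality."""
    full = frozenset(full)
    if include_rgb and RGB not in full:
        full = full | {RGB}
    if len(full) < 2:
        raise ValueError("selection needs at least two wavelengths")
    memo = loss_fn if isinstance(loss_fn, MemoizedLoss) else MemoizedLoss(loss_fn)
    protected = frozenset({RGB}) if include_rgb else frozenset()
    current = frozenset(protected)
    per_card: dict[int, tuple[frozenset[WavelengthLabel], float]] = {}
    trace_rows: list[tuple] = []

    def record_eval(iteration: int, step: str, evals: Iterable) -> None:
        for w, loss in evals:
            trace_rows.append((iteration, step, w.name, loss))

    if include_rgb:
        per_card[1] = (current, memo(current))
    iteration = 0
    limit = max_cardinality if max_cardinality is not None else len(full)
    while len(current) < limit:
        iteration += 1
        try:
            added, grown, evals = forward_step(current, full, memo)
        except ValueError as exc:
            raise RuntimeError(f"selection failed at iteration {iteration} "
                               f"on set {canonical_key(current)}") from exc
        record_eval(iteration, "forward", evals)
        if grown == full:
            current = grown
        else:
            removed, reduced, evals = backward_step(grown, memo, protected)
            record_eval(iteration, "backward", evals)
            added, current, evals = final_forward_step(reduced, full, memo)
            record_eval(iteration, "final_forward", evals)
        per_card[len(current)] = (current, memo(current))
    best_card = min(per_card,
                    key=lambda k: (per_card[k][1], k))
    best_set, best_loss = per_card[best_card]
    trace = pd.DataFrame(trace_rows, columns=["iteration", "step", "candidate", "loss"])
    return SelectionResult(per_cardinality=per_card, best_set=best_set,
                           best_loss=best_loss, trace=trace,
                           include_rgb=include_rgb)


def selection_rate_summary(results: Sequence[SelectionResult]
                           ) -> tuple[pd.Series, pd.Series]:
    """Per-wavelength selection frequency and band shares.

    Frequency of a wavelength = (number of per-cardinality best sets it
    appears in) / (total number of best sets), pooled over results.  Band
    shares divide the narrow-band selection slots among UV/VIS/NIR.
    """
    if not results:
        raise ValueError("need at least one selection result")
    counts: dict[str, int] = {}
    n_sets = 0
    for res in results:
        for _, (s, _loss) in res.per_cardinality.items():
            n_sets += 1
            for w in s:
                counts[w.name] = counts.get(w.name, 0) + 1
    freq = pd.Series(counts, dtype=float).sort_index() / n_sets
    band_slots: dict[str, int] = {b.value: 0 for b in (Band.UV, Band.VIS, Band.NIR)}
    total_narrow = 0
    for name, c in counts.items():
        label = WavelengthLabel(name)
        if not label.is_rgb:
            band_slots[label.band.value] += c
            total_narrow += c
    shares = pd.Series(band_slots, dtype=float)
    if total_narrow:
        shares = shares / total_narrow * 100.0
    return freq, shares
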