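"""Class-weighted scoring and grid-search parameter optimisation.

For every point of a picker's parameter grid the full chain
pick -> group -> classify -> count is run over the optimisation samples and
summarised by the linear score

    S = sum_c  w_c * n_c

where ``n_c`` is the number of peaks assigned to quality class c and ``w_c``
its weight.  The defaults reward high-quality peaks (A, B, C: +1), penalise
noise hardest (D: -1) and intermediate classes mildly (E, F, G: -0.5), so the
optimum balances coverage against false positives rather than maximising the
raw peak count.  Plain exhaustive grid search is used deliberately: the score
landscape is shallow and broad, so descent or annealing buys nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .classification import CLASS_LABELS, TrainedClassifier, classify
from .io_formats import RawRun
from .peak_detection import (DetectedPeak, PickerParams, build_eic_set,
                             get_picker, group_pseudospectra)

__all__ = ["ClassCounts", "ScoreWeights", "OptimizationResult",
           "score_counts", "grid_search", "DEFAULT_WEIGHTS"]


@dataclass
class ClassCounts:
    """Number of classified peaks per quality class."""

    n_c: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CLASS_LABELS})

    def __post_init__(self) -> None:
        for c in CLASS_LABELS:
            self.n_c.setdefault(c, 0)
        for c, n in self.n_c.items():
            if c not in CLASS_LABELS:
                raise ValueError(f"unknown class {c!r}")
            if n < 0:
                raise ValueError("counts must be non-negative")

    @classmethod
    def from_peaks(cls, peaks: Sequence[DetectedPeak]) -> "ClassCounts":
        counts = {c: 0 for c in CLASS_LABELS}
        for p in peaks:
            if p.class_label is None:
                raise ValueError(f"peak {p.peak_id} is unclassified")
            counts[p.class_label] += 1
        return cls(n_c=counts)

    def __add__(self, other: "ClassCounts") -> "ClassCounts":
        return ClassCounts({c: self.n_c[c] + other.n_c[c] for c in CLASS_LABELS})

    @property
    def total(self) -> int:
        return sum(self.n_c.values())

    def __getitem__(self, c: str) -> int:
        return self.n_c[c]


DEFAULT_WEIGHTS: dict[str, float] = {
    "A": 1.0, "B": 1.0, "C": 1.0, "D": -1.0, "E": -0.5, "F": -0.5, "G": -0.5,
}


@dataclass
class ScoreWeights:
    """Per-class weights of the scoring function (user-adjustable)."""

    w_c: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        for c in CLASS_LABELS:
            if c not in self.w_c:
                raise ValueError(f"missing weight for class {c}")
        if max(self.w_c[c] for c in ("A", "B", "C")) <= 0:
            raise ValueError("at least one high-quality class weight must be positive")
        if self.w_c["D"] > 0:
            raise ValueError("the noise class D must never be rewarded (w_D <= 0)")


def score_counts(counts: ClassCounts, weights: ScoreWeights) -> float:
    """Linear class-weighted score S = sum_c w_c * n_c."""
    return float(sum(weights.w_c[c] * counts.n_c[c] for c in CLASS_LABELS))


@dataclass
class OptimizationResult:
    """Full grid-search record for one picker."""

    algorithm_id: str
    per_combination: list[tuple[PickerParams, ClassCounts, float]]
    best: PickerParams

    def best_score(self) -> float:
        for params, _, s in self.per_combination:
            if params is self.best:
                return s
        raise RuntimeError("best parameters missing from per_combination")

    def to_frame(self):
        """One row per grid point: parameters, n_A..n_G, score."""
        import pandas as pd

        rows = []
        for params, counts, s in self.per_combination:
            row = {"grid_id": params.grid_id, **params.values}
            row.update({f"n_{c}": counts[c] for c in CLASS_LABELS})
            row["score"] = s
            rows.append(row)
        return pd.DataFrame(rows)


def grid_search(picker: str, grid: Sequence[PickerParams],
                optimisation_runs: Sequence[RawRun],
                classifier: TrainedClassifier, weights: ScoreWeights,
                rt_tol_group: float = 1.0) -> OptimizationResult:
    """Exhaustively score every grid point and select the best parameters.

    Counts are summed over the optimisation runs.  Ties on the score are
    broken by the fewest class-D peaks, then by lexicographic parameter
    order, so the selection is deterministic.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    if len(optimisation_runs) < 2:
        warnings.warn("fewer than 2 optimisation runs; 2+ recommended",
                      stacklevel=2)
    overlap = classifier.train_sample_ids & {r.sample_id for r in optimisation_runs}
    if overlap:
        warnings.warn(
            f"optimisation samples also used for training: {sorted(overlap)}",
            stacklevel=2)

    func = get_picker(picker)
    run_map = {r.sample_id: r for r in optimisation_runs}
    eic_cache = {r.sample_id: build_eic_set(r, bin_width=1.0)
                 for r in optimisation_runs}
    per_combination: list[tuple[PickerParams, ClassCounts, float]] = []
    for params in grid:
        total = ClassCounts()
        for run in optimisation_runs:
            peaks = group_pseudospectra(func(run, params), rt_tol=rt_tol_group)
            classify(classifier, peaks, run_map, eics=eic_cache)
            total = total + ClassCounts.from_peaks(peaks)
        per_combination.append((params, total, score_counts(total, weights)))

    best = min(per_combination,
               key=lambda item: (-item[2], item[1]["D"], item[0].key()))[0]
    return OptimizationResult(algorithm_id=picker,
                              per_combination=per_combination, best=best)
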