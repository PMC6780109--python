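"""Seven-class SVM peak-quality classification.

Every detected peak is represented by an apex-centred window of intensities
over its m/z channels and a fixed RT span, preprocessed (baseline-corrected,
scaled, flattened) and classified into one of seven quality classes:

========  =============================================  ============
label     shape                                          quality tier
========  =============================================  ============
A         apex shifted left of window centre             high
B         centred apex                                   high
C         apex shifted right of window centre            high
D         noise, no coherent peak                        noise
E         narrow peak, wide margins to window borders    intermediate
F         peak truncated by a window border              intermediate
G         merged / shoulder peak                         intermediate
========  =============================================  ============

One classifier is trained per picker algorithm: pickers differ in which
signals they report, so their peak populations differ and labels learned on
one picker's output are not reused for another.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import RawRun
from .peak_detection import (DetectedPeak, EICSet, PickerParams,
                             build_eic_set, get_picker, group_pseudospectra)

__all__ = [
    "CLASS_LABELS",
    "HIGH_QUALITY",
    "NOISE_CLASS",
    "INTERMEDIATE",
    "PeakWindow",
    "TrainedClassifier",
    "ConfusionMatrix",
    "extract_window",
    "preprocess_window",
    "sample_training_peaks",
    "export_annotation_sheet",
    "read_label_file",
    "train_classifier",
    "classify",
    "evaluate_classifier",
]

CLASS_LABELS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G")
HIGH_QUALITY = frozenset({"A", "B", "C"})
NOISE_CLASS = frozenset({"D"})
INTERMEDIATE = frozenset({"E", "F", "G"})


def validate_label(label: str) -> str:
    if label not in CLASS_LABELS:
        raise ValueError(f"unknown class label {label!r}; expected one of {CLASS_LABELS}")
    return label


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class PeakWindow:
    """Apex-centred (n_mz x n_t) intensity matrix fed to the classifier.

    Windows compare by identity; the content hash ``uid`` identifies equal
    content across processes."""

    intensities: np.ndarray
    mz_centers: np.ndarray
    rt_grid: np.ndarray
    source: DetectedPeak | None = None
    uid: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.mz_centers = np.asarray(self.mz_centers, dtype=np.float64)
        self.rt_grid = np.asarray(self.rt_grid, dtype=np.float64)
        if self.intensities.ndim != 2:
            raise ValueError("window intensities must be 2-D (n_mz x n_t)")
        if self.intensities.shape[0] != self.mz_centers.size:
            raise ValueError("one m/z centre per channel required")
        if self.intensities.shape[1] != self.rt_grid.size:
            raise ValueError("one RT per column required")
        if np.any(self.intensities < 0):
            raise ValueError("window intensities must be non-negative")
        if not self.uid:
            h = hashlib.sha1()
            h.update(np.round(self.intensities, 6).tobytes())
            h.update(np.round(self.rt_grid, 6).tobytes())
            h.update(np.round(self.mz_centers, 4).tobytes())
            self.uid = h.hexdigest()[:16]

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


def extract_window(run: RawRun, peak: DetectedPeak, window_s: float = 8.0,
                   n_t: int = 41, n_mz: int = 10,
                   eics: EICSet | None = None) -> PeakWindow:
    """Cut the apex-centred window of a detected peak out of the raw run.

    The window spans ``rt_apex +/- window_s/2`` resampled to ``n_t`` columns;
    channels are the peak's m/z channels ordered by descending apex height,
    padded with zero channels (or truncated) to ``n_mz``. Columns outside
    the run are zero-filled, so border peaks remain representable (class F).
    """
    lo, hi = run.rt_range
    if not (lo <= peak.rt_apex <= hi):
        raise ValueError(f"peak apex {peak.rt_apex} outside run RT range {run.rt_range}")
    if eics is None:
        eics = build_eic_set(run, bin_width=1.0)
    grid = np.linspace(peak.rt_apex - window_s / 2, peak.rt_apex + window_s / 2, n_t)
    channels = sorted(peak.mz_list, key=lambda t: -t[1])[:n_mz]
    mat = np.zeros((n_mz, n_t))
    centers = np.zeros(n_mz)
    for ch, (mz, _, _) in enumerate(channels):
        trace = eics.trace(mz)
        mat[ch] = np.interp(grid, eics.rts, trace, left=0.0, right=0.0)
        centers[ch] = mz
    return PeakWindow(intensities=mat, mz_centers=centers, rt_grid=grid,
                      source=peak)


def preprocess_window(window: PeakWindow) -> np.ndarray:
    """Baseline-correct, scale and flatten a window into a feature vector.

    Per channel a linear baseline through the means of the first and last
    10% of columns is subtracted and negatives are clipped; the whole window
    is then divided by its global maximum (all-zero maps to all-zero) and
    flattened row-major.
    """
    mat = window.intensities.astype(np.float64, copy=True)
    n_mz, n_t = mat.shape
    k = max(1, n_t // 10)
    x = np.arange(n_t)
    left = mat[:, :k].mean(axis=1)
    right = mat[:, -k:].mean(axis=1)
    x_left = (k - 1) / 2.0
    x_right = (n_t - 1) - (k - 1) / 2.0
    slope = (right - left) / (x_right - x_left)
    baseline = left[:, None] + slope[:, None] * (x[None, :] - x_left)
    mat = np.clip(mat - baseline, 0.0, None)
    top = mat.max()
    if top > 0:
        mat /= top
    return mat.ravel()


# ---------------------------------------------------------------------------
# training-set sampling and annotation export
# ---------------------------------------------------------------------------

def sample_training_peaks(runs: Sequence[RawRun], pickers: Sequence[str],
                          grids: Mapping[str, Sequence[PickerParams]],
                          n_target: int, seed: int, *,
                          rt_tol_group: float = 1.0, window_s: float = 8.0,
                          n_t: int = 41, n_mz: int = 10) -> dict[str, list[PeakWindow]]:
    """Pool candidate peaks over (picker, parameter set, RT stratum) cells and
    down-sample to ``n_target`` windows per picker, stratified over RT deciles.

    Returns a mapping picker -> list of windows; deduplication is on
    (picker, apex rounded to 1 s). Deterministic for a given seed. If fewer
    than ``n_target`` candidates exist, all are returned with a warning.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[PeakWindow]] = {}
    for picker_name in pickers:
        func = get_picker(picker_name)
        seen: set[tuple[str, int]] = set()
        candidates: list[tuple[float, PeakWindow]] = []
        for run in runs:
            eics = build_eic_set(run, bin_width=1.0)
            lo, hi = run.rt_range
            for params in grids[picker_name]:
                peaks = group_pseudospectra(func(run, params), rt_tol=rt_tol_group)
                for p in peaks:
                    key = (run.sample_id, int(round(p.rt_apex)))
                    if key in seen:
                        continue
                    seen.add(key)
                    w = extract_window(run, p, window_s=window_s, n_t=n_t,
                                       n_mz=n_mz, eics=eics)
                    frac = (p.rt_apex - lo) / max(hi - lo, 1e-9)
                    candidates.append((min(0.999, max(0.0, frac)), w))
        if len(candidates) <= n_target:
            if len(candidates) < n_target:
                warnings.warn(
                    f"{picker_name}: only {len(candidates)} candidate peaks "
                    f"for a target of {n_target}; returning all", stacklevel=2)
            out[picker_name] = [w for _, w in candidates]
            continue
        # stratify over RT deciles, uniform within each
        deciles: list[list[PeakWindow]] = [[] for _ in range(10)]
        for frac, w in candidates:
            deciles[int(frac * 10)].append(w)
        chosen: list[PeakWindow] = []
        remaining = n_target
        for d, bucket in enumerate(deciles):
            quota = round(n_target / 10)
            take = min(len(bucket), quota, remaining)
            idx = rng.choice(len(bucket), size=take, replace=False) if bucket else []
            chosen.extend(bucket[i] for i in sorted(idx))
            remaining -= take
        if remaining > 0:  # redistribute leftover quota
            pool = [w for _, w in candidates if w not in chosen]
            idx = rng.choice(len(pool), size=min(remaining, len(pool)), replace=False)
            chosen.extend(pool[i] for i in sorted(idx))
        out[picker_name] = chosen
    return out


def export_annotation_sheet(windows: Sequence[PeakWindow], out_dir: str | Path) -> Path:
    """Write one overlay plot per window plus a blank CSV label template.

    Window ids are content hashes, so re-export is idempotent. Returns the
    path of the template file (columns: window_id, label)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for w in windows:
        fig, ax = plt.subplots(figsize=(4, 3))
        for ch in range(w.shape[0]):
            if w.intensities[ch].any():
                ax.plot(w.rt_grid, w.intensities[ch], lw=0.8)
        ax.set_xlabel("RT (s)")
        ax.set_ylabel("intensity")
        ax.set_title(w.uid, fontsize=8)
        fig.tight_layout()
        fig.savefig(out_dir / f"{w.uid}.png", dpi=80)
        plt.close(fig)
        rows.append(w.uid)
    template = out_dir / "labels_template.csv"
    template.write_text("window_id,label\n" + "\n".join(f"{r}," for r in rows) + "\n")
    return template


def read_label_file(path: str | Path) -> dict[str, str]:
    """Read a filled-in label template; rejects labels outside A-G."""
    import csv

    labels: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            label = (row.get("label") or "").strip().upper()
            if not label:
                continue
            labels[row["window_id"]] = validate_label(label)
    return labels


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    """A fitted seven-class SVM for one picker plus its preprocessing recipe."""

    algorithm_id: str
    model: object
    preprocessing: dict
    cv_report: dict
    train_uids: frozenset[str] = frozenset()
    train_sample_ids: frozenset[str] = frozenset()

    def save(self, path: str | Path) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "TrainedClassifier":
        import joblib

        return joblib.load(path)


DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)


def train_classifier(labelled: Sequence[tuple[PeakWindow, str]],
                     algorithm_id: str, seed: int,
                     c_grid: Sequence[float] = DEFAULT_C_GRID,
                     gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
                     cv_folds: int = 5) -> TrainedClassifier:
    """Train the RBF-kernel one-vs-one SVM with 5-fold stratified CV over a
    log grid of (C, gamma) on preprocessed window vectors."""
    from sklearn.model_selection import GridSearchCV, StratifiedKFold
    from sklearn.svm import SVC

    if not labelled:
        raise ValueError("no labelled windows")
    # identical windows (same content hash) count once: duplicates would
    # leak across CV folds and distort hyper-parameter selection
    seen: set[str] = set()
    unique = []
    for w, lbl in labelled:
        if w.uid not in seen:
            seen.add(w.uid)
            unique.append((w, lbl))
    labelled = unique
    y = np.array([validate_label(lbl) for _, lbl in labelled])
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError(f"training needs >= 2 classes, got only {classes.tolist()}")
    small = classes[counts < 2]
    if small.size:
        raise ValueError(f"classes with fewer than 2 members: {small.tolist()}")
    if y.size < 700:
        warnings.warn(f"only {y.size} labelled windows; 700+ recommended",
                      stacklevel=2)
    if counts.min() < 7:
        warnings.warn("smallest class has fewer than 7 windows", stacklevel=2)

    X = np.stack([preprocess_window(w) for w, _ in labelled])
    folds = min(cv_folds, int(counts.min()))
    cv = StratifiedKFold(n_splits=max(2, folds), shuffle=True, random_state=seed)
    search = GridSearchCV(
        SVC(kernel="rbf", decision_function_shape="ovo"),
        {"C": list(c_grid), "gamma": list(gamma_grid)},
        cv=cv, n_jobs=1,
    )
    search.fit(X, y)
    i = search.best_index_
    fold_acc = [float(search.cv_results_[f"split{k}_test_score"][i])
                for k in range(cv.get_n_splits())]
    first = labelled[0][0]
    window_s = float(first.rt_grid[-1] - first.rt_grid[0])
    report = {
        "best_params": dict(search.best_params_),
        "mean_cv_accuracy": float(search.best_score_),
        "fold_accuracies": fold_acc,
        "n_training_windows": int(y.size),
        "class_counts": {str(c): int(n) for c, n in zip(classes, counts)},
    }
    sample_ids = {
        w.source.sample_id for w, _ in labelled
        if w.source is not None and w.source.sample_id
    }
    return TrainedClassifier(
        algorithm_id=algorithm_id,
        model=search.best_estimator_,
        preprocessing={
            "baseline": "linear, anchors = means of first/last 10% of columns",
            "scaling": "global max -> 1.0",
            "window_s": window_s,
            "n_t": int(first.shape[1]),
            "n_mz": int(first.shape[0]),
        },
        cv_report=report,
        train_uids=frozenset(w.uid for w, _ in labelled),
        train_sample_ids=frozenset(sample_ids),
    )


def classify(classifier: TrainedClassifier, peaks: Sequence[DetectedPeak],
             runs: RawRun | Mapping[str, RawRun],
             eics: Mapping[str, EICSet] | None = None) -> list[DetectedPeak]:
    """Assign one of the seven class labels to every peak, preserving order.

    ``runs`` maps sample ids to raw runs (a single run is accepted when all
    peaks come from it)."""
    if isinstance(runs, RawRun):
        runs = {p.sample_id for p in peaks} and {runs.sample_id: runs} or {}
    prep = classifier.preprocessing
    cache: dict[str, EICSet] = dict(eics) if eics else {}
    out: list[DetectedPeak] = []
    vectors = []
    for p in peaks:
        if p.algorithm != classifier.algorithm_id:
            raise ValueError(
                f"peak from {p.algorithm!r} given to the {classifier.algorithm_id!r} classifier"
            )
        run = runs.get(p.sample_id)
        if run is None:
            raise KeyError(f"no raw run supplied for sample {p.sample_id!r}")
        if p.sample_id not in cache:
            cache[p.sample_id] = build_eic_set(run, bin_width=1.0)
        w = extract_window(run, p, window_s=prep["window_s"], n_t=prep["n_t"],
                           n_mz=prep["n_mz"], eics=cache[p.sample_id])
        vectors.append(preprocess_window(w))
        out.append(p)
    if vectors:
        predicted = classifier.model.predict(np.stack(vectors))
        for p, label in zip(out, predicted):
            p.class_label = str(label)
    return out


@dataclass
class ConfusionMatrix:
    """7x7 confusion counts, rows = true class, columns = predicted."""

    counts: np.ndarray
    labels: tuple[str, ...] = CLASS_LABELS

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def misclassification_rates(self) -> dict[str, float]:
        """Per-class rate 1 - diagonal / row sum (NaN for absent classes)."""
        rates = {}
        for i, lbl in enumerate(self.labels):
            row = self.counts[i].sum()
            rates[lbl] = float("nan") if row == 0 else 1.0 - self.counts[i, i] / row
        return rates

    def accuracy(self) -> float:
        return float(np.trace(self.counts) / max(1, self.total))


def evaluate_classifier(classifier: TrainedClassifier,
                        test: Sequence[tuple[PeakWindow, str]]) -> ConfusionMatrix:
    """Confusion matrix of the classifier on a held-out labelled set.

    Raises if any test window was part of the training set (shared uid)."""
    overlap = classifier.train_uids & {w.uid for w, _ in test}
    if overlap:
        raise ValueError(f"{len(overlap)} test windows overlap the training set")
    X = np.stack([preprocess_window(w) for w, _ in test])
    y_true = [validate_label(lbl) for _, lbl in test]
    y_pred = classifier.model.predict(X)
    idx = {lbl: i for i, lbl in enumerate(CLASS_LABELS)}
    counts = np.zeros((7, 7), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[idx[t], idx[str(p)]] += 1
    return ConfusionMatrix(counts=counts)
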