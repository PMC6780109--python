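"""Filtering, deduplication, merging and cross-sample alignment of
classified peaks, plus simple two-group statistics.

The final peak set keeps three disjoint partitions: *high* (classes A/B/C,
fit for immediate downstream analysis), *review* (intermediate classes
E/F/G, kept aside for manual inspection) and *noise* (class D).  Nothing is
silently discarded: every classified input peak ends up in exactly one of
{high, review, noise, dropped-by-min-m/z, collapsed-as-duplicate}.

Two peaks count as duplicates only when BOTH their apexes co-elute within an
RT tolerance AND their fragment spectra agree (cosine above a threshold);
requiring both avoids collapsing co-eluting but chemically distinct
compounds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classification import HIGH_QUALITY, INTERMEDIATE, NOISE_CLASS
from .peak_detection import DetectedPeak

__all__ = [
    "IntegrationConfig",
    "MergedFeature",
    "FinalPeakSet",
    "spectral_cosine",
    "filter_min_mz",
    "dedup_within",
    "merge_across",
    "partition_by_class",
    "align_across_samples",
    "integrate_sample",
    "compute_group_stats",
]

#: duplicate-removal priority: centred apexes (B) quantify most reliably,
#: then the other high-quality classes, then shoulders, narrow, truncated,
#: noise last
DEFAULT_CLASS_PRIORITY: dict[str, int] = {
    "B": 6, "A": 5, "C": 5, "G": 4, "E": 3, "F": 2, "D": 1,
}


@dataclass
class IntegrationConfig:
    min_mz: int = 3
    dedup_rt_tol: float = 2.0
    merge_rt_tol: float = 2.0
    merge_min_spec_sim: float = 0.8
    class_priority: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PRIORITY))

    def __post_init__(self) -> None:
        if self.min_mz < 1:
            raise ValueError("min_mz must be >= 1")
        if self.dedup_rt_tol <= 0 or self.merge_rt_tol <= 0:
            raise ValueError("RT tolerances must be positive")
        if not (0 <= self.merge_min_spec_sim <= 1):
            raise ValueError("merge_min_spec_sim must be in [0, 1]")

    def priority(self, label: str | None) -> int:
        return self.class_priority.get(label or "", 0)


_feature_counter = itertools.count(1)


@dataclass
class MergedFeature:
    """A merged, provenance-carrying feature of the final peak set."""

    feature_id: str
    sample_id: str
    rt_apex: float
    rt_start: float
    rt_end: float
    mz_list: list[tuple[float, float, float]]
    class_label: str
    source_algorithms: set[str]
    source_peak_ids: list[str]
    ri: float | None = None

    @property
    def n_mz(self) -> int:
        return len(self.mz_list)

    @property
    def total_height(self) -> float:
        return float(sum(h for _, h, _ in self.mz_list))

    @property
    def total_area(self) -> float:
        return float(sum(a for _, _, a in self.mz_list))

    @classmethod
    def from_peak(cls, peak: DetectedPeak) -> "MergedFeature":
        if peak.class_label is None:
            raise ValueError(f"peak {peak.peak_id} is unclassified")
        return cls(
            feature_id=f"f{next(_feature_counter):06d}",
            sample_id=peak.sample_id, rt_apex=peak.rt_apex,
            rt_start=peak.rt_start, rt_end=peak.rt_end,
            mz_list=list(peak.mz_list), class_label=peak.class_label,
            source_algorithms={peak.algorithm}, source_peak_ids=[peak.peak_id],
        )


# ---------------------------------------------------------------------------
# spectral similarity and duplicate components
# ---------------------------------------------------------------------------

def spectral_cosine(a: Sequence[tuple[float, float, float]],
                    b: Sequence[tuple[float, float, float]],
                    mz_tol: float = 0.5) -> float:
    """Plain cosine between two fragment spectra aligned on m/z."""
    a_mz = np.array([t[0] for t in a])
    a_h = np.array([t[1] for t in a])
    b_mz = np.array([t[0] for t in b])
    b_h = np.array([t[1] for t in b])
    order = np.argsort(b_mz)
    b_mz, b_h = b_mz[order], b_h[order]
    matched_b = np.zeros_like(a_h)
    used = np.zeros(b_mz.size, dtype=bool)
    for i, mz in enumerate(a_mz):
        k = np.searchsorted(b_mz, mz)
        for j in (k - 1, k):
            if 0 <= j < b_mz.size and not used[j] and abs(b_mz[j] - mz) <= mz_tol:
                matched_b[i] = b_h[j]
                used[j] = True
                break
    na = np.linalg.norm(a_h)
    nb = np.linalg.norm(b_h)
    if na == 0 or nb == 0:
        return 0.0
    cross = float(np.dot(a_h, matched_b))
    return cross / (na * nb)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _duplicate_components(items: Sequence, rt_tol: float, min_sim: float
                          ) -> list[list]:
    """Connected components of the (|dRT| <= tol AND cosine >= sim) graph."""
    order = sorted(range(len(items)), key=lambda i: items[i].rt_apex)
    uf = _UnionFind(len(items))
    for a_pos, i in enumerate(order):
        for j in order[a_pos + 1:]:
            if items[j].rt_apex - items[i].rt_apex > rt_tol:
                break
            if spectral_cosine(items[i].mz_list, items[j].mz_list) >= min_sim:
                uf.union(i, j)
    groups: dict[int, list] = {}
    for i in range(len(items)):
        groups.setdefault(uf.find(i), []).append(items[i])
    # stable order: by earliest member RT
    return sorted(groups.values(), key=lambda g: min(x.rt_apex for x in g))


def _best_of(group: Sequence, cfg: IntegrationConfig):
    """Duplicate representative: highest class priority, then larger summed
    apex intensity, then earlier RT."""
    return min(group, key=lambda p: (-cfg.priority(p.class_label),
                                     -p.total_height, p.rt_apex))


# ---------------------------------------------------------------------------
# filtering / dedup / merge / partition
# ---------------------------------------------------------------------------

def filter_min_mz(peaks: Sequence, min_mz: int) -> list:
    """Keep only pseudospectra with at least ``min_mz`` fragment channels."""
    return [p for p in peaks if p.n_mz >= min_mz]


def dedup_within(peaks: Sequence[DetectedPeak], cfg: IntegrationConfig
                 ) -> list[DetectedPeak]:
    """Remove duplicates among peaks of one algorithm in one sample, keeping
    the class-priority representative of every duplicate group."""
    if not peaks:
        return []
    if len({(p.algorithm, p.sample_id) for p in peaks}) > 1:
        raise ValueError("dedup_within expects peaks of one algorithm and sample")
    groups = _duplicate_components(peaks, cfg.dedup_rt_tol, cfg.merge_min_spec_sim)
    return [_best_of(g, cfg) for g in groups]


def merge_across(per_algorithm_sets: Sequence[Sequence[DetectedPeak]],
                 cfg: IntegrationConfig) -> list[MergedFeature]:
    """Merge per-algorithm peak sets of one sample, collapsing cross-algorithm
    duplicates into single features whose provenance lists every contributing
    algorithm."""
    pooled = [p for peaks in per_algorithm_sets for p in peaks]
    if not pooled:
        return []
    groups = _duplicate_components(pooled, cfg.merge_rt_tol, cfg.merge_min_spec_sim)
    features = []
    for g in groups:
        rep = _best_of(g, cfg)
        if isinstance(rep, MergedFeature):  # idempotent on merged inputs
            feat = replace(rep, mz_list=list(rep.mz_list),
                           source_algorithms=set(rep.source_algorithms),
                           source_peak_ids=list(rep.source_peak_ids))
        else:
            feat = MergedFeature.from_peak(rep)
        feat.source_algorithms = set().union(
            *(p.source_algorithms if isinstance(p, MergedFeature)
              else {p.algorithm} for p in g))
        feat.source_peak_ids = sorted({
            pid for p in g
            for pid in (p.source_peak_ids if isinstance(p, MergedFeature)
                        else [p.peak_id])})
        features.append(feat)
    return features


def partition_by_class(items: Sequence) -> dict[str, list]:
    """Split labelled peaks/features into high / review / noise partitions."""
    parts: dict[str, list] = {"high": [], "review": [], "noise": []}
    for p in items:
        label = p.class_label
        if label is None:
            raise ValueError(f"unlabelled peak {getattr(p, 'peak_id', p)!r}")
        if label in HIGH_QUALITY:
            parts["high"].append(p)
        elif label in NOISE_CLASS:
            parts["noise"].append(p)
        elif label in INTERMEDIATE:
            parts["review"].append(p)
        else:
            raise ValueError(f"unknown class label {label!r}")
    return parts


def integrate_sample(per_algorithm_peaks: Mapping[str, Sequence[DetectedPeak]],
                     cfg: IntegrationConfig | None = None
                     ) -> tuple[dict[str, list[MergedFeature]], dict[str, int]]:
    """Filter, dedup, merge and partition one sample's classified peaks.

    Returns the three partitions plus an audit of where every input peak
    went; the audit satisfies
    ``input == dropped_min_mz + collapsed_as_duplicate + high + review + noise``.
    """
    cfg = cfg or IntegrationConfig()
    n_input = sum(len(v) for v in per_algorithm_peaks.values())
    surviving = {}
    n_after_filter = 0
    for alg, peaks in per_algorithm_peaks.items():
        kept = filter_min_mz(list(peaks), cfg.min_mz)
        n_after_filter += len(kept)
        surviving[alg] = dedup_within(kept, cfg)
    n_after_dedup = sum(len(v) for v in surviving.values())
    features = merge_across(list(surviving.values()), cfg)
    parts = partition_by_class(features)
    audit = {
        "input": n_input,
        "dropped_min_mz": n_input - n_after_filter,
        "collapsed_as_duplicate": (n_after_filter - n_after_dedup)
                                  + (n_after_dedup - len(features)),
        "high": len(parts["high"]),
        "review": len(parts["review"]),
        "noise": len(parts["noise"]),
    }
    return parts, audit


# ---------------------------------------------------------------------------
# cross-sample alignment
# ---------------------------------------------------------------------------

@dataclass
class FinalPeakSet:
    """Merged, partitioned features with cross-sample intensity tables."""

    samples: list[str]
    partitions: dict[str, list[MergedFeature]]
    tables: dict[tuple[str, str], pd.DataFrame]
    mask: pd.DataFrame

    def partition(self, name: str) -> list[MergedFeature]:
        if name not in self.partitions:
            raise KeyError(f"unknown partition {name!r}")
        return self.partitions[name]

    def intensity_matrix(self, kind: str = "height", partition: str = "high"
                         ) -> pd.DataFrame:
        return self.tables[(partition, kind)]


def align_across_samples(per_sample: Mapping[str, dict[str, list[MergedFeature]]],
                         cfg: IntegrationConfig | None = None) -> FinalPeakSet:
    """Cluster per-sample features into cross-sample rows of a feature table.

    Greedy clustering seeded from the most intense feature: a feature joins
    the first cluster whose seed co-elutes within ``merge_rt_tol`` and has a
    spectral cosine >= ``merge_min_spec_sim``; otherwise it seeds a new
    cluster.  Cells hold the summed apex height (and, in the area variant,
    integrated area) over the feature's m/z list; absent features are 0 with
    a separate missingness mask.
    """
    cfg = cfg or IntegrationConfig()
    if not per_sample:
        raise ValueError("need at least one sample")
    samples = list(per_sample)
    partitions: dict[str, list[MergedFeature]] = {}
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    mask_high = None
    prefix = {"high": "H", "review": "R", "noise": "N"}

    for part in ("high", "review", "noise"):
        pooled: list[tuple[str, MergedFeature]] = [
            (s, f) for s in samples for f in per_sample[s].get(part, [])
        ]
        pooled.sort(key=lambda t: -t[1].total_height)
        clusters: list[dict] = []
        for sample, feat in pooled:
            placed = False
            for cl in clusters:
                seed = cl["seed"]
                if (abs(feat.rt_apex - seed.rt_apex) <= cfg.merge_rt_tol
                        and spectral_cosine(feat.mz_list, seed.mz_list)
                        >= cfg.merge_min_spec_sim):
                    cl["members"].append((sample, feat))
                    placed = True
                    break
            if not placed:
                clusters.append({"seed": feat, "members": [(sample, feat)]})
        clusters.sort(key=lambda cl: cl["seed"].rt_apex)
        reps: list[MergedFeature] = []
        height = np.zeros((len(clusters), len(samples)))
        area = np.zeros_like(height)
        for i, cl in enumerate(clusters):
            seed = cl["seed"]
            rep = MergedFeature(
                feature_id=f"{prefix[part]}{i + 1:04d}",
                sample_id="", rt_apex=seed.rt_apex, rt_start=seed.rt_start,
                rt_end=seed.rt_end, mz_list=list(seed.mz_list),
                class_label=seed.class_label,
                source_algorithms=set().union(
                    *(f.source_algorithms for _, f in cl["members"])),
                source_peak_ids=sorted(
                    pid for _, f in cl["members"] for pid in f.source_peak_ids),
                ri=seed.ri,
            )
            reps.append(rep)
            for sample, feat in cl["members"]:
                j = samples.index(sample)
                height[i, j] += feat.total_height
                area[i, j] += feat.total_area
        index = [r.feature_id for r in reps]
        partitions[part] = reps
        tables[(part, "height")] = pd.DataFrame(height, index=index, columns=samples)
        tables[(part, "area")] = pd.DataFrame(area, index=index, columns=samples)
        if part == "high":
            mask_high = tables[(part, "height")] > 0
    return FinalPeakSet(samples=samples, partitions=partitions, tables=tables,
                        mask=mask_high if mask_high is not None else pd.DataFrame())


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def compute_group_stats(table: pd.DataFrame, groups: Mapping[str, str]
                        ) -> pd.DataFrame:
    """Per-feature fold change and Welch p-value between two conditions.

    The test is Welch's two-sample t-test on log2(intensity + 1).  The fold
    change is the ratio of raw group means r = mean(cond1)/mean(cond2),
    displayed as r when r >= 1 and as -1/r when r < 1, so a negative value
    denotes a decrease in the first condition.  Features where either group
    is all-zero are flagged and not tested.
    """
    from scipy import stats

    conditions = sorted(set(groups.values()))
    if len(conditions) != 2:
        raise ValueError(f"exactly 2 conditions required, got {conditions}")
    cols = {c: [s for s in table.columns if groups.get(s) == c]
            for c in conditions}
    for c, cs in cols.items():
        if len(cs) < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 samples")
    c1, c2 = conditions
    rows = []
    for fid, row in table.iterrows():
        x1 = row[cols[c1]].to_numpy(dtype=float)
        x2 = row[cols[c2]].to_numpy(dtype=float)
        if (x1 == 0).all() or (x2 == 0).all():
            rows.append({"feature_id": fid, "fold_change": np.nan,
                         "p_value": np.nan, "flag": "zero_group"})
            continue
        m1, m2 = x1.mean(), x2.mean()
        r = m1 / m2
        fold = r if r >= 1 else -1.0 / r
        l1, l2 = np.log2(x1 + 1), np.log2(x2 + 1)
        if np.allclose(l1.var(), 0) and np.allclose(l2.var(), 0):
            p = 1.0 if np.isclose(l1.mean(), l2.mean()) else 0.0
        else:
            p = float(stats.ttest_ind(l1, l2, equal_var=False).pvalue)
        rows.append({"feature_id": fid, "fold_change": float(fold),
                     "p_value": p, "flag": ""})
    out = pd.DataFrame(rows, columns=["feature_id", "fold_change", "p_value", "flag"])
    return out.set_index("feature_id")


def benjamini_hochberg(p_values: pd.Series) -> pd.Series:
    """Optional multiple-testing correction (off by default downstream)."""
    from statsmodels.stats.multitest import multipletests

    ok = p_values.notna()
    adjusted = pd.Series(np.nan, index=p_values.index)
    if ok.any():
        adjusted[ok] = multipletests(p_values[ok], method="fdr_bh")[1]
    return adjusted
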