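import itertools

import numpy as np
import pandas as pd
import pytest

from peakforge.integration import (FinalPeakSet, IntegrationConfig,
                                   MergedFeature, align_across_samples,
                                   compute_group_stats, dedup_within,
                                   filter_min_mz, integrate_sample,
                                   merge_across, partition_by_class,
                                   spectral_cosine)
from tests.conftest import make_peak


def brute_force_components(peaks, rt_tol, min_sim):
    """Independent BFS components of the duplicate graph."""
    n = len(peaks)
    adj = {i: [] for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        if (abs(peaks[i].rt_apex - peaks[j].rt_apex) <= rt_tol
                and spectral_cosine(peaks[i].mz_list, peaks[j].mz_list)
                >= min_sim):
            adj[i].append(j)
            adj[j].append(i)
    seen, comps = set(), 0
    for i in range(n):
        if i in seen:
            continue
        comps += 1
        stack = [i]
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            stack.extend(adj[k])
    return comps


class TestFilter:
    def test_boundary_inclusive(self, twelve_peak_fixture):
        peaks = twelve_peak_fixture["alg1"]
        kept = filter_min_mz(peaks, 3)
        assert [p.peak_id for p in kept] == ["p01", "p02", "p03", "p04", "p05"]

    def test_two_mz_rejected_at_default(self):
        p = make_peak(10.0, [(50.0, 1.0), (60.0, 1.0)])
        assert filter_min_mz([p], 3) == []

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        peaks = [make_peak(float(i), [(50.0 + j, 1.0)
                                      for j in range(rng.integers(1, 7))])
                 for i in range(30)]
        for n in (1, 3, 5):
            expected = sum(1 for p in peaks if len(p.mz_list) >= n)
            assert len(filter_min_mz(peaks, n)) == expected


class TestDedup:
    def test_priority_keeps_best_class(self, twelve_peak_fixture):
        cfg = IntegrationConfig()
        out = dedup_within(filter_min_mz(twelve_peak_fixture["alg1"], 3), cfg)
        assert sorted(p.peak_id for p in out) == ["p01", "p03", "p04"]

    def test_far_apart_peaks_survive(self):
        cfg = IntegrationConfig()
        peaks = [make_peak(100.0, [(50.0, 1.0)] * 1, "B"),
                 make_peak(110.0, [(50.0, 1.0)], "B")]
        assert len(dedup_within(peaks, cfg)) == 2

    def test_component_oracle(self):
        rng = np.random.default_rng(3)
        spectra = [[(50.0, 100.0), (60.0, 50.0)], [(80.0, 100.0), (90.0, 40.0)]]
        peaks = [make_peak(float(rng.uniform(0, 40)),
                           spectra[rng.integers(0, 2)], "B")
                 for _ in range(25)]
        cfg = IntegrationConfig()
        out = dedup_within(peaks, cfg)
        assert len(out) == brute_force_components(peaks, cfg.dedup_rt_tol,
                                                  cfg.merge_min_spec_sim)

    def test_idempotent(self, twelve_peak_fixture):
        cfg = IntegrationConfig()
        once = dedup_within(twelve_peak_fixture["alg1"], cfg)
        assert dedup_within(once, cfg) == once

    def test_mixed_sources_rejected(self):
        peaks = [make_peak(1.0, [(50.0, 1.0)], "B", algorithm="a"),
                 make_peak(2.0, [(50.0, 1.0)], "B", algorithm="b")]
        with pytest.raises(ValueError):
            dedup_within(peaks, IntegrationConfig())


class TestMerge:
    def test_cross_algorithm_overlap(self, twelve_peak_fixture):
        cfg = IntegrationConfig()
        alg1 = dedup_within(filter_min_mz(twelve_peak_fixture["alg1"], 3), cfg)
        alg2 = dedup_within(filter_min_mz(twelve_peak_fixture["alg2"], 3), cfg)
        feats = merge_across([alg1, alg2], cfg)
        assert len(feats) == 6
        shared = [f for f in feats if len(f.source_algorithms) == 2]
        assert len(shared) == 1
        assert shared[0].rt_apex == pytest.approx(100.0)
        assert shared[0].class_label == "B"  # priority representative

    def test_disjoint_sets_union(self):
        cfg = IntegrationConfig()
        a = [make_peak(100.0 * i, [(50.0, 1.0)] * 1, "B", "alg1")
             for i in range(1, 5)]
        b = [make_peak(1000.0 + 100.0 * i, [(60.0, 1.0)], "B", "alg2")
             for i in range(5)]
        assert len(merge_across([a, b], cfg)) == 9

    def test_oracle_component_count(self):
        rng = np.random.default_rng(12)
        spec = [(50.0, 100.0), (60.0, 70.0), (70.0, 30.0)]
        pooled = []
        for alg in ("alg1", "alg2"):
            pooled.append([make_peak(float(rng.uniform(0, 30)), spec, "B", alg)
                           for _ in range(12)])
        cfg = IntegrationConfig()
        feats = merge_across(pooled, cfg)
        flat = [p for peaks in pooled for p in peaks]
        assert len(feats) == brute_force_components(flat, cfg.merge_rt_tol,
                                                    cfg.merge_min_spec_sim)

    def test_idempotent_on_features(self, twelve_peak_fixture):
        cfg = IntegrationConfig()
        feats = merge_across([dedup_within(
            filter_min_mz(twelve_peak_fixture["alg1"], 3), cfg)], cfg)
        again = merge_across([feats], cfg)
        assert len(again) == len(feats)


class TestPartition:
    def test_all_seven_labels(self):
        peaks = [make_peak(10.0 * i, [(50.0, 1.0)], lbl)
                 for i, lbl in enumerate("ABCDEFG")]
        parts = partition_by_class(peaks)
        assert len(parts["high"]) == 3
        assert len(parts["review"]) == 3
        assert len(parts["noise"]) == 1

    def test_single_class(self):
        peaks = [make_peak(10.0 * i, [(50.0, 1.0)], "B") for i in range(4)]
        parts = partition_by_class(peaks)
        assert len(parts["high"]) == 4
        assert not parts["review"] and not parts["noise"]

    def test_unlabelled_rejected(self):
        with pytest.raises(ValueError, match="unlabelled"):
            partition_by_class([make_peak(1.0, [(50.0, 1.0)])])


class TestConservation:
    def test_five_way_identity(self, twelve_peak_fixture):
        parts, audit = integrate_sample(twelve_peak_fixture)
        assert audit["input"] == 12
        assert audit["dropped_min_mz"] == 2
        assert audit["collapsed_as_duplicate"] == 4
        assert (audit["high"], audit["review"], audit["noise"]) == (2, 3, 1)
        assert (audit["dropped_min_mz"] + audit["collapsed_as_duplicate"]
                + audit["high"] + audit["review"] + audit["noise"]) \
            == audit["input"]

    def test_high_partition_pure(self, twelve_peak_fixture):
        parts, _ = integrate_sample(twelve_peak_fixture)
        assert all(f.class_label in "ABC" for f in parts["high"])


class TestAlignment:
    def feature(self, rt, sample, height=100.0, label="B"):
        return MergedFeature(
            feature_id=f"f_{sample}_{rt:.0f}", sample_id=sample,
            rt_apex=rt, rt_start=rt - 2, rt_end=rt + 2,
            mz_list=[(50.0, height, 2 * height), (60.0, height / 2, height)],
            class_label=label, source_algorithms={"alg1"},
            source_peak_ids=[f"p_{sample}_{rt:.0f}"])

    def test_shared_feature_single_row(self):
        samples = [f"s{i}" for i in range(5)]
        per_sample = {s: {"high": [self.feature(100.0, s)], "review": [],
                          "noise": []} for s in samples}
        ps = align_across_samples(per_sample)
        table = ps.intensity_matrix("height", "high")
        assert table.shape == (1, 5)
        assert (table.iloc[0] > 0).all()

    def test_unique_feature_sparse_row(self):
        per_sample = {
            "s1": {"high": [self.feature(100.0, "s1")], "review": [], "noise": []},
            "s2": {"high": [self.feature(100.0, "s2"),
                            self.feature(400.0, "s2")], "review": [], "noise": []},
        }
        ps = align_across_samples(per_sample)
        table = ps.intensity_matrix("height", "high")
        assert table.shape == (2, 2)
        unique_row = table.loc[(table > 0).sum(axis=1) == 1]
        assert len(unique_row) == 1
        assert ps.mask.to_numpy().sum() == 3

    def test_row_count_matches_greedy_oracle(self):
        rng = np.random.default_rng(5)
        per_sample = {}
        rts = rng.uniform(100, 140, 20)
        for i in range(4):
            sample = f"s{i}"
            per_sample[sample] = {"high": [self.feature(float(rt), sample)
                                           for rt in rts[i * 5:(i + 1) * 5]],
                                  "review": [], "noise": []}
        cfg = IntegrationConfig()
        ps = align_across_samples(per_sample, cfg)
        # oracle: independent greedy pass in the same intensity order
        pooled = sorted([f for parts in per_sample.values()
                         for f in parts["high"]],
                        key=lambda f: -f.total_height)
        seeds = []
        for f in pooled:
            if not any(abs(f.rt_apex - s.rt_apex) <= cfg.merge_rt_tol
                       and spectral_cosine(f.mz_list, s.mz_list)
                       >= cfg.merge_min_spec_sim for s in seeds):
                seeds.append(f)
        assert len(ps.partition("high")) == len(seeds)

    def test_no_residual_duplicates_in_partition(self):
        rng = np.random.default_rng(6)
        per_sample = {"s1": {"high": [self.feature(float(rt), "s1")
                                      for rt in rng.uniform(100, 120, 10)],
                             "review": [], "noise": []}}
        cfg = IntegrationConfig()
        ps = align_across_samples(per_sample, cfg)
        reps = ps.partition("high")
        for a, b in itertools.combinations(reps, 2):
            close = abs(a.rt_apex - b.rt_apex) <= cfg.merge_rt_tol
            similar = spectral_cosine(a.mz_list, b.mz_list) \
                >= cfg.merge_min_spec_sim
            assert not (close and similar)


class TestGroupStats:
    def table(self, values):
        return pd.DataFrame([values],
                            index=["F0001"],
                            columns=[f"s{i}" for i in range(len(values))])

    def groups(self, n_each=3):
        g = {}
        for i in range(n_each):
            g[f"s{i}"] = "case"
            g[f"s{i + n_each}"] = "control"
        return g

    def test_fold_change_positive(self):
        t = self.table([20.0, 21.0, 19.0, 10.0, 10.5, 9.5])
        out = compute_group_stats(t, self.groups())
        assert out.loc["F0001", "fold_change"] == pytest.approx(2.0, rel=0.01)

    def test_fold_change_sign_convention(self):
        t = self.table([10.0, 10.5, 9.5, 20.0, 21.0, 19.0])
        out = compute_group_stats(t, self.groups())
        assert out.loc["F0001", "fold_change"] == pytest.approx(-2.0, rel=0.01)

    def test_identical_groups(self):
        t = self.table([10.0, 10.0, 10.0, 10.0, 10.0, 10.0])
        out = compute_group_stats(t, self.groups())
        assert out.loc["F0001", "fold_change"] == pytest.approx(1.0)
        assert out.loc["F0001", "p_value"] == pytest.approx(1.0)

    def test_zero_group_flagged(self):
        t = self.table([0.0, 0.0, 0.0, 5.0, 6.0, 7.0])
        out = compute_group_stats(t, self.groups())
        assert out.loc["F0001", "flag"] == "zero_group"
        assert np.isnan(out.loc["F0001", "p_value"])

    def test_too_few_samples_rejected(self):
        t = self.table([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="fewer than 2"):
            compute_group_stats(t, {"s0": "case", "s1": "case", "s2": "control"})

    def test_three_conditions_rejected(self):
        t = self.table([1.0, 2.0, 3.0, 4.0])
        groups = {"s0": "a", "s1": "a", "s2": "b", "s3": "c"}
        with pytest.raises(ValueError, match="2 conditions"):
            compute_group_stats(t, groups)
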