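import warnings

import numpy as np
import pytest

from peakforge.classification import (ConfusionMatrix, PeakWindow,
                                      evaluate_classifier, export_annotation_sheet,
                                      extract_window, preprocess_window,
                                      read_label_file, sample_training_peaks,
                                      train_classifier, classify)
from peakforge.peak_detection import build_eic_set, expand_grid
from peakforge.synthetic_data import generate_class_window
from tests.conftest import make_peak


class TestExtractWindow:
    def test_geometry(self, noisy_run):
        run, truth = noisy_run
        t = truth.true_peaks[3]
        peak = make_peak(t.rt_apex, [(mz, 100.0) for mz in t.mzs],
                         algorithm="matched_filter", sample_id=run.sample_id)
        w = extract_window(run, peak, window_s=8.0, n_t=41, n_mz=10)
        assert w.shape == (10, 41)
        assert w.rt_grid[0] == pytest.approx(t.rt_apex - 4.0)
        assert w.rt_grid[-1] == pytest.approx(t.rt_apex + 4.0)

    def test_channel_truncation_keeps_highest(self, noisy_run):
        run, _ = noisy_run
        spectrum = [(50.0 + i, 100.0 - i) for i in range(12)]
        peak = make_peak(200.0, spectrum, sample_id=run.sample_id)
        w = extract_window(run, peak, n_mz=10)
        assert w.shape[0] == 10
        np.testing.assert_allclose(w.mz_centers, [s[0] for s in spectrum[:10]])

    def test_run_border_zero_filled(self, noisy_run):
        run, _ = noisy_run
        lo, hi = run.rt_range
        peak = make_peak(hi - 2.0, [(73.0, 100.0)], sample_id=run.sample_id)
        w = extract_window(run, peak, window_s=8.0)
        outside = w.rt_grid > hi
        assert outside.any()
        assert np.all(w.intensities[:, outside] == 0)

    def test_apex_outside_run_rejected(self, noisy_run):
        run, _ = noisy_run
        peak = make_peak(5.0, [(73.0, 1.0)], sample_id=run.sample_id)
        with pytest.raises(ValueError, match="outside"):
            extract_window(run, peak)


class TestPreprocess:
    def test_baseline_offset_invariance(self):
        w, _ = generate_class_window("B", seed=3)
        offset = w.intensities + np.arange(1, 11)[:, None] * 7.0
        w2 = PeakWindow(intensities=offset, mz_centers=w.mz_centers,
                        rt_grid=w.rt_grid)
        np.testing.assert_allclose(preprocess_window(w), preprocess_window(w2),
                                   atol=1e-9)

    def test_scale_invariance_and_unit_max(self):
        w, _ = generate_class_window("B", seed=4)
        scaled = PeakWindow(intensities=w.intensities * 123.0,
                            mz_centers=w.mz_centers, rt_grid=w.rt_grid)
        v1, v2 = preprocess_window(w), preprocess_window(scaled)
        np.testing.assert_allclose(v1, v2, atol=1e-12)
        assert v1.max() == pytest.approx(1.0)

    def test_all_zero_window(self):
        w = PeakWindow(intensities=np.zeros((3, 11)),
                       mz_centers=np.zeros(3), rt_grid=np.linspace(0, 8, 11))
        assert not preprocess_window(w).any()


class TestTraining:
    def test_single_class_rejected(self):
        windows = [generate_class_window("B", seed=s) for s in range(4)]
        with pytest.raises(ValueError, match="2 classes"):
            train_classifier(windows, "matched_filter", seed=1)

    def test_tiny_class_rejected(self):
        windows = [generate_class_window("B", seed=s) for s in range(4)]
        windows.append(generate_class_window("D", seed=9))
        with pytest.raises(ValueError, match="fewer than 2"):
            train_classifier(windows, "matched_filter", seed=1)

    def test_small_corpus_warns(self):
        windows = [generate_class_window(lbl, seed=s)
                   for lbl in "BD" for s in range(3)]
        with pytest.warns(UserWarning, match="700"):
            train_classifier(windows, "matched_filter", seed=1)

    def test_duplicated_data_same_hyperparameters(self, small_corpus):
        subset = small_corpus[::3]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c1 = train_classifier(subset, "matched_filter", seed=2)
            c2 = train_classifier(list(subset) + list(subset),
                                  "matched_filter", seed=2)
        assert c1.cv_report["best_params"] == c2.cv_report["best_params"]

    def test_training_accuracy_floor(self, small_classifier, small_corpus):
        """Self-prediction on separable template classes stays >= 95%."""
        X = np.stack([preprocess_window(w) for w, _ in small_corpus])
        y = np.array([lbl for _, lbl in small_corpus])
        acc = (small_classifier.model.predict(X) == y).mean()
        assert acc >= 0.95


class TestClassify:
    def test_template_peaks_get_expected_classes(self, small_classifier,
                                                 silent_run):
        run, truth = silent_run
        isolated = truth.of_label("B")
        peaks = [make_peak(t.rt_apex, [(mz, 100.0) for mz in t.mzs],
                           algorithm="matched_filter", sample_id=run.sample_id)
                 for t in isolated]
        classify(small_classifier, peaks, {run.sample_id: run})
        labels = [p.class_label for p in peaks]
        assert all(lbl in "ABC" for lbl in labels)
        assert labels.count("B") >= 0.8 * len(labels)

    def test_algorithm_mismatch_rejected(self, small_classifier, noisy_run):
        run, _ = noisy_run
        peak = make_peak(100.0, [(73.0, 1.0)], algorithm="cwt",
                         sample_id=run.sample_id)
        with pytest.raises(ValueError, match="cwt"):
            classify(small_classifier, [peak], {run.sample_id: run})

    def test_empty_input(self, small_classifier, noisy_run):
        run, _ = noisy_run
        assert classify(small_classifier, [], {run.sample_id: run}) == []


class TestEvaluate:
    def test_confusion_row_sums_and_total(self, small_classifier):
        test = [generate_class_window(lbl, seed=1000 + s)
                for lbl in "ABCDEFG" for s in range(5)]
        cm = evaluate_classifier(small_classifier, test)
        assert cm.total == len(test)
        np.testing.assert_array_equal(cm.counts.sum(axis=1), [5] * 7)

    def test_training_overlap_rejected(self, small_classifier, small_corpus):
        with pytest.raises(ValueError, match="overlap"):
            evaluate_classifier(small_classifier, small_corpus[:5])

    def test_perfect_predictions_diagonal(self):
        counts = np.diag([3, 1, 4, 1, 5, 9, 2])
        cm = ConfusionMatrix(counts=counts)
        assert cm.accuracy() == 1.0
        assert all(v == 0.0 for v in cm.misclassification_rates().values())


class TestSampling:
    @pytest.fixture()
    def sampled(self, noisy_run):
        run, _ = noisy_run
        grids = {"matched_filter": expand_grid(
            "matched_filter", {"fwhm": [2.35, 4.0], "snthresh": [3.0, 6.0],
                               "step": [1.0]})}
        return sample_training_peaks([run], ["matched_filter"], grids,
                                     n_target=10, seed=21)

    def test_down_sampled_to_target(self, sampled):
        assert len(sampled["matched_filter"]) == 10

    def test_deterministic(self, noisy_run, sampled):
        run, _ = noisy_run
        grids = {"matched_filter": expand_grid(
            "matched_filter", {"fwhm": [2.35, 4.0], "snthresh": [3.0, 6.0],
                               "step": [1.0]})}
        again = sample_training_peaks([run], ["matched_filter"], grids,
                                      n_target=10, seed=21)
        assert [w.uid for w in again["matched_filter"]] == \
               [w.uid for w in sampled["matched_filter"]]

    def test_short_supply_warns_and_returns_all(self, noisy_run):
        run, _ = noisy_run
        grids = {"matched_filter": expand_grid(
            "matched_filter", {"fwhm": [2.35], "snthresh": [8.0], "step": [1.0]})}
        with pytest.warns(UserWarning, match="returning all"):
            out = sample_training_peaks([run], ["matched_filter"], grids,
                                        n_target=10000, seed=2)
        assert 0 < len(out["matched_filter"]) < 10000


class TestAnnotationSheet:
    def test_export_and_label_round_trip(self, tmp_path):
        windows = [generate_class_window(lbl, seed=3)[0] for lbl in "ABCDEFG"]
        template = export_annotation_sheet(windows, tmp_path)
        pngs = sorted(tmp_path.glob("*.png"))
        assert len(pngs) == 7
        lines = template.read_text().strip().splitlines()
        assert len(lines) == 8  # header + 7 rows
        # idempotent re-export: same ids, same file set
        template2 = export_annotation_sheet(windows, tmp_path)
        assert template2.read_text() == template.read_text()
        assert len(sorted(tmp_path.glob("*.png"))) == 7
        # fill in labels and read back
        filled = tmp_path / "labels.csv"
        filled.write_text("window_id,label\n" + "\n".join(
            f"{w.uid},{lbl}" for w, lbl in zip(windows, "ABCDEFG")) + "\n")
        labels = read_label_file(filled)
        assert len(labels) == 7

    def test_invalid_label_rejected(self, tmp_path):
        bad = tmp_path / "labels.csv"
        bad.write_text("window_id,label\nw1,H\n")
        with pytest.raises(ValueError, match="unknown class label"):
            read_label_file(bad)
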