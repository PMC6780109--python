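import warnings

import numpy as np
import pytest

from peakforge.peak_detection import DetectedPeak
from peakforge.synthetic_data import (CompoundSpec, NoiseModel, demo_compounds,
                                      generate_training_corpus, simulate_run)

SMALL_RT_RANGE = (60.0, 360.0)


@pytest.fixture(scope="session")
def small_panel():
    return demo_compounds(10, seed=1, rt_range=SMALL_RT_RANGE, n_shoulder_pairs=1)


@pytest.fixture(scope="session")
def noisy_run(small_panel):
    run, truth = simulate_run(small_panel, NoiseModel(bleed_onset=300.0),
                              rt_range=SMALL_RT_RANGE, seed=3, sample_id="noisy")
    return run, truth


@pytest.fixture(scope="session")
def silent_run(small_panel):
    run, truth = simulate_run(small_panel, NoiseModel.silent(),
                              rt_range=SMALL_RT_RANGE, seed=3, sample_id="silent")
    return run, truth


@pytest.fixture(scope="session")
def small_corpus():
    return generate_training_corpus(n_per_class=30, seed=11)


@pytest.fixture(scope="session")
def small_classifier(small_corpus):
    from peakforge.classification import train_classifier

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_classifier(small_corpus, "matched_filter", seed=11)


def make_peak(rt, spectrum, label=None, algorithm="alg1", sample_id="s",
              half_width=2.0, peak_id=None):
    """Hand-built pseudospectrum peak for filter/merge fixtures."""
    kwargs = {} if peak_id is None else {"peak_id": peak_id}
    return DetectedPeak(
        algorithm=algorithm, sample_id=sample_id,
        rt_apex=rt, rt_start=rt - half_width, rt_end=rt + half_width,
        mz_list=[(mz, h, 2.0 * h) for mz, h in spectrum],
        class_label=label, **kwargs)


@pytest.fixture()
def twelve_peak_fixture():
    """Hand-enumerated 12-peak scenario with known duplicates and m/z counts.

    Expected bookkeeping (min_mz=3, rt tolerances 2 s, cosine 0.8):
    2 dropped by min-m/z, 4 collapsed as duplicates, and 6 final features
    partitioned 2 high / 3 review / 1 noise.
    """
    spec_a = [(50.0, 100.0), (60.0, 50.0), (70.0, 25.0)]
    spec_b = [(81.0, 100.0), (91.0, 60.0), (101.0, 30.0)]
    spec_c = [(55.0, 100.0), (65.0, 80.0), (75.0, 60.0), (85.0, 40.0)]
    spec_c2 = [(55.0, 90.0), (65.0, 75.0), (75.0, 55.0), (85.0, 35.0)]
    spec_d = [(140.0, 100.0), (150.0, 70.0), (160.0, 40.0)]
    spec_d2 = [(140.0, 95.0), (150.0, 65.0), (160.0, 45.0)]
    alg1 = [
        make_peak(100.0, spec_a, "B", "alg1", peak_id="p01"),
        make_peak(101.0, [(m, h / 2) for m, h in spec_a], "E", "alg1", peak_id="p02"),
        make_peak(100.5, spec_b, "A", "alg1", peak_id="p03"),
        make_peak(200.0, spec_c, "G", "alg1", peak_id="p04"),
        make_peak(200.5, spec_c2, "D", "alg1", peak_id="p05"),
        make_peak(300.0, [(120.0, 100.0), (130.0, 50.0)], "B", "alg1", peak_id="p06"),
    ]
    alg2 = [
        make_peak(100.2, [(50.0, 95.0), (60.0, 52.0), (70.0, 24.0)], "C", "alg2",
                  peak_id="p07"),
        make_peak(400.0, spec_d, "D", "alg2", peak_id="p08"),
        make_peak(401.5, spec_d2, "D", "alg2", peak_id="p09"),
        make_peak(500.0, [(170.0, 100.0), (180.0, 60.0), (190.0, 30.0)], "F",
                  "alg2", peak_id="p10"),
        make_peak(600.0, [(200.0, 100.0)], "B", "alg2", peak_id="p11"),
        make_peak(700.0, [(210.0, 100.0), (220.0, 90.0), (230.0, 80.0)], "E",
                  "alg2", peak_id="p12"),
    ]
    return {"alg1": alg1, "alg2": alg2}
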