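"""Simulation of GC-MS runs and labelled peak-quality windows.

The generator emulates the setting the workflow is built for: electron-
ionisation GC-MS runs in which each compound elutes as a ~4 s wide
chromatographic peak mirrored on several fragment m/z channels, on top of a
drifting baseline with late-run column bleed, truncated-Gaussian shot noise
and occasional single-scan spikes.  Ground truth (every injected apex, its
bounds and an injected quality label) is known by construction, which makes
picker recovery, classifier accuracy and end-to-end integration directly
measurable.

``generate_class_window`` builds template windows for the seven peak-quality
classes (A: apex left, B: centred, C: apex right, D: noise, E: narrow peak
with wide margins, F: border-truncated, G: merged/shoulder pair);
``verify_window_label`` is the independent rule-based checker that re-derives
a template's label from apex position, width fraction, border truncation and
local-maxima count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc, erfcx

from .classification import CLASS_LABELS, PeakWindow, validate_label
from .io_formats import RawRun, Scan, SpectrumRecord

__all__ = [
    "CompoundSpec",
    "NoiseModel",
    "TruePeak",
    "GroundTruth",
    "simulate_run",
    "generate_class_window",
    "generate_training_corpus",
    "verify_window_label",
    "demo_compounds",
    "demo_alkane_anchors",
    "library_from_compounds",
    "DEFAULT_RT_RANGE",
    "DEFAULT_SCAN_HZ",
    "BLEED_IONS",
]

#: canonical demo acquisition: a 25-minute GC program sampled at 5 Hz
DEFAULT_RT_RANGE: tuple[float, float] = (60.0, 1560.0)
DEFAULT_SCAN_HZ: float = 5.0

#: polysiloxane column-bleed fragment ions
BLEED_IONS: tuple[float, ...] = (207.0, 281.0, 355.0)


@dataclass
class CompoundSpec:
    """One injected compound: elution position/shape and fragment spectrum.

    The default FWHM of 2.35 s gives a Gaussian with sigma = 1 s, i.e. a full
    base width (4 sigma) of ~4 s, the average full peak width the workflow is
    calibrated for.  ``shape="emg"`` adds exponential tailing with time
    constant ``emg_tau``.
    """

    name: str
    rt_apex: float
    fragments: list[tuple[float, float]]
    max_intensity: float = 1e5
    fwhm: float = 2.35
    shape: str = "gaussian"
    emg_tau: float = 0.0

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError(f"compound {self.name!r} needs >= 1 fragment")
        rel = [a for _, a in self.fragments]
        if max(rel) != 1.0 or min(rel) <= 0 or max(rel) > 1.0:
            raise ValueError(
                f"compound {self.name!r}: relative abundances must be in (0, 1] "
                "with at least one equal to 1"
            )
        if self.shape not in ("gaussian", "emg"):
            raise ValueError(f"unknown peak shape {self.shape!r}")
        if self.emg_tau < 0:
            raise ValueError("emg_tau must be >= 0")

    @property
    def sigma(self) -> float:
        return self.fwhm / 2.3548

    def profile(self, t: np.ndarray) -> np.ndarray:
        """Unit-height elution profile on the time grid ``t``."""
        s = self.sigma
        if self.shape == "gaussian" or self.emg_tau <= 1e-9:
            y = np.exp(-0.5 * ((t - self.rt_apex) / s) ** 2)
        else:
            # overflow-safe EMG: erfc(z)*exp(c - u/tau) == erfcx(z)*exp(-u^2/2s^2)
            tau = self.emg_tau
            u = t - self.rt_apex
            z = (s / tau - u / s) / math.sqrt(2)
            y = np.empty_like(u)
            lead = z >= 0  # left of the tail: erfcx form avoids exp overflow
            y[lead] = erfcx(z[lead]) * np.exp(-0.5 * (u[lead] / s) ** 2)
            tail = ~lead  # right tail: erfc in [1,2], exponent is negative
            y[tail] = erfc(z[tail]) * np.exp(
                0.5 * (s / tau) ** 2 - u[tail] / tau)
            top = y.max()
            if top > 0:
                y = y / top
        return y


@dataclass
class NoiseModel:
    """Baseline, drift, late-run column bleed, shot noise and spikes.

    All levels are detector counts. Bleed is a monotone ramp on the
    polysiloxane fragment channels starting at ``bleed_onset``.
    """

    baseline_level: float = 200.0
    baseline_drift_slope: float = 0.2
    bleed_onset: float = 1200.0
    bleed_slope: float = 25.0
    shot_noise_sd: float = 20.0
    spike_rate: float = 0.5  # events per minute

    def __post_init__(self) -> None:
        for name in ("baseline_level", "baseline_drift_slope", "bleed_onset",
                     "bleed_slope", "shot_noise_sd", "spike_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(baseline_level=0, baseline_drift_slope=0, bleed_onset=0,
                   bleed_slope=0, shot_noise_sd=0, spike_rate=0)


@dataclass
class TruePeak:
    """Ground-truth record of one injected compound peak."""

    compound: str
    mzs: list[float]
    rt_apex: float
    rt_start: float
    rt_end: float
    label: str


@dataclass
class GroundTruth:
    true_peaks: list[TruePeak] = field(default_factory=list)

    def of_label(self, label: str) -> list[TruePeak]:
        return [p for p in self.true_peaks if p.label == label]

    def __len__(self) -> int:
        return len(self.true_peaks)


# ---------------------------------------------------------------------------
# run simulation
# ---------------------------------------------------------------------------

def simulate_run(compounds: list[CompoundSpec], noise: NoiseModel,
                 rt_range: tuple[float, float] = DEFAULT_RT_RANGE,
                 scan_hz: float = DEFAULT_SCAN_HZ, seed: int = 0, *,
                 sample_id: str = "synthetic", rt_offset: float = 0.0
                 ) -> tuple[RawRun, GroundTruth]:
    """Simulate one centroided GC-MS run plus its ground truth.

    Deterministic for a given seed. Overlapping compounds are legal (that is
    how shoulder pairs are made) and are labelled G in the ground truth when
    another apex falls within the sum of their base half-widths; isolated
    compounds are labelled B.
    """
    lo, hi = rt_range
    if hi <= lo:
        raise ValueError("rt_range must have positive length")
    if scan_hz <= 0:
        raise ValueError("scan_hz must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(lo, hi, 1.0 / scan_hz)

    shifted: list[CompoundSpec] = []
    for c in compounds:
        apex = c.rt_apex + rt_offset
        if not (lo <= apex <= hi):
            raise ValueError(
                f"compound {c.name!r} apex {apex} s outside rt_range {rt_range}"
            )
        shifted.append(CompoundSpec(name=c.name, rt_apex=apex,
                                    fragments=list(c.fragments),
                                    max_intensity=c.max_intensity, fwhm=c.fwhm,
                                    shape=c.shape, emg_tau=c.emg_tau))

    channels = sorted({mz for c in shifted for mz, _ in c.fragments} | set(BLEED_IONS))
    ch_index = {mz: i for i, mz in enumerate(channels)}
    mz_arr = np.array(channels)
    signal = np.zeros((len(channels), t.size))

    truth = GroundTruth()
    profiles: list[np.ndarray] = []
    for c in shifted:
        prof = c.profile(t)
        profiles.append(prof)
        for mz, rel in c.fragments:
            signal[ch_index[mz]] += rel * c.max_intensity * prof
        above = prof >= 0.01
        i_apex = int(np.argmax(prof))
        idx = np.nonzero(above)[0]
        truth.true_peaks.append(TruePeak(
            compound=c.name,
            mzs=[mz for mz, _ in c.fragments],
            rt_apex=float(t[i_apex]),
            rt_start=float(t[idx[0]]) if idx.size else float(t[i_apex]),
            rt_end=float(t[idx[-1]]) if idx.size else float(t[i_apex]),
            label="B",
        ))
    # mark shoulder/merged pairs
    for i, a in enumerate(shifted):
        for j, b in enumerate(shifted):
            if i != j and abs(a.rt_apex - b.rt_apex) < 2.0 * (a.sigma + b.sigma):
                truth.true_peaks[i].label = "G"
                break

    # baseline + drift on every channel, bleed ramp on the bleed ions
    base = noise.baseline_level + noise.baseline_drift_slope * (t - lo)
    signal += base[None, :]
    if noise.bleed_slope > 0:
        ramp = np.clip(t - noise.bleed_onset, 0.0, None) * noise.bleed_slope
        for mz in BLEED_IONS:
            signal[ch_index[mz]] += ramp
    if noise.shot_noise_sd > 0:
        signal += rng.normal(0.0, noise.shot_noise_sd, signal.shape)
    if noise.spike_rate > 0:
        n_spikes = rng.poisson(noise.spike_rate * (hi - lo) / 60.0)
        for _ in range(n_spikes):
            ch = rng.integers(0, len(channels))
            at = rng.integers(0, t.size)
            signal[ch, at] += rng.uniform(20, 200) * max(noise.shot_noise_sd, 1.0)
    np.clip(signal, 0.0, None, out=signal)

    scans = [Scan(rt=float(t[j]), mz=mz_arr.copy(), intensity=signal[:, j].copy())
             for j in range(t.size)]
    run = RawRun(scans=scans, sample_id=sample_id, source_path="")
    return run, truth


# ---------------------------------------------------------------------------
# class-window templates
# ---------------------------------------------------------------------------

# geometry constants shared by the templates and the rule-based checker
_CENTRE_FRAC = 0.05       # |apex - centre| <= 5% of window -> centred (B)
_SHIFT_FRAC = (0.25, 0.40)  # A/C displacement range
_NARROW_FRAC = 0.27       # base width below this fraction of window -> E
_BORDER_VALUE = 0.40      # border intensity above this fraction of apex -> F
_VALLEY_RANGE = (0.45, 0.97)  # valley-to-apex band accepted as G
_PRESENCE_SNR = 8.0       # amplitude threshold for "a peak is present"
_PRESENCE_AUTOCORR = 0.85  # lag-1 autocorrelation threshold (smoothed trace)


def _gauss(n_t: int, center: float, sigma: float) -> np.ndarray:
    x = np.arange(n_t, dtype=np.float64)
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _skewed_peak(n_t: int, apex: float, sigma: float, tau: float) -> np.ndarray:
    """Unit-height, apex-anchored peak with optional exponential tailing.

    GC peaks commonly tail; templates carry a random amount of skew so the
    classifier learns shapes, not perfect symmetry.  The profile is shifted
    so its mode lands exactly at ``apex`` regardless of tau.
    """
    if tau <= 1e-9:
        return _gauss(n_t, apex, sigma)
    fine = np.linspace(-6 * sigma, 10 * sigma, 32 * n_t)
    z = (sigma / tau - fine / sigma) / math.sqrt(2.0)
    y = np.empty_like(fine)
    lead = z >= 0
    y[lead] = erfcx(z[lead]) * np.exp(-0.5 * (fine[lead] / sigma) ** 2)
    y[~lead] = erfc(z[~lead]) * np.exp(0.5 * (sigma / tau) ** 2
                                       - fine[~lead] / tau)
    y /= y.max()
    mode = fine[int(np.argmax(y))]
    x = np.arange(n_t, dtype=np.float64)
    return np.interp(x - apex + mode, fine, y, left=0.0, right=0.0)


def _channel_pattern(rng: np.random.Generator, n_mz: int) -> np.ndarray:
    """Descending per-channel relative abundances; inactive channels zero."""
    n_active = int(rng.integers(3, n_mz + 1))
    abund = np.zeros(n_mz)
    abund[0] = 1.0
    if n_active > 1:
        abund[1:n_active] = np.sort(rng.uniform(0.05, 0.9, n_active - 1))[::-1]
    return abund


def _g_template(rng: np.random.Generator, n_t: int) -> np.ndarray:
    """Two overlapping Gaussians with valley-to-apex ratio inside (0.5, 0.95)."""
    sigma = rng.uniform(0.08, 0.12) * n_t
    amp2 = rng.uniform(0.70, 0.95)
    target = rng.uniform(0.55, 0.90)
    centre = (n_t - 1) / 2.0

    def valley_ratio(d: float) -> float:
        y = _gauss(n_t * 4, centre * 4 - d * 2, sigma * 4) + \
            amp2 * _gauss(n_t * 4, centre * 4 + d * 2, sigma * 4)
        # ratio of the minimum between the two maxima to the smaller maximum
        i1, i2 = int(centre * 4 - d * 2), int(centre * 4 + d * 2)
        seg = y[min(i1, i2):max(i1, i2) + 1]
        if seg.size < 3:
            return 1.0
        return float(seg.min() / min(y[i1], y[i2]))

    lo_d, hi_d = 1.6 * sigma, 4.0 * sigma
    for _ in range(40):  # bisection: valley ratio decreases with separation
        mid = 0.5 * (lo_d + hi_d)
        if valley_ratio(mid) > target:
            lo_d = mid
        else:
            hi_d = mid
    d = 0.5 * (lo_d + hi_d)
    return _gauss(n_t, centre - d / 2, sigma) + amp2 * _gauss(n_t, centre + d / 2, sigma)


def generate_class_window(label: str, n_mz: int = 10, n_t: int = 41,
                          snr: float = 50.0, seed: int = 0
                          ) -> tuple[PeakWindow, str]:
    """Generate one labelled template window for a peak-quality class.

    ``snr`` is the ratio of the strongest channel's apex to the per-point
    noise sd; noise is Gaussian truncated at zero.
    """
    validate_label(label)
    if n_mz < 3 or n_t < 9:
        raise ValueError("need n_mz >= 3 and n_t >= 9")
    rng = np.random.default_rng(seed)
    centre = (n_t - 1) / 2.0
    abund = _channel_pattern(rng, n_mz)

    if label == "A" or label == "C":
        shift = rng.uniform(*_SHIFT_FRAC) * n_t
        sigma = rng.uniform(0.055, 0.075) * n_t
        apex = centre - shift if label == "A" else centre + shift
        shape = _skewed_peak(n_t, apex, sigma, rng.uniform(0, 0.5) * sigma)
    elif label == "B":
        apex = centre + rng.uniform(-_CENTRE_FRAC, _CENTRE_FRAC) * n_t
        sigma = rng.uniform(0.09, 0.15) * n_t
        shape = _skewed_peak(n_t, apex, sigma, rng.uniform(0, 0.7) * sigma)
    elif label == "D":
        shape = None
    elif label == "E":
        apex = centre + rng.uniform(-_CENTRE_FRAC, _CENTRE_FRAC) * n_t
        sigma = rng.uniform(0.030, 0.048) * n_t
        shape = _skewed_peak(n_t, apex, sigma, rng.uniform(0, 0.4) * sigma)
    elif label == "F":
        side = rng.choice([-1, 1])
        pos = rng.uniform(0.0, 0.04) * n_t
        apex = pos if side < 0 else (n_t - 1) - pos
        sigma = rng.uniform(0.09, 0.13) * n_t
        shape = _gauss(n_t, apex, sigma)
    else:  # G
        shape = _g_template(rng, n_t)

    sd = 1.0 / max(snr, 1e-9)
    if shape is None:  # pure noise, no coherent structure across channels
        mat = np.clip(rng.normal(0.0, sd, (n_mz, n_t)), 0.0, None)
        # keep at least the abundance-bearing channels busy with noise
        mat += np.clip(rng.normal(0.0, sd, (n_mz, n_t)), 0.0, None) * abund[:, None]
    else:
        mat = abund[:, None] * shape[None, :]
        mat = np.clip(mat + rng.normal(0.0, sd, mat.shape), 0.0, None)

    mz_centers = 60.0 + 15.0 * np.arange(n_mz) + rng.uniform(0, 5)
    rt_grid = np.linspace(0.0, 8.0, n_t)
    return PeakWindow(intensities=mat, mz_centers=mz_centers, rt_grid=rt_grid), label


def generate_training_corpus(n_per_class: int = 100, seed: int = 0,
                             n_mz: int = 10, n_t: int = 41, snr: float = 50.0
                             ) -> list[tuple[PeakWindow, str]]:
    """Balanced labelled corpus of 7 x ``n_per_class`` template windows.

    The default of 100 per class gives 700 windows, matching the recommended
    minimum size of a manually labelled training set.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(7 * n_per_class)
    corpus = []
    k = 0
    for label in CLASS_LABELS:
        for _ in range(n_per_class):
            corpus.append(generate_class_window(label, n_mz=n_mz, n_t=n_t,
                                                snr=snr, seed=int(child_seeds[k])))
            k += 1
    return corpus


# ---------------------------------------------------------------------------
# rule-based template checker
# ---------------------------------------------------------------------------

def _smooth3(y: np.ndarray) -> np.ndarray:
    return np.convolve(y, np.ones(3) / 3.0, mode="same")


def _lag1_autocorr(y: np.ndarray) -> float:
    y = y - y.mean()
    denom = float(np.dot(y, y))
    if denom <= 0:
        return 0.0
    return float(np.dot(y[:-1], y[1:]) / denom)


def _significant_maxima(s: np.ndarray, floor_frac: float = 0.30) -> list[int]:
    """Local maxima of a smoothed trace above ``floor_frac`` of its global max,
    collapsing plateau/adjacent maxima separated by shallow dips."""
    top = s.max()
    if top <= 0:
        return []
    idx = [i for i in range(1, s.size - 1)
           if s[i] > s[i - 1] and s[i] >= s[i + 1] and s[i] >= floor_frac * top]
    # merge maxima not separated by a real valley (dip below 97% of lower max)
    merged: list[int] = []
    for i in idx:
        if merged:
            j = merged[-1]
            valley = s[min(i, j):max(i, j) + 1].min()
            if valley > 0.97 * min(s[i], s[j]):
                if s[i] > s[j]:
                    merged[-1] = i
                continue
        merged.append(i)
    return merged


def verify_window_label(window: PeakWindow) -> str:
    """Re-derive a template window's class from shape rules alone.

    Decision order: peak presence (else D), merged pair (G), border
    truncation (F), narrow centred peak (E), then apex position (A/B/C).
    Thresholds are the same geometry constants the templates are built from,
    but the derivation is independent: it sees only the intensity matrix.
    """
    n_t = window.shape[1]
    trace = window.intensities.sum(axis=0)
    s = _smooth3(trace)

    # presence: amplitude well above the high-frequency residual noise AND a
    # coherent smooth shape (smoothing leaves white noise nearly uncorrelated
    # but a chromatographic hump strongly autocorrelated)
    resid = trace - s
    noise = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    amp = float(s.max() - s.min())
    coherent = _lag1_autocorr(s) > _PRESENCE_AUTOCORR
    if noise > 0 and amp / noise < _PRESENCE_SNR or not coherent:
        return "D"

    maxima = _significant_maxima(s)
    if len(maxima) >= 2:
        i, j = maxima[0], maxima[-1]
        valley = s[i:j + 1].min()
        ratio = valley / min(s[i], s[j])
        if _VALLEY_RANGE[0] < ratio < _VALLEY_RANGE[1]:
            return "G"

    apex = int(np.argmax(s))
    top = s[apex]
    base = np.median(s[s <= np.quantile(s, 0.25)]) if n_t > 8 else 0.0
    border = max(s[0], s[-1]) - base
    if border > _BORDER_VALUE * (top - base) and min(apex, n_t - 1 - apex) <= 0.08 * n_t:
        return "F"

    above = np.nonzero(s - base >= 0.10 * (top - base))[0]
    width = (above[-1] - above[0] + 1) if above.size else 0
    centre = (n_t - 1) / 2.0
    offset = (apex - centre) / n_t
    if width < _NARROW_FRAC * n_t and abs(offset) <= 0.15:
        return "E"
    if abs(offset) <= (_CENTRE_FRAC + 0.05):  # halfway to the A/C band
        return "B"
    return "A" if offset < 0 else "C"


# ---------------------------------------------------------------------------
# demo study
# ---------------------------------------------------------------------------

def demo_compounds(n: int = 30, seed: int = 0,
                   rt_range: tuple[float, float] = DEFAULT_RT_RANGE,
                   n_shoulder_pairs: int = 2) -> list[CompoundSpec]:
    """A reproducible compound panel spread over the run.

    Most compounds are isolated, well-formed peaks; ``n_shoulder_pairs``
    pairs are placed close enough to co-elute as shoulders (ground-truth
    class G). Fragment m/z are nominal EI-style masses in 50-400 Th.
    """
    rng = np.random.default_rng(seed)
    lo, hi = rt_range
    usable = (lo + 40.0, hi - 120.0)
    n_isolated = n - 2 * n_shoulder_pairs
    apexes = np.linspace(usable[0], usable[1], n_isolated)
    apexes = apexes + rng.uniform(-6, 6, n_isolated)
    compounds: list[CompoundSpec] = []

    def random_fragments() -> list[tuple[float, float]]:
        n_frag = int(rng.integers(4, 9))
        mzs = rng.choice(np.arange(50, 400), size=n_frag, replace=False)
        mzs = np.sort(mzs).astype(float)
        rels = np.sort(rng.uniform(0.08, 0.95, n_frag - 1))[::-1]
        return [(float(mzs[0]), 1.0)] + [(float(m), float(r))
                                         for m, r in zip(mzs[1:], rels)]

    for i, apex in enumerate(apexes):
        compounds.append(CompoundSpec(
            name=f"cmpd_{i + 1:03d}", rt_apex=float(apex),
            fragments=random_fragments(),
            max_intensity=float(10 ** rng.uniform(4.0, 5.7)),
            fwhm=float(rng.uniform(2.0, 2.8)),
            shape="emg" if rng.random() < 0.3 else "gaussian",
            emg_tau=float(rng.uniform(0.2, 0.6)),
        ))
    # shoulder pairs in free stretches near the middle of the run
    for k in range(n_shoulder_pairs):
        base_rt = usable[0] + (k + 0.6) * (usable[1] - usable[0]) / (n_shoulder_pairs + 1)
        sep = float(rng.uniform(2.0, 3.5))
        for half, dx in (("a", 0.0), ("b", sep)):
            compounds.append(CompoundSpec(
                name=f"pair_{k + 1}{half}", rt_apex=base_rt + dx + 7.0,
                fragments=random_fragments(),
                max_intensity=float(10 ** rng.uniform(4.5, 5.5)),
                fwhm=float(rng.uniform(2.0, 2.6)),
            ))
    compounds.sort(key=lambda c: c.rt_apex)
    return compounds


def demo_alkane_anchors(rt_range: tuple[float, float] = DEFAULT_RT_RANGE,
                        carbons: tuple[int, int] = (8, 30)) -> list[tuple[int, float]]:
    """Evenly spaced n-alkane ladder anchors over the usable run span."""
    lo, hi = rt_range
    c_lo, c_hi = carbons
    rts = np.linspace(lo + 20.0, hi - 60.0, c_hi - c_lo + 1)
    return [(c, float(rt)) for c, rt in zip(range(c_lo, c_hi + 1), rts)]


def library_from_compounds(compounds: list[CompoundSpec],
                           anchors: list[tuple[int, float]]) -> list[SpectrumRecord]:
    """Spectral library records (with retention indices) for a compound panel."""
    from .annotation import RICalibration, calibrate_ri

    cal = RICalibration(anchors=anchors)
    return [
        SpectrumRecord(name=c.name, peaks=list(c.fragments),
                       ri=calibrate_ri(cal, c.rt_apex).value, rt=c.rt_apex)
        for c in compounds
    ]
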