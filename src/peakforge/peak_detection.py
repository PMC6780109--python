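"""Chromatographic peak pickers and pseudospectrum grouping.

Two built-in pickers operate on extracted ion chromatograms (EICs):

``matched_filter``
    Convolves each EIC with a Gaussian second-derivative (Ricker) kernel of a
    stated FWHM and reports local maxima of the filter response above a
    robust noise threshold, with boundaries at the response zero-crossings.

``cwt``
    Continuous wavelet transform over Mexican-hat scales spanning a requested
    peak-width range; ridge maxima whose best scale lies inside the range are
    reported, after a centWave-style intensity prefilter.

Single-m/z hits are then grouped into compound-level pseudospectra by apex
proximity (``group_pseudospectra``), the stand-in for a deconvolution step:
electron ionisation fragments a compound into many co-eluting m/z traces
that belong to one chromatographic feature.

Additional pickers can be registered via :func:`register_picker`; a picker is
any callable ``(RawRun, PickerParams) -> list[DetectedPeak]`` with a declared
parameter schema.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .io_formats import RawRun

__all__ = [
    "PickerParams",
    "EIC",
    "DetectedPeak",
    "EICSet",
    "bin_to_eics",
    "build_eic_set",
    "pick_matched_filter",
    "pick_cwt",
    "group_pseudospectra",
    "register_picker",
    "get_picker",
    "picker_names",
    "expand_grid",
    "mad_sd",
]

_peak_counter = itertools.count(1)


def mad_sd(x: np.ndarray) -> float:
    """Robust noise sd: 1.4826 x median absolute deviation about the median."""
    x = np.asarray(x)
    if x.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PickerParams:
    """One point of a picker's parameter grid."""

    algorithm: str
    values: dict[str, float]
    grid_id: str = ""

    def key(self) -> tuple:
        """Lexicographic sort key over parameter names/values (tie-breaks)."""
        return tuple(sorted(self.values.items()))


@dataclass
class EIC:
    """Extracted ion chromatogram for one m/z bin on the run's scan grid."""

    mz_center: float
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if np.any(np.diff(self.rt) <= 0):
            raise ValueError("EIC retention times must be ascending")
        if np.any(self.intensity < 0):
            raise ValueError("EIC intensities must be non-negative")


@dataclass
class DetectedPeak:
    """One picker hit, possibly spanning several m/z channels after grouping.

    ``mz_list`` holds (m/z, apex height, integrated area) triples.
    """

    algorithm: str
    sample_id: str
    rt_apex: float
    rt_start: float
    rt_end: float
    mz_list: list[tuple[float, float, float]]
    class_label: str | None = None
    params: PickerParams | None = None
    peak_id: str = field(default_factory=lambda: f"p{next(_peak_counter):07d}")

    def __post_init__(self) -> None:
        if not (self.rt_start < self.rt_apex < self.rt_end):
            raise ValueError(
                f"peak {self.peak_id}: require rt_start < rt_apex < rt_end, "
                f"got {self.rt_start} / {self.rt_apex} / {self.rt_end}"
            )
        if not self.mz_list:
            raise ValueError(f"peak {self.peak_id}: empty mz_list")
        for mz, h, a in self.mz_list:
            if h < 0 or a < 0:
                raise ValueError(f"peak {self.peak_id}: negative height/area")

    @property
    def n_mz(self) -> int:
        return len(self.mz_list)

    @property
    def total_height(self) -> float:
        return float(sum(h for _, h, _ in self.mz_list))

    def spectrum(self) -> list[tuple[float, float]]:
        return [(mz, h) for mz, h, _ in self.mz_list]


# ---------------------------------------------------------------------------
# EIC binning
# ---------------------------------------------------------------------------

class EICSet:
    """Dense (n_bins x n_scans) EIC matrix for fast trace lookup."""

    def __init__(self, rts: np.ndarray, centers: np.ndarray, matrix: np.ndarray,
                 bin_width: float, origin: float = 0.0,
                 bin_index: dict[int, int] | None = None):
        self.rts = rts
        self.centers = centers
        self.matrix = matrix
        self.bin_width = bin_width
        self.origin = origin
        # occupied-bin number -> matrix row
        self.bin_index = bin_index if bin_index is not None else {
            int(round((c - origin) / bin_width - 0.5)): i
            for i, c in enumerate(centers)}

    def trace(self, mz: float, tol: float | None = None) -> np.ndarray:
        """Trace of the bin containing ``mz`` (zeros when that bin is empty);
        falls back to the nearest occupied bin within ``tol``."""
        tol = self.bin_width if tol is None else tol
        if self.centers.size == 0:
            return np.zeros_like(self.rts)
        row = self.bin_index.get(int(math.floor((mz - self.origin) / self.bin_width)))
        if row is not None:
            return self.matrix[row]
        i = int(np.argmin(np.abs(self.centers - mz)))
        if abs(self.centers[i] - mz) > tol:
            return np.zeros_like(self.rts)
        return self.matrix[i]

    def eics(self) -> list[EIC]:
        return [EIC(mz_center=float(c), rt=self.rts, intensity=row)
                for c, row in zip(self.centers, self.matrix)]


def build_eic_set(run: RawRun, bin_width: float = 1.0) -> EICSet:
    """Bin every (m/z, intensity) point of every scan into fixed-width m/z
    bins; each point contributes to exactly one bin."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    rts = run.rts
    lo = min((s.mz[0] for s in run.scans if s.mz.size), default=0.0)
    hi = max((s.mz[-1] for s in run.scans if s.mz.size), default=0.0)
    origin = math.floor(lo / bin_width) * bin_width
    n_bins = max(1, int((hi - origin) / bin_width) + 1)
    matrix = np.zeros((n_bins, len(run.scans)))
    for j, scan in enumerate(run.scans):
        if not scan.mz.size:
            continue
        idx = np.floor((scan.mz - origin) / bin_width).astype(np.int64)
        np.add.at(matrix[:, j], idx, scan.intensity)
    occupied = np.nonzero(matrix.any(axis=1))[0]
    centers = origin + (occupied + 0.5) * bin_width
    return EICSet(rts=rts, centers=centers, matrix=matrix[occupied],
                  bin_width=bin_width, origin=origin,
                  bin_index={int(b): i for i, b in enumerate(occupied)})


def bin_to_eics(run: RawRun, bin_width: float) -> list[EIC]:
    """Non-empty EICs on the run's scan grid (see :func:`build_eic_set`)."""
    return build_eic_set(run, bin_width).eics()


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def _ricker(sigma_pts: float) -> np.ndarray:
    """Mexican-hat kernel (negative-normalised Gaussian second derivative)."""
    half = max(2, int(math.ceil(4 * sigma_pts)))
    t = np.arange(-half, half + 1, dtype=np.float64)
    u = t / sigma_pts
    return (1.0 - u**2) * np.exp(-0.5 * u**2)


def _scan_interval(rts: np.ndarray) -> float:
    return float(np.median(np.diff(rts)))


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict-left / non-strict-right local maxima."""
    if y.size < 3:
        return np.empty(0, dtype=int)
    m = (y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])
    return np.nonzero(m)[0] + 1


def _bounded(rts: np.ndarray, i_apex: int, i_lo: int, i_hi: int) -> tuple[float, float, float]:
    """Apex/boundary RTs, nudged so rt_start < rt_apex < rt_end always holds."""
    dt = _scan_interval(rts)
    apex = float(rts[i_apex])
    lo = float(rts[max(0, i_lo)])
    hi = float(rts[min(len(rts) - 1, i_hi)])
    if lo >= apex:
        lo = apex - 0.5 * dt
    if hi <= apex:
        hi = apex + 0.5 * dt
    return apex, lo, hi


def _area(rts: np.ndarray, raw: np.ndarray, i_lo: int, i_hi: int) -> float:
    i_lo, i_hi = max(0, i_lo), min(len(rts) - 1, i_hi)
    if i_hi <= i_lo:
        return 0.0
    return float(np.trapezoid(raw[i_lo:i_hi + 1], rts[i_lo:i_hi + 1]))


# ---------------------------------------------------------------------------
# matched filter picker
# ---------------------------------------------------------------------------

MATCHED_FILTER_SCHEMA = {
    "fwhm": (0.1, 60.0),
    "snthresh": (0.0, 1e6),
    "step": (0.05, 10.0),
    "max_per_eic": (1, 1000),
}

CWT_SCHEMA = {
    "peakwidth_min": (0.1, 120.0),
    "peakwidth_max": (0.2, 600.0),
    "snthresh": (0.0, 1e6),
    "prefilter_k": (1, 100),
    "prefilter_i": (0.0, 1e12),
}


def _validate_params(params: PickerParams, schema: dict, defaults: dict) -> dict:
    values = dict(defaults)
    for name, value in params.values.items():
        if name not in schema:
            raise ValueError(
                f"parameter {name!r} not in the {params.algorithm!r} grid schema"
            )
        lo, hi = schema[name]
        if not (lo <= value <= hi):
            raise ValueError(f"parameter {name}={value} outside range [{lo}, {hi}]")
        values[name] = value
    return values


def pick_matched_filter(run: RawRun, params: PickerParams) -> list[DetectedPeak]:
    """Matched-filter peak picking on binned EICs.

    Each EIC is convolved with a Ricker kernel of the requested FWHM; local
    maxima of the response above ``snthresh`` robust noise sds are reported,
    with boundaries at the nearest response zero-crossings.
    """
    values = _validate_params(params, MATCHED_FILTER_SCHEMA,
                              {"snthresh": 3.0, "step": 1.0, "max_per_eic": 10})
    if "fwhm" not in values:
        raise ValueError("matched_filter requires an fwhm parameter")
    eset = build_eic_set(run, bin_width=values["step"])
    rts = eset.rts
    dt = _scan_interval(rts)
    if values["fwhm"] < 2 * dt:
        raise ValueError("fwhm below sampling resolution")
    sigma_pts = values["fwhm"] / 2.3548 / dt
    kernel = _ricker(sigma_pts)
    if eset.matrix.shape[0] == 0:
        return []
    response = fftconvolve(eset.matrix, kernel[None, :], mode="same", axes=1)

    peaks: list[DetectedPeak] = []
    half_width_pts = max(1, int(round(2 * sigma_pts)))
    for row_i in range(response.shape[0]):
        resp = response[row_i]
        raw = eset.matrix[row_i]
        sd = mad_sd(resp)
        # relative floor guards against FFT noise / profile tails on
        # otherwise silent traces, where the MAD estimate collapses to ~0
        thresh = max(values["snthresh"] * sd, 1e-6 * float(resp.max(initial=0.0)))
        guard = kernel.size // 2  # convolution edge artifacts
        cand = [i for i in _local_maxima(resp)
                if resp[i] > thresh and resp[i] > 0 and raw[i] > 0
                and guard <= i < resp.size - guard]
        cand.sort(key=lambda i: -resp[i])
        cand = cand[: int(values["max_per_eic"])]
        for i in sorted(cand):
            # boundaries: nearest zero-crossing of the response on each side
            left = i
            while left > 0 and resp[left - 1] > 0:
                left -= 1
            right = i
            while right < resp.size - 1 and resp[right + 1] > 0:
                right += 1
            if left == i:
                left = max(0, i - half_width_pts)
            if right == i:
                right = min(resp.size - 1, i + half_width_pts)
            apex, lo, hi = _bounded(rts, i, left, right)
            peaks.append(DetectedPeak(
                algorithm="matched_filter", sample_id=run.sample_id,
                rt_apex=apex, rt_start=lo, rt_end=hi,
                mz_list=[(float(eset.centers[row_i]), float(raw[i]),
                          _area(rts, raw, left, right))],
                params=params,
            ))
    peaks.sort(key=lambda p: (p.rt_apex, p.mz_list[0][0]))
    return peaks


# ---------------------------------------------------------------------------
# CWT picker
# ---------------------------------------------------------------------------

def _max_consecutive_above(row: np.ndarray, level: float) -> int:
    above = row > level
    if not above.any():
        return 0
    # run-length of True stretches
    edges = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    return int((ends - starts).max())


def pick_cwt(run: RawRun, params: PickerParams,
             n_scales: int = 10, bin_width: float = 1.0) -> list[DetectedPeak]:
    """CWT (Mexican-hat) peak picking with centWave-style parameters.

    Scales span the requested peak-width range; EICs failing the prefilter
    (``prefilter_k`` consecutive points above ``prefilter_i``) are skipped.
    A ridge whose response is maximal at the extreme smallest (or largest)
    scale and falls off steeply across scales indicates a peak narrower (or
    wider) than the requested width range and is rejected as a scale
    mismatch.
    """
    values = _validate_params(params, CWT_SCHEMA,
                              {"snthresh": 3.0, "prefilter_k": 3,
                               "prefilter_i": 100.0})
    if "peakwidth_min" not in values or "peakwidth_max" not in values:
        raise ValueError("cwt requires peakwidth_min and peakwidth_max")
    if values["peakwidth_min"] >= values["peakwidth_max"]:
        raise ValueError("peakwidth_min must be below peakwidth_max")

    eset = build_eic_set(run, bin_width=bin_width)
    rts = eset.rts
    dt = _scan_interval(rts)
    # With 1/a-normalised kernels the response of a Gaussian peak of width
    # sigma_p peaks at wavelet scale a = sqrt(2)*sigma_p; mapping a requested
    # full base width w (= 4 sigma_p) to a = sqrt(2)/4 * w places peaks with
    # widths inside [peakwidth_min, peakwidth_max] at interior scales.
    widths = np.geomspace(values["peakwidth_min"], values["peakwidth_max"], n_scales)
    sigmas_s = widths * math.sqrt(2.0) / 4.0
    kernels = [_ricker(max(s / dt, 1.0)) / max(s / dt, 1.0) for s in sigmas_s]

    peaks: list[DetectedPeak] = []
    k = int(values["prefilter_k"])
    level = values["prefilter_i"]
    for row_i in range(eset.matrix.shape[0]):
        raw = eset.matrix[row_i]
        if _max_consecutive_above(raw, level) < k:
            continue
        cwt = np.stack([fftconvolve(raw, kern, mode="same") for kern in kernels])
        finest_sd = mad_sd(cwt[0])
        best = cwt.max(axis=0)
        # same relative floor rationale as in the matched filter
        thresh = max(values["snthresh"] * finest_sd,
                     1e-6 * float(best.max(initial=0.0)))
        for i in _local_maxima(best):
            if best[i] <= thresh or best[i] <= 0 or raw[i] <= 0:
                continue
            s_best = int(np.argmax(cwt[:, i]))
            guard = kernels[s_best].size // 2  # convolution edge artifacts
            if i < guard or i >= raw.size - guard:
                continue
            # scale-mismatch rejection: response optimum outside the range
            if s_best == 0 and n_scales >= 2 and cwt[1, i] < 0.95 * cwt[0, i]:
                continue
            if (s_best == n_scales - 1 and n_scales >= 2
                    and cwt[-2, i] < 0.95 * cwt[-1, i]):
                continue
            sigma_s = sigmas_s[s_best]
            half_pts = max(1, int(round(1.5 * sigma_s / dt)))
            apex, lo, hi = _bounded(rts, i, i - half_pts, i + half_pts)
            peaks.append(DetectedPeak(
                algorithm="cwt", sample_id=run.sample_id,
                rt_apex=apex, rt_start=lo, rt_end=hi,
                mz_list=[(float(eset.centers[row_i]), float(raw[i]),
                          _area(rts, raw, i - half_pts, i + half_pts))],
                params=params,
            ))
    peaks.sort(key=lambda p: (p.rt_apex, p.mz_list[0][0]))
    return peaks


# ---------------------------------------------------------------------------
# pseudospectrum grouping
# ---------------------------------------------------------------------------

def group_pseudospectra(peaks: Sequence[DetectedPeak], rt_tol: float = 1.0) -> list[DetectedPeak]:
    """Merge single-m/z hits whose apexes co-elute into compound features.

    1-D single-linkage on apex RT: consecutive (sorted) apexes closer than
    ``rt_tol`` join the same pseudospectrum. The merged apex is the
    height-weighted mean apex; boundaries are the envelope union; the m/z
    list is the union (highest apex kept for a repeated channel).
    """
    if not peaks:
        return []
    algs = {p.algorithm for p in peaks}
    samples = {p.sample_id for p in peaks}
    if len(algs) > 1 or len(samples) > 1:
        raise ValueError("group_pseudospectra expects peaks from one sample "
                         f"and one algorithm, got {algs} / {samples}")
    ordered = sorted(peaks, key=lambda p: p.rt_apex)
    clusters: list[list[DetectedPeak]] = [[ordered[0]]]
    for p in ordered[1:]:
        if p.rt_apex - clusters[-1][-1].rt_apex <= rt_tol:
            clusters[-1].append(p)
        else:
            clusters.append([p])

    merged: list[DetectedPeak] = []
    for members in clusters:
        if len(members) == 1:
            merged.append(members[0])
            continue
        by_mz: dict[float, tuple[float, float, float]] = {}
        for m in members:
            for mz, h, a in m.mz_list:
                if mz not in by_mz or h > by_mz[mz][1]:
                    by_mz[mz] = (mz, h, a)
        weights = np.array([m.total_height for m in members])
        if weights.sum() <= 0:
            weights = np.ones(len(members))
        apex = float(np.average([m.rt_apex for m in members], weights=weights))
        lo = min(m.rt_start for m in members)
        hi = max(m.rt_end for m in members)
        if not lo < apex < hi:  # numeric guard for degenerate envelopes
            lo, hi = min(lo, apex - 1e-6), max(hi, apex + 1e-6)
        merged.append(DetectedPeak(
            algorithm=members[0].algorithm, sample_id=members[0].sample_id,
            rt_apex=apex, rt_start=lo, rt_end=hi,
            mz_list=sorted(by_mz.values()), params=members[0].params,
        ))
    return merged


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, tuple[Callable, dict]] = {}


def register_picker(name: str, func: Callable, schema: dict) -> None:
    """Register a picker callable ``(RawRun, PickerParams) -> [DetectedPeak]``
    together with its parameter-grid schema (name -> (min, max))."""
    _REGISTRY[name] = (func, schema)


def get_picker(name: str) -> Callable:
    if name not in _REGISTRY:
        raise KeyError(f"unknown picker {name!r}; known: {sorted(_REGISTRY)}")
    return _REGISTRY[name][0]


def picker_names() -> list[str]:
    return sorted(_REGISTRY)


def expand_grid(algorithm: str, axes: dict[str, Sequence[float]]) -> list[PickerParams]:
    """Cartesian expansion of per-parameter value lists into PickerParams."""
    names = sorted(axes)
    combos = itertools.product(*(axes[n] for n in names))
    return [
        PickerParams(algorithm=algorithm,
                     values=dict(zip(names, combo)),
                     grid_id=f"{algorithm}:{j}")
        for j, combo in enumerate(combos)
    ]


register_picker("matched_filter", pick_matched_filter, MATCHED_FILTER_SCHEMA)
register_picker("cwt", pick_cwt, CWT_SCHEMA)


# ---------------------------------------------------------------------------
# internal CSV serialisation
# ---------------------------------------------------------------------------

def peaks_to_frame(peaks: Sequence[DetectedPeak]):
    """Serialise peaks to a DataFrame (m/z list packed as ``mz:h:a;...``)."""
    import pandas as pd

    rows = [{
        "peak_id": p.peak_id, "algorithm": p.algorithm, "sample_id": p.sample_id,
        "rt_apex": p.rt_apex, "rt_start": p.rt_start, "rt_end": p.rt_end,
        "class_label": p.class_label or "",
        "grid_id": p.params.grid_id if p.params else "",
        "mz_list": ";".join(f"{mz:.4f}:{h:.6g}:{a:.6g}" for mz, h, a in p.mz_list),
    } for p in peaks]
    return pd.DataFrame(rows, columns=["peak_id", "algorithm", "sample_id",
                                       "rt_apex", "rt_start", "rt_end",
                                       "class_label", "grid_id", "mz_list"])


def frame_to_peaks(df) -> list[DetectedPeak]:
    peaks = []
    for _, row in df.iterrows():
        mz_list = [tuple(float(x) for x in chunk.split(":"))
                   for chunk in str(row["mz_list"]).split(";") if chunk]
        peaks.append(DetectedPeak(
            algorithm=row["algorithm"], sample_id=row["sample_id"],
            rt_apex=float(row["rt_apex"]), rt_start=float(row["rt_start"]),
            rt_end=float(row["rt_end"]), mz_list=mz_list,
            class_label=(str(row["class_label"]) or None)
            if str(row["class_label"]) not in ("", "nan") else None,
            peak_id=str(row["peak_id"]),
        ))
    return peaks
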