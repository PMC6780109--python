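"""Retention-index calibration and reverse spectral-library matching.

Features are annotated against an MSP library with a two-tier confidence
rule: a candidate must elute within a retention-index window (default 1.5 RI
units) of the library entry, and is reported as *high* confidence when its
reverse-match similarity also exceeds a threshold (default 0.9), otherwise
as *low* confidence.

Reverse matching scores the query only over the library spectrum's m/z
positions, which makes it robust to co-eluting contamination: extra query
ions absent from the library are ignored.  The similarity is a weighted
cosine with weights mz^2 * sqrt(intensity), the common choice for
electron-ionisation spectra where high-mass fragments are the diagnostic
ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import SpectrumRecord

__all__ = ["RICalibration", "RIValue", "AnnotationConfig", "AnnotationHit",
           "calibrate_ri", "reverse_match", "annotate"]


@dataclass
class RICalibration:
    """n-alkane ladder anchors: (carbon number, retention time in seconds),
    strictly increasing in both coordinates."""

    anchors: list[tuple[int, float]]

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValueError("need at least 2 alkane anchors")
        carbons = [c for c, _ in self.anchors]
        rts = [rt for _, rt in self.anchors]
        if any(b <= a for a, b in zip(carbons, carbons[1:])):
            raise ValueError("anchor carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("anchor retention times must be strictly increasing")


@dataclass
class RIValue:
    value: float
    extrapolated: bool = False

    def __float__(self) -> float:
        return self.value


def calibrate_ri(cal: RICalibration, rt: float, method: str = "linear") -> RIValue:
    """Retention index of ``rt`` by interpolation between alkane anchors.

    Linear interpolation (appropriate for temperature-programmed GC) is the
    default; ``method="kovats"`` uses the logarithmic (isothermal) form.
    Outside the anchor range the first/last segment is extrapolated and the
    result flagged.
    """
    anchors = cal.anchors
    extrapolated = rt < anchors[0][1] or rt > anchors[-1][1]
    # bracketing segment (clamped to the outer segments when extrapolating)
    k = 0
    for k in range(len(anchors) - 1):
        if rt < anchors[k + 1][1]:
            break
    else:
        k = len(anchors) - 2
    (n0, t0), (n1, t1) = anchors[k], anchors[k + 1]
    if method == "linear":
        frac = (rt - t0) / (t1 - t0)
    elif method == "kovats":
        if rt <= 0 or t0 <= 0:
            raise ValueError("kovats interpolation needs positive retention times")
        frac = (math.log(rt) - math.log(t0)) / (math.log(t1) - math.log(t0))
    else:
        raise ValueError(f"unknown RI method {method!r}")
    return RIValue(value=100.0 * (n0 + frac * (n1 - n0)), extrapolated=extrapolated)


def _as_pairs(spectrum) -> list[tuple[float, float]]:
    if isinstance(spectrum, SpectrumRecord):
        return spectrum.peaks
    return [(float(m), float(i)) for m, i in spectrum]


def reverse_match(query, library, mz_tol: float = 0.5,
                  mz_power: float = 2.0, intensity_power: float = 0.5) -> float:
    """Weighted-cosine reverse match of a query spectrum against a library
    spectrum, computed over the library's m/z positions only.

    Both spectra may be ``SpectrumRecord`` or (m/z, intensity) pair lists on
    any positive scale; the score is invariant to rescaling either side.
    """
    lib = _as_pairs(library)
    if not lib:
        raise ValueError("empty library spectrum")
    qry = _as_pairs(query)
    if not qry:
        raise ValueError("empty query spectrum")
    q_mz = np.array([m for m, _ in qry])
    q_in = np.array([i for _, i in qry])
    order = np.argsort(q_mz)
    q_mz, q_in = q_mz[order], q_in[order]

    l_mz = np.array([m for m, _ in lib])
    l_in = np.array([i for _, i in lib])
    matched = np.zeros_like(l_in)
    for j, mz in enumerate(l_mz):
        k = np.searchsorted(q_mz, mz)
        best = 0.0
        for i in (k - 1, k):
            if 0 <= i < q_mz.size and abs(q_mz[i] - mz) <= mz_tol:
                best = max(best, q_in[i])
        matched[j] = best
    wq = l_mz**mz_power * matched**intensity_power
    wl = l_mz**mz_power * l_in**intensity_power
    nq, nl = np.linalg.norm(wq), np.linalg.norm(wl)
    if nq == 0 or nl == 0:
        return 0.0
    return float(np.clip(np.dot(wq, wl) / (nq * nl), 0.0, 1.0))


@dataclass
class AnnotationConfig:
    ri_window: float = 1.5
    min_similarity: float = 0.9
    mz_tol: float = 0.5
    ri_method: str = "linear"

    def __post_init__(self) -> None:
        if self.ri_window <= 0:
            raise ValueError("ri_window must be positive")
        if not (0 < self.min_similarity <= 1):
            raise ValueError("min_similarity must be in (0, 1]")


@dataclass
class AnnotationHit:
    feature_id: str
    compound: str
    similarity: float
    delta_ri: float
    confidence: str  # "high" | "low"

    def __post_init__(self) -> None:
        if self.confidence not in ("high", "low"):
            raise ValueError("confidence must be 'high' or 'low'")


def annotate(features: Sequence, library: Sequence[SpectrumRecord],
             cal: RICalibration | None,
             cfg: AnnotationConfig | None = None) -> list[AnnotationHit]:
    """Annotate features against a library with the two-tier rule.

    Candidates are library entries within the RI window of the feature; the
    best candidate by reverse-match similarity is reported, at high
    confidence only if the similarity also clears ``min_similarity``.
    Features with no candidate in the window yield no hit.  Each feature
    needs ``rt_apex``, ``feature_id``, ``mz_list`` and optionally a
    precomputed ``ri``; a missing RI is calibrated from ``rt_apex``.
    """
    cfg = cfg or AnnotationConfig()
    hits: list[AnnotationHit] = []
    candidates = [rec for rec in library if rec.ri is not None]
    if not candidates:
        return hits
    for feat in features:
        ri = getattr(feat, "ri", None)
        if ri is None:
            if cal is None:
                raise ValueError("no RI calibration supplied and feature "
                                 f"{feat.feature_id!r} has no RI")
            ri = calibrate_ri(cal, feat.rt_apex, method=cfg.ri_method).value
            feat.ri = ri
        in_window = [rec for rec in candidates if abs(ri - rec.ri) <= cfg.ri_window]
        if not in_window:
            continue
        spectrum = [(mz, h) for mz, h, _ in feat.mz_list]
        scored = [(reverse_match(spectrum, rec, mz_tol=cfg.mz_tol), rec)
                  for rec in in_window]
        sim, best = max(scored, key=lambda t: (t[0], -abs(ri - t[1].ri)))
        hits.append(AnnotationHit(
            feature_id=feat.feature_id, compound=best.name,
            similarity=sim, delta_ri=float(ri - best.ri),
            confidence="high" if sim > cfg.min_similarity else "low",
        ))
    return hits
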