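"""Genotype calls and mutant-fraction estimates from melting peaks.

A designed assay expects two melting temperatures: the probe against its
perfectly matched allele (tm_match, higher) and against the other allele
(tm_mismatch, lower -- a mismatched or partially hybridized duplex always
melts earlier).  Calling assigns each detected peak to the nearest
expected Tm within a tolerance, then maps the assignment to a genotype:

germline   match only -> homozygous for the probe-matched allele;
           mismatch only -> homozygous for the other allele;
           both -> heterozygous;
somatic    mutant-side peak present (and carrying enough of the melt
           area) -> mutant_detected, otherwise wild_only.

The mutant fraction of an amplicon pool is estimated as the mutant-peak
share of the derivative area integrated over windows around the two
expected Tms, optionally passed through a monotone calibration map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np

from .signal import DerivativeCurve, MeltCurve, Peak, find_peaks, smooth_and_differentiate

Allele = Literal["wild", "mutant"]

CALLS = ("wild_hom", "heterozygous", "mutant_hom", "mutant_detected",
         "wild_only", "no_call")


@dataclass(frozen=True)
class AssayExpectation:
    """Expected match/mismatch melting temperatures of one probe assay.

    ``area_capture_match``/``area_capture_mismatch`` are the window-area
    capture coefficients of the two pure components (the chord-baseline
    area a pure-allele melt deposits in its own window, computed once at
    design time); they normalize the area-share estimator so a 50/50
    mixture of a sharp and a broad transition still reads ~0.5.
    """

    tm_match: float
    tm_mismatch: float
    probe_matches: Allele
    tol: float = 2.0
    tie_tol: float = 0.5
    area_capture_match: float = 1.0
    area_capture_mismatch: float = 1.0

    def __post_init__(self) -> None:
        if not self.tm_match > self.tm_mismatch:
            raise ValueError("tm_match must exceed tm_mismatch")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")

    def tm_of_allele(self, allele: Allele) -> float:
        return self.tm_match if allele == self.probe_matches else self.tm_mismatch

    @property
    def other_allele(self) -> Allele:
        return "mutant" if self.probe_matches == "wild" else "wild"


@dataclass(frozen=True)
class CallingConfig:
    """Peak-detection and decision thresholds for the two calling modes.

    Germline thresholds are relative to the dominant peak, as both alleles
    of a diploid genotype produce comparable signal.  Somatic mode hunts
    for a minor mutant population after enrichment, so its height and
    prominence thresholds are much lower and a second gate -- the mutant
    share of the melt area -- suppresses baseline-ripple false positives.
    """

    germline_min_height_frac: float = 0.10
    germline_min_prominence_frac: float = 0.05
    somatic_min_height_frac: float = 0.010
    somatic_min_prominence_frac: float = 0.008
    min_separation: float = 2.0
    somatic_min_area_fraction: float = 0.02
    area_halfwidth: float = 3.0
    smoothing_window: int = 15
    smoothing_polyorder: int = 3

    def peak_kwargs(self, mode: str) -> dict:
        if mode == "germline":
            return dict(min_height_frac=self.germline_min_height_frac,
                        min_prominence_frac=self.germline_min_prominence_frac,
                        min_separation=self.min_separation)
        return dict(min_height_frac=self.somatic_min_height_frac,
                    min_prominence_frac=self.somatic_min_prominence_frac,
                    min_separation=self.min_separation)


@dataclass
class GenotypeCall:
    call: str
    peaks_used: list[Peak] = field(default_factory=list)
    mutant_fraction_estimate: Optional[float] = None
    confidence: float = 0.0
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")


def _assign_peaks(peaks: Sequence[Peak], expect: AssayExpectation):
    """Map each expected Tm to at most one peak; flag ambiguity.

    Returns (assignment dict label->Peak, unassigned list, ambiguous flag).
    Labels are 'match' and 'mismatch'.
    """
    expected = {"match": expect.tm_match, "mismatch": expect.tm_mismatch}
    prefs = []
    for p in peaks:
        dists = {lab: abs(p.tm - tm) for lab, tm in expected.items()}
        in_tol = {lab: d for lab, d in dists.items() if d <= expect.tol}
        if len(in_tol) == 2 and abs(dists["match"] - dists["mismatch"]) < expect.tie_tol:
            return {}, list(peaks), True
        label = min(in_tol, key=in_tol.get) if in_tol else None
        prefs.append((p, label, dists.get(label, np.inf)))
    assignment: dict[str, Peak] = {}
    unassigned: list[Peak] = []
    for lab in expected:
        cands = [(d, -p.prominence, p) for p, l, d in prefs if l == lab]
        if cands:
            cands.sort(key=lambda c: (c[0], c[1]))
            assignment[lab] = cands[0][2]
            unassigned.extend(c[2] for c in cands[1:])
    unassigned.extend(p for p, l, _ in prefs if l is None)
    return assignment, unassigned, False


def call_genotype(peaks: Sequence[Peak], expect: AssayExpectation,
                  mode: str = "germline") -> GenotypeCall:
    """Rule-table genotype call from detected peaks.

    Extra unassignable peaks downgrade confidence (assigned prominence
    over total prominence) rather than forcing a no-call; a peak
    equidistant from both expectations within the tie tolerance is
    unresolvable and yields no_call.
    """
    if mode not in ("germline", "somatic"):
        raise ValueError("mode must be 'germline' or 'somatic'")
    if not peaks:
        return GenotypeCall(call="no_call", reason="no peaks detected")
    assignment, unassigned, ambiguous = _assign_peaks(peaks, expect)
    if ambiguous:
        return GenotypeCall(call="no_call", peaks_used=[],
                            reason="peak equidistant from both expected Tms")
    if not assignment:
        return GenotypeCall(call="no_call", peaks_used=[],
                            reason="no peak within tolerance of an expected Tm")
    total_prom = sum(p.prominence for p in peaks)
    conf = sum(p.prominence for p in assignment.values()) / total_prom
    used = sorted(assignment.values(), key=lambda p: p.tm)
    has_match, has_mismatch = "match" in assignment, "mismatch" in assignment
    if mode == "germline":
        if has_match and has_mismatch:
            call = "heterozygous"
        elif has_match:
            call = "wild_hom" if expect.probe_matches == "wild" else "mutant_hom"
        else:
            call = "wild_hom" if expect.other_allele == "wild" else "mutant_hom"
        return GenotypeCall(call=call, peaks_used=used, confidence=conf)
    mutant_label = "match" if expect.probe_matches == "mutant" else "mismatch"
    if mutant_label in assignment:
        return GenotypeCall(call="mutant_detected", peaks_used=used,
                            confidence=conf)
    return GenotypeCall(call="wild_only", peaks_used=used, confidence=conf)


def window_chord_area(dcurve: DerivativeCurve, center: float,
                      halfwidth: float) -> float:
    """Peak area above the local chord baseline in one Tm window.

    The chord joining the window edges removes the smooth tail a
    neighboring transition leaks into the window; what remains (clipped
    at zero) is the local peak mass.
    """
    t, d = dcurve.temperatures, dcurve.dfdt
    m = (t >= center - halfwidth) & (t <= center + halfwidth)
    if np.count_nonzero(m) < 3:
        return 0.0
    tw, dw = t[m], d[m]
    chord = dw[0] + (dw[-1] - dw[0]) * (tw - tw[0]) / (tw[-1] - tw[0])
    return float(np.trapezoid(np.clip(dw - chord, 0.0, None), tw))


def _unmix_fraction(dcurve: DerivativeCurve, assay,
                    min_total_weight: float) -> Optional[float]:
    """Mutant component share by nonnegative regression unmixing.

    The observed derivative is fitted as w_w * c_w(T) + w_m * c_m(T) +
    b, where c_a(T) = -d(theta_a)/dT are the two pure-allele melt
    components known from the assay's duplex thermodynamics and b
    absorbs linear baseline drift.  The mutant share of the fitted
    component weight is the fraction estimate: a minor mutant population
    shifts melt mass long before it forms a separate local maximum, and
    zero-mean noise cancels in the fit instead of accumulating as it
    does in windowed area sums.
    """
    from scipy.optimize import lsq_linear

    from .thermo import fraction_bound
    t = dcurve.temperatures
    cols = []
    for allele in ("wild", "mutant"):
        theta = fraction_bound(assay.duplexes[allele], t, _assay_thermo(assay))
        cols.append(-np.gradient(theta, t))
    design = np.column_stack([cols[0], cols[1], np.ones_like(t)])
    res = lsq_linear(design, dcurve.dfdt,
                     bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]))
    w_wild, w_mut = float(res.x[0]), float(res.x[1])
    total = w_wild + w_mut
    if total < min_total_weight:
        return None
    return w_mut / total


def _assay_thermo(assay):
    cfg = getattr(assay, "thermo", None)
    if cfg is None:
        from .thermo import ThermoConfig
        cfg = ThermoConfig()
    return cfg


def estimate_mutant_fraction(dcurve: DerivativeCurve, expect,
                             calibration: Optional[Callable[[float], float]] = None,
                             area_halfwidth: float = 3.0,
                             min_total_area: float = 1e-2) -> Optional[float]:
    """Mutant share of the melt signal, in [0, 1].

    ``expect`` may be a full probe assay (anything exposing ``duplexes``
    and ``expectation``), in which case the estimate is the mutant
    component share of a nonnegative regression fit of the derivative
    onto the two known pure-allele melt components (plus a constant for
    baseline drift) -- exact for noise-free mixtures at every fraction.
    With a bare :class:`AssayExpectation` the estimate falls back to
    chord-baseline peak areas in +/- ``area_halfwidth`` degC windows
    around the two expected Tms, normalized by the expectation's capture
    coefficients.

    Returns None -- not 0 -- when there is no appreciable melt signal.
    ``calibration`` is an optional monotone map applied to the raw
    share; the default is the identity.
    """
    exp_obj = getattr(expect, "expectation", expect)
    for tm in (exp_obj.tm_match, exp_obj.tm_mismatch):
        if not (dcurve.temperatures[0] <= tm <= dcurve.temperatures[-1]):
            raise ValueError(f"expected Tm {tm:.1f} outside the derivative grid")
    if hasattr(expect, "duplexes"):
        frac = _unmix_fraction(dcurve, expect, min_total_area)
    else:
        cap = {"match": exp_obj.area_capture_match,
               "mismatch": exp_obj.area_capture_mismatch}
        lab_mut = "match" if exp_obj.probe_matches == "mutant" else "mismatch"
        lab_wild = "mismatch" if lab_mut == "match" else "match"
        area_mut = window_chord_area(dcurve, exp_obj.tm_of_allele("mutant"),
                                     area_halfwidth) / cap[lab_mut]
        area_wild = window_chord_area(dcurve, exp_obj.tm_of_allele("wild"),
                                      area_halfwidth) / cap[lab_wild]
        total = area_mut + area_wild
        frac = None if total < min_total_area else area_mut / total
    if frac is None:
        return None
    if calibration is not None:
        frac = calibration(frac)
    return float(min(max(frac, 0.0), 1.0))


def call_sample(curve: MeltCurve, expect,
                mode: str = "germline",
                cfg: Optional[CallingConfig] = None,
                calibration: Optional[Callable[[float], float]] = None) -> GenotypeCall:
    """Full calling pipeline: smooth, differentiate, detect, decide.

    Germline calls follow the peak rule table.  Somatic detection is
    quantitative: the (capture-normalized, optionally calibrated) mutant
    share of the melt area is the authority, mirroring how the
    enrichment assays read the correlation of fluorescence intensity
    with mutant proportion -- a minor mutant population shifts melt area
    into the mutant window long before it forms a separate local
    maximum.  ``mutant_detected`` requires the share to reach
    ``cfg.somatic_min_area_fraction`` on a curve with at least one
    detected melt peak; a mutant-side peak without the area (baseline
    ripple) stays ``wild_only``.
    """
    cfg = cfg if cfg is not None else CallingConfig()
    exp_obj = getattr(expect, "expectation", expect)
    dcurve = smooth_and_differentiate(curve, cfg.smoothing_window,
                                      cfg.smoothing_polyorder)
    peaks = find_peaks(dcurve, **cfg.peak_kwargs(mode))
    call = call_genotype(peaks, exp_obj, mode=mode)
    try:
        frac = estimate_mutant_fraction(dcurve, expect, calibration,
                                        cfg.area_halfwidth)
    except ValueError:
        frac = None
    if call.call != "no_call":
        call.mutant_fraction_estimate = frac
    if mode == "somatic":
        if not peaks or frac is None:
            return GenotypeCall(call="no_call", reason="no usable melt signal")
        if frac >= cfg.somatic_min_area_fraction:
            return GenotypeCall(call="mutant_detected",
                                peaks_used=call.peaks_used,
                                mutant_fraction_estimate=frac,
                                confidence=call.confidence or 1.0)
        reason = ("mutant melt area below detection threshold"
                  if call.call == "mutant_detected" else None)
        return GenotypeCall(call="wild_only", peaks_used=call.peaks_used,
                            mutant_fraction_estimate=frac,
                            confidence=call.confidence, reason=reason)
    return call
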