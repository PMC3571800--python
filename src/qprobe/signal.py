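"""Fluorescence melt-curve synthesis and derivative-peak recovery.

A guanine-quenching probe is dark while hybridized and recovers its
fluorescence as the duplex melts, so the signal model is

    F(t) = b0 + b1*(t - t_min) + A * sum_a w_a * (1 - q * theta_a(t)) + eps

with per-allele occupancies theta_a from :mod:`qprobe.thermo`, quench
efficiency q, amplitude A, a linear baseline and additive Gaussian noise.
Fluorescence therefore *increases* on melting and melting transitions are
peaks in +dF/dT -- note the sign: much melt-analysis convention for
intercalating dyes uses -dF/dT instead.

Peak recovery mirrors the instrument pipeline: polynomial (Savitzky-Golay)
smoothing/differentiation followed by local-maximum detection with height,
prominence and separation thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import scipy.signal as _ss

from .thermo import DuplexParams, ThermoConfig, fraction_bound

DEFAULT_QUENCH_EFFICIENCY = 0.85
DEFAULT_AMPLITUDE = 1.0
DEFAULT_BASELINE_INTERCEPT = 0.05


@dataclass(frozen=True)
class TemperatureGrid:
    """Uniform melt ramp; default 40-85 degC in 0.1 degC steps."""

    t_min: float = 40.0
    t_max: float = 85.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if not (self.t_max > self.t_min and self.step > 0):
            raise ValueError("require t_max > t_min and step > 0")

    def temperatures(self) -> np.ndarray:
        n = int(round((self.t_max - self.t_min) / self.step)) + 1
        return self.t_min + self.step * np.arange(n)


@dataclass(frozen=True)
class NoiseConfig:
    """Additive Gaussian noise + linear drift + per-sample amplitude jitter."""

    sigma_additive: float = 2e-4
    baseline_slope: float = 0.002
    amplitude_cv: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_additive < 0 or self.amplitude_cv < 0:
            raise ValueError("sigma_additive and amplitude_cv must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(sigma_additive=0.0, baseline_slope=0.0, amplitude_cv=0.0)

    def with_seed(self, seed: int) -> "NoiseConfig":
        return replace(self, seed=seed)


@dataclass
class MeltCurve:
    temperatures: np.ndarray
    fluorescence: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, float)
        f = np.asarray(self.fluorescence, float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("temperature and fluorescence arrays must match")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if not np.all(np.isfinite(f)):
            raise ValueError("fluorescence values must be finite")
        self.temperatures, self.fluorescence = t, f

    @property
    def step(self) -> float:
        return float(self.temperatures[1] - self.temperatures[0])

    @property
    def uniform(self) -> bool:
        d = np.diff(self.temperatures)
        return bool(np.all(np.abs(d - d[0]) < 1e-9))


@dataclass
class DerivativeCurve:
    temperatures: np.ndarray
    dfdt: np.ndarray

    def __post_init__(self) -> None:
        if self.temperatures.shape != self.dfdt.shape:
            raise ValueError("array length mismatch")

    @property
    def step(self) -> float:
        return float(self.temperatures[1] - self.temperatures[0])


@dataclass(frozen=True)
class Peak:
    tm: float
    height: float
    prominence: float
    width_half_height: float

    def __post_init__(self) -> None:
        if not (self.height > 0 and 0 < self.prominence <= self.height + 1e-12
                and self.width_half_height > 0):
            raise ValueError("invalid peak geometry")


def simulate_melt_curve(assay,
                        pool: Mapping[str, float],
                        noise: Optional[NoiseConfig] = None,
                        grid: Optional[TemperatureGrid] = None,
                        thermo_cfg: Optional[ThermoConfig] = None,
                        *,
                        quench_efficiency: float = DEFAULT_QUENCH_EFFICIENCY,
                        amplitude: float = DEFAULT_AMPLITUDE,
                        rng: Optional[np.random.Generator] = None) -> MeltCurve:
    """Synthesize one melt curve for an allele mixture.

    ``assay`` is either a mapping allele -> :class:`DuplexParams` or any
    object exposing such a mapping as ``.duplexes`` (e.g. a designed probe
    assay).  ``pool`` gives allele weights summing to 1.  With zero noise
    the curve is exactly the fraction-weighted sum of the pure-allele
    curves and is non-decreasing in temperature.
    """
    duplexes: Mapping[str, DuplexParams] = getattr(assay, "duplexes", assay)
    noise = noise if noise is not None else NoiseConfig()
    grid = grid if grid is not None else TemperatureGrid()
    thermo_cfg = thermo_cfg if thermo_cfg is not None else ThermoConfig()
    total = float(sum(pool.values()))
    if abs(total - 1.0) > 1e-9 or any(not 0 <= w <= 1 + 1e-12 for w in pool.values()):
        raise ValueError("pool fractions must lie in [0, 1] and sum to 1")
    unknown = set(pool) - set(duplexes)
    if unknown:
        raise ValueError(f"pool alleles without duplex parameters: {sorted(unknown)}")

    t = grid.temperatures()
    warnings = []
    for allele, params in duplexes.items():
        if pool.get(allele, 0.0) > 0 and params.stable:
            if params.tm - 10.0 < grid.t_min or params.tm + 10.0 > grid.t_max:
                warnings.append(
                    f"grid [{grid.t_min}, {grid.t_max}] does not cover "
                    f"Tm({allele}) = {params.tm:.1f} +/- 10 degC")

    if rng is None:
        rng = np.random.default_rng(noise.seed)
    amp = amplitude
    if noise.amplitude_cv > 0:
        amp = amplitude * (1.0 + noise.amplitude_cv * rng.standard_normal())
    signal = np.zeros_like(t)
    for allele, w in pool.items():
        if w == 0:
            continue
        theta = fraction_bound(duplexes[allele], t, thermo_cfg)
        signal += w * (1.0 - quench_efficiency * theta)
    f = DEFAULT_BASELINE_INTERCEPT + noise.baseline_slope * (t - grid.t_min) + amp * signal
    if noise.sigma_additive > 0:
        f = f + noise.sigma_additive * rng.standard_normal(t.shape)
    meta = {"warnings": warnings, "pool": dict(pool), "seed": noise.seed}
    return MeltCurve(temperatures=t, fluorescence=f, meta=meta)


def smooth_and_differentiate(curve: MeltCurve, window: int = 15,
                             polyorder: int = 3) -> DerivativeCurve:
    """Savitzky-Golay derivative (+dF/dT), edge half-windows trimmed."""
    n = len(curve.temperatures)
    if window % 2 == 0 or window < 3 or window > n // 2:
        raise ValueError(f"window must be odd and in [3, {n // 2}] for a "
                         f"{n}-point curve")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if not curve.uniform:
        raise ValueError("derivative requires a uniform temperature grid")
    d = _ss.savgol_filter(curve.fluorescence, window, polyorder, deriv=1,
                          delta=curve.step)
    half = window // 2
    return DerivativeCurve(temperatures=curve.temperatures[half:n - half],
                           dfdt=d[half:n - half])


def find_peaks(dcurve: DerivativeCurve, min_height_frac: float = 0.10,
               min_prominence_frac: float = 0.05,
               min_separation: float = 2.0) -> list[Peak]:
    """Detect melting peaks in a derivative curve.

    Thresholds are fractions of the global derivative maximum; plateau
    ties report the lowest-temperature grid point of the plateau.  Peaks
    come back sorted by Tm ascending; an empty list is a valid result.
    """
    if not (0 <= min_height_frac <= 1 and 0 <= min_prominence_frac <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    step = dcurve.step
    if min_separation < step:
        raise ValueError("min_separation must be >= the grid step")
    d = dcurve.dfdt
    gmax = float(np.max(d)) if len(d) else 0.0
    if gmax <= 0:
        return []
    idx, props = _ss.find_peaks(
        d,
        height=max(min_height_frac * gmax, 0.0) or None,
        prominence=max(min_prominence_frac * gmax, 0.0) or None,
        distance=max(1, int(round(min_separation / step))),
        plateau_size=(1, None),
    )
    if len(idx) == 0:
        return []
    widths = _ss.peak_widths(d, idx, rel_height=0.5)[0] * step
    peaks = []
    for k, i in enumerate(idx):
        apex = int(props["left_edges"][k])  # plateau tie-break: lowest T
        height = float(d[apex])
        if height <= 0:
            continue
        prom = min(float(props["prominences"][k]), height)
        peaks.append(Peak(tm=float(dcurve.temperatures[apex]),
                          height=height,
                          prominence=prom,
                          width_half_height=float(max(widths[k], step))))
    peaks.sort(key=lambda p: p.tm)
    return peaks
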