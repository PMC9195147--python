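"""Thermal-denaturation analysis of CD scans.

Melting temperatures are read as the positions of the (at most two) most
prominent peaks of |dΘ₂₂₂/dT|: the ellipticity trace is Savitzky–Golay
smoothed, differentiated by central differences, and peak positions refined
by quadratic interpolation.  Using the magnitude of the derivative makes the
extraction agnostic to the sign convention of the ellipticity axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .types import MeltingCurve

__all__ = [
    "MeltingResult",
    "extract_tms",
    "delta_tm",
    "check_reversibility",
    "DEFAULT_SMOOTH_WINDOW",
    "DEFAULT_PROMINENCE_FRAC",
]

#: Default smoothing window in points: 11 points = 5.5 °C on the 0.5 °C grid,
#: odd and narrower than the closest transition pair handled (8 °C apart).
DEFAULT_SMOOTH_WINDOW = 11
DEFAULT_PROMINENCE_FRAC = 0.05


@dataclass(frozen=True)
class MeltingResult:
    """Extracted melting temperature(s) plus the derivative evidence."""

    tms: tuple
    derivative_t: np.ndarray
    derivative: np.ndarray
    prominences: tuple
    two_step: bool

    def __post_init__(self):
        tms = tuple(float(t) for t in self.tms)
        if not 1 <= len(tms) <= 2:
            raise ValueError("one or two melting temperatures expected")
        if list(tms) != sorted(tms):
            raise ValueError("melting temperatures must be ascending")
        if self.two_step != (len(tms) == 2):
            raise ValueError("two_step flag inconsistent with number of Tm values")
        object.__setattr__(self, "tms", tms)


def _quadratic_peak(x: np.ndarray, y: np.ndarray, i: int) -> float:
    if i == 0 or i == len(y) - 1:
        return float(x[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if abs(denom) < 1e-300:
        return float(x[i])
    h = 0.5 * (x[i + 1] - x[i - 1])
    return float(x[i] + h * 0.5 * (y0 - y2) / denom)


def _two_peak_fit(t: np.ndarray, deriv: np.ndarray, peaks: list[int]) -> list[float]:
    """Joint two-Gaussian fit of |dΘ/dT| around a pair of peaks.

    Falls back to independent quadratic interpolation if the fit fails or
    wanders away from the discrete maxima.
    """
    from scipy.optimize import curve_fit

    def model(x, a1, c1, s1, a2, c2, s2):
        return (a1 * np.exp(-0.5 * ((x - c1) / s1) ** 2)
                + a2 * np.exp(-0.5 * ((x - c2) / s2) ** 2))

    i1, i2 = peaks
    mask = (t >= t[i1] - 10.0) & (t <= t[i2] + 10.0)
    p0 = [deriv[i1], t[i1], 2.0, deriv[i2], t[i2], 2.0]
    try:
        popt, _ = curve_fit(model, t[mask], deriv[mask], p0=p0, maxfev=5000)
        centers = sorted([float(popt[1]), float(popt[4])])
        # accept only if each fitted center stays near its discrete peak
        if abs(centers[0] - t[i1]) <= 2.0 and abs(centers[1] - t[i2]) <= 2.0:
            return centers
    except RuntimeError:
        pass
    return [_quadratic_peak(t, deriv, i1), _quadratic_peak(t, deriv, i2)]


def extract_tms(c: MeltingCurve, smooth_window: int = DEFAULT_SMOOTH_WINDOW,
                prominence_frac: float = DEFAULT_PROMINENCE_FRAC) -> MeltingResult:
    """Extract 1–2 melting temperatures from the first derivative of Θ(T).

    Peaks of |dΘ/dT| with prominence ≥ ``prominence_frac`` × the global
    maximum are candidates; the top two by prominence are kept (ties broken
    toward lower temperature).  A single peak is refined by a parabola
    through the three surrounding samples; when two peaks are retained their
    positions come from a joint two-Gaussian fit to the derivative, which
    deconvolves the mutual pull that overlapping transitions exert on each
    other's apparent maximum.
    """
    if len(c) < 40:
        raise ValueError("need at least 40 points for a reliable derivative")
    steps = np.diff(c.temperatures)
    if steps.max() > 2.0 * steps.min():
        raise ValueError("temperature grid must be near-uniform")
    if smooth_window % 2 == 0 or smooth_window < 5:
        raise ValueError("smoothing window must be odd and >= 5")

    theta = savgol_filter(c.theta222, smooth_window, polyorder=3)
    deriv = np.abs(np.gradient(theta, c.temperatures))
    global_max = float(deriv.max())
    if global_max <= 0:
        raise ValueError("no thermal transition detected: derivative is flat")
    idx, props = find_peaks(deriv, prominence=prominence_frac * global_max)
    if len(idx) == 0:
        raise ValueError("no thermal transition detected above the prominence threshold")
    # rank by prominence, ties toward lower temperature
    ranking = sorted(range(len(idx)), key=lambda j: (-props["prominences"][j], idx[j]))
    chosen = sorted(ranking[:2], key=lambda j: idx[j])
    if len(chosen) == 2:
        tms = _two_peak_fit(c.temperatures, deriv, [int(idx[j]) for j in chosen])
    else:
        tms = [_quadratic_peak(c.temperatures, deriv, int(idx[chosen[0]]))]
    proms = [float(props["prominences"][j]) for j in chosen]
    order = np.argsort(tms)
    tms = [tms[i] for i in order]
    proms = [proms[i] for i in order]
    return MeltingResult(tms=tuple(tms), derivative_t=c.temperatures.copy(),
                         derivative=deriv, prominences=tuple(proms),
                         two_step=len(tms) == 2)


def delta_tm(with_metal: MeltingResult, without: MeltingResult) -> float:
    """Tm shift upon metal addition, °C: first (lowest) Tm with metal minus
    first Tm without.  Destabilization is negative."""
    return float(with_metal.tms[0] - without.tms[0])


def check_reversibility(heat: MeltingCurve, cool: MeltingCurve,
                        tol: float = 0.05) -> tuple[bool, float]:
    """Compare heating and cooling scans on their common temperature range.

    Returns (reversible, max deviation): reversible iff the maximum absolute
    Θ difference on the overlap stays within ``tol`` × the heating-scan
    dynamic range — the quantitative reading of "no hysteresis".
    """
    lo = max(heat.temperatures[0], cool.temperatures[0])
    hi = min(heat.temperatures[-1], cool.temperatures[-1])
    if lo >= hi:
        raise ValueError("heating and cooling scans do not overlap in temperature")
    mask = (heat.temperatures >= lo) & (heat.temperatures <= hi)
    grid = heat.temperatures[mask]
    h = heat.theta222[mask]
    c = np.interp(grid, cool.temperatures, cool.theta222)
    dev = float(np.max(np.abs(h - c)))
    span = float(heat.theta222.max() - heat.theta222.min())
    return dev <= tol * span, dev
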