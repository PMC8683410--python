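"""Thioflavin-T aggregation-kinetics descriptors and CD spectrum handling.

ThT fluorescence rises when the dye binds cross-beta structure, so a plate
reader time course reports the progress of fibrillization.  The trace is
summarised with a 4-parameter logistic

    F(t) = F0 + A / (1 + exp(-k (t - t50)))

from which the standard descriptors follow by tangent construction:
lag time = t50 - 2/k, and plateau time = t50 + ln(99)/k (99% of the
amplitude).  A model-free plateau detector (trailing-median band) is
provided alongside the parametric fit.

CD spectra are normalised to the ellipticity magnitude at a reference
wavelength (default 217 nm, the beta-sheet minimum), which makes spectra
of different concentration/pathlength comparable in shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import lmfit
import numpy as np

from .errors import ConvergenceError, InvalidParameterError

PLATEAU_QUANTILE_LOG = math.log(99.0)  # logistic reaches 99% at t50 + ln(99)/k


@dataclass
class ThTTrace:
    """A ThT fluorescence time course."""

    times: np.ndarray                  # h, strictly increasing
    fluorescence: np.ndarray           # a.u.
    background_corrected: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.shape != self.fluorescence.shape:
            raise InvalidParameterError("times and fluorescence must match")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")


def subtract_background(trace: ThTTrace, buffer: ThTTrace,
                        interpolate: bool = False) -> ThTTrace:
    """Background-correct a ThT trace by subtracting the buffer control.

    Grids must match exactly unless ``interpolate`` is set, in which case the
    buffer is linearly interpolated onto the trace's grid (and must cover it).
    """
    if trace.times.shape == buffer.times.shape and np.allclose(
            trace.times, buffer.times):
        bg = buffer.fluorescence
    elif interpolate:
        if trace.times[0] < buffer.times[0] or trace.times[-1] > buffer.times[-1]:
            raise InvalidParameterError("buffer grid does not cover the trace")
        bg = np.interp(trace.times, buffer.times, buffer.fluorescence)
    else:
        raise InvalidParameterError(
            "time grids differ; pass interpolate=True to resample the buffer")
    return ThTTrace(times=trace.times.copy(),
                    fluorescence=trace.fluorescence - bg,
                    background_corrected=True)


@dataclass
class ThTFit:
    """Logistic fit of a ThT trace with derived kinetic descriptors.

    Invariant (when a transition is present): lag = t50 - 2/k and
    plateau_time = t50 + ln(99)/k >= t50.
    """

    F0: float                          # a.u.
    A: float                           # amplitude, a.u.
    k: float                           # 1/h
    t50: float                         # h
    lag: float                         # h
    plateau_time: float                # h
    no_transition: bool = False
    rss: float = 0.0


def fit_tht_sigmoid(trace: ThTTrace, amplitude_floor: float | None = None) -> ThTFit:
    """Fit F(t) = F0 + A/(1 + exp(-k(t - t50))) by least squares.

    A trace whose fitted amplitude is below ``amplitude_floor`` (default:
    3x the residual scatter) is flagged ``no_transition`` with NaN
    descriptors.
    """
    t, f = trace.times, trace.fluorescence
    if t.size < 8:
        raise InvalidParameterError("need >= 8 time points for the logistic fit")
    f_rng = float(np.ptp(f))
    span = float(t[-1] - t[0])

    params = lmfit.Parameters()
    params.add("f0", value=float(np.min(f)))
    params.add("a", value=f_rng if f_rng > 0 else 1e-9, min=0.0)
    params.add("k", value=4.0 / span if span > 0 else 1.0, min=1e-6)
    half = float(np.min(f)) + 0.5 * f_rng
    t50_init = float(t[np.argmin(np.abs(f - half))])
    params.add("t50", value=t50_init, min=t[0] - span, max=t[-1] + span)

    def resid(p: lmfit.Parameters) -> np.ndarray:
        x = p["k"].value * (t - p["t50"].value)
        return p["f0"].value + p["a"].value / (1.0 + np.exp(-x)) - f

    result = lmfit.minimize(resid, params)
    if not result.success:
        raise ConvergenceError(f"ThT sigmoid fit did not converge: {result.message}")
    p = result.params
    rss = float(np.sum(resid(p) ** 2))
    noise = math.sqrt(rss / max(t.size - 4, 1))
    if amplitude_floor is None:
        # 3x residual scatter, or a tiny fraction of the signal scale for
        # numerically flat traces whose residual is ~0
        scale = max(float(np.max(np.abs(f))), 1.0)
        floor = max(3.0 * noise, 1e-6 * scale)
    else:
        floor = amplitude_floor
    a, k, t50 = p["a"].value, p["k"].value, p["t50"].value
    if a <= max(floor, 1e-12):
        return ThTFit(F0=p["f0"].value, A=a, k=k, t50=t50,
                      lag=float("nan"), plateau_time=float("nan"),
                      no_transition=True, rss=rss)
    return ThTFit(F0=p["f0"].value, A=a, k=k, t50=t50,
                  lag=t50 - 2.0 / k, plateau_time=t50 + PLATEAU_QUANTILE_LOG / k,
                  rss=rss)


@dataclass(frozen=True)
class PlateauResult:
    """Model-free plateau detection outcome."""

    plateau_time: float                # h (NaN when not reached)
    reached: bool
    level: float                       # trailing-window median, a.u.


def detect_plateau(trace: ThTTrace, tol: float = 0.02,
                   trailing_fraction: float = 0.1) -> PlateauResult:
    """Earliest time after which the trace stays within ``tol`` of its
    trailing-window median.

    The trailing window is the last ``trailing_fraction`` of points (at
    least 3).  A window that itself still drifts by more than the band
    (monotone rise that never settles) is reported as not reached.
    """
    t, f = trace.times, trace.fluorescence
    n_win = max(int(math.ceil(trailing_fraction * t.size)), 3)
    if n_win > t.size:
        raise InvalidParameterError("need >= 3 trailing points")
    level = float(np.median(f[-n_win:]))
    band = tol * max(abs(level), 1e-12)
    if np.ptp(f[-n_win:]) > 2.0 * band:
        return PlateauResult(plateau_time=float("nan"), reached=False, level=level)
    inside = np.abs(f - level) <= band
    # earliest index from which every later sample stays inside the band
    idx = t.size
    for i in range(t.size - 1, -1, -1):
        if inside[i]:
            idx = i
        else:
            break
    if idx == t.size:
        return PlateauResult(plateau_time=float("nan"), reached=False, level=level)
    return PlateauResult(plateau_time=float(t[idx]), reached=True, level=level)


# --------------------------------------------------------------------------
# CD spectra
# --------------------------------------------------------------------------

@dataclass
class CDSpectrum:
    """A far-UV CD spectrum."""

    wavelengths: np.ndarray            # nm, strictly increasing
    ellipticity: np.ndarray            # mdeg (or normalized)
    normalized: bool = False
    reference_wavelength: float | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.wavelengths.shape != self.ellipticity.shape:
            raise InvalidParameterError("wavelengths and ellipticity must match")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise InvalidParameterError("wavelengths must be strictly increasing")


def normalize_cd(spec: CDSpectrum, reference: float = 217.0) -> CDSpectrum:
    """Normalize a CD spectrum to |ellipticity| at the reference wavelength.

    The nearest grid wavelength is used; scale-invariant and idempotent.
    """
    if not (spec.wavelengths[0] <= reference <= spec.wavelengths[-1]):
        raise InvalidParameterError("reference wavelength outside spectral span")
    idx = int(np.argmin(np.abs(spec.wavelengths - reference)))
    ref = abs(float(spec.ellipticity[idx]))
    if ref == 0:
        raise InvalidParameterError("zero ellipticity at the reference wavelength")
    return CDSpectrum(wavelengths=spec.wavelengths.copy(),
                      ellipticity=spec.ellipticity / ref,
                      normalized=True,
                      reference_wavelength=float(spec.wavelengths[idx]))


def helix_minima_ratio(spec: CDSpectrum, wl_a: float = 208.0,
                       wl_b: float = 222.0) -> float:
    """Ratio of ellipticity at the two helical minima (208/222 nm).

    A simple two-point shape descriptor of helicity change; no secondary
    structure deconvolution.
    """
    vals = []
    for wl in (wl_a, wl_b):
        if not (spec.wavelengths[0] <= wl <= spec.wavelengths[-1]):
            raise InvalidParameterError(f"{wl} nm outside spectral span")
        vals.append(float(spec.ellipticity[np.argmin(np.abs(spec.wavelengths - wl))]))
    if vals[1] == 0:
        raise InvalidParameterError("zero ellipticity at the denominator wavelength")
    return vals[0] / vals[1]
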