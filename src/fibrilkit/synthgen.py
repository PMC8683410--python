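"""Synthetic instrument-data generators with known ground truth.

Every analysis stage in this package inverts a forward model; this module
implements those forward models directly, so each generator/analyzer pair
forms a round trip with known ground-truth parameters:

* correlograms -- Siegert-relation multi-exponential decays from species
  radii via Stokes-Einstein;
* ITC thermograms -- baseline plus rectangular (or Gaussian) heat pulses
  with an analytically known total heat;
* spin-diffusion build-ups -- linear-capped or exponential saturation with
  a prescribed build-up time;
* SPR isotherms -- Hill curves;
* ThT traces -- 4-parameter logistics;
* dH(T) tables -- continuous piecewise-linear enthalpy with two slopes;
* CD spectra -- sums of Gaussian bands at the canonical helix/sheet minima.

Noise is additive Gaussian everywhere, drawn from a generator seeded per
spec; ``noise_sd = 0`` produces bit-identical output for any seed because
no random numbers are drawn at all.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Any, NamedTuple

import numpy as np
import pandas as pd

from . import dls as _dls
from .binding import BindingIsotherm
from .errors import InvalidParameterError
from .kinetics import CDSpectrum, ThTTrace
from .nmr import BuildUpCurve
from .thermo import JOULE_PER_CALORIE, Thermogram

KINDS = ("correlogram", "thermogram", "buildup", "isotherm", "tht",
         "dH_table", "cd_spectrum")


@dataclass
class SimSpec:
    """Specification of one synthetic data set.

    ``grid`` is the sampling vector in the units of the target kind
    (lag times s / times s / mixing times ms / concentrations M /
    temperatures K / wavelengths nm); ``params`` carries the named
    ground-truth parameters of the forward model; ``noise_sd`` is the
    additive Gaussian noise standard deviation in the output's units.
    """

    kind: str
    params: dict[str, Any]
    grid: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise InvalidParameterError(f"unknown kind {self.kind!r}")
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.size < 3 or np.any(np.diff(self.grid) <= 0):
            raise InvalidParameterError("grid must be strictly increasing, length >= 3")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be nonnegative")


def _noise(spec: SimSpec, n: int) -> np.ndarray:
    # noise_sd = 0 never touches the RNG: bit-reproducible, seed-independent
    if spec.noise_sd == 0:
        return np.zeros(n)
    rng = np.random.default_rng(spec.seed)
    return rng.normal(0.0, spec.noise_sd, n)


def gen_correlogram(spec: SimSpec,
                    instrument: _dls.InstrumentConfig | None = None) -> _dls.CorrelogramTrace:
    """Multi-exponential DLS correlogram from a species list.

    ``params["species"]`` lists (R_H nm, intensity fraction) pairs; the
    forward model is g2-1 = beta * (sum_i f_i exp(-Gamma_i tau))^2 with
    Gamma_i = D_i q^2 and D_i from inverse Stokes-Einstein.
    """
    instrument = instrument or _dls.InstrumentConfig()
    species = spec.params.get("species", [])
    if not species:
        raise InvalidParameterError("species list is empty")
    radii = np.array([r for r, _ in species], dtype=float)
    fracs = np.array([f for _, f in species], dtype=float)
    if np.any(radii <= 0):
        raise InvalidParameterError("all radii must be positive")
    if abs(fracs.sum() - 1.0) > 1e-6:
        raise InvalidParameterError("intensity fractions must sum to 1")
    q = instrument.scattering_vector
    gammas = np.array([_dls.diffusion_from_radius(r, instrument) for r in radii]) * q ** 2
    g1 = np.sum(fracs[:, None] * np.exp(-np.outer(gammas, spec.grid)), axis=0)
    g2m1 = instrument.beta * g1 ** 2 + _noise(spec, spec.grid.size)
    return _dls.CorrelogramTrace(lags=spec.grid, g2m1=g2m1, config=instrument)


class SyntheticThermogram(NamedTuple):
    """A generated thermogram with its analytically known heat."""

    thermogram: Thermogram
    pulse_heats_J: list[float]         # per pulse, joules
    total_heat_J: float


def gen_thermogram(spec: SimSpec) -> SyntheticThermogram:
    """Baseline-plus-pulses ITC thermogram with known total heat.

    ``params``: ``baseline`` ucal/s; ``pulses`` list of (t_start s,
    duration s, amplitude ucal/s); ``n_mol`` protein amount (mol);
    ``shape`` "rect" (default) or "gauss".  The ground-truth heat of each
    pulse (amplitude x duration in ucal, converted to J at 4.184 J/cal) is
    returned alongside; overlapping pulses are allowed, pulses outside the
    grid are not.
    """
    baseline = float(spec.params.get("baseline", 0.0))
    pulses = spec.params.get("pulses", [])
    n_mol = float(spec.params.get("n_mol", 0.0))
    shape = spec.params.get("shape", "rect")
    if n_mol <= 0:
        raise InvalidParameterError("n_mol must be positive")
    t = spec.grid
    flow = np.full(t.size, baseline)
    heats = []
    for t0, dur, amp in pulses:
        if dur <= 0:
            raise InvalidParameterError("pulse duration must be positive")
        if t0 < t[0] or t0 + dur > t[-1]:
            raise InvalidParameterError(
                f"pulse [{t0}, {t0 + dur}] outside grid span [{t[0]}, {t[-1]}]")
        if shape == "rect":
            flow += np.where((t >= t0) & (t < t0 + dur), amp, 0.0)
        elif shape == "gauss":
            sigma = dur / 6.0
            centre = t0 + dur / 2.0
            # same analytic area as the rectangle: amp * dur
            peak = amp * dur / (sigma * math.sqrt(2.0 * math.pi))
            flow += peak * np.exp(-0.5 * ((t - centre) / sigma) ** 2)
        else:
            raise InvalidParameterError(f"unknown pulse shape {shape!r}")
        heats.append(amp * dur * 1e-6 * JOULE_PER_CALORIE)
    flow += _noise(spec, t.size)
    inj_time = min((p[0] for p in pulses), default=float(t[0]))
    tg = Thermogram(times=t, heat_flow=flow,
                    injections=[(float(inj_time), n_mol)])
    return SyntheticThermogram(thermogram=tg, pulse_heats_J=heats,
                               total_heat_J=float(sum(heats)))


def gen_buildup(spec: SimSpec) -> BuildUpCurve:
    """Spin-diffusion build-up with prescribed build-up time t_m^s.

    ``params``: ``t_m_s`` ms and ``model`` in {"linear_capped",
    "exponential"}: S(t) = min(t/t_m^s, 1) or 1 - exp(-t/t_m^s).
    """
    t_m_s = float(spec.params.get("t_m_s", 0.0))
    model = spec.params.get("model", "linear_capped")
    if t_m_s <= 0:
        raise InvalidParameterError("t_m_s must be positive")
    t = spec.grid
    if model == "linear_capped":
        s = np.minimum(t / t_m_s, 1.0)
    elif model == "exponential":
        s = 1.0 - np.exp(-t / t_m_s)
    else:
        raise InvalidParameterError(f"unknown build-up model {model!r}")
    s = s + _noise(spec, t.size)
    return BuildUpCurve(mixing_times=t, intensities=s,
                        normalized=spec.noise_sd == 0)


def gen_isotherm(spec: SimSpec) -> BindingIsotherm:
    """Hill-equation SPR isotherm R(c) = R_max c^n / (K_D^n + c^n).

    ``params``: ``k_d`` M, ``n``, ``r_max`` RU, optional labels.
    The grid is the concentration vector (M); nonpositive entries raise.
    """
    k_d = float(spec.params.get("k_d", 0.0))
    n = float(spec.params.get("n", 0.0))
    r_max = float(spec.params.get("r_max", 0.0))
    if k_d <= 0 or n <= 0 or r_max <= 0:
        raise InvalidParameterError("k_d, n and r_max must all be positive")
    c = spec.grid
    if np.any(c <= 0):
        raise InvalidParameterError("concentrations must be positive")
    r = r_max * c ** n / (k_d ** n + c ** n) + _noise(spec, c.size)
    return BindingIsotherm(concentrations=c, responses=r,
                           ligand_label=spec.params.get("ligand", ""),
                           analyte_label=spec.params.get("analyte", ""))


def gen_tht(spec: SimSpec) -> ThTTrace:
    """Logistic ThT trace F(t) = F0 + A/(1 + exp(-k(t - t50))).

    ``params``: ``f0``, ``a`` (a.u.), ``k`` (1/h), ``t50`` (h); grid in hours.
    """
    f0 = float(spec.params.get("f0", 0.0))
    a = float(spec.params.get("a", 0.0))
    k = float(spec.params.get("k", 0.0))
    t50 = float(spec.params.get("t50", 0.0))
    if k <= 0:
        raise InvalidParameterError("rate k must be positive")
    t = spec.grid
    f = f0 + a / (1.0 + np.exp(-k * (t - t50))) + _noise(spec, t.size)
    return ThTTrace(times=t, fluorescence=f, background_corrected=True)


def gen_dH_table(spec: SimSpec) -> pd.DataFrame:
    """Continuous piecewise-linear dH(T) table with two slopes.

    ``params``: ``breakpoint`` K, ``slope_low`` and ``slope_high`` kJ/mol/K,
    ``intercept`` kJ/mol (dH at the breakpoint); grid in K.  Returns columns
    T_K, dH_kJ_mol.  A grid entirely on one side of the breakpoint yields a
    single-phase table with a warning.
    """
    bp = float(spec.params.get("breakpoint", 0.0))
    s_lo = float(spec.params.get("slope_low", 0.0))
    s_hi = float(spec.params.get("slope_high", 0.0))
    intercept = float(spec.params.get("intercept", 0.0))
    t = spec.grid
    if not (t[0] <= bp <= t[-1]):
        warnings.warn("breakpoint outside grid span; single-phase table",
                      stacklevel=2)
    dh = np.where(t <= bp, intercept + s_lo * (t - bp), intercept + s_hi * (t - bp))
    dh = dh + _noise(spec, t.size)
    return pd.DataFrame({"T_K": t, "dH_kJ_mol": dh})


def gen_cd_spectrum(spec: SimSpec) -> CDSpectrum:
    """Far-UV CD spectrum as a sum of Gaussian bands.

    ``params["bands"]`` lists (centre nm, width nm, amplitude mdeg) tuples;
    defaults emulate an alpha-helical spectrum with minima near 208 and
    222 nm.  Grid in nm.
    """
    bands = spec.params.get("bands",
                            [(208.0, 6.0, -10.0), (222.0, 7.0, -9.0),
                             (193.0, 5.0, 25.0)])
    wl = spec.grid
    theta = np.zeros(wl.size)
    for centre, width, amp in bands:
        theta += amp * np.exp(-0.5 * ((wl - centre) / width) ** 2)
    theta += _noise(spec, wl.size)
    return CDSpectrum(wavelengths=wl, ellipticity=theta)
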