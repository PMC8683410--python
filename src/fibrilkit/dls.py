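"""Dynamic light scattering: correlogram inversion, Stokes-Einstein sizing,
mass calibration and critical-concentration estimation.

The intensity autocorrelation function of a dilute suspension of diffusing
particles obeys the Siegert relation

    g2(tau) - 1 = beta * |g1(tau)|^2,   g1(tau) = sum_i f_i exp(-Gamma_i tau)

with coherence factor beta, intensity fractions f_i and decay rates
Gamma_i = D_i q^2.  Inverting a correlogram therefore yields diffusion
coefficients, which map to apparent hydrodynamic radii through the
Stokes-Einstein equation R_H = k_B T / (6 pi eta D).

Molecular masses are obtained from radii through an empirical power law
M = a * R_H^b calibrated on (R_H, M) pairs; the instrument class this module
emulates reports masses internally without documenting its formula, so the
calibration is shipped as replaceable data, not hard-coded physics.

The critical concentration of a fibrillizing protein is estimated from a
dilution series as the lowest concentration at which the free
monomer/oligomer species is still detected: at equilibrium with fibrils the
free-unit concentration pins to the critical concentration, so the detection
limit of the sizing instrument brackets it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import lmfit
import numpy as np

from .errors import ConvergenceError, InvalidParameterError, NoDecayError, NotDeterminedError

BOLTZMANN_J_PER_K = 1.380649e-23

# Dynamic viscosity of water, mPa*s, at 5 degC steps from 0 to 60 degC
# (standard reference values; linear interpolation in between).
_WATER_VISCOSITY_TABLE_C = np.arange(0.0, 65.0, 5.0)
_WATER_VISCOSITY_TABLE_MPAS = np.array([
    1.7920, 1.5190, 1.3060, 1.1380, 1.0020, 0.8900, 0.7972,
    0.7190, 0.6527, 0.5958, 0.5465, 0.5036, 0.4660,
])


def water_viscosity(temperature_K: float) -> float:
    """Dynamic viscosity of water in Pa*s at the given temperature.

    Linear interpolation of a standard reference table covering 0-60 degC;
    temperatures outside that span raise.
    """
    t_c = temperature_K - 273.15
    if not (_WATER_VISCOSITY_TABLE_C[0] <= t_c <= _WATER_VISCOSITY_TABLE_C[-1]):
        raise InvalidParameterError(
            f"water viscosity table covers 0-60 degC, got {t_c:.2f} degC"
        )
    return float(np.interp(t_c, _WATER_VISCOSITY_TABLE_C, _WATER_VISCOSITY_TABLE_MPAS)) * 1e-3


@dataclass(frozen=True)
class InstrumentConfig:
    """Optical and sample parameters of a cuvette DLS instrument.

    Defaults are typical values for a 660 nm laser at 90 degrees in aqueous
    buffer; every field is overridable.  ``viscosity`` of ``None`` means
    "water at ``temperature``" via the embedded reference table.
    """

    wavelength: float = 660.0          # nm
    angle: float = 90.0                # degrees
    refractive_index: float = 1.33
    temperature: float = 293.15        # K
    viscosity: float | None = None     # Pa*s; None -> water at temperature
    beta: float = 0.9                  # Siegert coherence factor, (0, 1]

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise InvalidParameterError("temperature must be positive")
        if not (0.0 < self.beta <= 1.0):
            raise InvalidParameterError("beta must be in (0, 1]")
        if self.viscosity is not None and self.viscosity <= 0:
            raise InvalidParameterError("viscosity must be positive")
        if self.scattering_vector <= 0:
            raise InvalidParameterError("scattering vector q must be positive")

    @property
    def eta(self) -> float:
        """Solvent viscosity in Pa*s."""
        if self.viscosity is not None:
            return self.viscosity
        return water_viscosity(self.temperature)

    @property
    def scattering_vector(self) -> float:
        """Magnitude of the scattering vector q in 1/m."""
        lam_m = self.wavelength * 1e-9
        return 4.0 * math.pi * self.refractive_index / lam_m * math.sin(
            math.radians(self.angle) / 2.0
        )


@dataclass
class CorrelogramTrace:
    """An intensity-autocorrelation trace, g2 - 1 versus lag time."""

    lags: np.ndarray                   # s, strictly increasing, > 0
    g2m1: np.ndarray                   # dimensionless
    config: InstrumentConfig = field(default_factory=InstrumentConfig)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g2m1 = np.asarray(self.g2m1, dtype=float)
        if self.lags.shape != self.g2m1.shape:
            raise InvalidParameterError("lags and g2m1 must have equal length")
        if self.lags.size < 3 or np.any(np.diff(self.lags) <= 0) or self.lags[0] <= 0:
            raise InvalidParameterError("lags must be positive and strictly increasing")


@dataclass
class HydroSpecies:
    """One diffusing species: hydrodynamic radius, diffusion coefficient,
    intensity fraction and (after calibration) molecular mass."""

    radius: float                      # nm
    diffusion: float                   # m^2/s
    fraction: float                    # intensity weight in [0, 1]
    mass: float | None = None          # kDa


@dataclass
class SizeDistribution:
    """Discrete size distribution recovered from one correlogram."""

    species: list[HydroSpecies]
    residual: float                    # L2 norm of the fit residual

    def __post_init__(self) -> None:
        self.species.sort(key=lambda s: s.radius)
        total = sum(s.fraction for s in self.species)
        if abs(total - 1.0) > 1e-6:
            raise InvalidParameterError(f"fractions must sum to 1, got {total}")


def stokes_einstein(diffusion: float, config: InstrumentConfig) -> float:
    """Hydrodynamic radius in nm from a diffusion coefficient in m^2/s.

    R_H = k_B T / (6 pi eta D).
    """
    if diffusion <= 0:
        raise InvalidParameterError("diffusion coefficient must be positive")
    r_m = BOLTZMANN_J_PER_K * config.temperature / (6.0 * math.pi * config.eta * diffusion)
    return r_m * 1e9


def diffusion_from_radius(radius: float, config: InstrumentConfig) -> float:
    """Inverse Stokes-Einstein: diffusion coefficient (m^2/s) from R_H (nm)."""
    if radius <= 0:
        raise InvalidParameterError("radius must be positive")
    return BOLTZMANN_J_PER_K * config.temperature / (6.0 * math.pi * config.eta * radius * 1e-9)


def fit_correlogram(trace: CorrelogramTrace, n_components: int = 1) -> SizeDistribution:
    """Invert a correlogram into 1-3 diffusing species.

    Bounded nonlinear least squares on the Siegert model
    g2 - 1 = beta * (sum_i f_i exp(-Gamma_i tau))^2 with the coherence factor
    beta taken from the trace's instrument configuration.  Decay rates are
    initialised log-spaced across the reciprocal lag range; intensity
    fractions are parameterised as normalised non-negative amplitudes.
    """
    if not (1 <= n_components <= 3):
        raise InvalidParameterError("n_components must be 1, 2 or 3")
    if trace.lags.size < 5 * n_components:
        raise InvalidParameterError(
            f"need at least {5 * n_components} points for {n_components} components"
        )
    g0 = float(trace.g2m1[0])
    gend = float(np.mean(trace.g2m1[-max(3, trace.lags.size // 20):]))
    if g0 <= 0 or gend >= 0.9 * g0:
        raise NoDecayError(
            f"trace does not decay (initial {g0:.3g}, final {gend:.3g})"
        )

    beta = trace.config.beta
    lags = trace.lags
    # log-spaced Gamma initialisation across the observable decay window
    g_lo, g_hi = 1.0 / lags[-1], 1.0 / lags[0]
    if n_components == 1:
        gamma_init = [math.sqrt(g_lo * g_hi)]
    else:
        gamma_init = list(np.geomspace(g_lo * 3, g_hi / 3, n_components))

    params = lmfit.Parameters()
    for i, g in enumerate(gamma_init):
        params.add(f"lg{i}", value=math.log10(g),
                   min=math.log10(g_lo) - 2, max=math.log10(g_hi) + 2)
        params.add(f"a{i}", value=1.0, min=0.0, vary=i > 0)

    def model(p: lmfit.Parameters) -> np.ndarray:
        amps = np.array([p[f"a{i}"].value for i in range(n_components)])
        gammas = 10.0 ** np.array([p[f"lg{i}"].value for i in range(n_components)])
        fracs = amps / amps.sum()
        g1 = np.sum(fracs[:, None] * np.exp(-np.outer(gammas, lags)), axis=0)
        return beta * g1 ** 2

    result = lmfit.minimize(lambda p: model(p) - trace.g2m1, params)
    if not result.success:
        raise ConvergenceError(f"correlogram fit did not converge: {result.message}")

    p = result.params
    amps = np.array([p[f"a{i}"].value for i in range(n_components)])
    gammas = 10.0 ** np.array([p[f"lg{i}"].value for i in range(n_components)])
    fracs = amps / amps.sum()
    q = trace.config.scattering_vector
    species = []
    for gam, frac in zip(gammas, fracs):
        d = gam / q ** 2
        species.append(HydroSpecies(
            radius=stokes_einstein(d, trace.config), diffusion=d, fraction=float(frac)))
    residual = float(np.linalg.norm(model(p) - trace.g2m1))
    return SizeDistribution(species=species, residual=residual)


@dataclass
class MassCalibration:
    """Power-law radius-to-mass calibration M = a * R_H^b (kDa, nm)."""

    a: float                           # kDa / nm^b
    b: float
    pairs: list[tuple[float, float]]   # training (R_H nm, M kDa)

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise InvalidParameterError("calibration requires a > 0 and b > 0")


def calibrate_mass(pairs: Sequence[tuple[float, float]]) -> MassCalibration:
    """Fit log M = log a + b log R_H by least squares on (R_H nm, M kDa) pairs."""
    pairs = [(float(r), float(m)) for r, m in pairs]
    radii = np.array([r for r, _ in pairs])
    masses = np.array([m for _, m in pairs])
    if len(pairs) < 2 or np.ptp(radii) == 0:
        raise InvalidParameterError("need >= 2 pairs with distinct radii")
    if np.any(radii <= 0) or np.any(masses <= 0):
        raise InvalidParameterError("radii and masses must be positive")
    b, log_a = np.polyfit(np.log(radii), np.log(masses), 1)
    return MassCalibration(a=float(np.exp(log_a)), b=float(b), pairs=pairs)


def mass_from_radius(radius: float, cal: MassCalibration) -> float:
    """Predicted molecular mass in kDa for a hydrodynamic radius in nm."""
    if radius <= 0:
        raise InvalidParameterError("radius must be positive")
    return cal.a * radius ** cal.b


def annotate_masses(dist: SizeDistribution, cal: MassCalibration) -> SizeDistribution:
    """Return a copy of the distribution with calibrated masses attached."""
    species = [replace(s, mass=mass_from_radius(s.radius, cal)) for s in dist.species]
    return SizeDistribution(species=species, residual=dist.residual)


@dataclass(frozen=True)
class CriticalConcentration:
    """Critical-concentration estimate with its bound type.

    ``bound`` is "interior" when an untested-below/undetected concentration
    exists beneath the estimate, otherwise "lower_bound" (every tested
    concentration was detected, so the true value may lie lower).
    """

    value: float                       # M
    bound: str                         # "interior" | "lower_bound"


def estimate_critical_concentration(
    series: Sequence[tuple[float, bool]],
) -> CriticalConcentration:
    """Lowest concentration at which the free species is detected.

    ``series`` pairs each tested concentration (M) with a detection flag.
    """
    if len(series) == 0:
        raise InvalidParameterError("detection series is empty")
    entries = sorted((float(c), bool(d)) for c, d in series)
    detected = [c for c, d in entries if d]
    if not detected:
        raise NotDeterminedError("no concentration in the series was detected")
    c_min = min(detected)
    interior = any(c < c_min for c, _ in entries)
    if not interior:
        warnings.warn(
            "all tested concentrations were detected; the critical "
            "concentration is only bounded from above by the lowest one",
            stacklevel=2,
        )
    return CriticalConcentration(value=c_min, bound="interior" if interior else "lower_bound")
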