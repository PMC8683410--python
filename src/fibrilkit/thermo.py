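"""Fibrillization thermodynamics under the 1D-crystallization model, ITC
thermogram integration, and a stochastic check of the reaction scheme.

The 1D-crystallization (reversible polymerisation) picture treats fibril
elongation as single-unit addition at a constant number of fibril ends,

    C + F_(i-1) <=> F_i,      K_F = k_ass / k_diss.

Late in the reaction the concentration of docking sites is independent of
fibril length, so the elongation equilibrium constant collapses to the
reciprocal of the free-unit ("critical") concentration, K_F = 1/[C], and the
apparent free energy of fibrillization is

    dG_app = -R T ln K_F = R T ln [C]      (standard state 1 M).

The molar enthalpy of fibrillization comes from integrating ITC heat-flow
thermograms and normalising by the amount of protein converted; the entropy
follows from the Gibbs-Helmholtz relation dS = (dH - dG)/T, and the heat
capacity change dCp from the slope of dH versus temperature, fitted
independently on the two sides of a breakpoint where the temperature
dependence changes regime.

A continuous-time stochastic (Gillespie) simulation of the association /
dissociation scheme at a fixed number of fibril ends provides an independent
check that the free-unit concentration indeed relaxes to k_diss/k_ass = 1/K_F.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .errors import InvalidParameterError, NotDeterminedError

GAS_CONSTANT_J_PER_MOL_K = 8.314
JOULE_PER_CALORIE = 4.184
AVOGADRO = 6.02214076e23


# --------------------------------------------------------------------------
# ITC thermograms
# --------------------------------------------------------------------------

@dataclass
class Thermogram:
    """A time-resolved ITC heat-flow trace with injection metadata.

    ``injections`` lists (time s, n_mol of protein) per injection; the
    integration window of each injection runs to the next injection time
    (or the end of the trace).
    """

    times: np.ndarray                  # s, strictly increasing
    heat_flow: np.ndarray              # ucal/s
    injections: list[tuple[float, float]]
    baseline_model: str = "constant"   # constant | linear | als

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.heat_flow = np.asarray(self.heat_flow, dtype=float)
        if self.times.shape != self.heat_flow.shape:
            raise InvalidParameterError("times and heat_flow must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if any(n <= 0 for _, n in self.injections):
            raise InvalidParameterError("injection n_mol must be positive")
        if self.baseline_model not in ("constant", "linear", "als"):
            raise InvalidParameterError(f"unknown baseline model {self.baseline_model!r}")


def _als_baseline(y: np.ndarray, lam: float = 1e9, p: float = 0.01,
                  n_iter: int = 10) -> np.ndarray:
    # Asymmetric least squares (Whittaker smoother with asymmetric weights):
    # follows the slowly varying baseline, resists excursion into peaks.
    # Peak polarity is inferred from the skew of the trace (exothermic ITC
    # peaks are negative-going).
    n = y.size
    peaks_negative = float(np.mean(y)) < float(np.median(y))
    d = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        big_w = sparse.spdiags(w, 0, n, n)
        z = spsolve((big_w + lam * d @ d.T).tocsc(), w * y)
        if peaks_negative:
            w = np.where(y < z, p, 1.0 - p)
        else:
            w = np.where(y > z, p, 1.0 - p)
    return z


def estimate_baseline(tg: Thermogram) -> np.ndarray:
    """Baseline of the heat-flow trace in ucal/s, per the thermogram's model.

    constant -- mean of the samples before the first injection;
    linear   -- least-squares line through the pre-first-injection samples
                and the final 2% of the trace;
    als      -- asymmetric-least-squares smoother over the whole trace.
    """
    t, y = tg.times, tg.heat_flow
    if tg.baseline_model == "als":
        return _als_baseline(y)
    if not tg.injections:
        return np.full_like(y, float(np.median(y)))
    t_first = min(ti for ti, _ in tg.injections)
    pre = t < t_first
    if tg.baseline_model == "constant":
        if not pre.any():
            raise NotDeterminedError(
                "constant baseline needs samples before the first injection")
        return np.full_like(y, float(np.mean(y[pre])))
    # linear
    tail = t >= t[0] + 0.98 * (t[-1] - t[0])
    anchor = pre | tail
    if anchor.sum() < 2:
        raise NotDeterminedError("linear baseline needs >= 2 anchor samples")
    coef = np.polyfit(t[anchor], y[anchor], 1)
    return np.polyval(coef, t)


def integrate_thermogram(tg: Thermogram) -> list[float]:
    """Integrate baseline-corrected heat per injection window, in joules.

    Trapezoidal integration of (heat_flow - baseline) in ucal/s over each
    injection window, converted to J at 4.184 J/cal.
    """
    if tg.times.size < 3:
        raise InvalidParameterError("thermogram needs >= 3 samples")
    if not tg.injections:
        raise InvalidParameterError("thermogram has no injections")
    baseline = estimate_baseline(tg)
    corrected = tg.heat_flow - baseline
    inj_times = [ti for ti, _ in tg.injections]
    edges = inj_times + [float(tg.times[-1]) + 1.0]
    heats = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (tg.times >= lo) & (tg.times < hi)
        if mask.sum() < 2:
            warnings.warn(f"empty injection window [{lo}, {hi}); heat set to 0",
                          stacklevel=2)
            heats.append(0.0)
            continue
        q_ucal = np.trapezoid(corrected[mask], tg.times[mask])
        heats.append(float(q_ucal) * 1e-6 * JOULE_PER_CALORIE)
    return heats


def enthalpy_from_heats(q_joule: float, n_mol: float) -> float:
    """Molar enthalpy in kJ/mol from an integrated heat (J) and protein amount (mol)."""
    if n_mol <= 0:
        raise InvalidParameterError("n_mol must be positive")
    return q_joule / n_mol / 1000.0


# --------------------------------------------------------------------------
# Free-energy / entropy / heat-capacity chain
# --------------------------------------------------------------------------

def equilibrium_constant(critical_conc: float) -> float:
    """Fibril-elongation equilibrium constant K_F = 1/[C] (standard state 1 M)."""
    if critical_conc <= 0:
        raise InvalidParameterError("critical concentration must be positive")
    return 1.0 / critical_conc


def free_energy(critical_conc: float, temperature: float) -> float:
    """Apparent free energy of fibrillization, dG_app = R T ln [C], in kJ/mol."""
    if critical_conc <= 0 or temperature <= 0:
        raise InvalidParameterError("critical_conc and temperature must be positive")
    return GAS_CONSTANT_J_PER_MOL_K * temperature * math.log(critical_conc) / 1000.0


def entropy_gibbs_helmholtz(dh: float, dg: float, temperature: float) -> float:
    """Entropy change dS = (dH - dG)/T in kJ/mol/K (dH, dG in kJ/mol)."""
    if temperature <= 0:
        raise InvalidParameterError("temperature must be positive")
    return (dh - dg) / temperature


@dataclass
class HeatCapacityFit:
    """Two-phase linear fit of dH(T): slopes dCp on each side of a breakpoint."""

    dcp_low: float                     # kJ/mol/K, T <= breakpoint branch
    dcp_high: float                    # kJ/mol/K, T >= breakpoint branch
    breakpoint: float                  # K
    residual: float                    # total SSR of both branches


def _branch_fit(t: np.ndarray, h: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t, h, 1)
    ssr = float(np.sum((np.polyval([slope, intercept], t) - h) ** 2))
    return float(slope), ssr


def heat_capacity_fit(
    table: Sequence[tuple[float, float]],
    breakpoint: float | str = "auto",
) -> HeatCapacityFit:
    """Heat-capacity change(s) from a (T, dH) table by two-phase linear fit.

    Independent least-squares lines are fitted to the points at T <= and
    T >= the breakpoint; the two slopes are (dH/dT)_p = dCp of the low- and
    high-temperature regimes.  ``breakpoint="auto"`` scans the interior
    temperatures and keeps the split with the smallest total residual.
    A branch with fewer than 2 points yields a NaN slope with a warning.
    """
    t = np.array([row[0] for row in table], dtype=float)
    h = np.array([row[1] for row in table], dtype=float)
    if t.size < 2 or np.ptp(t) == 0:
        raise InvalidParameterError("need >= 2 distinct temperatures")
    order = np.argsort(t)
    t, h = t[order], h[order]

    def fit_at(bp: float) -> HeatCapacityFit:
        lo, hi = t <= bp, t >= bp
        slopes, ssr_total = [], 0.0
        for mask in (lo, hi):
            if mask.sum() >= 2 and np.ptp(t[mask]) > 0:
                slope, ssr = _branch_fit(t[mask], h[mask])
                slopes.append(slope)
                ssr_total += ssr
            else:
                slopes.append(float("nan"))
        return HeatCapacityFit(slopes[0], slopes[1], float(bp), ssr_total)

    if breakpoint == "auto":
        # candidate breakpoints at midpoints between consecutive samples, so
        # each branch is fitted on points strictly inside its own regime
        mids = (t[:-1] + t[1:]) / 2.0
        candidates = [bp for bp in mids
                      if (t <= bp).sum() >= 2 and (t >= bp).sum() >= 2]
        if not candidates:
            raise NotDeterminedError("no interior breakpoint with >= 2 points per branch")
        best = min((fit_at(bp) for bp in candidates), key=lambda f: f.residual)
    else:
        best = fit_at(float(breakpoint))
    if math.isnan(best.dcp_low) or math.isnan(best.dcp_high):
        warnings.warn("single-branch heat-capacity fit (one side of the "
                      "breakpoint has < 2 points)", stacklevel=2)
    return best


# --------------------------------------------------------------------------
# Consolidated thermodynamic state
# --------------------------------------------------------------------------

@dataclass
class ThermoParams:
    """Thermodynamic state of fibrillization with internal cross-checks.

    When enough fields are set, the constructor enforces
    dG_app = dH - T dS and dG_app = (R T / 1000) ln([C]/1 M) to 1e-6 kJ/mol.
    """

    T: float                                   # K
    critical_conc: float | None = None         # M
    K_F: float | None = None                   # 1/M
    dG_app: float | None = None                # kJ/mol
    dH: float | None = None                    # kJ/mol
    dS: float | None = None                    # kJ/mol/K
    dCp_low: float | None = None               # kJ/mol/K
    dCp_high: float | None = None              # kJ/mol/K
    R_const: float = GAS_CONSTANT_J_PER_MOL_K  # J/mol/K

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise InvalidParameterError("temperature must be positive")
        if None not in (self.dG_app, self.dH, self.dS):
            if abs(self.dG_app - (self.dH - self.T * self.dS)) > 1e-6:
                raise InvalidParameterError("dG != dH - T dS beyond 1e-6 kJ/mol")
        if None not in (self.dG_app, self.critical_conc):
            implied = self.R_const * self.T * math.log(self.critical_conc) / 1000.0
            if abs(self.dG_app - implied) > 1e-6:
                raise InvalidParameterError("dG != R T ln[C] beyond 1e-6 kJ/mol")
        if None not in (self.K_F, self.critical_conc):
            if abs(self.K_F * self.critical_conc - 1.0) > 1e-9:
                raise InvalidParameterError("K_F != 1/[C]")

    @classmethod
    def from_measurements(
        cls,
        critical_conc: float,
        dH: float,
        temperature: float = 293.15,
        dCp: tuple[float, float] | None = None,
    ) -> "ThermoParams":
        """Derive the full chain [C] -> K_F -> dG_app -> dS from measurements."""
        dg = free_energy(critical_conc, temperature)
        ds = entropy_gibbs_helmholtz(dH, dg, temperature)
        low, high = dCp if dCp is not None else (None, None)
        return cls(T=temperature, critical_conc=critical_conc,
                   K_F=equilibrium_constant(critical_conc),
                   dG_app=dg, dH=dH, dS=ds, dCp_low=low, dCp_high=high)


# --------------------------------------------------------------------------
# Stochastic 1D crystallization
# --------------------------------------------------------------------------

@dataclass
class CrystallizationModel:
    """Reversible single-unit polymerisation at a fixed number of fibril ends.

    Concentrations are represented as copy numbers inside an explicit
    simulation volume (``volume_scale``, litres); with ``k_diss > 0`` the
    free-unit concentration relaxes to k_diss/k_ass = 1/K_F.
    """

    k_ass: float                       # 1/(M s)
    k_diss: float                      # 1/s
    n_fibrils: int                     # fixed number of growing ends
    c0: float                          # initial free-unit concentration, M
    volume_scale: float = 1e-15        # L

    def __post_init__(self) -> None:
        if self.k_ass <= 0 or self.k_diss < 0:
            raise InvalidParameterError("k_ass must be > 0 and k_diss >= 0")
        if self.n_fibrils < 1:
            raise InvalidParameterError("need at least one fibril end")
        if self.c0 < 0 or self.volume_scale <= 0:
            raise InvalidParameterError("c0 >= 0 and volume_scale > 0 required")

    @property
    def K_F(self) -> float:
        if self.k_diss == 0:
            raise InvalidParameterError("K_F undefined for k_diss = 0")
        return self.k_ass / self.k_diss


@dataclass
class CrystallizationTrajectory:
    """Output of the stochastic simulation."""

    times: np.ndarray                  # event times, s (subsampled)
    concentrations: np.ndarray         # free-unit concentration, M
    c_eq: float                        # time-averaged late-window concentration, M
    c_eq_se: float                     # batch-means standard error of c_eq
    n_events: int
    fibril_mass: np.ndarray            # total units incorporated, per sample


def simulate_1d_crystallization(
    model: CrystallizationModel,
    t_end: float,
    seed: int | None = None,
    late_window: float = 0.5,
    n_batches: int = 20,
    sample_stride: int = 100,
) -> CrystallizationTrajectory:
    """Gillespie simulation of C + F <=> F' at fixed fibril-end count.

    Two reaction channels with propensities
    a_ass = k_ass * n_ends * n_C / (N_A V)  and  a_diss = k_diss * n_ends.
    The reported equilibrium concentration is the time-weighted mean of the
    free-unit concentration over the trailing ``late_window`` fraction of
    the simulated interval; its standard error comes from ``n_batches``
    equal-duration batch means.
    """
    if model.n_fibrils < 1:
        raise InvalidParameterError("zero fibrils")
    if t_end <= 0:
        raise InvalidParameterError("t_end must be positive")
    rng = np.random.default_rng(seed)
    na_v = AVOGADRO * model.volume_scale
    n_c = int(round(model.c0 * na_v))
    n_ends = model.n_fibrils
    t = 0.0
    t_window = (1.0 - late_window) * t_end
    batch_edges = np.linspace(t_window, t_end, n_batches + 1)
    batch_int = np.zeros(n_batches)     # integral of n_C dt per batch

    times, concs, mass = [0.0], [n_c / na_v], [0]
    incorporated = 0
    n_events = 0
    while t < t_end:
        a_ass = model.k_ass * n_ends * n_c / na_v
        a_diss = model.k_diss * n_ends
        a_tot = a_ass + a_diss
        if a_tot <= 0:
            dt = t_end - t
        else:
            dt = rng.exponential(1.0 / a_tot)
        t_next = min(t + dt, t_end)
        # accumulate the piecewise-constant n_C into the late-window batches
        if t_next > t_window:
            lo, hi = max(t, t_window), t_next
            i0 = np.searchsorted(batch_edges, lo, side="right") - 1
            i1 = np.searchsorted(batch_edges, hi, side="left") - 1
            for i in range(max(i0, 0), min(i1, n_batches - 1) + 1):
                seg = min(hi, batch_edges[i + 1]) - max(lo, batch_edges[i])
                if seg > 0:
                    batch_int[i] += n_c * seg
        t = t_next
        if t >= t_end or a_tot <= 0:
            break
        if rng.random() < a_ass / a_tot:
            n_c -= 1
            incorporated += 1
        else:
            n_c += 1
            incorporated -= 1
        n_events += 1
        if n_events % sample_stride == 0:
            times.append(t)
            concs.append(n_c / na_v)
            mass.append(incorporated)
    # always record the final state
    times.append(t_end)
    concs.append(n_c / na_v)
    mass.append(incorporated)

    batch_dur = np.diff(batch_edges)
    batch_means = batch_int / batch_dur / na_v
    c_eq = float(np.sum(batch_int) / np.sum(batch_dur) / na_v)
    c_eq_se = float(np.std(batch_means, ddof=1) / math.sqrt(n_batches))
    return CrystallizationTrajectory(
        times=np.array(times), concentrations=np.array(concs),
        c_eq=c_eq, c_eq_se=c_eq_se, n_events=n_events,
        fibril_mass=np.array(mass))
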