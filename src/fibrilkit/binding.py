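"""Equilibrium SPR analysis: double referencing, plateau extraction, Hill
fitting, and a cooperative-versus-noncooperative model comparison.

The equilibrium response of an analyte titration follows the Hill equation

    R(c) = R_max * c^n / (K_D^n + c^n)

where n is the Hill (cooperativity) coefficient: n = 1 recovers the
hyperbolic Langmuir isotherm, n > 1 indicates positive cooperativity.
Whether the extra cooperativity parameter is warranted is decided by an
extra-sum-of-squares F-test between the n-fixed-to-1 and free-n fits.

Fits are parameterised in log10 K_D for conditioning; standard errors for
K_D are propagated back with the delta method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
from scipy import stats

from .errors import ConvergenceError, InvalidParameterError

# Table of reference (K_D [M], Hill n) binding parameters per ligand and
# C-region preparation: monomeric MBP fusion (monomer_M), oligomeric/
# fibrillar His6 fusion (oligomer_H), oligomeric/fibrillar MBP fusion
# (oligomer_M).  Used by the synthetic generators and recovery tests.
REFERENCE_BINDING_PARAMS: dict[tuple[str, str], tuple[float, float]] = {
    ("VHH_B5", "monomer_M"): (46e-9, 1.4),
    ("VHH_B5", "oligomer_H"): (66e-9, 1.1),
    ("VHH_B5", "oligomer_M"): (70e-9, 1.1),
    ("NDEL1", "monomer_M"): (20e-6, 1.4),
    ("NDEL1", "oligomer_H"): (13e-6, 2.1),
    ("NDEL1", "oligomer_M"): (14e-6, 2.5),
    ("LIS1", "monomer_M"): (71e-9, 1.2),
    ("LIS1", "oligomer_H"): (31e-9, 2.4),
    ("LIS1", "oligomer_M"): (31e-9, 2.8),
}


@dataclass
class SensorgramSet:
    """Raw SPR traces of one cycle: active and reference flow cells for the
    analyte injection and for the matching buffer blank."""

    times: np.ndarray                  # s
    active: np.ndarray                 # RU
    reference: np.ndarray              # RU
    buffer_active: np.ndarray          # RU
    buffer_reference: np.ndarray       # RU
    analyte_conc: float                # M

    def __post_init__(self) -> None:
        arrays = [self.active, self.reference, self.buffer_active, self.buffer_reference]
        for name, arr in zip(
                ("active", "reference", "buffer_active", "buffer_reference"), arrays):
            arr = np.asarray(arr, dtype=float)
            setattr(self, name, arr)
            if arr.shape != np.asarray(self.times).shape:
                raise InvalidParameterError(f"{name} length mismatch with times")
        self.times = np.asarray(self.times, dtype=float)
        if self.analyte_conc <= 0:
            raise InvalidParameterError("analyte concentration must be positive")


def double_reference(sgram: SensorgramSet) -> np.ndarray:
    """Double-referenced trace: (active - reference) - (buffer_active - buffer_reference)."""
    return (sgram.active - sgram.reference) - (sgram.buffer_active - sgram.buffer_reference)


@dataclass(frozen=True)
class EquilibriumResponse:
    """Plateau response of one cycle with an equilibration flag."""

    response: float                    # RU
    at_equilibrium: bool
    window_slope: float                # RU/s over the evaluation window


def extract_equilibrium(
    times: np.ndarray,
    trace: np.ndarray,
    window: float = 0.1,
    slope_tol: float = 0.02,
) -> EquilibriumResponse:
    """Median response over the trailing ``window`` fraction of the trace.

    The window is additionally checked for flatness: if the linear drift
    across it exceeds ``slope_tol`` of the median magnitude the response is
    returned flagged as not-at-equilibrium.
    """
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    n = times.size
    n_win = max(int(math.ceil(window * n)), 3)
    if n_win > n:
        raise InvalidParameterError("window contains fewer than 3 samples")
    t_w, y_w = times[-n_win:], trace[-n_win:]
    med = float(np.median(y_w))
    slope = float(np.polyfit(t_w, y_w, 1)[0]) if np.ptp(t_w) > 0 else 0.0
    drift = abs(slope) * (t_w[-1] - t_w[0])
    flat = drift <= slope_tol * max(abs(med), 1e-12)
    return EquilibriumResponse(response=med, at_equilibrium=flat, window_slope=slope)


@dataclass
class BindingIsotherm:
    """Equilibrium responses versus analyte concentration for one pair."""

    concentrations: np.ndarray         # M, strictly increasing, > 0
    responses: np.ndarray              # RU
    ligand_label: str = ""
    analyte_label: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise InvalidParameterError("concentrations and responses must match")
        if np.any(self.concentrations <= 0) or np.any(np.diff(self.concentrations) <= 0):
            raise InvalidParameterError("concentrations must be positive, strictly increasing")


@dataclass
class HillFit:
    """Fitted Hill parameters with uncertainty and cooperativity verdict."""

    K_D: float                         # M
    n: float
    R_max: float                       # RU
    K_D_se: float | None = None
    n_se: float | None = None
    R_max_se: float | None = None
    rss: float = 0.0
    verdict: str = "indeterminate"     # noncooperative | cooperative | indeterminate
    comparison_stat: float | None = None  # extra-sum-of-squares F
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.K_D <= 0 or self.n <= 0 or self.R_max <= 0:
            raise InvalidParameterError("K_D, n and R_max must all be positive")


def hill_response(conc: np.ndarray, k_d: float, n: float, r_max: float) -> np.ndarray:
    """Hill equation R = R_max c^n / (K_D^n + c^n), evaluated in log space."""
    conc = np.asarray(conc, dtype=float)
    x = n * (np.log(conc) - math.log(k_d))
    return r_max / (1.0 + np.exp(-x))


def fit_hill(iso: BindingIsotherm, fix_n: float | None = None) -> HillFit:
    """Least-squares Hill fit of an equilibrium isotherm.

    Unweighted; parameterised in (log10 K_D, n, R_max).  ``fix_n`` pins the
    Hill coefficient (e.g. 1 for a pure Langmuir fit).  Standard errors come
    from the fit covariance; K_D's is delta-method propagated from log10 K_D.
    """
    c, r = iso.concentrations, iso.responses
    if c.size < 4:
        raise InvalidParameterError("need >= 4 concentration points")
    span = c[-1] / c[0]
    if span < 10.0:
        warnings.warn("concentration span below one decade; Hill fit may be "
                      "ill-conditioned", stacklevel=2)

    r_max0 = float(np.max(r)) * 1.05 or 1.0
    # initial K_D: concentration closest to half-maximal response
    half_idx = int(np.argmin(np.abs(r - 0.5 * np.max(r))))
    kd0 = float(c[half_idx])

    params = lmfit.Parameters()
    params.add("log10_kd", value=math.log10(kd0),
               min=math.log10(c[0]) - 4, max=math.log10(c[-1]) + 4)
    if fix_n is None:
        params.add("n", value=1.0, min=0.05, max=10.0)
    else:
        params.add("n", value=float(fix_n), vary=False)
    params.add("r_max", value=r_max0, min=1e-12)

    def resid(p: lmfit.Parameters) -> np.ndarray:
        return hill_response(c, 10.0 ** p["log10_kd"].value,
                             p["n"].value, p["r_max"].value) - r

    result = lmfit.minimize(resid, params)
    if not result.success:
        raise ConvergenceError(f"Hill fit did not converge: {result.message}")
    p = result.params
    k_d = 10.0 ** p["log10_kd"].value
    kd_se = (k_d * math.log(10.0) * p["log10_kd"].stderr
             if p["log10_kd"].stderr is not None else None)
    return HillFit(
        K_D=k_d, n=p["n"].value, R_max=p["r_max"].value,
        K_D_se=kd_se, n_se=p["n"].stderr, R_max_se=p["r_max"].stderr,
        rss=float(np.sum(resid(p) ** 2)))


def compare_cooperativity(iso: BindingIsotherm, alpha: float = 0.05) -> HillFit:
    """Cooperativity verdict by nested Langmuir-vs-Hill model comparison.

    Fits the isotherm with n fixed to 1 and with n free, and compares them
    with the extra-sum-of-squares F-test.  Verdict "cooperative" requires
    the free-n model preferred at ``alpha`` AND fitted n > 1; data whose
    free-n fit leaves essentially zero residual (noise-free input) cannot
    support the test and return "indeterminate".
    """
    fit1 = fit_hill(iso, fix_n=1.0)
    fit2 = fit_hill(iso)
    n_pts = iso.concentrations.size
    scale = float(np.sum(iso.responses ** 2)) or 1.0
    if fit2.rss < 1e-12 * scale or n_pts <= 3:
        fit2.verdict = "indeterminate"
        return fit2
    f_stat = (fit1.rss - fit2.rss) / 1.0 / (fit2.rss / (n_pts - 3))
    p_val = float(stats.f.sf(max(f_stat, 0.0), 1, n_pts - 3))
    fit2.comparison_stat = f_stat
    fit2.p_value = p_val
    if p_val < alpha and fit2.n > 1.0:
        fit2.verdict = "cooperative"
    else:
        fit2.verdict = "noncooperative"
    return fit2
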