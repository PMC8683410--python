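"""Water-edited spin-diffusion build-up analysis and chemical-shift-based
secondary-structure annotation for solid-state NMR of fibrils.

In a water-edited build-up experiment, magnetisation diffuses from water
into the protein during a mixing time t_m; the normalised protein signal
rises roughly linearly before saturating.  The reciprocal of the initial
slope, the build-up time t_m^s, is the time a linear extrapolation needs to
reach 100% transfer and reports the water accessibility of the object:

    V/S = sqrt(D_eff * t_m^s / pi)

with V the hydrated volume, S the water-accessible surface and D_eff an
effective magnetisation diffusion coefficient (default 0.2 nm^2/ms).  For a
long cylinder (fibril), V/S = d/4, so the core diameter is d = 4 V/S.

Secondary structure is annotated from backbone 13C chemical shifts by
nearest-reference classification in (CA, CB) ppm space against a shipped
per-residue table of average helix/strand/coil shifts.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import InvalidParameterError

DEFAULT_D_EFF_NM2_PER_MS = 0.2

# Plausible ppm windows per atom type, used to validate shift records.
_SHIFT_WINDOWS = {
    "CA": (38.0, 72.0), "CB": (10.0, 75.0), "C": (165.0, 185.0),
    "N": (100.0, 140.0), "H": (0.0, 12.0), "HN": (5.0, 12.0),
}


# --------------------------------------------------------------------------
# Build-up curves and hydration
# --------------------------------------------------------------------------

@dataclass
class BuildUpCurve:
    """Spin-diffusion build-up: protein signal versus 1H-1H mixing time."""

    mixing_times: np.ndarray           # ms, strictly increasing
    intensities: np.ndarray            # a.u., or normalized in [0, ~1]
    normalized: bool = False
    reference_time: float | None = None  # ms used for normalization

    def __post_init__(self) -> None:
        self.mixing_times = np.asarray(self.mixing_times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mixing_times.shape != self.intensities.shape:
            raise InvalidParameterError("mixing_times and intensities must match")
        if np.any(np.diff(self.mixing_times) <= 0):
            raise InvalidParameterError("mixing_times must be strictly increasing")
        if self.normalized and np.max(self.intensities) > 1.0 + 1e-9:
            raise InvalidParameterError("normalized curve exceeds 1")


def normalize_buildup(curve: BuildUpCurve, reference_time: float = 100.0) -> BuildUpCurve:
    """Divide a build-up curve by its intensity at the reference mixing time.

    The nearest grid point within 10% (relative) of ``reference_time`` is
    used.  Idempotent: a curve already normalized to the same reference has
    value 1 there and passes through unchanged.
    """
    idx = int(np.argmin(np.abs(curve.mixing_times - reference_time)))
    t_ref = curve.mixing_times[idx]
    if abs(t_ref - reference_time) > 0.1 * reference_time:
        raise InvalidParameterError(
            f"no mixing time within 10% of reference {reference_time} ms")
    ref = curve.intensities[idx]
    if ref == 0:
        raise InvalidParameterError("reference intensity is zero")
    return BuildUpCurve(
        mixing_times=curve.mixing_times.copy(),
        intensities=curve.intensities / ref,
        normalized=True, reference_time=float(t_ref))


@dataclass
class InitialSlopeFit:
    """Zero-intercept linear fit to the initial build-up."""

    t_m_s: float                       # ms; 1/slope, time to reach S = 1
    slope: float                       # 1/ms
    slope_se: float
    fit_window: tuple[float, float]    # ms span of points used
    n_points: int


def fit_initial_slope(curve: BuildUpCurve, window: float = 0.5) -> InitialSlopeFit:
    """Build-up time t_m^s from a zero-intercept line on the initial rise.

    Points with normalized intensity <= ``window`` enter a least-squares fit
    of S = slope * t through the origin; t_m^s = 1/slope is the mixing time
    at which the fitted line reaches full transfer (S = 1).
    """
    t = curve.mixing_times
    s = curve.intensities
    mask = s <= window
    if mask.sum() < 2:
        raise InvalidParameterError(
            f"need >= 2 points with intensity <= {window} for the initial slope")
    t_fit, s_fit = t[mask], s[mask]
    slope = float(np.sum(t_fit * s_fit) / np.sum(t_fit ** 2))
    if slope <= 0:
        raise InvalidParameterError("nonpositive initial slope")
    resid = s_fit - slope * t_fit
    dof = max(mask.sum() - 1, 1)
    slope_var = float(np.sum(resid ** 2) / dof / np.sum(t_fit ** 2))
    return InitialSlopeFit(
        t_m_s=1.0 / slope, slope=slope, slope_se=math.sqrt(slope_var),
        fit_window=(float(t_fit[0]), float(t_fit[-1])), n_points=int(mask.sum()))


def volume_to_surface(t_m_s: float, d_eff: float = DEFAULT_D_EFF_NM2_PER_MS) -> float:
    """V/S ratio in nm: sqrt(D_eff * t_m^s / pi) with t in ms, D_eff in nm^2/ms."""
    if t_m_s <= 0 or d_eff <= 0:
        raise InvalidParameterError("t_m_s and D_eff must be positive")
    return math.sqrt(d_eff * t_m_s / math.pi)


def fibril_diameter(v_over_s: float) -> float:
    """Cylinder core diameter d = 4 * (V/S), in nm."""
    if v_over_s <= 0:
        raise InvalidParameterError("V/S must be positive")
    return 4.0 * v_over_s


@dataclass
class HydrationResult:
    """Hydration analysis of one build-up curve.

    Internal identities (enforced at construction): v_over_s equals
    sqrt(D_eff * t_m_s / pi) and diameter equals 4 * v_over_s, both to 1e-9.
    The diameter rests on the long-cylinder assumption recorded in ``shape``.
    """

    t_m_s: float                       # ms
    d_eff: float                       # nm^2/ms
    v_over_s: float                    # nm
    diameter: float                    # nm
    fit_window: tuple[float, float]
    slope_se: float
    shape: str = "cylinder"

    def __post_init__(self) -> None:
        if abs(self.v_over_s - math.sqrt(self.d_eff * self.t_m_s / math.pi)) > 1e-9:
            raise InvalidParameterError("V/S inconsistent with sqrt(D_eff t/pi)")
        if abs(self.diameter - 4.0 * self.v_over_s) > 1e-9:
            raise InvalidParameterError("diameter inconsistent with 4 V/S")


def analyze_buildup(
    curve: BuildUpCurve,
    d_eff: float = DEFAULT_D_EFF_NM2_PER_MS,
    window: float = 0.5,
) -> HydrationResult:
    """Full chain: initial slope -> t_m^s -> V/S -> fibril core diameter."""
    fit = fit_initial_slope(curve, window=window)
    vs = volume_to_surface(fit.t_m_s, d_eff)
    return HydrationResult(
        t_m_s=fit.t_m_s, d_eff=d_eff, v_over_s=vs,
        diameter=fibril_diameter(vs), fit_window=fit.fit_window,
        slope_se=fit.slope_se)


# --------------------------------------------------------------------------
# 2D spectrum region-of-interest integration
# --------------------------------------------------------------------------

def integrate_roi(
    intensity: np.ndarray,
    x_ppm: np.ndarray,
    y_ppm: np.ndarray,
    box: tuple[float, float, float, float],
    normalizer: float | None = None,
) -> float:
    """Integrate a rectangular region of a 2D spectrum.

    ``intensity`` has shape (len(y_ppm), len(x_ppm)); ``box`` is
    (x_lo, x_hi, y_lo, y_hi) in ppm.  Cells whose centre falls inside the
    box are summed and scaled by the cell area; ``normalizer`` (e.g. number
    of scans) divides the result when given.
    """
    x_ppm = np.asarray(x_ppm, dtype=float)
    y_ppm = np.asarray(y_ppm, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != (y_ppm.size, x_ppm.size):
        raise InvalidParameterError("intensity shape must be (len(y), len(x))")
    x_lo, x_hi, y_lo, y_hi = box
    mx = (x_ppm >= min(x_lo, x_hi)) & (x_ppm <= max(x_lo, x_hi))
    my = (y_ppm >= min(y_lo, y_hi)) & (y_ppm <= max(y_lo, y_hi))
    if not mx.any() or not my.any():
        raise InvalidParameterError("ROI box does not overlap the spectrum grid")
    cell = abs(float(np.median(np.diff(x_ppm)))) * abs(float(np.median(np.diff(y_ppm))))
    total = float(intensity[np.ix_(my, mx)].sum()) * cell
    if normalizer is not None:
        if normalizer == 0:
            raise InvalidParameterError("normalizer must be nonzero")
        total /= normalizer
    return total


# --------------------------------------------------------------------------
# Chemical-shift secondary-structure classification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ShiftRecord:
    """One backbone chemical shift: residue type, atom, ppm value."""

    residue_type: str                  # 1-letter amino acid code
    atom: str                          # CA | CB | C | N | H | HN
    shift: float                       # ppm

    def __post_init__(self) -> None:
        if self.atom not in _SHIFT_WINDOWS:
            raise InvalidParameterError(f"unknown atom {self.atom!r}")
        lo, hi = _SHIFT_WINDOWS[self.atom]
        if not (lo <= self.shift <= hi):
            raise InvalidParameterError(
                f"{self.atom} shift {self.shift} ppm outside plausible [{lo}, {hi}]")


@dataclass(frozen=True)
class SSEAssignment:
    """Secondary-structure call for one residue with distance diagnostics."""

    residue_type: str
    sse: str                           # helix | strand | coil
    distance: float                    # ppm distance to the winning reference
    margin: float                      # gap to the runner-up
    tie: bool = False


def _load_reference_table() -> dict[tuple[str, str], tuple[float, float | None]]:
    """(residue, sse) -> (CA, CB) average reference shifts in ppm.

    The shipped table combines published per-residue random-coil CA/CB
    averages with canonical helix/strand secondary-shift offsets
    (helix: CA +3.1, CB -0.5; strand: CA -1.5, CB +2.2 ppm); glycine has
    no CB and is classified on CA alone.
    """
    table: dict[tuple[str, str], tuple[float, float | None]] = {}
    ref = resources.files("fibrilkit.data").joinpath("sse_reference_shifts.csv")
    with ref.open() as fh:
        for row in csv.DictReader(fh):
            cb = float(row["cb_ppm"]) if row["cb_ppm"] else None
            table[(row["residue"], row["sse"])] = (float(row["ca_ppm"]), cb)
    return table


_REFERENCE_TABLE = _load_reference_table()
SSE_CLASSES = ("helix", "strand", "coil")


def classify_sse(ca: ShiftRecord, cb: ShiftRecord | None = None) -> SSEAssignment:
    """Assign helix/strand/coil by nearest reference in (CA, CB) shift space.

    Euclidean distance in ppm to the residue's three reference rows; CB is
    optional (and absent for glycine).  Exact ties prefer coil and are
    flagged.
    """
    res = ca.residue_type.upper()
    if ca.atom != "CA":
        raise InvalidParameterError("first record must be a CA shift")
    if cb is not None and cb.atom != "CB":
        raise InvalidParameterError("second record must be a CB shift")
    if (res, "coil") not in _REFERENCE_TABLE:
        raise InvalidParameterError(f"unknown residue type {res!r}")
    dists = {}
    for sse in SSE_CLASSES:
        ref_ca, ref_cb = _REFERENCE_TABLE[(res, sse)]
        d2 = (ca.shift - ref_ca) ** 2
        if cb is not None and ref_cb is not None:
            d2 += (cb.shift - ref_cb) ** 2
        dists[sse] = math.sqrt(d2)
    # sort by distance; coil wins exact ties by ordering preference
    ranked = sorted(SSE_CLASSES, key=lambda s: (dists[s], s != "coil"))
    best, runner = ranked[0], ranked[1]
    tie = math.isclose(dists[best], dists[runner], rel_tol=0.0, abs_tol=1e-12)
    if tie:
        best = "coil" if dists["coil"] <= dists[best] + 1e-12 else best
        runner = next(s for s in ranked if s != best)
    return SSEAssignment(residue_type=res, sse=best, distance=dists[best],
                         margin=dists[runner] - dists[best], tie=tie)
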