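# Methods

This note documents the models implemented in fibrilkit, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions taken where the underlying experimental
protocols leave the design open.

## 1. Critical-concentration thermodynamics

Fibril elongation is treated as reversible addition of a single free unit
(monomer or small oligomer) at a fibril end:

    C + F_(i-1) <=> F_i,    K_F = k_ass / k_diss.

Two assumptions make this tractable late in the reaction: the number of
growing fibrils is constant (soluble material is too depleted for further
nucleation), and fibrils are unbranched, so the docking-site concentration
is independent of fibril length. Then K_F = 1/[C], where [C] is the free-unit
("critical") concentration, and

    dG_app = -R T ln K_F = R T ln([C] / 1 M).

*Standard state.* 1 M. K_F is reported in 1/M; dG_app in kJ/mol with
R = 8.314 J/(mol K).

*Temperature.* The dG/dS chain defaults to T = 293.15 K (20 degC), the
temperature at which the slow, well-resolved fibrillization regime is
observed and at which the chain reproduces a self-consistent
(dG, dH, dS) triple; the calorimetric dH itself is measured at 37 degC.
T is an explicit parameter of every function in the chain, so any other
convention is one argument away.

*Critical-concentration estimation.* The free-unit species appears in DLS
fits of fibril suspensions only intermittently, so its concentration is
taken to be the instrument's detection limit: the estimator returns the
lowest concentration in a dilution series at which the species is detected,
flagged "interior" when an undetected concentration exists below it and
"lower_bound" when every tested concentration was detected (the true value
may then be lower). This detection-limit protocol is a package convention;
the measurement itself does not prescribe one.

*Entropy.* dS = (dH - dG_app)/T (Gibbs-Helmholtz), assuming dH temperature-
independent to first order over the span between the dG reference
temperature and the calorimetric temperature.

*Heat capacity.* dCp = (ddH/dT)_p from independent least-squares lines on
the two sides of a breakpoint in the dH(T) table. The breakpoint defaults to
310.15 K (37 degC), where the temperature dependence of the enthalpy changes
regime; `breakpoint="auto"` scans candidate splits at midpoints between
consecutive temperatures and keeps the split with the smallest total
residual. Midpoint candidates guarantee that on noise-free piecewise-linear
input each branch is fitted only on points from its own regime, making the
auto fit exact for any breakpoint strictly inside the grid. Both slopes are
reported without interpretation; the module attaches no meaning to the sign
of either branch.

## 2. ITC thermogram integration

The heat-flow trace (ucal/s) is baseline-corrected and integrated
trapezoidally per injection window (an injection's window extends to the
next injection or the end of the trace); heats convert to joules at
4.184 J/cal and normalise to molar enthalpy by the protein amount per
injection.

Baseline models:

- `constant` (default): mean of the pre-first-injection samples. Requires a
  pre-injection region; errors out rather than guessing.
- `linear`: least-squares line through the pre-injection samples and the
  final 2% of the trace.
- `als`: asymmetric-least-squares (Whittaker) smoother, lambda = 1e9,
  p = 0.01, 10 iterations; peak polarity is inferred from the sign of
  (mean - median) so exothermic (negative) peaks are excluded from the
  baseline on the correct side.

## 3. DLS inversion and sizing

The intensity autocorrelation follows the Siegert relation
g2 - 1 = beta |g1|^2 with g1 a sum of 1-3 exponentials. Decay rates map to
diffusion coefficients via Gamma = D q^2, q = (4 pi n_r / lambda)
sin(theta/2), and to hydrodynamic radii via Stokes-Einstein
R_H = k_B T / (6 pi eta D).

*Instrument defaults* (all overridable): lambda = 660 nm, theta = 90 deg,
n_r = 1.33, coherence factor beta = 0.9, viscosity from an embedded
0-60 degC water table interpolated at the trace temperature. These are
typical cuvette-DLS values; the instrument class this emulates does not
publish its internals.

*Fitting.* Bounded nonlinear least squares (lmfit) over log10 decay rates
and non-negative normalised amplitudes, initialised log-spaced across the
reciprocal lag range. No regularised (CONTIN-style) inversion: at 1-3
discrete components it is unnecessary, and the discrete model keeps the
round-trip against the generator exact. Traces whose tail retains >= 90% of
the initial amplitude are rejected as non-decaying.

*Mass calibration.* M = a R_H^b fitted in log-log space to the printed
(R_H, M) pairs reported with the instrument's own histograms (shipped as
data, replaceable by the user). The instrument's internal radius-to-mass
formula is unknown; a power law reproduces the printed pairs to ~10% and
the extrapolated monomer mass to ~25%, which is the accuracy claimed for
`mass_from_radius`.

## 4. Water-edited build-up and fibril diameter

Build-up curves are normalised to the intensity at a reference mixing time
(default 100 ms). The initial build-up time t_m^s is the reciprocal slope of
a zero-intercept least-squares line through the points with normalised
intensity <= 0.5; zero intercept because zero mixing time transfers no
magnetisation, and the 0.5 bound because the linear regime of both candidate
forward models (capped-linear and saturating-exponential) extends at least
that far. Both choices are configurable. On the saturating-exponential model
the early-time curvature biases t_m^s low by up to ~12% with a window of
0.2 — the bound asserted in the tests.

The hydrated volume-to-surface ratio is V/S = sqrt(D_eff t_m^s / pi) with
D_eff = 0.2 nm^2/ms (literature value for protonated protein-water
magnetisation transfer; overridable), and the core diameter d = 4 V/S
assumes a long cylinder (length >> diameter). The cylinder assumption is
recorded in the result's `shape` field but never tested by the code; for
non-cylindrical objects the V/S value remains meaningful, the diameter does
not.

## 5. Chemical-shift secondary-structure annotation

Residues are classified helix/strand/coil by nearest reference in (CA, CB)
chemical-shift space (Euclidean distance in ppm; CA alone for glycine or
when CB is unavailable). The shipped reference table combines published
per-residue random-coil CA/CB averages with canonical secondary-shift
offsets (helix: CA +3.1, CB -0.5 ppm; strand: CA -1.5, CB +2.2 ppm); the
file `src/fibrilkit/data/sse_reference_shifts.csv` is versioned with the
package and documents its construction in `nmr._load_reference_table`.
Nearest-reference classification is a package choice — the underlying
experiments only overlay average shifts graphically. Exact ties prefer coil
(the least committal class) and are flagged.

Region-of-interest integration of 2D spectra sums cells whose centres fall
in the ppm box, scaled by the cell area, with an optional per-scan
normaliser. Exact ROI boxes for per-residue build-ups are spectrum-specific
and left to the caller.

## 6. SPR Hill analysis

Sensorgrams are double-referenced, (active - reference) -
(buffer_active - buffer_reference), and the equilibrium response is the
median of the trailing 10% of the corrected trace, flagged when the linear
drift across that window exceeds 2% of the response.

Isotherms are fitted with R = R_max c^n / (K_D^n + c^n) by unweighted least
squares in (log10 K_D, n, R_max); the log parameterisation conditions the
problem when K_D sits at the edge of the titration range. Standard errors
come from the fit covariance (delta method for K_D).

*Cooperativity verdict.* Nested comparison of the n = 1 fit against the
free-n fit by extra-sum-of-squares F-test, F = (RSS1 - RSS2)/(RSS2/(N-3));
"cooperative" requires preference at alpha (default 0.05) AND fitted n > 1.
Noise-free data leaves ~zero residual in both models and returns
"indeterminate" rather than a spurious verdict. An AIC comparison can be
derived from the reported RSS values by the caller; the F-test is the
built-in criterion.

*Recovery grid.* Synthetic recovery uses 12 log-spaced concentrations in
[0.1 K_D, 10 K_D]. A titration confined far above K_D saturates the site
and cannot identify n, so the generator brackets K_D symmetrically — a
deliberate idealisation chosen for testability rather than a reproduction
of any particular experimental concentration series.

## 7. ThT kinetics and CD

ThT traces are summarised by a 4-parameter logistic
F(t) = F0 + A/(1 + exp(-k(t - t50))); the underlying experiments report the
plateau qualitatively, so the logistic is a declared descriptive stand-in,
not a mechanistic nucleation-elongation model. Derived descriptors: lag =
t50 - 2/k (tangent construction at the midpoint) and plateau_time =
t50 + ln(99)/k (99% of the amplitude). A fitted amplitude below 3x the
residual scatter (or 1e-6 of the signal scale for numerically flat traces)
flags "no transition". The model-free plateau detector returns the earliest
time after which the trace stays within a tolerance band (default 2%)
around the trailing-window median, and reports "not reached" when the
trailing window itself still drifts beyond the band; its output is monotone
non-increasing in the tolerance.

CD spectra are normalised by the ellipticity magnitude at 217 nm (nearest
grid point), making spectra scale-free; the 208/222 nm two-point ratio is
offered as a helicity-change descriptor without any deconvolution.

## 8. Stochastic verification of the reaction scheme

`simulate_1d_crystallization` runs an exact Gillespie simulation of the
two-channel scheme (association consumes a free unit at propensity
k_ass n_ends n_C / (N_A V); dissociation releases one at k_diss n_ends) with
a fixed number of fibril ends, mirroring the constant-fibril-count
assumption of the analytic model. Copy numbers live in an explicit volume
(default 1 fL, i.e. ~450 free units at 750 nM), so concentration
fluctuations are Poisson-scale and the late-window time average converges
to k_diss/k_ass = 1/K_F as the volume grows. The reported standard error
comes from 20 equal-duration batch means over the trailing half of the
simulated interval; with the default rates the relaxation time (~60 s) is
much shorter than a batch (~500 s), so the batches are effectively
independent. Default problem size — 20 000 simulated seconds, ~3x10^5
events — gives a ~0.5% relative standard error and runs in under a second.

## 9. Synthetic data: what it does and does not emulate

Every generator implements exactly the forward model its partner analysis
inverts, plus additive Gaussian noise: exponential Siegert correlograms,
baseline-plus-rectangular(or Gaussian)-pulse thermograms, capped-linear or
exponential build-ups, Hill isotherms, logistic ThT traces, continuous
piecewise-linear dH(T) tables, Gaussian-band CD spectra. `noise_sd = 0`
draws no random numbers at all, so noiseless output is bit-identical across
seeds; noisy output is reproducible per seed.

Additive Gaussian noise is the simplest model consistent with the
unreported error structure of the real instruments; the generators do not
emulate correlated baseline drift, detector nonlinearity, multiplicative
intensity noise in DLS, mass-transport artefacts in SPR, or evaporation in
plate readers. Consequently, the parameter-recovery suites demonstrate that
the analysis chain is correct and well-conditioned under its own model
assumptions — not that it is robust to every artefact of real instrument
data. The noise magnitudes used in tests (e.g. 2 RU on a 100 RU isotherm,
2% of the ThT amplitude) are package choices of realistic scale, not
measured values.

## 10. Degenerate inputs and numerical conventions

- All internal computation is SI; reports surface kJ/mol, nm, ms, nM/uM.
- Fractions of a size distribution must sum to 1 within 1e-6; distributions
  are sorted ascending by radius.
- `ThermoParams` enforces its own cross-identities (Gibbs-Helmholtz and
  dG = RT ln[C]) to 1e-6 kJ/mol at construction, so an inconsistent state
  cannot be represented.
- `HydrationResult` enforces d = 4 V/S and V/S = sqrt(D_eff t/pi) to 1e-9.
- Fits that do not converge raise with the optimizer's diagnostics rather
  than returning best-effort values; degenerate cases that are scientifically
  meaningful (flat ThT trace, all-detected dilution series, single-branch
  dH(T) table) return flagged results with warnings instead.
- Pipeline runs are deterministic: a fixed config and seed produce a
  byte-identical report body (no timestamps in the report).

## 11. Known limitations

- The critical-concentration estimator assumes the dilution series brackets
  the detection limit; it cannot extrapolate below the tested range.
- The discrete 1-3 component DLS model cannot represent broad or continuous
  size distributions.
- The mass calibration is empirical and instrument-specific.
- Hill fits on titrations that saturate the site (all concentrations
  >> K_D) are ill-conditioned; the fit warns on sub-decade spans but cannot
  rescue an uninformative design.
- No kinetic (k_on/k_off) SPR analysis, no mechanistic aggregation-rate
  laws, no CD secondary-structure deconvolution, and no frequency-domain
  NMR processing — these are outside the package's scope.
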