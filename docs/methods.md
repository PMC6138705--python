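# Methods

## The physical model

The package models a soft-material waveguide: a straight dielectric tube of
internal diameter d, external diameter D and length L (the "internode"),
filled and surrounded by ionic solution.  Defaults are d = 48 mm,
D = 96 mm, L = 240 mm — a myelinated-axon segment scaled to desk
dimensions.  Material parameters (relative permittivity / conductivity):

| region              | ε_r   | σ (S/m) |
|---------------------|-------|---------|
| inner solution      | 136.0 | 0.487   |
| dielectric shell    | 10.3  | 0       |
| outer solution      | 136.0 | 1.454   |

Relative permeability is 1 everywhere.  The solution permittivity of 136
(above pure water's ≈ 80) is the literature value for these electrolyte
models and is used as given, not "corrected".  The control configuration
is the same domain filled homogeneously with one solution; the default is
the outer (extracellular) solution, since the control mimics the bath
without the tube, and the inner solution is available through
configuration.

Voxelization is by cell-center membership on a uniform cubic grid: a cell
is inner solution if its center lies within r < d/2 of the axis (at any
axial position — the tube is open, solution continues past both ends),
dielectric if d/2 ≤ r < D/2 within the internode span, and outer solution
otherwise.  No sub-cell material averaging is performed; the refinement
test in the suite bounds the voxelization error (shell volume within 2% of
π(D² − d²)L/4 at 2 mm cells).  The tube is centered transversally and
axially; the builder refuses grids whose cells cannot resolve the shell
with at least four cells.

## The FDTD solver

Maxwell's curl equations are integrated by the standard leapfrog scheme on
a Yee lattice with Δx = Δy = Δz.  The time step is coupled to the cell
size as Δt = Δx/(2c₀), i.e. a Courant number of 0.5 against the
three-dimensional bound 1/√3 ≈ 0.577; the bound is checked at
construction and any explicit Δt violating it is rejected.  Conduction is
treated semi-implicitly (σE averaged across the half step), which is
second-order accurate and reduces exactly to the lossless update at σ = 0.
Material coefficients are evaluated per cell; all components owned by a
cell use that cell's (ε, σ).

The absorbing boundary is a perfectly matched layer in stretched-coordinate
(convolutional, recursive-accumulator) form — the modern realization of the
uniaxial PML absorber, chosen because it adds loss to the spatial
derivatives directly and therefore composes cleanly with conductive
interior media.  Defaults: 10 cells per face, polynomial conductivity
grading of order 3, peak conductivity set from a theoretical
normal-incidence reflection of 1e−4.  Measured reflection against an
enlarged-domain reference is ≈ 1.4e−5.  Outer walls behind the PML (or
with the PML disabled) are perfectly conducting; any axis can instead be
made periodic, which is how the plane-wave testbeds (a uniform current
sheet in a 4×4-cell strip) are built.

Sources are soft: a current density added to the electric-field update, so
they do not reflect incident waves.  A point current J over one cell
corresponds to a dipole moment I·dl = J·Δx³, the calibration used when
comparing against the analytic Hertzian dipole.

Two discrete energy functionals are provided.  The leapfrog-compatible
form pairs E at an integer step with the product of the two bracketing H
half-steps; it is conserved to round-off by the lossless PEC-bounded
scheme and non-increasing for σ ≥ 0, and the suite asserts both.  The
sup-norm of the fields is *not* a conserved quantity of the linear scheme —
random initial data reorganizes under interference and local amplitudes
can transiently exceed the initial maximum — so long-horizon stability is
asserted through the conserved energy plus a constant-factor bound on the
field maximum over 10⁴ steps.

### Verification oracles

* **Dipole radiation**: a sinusoidal point source in vacuum at 20 cells per
  wavelength, measured at one wavelength broadside, against the exact
  near+far-field Hertzian expressions (gate 5%; measured ≈ 0.2%).
* **Lossy plane-wave decay**: a periodic strip of ε_r = 136, σ = 1.454
  driven at 208.2 MHz (vacuum wavelength 1.44 m); the fitted amplitude
  slope against α = ω√(µε/2)·√(√(1 + (σ/ωε)²) − 1), itself cross-checked
  against a complex-wavenumber evaluation (gate 5%; measured ≈ 0.1%).
* **PML reflection**: identical pulse and probe in a short and an enlarged
  domain; the residual bounds the reflection coefficient (gate 1e−3;
  measured ≈ 1.4e−5).

These closed forms never enter the time stepping.

## Excitations

* Gaussian pulse exp(−4π(t − t₀)²/τ²), τ = 2.40 ns, t₀ = 1.92 ns.  The
  transient (axon-like) excitation is a ring of eight such dipoles,
  radially polarized, 45° apart, at mid-shell radius (d + D)/4 in one
  cross-section.  Ring cells are snapped for two base angles and completed
  by exact quarter-turn index rotation, so the layout keeps its discrete
  four-fold symmetry even when a position falls on a cell boundary.
* Sine with vacuum wavelength λ = 1.44 m (f = c₀/λ ≈ 208.2 MHz), placed on
  the medial axis and polarized axially.  λ is interpreted as a vacuum
  wavelength; a direct frequency override exists because the in-medium
  reading (f larger by √ε_r) is also defensible.  Simulated sines ramp up
  under a cosine taper before measurement.
* Trapezoidal square-pulse trains (2.0 V peak-to-peak plateau, 2.5 ns
  edges inside the duration), the bench-style excitation.

Source axial station defaults to two cells past the internode start ("just
inside the tube mouth"); it is configurable, since published setups show
the position only pictorially.

## Field reductions

The axial energy profile takes, per axial station, the time-peak of the
transverse-plane sum of ½ε|E|² + ½µ|H|² (PML cells excluded), normalized
at the source station.  The time-peak definition lets pulse and sine runs
share one reduction; a time-average variant for steady sines would differ
only by a constant factor in the normalized profile.  Cross-section maps
are per-pixel running maxima of |E| over the monitor window.  Front
arrival is the first time |signal| exceeds 5% of the record's own maximum —
an operational definition chosen because the "onset period" of a station
has no unique definition; the waveguide/control comparison uses the same
threshold on both records, and the conclusion is insensitive to the
threshold over a wide range.

## The confinement study (scaled)

The study in `softwg.verification.confinement_study` keeps the standard
diameters, materials, excitations and the 2 mm cell size but halves the
internode to 120 mm and uses an 8-cell PML with a 6-cell working margin
(grid 76×76×88, ≈ 0.5 M cells).  Three comparisons are made:

* the Gaussian-ring pulse is run through the waveguide and the control
  grid; the normalized energy density at the output station (two cells
  before the tube end) is compared — the waveguide retains ≈ 3× the
  control's value;
* the same runs give output-plane front arrivals: ≈ 2.7 ns in the
  waveguide versus ≈ 5.1 ns in the control — the wall (phase velocity
  c₀/√10.3) carries the front faster than the solution (c₀/√136);
* an axial-sine run supplies the center-station cross-section map, whose
  maximum falls on the shell / inner-fluid interface ring (measured peak
  radius ≈ 25.5 mm against d/2 = 24 mm, within one cell) — the normal-field
  discontinuity concentrates E on the low-permittivity side of the inner
  interface, and the inner solution is the less lossy of the two fluids.

The halved internode and the monitor strides were chosen to keep the study
a few minutes long on one CPU; the compared quantities are ratios and
orderings that do not depend on the absolute scale of the run.

## The synthetic bench

The generator emulates the statistical structure of tube transmission
measurements; it is a statistical stand-in, not an electromagnetic
prediction of a bench fixture (cable and connector impedances are not
modelled).  Generative model, with defaults:

* plateau efficiency A₀ = 0.70 — the center of the 65–75% band saturated
  bench measurements reach;
* exponential decay with tube length, exp(−L/L₀), with per-duration
  attenuation lengths L₀ = 251, 229, 131, 10, 6.1 cm at 100 ns, 1 µs,
  10 µs, 100 µs, 1 ms (log-log interpolated between grid points);
* single-pole low-pass magnitude versus sine frequency, cutoff
  f_c = 30 kHz, and exponential saturation 1 − exp(−T/T_sat) versus pulse
  duration, T_sat = 30 µs.  Both defaults sit inside the reported 10–100 kHz
  and 10–100 µs bands.  The two characteristics are deliberately calibrated
  *independently* (a single pole cannot produce both bands at once:
  1/(2π·30 kHz) ≈ 5.3 µs ≠ 30 µs); square-pulse traces are therefore
  filtered with the pole at 1/(2πT_sat) so the trace-level and
  summary-level duration responses coincide, while sine traces use f_c;
* a logistic-bounded gain factor, equal to 1 at the reference condition
  (2 mm wall, 0.15 mol/L), rising with wall thickness (0.15 per mm) and
  with the log of ion concentration (0.05 per decade) — monotone and
  bounded in (0, 2), matching the qualitative trends without asserting a
  functional law the measurements do not constrain;
* noise: additive Gaussian on traces (2% of the excitation amplitude),
  multiplicative lognormal (2%) on summary efficiencies, inflated 3× for
  thickness sweeps, whose bench scatter is large.  A per-concentration
  cutoff table can emulate "lower concentration, lower cutoff".

Note an intentional asymmetry carried over from the measurements being
emulated: the duration/frequency sweeps show efficiency *rising* with
duration (saturation), while the length sweeps' L₀ table makes efficiency
at fixed length *fall* with duration.  The generator reproduces each
figure-level behaviour in its own sweep rather than forcing a single
reconciled model.

What passing tests show — and do not show.  Recovery tests demonstrate
that the estimators invert the generative model (exactly when noiseless,
within stated tolerances under 2% noise).  They cannot validate the
generative model against real hardware, impedance effects, drift, or
non-Gaussian noise.

## Analysis estimators

* **Efficiency**: V_pp/V_ref.  For square pulses the peak-to-peak value is
  the median of the top decile of plateau samples (samples above half the
  trace range) minus the median of the bottom value band — robust to edge
  ringing and to the pulse's duty cycle in the window; the residual bias on
  strongly low-passed (ramp-like) pulses is ≲ 4%.  For sines it is the
  full span of the steady oscillation.
* **Attenuation length**: OLS on (length, ln efficiency), L₀ = −1/slope,
  with free intercept and no weighting; the 95% interval inverts the
  t-based slope interval, and a non-negative slope is reported as the
  non-attenuating sentinel L₀ = ∞.  Note that for L₀ ≫ max length the
  log-spread across a 2–12 cm sweep is comparable to 2% noise, so point
  estimates are wide — the interval, whose coverage the suite verifies
  (≈ 96% over 200 replicates), is the meaningful output.
* **Cutoff**: the −3 dB point relative to the low-frequency plateau
  (mean of the two lowest-frequency points).  Implementation: the
  linearized single-pole ordinate (A₀/eff)² − 1 is fitted log-log over
  stations at least 3 dB below the plateau and the fit is solved at the
  value 1 — exact for an ideal single pole, robust on decade-spaced grids
  where direct interpolation of the magnitude curve is not.
* **Saturation duration**: the smallest duration reaching 95% of the
  plateau.  The linearized ordinate −ln(1 − eff/A₀) is regressed through
  the origin against duration over the rising region (points before the
  curve first reaches 90% of the plateau), with inverse-variance weights
  ((1 − r)/r)²; the 95% point is −ln(0.05) ≈ 3.0 time constants.  Exact on
  ideal data; within 10% under 2% noise.

Recovery protocols average three repeats per sweep point, mirroring bench
practice of measuring each device multiple times.

## Determinism and reproducibility

FDTD runs are deterministic (identical inputs give bit-identical records).
All generator randomness flows through a single seed
(`numpy.random.default_rng`); regenerating with the same seed reproduces a
dataset exactly.  CLI artifacts embed the resolved-configuration SHA-256
digest and seed in their headers.  `scripts/acceptance.py` derives every
sub-seed from its `--seed` argument.

## Known limitations

* No dispersive (frequency-dependent) media, no sub-cell conformal
  meshing, no modal (TE/TM) decomposition, single-threaded solver.
* Staircased cylinder surfaces: interface-sensitive quantities (e.g. the
  peak-radius statistic) are resolved only to about one cell.
* The λ = 1.44 m sine in the full-size model needs ~1440 time steps per
  period at 2 mm cells, which bounds how many periods desk-scale runs can
  afford; steady-state quantities are measured over the final one to two
  periods after a two-period ramp.
* The bench generator's functional forms (single pole, exponential
  saturation, logistic trends) are the minimal models consistent with the
  reported behaviour, not fitted laws.
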