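# Methods

## Model

One vocal fold is lumped into two masses, a lower body (m₁ = 0.17 g)
and an upper cover (m₂ = 0.03 g), each carrying a two-dimensional
displacement r_i = (r_ix, r_iy): x is vertical (inferior → superior),
y horizontal (medial → lateral). The equations of motion are

    m_i r̈_i + η_i ∘ ṙ_i + k_i ∘ r_i + k_c (r_i − r_j) = F_i

with element-wise spring and damper vectors. The horizontal
stiffnesses are k₁y = 150 N/m, k₂y = 40 N/m with coupling
k_c = 20 N/m; the vertical stiffnesses are never independent
parameters but always k_ix = Q·k_iy. Damping is
η_i = ζ_i·2√(m_i k_i) element-wise with ζ₁ = 0.1 and ζ₂ = 0.6, i.e.
the damping follows the stiffness: quadrupling Q doubles the vertical
damping coefficient and leaves the horizontal one unchanged. The
contralateral fold is the mirror image about the glottal midline;
left–right asymmetric motion is out of scope.

Because the structural terms act element-wise per axis, the x- and
y-dynamics are linearly decoupled; they interact only through the
aerodynamic surface forces and the contact penalty. This is what makes
Q a clean control knob: it rescales the vertical subsystem without
touching the horizontal one.

### Eigenmodes

The in-vacuo modes come from the undamped, unforced 4-DOF generalized
eigenproblem K·φ = ω²·M·φ with M = diag(m₁, m₁, m₂, m₂) and an
axis-block-diagonal K (per axis: [[k₁+k_c, −k_c], [−k_c, k₂+k_c]]).
Every mode is therefore purely horizontal or purely vertical; modes
are reported in ascending frequency with the axis label attached after
sorting, because the physically meaningful ordering (and the crossover
as Q grows) is by frequency. On an exact tie the horizontal mode is
listed first. The eigenfrequencies are validated two ways: against the
reference table of the standard constants (32 cells to 0.05 Hz) and
against time-domain free vibration integrated by the package's own
stepper (0.5% agreement), which guards against an inconsistency
between the matrix assembly and the force evaluation.

### Glottal geometry

The medial surface is the convex envelope of two circles (radii
r_cyl1, r_cyl2) joined by their common external tangent; each circle
translates rigidly with its mass. At rest both circles touch the
midline, so the prephonatory glottal gap and convergence angle are
zero and the glottis is closed at both mass levels. The half-width at
a vertical station is the y-coordinate of the envelope; negative
half-width means midline penetration (collision with the mirror
fold). The cylinder radii and rest offsets are not constrained by any
reference value; the defaults (2.0 mm and 1.0 mm radii, 3.0 mm
vertical separation, 17 mm anterior–posterior span matching the inlet
chamber depth) are plausible adult-male scale and are configuration,
not results — nothing in the acceptance surface depends on them.

One consequence of the rigid-circle construction worth noting: a
purely vertical displacement of one mass changes the fold thickness
and the tangent-segment length but not the tangent's angle (both
circles keep touching the midline), so the reported `entry_angle` —
defined as the angle of the common tangent to the flow axis — responds
to differential lateral motion, not to pure vertical motion.

### Glottal flow and surface forces

The flow is quasi-steady, incompressible Bernoulli flow with
separation: upstream of the separation station the static pressure is
p(x) = p_sub − ½ρ(U/A(x))², downstream it equals p_sup. Separation
defaults to the minimum-area station, which makes the pressure
continuous there; an area-ratio criterion (A/A* > 1.2) is available as
configuration. The flow rate follows from p(separation) = p_sup. Air
density defaults to ρ = 1.2 kg/m³. Closure is handled with an area
floor of 1e-7 m² below which U = 0 and the pressure splits
hydrostatically (p_sub below the first contact station, p_sup above).
There is no glottal inertance and no reverse-flow branch: all unsteady
acoustics lives in the tract lines, which is standard lumped-element
practice and keeps every flow quantity closed-form testable.

In the coupled loop the end pressures are not prescribed but depend on
the flow through the characteristic impedances of the two lines
(p_sub = 2f − Z_sub·U, p_sup = 2b + Z_sup·U), giving a quadratic for
U. This interactive solve is the mechanism by which tract acoustics
feed back on the source.

Surface forces integrate p·n̂ over the discretized envelope:
dF_y = L_g·p·dx and dF_x = −L_g·p·h'(x)·dx. Stations below the
tangent-segment midpoint load mass 1, the rest mass 2; the split is
evaluated by interpolating the cumulative integrals so it does not
snap to a grid station (this matters: snapping costs O(Δx) accuracy
and fails the 4× grid-refinement oracle). The x-components are the
per-mass "vertical forces" used as the entrainment diagnostic.

### Contact

No reference contact law exists for this configuration, so collisions
use the classic linear penalty: while the local half-width at a mass
station is negative, a restoring lateral force of stiffness
3·k_iy (configurable) times the penetration depth acts on that mass.
Damping coefficients are unchanged during contact by default (a
multiplier is exposed). The penalty raises the effective contact-phase
stiffness well below the stability limit of the integrator at the
default step.

### Tract acoustics

Both ducts are uniform Kelly–Lochbaum transmission lines with segment
length c·dt (c = 343 m/s; dt = 2.5e-5 s gives 17 subglottal and 20
supraglottal segments; segment counts are rounded and the realized
length recorded). A scalar per-segment loss factor (default 0.002)
stands in for wall losses. The supraglottal far end is a
frequency-independent reflection coefficient of −0.9 (an RL
piston-style load is declared in the radiation type but only the
reflection kind is implemented); the radiated pressure is the monopole
approximation ρ/(4πr)·dU/dt at r = 160 mm, delayed by r/c. The
subglottal far end models the inlet pressure chamber as a soft
constant-pressure reservoir: reflection +0.8 plus a source term whose
transmission is loss-compensated so that the static pressure at a
closed glottis settles to exactly the lung pressure (with a naive
(1−r)/2 transmission the scalar loss would silently drop the delivered
DC pressure by ~25%). Cross-sectional area defaults to 2.0 cm²;
the duct cross-sections are configuration, not results.

Every line is checked by a dual oracle: the time-domain impulse
response of the sampled system against the frequency-domain
transfer-matrix input impedance of the same discretized line, with
resonances required to match within one FFT bin, plus the closed-form
quarter-wave series for ideal terminations.

### Coupled loop

Per acoustic sample: rebuild the glottal profile from the mass
positions → solve the loaded Bernoulli flow against the incident
partial pressures → integrate surface forces → advance the mechanics
by 5 RK4 sub-steps (aerodynamic force held constant over the sample;
the position-dependent contact force is re-evaluated at every RK
stage through a scalar fast path) → inject ±U into the two lines and
propagate them one sample. The glottis starts closed at rest; the
lung pressure opens it, and a seeded 1e-4 m/s velocity perturbation
breaks the symmetry of the start-up so runs are reproducible
(bit-identical for a fixed seed) without being artificially clean.
Default run: 0.5 s at dt = 2.5e-5 s with the first 0.1 s discarded
(≥ 70 cycles retained at ~190 Hz). The acceptance-level behavioral
test uses 0.45 s runs — enough for the amplitude statistics it
measures while keeping the suite fast.

Integrator fidelity is pinned by three facts measured in the tests:
undamped energy drift < 1e-6 relative over 100 periods at dt = 2e-5 s,
fourth-order error scaling (sup-norm error ratio ≈ 16 when halving
dt), and monotone energy decay with damping on.

### Analysis

- **F0**: FFT autocorrelation peak, parabolically refined. A candidate
  half-period replaces the best lag only if its autocorrelation is at
  least 0.95 of the peak, so a weak subharmonic (5% amplitude) does not
  halve F0 while a strong one (30%) does.
- **SPL**: 20·log10(rms/20 µPa), mean removed, window ≥ 50 ms.
- **Spectra**: Welch, Hann, 50% overlap, nfft chosen for ≤ 5 Hz
  resolution (a 90 Hz subharmonic comb needs it).
- **Subharmonic index**: band power within ±1 bin of half-integer
  multiples of F0 over power at integer multiples; 0 for a harmonic
  comb, 1 for equal-strength half-harmonics; gain-invariant.
- **Entrainment ratio**: exhaustive search over p, q ≤ max_order
  minimizing |f0/f_res − p/q| (ties to the smaller denominator), with
  the residual and the difference tone min_k |f_res − k·f0| (90 Hz for
  180 vs 450).
- **Regime**: Poincaré section of (y₂, ẏ₂) at upward zero crossings of
  y₁; single-linkage clustering at a distance threshold relative to
  the orbit scale (scaling by the section's own scatter would
  degenerate for a limit cycle). One tight cluster → limit cycle; a
  few tight clusters → period-n; a filled closed curve (radius a
  smooth single-valued function of angle about the centroid) → torus;
  otherwise irregular. Labels are invariant to gain and time shift.
- **Displacement amplitude**: per-cycle peak-to-peak halved, averaged
  over cycles (the aggregation convention is configurable in the sense
  that the raw series are always available; RMS-based measures are one
  line away).

## What the surrogate does and does not show

The desk-scale flow model replaces a three-dimensional compressible
turbulent flow computation. It preserves the structural ingredients of
source–filter interaction — interactive acoustic loading of the flow,
sub- and supra-glottal standing waves at realistic lengths, per-mass
vertical pressure forces — and reproduces the robust behavioral trend:
self-sustained oscillation at 2000 Pa whose vertical motion collapses
(to a few percent in RMS) as Q goes from 1.5 to 100 while the
horizontal amplitude barely moves. It does **not** reproduce
quantitative coupled results: far-field SPL values, the exact
F0 (≈ 196 Hz here), the specific 2:5 entrainment window at low Q, or
force-spectrum ripple frequencies depend on jet dynamics, separation
behavior and three-dimensional tract geometry that a quasi-steady
Bernoulli channel with uniform ducts cannot carry. Those quantities
are treated as exploratory output, and the entrainment analyses are
validated on constructed signals instead.

The synthetic fixtures (sinusoid mixtures with seeded noise) exercise
the analysis layer under controlled conditions; they contain no
cycle-to-cycle aperiodicity, amplitude drift or measurement noise, so
passing them shows the estimators implement their definitions, not
that they are robust to every pathology of measured voice signals.

## Numerical choices

- RK4 with fixed step; acoustic dt = 2.5e-5 s tied to the segment
  length; 5 mechanics sub-steps per sample. Instability guard at
  20 mm displacement.
- Eigenproblem via symmetric generalized `scipy.linalg.eigh`; mode
  shapes unit-normalized, sign fixed by the largest component.
- Geometry sampled at 64 stations by default; the 4× refinement
  changes forces by well under 1%.
- Degenerate geometry (one cylinder swallowing the other) raises an
  error naming the offending configuration rather than producing a
  silent non-tangent surface.
- Time-series CSV uses 17-significant-digit text and round-trip float
  parsing, so stored runs re-analyze to identical results.

## Known limitations

Single symmetric fold (no left–right asymmetry), no glottal
inertance or reverse flow, frequency-independent terminations, scalar
wall loss, no jet deflection or turbulence, no perceptual voice
measures. The cylinder radii/offsets and duct areas are free
parameters with declared defaults; conclusions that depend on them
should sweep them.
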