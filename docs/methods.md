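# Methods

## The NITI constitutive model

Soft tissue is nearly incompressible, so the longitudinal Lamé constant λ is
four-plus orders of magnitude larger than any shear-scale modulus. The
dermis adds one symmetry axis (the dominant collagen / Langer's-line
direction), giving a transversely isotropic stiffness with five formal
constants; in the incompressible limit only three combinations are
observable through shear and surface waves:

| parameter | meaning | unit | typical forearm dermis |
|---|---|---|---|
| μ | shear modulus in the isotropy plane | Pa | 1–10 kPa |
| G | shear modulus out of the plane (along fibers) | Pa | 1–5 × μ |
| δ = Q2 − 2Q1 | tensile anisotropy | Pa | 0–10 × μ |
| ρ | density | kg/m³ | 1000 (fixed by assumption) |
| λ | incompressibility surrogate | Pa | 1e5 × max(μ, G, \|δ\|) |

Engineering moduli follow closed forms: E_L = 3μ + δ grows linearly with δ
while E_T = 3μ + μδ/(4μ+δ) is pinched between 3μ and 4μ; ν_LT = 1/2
exactly, and ν_TT + ν_TL = 1. Positivity of the Poisson ratios bounds the
physical range (E_L > E_T/2, E_T > 2μ, and 3μ < E_T < 4μ for δ > 0);
`validate_parameters` reports violations as diagnostics rather than errors
so that fitted parameter sets can be flagged without aborting.

The split of δ into (Q1, Q2) is not observable in the incompressible limit;
the default Q1 = 0, Q2 = δ is a convention, overridable. λ is never fitted:
it is fixed at 1e5 × the largest shear-scale modulus, and a convergence
check (doubling λ moves derived moduli and Rayleigh speeds by < 1e−4
relative) is part of the test suite. Density enters only as an overall
√(1/ρ) speed scale; 1000 kg/m³ is the standard soft-tissue assumption.
Moduli are stored in Pa internally and exposed in kPa at file interfaces.

## Bulk waves

For a propagation direction at angle θ from the symmetry axis (in the plane
containing the axis), the Christoffel eigenproblem Γu = ρc²u gives three
branches. The branch polarized normal to that plane is pure shear with the
exact closed form c_S = √((G cos²θ + μ sin²θ)/ρ). In the incompressible
limit the quasi-shear branch reduces to
c_qS = √((G cos²2θ + (μ + δ/4) sin²2θ)/ρ) — 90°-periodic, G-free at 45°.
The general-angle quasi-shear expression is validated purely against the
numeric eigen-solution (≤ 1e−3 relative at λ/μ = 1e6); eigenvalues are
clipped at zero with a 1e−9·λ tolerance to absorb round-off. Branch
labelling uses polarization (dominant out-of-plane component ⇒ pure shear),
not sort order, so branch crossings do not scramble the curves.

## Rayleigh surface waves (Stroh formalism)

The half-space occupies x > 0 with the symmetry axis in the free surface.
For a trial speed v the sextic Stroh eigenproblem yields six partial waves;
the three decaying into the depth (Im p > 0) are assembled into the surface
impedance matrix M(v) = −i L A⁻¹, which is Hermitian and positive definite
in the subsonic range and singular exactly at the Rayleigh speed. The
residual Re det M(v) therefore changes sign at c_R; a batched coarse scan
brackets it and Brent's method refines to 1e−8 relative. Blocks are
nondimensionalized by μ so determinant magnitudes stay tame at λ/μ = 1e5.

Numerical decisions worth knowing:

* **Symmetry-angle decoupling.** At θ = 0° and 90° one transverse
  displacement component decouples (pure SH). It is detected structurally
  and removed, reducing the problem to a 4×4 sextic. This matters at
  θ = 90° when G < μ: the decoupled out-of-plane branch is then slower than
  the sagittal motion and would otherwise truncate the subsonic search
  bracket below the genuine root (which is 0.9553·√(μ/ρ) regardless of G).
* **Near-cutoff roots and branch merging.** When δ < G the Rayleigh branch
  hugs the quasi-shear cutoff near 45° — the root can sit within a 1e−7
  sliver below it, so the coarse scan carries a geometric tail of points
  approaching the cutoff. Over part of the (G/μ, δ/μ, θ) space the branch
  merges with the bulk branch outright (the residual vanishes at the cutoff
  without crossing); the solver then returns the cutoff speed, which is the
  physical limit of the surface wave there. The acceptance threshold for
  declaring a merge is a residual below 1e−3 of the mid-bracket scale.
* **G-independence at 45° has a premise.** c_R(45°) ≈ c_qS(45°) =
  √((μ + δ/4)/ρ) holds only while the quasi-shear branch is the slowest
  coupled branch, i.e. δ < 2(G − μ). At G = μ the pure-shear branch
  c_S(45°) = √((G+μ)/2ρ) is slower and caps the root: measured spreads of
  c_R(45°) over G/μ ∈ [1, 5] are 26% at δ/μ = 2 and 4.7% even at δ = 0,
  versus 0.08% over G/μ ∈ [2, 5] at δ/μ = 0.5 where the premise holds.
* The solver returns the lowest-speed sign change (fundamental mode), and
  all angles go through the same numeric path — θ = 0°/90° are *tested*
  against the closed-form limits, not special-cased analytically.
* The incompressible limit is approximated by finite λ rather than an exact
  incompressible Stroh formulation, keeping a single solver for all
  regimes; λ-convergence of c_R (1e5 → 1e6 changes < 1e−4) is asserted.

The inversion fits measured *group* velocities with this *phase*-velocity
curve. For nondispersive wave packets the two coincide along symmetry
directions; off-symmetry they can differ in principle, which is a known
caveat of the approach rather than of this implementation.

### Cached speed profiles

Dimensional analysis gives c_R(θ) = √(μ/ρ)·f(θ; G/μ, δ/μ). The inversion
evaluates f on a 5° grid in [0°, 90°] (warm-started brackets from the
neighbouring angle) and interpolates with a clamped cubic spline
(dc/dθ = 0 at both ends by material symmetry). Measured interpolation error
is ~6e−6 relative — far below the 0.1% budget — and a regression test keeps
it under 1e−3. Profiles are cached per (G/μ, δ/μ), which makes the α-jitter
restarts and LOO folds cheap.

## Synthetic wavefields and group velocity

The generator is kinematic: a Gaussian-enveloped cosine pulse (center
1.5 kHz, −6 dB full bandwidth 4 kHz, matching the excitation band)
translating at a fixed group speed across the acquisition grid
(256 positions × 54.7 µm, 512 frames at 46.5 kHz), with optional
1/√(x + x₀) geometric decay and additive white Gaussian noise, seeded. It
deliberately emulates only the features the estimator consumes — arrival
kinematics, pulse shape, noise — not elastodynamics: no near field, no
dispersion, no mode conversion, no depth structure. Passing tests therefore
demonstrate the correctness of the estimation chain, not the fidelity of
any wave simulation; real-data effects (dispersion from layering, bulk
motion, speckle decorrelation) are out of scope.

Arrival times come from the analytic-signal envelope maximum with 3-point
parabolic sub-sample refinement (default) or from cross-correlation lags
against the first trace; speed is the inverse slope of the least-squares
arrival-time line. A non-positive slope raises (wave direction
inconsistent); R² below 0.9 warns. When the wavefield metadata records the
pulse width, a two-pass fit excludes positions within one speed×pulse-width
of the source side (near-field guard); on bare arrays the exclusion
distance is an explicit argument. The moving-kernel map applies the
estimator to every contiguous window of `kernel` positions at stride 1, so
n_x positions yield exactly n_x − kernel estimates per row (100 → 80 with
the 20-pixel kernel).

## PS-OCT optic-axis estimation

A linear retarder with physical axis ψ rotates Stokes states about the
equatorial Poincaré axis (cos 2ψ, sin 2ψ, 0). The simulator composes such
rotations depth step by depth step (pure retardance only — no diattenuation
or depolarization, matching the apparent-axis quantity being estimated),
launching circular polarization (0, 0, 1) by default. The estimator slides
a 3-state window along depth, fits the local plane by SVD of the centered
states, and reads ψ = ½·atan2(n_U, n_Q) from the plane normal. The normal's
sign is fixed by requiring right-handed advance of consecutive states about
+n (positive retardance), resolving the ψ vs ψ + 90° ambiguity of an
unsigned normal — a convention choice, stated here because the estimator's
output flips by 90° under the opposite convention. Windows with arc length
below 1° are masked as non-birefringent (the epidermis-like surface layer);
this threshold stands in for an unspecified instrument-side filter. With a
3-state window the plane interpolates the states exactly; the SVD path is
kept so larger windows work unchanged. Depth averaging uses the circular
mean with doubled angles, the correct average for 180°-periodic
orientations (e.g. {85°, −85°} average to ±90°, not 0°).

## Inversion

`RayleighAnisotropyModel.fit()` minimizes the (optionally 1/sd-weighted)
squared residuals between the scan speeds and the model curve over
(μ, G, δ, α) with `scipy.optimize.least_squares` (trust-region reflective,
box bounds μ, G ∈ (0.01, 1000] kPa, δ ∈ [0, 10⁴] kPa, α ∈ (−90°, 90°]).
Initialization uses printed limits: α₀ at the scan angle of maximum speed,
μ₀ = ρ(c_min/0.9553)², G₀ = ρ(c_max/0.9553)², δ₀ = μ₀. Because the cost is
180°-periodic in α, the default fit restarts 5 times with α₀ jittered by
±30° and keeps the best optimum. δ ≥ 0 (fast axis) is the default; slow-axis
mode removes the bound with a warning. A scan whose speed range is below
max(1% of the mean, 2× median sd) triggers an axis-unidentifiability
warning. LOO-CV refits N times, each omitting one angle and warm-starting
at the full fit; α statistics are computed on differences folded around the
full-fit α so wrap-around at ±90° cannot bias them.

## Synthetic subjects

`make_fixtures` generates the paired acquisition: 13 wavefields at
−90°:15°:+90° whose speeds follow the forward Rayleigh curve, plus a PS-OCT
volume whose dermal axis equals the mechanical α under a 20-step
non-birefringent surface layer (6°/step dermal retardance — deep enough per
window to clear the collinearity mask by two orders of magnitude). All
randomness flows from a single `SeedSequence`; per-artifact sub-seeds make
every file byte-reproducible from the manifest seed.

## Problem sizes and defaults used in the shipped checks

The test suite and the acceptance script use the acquisition-scale defaults
(13 angles, 256×512 wavefields, 20-pixel kernels) throughout. Monte-Carlo
studies use 100 seeds for the estimator and noisy-recovery properties;
the noiseless round-trip sweep covers a 3×3×3 grid of (μ, G/μ, δ/μ) with
the axis offset cycled over {−60°, 10°, 45°}; PS-OCT recovery sweeps a 5°
grid of axes at four retardances. Single fits take a few seconds; the
forward analytic benchmarks run in well under a minute.

## Known limitations

* Viscoelasticity, dispersion and guided modes of a finite-thickness dermis
  are out of scope; the half-space model presumes nondispersive wavefields.
* Slow-axis (δ < 0) materials are accepted only in the explicit slow-axis
  mode and near-90° propagation for G ≲ 0.91μ enters a leaky regime the
  solver does not model (the exact 90° case is handled by decoupling).
* The optic-axis estimator targets the apparent axis of a pure retarder;
  diattenuation, depolarization and multiple scattering are not modelled.
* Group-vs-phase velocity identification off the symmetry axes is an
  approximation inherited from the measurement strategy.
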