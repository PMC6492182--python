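# Methods

## Constitutive model

The wall material is hyperelastic with a volumetric/isochoric split.  The
isotropic exponential (Demiray) energy

Ψ = κ/2 (ln J)² + a/(2b) [exp(b(tr C̄ − 3)) − 1],  C̄ = J^(−2/3) C,

is the working model throughout (benchmark values a = 10 kPa, b = 8;
κ = 650 kPa unless stated).  The transversely isotropic Guccione energy
(defaults b_f = 18.48, b_t = 3.58, b_fs = 1.627) is implemented at the
point level — energy and analytic Cauchy stress with a
fiber/sheet/normal frame — for completeness of the material layer; the
shell solvers use the isotropic law.  Passive Cauchy stress is the
analytic push-forward σ = J⁻¹F(2∂Ψ/∂C)Fᵀ; the test suite verifies it
against central finite differences of an independently coded scalar
energy (relative tolerance 1e−5 over 100 random deformations per
material).

Active contraction is a spatially uniform twitch
S_a(t) = S_peak φ(λ) tanh²(t/τ_c) tanh²((t_dur−t)/τ_r) on 0 < t < t_dur,
zero outside.  The length-dependence φ(λ) is injectable and defaults to
the constant 1: no published functional form accompanies the twitch
model we mirror, and at the lumped-sphere level a constant simply
rescales S_peak, which is refitted anyway.  τ_r defaults to 30 ms
(absent from the published parameter table); τ_c and S_peak magnitudes
follow the published per-patient fits.

## Thick-walled shell ground truth

For a spherical shell (reference radii r₀ < R₀) two radial reductions
are provided.

**Incompressible** (J ≡ 1): material spheres map as
ρ³ = ξ³ + (r³ − r₀³); hoop stretch λ = ρ/ξ, radial stretch λ⁻².  The
luminal pressure is the equilibrium quadrature
p = ∫ 2(σ_θθ − σ_rr)/ρ dρ with
σ_θθ − σ_rr = a·exp(b(I₁−3))·(λ² − λ⁻⁴), I₁ = 2λ² + λ⁻⁴,
evaluated by 200-node Gauss–Legendre quadrature on the reference
thickness (doubling the nodes changes p by <1e−8 relative).  Inflation
to a target pressure is a bracketed Brent root-find on the deformed
inner radius (|p − p_target| < 1e−8 kPa).  Stress profiles integrate the
equilibrium ODE by cumulative Simpson on (default) 1001 radial samples.
An optional uniform active tension S_a adds to both in-plane stresses,
contributing 2·S_a·ln(R/r) to the pressure.

**Nearly incompressible** (penalty): the same radial equilibrium with
the compressible constitutive response σ_i = κ ln J/J + isochoric part,
solved as a two-point boundary-value problem by shooting (RK45,
rtol 1e−10) on the deformed inner radius.  This matters: at ~100 kPa
hoop stress the penalty model's volumetric strain is ln J ≈ σ/κ ≈ 15 %,
so the thin-shell benchmark deforms measurably differently from the
exactly incompressible limit.  The verification tables and the
acceptance script use the penalty formulation, which is the constitutive
model of the finite-element study whose printed values they mirror; the
cycle simulator uses the incompressible reduction (physically, myocardium
is incompressible; numerically, it conserves wall volume exactly and is
an order of magnitude cheaper).  As κ → ∞ the two agree (tested).

Internal work integrates the stress power density σ : ε̇ over shell and
ramp (for the radial motion, ε̇_θθ = ρ̇/ρ, ε̇_rr = −2ρ̇/ρ, and the
deformed volume element equals the reference one); external work is the
trapezoid PV integral ∫p dV.  The two agree within 1 % on all benchmark
ramps — the conservation check that validates the stress evaluation.

### Known gaps to the published reference values

The printed reference stresses were produced by 3-D finite elements with
~1 element across the wall for the thinnest shell and 2 for the
intermediate one.  Our two independent solvers agree with each other to
≤1 % and satisfy the mean-stress identity ∫σ dV = p·V_cav·I exactly, but
the published volume-averaged *radial* stresses (−1.77/−1.16/−0.63 kPa)
are systematically smaller in magnitude than the continuum values
(−1.91/−1.55/−0.73 kPa): the radial-stress boundary condition is only
weakly enforced in a displacement FE method and its recovery across one
or two elements is necessarily inaccurate.  The thick shell's mean hoop
stress (printed 1.44 vs continuum 1.50 kPa) and the percentage
deviations derived from it inherit the same gap.  The affected
acceptance assertions are left failing rather than loosened; all
Laplace-stress columns (which depend only on the deformed geometry)
reproduce the printed values to 0.15–1 %.

## Laplace estimators

Implemented literally as stated in the introduction of the README.  The
power bracket (ṙ/r₀ + Ṙ/R₀) is a *sum* over the two in-plane directions;
a `half_strain_rate` flag exposes the averaged alternative for
sensitivity analysis.  Radii rates use central finite differences
(one-sided at endpoints), with reference radii defaulting to the first
sample (end-diastole).  IHW evaluates σ_L,⋆ at the trace maximum (the
instant of peak stress), with the volume-based variant as default —
the variant used by the clinical studies that introduced the indicator —
and T_sct measured from end-diastole to that instant.  EHP is the stated
systolic time average (1/T_sys)∫p_ao·q dt; note that with this
normalization "EHP ≈ MAP·CO" only holds when CO is read as mean
*systolic* outflow, since the integral excludes diastole.  Efficiencies
are reported as magnitudes; power generated by the wall (ejection) is
positive in all user-facing tables, and the cycle report carries one
column in the opposite (compression-positive) convention for
comparability with the literature.

## Cycle simulator (synthetic-data generator)

One heartbeat of an incompressible active Demiray sphere against a
three-element Windkessel (valve impedance Z_v in series with aortic
characteristic impedance Z_a; peripheral R_art, compliance C_art;
implicit-Euler arterial compartment).  Phases: IVC (radius frozen,
pressure rises with S_a until it reaches p_ao), ejection (implicit
per-step balance p_sphere(r, S_a) = p_ao + Z_v·q, q = −dV/dt, solved by
bracketed Brent iteration; valve closes at q ≤ 0), IVR (radius frozen,
twitch decays), filling (quasi-static pressure ramp back to EDP by the
end of the period).  Timestep 1 ms; the passive pressure–radius relation
is pre-tabulated on a 900-point cubic spline.  The trace satisfies, by
construction, exact isovolumetric volume constancy, Δp = Z_v·q during
ejection, and exact wall-volume conservation.

Default study conditions are the published pretreatment records of four
aortic-stenosis patients (volumes, cuff pressures, heart rate,
transvalvular gradient) with the published per-patient Windkessel and
active-stress fits.  `config_from_patient` sizes the reference shell so
that the cavity volume *at* the end-diastolic pressure (default
1.33 kPa = 10 mmHg, a typical estimate; the source records carry none)
equals the record's EDV, takes the wall volume from the mean equatorial
wall thickness, and bisects S_peak until the simulated ejection fraction
is within ±5 % (relative) of the record's — the same fitting tolerance
the reference study used.  The patient-like passive stiffness default is
a = 2 kPa, b = 8 (softer than the a = 10 benchmark material, in line
with the sub-kPa stress scales fitted to patients).

Surface emission: concentric icospheres at the exact deformed radii
(`sphere` mode), or volume-matched prolate spheroids (`prolate` mode,
default for the comparison) with end-diastolic long/short axis ratio 1.8
and long semi-axis ∝ (V_cav/EDV)^0.15 — about 12 % longitudinal
shortening at EF 60 %, so the short axis carries most of the
contraction, as in a real LV.  The prolate mode exists because the
estimator disagreements under study are driven by nonsphericity: on an
exact sphere σ_L,V ≡ σ_L,H algebraically and the published ordering
P_int,V > P_int,h > P_int,H cannot arise.  Measurement noise is
available only through an explicit seed-controlled call; the simulator
itself is deterministic and bit-reproducible.

### What the generator does and does not emulate

It reproduces the magnitudes and temporal structure of the clinical
records (volumes, ejection fraction, pressures, transvalvular gradient,
cycle phases) and exact energy bookkeeping, so passing tests demonstrate
the estimators' behavior under controlled, perfectly known geometry.
It does not emulate regional heterogeneity, fiber architecture, atrial
or right-heart interaction, valve dynamics beyond a linear impedance, or
imaging noise — so quantitative error levels on real patients can be
larger than those measured here, and per-patient published power values
are out of reach by construction.

## Short-axis slicing

PCA of the endocardial vertex cloud gives the long axis (sign fixed so
the wider cross-section, the base, is +z; for a perfect sphere the axis
is arbitrary but the operation succeeds).  Slices of width 8 mm are
anchored at the axial centroid, keeping one slice width clear of apex
and base — the analog of excluding apical short-axis images, where the
cross-section reads surface curvature rather than chamber radius; this
margin is also what lets a sphere's mean slice radius recover its true
radius.  In each slice, 40 rays (Δφ = 9°) are cast from the axis point;
first hits on the endo- and epicardial surfaces give r_ij and
R_ij (vectorized Möller–Trumbore intersection; the polar-angle origin is
anchored to the endocardial PCA frame so that results are
rigid-motion equivariant for generic shapes).  Slices where any ray
misses either surface are dropped and logged.  Per-slice and multi-slice
means are plain arithmetic averages.  For a deforming surface sequence
the comparison pipeline determines the slice layout once and restricts
to the slices usable in every frame, keeping the derived radius and
wall-width traces free of slice-count discontinuities (the published
workflow's "constant distance to the LV center" rule).  PLY/STL surface
input is supported through trimesh.

## Numerical choices and degenerate inputs

Tolerances: inflation root-find 1e−12 on radius (pressure residual
<1e−8 kPa); ejection step root-find 1e−10 on radius; penalty BVP
rtol 1e−10.  Degenerate cases: zero target pressure returns the
reference state exactly; S_peak = 0 yields a beat with no ejection
(SV = 0) rather than an error; an EF target of 0 returns a passive
configuration; slicing a sphere accepts the arbitrary PCA axis; rays at
grazing incidence drop their slice rather than biasing it.  Problem
sizes used by the shipped analyses: 1001-sample stress profiles,
41-step inflation ramps, 1 ms cycle timestep with 10 ms analysis stride,
subdivision-3 icospheres (1280 faces) for the cycle meshes and
subdivision-4 for the slicing accuracy checks — chosen so each
experiment completes in seconds while all stated tolerances hold with
margin.

## Limitations

The ground truth is a sphere; the comparison isolates thin-wall,
radial-stress and strain-rate errors of Laplace analysis but not
shape-heterogeneity errors, which require 3-D anatomy.  The prolate
surface kinematics are volume-consistent but prescribed, not solved.
Windkessel parameters are used as published rather than refitted to the
synthetic flow waveforms, so simulated aortic pressures run above the
cuff recordings at matched ejection fraction (the transvalvular gradient
magnitudes remain representative).
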