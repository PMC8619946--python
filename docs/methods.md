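# Methods

This note records the modeling assumptions behind `dpitrack`, the defaults
that matter, the numerical choices, and what the synthetic test conditions
do and do not establish about real devices.

## Scope and philosophy

The package implements the *particle side* of inhaler aerosolization. The
carrier airflow is deliberately not solved: resolving the turbulent flow in
a real device geometry requires a RANS (or finer) CFD solver and a
proprietary CAD model. Instead, any steady velocity field satisfying a small
contract (`velocity(x)`, optional `velocity_gradient(x)`) can drive the
tracker — an analytic stand-in shipped with the package, or an externally
computed field sampled on a structured lattice. All of the bespoke physics
(capture-velocity sticking, rolling/sliding detachment, the aerodynamic
performance analysis) is independent of where the field comes from.

## Geometry stand-in

The device interior is modeled as two coaxial cylinders joined at a thin
perforated grid plane: a capsule/swirl chamber (radius 14.0 mm, i.e. the
28.0 mm maximal width) below a mouthpiece duct (radius 5.0 mm from the
10.0 mm outlet) up to the 47.5 mm total height. The chamber/grid split is
not a published dimension; the default 25.0 mm leaves a mouthpiece of
realistic length and is freely configurable. Particles are released 12 mm
above the chamber floor, matching the virtual release surface placed a
short distance downstream of the powder storage.

The grid is a zero-thickness plane with an open-area fraction (porosity,
default 0.6): a particle crossing inside the open bore impacts the lattice
with probability 1 − porosity, decided by a seeded draw; the annular
shoulder around the bore is solid and always impacts. Real grids have bar
geometry and secondary flow structures that this model cannot produce.

## Analytic flow field

The stand-in field is built from an axisymmetric stream function, so
incompressibility, the no-penetration condition at every wall, and an axial
flux equal to the volumetric flow Q hold *exactly*, not just to quadrature
tolerance. The through-flow is a Poiseuille-profile stream tube that spans
the chamber low down and contracts smoothly (cubic smoothstep over the top
40% of the chamber) to the mouthpiece bore; outside the tube the corner
region is quiescent. A solid-body-rotation swirl `u_θ = S·U_ch·(r/R_c)`
decaying linearly to zero at the grid represents the tangential-inlet swirl
(swirl number S, default 2). At 60 L/min the cross-section-averaged outlet
speed is Q/A = 12.73 m/s, the value implied by the operating point.

A flat plug profile joined directly to the mouthpiece would push the entire
flow into the grid shoulder and retain nearly all powder; the converging
core is what lets the stand-in reproduce the qualitative transport pattern
(swirl carries powder to the bore and out) at zero computational cost.

The velocity gradient — needed only for the small Saffman lift term — is
evaluated by central finite differences (step 1e-7 m) on the exact field;
for lattice fields it is tabulated with `numpy.gradient` and interpolated.

Limitations: no turbulence and no turbulent (eddy-interaction) dispersion of
particles; steady flow only (a reasonable stand-in for the plateau of an
inhalation maneuver); the swirl does not satisfy no-slip at the chamber
wall, a known idealization of solid-body rotation.

## Powder model

Formulation inputs are the volume quantiles d_v10/d_v50/d_v90 (µm), the
span, and the pycnometric true density. The size law is Rosin–Rammler;
since the quantile relation is log-linear, the two parameters come from
ordinary least squares on the three log-quantiles (exact round-trip when the
inputs are RR-consistent; residual reported otherwise). Sampling is
inverse-CDF with rejection outside [d_min, d_max], defaulting to
[d_v10/2, 1.5·d_v90] in the manner of solver-style RR injections.

Because the fitted law is volume-weighted, each sampled particle is an
*equal mass parcel* of the dispersed dose. Stage-binned panels of simulated
aerosols therefore weight parcels equally; weighting each sphere by its own
physical mass ∝ d³ would apply the volume weighting twice and bias MMAD
coarse by several µm. Fate summaries are reported under both number and
physical-mass weighting, and the two differ exactly when fate correlates
with size (as it does: coarse particles bounce more and are centrifuged
harder).

The aerodynamic diameter uses the standard convention
d_ae = d_g·√(ρ_p/ρ₀), ρ₀ = 1 g/cm³, with slip and shape factors of unity.

## Particle–wall interaction

Sticking: impacts with wall-normal speed v_n ≤ v_cr deposit; the tie is
resolved toward sticking (conservative, since the published criteria are
strict inequalities on both sides). v_cr = (2E/d_p)^(10/7) with the El
Batch parameter E assembled from the elastic compliances of the wall
(E_s = 4.1 GPa, ν_s = 0.35) and particle (E_p = 1 GPa, ν_p = 0.40) and the
particle density. For a 5 µm, 1050 kg/m³ particle v_cr ≈ 1.60 m/s; at 10 µm
it falls to 0.60 m/s — fine particles stick on almost any impact, coarse
particles rebound from all but grazing contacts. Rebounds keep their
tangential velocity and reverse the normal component scaled by a constant
restitution e_n (default 0.8; the source criteria state only that rebound
speed is reduced).

Detachment closures not fixed by the published criteria are standard
adhesion mechanics, each isolated in its own function so alternatives can
be swapped: JKR pull-off force F_st = (3/4)π W_A d_p; JKR zero-load contact
half-width a = [9π W_A (d_p/2)²/(2K)]^{1/3} with K = (4/3)/[(1−ν_s²)/E_s +
(1−ν_p²)/E_p] and chordal flattening b = a²/d_p; near-wall Stokes drag
F_D = 3πµ d_p u_rel f/C_u with the tabulated near-wall correction f = 1.70;
Saffman shear lift (switchable off). The fluid state entering these forces
is evaluated **one particle radius from the wall**, where viscous no-slip
makes the tangential slip far smaller than the bulk speed.

With the default constants and the 60 L/min field, neither the rolling
moment balance nor the sliding friction balance is ever met for
d_p ∈ [1, 13] µm: deposition is permanent, and the tracker's single
detachment re-test at the moment of sticking (legitimate because the field
is steady, so the force system never changes afterwards) always returns
"remains stuck". The margin is not unlimited: if the *bulk* speed were
applied directly at the particle center, the rolling inequality would flip
near u_rel ≈ 18 m/s for a 5 µm particle (≈ 13 m/s at 13 µm). The near-wall
evaluation rule is therefore load-bearing and is stated here explicitly.

## Tracking numerics

The velocity update is the closed-form solution of the linear drag
equation, v⁺ = u + (v − u)e^(−dt/τ), with the matching exact position
integral; it is unconditionally stable, and for dt ≫ τ simply locks the
particle to the streamline. The step is dt = τ/5 capped by a geometric CFL
(≤ 0.2 mm displacement per step, the accuracy-controlling constraint near
walls) and floored at 1 µs — for ~1 µm particles τ/5 would shrink the step
far below what trajectory accuracy requires at pure cost. Halving both the
cap and the floor moves the mass-weighted emitted fraction of the reference
run by well under 2 percentage points (it is bitwise identical in the
default scenario, because collisions are resolved geometrically on segment
crossings rather than on step boundaries).

Wall events are found as the first crossing of the straight sub-step
against the region's cylinder, the chamber floor, the grid plane, or the
outlet plane, so no impact can be stepped over. Fates partition the
injected count exactly: emitted + permanently stuck + still airborne at
max_time (default 0.5 s of steady flow; particles that time out are
reported separately, never folded into EF). Runs are deterministic given
the seed, which drives size sampling, injection positions, and grid
porosity draws from a single generator. Gravity is off by default
(switchable); at these Stokes numbers it is negligible over device
residence times.

## Impactor analysis

Stage binning assigns each particle to the first (largest-cut-off) stage
whose cut-off is at or below its d_ae — stage bins are [c_i, c_{i-1}) with
the top stage unbounded above, as in a physical impactor where everything
too coarse to pass a stage deposits on it. The default cut-offs are the
standard next-generation-impactor values at 60 L/min (8.06, 4.46, 2.82,
1.66, 0.94, 0.55, 0.34 µm), fully configurable.

The cumulative undersize curve (denominator: all aerosol mass past the
device, so induction-port deposit counts as failing the top cut-off) is
interpolated piecewise-linearly on probit vs log₁₀(diameter). MMAD is the
probit-zero crossing — equivalent to linear interpolation between the
stages flanking the 50th mass percentile — and GSD = √(d_84.13/d_15.87)
reads the curve one probit unit either side, which is exact for lognormal
aerosols. Extrapolation beyond the measured stages is refused for the MMAD
and FPD; a GSD whose flanking percentiles fall outside the stages is
reported as NaN rather than extrapolated. FPD is the emitted dose times the
undersize at the respirable cut-off (5 µm by default; 6.4 µm reproduces the
twin-stage-impinger convention), and FPF = 100·FPD/ED, EF = 100·ED/MD.

## Comparison statistics

RMSE = √(Σ(Pᵢ−Oᵢ)²/N), NRMSE = RMSE/mean(O) (normalized by the *reference*
mean, hence not symmetric), and R² is the squared Pearson correlation of
the paired values — the convention matching correlation-diagram comparisons.
Regression-through-origin R² is a defensible alternative; squared Pearson
was chosen because the compared quantities (EF, MMAD, GSD, FPF pairs across
formulations) are plotted as scatter correlations, not forced through zero.

## What the synthetic conditions show — and do not

The reference conditions are the study's: five formulations with published
micromeritics, 100-particle runs (particle counts beyond ~100 change the
statistics, not the mechanisms), 60 L/min, tabulated material constants.
Passing tests establish that the implemented physics is internally
consistent, matches arbitrary-precision evaluation of its own laws,
conserves particles and mass exactly, and recovers known size
distributions through the full analysis chain. They do *not* validate the
stand-in flow field against a real device: absolute deposition splits,
EF values (≈ 78–95% across seeds for F1, straddling the 83–92% range
reported for RANS-driven simulations) and regional fractions inherit the
idealized geometry and laminar steady flow, and should be read as
qualitative. Agglomeration, electrostatics, capsule-emptying dynamics,
particle–particle collisions (volume fraction ~1e-4) and particle breakage
are all outside the model.
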