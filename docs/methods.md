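# Methods

## Scope and model

`pwdb` generates pulse waves (pressure P, flow velocity U, luminal area A,
volume flow Q = U·A, and photoplethysmogram PPG) for virtual subjects whose
cardiovascular properties follow the typical aging of healthy adults
between 25 and 75 years. The model has three parts: a 1D arterial network
of thin, linearly tapered, viscoelastic vessels; a prescribed periodic
aortic-root inflow carrying the cardiac parameters; and three-element
(RCR) windkessel outlets representing the vascular beds.

Assumptions: laminar, incompressible, Newtonian blood (ρ = 1060 kg/m³,
μ = 2.5 mPa·s); axisymmetric flow with a parabolic velocity profile
(momentum correction α = 4/3, wall friction −8πμQ/(ρA); a flat-profile
option with α = 1 and −22πμQ/(ρA) is available); no energy loss at
bifurcations (total pressure P + ρu²/2 continuous); Voigt wall
viscoelasticity; no venous circulation, autoregulation, curvature or
vessel collapse.

### Tube law and wall parameters

P(A) = P_d + (β/A_d)(√A − √A_d) + Γ/(A_d√A_d)·dA/dt with
β = (4/3)√π·Eh, which makes the linearized wave speed at A = A_d equal
c_d = √(2Eh/(3ρR_d)) exactly. Stiffness follows
Eh(R_d) = R_d(k₁e^{k₂R_d} + k₃); the constants are conventionally quoted
in CGS (k₁, k₃ in g·s⁻²·cm⁻¹; k₂ in cm⁻¹) and converted to SI at the
configuration boundary (1 g·s⁻²·cm⁻¹ = 0.1 N/m², 1 cm⁻¹ = 100 m⁻¹); all
internal computation is SI. Wall viscosity Γ = b₁/(2R_d) + b₀ with
b₁ = 150 g·cm/s, b₀ = 600 g/s, age-invariant. The diastolic reference
pressure P_d is the age's diastolic blood pressure, at which the
(diastolic) radii are prescribed.

### Inflow

One cycle of duration T = 60/HR: a sinusoidal rise to the peak at PFT, a
cosinusoidal decay crossing zero at LVET, a sin² reverse lobe carrying the
reverse flow volume RFV, zero flow in diastole; the forward lobe is scaled
so the net cyclic integral equals SV (forward volume = SV + RFV). The
remaining shape features are held fixed across subjects and ages. LVET
covaries with HR and SV through LVET = 244 − 0.926·HR + 1.08·SV (ms),
applied in *deviation* form about the 282-ms age mean: the reported
population LVET (~283 ms) is inconsistent with the raw regression value at
baseline HR/SV (~249 ms), so the regression supplies the *slopes* only.
An `lvet_mode="absolute"` switch evaluates the regression directly.

## Aging model

Per-decade anchors (25…75 yr) for every input parameter are shipped as
data (`pwdb/data/aging_tables.json`), not code: means and SDs for HR, SV,
LVET, PFT, RFV, MAP, DBP, proximal aortic length, aortic diameters
(ascending / descending-thoracic / abdominal), carotid diameter, regional
PWV targets (aortic, arm, leg; SDs may be asymmetric) and peripheral
vascular compliance (PVC). Interpolation between anchors: shape-preserving
PCHIP for the HR mean, cubic spline for the MAP mean with linear SDs,
linear otherwise; anchors are reproduced exactly. Prescribed rows pinned
by the shipped tables: proximal aortic length 80.0→112.0 mm and PVC
40.1→17.3 ×10⁻⁹ m³/Pa across 25→75 yr, both linear per decade. The
carotid diameter anchors (6.1→7.0 mm) are literature-typical values, as
the source tables do not print them.

Six parameters shape the waves strongly and are varied in the database:
HR, SV, LVET, diameter, PWV, MAP. "Diameter" is a single factor moving
all age-varying diameters (aorta + carotid) coherently by their
age-specific SDs; "PWV" moves the aortic/arm/leg targets together. A
database enumerates all 3⁶ = 729 offset combinations per age
(deterministic order: HR, SV, LVET, diameter, PWV, MAP, last fastest,
each −1/0/+1), 4 374 subjects for six decades.

### MAP dependence of the stiffness target

Arterial stiffness rises with distending pressure, so a subject's aortic
PWV target is evaluated at their MAP: target(age, MAP) = target(age) +
s·(MAP − MAP_mean(age)). The sensitivity s defaults to 0.10 m/s per mmHg,
derived from population reference tables of carotid-femoral PWV by age and
BP category (≈3 m/s spread over ≈25–30 mmHg of mean pressure between
optimal and grade-II-hypertensive categories). The arm/leg targets scale
by the same ratio. This coupling is what the PP-based cardiac-output
algorithm's compliance ∝ 1/MAP assumption probes (case study 3).

### Per-subject calibration

* **Stiffness**: (k₁,k₂,k₃) are fitted (deterministic least squares, fixed
  initial guess) so that the *harmonic-mean* wave speed along the aortic
  path, L/Σ(dx/c_d), equals the subject's aortic target, with point
  anchors at representative arm (2.0 mm) and leg (2.5 mm) radii. The
  harmonic mean is what a foot-to-foot transit measurement observes on a
  tapered path; anchoring a single aortic radius instead biases the
  simulated PWV. A plain single-anchor fit
  (`calibrate_stiffness`) is also provided and property-tested.
* **Resistances**: required total R_T = (MAP − P_out)/CO (P_out = 0 mmHg
  by default, venous pressure neglected). Outlet R1 is the terminal
  segment's characteristic impedance ρc_d/A_d (reflection-minimizing);
  bed totals are scaled uniformly from baseline proportions by a scalar
  root-find on the *tree's* equivalent resistance (including segment
  Poiseuille resistance), so the simulated MAP lands on target without
  iteration; within a multi-outlet bed, per-outlet resistance ∝ 1/A.
* **Compliances**: per-outlet C scaled from baseline proportions so the
  total equals the age's PVC.

## The reduced network fixture

The full anatomical table behind the published 116-segment geometry is not
redistributed; the package ships a 13-segment anatomically shaped network
generated by code: the aorta in four tapering pieces (ascending, arch,
descending thoracic, abdominal — radii from the per-age diameter tables,
continuous across junctions), a head path (carotid → temporal), an arm
path (subclavian-brachial → radial + ulnar), a leg path (iliac-femoral →
tibial), and splanchnic/pelvic trunks. Measurement sites: aortic_root,
carotid, brachial, radial, femoral, ankle, iliac_bifurcation, finger
(PPG), temporal (PPG). Baseline bed flow fractions: head 0.04, arm 0.06,
splanchnic 0.50, pelvic 0.34, leg 0.06 (single head/arm/leg paths; the
visceral trunks absorb the contralateral/deep-branch flow so mean
velocities stay physiological).

Two deliberate equivalent-lumping choices, both off every PWV measurement
path:

* **Visceral trunks as compliance reservoirs.** Lumping ~100 conduit
  arteries into windkessels deletes their volume compliance (~3×10⁻⁹
  m³/Pa at 25 yr, estimated from ΣA·L/(ρc²) over the lumped vessels and
  cross-checked against the published cohort time constant SVR·C ≈ 1.3 s)
  and inflates central pulse pressure by ~60%. The splanchnic and pelvic
  trunk walls are therefore softened (Eh × 0.10) to carry that compliance
  explicitly. With it, the baseline cohort reproduces the expected aging
  signature: PP 30→43 mmHg, PP amplification 1.38→1.08 (strictly
  decreasing), carotid AIx −4→+45% (increasing), AGI_mod −1.5→−0.9.
* **Tiny distal compliance shares.** Distal beds (finger, temporal,
  ankle) receive ~0.1% of PVC so their windkessel time constant is short
  and the stored-volume PPG tracks the local pressure wave instead of
  integrating it into a featureless hump.

A 3-segment "tiny" fixture exists for solver unit tests.

## Numerics

* MacCormack predictor–corrector (forward/backward differences) on (A, Q)
  per segment; CFL 0.7 on the hyperbolic speed with 35% systolic headroom.
* Boundary conditions via the quasi-invariants W = u ± 4(c − c_d),
  interpolated at the characteristic foot and advanced with their
  analytic taper/friction source (which vanishes identically at rest).
  They are applied to the predictor state as well as the corrector state:
  boundary-flux consistency is what keeps the per-cycle mass defect small
  on tapered segments.
* Viscoelastic term by operator splitting: an implicit (backward-Euler,
  tridiagonal) diffusion substep on Q with diffusivity A·Γ/(ρA_d√A_d), so
  dt is set by the CFL condition alone. Reported pressures include the
  viscous term −Γ̃·∂Q/∂x (giving the positive P–A hysteresis loop area
  that vanishes when Γ = 0).
* Node spacing ≤ 2.5 mm (minimum 3 nodes/segment): at this resolution the
  per-cycle mass-conservation residual is ≤ 0.35% of stroke volume and
  the simulated MAP sits within ~1.5 mmHg of its calibration target.
* Initialization: windkessel pressures and (A, Q) warm-started from the
  steady resistive solution at the mean inflow; convergence when the
  relative L∞ change of root pressure between consecutive cycles
  < 10⁻³ (max 20 cycles, flagged otherwise). Typical run: ~10 cycles,
  ~10⁴ steps/cycle, a few seconds per subject (numba kernels).
* Pressures are Pa internally, mmHg externally (1 mmHg = 133.322 Pa);
  output waves are resampled to 500 Hz.

## Pulse wave analysis

Derivatives by Savitzky–Golay local polynomials (window 9 samples at
500 Hz, scaled with fs; 3× wider for the PPG second derivative, whose a–e
waves ride on subtle curvature). Fiducial points per cycle:

* **Foot** by intersecting tangents: the diastolic-minimum horizontal
  crossed with the tangent at the steepest point of the *initial*
  upstroke. The tangent point is the d1 maximum within 40 ms of the
  upstroke onset (the d2 maximum in the low-amplitude region preceded by
  a stretch of diastolic pressure). Anchoring at the onset matters for
  stiff central waves, whose slope keeps growing through systole as
  reflections superpose; a global max-slope tangent lands mid-rise and
  biases feet ~20 ms late. Alternative foot estimators (minimum, max-d2)
  reduce to parts of the same machinery.
* **P1/P2** by wave-type classification: if the systolic peak lags the
  foot by more than 160 ms the wave is A-type (P2 = peak; P1 = preceding
  local maximum or rising-edge shoulder, a d1 local minimum on the rise),
  otherwise C-type (P1 = first systolic maximum; P2 = following maximum
  or falling-edge shoulder). Absent shoulders are reported missing, never
  fabricated.
* **Dicrotic notch**: first local minimum after the last systolic peak
  (else the strongest d2 maximum in that window); **diastolic peak**: the
  local maximum after it, if any.
* **a–e waves**: dominant max/min/max/min/max sequence of the smoothed
  PPG second derivative within systole.

Indexes: SBP/DBP/MAP/PP; PP_amp = PP_brachial/PP_aortic; AP = P2 − P1,
AIx = 100·AP/PP, Tr = t(P1) − t(foot); RI (diastolic/systolic PPG
amplitude), SI = height/Δt(systolic→diastolic peak) with a constant
1.75-m height (the network has no subject height; SI ∝ 1/Δt preserves
correlation analyses), AGI_mod = (b − c − d − e)/a; foot-to-foot PTT/PWV
over the aortic, carotid-femoral, brachial-radial and femoral-ankle paths
(path lengths from the network topology); flow-derived SV, CO, LVET, PFT,
RFV, dP/dt_max, and flow volumes/velocities at t(P1), t(P2).

## Case studies

1. **PP amplification with age**: PP_amp decomposed with aortic P1/P2 into
   an early systolic amplification component PP_b/(P1_a − DBP_a) and a
   late systolic augmentation component PP_b/(P2_a − DBP_a).
2. **PPG stiffness surrogates**: R² (squared Pearson r) of RI/SI/AGI_mod
   against the reference foot-to-foot aortic PWV over the plausible
   subjects (all ages or one age), plus one-at-a-time relative sensitivity
   indexes I = 100·(index(+1 SD) − index(baseline))/index(baseline).
3. **Cardiac output monitoring**: two radial pulse-contour estimators —
   CO = k·RMS(P − mean P) (pulsatile RMS; raw-RMS switch available) and
   CO = k·PP/(T(SBP+DBP)) — calibrated on each age's baseline subject and
   scored by MAPE over single-parameter HR/SV (the "CO" group) and MAP
   variations. Study cohort: 6 ages × (baseline + 6 offset subjects) = 42
   simulations.

### A known, documented discrepancy in case study 3

On this reduced network the PP algorithm is robust to MAP changes (MAPE
≈ 0.7% vs ≈ 9.6% for RMS — the expected ordering, because the strong
stiffness–MAP coupling makes arterial compliance ∝ 1/MAP, which is
exactly what the PP algorithm normalizes away) but the RMS algorithm does
*not* track CO under HR changes, so RMS is not the better algorithm
overall here. The reason is structural: with a prescribed inflow and
per-subject resistance calibration to a fixed MAP target, an HR offset
rescales both the cycle length T and the time constant τ = R·C by the
same factor, leaving the waveform shape and pulse pressure nearly
unchanged — in the lumped-parameter limit the radial pulsatile RMS is
HR-blind. Full-scale anatomical networks exhibit frequency-dependent
amplification toward the arm that can restore RMS–CO tracking; the
13-segment fixture does not resolve it. The corresponding acceptance test
asserts both orderings and is expected to fail on "RMS better overall";
this is a scale limitation of the fixture, not of the implementation.

## What the synthetic population does and does not show

The generator reproduces the *prescribed* physiology (cardiac parameters,
calibrated MAP and PWV, deterministic ±1 SD grids) and the qualitative
aging of the *emergent* wave morphology (rising PP, SBP and augmentation;
falling PP amplification; PPG aging signatures). It does not reproduce
the absolute cohort statistics of a 116-segment network (central PP runs
~15–20% high; Tr falls faster with age because the aortic path is
shorter), does not model inter-parameter correlations beyond the LVET and
PWV–MAP couplings, holds blood properties and wall viscosity
age-invariant, and contains no measurement noise — clean signals flatter
any fiducial-detection algorithm relative to in vivo data.

## Problem sizes used by the tests and acceptance script

Tests simulate the six baseline decades once (session fixture), the
42-run CO-study cohort, a 3-subject single-parameter database, and
assorted single tubes; the acceptance script evaluates the aging tables
and one baseline 25-yr subject. A full 4 374-subject database is a
`pwdb database` run of a few hours on one core and is not exercised by
the test suite.
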