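# Methods

## Scope and model overview

`augerdose` estimates the absorbed dose delivered by the emissions of
Cu-64 — β⁻ and β⁺ particles, Auger electrons and characteristic X-rays —
to spherical water volumes containing a uniformly distributed source,
and propagates that dose through a chemical-dosimetry validation chain
(coumarin-3-carboxylic acid, C3CA) and a biological-effectiveness chain
(D10, RBE). It is a desk-scale condensed-history model, not an
event-by-event track-structure code: the quantities it is built to get
right are containment fractions, component ratios and their dependence
on sphere volume, which are governed by the ratio of particle range to
sphere radius.

## Physics data

**Electron stopping power.** A single packaged table spans 7.4 eV–1 MeV
for liquid water. Rows at and above 10 keV follow the Berger–Seltzer
collision stopping-power formula (mean excitation energy I = 75 eV,
Z/A = 0.55509; density effect and radiative losses neglected — both are
below 2% in this energy span), renormalised by +1.5% so that the
integrated CSDA range at the 0.573 MeV β⁻ endpoint equals the standard
2.1 mm. Rows below 10 keV are a track-structure-motivated compilation
constrained to the canonical low-energy anchors of liquid water: a
stopping-power maximum of 26 keV/μm at 150 eV, ≈ 7–8 keV/μm at 2 keV,
and a CSDA range of 120 nm for a 2 keV electron. These three anchors
cannot be met simultaneously by a smooth log–log interpolation of the
two LET values alone (that gives ≈ 190 nm); the table therefore carries
a broadened stopping maximum through 0.3–1.4 keV. The range integral is
the binding constraint; the 2 keV LET sits 11% above its nominal anchor,
within the tolerance we accept for sub-keV electron data, where
published liquid-water stopping powers themselves disagree by tens of
percent.

**CSDA ranges** are computed once as a cumulative trapezoid of 1/S(E) on
a 6000-node logarithmic grid (stable to < 0.01% under node doubling) and
interpolated for queries; the inverse map (residual energy at a given
consumed range) is interpolated from the same grid. Energies at or below
the 7.4 eV cutoff have zero range by definition; energies above 1 MeV
raise a range error rather than extrapolate.

**Photon attenuation.** Mass attenuation coefficients of water over
0.5–10 keV, log–log interpolated. Rows ≥ 1 keV are standard evaluated
values; 0.5–1 keV extends the above-edge photoelectric E⁻³ branch, which
only serves the weak 0.85 keV l line (absorbed within microns
regardless). The 7.5 keV attenuation length evaluates to 794 μm.

## Decay scheme

Branching ratios: β⁻ 40% (endpoint 0.573 MeV, daughter Zn, Z = 30), β⁺
19% (endpoint 0.656 MeV, daughter Ni, Z = 28), electron capture 41%.
β spectra use the allowed shape p·E_tot·(Q−T)²·F(Z,T) with the
nonrelativistic Coulomb factor F = 2πη/(1−e^(−2πη)), η = ±Zα/β, sampled
by inverse CDF on a 2048-point grid. Spectrum means evaluate to 0.190
(β⁻) and 0.283 MeV (β⁺), giving a mean emitted electron energy of
0.130 MeV per decay.

Electron capture leaves a K vacancy with probability 0.88; the vacancy
fluoresces with the Ni K fluorescence yield 0.41, else it de-excites by
Auger emission. These two defaults reproduce the scheme-level emission
fractions: 0.41 × 0.88 × 0.59 = 0.213 of decays emit Auger electrons
("22%"), 0.148 emit an X-ray. X-ray lines (l 0.85, kα1 7.48, kα2 7.46,
kβ1/kβ3 8.27 keV) are sampled by the relative weights of their published
per-decay fractions; because those published fractions sum to 0.164
rather than 0.148, the absolute per-decay line yields of this scheme are
≈ 10% below the published ones — the two published numbers are not
mutually consistent and we keep the vacancy/fluorescence factorization.

**Auger cascade representation.** One electron per Auger relaxation,
drawn from a discrete five-line spectrum (0.11–7.46 keV) with mean
2.0 keV. A real KLL/LMM cascade emits several electrons totalling the
K-shell binding energy; collapsing it to a single representative
electron matches the per-decay Auger energy budget implied by the
emission fractions (0.213 × 2 keV ≈ 0.43 keV/decay) and the measured
component ratios, which is what the dose model needs. Multiplicity is
therefore deliberately not modelled. Neutrinos and the 0.5% 1.346 MeV
gamma are omitted (negligible local deposition).

## Transport

Straight-ray condensed-history transport. Each electron advances along
its emission direction; per step the energy loss is bounded by a maximum
fractional loss (default 5%) *and* the step length by ⅛ of the sphere
radius, whichever is smaller. The geometric bound matters: at 0.5 MeV an
energy-limited step is ~140 μm and would skip over micron-scale spheres
entirely, mis-scoring the β dose there. Step length is the CSDA path
consumed times a detour factor (default 1.0 = straight CSDA tracks;
0.8 emulates multiple-scattering path shortening and raises containment
by a few percent at mm scales). Step energy is scored at the step
midpoint, inside or outside the sphere; below the 7.4 eV cutoff the
residual deposits locally. Because tracks are straight and sources start
inside, the ray crosses the boundary exactly once; residual energy past
the exit point is flushed as escaped in a single step, which makes the
cost per particle O(min(steps-to-exit, energy steps)) and is exact.
Energy is conserved identically (inside + escaped = emitted, tested to
1e-6 relative). δ rays are not produced; continuous loss along the
primary is a known bias at the smallest volumes.

Characteristic X-rays sample an exponential interaction depth with the
tabulated attenuation length and deposit their full energy at the
interaction point (the photoelectron range is far below the sphere radii
at which photons are relevant) or escape. The two 511 keV annihilation
quanta of each β⁺ are escape-only (mean free path ≫ any simulated
sphere) and tallied separately from the dose components.

**Dose normalisation.** Each tally reports

* `dose_per_decay` = E_inside × 1.602 × 10⁻¹³ / (mass × n_decays), the
  dose from a single decay of the uniformly distributed source, and
* `dose_per_decay_density`, the dose per unit decay density
  (Gy per decay/μL), proportional to the contained-energy fraction.

The second is what a constant activity-concentration experiment
measures (decays scale with volume, so the volume factors cancel); it
grows monotonically to the full-absorption plateau and is the quantity
used for volume-to-volume dose ratios, e.g. the ×1.11 rise from 10 to
30 μL at 10⁵ decays per volume. At 30 μL it evaluates to
1.68 × 10⁻⁸ Gy/(decay μL⁻¹).

**Reproducibility.** Every volume point draws from its own stream,
`default_rng([master_seed, volume_index])`, so sweeps are reproducible
independent of ordering.

**Full-absorption limit.** With straight tracks, ~5% of β energy still
escapes even the largest (10³ μL, 6.2 mm radius) sphere — the 2.1–2.6 mm
endpoint ranges are not negligible against 6.2 mm. The analytic
full-absorption limit (dose = mean emitted energy / mass) therefore
holds exactly only for components whose range is far below the radius;
tests assert it for the Auger component and validate the β component
against an independent 2-D quadrature of the same straight-ray
containment model instead.

## Chemical dosimetry

All conversions are linear and homogeneous. Measured 7OH-C3CA
concentration ÷ 0.047 (± 0.006) gives the hydroxyl-radical
concentration; with G(OH) = 2.7 per 100 eV for Co-60 gammas, 1 Gy in
water produces 2.80 × 10⁻⁷ mol/L of OH, so dose reconstruction is
concentration / (0.047 × 2.80 × 10⁻⁷ M/Gy). Calibration series are fit
by ordinary least squares; the copper-chloride correction factor is the
ratio of the buffer to copper-chloride slopes (2.6 by default),
propagated first order, and guarded against double application. The
"linear portion below 30 μL" is implemented as an inclusive x ≤ 30 μL
bound (configurable). Chlorine scavenging kinetics are deliberately
absorbed into the single empirical factor. Per-decay normalisation uses
constant-activity counts N = A·t by default, with an optional
half-life-corrected mode N = (A/λ)(1 − e^(−λt)).

## D10 and RBE

D10 extraction defaults to a linear-quadratic fit of −ln SF (β
constrained non-negative, positive root of αD + βD² = ln 10) when four
or more points are available, log-linear interpolation otherwise; data
not spanning SF = 0.1 raise an extrapolation error rather than
extrapolate. RBE is the gamma-reference D10 over the test D10; tables
keep full precision internally and round half-up to 2 d.p. only at
serialization. The packaged reference table lists D10 and published RBE
for CHO wild-type and xrs5 cells under gamma rays, protons, carbon and
iron ions and Cu-64; for Cu-64 the published RBE (2.53 / 1.12) differs
from the plain D10 ratio (2.86 / 1.28) and both are reported side by
side, never reconciled. Likewise the published absolute D10 values are
carried as reference constants, not recomputed: only their ratio is
arithmetically derivable from the activity ratio.

## Synthetic data

Generators emulate the three measurement types with multiplicative
Gaussian noise (default CV 5%) for concentrations and lognormal noise
for survival; each dataset embeds its generating truth, and identical
seeds produce identical bytes. Study conditions are fixed at their
experimental values: 6.2 Gy/min gamma exposures (1–6 min grid), slope
ratio 2.6, the 10–60 μL volume series at 0.2 MBq per 10 μL over 24 h
(1.728 × 10⁹ decays/μL), and LQ survival (defaults α = 0.15 Gy⁻¹,
β = 0.04 Gy⁻², D10 ≈ 5.9 Gy). The default volume-series dose model is a
parametric stand-in for the transport sweep, φ(V) = V^⅓/(V^⅓ + 0.85)
times the full-absorption specific dose, with the containment constant
calibrated once against the package's own 10⁵-decay Monte Carlo; its
concavity is what produces the positive extrapolated intercept of the
sub-30 μL linear fit. What the generators do *not* emulate: HPLC signal
processing, plating-efficiency statistics, volume-dependent geometry
effects of real PCR tubes (the simulation is a sphere), and any
dose-rate dependence — passing recovery tests show the estimators are
consistent under the assumed noise model, not that real measurements
obey it.

## Problem sizes and tolerances

Monte Carlo checks run at 10⁵ decays per volume for headline ratios
(the study's own event count) and 2–3 × 10⁴ for property tests; binomial
or per-decay-variance 3σ bands are used throughout. Deterministic
anchors are asserted at the precision they are quoted with (2
significant figures). The full test suite runs in well under a minute
on one CPU.

## Known limitations

* No angular deflection or δ-ray production; containment at the very
  smallest volumes (≲ 10⁻⁹ μL) is biased high for electrons because all
  energy stays on the primary ray.
* The low-energy stopping rows are an anchor-constrained compilation,
  not a measured dataset; absolute LET between 0.3 and 1.5 keV is the
  least certain part of the table.
* Single-electron Auger representation reproduces energy budgets, not
  electron multiplicity; do not use it for ionisation-cluster counting.
* Absolute dose-per-decay values depend on the normalisation convention;
  cross-study comparisons should use the density-normalised dose or
  containment fractions.
* Photon transport deposits at a point and ignores scattered-photon
  escape, adequate below 10 keV in ≲ mm volumes only.
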