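# Methods

`mwablate` simulates interstitial microwave ablation of lung tissue with a
thin coaxial slot antenna, and quantifies how the breathing state —
inflated (end-inspiration) versus deflated (end-expiration) lung — changes
the heating and the necrotic zone. The model is the standard one-way
coupled chain used in ablation treatment planning:

1. a frequency-domain electromagnetic solve for the antenna fields and the
   resistive heating density,
2. a transient Pennes bioheat solve driven by that heating,
3. an Arrhenius damage integral along each node's temperature history.

All three stages run on one axisymmetric structured grid.

## Model

**Electromagnetics.** In an axisymmetric, non-magnetic medium the antenna's
magnetic field is purely azimuthal, `H = H_phi(r, z) e_phi`, satisfying

    curl( eps_hat^-1 curl(H_phi e_phi) ) - k0^2 H_phi e_phi = 0,
    eps_hat = eps_r - j sigma / (omega eps0)          (exp(+j omega t)),

with the electric field recovered from `E = (curl H) / (j omega eps0
eps_hat)`. The resistive heating density is `Q_ext = 1/2 Re[(sigma - j
omega eps) E . E*]`, which for real `eps_r` reduces to `1/2 sigma |E|^2`
(hence `Q_ext >= 0` cell-wise, asserted on every solve), and `SAR = Q_ext /
rho`. The coax feed carries a power-normalized TEM mode: `E_r = C/r`,
`H_phi = C/(Z r)`, with `C = sqrt(P Z / (pi ln(r_out/r_in)))` from the
time-averaged power `P`.

**Bioheat.** Tissue temperature follows Pennes' equation

    rho c dT/dt = div(k grad T) + rho_b W_b c_b (T_b - T) + Q_ext + Q_m,

with metabolic heating `Q_m = 0`. The perfusion sink models capillary blood
entering at body temperature; with the default parameters its screening
length is `sqrt(k / (rho_b W_b c_b)) ~ 5.3 mm` and its pointwise relaxation
rate `rho_b W_b c_b / (rho c) ~ 9.3e-3 1/s` (a ~108 s time constant), which
sets the scale of the saturation times the package reports.

**Damage.** Thermal injury is a first-order rate process, `dalpha/dt = A
exp(-dE/(R T))`, integrated along each node's history; the necrotic
fraction is `theta_d = 1 - exp(-alpha)` and the ablation zone is the
`theta_d >= 1 - 1/e` region (`alpha >= 1`), the conventional contour.

## Discretization

Substituting `v = r H_phi` converts the curl-curl equation into a plain 2D
self-adjoint problem on the (r, z) half-plane,

    div( a grad v ) + b v = 0,    a = 1/(eps_hat r),    b = k0^2 / r,

solved with a node-centered finite-volume scheme on a graded tensor-product
grid that conforms exactly to every material interface. Radial integrals of
`1/r` (z-directed face conductances, the mass term) are evaluated in closed
form as logarithms, so the coax TEM mode `v = const` is *radially exact* on
the discrete grid: the matched-coax test reproduces the analytic mode to
3e-5 with 3e-11 spurious reflection. Boundary conditions: `v = 0` on the
axis (exact for azimuthal fields), natural zero-flux on metal (perfect
conductor), a matched TEM port at the coax inlet, and a first-order
scattering (Sommerfeld) condition with the local wavenumber on the open
tissue boundary. The sparse complex system (~22k unknowns at reference
resolution) is factorized directly; the relative residual is checked
against 1e-10.

Manufactured-solution tests show the operator converging at first order
(approached from below: observed rates 0.83 -> 0.96 over three
refinements); the order limiter is the node-value approximation of the
1/r-weighted axial fluxes near the axis. All reported summary quantities
change by < 0.5 % when both mesh and time step are halved, so the reference
resolution is comfortably converged for the comparative results.

The bioheat equation uses the same finite-volume machinery with the
revolved measure (`r dr dz` moments evaluated exactly) on the tissue region
only, backward-Euler stepping (unconditionally stable; the operator is
factorized once per run and reused across the 600 steps), Dirichlet `T =
T_b` on the far boundary, and zero-flux on the axis and on the
antenna/catheter surface. An implicit step satisfies the discrete energy
balance identically; an optional per-step audit recomputes storage,
conduction, perfusion and source integrals independently and checks the
imbalance. The damage integral is a trapezoid over stored snapshots (5 s
cadence for fields; every step for probe traces), evaluated in log space so
the 1e39-scale frequency factor never overflows.

## Geometry

The reference geometry: a 30 mm x 80 mm tissue cylinder with the antenna
on the axis; inner conductor 0.135 mm, PTFE dielectric (eps_r 2.03) to
0.470 mm, outer conductor to 0.595 mm, polymer catheter (eps_r 2.60) to
0.895 mm; a 1.0 mm ring slot centred 5.5 mm above the short-circuited tip
(0.5 mm metal cap), slot at the domain mid-height. These are the standard
thin monopole-slot reference dimensions of this model family; everything is
overridable through `AntennaGeometry`/`DomainGeometry`.

One deliberate choice: the catheter is modelled as a **closed sheath** — a
0.3 mm (wall-thickness) plastic cover seals the tip, so tissue never
touches bare metal. A hygienic catheter is closed by construction, and the
open variant puts tissue in contact with the shorting cap's edge
singularity: the first tissue cell then reaches unphysical 600-900 K and
dominates every summary quantity. With the sealed tip, peak temperatures
(342-402 K across the study) and saturation times (~100-150 s) sit in the
physically expected range, and the constant-property run agrees with the
inflated run at 2.45 GHz to 0.1 K.

The grid is graded: spacing <= 0.1 mm within 5 mm of the slot, growing to
<= 0.75 mm at the domain edges (reference resolution; the `fast()`
configuration uses 0.25/1.5 mm and dt = 2 s). The coarse spacing of each
axis is capped so no cell exceeds a 10:1 aspect ratio.

## Tissue parameters

| parameter | value | units | note |
|---|---|---|---|
| lung density rho | 385 | kg/m^3 | |
| lung heat capacity c | 3886 | J/(kg K) | |
| lung conductivity k | 0.39 | W/(m K) | |
| blood density rho_b | 1060 | kg/m^3 | |
| blood heat capacity c_b | 3639 | J/(kg K) | |
| perfusion rate W_b | 0.0036 | 1/s | |
| body temperature T_b | 310.15 | K | 37 C |
| Arrhenius A | 7.39e39 | 1/s | hepatic coagulation kinetics |
| Arrhenius dE | 2.577e5 | J/mol | hepatic coagulation kinetics |

Thermal properties do not vary with the breathing state; only the
dielectrics do.

**Dielectric property sets.** The inflated and deflated spectra are the
published Gabriel 4-term Cole-Cole fits for lung tissue; they are
published fits standing in for direct tissue measurements, and they
reproduce the features that matter here: the
deflated/inflated ratio is ~2 for both eps_r and sigma across 0.915-2.45
GHz, eps_r falls and sigma rises with frequency, and the inflated values at
2.45 GHz (20.48, 0.804 S/m) coincide with the constant baseline (20.5,
0.804 S/m). Parameter sets are config-overridable.

**Damage kinetics caveat.** The hepatic A/dE pair accumulates a
non-negligible baseline at body temperature (`alpha(37 C, 600 s) = 0.18`,
`theta_d = 0.16`) — a known artifact of extrapolating coagulation kinetics
far below their fitting range. The ablation-zone threshold (0.632) sits
well above this baseline, but it effectively places the 600 s zone boundary
near the ~42 C isotherm, which makes the zone (especially its backward tail
along the shaft) generous. Lung-specific kinetics are an open literature
question; both parameters are prominently overridable.

## Reporting conventions this package fixes

* **Probes.** The axial SAR profile and the damage probe sit at r = 2.5 mm
  (about 1.6 mm into tissue from the catheter), level with the slot centre.
* **Saturation time**: first time the spatial-peak temperature trace
  reaches 95 % of its final rise over T_b, interpolated between steps.
* **Complete necrosis**: probe necrotic fraction reaching 0.99,
  interpolated.
* **State comparisons**: percentage differences are `|a-b|/max(a,b) x 100`
  so the larger value is always the denominator.
* Zone extents are threshold-contour crossings interpolated along grid
  lines (sub-cell resolution); the zone area is the (r,z)-plane area with
  the revolved volume reported alongside.

## Synthetic data and what the tests show

The study consumes no external data: every input is a physical parameter.
The verification fixtures supply (a) closed-form references — the coax TEM
mode with its power round-trip, the conduction-free perfusion ODE, constant
and piecewise-constant temperature exposures for the damage integral — and
(b) manufactured solutions that inject a forcing term so a chosen smooth
field is exact for each discrete operator. Synthetic temperature histories
(constant / ramp-plateau / seeded noisy-plateau) emulate the
source-dominated linear rise followed by perfusion-limited saturation that
the coupled runs produce; they do not emulate spatial correlation between
neighbouring nodes, so damage-zone morphology is only exercised by the
coupled runs and by analytic ellipsoidal fields. Passing tests demonstrate
the solvers implement the stated model correctly; they cannot validate the
model's biophysics (no vaporization, static properties) against real
ablations.

## Known limitations

* No water vaporization or latent heat: above ~100 C the model keeps
  conducting sensible heat, so near-antenna temperatures overshoot what a
  real ablation (with steam formation) would show. Inherited from the
  modelled equations.
* Dielectric and thermal properties are temperature-independent; EM-thermal
  coupling is one-way (one EM solve per run, heating held fixed for 600 s).
* Static breathing extremes: the inflated/deflated comparison brackets the
  respiratory cycle rather than resolving it in time.
* Absolute field levels are sensitive to antenna dimensions that published
  studies rarely print; ratio/difference comparisons between states are the
  robust outputs. In this geometry the antenna is matched near 2.45 GHz;
  at 915 MHz-1.5 GHz feed mismatch and boundary outflow grow, the SAR
  profile peaks toward the tip rather than the slot, and the deflated state
  (higher permittivity load) can deposit *less* power than the inflated
  one, reversing the peak-temperature ordering seen near the design
  frequency.
* The EM power balance closes to 0.2-3 % at reference resolution
  (diagnostic Poynting integrals on boundary-adjacent cells), improving
  under refinement.

## Problem sizes

Reference resolution: 97 x 229 grid (~22k nodes), 600 implicit steps of
1 s; one coupled run takes a few seconds on one CPU, the full 8-run
comparative study about half a minute. The coarse qualitative
configuration (0.25/1.5 mm, dt = 2 s) runs the same study in ~15 s.
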