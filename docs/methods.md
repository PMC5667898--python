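# Methods

## Physical model

`hemospin` models the first centrifugation of whole blood as batch
sedimentation of rigid spherical particles (red cells, white cells,
platelets) in a Newtonian continuous phase (plasma). The gravitational
field perpendicular to the spin axis is neglected — valid for the
centrifugal accelerations of interest, 100–1500 g — so the motion is
one-dimensional along the radial coordinate r, which runs from the
rotation centre to the tube bottom at r = R_o.

For an incompressible solid–liquid mixture in a closed tube the mixture
volume flux vanishes everywhere, and combining the solids continuity
equation with the drift-flux closure gives a scalar conservation law
for the solids volume fraction α(t, r). In dimensionless form
(r\* = r/R_o, t\* = t ω²u∞/g):

    ∂α/∂t* + ∂/∂r*( r* f*(α) ) = 0

with hindered-settling (Richardson–Zaki) batch flux

    f*(α) = α (1 − α)^m        for 0 < α < α_max,   0 otherwise.

The r\* factor encodes the linear growth of centrifugal acceleration
with radius; it also slowly dilutes a uniform suspension, exactly as in
classical radial sedimentation theory. The clamp at the packing
fraction α_max makes the packed bed absorbing: particles enter it and
never leave.

Assumptions worth keeping in mind:

- cells are rigid spheres of uniform size and density per species;
  deformability enters only through the packing limit α_max = 0.8;
- hindered settling with m = 5 is valid for particle Reynolds numbers
  below 0.2 (the package warns when a protocol exceeds this);
- species settle independently (weak coupling): the white-cell field is
  solved separately from the red-cell field;
- below roughly 100 g the neglected gravity component matters and
  predictions are extrapolations (the configuration layer warns).

## Parameters, units, defaults

Strict SI internally; the CLI accepts mL, minutes, µm, mm and
g-multiples. Defaults:

| parameter | default | meaning |
|---|---|---|
| d_RBC, ρ_RBC | 8 µm, 1125 kg/m³ | red-cell diameter, density |
| d_WBC, ρ_WBC | 10 µm, 1065 kg/m³ | white-cell diameter, density |
| d_PLT, ρ_PLT | 1 µm, 1050 kg/m³ | platelet diameter, density |
| ρ_plas, μ_plas | 1032 kg/m³, 1.0 mPa·s | plasma density, viscosity |
| m | 5 | Richardson–Zaki exponent (rigid spheres, Re_p < 0.2) |
| α_max | 0.8 | packing fraction of the (deformable) cell bed |
| H_e set | {0.37, 0.45, 0.52} | hematocrit range across donors |
| β_o | 0.01 | initial white-cell volume fraction |
| c_w set | {10⁻³, 10⁻²} | empirical white-cell capture coefficient |
| tube | R_o = 150 mm, A = 120 mm², V_t = 15 mL, flat | reference tube |
| conical bottom | frustum, height 0.2 R_o, D → 0.25 D | clinical conical tube |
| sweep grids | 100–1500 g step 20 g; 2–15 min | protocol ranges |

Every default is overridable through `SweepSpec`, the YAML config or
CLI flags. "Hematocrit-averaged" quantities are arithmetic means over
the hematocrit set; white-cell recoveries are additionally averaged
over the two c_w endpoints (E_WBC is linear in c_w, so this equals
using their mean). The averaging quadrature is a package choice: only
the range, not the weighting, is externally prescribed.

### The conical bottom

The conical tube is modelled as a cylinder whose bottom 0.2 R_o tapers
linearly from the full diameter D at the cylinder–cone junction to
0.25 D at the bottom (a frustum). The two stated proportions of the
clinical tube (cone height one fifth, narrow end one quarter of the
bore) are preserved while keeping the profile continuous where the cone
meets the cylinder. A narrower cone top with a step at the junction is
also supported (`cone_top_diameter`); we verified it degrades agreement
with the flat/conical comparison behaviour and left the frustum as the
default. Volume ↔ fill-height conversions are closed form in both
sections (cube root of the frustum volume inside the cone).

### The white-cell surrogate field

The white-cell concentration field is solved with the *red-cell*
initial fraction, not β_o: white cells ride in the same crowded
suspension, so their front is hindered by the total cell load while
moving on the white-cell velocity scale u∞_WBC < u∞_RBC. Their front
I_pW therefore lags the red-cell front I_ns, and the layer between the
two is the white-cell–rich (buffy) layer. The true white-cell dilution
β_o appears only in the recovery normalisation
E_WBC = c_w · V_layer/(β_o V_WB). Solving the white-cell field at its
own tiny fraction instead would leave it essentially unhindered, put
its front *below* the red-cell front and force E_WBC ≡ 0 for every
protocol — inconsistent with the observed 10–25 % recoveries this
formula is meant to reproduce.

## Numerics

- **Scheme.** First-order explicit conservative (upwind) update with a
  monotone interface flux. For the single-extremum hindered-settling
  flux the Engquist–Osher and Godunov fluxes coincide; the splitting is
  evaluated in closed form from the extremum α\* = 1/(m+1). At faces
  bordering the packed bed, where the clamp makes the flux
  discontinuous, the exact Riemann (Godunov) value is used, so a
  settled bed under clear liquid exchanges exactly zero flux.
- **Packing limiter.** One bottom-up sweep per step caps each cell's
  influx so a step can never drive α above α_max. The cap redistributes
  flux conservatively (the donor cell keeps what the receiver cannot
  take), and total solids are conserved to machine precision.
- **Grid.** 200 uniform cells over the blood column
  r\* ∈ [(R_o−L)/R_o, 1]; conical sections use exact per-cell volumes
  and face areas (area-weighted finite volumes).
- **Time step.** Δt\* = CFL · Δr\*/max|∂(r\*f\*)/∂α| with CFL = 0.5; the
  wave-speed bound is found by dense grid search so it holds for any
  exponent m. With the defaults Δt\* ≈ 1.25×10⁻³.
- **Sampling.** Snapshots take the state after the last completed step
  at or before each requested time — no temporal interpolation; the
  induced error is O(Δt\*).
- **Interfaces.** The supernatant front I_ns is the topmost sub-cell
  linear crossing of α through eps_clear = 10⁻³ (absolute), the bed top
  I_sd the crossing of α_max − 10⁻³; both thresholds are configurable.
  Because the numerical front is a sharp jump spread over a few cells,
  a low absolute threshold sits at the *clear-side toe* of the jump:
  E_plas inherits a cell-quantised staircase (≈0.8 percentage points
  per cell at 200 cells) and a small systematic underestimate that
  vanishes under grid refinement. Grid-convergence tests pin the
  mid-front position to well under a cell.
- **Degenerate inputs.** All-clear or fully packed columns return
  flagged boundary interfaces rather than raising; zero wave speed
  collapses the march to a single step; non-finite states abort with a
  diagnostic.
- **Sweep evaluation.** The dimensionless equation depends on the
  protocol only through t\* = t_c·a_c·u∞/R_o, so one solve per
  (hematocrit, geometry, species) serves an entire acceleration or
  time sweep; each protocol samples the solve at its own t\*. This is
  exact, not an approximation — it is why full sweeps cost seconds.
  It also implies that (E_plas, E_PLT) pairs from different spin times
  collapse onto a single curve parameterised by t_c·a_c, which the
  tests assert.
- The inner march is numba-jitted (with a pure-Python fallback); a
  10-minute 1000 g solve takes ≈0.2 s after JIT warm-up.

## Correlation layer

The platelet/plasma recovery ratio follows the dimensional-analysis
correlation ln(E_PLT/E_plas) = c₁·Π₂Π₃Π₄ + c₂ with defaults
c₁ = −0.0122, c₂ = 0.5128 (so the zero-argument ratio is
exp(0.5128) = 1.670). Two conventions are resolved explicitly:

- the logarithm is **natural**: exp(0.5128) reproduces the exponential
  prefactor 1.67 exactly, base 10 would give 3.26;
- the reference velocity u∞ in Π₃ is the **red-cell** Stokes velocity
  (3.244×10⁻⁶ m/s): red cells are the dominant dispersed phase, and
  only this choice makes Π₂Π₃Π₄ of order 10–10² over clinical
  protocols, producing the observed exponential decay of the ratio
  with acceleration. The platelet velocity would make the exponent
  negligible. The choice is configurable and logged with every run.

E_PLT = ratio × E_plas is clipped at 1; the clip is flagged in all
outputs. Refitting (`fit_correlation`) uses ordinary least squares of
ln(ratio) on Π₂Π₃Π₄ (slope, intercept, standard errors, R²) or, with
free exponents, Levenberg–Marquardt in log space; refits never
silently replace the defaults.

## Synthetic data

`generate_correlation_fixture` emulates the structure of pooled
clinical observations: whole-blood volumes uniform on 3.5–9 mL, spin
times 5–10 min, accelerations 100–1500 g in the default tube, with
ln(ratio) following the correlation plus independent Gaussian noise of
configurable standard deviation (default 0 — exact). It reproduces the
*design structure* of such datasets, not their real-world error
structure: no heteroscedasticity, no between-study offsets, no
measurement error in the conditions. Passing the fit-recovery tests
therefore demonstrates correctness of the regression machinery, not
robustness to clinical data pathologies.

## Problem sizes used in tests and the acceptance script

Acceptance-style computations run at the standard study conditions:
200-cell grid, 20 g sweep step, three hematocrits — a full sweep is
three solves and the whole acceptance script runs in under a minute on
one CPU. Unit and property tests use 50–200 cells and coarser sweep
steps (chosen so every asserted property is resolved), keeping the full
suite under a minute after JIT warm-up.

## Known limitations

- Monodisperse, uncoupled species: no polydisperse momentum coupling
  (MLB-type models), no sediment compressibility or diffusion.
- The first-order scheme smears fronts over a few cells; recoveries at
  the default 200-cell grid carry ≈1–2 percentage points of
  discretisation bias (documented per-quantity in the tests).
- The critical-acceleration landscape is intrinsically flat near its
  maximum for hematocrit-averaged curves (≈1 percentage point over a
  ±100 g window); argmax locations are correspondingly soft even when
  the peak recovery value is sharp.
- Below ~100 g and above Re_p ≈ 0.2 the model leaves its validity
  envelope; both conditions produce warnings, not errors.
- Platelet spatial dynamics are not solved; platelets enter only
  through the correlation layer. White-cell recovery uses a surrogate
  concentration field and an empirical capture coefficient spanning an
  order of magnitude; treat E_WBC as order-of-magnitude guidance.
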