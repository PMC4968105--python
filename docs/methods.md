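# Methods

## Scope and state variables

The package models one bispecific antibody species interacting with two
non-interacting, monomeric membrane targets on a single spherical cell of
diameter 10 µm (surface area π·d² = 314.16 µm²). Receptor copy numbers per
cell (82 000/92 000 CD4/CD70 on dual-positive cells, 68 000 and 55 000 on
the single-positive lines) are converted to uniform surface concentrations
in mol/dm². The antibody concentration in solution is a molarity; surface
species are areal concentrations. Canonical internal units are (s, dm,
mol), matching the units in which the kinetic scheme is posed; the
particle simulator and all user-facing geometry work in (s, µm,
molecules), with exact Avogadro conversions between the two systems
(`bispec.units`).

No target synthesis, internalization or degradation is modeled (the
underlying experiments were run at 4 °C where turnover is suppressed), no
non-specific binding, and no target dimerization or oligomer/chain
formation. Rate constants measured at 25 °C are applied unchanged at
assay temperature; they are likely mild overestimates, a deliberate
simplification rather than an Arrhenius correction with unknown activation
energies.

## Rate-constant closure

Measured inputs per antibody variant: `k1, k-1` (CD4 arm) and `k2, k-2`
(CD70 arm), volume-phase, from surface plasmon resonance. Derived:

* **Surface association** `k3 = k4 = 4(D_1 + D_2)` per molecule — the
  steady diffusion-limited 2D encounter rate. With the adopted median
  lateral diffusion coefficient D = 5×10⁻¹⁰ cm²/s for both targets this is
  0.4 µm²/(molecule·s) = 2.41×10¹³ dm²/(mol·s). The 2D "rate constant" is
  not a true constant (it decays logarithmically with time/density), so
  this value should be read as the relevant scale; model outputs are
  insensitive to it as long as it far exceeds the dissociation scales,
  which it does by 3–5 orders of magnitude.
* **Surface dissociation** from microscopic reversibility around the
  closed cycle A+T1+T2 → AT1 → AT1T2 → AT2 → A+T1+T2:
  `k-4/k-3 = (k-1/k1)·(k2/k-2)`. One anchor is needed; the default pins
  the CD70 arm (`k-3 = k-2`, hence `k-4 = k-1·k2/k1`), motivated by
  measurements showing surface and volume off-rates of the same receptor
  pair differ only ~3-fold. The alternate anchor (`k-4 = k-1`) is provided
  and changes binding curves by <0.1% (regression-tested <5%), because the
  correction factor `k2/k1` is within 0.36–1 for the panel.

Every rate set constructed through `close_rate_set` satisfies the
reversibility residual `k1·k-2·k3·k-4 / (k-1·k2·k-3·k4) = 1` exactly;
`validate_rate_set` exposes the residual for externally supplied sets
(the printed, rounded off-rate table closes the cycle to within 3%).

## ODE engine

State `(AT1, AT2, AT1T2)` with free targets eliminated by conservation.
The system is stiff: pseudo-first-order cross-linking rates `k3·[T]` are
~10²/s while the slowest off-rates are ~10⁻⁴/s. Choices:

* LSODA with an analytic 3×3 Jacobian; `rtol = 1e-8`.
* Absolute tolerance is scaled to the problem, `atol = 1e-10·max(T1_tot,
  T2_tot)` (~10⁻²² mol/dm²), because a fixed atol anywhere near the
  surface-concentration scale (~10⁻¹² mol/dm²) would silently dominate
  the error control.
* Output grids are geometric so both the ~10 ms cross-linking transient
  and multi-hour equilibration are resolved.
* Tiny negative excursions within solver tolerance are clamped to zero;
  anything beyond tolerance raises.

**Steady state.** For reversibility-closed rate sets the equilibrium is
detailed-balanced and reduces to a single monotone scalar equation in free
T2 (after substituting `AT1 = (k1 A/k-1) T1`, `AT1T2 = (k3/k-3) AT1·T2`
and conservation), solved by bracketing to machine precision. For
non-closed sets a Newton root of the full right-hand side is used, seeded
by a 10⁴-hour integration. Every returned state is verified against
`rhs ≈ 0`.

**Antibody bath.** The default is a clamped concentration (the scheme's
stated regime). A finite-bath mode depletes `[A]` through the
surface-to-volume ratio; it exists for comparison with the particle
simulator, whose box holds a fixed number of antibody molecules. The
equivalent ODE bath volume is the patch column volume scaled to the whole
cell.

**Post-processing.** The wash correction multiplies the monovalent species
by `exp(-k_off·t_wash)` with `t_wash = 240 s` (two spin–resuspend cycles
plus acquisition) and leaves the ternary complex untouched — its off-rate
corresponds to half-lives of tens of hours, so its loss over four minutes
is negligible. The correction is applied to all cell types by default
(on dual-positive cells it is nearly a no-op because monovalent species
are scarce); a flag disables it. Bound molecules per cell are surface
concentration × cell area × N_A; MFI = molecules / 1.18.

**Avidity.** `Kd_eff` is the concentration at half of the equilibrium
total binding reached at 10 nM, located by bisection over [10⁻¹⁶, 10⁻⁸] M.
The 10 nM cap keeps the reference inside the ternary-dominant regime:
above ~50 nM binary complexes start accumulating and total binding grows
without a meaningful half-max. The enhancement is
`log10(min(Kd1, Kd2)/Kd_eff)`; for the parent antibody the model gives
Kd_eff ≈ 78 fM, an enhancement of ≈ 4.1 logs, and exactly 0 (by
construction) when cross-linking is disabled.

**Dissociation runs** start from the stoichiometrically cross-linked
state (`AT1T2 = min(T1_tot, T2_tot)`, excess target free, `[A] = 0`
clamped — released antibody is lost to an infinite sink). The computed
half-life of total bound antibody ranges from ≈ 29 h (weakest variant,
`k-1 = 36×10⁻³` 1/s) to ≈ 3100 h (parent), and the decay decelerates:
every ternary opening is far more likely to re-close than to release the
antibody, and recapture strengthens as freed targets accumulate. An
independent Gillespie realization of the same kinetics reproduces these
half-lives, so they are a property of the scheme and its parameters, not
of the integrator. Note that the instantaneous (log-slope) half-life at
50% remaining is substantially longer (~52 h for the weakest variant)
than the time-to-50% figure — the two conventions diverge strongly for
non-exponential decays, which matters when comparing against "about 40 h"
style statements read off decelerating curves.

## Particle engine

A cuboid with square 0.1 µm² base: the membrane is the bottom face, seeded
with targets at nearest-integer(density × patch area) — 26 and 29 for
dual-positive cells, 22 and 18 for the single-positive lines. 605 antibody
particles fill the column; its height realizes the molar concentration
(1005 µm at 10 nM), which keeps depletion below 10% at all tested
concentrations. Lateral boundaries are periodic by default (the patch
stands in for a piece of a much larger closed surface; reflective walls
are available), top and bottom reflective.

* **Diffusion**: independent Gaussian steps with per-axis variance
  `2·D·dt`; surface species in-plane only. Bound complexes move with the
  membrane anchor's D (5×10⁻¹⁰ cm²/s) — the anchor dominates the mobility
  of the complex; this is configurable. Default dt = 1 µs; tests and
  consistency runs use 50 µs, still inside the design range, and the
  configuration guard enforces rms step ≤ ⅓ of the surface reaction
  radius so contact statistics stay resolved.
* **Reactions**: association requires separation below the reaction
  radius (sum of hydrodynamic radii; defaults 5.5 nm antibody/complex,
  2.5 nm target — not critical, see calibration) and fires with a
  per-encounter probability `p`; dissociation is sampled exactly as
  `1 − exp(−k_off·dt)` per step with competing channels resolved by their
  branching ratio. Products are placed at contact separation + 0.1 nm; at
  most one reaction per particle per step, conflicts resolved in uniformly
  random order.
* **Calibration** pins `p` to the macroscopic constants, with the radius
  and placement conventions absorbed into the calibration so the
  macroscopic rates are honored regardless of those choices. Two regimes:
  * *Volume–surface* (`k1, k2` ≈ 10⁵ 1/(M·s)): four orders of magnitude
    below the 3D diffusion-limited encounter rate (4πDr ≈ 4 µm³/s per
    pair), and the antibody rms step (~9 nm at 1 µs) is of the order of
    the reaction radius or larger, so successive encounter samples are
    effectively independent and the event rate is exactly linear in `p`.
    Calibration measures ghost-counted (non-consuming) encounter rates in
    a well-mixed box and solves for `p` (≈ 0.02 at 50 µs). Because this
    channel is reaction-limited, the fine-step constraint that applies to
    surface pairs is unnecessary here; the per-step sampling is an
    uncorrelated Bernoulli draw whose rate calibration makes exact.
  * *Surface–surface*: the adopted chemical rate, 0.7 µm²/(molecule·s)
    (from the CD2–CD58 surface Kd ≈ 6 molecules/µm² and k_off = 5 1/s),
    *exceeds* the 2D encounter-limited ceiling ≈ 4D = 0.4 µm²/s at these
    radii and densities. Calibration (pseudo-first-order tracer decay at
    the operating density) detects this and refuses; the production
    engine then reacts on contact (`p = 1`), making the cross-linking
    step fully diffusion-controlled — precisely the regime the model
    asserts, and consistent with the ODE engine's `k3 = 4D`. Requested
    rates below the ceiling (e.g. 0.3 µm²/s) calibrate normally by
    bisection.
* **Far-field coarsening**: antibodies above z = 1 µm take 100× coarser
  time steps (they are centimeters of diffusion time away from the
  membrane at the molecular scale and cannot react); the near-field list
  is rebuilt every coarse step. This makes hour-scale columns tractable
  without touching near-membrane statistics.
* **Reproducibility**: replicate r of a run derives its placement and
  dynamics seeds from `SeedSequence(rng_seed)`; identical configuration
  and seed give bit-identical trajectories. Integer conservation of both
  target families and of total antibody holds exactly at every recorded
  frame.

## What the built-in conditions emulate — and what they do not

The packaged fixture *is* the study's condition set: the six-variant
kinetic panel, three cell lines, 1 h incubation, 240 s wash, 1.18
molecules/MFI. Model outputs are therefore predictions for those assays,
not fits — no parameter is estimated from binding data. What passing
tests show: the two engines agree with each other and with closed-form
limits under these conditions. What they do not show: agreement with any
particular experimental MFI value (the original flow-cytometry points are
not distributed with the package; `overlay_and_report` accepts a
user-digitized CSV for visual comparison only), correctness of the
uniform-mobility assumption (measured CD4 mobilities span two orders of
magnitude across subpopulations), or behavior with target turnover at
physiological temperature.

## Problem sizes used in the test suite

Deterministic checks run on 7–13-point log-spaced concentration grids
spanning 10 pM–100 nM (10 fM–10 µM for equilibrium composition).
Stochastic checks use the full 605-antibody box at 10 nM with 3
replicates over a 5-minute simulated window at dt = 50 µs — long enough
to cover the cross-linking transient and ~20 ternary complexes per patch
— with cross-engine agreement asserted at 3 ensemble standard errors;
equilibrium-level agreement is checked separately in a reduced
single-target system with a fast synthetic off-rate, where the occupancy
isotherm has a closed form. Brownian-motion statistics are verified on
10⁴-particle ensembles (mean-square displacement within 5% of 4Dt/6Dt).

## Known limitations

* The 2D association constant is treated as a single scale; a full
  treatment of the time-dependent 2D rate (or MCell-style ray-traced
  collisions) is out of scope. Calibration is density-windowed instead.
* The wash correction is algebraic (first-order loss), not a simulated
  wash; rebinding during washing is neglected.
* The dissociation bath is an infinite sink; in a closed volume released
  antibody would rebind avidly and slow the decay further, so measured
  cell-dissociation experiments in small volumes should read slower than
  these predictions.
* Cuboid seed counts for single-positive cells (22/18) follow from the
  stated densities by rounding; small-count discretization at patch scale
  contributes ~±2% to particle-engine densities.
* Particle-engine performance: ~7 µs per step per box on one core; hour
  simulations at 50 µs steps are minutes-to-hours of wall time, which is
  why routine consistency checks use 5-minute windows.
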