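# Methods

## The model

`viscoclutch` simulates the engagement of the actin–talin–integrin–
fibronectin molecular clutch on a viscoelastic substrate, and the
consequences of silencing the mechanosensitive channel Piezo1.  The
model couples three elements.

**Substrate (Standard Linear Solid).**  The matrix patch an adhesion
pulls on is a spring `k2` in parallel with a Maxwell arm (`k1` in
series with a dashpot `eta`), all in pN/nm at the adhesion scale.  The
response is instantaneous stiffness `k1 + k2` relaxing to `k2` with
time constant `tau = eta/k1`.  The state-space form (deformation `x`,
Maxwell force `f_m`) is integrated with an exact exponential update of
`f_m` within each step, so the integrator is accurate for any `dt`
(the public API still enforces `dt <= tau/10` as a configuration
contract).  When clutches unbind, the substrate recoils elastically
(through `k2` and the Maxwell spring, dashpot frozen) within the same
step, so the reported substrate force always balances the summed
clutch load exactly.

**Clutch ensemble.**  A pool of `n` clutches (initially 75, cap 750)
binds rearward-moving actin to the substrate.  Per fixed time step:
binding of free clutches (`k_on`), advection of bound clutches with
the actin flow, a linear solve for the substrate deformation that
balances the total clutch load, force-dependent unbinding, talin
unfolding above a force threshold `f_unfold`, vinculin binding to
unfolded talin at finite rate `k_vin`, and integrin recruitment
(`d_recruit` added per vinculin event).  Every stochastic transition
uses the exact per-step probability `1 - exp(-rate*dt)`.  Recruitment
is irreversible within a run; an unbinding clutch refolds talin and
loses its vinculin, but the recruited pool persists.

**Motors.**  Myosin drives retrograde flow with a linear
force–velocity relation, `v = v_u (1 - F/F_stall)` clamped at stall
(`F_stall = n_myosin * f_stall = 150 pN`, `v_u = 110 nm/s`).

**Piezo1.**  Knockdown (siPiezo1) is modelled purely as a 15% increase
of the force-free clutch dissociation rate, reflecting the loss of the
Piezo1–integrin interaction that otherwise stabilises the clutch.  The
factor is configurable; 1.0 recovers the scrambled-siRNA control.

## The bond law, and why it is catch–slip

The default dissociation law is catch–slip,

    koff(f) = koff0 * (c * exp(-f/f_catch) + (1-c) * exp(f/f_bond)),

with `c = 0.98`, `f_catch = 3 pN`, `f_bond = 2 pN`, `koff0 = 10/s`:
bond lifetime is maximal (~1 s) near 5 pN and collapses beyond
~12 pN.  The talin unfolding threshold (6 pN) sits inside this
long-lived regime.

This choice is load-bearing.  With a pure slip bond the vinculin race
is condition-symmetric — the time a clutch survives at the unfolding
force is `1/koff(f_unfold)` regardless of the substrate — so
fast-cycling stiff substrates always accumulate more reinforcement
events than soft viscoelastic ones, and the observed inversion
(soft V+ adhesions outgrowing stiff V+ ones) cannot occur at any
horizon.  The catch valley breaks the symmetry: clutches loaded
*slowly or held near stall* park at the valley force with seconds to
bind vinculin, while clutches loaded *fast* shoot through the valley
into the slip arm and unbind in milliseconds, faster than vinculin can
act.  This is also the bond phenomenology of the alpha5beta1
integrin–fibronectin pair that the clutch-reinforcement literature is
built on.  A pure slip law remains available (`bond_law="slip"`) and
is used by the test-suite closed-form checks.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `n_clutch_init` / `n_clutch_max` | 75 / 750 | – | initial / maximal integrin pool |
| `k_on` | 0.5 | 1/s | clutch association |
| `k_off0` | 10 | 1/s | force-free dissociation |
| `f_catch`, `catch_share` | 3, 0.98 | pN, – | catch pathway (valley near 5 pN) |
| `f_bond` | 2 | pN | slip arm force scale |
| `k_clutch` | 5 | pN/nm | clutch spring |
| `f_unfold` | 6 | pN | talin unfolding threshold |
| `k_vin` | 0.5 | 1/s | vinculin binding to unfolded talin |
| `d_recruit` | 3 | – | integrins per vinculin event |
| `n_myosin`, `f_stall`, `v_unloaded` | 75, 2 pN, 110 nm/s | | motor ensemble |
| siPiezo1 `koff_factor` | 1.15 | – | knockdown as faster unbinding |

Magnitudes (clutch spring, flow speed, pool sizes, motor stall) follow
the motor-clutch modelling literature.  The kinetic constants are a
calibrated set: they were chosen, once, so that the default substrate
grid reproduces the qualitative experimental orderings (see below),
and then frozen.  They are not measured molecular constants and every
one is config-overridable.

### The default substrate grid

Four substrates (pN/nm): soft V− (0.1, 0.25, η 0.1; τ 1 s), soft V+
(1.5, 0.25, η 0.75; τ 0.5 s), stiff V− (4, 5, η 8; τ 2 s), stiff V+
(15, 5, η 1.5; τ 0.1 s).  Equilibrium stiffness is matched within each
pair and the V+ member always relaxes faster, with a larger
loss-to-storage ratio at ~1 Hz working frequencies.  The two pairs
encode dissipation differently, mirroring the different gel
chemistries used to make soft and stiff viscoelastic substrates:

* *soft V+* carries a fifteen-fold larger Maxwell arm than soft V−.
  Its transient stiffness and drag add load to an otherwise
  under-loaded ensemble, pushing clutches up into the catch valley:
  engagement, adhesion growth and slowed flow follow.
* *stiff V−* carries a large sustained drag (η 8) that slows flow
  early and lets clutches dwell in the valley: reinforcement wins.
* *stiff V+* is spring-dominated and fast-relaxing: clutches load
  through the valley at nearly full motor speed and unbind before
  vinculin binds, so reinforcement underperforms stiff V− and flow
  stays fast.

A mapping from bulk Young's modulus (kPa) to these adhesion-scale
springs is not available beyond "soft ≈ below 1 pN/nm"; the grid
treats the conversion as sub-linear (25 kPa ↦ ~5–20 pN/nm) because the
ligand patch loaded by one adhesion is finite.  The hydrogel-scale SLS
parameters used to generate nanoindentation fixtures are a separate
set (instantaneous stiffness ≈ bulk modulus in kPa; τ = 20 s for V−,
10 s for V+) — bulk stress relaxation is slower than the local
rearrangements an adhesion feels.

### Simulation settings

`dt` is auto-chosen as `min(0.1/max zero-force rate,
f_bond/(5*k_clutch*v_u), tau/10)` (~0.7 ms at defaults): no transition
probability exceeds ~0.1 per step and a bond's force ramp is resolved
in ≥5 steps per `f_bond`.  Runs last 200 s ≈ 100× the slowest default
timescale (substrate relaxation, vinculin binding: 2 s); summaries are
time averages over the trailing 50%.  Because recruitment is
irreversible, "steady state" means the mature regime of a fixed
observation horizon — conditions are compared at equal simulated time,
as replicate cells are compared at equal culture time.  Each replicate
seeds an independent generator derived from (condition id, replicate
index, root seed); a root seed fixes every number in the output.

## Observables

Integrin density (the recruited pool, time-averaged over the steady
window) is scaled to focal-adhesion length by the published anchor
84.1 arb. units = 1 µm.  Condition summaries are mean ± sample SD over
N = 26 replicates.  `trend_check` evaluates six assertions on the
8-condition table: (a) soft V+ > soft V− FA length; (b) stiff V− >
soft V−; (c) soft V+ > stiff V+; (d) knockdown never significantly
exceeds control in any condition; (e) flow orders opposite to FA
length within each pair wherever the FA difference is significant;
(f) knockdown attenuates the soft viscous gain.  (d), (e) and (f) use
one-sided permutation tests (α = 0.05) rather than raw inequalities,
because 26 stochastic replicates can invert a null ordering by chance.
The YAP nuclear-to-cytoplasmic ratio implements the area-normalised
intensity ratio with cytoplasmic signal and area defined by
subtraction of the nuclear from the whole-cell compartment.

## Relaxometry

The nanoindentation pipeline reproduces the standard stress-relaxation
analysis: spherical-probe strain `0.2*sqrt(h*R)/R` (≈7% at h = 3 µm,
R = 27.5 µm); per-curve preprocessing (baseline alignment if negative,
peak detection giving (t0, F0), cropping to the hold phase, time shift
to t0, normalisation by F0); pointwise averaging of the normalised
replicates (linear interpolation onto the first curve's grid over the
shared window); t80 = first crossing of 0.8 with linear interpolation
between samples; and percent energy dissipation.  Energy dissipation
defaults to the relaxation amplitude `100*(1 - F_end/F0)`; an
area-under-curve alternative (`method="area"`) is provided, and
neither is claimed to reproduce any instrument-specific definition.
Young's moduli are extracted by a closed-form linear least-squares fit
of the spherical Hertz model `F = (4/3) E/(1-nu^2) sqrt(R) d^{3/2}`
with ν = 0.5.

## Synthetic data

Every generator is the forward model of an analysis stage, so
generator → analysis round-trips have known ground truth: SLS
relaxation records follow the indentation protocol (baseline, 0.6 s
Hertz-shaped approach at 5 µm/s, 60 s hold at 3 µm) with the hold
force equal to F0 times the SLS reduced relaxation function
(quasi-static assumption: the <1 s approach is not ramp-corrected,
matching an analysis that discards everything before the peak), plus
i.i.d. Gaussian force noise; indentation curves follow the Hertz
forward model.  What the generators do **not** emulate: instrument
drift, adhesive snap-off, contact-point uncertainty beyond additive
noise, heteroscedastic noise, or plastic deformation.  Passing
round-trip tests therefore demonstrates the correctness of the
analysis pipeline, not its robustness to every artefact of real
nanoindentation data.

## Numerical and design notes

* Tie-breaks: t80 takes the earliest threshold crossing; a curve whose
  first hold sample is already below 0.8 reports t80 = 0; a curve that
  never relaxes to 0.8 reports an explicit "not reached" (None), never
  a silent NaN.
* Degenerate inputs: `k1 = 0` is the pure-spring substrate everywhere
  (relaxation time infinite, loss zero); `eta -> inf` recovers a
  spring of stiffness `k1 + k2`; zero cytoplasmic YAP signal or area
  is an error, not a number.
* The event-driven (Gillespie) formulation of the binding kinetics
  exists only as a test oracle, deliberately sharing no code with the
  engine; the fixed-step engine is validated against it on a 3-clutch
  force-free toy by a chi-square test on occupancy distributions.
* Monte Carlo kernels are JIT-compiled (numba) with seeded MT19937
  streams; identical seeds give bit-identical trajectories.  The
  pure-python `step_ensemble` defines the reference semantics and is
  exercised by the invariant tests.

## Known limitations

* No spatial adhesion geometry, membrane tension, Ca2+ dynamics or
  Piezo1 gating: the channel is a scalar on `koff`, as intended.
* Adhesion growth never shrinks within a run, so condition contrasts
  are horizon-dependent; the 200 s default is part of the model
  specification.
* The calibrated kinetic set is one point in a degenerate parameter
  space: other sets may reproduce the same orderings.  Quantitative
  FA lengths and flow speeds are in model units anchored by a single
  published scaling constant, and only orderings and ratios should be
  interpreted.
* Substrate-spring/bulk-modulus conversion is an explicit assumption,
  not a measurement.
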