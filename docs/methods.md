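# Model and methods

`swarmqs` simulates the emergence of quorum-sensing (QS) activation in
swarms of bacteria-based biohybrid microrobots.  Three agent kinds are
modeled: free-swimming *E. coli* (the comparative baseline), NanoBEADS
(single bacteria carrying nanoparticle cargo; one QS-active cell per
agent, 2 um sphere) and BacteriaBots (6 um microparticles propelled by
~12 attached bacteria; 12 QS-active cells sharing one motile body).  The
simulator couples four layers on a single clock: data-driven motility,
hard-sphere collisions, intracellular circuit kinetics, and an
extracellular signal field.

## Motility

**Trajectory replay (biohybrids).**  Instead of a force-based propulsion
model, biohybrid agents replay tracked (speed, turn-rate) sequences *in
order* at the frame rate the tracks were recorded at (0.07 s for
NanoBEADS, 0.77 s for BacteriaBots).  Each simulated agent holds a cursor
into one track; per step its heading rotates by the recorded orientation
change and it translates by the recorded step length.  On exhausting a
track the agent draws a new one, uniformly when the environment is
isotropic.  Replaying in order preserves each track's temporal
correlation structure; this is what lets the simulation reproduce the
experimentally observed subpopulation of highly persistent agents, which
randomly resampling the same values destroys (kept in the code as the
`in_sequence=False` negative control).

Conventions: turn rates are signed, counter-clockwise positive, stored as
the smallest angle in (-180, 180] degrees per frame interval.  The first
turn rate of a track is zero (no orientation change leads into the first
velocity vector), so sequences satisfy `len(speeds) == len(turn_rates) ==
len(positions) - 1` and rotate-then-translate dead reckoning from the
initial velocity's heading rebuilds the positions exactly (tested to
1e-6 um per step).

**Chemotactic bias by group-gated sampling.**  To bias replayed motion up
a gradient without inventing forces, the track library is split into two
equal groups; an agent exhausting a track draws from group one if its
heading projects positively on the gradient direction and from group two
otherwise.  Splits that concentrate the more persistent tracks in the
up-gradient group rectify the motion.  `calibrate_bias` repeats
{random split -> simulate 1000 agents -> compare the chemotaxis partition
coefficient CPC(t) = (B_R - B_L)/(B_R + B_L) against a target curve}
300 times (both counts configurable) and keeps the split with the lowest
unweighted sum of squared errors at the target times.
`migration_bias_ladder` ranks splits by steady-state CPC (mean over the
final 20 min of an 85 min, 1000-agent run) and maps them linearly onto a
0..1 migration-bias scale with bias 1.0 at CPC 0.9.

**Run-and-tumble (free bacteria).**  Bacteria alternate exponential runs
(mean `tau0` = 0.86 s, speed 34 um/s) and exponential stationary tumbles
(mean `tauT` = 0.14 s).  The mean run time is modulated by the material
derivative of receptor occupancy,
`tau = tau0 * exp(sigma_chemo*C_T * Kd/(Kd+s)^2 * (ds/dt + V.grad s))`,
with Michaelis--Menten occupancy (Kd = 18 uM for l-aspartic acid) and the
fitted product `sigma_chemo*C_T` = 35 s; the exponent is clamped to +-5
purely as numerical hygiene for pathological synthetic fields.  The run
time is fixed when the run starts and not re-evaluated mid-run.  Tumble
angles have a log-normal magnitude whose *arithmetic* mean and SD are 68
and 36 degrees (the log-space parameters are solved from the moment
relations; the source statistics are ambiguous about which space they
refer to, and the arithmetic reading is adopted), with a uniform random
sign in 2D.

**Domain.**  Motion is planar (the assays used neutral buoyancy to
suppress vertical motion).  The motility domain is a square (default
1000x1000 um) with periodic y-boundaries, matching the field; an agent
whose proposed move would exit an x wall pauses for that step while its
heading continues to evolve, mirroring the inelastic collision rule.
Populations confined to a colonized patch (the two-population scenario)
pause at all four patch walls instead.

## Collisions

All agents are spheres (2 um bacteria and NanoBEADS, 6 um BacteriaBots).
Collisions are inelastic: a proposed move that would bring two centers
closer than the sum of radii is rejected and the agent pauses until a
heading change clears the contact.  Agents are resolved in random order
per step against current-or-already-accepted positions, with uniform
spatial hashing for neighbor search (verified against a brute-force
all-pairs oracle).  The engine screens a cached near-pair list each step
and only runs the full resolver on pairs whose proposed moves actually
threaten contact; an agent whose proposed position clears every
neighbor's current and proposed position is provably independent of
resolution order and is accepted directly.

## QS circuit and reporter

Each bacterial cell produces AHL at
`A_t = eta * (A1 + A2 * Q^H / (Q^H + Q0^H))` with basal rate A1 = 3.19
molecules/s, upregulated rate A2 = 234 molecules/s, Hill coefficient
H = 2.5 and threshold Q0 = 1.87 nM.  `eta` in (0, 1] is the
ribosome-binding-site strength (relative translation initiation rate),
the circuit-sensitivity design knob; by default it scales the whole
production rate, basal term included, and a config switch
(`eta_on_basal=False`) provides the alternative reading where it scales
only the upregulated term.  The GFP reporter follows two ODEs per cell --
Hill-driven translation of immature GFP (ktr = 0.4 molecules/s),
maturation (kGm = 3.02e-3 1/s), growth dilution mu, and saturable
protease degradation (kdeg = 5.54 molecules/s, Km = 6650 molecules/cell)
-- integrated by explicit Euler with sub-steps of at most 0.1 s
(far below the fastest kinetic timescale; a step-halving check and an
independent root-finder oracle for the saturated steady state are in the
test suite).  Non-negativity is enforced by clipping at zero.  GFP is
tracked in molecules per cell, the unit of the 218 molecules/bacterium
activation threshold; activation time is the first crossing of that
threshold by the mean over all living bacterial cells, interpolated
linearly between recorded samples.

## Signal transport

The extracellular AHL concentration obeys `dQ/dt = D lap Q - Rd Q` with
D = 490 um^2/s in water (scaled to 75% for the extracellular-matrix
scenario) and first-order degradation Rd = 10.8 %/h, solved by an
explicit 5-point stencil at the CFL-stable step with exact exponential
decay per sub-step.  The slab is one micrometre deep: this is the depth
at which the packaged agent-count <-> concentration mapping is exact
(48 agents over 1000x1000 um^2 = 4.8e7 bacteria/ml), and all
molecule-to-molar conversions use it.  Cells deposit their produced
molecules into the grid cell containing them and perceive the
concentration of that same cell.  Boundaries: zero-concentration
(Dirichlet) planes 1000 um beyond the motility domain in x, periodic y,
for the square scenarios; the large two-population domain uses
zero-concentration sinks at its four edges.  That choice is load-bearing
and was settled by experiment: with generous 1000 um far-field margins
instead, the background signal from one activated patch tips even a
two-agent minority over, and the scenario's defining feature -- a
critical minority fraction below which the small patch stays silent --
disappears entirely.  Edge sinks keep the cross-patch background
marginal and the bistable structure intact.

The field, circuit ODEs, deposition and growth advance together every 10
global steps (0.7 s); production rates are evaluated at the previously
synced concentrations.  Q evolves on minute timescales at these
parameters, so the stride is purely a performance choice; diffusion is
sub-stepped to its own stability limit within each sync.

## Growth

Each agent carries a doubling timer, initialized uniformly on
(0, tau_dbl) and reset to tau_dbl on firing.  Doubling times: 43 min for
free bacteria, 121 min for NanoBEADS and particle-attached bacteria;
"half-rate" scenarios double both.  Daughters appear at the mother's
position: NanoBEADS beget NanoBEADS, bacteria beget bacteria, and a
BacteriaBot's daughter detaches as a free-swimming bacterium that then
grows at the bacterial rate.  Daughters inherit the mother's reporter
state (cytoplasm is partitioned at division; a config switch starts them
at zero instead), and growth dilution enters the reporter ODEs as
mu = ln2/tau_dbl whenever growth is on.

## Scenarios and scales

* **Isotropic / gradient**: one population in the 1000x1000 um domain;
  the gradient scenario imposes the assay's linear 1.7e-5 M/mm
  l-aspartic-acid profile centered at Kd.
* **Sweeps**: activation-time mean/SD matrices over eta and migration
  bias (five replicates by default), with not-activated masks.
* **Two-population**: two 100x100 um patches of colonized agents in a
  4x4 mm domain, separated by 2.7 mm (1.3 mm and 1.7 mm presets exist for
  the reduced-separation variant), exchanging signal only by diffusion.
  Colonization is modeled by confining each population's motility to its
  patch: the defining scenario reports local densities and
  still-localized populations hours in, which free swimming at tens of
  um/s would destroy in seconds.

**Grid resolution.**  The default signal grid is dx = 10 um.  Long
parameter sweeps and the packaged acceptance runs use the coarse 25 um
mode (50 um for the very large two-population sweeps); activation times
at 25 um agree with 10 um to a few percent in the reference isotropic
scenario.

**Steady non-activated detection.**  A population is declared stably
non-activated when its mean Gm is below threshold and the rates of change
of mean Gm and mean perceived Q both stay below 1e-6 of their running
maxima for 30 simulated minutes, or at the configured horizon.  In
practice the exponential approach to steady state makes the derivative
criterion conservative, and scripted runs rely on explicit horizons
chosen generously above observed activation times.

## Synthetic trajectory libraries

The tracked data the replay engine was designed around are not publicly
deposited, so the package generates libraries with their published
statistics: per-step speeds from a normal truncated at zero (NanoBEADS
23.4 +- 10.0 um/s, ~14 FPS, ~6 s, 154 tracks; BacteriaBots 2.82 +- 1.62
um/s, 1.3 FPS, 50 s, 26 tracks) and headings from a correlated walk
whose per-track (noise scale, mean-reversion) pair is drawn from a
two-component mixture.  Persistent tracks are *anchored wobblers*: the
heading fluctuates with the full published turn-rate SD but reverts
toward the track's own drift axis, so the turn-rate sequence is
anticorrelated in time.  This reproduces three observations at once --
large turn-rate SDs (606 and 70 deg/s), a persistent subpopulation with
P(6 s) > 0.8 alongside low-persistence agents, and the failure of random
resampling to reproduce persistence.  The mixture weights, scales and
reversions are free calibration knobs: the published summary statistics
cannot distinguish mixtures from heavy tails, so they were fixed once to
match the pooled SD and the qualitative persistence split and not
revisited.  `drift_bias` tilts initial headings and heading increments
toward +x as a stand-in for gradient-condition tracking data; all
packaged presets are isotropic (`drift_bias=0`).

What the generator does *not* emulate: speed--turn-rate coupling within a
track, heavy-tailed turn distributions, track-to-track speed
heterogeneity beyond the mixture, and any agent--agent interaction during
tracking.  Results that depend only on motility statistics (mean speeds,
persistence structure, replay fidelity) transfer directly to real
libraries; quantitative activation-time ratios between agent kinds
inherit uncertainty from these unmodeled features, and the relative
ordering of bacteria, NanoBEADS and BacteriaBots proved robust while the
exact percentage gaps varied by tens of percent across generator
assumptions.

## Numerical and design choices

* Global step 0.07 s (the NanoBEADS frame interval); BacteriaBots update
  every 11th step (0.77 s); one shared clock honors both frame rates.
* Repeated tracked positions record speed 0 and carry the turn rate as 0,
  preserving sequence length.  Zero-path-length persistence is defined
  as 1.  CPC midline ties count as right-hand side.  Grid-cell edge
  positions belong to the lower-index cell.
* Random streams: one root seed, with per-subsystem and per-population
  child streams spawned deterministically, so runs are reproducible
  byte-for-byte and population-size changes do not scramble unrelated
  draws.
* The calibration error metric is an unweighted SSE over the target time
  points -- the simplest defensible reading of "best match".
* The bacteria-equivalence rule for concentration comparisons equates
  total bacteria: NanoBEADS count = 12 x BacteriaBot count at the same
  nominal concentration.

## Known limitations

* 2D only; no advection (the signal's Peclet number is well below 1 in
  the modeled regime); the chemoattractant field is static and
  unconsumed.
* Intracellular chemistry is deterministic per cell (no Gillespie noise);
  stochasticity enters through motility, growth timers and geometry.
* The migration-bias ladder for free bacteria scales the gradient slope
  linearly, which is approximate; sampler kinds use calibrated library
  splits.
* Synthetic libraries stand in for unreleased tracked data; see above for
  what that does and does not validate.
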