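# Methods

`anfsim` simulates a single cat auditory-nerve fiber (ANF) responding to
extracellular stimulation from a cochlear-implant ball electrode placed at
four positions in the scala tympani — the lateral wall (A), beneath the
peripheral dendrite (B), next to the modiolus (C) and mid scala (D) — and
computes the response statistics used to compare electrode placements:
firing-efficiency curves with threshold and relative spread, first-spike
latency and jitter, spike-initiation sites, conduction velocity, and for
pulse trains the PSTH, onset-rate/level function, dynamic range and
interspike-interval statistics.

## The fiber model

The fiber is a multicompartment cable: six peripheral nodes of Ranvier
(P1–P6, fiber diameter 1.2 µm), a passive cell body, and twenty central
nodes (C1–C20, diameter 2.3 µm), with each internode divided into nine
myelinated passive compartments.  Nodes are 1 µm long; internode length is
100 fiber diameters.  Per-node channel complements follow fixed densities
(Na 80 µm⁻², K 45 µm⁻² over the nodal area πdL), giving 302 Na / 170 K
channels at peripheral and 578 Na / 325 K channels at central nodes, with
single-channel conductances γ_Na = 22.65 pS and γ_K = 50 pS.  E_Na = 66 mV;
the initial K Nernst potential is −88 mV ([K]_in = 140 mM fixes the
baseline [K]_ext ≈ 5.2 mM through E = (RT/F) ln([K]_ext/[K]_in) at 37 °C,
where RT/F ≈ 26.7 mV).  Resting potential is −78 mV, with the nodal leak
reversal set there so the membrane is stationary at rest.

Channel gating is an exact-count Markov process: Na channels occupy the
8-state m³h scheme (conducting state m₃h₁) and K channels the 5-state n⁴
chain.  Each 1 µs step draws, per occupied state, a binomial number of
channels leaving through the summed exit probability and splits them between
competing destinations by conditional binomials, so each channel makes at
most one transition per step and counts are conserved by construction.
Rate functions are HH-type linoid/sigmoid forms of the depolarisation
relative to rest, referenced to 37 °C with Q₁₀ scaling (2.2 Na, 3.0 K);
every coefficient is a configuration value.  A deterministic limit
(expected-value flows in place of sampled counts) is available for
convergence checks and for bracketing thresholds; in that limit the
firing-efficiency curve is a step function of level.

The cable equation is integrated by Crank–Nicolson with the constant
passive terms time-centred; the stochastic channel conductance of the step
enters the diagonal semi-implicitly (the ionic current is linearised about
the current voltage), which removes the stiffness of the explicit ionic
term at strongly driven compartments without changing the scheme's accuracy
regime.  The extracellular drive enters through the axial difference term
of Ve[k][t] = R_t[k]·I(t), using the stimulus value over each sample
interval (the sampled pulse is piecewise constant, so this is exact in
charge at any step size; trapezoidal averaging would smear the pulse
edges).  Compartments in the electrode's near field have driven time
constants below 1 µs, so the samples just after a pulse edge carry a
boundary-layer discretisation transient; the recorded C16 trace is
unaffected (dt-halving changes it by ~0.2%).  Sweeps reset all state (channels from the
resting stationary distribution, [K]_ext to baseline) and are reproducible
bit-for-bit under a fixed seed.

### Cable parameters

The published morphology fixes the channel complement, which at these
densities supplies at most ~13 nS of Na conductance per central node.  For
a cable with that sparse complement to initiate and conduct action
potentials, the internodal load must be correspondingly small; the passive
parameters are therefore effective values chosen together (and exposed in
the configuration):

* axon core = 0.6 of the fiber outline, effective axoplasmic resistivity
  200 Ω·cm — internodal resistance ≈ 0.3 GΩ (central);
* nodal specific capacitance 0.4 µF/cm², nodal leak 3.3 mS/cm²;
* myelin as a series-capacitance divider: two membranes per 12 nm lamella
  period over the 1 µm sheath (attenuation ≈ 334);
* the soma is passive with light myelination (12 membrane wraps).

With these values the model yields a central-axon conduction velocity of
≈ 12–13 m/s, spike initiation during/just after the 40 µs cathodic phase
followed by a slow regenerative rise (~0.2–0.3 ms to full spike near
threshold), and FE=0.5 latencies at C16 of ≈ 0.55–0.70 ms depending on the
initiation site — the regime the experiment's reference values describe.

## The volume-conductor surrogate

The 3D finite-element field solve is replaced by an analytic point-source
model.  Each electrode is a monopole in the scala tympani (σ = 1.43 S/m,
published tissue table); the transfer resistance to compartment k is

    R_t[k] = T_k · exp(−r_k / L_s) / (4π σ_ST r_k)

with T_k = 2σ_ST/(σ_ST + σ_k) the planar-interface transmission factor into
the compartment's tissue and L_s = 0.8 mm an exponential screening length.
Two deliberate choices:

* **Transmission factor instead of a harmonic-mean effective conductivity.**
  A harmonic mean lets the very low organ-of-Corti conductivity (0.012 S/m)
  inflate the potential at peripheral compartments by an order of
  magnitude, which inverts the threshold ordering across electrode
  positions; the bounded transmission factor keeps the decay governed by
  the perilymph that actually carries the current.  The harmonic-mean
  blend remains available (`sigma_blend: "harmonic"`).
* **Screening.** An unbounded medium overstates the far field of a source
  inside a narrow fluid duct whose walls divert return current; the
  exponential factor is the simplest bounded-domain correction.  Without
  it, a distant electrode ignites the central axon directly through its
  far field and the latency ordering between electrode positions is lost.

The fiber runs along the x axis of the cross-section plane: peripheral
process from the origin through the organ of Corti, crossing into the bony
channel at x = 0.18 mm (the habenular transition), soma at x ≈ 0.62 mm,
central axon through the modiolus into nerve tissue.  Electrode positions
(mm): A (−0.95, −0.50), B (0.06, −0.35), C (0.52, −0.28), D (0.35, −0.50).
The electrode–fiber distances are free parameters of the surrogate (the
source experiment shows only a schematic); these defaults were calibrated
once so that the published electrode-position patterns emerge — nearest-node
distance and single-pulse threshold both ordered C < B < D < A, initiation
at P1/P2 for A and B, peripheral initiation for D, near-soma/central
initiation for C, and the C-vs-A latency difference — and they are not
revisited per run.  The ball diameter (0.45 mm) only guards against
compartments lying inside the conductor; at the distances used the monopole
term dominates.

Absolute thresholds come out roughly 2–10× the reference values (0.5–5 mA
instead of 0.3–2.7 mA) because the surrogate's activating function scales
with the reduced axial conductances discussed above; all ordering and
dispersion statistics are unaffected by this common scale.

## Potassium accumulation and rate adaptation

Outward K charge at each node — the gated K current plus the K-carried
fraction (0.8) of the nodal leak deviation — is convolved with
g(t) = exp(−t/τ), τ = 20 ms, and converted to a perinodal concentration
increase through an effective shell volume (nodal area × 3 nm).  The
elevated [K]_ext raises E_K, and because the leak is largely K-selective
the leak reversal follows with weight 0.8, depolarising the node and
inactivating Na channels during sustained firing.

In this membrane the mechanism is bistable: a mild [K]_ext rise facilitates
(the node sits closer to threshold) while a strong rise inactivates Na
faster than it approaches threshold.  The default shell volume places the
calibrated pulse-train conditions on the adapting side at both 250 and
5000 pulses/s, with the onset (0–12 ms) rate well above the steady
(100–200 ms) rate and the decline almost entirely attributable to the
mechanism (disabling g(t) leaves the steady rate near the onset rate).
The cost is that adaptation is stronger than the reference data: steady
rates decay toward tens of spikes/s rather than plateauing near
115–140 spikes/s, so steady-window interval statistics are sparse.  The
peripheral nodes, having half the area (twice the concentration gain),
adapt first, which shifts high-rate initiation sites centralward and
broadens the initiation-node distribution relative to single pulses.

## Analysis definitions

* Firing efficiency: fraction of sweeps with ≥1 spike at C16 (upward
  crossing of −20 mV with a 0.5 ms hold-off).
* FE curve: FE(I) = Φ((I − θ)/(RS·θ)) fitted by binomial maximum
  likelihood; θ is the FE=0.5 level and RS the relative spread.  A
  profile-likelihood CI for θ is available.
* Latency/jitter: mean/SD of first-spike times from stimulus onset.
* Initiation node: the node whose inward Na current first crosses 25% of
  its own peak; nodes whose peak is below 20% of the global peak are
  excluded (channel noise floor); ties break peripherally.  For trains the
  rule is applied within ±1 ms of each recorded spike.
* Conduction velocity: least-squares slope of node position vs first-spike
  time over C4–C14.
* Train threshold and dynamic range: line fit to onset-rate vs level;
  threshold at 100 spikes/s, dynamic range 20·log₁₀(I₂₅₀/I₁₀₀) (amplitude
  decibels).
* ISI histograms: successive-spike differences within a window, pooled
  across sweeps, 50 µs bins.
* Calibration: bisection on amplitude against a fixed-size Monte-Carlo
  objective (FE over 100 sweeps, tolerance 0.05; onset rate over 30
  sweeps, tolerance 10 spikes/s), bracketed by the deterministic-limit
  threshold.  Onset-rate calibrations simulate only the onset window.

## Problem sizes

The full study protocol uses 100 single-pulse sweeps per level and 30
pulse-train sweeps of 200 ms.  `scripts/acceptance.py` runs the full
single-pulse protocol (100-sweep calibrations and FE levels, 20-sweep
velocity estimate).  The test suite runs the same procedures at reduced
sizes chosen for a single-CPU run: 48-sweep calibrations and FE levels,
60-sweep latency measurements, 10–12 train sweeps, and chi-square channel
statistics over ~4×10⁵ pooled channel observations.  The reduced sizes
widen Monte-Carlo error accordingly; the tolerances used in the tests
reflect that (e.g. relative-spread extremes to ±0.010–0.012 instead of the
±10% used at full size).

## What the synthetic conditions do and do not show

All inputs are generated internally: there is no external data.  The
surrogate field reproduces first-order electrode-position physics —
distance-dominated thresholds, activating-function initiation sites,
conductivity contrasts at tissue boundaries — but not the FEM-specific
current pathways of a real (or meshed) cochlea.  Consequences observed with
the default geometry: the high-rate dynamic range is *narrowest* for the
perimodiolar contact (its recruitment is steepest because it is closest),
whereas the reference experiment reports it widest there with all high-rate
dynamic ranges compressed to ~0.2–0.4 dB; and absolute thresholds carry a
common scale offset.  Passing tests therefore validate the biophysics,
the analysis chain and the relative electrode-position patterns, not
patient- or cochlea-specific field predictions.

## Known limitations

* Adaptation strength at calibrated train levels exceeds the reference
  data (steady rates near zero); the facilitation/block balance of the
  K-accumulation mechanism is knife-edged in a two-state membrane.
* Jitter at the perimodiolar position (~0.04–0.06 ms) is larger than the
  reference 0.024 ms; jitter elsewhere (~0.01–0.02 ms) matches.
* Single fiber only: no fiber-diameter population, no demyelination
  pathology, no vector-strength analysis.
* The instability guard tolerates large driven polarisation near the
  electrode (limit 500 mV plus twice the decaying local drive envelope);
  extreme overdrive (≫10× threshold) can still be rejected as unstable.
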