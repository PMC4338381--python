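# anfsim

A stochastic multicompartment model of a cat auditory-nerve fiber (ANF)
under extracellular electrical stimulation, built to study how the position
of a cochlear-implant electrode in the scala tympani shapes the fiber's
spatiotemporal spike responses.  It is aimed at computational
neuroscientists and neural-prosthesis researchers who want a fast,
reproducible single-fiber testbench for electrode-placement questions.

## What it computes

The fiber is a Crank–Nicolson cable (1 µs step) with six peripheral nodes,
a passive soma and twenty central nodes of Ranvier; each node carries
integer-count Na (8-state m³h) and K (5-state n⁴) channel populations
updated by a Markov channel-number-tracking algorithm (binomial sampling of
per-step transitions).  Nodal ionic current is

    I_ion = γ_K N_{n⁴} (V − E_K) + γ_Na N_{m³h₁} (V − E_Na)

with γ_Na = 22.65 pS, γ_K = 50 pS, densities 80 and 45 µm⁻², E_Na = 66 mV
and E_K evolving with perinodal K⁺ accumulation,
E_K = (RT/F) ln([K⁺]_ext/[K⁺]_in), which drives spike-rate adaptation
during pulse trains.  The intracochlear field of a ball electrode is a
parametric volume-conductor surrogate (point source with tissue-interface
transmission factors and bounded-domain screening) standing in for a
finite-element solve; four default electrode positions A–D span lateral
wall to perimodiolar placements.

On top of the membrane core the package implements the standard
single-fiber analyses: firing-efficiency (FE) curves with integrated-
Gaussian fits for threshold θ (FE = 0.5) and relative spread RS = σ/θ,
first-spike latency and jitter at central node C16, Na-influx-based
spike-initiation sites, conduction velocity, PSTHs with the 0–12 /
… / 100–200 ms wide bins, onset-rate/level functions with train threshold
and dynamic range, and 50 µs interspike-interval histograms.

## Worked example

```python
from anfsim import (ExperimentConfig, calibrate_amplitude, firing_efficiency,
                    latency_stats, make_waveform, run_sweeps)
from anfsim.experiment import setup_for_electrode

config = ExperimentConfig()
cable, field = setup_for_electrode(config, "C")     # perimodiolar analog
pulse = make_waveform("single_pulse", 1.0, 40, duration=2.0, sample_step=1.0)

theta = calibrate_amplitude(cable, field, pulse, target=0.5,
                            seed=7, n_sweeps=100)
sweeps = run_sweeps(cable, field, pulse.scaled(theta), 100, seeds=12,
                    record_ina=True)
print(f"theta = {theta:.3f} mA, FE = {firing_efficiency(sweeps):.2f}")
stats = latency_stats(sweeps)
print(f"latency = {stats.mean_latency_ms:.3f} ms, "
      f"jitter = {stats.jitter_ms:.4f} ms")
print("initiation:", {s.initiation_node for s in sweeps if s.spiked})
```

prints (seeds as above):

```
theta = 0.608 mA, FE = 0.55
latency = 0.593 ms, jitter = 0.0521 ms
initiation: {'P5', 'P6'}
```

i.e. the perimodiolar contact fires the fiber at ~0.7 mA, with spikes
initiated at the near-soma nodes and arriving at C16 about 0.6 ms after
pulse onset.  The same calibration for the lateral-wall analog ("A") gives
a ~7× higher threshold, initiation at P1/P2 and a longer mean latency —
the position effect the model exists to quantify.

The command line mirrors the workflow
(`anfsim simulate-single --electrode C --level 0.7`,
`anfsim calibrate --electrode A`, `anfsim report-table2`,
`anfsim validate`); `report-table2` runs the full A–D × {single pulse,
250 pps, 5000 pps} grid and writes the summary tables and per-panel CSVs.

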