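# fishbone

A computational model of the **fishbone tactile illusion** (FTI): when a
fingertip strokes a flat smooth bar flanked by rough rib textures, the bar
feels hollow.  Presented through a passive pin matrix — which transmits only
the vertical component of the surface — the illusion weakens sharply
whenever the rib spacing is commensurate with the pin lattice, so that all
rib pins rise and fall in synchrony.  This package simulates the full chain
from surface geometry to afferent population statistics and asks whether the
*temporal frequency* and the *temporal asynchrony* of simulated spike trains
can account for the perceptual judgments.

It is written for computational neuroscientists and psychophysicists who
want to re-run, probe, or extend the simulated experiment: every stage is a
plain Python function over NumPy arrays / pandas frames, with a thin CLI on
top.

## The model

**Stimulus.** The fishbone surface is a height field Φ(x, y) ∈ {0, h₀} with a
spine of width `Lw` along y and ribs of thickness `L1` repeating with period
`L1 + L2`.  A stationary pin with spherical tip radius `r_p` riding on the
moving pattern Φ(x, y − Vt) has vertical displacement

    h = h₀ + √(r_p² − ξ²) − r_p   for ξ < ξ* = √(2 r_p h₀ − h₀²),  else 0,

where ξ is the axis-aligned distance to the nearest raised edge.

**Transduction.** Pin displacement maps linearly to mechanosensitive-channel
displacement σ = χ·h (σ in µm).  The receptor conductance is
g = g_max · p · (1 − q) with sigmoidal relaxation dynamics for the open
probability p (time constant τ_p, midpoint x_p shifted by α_p·q — adaptation)
and the inactivation probability q (τ_q, midpoint x_q) — a rapidly adapting
(Piezo2-like) receptor.

**Spiking.** Each of 72 afferents (6 × 12 lattice over a 10 × 20 mm
fingertip, 4 receptors placed at random within a 1 mm receptive field)
integrates its receptor currents I_stim = Σⱼ gⱼ·(v − v_eq + v_offset) at a
spike initiation zone modelled with the classical Hodgkin–Huxley equations
(0 mV rest convention).  The coupled system is advanced with classical RK4
at dt = 0.01 ms; firing events are upward crossings of v* = 40 mV.

**Statistics.** Spikes pooled over the population are counted in Δt = 4 ms
bins; synchrony is the Shannon entropy H = −Σ pᵢ ln pᵢ of the bin occupancy
(low H = synchronous firing) and the rate is F̄ = ΣFᵢ/(T·N_n).  The same
entropy applied to the times of maximum pin displacement (or maximum
|dh/dt|) measures the temporal incoherence of the stimulus itself.

**Psychophysics.** Two-alternative forced-choice indentation judgments over
the nine rib intervals are scaled with Thurstone's Case V model, and
perception ranks are compared with model statistics using Kendall's τ-b and
Spearman's ρ (exact permutation p-values at n = 9).  Because the study's raw
participant data are not deposited, a seeded Thurstonian generator produces
synthetic choice tables with the qualitative structure of the reported
judgments, so the analysis stage is testable end to end.

## Worked example

```python
from fishbone import SimulationConfig, run_condition, sample_seed_sequence

cfg = SimulationConfig(n_samples=5, master_seed=1)   # 800 ms at 50 mm/s
for L2 in (0.4, 1.0):
    spikes, row = run_condition(cfg, "PM1", L2, sample_seed_sequence(1, 0))
    print(f"L2={L2:.1f} mm: {row['n_events']} spikes, "
          f"mean rate {row['mean_rate_per_ms']*1000:.1f} Hz/afferent, "
          f"spike-time entropy {row['entropy_nats']:.3f} nats")
```

prints

```
L2=0.4 mm: 2225 spikes, mean rate 38.6 Hz/afferent, spike-time entropy 5.290 nats
L2=1.0 mm: 1560 spikes, mean rate 27.1 Hz/afferent, spike-time entropy 4.129 nats
```

The 0.4 mm rib interval drives the population hardest (the interval judged
most indented), while at 1.0 mm — commensurate with the 1.0 mm pin lattice —
the entropy drops by more than one nat: the rib pins move in phase and the
population fires in synchrony, the regime in which the perceived indentation
collapses.

The same experiment from the shell:

```bash
fishbone simulate --matrix PM1 --samples 5 --out summary.csv
fishbone run-all --config examples/run.toml --out-dir results/
```

`run-all` executes sweep → metrics → stimulus incoherence → synthetic
psychophysics → correlation table, writing CSVs, a `report.json`, and a
resolved-config sidecar with a hash for provenance.

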