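# Methods

This note documents the model, its parameters, the numerical choices, and
the design decisions taken where the formulation was genuinely open.  Units
are millimetres and milliseconds throughout the geometry and integration;
channel displacements are micrometres, potentials millivolts.

## Stimulus geometry and pin sampling

The fishbone surface is binary-valued: height h₀ on the spine
(|x| < Lw/2, spanning all y) and on the ribs (y mod (L1+L2) ∈ [0, L1),
spanning all x), zero elsewhere.  Because the spine spans all y and the
ribs span all x, the nearest raised point from any gap position is always
axis-aligned, so the four-candidate nearest-edge rule used for the pin
displacement is exact for this geometry (there are no corner cases in the
literal sense).

A pin whose tip is a sphere of radius r_p = d₂/2 stays in contact with a
raised edge out to ξ* = √(2 r_p h₀ − h₀²).  Two consequences worth noting:

- with h₀ = 0.1 mm and r_p = 0.4 mm, ξ* ≈ 0.265 mm, so in the 0.2 mm
  rib-interval condition the pin never reaches the floor between ribs; its
  displacement oscillates only between ≈ 0.087 and 0.1 mm;
- r_p < h₀ is rejected (the tip could not ride over the print).

Scanning moves the pattern in +y under the stationary pin lattice at
V = 0.05 mm/ms (50 mm/s).  A pin's trace is periodic with period
(L1+L2)/V; the initial pattern offset (phase) is drawn once per finger
sample as a uniform fraction of the rib period, so one draw serves every
rib interval and the same finger sample is comparable across conditions.
A fixed phase can be configured for exact-reproducibility runs.

Pin matrices: PM1 (spacing 1.0 mm, d₁ = d₂ = 0.8 mm), PM2 (spacing 2.0 mm,
d₁ = 1.8, d₂ = 0.8), PM3 (spacing 2.0, d₁ = d₂ = 1.8).  d₁ for PM2/PM3 is
taken as the larger pin-head diameter consistent with the apparatus
drawings; it is configurable, and only enters through the coupling radius
2·r₁.  The lattice always carries one column at x = 0 (under the spine
centre) and extends 2·r₁ beyond the 10 × 20 mm fingertip so edge receptors
see their full candidate pin set.

## Transduction

σ(t) = χ·h(t) with χ = 0.07 applied to the height in µm (full print height
→ 7 µm).  Channel dynamics (τ_p = 2.5 ms, τ_q = 8 ms, k_p = 2.6 µm⁻¹,
k_q = 1.2 µm⁻¹, x_p = 4 µm, x_q = 6 µm, α_p = 4.6 µm, g_max = 1) give a
rapidly adapting receptor: a sustained 7 µm step produces a conductance
transient that decays to g ≈ 0.046 per receptor, and a second pulse arriving
before q has relaxed is attenuated.  σ is sample-and-held over each
integration step (the trace is generated on the same grid; no interpolation
is invented).

## Afferent model and initialization

Each afferent sums the receptor currents of its N_r = 4 receptors,
I_stim = Σ g_j (v − v_eq + v_offset) with v_eq = 60, v_offset = −10 mV
(reversal at +70 mV, so contact depolarises), into a standard
Hodgkin–Huxley compartment (ḡ_Na = 120, ḡ_K = 36, ḡ_L = 0.3 mS/cm²,
v_Na = 115, v_K = −12, v_L = 10.6 mV, C_m = 1 µF/cm²; the sodium
inactivation gate is named `h_gate` to avoid colliding with the pin height
h).  Firing events are upward crossings of v* = 40 mV.

**Initialization policy.**  Receptors start at the channel equilibrium of
their actual t = 0 stimulus.  The membrane starts at the fixed point of the
full coupled system given the resulting standing conductance — not at the
zero-conductance rest state.  This matters: an afferent under sustained
full contact (e.g. over the spine) carries a standing conductance of
≈ 0.18 mS/cm², for which the membrane is bistable — a stable quiescent
fixed point (v ≈ 6 mV) coexists with a tonic limit cycle (≈ 67 Hz).
Starting at naive rest lands on the limit cycle and floods every condition
with sustained-contact firing; starting at the consistent fixed point
yields the silent-backbone, transient-dominated behaviour of a rapidly
adapting afferent population.  Afferents under time-varying stimulation are
kicked off the fixed point within the first scan cycle, so for them the
choice is immaterial.  No burn-in window is discarded; the full [0, T]
window is analysed.

## Receptor–pin coupling

Pins whose centre lies within 2·r₁ of a receptor are candidates.  By
default the receptor is driven by the **nearest** candidate pin: the skin
immediately under a pin head follows that pin.  Combining several
phase-staggered pins by a maximum (or sum) rule was evaluated as a
sensitivity variant and remains available
(`SimulationConfig(coupling_rule="max" | "sum")`), but it effectively
low-pass-filters the stimulus — the maximum of staggered periodic traces
loses its troughs — which suppresses exactly the displacement transients a
rapidly adapting channel responds to, and it shifts the firing-rate maximum
away from the 0.4 mm rib interval.  The nearest-pin rule is also the most
literal reading of a pin matrix: each patch of skin rides on one pin.
Receptors beyond 2·r₁ of every pin (possible only with narrow pin heads on
the coarse lattice) receive σ = 0.

## Numerics

- Classical RK4 on the coupled 4 + 2·N_r dimensional system per afferent;
  conductances are recomputed from channel states at every stage.
  dt = 0.01 ms (halving dt changes sub-threshold trajectories by < 10⁻⁶ mV
  and spike times by ≤ 0.1 ms against a tenfold finer reference).
- The inactivation target 1/(1+exp[−k_q(σ−x_q)]) depends only on the held
  stimulus, so it is tabulated once per rib period — an exact algebraic
  rewrite that removes half of the channel exponentials.
- The per-receptor stimulus is tabulated over one rib period and indexed
  modulo the period length; configurations whose period is not an integral
  number of steps fall back to tabulating the full window.
- Two interchangeable integrator backends: a numba-compiled per-afferent
  scalar kernel (default when numba is importable) and a vectorised NumPy
  loop.  Afferents are advanced independently in both, so batching finger
  samples into one call is bit-identical to running them separately; the
  backends agree to within one integration step on every spike time.
- The HH rate functions use x/expm1(x) with the analytic limit at the
  removable singularities (v = 25, v = 10 mV).
- Integration blow-up (non-finite state) raises immediately with the
  offending condition identified.
- Seeding: finger sample k draws from `SeedSequence(master_seed,
  spawn_key=(k,))`, so adding samples never perturbs earlier ones, and
  every result is reproducible from (config, master seed).

## Response statistics

Events are binned half-open into [(i−1)Δt, iΔt) with Δt = 4 ms over
T = 800 ms (n = 200 bins; the right edge folds into the last bin).  Entropy
uses natural logarithm (nats) with 0·ln 0 = 0 and H := 0 for an empty event
set, keeping the metric total.  The mean rate is F̄ = ΣFᵢ/(T·N_n) in
events/ms (×1000 for Hz).

Stimulus incoherence pools, over all pins of a condition, the times of
strict local maxima of h(t) (mode `height`) or of |dh/dt| by central
difference (mode `height_change`; the default, since displacement *changes*
are what the rapidly adapting channel transduces), then applies the same
binning and entropy.  Plateaus count once at their first sample; window
endpoints are never maxima; constant traces (spine pins) contribute
nothing.  Both modes assume the same Δt = 4 ms as the spike analysis;
the bin width is exposed as a parameter.

## Synthetic psychophysics generator

The generator emulates the structure of the pairwise-comparison experiment:
nine rib intervals, 36 unordered pairs, configurable participants and
trials per pair (the study used 12 participants and retained 4 trials per
condition).  Choices follow Thurstone Case V: each stimulus evokes an
independent normal draw around its latent scale value (common dispersion 1)
and the larger draw is chosen, so P(i over j) = Φ((sᵢ−sⱼ)/√2).  Bundled
latent profiles encode the qualitative shape of the reported judgments:
`unimodal` peaks at the 0.4 mm interval and decays monotonically beyond
1.4 mm; `unimodal_with_dips` additionally depresses 1.0 and 2.0 mm (the
coherent-stimulus dips); `flat` is the null profile; `custom` passes user
values through.  The package deliberately ships no numbers read off the
published figures — users with access to real per-interval probabilities
supply them as a CSV.

What the generator does *not* emulate: participant heterogeneity (optional
jitter is off by default), learning/fatigue, finger kinematics, or any
dependence of perception on the simulation itself.  Passing the closure
tests therefore shows that the analysis chain is correct and internally
consistent — not that the model predicts human judgments; that comparison
requires the study's own data.

## Scaling and analysis conventions

Thurstone scaling uses the classical least-squares Case V solution (column
means of the probit matrix with zero diagonal, zero-meaned), with unanimous
proportions clipped to [1/(2N), 1−1/(2N)].  Rank correlations are Kendall
τ-b and Spearman ρ; for n ≤ 9 items the two-sided p-value is computed by
exact enumeration of all n! orderings (362 880 at n = 9), which suits the
nine-interval setting better than asymptotics.  Constant inputs leave the
coefficient undefined (NaN) rather than raising.

## Problem sizes

The package's standard experiment is 9 rib intervals × 5 finger samples per
pin matrix at T = 800 ms and dt = 0.01 ms (45 population integrations of
72 afferents each per matrix); this is the size used by the test suite and
the acceptance script and completes in a few minutes per matrix on one
CPU.  The sample count is configurable (`n_samples=20` reproduces the
study-sized ensemble at proportional cost); condition means stabilise well
below that (between-sample standard deviations are ~2 % of the mean rate).

## Known limitations

- No skin mechanics: pin displacement transfers directly to the receptor
  (the model deliberately omits elastic coupling between pins).
- Under weak stimulus modulation (e.g. the 0.2 mm rib interval, where the
  pin cannot descend into the slit), afferents operate near the tonic
  regime and phase-lock only weakly, so their spike-time entropy is close
  to maximal; conclusions about that condition rest on the ideal-pin
  assumption above.
- The entropy is the only synchrony measure implemented; no
  cross-correlogram or spike-distance alternatives.
- Axonal propagation, SA-I (slowly adapting) channels, and
  receptive-field overlap statistics beyond uniform random placement are
  out of scope.
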