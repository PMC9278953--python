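# Methods

## Scope and model overview

`pvnet` simulates how a hyperpolarizing shift of the Kv3 potassium-channel
activation voltage changes the firing of fast-spiking parvalbumin (PV)
interneurons and, through them, the activity and gamma-band output of a
reduced cortical circuit.  Three stages share one code path:

1. **Channel gating** — closed-form steady states and time constants for
   each mechanism, exposed as pure functions of voltage.
2. **Cells and protocols** — single-compartment conductance-based PV and
   pyramidal-cell (PC) models advanced by a fixed-step integrator, plus
   the experiment runners (F–I curves, voltage clamp, synaptic
   bombardment, in-silico dynamic clamp, parameter scans).
3. **Network and analysis** — a 200 PC + 20 PV circuit with seeded random
   connectivity, an LFP proxy with Welch spectra, and the curve-fitting
   stages (Boltzmann, mono-exponential, exponential trend).

## Gating equations

Kv3 activation follows

    m_inf(v) = 1 − 1 / (1 + exp((v + 5 + vshift) / 12))

which places the control half-activation voltage at −5 mV.  The public
parameter `delta_shift` is the change of the half-activation voltage
(negative = hyperpolarizing); internally `vshift = −delta_shift`, so
`delta_shift = −10` moves half-activation to −15 mV, the AD-like
condition.  Inactivation is `h_inf(v) = 1/(1 + exp((v + 30 + vshift)/10))`
with a fixed time constant `tau_inact` (default 1000 ms; 50–1000 ms in the
inactivation scans, where an independent `inact_shift` can also move the
inactivation curve alone).

The activation/deactivation time constant is a Gaussian bell on a floor:

    mtau(v) = 0.5 + 4 · exp(−0.5 · ((v + vshift + 25) / 25)²) · scale   [ms]

peaking at 4.5 ms at v = −25 + delta_shift.  Two transcription choices
were genuinely open and are recorded here: the bell width (25 mV, chosen
so the time constant varies smoothly over the physiological range and the
kinetics knob has the observed effects on firing and spike width; a much
narrower bell would make the time constant effectively
voltage-independent) and the placement of the kinetics multiplier
(`kin_scale` multiplies the Gaussian term only, the printed operator
order; `kin_scale_mode="whole"` selects the alternative).  Both parses
agree at `scale = 1`, where the analytic checks are made.

Sodium is the classic Hodgkin–Huxley m³h scheme with three adjustable
parameters: a rigid voltage shift, a uniform kinetics multiplier
(`nav_kin_scale`), and `nav_h_scale`, which rescales the recovery rate
α_h alone.  The last knob slows recovery from inactivation (and lowers
the h steady state) without touching the depolarized closing rate that
shapes the spike, giving the model use-dependent sodium availability:
first spikes are unaffected while sustained high-frequency firing runs
down.  The α_m removable singularity at −40 mV is evaluated through
`scipy.special.exprel`.

Kv7 (M-current) activates at −27 mV with a 5 mV slope and slow
Yamada-style kinetics (~50–150 ms).  The steep slope means subthreshold
activation is negligible at both the control and the −10 mV-shifted
half-activation voltage; the M conductance that accumulates during
spiking is driven by the suprathreshold excursions, which saturate the
activation curve in either condition.  This is what makes the M-current
reduce firing when added while being insensitive to a ±10 mV shift of
its activation voltage.

## Integrator

All gates use the exact exponential update
`x ← x_inf + (x − x_inf)·exp(−dt/τ)`, which is the analytic solution at
frozen voltage (hence unconditionally stable and semigroup-consistent).
The voltage uses an exponential-Euler step: all conductance sources —
channels, alpha synapses, dynamic clamp, gap junctions with the partner
voltage frozen over the step — form one equivalent conductance G and
weighted reversal, and v relaxes toward their balance point with rate
G/C.  Default dt = 0.025 ms; halving dt changes subthreshold trajectories
by < 0.5 mV RMS and spike counts by ≤ 1 per window (tested).  A ±150 mV
guard raises `NumericalBlowup` with the failure time.

Alpha synapses (`g(t) = gmax·(t/τ)·exp(1 − t/τ)`, peak exactly `gmax` at
`t = τ`) are integrated as an exactly solvable two-state cascade, so
thousands of events per run cost two state variables per receptor class.

## PV model calibration

The PV cell is one 20 µm × 20 µm compartment (read as a cylinder,
lateral area π·d·L ≈ 1257 µm², 12.57 pF at 1 µF/cm²; a flat-sheet
reading is selectable).  Passive leak (8·10⁻⁴ S/cm², E_leak −68 mV)
gives ~100 MΩ input resistance and a stable rest near −72 mV.

Current amplitudes in the square-pulse protocols are specified in pA/pF
and converted with a normalization capacitance of 47 pF — the mean
measured capacitance of the recorded interneurons — rather than the
model compartment's 12.6 pF.  The model is calibrated to reproduce the
recorded cells' current-normalized input–output relation, not their
membrane area; using the model's own (4× smaller) capacitance would
compress the entire F–I range to a fraction of the printed amplitude
axis.

Active densities (gNa 0.3, gKv3 0.06 S/cm², `nav_kin_scale` 0.15,
`nav_h_scale` 0.4) were selected, before any network work, so that the
model jointly satisfies the single-cell phenotype battery:

- fast non-adapting spiking (last/first ISI < 1.3), rheobase ~5 pA/pF,
  maximum ~330 Hz, first-AP half-width ~280 µs;
- −10 mV Kv3 shift: near-threshold firing collapses; the maximum falls
  ~20% but returns to within 10% of control when the Kv3 kinetics are
  co-accelerated (`kin_scale` 0.5);
- Kv3 kinetics alone move both maximal rate and AP width in the expected
  directions;
- halving gNa produces high-current firing failures (use-dependent
  run-down via `nav_h_scale`) while the first-AP half-width changes
  < 5%, and max dV/dt grows monotonically with density;
- Kv3 inactivation kinetics (τ 50–1000 ms) and inactivation-voltage
  shifts are inert (< 5% on rates and width) because the ~300 µs APs are
  too brief for inactivation to accumulate.

## Bombardment, dynamic clamp, gEPSPs

The bombardment protocol attaches 1000 excitatory (0 mV) and 500
inhibitory (−90 mV) 10 nS alpha synapses at uniform random times over
1 s.  The synaptic time constants are not constrained by the protocol
definition; they are the calibration dial for this stage and are fixed
at 0.1 ms (excitatory) and 1.8 ms (inhibitory), which puts the control
firing rate at ~31 Hz against the 30.64 Hz target.  Event times are
drawn per seed and shared across shift conditions, so shift effects are
paired.

The in-silico dynamic clamp evaluates the identical Kv3 equations on the
live membrane potential and injects `g_total·m·h·(v − e_rev)`.  With the
default 20 nS: the unshifted conductance leaves the F–I curve within 2%
(it is small against the cell's intrinsic Kv3), while the −10 mV-shifted
version suppresses near-threshold firing and leaves the maximum within
5%.

gEPSP trains are regular 10 Hz alpha-conductance events.  The default
3.5 nS sits just above the ~3–4 nS single-EPSP spike threshold
(comparable to the ~4.7 nS used experimentally), which is the regime in
which the control and unshifted-supplement conditions fire on every
event while the shifted supplement blocks spiking.

## Pyramidal-cell burster

The PC is a square-wave pacemaker burster: instantaneous-activation fast
Na whose recovery variable is shared with the delayed-rectifier gate
(I_Na = g_Na·m∞³·(1−n)·(v−E_Na), I_K = g_K·n⁴·(v−E_K)), plus a
persistent Na current with seconds-scale inactivation as the burst
clock, plus leak.  The canonical constants are stated for a 21 pF
pacemaker cell; every conductance is rescaled by the capacitance ratio
to this package's 12.57 pF compartment, which leaves the dynamics
exactly invariant.  With E_leak −60 mV and a few pA of bias the model
produces bursts of ≥ 2 spikes with interburst intervals ~10× the
intraburst ISI; mean rate grows monotonically with bias.

## Network construction and calibration

Connectivity: independent Bernoulli draws per ordered pair at the stated
probabilities (PC→PC 10%, PV→PC 36%, PV→PV chemical 78%, PV gap 61%,
PC→PV 80%), no self-connections, gap junctions drawn per unordered pair
and symmetric.  Each seed fixes connectivity, weights and the per-cell
bias currents (uniform 2–8 pA for PCs, 100–200 pA for PVs).

Calibration followed the staged recipe: PV–PV chemical weights set for
moderate synchronization, gap-junction conductance (0.3 nS) raised until
synchrony increased further, then PSP amplitudes constrained — the
amplitude-bounded projections (PC→PC 0.15 nS, PC→PV 0.3 nS, PV→PC
0.35 nS) all give < 1 mV somatic PSPs measured on a quiescent
postsynaptic cell; PV→PV (2 nS) is calibrated for recurrent-inhibition
strength, the one projection without a stated amplitude bound.  Finally
the bias ranges were tuned against the control network targets.

At these settings the control network fires PCs at ~7.0 Hz and PVs at
~72 Hz; applying −10 mV to PV Kv3 only drops PV firing and releases the
PCs to ~30 Hz — the network hyperexcitability phenotype — with gamma
power rising ~10-fold and following an exponential in |shift|
(R² ≈ 0.93 at five seeds per grid point).  A known calibration limit:
with sub-mV inhibitory PSPs and 36% PV→PC connectivity, holding the
bursting PCs at ~7 Hz requires a PV population rate near 72 Hz in this
model — about 15% above the ~63 Hz reference value.  The inhibitory
efficacy per PV spike, capped by the PSP-amplitude constraint, is the
binding constraint; PC-rate fidelity (both conditions) was prioritized
over PV-rate fidelity, since the two cannot be met simultaneously here.

## LFP proxy and spectra

The LFP proxy is minus the summed ionic + synaptic + clamp current of
all 220 cells, scaled by a point-source volume-conduction factor
1/(4πσr) with σ = 0.3 S/m and r = 100 µm (≈ 2.65·10⁻³ mV/nA), band-passed
5–50 Hz with a 2nd-order zero-phase Butterworth, decimated to 1 kHz, and
analyzed with Welch's method (500 ms Hann windows, 50% overlap).  Gamma
power is the mean spectral density over 30–50 Hz inclusive.  Because the
reference analysis' LFP formula is not specified, absolute gamma-power
values carry the arbitrary scale of this proxy; ratios, orderings and
the exponential shift–gamma relation are scale-free and are what the
tests assert.

Synchrony is the mean pairwise Pearson correlation of 5 ms-binned spike
counts, excluding zero-variance trains.

## Fitters and synthetic data

All fits go through `scipy.optimize.curve_fit` with data-driven
initialization (Boltzmann: plateau/half-crossing/quartile-span;
mono-exponential: 63% crossing).  R² for the nonlinear exponential trend
is 1 − RSS/TSS about the mean — conventions differ for nonlinear fits,
so the definition is fixed here.  A Boltzmann "fit" explaining less than
75% of the variance is flagged non-converged (this catches
descending-sigmoid and otherwise degenerate inputs).

The synthetic patch generator produces voltage-clamp current families
with Boltzmann activation, a Gaussian-bell activation time constant,
mono-exponential slow inactivation and additive white Gaussian current
noise, and serializes its ground truth beside the data.  It emulates the
analysis-relevant structure of outside-out-patch recordings, not their
artifacts: no capacitive transients, series-resistance error, or
leak/TEA-subtraction residue.  Passing round-trip tests therefore show
the fitting stages recover generative parameters under clean and mildly
noisy conditions; they do not certify robustness to uncorrected
recording artifacts.  One measurable bias is real and reproduced: with
slow inactivation present, peak-current chord conductance slightly
depolarizes the fitted half-activation (≈ 0.4 mV at τ_inact = 1 s), in
the simulation and generator alike.

## Problem sizes

Defaults were chosen so a full verification pass stays interactive:
acceptance reproductions use 1 s simulations, ten bombardment seeds, and
a six-point shift sweep at five seeds (30 network runs); the test suite
runs the same science at three seeds and five grid points.  All sizes
are parameters, and every stochastic stage takes an explicit seed;
identical (config, seed) pairs are bit-identical.

## Known limitations

- Single compartments: no dendritic filtering, axonal AP initiation, or
  morphology-dependent LFP structure.
- Deterministic channels: no stochastic gating; temperature is implicit
  in the calibrated kinetics (no Q10 machinery).
- The PC burster is a generic conductance pacemaker calibrated at the
  network level, not a transcription of any specific cortical PC model.
- The PV-rate/PC-rate calibration tension and the arbitrary LFP scale,
  both described above.
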