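# Methods

## The model

`picsim` implements a conductance-based multicompartment model of a
medullary serotonergic (5-HT) neuron as an unbranched cable chain of four
sections — axon (9 compartments, d = 1.8 µm, 20 µm), initial segment
(7 compartments, d tapering 8.2→1.8 µm, 10 µm), soma (one compartment,
d = 12 µm, L = 20 µm, area ≈ 754 µm²) and dendrite (25 compartments,
600 µm, diameter rising 1.4→5.4 µm over the proximal 20 % and falling
linearly to a closed tip).  Passive constants are per-section R_M
(50 000 / 50 000 / 16 666 / 34 483 Ω·cm²), R_A = 70 Ω·cm, C_M = 1 µF/cm².
Each compartment obeys

    C_m dV/dt = −I_leak − ΣI_ion − I_coupling + I_inj

with symmetric axial coupling from the half-cylinder resistances.

Active currents (Hodgkin–Huxley form, x' = (x∞−x)/τ):

* **NaT** — transient sodium, g·m³·h·(V−50).  m from the linoid rate pair
  α_m = 0.4(V+20)/(1−e^(−(V+20)/7.2)), β_m mirrored with coefficient 0.124;
  h∞ = 1/(1+e^((V+40.5)/4.8)), τ_h from the analogous (V+25)/1.3 rate pair.
  Both τ are divided by Q(T) = 2.46 (37 °C).
* **NaP** — persistent sodium, g·m·s·(V−50).  m∞ a sigmoid with midpoint
  −37.3 mV and slope V_S (default 5 mV), τ_m = 1 ms.  The slow gate s has
  s∞ = s_gate + (1−s_gate)·α_s/(α_s+β_s) with α_s = 0.001·e^(−(V+85)/30),
  β_s = 0.0034/(1+e^(−(V+17)/10)) and τ_s = 1/(α_s+β_s) ≈ 0.3–2.5 s.
  `s_gate` is the non-inactivating floor (default 0.4); s_gate = 1 pins the
  gate open.  The seconds-scale τ_s is what lets a 10-s bi-ramp separate
  the ascending from the descending PIC.
* **Kdr** — delayed rectifier, g·n⁴·(V+77); n∞ midpoint −25 mV, slope
  20 mV; bell-shaped τ_n peaking 5.8 ms at −39 mV.
* **KCa** — calcium-activated potassium, g·n·(V+77), with
  α_n = 0.1·(Ca−Ca∞)², β_n = 0.1.  Two first-order calcium pools feed it:
  a somatic AHP pool (τ_Ca = 76 ms, shell depth 0.6 µm) and a distal
  dendritic pool (τ_Ca = 120 ms, depth 100 µm), each obeying
  dCa/dt = (Ca∞−Ca)/τ_Ca − i_Ca·scale/depth with inward current raising Ca.
* **CaL** — L-type calcium, g·m·(V−E_Ca); m∞ midpoint V_1/2 (default
  −41 mV), slope V_S (default 4 mV), τ_m = 1 ms; confined to the
  mid-dendritic zone (0.32–0.56 of dendritic length).
* **CaHVA** — a small spike-gated somatic calcium source (m², midpoint
  +10 mV, slope 4 mV, τ = 0.5 ms) feeding only the somatic AHP pool.  The
  tabulated channel set places no calcium channel at the soma, yet the
  somatic KCa pool needs a per-spike influx to produce the cell's slow
  AHP; a high-voltage-activated source is the convention of the
  motoneuron-model family this cell derives from.  Its midpoint is above
  the voltage-ramp range, so it contributes nothing to the clamp
  protocols, and it is deliberately excluded from CaL blockade and CaL
  conductance scaling so the L-type studies isolate the dendritic channel.

Conductance densities follow the tabulated distribution: dense NaT/NaP/Kdr
on axon and initial segment, moderate at the soma, a high-density collar on
the most proximal 4 % of the dendrite, sparse channels distally, and
KCa/CaL only in the 0.32–0.56 dendritic zone.

### Leak and calibration constants

Three constants are not fixed by the published parameter set and are
calibrated once against the published membrane observables, then frozen:

* **Leak density.**  The tabulated per-section R_M and the tabulated
  "Kleak" densities double-book one another: 1/R_M − Kleak ≈ 0.02 mS/cm²
  uniformly in every section.  Only the uniform ~0.02 mS/cm² component
  reproduces the published passive observables (R_in 851 MΩ simulated vs
  776 MΩ published; rheobase 10 pA exactly), whereas using the full 1/R_M
  gives R_in ≈ 502 MΩ and rheobase 20 pA.  The implemented leak is
  therefore `1/R_M − Kleak` per section.
* **E_leak = −62.35 mV**, one value for all compartments, set so the
  free-running somatic potential is −62 mV.
* **Calcium scale.**  Calcium is carried in dimensionless model units
  (Ca∞ = 0.1); the influx gain (the 1/(2Fd) factor) is unit-arbitrary, so
  a single global scale (0.135) and the CaHVA density (0.52 mS/cm²) are
  calibrated against the published AHP amplitude and half-width.  The two
  pools keep the published depth ratio (0.6 µm vs 100 µm).

### Numerics

Staggered scheme at dt = 0.025 ms: gates advance by exact exponential
steps at frozen voltage, calcium pools by their closed-form first-order
solution, voltages by one backward-Euler step with ohmic channel
conductances frozen at the updated gate values — a tridiagonal solve along
the chain (Thomas algorithm), compiled with numba.  The scheme is
unconditionally stable; on a subthreshold bi-ramp, halving dt changes the
somatic trajectory by ~1e-5 mV (max-norm).  Pointwise dt-convergence is
checked subthreshold only: once the cell spikes, infinitesimal spike-time
shifts produce ~100 mV pointwise differences under any integrator.
Voltage clamp is ideal (zero series resistance): the soma row of the
linear system is replaced by the command, and the recorded current is the
capacitive + ionic + axial demand at the soma; inward deflections are
negative.  Divergence (non-finite or |V| > 500 mV) raises an error naming
the first bad time.

## Protocols

* **Bi-ramp voltage clamp** — symmetric triangular command, default
  −70 → 0 → −70 mV over 10 s after a 1-s settle at holding.  The
  experimental family reaches +50 mV, but the model's PICs live below
  0 mV; the peak is configurable.  A `tea` flag zeroes Kdr and KCa
  (recording-solution analog), default off.
* **Bi-ramp current clamp** — default 0 → 70 pA → 0 over 10 s (holding
  0 pA), the midpoint of the published 60–80 pA range.
* **Membrane battery** — resting potential from a 5-s free run; input
  resistance from the steady-state deflection to a −10 pA somatic step;
  rheobase by bisection of 1-s somatic steps at 1 pA resolution; spike
  threshold as the voltage where dV/dt first exceeds 10 mV/ms on the first
  rheobase spike; AP height = peak − threshold; AHP amplitude =
  threshold − post-spike minimum; half-widths at 50 % of the respective
  amplitudes (the AHP half-level is measured within the window ending at
  the next spike, so near rheobase it effectively tracks the inter-spike
  interval).  These estimator conventions are stated because the
  observables were published without algorithmic definitions.

## Trace analysis

The manual "tangent line" measurement of PIC boundaries is automated as a
baseline-deviation detector on the leak-subtracted trace:

1. **Leak subtraction** fits I = g·V + b on the sub-threshold window of
   the ascending limb (default: first 15 mV of command) and subtracts the
   line everywhere.
2. The trace is cleaned with a centered rolling **median** (default 25 ms,
   capped at 63 samples), which suppresses noise without displacing the
   baseline-departure edges; descending-limb quantities are measured
   against that limb's own tail baseline because ramp-charging currents
   offset it by a constant after an ascending-limb fit.
3. A PIC component exists on a limb when the smoothed current stays below
   −(detection floor) (default 5 pA) for a sustained window (default
   50 ms); its amplitude is the limb's trough depth.  The floor is what
   makes the single-component patterns possible.
4. **Boundary placement** (V_onset, V_offset) uses a second, wider median
   filter and places each boundary where the trace leaves/returns to a
   band that is the *same fraction* (default 2 %, raised to clear 3× the
   estimated noise SD) of that limb's trough depth.  Equal fractions put
   the two boundaries at mirror-image points of their trough edges, so
   their placement biases cancel in ΔV = V_offset − V_onset — without
   this, the ΔV = 0 pattern class (tolerance ±0.5 mV) is not decidable.
   Onset is the end of the last sustained in-band run before the
   ascending trough; offset is the start of the first sustained in-band
   run after the descending trough.
5. **Classification**: ΔV category with tolerance τ_ΔV = 0.5 mV; loop
   rotation counterclockwise iff a-PIC exceeds d-PIC (tie band 1 pA);
   patterns 1/4 by single-component presence, 2/3 by ΔV ≥ 0 with both
   components, 5/6 by the amplitude order at ΔV < 0.  The mapping is total
   over any feature set with at least one detected component.

Firing analysis detects spikes as upward 0-mV crossings (the model's
spikes overshoot by ~20 mV) with a 2-ms refractory; I_onset/I_offset are
the ramp currents at the first/last spike, instantaneous frequency
1000/ISI is attached to the second spike of each pair and assigned to its
limb; types 1/2/3 by the sign of ΔI = I_offset − I_onset with τ_I = 1 pA.

## Synthetic traces

The generator emulates leak-subtractable voltage-clamp sweeps (linear leak
+ raised-cosine inward troughs + i.i.d. Gaussian noise, default σ = 2 pA)
and bi-ramp spike trains (template spikes placed so the command at the
first/last spike equals the programmed recruitment/de-recruitment current,
with linear frequency–current gains per limb).  Raised cosines have
compact support whose edges sit exactly at the programmed onset/offset
voltages, so ground truth is unambiguous.  The generator does **not**
emulate series-resistance artifacts, 1/f or line noise, seal instability,
or escape spikes — a green recovery suite establishes that the analysis
conventions are unbiased and noise-robust in that idealized world, not
that they are robust to every pathology of real recordings.  Cohort
bookkeeping converts the recorded per-pattern counts (18, 14, 5, 2, 5, 3
of 47) and per-type counts (60, 6, 13 of 79) to rounded percentages.

## Parameter studies

Sweeps rebuild the cell per grid point (conductance scales in percent of
the defaults, kinetic midpoints/slopes in mV, the slow-gate floor in
[0, 1], dendritic length in percent of 600 µm).  Following the
experimental design, studies of one PIC channel block the other.
Extending the dendrite scales the compartment count with length (constant
per-compartment electrotonic length), preserves the taper in relative
coordinates, and keeps the CaL/KCa zone at the same relative interval and
density, so total dendritic L-type conductance grows in proportion to
length.  Threshold queries report bracketing grid intervals, never
interpolated values; the firing-type crossing additionally uses the onset
of the *persistent* ΔI < 0 regime, because ΔI carries a de-recruitment
granularity of a few pA (one inter-spike interval of ramp current) that
makes single-sample sign changes near zero meaningless.

## Known limitations

* The transient-sodium window current (~4.6 nS near −32 mV) dominates the
  somatic PIC trough, compressing the dynamic range of V_onset/V_offset
  across parameter studies relative to the published curves; the published
  rate pairs for NaT are internally inconsistent (α and β share one
  functional form), so the true window magnitude is uncertain.
* Quantities that are emergent from the published kinetics and not
  adjustable by any declared-free constant: spike threshold lands at
  −36.2 mV (published −38.9), AP half-width at 0.575 ms (published 1.1),
  and the residual a/d-PIC asymmetry with the slow gate pinned open is
  ~6 % (fast NaT inactivation lags the 14 mV/s ramp by a few ms on each
  limb).
* The firing-type hysteresis (ΔI) of the default cell is a few pA around
  zero rather than the published ≈ +10 pA; the slow-gate recovery during
  the descending limb (τ_s ≈ 2 s at −50 mV, as published) erases most of
  the NaP adaptation before de-recruitment.  Trends with every swept
  parameter match the published directions; absolute crossings shift
  accordingly.
* Single unbranched dendrite, ideal clamp, no synaptic input, no
  stochastic gating.
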