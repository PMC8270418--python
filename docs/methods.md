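# Methods

## The model

`granulenet` simulates the input layer of the cerebellar cortex as two
interacting point-neuron populations driven by mossy fibers (MFs):
excitatory granule cells (GCs) and inhibitory Golgi cells (GoCs). MFs are
not modelled as neurons; each is an independent homogeneous Poisson spike
source (25 Hz by default).

### Single cells

GCs follow a nonlinear-leak integrate-and-fire equation

    C_m dV/dt = -g_L (V - E_L) exp(-(V - E_L)/5 mV)
                - I_noise - g_AHP z_AHP (V - E_K) - I_syn

The multiplicative `exp(-(V - E_L)/5)` factor suppresses the leak above the
leak reversal, so a depolarized GC integrates its synaptic input almost
perfectly; below `E_L` the leak grows steeply and acts as a soft floor.

GoCs are exponential integrate-and-fire neurons with slope factor
`delta_T = 3 mV` plus a gap-junction current
`I_gap,i = sum_j g_ij (V_i - V_j)`:

    C_m dV/dt = -g_L (V - E_L) + g_L delta_T exp((V - V_T)/delta_T)
                - I_gap - I_noise - g_AHP z_AHP (V - E_K) - I_syn

The spike-initiation term is implemented as depolarizing (standard EIF,
inward-current sign convention); the literal subtracted form is available
behind `CellParams.eif_depolarizing=False`. A consequence of the EIF form
with GoC `E_L = -50 mV` and threshold `-45 +/- 2.25 mV` is that cells whose
drawn threshold lies below about `-47 mV` (roughly a fifth of the
population) have no stable rest and fire intrinsically — they behave as
AHP-paced pacemakers at ~20-25 Hz, which Golgi cells indeed are in vivo.

On threshold crossing, V is clamped to +40 mV for the spike plateau
(0.6 ms for GCs, 1 ms for GoCs), then reset to `V_rest`; an absolute
refractory period of 2 ms follows the plateau. At the plateau end the AHP
resource jumps by one unit:

    dz/dt = (1 - z) * x / (1 ms) - z / tau_AHP
    dx/dt = -x / (1 ms),   x -> x + 1 at each spike end

The gating law above is the "multiplicative" reading of the AHP activation.
The literal form `(1 - z)/x` is singular as `x -> 0` and pins `z` at 1
permanently once any spike has occurred (with any small floor on x), which
abolishes spiking; it is kept behind `ahp_form="literal"` for comparison
only.

Background activity is an Ornstein-Uhlenbeck conductance
(`tau_N dg_N/dt = -g_N + sigma_N sqrt(tau_N) xi(t)`, `sigma_N = 0.12 nS`,
`tau_N = 1000 ms`) injected as `I_noise = (V - V_E) g_N` with `V_E = 0 mV`
(an excitatory noise reversal; the slow correlation time makes this a
quasi-static per-cell excitability bias rather than fast jitter). The
discretization is exact (the stationary SD `sigma_N/sqrt(2)` is preserved
for any step size).

### Synapses

Each projection carries one or more receptor channels (Table below), each a
two-variable gating cascade

    s' = -s/tau_rise + R u * sum_k delta(t - t_k)
    r' = -r/tau_decay + alpha s (1 - r)

with current `I = g r Y(V) (V - E_syn)`. `Y` is the NMDA voltage factor
`1/(1 + exp(-(V - 84)/38))` and 1 otherwise. The NMDA expression is used
exactly as stated in the parameter source; the conceivable `(V + 84)`
reading was tested and drives the network into implausibly high rates, so
the printed form is kept.

| projection | channels (g as multiple of W) |
|---|---|
| MF->GC  | AMPA_fast (1 W), AMPA_slow (2 W), NMDA (2.4 W) |
| MF->GoC | AMPA_fast (1 W), AMPA_slow (2 W) |
| GC->GoC | AMPA_fast (1 W) |
| GoC->GC | GABA_fast (1 W), GABA_slow (0.15 W) |

Reversal potentials are 0 mV for AMPA/NMDA and -75 mV for GABA
(conventional values; not stated in the parameter source). Weight means
default to `W_MF-GC = W_MF-GoC = W_GC-GoC = 3 nS`, `W_GoC-GC = 4 nS`
(2.5 nS when gap junctions are enabled). Per-synapse weights are Gaussian
around the projection mean with variance `0.1 x mean` (nS^2), truncated at
zero. Transmission delays are Gaussian (1 +/- 0.2 ms) rounded to the dt
grid for all projections except GoC->GC, which transmits without delay.

Short-term plasticity follows the Tsodyks-Markram resource/utilization
pair; at each presynaptic spike the event order is facilitate -> release ->
deplete (`R u` after facilitation enters `s`); the release-first
alternative is available via `stp_order`. With STP disabled the pair is
frozen at `(R, u) = (1, U)` and each spike adds exactly `U` to `s`. Rows
without recovery/facilitation time constants (MF->GoC, GC->GoC, NMDA) are
always static.

### Network

Random fixed-fan-in wiring: every GC receives 4 MF and 10 GoC inputs,
every GoC 10 MF and 50 GC inputs, sampled without replacement, independent
of position. The three inhibition scenarios differ only in which
projections exist: `ffi` (MF->GoC only, no GC->GoC), `fbi` (GC->GoC only,
no MF->GoC), `ffi_fbi` (both).

Gap junctions: GoCs sit on a jittered square grid (12x12 at 33 um spacing
for the full network, +/-25% positional jitter), each cell a disk of radius
0.7-1.3 x 70 um with a process density 0.7-1.3 x nominal; the junctional
conductance between two cells is proportional to the overlap area of their
disks times both densities. Absolute conductance values are not printed in
the model description. The proportionality constant is calibrated so that
the mean **summed** gap conductance per cell equals 1 nS — the GoC leak
conductance. Calibrating a per-pair mean instead (each cell has ~30-40
overlapping partners) puts 14-20 nS of electrical coupling on every cell;
the +40 mV spike plateaus then drive coupled neighbours into saturated
firing at the refractory limit and destroy the very oscillation the
junctions support. The per-cell-total calibration keeps individual
junctions at tens of pS (coupling coefficients of a few percent, the
experimentally reported regime) while retaining population-level
synchronization. `gap_scale_factor` sweeps the whole matrix (0.75x/1.25x
robustness checks).

### Integration

Forward Euler at dt = 0.1 ms (configurable) for the membrane and the `r`
gating equation; the linear decays of `s`, `R`, `u`, the AHP resource and
the OU noise use exact exponential factors. Delayed spikes are binned to
the dt grid; deliveries landing on the same step accumulate. Synapses that
share the presynaptic cell, the grid delay and the receptor type receive
identical spike trains and therefore have identical state trajectories;
the engine exploits this exactly by keying state on (pre, delay) pairs and
folding per-synapse weights into a sparse readout matrix. Threshold tests
happen after the Euler step; crossings during a plateau or refractory
window are ignored. The hot per-step updates (receptor gating/STP, and the
AHP + membrane + threshold pass) run in numba-compiled kernels that
replicate the reference numpy implementations' floating-point operation
order exactly — results are bit-for-bit identical to the pure-numpy
fallback, which remains in place. One `SeedSequence` per run spawns a topology stream
and one stream per trial, so rasters are bit-for-bit reproducible per seed
and trial variability is attributable to input and noise (topology is
frozen across trials unless `resample_topology` is set).

## Analysis

* **Population rate**: spike counts in 2 ms bins (fs = 500 Hz) divided by
  bin width and cell count (spikes/s per cell).
* **Spectrum**: direct FFT of the mean-subtracted rate, one-sided,
  normalized so total power equals variance (no windowing; a Hann-style
  alternative is unnecessary for these long stationary traces).
* **Oscillation frequency (OF)**: in-band (5-200 Hz) argmax of the 5-bin
  Daniell-smoothed spectrum. A peak counts as an oscillation only if the
  smoothed power-to-background ratio exceeds the 99th percentile of the
  maximum in-band ratio over 100 AR(1) surrogates matched to the signal's
  lag-1 autocorrelation (a red-noise null in the Torrence-Compo style).
  A white/permutation null is miscalibrated here because the shot-noise
  background of a population rate is colored. Smoothing makes the
  detection sensitive to the broad (~10-15 Hz wide) peaks these networks
  produce while the surrogate threshold keeps the family-wise false-alarm
  rate on structureless input at ~1%.
* **Oscillation events**: peaks of the boxcar-smoothed (3-bin) rate with
  prominence at least the full interquartile range of the series, so an
  event is a population burst that stands out of the background
  fluctuation band, not any local maximum; with a noise-level threshold
  the inter-event interval degenerates to the carrier period and cannot
  register weakened or skipped cycles. Amplitude is the rate at the peak;
  event times are refined by parabolic interpolation so inter-event
  intervals are not quantized to the bin width; width is the distance
  between the absolute half-amplitude crossings flanking the peak (for a
  pure cosine of peak A this gives T/3; for a Gaussian bump the standard
  FWHM).
* **Spike statistics**: per-cell ISI mean/SD/CV and rate; cells with fewer
  than two spikes are excluded from ISI statistics and counted.
* **Scenario clustering**: trial-level metric vectors are standardized,
  projected onto two principal components and k-means clustered (k = 3,
  20 restarts, seeded); 95% ellipses from per-cluster covariance
  (chi-square, 2 df).
* **E-I delay**: lag of the cross-correlation maximum between the
  magnitude envelopes of EPSC and IPSC traces recorded at fixed holding
  potentials (-70 mV excitatory, 0 mV inhibitory); positive lag =
  inhibition follows excitation.

## Cross-frequency coupling

The envelope-to-signal correlation (ESC) of a frequency pair
`(f_phase, f_amp)` is the Pearson correlation between the signal band-pass
filtered around `f_phase` and the amplitude envelope (Hilbert magnitude) of
the signal band-pass filtered around `f_amp`. Filters are zero-phase
fifth-order Butterworth band-passes; grid frequencies map to bands
`[0.75 f, 1.25 f]` (phase) and `[0.8 f, 1.2 f]` (envelope) — the source
specifies only the cutoff ranges (0-30 Hz low, 0-100 Hz high), so the
fractional bandwidths are a package choice, configurable per call. A
complex-Morlet filtering alternative (width 7) sits behind
`method="morlet"`. The PACgram evaluates ESC over the full grid;
significance per cell comes from correlating the intact low-band signal
against window-shuffled copies of the high-band envelope (200 windows, 200
surrogates, two-sided).

## Synthetic fixtures

`granulenet.synth` generates the analysis test surface: pure tones, white
noise, amplitude-modulated tones with constructed coupling at a known
(f_phase, f_amp) pair (`invert_modulator` flips only the modulation sign,
so the ESC sign flips while the magnitude is preserved), perfectly
periodic rasters (CV = 0) and Poisson rasters. These signals have known
closed-form spectra, envelopes and event metrics and anchor the analysis
stack independently of the simulator. They emulate idealized rhythms and
stationary noise — not slow drift, non-stationary input statistics, or
finite-population shot noise with history dependence — so green analysis
tests certify the estimators on clean ground truth, not performance on
arbitrary experimental recordings.

## Problem sizes and reproducibility

The full-size network is 500 MF / 2000 GC / 144 GoC; the `desk` preset
(125/500/36, fan-ins preserved) is used for direction/significance checks
and sweeps, with 6-10 s of simulated time — long enough that the
oscillation statistics stabilize (the spectral argmax of a single trial
still fluctuates by a few Hz between seeds because network trajectories
are chaotic; directional claims therefore use seed-averaged values).
`scripts/acceptance.py` recomputes the headline number — the oscillation
frequency of the full-size feedback-inhibition network with GoC-GC
short-term plasticity at 25 Hz input — from scratch over three seeds.

## Known limitations

* The quantitative operating point is sensitive to quantities the
  granular-layer literature leaves unconstrained and that are set here by
  convention (reversal potentials, per-synapse weight variance, the noise
  reversal, the junctional conductance scale, the STP event ordering).
  With the documented defaults the feedback-inhibition rhythm sits at
  ~55-80 Hz — the upper gamma band, above the ~40 Hz regime reported for
  comparable granular-layer models — and the doubly-inhibited (`ffi_fbi`)
  network is suppressed to ~2 spikes/s per GC, too sparse for a
  significant rate rhythm. The directional results (scenario dependence,
  STP suppression, gap-junction rescue, E/I control of frequency, PAC
  directionality) are robust to these choices.
* Desk-scale networks share a larger fraction of their inputs, so
  correlation-borne effects (e.g., the weak ~23 Hz feedforward GoC rhythm)
  are relatively stronger than at full size.
* MF drive is homogeneous Poisson only; no correlated or burst input, no
  long-term plasticity, no spillover inhibition, no unipolar brush cells,
  no downstream (Purkinje) targets.
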