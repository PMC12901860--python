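# Methods

## The circuit

The package simulates the early binaural pathway that computes
interaural level and envelope-time differences: auditory-nerve (AN)
fibers drive spherical and globular bushy cells (SBC, GBC) in the
cochlear nucleus, whose outputs converge — excitation from the
ipsilateral SBCs, inhibition from contralateral GBCs relayed by the MNTB
— on a sustained-type neuron of the lateral superior olive (LSO).  Three
wirings are compared: `an_only` (AN fibers on both sides), `an_gbc`
(GBCs only in the inhibitory pathway) and `sbc_gbc` (bushy cells on both
sides).  The MNTB is treated as a perfect sign inverter, and no synaptic
or axonal delays or jitter are modeled: the interaural time variable is
the envelope phase offset applied to the contralateral fibers' phase
distribution.

## Bushy-cell model

Both bushy-cell types are one adaptive coincidence-counting point
neuron.  Each input spike contributes a rectangular pulse of amplitude
`A` (normalized to the static threshold) and duration `W = 0.5` ms to
the summed input count `v(t)`; the threshold is `θ(t) = 1 + θ_D(t)` with

    T dθ_D/dt = −θ_D + S · v(t),        S = 0.9,  T = 0.3 ms,

and the cell fires whenever `v ≥ θ` outside its refractory period `R`.
The GBC receives 20 identical subthreshold inputs (`A = 0.40`,
`R = 1.2` ms); the SBC receives 2 barely suprathreshold endbulbs
(`A_E = 1.05`) plus 18 small boutons (`A_B = 0.21`) and a shorter
refractory period (`R = 0.7` ms).  Adaptation makes the cell a
synchrony detector: sustained or poorly timed input raises `θ_D` and is
rejected; coincident volleys cross threshold before adaptation catches
up.

Numerics.  The engine runs on a uniform grid (`dt = 0.01` ms).  Window
counts use half-open trailing windows `(t−W, t]` (an event contributes
from its own step, inclusive); simultaneous events sum linearly; inputs
arriving during refractoriness still drive `v` and `θ_D` (no reset).
`θ_D` is integrated with the exact exponential one-step update
`θ_n = a θ_{n−1} + (1−a) S v_{n−1}`, `a = e^{−dt/T}`, which for on-grid
events reproduces the continuous solution exactly; the test suite checks
the stepped engine against an independent event-driven simulator (exact
exponentials between event edges) on a thousand random inputs.  The
spike test is level-triggered ("reaches or exceeds"), so a pulse that
still straddles the end of a refractory period can re-fire the cell at
the refractory boundary — a deliberate reading of the model definition,
verified by the engine-equivalence test.

## LSO model

The LSO neuron is a *non-adapting* anticoincidence counter: at each step
`c = (#exc in 0.8 ms) − g · (#inh in 1.6 ms)`, and the cell fires when
`c ≥ 9` outside a 1.5 ms refractory period (`g = 1`).  These five
numbers are not anatomical constants; they are configuration entries
chosen once so that the input-count calibration below can place the
ILD-curve extremes inside the physiological windows, with the window
durations in the range used by earlier LSO coincidence-counting models.
The refractory period doubles as the only continuous lever on the
curve maximum (input counts move it in ~20 spikes/s jumps) and was set
so the calibrated maximum sits mid-window.

## Surrogate auditory nerve

The AN front end is a statistical surrogate, not a transduction model:
an inhomogeneous point process with a 70 spikes/s spontaneous floor,
a 0.45 ms absolute dead time, an exponential relative-refractory
recovery (τ = 0.5125 ms), a saturating (sigmoid-in-dB) rate-level
function (200 spikes/s pure, 210 AM), and von Mises phase locking.
Realization is by thinning a homogeneous majorant; the base rate is
compensated (numerically inverting the renewal-rate formula of the
dead-time process) so the realized sustained rate matches the nominal
rate-level function — exact for unmodulated stimuli, approximate under
modulation.

The synchrony profile emulates the qualitative shapes of the driven
periphery: pure-tone vector strength is low-pass in frequency (nominal
0.77 at 350 Hz, zero above 5 kHz) and saturates above ~30 dB SPL;
AM-envelope vector strength is non-monotonic in level (nominal peak 0.92
near 25 dB, declining above ~50 dB) and low-pass in modulation frequency
(corner 400 Hz, order 3); the preferred phase advances linearly with
level.  Two deliberate points:

* Refractory thinning compresses the *realized* vector strength below
  its nominal von Mises value at high driven rates (e.g. ≈0.6 realized
  at the envelope-VS peak, ≈0.58 at 350 Hz/70 dB).  The nominal
  envelope peak was set high (0.92) precisely so that the realized
  values land in the physiological range; the realized-vs-nominal match
  is tested only at low rates where the compression is negligible.
* The envelope low-pass corner controls how much envelope synchrony
  survives at 600 Hz, and with it whether the direct-AN circuit loses
  phase sensitivity there; 400 Hz/order 3 reproduces that loss while
  the full circuit retains significant tuning.

Onset adaptation is two multiplicative exponentials (gains 2.0/0.6,
τ 2/60 ms), giving primary-like onset peaks; sustained-window analyses
are insensitive to it.  What the surrogate deliberately omits:
basilar-membrane filtering, off-CF responses, rate fluctuations beyond
the point-process noise, and the skewed envelope-phase distributions of
the real periphery — so asymmetries of phase-tuning curves are outside
what passing tests demonstrate, and driven-rate statistics (e.g. the
endbulb failure rate under sound) are checked only qualitatively.

## Stimuli and analysis conventions

Pure-tone protocol: 25 ms bursts, 3.9 ms linear ramps, default
70 dB SPL, sustained window 10–25 ms.  AM protocol: 7 kHz carrier,
100–700 Hz sinusoidal envelope at 100% depth, 420 ms, default
35 dB SPL, first 20 ms discarded.  ILD experiments use unmodulated
7 kHz tones on the 420 ms time base with the ipsilateral level fixed at
35 dB SPL and 50–100 trials (the printed protocol specifies the levels
but not duration/repetitions; these are the AM-protocol values).
ILD = contra − ipsi level; positive envelope phase difference = contra
leads.  Vector strength is `|Σ exp(2πif t_k)|/N`; modulation depth is
the peak-minus-trough rate of a tuning curve.

## Calibration of LSO input counts

`calibrate_counts` grid-searches the number of excitatory (24–34) and
inhibitory (9–13) LSO input lines so that the ILD curve's maximum falls
in 115–120 spikes/s and its minimum in 15–20 spikes/s, minimizing the
distance to the window midpoints among feasible pairs (deterministic
given the seed; an exhaustive-enumeration equivalence test guards the
fast path, which shares simulated lines across pairs through the
per-(trial, pathway, line, fiber) seeding).  At 150 trials per ILD the
full circuit calibrates to (n_exc, n_inh) = (24, 10) with both extremes
mid-window (max ≈ 118, min ≈ 17 spikes/s).  For `an_only` and `an_gbc` the count grid is too coarse to
land both extremes strictly inside the 5-spikes/s-wide windows (one
excitatory line moves the maximum by ~20 spikes/s), so the sweep
experiments use the closest pair found — (31, 13) and (28, 11) — which
is the same "make the curves resemble each other" logic at the
resolution the discrete counts permit.

## Problem sizes

Default experiment grids: ILD −25…+25 dB step 5; envelope phase
−180…+180° step 30°; modulation frequency 100–700 Hz step 100; level
10–70 dB step 10.  Library defaults run 100 trials per binaural
condition; the test suite runs reduced sizes chosen for desk-scale
turnaround (10–20 binaural trials per grid point, 200 s spontaneous
runs, 120–400 monaural trials) with correspondingly widened Monte-Carlo
tolerances; the acceptance script uses 200 s spontaneous runs, 150-trial
calibration and a 60-trial final ILD curve.

## Known limitations

* The surrogate's envelope-phase distributions are symmetric, so the
  slight asymmetry of physiological phase-tuning curves is not
  reproduced.
* Total-excitatory-input-rate comparisons across configurations are
  qualitative (parity within ~20%), since they inherit the surrogate's
  rate-level choices rather than a transduction model's.
* The GBC spontaneous output rate computes to ≈18 spikes/s against the
  ≈20 spikes/s cat benchmark (−11%): spontaneous coincidence statistics
  depend on fine ISI correlations the renewal surrogate does not carry.
* Heterogeneous endbulb amplitudes, spontaneous-rate-class mixtures,
  inhibitory inputs to bushy cells, onset-type LSO neurons and tonotopic
  parameter gradients are out of scope.
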