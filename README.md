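# bushylso

Spiking models of the early binaural brainstem circuit: a surrogate
auditory-nerve (AN) spike generator feeding adaptive
coincidence-counting bushy-cell models — the globular bushy cell (GBC,
20 subthreshold inputs) and the spherical bushy cell (SBC, 2 endbulb +
18 bouton inputs) — whose outputs drive a non-adapting
excitatory–inhibitory coincidence counter standing for a sustained-type
neuron of the lateral superior olive (LSO).

The scientific question the package is built around: how does the
enhancement of phase-locking in cochlear-nucleus bushy cells shape the
LSO's coding of interaural level differences (ILD) and envelope
interaural time differences (envelope ITD)?  It is intended for
auditory computational neuroscientists who want a fast, reproducible
circuit model without running a full cochlear periphery.

## The model in brief

Each bushy cell is an adaptive coincidence counter.  Input spikes
contribute rectangular pulses of amplitude `A` and width `W = 0.5` ms to
a summed input count `v(t)`; the spiking threshold is
`θ(t) = θ_S + θ_D(t)` with `θ_S = 1` and

    T dθ_D/dt = −θ_D(t) + S·v(t),     S = 0.9, T = 0.3 ms,

and the cell fires when `v ≥ θ` outside its refractory period
(GBC: `A = 0.40`, `R = 1.2` ms; SBC: `A_E = 1.05`, `A_B = 0.21`,
`R = 0.7` ms).  The LSO stage counts excitatory events in a trailing
coincidence window, subtracts `g` times the inhibitory count in an
inhibition window, and fires at a fixed threshold — an "anticoincidence
detector" for the two ears.  The AN surrogate is an inhomogeneous point
process with dead-time refractoriness (0.45 / 0.5125 ms), a 70 spikes/s
spontaneous rate, saturating rate-level functions and von Mises
phase-locking; see `docs/methods.md` for every default and why.

Three circuit configurations are provided: `an_only`, `an_gbc` and
`sbc_gbc` (full circuit: 660 AN fibers for one LSO neuron).

## Worked example

```python
import numpy as np
from bushylso import (ANParams, make_stimulus, sample_an_train,
                      run_gbc, run_sbc, vector_strength)

an = ANParams()
spec = make_stimulus("am", mod_freq=300.0)      # 7 kHz carrier, 35 dB SPL
lo, hi = spec.analysis_window

pooled = {"an": [], "gbc": [], "sbc": []}
for trial in range(40):
    fibers = [sample_an_train(spec, an, (5, trial, k)) for k in range(20)]
    gbc = run_gbc(fibers)
    sbc, _log = run_sbc(fibers[:2], fibers[2:])
    for name, train in [("an", fibers[0]), ("gbc", gbc), ("sbc", sbc)]:
        t = train.times
        pooled[name].append(t[(t >= lo) & (t <= hi)])

for name, parts in pooled.items():
    spikes = np.concatenate(parts)
    rate = 1000 * spikes.size / ((hi - lo) * 40)
    print(f"{name}: rate {rate:5.1f} spikes/s   "
          f"envelope VS {vector_strength(spikes, 300.0):.3f}")
```

prints

```
an: rate 213.8 spikes/s   envelope VS 0.453
gbc: rate 269.8 spikes/s   envelope VS 0.794
sbc: rate 263.4 spikes/s   envelope VS 0.605
```

i.e. both bushy-cell types fire somewhat faster than a single AN fiber
and, more importantly, lock substantially better to the 300 Hz envelope
(GBC more than SBC, both more than AN) — the property whose downstream
consequence is sharper envelope-ITD tuning in the LSO.

The command-line interface wraps the experiment recipes:

```bash
bushylso validate-bc --trials 50 --outdir results/validate
bushylso calibrate --configuration sbc_gbc --trials 50 --outdir results/calib
bushylso itd --configuration sbc_gbc --n-exc 24 --n-inh 10 --mod-freq 300 \
         --trials 25 --outdir results/itd
bushylso level-sweep --configuration sbc_gbc --n-exc 24 --n-inh 10 \
         --trials 20 --outdir results/levels
bushylso targets --trials 50 --outdir results/targets
```

Every output directory receives the fully resolved configuration and the
root seed, so a run is reproducible bit for bit.

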