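"""Independent event-driven reference implementation of the adaptive
coincidence-counting neuron.

Used only by the tests: between event/window edges the summed input
count ``v(t)`` is piecewise constant, so the dynamic threshold obeys
``theta(t) = S*v + (theta0 - S*v) * exp(-dt/T)`` exactly on each
segment.  Spikes are found by checking the threshold condition at
segment starts, at intra-segment downward crossings of the decaying
threshold, and at refractory-period ends.  This never touches the
stepped engine's code path.
"""

from __future__ import annotations

import math

import numpy as np


def event_driven_adaptive_cc(inputs, static_threshold, strength, tau,
                             refractory, duration):
    """Exact event-driven simulation.

    ``inputs`` is a list of ``(times_array, amplitude, window)``.
    Returns a sorted array of spike times (ms).
    """
    # breakpoints where v changes: event starts and ends (+ window)
    edges = {0.0, duration}
    steps = []  # (time, delta_v)
    for times, amp, win in inputs:
        for te in np.asarray(times, dtype=float):
            steps.append((te, amp))
            steps.append((te + win, -amp))
            edges.add(te)
            edges.add(te + win)
    edges = sorted(e for e in edges if 0.0 <= e <= duration)
    steps.sort()

    # v on each segment [edges[i], edges[i+1])
    spikes = []
    theta = 0.0
    last_spike = -math.inf
    si = 0
    v = 0.0
    for i, t0 in enumerate(edges):
        while si < len(steps) and steps[si][0] <= t0 + 1e-12:
            v += steps[si][1]
            si += 1
        t1 = edges[i + 1] if i + 1 < len(edges) else duration
        seg = t1 - t0
        # repeatedly handle spikes within this segment (refractory exits)
        t = t0
        while True:
            refr_end = last_spike + refractory
            t_check = max(t, refr_end)
            if t_check >= t1 - 1e-12 and not math.isclose(t_check, t0):
                # advance theta to end of segment and leave
                theta = strength * v + (theta - strength * v) * math.exp(
                    -(t1 - t) / tau)
                break
            if t_check > t:
                # advance theta to the refractory end first
                theta = strength * v + (theta - strength * v) * math.exp(
                    -(t_check - t) / tau)
                t = t_check
            # now t >= refractory end; check immediate crossing
            if v >= static_threshold + theta - 1e-12:
                spikes.append(t)
                last_spike = t
                continue
            # otherwise theta decays toward S*v; crossing possible only if
            # v >= static_threshold + S*v (asymptote below v)
            asymptote = strength * v
            if v - static_threshold > asymptote + 1e-12 and theta > v - static_threshold:
                # theta(t*) = v - static_threshold
                ratio = (theta - asymptote) / (v - static_threshold - asymptote)
                t_cross = t + tau * math.log(ratio)
                if t_cross < t1 - 1e-12:
                    theta = v - static_threshold
                    t = t_cross
                    if t >= last_spike + refractory - 1e-12:
                        spikes.append(t)
                        last_spike = t
                    continue
            # no more spikes in this segment
            theta = strength * v + (theta - strength * v) * math.exp(
                -(t1 - t) / tau)
            break
    return np.asarray(spikes)
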