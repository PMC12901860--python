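"""Discrete-time machinery shared by the bushy-cell and LSO stages.

All stages run on a uniform grid ``t_n = n * dt`` (default dt = 0.01 ms).
Each input event contributes a rectangular pulse to a sliding-window
count: an event at time ``te`` is counted at steps with
``t_n in [te, te + W)``, i.e. the window ``(t_n - W, t_n]`` is half-open
and an event contributes from its own step inclusive.  The window count
is built with difference arrays (O(events)), the adaptive-threshold
recursion is a first-order linear filter (O(steps) in C), and the
refractory spike scan touches only threshold-eligible steps.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.signal import lfilter

try:  # pragma: no cover
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = ["n_steps", "event_steps", "window_count", "theta_dynamic",
           "refractory_scan", "steps_to_times"]


def n_steps(duration: float, dt: float) -> int:
    """Number of grid intervals; the grid has ``n_steps + 1`` points."""
    return int(round(duration / dt))


def event_steps(times: np.ndarray, dt: float) -> np.ndarray:
    """Map event times to the first grid step at/after each event."""
    return np.ceil(times / dt - 1e-9).astype(np.int64)


def window_count(times: np.ndarray, window: float, dt: float,
                 nsteps: int) -> np.ndarray:
    """Per-step count of events inside the trailing window ``(t-W, t]``.

    Returns an int array of length ``nsteps + 1`` (steps 0..nsteps).
    """
    counts = np.zeros(nsteps + 2, dtype=np.float64)
    if times.size:
        start = event_steps(times, dt)
        if start.size and (start[0] < 0 or start[-1] > nsteps):
            raise ValueError("event time outside [0, duration]")
        wlen = max(1, int(round(window / dt)))
        stop = np.minimum(start + wlen, nsteps + 1)
        np.add.at(counts, start, 1.0)
        np.add.at(counts, stop, -1.0)
        counts = np.cumsum(counts)
    return counts[: nsteps + 1]


def theta_dynamic(v: np.ndarray, strength: float, tau: float,
                  dt: float) -> np.ndarray:
    """Adaptive threshold component driven by the summed input count.

    Integrates ``tau * dtheta/dt = -theta + strength * v`` with
    ``theta(0) = 0`` using the exact exponential one-step update for the
    piecewise-constant ``v`` (events land on the grid, so ``v`` is truly
    constant over each step): ``theta_n = a theta_{n-1} +
    (1 - a) S v_{n-1}`` with ``a = exp(-dt/tau)``.
    """
    if strength == 0.0:
        return np.zeros_like(v)
    a = math.exp(-dt / tau)
    return lfilter([0.0, (1.0 - a) * strength], [1.0, -a], v)


@njit(cache=False)
def _scan(eligible_idx, refr_steps):  # pragma: no cover - jit kernel
    out = np.empty(eligible_idx.size, np.int64)
    k = 0
    next_ok = -1
    for i in range(eligible_idx.size):
        n = eligible_idx[i]
        if n >= next_ok:
            out[k] = n
            k += 1
            next_ok = n + refr_steps
    return out[:k]


def refractory_scan(eligible: np.ndarray, refractory: float,
                    dt: float) -> np.ndarray:
    """Greedy left-to-right spike placement with a hard refractory period.

    ``eligible`` is a boolean per-step array (threshold condition met
    while ignoring refractoriness); a spike is emitted at every eligible
    step at least ``refractory`` after the previous spike (a spike
    exactly at the refractory boundary is allowed).
    """
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return idx
    refr_steps = int(math.ceil(refractory / dt - 1e-9))
    return _scan(idx.astype(np.int64), refr_steps)


def steps_to_times(steps: np.ndarray, dt: float) -> np.ndarray:
    return steps.astype(np.float64) * dt
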