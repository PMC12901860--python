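"""Adaptive coincidence-counting bushy-cell (BC) models.

Both cochlear-nucleus bushy-cell types are instances of one point-neuron
model.  Each presynaptic spike contributes a rectangular pulse of
amplitude ``A`` (normalized to the static threshold) and duration ``W``
to the summed input count ``v(t)``.  The spiking threshold is adaptive,
``theta(t) = theta_S + theta_D(t)`` with ``theta_S = 1`` and

    T * dtheta_D/dt = -theta_D(t) + S * v(t),

so sustained or poorly synchronized input raises the threshold and only
sufficiently coincident input fires the cell.  A spike is emitted when
``v`` reaches or exceeds ``theta`` outside the refractory period ``R``.

The globular bushy cell (GBC) receives 20 identical subthreshold inputs
(A = 0.40); the spherical bushy cell (SBC) receives 2 barely
suprathreshold endbulb inputs (A_E = 1.05) plus 18 small bouton inputs
(A_B = 0.21) and has a shorter refractory period (0.7 vs 1.2 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import _engine
from .spikes import SpikeTrain

__all__ = [
    "InputClass", "BCParams", "StateTrace", "EndbulbLog",
    "GBC_PRESET", "SBC_PRESET", "bc_preset",
    "simulate_adaptive_cc", "run_gbc", "run_sbc", "endbulb_success_stats",
]


@dataclass(frozen=True)
class InputClass:
    """One synaptic input class: pulse amplitude, duration, fan-in."""

    amplitude: float   # threshold-normalized units
    window: float      # ms
    count: int

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.window <= 0 or self.count < 1:
            raise ValueError("amplitude and window must be > 0, count >= 1")


@dataclass(frozen=True)
class BCParams:
    """Parameters of the adaptive coincidence-counting model."""

    input_classes: tuple[InputClass, ...]
    refractory: float        # ms
    adapt_strength: float    # S
    adapt_tau: float         # ms, T
    static_threshold: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_classes", tuple(self.input_classes))
        if self.refractory <= 0:
            raise ValueError("refractory must be > 0")
        if self.adapt_strength < 0:
            raise ValueError("adapt_strength must be >= 0")
        if self.adapt_tau <= 0:
            raise ValueError("adapt_tau must be > 0")

    @property
    def total_inputs(self) -> int:
        return sum(c.count for c in self.input_classes)

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "BCParams":
        d = dict(d)
        unknown = set(d) - set(BCParams.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown BCParams fields: {sorted(unknown)}")
        d["input_classes"] = tuple(
            InputClass(**c) if isinstance(c, dict) else c
            for c in d["input_classes"])
        return BCParams(**d)


#: GBC: 20 identical subthreshold modified-endbulb inputs.
GBC_PRESET = BCParams(
    input_classes=(InputClass(amplitude=0.40, window=0.5, count=20),),
    refractory=1.2, adapt_strength=0.9, adapt_tau=0.3)

#: SBC: 2 suprathreshold endbulbs + 18 subthreshold boutons, shorter R.
SBC_PRESET = BCParams(
    input_classes=(InputClass(amplitude=1.05, window=0.5, count=2),
                   InputClass(amplitude=0.21, window=0.5, count=18)),
    refractory=0.7, adapt_strength=0.9, adapt_tau=0.3)

_PRESETS = {"gbc": GBC_PRESET, "sbc": SBC_PRESET}


def bc_preset(name: str) -> BCParams:
    """Look up a named parameter preset (``"gbc"`` or ``"sbc"``)."""
    try:
        return _PRESETS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown BC preset {name!r}; "
                         f"known: {sorted(_PRESETS)}") from None


@dataclass
class StateTrace:
    """Optional per-step record of the model state (for debugging/plots)."""

    t: np.ndarray        # ms
    v: np.ndarray        # summed input count
    theta_d: np.ndarray  # dynamic threshold component

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"t_ms": self.t, "v": self.v,
                      "theta_d": self.theta_d}).to_csv(path, index=False)


def simulate_adaptive_cc(inputs, params: BCParams, dt: float = 0.01,
                         duration: float | None = None,
                         return_trace: bool = False):
    """Run the adaptive coincidence-counting neuron on explicit inputs.

    Parameters
    ----------
    inputs:
        Iterable of ``(SpikeTrain, amplitude, window)`` triples.
    params:
        Provides refractory period, adaptation strength/time constant and
        the static threshold (the per-input amplitudes/windows come from
        ``inputs``).
    dt:
        Step size in ms.
    duration:
        Simulated time; defaults to the longest input train duration.

    Returns
    -------
    SpikeTrain, or ``(SpikeTrain, StateTrace)`` if ``return_trace``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    inputs = list(inputs)
    if duration is None:
        if not inputs:
            raise ValueError("duration required when there are no inputs")
        duration = max(tr.duration for tr, _, _ in inputs)
    nsteps = _engine.n_steps(duration, dt)

    v = np.zeros(nsteps + 1)
    for train, amplitude, window in inputs:
        if train.times.size and train.times[-1] > duration + 1e-9:
            raise ValueError("input event time outside [0, duration]")
        v += amplitude * _engine.window_count(train.times, window, dt, nsteps)

    theta_d = _engine.theta_dynamic(v, params.adapt_strength,
                                    params.adapt_tau, dt)
    eligible = v >= params.static_threshold + theta_d
    spike_steps = _engine.refractory_scan(eligible, params.refractory, dt)
    out = SpikeTrain(_engine.steps_to_times(spike_steps, dt), duration, "bc")
    if return_trace:
        t = np.arange(nsteps + 1) * dt
        return out, StateTrace(t, v, theta_d)
    return out


def _grouped_inputs(trains, params: BCParams):
    """Pair trains with (amplitude, window) per input class, checking counts."""
    trains = list(trains)
    expected = params.total_inputs
    if len(trains) != expected:
        raise ValueError(f"expected {expected} input trains, got {len(trains)}")
    inputs = []
    i = 0
    for cls in params.input_classes:
        for _ in range(cls.count):
            inputs.append((trains[i], cls.amplitude, cls.window))
            i += 1
    return inputs


def run_gbc(an_trains, params: BCParams | None = None, dt: float = 0.01,
            duration: float | None = None,
            return_trace: bool = False):
    """Simulate a GBC from its (20 by default) AN input trains."""
    params = params or GBC_PRESET
    return simulate_adaptive_cc(_grouped_inputs(an_trains, params), params,
                                dt=dt, duration=duration,
                                return_trace=return_trace)


@dataclass
class EndbulbLog:
    """Per-endbulb-event record of immediate threshold crossings.

    ``success[i]`` is True when an SBC output spike was emitted at the
    same time step as endbulb event ``times[i]``.
    """

    times: np.ndarray
    success: np.ndarray
    duration: float
    windows: dict = field(default_factory=dict)  # condition -> (lo, hi) ms

    @property
    def n_events(self) -> int:
        return int(self.times.size)


def run_sbc(endbulb_trains, bouton_trains, params: BCParams | None = None,
            dt: float = 0.01, duration: float | None = None,
            return_trace: bool = False,
            condition_windows: dict | None = None):
    """Simulate an SBC from its endbulb and bouton AN input trains.

    Returns ``(SpikeTrain, EndbulbLog)`` (plus a ``StateTrace`` when
    ``return_trace``).  The log marks, for every endbulb input event,
    whether an output spike occurred at that event's time step --
    failures reflect threshold adaptation or refractoriness.
    """
    params = params or SBC_PRESET
    endbulb_trains = list(endbulb_trains)
    bouton_trains = list(bouton_trains)
    n_end = params.input_classes[0].count
    n_bout = params.input_classes[1].count if len(params.input_classes) > 1 else 0
    if len(endbulb_trains) != n_end or len(bouton_trains) != n_bout:
        raise ValueError(
            f"expected {n_end} endbulb and {n_bout} bouton trains, got "
            f"{len(endbulb_trains)} and {len(bouton_trains)}")

    result = simulate_adaptive_cc(
        _grouped_inputs(endbulb_trains + bouton_trains, params), params,
        dt=dt, duration=duration, return_trace=return_trace)
    out = result[0] if return_trace else result
    dur = out.duration

    end_times = np.sort(np.concatenate(
        [tr.times for tr in endbulb_trains])) if endbulb_trains else np.empty(0)
    end_steps = _engine.event_steps(end_times, dt)
    spike_steps = _engine.event_steps(out.times, dt)
    success = np.isin(end_steps, spike_steps)
    log = EndbulbLog(end_times, success, dur, condition_windows or {})
    if return_trace:
        return out, log, result[1]
    return out, log


def endbulb_success_stats(log: EndbulbLog, condition: str | None = None):
    """Fraction of endbulb events that immediately triggered an SBC spike.

    ``condition`` selects one of the time windows recorded on the log
    (e.g. ``"spontaneous"`` or ``"driven"``); with no windows recorded
    all events are used.  Returns ``(probability, failure_fraction)``.
    """
    mask = np.ones(log.times.size, dtype=bool)
    if condition is not None and log.windows:
        try:
            lo, hi = log.windows[condition]
        except KeyError:
            raise ValueError(f"log has no window for condition {condition!r}; "
                             f"known: {sorted(log.windows)}") from None
        mask = (log.times >= lo) & (log.times <= hi)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no endbulb events recorded for this condition")
    p = float(log.success[mask].sum()) / n
    return p, 1.0 - p
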