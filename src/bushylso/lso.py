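"""Non-adapting excitatory-inhibitory coincidence counter for the LSO.

The lateral superior olive (LSO) neuron is modeled as an
"anticoincidence detector": at each time step it counts excitatory
events in a trailing coincidence window, subtracts ``g`` times the
inhibitory count in a (typically longer) inhibition window, and fires
when the net count reaches the coincidence threshold outside its
refractory period.  There is no threshold adaptation at this stage.

The coincidence parameters are not constrained by anatomy the way the
bushy-cell parameters are; the defaults here were chosen so that the
input-count calibration (see :mod:`bushylso.experiments`) can reach the
physiological ILD-tuning rate bounds, and are plain config entries.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import _engine
from .spikes import SpikeTrain

__all__ = ["LSOParams", "LSO_SUSTAINED", "lso_preset", "run_lso"]


@dataclass(frozen=True)
class LSOParams:
    """Coincidence-counting parameters of the sustained-type LSO neuron."""

    coincidence_threshold: float = 9.0  # net count needed to fire
    exc_window: float = 0.8             # ms
    inhibition_strength: float = 1.0    # g, count multiplier
    inhibition_window: float = 1.6      # ms
    refractory: float = 1.5             # ms

    def __post_init__(self) -> None:
        if self.coincidence_threshold < 1:
            raise ValueError("coincidence_threshold must be >= 1")
        for name in ("exc_window", "inhibition_strength",
                     "inhibition_window", "refractory"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "LSOParams":
        unknown = set(d) - set(LSOParams.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown LSOParams fields: {sorted(unknown)}")
        return LSOParams(**d)


LSO_SUSTAINED = LSOParams()
_PRESETS = {"lso_sustained": LSO_SUSTAINED}


def lso_preset(name: str) -> LSOParams:
    try:
        return _PRESETS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown LSO preset {name!r}; "
                         f"known: {sorted(_PRESETS)}") from None


def run_lso(exc_trains, inh_trains, params: LSOParams | None = None,
            dt: float = 0.01, duration: float | None = None) -> SpikeTrain:
    """Run the LSO coincidence counter on excitatory/inhibitory trains.

    At each step ``n`` the net count is ``c_n = (# excitatory events in
    (t_n - exc_window, t_n]) - g * (# inhibitory events in
    (t_n - inhibition_window, t_n])``; a spike is emitted when ``c_n >=
    coincidence_threshold`` outside the refractory period.  Negative net
    counts are allowed (only the threshold comparison matters).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    params = params or LSO_SUSTAINED
    exc_trains = list(exc_trains)
    inh_trains = list(inh_trains)
    if duration is None:
        all_trains = exc_trains + inh_trains
        if not all_trains:
            raise ValueError("duration required when there are no inputs")
        duration = max(tr.duration for tr in all_trains)
    nsteps = _engine.n_steps(duration, dt)

    net = np.zeros(nsteps + 1)
    for tr in exc_trains:
        if tr.times.size and tr.times[-1] > duration + 1e-9:
            raise ValueError("input event time outside [0, duration]")
        net += _engine.window_count(tr.times, params.exc_window, dt, nsteps)
    for tr in inh_trains:
        if tr.times.size and tr.times[-1] > duration + 1e-9:
            raise ValueError("input event time outside [0, duration]")
        net -= params.inhibition_strength * _engine.window_count(
            tr.times, params.inhibition_window, dt, nsteps)

    eligible = net >= params.coincidence_threshold
    spike_steps = _engine.refractory_scan(eligible, params.refractory, dt)
    return SpikeTrain(_engine.steps_to_times(spike_steps, dt), duration, "lso")
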