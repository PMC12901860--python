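"""Spike-train containers shared by all model stages.

A :class:`SpikeTrain` is the universal currency of the simulator: the
auditory-nerve surrogate produces them, the bushy-cell and LSO stages
consume and produce them, and all metrics operate on them.  Times are in
milliseconds from stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = ["SpikeTrain", "TrialEnsemble"]


@dataclass(frozen=True)
class SpikeTrain:
    """An ordered set of spike times on ``[0, duration]``.

    Parameters
    ----------
    times:
        Spike times in ms, strictly increasing.
    duration:
        Length of the observation interval in ms.
    label:
        Free-text provenance (fiber/cell id, trial id).
    """

    times: np.ndarray
    duration: float
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if times.size and (times[0] < 0.0 or times[-1] > self.duration):
            raise ValueError(
                f"spike times must lie within [0, {self.duration}] ms"
            )
        if times.size > 1 and np.any(np.diff(times) <= 0.0):
            raise ValueError("spike times must be strictly increasing")
        if self.duration <= 0.0:
            raise ValueError("duration must be positive")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def rate(self, window: tuple[float, float] | None = None) -> float:
        """Mean firing rate in spikes/s, optionally within ``window`` (ms)."""
        if window is None:
            window = (0.0, self.duration)
        lo, hi = window
        if not (0.0 <= lo < hi <= self.duration + 1e-9):
            raise ValueError("window must lie within [0, duration]")
        n = int(np.searchsorted(self.times, hi, side="right")
                - np.searchsorted(self.times, lo, side="left"))
        return 1000.0 * n / (hi - lo)

    def min_isi(self) -> float:
        """Smallest inter-spike interval in ms (inf if fewer than 2 spikes)."""
        if self.times.size < 2:
            return float("inf")
        return float(np.min(np.diff(self.times)))

    @staticmethod
    def from_unsorted(times: Iterable[float], duration: float,
                      label: str = "") -> "SpikeTrain":
        """Build a train from possibly unsorted times (sorts, drops dupes)."""
        arr = np.unique(np.asarray(list(times), dtype=float))
        return SpikeTrain(arr, duration, label)


@dataclass
class TrialEnsemble:
    """A collection of spike trains from repeated trials of one condition."""

    trains: list[SpikeTrain] = field(default_factory=list)
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.trains and self.duration == 0.0:
            self.duration = self.trains[0].duration
        for tr in self.trains:
            if abs(tr.duration - self.duration) > 1e-9:
                raise ValueError("all trains in an ensemble share one duration")

    def __len__(self) -> int:
        return len(self.trains)

    def __iter__(self) -> Iterator[SpikeTrain]:
        return iter(self.trains)

    def __getitem__(self, idx: int) -> SpikeTrain:
        return self.trains[idx]

    @property
    def n_trials(self) -> int:
        return len(self.trains)

    def total_spikes(self) -> int:
        return sum(len(tr) for tr in self.trains)

    def pooled_times(self) -> np.ndarray:
        """All spike times pooled across trials (sorted)."""
        if not self.trains:
            return np.empty(0)
        return np.sort(np.concatenate([tr.times for tr in self.trains]))

    @staticmethod
    def from_trains(trains: Sequence[SpikeTrain]) -> "TrialEnsemble":
        return TrialEnsemble(list(trains))
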