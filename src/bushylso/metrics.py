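"""Spike-train statistics: rates, histograms, vector strength, tuning curves."""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spikes import SpikeTrain, TrialEnsemble

__all__ = [
    "TuningCurve", "vector_strength", "mean_rate", "psth",
    "period_histogram", "latency_distributions", "modulation_depth",
    "overlap_coefficient",
]


@dataclass
class TuningCurve:
    """Rates (spikes/s) over a stimulus-parameter grid.

    ``x`` may be ILD in dB, interaural envelope phase in degrees,
    modulation frequency in Hz, or sound level in dB SPL -- the ``meta``
    dict records which, together with the configuration and stimulus.
    """

    x: np.ndarray
    rate: np.ndarray
    sem: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if not (len(self.x) == len(self.rate) == len(self.sem)):
            raise ValueError("x, rate and sem must have equal lengths")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if np.any(self.rate < 0):
            raise ValueError("rates must be non-negative")

    def __len__(self) -> int:
        return len(self.x)

    def to_csv(self, path_or_buf) -> None:
        """Write as CSV with '#'-prefixed metadata header lines."""
        buf = io.StringIO()
        for key in sorted(self.meta):
            buf.write(f"# {key}: {self.meta[key]}\n")
        pd.DataFrame({"x": self.x, "rate": self.rate,
                      "sem": self.sem}).to_csv(buf, index=False)
        text = buf.getvalue()
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @staticmethod
    def from_csv(path) -> "TuningCurve":
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        data_lines = []
        for line in lines:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            else:
                data_lines.append(line)
        df = pd.read_csv(io.StringIO("".join(data_lines)))
        return TuningCurve(df["x"].to_numpy(), df["rate"].to_numpy(),
                           df["sem"].to_numpy(), meta)


def vector_strength(times, f: float) -> float:
    """Vector strength of spike times (ms) at reference frequency ``f`` (Hz).

    ``VS = |sum_k exp(2 pi i f t_k)| / N``.  Undefined (raises) for an
    empty spike set.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("vector strength is undefined for zero spikes")
    phases = 2.0 * np.pi * f * times / 1000.0
    return float(np.abs(np.mean(np.exp(1j * phases))))


def _as_ensemble(ensemble) -> TrialEnsemble:
    if isinstance(ensemble, SpikeTrain):
        return TrialEnsemble([ensemble])
    if isinstance(ensemble, TrialEnsemble):
        return ensemble
    return TrialEnsemble(list(ensemble))


def mean_rate(ensemble, window: tuple[float, float]) -> float:
    """Trial-averaged rate (spikes/s) within ``window`` (ms)."""
    ens = _as_ensemble(ensemble)
    if ens.n_trials == 0:
        raise ValueError("empty ensemble")
    lo, hi = window
    if not (0.0 <= lo < hi <= ens.duration + 1e-9):
        raise ValueError("window must lie within [0, duration]")
    total = sum(
        int(np.searchsorted(tr.times, hi, side="right")
            - np.searchsorted(tr.times, lo, side="left"))
        for tr in ens)
    return 1000.0 * total / ((hi - lo) * ens.n_trials)


def psth(ensemble, bin_width: float = 0.1):
    """Peristimulus time histogram.

    Returns ``(edges, rate)`` with rate in spikes/s per trial, so that
    ``sum(rate) * bin_width / 1000 * n_trials`` equals the total spike
    count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    ens = _as_ensemble(ensemble)
    nbins = max(1, int(np.ceil(ens.duration / bin_width - 1e-9)))
    edges = np.arange(nbins + 1) * bin_width
    counts, _ = np.histogram(ens.pooled_times(), bins=edges)
    n_trials = max(ens.n_trials, 1)
    rate = counts * 1000.0 / (bin_width * n_trials)
    return edges, rate


def period_histogram(ensemble, f: float, n_bins: int = 64,
                     window: tuple[float, float] | None = None):
    """Spike-phase histogram over one cycle of frequency ``f`` (Hz).

    Returns ``(bin_edges_cycles, counts)``; the edges span [0, 1) cycle.
    The VS of the raw phases equals :func:`vector_strength` on the same
    spikes.
    """
    if f <= 0:
        raise ValueError("f must be > 0")
    ens = _as_ensemble(ensemble)
    times = ens.pooled_times()
    if window is not None:
        lo, hi = window
        times = times[(times >= lo) & (times <= hi)]
    phases = np.mod(times * f / 1000.0, 1.0)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(phases, bins=edges)
    return edges, counts


def latency_distributions(ensemble):
    """First- and second-spike times per trial (after stimulus onset).

    Trials with fewer than two spikes contribute what they have.
    """
    ens = _as_ensemble(ensemble)
    first, second = [], []
    for tr in ens:
        if len(tr) >= 1:
            first.append(tr.times[0])
        if len(tr) >= 2:
            second.append(tr.times[1])
    return np.asarray(first), np.asarray(second)


def overlap_coefficient(a, b, bin_width: float = 0.1) -> float:
    """Histogram overlap of two samples (sum of min of the normalized bins).

    Used to compare how separated the first- and second-spike latency
    distributions are (1 = identical, 0 = disjoint).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max()) + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    pa, _ = np.histogram(a, bins=edges, density=False)
    pb, _ = np.histogram(b, bins=edges, density=False)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(np.minimum(pa, pb).sum())


def modulation_depth(curve: TuningCurve) -> float:
    """Peak-minus-trough rate (spikes/s) of a tuning curve."""
    if len(curve) < 2:
        raise ValueError("modulation depth needs at least 2 points")
    return float(np.max(curve.rate) - np.min(curve.rate))
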