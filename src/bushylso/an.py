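"""Surrogate auditory-nerve (AN) spike generator.

The downstream bushy-cell and LSO stages only see AN spike *statistics*,
so the front end here is a statistical surrogate rather than a full
cochlear transduction model: an inhomogeneous point process with

* a high spontaneous rate (70 spikes/s),
* absolute (0.45 ms) and relative (0.5125 ms exponential-recovery)
  refractoriness,
* saturating rate-level functions,
* von Mises phase-locking to the tone fine structure (declining with
  frequency, vanishing above ~5 kHz) or to the AM envelope
  (non-monotonic in level, peaking at low-to-medium intensities), and
* a primary-like onset adaptation profile.

Spikes are realized by thinning a homogeneous majorant process; the base
rate is compensated for refractory losses so that the realized sustained
rate matches the nominal rate-level function.  An adapter seam
(:func:`periphery_adapter`) lets a full waveform-driven periphery model
be substituted for the surrogate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Callable

import numpy as np
from scipy import integrate, optimize, special

from .spikes import SpikeTrain
from .stimuli import StimulusSpec

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "RateLevel", "SyncProfile", "OnsetAdapt", "ANParams",
    "vs_from_kappa", "kappa_from_vs", "an_intensity", "sample_an_train",
    "silence", "periphery_adapter", "register_periphery",
    "MissingPeripheryError",
]


# ----------------------------------------------------------------------
# von Mises synchrony helpers
# ----------------------------------------------------------------------

def vs_from_kappa(kappa: float) -> float:
    """Vector strength of a von Mises phase distribution.

    Returns the mean resultant length ``I1(kappa)/I0(kappa)``; strictly
    increasing in ``kappa``, 0 at ``kappa = 0`` and approaching 1 as
    ``kappa`` grows.
    """
    if not np.isfinite(kappa):
        raise ValueError("kappa must be finite")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 0.0:
        return 0.0
    # exponentially-scaled Bessel ratio is stable for large kappa
    return float(special.i1e(kappa) / special.i0e(kappa))


def kappa_from_vs(target_vs: float, kappa_max: float = 1e6) -> float:
    """Invert :func:`vs_from_kappa` by bisection.

    ``kappa_from_vs(0) == 0``; values of ``target_vs`` at or above 1 are
    unattainable and raise ``ValueError``.
    """
    if not 0.0 <= target_vs < 1.0:
        raise ValueError("target vector strength must be in [0, 1)")
    if target_vs == 0.0:
        return 0.0
    if vs_from_kappa(kappa_max) < target_vs:
        raise ValueError(
            f"target VS {target_vs} needs kappa above cap {kappa_max}")
    return float(optimize.brentq(
        lambda k: vs_from_kappa(k) - target_vs, 0.0, kappa_max,
        xtol=1e-12, rtol=1e-13))


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ----------------------------------------------------------------------
# Parameter blocks
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class RateLevel:
    """Saturating (sigmoidal in dB) driven-rate vs. level function."""

    threshold_db: float = 0.0
    slope_db: float = 5.0
    sat_rate: float = 200.0     # spikes/s
    half_rise_db: float = 15.0  # midpoint of the sigmoid above threshold

    def driven(self, level_db):
        """Nominal sustained driven rate (spikes/s) at ``level_db``."""
        x = (np.asarray(level_db, dtype=float)
             - self.threshold_db - self.half_rise_db) / self.slope_db
        return self.sat_rate * _logistic(x)


@dataclass(frozen=True)
class SyncProfile:
    """Phase-locking profile of the surrogate fiber.

    Pure tones: vector strength is a low-pass function of frequency
    (zero above ``pure_cutoff_hz``) scaled by a saturating level factor,
    so VS is roughly level-independent above 30-40 dB SPL.

    AM envelopes: vector strength is non-monotonic in level (product of
    a rising and a falling sigmoid, peaking near 25 dB SPL) and low-pass
    in modulation frequency.  The preferred phase advances (decreases)
    linearly with level.
    """

    # pure-tone fine structure
    pure_vs_base: float = 0.78
    pure_freq_corner_hz: float = 1500.0
    pure_freq_order: float = 3.0
    pure_cutoff_hz: float = 5000.0
    pure_level_mid_db: float = 10.0
    pure_level_slope_db: float = 7.0
    # AM envelope
    env_vs_peak: float = 0.92
    env_low_mid_db: float = 8.0
    env_low_slope_db: float = 5.0
    env_high_mid_db: float = 48.0
    env_high_slope_db: float = 9.0
    env_freq_corner_hz: float = 400.0
    env_freq_order: float = 3.0
    env_cutoff_hz: float = 1500.0
    # preferred phase (radians), advancing with level
    phase0_rad: float = 2.0
    phase_advance_rad_per_db: float = 0.02
    vs_cap: float = 0.95

    def vector_strength(self, kind: str, freq_hz: float, level_db: float,
                        mod_depth: float = 1.0) -> float:
        """Target VS of the fiber for the given stimulus parameters."""
        if kind == "pure":
            if freq_hz > self.pure_cutoff_hz:
                return 0.0
            lowpass = self.pure_vs_base / (
                1.0 + (freq_hz / self.pure_freq_corner_hz) ** self.pure_freq_order)
            level = _logistic((level_db - self.pure_level_mid_db)
                              / self.pure_level_slope_db)
            vs = lowpass * level
        elif kind == "am":
            if freq_hz > self.env_cutoff_hz:
                return 0.0
            rise = _logistic((level_db - self.env_low_mid_db)
                             / self.env_low_slope_db)
            fall = _logistic((self.env_high_mid_db - level_db)
                             / self.env_high_slope_db)
            lowpass = 1.0 / (
                1.0 + (freq_hz / self.env_freq_corner_hz) ** self.env_freq_order)
            vs = self.env_vs_peak * rise * fall * lowpass * mod_depth
        else:
            raise ValueError(f"unknown stimulus kind {kind!r}")
        return float(min(vs, self.vs_cap))

    def kappa_phase(self, kind: str, freq_hz: float, level_db: float,
                    mod_depth: float = 1.0) -> tuple[float, float]:
        """Von Mises concentration and preferred phase (radians)."""
        vs = self.vector_strength(kind, freq_hz, level_db, mod_depth)
        kappa = kappa_from_vs(vs)
        mu = self.phase0_rad - self.phase_advance_rad_per_db * level_db
        return kappa, mu


@dataclass(frozen=True)
class OnsetAdapt:
    """Two-exponential onset adaptation (primary-like PSTH envelope)."""

    rapid_gain: float = 2.0
    rapid_tau: float = 2.0    # ms
    short_gain: float = 0.6
    short_tau: float = 60.0   # ms

    def factor(self, t_ms):
        t = np.asarray(t_ms, dtype=float)
        return (1.0 + self.rapid_gain * np.exp(-t / self.rapid_tau)
                + self.short_gain * np.exp(-t / self.short_tau))


@dataclass(frozen=True)
class ANParams:
    """Statistical parameters of a surrogate high-SR AN fiber."""

    spont_rate: float = 70.0        # spikes/s
    abs_dead: float = 0.45          # ms, absolute refractory period
    rel_recovery_tau: float = 0.5125  # ms, relative-refractory recovery
    rate_level_pure: RateLevel = field(default_factory=RateLevel)
    rate_level_am: RateLevel = field(
        default_factory=lambda: RateLevel(sat_rate=210.0))
    sync_profile: SyncProfile = field(default_factory=SyncProfile)
    onset_adapt: OnsetAdapt = field(default_factory=OnsetAdapt)

    def __post_init__(self) -> None:
        if self.spont_rate < 0:
            raise ValueError("spont_rate must be >= 0")
        if self.abs_dead <= 0 or self.rel_recovery_tau <= 0:
            raise ValueError("refractory constants must be positive")
        for rl in (self.rate_level_pure, self.rate_level_am):
            if rl.sat_rate < self.spont_rate:
                raise ValueError("sat_rate must be >= spont_rate")

    def rate_level(self, kind: str) -> RateLevel:
        return self.rate_level_pure if kind == "pure" else self.rate_level_am

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ANParams":
        d = dict(d)
        known = set(ANParams.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ANParams fields: {sorted(unknown)}")
        for key, cls in (("rate_level_pure", RateLevel),
                         ("rate_level_am", RateLevel),
                         ("sync_profile", SyncProfile),
                         ("onset_adapt", OnsetAdapt)):
            if key in d and isinstance(d[key], dict):
                d[key] = cls(**d[key])
        return ANParams(**d)


# ----------------------------------------------------------------------
# Instantaneous intensity
# ----------------------------------------------------------------------

def _ramp_gain(t, duration, rise_fall):
    """Linear rise/fall amplitude gain in [0, 1]."""
    t = np.asarray(t, dtype=float)
    gain = np.ones_like(t)
    if rise_fall > 0:
        gain = np.minimum(gain, t / rise_fall)
        gain = np.minimum(gain, (duration - t) / rise_fall)
    return np.clip(gain, 0.0, 1.0)


def an_intensity(spec: StimulusSpec, params: ANParams, t,
                 phase_offset_deg: float = 0.0):
    """Nominal instantaneous firing rate (spikes/s) at time ``t`` (ms).

    The intensity is ``max(spont, driven(level) * phase_factor(t) *
    onset_factor(t))`` within the tone, where the phase factor is a von
    Mises density normalized to unit cycle mean (so the cycle mean of
    the driven part equals the rate-level function), and the driven
    level follows the stimulus amplitude ramp.  ``phase_offset_deg``
    shifts the preferred phase (used for interaural envelope delays).
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0) or np.any(t > spec.duration + 1e-9):
        raise ValueError("t must lie within [0, duration]")

    gain = _ramp_gain(t, spec.duration, spec.rise_fall)
    with np.errstate(divide="ignore"):
        eff_level = np.where(gain > 0,
                             spec.level + 20.0 * np.log10(np.maximum(gain, 1e-30)),
                             -np.inf)
    rl = params.rate_level(spec.kind)
    driven = np.where(np.isfinite(eff_level), rl.driven(eff_level), 0.0)

    kappa, mu = params.sync_profile.kappa_phase(
        spec.kind, spec.sync_freq, spec.level, spec.mod_depth or 1.0)
    mu = mu + math.radians(phase_offset_deg)
    if kappa > 0:
        phase = 2.0 * math.pi * spec.sync_freq * t / 1000.0
        phase_factor = np.exp(kappa * np.cos(phase - mu)) / special.i0(kappa)
    else:
        phase_factor = 1.0

    onset_factor = params.onset_adapt.factor(t)
    lam = np.maximum(params.spont_rate, driven * phase_factor * onset_factor)
    return float(lam[0]) if scalar else lam


def silence(duration: float) -> StimulusSpec:
    """A stimulus descriptor that drives the fiber at spontaneous rate only."""
    return StimulusSpec(kind="pure", carrier_freq=7000.0, level=-120.0,
                        mod_freq=0.0, mod_depth=0.0, duration=duration,
                        rise_fall=0.0, analysis_window=(0.0, duration))


# ----------------------------------------------------------------------
# Refractory compensation
# ----------------------------------------------------------------------

def _renewal_rate(lam_ms: float, dead: float, tau: float) -> float:
    """Long-run rate (spikes/ms) of a hazard-``lam`` process with dead time
    ``dead`` and exponential relative recovery ``tau`` (ms)."""
    if lam_ms <= 0:
        return 0.0

    def survival(x):
        return math.exp(-lam_ms * (x - tau * (1.0 - math.exp(-x / tau))))

    # survival is bounded by exp(-lam*(x - tau)); beyond `upper` the
    # remaining mass is negligible for any rate of interest
    upper = tau * 10.0 + 50.0 / lam_ms
    mean_excess, _ = integrate.quad(survival, 0.0, upper, limit=200)
    return 1.0 / (dead + mean_excess)


@lru_cache(maxsize=4096)
def _compensation(spec: StimulusSpec, params: ANParams,
                  phase_offset_deg: float, dt: float) -> tuple[float, float]:
    """Scale factor and majorant for thinning.

    Returns ``(c, lam_max_ms)`` where ``c`` scales the nominal intensity
    so that a refractory-thinned process with hazard ``c * intensity``
    realizes the nominal sustained rate, and ``lam_max_ms`` is the
    majorant hazard (per ms) over the whole stimulus.
    """
    grid = np.arange(0.0, spec.duration + dt / 2, dt)
    lam0 = an_intensity(spec, params, grid, phase_offset_deg) / 1000.0  # /ms
    lo, hi = spec.analysis_window
    in_win = (grid >= lo) & (grid <= hi)
    nominal = float(np.mean(lam0[in_win]))
    dead, tau = params.abs_dead, params.rel_recovery_tau
    if nominal <= 0 or _renewal_rate(1e3, dead, tau) <= nominal:
        raise ValueError("nominal rate unattainable under refractoriness")
    lam_base = optimize.brentq(
        lambda lam: _renewal_rate(lam, dead, tau) - nominal,
        nominal, 1e3, xtol=1e-12)
    c = lam_base / nominal
    lam_max = c * float(np.max(lam0))
    return c, lam_max


# ----------------------------------------------------------------------
# Spike sampling (thinning with refractoriness)
# ----------------------------------------------------------------------

@njit(cache=False)
def _thin_candidates(times, rel_intensity, u, dead, tau):  # pragma: no cover
    out = np.empty(times.size)
    k = 0
    last = -1.0e12
    for i in range(times.size):
        gap = times[i] - last
        if gap <= dead:
            continue
        recovery = 1.0 - np.exp(-(gap - dead) / tau)
        if u[i] < rel_intensity[i] * recovery:
            out[k] = times[i]
            k += 1
            last = times[i]
    return out[:k]


def sample_an_train(spec: StimulusSpec, params: ANParams, seed,
                    phase_offset_deg: float = 0.0, dt: float = 0.01,
                    label: str = "an") -> SpikeTrain:
    """Realize one AN fiber spike train for the given stimulus.

    An inhomogeneous point process is generated by thinning a homogeneous
    majorant, with a hard dead time ``abs_dead`` and an exponential
    relative-refractory recovery of the acceptance probability.  The base
    intensity is internally scaled (see :func:`_compensation`) so that
    the realized sustained rate matches the nominal one.

    ``seed`` may be an int, a ``numpy.random.SeedSequence`` or a
    ``numpy.random.Generator``.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)
    c, lam_max = _compensation(spec, params, float(phase_offset_deg), dt)
    n_cand = rng.poisson(lam_max * spec.duration)
    if n_cand == 0:
        return SpikeTrain(np.empty(0), spec.duration, label)
    times = np.sort(rng.uniform(0.0, spec.duration, n_cand))
    lam = c * an_intensity(spec, params, times, phase_offset_deg) / 1000.0
    rel = lam / lam_max
    u = rng.uniform(0.0, 1.0, n_cand)
    accepted = _thin_candidates(times, rel, u,
                                params.abs_dead, params.rel_recovery_tau)
    return SpikeTrain(np.asarray(accepted), spec.duration, label)


# ----------------------------------------------------------------------
# Optional real-periphery adapter
# ----------------------------------------------------------------------

class MissingPeripheryError(RuntimeError):
    """Raised when no waveform-driven periphery model is registered."""


_PERIPHERY_REGISTRY: dict[str, Callable] = {}


def register_periphery(name: str, fn: Callable) -> None:
    """Register a waveform-driven periphery model.

    ``fn(spec) -> array of spike times (ms)`` may return unsorted times;
    they are normalized on the way in.
    """
    _PERIPHERY_REGISTRY[name] = fn


def periphery_adapter(handle, spec: StimulusSpec,
                      label: str = "periphery") -> SpikeTrain:
    """Run a registered (or directly supplied) periphery model.

    ``handle`` is a registered name or a callable.  The result is
    normalized into a sorted :class:`SpikeTrain`, interchangeable with
    surrogate trains at the bushy-cell stage.
    """
    if callable(handle):
        fn = handle
    else:
        try:
            fn = _PERIPHERY_REGISTRY[handle]
        except KeyError:
            raise MissingPeripheryError(
                f"no periphery model registered under {handle!r}; this is an "
                "optional dependency seam - register one with "
                "register_periphery(name, fn) or use the built-in surrogate "
                "(sample_an_train)") from None
    times = np.asarray(fn(spec), dtype=float)
    return SpikeTrain.from_unsorted(times, spec.duration, label)
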