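"""Stimulus descriptors for the two stimulation protocols.

Stimuli are descriptors, not waveforms: the auditory-nerve surrogate
consumes level, frequency and envelope phase directly, so no audio is
synthesized.  Two protocols are supported:

* pure tone bursts (default 25 ms, 3.9 ms linear rise/fall, 70 dB SPL,
  sustained analysis window 10-25 ms), and
* sinusoidally amplitude-modulated (AM) tones (default 7 kHz carrier,
  420 ms, 35 dB SPL, 100% modulation depth, first 20 ms discarded from
  the sustained analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

__all__ = ["StimulusSpec", "make_stimulus", "PURE_DEFAULTS", "AM_DEFAULTS"]

_KINDS = ("pure", "am")


@dataclass(frozen=True)
class StimulusSpec:
    """Descriptor of a monaural tone stimulus.

    Attributes
    ----------
    kind:
        ``"pure"`` for an unmodulated tone, ``"am"`` for a sinusoidally
        amplitude-modulated tone.
    carrier_freq:
        Carrier frequency in Hz (> 0).
    level:
        Sound intensity in dB SPL.
    mod_freq:
        Envelope frequency in Hz (0 for pure tones).
    mod_depth:
        Modulation depth in [0, 1] (0 for pure tones).
    duration:
        Stimulus duration in ms.
    rise_fall:
        Linear onset/offset ramp duration in ms.
    analysis_window:
        (start, end) in ms of the sustained-response analysis window.
    """

    kind: str
    carrier_freq: float
    level: float
    mod_freq: float
    mod_depth: float
    duration: float
    rise_fall: float
    analysis_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if not self.carrier_freq > 0:
            raise ValueError("carrier_freq must be > 0")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if self.rise_fall < 0:
            raise ValueError("rise_fall must be >= 0")
        if self.rise_fall > self.duration / 2:
            raise ValueError("rise_fall must be <= duration/2")
        if self.kind == "am":
            if not self.mod_freq > 0:
                raise ValueError("mod_freq must be > 0 for AM tones")
            if not 0.0 < self.mod_depth <= 1.0:
                raise ValueError("mod_depth must be in (0, 1] for AM tones")
        else:
            if self.mod_freq != 0:
                raise ValueError("mod_freq must be 0 for pure tones")
            if self.mod_depth != 0:
                raise ValueError("mod_depth must be 0 for pure tones")
        lo, hi = self.analysis_window
        if not (0.0 <= lo < hi <= self.duration + 1e-9):
            raise ValueError("analysis_window must lie within [0, duration]")
        object.__setattr__(self, "analysis_window", (float(lo), float(hi)))

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["analysis_window"] = list(self.analysis_window)
        return d

    @staticmethod
    def from_dict(d: dict) -> "StimulusSpec":
        d = dict(d)
        unknown = set(d) - {f for f in StimulusSpec.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown StimulusSpec fields: {sorted(unknown)}")
        d["analysis_window"] = tuple(d["analysis_window"])
        return StimulusSpec(**d)

    def with_(self, **overrides) -> "StimulusSpec":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **overrides)

    @property
    def sync_freq(self) -> float:
        """The frequency spikes phase-lock to: envelope for AM, carrier else."""
        return self.mod_freq if self.kind == "am" else self.carrier_freq


PURE_DEFAULTS = dict(
    kind="pure",
    carrier_freq=7000.0,
    level=70.0,
    mod_freq=0.0,
    mod_depth=0.0,
    duration=25.0,
    rise_fall=3.9,
    analysis_window=(10.0, 25.0),
)

AM_DEFAULTS = dict(
    kind="am",
    carrier_freq=7000.0,
    level=35.0,
    mod_freq=300.0,
    mod_depth=1.0,
    duration=420.0,
    rise_fall=3.9,
    analysis_window=(20.0, 420.0),
)

_ALIASES = {"freq": "carrier_freq", "frequency": "carrier_freq"}


def make_stimulus(kind: str, **overrides) -> StimulusSpec:
    """Build a validated stimulus descriptor with protocol defaults.

    Parameters
    ----------
    kind:
        ``"pure"`` or ``"am"``.
    **overrides:
        Any :class:`StimulusSpec` field (``freq`` accepted as an alias for
        ``carrier_freq``).  Unknown names raise ``ValueError``.

    Notes
    -----
    If ``duration`` is overridden without an explicit ``analysis_window``,
    the window end is moved to the new duration (same sustained-onset
    discard as the default protocol).
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    defaults = dict(PURE_DEFAULTS if kind == "pure" else AM_DEFAULTS)
    clean: dict = {}
    for key, val in overrides.items():
        key = _ALIASES.get(key, key)
        if key == "kind":
            raise ValueError("kind is given positionally, not as an override")
        if key not in defaults:
            raise ValueError(f"unknown StimulusSpec field: {key!r}")
        clean[key] = val
    if "duration" in clean and "analysis_window" not in clean:
        start = defaults["analysis_window"][0]
        clean["analysis_window"] = (start, float(clean["duration"]))
    defaults.update(clean)
    return StimulusSpec(**defaults)
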