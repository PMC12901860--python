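"""Wiring of AN, bushy-cell and LSO stages into binaural circuits.

Three input configurations are supported:

* ``an_only``  - AN fibers from both sides project directly to the LSO;
* ``an_gbc``   - the contralateral (inhibitory) pathway runs through
  GBCs (via the MNTB, modeled as a perfect sign inverter), while the
  ipsilateral excitation comes straight from AN fibers;
* ``sbc_gbc``  - the full circuit: every excitatory line is an SBC and
  every inhibitory line a GBC, each fed by its own AN fibers.

All AN fibers are statistically independent realizations sharing one
characteristic frequency; no fiber is shared between cells or pathways.
No synaptic or axonal delays are modeled -- the interaural time variable
is the envelope phase offset applied to the contralateral fibers.

Reproducibility: a root seed plus the (trial, pathway, line, fiber)
coordinates deterministically key an independent random stream for every
fiber, so any sub-circuit built from the same root seed sees identical
fiber realizations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .an import ANParams, sample_an_train
from .bushy import BCParams, GBC_PRESET, SBC_PRESET, run_gbc, run_sbc
from .lso import LSOParams, LSO_SUSTAINED, run_lso
from .spikes import SpikeTrain, TrialEnsemble
from .stimuli import StimulusSpec

__all__ = [
    "CONFIGURATIONS", "DEFAULT_COUNTS", "CircuitConfig", "Circuit",
    "RunResult", "build_circuit", "count_an_fibers", "simulate_binaural",
    "total_excitatory_input_rate",
]

CONFIGURATIONS = ("an_only", "an_gbc", "sbc_gbc")

#: Default (n_exc, n_inh) per configuration.  The exc/inh ranges are the
#: anatomically observed 24-34 and 9-13; these defaults reconcile the
#: total fiber counts of the full circuit (660) and the direct circuit
#: (47).
DEFAULT_COUNTS = {"an_only": (34, 13), "an_gbc": (34, 13),
                  "sbc_gbc": (24, 9)}

_EXC_RANGE = (24, 34)
_INH_RANGE = (9, 13)


@dataclass(frozen=True)
class CircuitConfig:
    """Which configuration to build and how many LSO input lines it has."""

    configuration: str
    n_exc_inputs: int | None = None
    n_inh_inputs: int | None = None
    an_fanin_per_bc: int = 20
    cf: float = 7000.0
    allow_out_of_range: bool = False

    def __post_init__(self) -> None:
        if self.configuration not in CONFIGURATIONS:
            raise ValueError(f"configuration must be one of {CONFIGURATIONS}")
        n_exc, n_inh = DEFAULT_COUNTS[self.configuration]
        if self.n_exc_inputs is None:
            object.__setattr__(self, "n_exc_inputs", n_exc)
        if self.n_inh_inputs is None:
            object.__setattr__(self, "n_inh_inputs", n_inh)
        if not self.allow_out_of_range:
            if not _EXC_RANGE[0] <= self.n_exc_inputs <= _EXC_RANGE[1]:
                raise ValueError(
                    f"n_exc_inputs must be in {_EXC_RANGE} "
                    f"(got {self.n_exc_inputs}); pass allow_out_of_range=True "
                    "to experiment outside the anatomical range")
            if not _INH_RANGE[0] <= self.n_inh_inputs <= _INH_RANGE[1]:
                raise ValueError(
                    f"n_inh_inputs must be in {_INH_RANGE} "
                    f"(got {self.n_inh_inputs}); pass allow_out_of_range=True "
                    "to experiment outside the anatomical range")
        if self.an_fanin_per_bc < 1:
            raise ValueError("an_fanin_per_bc must be >= 1")


@dataclass(frozen=True)
class _Line:
    """One LSO input line: a raw AN fiber or a bushy cell with its fibers."""

    pathway: str          # "exc" or "inh"
    index: int            # line index within its pathway
    kind: str             # "an", "gbc" or "sbc"
    fiber_ids: tuple[int, ...]


@dataclass
class Circuit:
    """A fully enumerated wiring of fibers, bushy cells and one LSO."""

    config: CircuitConfig
    an_params: ANParams
    gbc_params: BCParams
    sbc_params: BCParams
    lso_params: LSOParams
    exc_lines: list[_Line] = field(default_factory=list)
    inh_lines: list[_Line] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        """Export the wiring adjacency (fibers -> cells -> LSO) as JSON."""
        doc = {
            "configuration": self.config.configuration,
            "n_exc_inputs": self.config.n_exc_inputs,
            "n_inh_inputs": self.config.n_inh_inputs,
            "cf_hz": self.config.cf,
            "exc_lines": [asdict(l) for l in self.exc_lines],
            "inh_lines": [asdict(l) for l in self.inh_lines],
            "n_an_fibers": count_an_fibers(self),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_circuit(config: CircuitConfig,
                  an: ANParams | None = None,
                  gbc: BCParams | None = None,
                  sbc: BCParams | None = None,
                  lso: LSOParams | None = None) -> Circuit:
    """Enumerate every AN fiber and bushy-cell instance for a configuration.

    The MNTB stage is the identity map on GBC output, so inhibitory
    lines are simply GBC (or raw AN) spike trains consumed with negative
    sign by the LSO model.
    """
    an = an or ANParams()
    gbc = gbc or GBC_PRESET
    sbc = sbc or SBC_PRESET
    lso = lso or LSO_SUSTAINED
    kind_exc = {"an_only": "an", "an_gbc": "an", "sbc_gbc": "sbc"}[
        config.configuration]
    kind_inh = {"an_only": "an", "an_gbc": "gbc", "sbc_gbc": "gbc"}[
        config.configuration]
    fanin = config.an_fanin_per_bc
    next_fiber = 0
    exc_lines, inh_lines = [], []
    for pathway, kind, count, lines in (
            ("exc", kind_exc, config.n_exc_inputs, exc_lines),
            ("inh", kind_inh, config.n_inh_inputs, inh_lines)):
        n_fib = 1 if kind == "an" else fanin
        for i in range(count):
            ids = tuple(range(next_fiber, next_fiber + n_fib))
            next_fiber += n_fib
            lines.append(_Line(pathway, i, kind, ids))
    return Circuit(config, an, gbc, sbc, lso, exc_lines, inh_lines)


def count_an_fibers(circuit: Circuit) -> int:
    """Number of distinct AN fiber instances feeding the circuit."""
    return sum(len(l.fiber_ids)
               for l in circuit.exc_lines + circuit.inh_lines)


# ----------------------------------------------------------------------
# Simulation
# ----------------------------------------------------------------------

_PATHWAY_CODE = {"exc": 0, "inh": 1}


def _fiber_seed(root_seed: int, trial: int, line: _Line,
                fiber_idx: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        (int(root_seed), int(trial), _PATHWAY_CODE[line.pathway],
         line.index, fiber_idx))


def simulate_line(circuit: Circuit, line: _Line, spec: StimulusSpec,
                  trial: int, root_seed: int,
                  phase_offset_deg: float = 0.0,
                  dt: float = 0.01) -> SpikeTrain:
    """Simulate one LSO input line (AN fiber or bushy cell) for one trial."""
    an = circuit.an_params

    def fiber(k):
        return sample_an_train(
            spec, an, _fiber_seed(root_seed, trial, line, k),
            phase_offset_deg=phase_offset_deg, dt=dt,
            label=f"an/{line.pathway}{line.index}.{k}")

    if line.kind == "an":
        return fiber(0)
    n_fib = len(line.fiber_ids)
    trains = [fiber(k) for k in range(n_fib)]
    if line.kind == "gbc":
        return run_gbc(trains, circuit.gbc_params, dt=dt)
    if line.kind == "sbc":
        n_end = circuit.sbc_params.input_classes[0].count
        out, _log = run_sbc(trains[:n_end], trains[n_end:],
                            circuit.sbc_params, dt=dt)
        return out
    raise ValueError(f"unknown line kind {line.kind!r}")


def simulate_pathway(circuit: Circuit, pathway: str, spec: StimulusSpec,
                     trial: int, root_seed: int,
                     phase_offset_deg: float = 0.0,
                     dt: float = 0.01) -> list[SpikeTrain]:
    """All line trains of one pathway ("exc" or "inh") for one trial."""
    lines = circuit.exc_lines if pathway == "exc" else circuit.inh_lines
    return [simulate_line(circuit, l, spec, trial, root_seed,
                          phase_offset_deg, dt) for l in lines]


@dataclass
class RunResult:
    """Output of a binaural run: the LSO ensemble plus optional line logs."""

    lso: TrialEnsemble
    circuit: Circuit
    ipsi_spec: StimulusSpec
    contra_spec: StimulusSpec
    exc_line_trains: list[list[SpikeTrain]] | None = None
    inh_line_trains: list[list[SpikeTrain]] | None = None


def simulate_binaural(circuit: Circuit, ipsi_spec: StimulusSpec,
                      contra_spec: StimulusSpec, n_trials: int, seed: int,
                      contra_phase_deg: float = 0.0, dt: float = 0.01,
                      record_lines: bool = False) -> RunResult:
    """Run the full binaural circuit for ``n_trials`` trials.

    Ipsilateral fibers are driven by ``ipsi_spec`` (excitatory pathway),
    contralateral fibers by ``contra_spec`` (inhibitory pathway, via the
    MNTB sign inversion).  ``contra_phase_deg`` shifts the envelope
    phase of the contralateral fibers; positive values mean the sound
    arrives earlier at the contralateral ear.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if abs(ipsi_spec.duration - contra_spec.duration) > 1e-9:
        raise ValueError("ipsi and contra stimuli must share one duration")
    lso_trains = []
    exc_rec = [] if record_lines else None
    inh_rec = [] if record_lines else None
    for trial in range(n_trials):
        exc = simulate_pathway(circuit, "exc", ipsi_spec, trial, seed,
                               0.0, dt)
        # contra leads by +phi  ->  its envelope (and spikes) come earlier
        inh = simulate_pathway(circuit, "inh", contra_spec, trial, seed,
                               -contra_phase_deg, dt)
        out = run_lso(exc, inh, circuit.lso_params, dt=dt,
                      duration=ipsi_spec.duration)
        lso_trains.append(out)
        if record_lines:
            exc_rec.append(exc)
            inh_rec.append(inh)
    return RunResult(TrialEnsemble(lso_trains), circuit, ipsi_spec,
                     contra_spec, exc_rec, inh_rec)


def total_excitatory_input_rate(run: RunResult,
                                window: tuple[float, float] | None = None
                                ) -> float:
    """Mean sustained rate per excitatory line times the number of lines.

    Units: inputs/s.  Requires the run to have recorded line trains
    (``record_lines=True``).
    """
    if not run.exc_line_trains:
        raise ValueError("run has no recorded excitatory lines; "
                         "pass record_lines=True to simulate_binaural")
    window = window or run.ipsi_spec.analysis_window
    lo, hi = window
    total = 0
    n = 0
    for trial_lines in run.exc_line_trains:
        for tr in trial_lines:
            total += int(np.searchsorted(tr.times, hi, "right")
                         - np.searchsorted(tr.times, lo, "left"))
            n += 1
    mean_line_rate = 1000.0 * total / ((hi - lo) * n)
    return mean_line_rate * len(run.circuit.exc_lines)
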