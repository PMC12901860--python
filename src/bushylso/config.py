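"""Run configuration: schema-checked parameter blocks in YAML or JSON.

A :class:`RunConfig` gathers every tunable of a simulation run -- AN
surrogate, bushy-cell presets, LSO, circuit wiring and the experiment
recipe -- so that an output directory can record full provenance (the
resolved config plus the root seed reproduces a run bit for bit).
Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .an import ANParams
from .bushy import BCParams, GBC_PRESET, SBC_PRESET
from .circuit import CircuitConfig
from .lso import LSOParams

__all__ = ["ExperimentConfig", "RunConfig", "read_config", "write_config"]

_EXPERIMENTS = ("validate-bc", "calibrate", "itd", "level-sweep", "targets")


@dataclass(frozen=True)
class ExperimentConfig:
    """Which experiment to run and at what scale."""

    name: str
    n_trials: int = 100
    seed: int = 1
    configuration: str = "sbc_gbc"
    mod_freq: float = 300.0
    level: float = 35.0
    grid: tuple | None = None   # experiment-specific x grid

    def __post_init__(self) -> None:
        if self.name not in _EXPERIMENTS:
            raise ValueError(
                f"experiment.name must be one of {_EXPERIMENTS}, "
                f"got {self.name!r}")
        if self.n_trials < 1:
            raise ValueError("experiment.n_trials must be >= 1")
        if self.grid is not None:
            object.__setattr__(self, "grid", tuple(self.grid))


@dataclass
class RunConfig:
    """Fully resolved parameters of one simulation run."""

    experiment: ExperimentConfig
    an: ANParams = field(default_factory=ANParams)
    gbc: BCParams = field(default_factory=lambda: GBC_PRESET)
    sbc: BCParams = field(default_factory=lambda: SBC_PRESET)
    lso: LSOParams = field(default_factory=LSOParams)
    circuit: CircuitConfig | None = None
    outdir: str = "results"

    def resolved_circuit(self) -> CircuitConfig:
        if self.circuit is not None:
            return self.circuit
        return CircuitConfig(self.experiment.configuration)

    def to_dict(self) -> dict:
        d = {
            "experiment": asdict(self.experiment),
            "an": self.an.to_dict(),
            "gbc": self.gbc.to_dict(),
            "sbc": self.sbc.to_dict(),
            "lso": self.lso.to_dict(),
            "outdir": self.outdir,
        }
        if self.circuit is not None:
            d["circuit"] = asdict(self.circuit)
        if d["experiment"].get("grid") is not None:
            d["experiment"]["grid"] = list(d["experiment"]["grid"])
        return d

    @staticmethod
    def from_dict(doc: dict) -> "RunConfig":
        doc = dict(doc)
        known = {"experiment", "an", "gbc", "sbc", "lso", "circuit", "outdir"}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "experiment" not in doc:
            raise ValueError("config requires an 'experiment' block")
        exp = doc["experiment"]
        if isinstance(exp, str):
            exp = {"name": exp}
        exp_unknown = set(exp) - set(ExperimentConfig.__dataclass_fields__)
        if exp_unknown:
            raise ValueError(
                f"unknown keys under 'experiment': {sorted(exp_unknown)}")
        kwargs: dict = {"experiment": ExperimentConfig(**exp)}
        if "an" in doc:
            kwargs["an"] = ANParams.from_dict(doc["an"])
        if "gbc" in doc:
            kwargs["gbc"] = BCParams.from_dict(doc["gbc"])
        if "sbc" in doc:
            kwargs["sbc"] = BCParams.from_dict(doc["sbc"])
        if "lso" in doc:
            kwargs["lso"] = LSOParams.from_dict(doc["lso"])
        if "circuit" in doc:
            circ = dict(doc["circuit"])
            circ_unknown = set(circ) - set(CircuitConfig.__dataclass_fields__)
            if circ_unknown:
                raise ValueError(
                    f"unknown keys under 'circuit': {sorted(circ_unknown)}")
            kwargs["circuit"] = CircuitConfig(**circ)
        if "outdir" in doc:
            kwargs["outdir"] = str(doc["outdir"])
        return RunConfig(**kwargs)


def read_config(path) -> RunConfig:
    """Read a YAML (.yml/.yaml) or JSON (.json) run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    try:
        return RunConfig.from_dict(doc)
    except (ValueError, TypeError) as err:
        raise ValueError(f"{path}: {err}") from err


def write_config(config: RunConfig, path) -> None:
    """Write the fully resolved configuration (defaults made explicit)."""
    path = Path(path)
    doc = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
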