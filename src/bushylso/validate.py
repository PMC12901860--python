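"""Model-validation computations shared by the CLI and scripts.

These routines re-measure, from fresh simulations, the benchmark
quantities the model is expected to reproduce: spontaneous output rates
of the two bushy-cell types, the endbulb immediate-crossing probability,
the AN-fiber count identities of the circuit configurations, and the
calibrated ILD-tuning extremes.
"""

from __future__ import annotations

import numpy as np

from .an import ANParams, sample_an_train, silence
from .bushy import run_gbc, run_sbc
from .circuit import CircuitConfig, build_circuit, count_an_fibers
from .experiments import (CalibrationCriteria, calibrate_counts, ild_curve,
                          DEFAULT_ILD_GRID)

__all__ = ["spontaneous_bc_stats", "fiber_count_identities",
           "calibrated_ild_extremes"]


def spontaneous_bc_stats(total_duration_s: float = 200.0,
                         chunk_s: float = 10.0, seed: int = 1,
                         an: ANParams | None = None,
                         dt: float = 0.01) -> dict:
    """Long spontaneous-activity run of the GBC and SBC models.

    Simulates ``total_duration_s`` of stimulus-free activity in
    independent chunks (the spontaneous process is stationary), feeding
    each model fresh surrogate AN fibers at the spontaneous rate, and
    returns the sustained output rates plus the endbulb
    immediate-crossing statistics.
    """
    an = an or ANParams()
    n_chunks = max(1, int(round(total_duration_s / chunk_s)))
    spec = silence(chunk_s * 1000.0)
    gbc_spikes = sbc_spikes = 0
    endbulb_succ = endbulb_tot = 0
    for chunk in range(n_chunks):
        gbc_in = [sample_an_train(spec, an, (seed, chunk, 0, k), dt=dt)
                  for k in range(20)]
        gbc_spikes += len(run_gbc(gbc_in, dt=dt))
        sbc_in = [sample_an_train(spec, an, (seed, chunk, 1, k), dt=dt)
                  for k in range(20)]
        out, log = run_sbc(sbc_in[:2], sbc_in[2:], dt=dt)
        sbc_spikes += len(out)
        endbulb_succ += int(log.success.sum())
        endbulb_tot += log.n_events
    total_s = n_chunks * chunk_s
    return {
        "gbc_spont_rate": gbc_spikes / total_s,
        "sbc_spont_rate": sbc_spikes / total_s,
        "endbulb_crossing_prob": endbulb_succ / endbulb_tot,
        "n_endbulb_events": endbulb_tot,
        "duration_s": total_s,
    }


def fiber_count_identities() -> dict:
    """AN fiber counts of the default circuit configurations."""
    out = {}
    for conf in ("an_only", "an_gbc", "sbc_gbc"):
        circ = build_circuit(CircuitConfig(conf))
        out[conf] = count_an_fibers(circ)
    return out


def calibrated_ild_extremes(n_trials_calib: int = 150,
                            n_trials_curve: int = 50, seed: int = 1,
                            configuration: str = "sbc_gbc",
                            strict: bool = True) -> dict:
    """Calibrate the input counts, then re-measure the ILD-curve extremes.

    The final curve is computed with a fresh trial seed (``seed + 1``)
    so the reported extremes are an out-of-sample measurement of the
    calibrated circuit.
    """
    config, achieved = calibrate_counts(
        configuration, CalibrationCriteria(), n_trials=n_trials_calib,
        seed=seed, strict=strict)
    circ = build_circuit(config)
    curve = ild_curve(circ, DEFAULT_ILD_GRID, n_trials=n_trials_curve,
                      seed=seed + 1)
    return {
        "configuration": configuration,
        "n_exc": config.n_exc_inputs,
        "n_inh": config.n_inh_inputs,
        "calib_max": achieved[0],
        "calib_min": achieved[1],
        "curve_max": float(np.max(curve.rate)),
        "curve_min": float(np.min(curve.rate)),
        "curve": curve,
    }
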