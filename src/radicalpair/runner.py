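"""Execute a validated run configuration and write its artifacts.

Outputs per run, under the configured directory:

* ``trajectory.csv``  -- time_s plus the four spin-state probabilities;
* ``blocks.csv``      -- per-(j1, j2) sector series (collective runs);
* ``spectrum.csv``    -- radical, block, omega_hz of every transition;
* ``rates.csv``       -- omega_hz, gamma_per_s, n_thermal;
* ``summary.json``    -- lifetime, spectrum summary, gamma_d, resolved
  physical parameters, config hash and package version;
* ``blocks.h5``       -- optional HDF5 per-block bulk storage.

Runs are deterministic: the same configuration produces byte-identical CSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .hamiltonians import GAMMA_E, SystemSpec, zeeman_angular_frequency
from .observables import (
    TrajectoryResult,
    block_lifetimes,
    coherence_lifetime,
    transition_spectrum,
)
from .rates_env import build_rate_table
from .simulate import prepare_blocks, run_collective, run_noncollective

__all__ = ["time_grid", "run"]

log = logging.getLogger("radicalpair")


def time_grid(solver) -> np.ndarray:
    """Uniform or geometric grid over [0, horizon]; the geometric grid gives
    the same relative resolution to ms-scale decay and 100 s-scale tails."""
    if solver.geometric_grid:
        return np.concatenate(
            [[0.0], np.geomspace(solver.horizon_s * 1e-6, solver.horizon_s,
                                 solver.grid_points - 1)]
        )
    return np.linspace(0.0, solver.horizon_s, solver.grid_points)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Full pipeline: build, diagonalize, decompose, rates, propagate,
    analyze, write.  Returns the summary dictionary."""
    spec = config.system.to_spec()
    out = Path(out_dir if out_dir is not None else config.outputs.directory)
    out.mkdir(parents=True, exist_ok=True)
    times = time_grid(config.solver)

    log.info("resolved parameters: B0=%.3g T, T=%.1f K, alpha=%.2f, mode=%s",
             spec.b0_tesla, spec.temperature_k, spec.alpha, spec.mode)
    log.info("gamma_e = %.6g rad/s/T; Larmor frequency = %.6g Hz",
             GAMMA_E, zeeman_angular_frequency(spec.b0_tesla) / (2 * math.pi))

    runner = run_collective if spec.mode == "collective" else run_noncollective
    tr: TrajectoryResult = runner(spec, times, schrodinger=config.solver.schrodinger)

    # trajectory
    df = pd.DataFrame({
        "time_s": tr.times,
        "p_singlet": tr.p_singlet,
        "p_triplet1_sz_plus1": tr.p_t1,
        "p_triplet2_sz_0": tr.p_t2,
        "p_triplet3_sz_minus1": tr.p_t3,
    })
    df.to_csv(out / "trajectory.csv", index=False)

    rows = []
    for (j1, j2), series in tr.per_block.items():
        for i, t in enumerate(tr.times):
            rows.append((str(j1), str(j2), t, *np.asarray(series)[:, i]))
    if rows:
        pd.DataFrame(
            rows, columns=["block_j1", "block_j2", "time_s", "p_singlet",
                           "p_triplet1_sz_plus1", "p_triplet2_sz_0",
                           "p_triplet3_sz_minus1"],
        ).to_csv(out / "blocks.csv", index=False)

    # spectrum + rates
    report = transition_spectrum(spec)
    blocks1, blocks2, rt = prepare_blocks(spec)
    spec_rows = [
        (b.hamiltonian.radical_index, key, w / (2 * math.pi), np.linalg.norm(vq))
        for blocks in (blocks1, blocks2)
        for key, b in sorted(blocks.items(), key=lambda kv: str(kv[0]))
        for w, vq in b.transitions.transitions
    ]
    pd.DataFrame(
        spec_rows, columns=["radical", "block_j", "omega_hz", "operator_norm"]
    ).to_csv(out / "spectrum.csv", index=False)
    pd.DataFrame({
        "omega_hz": rt.omegas / (2 * math.pi),
        "gamma_per_s": rt.gammas,
        "n_thermal": rt.n_thermal,
    }).to_csv(out / "rates.csv", index=False)

    lifetime = (coherence_lifetime(tr)
                if tr.picture == "interaction" else None)
    dominant = None
    if tr.picture == "schrodinger" and not config.solver.geometric_grid:
        from .observables import oscillation_frequency

        dominant = oscillation_frequency(tr)
    summary = {
        "preset": config.preset,
        "mode": spec.mode,
        "lifetime_s": ("censored" if lifetime == math.inf else lifetime),
        "block_lifetimes_s": (
            {f"{k[0]},{k[1]}": (None if v == math.inf else v)
             for k, v in block_lifetimes(tr).items()}
            if tr.picture == "interaction" else None
        ),
        "dominant_freq_hz": dominant,
        "n_transition_freqs": report.count,
        "freq_range_hz": [report.min_hz, report.max_hz],
        "gamma_d_per_s": rt.gamma_d,
        "larmor_hz": zeeman_angular_frequency(spec.b0_tesla) / (2 * math.pi),
        "config_hash": _config_hash(config),
        "version": __version__,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    # the resolved configuration reproduces this run exactly
    (out / "resolved_config.json").write_text(
        json.dumps(config.model_dump(), indent=2, default=str))

    if "hdf5" in config.outputs.formats:
        import h5py

        with h5py.File(out / "blocks.h5", "w") as f:
            f.create_dataset("time_s", data=tr.times)
            for (j1, j2), series in tr.per_block.items():
                g = f.create_group(f"block_{j1}_{j2}")
                g.create_dataset("probabilities", data=np.asarray(series))
                g.attrs["weight"] = tr.weights[(j1, j2)]
    log.info("run complete: lifetime=%s s, %d transition frequencies",
             summary["lifetime_s"], report.count)
    return summary
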