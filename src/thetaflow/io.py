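"""Run configuration, file formats, fixtures and output writing.

All artifacts are plain text: YAML configs, whitespace-delimited
matrices, and delimited columnar trajectories/spike lists.  A manifest
(config + seed + package version) accompanies every output set so any
run can be reproduced bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import presets
from .connectivity import read_matrix, two_node_matrix, write_matrix
from .dynamics import InputSchedule, NetworkParams, SimulationResult

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "make_fixture",
    "write_outputs",
    "FIXTURE_NAMES",
]

_KNOWN_KEYS = {
    "n", "matrix", "matrix_file", "input", "duration", "dt", "seed",
    "tau_s", "k", "b", "tau_theta", "record_stride",
    "package_version",  # written into manifests; ignored on load
}

_DEFAULTS = {
    "duration": 1000.0, "dt": 0.05, "seed": 0,
    "tau_s": 20.0, "k": 0.1, "b": 1.0, "tau_theta": 1.0,
    "record_stride": 20,
}


@dataclass
class RunConfig:
    """Validated simulation configuration."""

    n: int
    coupling: np.ndarray
    input: np.ndarray
    duration: float
    dt: float
    seed: int
    tau_s: float = 20.0
    k: float = 0.1
    b: float = 1.0
    tau_theta: float = 1.0
    record_stride: int = 20
    source: dict = field(default_factory=dict, repr=False)

    def network(self) -> NetworkParams:
        return NetworkParams(
            n=self.n, coupling=self.coupling, tau_s=self.tau_s, k=self.k,
            b=self.b, tau_theta=self.tau_theta,
        )

    def schedule(self) -> InputSchedule:
        return InputSchedule.constant(self.input, self.n)


def _validate(raw: dict, base_dir: Path) -> RunConfig:
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("n",):
        if key not in raw:
            raise ValueError(f"missing required config key: {key!r}")
    merged = {**_DEFAULTS, **raw}
    for key in ("tau_s", "dt", "duration", "b", "tau_theta"):
        if merged[key] <= 0:
            raise ValueError(f"config key {key!r} must be positive, got {merged[key]}")
    n = int(merged["n"])
    if "matrix" in raw:
        coupling = np.asarray(raw["matrix"], dtype=float)
    elif "matrix_file" in raw:
        coupling = read_matrix(base_dir / raw["matrix_file"])
    else:
        raise ValueError("config needs either 'matrix' or 'matrix_file'")
    if coupling.shape != (n, n):
        raise ValueError(
            f"config key 'matrix': expected ({n}, {n}), got {coupling.shape}"
        )
    inp = np.broadcast_to(
        np.asarray(raw.get("input", 0.0), dtype=float), (n,)
    ).copy()
    return RunConfig(
        n=n, coupling=coupling, input=inp,
        duration=float(merged["duration"]), dt=float(merged["dt"]),
        seed=int(merged["seed"]), tau_s=float(merged["tau_s"]),
        k=float(merged["k"]), b=float(merged["b"]),
        tau_theta=float(merged["tau_theta"]),
        record_stride=int(merged["record_stride"]),
        source=dict(raw),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return _validate(raw, path.parent)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config back to YAML (inline matrix form); round-trips with
    :func:`load_config`."""
    raw = {
        "n": config.n,
        "matrix": np.asarray(config.coupling).tolist(),
        "input": np.asarray(config.input).tolist(),
        "duration": config.duration,
        "dt": config.dt,
        "seed": config.seed,
        "tau_s": config.tau_s,
        "k": config.k,
        "b": config.b,
        "tau_theta": config.tau_theta,
        "record_stride": config.record_stride,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


FIXTURE_NAMES = (
    "table1-fixed-point", "table1-limit-cycle", "table1-bistable",
    "table1-monostable", "heteroclinic", "fig5-sync", "fig6-timing",
    "fig7-composed",
)


def make_fixture(name: str, out_dir: str | Path) -> Path:
    """Write the canonical inputs of a named experiment.

    Emits the coupling matrix and a ready-to-run YAML config in
    ``out_dir``; returns the config path.  Names cover the four two-node
    flows, the 3-node heteroclinic family, the 50-oscillator
    synchronization demo, the two-oscillator timing regimes and the
    composed 25-neuron circuit.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if name.startswith("table1-"):
        preset = name.removeprefix("table1-")
        decomp, inputs = presets.TWO_NODE_PRESETS[preset]
        coupling = two_node_matrix(decomp)
        n, inp, duration = 2, np.asarray(inputs), 1500.0
    elif name == "heteroclinic":
        coupling = presets.three_node_matrix(presets.ALPHA_CYCLE_FULL)
        n, inp, duration = 3, np.full(3, presets.HETEROCLINIC_INPUT), 2000.0
    elif name == "fig5-sync":
        # phase-network demo: stored as metadata config (no matrix run)
        meta = {
            "n": 50, "eta": presets.ETA_SYNC,
            "couplings": presets.SYNC_COUPLINGS, "duration": 8000.0,
        }
        path = out_dir / f"{name}.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(meta, fh)
        return path
    elif name == "fig6-timing":
        meta = {
            regime: dict(zip(("eta_a", "eta_b", "k_ab", "k_ba"), vals))
            for regime, vals in presets.TIMING_PRESETS.items()
        }
        path = out_dir / f"{name}.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(meta, fh)
        return path
    elif name == "fig7-composed":
        from .compose import COMPOSED_ACTIVE_LEVEL, composed_skeleton, expand_skeleton

        ske = composed_skeleton()
        coupling = expand_skeleton(ske)
        n, inp, duration = ske.n_neurons, np.full(ske.n_neurons, COMPOSED_ACTIVE_LEVEL), 1600.0
        write_matrix(out_dir / f"{name}-skeleton.txt", ske.coupling)
    else:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")

    matrix_file = f"{name}-matrix.txt"
    write_matrix(out_dir / matrix_file, coupling)
    raw = {
        "n": int(n), "matrix_file": matrix_file,
        "input": np.asarray(inp, dtype=float).tolist(),
        "duration": float(duration), "dt": 0.05, "seed": 0,
    }
    path = out_dir / f"{name}.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)
    return path


def write_outputs(result: SimulationResult, config: RunConfig, out_dir: str | Path) -> dict:
    """Write trajectories, spikes and a reproduction manifest.

    Trajectory columns: ``t, theta_0..theta_{n-1}, omega_0..omega_{n-1}``
    (ms); spikes: ``t_ms, neuron_index`` sorted by time.  The manifest
    holds the full config, seed and package version.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = result.theta.shape[0]
    header = "t," + ",".join(
        [f"theta_{i}" for i in range(n)] + [f"omega_{i}" for i in range(n)]
    )
    table = np.column_stack([result.t, result.theta.T, result.omega.T])
    traj_path = out_dir / "trajectory.csv"
    np.savetxt(traj_path, table, delimiter=",", header=header, comments="")
    spikes_path = out_dir / "spikes.csv"
    np.savetxt(
        spikes_path,
        np.column_stack([result.spikes.times, result.spikes.neurons]),
        delimiter=",", header="t_ms,neuron_index", comments="",
        fmt=["%.6f", "%d"],
    )
    manifest_path = out_dir / "manifest.yaml"
    save_config(config, manifest_path)
    with open(manifest_path, "a") as fh:
        fh.write(f"package_version: {__version__}\n")
    return {
        "trajectory": traj_path, "spikes": spikes_path, "manifest": manifest_path,
    }
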