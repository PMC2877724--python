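"""Run configuration: YAML serialization, validation, manifests.

A single nested key-value file describes everything a run needs —
membrane constants, grid, drive, experiment id, sweep grids, trial count
and base seed.  Every paper-style experiment differs only in a handful
of these fields, so the CLI exposes the common ones as flag overrides.

An empty file (or no file) yields the package's calibrated defaults.
Unknown keys and invariant violations raise errors naming the offending
field; a loaded config records which fields were defaulted.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cable import CableGrid
from .membrane import MembraneParams
from .stimulation import DriveSpec, SynapticParams

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]

_SECTIONS = {
    "membrane": MembraneParams,
    "grid": CableGrid,
    "synaptic": SynapticParams,
}


@dataclass
class RunConfig:
    """Fully validated description of one simulation or experiment run."""

    membrane: MembraneParams = field(default_factory=MembraneParams)
    grid: CableGrid = field(default_factory=CableGrid)
    drive: DriveSpec = field(default_factory=DriveSpec)
    experiment: str = "simulate"
    n_trials: int = 50
    base_seed: int = 0
    outdir: str = "runs"
    sigmas: tuple = (0.0, 0.02, 0.05, 0.1, 0.15, 0.2, 0.3)
    defaulted: list[str] = field(default_factory=list, compare=False)

    def validate(self) -> "RunConfig":
        self.grid.validate(self.membrane)
        L = self.grid.L
        for name, win in (
            ("drive.signal_window", self.drive.signal_window),
            ("drive.noise_window", self.drive.noise_window),
        ):
            if win[0] < -1e-9 or win[1] > L + 1e-9:
                raise ValueError(f"{name}={win} lies outside the cable [0, {L}]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        return self

    def to_dict(self) -> dict:
        d = {
            "membrane": dataclasses.asdict(self.membrane),
            "grid": dataclasses.asdict(self.grid),
            "drive": {
                "mu": self.drive.mu,
                "signal_window": list(self.drive.signal_window),
                "noise_kind": self.drive.noise_kind,
                "sigma": self.drive.sigma,
                "noise_window": list(self.drive.noise_window),
            },
            "synaptic": dataclasses.asdict(self.drive.synaptic),
            "experiment": self.experiment,
            "n_trials": self.n_trials,
            "base_seed": self.base_seed,
            "outdir": self.outdir,
            "sigmas": list(self.sigmas),
        }
        return d


def _build_section(cls, data: dict, prefix: str, defaulted: list[str]):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown key(s) in {prefix}: {sorted(unknown)}")
    for f in sorted(fields - set(data)):
        defaulted.append(f"{prefix}.{f}")
    return cls(**data)


def from_dict(data: dict | None) -> RunConfig:
    """Build and validate a RunConfig from a nested plain dict."""
    data = dict(data or {})
    defaulted: list[str] = []
    top_known = {
        "membrane", "grid", "drive", "synaptic",
        "experiment", "n_trials", "base_seed", "outdir", "sigmas",
    }
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")

    membrane = _build_section(MembraneParams, data.get("membrane", {}), "membrane", defaulted)
    grid = _build_section(CableGrid, data.get("grid", {}), "grid", defaulted)
    synaptic = _build_section(SynapticParams, data.get("synaptic", {}), "synaptic", defaulted)

    draw = dict(data.get("drive", {}))
    known_drive = {"mu", "signal_window", "noise_kind", "sigma", "noise_window"}
    unknown = set(draw) - known_drive
    if unknown:
        raise ValueError(f"unknown key(s) in drive: {sorted(unknown)}")
    for f in sorted(known_drive - set(draw)):
        defaulted.append(f"drive.{f}")
    if "signal_window" in draw:
        draw["signal_window"] = tuple(draw["signal_window"])
    if "noise_window" in draw:
        draw["noise_window"] = tuple(draw["noise_window"])
    drive = DriveSpec(synaptic=synaptic, **draw)

    cfg = RunConfig(
        membrane=membrane,
        grid=grid,
        drive=drive,
        experiment=data.get("experiment", "simulate"),
        n_trials=int(data.get("n_trials", 50)),
        base_seed=int(data.get("base_seed", 0)),
        outdir=str(data.get("outdir", "runs")),
        sigmas=tuple(data.get("sigmas", RunConfig.sigmas)),
        defaulted=defaulted,
    )
    return cfg.validate()


def load_config(path: str | Path | None) -> RunConfig:
    """Load, default-fill and validate a YAML run configuration.

    ``None`` or an empty file yields the calibrated default config.
    """
    if path is None:
        return from_dict({})
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is not None and not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash identifying a configuration (for manifests)."""
    canon = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha1(canon.encode()).hexdigest()[:12]


def save_snapshots(record, cfg: RunConfig, path: str | Path) -> None:
    """Write a solution record to a compressed ``.npz`` container.

    Named datasets: V (snapshots x nx), t, x, the final gating fields,
    plus the config hash and base seed as zero-d metadata arrays.
    """
    np.savez_compressed(
        path,
        V=record.snapshot_V(),
        snapshot_times=record.snapshot_times,
        x=record.grid.x,
        V_final=record.final.V,
        n_final=np.asarray(record.final.gating.n),
        m_final=np.asarray(record.final.gating.m),
        h_final=np.asarray(record.final.gating.h),
        config_hash=np.array(config_hash(cfg)),
        base_seed=np.array(cfg.base_seed),
    )
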