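"""Run configuration, seeding discipline and CSV/JSON artifact round trips.

A :class:`RunConfig` bundles the per-module parameter dataclasses (geometry,
denervation, DA, cAMP, compensation, pipeline options) with one master seed.
Every stochastic stage derives its own seed deterministically from the
master seed and a short operation tag, so a run is reproducible end to end
from the config file alone.

Configs are YAML (JSON parses too); unknown keys are rejected.  Tabular
artifacts are CSV with ``# key=value`` header comments carrying the config
hash and seeds; network snapshots get a JSON sidecar with the generating
config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .camp import CAMPParams
from .compensation import CompensationSpec
from .denervation import DenervationParams, DenervationTrajectory
from .dopamine import DAParams
from .geometry import ArborNetwork, EllipsoidStriatum, NetworkConfig

logger = logging.getLogger("striatum")

__all__ = [
    "RunConfig",
    "PipelineOptions",
    "load_config",
    "dump_config",
    "config_hash",
    "derive_seed",
    "save_network",
    "load_network",
    "save_trajectory",
    "load_trajectory",
    "save_table",
    "load_table",
]


@dataclass(frozen=True)
class PipelineOptions:
    """Options of the spatial activity pipeline."""

    n_points: int = 10_000
    n_grid: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 25.0, 40.0, 60.0, 80.0, 100.0, 125.0, 150.0, 200.0)
    n_neurons: int = 100
    model: str = "hh"
    d2_homeostasis: bool = False

    def __post_init__(self) -> None:
        if self.n_points <= 0:
            raise ValueError("n_points must be > 0")
        if self.model not in ("hh", "izh"):
            raise ValueError("model must be 'hh' or 'izh'")


@dataclass(frozen=True)
class RunConfig:
    """Complete, hashable configuration of one simulation run."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    denervation: DenervationParams = field(default_factory=DenervationParams)
    da: DAParams = field(default_factory=DAParams)
    camp: CAMPParams = field(default_factory=CAMPParams)
    compensation: CompensationSpec = field(default_factory=CompensationSpec)
    pipeline: PipelineOptions = field(default_factory=PipelineOptions)
    master_seed: int = 0
    output_dir: str = "."

    def seed_for(self, tag: str) -> int:
        return derive_seed(self.master_seed, tag)


def derive_seed(master_seed: int, tag: str) -> int:
    """Deterministic per-operation seed below 2**31."""
    mix = np.random.SeedSequence([int(master_seed), zlib.crc32(tag.encode())])
    return int(mix.generate_state(1)[0] % (2**31))


_SECTIONS = {
    "network": NetworkConfig,
    "denervation": DenervationParams,
    "da": DAParams,
    "camp": CAMPParams,
    "compensation": CompensationSpec,
    "pipeline": PipelineOptions,
}


def _build_section(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"section {path!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {path!r}: {sorted(unknown)}")
    kwargs = dict(data)
    if cls is NetworkConfig and "ellipsoid" in kwargs:
        ell = kwargs["ellipsoid"]
        if isinstance(ell, dict):
            extra = set(ell) - {"semi_axes"}
            if extra:
                raise ValueError(f"unknown keys in 'network.ellipsoid': {sorted(extra)}")
            ell = ell.get("semi_axes", EllipsoidStriatum().semi_axes)
        kwargs["ellipsoid"] = EllipsoidStriatum(tuple(float(a) for a in ell))
    for name in ("segments", "n_grid", "semi_axes", "window"):
        if name in kwargs and isinstance(kwargs[name], list):
            kwargs[name] = tuple(
                tuple(x) if isinstance(x, list) else x for x in kwargs[name]
            )
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration.

    Missing sections and keys fall back to the documented defaults; unknown
    keys raise with the offending names.  An empty file yields the default
    config.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    top_known = set(_SECTIONS) | {"master_seed", "output_dir"}
    unknown = set(raw) - top_known
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build_section(cls, raw[name], name)
    if "master_seed" in raw:
        kwargs["master_seed"] = int(raw["master_seed"])
    if "output_dir" in raw:
        kwargs["output_dir"] = str(raw["output_dir"])
    return RunConfig(**kwargs)


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_as_plain(x) for x in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def dump_config(config: RunConfig, path: str | Path | None = None) -> str:
    """Serialize a config to YAML; optionally write it to ``path``."""
    text = yaml.safe_dump(_as_plain(config), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_hash(config: RunConfig) -> str:
    """Short stable hash identifying a config."""
    canon = json.dumps(_as_plain(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


# --------------------------------------------------------------------------
# artifact IO


def _write_csv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    lines = "".join(f"# {k}={v}\n" for k, v in meta.items())
    with open(path, "w") as fh:
        fh.write(lines)
        df.to_csv(fh, index=False)


def _read_meta(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line[1:].strip().split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def save_network(network: ArborNetwork, path: str | Path, seed_info: dict | None = None) -> None:
    """Write a network snapshot as CSV plus a JSON sidecar with the config."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "id": np.arange(network.n_arbors),
            "x_mm": network.centers[:, 0],
            "y_mm": network.centers[:, 1],
            "z_mm": network.centers[:, 2],
            "radius_mm": network.radii,
            "alive": network.alive.astype(int),
        }
    )
    df.to_csv(path, index=False)
    sidecar = {
        "config": _as_plain(network.config),
        "overlap_threshold": network.overlap_threshold,
    }
    if seed_info:
        sidecar.update(seed_info)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_network(path: str | Path) -> ArborNetwork:
    """Reload a network snapshot (lossless for all numeric fields)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    config = NetworkConfig()
    overlap = 0.5
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        cfg = dict(sidecar.get("config", {}))
        if "ellipsoid" in cfg:
            cfg["ellipsoid"] = EllipsoidStriatum(tuple(cfg["ellipsoid"]["semi_axes"]))
        config = NetworkConfig(**cfg)
        overlap = sidecar.get("overlap_threshold", 0.5)
    order = np.argsort(df["id"].to_numpy())
    df = df.iloc[order]
    return ArborNetwork(
        config,
        df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        df["radius_mm"].to_numpy(),
        df["alive"].to_numpy().astype(bool),
        overlap_threshold=overlap,
    )


def save_trajectory(traj: DenervationTrajectory, path: str | Path, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "event_index": np.arange(len(traj.times)),
            "time": traj.times,
            "arbor_id": traj.ids,
            "cause": np.where(traj.causes == 0, "death", "infection"),
        }
    )
    info = {"model": traj.params.model, "seed": traj.params.seed}
    if meta:
        info.update(meta)
    _write_csv(df, Path(path), info)


def load_trajectory(path: str | Path, network: ArborNetwork, params: DenervationParams | None = None):
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    meta = _read_meta(Path(path))
    params = params or DenervationParams(
        model=meta.get("model", "rd"), seed=int(meta.get("seed", 0))
    )
    causes = (df["cause"].to_numpy() == "infection").astype(np.int8)
    return DenervationTrajectory(
        network,
        df["time"].to_numpy(),
        df["arbor_id"].to_numpy().astype(np.int64),
        causes,
        params,
    )


def save_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write any tabular artifact (trace, lookup, map, sweep) as CSV with a
    metadata header."""
    _write_csv(df, Path(path), meta or {})


def load_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV artifact; returns (dataframe, header metadata)."""
    return pd.read_csv(path, comment="#", float_precision="round_trip"), _read_meta(Path(path))
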