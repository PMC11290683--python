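"""Structured run configuration.

One YAML file with sections ``mesh``, ``connectome``, ``neurons``, ``state``,
``run`` and ``analysis``; every key addresses a field of the corresponding
parameter dataclass (``MapParams``/``SynapseParams`` keys under ``neurons``,
``ConnectivityConfig`` under ``connectome``, ``RunConfig`` under ``run``).
Unknown keys raise, so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
from pathlib import Path

import yaml

from .connectome import ConnectivityConfig
from .engine import RunConfig
from .neurons import MapParams, SynapseParams


@dataclasses.dataclass
class MeshConfig:
    level: int = 3
    target_max_geodesic_mm: float = 226.1
    medial_wall_fraction: float = 870.0 / 10242.0
    n_parcels: int = 180
    parcel_seed: int = 0
    gradient_axis: tuple = (0.0, 1.0, 0.0)
    hierarchy_table: str | None = None   # optional TSV path overriding the surrogate


@dataclasses.dataclass
class AnalysisConfig:
    v_up: float = -65.0
    v_down: float = -68.0
    snr: float = 5.0
    coherence_threshold: float = 0.3
    distance_scaling: str = "none"
    apen_m: int = 2
    apen_r_factor: float = 0.2
    apen_resample_hz: float = 100.0
    regularity_mixed_band: tuple = (4.0, 12.0)


@dataclasses.dataclass
class FullConfig:
    mesh: MeshConfig
    connectome: ConnectivityConfig
    map_params: MapParams
    syn_params: SynapseParams
    run: RunConfig
    analysis: AnalysisConfig

    def manifest_hash(self) -> str:
        blob = json.dumps(to_dict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_SECTIONS = {
    "mesh": ("mesh", MeshConfig),
    "connectome": ("connectome", ConnectivityConfig),
    "neurons": None,  # split between MapParams and SynapseParams
    "run": ("run", RunConfig),
    "analysis": ("analysis", AnalysisConfig),
}


def default_config() -> FullConfig:
    return FullConfig(
        mesh=MeshConfig(),
        connectome=ConnectivityConfig(),
        map_params=MapParams(),
        syn_params=SynapseParams(),
        run=RunConfig(),
        analysis=AnalysisConfig(),
    )


def _apply(obj, updates: dict, section: str):
    fields = {f.name for f in dataclasses.fields(obj)}
    unknown = set(updates) - fields
    if unknown:
        raise KeyError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    return dataclasses.replace(obj, **updates)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> FullConfig:
    """Load a YAML configuration, falling back to defaults for everything
    unspecified.  The ``state`` section ('wake'/'sleep') sets ``run.state``."""
    cfg = default_config()
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        for k, v in overrides.items():
            data.setdefault(k, {}).update(v)
    if "mesh" in data:
        cfg.mesh = _apply(cfg.mesh, data["mesh"], "mesh")
    if "connectome" in data:
        cc = dict(data["connectome"])
        for tup_key in ("intracolumn_adjacency",):
            if tup_key in cc:
                cc[tup_key] = tuple(tuple(x) for x in cc[tup_key])
        cfg.connectome = _apply(cfg.connectome, cc, "connectome")
    if "neurons" in data:
        nd = dict(data["neurons"])
        map_fields = {f.name for f in dataclasses.fields(MapParams)}
        syn_fields = {f.name for f in dataclasses.fields(SynapseParams)}
        mp = {k: v for k, v in nd.items() if k in map_fields}
        sp = {k: v for k, v in nd.items() if k in syn_fields}
        unknown = set(nd) - map_fields - syn_fields
        if unknown:
            raise KeyError(f"unknown key(s) in [neurons]: {sorted(unknown)}")
        cfg.map_params = dataclasses.replace(cfg.map_params, **mp)
        cfg.syn_params = dataclasses.replace(cfg.syn_params, **sp)
    if "state" in data:
        state = data["state"]
        if isinstance(state, dict):
            state = state.get("state", "sleep")
        cfg.run = dataclasses.replace(cfg.run, state=state)
    if "run" in data:
        cfg.run = _apply(cfg.run, data["run"], "run")
    if "analysis" in data:
        cfg.analysis = _apply(cfg.analysis, data["analysis"], "analysis")
    return cfg


def to_dict(cfg: FullConfig) -> dict:
    def enc(o):
        d = dataclasses.asdict(o)
        d = {k: (v.tolist() if hasattr(v, "tolist") else v) for k, v in d.items()}
        # normalize tuples to lists so the YAML round-trip is exact
        return json.loads(json.dumps(d))

    return {
        "mesh": enc(cfg.mesh),
        "connectome": enc(cfg.connectome),
        "neurons": {**enc(cfg.map_params), **enc(cfg.syn_params)},
        "run": enc(cfg.run),
        "analysis": enc(cfg.analysis),
    }


def save_config(cfg: FullConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(to_dict(cfg), sort_keys=False))
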