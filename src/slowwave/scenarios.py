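"""Scenario presets: the connectivity-manipulation experiment grid.

A preset fully determines a run given a mesh level and seed: build the
hemisphere and its synthetic connectome, apply one manipulation
(density / radius / delay / strength), simulate, and run the slow-
oscillation (and optionally regularity / coherence) analysis, emitting one
summary row.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import so as so_mod
from . import coherence as coh_mod
from .connectome import (
    Connectome,
    apply_delay_scaling,
    apply_density,
    apply_radius,
    apply_strength_scaling,
    apply_uniform_delay,
)
from .engine import RunConfig, SimulationRun, firing_rates, record_lfp, run
from .fixtures import mini_hemisphere
from .mesh import HemisphereMesh
from .neurons import MapParams, SynapseParams

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ScenarioPreset:
    name: str                       # wake_baseline, sleep_baseline, density_P, ...
    state: str = "sleep"
    P: float | None = None          # density retention probability
    R_mm: float | None = None       # maximum connection radius
    delay_ms: float | None = None   # uniform delay
    max_delay_ms: float | None = None  # rescaled maximum delay
    factor: float | None = None     # strength scaling factor
    R_th_mm: float | None = None    # strength-scaling radius threshold
    mesh_level: int = 3
    n_parcels: int = 60
    duration_s: float = 60.0
    seed: int = 0
    burn_in_s: float = 0.0


def preset(name: str, **kw) -> ScenarioPreset:
    base = {
        "wake_baseline": dict(state="wake", duration_s=12.0, burn_in_s=2.0),
        "sleep_baseline": dict(state="sleep"),
        "density_P": dict(state="sleep"),
        "radius_R": dict(state="sleep"),
        "delay_uniform": dict(state="sleep"),
        "delay_scaled": dict(state="sleep"),
        "strength_global": dict(state="sleep"),
        "strength_longrange": dict(state="sleep"),
    }
    if name not in base:
        raise ValueError(f"unknown preset {name!r}")
    d = dict(base[name])
    d.update(kw)
    return ScenarioPreset(name=name, **d)


def apply_manipulation(conn: Connectome, p: ScenarioPreset, seed: int) -> Connectome:
    if p.name == "density_P":
        return apply_density(conn, p.P, seed=seed)
    if p.name == "radius_R":
        return apply_radius(conn, p.R_mm)
    if p.name == "delay_uniform":
        return apply_uniform_delay(conn, p.delay_ms)
    if p.name == "delay_scaled":
        return apply_delay_scaling(conn, p.max_delay_ms)
    if p.name == "strength_global":
        return apply_strength_scaling(conn, p.factor, None)
    if p.name == "strength_longrange":
        return apply_strength_scaling(conn, p.factor, p.R_th_mm)
    return conn


def analyze_sleep_run(
    r: SimulationRun,
    mesh: HemisphereMesh,
    skip_s: float = 0.0,
) -> dict:
    """Standard slow-oscillation summary of one sleep run."""
    skip = int(skip_s / (r.dt_ms / 1000.0))
    lfp = record_lfp(r, mesh)[skip:]
    catalog = so_mod.detect_global_up_states(lfp, dt_s=r.dt_ms / 1000.0)
    vcols = r.v_l2[skip // r.record_stride:]
    catalog = so_mod.onsets_offsets(catalog, vcols, r.mean_v_l2[skip:], r.record_stride)
    catalog = so_mod.summarize(catalog, mesh, r.active_columns)
    return dict(
        n_events=catalog.n_events,
        frequency_hz=catalog.frequency_hz,
        amplitude=catalog.mean_amplitude,
        participation_pct=catalog.mean_participation,
        onset_std_ms=catalog.onset_std_ms,
        offset_std_ms=catalog.offset_std_ms,
        speed_mm_s=catalog.mean_speed_mm_s,
    )


def run_scenario(
    p: ScenarioPreset,
    out_dir: str | Path | None = None,
    network: tuple[HemisphereMesh, Connectome] | None = None,
    baseline: dict | None = None,
    map_params: MapParams | None = None,
    syn_params: SynapseParams | None = None,
    run_cfg: RunConfig | None = None,
    with_regularity: bool = False,
    with_coherence: bool = False,
) -> dict:
    """Execute one scenario end to end and return its summary row.

    ``network`` reuses a prebuilt (mesh, connectome); ``baseline`` supplies
    the stored baseline summary for ratio metrics (computed and cached in
    ``out_dir`` automatically when absent).
    """
    if network is None:
        mesh, base_conn = mini_hemisphere(level=p.mesh_level, n_parcels=p.n_parcels,
                                          seed=p.seed)
    else:
        mesh, base_conn = network
    conn = apply_manipulation(base_conn, p, seed=p.seed + 1)

    cfg = run_cfg or RunConfig()
    cfg = dataclasses.replace(
        cfg,
        duration_s=p.duration_s + p.burn_in_s,
        seed=p.seed,
        state=p.state,
        thalamus_on=False,
        record_parcels=with_regularity or with_coherence,
        record_all_py_hist=(p.state == "wake"),
        hist_skip_s=p.burn_in_s,
    )
    r = run(conn, mesh, cfg, map_params=map_params, syn_params=syn_params)

    row: dict = dict(name=p.name, state=p.state, seed=p.seed,
                     duration_s=p.duration_s)
    for field in ("P", "R_mm", "delay_ms", "max_delay_ms", "factor", "R_th_mm"):
        v = getattr(p, field)
        if v is not None:
            row[field] = v

    if p.state == "sleep":
        row.update(analyze_sleep_run(r, mesh, skip_s=p.burn_in_s))
        if baseline is None and p.name != "sleep_baseline" and out_dir is not None:
            baseline = _cached_baseline(p, out_dir, network=(mesh, base_conn),
                                        map_params=map_params, syn_params=syn_params,
                                        run_cfg=run_cfg)
        if baseline and baseline.get("amplitude"):
            row["amplitude_ratio"] = row["amplitude"] / baseline["amplitude"]
    else:
        skip = int(p.burn_in_s / (cfg.dt_ms / 1000.0))
        sp = r.spikes[(r.spikes[:, 0] < conn.n_py) & (r.spikes[:, 1] >= skip)]
        row["mean_rate_hz"] = len(sp) / conn.n_py / p.duration_s
        if r.py_hist is not None:
            sub = r.py_hist[:80]  # sub-threshold bins, below -40 mV
            row["hist_mode_mv"] = float(np.argmax(sub) - 120)

    row["intact_score"] = so_mod.intact_score(conn, base_conn)

    if with_regularity and r.parcel_v is not None:
        reg = so_mod.regularity(r.parcel_v.T, fs_hz=1000.0 / cfg.dt_ms)
        row["regularity_mean"] = reg.mean
        row["regularity_var"] = reg.variance
        row["regime"] = reg.regime

    if with_coherence and r.parcel_v is not None:
        sig = coh_mod.parcel_signals(r.parcel_v, 1000.0 / cfg.dt_ms, mesh,
                                     snr=5.0, seed=p.seed + 100)
        bands = coh_mod.default_bands(0.5, 4.0, 0.5)
        land = coh_mod.coherence_matrices(sig, bands)
        land = coh_mod.fit_exponential(land)
        pct, ncomm = coh_mod.functional_connectivity(land)
        row["lambda_mm_05"] = land.lambda_05
        row["alpha_so"] = land.mean_alpha_so
        row["percent_connected"] = pct
        row["n_communities"] = ncomm

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / f"summary_{p.name}.json").write_text(json.dumps(row, indent=2, default=float))
    return row


def _cached_baseline(p: ScenarioPreset, out_dir, network, map_params, syn_params, run_cfg):
    cache = Path(out_dir) / f"baseline_sleep_ico{p.mesh_level}_seed{p.seed}.json"
    if cache.exists():
        return json.loads(cache.read_text())
    logger.info("baseline summary missing; computing it")
    bp = dataclasses.replace(p, name="sleep_baseline")
    row = run_scenario(bp, out_dir=None, network=network, map_params=map_params,
                       syn_params=syn_params, run_cfg=run_cfg)
    cache.parent.mkdir(parents=True, exist_ok=True)
    cache.write_text(json.dumps(row, indent=2, default=float))
    return row
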