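"""Deterministic fixture generators for tests and demonstrations.

Every generator is a pure function of its seed: the same seed yields
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import (
    AMPA,
    Connectome,
    ConnectivityConfig,
    WITHIN_COLUMN,
    build_connectome,
)
from .mesh import HemisphereMesh, assign_hierarchy, assign_parcels, build_icosphere


def two_cell_network(delay_ms: float = 5.0, weight_factor: float = 1.0,
                     dt_ms: float = 0.5) -> Connectome:
    """Two PY cells in one column with a single AMPA synapse 0 -> 1.

    The canonical fixture for delay-delivery tests: a spike in cell 0 must
    first change cell 1's conductance exactly ``delay_ms`` later.
    """
    steps = max(1, int(np.ceil(delay_ms / dt_ms - 1e-9)))
    conn = Connectome(
        n_columns=1,
        n_thalamic=0,
        pre=np.array([0], dtype=np.int32),
        post=np.array([1], dtype=np.int32),
        receptor=np.array([AMPA], dtype=np.int8),
        weight_factor=np.array([weight_factor], dtype=np.float32),
        cls=np.array([WITHIN_COLUMN], dtype=np.int8),
        length_mm=np.array([0.0], dtype=np.float32),
        fiber_mm=np.array([0.0], dtype=np.float32),
        delay_steps=np.array([steps], dtype=np.int16),
        manifest={"fixture": "two_cell", "delay_ms": delay_ms},
    )
    conn.recompute_normalization()
    return conn


def two_cell_mesh() -> HemisphereMesh:
    """Degenerate one-column mesh to accompany :func:`two_cell_network`."""
    verts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    faces = np.array([[0, 1, 2]])
    m = HemisphereMesh(vertices=verts[:1], faces=np.zeros((0, 3), dtype=int), is_flat=True)
    m.parcel_label[:] = 0
    m.hierarchy_index = np.array([0.0])
    return m


def patch_mesh(nx: int = 20, ny: int = 20, spacing_mm: float = 2.2) -> HemisphereMesh:
    """Planar nx x ny column grid (triangulated), ico5-like spacing."""
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    verts = np.column_stack([
        xs.ravel() * spacing_mm, ys.ravel() * spacing_mm, np.zeros(nx * ny)
    ])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    mesh = HemisphereMesh(vertices=verts, faces=np.array(faces), is_flat=True)
    mesh.parcel_label[:] = 0
    mesh.hierarchy_index = np.array([0.5])
    return mesh


def patch_network(nx: int = 20, ny: int = 20, spacing_mm: float = 2.2,
                  seed: int = 0) -> tuple[HemisphereMesh, Connectome]:
    """Locally connected planar patch: full canonical columns plus the
    distance kernel restricted to the patch extent."""
    mesh = patch_mesh(nx, ny, spacing_mm)
    mesh = assign_parcels(mesh, max(1, (nx * ny) // 100), seed=seed)
    mesh = assign_hierarchy(mesh, gradient_axis=(1.0, 0.0, 0.0))
    cfg = ConnectivityConfig(thalamus_level=None, reference_columns=None)
    conn = build_connectome(mesh, cfg, seed=seed, thalamus=False)
    return mesh, conn


def mini_hemisphere(level: int = 3, n_parcels: int = 60, seed: int = 0,
                    thalamus: bool = False,
                    config: ConnectivityConfig | None = None):
    """Full-size-geometry hemisphere at reduced resolution with a synthetic
    connectome; the standard scaled-down study network."""
    mesh = build_icosphere(level)
    mesh = assign_parcels(mesh, n_parcels, seed=seed)
    mesh = assign_hierarchy(mesh)
    cfg = config or ConnectivityConfig(thalamus_level=min(level, 3) if thalamus else None)
    conn = build_connectome(mesh, cfg, seed=seed, thalamus=thalamus)
    return mesh, conn


def synthetic_coherence_field(
    lambda_mm: float = 25.0,
    alpha: float = 0.8,
    n_channels: int = 40,
    fs_hz: float = 200.0,
    duration_s: float = 120.0,
    extent_mm: float = 120.0,
    seed: int = 0,
):
    """Signals with a planted exponential coherence-vs-distance profile.

    Channels at random planar positions; the target magnitude-squared
    coherence between channels at distance d is ``alpha * exp(-d /
    lambda_mm)``, planted by static mixing of white noise with correlation
    sqrt of the target (frequency-flat, so every band sees the same
    landscape).  Returns (signals [channels x samples], distances, fs).
    """
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, extent_mm, size=(n_channels, 2))
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    # sqrt(alpha) * exp(-d / 2L) correlation => MSC = alpha * exp(-d / L).
    # The exponential kernel is positive definite in the plane, and mixing in
    # (1 - sqrt(alpha)) of independent variance keeps the matrix a valid
    # correlation matrix without projection.
    a = np.sqrt(alpha)
    c = a * np.exp(-d / (2 * lambda_mm)) + (1.0 - a) * np.eye(n_channels)
    chol = np.linalg.cholesky(c + 1e-10 * np.eye(n_channels))
    n = int(duration_s * fs_hz)
    white = rng.standard_normal((n_channels, n))
    signals = chol @ white
    return signals, d, fs_hz


def write_fixture(kind: str, outdir: str | Path, seed: int = 0) -> Path:
    """Write a named fixture to ``outdir`` as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "two_cell":
        from .connectome import save_connectome

        conn = two_cell_network()
        save_connectome(conn, outdir)
    elif kind == "patch_20x20":
        from .connectome import save_connectome
        from .mesh import save_mesh

        mesh, conn = patch_network(seed=seed)
        save_mesh(mesh, outdir / "patch.off")
        save_connectome(conn, outdir)
    elif kind == "mini_hemisphere_ico3":
        from .connectome import save_connectome
        from .mesh import save_mesh

        mesh, conn = mini_hemisphere(seed=seed)
        save_mesh(mesh, outdir / "hemisphere.off")
        save_connectome(conn, outdir)
    elif kind == "synthetic_coherence_field":
        signals, d, fs = synthetic_coherence_field(seed=seed)
        pd.DataFrame(signals.T).to_csv(outdir / "signals.tsv", sep="\t", index=False,
                                       float_format="%.6f")
        pd.DataFrame(d).to_csv(outdir / "distances.tsv", sep="\t", index=False,
                               float_format="%.4f")
        (outdir / "meta.txt").write_text(f"fs_hz\t{fs}\nseed\t{seed}\n")
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return outdir
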